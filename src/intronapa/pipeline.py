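"""End-to-end pipeline orchestration over declared files.

``run_pipeline`` executes the stages in dependency order — simulate,
classify, truncation ratios, cohort differential calls, conservation,
cross-cancer frequency, relative positions, peptides, domain summaries,
survival — writing each stage's outputs under one directory and returning
a manifest of files with checksums.  A rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import differential as diff
from . import domainomics as dom
from . import lengthscape as ls
from . import quantify as qt
from . import survival as surv
from . import synthetic as syn
from .cterminome import build_srm_database

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the whole workflow, JSON-round-trippable.

    Defaults are the workflow's published operating points: pairwise
    chi-square p < 0.05 with |dTR| > 0.1, cohort t-test p < 0.01, 80%
    conservation, variance floors 1 (expression) / 0.01 (TR), +/-10%
    protein-length band.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    pairwise_alpha: float = 0.05
    pairwise_min_delta: float = 0.1
    cohort_alpha: float = 0.01
    conservation_threshold: float = 0.8
    conservation_center: str = "mean"
    variance_threshold_expr: float = 1.0
    variance_threshold_tr: float = 0.01
    length_band: float = 0.10
    min_gene_tpm: float = 1.0
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)

    def validate(self) -> None:
        for name in ("pairwise_alpha", "cohort_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 < self.conservation_threshold <= 1:
            raise ValueError("conservation_threshold must be in (0,1]")
        if self.length_band < 0:
            raise ValueError("length_band must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        syn_raw = raw.pop("synthetic", {})
        if "position_modes" in syn_raw:
            syn_raw["position_modes"] = tuple(syn_raw["position_modes"])
        return cls(synthetic=syn.SyntheticConfig(**syn_raw), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; return the output manifest."""
    config.validate()
    config.synthetic.seed = config.seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    # simulate
    annotation = syn.generate_annotation(config.synthetic)
    expression = syn.generate_expression(config.synthetic, annotation)
    syn.write_gtf(annotation.genes, out / "annotation.gtf")
    syn.write_fasta(annotation.genome, out / "genome.fa")
    expression.expression.to_csv(out / "expression_tpm.tsv", sep="\t",
                                 index_label="transcript_id")
    syn.write_truth_tables(annotation, expression, out)

    # classify (re-read from the emitted GTF: each stage talks through files)
    genes = ann.read_gtf(out / "annotation.gtf")
    genes = ann.classify_all(genes)
    ann.write_label_table(genes, out / "labels.tsv")
    universe = ann.count_apa_universe(genes)

    # truncation ratios
    expr = qt.read_expression(out / "expression_tpm.tsv")
    trm = qt.truncation_ratio(expr, genes, min_tpm=config.min_gene_tpm)
    trm.to_tsv(out / "tr_matrix.tsv", out / "tr_parts.tsv")

    groups = expression.sample_groups
    tumor = [s for s in trm.sample_ids if groups[s] == "tumor"]
    normal = [s for s in trm.sample_ids if groups[s] == "normal"]

    # cohort differential + conservation
    calls = diff.call_cohort(trm.tr[tumor], trm.tr[normal], "synthetic",
                             alpha=config.cohort_alpha)
    calls = diff.annotate_conservation(
        calls, trm.tr[tumor], trm.tr[normal],
        threshold=config.conservation_threshold,
        center=config.conservation_center,
    )
    calls.table.to_csv(out / "cohort_calls.tsv", sep="\t", index_label="gene_id")

    profile = diff.frequency_profile({"synthetic": calls})
    profile.table.to_csv(out / "frequency.tsv", sep="\t", index_label="gene_id")

    # relative positions and protein lengths
    records = ls.relative_positions(genes)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        out / "relative_positions.tsv", sep="\t", index=False
    )
    hist, _members = ls.bin_distribution(records)
    hist.to_frame("count").to_csv(out / "position_bins.tsv", sep="\t",
                                  index_label="bin")
    pairs = [
        ls.ProteinLengthPair(
            r.gene_id, int(r.coding_length_apa // 3),
            int(r.coding_length_full // 3), band=config.length_band,
        )
        for r in records if not r.flagged
    ]
    ls.protein_length_scatter(pairs).to_csv(out / "protein_lengths.tsv",
                                            sep="\t", index=False)

    # peptides
    db = build_srm_database(genes, annotation.genome)
    db.to_fasta(out / "peptides.fa")
    db.to_tsv(out / "peptides.tsv")

    # domain loss on the synthetic proteome: domains placed uniformly over
    # each full-length protein, lost where they overlap the truncated span
    rng = np.random.default_rng([config.seed, 7])
    loss_records = []
    for r in records:
        if r.flagged:
            continue
        full_aa = int(r.coding_length_full // 3)
        trunc_aa = min(int(r.coding_length_apa // 3), full_aa)
        hits = []
        for k in range(int(rng.integers(1, 4))):
            start = int(rng.integers(1, max(2, full_aa - 30)))
            end = min(full_aa, start + int(rng.integers(20, 60)))
            hits.append(dom.DomainHit(r.gene_id, f"DOM{k}", start, end))
        span = (trunc_aa + 1, full_aa) if trunc_aa < full_aa else None
        lost = dom.lost_domains(hits, span)
        if lost:
            side = annotation.truth.at[r.gene_id, "side"]
            loss_records.append(dom.DomainLossRecord(
                r.gene_id, "synthetic",
                "tumor" if side == syn.TUMOR_ENRICHED else "normal",
                frozenset(lost), span,
            ))
    summary = dom.domain_swap_summary(loss_records)
    summary.tumor_heatmap.to_csv(out / "domain_heatmap_tumor.tsv", sep="\t")
    summary.normal_heatmap.to_csv(out / "domain_heatmap_normal.tsv", sep="\t")

    # survival on TR covariates of effect genes
    effect = [g for g in trm.gene_ids
              if annotation.truth.at[g, "side"] != syn.NULL]
    beta = pd.Series(0.0, index=trm.gene_ids)
    beta[effect[: max(1, len(effect) // 10)]] = np.log(2.0)
    covariates = trm.tr.fillna(0.0)
    clinical = syn.generate_survival(config.synthetic, covariates, beta)
    model = surv.prognostic_pipeline(
        covariates.loc[surv.variance_filter(covariates,
                                            config.variance_threshold_tr)],
        clinical, seed=config.seed,
    )
    with open(out / "survival_summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        if model is None:
            fh.write("logrank_p\tNA\n")
        else:
            fh.write(f"logrank_p\t{model.logrank_p:.6g}\n")
            fh.write(f"n_selected\t{len(model.beta[model.beta != 0])}\n")

    with open(out / "universe.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in universe.items():
            fh.write(f"{k}\t{v}\n")

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
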