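"""Synthetic annotation, expression, sequence and clinical-data generator.

The generator emits data with the statistical structure the analysis
assumes, together with complete truth tables, so that every downstream
stage can be validated against planted ground truth:

* gene models in which intronic-APA isoforms satisfy the two-condition
  classification rule by construction, with the APA isoform's 3'-most exon
  placed to realize a planted relative truncation position;
* genome sequences with a clean open reading frame along each annotated
  CDS (no internal stop in frame) so the peptide route round-trips;
* transcript TPM matrices where each gene's per-sample truncation ratio is
  drawn from a Beta distribution with side-specific means (tumor-enriched
  and normal-enriched effect genes) and the gene total from a log-normal;
* survival times from an exponential proportional-hazards model with known
  coefficients and independent uniform censoring.

Everything is a deterministic function of ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation import GeneModel, TranscriptModel, classify_transcripts
from .cterminome import reverse_complement
from .survival import ClinicalTable

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c
           for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]

TUMOR_ENRICHED = "tumor"
NORMAL_ENRICHED = "normal"
# sentinel chosen to survive a pandas round-trip ("null"/"None" would be
# read back as NaN by default)
NULL = "no_effect"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a TCGA-like tumor/normal contrast: ~10% normal
    samples, moderate TR dispersion (Beta concentration 50), a planted TR
    shift of 0.2 for effect genes, and bimodal relative truncation
    positions (normal-enriched events early, tumor-enriched late).
    """

    seed: int = 0
    n_genes: int = 300
    apa_fraction: float = 0.7       # genes given >=1 intronic-APA isoform
    effect_fraction: float = 0.3    # APA genes with a planted TR shift
    coding_length: int = 900        # reference coding length (nt, multiple of 3)
    n_tumor: int = 100
    n_normal: int = 20
    tr_mean_null: float = 0.3
    delta_tr: float = 0.2
    tr_concentration: float = 50.0
    expr_log_mu: float = 3.0
    expr_log_sigma: float = 1.0
    position_modes: tuple[float, float] = (0.25, 0.9)  # (normal side, tumor side)
    position_sd: float = 0.06
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    minus_strand_fraction: float = 0.5


@dataclass
class SyntheticAnnotation:
    genes: list[GeneModel]
    genome: dict[str, str]
    truth: pd.DataFrame  # index gene_id; columns apa_transcript, side,
    #                      planted_position, coding_length_full, coding_length_apa


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_CODONS, size=n_codons))


def _clip_position(r: float) -> float:
    return float(min(max(r, 0.05), 0.97))


def _build_gene(
    rng: np.random.Generator,
    gene_idx: int,
    has_apa: bool,
    side: str,
    position: Optional[float],
    cfg: SyntheticConfig,
) -> tuple[GeneModel, str, dict]:
    """Construct one gene (in + orientation, then optionally mirrored).

    Reference: three coding exons with total coding length
    ``cfg.coding_length``; the APA isoform shares exon 1 and replaces exon 2
    by a composite last exon extending into intron 2 (exonized intron), so
    its 3'-most exon's 5' boundary projects to exactly
    ``round(position * L) / L`` of the reference coding length.
    """
    gid = f"G{gene_idx:04d}"
    chrom = f"chr_{gid}"
    L = cfg.coding_length
    if has_apa:
        m = int(round(_clip_position(position) * L))
        m = min(max(m, 30), L - 60)
    else:
        m = L // 3
    c1 = m
    rest = L - c1
    c2 = max(30, rest // 2)
    c3 = rest - c2
    intron1 = int(rng.integers(120, 300))
    intron2 = int(rng.integers(300, 600))
    utr3 = int(rng.integers(50, 150))
    left_pad = 10

    a1 = left_pad + 1
    b1 = a1 + c1 - 1
    a2 = b1 + intron1 + 1
    b2 = a2 + c2 - 1
    a3 = b2 + intron2 + 1
    b3 = a3 + c3 - 1
    chrom_len = b3 + utr3 + 20

    orf = _random_orf(rng, L // 3)
    seq = list("".join(rng.choice(list("ACGT"), size=chrom_len)))
    # lay the reference ORF across its three coding exons
    pieces = [(a1, b1), (a2, b2), (a3, b3)]
    pos = 0
    for s, e in pieces:
        seg = orf[pos:pos + (e - s + 1)]
        seq[s - 1:e] = list(seg)
        pos += e - s + 1

    transcripts = []
    ref = TranscriptModel(
        transcript_id=f"{gid}.ref", gene_id=gid, chrom=chrom, strand="+",
        exons=[(a1, b1), (a2, b2), (a3, b3 + utr3)],
        cds=[(a1, b1), (a2, b2), (a3, b3)],
        biotype="protein_coding",
    )
    transcripts.append(ref)

    info = {
        "apa_transcript": "", "side": side,
        "planted_position": np.nan,
        "coding_length_full": L, "coding_length_apa": np.nan,
    }

    if has_apa:
        # exonized-intron extension: continue the ORF frame past exon 2 with
        # non-stop codons, terminate with an explicit stop, then UTR
        ext_cds = 3 * int(rng.integers(10, 40))
        rem = (c1 + c2) % 3         # nt of the boundary-spanning codon inside exon 2
        lead = (3 - rem) % 3        # nt needed after b2 to complete that codon
        parts = []
        if lead:
            prefix = orf[c1 + c2 - rem:c1 + c2]
            spanning = rng.choice([c for c in _CODONS if c.startswith(prefix)])
            parts.append(spanning[rem:])
        parts.append(_random_orf(rng, ext_cds // 3))
        ext_seq = "".join(parts)
        ext_total = lead + ext_cds
        ext_start = b2 + 1
        seq[ext_start - 1:ext_start - 1 + ext_total] = list(ext_seq)
        stop_at = ext_start + ext_total
        seq[stop_at - 1:stop_at + 2] = list("TAA")
        apa_utr = int(rng.integers(20, min(60, a3 - stop_at - 3)))
        apa_end = stop_at + 2 + apa_utr
        apa = TranscriptModel(
            transcript_id=f"{gid}.apa", gene_id=gid, chrom=chrom, strand="+",
            exons=[(a1, b1), (a2, apa_end)],
            cds=[(a1, b1), (a2, stop_at + 2)],  # stop included in CDS
            biotype="protein_coding",
        )
        transcripts.append(apa)
        info.update(
            apa_transcript=f"{gid}.apa",
            planted_position=c1 / L,
            coding_length_apa=float(c1 + c2 + ext_total + 3),
        )

    if rng.random() < 0.4:
        # a UTR-length variant that stays FULL_LENGTH (coding end is maximal)
        variant = TranscriptModel(
            transcript_id=f"{gid}.utr", gene_id=gid, chrom=chrom, strand="+",
            exons=[(a1, b1), (a2, b2), (a3, b3 + max(5, utr3 // 2))],
            cds=[(a1, b1), (a2, b2), (a3, b3)],
            biotype="protein_coding",
        )
        transcripts.append(variant)

    genome_seq = "".join(seq)
    if rng.random() < cfg.minus_strand_fraction:
        genome_seq = reverse_complement(genome_seq)
        n = chrom_len
        for t in transcripts:
            t.strand = "-"
            t.exons = sorted((n - e + 1, n - s + 1) for s, e in t.exons)
            t.cds = sorted((n - e + 1, n - s + 1) for s, e in t.cds)

    gene = GeneModel(gene_id=gid, gene_name=f"SYN{gene_idx:04d}",
                     transcripts=transcripts)
    for t in transcripts:
        t.validate()
    return gene, genome_seq, info


def generate_annotation(cfg: SyntheticConfig) -> SyntheticAnnotation:
    """Generate gene models, genome sequences and the gene-level truth table."""
    rng = np.random.default_rng([cfg.seed, 1])
    n_apa = int(round(cfg.apa_fraction * cfg.n_genes))
    n_effect = int(round(cfg.effect_fraction * n_apa))
    sides = ([TUMOR_ENRICHED] * (n_effect // 2 + n_effect % 2)
             + [NORMAL_ENRICHED] * (n_effect // 2)
             + [NULL] * (n_apa - n_effect))
    rng.shuffle(sides)

    genes, genome, rows = [], {}, {}
    for i in range(cfg.n_genes):
        has_apa = i < n_apa
        side = sides[i] if has_apa else NULL
        if has_apa:
            mode = (cfg.position_modes[1] if side == TUMOR_ENRICHED
                    else cfg.position_modes[0] if side == NORMAL_ENRICHED
                    else cfg.position_modes[int(rng.random() < 0.5)])
            position = _clip_position(rng.normal(mode, cfg.position_sd))
        else:
            position = None
        gene, seq, info = _build_gene(rng, i, has_apa, side, position, cfg)
        classify_transcripts(gene)
        genes.append(gene)
        genome[gene.chrom] = seq
        rows[gene.gene_id] = info

    truth = pd.DataFrame.from_dict(rows, orient="index")
    truth.index.name = "gene_id"
    return SyntheticAnnotation(genes=genes, genome=genome, truth=truth)


def write_gtf(genes, path) -> None:
    """Write gene models as GENCODE-dialect GTF (deterministic ordering)."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                attrs = (f'gene_id "{g.gene_id}"; transcript_id '
                         f'"{t.transcript_id}"; gene_name "{g.gene_name}"; '
                         f'transcript_type "{t.biotype or "protein_coding"}";')
                for s, e in t.exons:
                    fh.write(f"{t.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t"
                             f"{t.strand}\t.\t{attrs}\n")
                for s, e in t.cds:
                    fh.write(f"{t.chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t"
                             f"{t.strand}\t0\t{attrs}\n")


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass
class SyntheticExpression:
    expression: pd.DataFrame      # transcripts x samples (TPM)
    tr_truth: pd.DataFrame        # genes x samples true TR
    sample_groups: pd.Series      # sample_id -> tumor|normal
    gene_means: pd.DataFrame      # planted Beta means per side


def _beta_draw(rng, mean: float, conc: float, size) -> np.ndarray:
    a = mean * conc
    b = (1.0 - mean) * conc
    return rng.beta(a, b, size=size)


def generate_expression(
    cfg: SyntheticConfig, annotation: SyntheticAnnotation
) -> SyntheticExpression:
    """Draw transcript TPM with planted per-gene, per-side TR structure."""
    rng = np.random.default_rng([cfg.seed, 2])
    samples = ([f"tumor_{i:03d}" for i in range(cfg.n_tumor)]
               + [f"normal_{i:03d}" for i in range(cfg.n_normal)])
    groups = pd.Series(
        ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal, index=samples
    )
    is_tumor = (groups == "tumor").to_numpy()

    tx_rows: dict[str, np.ndarray] = {}
    tr_rows: dict[str, np.ndarray] = {}
    mean_rows: dict[str, dict] = {}
    n = len(samples)
    for g in annotation.genes:
        side = annotation.truth.at[g.gene_id, "side"]
        apa_ids = [t.transcript_id for t in g.apa_transcripts()]
        fl_ids = [t.transcript_id for t in g.full_length_transcripts()]
        mu_t = mu_n = cfg.tr_mean_null
        if apa_ids and side == TUMOR_ENRICHED:
            mu_t = cfg.tr_mean_null + cfg.delta_tr
        elif apa_ids and side == NORMAL_ENRICHED:
            mu_n = cfg.tr_mean_null + cfg.delta_tr
        total = rng.lognormal(cfg.expr_log_mu, cfg.expr_log_sigma, size=n)
        if apa_ids:
            tr = np.where(
                is_tumor,
                _beta_draw(rng, mu_t, cfg.tr_concentration, n),
                _beta_draw(rng, mu_n, cfg.tr_concentration, n),
            )
        else:
            tr = np.zeros(n)
        tr_rows[g.gene_id] = tr
        mean_rows[g.gene_id] = {"mean_tumor": mu_t if apa_ids else 0.0,
                                "mean_normal": mu_n if apa_ids else 0.0,
                                "side": side if apa_ids else NULL}
        apa_total, fl_total = tr * total, (1.0 - tr) * total
        for tid in apa_ids:
            tx_rows[tid] = apa_total / len(apa_ids)
        for tid in fl_ids:
            tx_rows[tid] = fl_total / len(fl_ids)

    expr = pd.DataFrame(tx_rows, index=samples).T
    expr.index.name = "transcript_id"
    tr_truth = pd.DataFrame(tr_rows, index=samples).T
    tr_truth.index.name = "gene_id"
    return SyntheticExpression(
        expression=expr,
        tr_truth=tr_truth,
        sample_groups=groups,
        gene_means=pd.DataFrame.from_dict(mean_rows, orient="index"),
    )


def generate_survival(
    cfg: SyntheticConfig,
    covariates: pd.DataFrame,  # features x samples
    beta: pd.Series,           # true log-hazard coefficients per feature
    seed_offset: int = 3,
) -> ClinicalTable:
    """Exponential proportional-hazards times with uniform censoring.

    hazard_s = baseline * exp(sum_i beta_i x_is); the uniform censoring
    horizon is solved so the expected censored fraction matches
    ``cfg.censoring_rate`` at the cohort's mean hazard.
    """
    rng = np.random.default_rng([cfg.seed, seed_offset])
    X = covariates.loc[beta.index].to_numpy(dtype=float)
    lin = beta.to_numpy(dtype=float) @ X
    rate = cfg.baseline_hazard * np.exp(lin)
    times = rng.exponential(1.0 / rate)
    if cfg.censoring_rate <= 0:
        event = np.ones_like(times, dtype=int)
        obs = times
    elif cfg.censoring_rate >= 1:
        event = np.zeros_like(times, dtype=int)
        obs = rng.uniform(0, times)
    else:
        lam = float(np.mean(rate))
        # P(censored) = P(T > C) for C ~ U(0,u), T ~ Exp(lam):
        #   E[e^{-lam C}] = (1 - e^{-lam u}) / (lam u), decreasing in u
        def censored_frac(u):
            return (1.0 - np.exp(-lam * u)) / (lam * u)
        u = brentq(lambda v: censored_frac(v) - cfg.censoring_rate,
                   1e-9 / lam, 1e6 / lam)
        cens = rng.uniform(0, u, size=times.shape)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    frame = pd.DataFrame(
        {"time": obs, "event": event}, index=covariates.columns
    )
    frame.index.name = "sample_id"
    return ClinicalTable(frame)


def annotation_with_positions(
    positions: list[float], seed: int = 0, coding_length: int = 1200
) -> SyntheticAnnotation:
    """One APA gene per requested relative truncation position.

    The realized position is ``round(r * L) / L`` (recorded in the truth
    table), exact whenever ``r * L`` is integral.
    """
    cfg = SyntheticConfig(seed=seed, n_genes=len(positions),
                          coding_length=coding_length)
    rng = np.random.default_rng([seed, 4])
    genes, genome, rows = [], {}, {}
    for i, r in enumerate(positions):
        gene, seq, info = _build_gene(rng, i, True, NULL, r, cfg)
        classify_transcripts(gene)
        genes.append(gene)
        genome[gene.chrom] = seq
        rows[gene.gene_id] = info
    truth = pd.DataFrame.from_dict(rows, orient="index")
    truth.index.name = "gene_id"
    return SyntheticAnnotation(genes=genes, genome=genome, truth=truth)


def generate_feature_blocks(
    seed: int,
    n_samples: int = 800,
    n_signal: int = 4,
    n_noise: int = 4,
    effect: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Two covariate blocks (GE and TR) with evenly split prognostic signal.

    Each block carries ``n_signal`` standard-normal covariates with true
    log-hazard coefficient ``effect`` plus ``n_noise`` pure-noise
    covariates; the hazard depends on the sum over both blocks, so neither
    block alone sees the full signal.  The cohort size default matches the
    largest tumor cohorts this kind of model is fit on (~1000 samples).

    Returns (ge_block, tr_block, true_beta); blocks are features x samples.
    """
    rng = np.random.default_rng([seed, 5])
    samples = [f"s{i:04d}" for i in range(n_samples)]

    def _block(prefix: str) -> pd.DataFrame:
        rows = {}
        for i in range(n_signal):
            rows[f"{prefix}:sig{i}"] = rng.normal(size=n_samples)
        for i in range(n_noise):
            rows[f"{prefix}:noise{i}"] = rng.normal(size=n_samples)
        return pd.DataFrame(rows, index=samples).T

    ge, tr = _block("GE"), _block("TR")
    beta = pd.Series(0.0, index=list(ge.index) + list(tr.index))
    for i in range(n_signal):
        beta[f"GE:sig{i}"] = effect
        beta[f"TR:sig{i}"] = effect
    return ge, tr, beta


def write_truth_tables(
    annotation: SyntheticAnnotation,
    expression: SyntheticExpression,
    outdir,
) -> None:
    outdir = Path(outdir)
    annotation.truth.to_csv(outdir / "truth_genes.tsv", sep="\t")
    expression.tr_truth.to_csv(outdir / "truth_tr.tsv", sep="\t")
    expression.gene_means.to_csv(outdir / "truth_means.tsv", sep="\t",
                                 index_label="gene_id")
    expression.sample_groups.to_frame("group").to_csv(
        outdir / "sample_groups.tsv", sep="\t", index_label="sample_id"
    )
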