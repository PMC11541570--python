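"""Domain-loss analysis: which functional domains vanish when a gene's
full-length protein is replaced by its intronic-APA truncation.

Intronic APA preserves the protein N-terminus and alters only the C-terminal
region, so the differential sequence between a full-length protein and its
truncated isoform is everything past their longest common prefix.  Pfam
domains (supplied as PfamScan tabular output or explicit coordinates) whose
residue span overlaps that differential region are reported as lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ProteinIsoform:
    transcript_id: str
    aa_sequence: str

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


@dataclass
class DomainHit:
    """One Pfam hit; residue coordinates 1-based inclusive."""

    protein_id: str
    domain_name: str
    aa_start: int
    aa_end: int
    evalue: Optional[float] = None


@dataclass
class DifferentialRegion:
    """Result of comparing a full-length protein with a truncation.

    ``span`` is the 1-based inclusive residue range of the full-length
    protein absent from the truncated isoform (None when the truncation is
    a strict extension or identical); ``novel_tail`` is the truncated
    isoform's C-terminal sequence beyond the common prefix (the
    exonized-intron-encoded tail, possibly empty).
    """

    span: Optional[tuple[int, int]]
    novel_tail: str


@dataclass
class DomainLossRecord:
    gene_id: str
    cancer_type: str
    side: str  # tumor | normal
    lost_domains: frozenset[str]
    span: Optional[tuple[int, int]] = None


def differential_sequence(
    full: ProteinIsoform | str, truncated: ProteinIsoform | str
) -> DifferentialRegion:
    """Residues of the full-length protein missing from the truncation.

    Defined via the longest common prefix p: span = (p+1 .. len(full)),
    novel_tail = truncated[p:].  Identical sequences give an empty span and
    empty tail.
    """
    f = full.aa_sequence if isinstance(full, ProteinIsoform) else full
    t = truncated.aa_sequence if isinstance(truncated, ProteinIsoform) else truncated
    if not f or not t:
        raise ValueError("empty protein sequence")
    p = 0
    for a, b in zip(f, t):
        if a != b:
            break
        p += 1
    span = (p + 1, len(f)) if p < len(f) else None
    return DifferentialRegion(span=span, novel_tail=t[p:])


def read_pfamscan_table(path) -> tuple[list[DomainHit], list[int]]:
    """Parse PfamScan whitespace-delimited output ('#' lines are comments).

    Columns used: seq id (1), alignment start (2), alignment end (3),
    hmm name (7), e-value (13) when present.  Returns the hits and the
    1-based line numbers that could not be parsed.
    """
    hits: list[DomainHit] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                bad.append(lineno)
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                bad.append(lineno)
                continue
            if start < 1 or end < start:
                bad.append(lineno)
                continue
            evalue = None
            if len(parts) >= 13:
                try:
                    evalue = float(parts[12])
                except ValueError:
                    evalue = None
            hits.append(DomainHit(parts[0], parts[6], start, end, evalue))
    if bad:
        log.warning("read_pfamscan_table: %d malformed line(s) skipped", len(bad))
    return hits, bad


def validate_hits(
    hits: Iterable[DomainHit], protein_lengths: dict[str, int]
) -> list[DomainHit]:
    """Drop hits whose coordinates exceed the protein length (with a warning)."""
    out = []
    for h in hits:
        n = protein_lengths.get(h.protein_id)
        if n is not None and h.aa_end > n:
            log.warning("hit %s on %s exceeds protein length %d; dropped",
                        h.domain_name, h.protein_id, n)
            continue
        out.append(h)
    return out


def lost_domains(
    full_hits: Sequence[DomainHit],
    span: Optional[tuple[int, int]],
    exclusive_exon_span: Optional[tuple[int, int]] = None,
    min_overlap_fraction: float = 0.0,
) -> set[str]:
    """Domains on the full-length protein overlapping the differential span.

    Overlap of >=1 residue counts as loss by default; a fractional threshold
    on the domain length is available.  When ``exclusive_exon_span`` is
    given (residues encoded by exons exclusive to the full-length
    transcript), the overlap must additionally fall within it.
    """
    if span is None:
        return set()
    lo, hi = span
    lost = set()
    for h in full_hits:
        ov_lo, ov_hi = max(h.aa_start, lo), min(h.aa_end, hi)
        if ov_hi < ov_lo:
            continue
        if exclusive_exon_span is not None:
            ov_lo = max(ov_lo, exclusive_exon_span[0])
            ov_hi = min(ov_hi, exclusive_exon_span[1])
            if ov_hi < ov_lo:
                continue
        if min_overlap_fraction > 0:
            frac = (ov_hi - ov_lo + 1) / (h.aa_end - h.aa_start + 1)
            if frac < min_overlap_fraction:
                continue
        lost.add(h.domain_name)
    return lost


def heatmap_value(count: int) -> float:
    """Display scale for event counts: log2(count + 1)."""
    return float(np.log2(count + 1))


@dataclass
class DomainSwapSummary:
    tumor_matrix: pd.DataFrame   # domain x cancer event counts
    normal_matrix: pd.DataFrame
    tumor_heatmap: pd.DataFrame  # log2(count+1)
    normal_heatmap: pd.DataFrame
    tumor_domains: set[str] = field(default_factory=set)
    normal_domains: set[str] = field(default_factory=set)
    shared_domains: set[str] = field(default_factory=set)
    recurrent_domains: dict[str, set[str]] = field(default_factory=dict)


def domain_swap_summary(
    records: Iterable[DomainLossRecord], recurrent_min_cancers: int = 5
) -> DomainSwapSummary:
    """Aggregate loss records into per-side domain x cancer count matrices.

    Also computes the tumor/normal lost-domain sets and their intersection,
    and flags domains recurrently lost (conserved across at least
    ``recurrent_min_cancers`` cancer types) per side.
    """
    counts: dict[str, dict[tuple[str, str], int]] = {"tumor": {}, "normal": {}}
    for rec in records:
        if rec.side not in counts:
            raise ValueError(f"unknown side {rec.side!r}")
        for d in rec.lost_domains:
            key = (d, rec.cancer_type)
            counts[rec.side][key] = counts[rec.side].get(key, 0) + 1

    def _matrix(side: str) -> pd.DataFrame:
        c = counts[side]
        if not c:
            return pd.DataFrame(dtype=int)
        domains = sorted({d for d, _ in c})
        cancers = sorted({k for _, k in c})
        m = pd.DataFrame(0, index=domains, columns=cancers, dtype=int)
        for (d, k), v in c.items():
            m.at[d, k] = v
        return m

    tm, nm = _matrix("tumor"), _matrix("normal")
    t_dom, n_dom = set(tm.index), set(nm.index)
    recurrent = {
        side: set(m.index[(m > 0).sum(axis=1) >= recurrent_min_cancers])
        for side, m in (("tumor", tm), ("normal", nm))
    }
    return DomainSwapSummary(
        tumor_matrix=tm,
        normal_matrix=nm,
        tumor_heatmap=np.log2(tm + 1) if not tm.empty else tm.astype(float),
        normal_heatmap=np.log2(nm + 1) if not nm.empty else nm.astype(float),
        tumor_domains=t_dom,
        normal_domains=n_dom,
        shared_domains=t_dom & n_dom,
        recurrent_domains=recurrent,
    )
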