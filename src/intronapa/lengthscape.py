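"""Relative truncation positions and protein-length relationships.

Where along a gene's coding region does the intronic-APA isoform diverge?
Per gene, the full-length reference is the transcript with the most distal
coding end (ties broken by maximal coding length, then transcript id).  The
5' genomic boundary of an APA transcript's 3'-most exon is projected into
the reference's coding coordinate system (cumulative coding nucleotides
from the start codon, introns skipped); dividing by the reference coding
length gives a relative position in (0, 1].

Positions are binned left-open/right-closed into EARLY (0, 0.4], MID
(0.4, 0.8] and LATE (0.8, 1.0]; protein-length pairs are compared through
the truncated/full length ratio with a configurable ±band (default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .annotation import FULL_LENGTH, GeneModel, TranscriptModel

EARLY, MID, LATE = "EARLY", "MID", "LATE"
BIN_EDGES = (0.4, 0.8)


@dataclass
class RelativePositionRecord:
    gene_id: str
    transcript_id: str
    relative_position: float
    bin: str
    coding_length_apa: int
    coding_length_full: int
    flagged: bool = False


@dataclass
class ProteinLengthPair:
    gene_id: str
    len_truncated_aa: int
    len_full_aa: int
    band: float = 0.10

    @property
    def ratio(self) -> float:
        if self.len_full_aa <= 0 or self.len_truncated_aa <= 0:
            raise ValueError("protein lengths must be positive")
        return self.len_truncated_aa / self.len_full_aa

    @property
    def within_band(self) -> bool:
        return abs(self.ratio - 1.0) <= self.band


def define_full_length_reference(gene: GeneModel) -> str:
    """Pick the reference isoform: most distal coding end, then maximum
    coding length, then lexicographic transcript id."""
    fl = [t for t in gene.coding_transcripts()
          if gene.labels.get(t.transcript_id) == FULL_LENGTH]
    if not fl:
        raise ValueError(f"gene {gene.gene_id} has no FULL_LENGTH transcript; "
                         "run classification first")
    return min(
        fl, key=lambda t: (-t.coding_end_key, -t.coding_length(), t.transcript_id)
    ).transcript_id


def assign_bin(position: float) -> str:
    """Left-open/right-closed bins over (0, 1]: (0,0.4], (0.4,0.8], (0.8,1],
    so a position of exactly 0.4 falls in EARLY and exactly 0.8 in MID."""
    if not 0 < position <= 1:
        raise ValueError(f"relative position {position} outside (0, 1]")
    if position <= BIN_EDGES[0]:
        return EARLY
    if position <= BIN_EDGES[1]:
        return MID
    return LATE


def relative_position(
    gene: GeneModel,
    apa_transcript: TranscriptModel | str,
    reference: TranscriptModel | str | None = None,
    boundary: str = "five_prime",
) -> RelativePositionRecord:
    """Project the APA transcript's 3'-most exon onto reference coding space.

    ``boundary`` selects which edge of that exon is projected: its 5' edge
    (default — where the transcript diverges into exonized intron) or its
    3' edge.  The result is clipped to (0, 1].  A boundary upstream of the
    reference start codon yields a flagged record (excluded from binning).
    """
    if isinstance(apa_transcript, str):
        apa_transcript = gene.get(apa_transcript)
    if reference is None:
        reference = gene.get(define_full_length_reference(gene))
    elif isinstance(reference, str):
        reference = gene.get(reference)

    coding_full = reference.coding_length()
    coding_apa = apa_transcript.coding_length()
    if apa_transcript.transcript_id == reference.transcript_id:
        return RelativePositionRecord(
            gene.gene_id, apa_transcript.transcript_id, 1.0, LATE,
            coding_apa, coding_full,
        )

    exons = sorted(apa_transcript.exons)
    last = exons[-1] if apa_transcript.strand == "+" else exons[0]
    if boundary == "five_prime":
        pos = last[0] if apa_transcript.strand == "+" else last[1]
    elif boundary == "three_prime":
        pos = last[1] if apa_transcript.strand == "+" else last[0]
    else:
        raise ValueError("boundary must be 'five_prime' or 'three_prime'")

    # five_prime counts coding nt strictly before the divergence point;
    # three_prime includes the boundary nucleotide itself
    offset = _coding_offset(reference, pos, inclusive=(boundary == "three_prime"))
    if offset is None or offset == 0:
        return RelativePositionRecord(
            gene.gene_id, apa_transcript.transcript_id, float("nan"), "",
            coding_apa, coding_full, flagged=True,
        )
    rel = min(offset / coding_full, 1.0)
    return RelativePositionRecord(
        gene.gene_id, apa_transcript.transcript_id, rel, assign_bin(rel),
        coding_apa, coding_full,
    )


def _coding_offset(
    reference: TranscriptModel, genomic_pos: int, inclusive: bool = False
) -> Optional[int]:
    """Cumulative coding nt from the reference start codon to ``genomic_pos``.

    Walks coding exons in transcription direction.  Within a coding exon the
    offset counts nucleotides strictly before the position (``inclusive``
    adds the position's own nucleotide); inside an intron the offset is the
    length of all upstream coding exons.  None if the position is 5' of the
    start codon.
    """
    cds = sorted(reference.cds)
    ordered = cds if reference.strand == "+" else cds[::-1]
    sign = 1 if reference.strand == "+" else -1
    key = sign * genomic_pos
    first = ordered[0]
    start_codon_key = sign * (first[0] if reference.strand == "+" else first[1])
    if key < start_codon_key:
        return None
    offset = 0
    for s, e in ordered:
        lo = sign * (s if reference.strand == "+" else e)
        hi = sign * (e if reference.strand == "+" else s)
        if key < lo:
            return offset  # inside the preceding intron
        if key <= hi:
            return offset + (key - lo) + (1 if inclusive else 0)
        offset += e - s + 1
    return offset


def relative_positions(
    genes: Iterable[GeneModel], boundary: str = "five_prime"
) -> list[RelativePositionRecord]:
    out = []
    for g in genes:
        apa = g.apa_transcripts()
        if not apa:
            continue
        ref = g.get(define_full_length_reference(g))
        for t in apa:
            out.append(relative_position(g, t, ref, boundary))
    return out


def bin_distribution(
    records: Iterable[RelativePositionRecord],
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Histogram over bins plus the per-bin gene lists (flagged records skipped)."""
    counts = {EARLY: 0, MID: 0, LATE: 0}
    members: dict[str, list[str]] = {EARLY: [], MID: [], LATE: []}
    for r in records:
        if r.flagged:
            continue
        counts[r.bin] += 1
        members[r.bin].append(r.gene_id)
    return pd.Series(counts), members


def position_histogram(
    records: Iterable[RelativePositionRecord], n_bins: int = 20
) -> np.ndarray:
    """Fine-grained histogram of relative positions over (0, 1]."""
    vals = [r.relative_position for r in records if not r.flagged]
    hist, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return hist


def count_histogram_modes(hist: np.ndarray) -> int:
    """Number of strict local maxima of a histogram (plateaus merged)."""
    # compress equal-neighbour runs, then count interior peaks + edge peaks
    vals = [h for i, h in enumerate(hist) if i == 0 or h != hist[i - 1]]
    modes = 0
    for i, v in enumerate(vals):
        left = vals[i - 1] if i > 0 else -1
        right = vals[i + 1] if i < len(vals) - 1 else -1
        if v > left and v > right:
            modes += 1
    return modes


def protein_length_scatter(
    pairs: Iterable[ProteinLengthPair],
    bins: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Tabulate length ratios with band flags, optionally stratified by the
    relative-position bin of the event (``bins``: gene_id -> bin)."""
    rows = []
    for p in pairs:
        rows.append({
            "gene_id": p.gene_id,
            "len_truncated_aa": p.len_truncated_aa,
            "len_full_aa": p.len_full_aa,
            "ratio": p.ratio,
            "within_band": p.within_band,
            "longer_than_full": p.ratio > 1.0,
            "bin": (bins or {}).get(p.gene_id, ""),
        })
    return pd.DataFrame(rows)
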