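"""Gene-annotation ingest and intronic-APA isoform classification.

A gene transcribed with multiple polyadenylation sites can terminate inside
an intron, producing a transcript whose coding region and transcript body
both stop short of the gene's full extent.  Classification is therefore a
two-condition rule applied per gene, in transcription direction:

a coding transcript is an intronic-APA isoform iff

1. its coding end is not the maximal coding end among the gene's coding
   transcripts, and
2. its transcript end is not the maximal transcript end among all of the
   gene's transcripts.

All genomic coordinates in this package are 1-based, closed intervals (the
GTF convention), on both strands.  "3'-most" / "maximal" are taken in
transcription direction: genomic maximum on '+', genomic minimum on '-'.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

log = logging.getLogger(__name__)

APA = "INTRONIC_APA"
FULL_LENGTH = "FULL_LENGTH"

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; carries the 1-based line number."""


class AnnotationValidationError(ValueError):
    """Raised when a transcript's feature set is internally inconsistent."""


@dataclass
class TranscriptModel:
    """One transcript: exon and CDS interval chains on a strand.

    Intervals are ``(start, end)`` tuples, 1-based closed, sorted by genomic
    coordinate regardless of strand.  ``cds`` is empty for non-coding
    transcripts, which are excluded from classification.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = ""

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    def _directional(self, pos: int) -> int:
        """Map a genomic position to a key increasing in transcription direction."""
        return pos if self.strand == "+" else -pos

    @property
    def transcript_end(self) -> int:
        """Genomic coordinate of the 3'-most transcribed position."""
        if self.strand == "+":
            return max(e[1] for e in self.exons)
        return min(e[0] for e in self.exons)

    @property
    def coding_end(self) -> Optional[int]:
        """Genomic coordinate of the 3'-most coding position (None if non-coding)."""
        if not self.cds:
            return None
        if self.strand == "+":
            return max(c[1] for c in self.cds)
        return min(c[0] for c in self.cds)

    @property
    def transcript_end_key(self) -> int:
        return self._directional(self.transcript_end)

    @property
    def coding_end_key(self) -> Optional[int]:
        ce = self.coding_end
        return None if ce is None else self._directional(ce)

    def coding_length(self) -> int:
        """Total CDS length in nucleotides."""
        return sum(e - s + 1 for s, e in self.cds)

    def exon_chain_key(self) -> tuple:
        """Identity key for de-duplication across annotation sources."""
        return (self.chrom, self.strand, tuple(self.exons), tuple(self.cds))

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: no exons"
            )
        for s, e in self.exons + self.cds:
            if s > e:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: interval ({s},{e}) inverted"
                )
        prev_end = None
        for s, e in self.exons:
            if prev_end is not None and s <= prev_end:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: CDS ({cs},{ce}) not contained "
                    "in any exon"
                )


@dataclass
class GeneModel:
    """A gene: its transcripts plus (after classification) their labels."""

    gene_id: str
    gene_name: str = ""
    transcripts: list[TranscriptModel] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(e[0] for t in self.transcripts for e in t.exons)

    def coding_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.is_coding]

    def apa_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if self.labels.get(t.transcript_id) == APA]

    def full_length_transcripts(self) -> list[TranscriptModel]:
        return [
            t for t in self.transcripts
            if self.labels.get(t.transcript_id) == FULL_LENGTH
        ]

    def get(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


def _open_text(path) -> Iterable[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_attributes(raw: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(raw))


def read_gtf(path, biotype_filter: Optional[set[str]] = None) -> list[GeneModel]:
    """Parse a GTF (GENCODE/RefSeq dialect, gzip-transparent) into gene models.

    Only ``exon``, ``CDS`` and ``stop_codon`` features are consumed.  A
    ``stop_codon`` feature adjacent to a CDS end is merged into the CDS so
    that annotation dialects that exclude the stop from the CDS (GENCODE)
    and those that include it compare identically.

    ``biotype_filter``, when given, drops transcripts whose
    ``transcript_type``/``transcript_biotype`` attribute is present and not
    in the set; transcripts without a biotype tag are retained (their coding
    status is decided by CDS presence).

    Raises :class:`GtfParseError` with the offending line number on a
    malformed line, and :class:`AnnotationValidationError` when a CDS lies
    outside all exons of its transcript.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    gene_names: dict[str, str] = {}
    gene_order: dict[str, str] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, frame, attrs = fields
            if feature not in ("exon", "CDS", "stop_codon"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            a = _parse_attributes(attrs)
            gid, tid = a.get("gene_id"), a.get("transcript_id")
            if not gid or not tid:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing gene_id/transcript_id"
                )
            biotype = a.get("transcript_type") or a.get("transcript_biotype") or ""
            if biotype_filter and biotype and biotype not in biotype_filter:
                continue
            if tid not in meta:
                meta[tid] = {
                    "gene_id": gid, "chrom": chrom, "strand": strand,
                    "biotype": biotype,
                }
            gene_names.setdefault(gid, a.get("gene_name", gid))
            gene_order.setdefault(gid, chrom)
            target = {"exon": exons, "CDS": cds, "stop_codon": stops}[feature]
            target.setdefault(tid, []).append((start, end))

    genes: dict[str, GeneModel] = {}
    for tid, m in meta.items():
        t = TranscriptModel(
            transcript_id=tid, gene_id=m["gene_id"], chrom=m["chrom"],
            strand=m["strand"], biotype=m["biotype"],
            exons=sorted(exons.get(tid, [])),
            cds=_merge_stop(sorted(cds.get(tid, [])), stops.get(tid, []), m["strand"]),
        )
        if not t.exons:
            log.warning("transcript %s has CDS but no exons; skipped", tid)
            continue
        t.validate()
        g = genes.setdefault(m["gene_id"],
                             GeneModel(m["gene_id"], gene_names[m["gene_id"]]))
        g.transcripts.append(t)

    out = list(genes.values())
    for g in out:
        g.transcripts.sort(key=lambda t: (t.exons[0][0], t.transcript_id))
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def _merge_stop(cds: list[tuple[int, int]], stops: Sequence[tuple[int, int]],
                strand: str) -> list[tuple[int, int]]:
    """Extend the CDS with an adjacent stop_codon feature, if present."""
    if not cds or not stops:
        return cds
    cds = list(cds)
    for ss, se in sorted(stops):
        if strand == "+":
            last = cds[-1]
            if ss == last[1] + 1:
                cds[-1] = (last[0], se)
            elif not any(s <= ss and se <= e for s, e in cds):
                cds.append((ss, se))
                cds.sort()
        else:
            first = cds[0]
            if se == first[0] - 1:
                cds[0] = (ss, first[1])
            elif not any(s <= ss and se <= e for s, e in cds):
                cds.append((ss, se))
                cds.sort()
    return cds


def classify_transcripts(gene: GeneModel) -> GeneModel:
    """Label each coding transcript of ``gene`` as INTRONIC_APA or FULL_LENGTH.

    The comparison keys are strand-aware so that mirroring a gene's
    coordinates and flipping its strand leaves labels unchanged.  A gene
    with no coding transcript is flagged ``no_coding_transcript`` and left
    unlabeled.  Labels are written into ``gene.labels`` in place; the gene
    is also returned for chaining.
    """
    coding = gene.coding_transcripts()
    gene.labels = {}
    if not coding:
        if "no_coding_transcript" not in gene.flags:
            gene.flags.append("no_coding_transcript")
        return gene
    max_coding_end = max(t.coding_end_key for t in coding)
    max_transcript_end = max(t.transcript_end_key for t in gene.transcripts)
    for t in coding:
        is_apa = (t.coding_end_key != max_coding_end
                  and t.transcript_end_key != max_transcript_end)
        gene.labels[t.transcript_id] = APA if is_apa else FULL_LENGTH
    return gene


def classify_all(genes: Iterable[GeneModel]) -> list[GeneModel]:
    return [classify_transcripts(g) for g in genes]


def merge_annotations(a: list[GeneModel], b: list[GeneModel]) -> list[GeneModel]:
    """Union two annotation sources gene-by-gene and re-classify.

    Genes are matched by ``gene_name`` (falling back to a strand-aware
    coordinate-overlap check when names differ); transcripts are
    de-duplicated by identical (chrom, strand, exon chain, CDS chain).
    Same-name genes on different chromosomes are kept separate with a
    logged warning.
    """
    merged: list[GeneModel] = []
    index: dict[tuple[str, str], GeneModel] = {}
    for g in a:
        copy = GeneModel(g.gene_id, g.gene_name, list(g.transcripts))
        merged.append(copy)
        index[(g.gene_name or g.gene_id, g.chrom)] = copy

    for g in b:
        key = (g.gene_name or g.gene_id, g.chrom)
        target = index.get(key)
        if target is None:
            if any((g.gene_name or g.gene_id) == n for n, _c in index):
                log.warning(
                    "gene name %s occurs on multiple chromosomes; kept separately",
                    g.gene_name,
                )
            target = _find_overlap(merged, g)
        if target is None:
            copy = GeneModel(g.gene_id, g.gene_name, list(g.transcripts))
            merged.append(copy)
            index[key] = copy
        else:
            seen = {t.exon_chain_key() for t in target.transcripts}
            for t in g.transcripts:
                if t.exon_chain_key() not in seen:
                    target.transcripts.append(t)
                    seen.add(t.exon_chain_key())

    for g in merged:
        g.transcripts.sort(key=lambda t: (t.exons[0][0], t.transcript_id))
        classify_transcripts(g)
    merged.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return merged


def _find_overlap(genes: list[GeneModel], query: GeneModel) -> Optional[GeneModel]:
    q_start = query.start
    q_end = max(e[1] for t in query.transcripts for e in t.exons)
    for g in genes:
        if g.chrom != query.chrom or g.strand != query.strand:
            continue
        g_end = max(e[1] for t in g.transcripts for e in t.exons)
        if g.start <= q_end and q_start <= g_end:
            return g
    return None


def count_apa_universe(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Summarize the APA universe over genes that have >=1 intronic-APA isoform.

    Transcript counts sum over APA-bearing genes only, matching how a
    transcript universe is reported for an annotation-wide APA survey.
    """
    n_genes = n_apa = n_fl = 0
    for g in genes:
        apa = sum(1 for v in g.labels.values() if v == APA)
        if apa == 0:
            continue
        n_genes += 1
        n_apa += apa
        n_fl += sum(1 for v in g.labels.values() if v == FULL_LENGTH)
    return {
        "n_genes_with_apa": n_genes,
        "n_apa_transcripts": n_apa,
        "n_full_length_transcripts": n_fl,
    }


def write_label_table(genes: Iterable[GeneModel], path) -> None:
    """Write the per-transcript label table (TSV, 1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_name\ttranscript_id\tlabel\tchrom\tstrand\t"
                 "coding_end\ttranscript_end\n")
        for g in genes:
            for t in g.transcripts:
                label = g.labels.get(t.transcript_id, "NON_CODING")
                fh.write(
                    f"{g.gene_id}\t{g.gene_name}\t{t.transcript_id}\t{label}\t"
                    f"{t.chrom}\t{t.strand}\t{t.coding_end or ''}\t"
                    f"{t.transcript_end}\n"
                )


def read_label_table(path) -> dict[str, dict[str, str]]:
    """Read a label table back as {gene_id: {transcript_id: label}}."""
    import csv

    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["gene_id"], {})[row["transcript_id"]] = row["label"]
    return out
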