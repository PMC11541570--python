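"""In-silico C-terminal peptide database for targeted proteomics (SRM).

Truncated transcripts carry C-termini that distinguish them from the
full-length isoform, so a targeted assay needs candidate peptides from two
provenance routes:

* annotated route — the last coding exon of an annotated intronic-APA
  transcript, translated in its annotated frame;
* exonized-intron route — the exon preceding an intron-accumulation region
  concatenated with that intronic sequence and translated in all three
  frames; a frame is discarded if a stop codon falls inside the
  exon-derived portion, or if translation extends no more than 6 nt (2
  codons) past the exon boundary.

Candidate proteins are then digested with trypsin (cleave after every K and
R, no missed cleavages), peptides containing methionine or shorter than 7
residues are removed, and the predicted charge state

    charge = #K + #R + #H + 1

must exceed 1 for a peptide to be retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .annotation import APA, GeneModel, TranscriptModel

log = logging.getLogger(__name__)

ANNOTATED_LAST_EXON = "ANNOTATED_LAST_EXON"

_CLEAVE_RE = re.compile(r"(?<=[KR])")


@dataclass
class ProteinCandidate:
    candidate_id: str
    source_transcript_id: str
    provenance: str  # ANNOTATED_LAST_EXON or EXONIZED_INTRON_FRAME_{0,1,2}
    aa_sequence: str
    exon_aa_span: Optional[tuple[int, int]] = None  # 0-based [start, end) in aa


@dataclass
class PeptideCandidate:
    aa_sequence: str
    parent_id: str
    start: int  # 0-based start index in parent
    end: int    # exclusive
    charge_state: int
    is_terminal: bool
    provenance: str = ""


def translate(nt: str) -> str:
    """Translate a nucleotide string (standard code), trailing partial codon
    dropped, stops rendered as '*'."""
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


class GenomeSource:
    """Uniform 1-based-closed sequence access over pyfaidx or a dict of strings."""

    def __init__(self, source):
        self._src = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end] (1-based, closed) on the forward strand."""
        seq = self._src[chrom]
        if hasattr(seq, "__getitem__") and isinstance(seq, str):
            return seq[start - 1:end].upper()
        # pyfaidx FastaRecord supports python slicing with 0-based coords
        return str(seq[start - 1:end]).upper()

    def __contains__(self, chrom) -> bool:
        try:
            self._src[chrom]
            return True
        except KeyError:
            return False


def _spliced_sequence(intervals: Sequence[tuple[int, int]], chrom: str,
                      strand: str, genome: GenomeSource) -> str:
    """Concatenate genomic intervals in transcription direction."""
    parts = [genome.fetch(chrom, s, e) for s, e in sorted(intervals)]
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


def translate_annotated_last_exon(
    transcript: TranscriptModel, genome: GenomeSource
) -> ProteinCandidate:
    """Translate the last coding exon of an annotated truncated transcript.

    The reading frame is derived from the cumulative CDS length upstream of
    the last coding exon (transcription direction); on '-' strand the exon
    is reverse-complemented first.  The trailing stop, when present, is
    stripped.  An internal stop in the annotated frame is a biological
    inconsistency and raises ValueError.
    """
    if not transcript.cds:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS")
    cds = sorted(transcript.cds)
    ordered = cds if transcript.strand == "+" else cds[::-1]
    *upstream, last = ordered
    upstream_len = sum(e - s + 1 for s, e in upstream)
    frame = (-upstream_len) % 3  # nt to skip so the exon starts on a codon
    exon_nt = _spliced_sequence([last], transcript.chrom, transcript.strand, genome)
    aa = translate(exon_nt[frame:])
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(
            f"internal stop codon in annotated frame of {transcript.transcript_id}"
        )
    return ProteinCandidate(
        candidate_id=f"{transcript.transcript_id}|last_exon",
        source_transcript_id=transcript.transcript_id,
        provenance=ANNOTATED_LAST_EXON,
        aa_sequence=aa,
    )


def three_frame_intron_candidates(
    exon_seq: str,
    intron_seq: str,
    source_id: str = "region",
    min_extension_nt: int = 7,
) -> list[ProteinCandidate]:
    """Three-frame translation of exon + intron-accumulation sequence.

    For each frame f in {0, 1, 2}, the concatenation is translated from
    offset f until the first stop codon (or sequence end).  The frame is
    dropped when (a) a stop codon lies within the exon-derived portion, or
    (b) the translated extension past the exon boundary covers fewer than
    ``min_extension_nt`` nucleotides (default: strictly more than 6 nt
    required).  Survivors carry ``exon_aa_span``, the residue range encoded
    at least partly by the exon.
    """
    exon_seq, intron_seq = exon_seq.upper(), intron_seq.upper()
    if len(exon_seq) < 3:
        log.warning("exon sequence shorter than 3 nt for %s; no candidates",
                    source_id)
        return []
    full = exon_seq + intron_seq
    out = []
    for frame in range(3):
        aa = translate(full[frame:])
        stop = aa.find("*")
        prot = aa if stop == -1 else aa[:stop]
        if not prot:
            continue
        translated_nt_end = frame + 3 * len(prot)  # nt consumed before the stop
        if stop != -1:
            stop_nt_start = frame + 3 * stop  # first nt of the stop codon
            if stop_nt_start < len(exon_seq):
                continue  # rule (a): stop within the exon region
        extension = translated_nt_end - len(exon_seq)
        if extension < min_extension_nt:
            continue  # rule (b): <=6 nt beyond the exon boundary
        # residues whose codon starts within the exon
        exon_aa = max(0, -(-(len(exon_seq) - frame) // 3))  # ceil
        out.append(
            ProteinCandidate(
                candidate_id=f"{source_id}|frame{frame}",
                source_transcript_id=source_id,
                provenance=f"EXONIZED_INTRON_FRAME_{frame}",
                aa_sequence=prot,
                exon_aa_span=(0, min(exon_aa, len(prot))),
            )
        )
    return out


def trypsin_digest(protein: str) -> list[str]:
    """Cleave after every K and R (no proline exception, no missed cleavages).

    The peptides tile the input: ``''.join(result) == protein``.
    """
    if "*" in protein:
        raise ValueError("protein sequence contains a stop character")
    if not protein:
        return []
    return [p for p in _CLEAVE_RE.split(protein) if p]


def charge_state(peptide: str) -> int:
    """Predicted SRM charge: one proton per K, R and H plus the N-terminus."""
    return peptide.count("K") + peptide.count("R") + peptide.count("H") + 1


def skyline_charge(peptide: str) -> int:
    """Instrument-method assumption: +2 unless the peptide contains histidine."""
    return 3 if "H" in peptide else 2


def filter_and_charge(
    peptides: Sequence[str],
    parent: ProteinCandidate,
    min_length: int = 7,
) -> list[PeptideCandidate]:
    """Apply the SRM candidate filters and annotate charge states.

    Removes peptides containing methionine or shorter than ``min_length``;
    keeps only charge states > 1.  Positions are recovered by tiling, so
    ``peptides`` must be a full digest of the parent in order.
    """
    out = []
    pos = 0
    n = len(peptides)
    for i, pep in enumerate(peptides):
        start, end = pos, pos + len(pep)
        pos = end
        if "M" in pep or len(pep) < min_length:
            continue
        z = charge_state(pep)
        if z <= 1:
            continue
        out.append(
            PeptideCandidate(
                aa_sequence=pep,
                parent_id=parent.candidate_id,
                start=start,
                end=end,
                charge_state=z,
                is_terminal=(i == n - 1),
                provenance=parent.provenance,
            )
        )
    return out


@dataclass
class PeptideDatabase:
    """De-duplicated peptide candidates with per-sequence provenance lists."""

    peptides: dict[str, list[PeptideCandidate]] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)

    def add(self, candidates: Iterable[PeptideCandidate]) -> None:
        for c in candidates:
            self.peptides.setdefault(c.aa_sequence, []).append(c)

    def __len__(self) -> int:
        return len(self.peptides)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for seq in sorted(self.peptides):
                entries = self.peptides[seq]
                prov = ";".join(
                    f"{e.parent_id}:{e.provenance}" for e in entries
                )
                z = entries[0].charge_state
                fh.write(f">{seq} charge={z} skyline_charge={skyline_charge(seq)} "
                         f"sources={prov}\n{seq}\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\tcharge_state\tskyline_charge\tn_sources\tsources\n")
            for seq in sorted(self.peptides):
                entries = self.peptides[seq]
                prov = ";".join(f"{e.parent_id}:{e.provenance}" for e in entries)
                fh.write(f"{seq}\t{entries[0].charge_state}\t"
                         f"{skyline_charge(seq)}\t{len(entries)}\t{prov}\n")


def build_srm_database(
    genes: Iterable[GeneModel],
    genome: GenomeSource | Mapping[str, str],
    intron_regions: Optional[Mapping[str, tuple[str, str]]] = None,
    min_length: int = 7,
    min_extension_nt: int = 7,
) -> PeptideDatabase:
    """Build the candidate peptide database for every labeled APA transcript.

    ``intron_regions`` optionally maps a region id to an (exon_seq,
    intron_seq) pair for the unannotated exonized-intron route.  Transcripts
    on missing contigs, or whose candidates yield no surviving peptide, are
    recorded in the exclusion report rather than raised.
    """
    if not isinstance(genome, GenomeSource):
        genome = GenomeSource(genome)
    db = PeptideDatabase()
    for gene in genes:
        for t in gene.apa_transcripts():
            if t.chrom not in genome:
                db.exclusions.append(f"{t.transcript_id}: contig {t.chrom} missing")
                continue
            try:
                cand = translate_annotated_last_exon(t, genome)
            except ValueError as exc:
                db.exclusions.append(f"{t.transcript_id}: {exc}")
                continue
            if not cand.aa_sequence:
                db.exclusions.append(f"{t.transcript_id}: empty translation")
                continue
            peps = filter_and_charge(
                trypsin_digest(cand.aa_sequence), cand, min_length
            )
            if not peps:
                db.exclusions.append(f"{t.transcript_id}: no surviving peptide")
            db.add(peps)
    for region_id, (exon_seq, intron_seq) in (intron_regions or {}).items():
        for cand in three_frame_intron_candidates(
            exon_seq, intron_seq, region_id, min_extension_nt
        ):
            peps = filter_and_charge(
                trypsin_digest(cand.aa_sequence), cand, min_length
            )
            if not peps:
                db.exclusions.append(f"{cand.candidate_id}: no surviving peptide")
            db.add(peps)
    return db
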