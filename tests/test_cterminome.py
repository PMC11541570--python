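import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronapa import cterminome as ct
from intronapa.annotation import TranscriptModel

AA = "ACDEFGHIKLMNPQRSTVWY"
STOPS = {"TAA", "TAG", "TGA"}
CODON_TABLE = {}
for _a in "ACGT":
    for _b in "ACGT":
        for _c in "ACGT":
            codon = _a + _b + _c
            from Bio.Seq import Seq

            CODON_TABLE[codon] = str(Seq(codon).translate())


def brute_translate(nt):
    return "".join(
        CODON_TABLE[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


class TestTranslation:
    def test_codon_table_example(self):
        assert ct.translate("GCTAAAAGA") == "AKR"

    def test_partial_codon_dropped(self):
        assert ct.translate("GCTAA") == "A"

    def test_reverse_complement_strand_rule(self):
        # genomic "TCTTTTAGC" on '-' strand reads GCTAAAAGA
        assert ct.translate(ct.reverse_complement("TCTTTTAGC")) == "AKR"


class TestAnnotatedLastExon:
    def _transcript(self, strand, exons, cds):
        return TranscriptModel("t1", "g", "chr1", strand,
                               exons=exons, cds=cds)

    def test_plus_strand_frame0(self):
        genome = {"chr1": "GCTAAAAGA" + "TTTT"}
        t = self._transcript("+", [(1, 13)], [(1, 9)])
        cand = ct.translate_annotated_last_exon(t, ct.GenomeSource(genome))
        assert cand.aa_sequence == "AKR"
        assert cand.provenance == ct.ANNOTATED_LAST_EXON

    def test_minus_strand_reverse_complements(self):
        genome = {"chr1": "TCTTTTAGC"}
        t = self._transcript("-", [(1, 9)], [(1, 9)])
        cand = ct.translate_annotated_last_exon(t, ct.GenomeSource(genome))
        assert cand.aa_sequence == "AKR"

    def test_two_exon_frame_offset_hand_translated(self):
        # exon1 CDS contributes 4 nt -> last exon starts mid-codon; the
        # spanning codon is dropped, frame skip = 2; expectation derived by
        # hand from the codon table before implementation.
        #  exon1: GCTA     exon2: AGGCTAAATAA (skip AG -> GCT AAA TAA -> AK*)
        genome = {"chr1": "GCTA" + "XXXX".replace("X", "T") + "AGGCTAAATAA"}
        t = self._transcript("+", [(1, 4), (9, 19)], [(1, 4), (9, 19)])
        cand = ct.translate_annotated_last_exon(t, ct.GenomeSource(genome))
        assert cand.aa_sequence == "AK"

    def test_internal_stop_raises(self):
        genome = {"chr1": "TAAGCTAAA"}
        t = self._transcript("+", [(1, 9)], [(1, 9)])
        with pytest.raises(ValueError, match="internal stop"):
            ct.translate_annotated_last_exon(t, ct.GenomeSource(genome))


def brute_three_frame(exon, intron, min_ext=7):
    """Independent enumerator of surviving frames (straight re-derivation)."""
    full = exon + intron
    survivors = {}
    for frame in range(3):
        prot = []
        stop_start = None
        for i in range(frame, len(full) - 2, 3):
            codon = full[i:i + 3]
            if codon in STOPS:
                stop_start = i
                break
            prot.append(CODON_TABLE[codon])
        if not prot:
            continue
        if stop_start is not None and stop_start < len(exon):
            continue
        last_nt = frame + 3 * len(prot)
        if last_nt - len(exon) < min_ext:
            continue
        survivors[frame] = "".join(prot)
    return survivors


class TestThreeFrame:
    def test_short_extension_drops_all_frames(self):
        # a 6-nt intron can never provide >6 nt of translated extension
        out = ct.three_frame_intron_candidates("ATGGCA", "TTAGTT")
        assert out == []

    def test_stop_in_exon_drops_only_that_frame(self):
        # TAG in frame 1 only: exon = A TAG GGG ...
        exon = "ATAGGG"
        intron = "GCAGCAGCAGCAGCA"
        out = ct.three_frame_intron_candidates(exon, intron)
        frames = {c.provenance for c in out}
        assert "EXONIZED_INTRON_FRAME_1" not in frames
        assert frames  # other frames evaluated independently

    def test_short_exon_warns_and_returns_empty(self):
        assert ct.three_frame_intron_candidates("AT", "GCAGCAGCA") == []

    def test_matches_brute_force_enumerator(self):
        rng = np.random.default_rng(97)
        for _ in range(200):
            exon = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 60))))
            intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 240))))
            expected = brute_three_frame(exon, intron)
            got = {
                int(c.provenance[-1]): c.aa_sequence
                for c in ct.three_frame_intron_candidates(exon, intron)
            }
            assert got == expected, (exon, intron)


class TestDigestAndCharge:
    def test_cleaves_after_k_and_r(self):
        assert ct.trypsin_digest("MKTRAAK") == ["MK", "TR", "AAK"]

    def test_no_site_returns_whole(self):
        assert ct.trypsin_digest("AAAA") == ["AAAA"]

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=80))
    def test_digest_tiles_input(self, protein):
        peps = ct.trypsin_digest(protein)
        assert "".join(peps) == protein
        for p in peps[:-1]:
            assert p[-1] in "KR"

    @pytest.mark.parametrize(
        "pep,charge", [("AAAAAAK", 2), ("HHRAAAK", 5), ("AAAAAAA", 1)]
    )
    def test_charge_formula(self, pep, charge):
        assert ct.charge_state(pep) == charge

    def test_filters_methionine_and_length(self):
        parent = ct.ProteinCandidate("p", "t", ct.ANNOTATED_LAST_EXON,
                                     "MAAAAAKAAAAAAKSHORTK")
        peps = ct.trypsin_digest(parent.aa_sequence)
        kept = ct.filter_and_charge(peps, parent)
        seqs = [p.aa_sequence for p in kept]
        assert "MAAAAAK" not in seqs          # contains M
        assert "AAAAAAK" in seqs              # clean, length 7, charge 2
        assert all(len(s) >= 7 for s in seqs)

    def test_charge_gt1_only_removes_terminal_krh_free_peptides(self):
        """A surviving non-terminal peptide always ends in K/R, so its
        charge is >= 2; the charge filter can only drop terminal peptides."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            protein = "".join(rng.choice(list(AA), size=int(rng.integers(10, 60))))
            parent = ct.ProteinCandidate("p", "t", ct.ANNOTATED_LAST_EXON, protein)
            peps = ct.trypsin_digest(protein)
            removed_by_charge = [
                (i, p) for i, p in enumerate(peps)
                if "M" not in p and len(p) >= 7 and ct.charge_state(p) <= 1
            ]
            for i, _p in removed_by_charge:
                assert i == len(peps) - 1

    def test_skyline_charge_metadata(self):
        assert ct.skyline_charge("AAAAK") == 2
        assert ct.skyline_charge("AAHAK") == 3


class TestBuildDatabase:
    def test_hand_built_toy_database(self):
        # one APA transcript whose last coding exon encodes two clean
        # tryptic peptides (hand-derived): GCTGCTGCTGCTGCTGCTAAA -> AAAAAAK
        exon_nt = "GCTGCTGCTGCTGCTGCTAAA" + "TTTGCTGCTGCTGCTGCTCGT"
        genome = {"chr1": exon_nt}
        fl = TranscriptModel("t.fl", "g", "chr1", "+",
                             exons=[(1, 42), (60, 100)],
                             cds=[(1, 42), (60, 90)])
        apa = TranscriptModel("t.apa", "g", "chr1", "+",
                              exons=[(1, 42)], cds=[(1, 42)])
        from intronapa.annotation import GeneModel, classify_transcripts

        gene = classify_transcripts(GeneModel("g", "G", [fl, apa]))
        db = ct.build_srm_database([gene], genome)
        assert set(db.peptides) == {"AAAAAAK", "FAAAAAR"}

    def test_duplicate_peptide_two_provenances(self):
        parent1 = ct.ProteinCandidate("p1", "t1", ct.ANNOTATED_LAST_EXON,
                                      "AAAAAAK")
        parent2 = ct.ProteinCandidate("p2", "t2", "EXONIZED_INTRON_FRAME_0",
                                      "AAAAAAK")
        db = ct.PeptideDatabase()
        for parent in (parent1, parent2):
            db.add(ct.filter_and_charge(ct.trypsin_digest(parent.aa_sequence),
                                        parent))
        assert len(db) == 1
        assert len(db.peptides["AAAAAAK"]) == 2

    def test_transcript_with_no_surviving_peptides_reported(self):
        genome = {"chr1": "GCTAAAAGA" * 3}
        fl = TranscriptModel("t.fl", "g", "chr1", "+",
                             exons=[(1, 27)], cds=[(1, 27)])
        apa = TranscriptModel("t.apa", "g", "chr1", "+",
                              exons=[(1, 9)], cds=[(1, 6)])
        from intronapa.annotation import GeneModel, classify_transcripts

        gene = classify_transcripts(GeneModel("g", "G", [fl, apa]))
        db = ct.build_srm_database([gene], genome)
        assert len(db) == 0
        assert any("t.apa" in e for e in db.exclusions)

    def test_missing_contig_skipped_with_report(self):
        fl = TranscriptModel("t.fl", "g", "chrZ", "+",
                             exons=[(1, 30)], cds=[(1, 30)])
        apa = TranscriptModel("t.apa", "g", "chrZ", "+",
                              exons=[(1, 9)], cds=[(1, 6)])
        from intronapa.annotation import GeneModel, classify_transcripts

        gene = classify_transcripts(GeneModel("g", "G", [fl, apa]))
        db = ct.build_srm_database([gene], {"chr1": "ACGT"})
        assert any("chrZ" in e for e in db.exclusions)
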