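import random

import pytest

from varshare.core import (
    CdnaPosition,
    ConsequenceRanking,
    GenomicVariant,
    NormalizedVariant,
    TranscriptAnnotation,
    TranscriptModel,
    apply_variant,
    map_to_cdna,
    normalize,
    select_main_transcript,
    shift_left,
    shift_right,
    trim_alleles,
)
from varshare.errors import (
    NoCandidateTranscriptError,
    NonVariantError,
    OutsideTranscriptError,
    ReferenceMismatchError,
    UnknownConsequenceError,
    VarShareError,
)

V = GenomicVariant


# ---------------------------------------------------------------------------
# brute-force placement oracle (independent of the shifting implementation)
# ---------------------------------------------------------------------------


def _pure(v: V) -> tuple[int, str, str]:
    """Strip shared prefix then suffix fully -> (0-based start, del, ins)."""
    ref, alt = v.ref, v.alt
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    ref, alt = ref[p:], alt[p:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return v.pos - 1 + p, ref, alt


def indel_placements(seq: str, v: V) -> list[int]:
    """All 0-based pure-edit positions yielding the same edited sequence."""
    target = apply_variant(seq, v)
    delta = len(target) - len(seq)
    assert delta != 0, "oracle only covers indels"
    size = abs(delta)
    if delta < 0:  # deletion of `size` bases at i
        return [
            i for i in range(len(seq) - size + 1) if seq[:i] + seq[i + size :] == target
        ]
    return [  # insertion of target[i:i+size] before index i
        i for i in range(len(seq) + 1) if seq[:i] + target[i : i + size] + seq[i:] == target
    ]


def anchored_deletion(seq: str, chrom: str, i: int, size: int) -> V:
    if i > 0:
        return V(chrom, i, seq[i - 1 : i + size], seq[i - 1])
    return V(chrom, 1, seq[: size + 1], seq[size])


def anchored_insertion(seq: str, chrom: str, i: int, ins: str) -> V:
    if i > 0:
        return V(chrom, i, seq[i - 1], seq[i - 1] + ins)
    return V(chrom, 1, seq[0], ins + seq[0])


class TestTrimAlleles:
    def test_shared_prefix_and_suffix(self):
        assert trim_alleles(V("1", 100, "CAG", "CTG")) == V("1", 101, "A", "T")

    def test_non_variant_rejected(self):
        with pytest.raises(NonVariantError):
            trim_alleles(V("1", 7, "T", "T"))

    def test_anchor_base_retained(self):
        # both edits must produce the same sequence on a test reference
        seq = "GGACCATT"
        original = V("1", 3, "ACCA", "ACA")
        trimmed = trim_alleles(original)
        assert trimmed == V("1", 3, "AC", "A")
        assert apply_variant(seq, original) == apply_variant(seq, trimmed)

    def test_invalid_alleles_rejected(self):
        with pytest.raises(VarShareError):
            V("1", 5, "", "A")
        with pytest.raises(VarShareError):
            V("1", 5, "AXA", "A")
        with pytest.raises(VarShareError):
            V("1", 0, "A", "T")


class TestShifting:
    SEQ = "GATATATC"

    def test_deletion_shifts_left(self):
        assert shift_left(V("1", 3, "TAT", "T"), self.SEQ) == V("1", 1, "GAT", "G")

    def test_deletion_shifts_right(self):
        assert shift_right(V("1", 1, "GAT", "G"), self.SEQ) == V("1", 5, "TAT", "T")

    def test_snv_unchanged(self):
        snv = V("1", 5, "T", "C")
        assert shift_left(snv, self.SEQ) == snv
        assert shift_right(snv, self.SEQ) == snv

    def test_idempotent(self):
        v = V("1", 3, "TAT", "T")
        once = shift_left(v, self.SEQ)
        assert shift_left(once, self.SEQ) == once
        once_r = shift_right(v, self.SEQ)
        assert shift_right(once_r, self.SEQ) == once_r

    def test_left_right_same_edit(self):
        v = V("1", 3, "TAT", "T")
        assert apply_variant(self.SEQ, shift_left(v, self.SEQ)) == apply_variant(
            self.SEQ, shift_right(v, self.SEQ)
        )

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatchError):
            shift_left(V("1", 3, "GGG", "G"), self.SEQ)

    def test_mnv_not_shifted(self):
        v = V("1", 2, "AT", "TA")
        assert shift_left(v, self.SEQ) == v


class TestBruteForceOracle:
    """Shifted placements must match exhaustive enumeration."""

    def _random_indel(self, rng: random.Random, seq: str) -> V:
        pos = rng.randrange(1, len(seq) - 6)
        size = rng.randrange(1, 4)
        if rng.random() < 0.5:  # deletion
            return V("1", pos, seq[pos - 1 : pos + size], seq[pos - 1])
        ins = "".join(rng.choice("ACGT") for _ in range(size))
        return V("1", pos, seq[pos - 1], seq[pos - 1] + ins)

    def test_random_indels_match_enumeration(self, repeat_reference):
        rng = random.Random(42)
        for _ in range(300):
            v = self._random_indel(rng, repeat_reference)
            placements = indel_placements(repeat_reference, v)
            left = shift_left(v, repeat_reference)
            right = shift_right(v, repeat_reference)
            assert _pure(left)[0] == min(placements)
            assert _pure(right)[0] == max(placements)
            assert apply_variant(repeat_reference, left) == apply_variant(
                repeat_reference, v
            )
            assert apply_variant(repeat_reference, right) == apply_variant(
                repeat_reference, v
            )

    def test_all_placements_collapse_to_one_key(self, repeat_reference):
        seq = repeat_reference
        rng = random.Random(99)
        for _ in range(60):
            v = self._random_indel(rng, seq)
            placements = indel_placements(seq, v)
            delta = len(v.alt) - len(v.ref)
            target = apply_variant(seq, v)
            keys = set()
            for i in placements:
                if delta < 0:
                    w = anchored_deletion(seq, "1", i, -delta)
                else:
                    w = anchored_insertion(seq, "1", i, target[i : i + delta])
                keys.add(normalize(w, seq).key)
            assert len(keys) == 1

    def test_normalized_variant_key_is_left_form(self, repeat_reference):
        v = V("1", 51, "T", "TAT")  # inside the AT tract
        norm = normalize(v, repeat_reference)
        assert isinstance(norm, NormalizedVariant)
        assert norm.key == norm.left.key
        assert norm.left.pos <= norm.right.pos


# ---------------------------------------------------------------------------
# transcript mapping
# ---------------------------------------------------------------------------


FWD = TranscriptModel(
    id="T1", gene="G1", strand="+", exons=((1, 10), (21, 30)), cds_start=1, cds_end=30
)
REV = TranscriptModel(
    id="T2", gene="G1", strand="-", exons=((1, 10), (21, 30)), cds_start=1, cds_end=30
)
SINGLE = TranscriptModel(
    id="T3", gene="G1", strand="+", exons=((1, 20),), cds_start=1, cds_end=20
)


class TestMapToCdna:
    def test_fourth_coding_base(self):
        assert map_to_cdna(V("1", 4, "A", "G"), SINGLE) == CdnaPosition(4, 0)

    def test_exonic_second_exon(self):
        # hand-computed: exon1 has 10 bases, position 27 is base 7 of exon2
        assert map_to_cdna(V("1", 27, "A", "G"), FWD) == CdnaPosition(17, 0)

    def test_donor_side_offset(self):
        # 3 bases 3' of the exon-1 end (position 10) -> c.10+3
        assert map_to_cdna(V("1", 13, "A", "G"), FWD) == CdnaPosition(10, 3)

    def test_acceptor_side_offset(self):
        # position 18 is 3 bases 5' of exon-2 start (21) -> c.11-3
        assert map_to_cdna(V("1", 18, "A", "G"), FWD) == CdnaPosition(11, -3)

    def test_reverse_strand_exonic(self):
        # transcript runs 30..21 then 10..1; genomic 25 is transcript base 6
        assert map_to_cdna(V("1", 25, "A", "G"), REV) == CdnaPosition(6, 0)

    def test_reverse_strand_intron(self):
        # genomic 18 is 3 bases downstream (transcript sense) of exon end 21
        assert map_to_cdna(V("1", 18, "A", "G"), REV) == CdnaPosition(10, 3)
        # genomic 13 is 3 bases upstream of the acceptor at genomic 10
        assert map_to_cdna(V("1", 13, "A", "G"), REV) == CdnaPosition(11, -3)

    def test_outside_span(self):
        with pytest.raises(OutsideTranscriptError):
            map_to_cdna(V("1", 35, "A", "G"), FWD)

    def test_independent_walker_oracle(self):
        """Exonic mapping agrees with a naive base-by-base walk."""
        for transcript in (FWD, REV):
            walk = [
                p
                for start, end in transcript.exons
                for p in range(start, end + 1)
            ]
            if transcript.strand == "-":
                walk.reverse()
            for c_expected, g in enumerate(walk, start=1):
                got = map_to_cdna(V("1", g, "A", "G"), transcript)
                assert got == CdnaPosition(c_expected, 0)

    def test_invalid_transcript_models(self):
        with pytest.raises(VarShareError):
            TranscriptModel("bad", "G", "+", ((10, 5),), 5, 8)
        with pytest.raises(VarShareError):
            TranscriptModel("bad", "G", "+", ((1, 10), (5, 20)), 1, 20)


class TestSelectMainTranscript:
    def _tm(self, tid, gene, lrg=False, canonical=False):
        return TranscriptModel(
            id=tid, gene=gene, strand="+", exons=((1, 100),), cds_start=1,
            cds_end=100, is_lrg_first=lrg, is_canonical=canonical,
        )

    def test_lrg_first_beats_canonical(self):
        anns = [
            TranscriptAnnotation(self._tm("T1", "G1", lrg=True), "missense_variant"),
            TranscriptAnnotation(self._tm("T2", "G1", canonical=True), "missense_variant"),
        ]
        assert select_main_transcript(anns) == "T1"

    def test_canonical_when_no_lrg(self):
        anns = [
            TranscriptAnnotation(self._tm("T2", "G1", canonical=True), "missense_variant"),
            TranscriptAnnotation(self._tm("T9", "G1"), "stop_gained"),
        ]
        assert select_main_transcript(anns) == "T2"

    def test_multi_gene_most_severe(self):
        anns = [
            TranscriptAnnotation(self._tm("TA", "G1", canonical=True), "missense_variant"),
            TranscriptAnnotation(self._tm("TB", "G2", canonical=True), "synonymous_variant"),
        ]
        assert select_main_transcript(anns) == "TA"

    def test_tie_broken_by_transcript_id(self):
        anns = [
            TranscriptAnnotation(self._tm("TB", "G2", canonical=True), "missense_variant"),
            TranscriptAnnotation(self._tm("TA", "G1", canonical=True), "missense_variant"),
        ]
        assert select_main_transcript(anns) == "TA"

    def test_no_candidates(self):
        with pytest.raises(NoCandidateTranscriptError):
            select_main_transcript([])
        with pytest.raises(NoCandidateTranscriptError):
            select_main_transcript(
                [TranscriptAnnotation(self._tm("T1", "G1"), "missense_variant")]
            )

    def test_unknown_consequence(self):
        anns = [
            TranscriptAnnotation(self._tm("TA", "G1", canonical=True), "mystery_variant"),
        ]
        with pytest.raises(UnknownConsequenceError):
            select_main_transcript(anns)

    def test_duplicate_ranking_terms_rejected(self):
        with pytest.raises(VarShareError):
            ConsequenceRanking(("a", "b", "a"))


class TestReferenceIO:
    def test_fasta_round_trip(self, tmp_path, repeat_reference):
        from varshare.core import ReferenceGenome
        from varshare.fixtures import write_fasta

        path = tmp_path / "ref.fa"
        write_fasta({"1": repeat_reference, "2": "ACGTACGT"}, path)
        genome = ReferenceGenome.from_fasta(str(path))
        assert genome["1"] == repeat_reference
        assert "2" in genome and "3" not in genome
        assert sorted(genome.keys()) == ["1", "2"]

    def test_transcript_table_reader(self, tmp_path):
        from varshare.core import read_transcripts

        path = tmp_path / "tx.tsv"
        path.write_text(
            "# id gene strand exons cds_start cds_end lrg canonical\n"
            "T1\tG1\t+\t1-10,21-30\t1\t30\t1\t0\n"
            "T2\tG1\t-\t1-10,21-30\t1\t30\t0\t1\n"
        )
        models = read_transcripts(str(path))
        assert [t.id for t in models] == ["T1", "T2"]
        assert models[0].exons == ((1, 10), (21, 30))
        assert models[0].is_lrg_first and not models[0].is_canonical
        assert models[1].strand == "-" and models[1].is_canonical
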