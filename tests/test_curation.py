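"""Curation funnel: FASTA I/O, filters, local alignment, deduplication."""

import numpy as np
import pytest

from rubisco_prospector.curation import (
    CurationConfig,
    curate,
    deduplicate,
    filter_ambiguous,
    filter_by_coverage,
    filter_by_length,
    local_align,
)
from rubisco_prospector.records import FastaError, ProteinRecord, read_fasta, write_fasta
from rubisco_prospector.synthetic import gen_sequence_family

from conftest import random_protein


def _rec(rid, seq):
    return ProteinRecord(id=rid, sequence=seq)


class TestReadFasta:
    def test_two_entries(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a desc\nMKVL\n>b\nMKIL\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].sequence == "MKVL"

    def test_lowercase_uppercased_and_stop_stripped(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">a\nmkvl*\n")
        assert read_fasta(p)[0].sequence == "MKVL"

    def test_round_trip_generated_fixture(self, tmp_path):
        records, _, _ = gen_sequence_family(
            n_families=10, members_per_family=10, length=120, seed=5
        )
        assert len(records) == 100
        p = tmp_path / "rt.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in records]

    def test_malformed_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("MKVL\n>a\nMKVL\n")
        with pytest.raises(FastaError, match="line 1"):
            read_fasta(p)

    def test_duplicate_ids_listed(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nMK\n>a\nML\n")
        with pytest.raises(FastaError, match="duplicate ids: a"):
            read_fasta(p)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept",
        [(250, False), (300, False), (301, True), (500, True), (699, True),
         (700, False), (705, False)],
    )
    def test_strict_open_interval(self, length, kept):
        rec = _rec("x", "A" * length)
        retained, removed = filter_by_length([rec])
        assert (rec in retained) is kept
        assert (rec in removed) is (not kept)

    def test_enumerated_set(self):
        recs = [_rec(str(n), "A" * n) for n in (250, 300, 301, 699, 700, 705)]
        retained, _ = filter_by_length(recs)
        assert sorted(len(r) for r in retained) == [301, 699]


class TestAmbiguityFilter:
    @pytest.mark.parametrize("residue", list("BZXUO"))
    def test_noncanonical_removed(self, residue):
        retained, removed = filter_ambiguous([_rec("x", "MKVL" + residue + "AT")])
        assert not retained and len(removed) == 1

    def test_mixed_set(self):
        recs = [_rec("b", "MKBVL"), _rec("z", "MKZVL"), _rec("ok", "MKVLA")]
        retained, removed = filter_ambiguous(recs)
        assert [r.id for r in retained] == ["ok"]
        assert len(removed) == 2


class TestLocalAlign:
    def test_identical_sequences_full_span(self):
        seq = "MKVLATGHWE"
        aln = local_align(seq, seq)
        assert aln.query_span == (0, 10) and aln.reference_span == (0, 10)
        assert aln.score > 0

    def test_fragment_span_length(self, rng):
        ref = random_protein(rng, 100)
        query = ref[1:41]
        aln = local_align(query, ref)
        start, end = aln.reference_span
        assert end - start == 40

    def test_no_positive_pair_empty(self):
        aln = local_align("PPPP", "GGGG")
        assert aln.score == 0
        assert aln.query_span == (0, 0) and aln.reference_span == (0, 0)

    def test_unknown_residue_named(self):
        with pytest.raises(KeyError, match="U"):
            local_align("MKUL", "MKVL")

    def test_matches_independent_affine_dp_on_short_strings(self, rng):
        """Score agrees with an independently written Gotoh local DP."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")

        def gotoh_local(a, b, open_=11.0, ext=1.0):
            n, m = len(a), len(b)
            NEG = -1e9
            M = np.full((n + 1, m + 1), 0.0)
            X = np.full((n + 1, m + 1), NEG)  # gap in b
            Y = np.full((n + 1, m + 1), NEG)  # gap in a
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = blosum[a[i - 1], b[j - 1]]
                    M[i, j] = max(0.0, max(M[i - 1, j - 1], X[i - 1, j - 1],
                                           Y[i - 1, j - 1]) + s)
                    X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext)
                    Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext)
                    best = max(best, M[i, j])
            return best

        for _ in range(30):
            a = random_protein(rng, int(rng.integers(3, 9)))
            b = random_protein(rng, int(rng.integers(3, 9)))
            assert local_align(a, b).score == pytest.approx(gotoh_local(a, b))


class TestCoverageFilter:
    def test_identical_retained(self, bait):
        rec = _rec("same", bait.sequence)
        retained, _ = filter_by_coverage([rec], bait)
        assert retained == [rec]

    def test_short_fragment_removed(self, bait):
        frag = _rec("frag", bait.sequence[:160])  # 160/400 = 0.4 < 0.5
        _, removed = filter_by_coverage([frag], bait)
        assert removed == [frag]

    def test_unrelated_removed(self, rng, bait):
        junk = _rec("junk", "".join(rng.choice(list("PG"), size=100)))
        _, removed = filter_by_coverage([junk], bait)
        assert removed == [junk]


class TestDeduplicate:
    def test_identical_pair_collapsed(self):
        out = deduplicate([_rec("a", "MKVL"), _rec("b", "MKVL")])
        assert len(out) == 1 and out[0].id == "a" and out[0].synonyms == ["b"]

    def test_case_only_difference_collapsed(self):
        out = deduplicate([_rec("a", "MKVL"), _rec("b", "mkvl")])
        assert len(out) == 1

    def test_distinct_passthrough(self):
        recs = [_rec("a", "MKVL"), _rec("b", "MKIL")]
        assert deduplicate(recs) == recs


class TestCurate:
    @staticmethod
    def _fixture(rng, bait):
        good = [
            ProteinRecord(f"good{i}", bait.sequence[:320] + random_protein(rng, 30))
            for i in range(15)
        ]
        planted = [
            _rec("short", "MKVL" * 20),                      # length 80
            _rec("long", "A" * 750),                          # length 750
            _rec("ambig", bait.sequence[:320] + "X" * 30),    # ambiguous
            _rec("lowcov", bait.sequence[:150] + "GP" * 100),  # cov 0.375
            ProteinRecord("dupe", good[0].sequence),          # duplicate
        ]
        return good + planted

    def test_planted_violations(self, rng, bait):
        recs = self._fixture(rng, bait)
        retained, report = curate(recs, bait)
        assert len(retained) == 15
        assert report.input_count == 20 and report.retained_count == 15
        stages = {rid: stage for rid, (stage, _) in report.reasons.items()}
        assert stages == {
            "short": "length", "long": "length", "ambig": "ambiguity",
            "lowcov": "coverage", "dupe": "duplicate",
        }

    def test_empty_input(self, bait):
        retained, report = curate([], bait)
        assert retained == [] and report.input_count == 0 and report.removed_count == 0

    def test_all_valid_passthrough(self, rng, bait):
        recs = [
            ProteinRecord(f"v{i}", bait.sequence[:310] + random_protein(rng, 40))
            for i in range(5)
        ]
        retained, report = curate(recs, bait)
        assert [r.id for r in retained] == [r.id for r in recs]
        assert report.removed_count == 0

    def test_idempotent(self, rng, bait):
        recs = self._fixture(rng, bait)
        once, _ = curate(recs, bait)
        twice, report2 = curate(once, bait)
        assert [(r.id, r.sequence) for r in twice] == [(r.id, r.sequence) for r in once]
        assert report2.removed_count == 0

    def test_order_independent_retained_multiset(self, rng, bait):
        recs = self._fixture(rng, bait)
        base, _ = curate(recs, bait)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        perm, _ = curate(shuffled, bait)
        assert sorted(r.sequence for r in base) == sorted(r.sequence for r in perm)

    def test_funnel_conservation(self, rng, bait):
        recs = self._fixture(rng, bait)
        retained, report = curate(recs, bait)
        assert report.removed_count + len(retained) == len(recs)
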