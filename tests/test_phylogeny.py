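"""Alignment, trimming, NJ trees and form-label propagation."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from rubisco_prospector.clustering import _global_aligner
from rubisco_prospector.phylogeny import (
    MultipleAlignment,
    distance_matrix,
    drop_form_iv,
    nj_tree,
    propagate_forms,
    star_align,
    trim_alignment,
)
from rubisco_prospector.records import FormLabel, ProteinRecord
from rubisco_prospector.synthetic import gen_sequence_family

from conftest import random_protein


class TestStarAlign:
    def test_two_sequences_match_pairwise(self):
        a = ProteinRecord("a", "MKVLATGHWE")
        b = ProteinRecord("b", "MKVLTGHWE")
        msa = star_align([a, b])
        aln = _global_aligner().align(a.sequence, b.sequence)[0]
        assert sorted(msa.rows) == sorted([str(aln[0]), str(aln[1])])

    def test_substring_row_gaps_flank(self):
        recs = [
            ProteinRecord("long1", "MKVLATGH"),
            ProteinRecord("long2", "MKVLATGH"),
            ProteinRecord("short", "VLATG"),
        ]
        msa = star_align(recs)
        short_row = msa.rows[msa.ids.index("short")]
        assert short_row.strip("-") == "VLATG"  # gaps only at the flanks

    def test_degap_recovers_inputs(self, rng):
        recs = [
            ProteinRecord(f"r{i}", random_protein(rng, int(rng.integers(30, 50))))
            for i in range(5)
        ]
        msa = star_align(recs)
        for i, rec in enumerate(recs):
            assert msa.ids[i] == rec.id
            assert msa.degapped(i) == rec.sequence

    def test_single_record_errors(self):
        with pytest.raises(ValueError, match="pass single records through"):
            star_align([ProteinRecord("a", "MKVL")])


class TestTrim:
    def test_gap_free_column_retained_all_gap_removed(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["M-K", "M-L"])
        out = trim_alignment(msa, min_occupancy=0.5)
        assert out.rows == ["MK", "ML"]

    def test_occupancy_exactly_at_bound_removed(self):
        # 20 rows, one column with exactly 1 gap: occupancy 0.95, strict > removes it
        rows = ["MA"] * 19 + ["M-"]
        msa = MultipleAlignment(ids=[f"r{i}" for i in range(20)], rows=rows)
        out = trim_alignment(msa, min_occupancy=0.95)
        assert out.n_columns == 1 and out.rows[0] == "M"

    def test_all_columns_removed_errors(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["M-", "-K"])
        with pytest.raises(ValueError, match="every column"):
            trim_alignment(msa, min_occupancy=0.95)

    def test_row_and_column_order_preserved(self):
        msa = MultipleAlignment(ids=["a", "b", "c"], rows=["MKV", "MK-", "MKI"])
        out = trim_alignment(msa, min_occupancy=0.7)  # col 2 occupancy 2/3
        assert out.ids == ["a", "b", "c"]
        assert out.rows == ["MK", "MK", "MK"]


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["MKVL", "MKVL"])
        assert distance_matrix(msa)["a", "b"] == 0.0

    def test_two_of_ten_comparable_differ(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["ACDEFGHIKL", "ACDEFGHIVV"])
        assert distance_matrix(msa)["a", "b"] == pytest.approx(0.2)

    def test_gapped_columns_ignored(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["MK-L", "MKV-"])
        # comparable columns: positions 0,1 only
        assert distance_matrix(msa)["a", "b"] == 0.0

    def test_no_comparable_columns_names_pair(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["M-", "-K"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            distance_matrix(msa)

    def test_symmetric_random(self, rng):
        rows = ["".join(rng.choice(list("MKVL-"), size=30)) for _ in range(4)]
        rows = [r if r.replace("-", "") else "MKVL" + r[4:] for r in rows]
        msa = MultipleAlignment(ids=list("abcd"), rows=rows)
        dm = distance_matrix(msa)
        assert np.allclose(dm.data, dm.data.T)


def _random_additive_matrix(rng, n_taxa):
    """Distances induced by a random binary tree with random branch lengths."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # build a random tree by sequential attachment; store as parent pointers
    newick_nodes = {i: ids[i] for i in range(3)}
    lengths = {i: rng.uniform(0.05, 0.5) for i in range(3)}
    tree = TreeNode.read(
        [f"({ids[0]}:{lengths[0]:.4f},{ids[1]}:{lengths[1]:.4f},{ids[2]}:{lengths[2]:.4f});"]
    )
    for i in range(3, n_taxa):
        tips = list(tree.tips())
        target = tips[int(rng.integers(len(tips)))]
        old_len = target.length
        split = rng.uniform(0.2, 0.8) * old_len
        parent = target.parent
        inner = TreeNode(length=old_len - split)
        parent.remove(target)
        parent.append(inner)
        target.length = split
        new_tip = TreeNode(name=ids[i], length=float(rng.uniform(0.05, 0.5)))
        inner.append(new_tip)
        inner.append(target)
    dm = tree.tip_tip_distances()
    return DistanceMatrix(dm.data, ids=list(dm.ids))


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("abc"))
        tree = nj_tree(dm)
        dist = tree.tip_tip_distances()
        # three-point formulas: la=(3+4-5)/2=1, lb=(3+5-4)/2=2, lc=(4+5-3)/2=3
        assert dist["a", "b"] == pytest.approx(3)
        assert dist["a", "c"] == pytest.approx(4)
        assert dist["b", "c"] == pytest.approx(5)

    def test_four_taxa_additive_exact(self):
        data = [[0, 0.3, 0.45, 0.45], [0.3, 0, 0.45, 0.45],
                [0.45, 0.45, 0, 0.3], [0.45, 0.45, 0.3, 0]]
        dm = DistanceMatrix(data, ids=list("abcd"))
        tree = nj_tree(dm)
        dist = tree.tip_tip_distances()
        for i in "abcd":
            for j in "abcd":
                if i != j:
                    assert dist[i, j] == pytest.approx(dm[i, j])

    def test_ultrametric_pairs_closest_leaves(self):
        dm = DistanceMatrix(
            [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.5, 0.5],
             [0.5, 0.5, 0, 0.2], [0.5, 0.5, 0.2, 0]],
            ids=list("abcd"),
        )
        tree = nj_tree(dm)
        parent_a = next(t for t in tree.tips() if t.name == "a").parent
        assert {t.name for t in parent_a.tips()} == {"a", "b"}

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_exact_on_random_additive_matrices(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(5):
            dm = _random_additive_matrix(rng, n_taxa)
            dist = nj_tree(dm).tip_tip_distances()
            for i in dm.ids:
                for j in dm.ids:
                    if i != j:
                        assert dist[i, j] == pytest.approx(dm[i, j], abs=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


@pytest.fixture
def labeled_tree():
    # ((a,b),(c,d),(e,f)) unrooted-ish star of cherries
    return TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);"])


class TestPropagateForms:
    def test_clade_inherits_single_curated_label(self, labeled_tree):
        labels = propagate_forms(labeled_tree, {"a": FormLabel.II})
        assert labels["b"] is FormLabel.II

    def test_conflicting_labels_give_unknown(self, labeled_tree):
        labels = propagate_forms(
            labeled_tree, {"a": FormLabel.II, "b": FormLabel.IIIb}
        )
        # smallest informative clade for c contains both curated labels
        assert labels["c"] is FormLabel.unknown

    def test_curated_leaf_keeps_label(self, labeled_tree):
        labels = propagate_forms(
            labeled_tree, {"a": FormLabel.II, "b": FormLabel.IV}
        )
        assert labels["a"] is FormLabel.II and labels["b"] is FormLabel.IV

    def test_invariant_to_rerooting(self, labeled_tree):
        curated = {"a": FormLabel.II, "c": FormLabel.IIIb}
        base = propagate_forms(labeled_tree, curated)
        rerooted = labeled_tree.root_at(
            next(t for t in labeled_tree.tips() if t.name == "e").parent
        )
        assert propagate_forms(rerooted, curated) == base

    def test_invariant_to_leaf_order(self):
        t1 = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);"])
        t2 = TreeNode.read(["((f:1,e:1):1,(d:1,c:1):1,(b:1,a:1):1);"])
        curated = {"a": FormLabel.II, "d": FormLabel.Ia}
        assert propagate_forms(t1, curated) == propagate_forms(t2, curated)

    def test_no_curated_leaf_errors(self, labeled_tree):
        with pytest.raises(ValueError, match="no curated leaf"):
            propagate_forms(labeled_tree, {"zzz": FormLabel.II})


class TestDropFormIV:
    def _recs(self, n):
        return [ProteinRecord(f"r{i}", "MKVLATGH") for i in range(n)]

    def test_two_of_ten_dropped(self):
        recs = self._recs(10)
        labels = {r.id: FormLabel.II for r in recs}
        labels["r3"] = labels["r7"] = FormLabel.IV
        assert len(drop_form_iv(recs, labels)) == 8

    def test_unknown_retained(self):
        recs = self._recs(2)
        labels = {"r0": FormLabel.unknown, "r1": FormLabel.IV}
        assert [r.id for r in drop_form_iv(recs, labels)] == ["r0"]

    def test_no_iv_unchanged(self):
        recs = self._recs(3)
        labels = {r.id: FormLabel.Ib for r in recs}
        assert drop_form_iv(recs, labels) == recs

    def test_all_iv_empty_with_warning(self):
        recs = self._recs(2)
        labels = {r.id: FormLabel.IV for r in recs}
        with pytest.warns(UserWarning, match="form IV"):
            assert drop_form_iv(recs, labels) == []


def test_pipeline_cluster_label_inheritance():
    """Labels assigned at clustering resolution attach to every member."""
    from rubisco_prospector.clustering import ClusterConfig, greedy_cluster
    from rubisco_prospector.phylogeny import inherit_cluster_labels

    recs, curated, manifest = gen_sequence_family(
        n_families=3, members_per_family=4, length=150, seed=9
    )
    clusters = greedy_cluster(recs, ClusterConfig(threshold=0.70))
    centroid_labels = {}
    for cluster in clusters:
        for member in cluster.member_ids:
            if member in curated:
                centroid_labels[cluster.centroid_id] = curated[member]
    member_labels = inherit_cluster_labels(clusters, centroid_labels)
    membership = manifest.truth["membership"]
    forms = manifest.truth["family_forms"]
    for rid, label in member_labels.items():
        assert label.value == forms[membership[rid]]
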