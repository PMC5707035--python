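"""Pearson-distance Ward clustering: distances, linkage, cuts, export."""

import numpy as np
import pandas as pd
import pytest

from evpanel import (
    AbundanceMatrix,
    cut_tree,
    log2_transform,
    pearson_distance_matrix,
    to_newick,
    ward_linkage,
)


def wardD_oracle(dist: np.ndarray):
    """Independent agglomerative Ward implementation: the Lance-Williams
    recurrence applied directly to the given dissimilarities (no squaring).

    Returns the merge list as (frozenset of leaf indices, height).
    """
    n = dist.shape[0]
    active = list(range(n))
    members = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}

    def get(a, b):
        return d[(a, b) if a < b else (b, a)]

    merges = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((get(a, b), a, b) for i, a in enumerate(active) for b in active[i + 1 :]),
        )
        h, a, b = best
        merged = members[a] | members[b]
        merges.append((merged, h))
        for c in active:
            if c in (a, b):
                continue
            na, nb, nc = sizes[a], sizes[b], sizes[c]
            new = ((na + nc) * get(a, c) + (nb + nc) * get(b, c) - nc * h) / (na + nb + nc)
            d[(min(c, next_id), max(c, next_id))] = new
        members[next_id] = merged
        sizes[next_id] = sizes[a] + sizes[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return merges


def merges_from_dendrogram(dend):
    """(leaf index set, height) per merge, from the scipy-layout matrix."""
    n = dend.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for j, (a, b, h, _s) in enumerate(dend.merges):
        merged = members[int(a)] | members[int(b)]
        members[n + j] = merged
        out.append((merged, float(h)))
    return out


class TestPearsonDistance:
    def test_identical_and_opposite_profiles(self):
        data = pd.DataFrame(
            {"s1": [1.0, 2, 3], "s2": [2.0, 4, 6], "s3": [3.0, 2, 1]},
            index=["a", "b", "c"],
        )
        m = AbundanceMatrix(data, {"s1": "case", "s2": "case", "s3": "ctrl"})
        dist = pearson_distance_matrix(m, axis="samples")
        assert dist.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-12)  # r = 1
        assert dist.loc["s1", "s3"] == pytest.approx(2.0, abs=1e-12)  # r = -1
        assert (np.diag(dist) == 0).all()

    def test_hand_computed_pearson_value(self):
        data = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 4]}, index=["g1", "g2", "g3"])
        m = AbundanceMatrix(data, {"x": "case", "y": "ctrl"})
        dist = pearson_distance_matrix(m, axis="samples")
        # r((1,2,3),(1,2,4)) = 0.981981..., d = 0.018019
        assert dist.loc["x", "y"] == pytest.approx(0.01802, abs=5e-6)

    def test_bounds_on_random_data(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 8)), columns=[f"s{i}" for i in range(8)])
        m = AbundanceMatrix(
            data - data.min().min(), {f"s{i}": "case" if i < 4 else "ctrl" for i in range(8)}
        )
        dist = pearson_distance_matrix(m, axis="samples").to_numpy()
        assert ((dist >= 0) & (dist <= 2)).all()

    def test_zero_variance_profile_reported(self):
        data = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 6.0], "s3": [1.0, 7.0]},
                            index=["flat", "ok"])
        m = AbundanceMatrix(data, {"s1": "case", "s2": "ctrl", "s3": "ctrl"})
        with pytest.raises(ValueError, match="flat"):
            pearson_distance_matrix(m, axis="genes")
        with pytest.raises(ValueError, match="fewer than 2"):
            # dropping the flat gene leaves a single profile
            pearson_distance_matrix(m, axis="genes", on_zero_variance="drop")


class TestWardLinkage:
    FIXTURE = np.array(
        [
            [0.0, 0.10, 0.90, 1.00],
            [0.10, 0.0, 0.80, 0.95],
            [0.90, 0.80, 0.0, 0.20],
            [1.00, 0.95, 0.20, 0.0],
        ]
    )

    def test_two_items_merge_at_their_distance(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["a", "b"], columns=["a", "b"])
        dend = ward_linkage(d)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.3)

    def test_four_item_tree_matches_independent_ward(self):
        labels = list("ABCD")
        d = pd.DataFrame(self.FIXTURE, index=labels, columns=labels)
        dend = ward_linkage(d)
        got = merges_from_dendrogram(dend)
        want = wardD_oracle(self.FIXTURE)
        assert [m for m, _ in got] == [m for m, _ in want]
        for (_, h1), (_, h2) in zip(got, want):
            assert h1 == pytest.approx(h2, rel=1e-9)

    def test_random_tables_match_independent_ward(self, rng):
        for _ in range(10):
            profiles = rng.normal(size=(6, 12))
            corr = np.corrcoef(profiles)
            dist = 1 - corr
            np.fill_diagonal(dist, 0.0)
            labels = [f"i{k}" for k in range(6)]
            dend = ward_linkage(pd.DataFrame(dist, index=labels, columns=labels))
            got = merges_from_dendrogram(dend)
            want = wardD_oracle(dist)
            assert [m for m, _ in got] == [m for m, _ in want]
            for (_, h1), (_, h2) in zip(got, want):
                assert h1 == pytest.approx(h2, rel=1e-9)

    def test_heights_are_monotone(self, rng):
        profiles = rng.normal(size=(10, 20))
        dist = 1 - np.corrcoef(profiles)
        np.fill_diagonal(dist, 0.0)
        labels = [f"i{k}" for k in range(10)]
        dend = ward_linkage(pd.DataFrame(dist, index=labels, columns=labels))
        heights = dend.merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_asymmetric_table_rejected(self):
        d = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            ward_linkage(d)


class TestCutAndExport:
    def _dend(self):
        labels = list("ABCD")
        d = pd.DataFrame(TestWardLinkage.FIXTURE, index=labels, columns=labels)
        return ward_linkage(d)

    def test_k_extremes(self):
        dend = self._dend()
        assert set(cut_tree(dend, 1).values()) == {1}
        assert sorted(cut_tree(dend, 4).values()) == [1, 2, 3, 4]
        with pytest.raises(ValueError):
            cut_tree(dend, 5)

    def test_two_cut_matches_hand_partition(self):
        cut = cut_tree(self._dend(), 2)
        assert cut["A"] == cut["B"]
        assert cut["C"] == cut["D"]
        assert cut["A"] != cut["C"]

    def test_newick_is_parseable_and_complete(self):
        import dendropy

        newick = to_newick(self._dend())
        tree = dendropy.Tree.get(data=newick, schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set("ABCD")


def test_sample_clustering_separates_strong_groups(rng):
    """With a big planted shift in half the genes, the 2-cut of the sample
    tree reproduces the case/control split."""
    n_genes, n_case, n_ctrl = 60, 6, 6
    base = rng.normal(8, 1.5, n_genes)
    vals = base[:, None] + rng.normal(0, 0.5, (n_genes, n_case + n_ctrl))
    vals[: n_genes // 2, :n_case] += 3.0
    data = pd.DataFrame(
        np.exp2(vals), index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_case + n_ctrl)],
    )
    m = AbundanceMatrix(data, {f"s{i}": "case" if i < n_case else "ctrl"
                               for i in range(n_case + n_ctrl)})
    dend = ward_linkage(pearson_distance_matrix(log2_transform(m), axis="samples"))
    cut = cut_tree(dend, 2)
    case_labels = {cut[s] for s in m.case_samples}
    ctrl_labels = {cut[s] for s in m.ctrl_samples}
    assert len(case_labels) == 1 and len(ctrl_labels) == 1 and case_labels != ctrl_labels
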