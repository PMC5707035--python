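"""Abundance matrix I/O, transforms, partitioning, and NSAF."""

import numpy as np
import pandas as pd
import pytest

from evpanel import (
    AbundanceMatrix,
    CohortConfig,
    collapse_by_gene,
    compute_nsaf,
    generate_cohort,
    log2_transform,
    partition_by_abundance,
    read_abundance_matrix,
    write_abundance_matrix,
)
from evpanel.matrix import MatrixFormatError


class TestIO:
    def test_round_trip_small_fixture(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_abundance_matrix(tiny_matrix, path)
        back = read_abundance_matrix(path)
        assert back.data.shape == (3, 4)
        pd.testing.assert_frame_equal(back.data, tiny_matrix.data)
        assert dict(back.groups) == dict(tiny_matrix.groups)

    def test_round_trip_generated_cohort(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_proteins=40, n_diff=5, n_exclusive=2, seed=4))
        path = tmp_path / "cohort.tsv"
        write_abundance_matrix(cohort.matrix, path)
        back = read_abundance_matrix(path)
        np.testing.assert_allclose(
            back.data.to_numpy(), cohort.matrix.data.to_numpy(), rtol=1e-9
        )

    def test_negative_value_names_the_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ngroup\tcase\tctrl\nG1\t1\t-5\n")
        with pytest.raises(MatrixFormatError, match="G1.*s2"):
            read_abundance_matrix(path)

    def test_unknown_group_label_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ngroup\tcase\ttumor\nG1\t1\t2\n")
        with pytest.raises(MatrixFormatError, match="tumor"):
            read_abundance_matrix(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ngroup\tcase\tctrl\nG1\t1\t2\nG1\t3\t4\n")
        with pytest.raises(MatrixFormatError, match="duplicate"):
            read_abundance_matrix(path)


class TestCollapse:
    def test_two_accessions_same_gene_sum(self):
        data = pd.DataFrame({"s1": [3.0, 5.0], "s2": [1.0, 1.0]}, index=["P1", "P2"])
        m = AbundanceMatrix(data, {"s1": "case", "s2": "ctrl"})
        out = collapse_by_gene(m, {"P1": "G", "P2": "G"})
        assert out.data.loc["G", "s1"] == 8.0
        assert out.data.shape == (1, 2)

    def test_identity_mapping_unchanged(self, tiny_matrix):
        out = collapse_by_gene(tiny_matrix, {g: g for g in tiny_matrix.genes})
        pd.testing.assert_frame_equal(
            out.data.sort_index(), tiny_matrix.data.sort_index()
        )

    def test_matches_brute_force_group_and_sum(self, rng):
        ids = [f"P{i}" for i in range(10)]
        mapping = {i: f"G{rng.integers(0, 4)}" for i in ids}
        data = pd.DataFrame(
            rng.integers(0, 50, size=(10, 3)).astype(float),
            index=ids,
            columns=["a", "b", "c"],
        )
        m = AbundanceMatrix(data, {"a": "case", "b": "ctrl", "c": "ctrl"})
        out = collapse_by_gene(m, mapping)
        # oracle: explicit accumulation
        expected: dict[str, np.ndarray] = {}
        for pid in ids:
            expected.setdefault(mapping[pid], np.zeros(3))
            expected[mapping[pid]] += data.loc[pid].to_numpy()
        for gene, vals in expected.items():
            np.testing.assert_allclose(out.data.loc[gene].to_numpy(), vals)

    def test_collapse_on_log2_scale_rejected(self, tiny_matrix):
        logm = log2_transform(tiny_matrix)
        with pytest.raises(ValueError, match="linear"):
            collapse_by_gene(logm, {g: g for g in logm.genes})

    def test_missing_mapping_entry_rejected(self, tiny_matrix):
        with pytest.raises(KeyError, match="B"):
            collapse_by_gene(tiny_matrix, {"A": "A", "C": "C"})


class TestLog2:
    def test_zero_maps_to_zero_and_4095_to_12(self):
        data = pd.DataFrame({"s1": [0.0], "s2": [4095.0]}, index=["G"])
        m = AbundanceMatrix(data, {"s1": "case", "s2": "ctrl"})
        out = log2_transform(m)
        assert out.scale == "log2"
        assert out.data.loc["G", "s1"] == 0.0
        assert out.data.loc["G", "s2"] == pytest.approx(12.0)

    def test_inverse_recovers_input(self, rng):
        data = pd.DataFrame(rng.uniform(0, 1e5, size=(6, 4)))
        data.columns = [f"s{i}" for i in range(4)]
        m = AbundanceMatrix(data, {f"s{i}": "case" if i < 2 else "ctrl" for i in range(4)})
        out = log2_transform(m, offset=1.0)
        np.testing.assert_allclose(
            np.exp2(out.data.to_numpy()) - 1.0, data.to_numpy(), atol=1e-9, rtol=1e-12
        )

    def test_double_transform_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="already"):
            log2_transform(log2_transform(tiny_matrix))


class TestPartition:
    def _log2_matrix(self, means):
        data = pd.DataFrame(
            {f"s{j}": list(means) for j in range(2)},
            index=[f"G{i}" for i in range(len(means))],
        )
        return AbundanceMatrix(data, {"s0": "case", "s1": "ctrl"}, scale="log2")

    def test_boundary_exactly_at_cutoff_is_low(self):
        part = partition_by_abundance(self._log2_matrix([12.0, 12.000001, 11.9]))
        assert part.high == {"G1"}
        assert part.low == {"G0", "G2"}

    def test_exhaustive_and_exclusive(self, rng):
        means = rng.uniform(5, 20, size=30)
        part = partition_by_abundance(self._log2_matrix(means))
        assert part.high | part.low == {f"G{i}" for i in range(30)}
        assert not part.high & part.low

    def test_planted_high_mode_count_recovered(self):
        # tight modes well separated by the cutoff: the partition must
        # recover exactly the planted high-abundance group
        cfg = CohortConfig(n_proteins=200, frac_high_abundance=0.2, sd=0.3,
                           n_diff=0, n_exclusive=0, seed=11)
        cohort = generate_cohort(cfg)
        part = partition_by_abundance(log2_transform(cohort.matrix))
        assert part.n_high == 40
        assert part.n_low == 160

    def test_linear_scale_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="log2"):
            partition_by_abundance(tiny_matrix)


class TestNsaf:
    def test_single_gene_normalizes_to_one(self):
        data = pd.DataFrame({"s1": [7.0]}, index=["G"])
        m = AbundanceMatrix(data, {"s1": "case"})
        out = compute_nsaf(m, {"G": 350})
        assert out.values.loc["G", "s1"] == 1.0

    def test_hand_computed_fractions(self):
        data = pd.DataFrame({"s1": [10.0, 20.0], "s2": [30.0, 10.0]}, index=["A", "B"])
        m = AbundanceMatrix(data, {"s1": "case", "s2": "ctrl"})
        out = compute_nsaf(m, {"A": 100, "B": 200})
        # s1: (10/100, 20/200) -> (0.5, 0.5)
        np.testing.assert_allclose(out.values["s1"], [0.5, 0.5])
        out2 = compute_nsaf(m, {"A": 100, "B": 100})
        # s2: (30/100, 10/100) -> (0.75, 0.25)
        np.testing.assert_allclose(out2.values["s2"], [0.75, 0.25])

    def test_columns_sum_to_one(self, rng):
        data = pd.DataFrame(
            rng.integers(0, 30, size=(20, 5)).astype(float),
            index=[f"G{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(5)],
        )
        m = AbundanceMatrix(data, {f"s{i}": "case" if i < 3 else "ctrl" for i in range(5)})
        lengths = {f"G{i}": 100 + 13 * i for i in range(20)}
        out = compute_nsaf(m, lengths)
        np.testing.assert_allclose(out.values.sum(axis=0), 1.0, atol=1e-9)

    def test_missing_length_for_detected_gene_rejected(self, tiny_matrix):
        with pytest.raises(KeyError, match="C"):
            compute_nsaf(tiny_matrix, {"A": 100, "B": 100})

    def test_no_lengths_falls_back_to_spectral_fraction(self, tiny_matrix):
        out = compute_nsaf(tiny_matrix)
        assert not out.length_normalized
        np.testing.assert_allclose(out.values.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_sample_warns_and_zeroes(self):
        data = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, index=["A", "B"])
        m = AbundanceMatrix(data, {"s1": "case", "s2": "ctrl"})
        with pytest.warns(UserWarning, match="all-zero"):
            out = compute_nsaf(m, {"A": 10, "B": 10})
        assert (out.values["s2"] == 0).all()
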