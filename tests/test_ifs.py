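"""Regional/inter-system IFS sums, conservation laws and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gcflow.granger import EffConnMatrix
from gcflow.errors import GroupSizeError
from gcflow.ifs import (
    bh_fdr,
    compare_correlations,
    group_compare,
    intersystem_group_tests,
    intersystem_ifs,
    intra_inter_correlation,
    pearson,
    regional_ifs,
)
from gcflow.types import NetworkPartition


def toy_ecm(toy_partition):
    """a,b in X=MTL; c,d in Y=DAN with F(a->b)=2, F(c->a)=1, F(b->d)=3."""
    F = np.zeros((4, 4))
    F[0, 1] = 2.0
    F[2, 0] = 1.0
    F[1, 3] = 3.0
    return EffConnMatrix("toy", F, tuple(toy_partition.roi_labels), 1)


def random_ecm(seed, partition):
    r = np.random.default_rng(seed)
    F = np.abs(r.normal(size=(partition.n_rois,) * 2))
    np.fill_diagonal(F, 0.0)
    return EffConnMatrix(f"s{seed}", F, tuple(partition.roi_labels), 1)


class TestRegionalIFS:
    def test_zero_matrix_all_zero(self, toy_partition):
        ecm = EffConnMatrix("z", np.zeros((4, 4)), tuple(toy_partition.roi_labels), 1)
        table = regional_ifs(ecm, toy_partition)
        assert (table[list(table.columns[3:])] == 0).all().all()

    def test_toy_edge_enumeration(self, toy_partition):
        table = regional_ifs(toy_ecm(toy_partition), toy_partition).set_index("roi")
        assert table.loc["b", "intra_in"] == 2.0
        assert table.loc["a", "intra_out"] == 2.0
        assert table.loc["a", "inter_in"] == 1.0
        assert table.loc["b", "inter_out"] == 3.0
        assert table.loc["b", "inter_in_out"] == 3.0

    def test_sum_identities_exact(self, partition):
        table = regional_ifs(random_ecm(0, partition), partition)
        np.testing.assert_array_equal(
            table["intra_in_out"], table["intra_in"] + table["intra_out"]
        )
        np.testing.assert_array_equal(
            table["inter_in_out"], table["inter_in"] + table["inter_out"]
        )
        np.testing.assert_array_equal(
            table["intra_inter_in"], table["intra_in"] + table["inter_in"]
        )
        np.testing.assert_array_equal(
            table["intra_inter_out"], table["intra_out"] + table["inter_out"]
        )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_conservation_per_network(self, seed):
        partition = NetworkPartition(
            tuple("abcdefg"),
            dict(zip("abcdefg", ["MTL", "MTL", "DM", "DM", "DM", "DAN", "DAN"])),
        )
        table = regional_ifs(random_ecm(seed, partition), partition)
        for net, sub in table.groupby("network"):
            assert abs(sub["intra_in"].sum() - sub["intra_out"].sum()) < 1e-10


class TestIntersystemIFS:
    def test_zero_matrix(self, partition):
        ecm = EffConnMatrix("z", np.zeros((52, 52)), tuple(partition.roi_labels), 1)
        vals = intersystem_ifs(ecm, partition)
        assert len(vals) == 30
        assert all(v == 0 for v in vals.values())

    def test_toy_values(self, toy_partition):
        vals = intersystem_ifs(toy_ecm(toy_partition), toy_partition)
        assert vals[("MTL", "DAN")] == 3.0
        assert vals[("DAN", "MTL")] == 1.0

    def test_global_conservation(self, partition):
        ecm = random_ecm(3, partition)
        table = regional_ifs(ecm, partition)
        inter = intersystem_ifs(ecm, partition)
        total = sum(inter.values())
        assert abs(table["inter_in"].sum() - table["inter_out"].sum()) < 1e-9
        assert abs(table["inter_in"].sum() - total) < 1e-9


class TestGroupCompare:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        res = group_compare(g, g)
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_direct_formula_and_scipy(self, rng):
        a = rng.normal(loc=1.0, size=27)
        b = rng.normal(loc=0.0, size=24)
        res = group_compare(a, b)
        # independent direct pooled-variance computation
        sp2 = ((26 * a.var(ddof=1)) + (23 * b.var(ddof=1))) / 49
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 27 + 1 / 24))
        assert abs(res.t - t) < 1e-10
        assert res.df == 49
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert abs(res.t - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10

    def test_degenerate_constant_groups_flagged(self):
        res = group_compare(np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        assert res.infinite and np.isinf(res.t) and res.t > 0

    def test_too_small(self):
        with pytest.raises(GroupSizeError):
            group_compare(np.array([1.0]), np.array([1.0, 2.0]))


class TestBhFdr:
    def test_step_up_hand_example(self):
        p = np.array([0.001, 0.013, 0.04, 0.5, 0.9])
        mask, threshold = bh_fdr(p, q=0.05)
        assert mask.tolist() == [True, True, False, False, False]
        assert threshold == 0.013

    def test_all_zero_all_significant(self):
        mask, threshold = bh_fdr(np.zeros(4), q=0.05)
        assert mask.all() and threshold == 0.0

    def test_null_calibration(self):
        """Realised FDR under a global null stays at/below q."""
        q = 0.05
        false_rates = []
        r = np.random.default_rng(8)
        for _ in range(1000):
            mask, _ = bh_fdr(r.uniform(size=30), q=q)
            false_rates.append(mask.any())
        assert np.mean(false_rates) <= q + 0.02

    def test_threshold_reproduces_mask(self, rng):
        p = rng.uniform(size=30) ** 2
        mask, threshold = bh_fdr(p, q=0.05)
        np.testing.assert_array_equal(mask, p <= threshold if mask.any() else mask)


class TestCorrelations:
    def test_affine_relation_r1(self):
        table = pd.DataFrame(
            {
                "group": ["AD"] * 5,
                "roi": ["a"] * 5,
                "intra_in_out": [1.0, 2, 3, 4, 5],
                "inter_in_out": [2.0, 4, 6, 8, 10],
            }
        )
        res = intra_inter_correlation(table, ["a"], "AD")["a"]
        assert res.r == pytest.approx(1.0)

    def test_formula_oracle(self):
        x = np.array([0.3, 1.2, -0.5, 2.2, 0.9, -1.4])
        y = np.array([1.0, 0.2, 0.4, -0.7, 1.9, 0.3])
        res = pearson(x, y)
        ref = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert abs(res.r - ref) < 1e-12
        assert res.fisher_z == pytest.approx(np.arctanh(ref), abs=1e-12)

    def test_null_band(self):
        big = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            res = pearson(r.normal(size=24), r.normal(size=24))
            big += abs(res.r) >= 0.5
        assert big <= 10

    def test_too_few_subjects(self):
        table = pd.DataFrame(
            {"group": ["AD"] * 2, "roi": ["a"] * 2, "intra_in_out": [1.0, 2], "inter_in_out": [1.0, 2]}
        )
        with pytest.raises(GroupSizeError):
            intra_inter_correlation(table, ["a"], "AD")


class TestCompareCorrelations:
    def test_equal_r_zero(self):
        z, p = compare_correlations(0.4, 20, 0.4, 30)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_example(self):
        z, _ = compare_correlations(0.95, 27, 0.5, 24)
        expected = (np.arctanh(0.95) - np.arctanh(0.5)) / np.sqrt(1 / 24 + 1 / 21)
        assert z == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(4.29, abs=0.01)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 20, 0.5, 20)

    def test_null_calibration_standard_normal(self):
        """Equal-rho groups: Z follows N(0,1) (KS over 500 replicates)."""
        rho = 0.5
        r = np.random.default_rng(11)
        cov = np.array([[1, rho], [rho, 1]])
        zs = []
        for _ in range(500):
            a = r.multivariate_normal([0, 0], cov, size=27)
            b = r.multivariate_normal([0, 0], cov, size=24)
            r1 = np.corrcoef(a.T)[0, 1]
            r2 = np.corrcoef(b.T)[0, 1]
            zs.append(compare_correlations(r1, 27, r2, 24)[0])
        assert stats.kstest(zs, "norm").pvalue > 0.05


def test_intersystem_group_tests_table(partition, rng):
    rows = []
    for s in range(8):
        ecm = random_ecm(s, partition)
        group = "NC" if s < 4 else "AD"
        vals = intersystem_ifs(ecm, partition)
        for (src, tgt), v in vals.items():
            rows.append(
                {"subject_id": f"s{s}", "group": group, "source": src, "target": tgt, "ifs": v}
            )
    out = intersystem_group_tests(pd.DataFrame(rows))
    assert len(out) == 30
    assert {"t", "df", "p", "significant_fdr"} <= set(out.columns)
    assert (out["df"] == 6).all()
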