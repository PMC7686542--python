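"""Full/partial FC strength and the FPCNA regulatory-effect index."""

import numpy as np
import pytest
from scipy import stats

from gcflow.errors import ConstantSeriesError, GroupSizeError
from gcflow.regulation import (
    DEFAULT_BLOCKS,
    full_fc_strength,
    partial_fc_strength,
    regulation_table,
    regulation_tests,
)
from gcflow.synthetic import simulate_common_driver_cohort
from tests.conftest import make_record


class TestFullStrength:
    def test_independent_noise_small(self, partition, rng):
        rec = make_record(rng.normal(size=(5000, 52)))
        strength = full_fc_strength(rec, partition, "within-MTL")
        # 15 unordered pairs, each |z| <~ 0.05 at T=5000
        assert abs(strength) < 15 * 0.05

    def test_equicorrelated_trio_closed_form(self, partition, rng):
        T = 20_000
        common = rng.normal(size=T)
        data = rng.normal(size=(T, 52)) * 0.4
        mtl = partition.indices_of("MTL")[:3]
        for i in mtl:
            data[:, i] = common + rng.normal(size=T) * 0.4
        # 3 equicorrelated pairs dominate the 15-pair MTL block sum
        strength = full_fc_strength(make_record(data), partition, "within-MTL")
        rho = 1.0 / 1.16  # var(common) / var(common + 0.4 * noise)
        expected = 3 * np.arctanh(rho)
        assert abs(strength - expected) < 0.15 * expected

    def test_orthogonal_pair_zero(self, toy_partition):
        T = 100
        t = np.arange(T)
        data = np.random.default_rng(1).normal(size=(T, 4))
        data[:, 0] = np.sin(2 * np.pi * t / 20)  # a and b span quadrature phases:
        data[:, 1] = np.cos(2 * np.pi * t / 20)  # exactly zero correlation
        strength = full_fc_strength(
            make_record(data), toy_partition, "within-MTL", {"within-MTL": ("MTL",)}
        )
        assert abs(strength) < 1e-12

    def test_constant_series_rejected(self, partition, rng):
        data = rng.normal(size=(50, 52))
        data[:, partition.indices_of("Core")[0]] = 1.0
        with pytest.raises(ConstantSeriesError):
            full_fc_strength(make_record(data), partition, "within-Core")


class TestPartialStrength:
    def test_empty_removed_network_identity(self, toy_partition, rng):
        rec = make_record(rng.normal(size=(60, 4)))
        blocks = {"within-MTL": ("MTL",)}
        full = full_fc_strength(rec, toy_partition, "within-MTL", blocks)
        part = partial_fc_strength(rec, toy_partition, "within-MTL", "FPCNA", blocks)
        assert part == pytest.approx(full, abs=1e-10)

    def test_orthogonal_fpcna_no_change(self, partition, rng):
        T = 300
        data = rng.normal(size=(T, 52))
        # make FPCNA columns exactly orthogonal to the Core block columns
        fp = partition.indices_of("FPCNA")
        core = partition.indices_of("Core")
        block = data[:, core] - data[:, core].mean(0)
        q, _ = np.linalg.qr(np.column_stack([np.ones(T), block]))
        for c in fp:
            col = data[:, c]
            data[:, c] = col - q @ (q.T @ col)
        rec = make_record(data)
        full = full_fc_strength(rec, partition, "within-Core")
        part = partial_fc_strength(rec, partition, "within-Core")
        assert abs(part - full) < 1e-8

    def test_common_driver_closed_form(self, partition):
        """x = d + e1, y = d + e2 with unit variances: full r ~ 0.5, partial ~ 0."""
        records = simulate_common_driver_cohort(
            partition, n=5, driver_sd=1.0, T=20_000, seed=0, driven_networks=("Core",)
        )
        effects = []
        for rec in records:
            full = full_fc_strength(rec, partition, "within-Core")
            part = partial_fc_strength(rec, partition, "within-Core")
            n_pairs = 9 * 8 // 2
            effects.append((full - part) / n_pairs)
        expected = np.arctanh(0.5)
        assert np.mean(effects) == pytest.approx(expected, rel=0.05)

    def test_precision_matrix_oracle(self, partition, rng):
        """Residual correlation equals the partial correlation computed from
        the inverse covariance of (pair + removed set)."""
        T = 400
        data = rng.normal(size=(T, 52))
        # add shared structure so partial != full
        fp = partition.indices_of("FPCNA")
        core = partition.indices_of("Core")
        data[:, core[:4]] += data[:, fp[:2]].sum(1, keepdims=True) * 0.7
        rec = make_record(data)
        i, j = int(core[0]), int(core[1])
        blocks = {"pair": ("Core",)}
        # residualise and correlate just the pair
        from gcflow.regulation import _residualise

        resid = _residualise(data, fp, [i, j])
        r_resid = np.corrcoef(resid.T)[0, 1]
        cols = [i, j] + fp.tolist()
        cov = np.cov(data[:, cols].T, ddof=1)
        prec = np.linalg.inv(cov)
        r_prec = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert abs(r_resid - r_prec) < 1e-8

    def test_scale_invariance(self, partition, rng):
        data = rng.normal(size=(200, 52))
        rec = make_record(data)
        scaled = make_record(data * rng.uniform(0.5, 20.0, size=52))
        for block in DEFAULT_BLOCKS:
            a_full = full_fc_strength(rec, partition, block)
            b_full = full_fc_strength(scaled, partition, block)
            assert abs(a_full - b_full) < 1e-8
            a = a_full - partial_fc_strength(rec, partition, block)
            b = b_full - partial_fc_strength(scaled, partition, block)
            assert abs(a - b) < 1e-8

    def test_rank_deficient_regressors_warn(self, partition, rng):
        data = rng.normal(size=(120, 52))
        fp = partition.indices_of("FPCNA")
        data[:, fp[1]] = 2.0 * data[:, fp[0]]  # dependent FPCNA column
        rec = make_record(data)
        with pytest.warns(RuntimeWarning, match="dependent"):
            partial_fc_strength(rec, partition, "within-Core")


class TestRegulationTests:
    def _cohort(self, partition, driver_nc, driver_ad, seed=0, n=5, T=150):
        nc = simulate_common_driver_cohort(partition, n, driver_nc, T, seed=seed, group="NC")
        ad = simulate_common_driver_cohort(partition, n, driver_ad, T, seed=seed + 1, group="AD")
        return nc + ad

    def test_partial_equals_full_gives_zero_paired_t(self, toy_partition, rng):
        import pandas as pd

        table = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(6)],
                "group": ["NC"] * 3 + ["AD"] * 3,
                "block": ["b"] * 6,
                "full": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
                "partial": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
            }
        )
        table["effect"] = table["full"] - table["partial"]
        res = regulation_tests(table)[0]
        assert np.isnan(res.paired_t_nc) or res.paired_t_nc == 0.0

    def test_paired_t_equals_one_sample_t_of_differences(self, partition):
        records = self._cohort(partition, 1.0, 0.5)
        table = regulation_table(records, partition)
        res = next(r for r in regulation_tests(table) if r.block == "within-Core")
        sub = table[(table.block == "within-Core") & (table.group == "NC")]
        ref = stats.ttest_1samp(sub["full"] - sub["partial"], 0.0)
        assert res.paired_t_nc == pytest.approx(ref.statistic, abs=1e-12)

    def test_group_contrast_detected(self, partition):
        """A stronger common driver in AD shows as a larger regulatory effect."""
        detections = 0
        for seed in range(10):
            records = self._cohort(partition, 0.3, 1.2, seed=100 + 2 * seed, n=8)
            table = regulation_table(records, partition)
            res = next(r for r in regulation_tests(table) if r.block == "within-Core")
            detections += (res.between.p < 0.05) and (res.between.mean2 > res.between.mean1)
        assert detections >= 7

    def test_effect_monotone_in_driver_variance(self, partition):
        means = []
        for sd in (0.0, 0.7, 1.0, 1.4):
            effs = []
            for seed in range(20):
                recs = simulate_common_driver_cohort(partition, 2, sd, 150, seed=seed)
                tab = regulation_table(recs, partition)
                effs.append(tab[tab.block == "within-Core"]["effect"].mean())
            means.append(np.mean(effs))
        assert means == sorted(means)

    def test_small_group_rejected(self, partition):
        records = simulate_common_driver_cohort(partition, 1, 1.0, 100, seed=0, group="NC")
        records += simulate_common_driver_cohort(partition, 2, 1.0, 100, seed=1, group="AD")
        table = regulation_table(records, partition)
        with pytest.raises(GroupSizeError):
            regulation_tests(table)
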