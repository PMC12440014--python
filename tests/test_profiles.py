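"""Depth profiles, normalisation and repeated-measures statistics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from laminalpha import profiles as pr
from laminalpha.laminar import ColumnSet, DepthMap


def _toy_grid(col_betas):
    """Columns along x, depths along z; col_betas[c][d] = list of betas."""
    n_cols = len(col_betas)
    nd = 6
    max_n = max(len(v) for c in col_betas for v in c)
    shape = (n_cols, max_n, nd)
    beta = np.full(shape, np.nan)
    labels = -np.ones(shape, dtype=int)
    bins = np.zeros(shape, dtype=int)
    for c, depths_list in enumerate(col_betas):
        for d, vals in enumerate(depths_list):
            for i, b in enumerate(vals):
                beta[c, i, d] = b
                labels[c, i, d] = c
                bins[c, i, d] = d + 1
    cols = ColumnSet(labels=labels, n_columns=n_cols, seeds=np.zeros((n_cols, 3)))
    depths = DepthMap(bin=bins, frac=np.where(bins > 0, (bins - 0.5) / 6, np.nan))
    retained = labels >= 0
    return beta, cols, depths, retained


class TestGlobalMeanProfile:
    def test_hand_arithmetic(self):
        layout = [[[], [-2.0, -4.0], [], [], [], []]]
        beta, cols, depths, retained = _toy_grid(layout)
        prof = pr.global_mean_profile(beta, cols, depths, np.array([0]), retained)
        assert prof.mean[1] == pytest.approx(-3.0)
        assert prof.sem[1] == pytest.approx(1.0)
        assert prof.n[1] == 2

    def test_all_positive_map_is_missing(self):
        layout = [[[1.0, 2.0]] * 6]
        beta, cols, depths, retained = _toy_grid(layout)
        prof = pr.global_mean_profile(beta, cols, depths, np.array([0]), retained)
        assert np.all(np.isnan(prof.mean)) and np.all(prof.n == 0)

    def test_positive_voxels_excluded_per_map(self):
        layout = [[[-1.0, 2.0, -3.0], [], [], [], [], []]]
        beta, cols, depths, retained = _toy_grid(layout)
        prof = pr.global_mean_profile(beta, cols, depths, np.array([0]), retained)
        assert prof.mean[0] == pytest.approx(-2.0)
        assert prof.n[0] == 2


class TestColumnProfileMean:
    def test_single_column_equals_global(self):
        layout = [[[-1.0, -2.0], [-3.0], [-4.0, -6.0], [], [-1.5], [-2.5]]]
        beta, cols, depths, retained = _toy_grid(layout)
        g = pr.global_mean_profile(beta, cols, depths, np.array([0]), retained)
        c = pr.column_profile_mean(beta, cols, depths, np.array([0]), retained)
        assert np.allclose(np.nan_to_num(g.mean), np.nan_to_num(c.mean))

    def test_unweighted_column_average(self):
        # depth 3: column A mean -1 (3 voxels), column B mean -5 (1 voxel)
        layout = [
            [[], [], [-1.0, -1.0, -1.0], [], [], []],
            [[], [], [-5.0], [], [], []],
        ]
        beta, cols, depths, retained = _toy_grid(layout)
        c = pr.column_profile_mean(beta, cols, depths, np.array([0, 1]), retained)
        g = pr.global_mean_profile(beta, cols, depths, np.array([0, 1]), retained)
        assert c.mean[2] == pytest.approx(-3.0)       # (−1 + −5)/2, count-blind
        assert g.mean[2] == pytest.approx(-2.0)       # voxel-weighted


class TestRangeNormalize:
    def test_two_depth_example(self):
        prof = pr.DepthProfile(
            mean=np.array([-2.0, -4.0, np.nan, np.nan, np.nan, np.nan]),
            sem=np.zeros(6), n=np.array([1, 1, 0, 0, 0, 0]),
        )
        out = pr.range_normalize(prof)
        assert out.mean[0] == pytest.approx(-1.0)
        assert out.mean[1] == pytest.approx(-2.0)

    def test_unit_range_profile_unchanged(self):
        prof = pr.DepthProfile(np.linspace(-1.0, -2.0, 6), np.zeros(6), np.ones(6, int))
        out = pr.range_normalize(prof)
        assert np.allclose(out.mean, prof.mean)

    @settings(max_examples=100, deadline=None)
    @given(
        p=arrays(np.float64, 6, elements=st.floats(-10, -0.1)),
        c=st.floats(0.1, 50),
    )
    def test_scale_invariance(self, p, c):
        if np.ptp(p) < 1e-6:
            return
        prof = pr.DepthProfile(p, np.zeros(6), np.ones(6, int))
        scaled = pr.DepthProfile(c * p, np.zeros(6), np.ones(6, int))
        assert np.allclose(
            pr.range_normalize(prof).mean, pr.range_normalize(scaled).mean, rtol=1e-9
        )

    def test_zero_range_rejected(self):
        prof = pr.DepthProfile(np.full(6, -1.0), np.zeros(6), np.ones(6, int))
        with pytest.raises(ValueError):
            pr.range_normalize(prof)


class TestRoiAverage:
    def _prof(self, val):
        return pr.DepthProfile(np.full(6, val), np.zeros(6), np.ones(6, int))

    def test_equal_weights_plain_mean(self):
        out = pr.roi_weighted_average([self._prof(-1.0), self._prof(-3.0)], [10, 10])
        assert np.allclose(out.mean, -2.0)

    def test_column_count_weighting(self):
        # V1: 100 columns at -1, V2: 50 columns at -4 -> (-100-200)/150 = -2
        out = pr.roi_weighted_average([self._prof(-1.0), self._prof(-4.0)], [100, 50])
        assert np.allclose(out.mean, -2.0)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            pr.roi_weighted_average([self._prof(-1.0)], [0])


def _oracle_rm1(data):
    """Brute-force one-way rm-ANOVA from explicit cell deviations."""
    n, k = data.shape
    grand = data.mean()
    ss_level = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (
                data[i, j] - data[i].mean() - data[:, j].mean() + grand
            ) ** 2
    return (ss_level / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def _oracle_rm2(y):
    """Brute-force two-way within-subject ANOVA via explicit deviations."""
    n, a, b = y.shape
    g = y.mean()
    ms = y.mean(axis=(1, 2))
    ma = y.mean(axis=(0, 2))
    mb = y.mean(axis=(0, 1))
    out = {}
    ss_a = sum(n * b * (ma[j] - g) ** 2 for j in range(a))
    ss_sa = sum(
        b * (y[i, j].mean() - ms[i] - ma[j] + g) ** 2 for i in range(n) for j in range(a)
    )
    out["A"] = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))
    ss_b = sum(n * a * (mb[k] - g) ** 2 for k in range(b))
    ss_sb = sum(
        a * (y[i, :, k].mean() - ms[i] - mb[k] + g) ** 2 for i in range(n) for k in range(b)
    )
    out["B"] = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (n - 1)))
    ss_ab = sum(
        n * (y[:, j, k].mean() - ma[j] - mb[k] + g) ** 2 for j in range(a) for k in range(b)
    )
    ss_sab = sum(
        (y[i, j, k] - y[i, j].mean() - y[i, :, k].mean() - y[:, j, k].mean()
         + ms[i] + ma[j] + mb[k] - g) ** 2
        for i in range(n) for j in range(a) for k in range(b)
    )
    out["AxB"] = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((a - 1) * (b - 1) * (n - 1)))
    return out


class TestRmAnova:
    def test_identical_levels_give_f0_p1(self):
        data = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        eff = pr.rm_anova_1way(data)
        assert eff.F == 0.0 and eff.p == 1.0

    def test_oneway_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            data = rng.normal(size=(rng.integers(3, 9), rng.integers(3, 7)))
            eff = pr.rm_anova_1way(data)
            assert eff.F == pytest.approx(_oracle_rm1(data), abs=1e-10, rel=1e-10)

    def test_oneway_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(8)
        data = rng.normal(size=(6, 4))
        eff = pr.rm_anova_1way(data)
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "subject": np.repeat(np.arange(6), 4),
                "level": np.tile(np.arange(4), 6),
            }
        )
        res = pg.rm_anova(data=long, dv="y", within="level", subject="subject")
        assert eff.F == pytest.approx(float(res["F"].iloc[0]), rel=1e-6)
        assert eff.p == pytest.approx(float(res["p_unc"].iloc[0]), rel=1e-6)

    def test_twoway_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            y = rng.normal(size=(rng.integers(3, 7), rng.integers(2, 5), rng.integers(2, 4)))
            eff = pr.rm_anova_2way(y)
            oracle = _oracle_rm2(y)
            for key in ("A", "B", "AxB"):
                assert eff[key].F == pytest.approx(oracle[key], abs=1e-10, rel=1e-10)

    def test_twoway_constant_factor_gives_zero_f(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(5, 4))
        y = np.stack([base, base], axis=2)  # identical across factor B
        eff = pr.rm_anova_2way(y)
        assert eff["B"].F == 0.0 and eff["AxB"].F == 0.0

    def test_missing_cells_rejected(self):
        data = np.ones((3, 4))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            pr.rm_anova_1way(data)


class TestPosthoc:
    def test_identical_levels(self):
        data = np.tile(np.array([[1.0], [4.0], [2.0]]), (1, 3))
        out = pr.posthoc_paired_t(data)
        assert np.all(out["t"] == 0.0) and np.all(out["p_adj"] == 1.0)

    def test_bonferroni_arithmetic(self):
        out = pr.posthoc_paired_t(np.random.default_rng(0).normal(size=(5, 3)), family_size=15)
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p_raw"] * 15))
        assert 0.004 * 15 == pytest.approx(0.06)  # the clipping rule in numbers

    def test_family_defaults_to_pair_count(self):
        out = pr.posthoc_paired_t(np.random.default_rng(1).normal(size=(4, 6)))
        assert len(out) == 15
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p_raw"] * 15))

    def test_matches_scipy_paired_t(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        data = rng.normal(size=(6, 3))
        out = pr.posthoc_paired_t(data)
        t, p = stats.ttest_rel(data[:, 0], data[:, 1])
        row = out[(out["level_a"] == 1) & (out["level_b"] == 2)].iloc[0]
        assert row["t"] == pytest.approx(t) and row["p_raw"] == pytest.approx(p)
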