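"""Normalization methods: hand oracles, re-implementation oracles, invariants."""

import numpy as np
import pytest

from swathbench import (
    DegenerateScaleError,
    NormalizeParams,
    apply_normalization,
    eigenms_normalize,
    regression_normalize,
    tmm_factors,
    vsn_normalize,
)
from conftest import make_table


def _normalize(values, code, groups=None, **kw):
    table = make_table(values, groups=groups)
    return apply_normalization(table, NormalizeParams(code=code, **kw)).values


class TestLocationScaleMethods:
    def test_tic_hand_oracle(self):
        # column sums 4 and 8; grand mean of sums 6
        out = _normalize([[1.0, 2.0], [3.0, 6.0]], "TIC")
        np.testing.assert_allclose(out, [[1.5, 1.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.sum(axis=0), [6.0, 6.0])

    def test_med_equalizes_column_medians(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(2, 1, size=(51, 4)))
        out = _normalize(vals, "MED")
        med = np.median(out, axis=0)
        np.testing.assert_allclose(med, med[0], rtol=1e-12)

    def test_mea_equalizes_column_means(self):
        rng = np.random.default_rng(1)
        out = _normalize(np.exp(rng.normal(0, 1, size=(40, 5))), "MEA")
        means = out.mean(axis=0)
        np.testing.assert_allclose(means, means[0], rtol=1e-12)

    def test_zsc_column_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        out = _normalize(rng.normal(5, 3, size=(100, 6)), "ZSC")
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_mad_centers_on_median_unit_mad(self):
        rng = np.random.default_rng(3)
        out = _normalize(rng.normal(size=(101, 3)), "MAD")
        np.testing.assert_allclose(np.median(out, axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            np.median(np.abs(out - np.median(out, axis=0)), axis=0), 1.0, rtol=1e-12
        )

    def test_zsc_degenerate_scale_error(self):
        with pytest.raises(DegenerateScaleError) as err:
            _normalize([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]], "ZSC")
        assert err.value.stage == "normalization"

    def test_non_is_bit_exact_identity(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        out = _normalize(vals, "NON")
        assert np.array_equal(out, vals, equal_nan=True)


class TestRowScalingMethods:
    def test_aut_rows_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        out = _normalize(rng.normal(size=(30, 8)), "AUT")
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_par_divides_by_sqrt_sd(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 6))
        out = _normalize(vals, "PAR")
        expected = (vals - vals.mean(axis=1, keepdims=True)) / np.sqrt(
            vals.std(axis=1, ddof=1, keepdims=True)
        )
        np.testing.assert_allclose(out, expected)

    def test_single_observation_row_emitted_missing(self):
        vals = np.array([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]])
        out = _normalize(vals, "AUT")
        assert np.isnan(out[0]).all()
        assert np.isfinite(out[1]).all()


class TestQuantile:
    def test_rank_mean_oracle(self):
        # sorted columns [2,6] and [4,8]; rank means [3, 7]
        out = _normalize([[2.0, 8.0], [6.0, 4.0]], "QUA")
        np.testing.assert_allclose(out, [[3.0, 7.0], [7.0, 3.0]])

    def test_all_columns_share_sorted_values(self):
        rng = np.random.default_rng(6)
        out = _normalize(rng.normal(size=(200, 5)), "QUA")
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_ties_get_mean_of_means(self):
        # column 1 has a tie at rank 1-2; both receive the average of the
        # rank-1 and rank-2 means
        out = _normalize([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]], "QUA")
        assert out[0, 0] == out[1, 0] == pytest.approx((5.5 + 10.5) / 2)

    def test_missing_values_stay_missing(self):
        vals = np.array([[1.0, np.nan], [2.0, 5.0], [3.0, 9.0]])
        out = _normalize(vals, "QUA")
        assert np.isnan(out[0, 1]) and np.isfinite(out[0, 0])


class TestPQN:
    def test_pure_dilution_equalized(self):
        rng = np.random.default_rng(7)
        base = np.exp(rng.normal(2, 1, size=(100, 1)))
        vals = base * np.array([[1.0, 2.0, 0.5]])
        out = _normalize(vals, "PQN")
        np.testing.assert_allclose(out[:, 1], out[:, 0], rtol=1e-9)
        np.testing.assert_allclose(out[:, 2], out[:, 0], rtol=1e-9)


class TestTMM:
    def test_pure_scaling_factor_ratio(self):
        rng = np.random.default_rng(8)
        a = np.exp(rng.normal(6, 1, size=(100, 1)))
        table = make_table(np.hstack([a, 2.0 * a]))
        factors = tmm_factors(table)
        assert factors[1] / factors[0] == pytest.approx(2.0, rel=1e-9)
        out = apply_normalization(table, NormalizeParams(code="TMM")).values
        np.testing.assert_allclose(out[:, 0], out[:, 1], rtol=1e-9)

    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(9)
        a = np.exp(rng.normal(6, 1, size=(60, 1)))
        table = make_table(np.hstack([a, a, a]))
        np.testing.assert_allclose(tmm_factors(table), 1.0)

    def test_outlier_robust_factor_matches_trimming_oracle(self):
        """50-protein table, 10% outliers in one sample, vs a direct
        re-implementation of the trimmed weighted mean."""
        rng = np.random.default_rng(10)
        a = np.exp(rng.normal(8, 0.5, size=50))
        b = a * 1.5
        b[:5] *= 40.0  # outlier proteins
        table = make_table(np.column_stack([a, b]))
        factors = tmm_factors(table)

        # oracle: reference = column 0 (upper quartiles differ; recompute)
        uq = [np.quantile(a, 0.75), np.quantile(b, 0.75)]
        ref = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
        other = 1 - ref
        cols = [a, b]
        m = np.log2(cols[other] / cols[ref])
        aa = 0.5 * np.log2(cols[other] * cols[ref])
        keep = (
            (m >= np.quantile(m, 0.3)) & (m <= np.quantile(m, 0.7))
            & (aa >= np.quantile(aa, 0.05)) & (aa <= np.quantile(aa, 0.95))
        )
        w = 1.0 / (1.0 / cols[other][keep] + 1.0 / cols[ref][keep])
        lf = np.average(m[keep], weights=w)
        expect = 2.0 ** np.array([-lf / 2, lf / 2]) if ref == 0 else 2.0 ** np.array([lf / 2, -lf / 2])
        np.testing.assert_allclose(factors, expect, rtol=0.02)


class TestRegressionMethods:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(11)
        a = rng.normal(20, 3, size=(100, 1))
        vals = np.hstack([a, a])
        for method in ("LOW", "RLR", "CYC"):
            out = regression_normalize(make_table(vals), method)
            np.testing.assert_allclose(out.values, vals, atol=1e-8)

    def test_rlr_removes_constant_offset(self):
        rng = np.random.default_rng(12)
        a = rng.normal(20, 3, size=(200, 1))
        vals = np.hstack([a, a + 3.0])
        out = regression_normalize(make_table(vals), "RLR")
        # offset split between both columns relative to the median reference
        diff = out.values[:, 1] - out.values[:, 0]
        np.testing.assert_allclose(diff, 0.0, atol=1e-6)

    def test_cyclic_loess_reduces_intensity_dependent_bow(self):
        rng = np.random.default_rng(13)
        a = rng.normal(20, 3, size=(500, 1))
        bow = 0.5 * (a - a.mean()) / a.std()
        vals = np.hstack([a, a + bow + 0.1 * rng.normal(size=(500, 1))])
        table = make_table(vals)
        out = regression_normalize(table, "CYC")
        m_before = np.abs(vals[:, 0] - vals[:, 1]).mean()
        m_after = np.abs(out.values[:, 0] - out.values[:, 1]).mean()
        assert m_after < m_before


class TestVSN:
    def test_identical_columns_equalized_with_equal_coefficients(self):
        rng = np.random.default_rng(14)
        a = np.exp(rng.normal(6, 1, size=(100, 1)))
        out = vsn_normalize(make_table(np.hstack([a, a])))
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_pure_scaling_removed(self):
        rng = np.random.default_rng(15)
        a = np.exp(rng.normal(14, 2, size=(300, 1)))
        out = vsn_normalize(make_table(np.hstack([a, 3.0 * a])))
        diff = out.values[:, 1] - out.values[:, 0]
        assert np.ptp(diff) < 1e-3

    def test_arsinh_concave_for_large_inputs(self):
        rng = np.random.default_rng(16)
        a = np.exp(rng.normal(6, 1, size=(200, 2)))
        out = vsn_normalize(make_table(a))
        x = np.sort(a[:, 0])[-20:]
        h = np.sort(out.values[:, 0])[-20:]
        second = np.diff(h) / np.diff(x)
        assert np.all(np.diff(second) < 0)


class TestEigenMS:
    @staticmethod
    def _grouped_residual_table(rng, trend_scale=0.0, p=80, n_per_group=5):
        groups = ["A"] * n_per_group + ["B"] * n_per_group
        s = 2 * n_per_group
        base = rng.normal(20, 2, size=(p, 1))
        effect = np.where(rng.random((p, 1)) < 0.3, 2.0, 0.0)
        in_b = np.array([g == "B" for g in groups], dtype=float)[None, :]
        noise = rng.normal(0, 1.0, size=(p, s))
        vals = base + effect * in_b + noise
        if trend_scale > 0:
            u = rng.normal(size=(p, 1))
            v = rng.normal(size=(1, s))
            v -= v.mean()
            vals += trend_scale * (u / np.abs(u).max()) @ v
        return make_table(vals, groups=groups)

    def test_group_mean_gap_preserved_when_no_trend_removed(self):
        rng = np.random.default_rng(17)
        table = self._grouped_residual_table(rng)
        out = eigenms_normalize(table, NormalizeParams(code="EIG",
                                                       eigenms_n_perm=100, seed=0))
        assert out.eigenms_n_trends == 0
        gap_in = (table.values[:, 5:].mean(axis=1) - table.values[:, :5].mean(axis=1))
        gap_out = (out.values[:, 5:].mean(axis=1) - out.values[:, :5].mean(axis=1))
        np.testing.assert_allclose(gap_in, gap_out, atol=1e-9)

    def test_planted_batch_trend_detected_and_variance_reduced(self):
        rng = np.random.default_rng(18)
        table = self._grouped_residual_table(rng, trend_scale=5.0)
        out = eigenms_normalize(table, NormalizeParams(code="EIG",
                                                       eigenms_n_perm=200, seed=1))
        assert out.eigenms_n_trends == 1

        def resid_var(t):
            v = t.values.copy()
            v[:, :5] -= v[:, :5].mean(axis=1, keepdims=True)
            v[:, 5:] -= v[:, 5:].mean(axis=1, keepdims=True)
            return v.var()

        assert resid_var(out) <= 0.5 * resid_var(table)


class TestInvariants:
    @pytest.mark.parametrize("code", ["MEA", "MED", "TIC", "ZSC", "MAD", "QUA",
                                      "PQN", "TMM", "AUT", "PAR"])
    def test_commutes_with_sample_reordering(self, code):
        rng = np.random.default_rng(19)
        vals = np.exp(rng.normal(6, 1, size=(60, 5)))
        table = make_table(vals)
        perm = np.array([3, 0, 4, 1, 2])
        permuted = make_table(vals[:, perm])
        out_then_perm = apply_normalization(table, NormalizeParams(code=code)).values[:, perm]
        perm_then_out = apply_normalization(permuted, NormalizeParams(code=code)).values
        np.testing.assert_allclose(perm_then_out, out_then_perm, rtol=1e-10)

    @pytest.mark.parametrize("code", ["MEA", "MED", "TIC", "ZSC", "MAD", "QUA", "PQN"])
    def test_missing_cells_pass_through(self, code, missing_table):
        out = apply_normalization(missing_table, NormalizeParams(code=code))
        assert np.array_equal(out.missing_mask, missing_table.missing_mask)
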