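import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from silacswap.detect import (
    MethodResult,
    _fit_prior_variance,
    bh_adjust,
    ensemble_union,
    fcros,
    fold_change_estimate,
    fold_change_method,
    m_score_test,
    moderated_treat,
    rank_product,
    significance_b,
    z_score_test,
)
from silacswap.simulate import SimulationParams, simulate_exposure

from conftest import make_dataset


def _flat_dataset(x, intensity=None):
    """One protein per value of x, all four treated slots equal to x."""
    x = np.asarray(x, dtype=float)
    treated = np.tile(x[:, None], (1, 4))
    control = np.zeros((len(x), 2))
    return make_dataset(treated, control, intensity=intensity)


class TestBhAdjust:
    def test_single_p_is_itself(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_against_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_nan_propagates(self):
        got = bh_adjust([0.1, np.nan, 0.2])
        assert np.isnan(got[1]) and np.isfinite(got[0])


class TestFoldChange:
    def test_up_two_fold(self):
        rs = dict(zip(["treated_r1_HL", "treated_r1_HM", "treated_r2_LH",
                       "treated_r2_MH"], [1.0] * 4))
        fc, direction = fold_change_estimate(rs)
        assert fc == pytest.approx(2.0) and direction == "up"

    def test_boundary_magnitude(self):
        rs = dict(zip(["treated_r1_HL", "treated_r1_HM", "treated_r2_LH",
                       "treated_r2_MH"], [-0.263] * 4))
        fc, direction = fold_change_estimate(rs)
        assert fc == pytest.approx(1.2, abs=1e-3) and direction == "down"

    def test_zero_mean_is_unity(self):
        rs = dict(zip(["treated_r1_HL", "treated_r1_HM", "treated_r2_LH",
                       "treated_r2_MH"], [0.5, -0.5, 0.5, -0.5]))
        fc, _ = fold_change_estimate(rs)
        assert fc == pytest.approx(1.0)

    def test_missing_slot_undefined(self):
        rs = {"treated_r1_HL": 1.0, "treated_r1_HM": np.nan,
              "treated_r2_LH": 1.0, "treated_r2_MH": 1.0}
        fc, direction = fold_change_estimate(rs)
        assert np.isnan(fc) and direction == "undefined"


class TestZScore:
    def test_protein_at_mean_has_zero_z(self):
        res = z_score_test(_flat_dataset([1.0, 2.0, 3.0]))
        assert res.table.iloc[1]["statistic"] == pytest.approx(0.0)
        assert res.table.iloc[1]["p_raw"] == pytest.approx(1.0)

    def test_tier_fraction_on_standard_normal(self):
        rng = np.random.default_rng(3)
        res = z_score_test(_flat_dataset(rng.normal(size=10_000)))
        frac = (np.abs(res.table["statistic"]) > 1.96).mean()
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert frac == pytest.approx(0.05, abs=3 * se)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="standard deviation"):
            z_score_test(_flat_dataset([1.0, 1.0, 1.0]))


class TestMScore:
    def test_protein_at_median_zero(self):
        res = m_score_test(_flat_dataset([1.0, 2.0, 3.0]))
        assert res.table.iloc[1]["statistic"] == pytest.approx(0.0)

    def test_hand_oracle_outlier(self):
        # x = (1,2,3,4,100): median 3, unscaled MAD 1 -> M(100) = 0.6745*97
        res = m_score_test(_flat_dataset([1, 2, 3, 4, 100]))
        assert res.table.iloc[4]["statistic"] == pytest.approx(0.6745 * 97)

    def test_distributionally_close_to_z_on_normal(self):
        rng = np.random.default_rng(4)
        ds = _flat_dataset(rng.normal(size=10_000))
        z = z_score_test(ds).table["statistic"].to_numpy()
        m = m_score_test(ds).table["statistic"].to_numpy()
        d = stats.ks_2samp(z, m).statistic
        assert d < 0.02

    def test_equals_z_on_matched_symmetric_fixture(self):
        # symmetric x with mean == median and sd == MAD/0.6745 => Z == M
        b = 1.0
        a = float(np.sqrt(2.0 / 0.6745**2 - 1.0))
        x = [-a, -b, 0.0, b, a]
        ds = _flat_dataset(x)
        z = z_score_test(ds).table["statistic"].to_numpy()
        m = m_score_test(ds).table["statistic"].to_numpy()
        np.testing.assert_allclose(z, m, rtol=1e-12)

    def test_zero_mad_errors(self):
        with pytest.raises(ValueError, match="MAD"):
            m_score_test(_flat_dataset([1.0, 1.0, 1.0, 5.0]))


class TestSignificanceB:
    def test_median_protein_tail_half(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.normal(size=301))
        ds = _flat_dataset(x)
        res = significance_b(ds, min_bin=300)
        med_gid = res.table.index[np.argmin(np.abs(res.table["statistic"]))]
        assert res.table.at[med_gid, "p_tail"] == pytest.approx(0.5, abs=0.02)

    def test_percentile_consistency_single_bin(self):
        rng = np.random.default_rng(6)
        sigma = 0.5
        x = rng.normal(0, sigma, 20_000)
        x[0] = 1.96 * sigma
        res = significance_b(_flat_dataset(x), min_bin=30_000)
        assert res.table.iloc[0]["p_tail"] == pytest.approx(0.025, abs=0.006)

    def test_intensity_dependent_calibration(self):
        # equal |x| outlier: smaller p in the tight high-intensity bin
        rng = np.random.default_rng(7)
        n = 600
        intensity = np.arange(1, n + 1, dtype=float)
        x = np.concatenate([
            2.0 * rng.normal(size=300),   # low intensity, wide spread
            0.5 * rng.normal(size=300),   # high intensity, tight spread
        ])
        x[10] = 1.5
        x[590] = 1.5
        ds = _flat_dataset(x, intensity=intensity)
        res = significance_b(ds, min_bin=300)
        gid_lo, gid_hi = "G0010", "G0590"
        assert res.table.at[gid_hi, "p_raw"] < res.table.at[gid_lo, "p_raw"]

    def test_degenerate_percentiles_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            significance_b(_flat_dataset([1.0] * 10 + [2.0]), min_bin=5)


class TestRankProduct:
    def test_exact_top_protein_probability(self):
        # rank 1 in all four columns of n=5: p_up = 1/5^4
        rng = np.random.default_rng(8)
        treated = rng.normal(0, 0.2, (5, 4))
        treated[0] = 5.0 + rng.random(4)  # strictly largest everywhere
        ds = make_dataset(treated, np.zeros((5, 2)))
        res = rank_product(ds, exact=True)
        assert res.table.iloc[0]["p_up"] == pytest.approx(1.0 / 5**4)

    def test_identical_columns_degenerate_spectrum(self):
        x = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        treated = np.tile(x[:, None], (1, 4))
        ds = make_dataset(treated, np.zeros((5, 2)))
        res = rank_product(ds, exact=True)
        top = res.table.iloc[4]  # largest value, rank 1 everywhere
        assert top["statistic"] == pytest.approx(1 / 5)
        assert top["direction"] == "up"

    def test_permutation_close_to_exact(self):
        rng = np.random.default_rng(9)
        treated = rng.normal(size=(6, 4))
        ds = make_dataset(treated, np.zeros((6, 2)))
        ex = rank_product(ds, exact=True)
        mc = rank_product(ds, n_perm=20_000, seed=0)
        np.testing.assert_allclose(
            mc.table["p_raw"], ex.table["p_raw"], atol=0.02
        )

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        ds = make_dataset(rng.normal(size=(50, 4)), np.zeros((50, 2)))
        a = rank_product(ds, n_perm=500, seed=3)
        b = rank_product(ds, n_perm=500, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng.normal(size=(10, 4)), np.zeros((10, 2)))
        with pytest.warns(UserWarning, match="n_perm"):
            rank_product(ds, n_perm=50, seed=0)


class TestFcros:
    def test_central_protein_p_one(self):
        # middle rank in every column -> mean rank fraction exactly 0.5
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        treated = np.tile(x[:, None], (1, 4))
        ds = make_dataset(treated, np.zeros((5, 2)))
        with pytest.warns(UserWarning, match="n < 20"):
            res = fcros(ds)
        assert res.table.iloc[2]["p_raw"] == pytest.approx(1.0)

    def test_extreme_protein_has_smallest_p(self):
        rng = np.random.default_rng(12)
        treated = rng.normal(size=(40, 4))
        treated[7] = treated.max() + 1.0 + rng.random(4)
        ds = make_dataset(treated, np.zeros((40, 2)))
        res = fcros(ds)
        assert res.table["p_raw"].idxmin() == "G0007"
        assert res.table.loc["G0007", "direction"] == "up"


class TestModeratedTreat:
    @staticmethod
    def _dataset_with_contrasts(contrasts, noise=1e-6, seed=0):
        rng = np.random.default_rng(seed)
        c = np.asarray(contrasts, dtype=float)
        n = len(c)
        treated = c[:, None] + rng.normal(0, noise, (n, 4))
        control = rng.normal(0, noise, (n, 2))
        return make_dataset(treated, control)

    def test_threshold_limit_p_half(self):
        # contrast estimate exactly log2(tau) with zero residual: the
        # right tail sits at t=0 and the left tail vanishes -> p -> 0.5
        rng = np.random.default_rng(0)
        n = 50
        treated = 0.1 + rng.normal(0, 1e-3, (n, 4))
        control = rng.normal(0, 1e-3, (n, 2))
        treated[0] = np.log2(1.2)  # no within-protein spread
        control[0] = 0.0
        ds = make_dataset(treated, control)
        res = moderated_treat(ds, tau=1.2)
        assert res.table.iloc[0]["p_raw"] == pytest.approx(0.5, abs=0.01)

    def test_tau_one_with_zero_contrast(self):
        c = np.zeros(30)
        c[5] = 0.0
        rng = np.random.default_rng(1)
        treated = rng.normal(0, 0.1, (30, 4))
        control = rng.normal(0, 0.1, (30, 2))
        ds = make_dataset(treated, control)
        res = moderated_treat(ds, tau=1.0)
        # ordinary two-sided moderated t: p in (0, 1], symmetric around |c|
        assert ((res.table["p_raw"] > 0) & (res.table["p_raw"] <= 1)).all()

    def test_p_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        treated = rng.normal(0.3, 0.2, (100, 4))
        control = rng.normal(0, 0.2, (100, 2))
        ds = make_dataset(treated, control)
        p1 = moderated_treat(ds, tau=1.0).table["p_raw"]
        p2 = moderated_treat(ds, tau=1.5).table["p_raw"]
        assert (p2 >= p1 - 1e-12).all()

    def test_prior_variance_recovery(self):
        # s^2 drawn from s0^2 * (chi2_d/d) / (chi2_d0/d0): fit recovers (d0, s0)
        rng = np.random.default_rng(3)
        d, d0_true, s0_true = 4, 4.0, 0.1
        n = 20_000
        sigma2 = s0_true**2 * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        d0, s02 = _fit_prior_variance(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert np.sqrt(s02) == pytest.approx(s0_true, rel=0.05)

    def test_regulated_protein_detected(self):
        # pure-noise generator (sigma0 only): label bias would sit in the
        # residual of the two-mean model and legitimately soak up power
        p = SimulationParams(
            n_proteins=2000, frac_regulated=0.01,
            effect_log2fc_range=(1.0, 1.0), noise_sd_base=0.1,
            noise_intensity_slope=0.0, label_bias_sd_hl=0.0,
            label_bias_sd_hm=0.0, seed=14,
        )
        ds, truth = simulate_exposure(p)
        res = moderated_treat(ds, tau=1.2)
        reg = set(truth.loc[truth.regulated, "group_id"])
        called = set(res.table.index[res.table["p_adj"] < 0.05])
        assert len(called & reg) / len(reg) >= 0.8

    def test_tau_below_one_rejected(self):
        ds = self._dataset_with_contrasts(np.zeros(5))
        with pytest.raises(ValueError):
            moderated_treat(ds, tau=0.5)


class TestEnsembleUnion:
    @staticmethod
    def _method(name, gids, fc, p, direction="up"):
        tab = pd.DataFrame(
            {
                "fc": fc,
                "direction": direction,
                "statistic": 0.0,
                "p_raw": p,
                "p_adj": bh_adjust(np.asarray(p, dtype=float)),
            },
            index=pd.Index(gids),
        )
        return MethodResult(name, tab)

    def test_single_method_membership_with_provenance(self):
        rp = self._method("RankProd", ["a", "b"], [1.5, 1.1], [0.04, 0.8])
        z = self._method("Z", ["a", "b"], [1.5, 1.1], [0.9, 0.9])
        ens = ensemble_union([rp, z], fc_tier=1.2, p_tier=0.05, require_fc=True)
        assert ens.table.at["a", "member"]
        assert "RankProd" in ens.table.at["a", "methods"]
        assert not ens.table.at["b", "member"]

    def test_fc_only_method_uses_fc_tier(self):
        fc = self._method("FC", ["a", "b"], [1.6, 1.1], [np.nan, np.nan])
        ens = ensemble_union([fc], fc_tier=1.5, p_tier=0.05)
        assert ens.table.at["a", "member"] and not ens.table.at["b", "member"]

    def test_no_method_significant_non_member(self):
        z = self._method("Z", ["a"], [1.5], [0.5])
        ens = ensemble_union([z], fc_tier=1.2, p_tier=0.05)
        assert not ens.table.at["a", "member"]

    def test_monotone_in_p_tier(self):
        rng = np.random.default_rng(15)
        gids = [f"g{i}" for i in range(100)]
        z = self._method("Z", gids, rng.uniform(1.0, 2.0, 100), rng.random(100))
        members = []
        for tier in (0.01, 0.05, 0.1):
            ens = ensemble_union([z], fc_tier=None, p_tier=tier)
            members.append(set(ens.members))
        assert members[0] <= members[1] <= members[2]

    def test_conflicting_directions_flagged(self):
        up = self._method("Z", ["a"], [1.5], [0.01], direction="up")
        down = self._method("M", ["a"], [1.5], [0.01], direction="down")
        ens = ensemble_union([up, down], fc_tier=None, p_tier=0.05)
        assert ens.table.at["a", "conflicted"]
        assert ens.table.at["a", "direction"] == "conflict"

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            ensemble_union([])


class TestFoldChangeMethod:
    def test_p_columns_are_nan(self):
        ds = _flat_dataset([0.5, -0.5, 1.0])
        res = fold_change_method(ds)
        assert res.table["p_raw"].isna().all()
        assert res.table["fc"].tolist() == pytest.approx(
            [2**0.5, 2**0.5, 2.0]
        )
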