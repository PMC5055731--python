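import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metharray.errors import IntegrityError
from metharray.methstats import (
    beta_to_m,
    call_dmps,
    compute_beta,
    distribution_summary,
    dmp_agreement,
    fit_variance_prior,
    m_to_beta,
    platform_correlation,
)


def frames(m_vals, u_vals, samples=("s1",)):
    idx = [f"cg{i}" for i in range(len(m_vals))]
    meth = pd.DataFrame(np.array(m_vals, dtype=float), index=idx, columns=samples)
    unmeth = pd.DataFrame(np.array(u_vals, dtype=float), index=idx, columns=samples)
    return meth, unmeth


class TestBeta:
    def test_zero_intensities_give_zero_beta(self):
        meth, unmeth = frames([[0.0]], [[0.0]])
        bm = compute_beta(meth, unmeth)
        assert bm.beta.iloc[0, 0] == 0.0

    def test_formula_900_0(self):
        meth, unmeth = frames([[900.0]], [[0.0]])
        bm = compute_beta(meth, unmeth)
        assert bm.beta.iloc[0, 0] == pytest.approx(0.9)

    def test_beta_strictly_below_one(self):
        meth, unmeth = frames([[1e9]], [[0.0]])
        bm = compute_beta(meth, unmeth)
        assert bm.beta.iloc[0, 0] < 1.0

    def test_monotone_in_meth_signal(self):
        meth, unmeth = frames([[100.0], [200.0], [400.0]], [[50.0], [50.0], [50.0]])
        bm = compute_beta(meth, unmeth)
        assert bm.beta["s1"].is_monotonic_increasing

    def test_background_subtraction_floors_at_zero(self):
        meth, unmeth = frames([[10.0]], [[5.0]])
        ctrl_m = pd.DataFrame({"s1": [100.0] * 5}, index=[f"n{i}" for i in range(5)])
        ctrl_u = ctrl_m.copy()
        bm = compute_beta(meth, unmeth, ctrl_m, ctrl_u)
        assert bm.beta.iloc[0, 0] == 0.0

    def test_probe_below_all_controls_fails_detection(self):
        meth, unmeth = frames([[10.0]], [[5.0]])
        ctrl_m = pd.DataFrame({"s1": np.full(200, 100.0)})
        ctrl_u = ctrl_m.copy()
        bm = compute_beta(meth, unmeth, ctrl_m, ctrl_u)
        assert bm.detection_p.iloc[0, 0] == 1.0

    def test_bright_probe_passes_detection(self):
        meth, unmeth = frames([[10_000.0]], [[5_000.0]])
        ctrl_m = pd.DataFrame({"s1": np.full(200, 100.0)})
        bm = compute_beta(meth, unmeth, ctrl_m, ctrl_m.copy())
        assert bm.detection_p.iloc[0, 0] == pytest.approx(1 / 201)

    def test_negative_intensity_rejected(self):
        meth, unmeth = frames([[-1.0]], [[0.0]])
        with pytest.raises(IntegrityError):
            compute_beta(meth, unmeth)

    def test_misaligned_matrices_rejected(self):
        meth, _ = frames([[1.0]], [[1.0]])
        _, unmeth = frames([[1.0], [2.0]], [[1.0], [2.0]])
        with pytest.raises(IntegrityError):
            compute_beta(meth, unmeth)


class TestMValues:
    def test_half_maps_to_zero(self):
        assert beta_to_m(0.5) == pytest.approx(0.0)

    def test_point_eight_maps_to_two(self):
        assert beta_to_m(0.8) == pytest.approx(2.0)

    def test_clamp_at_extremes(self):
        assert beta_to_m(0.999) == pytest.approx(np.log2(99))
        assert beta_to_m(1.0) == pytest.approx(np.log2(99))
        assert beta_to_m(0.0) == pytest.approx(np.log2(0.01 / 0.99))

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.01, 0.99))
    def test_round_trip_identity_inside_caps(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-12)


class TestDistributionSummary:
    def test_constant_beta_occupies_single_bin(self):
        beta = pd.DataFrame({"s1": [0.5] * 10}, index=[f"cg{i}" for i in range(10)])
        table = distribution_summary(beta)
        occupied = table[table["density"] > 0]
        assert len(occupied) == 1
        assert occupied["bin_left"].iloc[0] == pytest.approx(0.5)

    def test_densities_integrate_to_one(self, beta_matrix):
        table = distribution_summary(beta_matrix.beta, bin_width=0.02)
        for (_, sample), grp in table.groupby(["subset", "sample"]):
            assert grp["density"].sum() * 0.02 == pytest.approx(1.0, abs=1e-9)

    def test_bimodal_truth_yields_two_modes(self, dataset, beta_matrix):
        table = distribution_summary(beta_matrix.beta[["A1"]], bin_width=0.02)
        dens = table.set_index("bin_left")["density"]
        lo_mass = dens[dens.index < 0.3].sum()
        hi_mass = dens[dens.index >= 0.6].sum()
        mid_mass = dens[(dens.index >= 0.3) & (dens.index < 0.6)].sum()
        assert lo_mass > mid_mass and hi_mass > mid_mass

    def test_empty_subset_warns(self, beta_matrix):
        with pytest.warns(UserWarning, match="empty"):
            table = distribution_summary(
                beta_matrix.beta, {"none": pd.Index(["nope"])}
            )
        assert table.empty


class TestPlatformCorrelation:
    def test_identical_vectors_rho_one(self, beta_matrix):
        rho = platform_correlation(
            beta_matrix.beta, beta_matrix.beta, [("A1", "A1")]
        )
        assert rho.iloc[0] == pytest.approx(1.0)

    def test_reversed_vector_rho_minus_one(self):
        beta = pd.DataFrame({"s": np.linspace(0.05, 0.95, 20)})
        flipped = pd.DataFrame({"s": np.linspace(0.95, 0.05, 20)})
        rho = platform_correlation(beta, flipped, [("s", "s")])
        assert rho.iloc[0] == pytest.approx(-1.0)

    def test_replicates_within_monte_carlo_band(self):
        """Noisy replicates of a continuum truth: observed rho falls inside
        the band computed by an independent Monte-Carlo oracle at seed 1."""
        rng = np.random.default_rng(1)
        truth = rng.uniform(0.05, 0.95, size=500)
        sigma = 0.02
        oracle = []
        for _ in range(200):
            x = truth + rng.normal(0, sigma, 500)
            y = truth + rng.normal(0, sigma, 500)
            oracle.append(stats.spearmanr(x, y).statistic)
        lo, hi = np.quantile(oracle, [0.001, 0.999])
        a = pd.DataFrame({"s": truth + rng.normal(0, sigma, 500)})
        b = pd.DataFrame({"s": truth + rng.normal(0, sigma, 500)})
        rho = platform_correlation(a, b, [("s", "s")]).iloc[0]
        assert lo <= rho <= hi

    def test_too_few_probes_rejected(self):
        beta = pd.DataFrame({"s": [0.1, 0.2]})
        with pytest.raises(IntegrityError):
            platform_correlation(beta, beta, [("s", "s")])


class TestVariancePrior:
    def test_recovers_simulated_prior(self):
        rng = np.random.default_rng(1)
        d0_true, s0_true, df = 8.0, 0.04, 4
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=20_000)
        s2 = sigma2 * rng.chisquare(df, size=20_000) / df
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.2)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_equal_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(2)
        df = 4
        s2 = 0.01 * rng.chisquare(df, size=50_000) / df
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 > 100 or np.isinf(d0)
        assert s0 == pytest.approx(0.01, rel=0.05)


def simulate_beta(rng, n_probes, delta_m=0.0, sigma_m=0.1, n=3, base_m=0.0):
    m_a = rng.normal(base_m, sigma_m, size=(n_probes, n))
    m_b = rng.normal(base_m + delta_m, sigma_m, size=(n_probes, n))
    m = np.hstack([m_a, m_b])
    beta = 2.0**m / (1 + 2.0**m)
    cols = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    df = pd.DataFrame(beta, index=[f"cg{i}" for i in range(n_probes)], columns=cols)
    groups = pd.Series(["A"] * n + ["B"] * n, index=cols)
    return df, groups


class TestDmpCalling:
    def test_identical_groups_not_dmp(self):
        beta = pd.DataFrame(
            np.tile(np.linspace(0.2, 0.8, 50)[:, None], (1, 6)),
            index=[f"cg{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=beta.columns)
        res = call_dmps(beta, groups)
        assert (res["delta_beta"] == 0).all()
        assert not res["is_dmp"].any()

    def test_single_sample_group_rejected(self):
        beta = pd.DataFrame(
            np.random.default_rng(0).uniform(size=(10, 3)),
            columns=["a", "b", "c"],
        )
        groups = pd.Series(["A", "A", "B"], index=beta.columns)
        with pytest.raises(IntegrityError):
            call_dmps(beta, groups)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        beta, groups = simulate_beta(rng, 200, delta_m=1.0)
        res1 = call_dmps(beta, groups)
        shuffled = beta[list(beta.columns[::-1])]
        res2 = call_dmps(shuffled, groups)
        pd.testing.assert_frame_equal(res1, res2)

    def test_zero_prior_df_equals_ordinary_t(self):
        """With the moderation prior switched off the statistic is the
        classical pooled two-sample t-test."""
        rng = np.random.default_rng(4)
        beta, groups = simulate_beta(rng, 100, delta_m=0.5)
        res = call_dmps(beta, groups, prior_df=0)
        m = beta_to_m(beta)
        t_ref, p_ref = stats.ttest_ind(
            m[["B0", "B1", "B2"]], m[["A0", "A1", "A2"]], axis=1
        )
        np.testing.assert_allclose(res["moderated_t"], t_ref, rtol=1e-9)
        np.testing.assert_allclose(res["p_value"], p_ref, rtol=1e-9)

    def test_planted_dmps_recovered_on_dataset(self, dataset, beta_matrix):
        res = call_dmps(
            beta_matrix.beta,
            dataset.intensities.groups,
            detection_p=beta_matrix.detection_p,
        )
        called = set(res.index[res["is_dmp"]])
        assert called == set(dataset.ground_truth.true_dmp_ids)

    def test_detection_filter_drops_probes(self, dataset, beta_matrix):
        dp = beta_matrix.detection_p.copy()
        bad = dp.index[0]
        dp.loc[bad, dp.columns[0]] = 0.5
        res = call_dmps(beta_matrix.beta, dataset.intensities.groups, detection_p=dp)
        assert bad not in res.index

    def test_delta_beta_threshold_is_two_sided(self):
        rng = np.random.default_rng(5)
        beta_up, groups = simulate_beta(rng, 100, delta_m=2.0, sigma_m=0.05)
        res_up = call_dmps(beta_up, groups)
        beta_dn, _ = simulate_beta(rng, 100, delta_m=-2.0, sigma_m=0.05)
        res_dn = call_dmps(beta_dn, groups)
        assert res_up["is_dmp"].mean() > 0.9
        assert res_dn["is_dmp"].mean() > 0.9
        assert (res_dn["delta_beta"] < 0).all()


class TestAgreement:
    def test_identical_results_confirm_fully(self):
        rng = np.random.default_rng(6)
        beta, groups = simulate_beta(rng, 300, delta_m=1.5)
        res = call_dmps(beta, groups)
        summary = dmp_agreement(res, res)
        assert summary.n_confirmed_at_primary_threshold == summary.n_a_probes_on_b
        assert summary.spearman_rho == pytest.approx(1.0)

    def test_relaxing_threshold_is_monotone(self):
        rng = np.random.default_rng(7)
        beta, groups = simulate_beta(rng, 500, delta_m=1.2)
        res_a = call_dmps(beta, groups)
        res_b = res_a.copy()
        res_b["p_value"] = np.minimum(res_b["p_value"] * 5, 1.0)
        res_b["is_dmp"] = (res_b["p_value"] < 1e-3) & (res_b["delta_beta"].abs() > 0.1)
        confirmed = [
            dmp_agreement(res_a, res_b, relaxed_p=p).n_confirmed_at_relaxed_threshold
            for p in (1e-3, 1e-2, 1e-1)
        ]
        assert confirmed == sorted(confirmed)
        assert confirmed[-1] >= dmp_agreement(res_a, res_b).n_confirmed_at_primary_threshold

    def test_confirmed_never_exceeds_shared(self):
        rng = np.random.default_rng(8)
        beta, groups = simulate_beta(rng, 400, delta_m=1.0)
        res_a = call_dmps(beta, groups)
        res_b = res_a.iloc[: len(res_a) // 2]
        summary = dmp_agreement(res_a, res_b)
        assert summary.n_confirmed_at_primary_threshold <= summary.n_a_probes_on_b
        assert summary.n_a_probes_on_b <= summary.n_dmps_a

    def test_disjoint_universes_rejected(self):
        rng = np.random.default_rng(9)
        beta, groups = simulate_beta(rng, 10)
        res = call_dmps(beta, groups)
        other = res.copy()
        other.index = [f"other{i}" for i in range(len(other))]
        with pytest.raises(IntegrityError):
            dmp_agreement(res, other)
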