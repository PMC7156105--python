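import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import expon, ks_2samp

from ggam.model import (
    BroodRecord,
    ChainConfig,
    Design,
    FitDiagnosticsWarning,
    PosteriorSamples,
    PriorSpec,
    adaptive_thin,
    build_design,
    fit_mcmc,
    hpd_interval,
    posterior_mode,
    predict_genetic_values,
    read_broods,
    summarize,
)
from ggam.pedigree import assign_genetic_groups, compute_q, prune_pedigree

from .oracles import batch_means_se, reference_oneway_gibbs


class TestBroodRecords:
    def test_empty_brood_rejected(self):
        with pytest.raises(ValueError, match="n_offspring"):
            BroodRecord("b1", 2000, "f", "m", 2, 0, 0)

    def test_epo_bounds_enforced(self):
        with pytest.raises(ValueError, match="n_epo"):
            BroodRecord("b1", 2000, "f", "m", 2, 3, 4)

    def test_read_broods_validates(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "brood_id,year,female_id,male_id,male_age,n_offspring,n_epo\n"
            "b1,2000,f,m,2,3,4\n"
        )
        with pytest.raises(ValueError, match="n_epo"):
            read_broods(path)


class TestDesign:
    def _broods(self):
        return pd.DataFrame(
            {
                "brood_id": ["b1", "b2", "b3"],
                "year": [2000, 2000, 2001],
                "female_id": ["f1", "f1", "f2"],
                "male_id": ["m1", "m1", "m2"],
                "male_age": [2, 2, 3],
                "n_offspring": [3, 2, 4],
                "n_epo": [1, 0, 2],
            }
        )

    def _ped(self):
        from .conftest import make_pedigree

        return make_pedigree(
            [
                ("f1", None, None, "F", 1999, False),
                ("m1", None, None, "M", 1999, False),
                ("f2", None, None, "F", 1999, True),
                ("m2", None, None, "M", 1999, False),
            ]
        )

    def test_fixed_row_layout(self):
        ped = self._ped()
        q = compute_q(ped, assign_genetic_groups(ped))
        d = build_design(ped, q, self._broods())
        # brood b3: female f2 immigrant (q=1), male m2 local (q=0), year offset 1, age 3
        row = d.X[2]
        assert list(row) == [1.0, 1.0, 0.0, 1.0, 3.0]
        assert d.fixed_names == ["intercept", "g_f", "g_m", "beta_year", "beta_age"]

    def test_repeat_pairs_share_pair_level(self):
        ped = self._ped()
        q = compute_q(ped, assign_genetic_groups(ped))
        d = build_design(ped, q, self._broods())
        assert d.pair_idx[0] == d.pair_idx[1] != d.pair_idx[2]
        assert d.n_pair == 2

    def test_unknown_individual_is_error(self):
        ped = self._ped()
        q = compute_q(ped, assign_genetic_groups(ped))
        broods = self._broods()
        broods.loc[0, "female_id"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            build_design(ped, q, broods)

    def test_individual_in_both_roles_rejected(self):
        ped = self._ped()
        q = compute_q(ped, assign_genetic_groups(ped))
        broods = self._broods()
        broods.loc[2, "male_id"] = "f1"
        with pytest.raises(ValueError, match="both sexes"):
            build_design(ped, q, broods)

    def test_pair_dimension_equals_distinct_pairings(self, small_dataset):
        ds = small_dataset
        phen = set(ds.broods["female_id"]) | set(ds.broods["male_id"])
        ped = prune_pedigree(ds.pedigree, phen)
        q = compute_q(ped, assign_genetic_groups(ped), phenotyped=phen)
        d = build_design(ped, q, ds.broods)
        assert d.n_pair == ds.broods[["female_id", "male_id"]].drop_duplicates().shape[0]

    def test_label_swap_symmetry(self, small_dataset):
        """Swapping female/male roles everywhere swaps the g_f/g_m columns
        and the sex-specific incidence structures, leaving the binomial data
        (and hence the likelihood) untouched."""
        ds = small_dataset
        phen = set(ds.broods["female_id"]) | set(ds.broods["male_id"])
        ped = prune_pedigree(ds.pedigree, phen)
        q = compute_q(ped, assign_genetic_groups(ped), phenotyped=phen)
        d = build_design(ped, q, ds.broods)
        swapped = ds.broods.rename(
            columns={"female_id": "male_id", "male_id": "female_id"}
        )
        ds_swap = build_design(ped, q, swapped)
        assert np.array_equal(ds_swap.X[:, 1], d.X[:, 2])
        assert np.array_equal(ds_swap.X[:, 2], d.X[:, 1])
        assert np.array_equal(ds_swap.X[:, [0, 3, 4]], d.X[:, [0, 3, 4]])
        assert np.array_equal(ds_swap.fem_pos, d.male_pos)
        assert np.array_equal(ds_swap.male_pos, d.fem_pos)
        assert np.array_equal(ds_swap.y, d.y)
        assert np.array_equal(ds_swap.n_trials, d.n_trials)
        # the pair partition is identical up to level relabelling
        a = pd.factorize(d.pair_idx)[0]
        b = pd.factorize(ds_swap.pair_idx)[0]
        assert np.array_equal(a, b)


class TestSamplerValidation:
    def test_gaussian_conjugate_intercept(self):
        """Identity link, known variance, intercept only: posterior matches
        the conjugate normal closed form."""
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.5, 40)
        s2, V = 1.5**2, 1e8
        d = Design(X=np.ones((40, 1)), fixed_names=["intercept"], y=y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitDiagnosticsWarning)
            s = fit_mcmc(
                d, PriorSpec(), ChainConfig(n_iter=6000, burn_in=1000, thin=1, seed=3),
                family="gaussian", known_residual=s2, store_animal=False,
            )
        prec = 40 / s2 + 1 / V
        mu_exact, sd_exact = (y.sum() / s2) / prec, np.sqrt(1 / prec)
        draws = s.params["intercept"].to_numpy()
        assert abs(draws.mean() - mu_exact) < 3 * batch_means_se(draws)
        assert abs(draws.std(ddof=1) - sd_exact) / sd_exact < 0.05

    def test_matches_independent_reference_sampler(self):
        """One-way Gaussian mixed model, 30 observations: blocked sampler
        agrees with a naive scalar-conditional Gibbs within 3 MC SEs."""
        rng = np.random.default_rng(7)
        J, m = 6, 5
        u = rng.normal(0, 1.0, J)
        group = np.repeat(np.arange(J), m)
        y = 1.5 + u[group] + rng.normal(0, 0.8, J * m)
        d = Design(
            X=np.ones((J * m, 1)), fixed_names=["intercept"], y=y,
            year_idx=group, n_year=J,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitDiagnosticsWarning)
            s = fit_mcmc(
                d, PriorSpec(), ChainConfig(n_iter=22000, burn_in=2000, thin=1, seed=5),
                family="gaussian", store_animal=False,
            )
        ref = reference_oneway_gibbs(y, group, n_iter=40000, seed=11)
        for mine, theirs in (
            ("intercept", "mu"), ("var_year", "var_u"), ("var_residual", "var_e"),
        ):
            a = s.params[mine].to_numpy()
            b = ref[theirs][2000:]
            tol = 3 * np.sqrt(batch_means_se(a) ** 2 + batch_means_se(b) ** 2)
            assert abs(a.mean() - b.mean()) < tol, (mine, a.mean(), b.mean(), tol)

    def test_parameter_without_data_contribution_returns_prior(self):
        """A regression column that is identically zero (no immigrants, so
        q = 0 everywhere) has posterior equal to its prior (KS < 0.1)."""
        B = 60
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(B), np.zeros(B)])  # intercept, g_f on q=0
        y = rng.binomial(1, 0.4, B).astype(float)
        d = Design(X=X, fixed_names=["intercept", "g_f"], y=y,
                   n_trials=np.ones(B, dtype=np.int64))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitDiagnosticsWarning)
            s = fit_mcmc(
                d, PriorSpec(), ChainConfig(n_iter=2500, burn_in=500, thin=1, seed=9),
                store_animal=False,
            )
        prior_draws = np.random.default_rng(1).normal(0, np.sqrt(1e8), 2000)
        stat = ks_2samp(s.params["g_f"].to_numpy(), prior_draws).statistic
        assert stat < 0.1

    def test_G_draws_psd_every_iteration(self, small_fit):
        p = small_fit["samples"].params
        det = p["var_af"] * p["var_am"] - p["cov_afam"] ** 2
        assert (p["var_af"] > 0).all() and (p["var_am"] > 0).all()
        assert (det > 0).all()

    def test_divergence_raises_not_nan(self):
        d = Design(
            X=np.column_stack([np.ones(4), [np.inf, 1, 2, 3]]),
            fixed_names=["intercept", "bad"], y=np.array([1.0, 0, 1, 0]),
            n_trials=np.ones(4, dtype=np.int64),
        )
        with pytest.raises((RuntimeError, ValueError)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_mcmc(d, PriorSpec(), ChainConfig(n_iter=50, burn_in=10, thin=1, seed=1),
                         store_animal=False)


class TestSummaries:
    def test_standard_normal_summary(self):
        rng = np.random.default_rng(0)
        draws = pd.DataFrame({"x": rng.standard_normal(10000)})
        s = summarize(draws)
        assert abs(s.loc["x", "mean"]) < 0.05
        assert abs(s.loc["x", "hpd_low"] + 1.96) < 0.08
        assert abs(s.loc["x", "hpd_high"] - 1.96) < 0.08
        assert abs(s.loc["x", "pct_negative"] - 50) < 2

    def test_all_positive_draws_zero_pct_negative(self):
        s = summarize(pd.DataFrame({"v": np.abs(np.random.default_rng(1).normal(2, 1, 500))}))
        assert s.loc["v", "pct_negative"] == 0.0

    def test_exponential_hpd_anchored_at_zero_and_shortest(self):
        """For Exp(1) the 95% HPD is [0, -ln(0.05)]; it must beat the
        equal-tailed interval and start near zero."""
        rng = np.random.default_rng(2)
        x = rng.exponential(1.0, 20000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo < 0.01
        assert abs(hi - (-np.log(0.05))) < 0.15
        eq_lo, eq_hi = np.quantile(x, [0.025, 0.975])
        assert (hi - lo) < (eq_hi - eq_lo)

    def test_mode_tracks_density_peak(self):
        rng = np.random.default_rng(3)
        x = rng.normal(3.0, 0.5, 5000)
        assert abs(posterior_mode(x) - 3.0) < 0.1

    def test_hpd_contains_requested_mass(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, 1.0, 5000)
        lo, hi = hpd_interval(x, 0.9)
        assert np.mean((x >= lo) & (x <= hi)) >= 0.9


class TestAdaptiveThin:
    def test_reduces_autocorrelation_or_warns(self):
        rng = np.random.default_rng(0)
        # AR(1) chain with rho 0.9
        n = 20000
        x = np.empty(n)
        x[0] = 0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + eps[i]
        s = PosteriorSamples(params=pd.DataFrame({"x": x}), animal=None, animal_ids=None, meta={})
        thinned = adaptive_thin(s)
        assert thinned.lag1_autocorr()["x"] < 0.05
        assert thinned.n_draws >= 200


class TestPrediction:
    def test_u_equals_a_for_zero_q_drawwise(self, small_fit):
        q = small_fit["q"]
        samples = small_fit["samples"]
        zero_ids = [i for i in samples.animal_ids if q[i] == 0.0][:5]
        if not zero_ids:
            pytest.skip("no q=0 individuals in fixture")
        pred = predict_genetic_values(samples, q, ids=zero_ids)
        assert np.allclose(pred["u_f_mean"], pred["a_f_mean"])
        assert np.allclose(pred["u_m_mean"], pred["a_m_mean"])

    def test_zero_group_effect_draws_collapse_u_to_a(self, small_fit):
        samples = small_fit["samples"]
        params = samples.params.copy()
        params["g_f"] = 0.0
        params["g_m"] = 0.0
        zeroed = PosteriorSamples(
            params=params, animal=samples.animal, animal_ids=samples.animal_ids, meta={}
        )
        pred = predict_genetic_values(zeroed, small_fit["q"])
        assert np.allclose(pred["u_f_mean"], pred["a_f_mean"])

    def test_missing_q_is_error(self, small_fit):
        import pandas as pd

        from ggam.pedigree import GroupCoefficients

        samples = small_fit["samples"]
        tiny_q = GroupCoefficients(q=pd.Series({samples.animal_ids[0]: 0.5}), var_q=0.0)
        with pytest.raises(ValueError, match="group coefficient"):
            predict_genetic_values(samples, tiny_q, ids=samples.animal_ids[:3])

    def test_predicted_u_correlates_with_truth(self, small_fit):
        """Posterior-mean total genetic values recover the simulated truth
        direction: positive correlation, clearly above noise."""
        ds = small_fit["dataset"]
        samples = small_fit["samples"]
        q = small_fit["q"]
        females = sorted(set(ds.broods["female_id"]))
        pred = predict_genetic_values(samples, q, ids=females)
        true_u = ds.truth.loc[females, "u_f"]
        r = np.corrcoef(pred["u_f_mean"], true_u)[0, 1]
        assert r >= 0.3
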