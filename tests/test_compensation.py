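import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from argos.compensation import (
    CompensationFit,
    InferenceConfig,
    NBRegressionModel,
    classify_compensation,
    fit_gene_cellline,
    fit_gene_tumor,
    gene_set_difference,
    normalize_deviation,
    score_fit,
    shrink_score,
)
from argos.preprocess import compute_gene_mean, select_samples_for_gene


def make_fit(beta2_mean, beta2_sd=0.1, beta1_means=(1.0,), kind="cellline"):
    b1 = np.asarray(beta1_means, dtype=float)
    return CompensationFit(
        gene_id="g",
        cohort_kind=kind,
        tissues=[f"t{i}" for i in range(len(b1))],
        beta1_mean=b1,
        beta1_sd=np.full_like(b1, 0.05),
        beta2_mean=beta2_mean,
        beta2_sd=beta2_sd,
        beta3_mean=None,
        beta3_sd=None,
        shape_mean=10.0,
        mu_hat=np.ones(3),
        n_samples=3,
    )


def build_model(rng, n=12, kind="cellline", n_tissues=1):
    tissues = [f"t{i}" for i in range(n_tissues)]
    codes = rng.integers(0, n_tissues, size=n)
    c = rng.choice([1.0, 2.0], size=n)
    counts = rng.poisson(50, size=n).astype(float)
    return NBRegressionModel(
        counts=counts,
        c=c,
        d=c - 1.0,
        size_factors=rng.uniform(0.7, 1.4, size=n),
        m=40.0,
        tissue_codes=codes,
        tissues=tissues,
        cohort_kind=kind,
        purity=rng.uniform(0.3, 1.0, size=n) if kind == "tumor" else None,
    )


class TestNBLikelihood:
    def test_matches_scipy_pmf_summation(self):
        """Brute-force NB log-pmf summation oracle, <=20 samples, 1e-8."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            model = build_model(rng, n=rng.integers(5, 20))
            theta = np.array([0.1, -0.3, np.log(7.0)])
            beta1, beta2, beta3, shape = model._unpack(theta[None, :])
            mu = model.linear_predictor(beta1, beta2, beta3)
            got = model.log_likelihood_terms(mu, shape)[0]
            mean = model.s * model.m * mu[0]
            sh = shape[0]
            want = stats.nbinom.logpmf(model.counts, sh, sh / (sh + mean)).sum()
            assert got == pytest.approx(want, abs=1e-8)

    def test_tumor_at_purity_one_equals_cellline(self):
        """The purity-corrected likelihood collapses onto the cell-line one
        at p = 1 for any parameter draw (beta3 terms vanish)."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            cell = build_model(rng, n=15, n_tissues=2)
            tumor = NBRegressionModel(
                counts=cell.counts, c=cell.c, d=cell.d,
                size_factors=cell.s, m=cell.m,
                tissue_codes=cell.tissue_codes, tissues=cell.tissues,
                cohort_kind="tumor", purity=np.ones_like(cell.c),
                beta2_prior_sd=0.5,
            )
            theta_cell = rng.normal(0, 0.3, size=cell.ndim)
            theta_tumor = np.concatenate(
                [theta_cell[:-1], rng.normal(0, 1, 2), theta_cell[-1:]]
            )
            b1, b2, b3, sh = tumor._unpack(theta_tumor[None, :])
            mu_t = tumor.linear_predictor(b1, b2, b3)
            b1c, b2c, _, shc = cell._unpack(theta_cell[None, :])
            mu_c = cell.linear_predictor(b1c, b2c, None)
            assert np.allclose(mu_t, mu_c)
            assert tumor.log_likelihood_terms(mu_t, sh)[0] == pytest.approx(
                cell.log_likelihood_terms(mu_c, shc)[0], rel=1e-12
            )

    def test_negative_linear_predictor_rejected(self):
        rng = np.random.default_rng(2)
        model = build_model(rng)
        theta = np.array([np.log(0.1), -5.0, np.log(5.0)])  # mu < 0 when amplified
        assert model.log_posterior(theta[None, :])[0] == -np.inf


class TestScoreArithmetic:
    def test_normalizer_is_unweighted_tissue_mean(self):
        assert normalize_deviation(make_fit(-0.5, beta1_means=(1.0, 1.5))) == (
            pytest.approx(-0.4)
        )

    def test_zero_beta2_gives_zero(self):
        assert normalize_deviation(make_fit(0.0, beta1_means=(2.0,))) == 0.0

    def test_single_tissue_ratio(self):
        assert normalize_deviation(make_fit(1.0, beta1_means=(2.0,))) == (
            pytest.approx(0.5)
        )

    def test_weighted_normalizer_option(self):
        fit = make_fit(-0.6, beta1_means=(1.0, 2.0))
        assert normalize_deviation(fit, sample_weights=[3, 1]) == pytest.approx(
            -0.6 / 1.25
        )

    def test_null_posterior_scores_zero(self):
        sc = shrink_score(make_fit(0.0, beta2_sd=0.2), beta2_star=0.0)
        assert sc.z == 0 and sc.pseudo_p == pytest.approx(1.0) and sc.score == 0

    def test_huge_z_recovers_beta2_star(self):
        sc = shrink_score(make_fit(-1.0, beta2_sd=1e-4), beta2_star=-0.8)
        assert sc.score == pytest.approx(-0.8, abs=1e-12)

    def test_z_1_96_shrinks_by_five_percent(self):
        fit = make_fit(-0.5, beta2_sd=0.5 / 1.96)
        sc = shrink_score(fit, beta2_star=-0.4)
        assert sc.pseudo_p == pytest.approx(0.05, abs=0.001)
        assert sc.score == pytest.approx(-0.38, abs=0.001)

    @given(
        st.floats(-2, 2, allow_nan=False),
        st.floats(0.01, 50, allow_nan=False),
    )
    def test_shrinkage_bound_and_sign(self, beta2_star, z):
        fit = make_fit(beta2_mean=z * 0.1, beta2_sd=0.1)
        sc = shrink_score(fit, beta2_star)
        assert abs(sc.score) <= abs(beta2_star) + 1e-12
        assert sc.score == 0 or np.sign(sc.score) == np.sign(beta2_star)

    @given(st.floats(0.01, 30), st.floats(0.01, 30))
    def test_shrinkage_monotone_in_abs_z(self, z1, z2):
        lo, hi = sorted([z1, z2])
        s_lo = shrink_score(make_fit(lo * 0.1, 0.1), 1.0).score
        s_hi = shrink_score(make_fit(hi * 0.1, 0.1), 1.0).score
        assert s_lo <= s_hi + 1e-12


class TestClassification:
    @pytest.mark.parametrize(
        "a,b,status",
        [
            (-0.5, -0.4, "compensated"),
            (-0.5, -0.2, "neither"),
            (0.4, 0.35, "hyperactivated"),
            (-0.3, -0.5, "neither"),  # strict boundary
            (0.3, 0.5, "neither"),
        ],
    )
    def test_requires_both_cohorts_beyond_threshold(self, a, b, status):
        out = classify_compensation(
            pd.Series({"g": a}), pd.Series({"g": b})
        )
        assert out.loc["g", "status"] == status

    def test_single_cohort_gene_labeled(self):
        out = classify_compensation(
            pd.Series({"g": -0.9, "h": -0.9}), pd.Series({"g": -0.9})
        )
        assert out.loc["h", "status"] == "single-cohort"
        assert not out.loc["h", "compensated"]


class TestGeneSetDifference:
    def test_no_difference_estimates_zero(self):
        scores = pd.Series(np.r_[np.full(5, 0.2), np.full(5, 0.2)])
        member = pd.Series([True] * 5 + [False] * 5)
        assert gene_set_difference(scores, member).estimate == pytest.approx(0.0)

    def test_noiseless_shift_recovered(self):
        scores = pd.Series(np.r_[np.full(4, -0.5), np.zeros(6)])
        member = pd.Series([True] * 4 + [False] * 6)
        res = gene_set_difference(scores, member)
        assert res.estimate == pytest.approx(-0.5)
        assert np.isnan(res.p)  # zero residual variance: p undefined

    def test_matches_pooled_two_group_statistic(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(0, 1, 30))
        member = pd.Series([True] * 10 + [False] * 20)
        res = gene_set_difference(scores, member)
        a, b = scores[member.values], scores[~member.values]
        t, p = stats.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.wald == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)
        assert res.estimate == pytest.approx(a.mean() - b.mean(), rel=1e-10)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gene_set_difference(pd.Series([1.0, 2.0]), pd.Series([True, True]))


def _gene_inputs(cohort, design, info, gene, kind="cellline"):
    neutral, amplified, _ = select_samples_for_gene(design.c.loc[gene], kind)
    mask = neutral | amplified
    inc = mask[mask].index
    m = compute_gene_mean(cohort.counts.loc[gene], info["size_factor"], mask)
    return (
        cohort.counts.loc[gene, inc],
        design.c.loc[gene, inc],
        design.d.loc[gene, inc],
        info.loc[inc],
        m,
    )


class TestGeneFits:
    def test_pure_scaling_gene_scores_near_zero(self, small_cohort):
        cohort, design, info = small_cohort
        fit = fit_gene_cellline(
            *_gene_inputs(cohort, design, info, "scal"),
            InferenceConfig(seed=5),
        )
        assert abs(score_fit(fit).score) < 0.1

    def test_fully_compensated_gene_scores_near_minus_one(self, small_cohort):
        cohort, design, info = small_cohort
        fit = fit_gene_cellline(
            *_gene_inputs(cohort, design, info, "comp"),
            InferenceConfig(seed=5),
        )
        assert score_fit(fit).score == pytest.approx(-1.0, abs=0.15)

    def test_seeded_inference_is_reproducible(self, small_cohort):
        cohort, design, info = small_cohort
        args = _gene_inputs(cohort, design, info, "hyper")
        cfg = InferenceConfig(seed=9, draws=300, warmup=300)
        f1 = fit_gene_cellline(*args, cfg)
        f2 = fit_gene_cellline(*args, cfg)
        assert f1.beta2_mean == f2.beta2_mean
        assert f1.beta2_sd == f2.beta2_sd

    def test_independent_seeds_agree_within_monte_carlo_error(self, small_cohort):
        cohort, design, info = small_cohort
        args = _gene_inputs(cohort, design, info, "comp")
        fits = [
            fit_gene_cellline(*args, InferenceConfig(seed=s)) for s in (5, 1005)
        ]
        # difference of two independent run means: se * sqrt(2)
        mc_se = fits[0].beta2_sd / np.sqrt(min(f.diagnostics["ess"] for f in fits))
        bound = 3 * np.sqrt(2) * max(mc_se, 1e-4)
        assert abs(fits[0].beta2_mean - fits[1].beta2_mean) < bound

    def test_laplace_backend_matches_mcmc_posterior(self, small_cohort):
        cohort, design, info = small_cohort
        args = _gene_inputs(cohort, design, info, "comp")
        mcmc = fit_gene_cellline(*args, InferenceConfig(seed=5))
        lap = fit_gene_cellline(*args, InferenceConfig(backend="laplace", seed=5))
        assert lap.beta2_mean == pytest.approx(mcmc.beta2_mean, abs=3 * mcmc.beta2_sd)
        assert lap.beta2_sd == pytest.approx(mcmc.beta2_sd, rel=0.5)

    def test_tumor_purity_near_zero_returns_prior(self):
        # likelihood carries no beta2 information when p ~ 0
        rng = np.random.default_rng(6)
        n = 40
        c = np.r_[np.ones(30), np.full(10, 2.0)]
        counts = pd.Series(
            rng.poisson(100, n), index=[f"s{i}" for i in range(n)], name="g"
        )
        info = pd.DataFrame(
            {
                "tissue": "t1",
                "purity": 1e-4,
                "size_factor": 1.0,
            },
            index=counts.index,
        )
        fit = fit_gene_tumor(
            counts,
            pd.Series(c, index=counts.index),
            pd.Series(c - 1.0, index=counts.index),
            info,
            m=100.0,
            config=InferenceConfig(seed=7),
        )
        assert fit.beta2_mean == pytest.approx(0.0, abs=0.1)
        assert fit.beta2_sd == pytest.approx(0.2, abs=0.05)

    def test_zero_purity_rejected(self):
        counts = pd.Series([10, 20], index=["s0", "s1"], name="g")
        info = pd.DataFrame(
            {"tissue": "t1", "purity": 0.0, "size_factor": 1.0},
            index=counts.index,
        )
        c = pd.Series([1.0, 2.0], index=counts.index)
        with pytest.raises(ValueError, match="purity"):
            fit_gene_tumor(counts, c, c - 1, info, m=15.0)
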