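"""Bayesian Negative Binomial dosage-compensation model.

For each gene, observed counts ``r`` over copy-neutral and amplified
samples are modeled as

    r ~ NB(s * m * mu, sigma)                 (variance = mu + mu^2/sigma)

with, for cell lines,

    mu = sum_t beta1_t * c + beta2 * d

and, for tumors with purity ``p``,

    mu = sum_t beta1_t * c * p + beta2 * d * p + sum_t beta3_t * (1 - p)

where ``c`` is the linear copy ratio (euploid equivalents), ``d = c - 1``
its deviation from baseline, ``s`` the library size factor, ``m`` the mean
normalized expression of the gene, ``beta1_t`` a per-tissue dosage-scaling
term, ``beta2`` the shared deviation (compensation) term and ``beta3_t``
the per-tissue non-cancer compartment.  The two formulas coincide at
purity 1.  Priors: ``beta1, beta3 ~ logNormal(0, 1)``;
``beta2 ~ Normal(0, 0.5)`` for cell lines and ``Normal(0, 0.2)`` for
tumors; a weakly-informative Gamma(0.01, 0.01) on the shape.  The identity
link admits negative means, so parameter draws implying ``mu <= 0`` on any
retained sample are rejected (log-posterior -inf).

The normalized deviation ``beta2* = beta2 / mean_t(beta1_t)`` is shrunk
by the pseudo-p-value of the posterior z-score of beta2 into the final
compensation score ``score = (1 - pseudo_p) * beta2*``: -1 means a gain
leaves expression unchanged (full compensation), 0 pure dosage scaling,
+1 twice the per-copy increment (full hyperactivation).

Posterior inference runs on an affine-invariant ensemble sampler (emcee)
initialized at the posterior mode, with walker chains feeding a split
R-hat convergence check; a fast Laplace (mode + Gaussian curvature)
backend is available where full MCMC is not needed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .preprocess import (
    CopyNumberDesign,
    compute_gene_mean,
    gene_summaries,
    select_samples_for_gene,
)

logger = logging.getLogger(__name__)

BETA2_PRIOR_SD = {"cellline": 0.5, "tumor": 0.2}
SCORE_THRESHOLD = 0.3


@dataclass
class InferenceConfig:
    """Posterior-inference settings shared by all gene fits."""

    backend: str = "mcmc"  # "mcmc" or "laplace"
    chains: int = 4
    draws: int = 1000  # post-warmup draws per chain
    warmup: int = 500
    seed: int = 0
    # classic Gelman-Rubin rule of thumb; chains are flagged, not repaired
    rhat_threshold: float = 1.1
    shape_prior: tuple[float, float] = (0.01, 0.01)  # Gamma(a, rate)
    beta2_prior_sd: float | None = None  # None -> cohort default

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws


@dataclass
class CompensationFit:
    """Posterior summaries of one gene's compensation regression."""

    gene_id: str
    cohort_kind: str
    tissues: list[str]
    beta1_mean: np.ndarray  # per tissue
    beta1_sd: np.ndarray
    beta2_mean: float
    beta2_sd: float
    beta3_mean: np.ndarray | None
    beta3_sd: np.ndarray | None
    shape_mean: float
    mu_hat: np.ndarray  # linear predictor at posterior means, per sample
    n_samples: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


@dataclass
class CompensationScore:
    """Normalized and significance-shrunk compensation score."""

    gene_id: str
    beta2_star: float
    z: float
    pseudo_p: float
    score: float


@dataclass
class GeneSetDifference:
    """In-set vs out-set mean difference from an indicator linear model."""

    estimate: float
    se: float
    wald: float
    p: float
    n_in: int
    n_out: int


class NBRegressionModel:
    """Log-posterior of the per-gene NB regression, walker-vectorized.

    Parameter vector layout: ``[log beta1_1..log beta1_T, beta2,
    (log beta3_1..log beta3_T for tumors), log shape]``.
    """

    def __init__(
        self,
        counts: np.ndarray,
        c: np.ndarray,
        d: np.ndarray,
        size_factors: np.ndarray,
        m: float,
        tissue_codes: np.ndarray,
        tissues: list[str],
        cohort_kind: str,
        purity: np.ndarray | None = None,
        beta2_prior_sd: float | None = None,
        shape_prior: tuple[float, float] = (0.01, 0.01),
    ):
        if cohort_kind not in ("cellline", "tumor"):
            raise ValueError(f"unknown cohort kind {cohort_kind!r}")
        if m <= 0:
            raise ValueError("gene mean m must be positive")
        self.counts = np.asarray(counts, dtype=float)
        self.c = np.asarray(c, dtype=float)
        self.d = np.asarray(d, dtype=float)
        self.s = np.asarray(size_factors, dtype=float)
        self.m = float(m)
        self.tissue_codes = np.asarray(tissue_codes)
        self.tissues = list(tissues)
        self.kind = cohort_kind
        self.n_tissues = len(tissues)
        if cohort_kind == "tumor":
            if purity is None:
                raise ValueError("tumor model requires purity")
            purity = np.asarray(purity, dtype=float)
            if (purity <= 0).any() or (purity > 1).any():
                msg = "purity must lie in (0, 1]"
                if (purity <= 0).all():
                    msg += "; all-zero purity leaves the cancer component unidentifiable"
                raise ValueError(msg)
            self.purity = purity
        else:
            self.purity = np.ones_like(self.c)
        self.beta2_prior_sd = (
            BETA2_PRIOR_SD[cohort_kind] if beta2_prior_sd is None else beta2_prior_sd
        )
        self.shape_prior = shape_prior
        self.ndim = self.n_tissues + 2 + (self.n_tissues if cohort_kind == "tumor" else 0)
        # gammaln(r + 1) is constant across draws
        self._lgamma_r1 = gammaln(self.counts + 1.0)

    # -- parameter unpacking ------------------------------------------------
    def _unpack(self, theta: np.ndarray):
        theta = np.atleast_2d(theta)
        T = self.n_tissues
        beta1 = np.exp(theta[:, :T])
        beta2 = theta[:, T]
        if self.kind == "tumor":
            beta3 = np.exp(theta[:, T + 1 : 2 * T + 1])
        else:
            beta3 = None
        shape = np.exp(theta[:, -1])
        return beta1, beta2, beta3, shape

    def linear_predictor(
        self,
        beta1: np.ndarray,
        beta2: np.ndarray,
        beta3: np.ndarray | None,
    ) -> np.ndarray:
        """mu per (draw, sample) for draw-stacked coefficient arrays."""
        p = self.purity
        mu = beta1[:, self.tissue_codes] * (self.c * p) + beta2[:, None] * (self.d * p)
        if self.kind == "tumor":
            mu = mu + beta3[:, self.tissue_codes] * (1.0 - p)
        return mu

    def log_likelihood_terms(self, mu: np.ndarray, shape: np.ndarray) -> np.ndarray:
        """NB log-likelihood per draw given linear predictor mu (> 0)."""
        mean = self.s * self.m * mu
        sh = shape[:, None]
        r = self.counts
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                gammaln(r + sh)
                - gammaln(sh)
                - self._lgamma_r1
                + sh * np.log(sh / (sh + mean))
                + r * np.log(mean / (sh + mean))
            )
        # lim mean->0: pmf(0) = 1
        ll = np.where((mean == 0) & (r == 0), 0.0, ll)
        return ll.sum(axis=1)

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta1, beta2, beta3, shape = self._unpack(theta)
        mu = self.linear_predictor(beta1, beta2, beta3)
        ok = np.isfinite(mu).all(axis=1) & (mu > 0).all(axis=1)
        out = np.full(theta.shape[0], -np.inf)
        if not ok.any():
            return out
        ll = np.full(theta.shape[0], -np.inf)
        ll[ok] = self.log_likelihood_terms(mu[ok], shape[ok])
        # priors (log-scale sampling: logN prior on beta1/beta3 is N on logs)
        T = self.n_tissues
        lp = -0.5 * (theta[:, :T] ** 2).sum(axis=1)
        lp += -0.5 * (beta2 / self.beta2_prior_sd) ** 2
        if self.kind == "tumor":
            lp += -0.5 * (theta[:, T + 1 : 2 * T + 1] ** 2).sum(axis=1)
        a, rate = self.shape_prior
        log_shape = theta[:, -1]
        lp += a * log_shape - rate * shape  # Gamma logpdf + log-Jacobian
        out[ok] = (ll + lp)[ok]
        return out

    def log_posterior_single(self, theta: np.ndarray) -> float:
        return float(self.log_posterior(theta[None, :])[0])


def _split_rhat(chains: np.ndarray) -> float:
    """Split R-hat for one parameter; chains shaped (n_chain, n_draw)."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, ndraw = halves.shape
    chain_means = halves.mean(axis=1)
    b = ndraw * chain_means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_hat = (ndraw - 1) / ndraw * w + b / ndraw
    return float(np.sqrt(var_hat / w))


def _map_estimate(model: NBRegressionModel) -> np.ndarray:
    """Posterior mode used to initialize walkers / anchor the Laplace fit."""
    x0 = np.zeros(model.ndim)
    x0[-1] = np.log(10.0)  # moderate overdispersion start
    nlp = lambda th: -model.log_posterior_single(th)
    with warnings.catch_warnings():
        # numeric gradients probing the mu <= 0 boundary hit -inf; harmless
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(nlp, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-6})
        res2 = optimize.minimize(nlp, res.x, method="BFGS",
                                 options={"maxiter": 200})
    best = res2.x if np.isfinite(res2.fun) and res2.fun <= res.fun else res.x
    return best


def _sample_posterior_mcmc(
    model: NBRegressionModel, config: InferenceConfig
) -> tuple[np.ndarray, dict]:
    """Ensemble-MCMC draws; returns (chain, draw, dim) array + diagnostics."""
    import emcee

    ndim = model.ndim
    nwalkers = max(2 * ndim + 2, 8)
    nwalkers += nwalkers % 2
    steps_keep = int(np.ceil(config.total_draws / nwalkers))
    # warmup expressed in sampler steps, scaled like the kept steps
    warmup_steps = max(int(np.ceil(config.warmup * config.chains / nwalkers)), 50)

    rng = np.random.RandomState(config.seed % (2**31))
    x_map = _map_estimate(model)
    p0 = x_map[None, :] + 0.02 * rng.randn(nwalkers, ndim)
    lp0 = model.log_posterior(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while bad.any() and tries < 100:
        p0[bad] = x_map[None, :] + 0.02 * rng.randn(int(bad.sum()), ndim)
        lp0 = model.log_posterior(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if bad.any():
        raise RuntimeError("could not initialize walkers in the posterior support")

    # DE moves decorrelate much faster than the stretch move on the
    # near-Gaussian per-gene posteriors (tau ~10 vs ~30 steps)
    moves = [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, model.log_posterior, vectorize=True, moves=moves
    )
    sampler.random_state = rng.get_state()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler.run_mcmc(p0, warmup_steps + steps_keep, progress=False)
    chain = sampler.get_chain(discard=warmup_steps)  # (steps, walkers, dim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, dim)

    rhat = max(_split_rhat(chain[:, :, k]) for k in range(ndim))
    n_total = chain.shape[0] * chain.shape[1]
    try:
        tau = float(np.max(sampler.get_autocorr_time(discard=warmup_steps, tol=0)))
    except Exception:  # pragma: no cover - pathological chains
        tau = np.nan
    ess = float(n_total / tau) if np.isfinite(tau) and tau > 0 else float(n_total)
    diagnostics = {
        "backend": "mcmc",
        "n_chains": nwalkers,
        "n_draws": chain.shape[1],
        "rhat": rhat,
        "tau": tau,
        "ess": ess,
        "accept_fraction": float(np.mean(sampler.acceptance_fraction)),
    }
    return chain, diagnostics


def _sample_posterior_laplace(
    model: NBRegressionModel, config: InferenceConfig
) -> tuple[np.ndarray, dict]:
    """Gaussian approximation at the mode; draws shaped like one chain."""
    x_map = _map_estimate(model)
    ndim = model.ndim
    h = 1e-4
    hess = np.zeros((ndim, ndim))
    f0 = model.log_posterior_single(x_map)
    for i in range(ndim):
        for j in range(i, ndim):
            ei = np.zeros(ndim); ei[i] = h
            ej = np.zeros(ndim); ej[j] = h
            fpp = model.log_posterior_single(x_map + ei + ej)
            fpm = model.log_posterior_single(x_map + ei - ej)
            fmp = model.log_posterior_single(x_map - ei + ej)
            fmm = model.log_posterior_single(x_map - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    cov = np.linalg.inv(-hess)
    # guard against a non-PD curvature estimate
    w, v = np.linalg.eigh(cov)
    ok = (w > 0).all() and np.isfinite(f0)
    w = np.clip(w, 1e-12, None)
    cov = (v * w) @ v.T
    rng = np.random.default_rng(config.seed)
    draws = rng.multivariate_normal(x_map, cov, size=config.total_draws)
    chain = draws[None, :, :]
    diagnostics = {
        "backend": "laplace",
        "n_chains": 1,
        "n_draws": config.total_draws,
        "rhat": 1.0,
        "ess": float(config.total_draws),
        "curvature_ok": bool(ok),
    }
    return chain, diagnostics


def _fit_gene(
    gene_id: str,
    model: NBRegressionModel,
    config: InferenceConfig,
) -> CompensationFit:
    if config.backend == "mcmc":
        chain, diag = _sample_posterior_mcmc(model, config)
        diag["converged"] = diag["rhat"] < config.rhat_threshold
    elif config.backend == "laplace":
        chain, diag = _sample_posterior_laplace(model, config)
        diag["converged"] = diag.get("curvature_ok", False)
    else:
        raise ValueError(f"unknown inference backend {config.backend!r}")

    flat = chain.reshape(-1, model.ndim)
    T = model.n_tissues
    beta1 = np.exp(flat[:, :T])
    beta2 = flat[:, T]
    beta3 = np.exp(flat[:, T + 1 : 2 * T + 1]) if model.kind == "tumor" else None
    shape = np.exp(flat[:, -1])

    b1m, b2m = beta1.mean(axis=0), float(beta2.mean())
    b3m = beta3.mean(axis=0) if beta3 is not None else None
    mu_hat = model.linear_predictor(
        b1m[None, :], np.array([b2m]), None if b3m is None else b3m[None, :]
    )[0]
    return CompensationFit(
        gene_id=gene_id,
        cohort_kind=model.kind,
        tissues=model.tissues,
        beta1_mean=b1m,
        beta1_sd=beta1.std(axis=0, ddof=1),
        beta2_mean=b2m,
        beta2_sd=float(beta2.std(ddof=1)),
        beta3_mean=b3m,
        beta3_sd=beta3.std(axis=0, ddof=1) if beta3 is not None else None,
        shape_mean=float(shape.mean()),
        mu_hat=mu_hat,
        n_samples=len(model.counts),
        diagnostics=diag,
    )


def _build_model(
    counts_row: pd.Series,
    c_row: pd.Series,
    d_row: pd.Series,
    sample_info: pd.DataFrame,
    m: float,
    cohort_kind: str,
    config: InferenceConfig,
) -> NBRegressionModel:
    samples = counts_row.index
    tissues = sorted(sample_info.loc[samples, "tissue"].unique())
    codes = sample_info.loc[samples, "tissue"].map({t: i for i, t in enumerate(tissues)})
    purity = None
    if cohort_kind == "tumor":
        purity = sample_info.loc[samples, "purity"].to_numpy(dtype=float)
    return NBRegressionModel(
        counts=counts_row.to_numpy(dtype=float),
        c=c_row.to_numpy(dtype=float),
        d=d_row.to_numpy(dtype=float),
        size_factors=sample_info.loc[samples, "size_factor"].to_numpy(dtype=float),
        m=m,
        tissue_codes=codes.to_numpy(),
        tissues=tissues,
        cohort_kind=cohort_kind,
        purity=purity,
        beta2_prior_sd=config.beta2_prior_sd,
        shape_prior=config.shape_prior,
    )


def fit_gene_cellline(
    counts_row: pd.Series,
    c_row: pd.Series,
    d_row: pd.Series,
    sample_info: pd.DataFrame,
    m: float,
    config: InferenceConfig | None = None,
) -> CompensationFit:
    """Fit the cell-line model on one gene's included samples.

    All series must be aligned to the retained (copy-neutral or amplified)
    samples; ``sample_info`` needs ``tissue`` and ``size_factor`` columns.
    """
    config = config or InferenceConfig()
    model = _build_model(counts_row, c_row, d_row, sample_info, m, "cellline", config)
    return _fit_gene(str(counts_row.name), model, config)


def fit_gene_tumor(
    counts_row: pd.Series,
    c_row: pd.Series,
    d_row: pd.Series,
    sample_info: pd.DataFrame,
    m: float,
    config: InferenceConfig | None = None,
) -> CompensationFit:
    """Fit the purity-corrected tumor model on one gene.

    Requires a ``purity`` column in (0, 1]; at purity 1 the model reduces
    exactly to the cell-line model.
    """
    config = config or InferenceConfig()
    model = _build_model(counts_row, c_row, d_row, sample_info, m, "tumor", config)
    return _fit_gene(str(counts_row.name), model, config)


def normalize_deviation(
    fit: CompensationFit, sample_weights: np.ndarray | None = None
) -> float:
    """beta2 normalized by the mean euploid expression over fitted tissues.

    The normalizer is the unweighted mean of the per-tissue beta1
    posterior means; pass per-tissue ``sample_weights`` for a
    sample-size-weighted alternative.
    """
    if sample_weights is None:
        denom = float(np.mean(fit.beta1_mean))
    else:
        w = np.asarray(sample_weights, dtype=float)
        denom = float(np.average(fit.beta1_mean, weights=w))
    if denom <= 0:
        raise ValueError("mean euploid expression must be positive")
    return fit.beta2_mean / denom


def shrink_score(fit: CompensationFit, beta2_star: float) -> CompensationScore:
    """Shrink beta2* by the pseudo-p of the posterior z-score of beta2.

    z = posterior mean / posterior sd; pseudo-p is the two-sided standard
    normal tail probability; score = (1 - pseudo_p) * beta2*.
    """
    if fit.beta2_sd <= 0:
        raise ValueError("posterior sd of beta2 must be positive")
    z = fit.beta2_mean / fit.beta2_sd
    pseudo_p = float(2.0 * stats.norm.sf(abs(z)))
    return CompensationScore(
        gene_id=fit.gene_id,
        beta2_star=beta2_star,
        z=float(z),
        pseudo_p=pseudo_p,
        score=(1.0 - pseudo_p) * beta2_star,
    )


def score_fit(fit: CompensationFit) -> CompensationScore:
    """Normalize and shrink in one step."""
    return shrink_score(fit, normalize_deviation(fit))


def classify_compensation(
    scores_a: pd.Series,
    scores_b: pd.Series,
    threshold: float = SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Joint compensated/hyperactivated calls over two cohorts.

    A gene is compensated iff its score is strictly below ``-threshold``
    in both cohorts, hyperactivated iff strictly above ``threshold`` in
    both; genes scored in a single cohort are labeled ``single-cohort``.
    """
    genes = scores_a.index.union(scores_b.index)
    both = scores_a.index.intersection(scores_b.index)
    rows = []
    for gene in genes:
        if gene in both:
            a, b = float(scores_a[gene]), float(scores_b[gene])
            compensated = a < -threshold and b < -threshold
            hyper = a > threshold and b > threshold
            status = (
                "compensated" if compensated
                else "hyperactivated" if hyper
                else "neither"
            )
        else:
            a = float(scores_a.get(gene, np.nan))
            b = float(scores_b.get(gene, np.nan))
            compensated = hyper = False
            status = "single-cohort"
        rows.append(
            {
                "gene": gene,
                "score_a": a,
                "score_b": b,
                "compensated": compensated,
                "hyperactivated": hyper,
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def gene_set_difference(
    scores: pd.Series, membership: pd.Series
) -> GeneSetDifference:
    """In-set minus out-set mean difference via an indicator linear model.

    Equivalent to the classical two-group pooled-variance statistic; the
    Wald p-value is two-sided.  With zero residual variance the p-value is
    undefined (NaN).
    """
    member = membership.reindex(scores.index).fillna(False).astype(bool)
    y = scores.to_numpy(dtype=float)
    x = member.to_numpy(dtype=float)
    n_in, n_out = int(x.sum()), int((1 - x).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("set and complement must both be non-empty")
    import statsmodels.api as sm

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit()
    est = float(res.params[1])
    se = float(res.bse[1])
    # zero residual variance (to numerical precision): Wald test undefined
    resid_scale = math.sqrt(max(res.ssr, 0.0) / max(res.df_resid, 1))
    degenerate = resid_scale <= 1e-10 * max(1.0, float(np.abs(y).max()))
    if not np.isfinite(se) or se == 0 or degenerate:
        return GeneSetDifference(est, se, np.nan, np.nan, n_in, n_out)
    return GeneSetDifference(
        est, se, float(res.tvalues[1]), float(res.pvalues[1]), n_in, n_out
    )


def fit_cohort(
    counts: pd.DataFrame,
    design: CopyNumberDesign,
    sample_info: pd.DataFrame,
    cohort_kind: str,
    config: InferenceConfig | None = None,
    genes: list[str] | None = None,
    tissue: str | None = None,
    neutral_tolerance: float = 0.15,
    min_amplified: int | None = None,
    weighted_normalizer: bool = False,
) -> pd.DataFrame:
    """Score every eligible gene of a cohort.

    ``tissue`` switches to tissue-specific mode: the identical model
    restricted to that tissue's samples (eligibility thresholds
    unchanged).  Returns one row per eligible gene with posterior
    summaries, the shrunk score and convergence status.
    """
    config = config or InferenceConfig()
    if "size_factor" not in sample_info.columns:
        from .preprocess import compute_size_factors

        sample_info = sample_info.copy()
        sample_info["size_factor"] = compute_size_factors(counts)
    if tissue is not None:
        keep = sample_info.index[sample_info["tissue"] == tissue]
        counts = counts[keep]
        design = CopyNumberDesign(
            linear_ratio=design.linear_ratio[keep],
            c=design.c[keep],
            d=design.d[keep],
            missing=design.missing[keep],
        )
        sample_info = sample_info.loc[keep]

    summaries = gene_summaries(
        counts, design, cohort_kind, sample_info["size_factor"],
        neutral_tolerance, min_amplified,
    )
    if genes is not None:
        summaries = summaries.loc[summaries.index.intersection(genes)]

    rows = []
    for gene, summ in summaries.iterrows():
        if not summ["eligible"]:
            logger.info("gene %s skipped: ineligible (%d amplified samples)",
                        gene, summ["n_amplified"])
            continue
        neutral, amplified, _ = select_samples_for_gene(
            design.c.loc[gene], cohort_kind, neutral_tolerance, min_amplified
        )
        mask = neutral | amplified
        included = mask[mask].index
        fitter = fit_gene_tumor if cohort_kind == "tumor" else fit_gene_cellline
        fit = fitter(
            counts.loc[gene, included],
            design.c.loc[gene, included],
            design.d.loc[gene, included],
            sample_info.loc[included],
            float(summ["m"]),
            config,
        )
        weights = None
        if weighted_normalizer:
            tissue_counts = sample_info.loc[included, "tissue"].value_counts()
            weights = tissue_counts.reindex(fit.tissues).fillna(0).to_numpy()
        sc = shrink_score(fit, normalize_deviation(fit, weights))
        rows.append(
            {
                "gene": gene,
                "cohort": cohort_kind,
                "tissue_mode": tissue or "pan",
                "beta2_mean": fit.beta2_mean,
                "beta2_sd": fit.beta2_sd,
                "beta2_star": sc.beta2_star,
                "z": sc.z,
                "pseudo_p": sc.pseudo_p,
                "score": sc.score,
                "n_neutral": int(summ["n_neutral"]),
                "n_amplified": int(summ["n_amplified"]),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
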