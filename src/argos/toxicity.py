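"""Overexpression toxicity from ORF-screen barcode depletion.

Barcode abundance is the growth proxy: the log2 fold change of a
lentiviral barcode between the early (post-selection) and late time
points measures the fitness effect of overexpressing its ORF.  Every
barcode measurement of a gene in any screen in scope is one independent
observation of an intercept-only linear model, whose Wald test is the
classical one-sample t-test.  A gene is called toxic when its pooled
depletion corresponds to at least a 30% decrease in growth
(mean lfc <= log2(0.7)) at P < 1e-5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: minimal fractional growth decrease for a toxic call
TOXIC_GROWTH_DECREASE = 0.30
#: significance bound for a toxic call
TOXIC_P = 1e-5
#: pseudocount added to barcode counts before the log ratio
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ToxicityFit:
    """Pooled depletion estimate for one gene in one scope."""

    gene_id: str
    scope: str  # "pan-cancer" or "tissue:<label>"
    estimate: float
    se: float
    wald: float
    p: float
    n_obs: int


def compute_barcode_lfc(
    table: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Barcode log2 fold changes from early/late counts, per screen.

    ``lfc = log2((late + pc) / N_late) - log2((early + pc) / N_early)``
    with ``N`` the screen's total raw reads at that time point.  With the
    pseudocount disabled, barcodes absent at the early time point are
    excluded (ratio undefined).

    Expects columns ``screen, tissue, barcode, gene, early_count,
    late_count``; returns the table with an ``lfc`` column.
    """
    required = {"screen", "barcode", "gene", "early_count", "late_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    totals = out.groupby("screen")[["early_count", "late_count"]].transform("sum")
    early = out["early_count"].astype(float) + pseudocount
    late = out["late_count"].astype(float) + pseudocount
    if pseudocount == 0:
        dead = early <= 0
        if dead.any():
            logger.info(
                "excluding %d barcodes absent at the early time point", dead.sum()
            )
            out = out[~dead].copy()
            early, late = early[~dead], late[~dead]
            totals = totals[~dead]
    out["lfc"] = np.log2(late / totals["late_count"]) - np.log2(
        early / totals["early_count"]
    )
    return out


def fit_gene_toxicity(
    observations: pd.Series | np.ndarray, gene_id: str = "", scope: str = "pan-cancer"
) -> ToxicityFit:
    """Intercept-only linear model on pooled barcode lfc values.

    estimate = pooled mean; Wald statistic and two-sided p-value are the
    one-sample t-test with n - 1 degrees of freedom.  Fewer than two
    observations (or zero variance) leaves the p-value undefined, and such
    fits are never classified toxic.
    """
    lfc = np.asarray(observations, dtype=float)
    if not np.isfinite(lfc).all():
        raise ValueError("non-finite lfc observations")
    n = len(lfc)
    if n == 0:
        raise ValueError("no observations")
    est = float(lfc.mean())
    if n < 2:
        return ToxicityFit(gene_id, scope, est, np.nan, np.nan, np.nan, n)
    se = float(lfc.std(ddof=1) / math.sqrt(n))
    if se == 0:
        return ToxicityFit(gene_id, scope, est, 0.0, np.nan, np.nan, n)
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return ToxicityFit(gene_id, scope, est, se, float(t), p, n)


def classify_toxic(
    fit: ToxicityFit,
    growth_decrease: float = TOXIC_GROWTH_DECREASE,
    p_threshold: float = TOXIC_P,
) -> bool:
    """Toxic iff depletion reaches the growth-decrease bound and P < 1e-5.

    The lfc bound is ``log2(1 - growth_decrease)`` (log2(0.7) ~ -0.515
    for the default 30%); an undefined p-value is never toxic.
    """
    if not np.isfinite(fit.p):
        return False
    return fit.estimate <= math.log2(1.0 - growth_decrease) and fit.p < p_threshold


def fit_toxicity_table(
    observations: pd.DataFrame,
    scope: str = "pan-cancer",
    growth_decrease: float = TOXIC_GROWTH_DECREASE,
    p_threshold: float = TOXIC_P,
    center_screens: bool = False,
) -> pd.DataFrame:
    """Per-gene toxicity fits over a barcode observation table.

    ``scope`` is ``"pan-cancer"`` (all screens) or ``"tissue:<label>"``
    (screens sharing that cancer type).  ``center_screens`` subtracts each
    screen's median lfc first (off by default).  Returns one row per gene:
    estimate, se, wald, p, n_obs, toxic.
    """
    required = {"screen", "gene", "lfc"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    obs = observations
    if scope != "pan-cancer":
        if not scope.startswith("tissue:"):
            raise ValueError("scope must be 'pan-cancer' or 'tissue:<label>'")
        label = scope.split(":", 1)[1]
        obs = obs[obs["tissue"] == label]
    if center_screens:
        obs = obs.copy()
        obs["lfc"] = obs["lfc"] - obs.groupby("screen")["lfc"].transform("median")
    rows = []
    for gene, sub in obs.groupby("gene", sort=True):
        fit = fit_gene_toxicity(sub["lfc"], gene_id=str(gene), scope=scope)
        rows.append(
            {
                "gene": gene,
                "scope": scope,
                "estimate": fit.estimate,
                "se": fit.se,
                "wald": fit.wald,
                "p": fit.p,
                "n_obs": fit.n_obs,
                "toxic": classify_toxic(fit, growth_decrease, p_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
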