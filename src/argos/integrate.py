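"""ARGOS gene calls and protein-complex prioritization.

An ARGOS (Amplification-Related Gain Of Sensitivity) gene is compensated
when amplified AND toxic when overexpressed.  Frequent amplification is
annotated alongside but not required for the call.  Complexes are
prioritized by over-representation of compensated genes among their
members (one-sided Fisher's exact test, BH-adjusted) together with the
Wald statistic of an indicator linear model on their members' ORF
dropout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compensation import gene_set_difference

logger = logging.getLogger(__name__)


@dataclass
class ComplexEnrichment:
    complex_id: str
    members: list[str]
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    fisher_p: float
    toxicity_wald: float = np.nan


def call_argos(
    compensation_class: pd.DataFrame,
    toxicity: pd.DataFrame,
    amp_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Combine per-gene flags into the final classification table.

    Gene universes are harmonized by identifier intersection (attrition is
    logged).  Columns: compensated, hyperactivated, toxic,
    frequently_amplified, argos, and provenance scores.
    """
    genes = compensation_class.index.intersection(toxicity.index)
    if len(genes) == 0:
        raise ValueError("compensation and toxicity tables share no genes")
    dropped = (
        len(compensation_class.index) - len(genes),
        len(toxicity.index) - len(genes),
    )
    if any(dropped):
        logger.info(
            "gene universe intersection dropped %d compensation-only and "
            "%d toxicity-only genes", *dropped
        )
    out = pd.DataFrame(index=genes)
    out["compensated"] = compensation_class.loc[genes, "compensated"].astype(bool)
    out["hyperactivated"] = compensation_class.loc[genes, "hyperactivated"].astype(bool)
    out["toxic"] = toxicity.loc[genes, "toxic"].astype(bool)
    if amp_flags is not None:
        out["frequently_amplified"] = (
            amp_flags["frequently_amplified"].reindex(genes).fillna(False).astype(bool)
        )
    else:
        out["frequently_amplified"] = False
    out["argos"] = out["compensated"] & out["toxic"]
    for col in ("score_a", "score_b"):
        if col in compensation_class.columns:
            out[col] = compensation_class.loc[genes, col]
    if "estimate" in toxicity.columns:
        out["toxicity_lfc"] = toxicity.loc[genes, "estimate"]
        out["toxicity_p"] = toxicity.loc[genes, "p"]
    return out


def complex_enrichment(
    complex_id: str,
    members: list[str],
    compensated: set[str],
    universe: set[str],
) -> ComplexEnrichment | None:
    """One-sided Fisher's exact test for compensated-gene enrichment.

    2x2 table over the tested universe: membership x compensation.
    Members outside the universe are dropped with a warning; an empty
    complex after intersection is skipped (returns None).
    """
    mem = [g for g in members if g in universe]
    outside = len(members) - len(mem)
    if outside:
        logger.warning(
            "complex %s: %d members outside the tested universe dropped",
            complex_id, outside,
        )
    if not mem:
        logger.info("complex %s skipped: no members in universe", complex_id)
        return None
    comp = compensated & universe
    a = sum(g in comp for g in mem)  # member & compensated
    b = len(mem) - a
    c = len(comp) - a
    d = len(universe) - len(mem) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return ComplexEnrichment(
        complex_id=complex_id,
        members=mem,
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        fisher_p=float(p),
    )


def complex_toxicity(
    members: list[str], toxicity_estimates: pd.Series
) -> float:
    """Wald statistic of an indicator linear model on ORF dropout.

    Negative values mean complex members drop out more strongly than the
    rest of the universe.
    """
    membership = pd.Series(
        toxicity_estimates.index.isin(members), index=toxicity_estimates.index
    )
    return gene_set_difference(toxicity_estimates.dropna(), membership).wald


def rank_complexes(
    complexes: pd.DataFrame,
    compensated: set[str],
    universe: set[str],
    toxicity_estimates: pd.Series | None = None,
) -> pd.DataFrame:
    """Test, BH-adjust and rank complexes.

    ``complexes`` has one row per membership (complex_id, gene).  Output
    is ordered by (fdr_q ascending, toxicity_wald ascending) with columns
    n_members, n_compensated, odds_ratio, fisher_p, fdr_q, toxicity_wald.
    """
    rows = []
    for cid, sub in complexes.groupby("complex_id", sort=True):
        enr = complex_enrichment(str(cid), list(sub["gene"]), compensated, universe)
        if enr is None:
            continue
        wald = np.nan
        if toxicity_estimates is not None:
            try:
                wald = complex_toxicity(enr.members, toxicity_estimates)
            except ValueError:
                pass
        rows.append(
            {
                "complex_id": enr.complex_id,
                "n_members": len(enr.members),
                "n_compensated": enr.table[0][0],
                "odds_ratio": enr.odds_ratio,
                "fisher_p": enr.fisher_p,
                "toxicity_wald": wald,
            }
        )
    if not rows:
        raise ValueError("no testable complexes")
    out = pd.DataFrame(rows).set_index("complex_id")
    out["fdr_q"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    out = out.sort_values(
        ["fdr_q", "toxicity_wald"], ascending=[True, True], na_position="last"
    )
    return out
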