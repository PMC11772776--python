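"""Model-ready covariates from raw counts and copy-number tables.

Copy-number ratios are re-parameterized on the linear scale into *euploid
equivalents* ``c`` (the part of expression expected to scale with DNA
content; 1 at baseline ploidy, 0 when the gene is absent) and the *euploid
deviation* ``d = c - 1`` (0 at baseline, -1 with no copies, +1 with one
extra copy set).  ``c`` carries the dosage-scaling coefficient and ``d``
the departure-from-scaling coefficient in the compensation regression.

Library-size factors use the median-of-ratios estimator on raw counts,
rescaled to geometric mean 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: absolute tolerance on the linear copy ratio for "no copy-number change"
NEUTRAL_TOLERANCE = 0.15
#: minimum amplified samples for a gene to be fit, by cohort kind
MIN_AMPLIFIED = {"cellline": 3, "tumor": 5}
#: strict gain-frequency bound above which a gene is "commonly amplified"
AMP_FREQUENCY_THRESHOLD = 0.15


@dataclass
class CopyNumberDesign:
    """Per gene x sample copy-number covariates on the linear scale.

    Attributes
    ----------
    linear_ratio : DataFrame
        ``2**log2_ratio``; euploid = 1, absent gene = 0.
    c : DataFrame
        Euploid equivalents (identical to ``linear_ratio``).
    d : DataFrame
        Euploid deviation ``c - 1``.
    missing : DataFrame of bool
        Entries that were NaN in the input; excluded downstream.
    """

    linear_ratio: pd.DataFrame
    c: pd.DataFrame
    d: pd.DataFrame
    missing: pd.DataFrame
    annotations: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def genes(self) -> pd.Index:
        return self.c.index

    @property
    def samples(self) -> pd.Index:
        return self.c.columns


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, geometric mean rescaled to 1.

    Parameters
    ----------
    counts : DataFrame
        gene x sample raw counts (nonnegative integers).

    Returns
    -------
    Series of positive size factors indexed by sample.

    Raises
    ------
    ValueError
        If no gene has nonzero counts in every sample (the reference
        geometric mean is undefined).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "size factors are undefined"
        )
    sub = mat[expressed]
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def encode_copy_number(log2_table: pd.DataFrame) -> CopyNumberDesign:
    """Encode a gene x sample log2 copy-ratio table as (c, d) covariates.

    ``-inf`` is the accepted sentinel for zero DNA copies (linear ratio 0,
    so d = -1).  NaN entries are flagged missing and excluded downstream.
    """
    log2 = log2_table.astype(float)
    missing = log2.isna()
    if np.isposinf(log2.to_numpy()).any():
        raise ValueError("log2 copy ratios contain +inf")
    linear = 2.0 ** log2
    c = linear
    d = c - 1.0
    ann = log2_table.attrs.get("annotations")
    return CopyNumberDesign(
        linear_ratio=linear, c=c, d=d, missing=missing, annotations=ann
    )


def select_samples_for_gene(
    c_row: pd.Series,
    cohort_kind: str,
    neutral_tolerance: float = NEUTRAL_TOLERANCE,
    min_amplified: int | None = None,
) -> tuple[pd.Series, pd.Series, bool]:
    """Per-sample inclusion masks and eligibility for one gene.

    Included samples are copy-neutral (``|c - 1| <= tol``) or amplified by
    at least one copy (``c >= 2 - tol``).  Samples in between, deleted
    samples and missing entries are excluded.  A gene is eligible when it
    has at least 3 (cell lines) or 5 (tumors) amplified samples.

    Returns
    -------
    (neutral_mask, amplified_mask, eligible)
    """
    if cohort_kind not in MIN_AMPLIFIED:
        raise ValueError(f"unknown cohort kind {cohort_kind!r}")
    if min_amplified is None:
        min_amplified = MIN_AMPLIFIED[cohort_kind]
    c = c_row.astype(float)
    ok = c.notna()
    neutral = ok & ((c - 1.0).abs() <= neutral_tolerance)
    amplified = ok & (c >= 2.0 - neutral_tolerance)
    eligible = int(amplified.sum()) >= min_amplified
    return neutral, amplified, eligible


def classify_frequently_amplified(
    design: CopyNumberDesign,
    gain_calls: pd.DataFrame | None = None,
    threshold: float = AMP_FREQUENCY_THRESHOLD,
) -> pd.DataFrame:
    """Flag genes gained in strictly more than ``threshold`` of samples.

    The in-house gain call is ``c >= 2 - NEUTRAL_TOLERANCE`` (gain of at
    least one copy); an external boolean gene x sample call table (e.g.
    GISTIC-derived) overrides it when provided.  The frequency denominator
    is the full cohort sample count; missing entries count as not gained.

    Returns a DataFrame with ``amp_frequency`` and ``frequently_amplified``
    per gene.
    """
    if gain_calls is not None:
        calls = gain_calls.astype(bool)
        n = calls.shape[1]
        freq = calls.sum(axis=1) / n
    else:
        gained = (design.c >= 2.0 - NEUTRAL_TOLERANCE) & ~design.missing
        freq = gained.sum(axis=1) / design.c.shape[1]
    return pd.DataFrame(
        {
            "amp_frequency": freq,
            "frequently_amplified": freq > threshold,
        }
    )


def compute_gene_mean(
    counts_row: pd.Series, size_factors: pd.Series, mask: pd.Series
) -> float:
    """Mean size-factor-normalized count m over included samples.

    m anchors the NB regression mean (``s * m * mu``) so coefficients are
    comparable across genes regardless of expression level.
    """
    included = mask[mask].index
    if len(included) == 0:
        raise ValueError("no samples included; gene mean undefined")
    norm = counts_row[included].astype(float) / size_factors[included]
    return float(norm.mean())


def gene_summaries(
    counts: pd.DataFrame,
    design: CopyNumberDesign,
    cohort_kind: str,
    size_factors: pd.Series | None = None,
    neutral_tolerance: float = NEUTRAL_TOLERANCE,
    min_amplified: int | None = None,
) -> pd.DataFrame:
    """Per-gene eligibility, amplification frequency and normalized mean.

    Columns: gene (index), m, n_neutral, n_amplified, amp_frequency,
    eligible.  Genes with m = 0 over their included samples are marked
    ineligible (the regression mean would be identically zero).
    """
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    common = counts.index.intersection(design.genes)
    amp = classify_frequently_amplified(design)
    rows = []
    for gene in common:
        neutral, amplified, eligible = select_samples_for_gene(
            design.c.loc[gene], cohort_kind, neutral_tolerance, min_amplified
        )
        mask = neutral | amplified
        m = np.nan
        if mask.any():
            m = compute_gene_mean(counts.loc[gene], size_factors, mask)
            if m == 0:
                logger.info("gene %s skipped: zero mean expression", gene)
                eligible = False
        rows.append(
            {
                "gene": gene,
                "m": m,
                "n_neutral": int(neutral.sum()),
                "n_amplified": int(amplified.sum()),
                "amp_frequency": float(amp.loc[gene, "amp_frequency"]),
                "eligible": bool(eligible),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
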