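"""Gene-signature activity scoring and cohort stratification.

The activity score of a sample is the mean, over the signature genes, of the
per-gene z-score computed across samples — the standard single-sample
signature construction used to stratify tumour cohorts by, e.g., GR
(glucocorticoid receptor) pathway activity.  Strata are compared with the
Wilcoxon rank-sum test with continuity correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def signature_score(
    expr: pd.DataFrame,
    signature: list[str],
    method: str = "mean",
    ddof: int = 1,
) -> pd.Series:
    """Per-sample signature activity score.

    Parameters
    ----------
    expr
        Gene x sample expression matrix (continuous scale, log values
        expected).
    signature
        Gene identifiers; genes absent from the matrix are skipped with a
        logged count, genes with zero variance across samples are excluded
        with a warning.
    method
        ``"mean"`` (default) or ``"sum"`` of per-gene z-scores.
    ddof
        Degrees of freedom for the per-gene standard deviation (1 = sample
        sd).

    Returns a Series indexed by sample.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score across samples")
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers")
    present = [g for g in signature if g in expr.index]
    n_missing = len(signature) - len(present)
    if n_missing:
        logger.info("signature_score: %d signature gene(s) absent from the "
                    "matrix, skipped", n_missing)
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expr.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=ddof)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("signature_score: %d zero-variance signature gene(s) "
                       "excluded", int(degenerate.sum()))
        sub = sub.loc[~degenerate]
        sd = sd.loc[~degenerate]
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    if method == "mean":
        return z.mean(axis=0)
    if method == "sum":
        return z.sum(axis=0)
    raise ValueError(f"unknown aggregation method {method!r}")


def stratify(scores: pd.Series, scheme: str = "quartile-extremes") -> pd.Series:
    """Assign stratum labels from activity scores.

    Schemes
    -------
    ``quartile-extremes``
        Top 25 % of samples -> ``high``, bottom 25 % -> ``low``, middle 50 %
        -> ``excluded`` (the quartile split used to compare cohort extremes).
    ``tertiles``
        Three equal-count groups ``low`` / ``mid`` / ``high``.

    Ties are broken by stable sample order.  All-equal scores are refused.
    """
    n = len(scores)
    if scheme == "quartile-extremes":
        if n < 4:
            raise ValueError("quartile-extremes needs >= 4 samples")
    elif scheme == "tertiles":
        if n < 3:
            raise ValueError("tertiles needs >= 3 samples")
    else:
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    if scores.nunique() == 1:
        raise ValueError("all scores equal; stratification is degenerate")
    order = np.argsort(scores.to_numpy(), kind="stable")
    labels = pd.Series("excluded", index=scores.index, dtype=object)
    if scheme == "quartile-extremes":
        k = n // 4
        labels.iloc[order[:k]] = "low"
        labels.iloc[order[n - k:]] = "high"
    else:
        k = n // 3
        rem = n - 3 * k
        # distribute any remainder to the lower strata, keeping counts within 1
        sizes = [k + (1 if i < rem else 0) for i in range(3)]
        bounds = np.cumsum([0] + sizes)
        for name, lo, hi in zip(("low", "mid", "high"), bounds[:-1], bounds[1:]):
            labels.iloc[order[lo:hi]] = name
    return labels


def compare_groups(
    scores: pd.Series, group_labels: pd.Series, groups: tuple[str, str] | None = None
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of two score groups.

    Uses exact enumeration when both groups have <= 8 observations and there
    are no ties; otherwise the normal approximation with continuity
    correction and mid-rank ties.

    Returns ``(U statistic, two-sided p)`` where U counts pairs won by the
    first group.
    """
    group_labels = group_labels.reindex(scores.index)
    if groups is None:
        uniq = [g for g in pd.unique(group_labels.dropna()) if g != "excluded"]
        if len(uniq) != 2:
            raise ValueError(
                f"expected exactly two groups, found {list(uniq)}; "
                "pass groups=(a, b)"
            )
        groups = (uniq[0], uniq[1])
    x = scores[group_labels == groups[0]].to_numpy(float)
    y = scores[group_labels == groups[1]].to_numpy(float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 samples per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return float(res.statistic), float(res.pvalue)
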