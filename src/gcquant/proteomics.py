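"""Statistical post-processing of label-free (LFQ) proteomics matrices.

Implements the standard Perseus-style workflow applied downstream of the
database search: valid-value filtering, imputation of missing values from a
downshifted normal distribution (missing-not-at-random model for
low-abundance dropouts), per-protein differential t-testing with fold-change
thresholds and on/off calling, and IP-enrichment calling against an IgG
control.

Matrices are protein x sample :class:`pandas.DataFrame` objects of log2
intensities with ``NaN`` marking missing measurements.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: printed enrichment rule presets: (log2 enrichment cut, -log10 p cut)
ENRICHMENT_PRESETS = {"GR": (2.5, 2.0), "p57": (1.5, 1.3)}


def _group_columns(matrix: pd.DataFrame, groups: pd.Series) -> dict[str, list]:
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = matrix.columns[groups.isna()].tolist()
        raise ValueError(f"samples without a group label: {missing}")
    return {g: list(cols) for g, cols in matrix.columns.groupby(groups).items()}


def filter_valid(
    matrix: pd.DataFrame,
    mode: str = "overall-fraction",
    min_fraction: float = 0.66,
    min_count: int = 2,
    groups: pd.Series | None = None,
    require: str = "all-groups",
) -> pd.DataFrame:
    """Keep proteins with enough observed (non-missing) values.

    Modes
    -----
    ``overall-fraction``
        Keep rows with at least ``min_fraction`` of all samples observed
        (e.g. 0.66 for the "at least 66 % valid values" rule).
    ``per-group-count``
        Keep rows with at least ``min_count`` observed values in every group
        (``require="all-groups"``, e.g. "two valid values out of 3 in both
        conditions") or in at least one group (``require="any-group"``).

    Idempotent; never increases the row count.
    """
    observed = matrix.notna()
    if mode == "overall-fraction":
        keep = observed.mean(axis=1) >= min_fraction
    elif mode == "per-group-count":
        if groups is None:
            raise ValueError("per-group-count filtering needs group labels")
        per_group = pd.DataFrame(
            {g: observed[cols].sum(axis=1)
             for g, cols in _group_columns(matrix, groups).items()}
        )
        if require == "all-groups":
            keep = (per_group >= min_count).all(axis=1)
        elif require == "any-group":
            keep = (per_group >= min_count).any(axis=1)
        else:
            raise ValueError(f"unknown require mode {require!r}")
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out = matrix.loc[keep]
    if out.empty:
        logger.warning("filter_valid removed every protein")
    return out


def impute_downshift(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Replace missing values with draws from a downshifted normal.

    Per sample column with observed mean ``mu`` and sd ``sigma``, missing
    entries are drawn independently from
    ``Normal(mu - downshift * sigma, (width * sigma)^2)`` — the Perseus
    convention (width 0.3, downshift 1.8 in sd units) modelling dropouts as
    low-abundance measurements.  Deterministic given the seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        observed = vals.dropna()
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        if observed.size < 3:
            raise ValueError(
                f"column {col!r}: fewer than 3 observed values; cannot impute"
            )
        mu, sigma = observed.mean(), observed.std(ddof=1)
        if sigma == 0:
            raise ValueError(f"column {col!r}: zero variance; cannot impute")
        draws = rng.normal(mu - downshift * sigma, width * sigma, n_missing)
        out.loc[vals.isna(), col] = draws
    return out


def differential_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    p_cut: float = 0.05,
    diff_cut: float = 1.5,
    diff_scale: str = "log2",
    raw_matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-protein two-sided Welch t-test between two groups.

    ``diff_cut`` is interpreted on the log2-difference scale by default
    (``[x/y] >= 1.5`` meaning a log2 difference of 1.5); pass
    ``diff_scale="ratio"`` to threshold at ``|difference| >= log2(diff_cut)``
    instead.

    When ``raw_matrix`` (the pre-imputation matrix) is given, proteins fully
    observed in one group and fully missing in the other bypass the test and
    are flagged ``on``/``off`` (present/absent in the second group).

    Returns a table indexed by protein with group means, ``log2_diff``
    (second group minus first, in group-label sort order), ``p``,
    ``neg_log10_p``, ``call`` in {up, down, ns, on, off} and ``on_off``.
    """
    cols = _group_columns(matrix, groups)
    if len(cols) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(cols)}")
    (g1, c1), (g2, c2) = sorted(cols.items())
    thresh = diff_cut if diff_scale == "log2" else np.log2(diff_cut)
    if diff_scale not in ("log2", "ratio"):
        raise ValueError(f"unknown diff_scale {diff_scale!r}")

    rows = []
    for protein, row in matrix.iterrows():
        a = row[c1].dropna().to_numpy(float)
        b = row[c2].dropna().to_numpy(float)
        rec = {"protein": protein, f"mean_{g1}": np.nan, f"mean_{g2}": np.nan,
               "log2_diff": np.nan, "p": np.nan, "neg_log10_p": np.nan,
               "call": "ns", "on_off": False}
        if raw_matrix is not None:
            raw = raw_matrix.loc[protein]
            ra, rb = raw[c1], raw[c2]
            if ra.notna().all() and rb.isna().all():
                rec.update(call="off", on_off=True,
                           **{f"mean_{g1}": ra.mean()})
                rows.append(rec)
                continue
            if ra.isna().all() and rb.notna().all():
                rec.update(call="on", on_off=True,
                           **{f"mean_{g2}": rb.mean()})
                rows.append(rec)
                continue
        if a.size < 2 or b.size < 2:
            logger.info("differential_test: %s has <2 observed values in a "
                        "group; skipped", protein)
            rows.append(rec)
            continue
        diff = float(b.mean() - a.mean())
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if a[0] == b[0] else 0.0
        else:
            p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        call = "ns"
        if p <= p_cut and abs(diff) >= thresh:
            call = "up" if diff > 0 else "down"
        rec.update(
            {f"mean_{g1}": a.mean(), f"mean_{g2}": b.mean(),
             "log2_diff": diff, "p": p,
             "neg_log10_p": -np.log10(p) if p > 0 else np.inf, "call": call}
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("protein")


def run_differential(
    matrix: pd.DataFrame,
    groups: pd.Series,
    filter_mode: str = "per-group-count",
    min_fraction: float = 0.66,
    min_count: int = 2,
    width: float = 0.3,
    downshift: float = 1.8,
    p_cut: float = 0.05,
    diff_cut: float = 1.5,
    diff_scale: str = "log2",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Full differential workflow: on/off detection, valid-value filtering,
    downshifted-normal imputation and per-protein testing.

    On/off proteins (fully observed in one group, fully missing in the
    other) are identified on the unfiltered matrix, so they survive even
    when the valid-value filter would discard them; remaining proteins are
    filtered, imputed and t-tested.  Proteins failing the filter and not
    on/off are untestable and omitted.
    """
    cols = _group_columns(matrix, groups)
    if len(cols) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(cols)}")
    (g1, c1), (g2, c2) = sorted(cols.items())
    obs1 = matrix[c1].notna()
    obs2 = matrix[c2].notna()
    on = obs1.sum(axis=1).eq(0) & obs2.all(axis=1)
    off = obs1.all(axis=1) & obs2.sum(axis=1).eq(0)
    onoff = matrix.loc[on | off]

    rest = matrix.loc[~(on | off)]
    filtered = filter_valid(rest, mode=filter_mode, min_fraction=min_fraction,
                            min_count=min_count, groups=groups)
    completed = impute_downshift(filtered, width=width, downshift=downshift,
                                 seed=seed)
    tested = differential_test(completed, groups, p_cut=p_cut,
                               diff_cut=diff_cut, diff_scale=diff_scale)
    if not onoff.empty:
        onoff_table = differential_test(onoff, groups, p_cut=p_cut,
                                        diff_cut=diff_cut,
                                        diff_scale=diff_scale,
                                        raw_matrix=onoff)
        tested = pd.concat([tested, onoff_table]).loc[
            matrix.index.intersection(
                tested.index.union(onoff_table.index), sort=False
            )
        ]
    return tested


def enrichment_call(
    ip: pd.DataFrame,
    control: pd.DataFrame,
    enrich_cut: float | None = None,
    logp_cut: float | None = None,
    preset: str | None = None,
) -> pd.DataFrame:
    """Call proteins enriched in an IP over an IgG control.

    Per protein the log2 difference of IP minus control means and a
    two-sided Welch t-test are computed; a protein is an interactor iff
    ``difference >= enrich_cut`` and ``-log10 p > logp_cut``.  Presets
    ``"GR"`` (2.5 / 2) and ``"p57"`` (1.5 / 1.3) encode the standard GR-RIME and
    p57-RIME rule boundaries.
    """
    if preset is not None:
        if preset not in ENRICHMENT_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; options: {list(ENRICHMENT_PRESETS)}"
            )
        enrich_cut, logp_cut = ENRICHMENT_PRESETS[preset]
    if control.empty or control.shape[1] == 0:
        raise ValueError("missing control (IgG) matrix")
    if enrich_cut is None or logp_cut is None:
        raise ValueError("both enrich_cut and logp_cut (or a preset) required")
    shared = ip.index.intersection(control.index)
    rows = []
    for protein in shared:
        a = ip.loc[protein].dropna().to_numpy(float)
        b = control.loc[protein].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            continue
        diff = float(a.mean() - b.mean())
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if a[0] == b[0] else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        neg_log10_p = -np.log10(p) if p > 0 else np.inf
        rows.append(
            {
                "protein": protein,
                "log2_enrichment": diff,
                "p": p,
                "neg_log10_p": neg_log10_p,
                "interactor": bool(diff >= enrich_cut
                                   and neg_log10_p > logp_cut),
            }
        )
    return pd.DataFrame(rows).set_index("protein")


def igg_correct(matrix: pd.DataFrame, igg: pd.DataFrame) -> pd.DataFrame:
    """Subtract each protein's mean IgG intensity from an IP matrix.

    Proteins absent from the IgG matrix are left unchanged.
    """
    means = igg.mean(axis=1)
    out = matrix.copy()
    common = out.index.intersection(means.index)
    out.loc[common] = out.loc[common].sub(means.loc[common], axis=0)
    return out
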