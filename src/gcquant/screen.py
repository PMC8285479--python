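"""Viability-screen scoring: NPI normalization, differential survival and hit calling.

Plates are handled as long-format :class:`pandas.DataFrame` objects with the
columns ``plate, row, column, role, compound, concentration_uM, arm,
replicate, value``.  Roles are ``pos_ctrl`` (full-kill control), ``neg_ctrl``
(vehicle-only control), ``compound`` and ``empty``.

The scoring model: each plate is normalized with the normalised percentage
inhibition (NPI) method, anchoring the positive-control mean to 0 and the
negative-control mean to 1.  Per compound and concentration the treated-arm
mean is compared to the vehicle-arm mean; the difference of means is the
differential survival value, tested with a two-sided Welch t-test over the
replicate values and corrected across compounds with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PLATE_COLUMNS = [
    "plate", "row", "column", "role", "compound",
    "concentration_uM", "arm", "replicate", "value",
]

ROLES = {"pos_ctrl", "neg_ctrl", "compound", "empty"}


class DegeneratePlateError(ValueError):
    """Raised when a plate's control means coincide and NPI is undefined."""


def validate_plate_table(plates: pd.DataFrame) -> None:
    """Check the long-format plate table schema and control requirements."""
    missing = [c for c in PLATE_COLUMNS if c not in plates.columns]
    if missing:
        raise ValueError(f"plate table is missing required column(s): {missing}")
    bad_roles = set(plates["role"].unique()) - ROLES
    if bad_roles:
        raise ValueError(f"unknown well role(s): {sorted(bad_roles)}")
    values = plates.loc[plates["role"] != "empty", "value"]
    if not np.isfinite(values.to_numpy(float)).all():
        raise ValueError("non-finite viability values in plate table")
    for plate_id, grp in plates.groupby("plate"):
        counts = grp["role"].value_counts()
        for role in ("pos_ctrl", "neg_ctrl"):
            if counts.get(role, 0) < 2:
                raise ValueError(
                    f"plate {plate_id!r} has fewer than 2 {role} wells"
                )


def npi_normalize(plates: pd.DataFrame) -> pd.DataFrame:
    """Normalise raw viability per plate with the NPI method.

    Per plate, ``value' = (value - mean_pos) / (mean_neg - mean_pos)`` so that
    the positive-control (full-kill) mean maps to 0 and the negative-control
    (vehicle) mean maps to 1.  The transform is invariant to any per-plate
    affine rescaling of the raw values.

    Returns a copy of the table with normalized ``value``.
    """
    validate_plate_table(plates)
    out = plates.copy()
    normed = pd.Series(np.nan, index=out.index, dtype=float)
    for plate_id, grp in out.groupby("plate"):
        mean_pos = grp.loc[grp["role"] == "pos_ctrl", "value"].mean()
        mean_neg = grp.loc[grp["role"] == "neg_ctrl", "value"].mean()
        span = mean_neg - mean_pos
        if span == 0 or not np.isfinite(span):
            raise DegeneratePlateError(
                f"plate {plate_id!r}: positive- and negative-control means "
                f"coincide ({mean_pos}); NPI undefined"
            )
        normed.loc[grp.index] = (grp["value"] - mean_pos) / span
    out["value"] = normed
    return out


def differential_viability(
    treated: np.ndarray, vehicle: np.ndarray, welch: bool = True
) -> tuple[float, float]:
    """Differential survival (treated mean - vehicle mean) and two-sided
    t-test p-value.

    ``welch=True`` (default) uses the unequal-variance Welch t-test;
    ``welch=False`` the pooled-variance Student t-test, which is exactly
    calibrated when the arm variances are equal — at 3 replicates per arm
    the Welch degrees-of-freedom approximation is conservative at the tails.

    Degenerate convention: when both arms have zero variance the t statistic
    is undefined; equal means give p = 1 (no evidence of difference), unequal
    means give p = 0 (the difference is exact).
    """
    treated = np.asarray(treated, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    treated = treated[np.isfinite(treated)]
    vehicle = vehicle[np.isfinite(vehicle)]
    if treated.size < 2 or vehicle.size < 2:
        raise ValueError("need >= 2 replicates per arm for the t-test")
    diff = float(treated.mean() - vehicle.mean())
    if np.ptp(treated) == 0.0 and np.ptp(vehicle) == 0.0:
        p = 1.0 if treated[0] == vehicle[0] else 0.0
    else:
        p = float(stats.ttest_ind(treated, vehicle, equal_var=not welch).pvalue)
    return diff, p


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_screen(
    plates: pd.DataFrame,
    treated_arm: str,
    vehicle_arm: str = "vehicle",
    normalized: bool = False,
    welch: bool = True,
) -> pd.DataFrame:
    """Score every compound x concentration of a screen.

    Parameters
    ----------
    plates
        Long-format plate table (raw values unless ``normalized=True``).
    treated_arm, vehicle_arm
        Arm labels to compare (e.g. ``pretreat`` vs ``vehicle``).

    Returns a table with one row per (compound, concentration):
    per-arm means, ``differential`` survival, ``p``, ``padj`` and
    ``hit_class`` (from :func:`classify_hits` at its defaults).
    """
    if not normalized:
        plates = npi_normalize(plates)
    wells = plates[plates["role"] == "compound"].copy()
    n_nan = wells["value"].isna().sum()
    if n_nan:
        logger.warning("dropping %d NaN compound wells", n_nan)
        wells = wells.dropna(subset=["value"])

    rows = []
    for (compound, conc), grp in wells.groupby(
        ["compound", "concentration_uM"], sort=True
    ):
        treated = grp.loc[grp["arm"] == treated_arm, "value"].to_numpy()
        vehicle = grp.loc[grp["arm"] == vehicle_arm, "value"].to_numpy()
        if treated.size < 2 or vehicle.size < 2:
            logger.warning(
                "compound %s @ %s uM: fewer than 2 replicates in an arm; skipped",
                compound, conc,
            )
            continue
        diff, p = differential_viability(treated, vehicle, welch=welch)
        rows.append(
            {
                "compound": compound,
                "concentration_uM": conc,
                "mean_vehicle": vehicle.mean(),
                "mean_treated": treated.mean(),
                "differential": diff,
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["padj"] = adjust_bh(result["p"].to_numpy())
    return classify_hits(result)


def classify_hits(
    results: pd.DataFrame,
    alpha: float = 0.05,
    sensitize_cut: float = -0.3,
    tolerance_cut: float = 0.3,
) -> pd.DataFrame:
    """Call hits: sensitized iff padj < alpha and differential < sensitize_cut;
    tolerant iff padj < alpha and differential > tolerance_cut; else unchanged.
    """
    if "padj" not in results.columns:
        raise ValueError("classify_hits requires adjusted p-values ('padj')")
    out = results.copy()
    sig = out["padj"] < alpha
    out["hit_class"] = "unchanged"
    out.loc[sig & (out["differential"] < sensitize_cut), "hit_class"] = "sensitized"
    out.loc[sig & (out["differential"] > tolerance_cut), "hit_class"] = "tolerant"
    return out


def select_followup(
    plates: pd.DataFrame,
    cut: float = 0.7,
    concentration: float = 5.0,
    arm: str = "vehicle",
    normalized: bool = False,
) -> list[str]:
    """Compounds whose mean normalized viability in the given arm at the given
    concentration is strictly below ``cut`` (the follow-up screen selection).
    """
    if not normalized:
        plates = npi_normalize(plates)
    wells = plates[
        (plates["role"] == "compound")
        & (plates["arm"] == arm)
        & (plates["concentration_uM"] == concentration)
    ]
    means = wells.groupby("compound")["value"].mean()
    return sorted(means.index[means < cut].tolist())
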