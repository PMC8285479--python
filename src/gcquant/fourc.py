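"""Region-restricted comparison of 4C contact profiles between two conditions.

A 4C profile holds normalized contact signal for an ordered set of restriction
fragments around one viewpoint, per condition and replicate.  Conditions are
compared inside named genomic regions (printed in 1-based inclusive
coordinates, e.g. ``chr11: 2773921-2812270``): per fragment the replicate
means of the two conditions are paired and the paired differences are tested
with the Wilcoxon signed-rank test.  An unpaired rank-sum variant is
available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RegionDef:
    """Named genomic region in 1-based inclusive coordinates."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"region {self.name!r}: start {self.start} > end {self.end}"
            )

    @property
    def span(self) -> int:
        """Number of positions covered (inclusive arithmetic)."""
        return self.end - self.start + 1


_REGION_RE = re.compile(
    r"^\s*(?P<chrom>[\w.]+)\s*:\s*(?P<start>[\d,]+)\s*-\s*(?P<end>[\d,]+)\s*$"
)


def parse_region(text: str, name: str | None = None) -> RegionDef:
    """Parse a printed region string like ``"chr11: 2773921-2812270"``."""
    m = _REGION_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse region string {text!r}")
    return RegionDef(
        name=name or text.strip(),
        chrom=m["chrom"],
        start=int(m["start"].replace(",", "")),
        end=int(m["end"].replace(",", "")),
    )


class EmptyRegionError(ValueError):
    """Raised when no fragment midpoint falls inside a region."""


def validate_profile(profile: pd.DataFrame) -> None:
    """Check a tidy 4C profile table (1-based inclusive fragment coords)."""
    required = {"chrom", "start", "end", "condition", "replicate", "signal"}
    missing = required - set(profile.columns)
    if missing:
        raise ValueError(f"profile table missing column(s): {sorted(missing)}")
    if (profile["signal"] < 0).any():
        raise ValueError("negative 4C signal values")
    frags = profile[["chrom", "start", "end"]].drop_duplicates()
    for chrom, grp in frags.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping fragments on {chrom}")
    conds = profile["condition"].unique()
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, found {list(conds)}")
    sets = [
        set(map(tuple, profile.loc[profile["condition"] == c,
                                   ["chrom", "start", "end"]].to_numpy()))
        for c in conds
    ]
    if sets[0] != sets[1]:
        raise ValueError("conditions cover different fragment sets")


def fragments_in_region(profile: pd.DataFrame, region: RegionDef) -> pd.DataFrame:
    """Rows whose fragment midpoint lies within the region (inclusive).

    Fragment coordinates are 1-based inclusive; a fragment belongs to the
    region iff its midpoint ``(start + end) / 2`` satisfies
    ``region.start <= midpoint <= region.end``.
    """
    sub = profile[profile["chrom"] == region.chrom]
    if sub.empty:
        raise EmptyRegionError(
            f"chromosome {region.chrom!r} absent from profile"
        )
    mid = 0.5 * (sub["start"] + sub["end"])
    sub = sub[(mid >= region.start) & (mid <= region.end)]
    if sub.empty:
        raise EmptyRegionError(f"no fragment midpoint inside {region.name!r}")
    return sub


def signed_rank_test(differences: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped; exact enumeration is used for <= 20
    non-zero differences without tied magnitudes, otherwise the normal
    approximation with continuity correction.  All-zero input gives p = 1.
    """
    d = np.asarray(differences, float)
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    mags = np.abs(nz)
    has_ties = np.unique(mags).size < mags.size
    if nz.size <= 20 and not has_ties:
        mode = "exact"
    else:
        mode = "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(mode == "approx"),
        alternative="two-sided", method=mode,
    )
    return float(res.pvalue)


def region_compare(
    profile: pd.DataFrame,
    region: RegionDef,
    paired: bool = True,
    min_fragments: int = 5,
) -> tuple[float, float]:
    """Compare the two conditions of a profile inside one region.

    Per fragment, replicate signals are averaged within condition; the paired
    per-fragment differences (condition 2 minus condition 1, in the order the
    conditions appear in the table) feed the Wilcoxon signed-rank test.  With
    ``paired=False`` the per-fragment condition means are compared with the
    unpaired rank-sum test instead.

    Returns ``(median per-fragment difference, two-sided p)``.
    """
    sub = fragments_in_region(profile, region)
    conds = list(profile["condition"].unique())
    means = (
        sub.groupby(["chrom", "start", "end", "condition"])["signal"]
        .mean()
        .unstack("condition")
    )
    if means.shape[0] < min_fragments:
        raise ValueError(
            f"region {region.name!r} holds {means.shape[0]} fragments; "
            f"need >= {min_fragments}"
        )
    a = means[conds[0]].to_numpy()
    b = means[conds[1]].to_numpy()
    diff = b - a
    median_diff = float(np.median(diff))
    if paired:
        if np.all(diff == 0):
            return 0.0, 1.0
        p = signed_rank_test(diff)
    else:
        res = stats.mannwhitneyu(
            b, a, alternative="two-sided",
            method="exact" if (len(a) <= 8 and np.unique(np.r_[a, b]).size
                               == len(a) + len(b)) else "asymptotic",
        )
        p = float(res.pvalue)
    return median_diff, p


def compare_regions(
    profile: pd.DataFrame, regions: list[RegionDef], paired: bool = True
) -> pd.DataFrame:
    """Run :func:`region_compare` over a list of regions.

    Returns a table (region, chrom, start, end, n_fragments, median_diff, p).
    """
    validate_profile(profile)
    rows = []
    for region in regions:
        sub = fragments_in_region(profile, region)
        n_frag = sub[["chrom", "start", "end"]].drop_duplicates().shape[0]
        median_diff, p = region_compare(profile, region, paired=paired)
        rows.append(
            {
                "region": region.name,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "n_fragments": n_frag,
                "median_diff": median_diff,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
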