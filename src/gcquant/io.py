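"""Readers and writers for the pipeline's plain-text and image formats.

Conventions
-----------
* matrices (expression, accessibility, LFQ): TSV with row ids in the first
  column, samples across columns; empty cells are missing values.
* plates: long-format TSV with the schema of :mod:`gcquant.screen`.
* BED: 0-based half-open intervals, tab-separated chrom/start/end/name.
* region files: one region per line, ``name<TAB>chrom: start-end`` with
  printed 1-based inclusive coordinates.
* 4C profiles: tidy TSV (chrom, start, end, condition, replicate, signal),
  1-based inclusive fragment coordinates.
* images: TIFF (any integer or float dtype) with a JSON sidecar carrying
  ``pixel_size_um``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fourc import RegionDef, parse_region
from .screen import PLATE_COLUMNS


def read_matrix(path) -> pd.DataFrame:
    """Read a row-id x sample TSV matrix (blank cells -> NaN)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_plates(path) -> pd.DataFrame:
    """Read a long-format plate table, validating the schema."""
    df = pd.read_csv(path, sep="\t", dtype={"compound": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: plate table missing required column(s): {missing}"
        )
    df["compound"] = df["compound"].fillna("")
    return df


def write_plates(plates: pd.DataFrame, path) -> None:
    plates.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file of 0-based half-open intervals.

    Malformed coordinates are rejected with the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {start}-{end} "
                    "(need 0 <= start < end)"
                )
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(bed: pd.DataFrame, path) -> None:
    bed[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_regions(path) -> list[RegionDef]:
    """Read a region file: ``name<TAB>chrom: start-end`` per line
    (1-based inclusive, as printed in publications)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, spec = line.split("\t", 1)
            else:
                name, spec = None, line
            try:
                regions.append(parse_region(spec, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


def read_fourc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fourc(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def read_groups(path) -> pd.Series:
    """Read a sample -> group map TSV (columns ``sample``, ``group``)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: group map missing column {col!r}")
    return df.set_index("sample")["group"]


def write_image(path, channels: np.ndarray, pixel_size_um: float) -> None:
    """Write a multi-channel image as 16-bit TIFF with a JSON sidecar."""
    arr = np.asarray(channels)
    arr16 = np.clip(np.round(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, arr16)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({"pixel_size_um": pixel_size_um}))


def read_image(path, pixel_size_um: float | None = None):
    """Read a TIFF image; pixel size comes from the JSON sidecar unless
    overridden.  Returns ``(array, pixel_size_um)``."""
    arr = tifffile.imread(path)
    if pixel_size_um is None:
        sidecar = Path(path).with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no pixel size given and sidecar {sidecar} not found"
            )
        pixel_size_um = float(json.loads(sidecar.read_text())["pixel_size_um"])
    return np.asarray(arr, float), pixel_size_um
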