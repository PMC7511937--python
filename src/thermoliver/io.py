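"""Reading and writing temperature maps, ROIs, manifests, and feature tables.

A temperature map is a plain 2-D ``numpy.ndarray`` of floats in °C. The
canonical on-disk format is a headerless CSV matrix (one image row per CSV
row); 32-bit float TIFF is supported as an alternative, selected by file
extension. Manifests and feature tables are CSV files with a header row.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Fixed, documented order of the nine ROI features.
FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "entropy",
    "contrast",
    "homogeneity",
    "energy",
    "correlation",
)

#: Camera-plausible temperature range in °C; values outside trigger a warning.
PLAUSIBLE_RANGE = (-20.0, 120.0)

MANIFEST_COLUMNS = ("mouse_id", "group", "week", "image_path")
GROUPS = ("control", "diseased")


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, bad schema)."""


def validate_map(values: np.ndarray) -> np.ndarray:
    """Coerce to a float64 2-D array and enforce map invariants.

    All values must be finite; values outside the camera's plausible
    range emit a warning but are accepted.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"temperature map must be a non-empty 2-D grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"non-finite temperature at (row {bad[0]}, col {bad[1]})")
    lo, hi = PLAUSIBLE_RANGE
    if arr.min() < lo or arr.max() > hi:
        warnings.warn(
            f"temperatures outside plausible camera range [{lo}, {hi}] °C "
            f"(observed {arr.min():.2f}..{arr.max():.2f})",
            stacklevel=2,
        )
    return arr


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open [start, end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ValueError(f"degenerate ROI {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)

    def check_bounds(self, rows: int, cols: int) -> None:
        if self.row_end > rows or self.col_end > cols:
            raise ValueError(
                f"ROI {self} out of bounds for map of shape ({rows}, {cols})"
            )


def crop(values: np.ndarray, roi: ROI) -> np.ndarray:
    """Return the ROI sub-matrix of a temperature map."""
    arr = np.asarray(values, dtype=np.float64)
    roi.check_bounds(*arr.shape)
    return arr[roi.row_start : roi.row_end, roi.col_start : roi.col_end]


def full_roi(values: np.ndarray) -> ROI:
    """ROI covering the entire map."""
    r, c = np.asarray(values).shape
    return ROI(0, r, 0, c)


def read_map(path: str | Path) -> np.ndarray:
    """Read a temperature map from a CSV matrix or a float TIFF.

    CSV rows must be rectangular and numeric; errors name the offending
    row and column. TIFF files must hold a 2-D float image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such map file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".csv":
        rows: list[list[float]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            for r, record in enumerate(csv.reader(fh)):
                if not record:
                    continue
                parsed = []
                for c, cell in enumerate(record):
                    try:
                        parsed.append(float(cell))
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric cell {cell!r} at row {r}, column {c}"
                        ) from None
                if rows and len(parsed) != len(rows[0]):
                    raise FormatError(
                        f"{path}: ragged row {r} has {len(parsed)} cells, expected {len(rows[0])}"
                    )
                rows.append(parsed)
        if not rows:
            raise FormatError(f"{path}: empty map file")
        return validate_map(np.array(rows))
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if not np.issubdtype(arr.dtype, np.floating):
            raise FormatError(f"{path}: TIFF map must be a float image, got dtype {arr.dtype}")
        return validate_map(arr)
    raise FormatError(f"{path}: unsupported map extension {suffix!r} (use .csv or .tif)")


def write_map(values: np.ndarray, path: str | Path) -> None:
    """Write a temperature map; CSV with 8 significant digits, or float32 TIFF."""
    arr = validate_map(values)
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        np.savetxt(path, arr, fmt="%.8g", delimiter=",")
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    else:
        raise FormatError(f"{path}: unsupported map extension {suffix!r} (use .csv or .tif)")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Columns: mouse_id, group, week, image_path. Groups must be
    ``control``/``diseased`` and constant per mouse across weeks.
    """
    df = pd.read_csv(path, dtype={"mouse_id": str, "group": str, "image_path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    unknown = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: manifest has unknown columns {unknown}")
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise FormatError(f"{path}: unknown group labels {bad_groups} (expected {GROUPS})")
    groups_per_mouse = df.groupby("mouse_id")["group"].nunique()
    inconsistent = groups_per_mouse[groups_per_mouse > 1].index.tolist()
    if inconsistent:
        raise FormatError(
            f"{path}: group label changes across weeks for mouse_id(s) {inconsistent}"
        )
    df["week"] = df["week"].astype(int)
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


@dataclass
class WeeklyFeatureTable:
    """Per-mouse feature vectors for one week.

    ``data`` has columns ``mouse_id``, ``group`` and the nine features in
    :data:`FEATURE_NAMES` order; mouse ids are unique within the week.
    """

    week: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("mouse_id", "group", *FEATURE_NAMES) if c not in self.data.columns]
        if missing:
            raise FormatError(f"feature table missing columns {missing}")
        if self.data["mouse_id"].duplicated().any():
            dup = self.data.loc[self.data["mouse_id"].duplicated(), "mouse_id"].tolist()
            raise FormatError(f"duplicate mouse_id(s) in week {self.week}: {dup}")
        vals = self.data.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite feature values in week {self.week}")

    @property
    def mouse_ids(self) -> list[str]:
        return self.data["mouse_id"].tolist()

    def matrix(self) -> np.ndarray:
        """N×9 feature matrix in the documented column order."""
        return self.data.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)


FEATURE_TABLE_COLUMNS = ("mouse_id", "group", "week", *FEATURE_NAMES)


def write_feature_table(tables: WeeklyFeatureTable | list[WeeklyFeatureTable], path: str | Path) -> None:
    """Write one or several weekly feature tables to a single long CSV."""
    if isinstance(tables, WeeklyFeatureTable):
        tables = [tables]
    frames = []
    for t in tables:
        df = t.data.copy()
        df.insert(2, "week", t.week)
        frames.append(df.loc[:, list(FEATURE_TABLE_COLUMNS)])
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(FEATURE_TABLE_COLUMNS))
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[WeeklyFeatureTable]:
    """Read a long feature CSV back into per-week tables (sorted by week)."""
    df = pd.read_csv(path, dtype={"mouse_id": str, "group": str})
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    unknown = [c for c in df.columns if c not in FEATURE_TABLE_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: feature table has unknown columns {unknown}")
    tables = []
    for week, sub in df.groupby("week"):
        tables.append(WeeklyFeatureTable(int(week), sub.drop(columns="week").reset_index(drop=True)))
    return sorted(tables, key=lambda t: t.week)
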