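"""Reading, validating and normalising per-cell segmentation exports.

The upstream image-analysis step (cell segmentation + per-marker intensity
thresholding) exports one table per slide with, per cell, a bounding box or
centroid and a binary positivity call for each of the 8 panel markers. This
module turns those exports into canonical micron-coordinate
:class:`CellTable` objects; all coordinates downstream are in µm.

Canonical columns of ``CellTable.cells``: ``cell_id``, ``x``, ``y``
(centroid, µm), optional ``x_min/x_max/y_min/y_max`` (µm), and one boolean
column per panel marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .panel import MarkerPanel

BBOX_COLS = ("x_min", "x_max", "y_min", "y_max")

_TRUTHY = {"1", "true", "yes", "pos", "positive", "t"}
_FALSY = {"0", "false", "no", "neg", "negative", "f", ""}


class SchemaError(ValueError):
    """Input table is missing a required column."""


class ParseError(ValueError):
    """A cell row could not be parsed (non-numeric coordinate etc.)."""


class EmptyInputError(ValueError):
    """Input table contains no cells."""


@dataclass
class CellTable:
    """Per-cell records for one slide, in µm, plus slide metadata."""

    panel: MarkerPanel
    slide_id: str
    cells: pd.DataFrame
    response: str = "unknown"  # responder | non-responder | unknown
    sample_type: str = "resection"  # resection | biopsy

    def __post_init__(self) -> None:
        if self.response not in ("responder", "non-responder", "unknown"):
            raise ValueError(f"bad response label {self.response!r}")
        if self.sample_type not in ("resection", "biopsy"):
            raise ValueError(f"bad sample type {self.sample_type!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def positivity(self) -> np.ndarray:
        """(n_cells, 8) boolean positivity matrix in panel marker order."""
        return self.cells[list(self.panel.markers)].to_numpy(dtype=bool)

    def coords(self) -> np.ndarray:
        """(n_cells, 2) centroid coordinates in µm."""
        return self.cells[["x", "y"]].to_numpy(dtype=float)


def compute_centroid(
    x_min: float, x_max: float, y_min: float, y_max: float
) -> tuple[float, float]:
    """Bounding-box centroid: ((x_min+x_max)/2, (y_min+y_max)/2)."""
    if x_min > x_max or y_min > y_max:
        raise ValueError(
            f"inverted bounding box: x=[{x_min},{x_max}] y=[{y_min},{y_max}]"
        )
    return (x_min + x_max) / 2.0, (y_min + y_max) / 2.0


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    as_str = series.astype(str).str.strip().str.lower()
    truthy = as_str.isin(_TRUTHY)
    falsy = as_str.isin(_FALSY)
    bad = ~(truthy | falsy) & series.notna()
    if bad.any():
        # numeric fallback: any nonzero number is positive
        numeric = pd.to_numeric(series[bad], errors="coerce")
        if numeric.isna().any():
            row = int(series.index[bad][0])
            raise ParseError(
                f"column {column!r}: unparseable positivity value at row {row}"
            )
        truthy = truthy | (pd.to_numeric(as_str, errors="coerce") != 0).fillna(False)
    missing = series.isna()
    if missing.any():
        row = int(series.index[missing][0])
        raise ParseError(f"column {column!r}: missing marker call at row {row}")
    return truthy


def read_cell_table(
    path: str | Path,
    panel: MarkerPanel,
    slide_id: str | None = None,
    coord_unit: str = "um",
    column_map: Mapping[str, str] | None = None,
    response: str = "unknown",
    sample_type: str = "resection",
) -> CellTable:
    """Read one slide's per-cell export into a canonical µm CellTable.

    Parameters
    ----------
    path
        CSV or Parquet file with one row per cell.
    panel
        Marker panel; one positivity column per marker is required.
    coord_unit
        ``"um"`` (coordinates kept as-is) or ``"px"`` (multiplied by the
        panel resolution).
    column_map
        Optional mapping from canonical names (``cell_id``, ``x``, ``y``,
        ``x_min`` ... and marker names) to the vendor's column names; absorbs
        whatever export schema the segmentation software produced.

    Either a centroid (``x``/``y``) or a full bounding box must be present;
    the centroid is derived from the box when absent. Cells with a missing
    marker call are rejected, not imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".parquet", ".pq"):
        raw = pd.read_parquet(path)
    else:
        raw = pd.read_csv(path)
    if coord_unit not in ("um", "px"):
        raise ValueError(f"coord_unit must be 'um' or 'px', got {coord_unit!r}")

    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items() if v in raw.columns}
    df = raw.rename(columns=rename)

    for marker in panel.markers:
        if marker not in df.columns:
            raise SchemaError(f"missing positivity column for marker {marker!r}")

    have_bbox = all(c in df.columns for c in BBOX_COLS)
    have_centroid = "x" in df.columns and "y" in df.columns
    if not (have_bbox or have_centroid):
        raise SchemaError(
            "need coordinate columns: either x/y centroids or "
            "x_min/x_max/y_min/y_max bounding boxes"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no cells")

    coord_cols = [c for c in ("x", "y", *BBOX_COLS) if c in df.columns]
    coords = df[coord_cols].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1)
    if bad.any():
        raise ParseError(
            f"{path}: non-numeric coordinate at row {int(np.flatnonzero(bad)[0])}"
        )

    scale = panel.resolution_um_per_px if coord_unit == "px" else 1.0
    out = pd.DataFrame(index=df.index)
    if "cell_id" in df.columns:
        out["cell_id"] = df["cell_id"].astype(str)
    else:
        out["cell_id"] = [f"{slide_id or path.stem}-{i}" for i in range(len(df))]
    for c in coord_cols:
        out[c] = coords[c] * scale
    if have_bbox:
        if (out["x_min"] > out["x_max"]).any() or (out["y_min"] > out["y_max"]).any():
            bad_row = int(
                np.flatnonzero(
                    (out["x_min"] > out["x_max"]) | (out["y_min"] > out["y_max"])
                )[0]
            )
            raise ParseError(f"{path}: inverted bounding box at row {bad_row}")
        if not have_centroid:
            out["x"] = (out["x_min"] + out["x_max"]) / 2.0
            out["y"] = (out["y_min"] + out["y_max"]) / 2.0
    for marker in panel.markers:
        out[marker] = _coerce_bool(df[marker], marker).to_numpy()

    sid = slide_id
    if sid is None:
        sid = str(df["slide_id"].iloc[0]) if "slide_id" in df.columns else path.stem
    out = out.reset_index(drop=True)
    return CellTable(
        panel=panel,
        slide_id=sid,
        cells=out,
        response=response,
        sample_type=sample_type,
    )


def write_cell_table(table: CellTable, path: str | Path) -> Path:
    """Write the canonical cell table (µm) to CSV or Parquet."""
    path = Path(path)
    df = table.cells.copy()
    df.insert(0, "slide_id", table.slide_id)
    if path.suffix.lower() in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def validate_cell_table(table: CellTable) -> list[str]:
    """Check per-cell invariants; violations are returned, not raised.

    Rules checked per cell: finite non-negative coordinates; x_min <= x_max
    and y_min <= y_max; centroid inside the bounding box (when present).
    Each violation string names the offending cell_id and the rule.
    """
    df = table.cells
    violations: list[str] = []
    ids = df["cell_id"].astype(str)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    finite = np.isfinite(xy).all(axis=1)
    nonneg = (xy >= 0).all(axis=1)
    for i in np.flatnonzero(~finite):
        violations.append(f"{ids.iloc[i]}: non-finite centroid")
    for i in np.flatnonzero(finite & ~nonneg):
        violations.append(f"{ids.iloc[i]}: negative coordinate")
    if all(c in df.columns for c in BBOX_COLS):
        box = df[list(BBOX_COLS)].to_numpy(dtype=float)
        inverted = (box[:, 0] > box[:, 1]) | (box[:, 2] > box[:, 3])
        for i in np.flatnonzero(inverted):
            violations.append(f"{ids.iloc[i]}: inverted bounding box")
        eps = 1e-9
        inside = (
            (xy[:, 0] >= box[:, 0] - eps)
            & (xy[:, 0] <= box[:, 1] + eps)
            & (xy[:, 1] >= box[:, 2] - eps)
            & (xy[:, 1] <= box[:, 3] + eps)
        )
        for i in np.flatnonzero(~inverted & ~inside):
            violations.append(f"{ids.iloc[i]}: centroid outside bounding box")
    return violations


def read_slide_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata CSV (slide_id, response, sample_type)."""
    meta = pd.read_csv(path)
    required = {"slide_id", "response", "sample_type"}
    missing = required - set(meta.columns)
    if missing:
        raise SchemaError(f"metadata missing columns: {sorted(missing)}")
    return meta


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a YAML canonical-name -> vendor-column mapping."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError("column map YAML must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def concat_metadata(tables: Iterable[CellTable]) -> pd.DataFrame:
    """Slide metadata DataFrame for a sequence of CellTables."""
    rows = [
        {
            "slide_id": t.slide_id,
            "response": t.response,
            "sample_type": t.sample_type,
            "n_cells": t.n_cells,
        }
        for t in tables
    ]
    return pd.DataFrame(rows)
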