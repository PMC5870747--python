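"""Table and image-stack I/O plus ROI coarse-graining.

Fields travel as delimited text tables with columns (id, x, y, value) and a
JSON sidecar (``<path>.json``) recording variant and wrapping convention;
time-series stacks as tables with a leading ``time_h`` column and one column
per unit, with locations and kind in the sidecar.  Image stacks (T x H x W,
e.g. multi-page TIFF) are coarse-grained to square ROI grids by block
averaging, with dim ROIs masked out of the index space entirely.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .moran import PhaseField, SpatialField, wrap_angle
from .phases import TimeSeriesStack
from .weights import Locations, NoUsableUnitsError

__all__ = [
    "RoiGridSpec",
    "SchemaError",
    "coarse_grain_stack",
    "read_tiff_stack",
    "write_field",
    "read_field",
    "write_stack",
    "read_stack",
]

logger = logging.getLogger("circamoran")


class SchemaError(ValueError):
    """A table violates the expected schema; names the column and row."""


@dataclass(frozen=True)
class RoiGridSpec:
    """Square ROI grid: edge length in pixels, a mean-intensity threshold
    below which an ROI is masked, and the crop policy for non-divisible
    frame dimensions ("trailing" keeps the top-left divisible region)."""

    roi_edge_px: int
    intensity_threshold: float | None = None
    crop: str = "trailing"

    def __post_init__(self) -> None:
        if self.roi_edge_px < 1:
            raise ValueError("roi_edge_px must be >= 1")
        if self.crop != "trailing":
            raise ValueError(f"unknown crop policy {self.crop!r}")


def coarse_grain_stack(
    images: np.ndarray, spec: RoiGridSpec
) -> tuple[TimeSeriesStack, np.ndarray]:
    """Average a T x H x W image stack over square ROI blocks.

    Each ROI value is the mean over its pixel block per frame.  ROIs whose
    temporal-mean intensity falls below the threshold are masked out of all
    downstream statistics (removed from the stack's columns).  Returns the
    stack over valid ROIs (locations are ROI grid indices; pixel-centre
    coordinates are recorded in ``meta``) and the boolean ROI validity grid.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValueError("expected a T x H x W stack")
    T, H, Wd = images.shape
    e = spec.roi_edge_px
    if H < e or Wd < e:
        raise ValueError("frames smaller than one ROI")
    nr, nc = H // e, Wd // e
    block = images[:, : nr * e, : nc * e].reshape(T, nr, e, nc, e).mean(axis=(2, 4))
    mask = np.ones((nr, nc), dtype=bool)
    if spec.intensity_threshold is not None:
        mask = block.mean(axis=0) >= spec.intensity_threshold
    if not mask.any():
        raise NoUsableUnitsError("intensity threshold masks every ROI")
    rr, cc = np.nonzero(mask)
    centers = np.column_stack([rr * e + (e - 1) / 2.0, cc * e + (e - 1) / 2.0])
    stack = TimeSeriesStack(
        times=np.arange(T, dtype=float),
        values=block[:, mask],
        locs=Locations(np.column_stack([rr, cc]).astype(float), frame="grid"),
        kind="intensity",
        meta={
            "roi_edge_px": e,
            "grid_shape": [int(nr), int(nc)],
            "pixel_centers": centers.tolist(),
            "intensity_threshold": spec.intensity_threshold,
        },
    )
    return stack, mask


def read_tiff_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a T x H x W float array."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# delimited tables + JSON sidecars
# ---------------------------------------------------------------------------

_FMT = "%.12g"  # 12 significant digits: lossless round-trip for our data


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_field(fld: SpatialField | PhaseField, path, sep: str = "\t") -> None:
    circular = isinstance(fld, PhaseField)
    values = fld.phases if circular else fld.values
    if fld.locs is None:
        raise ValueError("cannot serialise a field without locations")
    df = pd.DataFrame(
        {
            "id": np.arange(values.size),
            "x": fld.locs.coords[:, 0],
            "y": fld.locs.coords[:, 1],
            "value": values,
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format=_FMT)
    _sidecar(path).write_text(
        json.dumps(
            {
                "variant": "circular" if circular else "scalar",
                "wrapping": "(-pi, pi]" if circular else None,
                "frame": fld.locs.frame,
                "label": fld.label,
            }
        )
    )


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def read_field(path, variant: str | None = None, sep: str = "\t"):
    """Read a (id, x, y, value) table as a SpatialField or PhaseField.

    ``variant`` ("scalar" | "circular") defaults to the sidecar's record.
    Phase values outside (-pi, pi] are wrapped with a logged warning.
    """
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    if variant is None:
        variant = meta.get("variant", "scalar")
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ("id", "x", "y", "value"), path)
    for col in ("x", "y", "value"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col!r} at row {int(bad[0])}")
    locs = Locations(df[["x", "y"]].to_numpy(float), frame=meta.get("frame", "free"))
    vals = df["value"].to_numpy(float)
    if variant == "circular":
        if (vals <= -np.pi).any() or (vals > np.pi).any():
            logger.warning("%s: phase values outside (-pi, pi]; wrapping", path)
        return PhaseField(phases=wrap_angle(vals), locs=locs,
                          label=meta.get("label", ""))
    return SpatialField(values=vals, locs=locs, label=meta.get("label", ""))


def write_stack(stack: TimeSeriesStack, path, sep: str = "\t") -> None:
    cols = {"time_h": stack.times}
    for j in range(stack.n_units):
        cols[f"u{j}"] = stack.values[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format=_FMT)
    meta = {
        "kind": stack.kind,
        "locations": stack.locs.coords.tolist() if stack.locs is not None else None,
        "frame": stack.locs.frame if stack.locs is not None else None,
        "meta": _jsonable(stack.meta),
    }
    _sidecar(path).write_text(json.dumps(meta))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_stack(path, sep: str = "\t") -> TimeSeriesStack:
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ("time_h",), path)
    unit_cols = [c for c in df.columns if c != "time_h"]
    if not unit_cols:
        raise SchemaError(f"{path}: no unit columns")
    locs = None
    if meta.get("locations") is not None:
        locs = Locations(np.asarray(meta["locations"], float),
                         frame=meta.get("frame", "free"))
    return TimeSeriesStack(
        times=df["time_h"].to_numpy(float),
        values=df[unit_cols].to_numpy(float),
        locs=locs,
        kind=meta.get("kind", "intensity"),
        meta=meta.get("meta", {}),
    )
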