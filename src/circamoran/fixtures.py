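"""Synthetic inputs: binary grids, phase patterns and SCN-like movies.

Every generator is seed-deterministic and emits its ground truth (cluster
labels, planted phases) in the ``meta`` of the returned object, so pipeline
recovery can be asserted without external data.  The movie generator layers
a bioluminescence-like baseline (offset + linear slope + exponential rundown)
and Gaussian noise over cosine oscillations, so the detrend -> analytic
signal pipeline is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .moran import PhaseField, SpatialField, wrap_angle
from .phases import TimeSeriesStack
from .weights import Locations, grid_locations

__all__ = [
    "binary_grid",
    "phase_pattern",
    "MovieSpec",
    "synthetic_movie",
]


def binary_grid(
    rows: int,
    cols: int,
    kind: str = "random",
    p: float = 0.5,
    seed: int | None = 0,
    ragged: bool = False,
) -> SpatialField:
    """Binary 0/1 fields on a grid, archetypes of spatial (in)coherence.

    ``"blocks"``: two homogeneous half-planes (top rows 1, bottom 0) — near
    the positive extreme of Moran's I; with ``ragged=True`` cells along the
    boundary are flipped at random for a natural-looking interface.
    ``"checkerboard"``: strict parity alternation — exactly I = -1 under
    range-1 von Neumann weights.  ``"random"``: i.i.d. Bernoulli(p) cells.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if kind == "checkerboard":
        grid = ((rr + cc) % 2).astype(float)
    elif kind == "blocks":
        grid = (rr < rows // 2).astype(float)
        if ragged:
            boundary = np.isin(rr, [rows // 2 - 1, rows // 2])
            flip = boundary & (rng.random((rows, cols)) < 0.3)
            grid[flip] = 1.0 - grid[flip]
    elif kind == "random":
        if not (0.0 <= p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        grid = (rng.random((rows, cols)) < p).astype(float)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return SpatialField(
        values=grid.ravel(),
        locs=grid_locations(rows, cols),
        label=f"binary_{kind}",
        meta={"kind": kind, "rows": rows, "cols": cols, "seed": seed},
    )


def phase_pattern(
    rows: int,
    cols: int,
    kind: str = "random",
    *,
    center: tuple[float, float] | None = None,
    wavelength: float = 10.0,
    direction: float = 0.0,
    separation: float = 1.93,
    concentration: float = 8.0,
    weight: float = 0.5,
    seed: int | None = 0,
) -> PhaseField:
    """Archetypal phase arrangements on a grid.

    ``"spiral"``: theta(x, y) = atan2(y - y0, x - x0) around an off-node
    center — radially arranged phases covering the whole co-domain, hence
    low global coherence R but strong local spatial order.  ``"plane_wave"``:
    phase advances linearly along ``direction`` with the given wavelength
    (grid cells).  ``"random"``: i.i.d. uniform phases.  ``"two_cluster"``:
    upper and lower half-planes drawn from von Mises distributions whose mean
    directions sit ``separation`` radians apart (mimicking the ventro-lateral
    / dorso-medial clusters of long-photoperiod SCN slices).
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = rr.astype(float)
    cc = cc.astype(float)
    meta: dict = {"kind": kind, "rows": rows, "cols": cols, "seed": seed}
    if kind == "spiral":
        if center is None:
            center = ((rows - 1) / 2 + 0.5, (cols - 1) / 2 + 0.5)
        y0, x0 = center
        if float(y0).is_integer() and float(x0).is_integer() \
                and 0 <= y0 < rows and 0 <= x0 < cols:
            raise ValueError("spiral center on a lattice node leaves that "
                             "cell's phase undefined; use an off-node center")
        phases = np.arctan2(rr - y0, cc - x0)
        meta["center"] = (float(y0), float(x0))
    elif kind == "plane_wave":
        if wavelength <= 0:
            raise ValueError("wavelength must be positive")
        proj = cc * np.cos(direction) + rr * np.sin(direction)
        phases = 2.0 * np.pi * proj / wavelength
        meta.update(wavelength=wavelength, direction=direction)
    elif kind == "random":
        phases = rng.uniform(-np.pi, np.pi, size=(rows, cols))
    elif kind == "two_cluster":
        if not (0.0 <= separation <= np.pi):
            raise ValueError("separation must lie in [0, pi]")
        labels = (rr >= rows / 2).astype(int)
        mus = np.array([-separation / 2.0, separation / 2.0])
        phases = rng.vonmises(mus[labels], concentration)
        meta.update(separation=separation, concentration=concentration,
                    cluster_means=mus.tolist(), labels=labels.ravel().tolist())
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return PhaseField(
        phases=wrap_angle(phases.ravel()),
        locs=grid_locations(rows, cols),
        label=f"phase_{kind}",
        meta=meta,
    )


@dataclass(frozen=True)
class MovieSpec:
    """Specification of an SCN-like oscillatory intensity movie.

    Per ROI: ``baseline(t) + amplitude * cos(2 pi t / period + phase) +
    noise``, where the baseline is ``offset * exp(-decay * t) + slope * t``
    (mimicking bioluminescence signal rundown) and the planted phase is the
    ROI's cluster phase.  Defaults mirror circadian slice recordings:
    24 h period, 0.5 h sampling, a week of data.
    """

    rows: int = 10
    cols: int = 10
    cluster_map: np.ndarray | None = None  # per-ROI integer labels; None = all 0
    cluster_phases: tuple[float, ...] = (0.0,)
    period_h: float = 24.0
    amplitude: float = 10.0
    noise_sd: float = 0.0
    baseline: tuple[float, float, float] = (100.0, -0.05, 0.01)  # offset, slope, decay
    dt: float = 0.5
    duration_h: float = 168.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration_h < 2 * self.period_h:
            raise ValueError("duration must cover at least two periods")
        if self.cluster_map is not None:
            cm = np.asarray(self.cluster_map, dtype=int)
            if cm.shape != (self.rows, self.cols):
                raise ValueError("cluster_map shape must match the grid")
            if cm.max() >= len(self.cluster_phases) or cm.min() < 0:
                raise ValueError("cluster_map labels exceed cluster_phases")
            object.__setattr__(self, "cluster_map", cm)

    @classmethod
    def two_cluster(cls, rows: int = 10, cols: int = 10,
                    separation: float = 1.93, **kwargs) -> "MovieSpec":
        """Upper/lower half-plane clusters with phases -/+ separation / 2."""
        rr = np.arange(rows)[:, None] >= rows / 2
        cmap = np.broadcast_to(rr, (rows, cols)).astype(int)
        return cls(rows=rows, cols=cols, cluster_map=cmap,
                   cluster_phases=(-separation / 2.0, separation / 2.0), **kwargs)


def synthetic_movie(spec: MovieSpec) -> TimeSeriesStack:
    """Generate the intensity stack for ``spec``; ground truth in ``meta``.

    ``meta["true_phases"]`` holds each ROI's planted phase offset and
    ``meta["labels"]`` its cluster label, enabling recovery tests for the
    detrend -> analytic-signal pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.rows * spec.cols
    labels = (np.zeros((spec.rows, spec.cols), dtype=int)
              if spec.cluster_map is None else spec.cluster_map).ravel()
    phi = np.asarray(spec.cluster_phases, dtype=float)[labels]
    t = np.arange(0.0, spec.duration_h + 0.5 * spec.dt, spec.dt)
    offset, slope, decay = spec.baseline
    base = offset * np.exp(-decay * t) + slope * t
    osc = spec.amplitude * np.cos(2.0 * np.pi * t[:, None] / spec.period_h + phi[None, :])
    values = base[:, None] + osc
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return TimeSeriesStack(
        times=t,
        values=values,
        locs=grid_locations(spec.rows, spec.cols),
        kind="intensity",
        meta={
            "true_phases": wrap_angle(phi).tolist(),
            "labels": labels.tolist(),
            "period_h": spec.period_h,
            "seed": spec.seed,
        },
    )
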