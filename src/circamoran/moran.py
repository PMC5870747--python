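"""Moran's I for scalar fields and its circular variant for phase fields.

Moran's I is the ratio of local (neighbourhood-weighted) to global coherence,

    I = [ sum_ij w_ij (X_i - Xbar)(X_j - Xbar) / sum_ij w_ij ]
        / [ (1/N) sum_i (X_i - Xbar)^2 ],

near +1 for locally coherent fields, -1 for locally alternating fields, and
-1/(N-1) in expectation for spatially random fields.  For circular variates
(instantaneous oscillator phases on (-pi, pi]) arithmetic deviations are
meaningless across the branch cut, so the circular variant I_theta replaces
``X_i - Xbar`` with the signed shortest angular displacement to the circular
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .weights import EmptyBandError, Locations, WeightMatrix, distance_band_weights

__all__ = [
    "SpatialField",
    "PhaseField",
    "MoranResult",
    "CorrelogramBin",
    "DegenerateFieldError",
    "UndefinedCircularMeanError",
    "wrap_angle",
    "circular_distance",
    "circular_mean",
    "morans_i",
    "morans_i_circular",
    "correlogram",
]

#: resultant lengths below this leave the circular mean undefined
RESULTANT_TOL = 1e-9


class DegenerateFieldError(ValueError):
    """Raised for constant fields (zero variance), where I is undefined."""


class UndefinedCircularMeanError(ValueError):
    """Raised when the mean resultant vector is (numerically) zero."""


def wrap_angle(x):
    """Wrap angles canonically to (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    w = np.mod(x + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return w if w.ndim else float(w)


def circular_distance(a, b):
    """Signed shortest angular displacement a - b, in (-pi, pi].

    ``atan2(sin(a-b), cos(a-b))`` — the geodesic displacement on the unit
    circle, which Euclidean subtraction gets wrong across the branch cut
    (pi and -pi + eps are eps apart, not 2 pi - eps).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.arctan2(np.sin(a - b), np.cos(a - b))
    return d if d.ndim else float(d)


def circular_mean(phases) -> float:
    """Circular mean atan2(mean sin, mean cos), wrapped to (-pi, pi].

    Undefined (raises) when the mean resultant length is below
    ``RESULTANT_TOL``, e.g. for an antipodal pair.
    """
    phases = np.asarray(phases, dtype=float)
    c = np.cos(phases).mean()
    s = np.sin(phases).mean()
    if np.hypot(c, s) <= RESULTANT_TOL:
        raise UndefinedCircularMeanError(
            "mean resultant length ~ 0; circular mean undefined"
        )
    return float(wrap_angle(np.arctan2(s, c)))


@dataclass
class SpatialField:
    """N scalar observations X_i with (optional) 2-D locations."""

    values: np.ndarray
    locs: Locations | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 2:
            raise ValueError("a spatial field needs at least two units")
        if not np.isfinite(v).all():
            raise ValueError("field values must be finite")
        if self.locs is not None and len(self.locs) != v.size:
            raise ValueError("values and locations disagree in length")
        self.values = v

    @property
    def n_units(self) -> int:
        return self.values.size


@dataclass
class PhaseField:
    """N circular observations theta_i, canonically wrapped to (-pi, pi]."""

    phases: np.ndarray
    locs: Locations | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float).ravel()
        if p.size < 2:
            raise ValueError("a phase field needs at least two units")
        if not np.isfinite(p).all():
            raise ValueError("phases must be finite")
        if self.locs is not None and len(self.locs) != p.size:
            raise ValueError("phases and locations disagree in length")
        self.phases = wrap_angle(p)

    @property
    def n_units(self) -> int:
        return self.phases.size


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    n_units: int
    total_weight: float
    variant: str  # "scalar" | "circular"


def _moran_from_deviations(d: np.ndarray, W: WeightMatrix, variant: str) -> MoranResult:
    n = d.size
    if W.n_units != n:
        raise ValueError(f"weight matrix indexes {W.n_units} units, field has {n}")
    s0 = W.s0
    if s0 <= 0:
        raise ValueError("total weight S0 must be positive")
    denom = float(d @ d)
    if denom <= 0:
        raise DegenerateFieldError("zero variance; Moran's I undefined")
    num = float(d @ (W.matrix @ d))
    return MoranResult(
        statistic=n * num / (s0 * denom), n_units=n, total_weight=s0, variant=variant
    )


def morans_i(fld: SpatialField, W: WeightMatrix) -> MoranResult:
    """Moran's I of a scalar field under weight matrix ``W``.

    Raises :class:`DegenerateFieldError` for constant fields.
    """
    d = fld.values - fld.values.mean()
    return _moran_from_deviations(d, W, "scalar")


def morans_i_circular(fld: PhaseField, W: WeightMatrix) -> MoranResult:
    """Circular Moran's I_theta of a phase field.

    Deviations are signed shortest angular displacements from the circular
    mean.  Raises :class:`UndefinedCircularMeanError` for balanced fields
    (e.g. exactly anti-phase clusters of equal size) and
    :class:`DegenerateFieldError` for constant phases.
    """
    mean = circular_mean(fld.phases)
    d = circular_distance(fld.phases, mean)
    return _moran_from_deviations(np.asarray(d), W, "circular")


@dataclass(frozen=True)
class CorrelogramBin:
    d_lo: float
    d_hi: float
    result: MoranResult | None  # None iff the band is empty
    empty: bool


def correlogram(fld: SpatialField | PhaseField, bin_edges) -> list[CorrelogramBin]:
    """Moran statistic per distance band (d_lo, d_hi], one per edge pair.

    Empty bands are flagged (``empty=True``) rather than silently dropped;
    degenerate-field errors propagate.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be at least two strictly increasing values")
    if fld.locs is None:
        raise ValueError("correlogram requires locations")
    stat = morans_i_circular if isinstance(fld, PhaseField) else morans_i
    out: list[CorrelogramBin] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        try:
            W = distance_band_weights(fld.locs, float(lo), float(hi))
        except EmptyBandError:
            out.append(CorrelogramBin(float(lo), float(hi), None, True))
            continue
        out.append(CorrelogramBin(float(lo), float(hi), stat(fld, W), False))
    return out
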