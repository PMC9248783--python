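"""Raw fluorescence to melting curves and difference curves.

The processing chain mirrors standard HRM practice: optionally smooth the
raw fluorescence F(T) with a local least-squares (Savitzky-Golay) filter,
take the negative first derivative -dF/dT to obtain the melting curve, call
the melting temperature Tm at the curve's peak, average technical
replicates, and express each curve as its deviation from the mean curve of
a reference set (the difference curve).

Sign convention: a difference curve is mean minus curve,
``delta_i(T) = m(T) - dneg_i(T)``, where m(T) is the mean over the
generating reference set.  Whatever the sign, the deltas over the
generating set sum to zero at every temperature.

Difference curves are computed on -dF/dT melting curves by default.  A
classic normalized-fluorescence mode (linear baselines fit in pre/post-melt
windows) is available via :func:`normalize_fluorescence` for users who want
the commercial-software style difference plot; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .meltio import MeltDataset

__all__ = [
    "MeltCurve",
    "DifferenceCurve",
    "SmoothingConfig",
    "smooth",
    "negative_derivative",
    "call_tm",
    "average_replicates",
    "difference_curves",
    "regrid",
    "process_dataset",
    "normalize_fluorescence",
]

_GRID_TOL = 1e-6  # max allowed deviation from uniform spacing, degC


@dataclass
class SmoothingConfig:
    """Savitzky-Golay smoothing parameters applied to raw F(T).

    Defaults (window 7 points, order 2) preserve peak position on a 0.1 degC
    grid while suppressing well-to-well measurement noise.  Smoothing is
    applied to raw fluorescence before differentiation, never to -dF/dT.
    """

    window: int = 7
    poly_order: int = 2
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("smoothing window must be odd")
        if self.window < self.poly_order + 2:
            raise ValueError("smoothing window must be >= poly_order + 2")


@dataclass
class MeltCurve:
    """A melting curve: -dF/dT on a temperature grid, with called Tm.

    ``tm`` is None when no interior peak exists (``no_peak`` is then True).
    """

    temperatures: np.ndarray
    dneg: np.ndarray
    source_id: str
    tm: float | None = None
    no_peak: bool = False
    label: str | None = None
    replicate_group: str | None = None
    role: str = "unknown"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.dneg = np.asarray(self.dneg, dtype=float)
        if self.temperatures.shape != self.dneg.shape:
            raise ValueError(f"curve {self.source_id!r}: grid/value length mismatch")
        if self.tm is not None:
            lo, hi = self.temperatures[0], self.temperatures[-1]
            if not (lo <= self.tm <= hi):
                raise ValueError(f"curve {self.source_id!r}: tm {self.tm} outside grid")


@dataclass
class DifferenceCurve:
    """Deviation of one melting curve from a reference-set mean curve."""

    temperatures: np.ndarray
    delta: np.ndarray
    source_id: str
    reference_set_id: str = "all"
    label: str | None = None
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.temperatures.shape != self.delta.shape:
            raise ValueError(f"difference curve {self.source_id!r}: length mismatch")


def _require_uniform_grid(temperatures: np.ndarray) -> None:
    steps = np.diff(temperatures)
    if steps.size and (steps.max() - steps.min()) >= _GRID_TOL:
        raise ValueError(
            "temperature grid is not uniform; regrid() the data explicitly first"
        )


def smooth(series: Sequence[float], temperatures: Sequence[float],
           cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Savitzky-Golay smooth an RFU series on a uniform grid."""
    series = np.asarray(series, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    if cfg is None:
        cfg = SmoothingConfig()
    if not cfg.enabled:
        return series
    _require_uniform_grid(temperatures)
    if series.size < cfg.window:
        raise ValueError(
            f"series length {series.size} shorter than smoothing window {cfg.window}"
        )
    return savgol_filter(series, cfg.window, cfg.poly_order)


def negative_derivative(series: Sequence[float], temperatures: Sequence[float],
                        source_id: str = "") -> MeltCurve:
    """Melting curve -dF/dT: central differences inside, one-sided at ends.

    Tm is not yet called; use :func:`call_tm`.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 points to differentiate")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperatures must be strictly increasing")
    dneg = -np.gradient(series, t, edge_order=1)
    return MeltCurve(temperatures=t, dneg=dneg, source_id=source_id)


def call_tm(curve: MeltCurve) -> MeltCurve:
    """Call Tm at the interior peak of -dF/dT, with parabolic refinement.

    The global maximum over interior points is located (ties broken toward
    lower temperature) and refined by the vertex of the parabola through the
    peak and its two neighbours.  A maximum sitting on a boundary point sets
    the ``no_peak`` flag instead.
    """
    t, y = curve.temperatures, curve.dneg
    if t.size < 3:
        raise ValueError("need at least 3 points to call Tm")
    i = int(np.argmax(y))  # argmax returns the first (lowest-T) maximum
    if i == 0 or i == t.size - 1:
        curve.tm, curve.no_peak = None, True
        return curve
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:  # flat top: keep the grid point
        tm = t[i]
    else:
        # vertex of the interpolating parabola on the (assumed uniform
        # locally) 3-point stencil
        offset = 0.5 * (y0 - y2) / denom
        offset = float(np.clip(offset, -0.5, 0.5))
        tm = t[i] + offset * (t[i + 1] - t[i - 1]) / 2.0
    curve.tm, curve.no_peak = float(tm), False
    return curve


def average_replicates(curves: Sequence[MeltCurve],
                       groups: Mapping[str, str] | None = None) -> list[MeltCurve]:
    """Average technical replicates pointwise, per replicate group.

    ``groups`` maps source_id -> replicate_group; if omitted, each curve's
    own ``replicate_group`` attribute is used (curves without one pass
    through unchanged as singleton groups).  Tm is re-called on each mean
    curve.  Output order follows first occurrence of each group.
    """
    order: list[str] = []
    members: dict[str, list[MeltCurve]] = {}
    for c in curves:
        g = groups.get(c.source_id) if groups is not None else c.replicate_group
        key = g if g is not None else f"__single__{c.source_id}"
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(c)

    out: list[MeltCurve] = []
    for key in order:
        group = members[key]
        grid = group[0].temperatures
        for c in group[1:]:
            if c.temperatures.shape != grid.shape or not np.allclose(c.temperatures, grid):
                raise ValueError(f"replicate group {key!r}: mismatched temperature grids")
        if len(group) == 1:
            out.append(group[0])
            continue
        mean = np.mean([c.dneg for c in group], axis=0)
        name = key if not key.startswith("__single__") else group[0].source_id
        merged = MeltCurve(
            temperatures=grid, dneg=mean, source_id=name,
            label=group[0].label, replicate_group=name, role=group[0].role,
        )
        out.append(call_tm(merged) if grid.size >= 3 else merged)
    return out


def difference_curves(curves: Sequence[MeltCurve],
                      reference_set: Sequence[str] | None = None,
                      reference_set_id: str = "all") -> list[DifferenceCurve]:
    """Difference curves: each curve subtracted from the reference-set mean.

    The mean m(T) is computed over ``reference_set`` (source_ids; defaults
    to all input curves); every input curve i — inside or outside that set —
    yields ``delta_i(T) = m(T) - dneg_i(T)``.  Deltas over the generating
    set sum to zero pointwise.
    """
    if not curves:
        raise ValueError("no curves given")
    grid = curves[0].temperatures
    for c in curves[1:]:
        if c.temperatures.shape != grid.shape or not np.allclose(c.temperatures, grid):
            raise ValueError(f"curve {c.source_id!r}: temperature grid mismatch")
    if reference_set is None:
        ref = list(curves)
    else:
        wanted = set(reference_set)
        ref = [c for c in curves if c.source_id in wanted]
        if not ref:
            raise ValueError("reference_set matches no input curves")
    mean = np.mean([c.dneg for c in ref], axis=0)
    return [
        DifferenceCurve(
            temperatures=grid, delta=mean - c.dneg, source_id=c.source_id,
            reference_set_id=reference_set_id, label=c.label,
            replicate_group=c.replicate_group,
        )
        for c in curves
    ]


def regrid(values: Sequence[float], temperatures: Sequence[float],
           target: Sequence[float]) -> np.ndarray:
    """Linearly interpolate a series onto a target grid; no extrapolation."""
    t = np.asarray(temperatures, dtype=float)
    target = np.asarray(target, dtype=float)
    if target[0] < t[0] or target[-1] > t[-1]:
        raise ValueError(
            f"target grid [{target[0]}, {target[-1]}] extends outside the "
            f"source range [{t[0]}, {t[-1]}]; extrapolation is refused"
        )
    return np.interp(target, t, np.asarray(values, dtype=float))


def process_dataset(dataset: MeltDataset,
                    smoothing: SmoothingConfig | None = None) -> list[MeltCurve]:
    """Full raw-to-melting-curve run on every well of a dataset.

    Smooths raw F(T) (default Savitzky-Golay 7/2), differentiates, and calls
    Tm.  Sample metadata (label, replicate group, role) is carried onto the
    curves.
    """
    if smoothing is None:
        smoothing = SmoothingConfig()
    out = []
    for s in dataset.samples:
        f = smooth(s.rfu, dataset.temperatures, smoothing)
        curve = negative_derivative(f, dataset.temperatures, source_id=s.sample_id)
        curve.label, curve.replicate_group, curve.role = s.label, s.replicate_group, s.role
        out.append(call_tm(curve))
    return out


def normalize_fluorescence(series: Sequence[float], temperatures: Sequence[float],
                           pre_window: tuple[float, float] = (65.0, 70.0),
                           post_window: tuple[float, float] = (90.0, 95.0)) -> np.ndarray:
    """Classic HRM normalization of raw fluorescence to [0, 1].

    Linear baselines are fit to the pre-melt and post-melt temperature
    windows and the signal is rescaled so the pre-melt baseline maps to 1
    and the post-melt baseline to 0.  Provided for commercial-software-style
    normalized difference plots; the default pipeline differences -dF/dT
    curves instead.
    """
    f = np.asarray(series, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    lines = []
    for lo, hi in (pre_window, post_window):
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            raise ValueError(f"baseline window [{lo}, {hi}] covers fewer than 2 grid points")
        coef = np.polyfit(t[mask], f[mask], 1)
        lines.append(np.polyval(coef, t))
    upper, lower = lines
    span = upper - lower
    if np.any(span <= 0):
        raise ValueError("pre-melt baseline does not lie above the post-melt baseline")
    return (f - lower) / span
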