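"""Assigning unknown melt curves to reference taxa and clustering genotypes.

The reference library holds one replicate-averaged melting curve per taxon
label.  A query is assigned by nearest curve distance D, with two guard
thresholds: a query farther than ``tau_reject`` from every entry is
*unassigned* (no library member explains it), and a query whose runner-up
lies within ``tau_margin`` of the best hit is *ambiguous* — the honest
outcome when two taxa's amplicons melt indistinguishably, as with
*Aporrectodea caliginosa* vs *Aporrectodea longa* in this assay.  Ambiguous
calls can then be resolved by a multiplex PCR melt readout in which each
candidate species yields a product in a distinct Tm window.

Distances are computed on an analysis window (default 70-85 degC) so that
baseline-region noise outside the melt transition does not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .meltproc import DifferenceCurve, MeltCurve, average_replicates, call_tm

__all__ = [
    "ReferenceLibrary",
    "Assignment",
    "ClusterResult",
    "MultiplexRule",
    "curve_distance",
    "build_reference_library",
    "classify",
    "multiplex_resolve",
    "cluster_groups",
]

DEFAULT_WINDOW = (70.0, 85.0)
METRICS = ("euclidean", "max_abs", "tm_delta")

#: Default threshold multipliers on the library's within-replicate spread.
REJECT_FACTOR = 5.0
MARGIN_FACTOR = 2.0


def _values(curve) -> np.ndarray:
    if isinstance(curve, DifferenceCurve):
        return curve.delta
    return curve.dneg


def _window_mask(t: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(t.shape, dtype=bool)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"analysis window [{lo}, {hi}] contains no grid points")
    return mask


def curve_distance(a, b, metric: str = "euclidean",
                   window: tuple[float, float] | None = None) -> float:
    """Distance between two curves of the same kind on the same grid.

    ``euclidean``: root of summed squared pointwise differences;
    ``max_abs``: largest absolute pointwise difference;
    ``tm_delta``: absolute difference of called Tms.
    """
    ta, tb = a.temperatures, b.temperatures
    if ta.shape != tb.shape or not np.allclose(ta, tb):
        raise ValueError("curves are on different temperature grids; regrid first")
    if metric == "tm_delta":
        if a.tm is None or b.tm is None:
            raise ValueError("tm_delta requires both curves to have a called Tm")
        return abs(a.tm - b.tm)
    mask = _window_mask(ta, window)
    diff = _values(a)[mask] - _values(b)[mask]
    if metric == "euclidean":
        return float(np.sqrt(np.sum(diff ** 2)))
    if metric == "max_abs":
        return float(np.max(np.abs(diff)))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass
class ReferenceLibrary:
    """Label -> mean melting curve, with calibration statistics.

    ``replicate_spread`` is the median distance of individual replicate
    curves to their label's mean curve — the library's natural scale for
    the reject/ambiguity thresholds.  None when the library was built from
    single curves.
    """

    entries: dict[str, MeltCurve]
    grid: np.ndarray
    built_from: str = ""
    replicate_spread: float | None = None
    metric: str = "euclidean"
    window: tuple[float, float] | None = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a reference library needs at least one entry")
        for label, curve in self.entries.items():
            if curve.temperatures.shape != self.grid.shape or not np.allclose(
                curve.temperatures, self.grid
            ):
                raise ValueError(f"library entry {label!r} is not on the shared grid")

    @property
    def labels(self) -> list[str]:
        return list(self.entries)


@dataclass
class Assignment:
    """Outcome of classifying one query curve.

    ``candidates`` is the full (label, distance) list sorted by ascending
    distance; ``margin`` is runner-up distance minus best distance (inf for
    a one-entry library).
    """

    sample_id: str
    status: str  # assigned | ambiguous | unassigned
    best_label: str | None
    candidates: list[tuple[str, float]]
    margin: float
    method: str = "hrm"


@dataclass
class ClusterResult:
    """Curve clustering outcome: sample -> group index (contiguous from 1)."""

    groups: dict[str, int]
    n_groups: int
    linkage_height_cut: float

    def members(self, group: int) -> list[str]:
        return [sid for sid, g in self.groups.items() if g == group]


def build_reference_library(curves: Sequence[MeltCurve], *, metric: str = "euclidean",
                            window: tuple[float, float] | None = DEFAULT_WINDOW,
                            built_from: str = "") -> ReferenceLibrary:
    """Average labeled replicate curves into one reference entry per label.

    Every curve must carry a ``label``; curves sharing a label are averaged
    pointwise and the within-replicate distance spread (median replicate-to-
    mean distance over all labels) is recorded for threshold calibration.
    """
    unlabeled = [c.source_id for c in curves if c.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled curves cannot enter a reference library: {unlabeled}")
    by_label: dict[str, list[MeltCurve]] = {}
    for c in curves:
        by_label.setdefault(c.label, []).append(c)
    grid = curves[0].temperatures
    entries: dict[str, MeltCurve] = {}
    spreads: list[float] = []
    for label, group in by_label.items():
        for c in group:
            if c.temperatures.shape != grid.shape or not np.allclose(c.temperatures, grid):
                raise ValueError(f"label {label!r}: replicate grids differ")
        mean = MeltCurve(
            temperatures=grid,
            dneg=np.mean([c.dneg for c in group], axis=0),
            source_id=label, label=label, role="reference",
        )
        call_tm(mean)
        entries[label] = mean
        if len(group) > 1:
            spreads.extend(
                curve_distance(c, mean, metric=metric, window=window) for c in group
            )
    spread = float(np.median(spreads)) if spreads else None
    return ReferenceLibrary(entries=entries, grid=grid, built_from=built_from,
                            replicate_spread=spread, metric=metric, window=window)


def _resolve_threshold(value, spread: float | None, factor: float, name: str) -> float:
    if value == "auto" or value is None:
        if spread is None:
            raise ValueError(
                f"{name}='auto' needs a library built from replicates "
                "(no within-replicate spread recorded); pass a numeric threshold"
            )
        return factor * spread
    value = float(value)
    if value < 0:
        raise ValueError(f"{name} must be >= 0")
    return value


def classify(query: MeltCurve, lib: ReferenceLibrary,
             reject: float | str | None = "auto",
             margin: float | str | None = "auto") -> Assignment:
    """Nearest-reference classification with reject and ambiguity guards.

    Thresholds default to ``"auto"``: reject = 5x and margin = 2x the
    library's within-replicate spread.  Exact distance ties are ordered by
    label lexicographically and reported as ambiguous.
    """
    tau_reject = _resolve_threshold(reject, lib.replicate_spread, REJECT_FACTOR, "reject")
    tau_margin = _resolve_threshold(margin, lib.replicate_spread, MARGIN_FACTOR, "margin")
    dists = sorted(
        ((label, curve_distance(query, entry, metric=lib.metric, window=lib.window))
         for label, entry in lib.entries.items()),
        key=lambda x: (x[1], x[0]),
    )
    best_label, best = dists[0]
    margin_value = (dists[1][1] - best) if len(dists) > 1 else float("inf")
    if best > tau_reject:
        return Assignment(query.source_id, "unassigned", None, dists, margin_value)
    within = [(l, d) for l, d in dists if d - best < tau_margin or d == best]
    if len(within) > 1:
        return Assignment(query.source_id, "ambiguous", best_label, dists, margin_value)
    return Assignment(query.source_id, "assigned", best_label, dists, margin_value)


#: label -> (tm_low, tm_high) in degC; windows must be pairwise disjoint.
MultiplexRule = Mapping[str, tuple[float, float]]


def _check_disjoint(rule: MultiplexRule) -> None:
    spans = sorted(rule.items(), key=lambda kv: kv[1][0])
    for (la, (lo_a, hi_a)), (lb, (lo_b, hi_b)) in zip(spans, spans[1:]):
        if lo_b < hi_a:
            raise ValueError(f"multiplex Tm windows for {la!r} and {lb!r} overlap")


def multiplex_resolve(ambiguous: Assignment, multiplex_curve: MeltCurve,
                      rule: MultiplexRule) -> Assignment:
    """Resolve an ambiguous call from the multiplex assay's melt peak.

    The multiplex reaction contains one diagnostic primer pair per
    candidate species; whichever pair amplifies determines the product Tm.
    If the called Tm falls in exactly one candidate's window, that label is
    assigned (method "multiplex"); no peak, or Tm outside all windows,
    yields unassigned; overlapping windows at the observed Tm leave the
    call ambiguous.
    """
    if ambiguous.status != "ambiguous":
        raise ValueError(f"multiplex_resolve needs an ambiguous assignment, got {ambiguous.status!r}")
    candidate_labels = {label for label, _ in ambiguous.candidates}
    extra = set(rule) - candidate_labels
    if extra:
        raise ValueError(f"multiplex rule covers labels absent from candidates: {sorted(extra)}")
    curve = multiplex_curve if multiplex_curve.tm is not None or multiplex_curve.no_peak \
        else call_tm(multiplex_curve)
    if curve.tm is None:
        return Assignment(ambiguous.sample_id, "unassigned", None,
                          ambiguous.candidates, ambiguous.margin, method="multiplex")
    hits = [label for label, (lo, hi) in rule.items() if lo <= curve.tm <= hi]
    if len(hits) == 1:
        return Assignment(ambiguous.sample_id, "assigned", hits[0],
                          ambiguous.candidates, ambiguous.margin, method="multiplex")
    if len(hits) == 0:
        return Assignment(ambiguous.sample_id, "unassigned", None,
                          ambiguous.candidates, ambiguous.margin, method="multiplex")
    return Assignment(ambiguous.sample_id, "ambiguous", ambiguous.best_label,
                      ambiguous.candidates, ambiguous.margin, method="multiplex")


def cluster_groups(diffs: Sequence[DifferenceCurve | MeltCurve],
                   cut: float | str = "auto",
                   window: tuple[float, float] | None = DEFAULT_WINDOW) -> ClusterResult:
    """Agglomerative (average-linkage, euclidean) clustering of curves.

    The ``"auto"`` cut height is 3x the median within-replicate-group
    distance when replicate structure is annotated on the curves, else 3x
    the median nearest-neighbour distance.  Group indices are contiguous
    from 1, numbered by first occurrence in the input.
    """
    if len(diffs) < 2:
        raise ValueError("clustering needs at least 2 curves")
    grid = diffs[0].temperatures
    n = len(diffs)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = curve_distance(diffs[i], diffs[j],
                                                     metric="euclidean", window=window)
    if cut == "auto":
        cut_value = _auto_cut(diffs, dmat)
    else:
        cut_value = float(cut)
    z = linkage(squareform(dmat, checks=False), method="average")
    raw = fcluster(z, t=cut_value, criterion="distance")
    # relabel groups canonically by first occurrence
    relabel: dict[int, int] = {}
    groups: dict[str, int] = {}
    for curve, g in zip(diffs, raw):
        if g not in relabel:
            relabel[g] = len(relabel) + 1
        groups[curve.source_id] = relabel[g]
    return ClusterResult(groups=groups, n_groups=len(relabel),
                         linkage_height_cut=cut_value)


def _auto_cut(diffs, dmat: np.ndarray) -> float:
    rep_groups: dict[str, list[int]] = {}
    for i, c in enumerate(diffs):
        g = getattr(c, "replicate_group", None)
        if g is not None:
            rep_groups.setdefault(g, []).append(i)
    within = [
        dmat[i, j]
        for members in rep_groups.values() if len(members) > 1
        for a, i in enumerate(members) for j in members[a + 1:]
    ]
    if within:
        return 3.0 * float(np.median(within))
    nn = np.where(np.eye(len(diffs), dtype=bool), np.inf, dmat).min(axis=1)
    return 3.0 * float(np.median(nn))
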