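"""Three-population gating, morphology split, and count-to-concentration math.

Gating happens in log10 total-fluorescence space: the (green, red) plane
separates viable cells (FDA-positive), dead cells (PI-positive) and medium
background.  Because SSL particles can pick up partial red fluorescence,
membership in a fluorescence gate alone is not enough — events must also sit
inside size (FSC length) and shape (SSC total) windows spanned by the cell
reference populations before they count as biomass.  Gate geometry is fitted
from reference runs of the pure populations, not hard-coded.

The morphology split uses a straight-line discriminant in
(FSC length, SSC total) space: budding mother-daughter doublets produce
longer pulses with higher total side scatter than single cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .pulse import EventFeatureTable, ParameterError

LOG_FLOOR = 1.0  # a.u.; totals are floored here before log10


class GateFitError(ValueError):
    """Reference populations do not support a valid gate set."""


def log_fluorescence(table: EventFeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """(log10 green total, log10 red total) with the sub-1 a.u. floor applied."""
    g = np.log10(np.clip(table.data["fl_green_total"].to_numpy(float), LOG_FLOOR, None))
    r = np.log10(np.clip(table.data["fl_red_total"].to_numpy(float), LOG_FLOOR, None))
    return g, r


def _quantile_hull(x: np.ndarray, y: np.ndarray, quantile: float) -> Polygon:
    """Convex hull of the central ``quantile`` mass of a 2-D point cloud.

    Points are ranked by Mahalanobis-style distance from the coordinate-wise
    median (robust to the log-normal cloud shapes seen here); the outermost
    ``1 - quantile`` fraction is trimmed before the hull is taken.
    """
    pts = np.column_stack([x, y])
    center = np.median(pts, axis=0)
    scale = np.maximum(pts.std(axis=0), 1e-9)
    d = np.linalg.norm((pts - center) / scale, axis=1)
    keep = max(3, int(np.floor(quantile * len(pts))))
    pts = pts[np.argsort(d)[:keep]]
    # degenerate (collinear/identical) clouds get a tiny box instead of a hull
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        lo, hi = pts.min(axis=0) - 1e-6, pts.max(axis=0) + 1e-6
        return Polygon([(lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])])
    hull = ConvexHull(pts)
    return Polygon(pts[hull.vertices])


@dataclass
class GateSet:
    """Fitted classification geometry for the three populations + morphology.

    Fluorescence gates are convex polygons in (log10 green total, log10 red
    total); the size window is an interval over FSC length (um) and the shape
    window an interval over SSC total (a.u.).  ``morphology_boundary`` is
    ``(w_length, w_ssc, b)`` acting on (log10 length, log10 SSC total), with
    a positive score meaning budding.
    """

    viable_gate: Polygon
    dead_gate: Polygon
    background_gate: Polygon
    cell_size_window: tuple[float, float]
    cell_shape_window: tuple[float, float]
    morphology_boundary: Optional[tuple[float, float, float]] = None

    def to_dict(self) -> dict[str, Any]:
        def poly(p: Polygon) -> list[list[float]]:
            return [[float(a), float(b)] for a, b in np.asarray(p.exterior.coords)[:-1]]

        return {
            "viable_gate": poly(self.viable_gate),
            "dead_gate": poly(self.dead_gate),
            "background_gate": poly(self.background_gate),
            "cell_size_window": [float(v) for v in self.cell_size_window],
            "cell_shape_window": [float(v) for v in self.cell_shape_window],
            "morphology_boundary": (
                None
                if self.morphology_boundary is None
                else [float(v) for v in self.morphology_boundary]
            ),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GateSet":
        mb = d.get("morphology_boundary")
        return cls(
            viable_gate=Polygon(d["viable_gate"]),
            dead_gate=Polygon(d["dead_gate"]),
            background_gate=Polygon(d["background_gate"]),
            cell_size_window=tuple(d["cell_size_window"]),
            cell_shape_window=tuple(d["cell_shape_window"]),
            morphology_boundary=None if mb is None else tuple(mb),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GateSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_gates(
    pure_viable: EventFeatureTable,
    pure_dead: EventFeatureTable,
    medium_blank: EventFeatureTable,
    quantile: float = 0.99,
    window_quantiles: tuple[float, float] = (0.005, 0.995),
    hull_margin: float = 0.15,
    window_pad_frac: float = 0.05,
) -> GateSet:
    """Fit the three fluorescence gates and cell size/shape windows.

    Each gate is the convex hull of the central ``quantile`` mass of the
    corresponding reference population in log-fluorescence space, expanded
    outward by ``hull_margin`` (log10 units) — gates drawn around clusters
    carry a margin so the reference's own tail events still fall inside.
    The size and shape windows span the ``window_quantiles`` of the pooled
    cell references, padded by ``window_pad_frac`` of the span on each side.
    Deterministic for fixed inputs.

    Raises :class:`GateFitError` (reporting the overlap fraction) when the
    viable and dead hulls overlap — e.g. when the references are not actually
    distinct populations.
    """
    for name, t in (
        ("pure_viable", pure_viable),
        ("pure_dead", pure_dead),
        ("medium_blank", medium_blank),
    ):
        if len(t) < 100:
            raise ParameterError(f"{name} reference needs >= 100 events, got {len(t)}")
    if not 0.0 < quantile <= 1.0:
        raise ParameterError("quantile must lie in (0, 1]")

    if hull_margin < 0 or window_pad_frac < 0:
        raise ParameterError("hull_margin and window_pad_frac must be >= 0")

    gv = _quantile_hull(*log_fluorescence(pure_viable), quantile)
    gd = _quantile_hull(*log_fluorescence(pure_dead), quantile)
    gb = _quantile_hull(*log_fluorescence(medium_blank), quantile)
    if hull_margin > 0:
        gv = gv.buffer(hull_margin, join_style=2)
        gd = gd.buffer(hull_margin, join_style=2)
        gb = gb.buffer(hull_margin, join_style=2)

    inter = gv.intersection(gd)
    if inter.area > 1e-12:
        frac = inter.area / min(gv.area, gd.area)
        raise GateFitError(
            f"viable and dead reference hulls overlap (fraction {frac:.3f}); "
            "references are not separable in fluorescence space"
        )

    lo_q, hi_q = window_quantiles
    pooled_len = np.concatenate(
        [
            pure_viable.data["fsc_length"].to_numpy(float),
            pure_dead.data["fsc_length"].to_numpy(float),
        ]
    )
    pooled_ssc = np.concatenate(
        [
            pure_viable.data["ssc_total"].to_numpy(float),
            pure_dead.data["ssc_total"].to_numpy(float),
        ]
    )
    def window(values: np.ndarray) -> tuple[float, float]:
        lo, hi = float(np.quantile(values, lo_q)), float(np.quantile(values, hi_q))
        pad = window_pad_frac * (hi - lo)
        return (max(0.0, lo - pad), hi + pad)

    return GateSet(gv, gd, gb, window(pooled_len), window(pooled_ssc))


def fit_morphology_boundary(
    single_reference: EventFeatureTable, budding_reference: EventFeatureTable
) -> tuple[float, float, float]:
    """Straight-line discriminant between single-cell and budding references.

    Linear discriminant analysis on (log10 FSC length, log10 SSC total) with
    equal class priors, so the boundary is the balanced (equal-error style)
    separator rather than a prevalence-weighted one.  The log transform
    turns the doublet's multiplicative increase in pulse extent and side
    scatter into an additive shift, where a straight line separates cleanly.
    Returns ``(w_length, w_ssc, b)`` acting on the log10 features.
    """
    if len(single_reference) < 10 or len(budding_reference) < 10:
        raise ParameterError("morphology references need >= 10 events each")

    def xy(t: EventFeatureTable) -> np.ndarray:
        return np.column_stack(
            [
                np.log10(np.clip(t.data["fsc_length"].to_numpy(float), 1e-3, None)),
                np.log10(np.clip(t.data["ssc_total"].to_numpy(float), LOG_FLOOR, None)),
            ]
        )

    X = np.vstack([xy(single_reference), xy(budding_reference)])
    y = np.concatenate([np.zeros(len(single_reference)), np.ones(len(budding_reference))])
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    lda.fit(X, y)
    w = lda.coef_[0]
    b = float(lda.intercept_[0])
    return (float(w[0]), float(w[1]), b)


@dataclass
class ClassificationResult:
    """Counts, concentrations and QC flags for one classified sample."""

    counts: dict[str, int]
    viability_percent: Optional[float]
    concentrations_per_ml: Optional[dict[str, float]] = None
    flags: dict[str, Any] = field(default_factory=dict)
    labels: Optional[np.ndarray] = None  # per-event assignment, table order

    @property
    def total_events(self) -> int:
        return int(sum(self.counts.values()))

    def to_dict(self) -> dict[str, Any]:
        return {
            "counts": dict(self.counts),
            "viability_percent": self.viability_percent,
            "concentrations_per_ml": self.concentrations_per_ml,
            "flags": dict(self.flags),
        }


def counts_to_concentration(
    count: float, analyzed_volume_ul: float, dilution_factor: float = 1.0
) -> float:
    """Convert an event count to events/mL of the undiluted sample.

    ``concentration = count / volume_ul * 1000 * dilution_factor``.
    """
    if analyzed_volume_ul <= 0:
        raise ParameterError("analyzed_volume_ul must be > 0")
    if dilution_factor < 1:
        raise ParameterError("dilution_factor must be >= 1")
    return count / analyzed_volume_ul * 1000.0 * dilution_factor


def classify(
    events: EventFeatureTable,
    gates: GateSet,
    analyzed_volume_ul: Optional[float] = None,
    dilution_factor: float = 1.0,
    overload: bool = False,
) -> ClassificationResult:
    """Assign every event to viable / dead / background / unclassified.

    Decision rules, in order:

    1. inside the dead gate *and* the cell size/shape windows -> dead
       (an event in both fluorescence gates counts as dead: PI positivity is
       the membrane-integrity criterion);
    2. inside the viable gate — or green-saturated, which signals very high
       esterase activity (typically budding agglomerates) — *and* inside the
       windows -> viable;
    3. inside the background gate, or outside the size/shape windows ->
       background;
    4. otherwise unclassified.

    The fraction of viable events with green saturation is reported in
    ``flags["saturation_fraction"]``.
    """
    df = events.data
    n = len(df)
    if n == 0:
        counts = {k: 0 for k in ("viable", "dead", "background", "unclassified")}
        return ClassificationResult(counts, None, None, {"overload": overload})

    g, r = log_fluorescence(events)
    in_v = shapely.intersects_xy(gates.viable_gate, g, r)
    in_d = shapely.intersects_xy(gates.dead_gate, g, r)
    in_b = shapely.intersects_xy(gates.background_gate, g, r)
    lo_s, hi_s = gates.cell_size_window
    lo_c, hi_c = gates.cell_shape_window
    fsc_len = df["fsc_length"].to_numpy(float)
    ssc_tot = df["ssc_total"].to_numpy(float)
    in_windows = (fsc_len >= lo_s) & (fsc_len <= hi_s) & (ssc_tot >= lo_c) & (ssc_tot <= hi_c)
    green_sat = df["fl_green_saturated"].to_numpy(bool)

    dead_mask = in_d & in_windows
    viable_mask = ~dead_mask & (in_v | green_sat) & in_windows
    background_mask = ~dead_mask & ~viable_mask & (in_b | ~in_windows)

    labels = np.full(n, "unclassified", dtype=object)
    labels[background_mask] = "background"
    labels[viable_mask] = "viable"
    labels[dead_mask] = "dead"

    counts = {
        k: int((labels == k).sum()) for k in ("viable", "dead", "background", "unclassified")
    }
    assert sum(counts.values()) == n  # classification is a partition

    n_cells = counts["viable"] + counts["dead"]
    viability = 100.0 * counts["viable"] / n_cells if n_cells > 0 else None
    n_viable = counts["viable"]
    sat_fraction = float(green_sat[viable_mask].sum()) / n_viable if n_viable else 0.0

    concentrations = None
    if analyzed_volume_ul is not None:
        concentrations = {
            k: counts_to_concentration(c, analyzed_volume_ul, dilution_factor)
            for k, c in counts.items()
        }
        concentrations["total"] = counts_to_concentration(
            n, analyzed_volume_ul, dilution_factor
        )

    return ClassificationResult(
        counts=counts,
        viability_percent=viability,
        concentrations_per_ml=concentrations,
        flags={"overload": bool(overload), "saturation_fraction": sat_fraction},
        labels=labels,
    )


@dataclass
class MorphologyResult:
    """Single-vs-budding split of the viable population."""

    n_single: int
    n_budding: int
    budding_ratio: Optional[float]  # budding / single; None when single == 0
    budding_ratio_infinite: bool

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_single": self.n_single,
            "n_budding": self.n_budding,
            "budding_ratio": self.budding_ratio,
            "budding_ratio_infinite": self.budding_ratio_infinite,
        }


def classify_morphology(
    viable_events: EventFeatureTable, gates: GateSet
) -> MorphologyResult:
    """Split already-viable events into single vs budding cells.

    Events on the high side of the morphology boundary (longer pulse and/or
    higher SSC total) are budding.  ``budding_ratio = budding / single``; a
    sample with no singles reports the ratio as infinite via a flag.
    """
    if gates.morphology_boundary is None:
        raise ParameterError("gate set has no fitted morphology boundary")
    w_len, w_ssc, b = gates.morphology_boundary
    df = viable_events.data
    if len(df) == 0:
        return MorphologyResult(0, 0, None, False)
    score = (
        w_len * np.log10(np.clip(df["fsc_length"].to_numpy(float), 1e-3, None))
        + w_ssc * np.log10(np.clip(df["ssc_total"].to_numpy(float), LOG_FLOOR, None))
        + b
    )
    budding = score > 0
    n_budding = int(budding.sum())
    n_single = int(len(df) - n_budding)
    if n_single > 0:
        return MorphologyResult(n_single, n_budding, n_budding / n_single, False)
    return MorphologyResult(n_single, n_budding, None, n_budding > 0)
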