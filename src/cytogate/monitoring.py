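"""Bioprocess monitoring: time courses, washout dynamics, specific productivity.

Assembles per-timepoint classification results and process metadata into the
quantities used to follow a continuous yeast cultivation: viability and
budding-activity time courses, the SSL-particle background fraction,
chemostat washout/background dynamics, specific ethanol productivity on a
total- vs viable-biomass basis, and a simple viability-triggered nutrient
pulse rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .gating import ClassificationResult
from .pulse import ParameterError

#: default single-cell dry mass for S. cerevisiae, pg/cell (order-of-magnitude
#: literature value; normalized productivity outputs are invariant to it).
DEFAULT_CELL_DRY_MASS_PG = 15.0


@dataclass
class ProcessSample:
    """One monitoring timepoint: classified counts plus offline metadata."""

    time_h: float
    classification: ClassificationResult
    total_dry_weight_g_l: Optional[float] = None
    ethanol_g_l: Optional[float] = None
    residual_sugar_g_l: Optional[float] = None
    phase: str = ""

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ParameterError("time_h must be >= 0")


@dataclass
class ProcessTimeSeries:
    """Ordered process samples with reactor-level constants."""

    samples: list[ProcessSample] = field(default_factory=list)
    working_volume_l: float = 1.0
    dilution_rate_per_h: float = 0.0
    feed_particle_conc_per_ml: float = 0.0

    def __post_init__(self) -> None:
        times = [s.time_h for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("sample times must be strictly increasing")
        if self.working_volume_l <= 0:
            raise ParameterError("working_volume_l must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_h for s in self.samples])

    def counts(self, label: str) -> np.ndarray:
        return np.array([s.classification.counts.get(label, 0) for s in self.samples], float)

    def concentrations(self, label: str) -> np.ndarray:
        out = []
        for s in self.samples:
            conc = s.classification.concentrations_per_ml
            out.append(np.nan if conc is None else conc.get(label, np.nan))
        return np.array(out, float)


def viability_series(ts: ProcessTimeSeries) -> pd.Series:
    """Viable / (viable + dead) per timepoint, %.  NaN where no cells counted."""
    v, d = ts.counts("viable"), ts.counts("dead")
    cells = v + d
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cells > 0, 100.0 * v / np.where(cells > 0, cells, 1), np.nan)
    return pd.Series(out, index=ts.times, name="viability_percent")


def ssl_fraction_series(ts: ProcessTimeSeries) -> pd.Series:
    """Background / total particle count per timepoint, %.  NaN on empty samples."""
    v, d, b = ts.counts("viable"), ts.counts("dead"), ts.counts("background")
    total = v + d + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * b / np.where(total > 0, total, 1), np.nan)
    return pd.Series(out, index=ts.times, name="ssl_fraction_percent")


def budding_series(
    ts: ProcessTimeSeries, budding_ratios: Sequence[Optional[float]]
) -> pd.Series:
    """Per-timepoint budding/single ratio series (ratios come from gating)."""
    if len(budding_ratios) != len(ts.samples):
        raise ParameterError("budding_ratios length must match the time series")
    vals = [np.nan if r is None else float(r) for r in budding_ratios]
    return pd.Series(vals, index=ts.times, name="budding_ratio")


def feed_rate(dilution_rate_per_h: float, working_volume_l: float) -> float:
    """Feed rate in mL/h implied by a dilution rate and working volume."""
    if dilution_rate_per_h < 0:
        raise ParameterError("dilution rate must be >= 0")
    if working_volume_l <= 0:
        raise ParameterError("working volume must be > 0")
    return dilution_rate_per_h * working_volume_l * 1000.0


def washout_curve(
    x0: float, dilution_rate_per_h: float, mu_per_h: float, t_h: float | np.ndarray
) -> float | np.ndarray:
    """Biomass washout/growth in a chemostat: ``X(t) = X0 * exp((mu - D) t)``.

    Non-growing material (mu = 0) washes out with half-life ln2 / D; at
    mu = D the concentration is stationary.
    """
    t = np.asarray(t_h, dtype=float)
    out = x0 * np.exp((mu_per_h - dilution_rate_per_h) * t)
    return float(out) if np.isscalar(t_h) else out


def background_approach_curve(
    c0: float, c_feed: float, dilution_rate_per_h: float, t_h: float | np.ndarray
) -> float | np.ndarray:
    """Inert particle background relaxing toward the feed level.

    ``C(t) = C_feed + (C0 - C_feed) * exp(-D t)``: with constant feeding the
    background concentration eventually reaches the level present in the feed
    medium.
    """
    t = np.asarray(t_h, dtype=float)
    out = c_feed + (c0 - c_feed) * np.exp(-dilution_rate_per_h * t)
    return float(out) if np.isscalar(t_h) else out


def specific_productivity(
    ts: ProcessTimeSeries,
    basis: str = "total_dw",
    cell_dry_mass_pg: float = DEFAULT_CELL_DRY_MASS_PG,
    normalize: bool = False,
) -> pd.Series:
    """Specific ethanol productivity q (g ethanol / g biomass / h) per timepoint.

    The volumetric rate is ``r(t) = D * c(t) + dc/dt`` (finite differences;
    central where possible, one-sided at the boundaries) — at chemostat
    steady state this reduces to ``D * c``.  The biomass basis is either the
    measured total dry weight or the viable-cell dry weight reconstructed
    from the viable concentration and a per-cell dry mass.  Timepoints with a
    zero or missing basis are reported NaN.  ``normalize=True`` rescales to
    the series maximum (how such curves are usually plotted, and invariant to
    the per-cell mass).
    """
    if basis not in ("total_dw", "viable_dw"):
        raise ParameterError(f"basis must be 'total_dw' or 'viable_dw', got {basis!r}")
    if cell_dry_mass_pg <= 0:
        raise ParameterError("cell_dry_mass_pg must be > 0")
    etoh = np.array(
        [np.nan if s.ethanol_g_l is None else s.ethanol_g_l for s in ts.samples], float
    )
    if np.isfinite(etoh).sum() < 2:
        raise ParameterError("need ethanol data at >= 2 timepoints")
    t = ts.times
    dcdt = np.gradient(etoh, t) if len(t) > 1 else np.zeros_like(etoh)
    r_vol = ts.dilution_rate_per_h * etoh + dcdt  # g/L/h

    if basis == "total_dw":
        x = np.array(
            [np.nan if s.total_dry_weight_g_l is None else s.total_dry_weight_g_l
             for s in ts.samples],
            float,
        )
    else:
        viable_per_ml = ts.concentrations("viable")
        # pg/cell * cells/mL -> g/L: 1e-12 g/pg * 1e3 mL/L
        x = viable_per_ml * cell_dry_mass_pg * 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(np.isfinite(x) & (x > 0), r_vol / np.where(x > 0, x, 1), np.nan)
    if normalize:
        peak = np.nanmax(np.abs(q))
        if peak > 0:
            q = q / peak
    return pd.Series(q, index=t, name=f"q_ethanol_{basis}")


def nutrient_pulse_rule(
    viability: pd.Series | Sequence[float],
    times: Optional[Sequence[float]] = None,
    threshold_percent: float = 50.0,
    min_duration_h: float = 5.0,
) -> list[float]:
    """Timepoints at which a nutrient pulse should be triggered.

    An alert fires at the first timepoint of every sustained excursion where
    viability has stayed below ``threshold_percent`` for at least
    ``min_duration_h``; one alert per excursion, brief dips shorter than the
    minimum duration are ignored.  Missing (NaN) values end an excursion.
    """
    if not 0.0 < threshold_percent < 100.0:
        raise ParameterError("threshold_percent must lie in (0, 100)")
    if min_duration_h < 0:
        raise ParameterError("min_duration_h must be >= 0")
    if isinstance(viability, pd.Series):
        vals = viability.to_numpy(float)
        ts = viability.index.to_numpy(float)
    else:
        vals = np.asarray(list(viability), float)
        if times is None:
            raise ParameterError("times required when viability is not a pandas Series")
        ts = np.asarray(list(times), float)
    if len(vals) != len(ts):
        raise ParameterError("viability and times must have equal length")

    alerts: list[float] = []
    excursion_start: Optional[float] = None
    fired = False
    for t, v in zip(ts, vals):
        below = math.isfinite(v) and v < threshold_percent
        if below:
            if excursion_start is None:
                excursion_start = t
                fired = False
            if not fired and t - excursion_start >= min_duration_h:
                alerts.append(float(t))
                fired = True
        else:
            excursion_start = None
            fired = False
    return alerts


# ---------------------------------------------------------------------------
# flat-file schema for process time series

PROCESS_CSV_COLUMNS = [
    "time_h",
    "viable_per_ml",
    "dead_per_ml",
    "background_per_ml",
    "dw_g_l",
    "etoh_g_l",
    "sugar_g_l",
    "phase",
]


def timeseries_from_frame(
    df: pd.DataFrame,
    working_volume_l: float = 1.0,
    dilution_rate_per_h: float = 0.0,
    feed_particle_conc_per_ml: float = 0.0,
) -> ProcessTimeSeries:
    """Build a :class:`ProcessTimeSeries` from the documented flat CSV schema.

    Counts are taken equal to the per-mL concentrations (one notional mL of
    analyzed undiluted sample), which keeps all ratio-based series exact.
    """
    missing = [c for c in PROCESS_CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParameterError(f"process table missing required columns {missing}")
    samples = []
    for _, row in df.iterrows():
        counts = {
            "viable": int(round(row["viable_per_ml"])),
            "dead": int(round(row["dead_per_ml"])),
            "background": int(round(row["background_per_ml"])),
            "unclassified": 0,
        }
        cells = counts["viable"] + counts["dead"]
        result = ClassificationResult(
            counts=counts,
            viability_percent=100.0 * counts["viable"] / cells if cells else None,
            concentrations_per_ml={
                "viable": float(row["viable_per_ml"]),
                "dead": float(row["dead_per_ml"]),
                "background": float(row["background_per_ml"]),
            },
        )

        def opt(col: str) -> Optional[float]:
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        samples.append(
            ProcessSample(
                time_h=float(row["time_h"]),
                classification=result,
                total_dry_weight_g_l=opt("dw_g_l"),
                ethanol_g_l=opt("etoh_g_l"),
                residual_sugar_g_l=opt("sugar_g_l"),
                phase=str(row["phase"]) if "phase" in df.columns and not pd.isna(row["phase"]) else "",
            )
        )
    return ProcessTimeSeries(
        samples=samples,
        working_volume_l=working_volume_l,
        dilution_rate_per_h=dilution_rate_per_h,
        feed_particle_conc_per_ml=feed_particle_conc_per_ml,
    )


def monitoring_report(ts: ProcessTimeSeries, budding_ratios=None) -> dict[str, Any]:
    """Assemble the standard monitoring outputs into a serializable dict."""
    viability = viability_series(ts)
    ssl = ssl_fraction_series(ts)
    out: dict[str, Any] = {
        "time_h": [float(t) for t in ts.times],
        "viability_percent": [None if np.isnan(v) else float(v) for v in viability],
        "ssl_fraction_percent": [None if np.isnan(v) else float(v) for v in ssl],
        "feed_rate_ml_h": feed_rate(ts.dilution_rate_per_h, ts.working_volume_l),
    }
    if budding_ratios is not None:
        bud = budding_series(ts, budding_ratios)
        out["budding_ratio"] = [None if np.isnan(v) else float(v) for v in bud]
    return out
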