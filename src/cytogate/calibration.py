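"""Mixture-calibration math: expected counts/ratios, yield-factor fits, QC.

When a dead-cell suspension is prepared by harsh killing (e.g. microwave),
partial disintegration means a "100 % dead" suspension contains fewer
countable events per volume than the viable suspension it came from.  A
volumetric mixture of the two therefore does *not* contain the volumetric
percentage of viable events.  The expected event-level composition follows
from the measured pure-suspension counts:

    N_exp_viable = N_FDA_V100 * P_viable/100 + N_FDA_D100 * P_dead/100
    N_exp_dead   = N_PI_V100  * P_viable/100 + N_PI_D100  * P_dead/100
    Ratio_V_exp  = 100 * N_exp_viable / (N_exp_viable + N_exp_dead)
    Ratio_D_exp  = 100 * N_exp_dead   / (N_exp_viable + N_exp_dead)

where N_FDA_V100 is the FDA(green)-positive count per mL in the pure viable
suspension, N_PI_D100 the PI(red)-positive count in the pure dead one, and
the cross terms capture cross-staining (typically negligible).  With zero
cross-staining the whole family collapses to a single event-yield factor
``r = N_PI_D100 / N_FDA_V100``:

    Ratio_V_exp(P) = P / (P + r * (100 - P)) * 100
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .pulse import ParameterError

#: particle-concentration ceiling (events/mL) above which acquisition
#: throttling makes counts unreliable; samples must be diluted below it.
PARTICLE_LIMIT_PER_ML = 1e6


@dataclass(frozen=True)
class PureSuspensionCounts:
    """Per-mL stained counts measured on the two pure calibration suspensions."""

    n_fda_v100: float  # FDA(green)-positive in the 100% viable suspension
    n_fda_d100: float = 0.0  # FDA-positive in the 100% dead suspension (cross-stain)
    n_pi_v100: float = 0.0  # PI(red)-positive in the 100% viable suspension (cross-stain)
    n_pi_d100: float = 0.0  # PI-positive in the 100% dead suspension

    def __post_init__(self) -> None:
        for name in ("n_fda_v100", "n_fda_d100", "n_pi_v100", "n_pi_d100"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MixtureDesignPoint:
    """One cell of the calibration design: mixing ratio x medium x load scales."""

    p_viable: float
    p_dead: float
    medium: str = "PBS"  # PBS | filtered_SSL | unfiltered_SSL
    od_scale: float = 1.0
    ssl_scale: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.p_viable + self.p_dead - 100.0) > 1e-9:
            raise ParameterError("p_viable + p_dead must equal 100")
        if self.medium not in ("PBS", "filtered_SSL", "unfiltered_SSL"):
            raise ParameterError(f"unknown medium {self.medium!r}")


@dataclass(frozen=True)
class ExpectedRatioResult:
    """Expected counts and percentages for one mixture."""

    n_exp_viable: float
    n_exp_dead: float
    ratio_v_exp: float
    ratio_d_exp: float

    def rounded(self) -> tuple[int, int]:
        """Integer-percent report form (internal math stays double precision)."""
        return int(round(self.ratio_v_exp)), int(round(self.ratio_d_exp))

    def to_dict(self) -> dict[str, float]:
        return {
            "n_exp_viable": self.n_exp_viable,
            "n_exp_dead": self.n_exp_dead,
            "ratio_v_exp": self.ratio_v_exp,
            "ratio_d_exp": self.ratio_d_exp,
        }


def expected_counts(
    pure: PureSuspensionCounts, point: MixtureDesignPoint
) -> tuple[float, float]:
    """Expected viable/dead event counts (per mL) for a volumetric mixture."""
    pv, pd_ = point.p_viable / 100.0, point.p_dead / 100.0
    n_exp_viable = pure.n_fda_v100 * pv + pure.n_fda_d100 * pd_
    n_exp_dead = pure.n_pi_v100 * pv + pure.n_pi_d100 * pd_
    return n_exp_viable, n_exp_dead


def expected_ratio(n_exp_viable: float, n_exp_dead: float) -> ExpectedRatioResult:
    """Expected viable/dead percentages from expected counts."""
    total = n_exp_viable + n_exp_dead
    if total <= 0:
        raise ParameterError("expected counts sum to zero; ratio undefined")
    rv = 100.0 * n_exp_viable / total
    return ExpectedRatioResult(n_exp_viable, n_exp_dead, rv, 100.0 - rv)


def expected_ratio_for_mixture(
    pure: PureSuspensionCounts, point: MixtureDesignPoint
) -> ExpectedRatioResult:
    """Convenience composition of :func:`expected_counts` and :func:`expected_ratio`."""
    return expected_ratio(*expected_counts(pure, point))


def ratio_v_from_yield(p_viable: float, r_yield: float) -> float:
    """Zero-cross-staining expected viable % as a function of the yield factor."""
    if p_viable <= 0:
        return 0.0
    return 100.0 * p_viable / (p_viable + r_yield * (100.0 - p_viable))


def fit_yield_factor(
    expected_row: Sequence[tuple[float, float]],
) -> float:
    """Least-squares fit of the dead-suspension yield factor ``r``.

    ``expected_row`` holds ``(P_viable, Ratio_V_exp)`` pairs from a reported
    expected-ratio row.  Endpoints (P = 0 or 100) carry no information about
    ``r`` and are ignored; at least two non-endpoint points are required.
    """
    pts = [(p, rv) for p, rv in expected_row if 0.0 < p < 100.0]
    if len(pts) < 2:
        raise ParameterError("need >= 2 non-endpoint design points to fit r_yield")
    ps = np.array([p for p, _ in pts])
    rvs = np.array([rv for _, rv in pts])

    def loss(r: float) -> float:
        pred = 100.0 * ps / (ps + r * (100.0 - ps))
        return float(((pred - rvs) ** 2).sum())

    res = minimize_scalar(loss, bounds=(1e-6, 1.0), method="bounded")
    return float(res.x)


@dataclass(frozen=True)
class AccuracyReport:
    """Measured-vs-expected summary over technical replicates."""

    mean: float
    sd: float
    expected: float
    abs_deviation: float
    tolerance: float
    passed: bool

    def to_dict(self) -> dict[str, Any]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "expected": self.expected,
            "abs_deviation": self.abs_deviation,
            "tolerance": self.tolerance,
            "passed": self.passed,
        }


def evaluate_accuracy(
    measured_replicates: Sequence[float],
    expected: ExpectedRatioResult | float,
    tolerance: float = 10.0,
) -> AccuracyReport:
    """Compare replicate viability measurements against the expected ratio.

    Passes iff both the absolute deviation of the replicate mean from the
    expectation *and* the replicate SD stay within ``tolerance`` percentage
    points (default 10).
    """
    reps = np.asarray(list(measured_replicates), dtype=float)
    if reps.size < 2:
        raise ParameterError("need >= 2 technical replicates")
    exp_v = expected.ratio_v_exp if isinstance(expected, ExpectedRatioResult) else float(expected)
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1))
    dev = abs(mean - exp_v)
    return AccuracyReport(mean, sd, exp_v, dev, tolerance, dev <= tolerance and sd <= tolerance)


@dataclass(frozen=True)
class QCVerdict:
    """Particle-load QC outcome with a dilution recommendation."""

    passed: bool
    concentration: float
    limit: float
    recommended_dilution: int  # power-of-10 factor bringing the sample in range

    def to_dict(self) -> dict[str, Any]:
        return {
            "passed": self.passed,
            "concentration": self.concentration,
            "limit": self.limit,
            "recommended_dilution": self.recommended_dilution,
        }


def qc_particle_load(
    total_concentration: float, limit: float = PARTICLE_LIMIT_PER_ML
) -> QCVerdict:
    """Check a sample's total particle load against the instrument limit.

    Passes at or below ``limit`` (default 1e6 events/mL).  Overloaded samples
    get the smallest power-of-10 dilution factor that brings them in range,
    matching serial-dilution lab practice.
    """
    if limit <= 0:
        raise ParameterError("limit must be > 0")
    if total_concentration < 0:
        raise ParameterError("total_concentration must be >= 0")
    if total_concentration <= limit:
        return QCVerdict(True, total_concentration, limit, 1)
    factor = 10
    while total_concentration / factor > limit:
        factor *= 10
    return QCVerdict(False, total_concentration, limit, factor)


# ---------------------------------------------------------------------------
# End-to-end synthetic calibration sweep

#: medium -> (dead-suspension yield factor, SSL load level) pairings used by
#: the calibration design: buffer mixtures came from a harshly killed
#: suspension (low yield), filtered-SSL mixtures from a gently killed one,
#: unfiltered-SSL mixtures behave as yield 1.
SWEEP_MEDIA = {
    "PBS": {"r_yield": 0.51, "ssl_level": 0.0},
    "filtered_SSL": {"r_yield": 0.96, "ssl_level": 0.5},
    "unfiltered_SSL": {"r_yield": 1.0, "ssl_level": 2.0},
}

SWEEP_P_VIABLE = (100.0, 80.0, 60.0, 50.0, 40.0, 20.0, 0.0)


@dataclass
class SweepPointResult:
    medium: str
    p_viable: float
    r_yield: float
    expected_viability: float
    measured_replicates: list[float]
    report: AccuracyReport

    def to_dict(self) -> dict[str, Any]:
        return {
            "medium": self.medium,
            "p_viable": self.p_viable,
            "r_yield": self.r_yield,
            "expected_viability": self.expected_viability,
            "measured_replicates": list(self.measured_replicates),
            **self.report.to_dict(),
        }


def run_calibration_sweep(
    seed: int = 1,
    n_events_per_replicate: int = 20000,
    n_replicates: int = 3,
    media: Optional[dict[str, dict[str, float]]] = None,
    p_viable_grid: Sequence[float] = SWEEP_P_VIABLE,
    tolerance: float = 10.0,
    n_reference_events: int = 4000,
) -> list[SweepPointResult]:
    """Simulate the full calibration design and score recovered vs expected viability.

    For each medium, gates are fitted once on pure-population reference runs;
    each (medium, mixing ratio) design point is then simulated in
    ``n_replicates`` technical replicates of ``n_events_per_replicate`` cell
    events, classified, and the recovered viability compared with the
    zero-cross-staining expectation for that medium's yield factor.

    Endpoint mixtures (P = 0 or 100) have an expected viability of 0 or 100
    regardless of the yield factor and are scored the same way.
    """
    from .gating import classify, fit_gates
    from .pulse import build_feature_table
    from .simulate import (
        DEFAULT_LENGTH_THRESHOLD,
        MixtureSimSpec,
        dead_spec,
        simulate_mixture,
        simulate_population,
        ssl_spec,
        viable_spec,
    )

    media = dict(SWEEP_MEDIA if media is None else media)
    rng = np.random.default_rng(seed)

    def features(events):
        return build_feature_table(events, length_threshold=DEFAULT_LENGTH_THRESHOLD)

    results: list[SweepPointResult] = []
    for medium, cfg in media.items():
        r_yield = float(cfg["r_yield"])
        ssl_level = float(cfg["ssl_level"])
        sub = int(rng.integers(0, 2**31 - 1000))
        ref_viable = features(
            simulate_population(viable_spec(), n_reference_events, seed=sub)
        )
        ref_dead = features(
            simulate_population(dead_spec(), n_reference_events, seed=sub + 1)
        )
        ref_blank = features(
            simulate_population(ssl_spec(), n_reference_events, seed=sub + 2)
        )
        gates = fit_gates(ref_viable, ref_dead, ref_blank)

        for p_viable in p_viable_grid:
            if p_viable >= 100.0:
                exp_v = 100.0
            else:
                exp_v = ratio_v_from_yield(p_viable, r_yield)
            measured: list[float] = []
            for rep in range(n_replicates):
                spec = MixtureSimSpec(
                    p_viable=p_viable,
                    p_dead=100.0 - p_viable,
                    r_yield=r_yield,
                    ssl_level=ssl_level,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    n_cell_events=n_events_per_replicate,
                )
                events, _ = simulate_mixture(spec)
                result = classify(features(events), gates)
                if result.viability_percent is None:
                    raise RuntimeError("sweep replicate classified no cells")
                measured.append(result.viability_percent)
            report = evaluate_accuracy(measured, exp_v, tolerance=tolerance)
            results.append(
                SweepPointResult(medium, p_viable, r_yield, exp_v, measured, report)
            )
    return results


def sweep_max_abs_deviation(results: Sequence[SweepPointResult]) -> float:
    """Maximum |mean measured - expected| viability over sweep points, in points."""
    return max(r.report.abs_deviation for r in results)
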