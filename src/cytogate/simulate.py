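"""Seeded synthetic pulse-shape event generator.

Emulates the three particle populations a stained yeast sample in spent
sulfite liquor (SSL) medium presents to a pulse-shape cytometer:

* **viable cells** — esterase-active, so FDA hydrolysis gives a strong green
  fluorescence pulse; intact membranes exclude PI, so red stays at noise;
* **dead cells** — PI enters the compromised membrane, giving a strong red
  pulse with green at noise.  Harsh killing (microwave) partially
  disintegrates cells, so a "100 % dead" suspension yields fewer countable
  events per volume than its viable counterpart; the ``r_yield`` factor of a
  mixture models that event-count ratio;
* **SSL particles** — lignosulfonate solids with a very broad size range that
  overlaps and exceeds the cells' in scatter, zero green by construction
  (FDA needs esterase activity), and a stochastic, low-level, heavy-tailed
  red component from PI adsorbing to particles.

Viable cells can additionally be emitted as budding mother-daughter doublets:
two overlapping Gaussian lobes that lengthen the pulse, raise the total SSC
signal and can drive the green detector into saturation.

Every trace is a noisy Gaussian profile clipped to ``[0, adc_max]``; a fixed
seed reproduces the byte-identical event stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pulse import (
    CHANNELS,
    DEFAULT_ADC_MAX,
    DEFAULT_SAMPLE_SPACING_UM,
    ParameterError,
    PulseEvent,
)

#: length threshold (a.u.) used by the default analysis pipeline: safely above
#: the simulated noise floor so pulse extent reflects the particle, not noise.
DEFAULT_LENGTH_THRESHOLD = 50.0

#: default per-sample additive noise (a.u., std of a zero-mean Gaussian).
NOISE_SIGMA = 3.0

_N_SAMPLES = 64
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.355


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional description of one particle population.

    Sizes are log-normal over pulse width (FWHM, micrometers); channel
    intensities are log-normal over pulse amplitude (a.u.).  ``median``/
    ``sigma`` below are the log-normal median and log-space std.
    """

    kind: str  # viable | dead | ssl_particle
    concentration: float = 3e5  # events per mL in the measured sample
    size_median_um: float = 4.5
    size_sigma: float = 0.10
    fsc_amp_median: float = 3000.0
    fsc_amp_sigma: float = 0.3
    ssc_amp_median: float = 2000.0
    ssc_amp_sigma: float = 0.3
    green_amp_median: float = 8000.0
    green_amp_sigma: float = 0.35
    red_amp_median: float = 6000.0
    red_amp_sigma: float = 0.35
    green_positive_fraction: float = 0.0
    red_positive_fraction: float = 0.0
    budding_fraction: float = 0.0
    green_to_red_bleed: float = 0.0  # spectral spillover coefficient

    def __post_init__(self) -> None:
        if self.kind not in ("viable", "dead", "ssl_particle"):
            raise ParameterError(f"unknown population kind {self.kind!r}")
        for name in ("green_positive_fraction", "red_positive_fraction", "budding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.concentration < 0:
            raise ParameterError("concentration must be >= 0")


def viable_spec(**overrides) -> PopulationSpec:
    """Default viable-cell population: green-positive, red-negative."""
    return replace(
        PopulationSpec(kind="viable", green_positive_fraction=1.0, red_positive_fraction=0.0),
        **overrides,
    )


def dead_spec(**overrides) -> PopulationSpec:
    """Default dead-cell population: red-positive, green-negative, slightly shrunken."""
    base = PopulationSpec(
        kind="dead",
        size_median_um=4.0,
        size_sigma=0.18,
        fsc_amp_median=2500.0,
        ssc_amp_median=1800.0,
        green_positive_fraction=0.0,
        red_positive_fraction=1.0,
    )
    return replace(base, **overrides)


def ssl_spec(**overrides) -> PopulationSpec:
    """Default SSL particle background: broad scatter, partial low-level red."""
    base = PopulationSpec(
        kind="ssl_particle",
        concentration=2e5,
        size_median_um=3.0,
        size_sigma=0.9,
        fsc_amp_median=1500.0,
        fsc_amp_sigma=0.8,
        ssc_amp_median=1000.0,
        ssc_amp_sigma=0.8,
        red_amp_median=150.0,
        red_amp_sigma=1.0,
        green_positive_fraction=0.0,
        red_positive_fraction=0.3,
    )
    return replace(base, **overrides)


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    if median <= 0:
        return np.zeros(n)
    return np.exp(rng.normal(np.log(median), sigma, size=n))


def _gaussian_lobes(
    amps: np.ndarray,
    centers: np.ndarray,
    sigmas: np.ndarray,
    n_samples: int,
) -> np.ndarray:
    """Stack of Gaussian pulses, one row per event (vectorised)."""
    x = np.arange(n_samples, dtype=float)[None, :]
    return amps[:, None] * np.exp(
        -0.5 * ((x - centers[:, None]) / sigmas[:, None]) ** 2
    )


def _simulate_traces(
    spec: PopulationSpec,
    n_events: int,
    rng: np.random.Generator,
    sample_spacing: float,
    adc_max: float,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Generate raw trace matrices per channel plus a doublet (budding) mask."""
    n = n_events
    widths_um = _lognormal(rng, spec.size_median_um, spec.size_sigma, n)
    sigmas = widths_um / (_FWHM_TO_SIGMA * sample_spacing)
    centers = _N_SAMPLES / 2.0 + rng.uniform(-2.0, 2.0, size=n)

    is_budding = rng.random(n) < spec.budding_fraction
    # daughter lobe: offset along the flow axis, smaller amplitude; the
    # offset is what lengthens the pulse relative to a single cell
    offsets = (3.2 + 0.6 * rng.random(n)) * sigmas
    daughter_scale = 0.75 + 0.2 * rng.random(n)

    green_pos = rng.random(n) < spec.green_positive_fraction
    red_pos = rng.random(n) < spec.red_positive_fraction

    amp_medians = {
        "FSC": (spec.fsc_amp_median, spec.fsc_amp_sigma, np.ones(n, dtype=bool)),
        "SSC": (spec.ssc_amp_median, spec.ssc_amp_sigma, np.ones(n, dtype=bool)),
        "FL_GREEN": (spec.green_amp_median, spec.green_amp_sigma, green_pos),
        "FL_RED": (spec.red_amp_median, spec.red_amp_sigma, red_pos),
    }

    traces: dict[str, np.ndarray] = {}
    green_amps = None
    for channel in CHANNELS:
        median, sigma, positive = amp_medians[channel]
        amps = _lognormal(rng, median, sigma, n) * positive
        if channel == "FL_GREEN":
            # budding agglomerates fluoresce strongly; can clip the detector
            amps = np.where(is_budding, amps * 2.2, amps)
            green_amps = amps
        if channel == "FL_RED" and spec.green_to_red_bleed > 0 and green_amps is not None:
            amps = amps + spec.green_to_red_bleed * green_amps
        m = _gaussian_lobes(amps, centers, sigmas, _N_SAMPLES)
        if is_budding.any():
            m2 = _gaussian_lobes(
                amps * daughter_scale, centers + offsets, sigmas, _N_SAMPLES
            )
            m = np.where(is_budding[:, None], m + m2, m)
        m = m + rng.normal(0.0, NOISE_SIGMA, size=m.shape)
        traces[channel] = np.clip(m, 0.0, adc_max)
    return traces, is_budding


def _wrap_events(
    traces: dict[str, np.ndarray],
    start_id: int,
    sample_spacing: float,
    adc_max: float,
) -> list[PulseEvent]:
    n = traces[CHANNELS[0]].shape[0]
    events = []
    for i in range(n):
        events.append(
            PulseEvent(
                event_id=start_id + i,
                channel_traces={c: traces[c][i] for c in CHANNELS},
                sample_spacing=sample_spacing,
                adc_max=adc_max,
            )
        )
    return events


def simulate_population(
    spec: PopulationSpec,
    n_events: int,
    seed: int,
    sample_spacing: float = DEFAULT_SAMPLE_SPACING_UM,
    adc_max: float = DEFAULT_ADC_MAX,
    start_id: int = 0,
) -> list[PulseEvent]:
    """Draw ``n_events`` pulse events from one population specification."""
    if n_events < 0:
        raise ParameterError("n_events must be >= 0")
    if n_events == 0:
        return []
    rng = np.random.default_rng(seed)
    traces, _ = _simulate_traces(spec, n_events, rng, sample_spacing, adc_max)
    return _wrap_events(traces, start_id, sample_spacing, adc_max)


@dataclass(frozen=True)
class MixtureSimSpec:
    """A calibration-style mixture of viable and dead suspensions plus SSL background.

    ``p_viable``/``p_dead`` are the *volumetric* mixing percentages of the
    pure suspensions (must sum to 100).  ``r_yield`` is the event-count yield
    of the dead suspension relative to the viable one (cell disintegration
    during killing); the *event-level* ground-truth viable fraction therefore
    exceeds ``p_viable`` whenever ``r_yield < 1``.  ``ssl_level`` scales the
    SSL particle load (0 = clean buffer), ``biomass_scale`` the cell load
    (OD-equivalent multiplier).
    """

    p_viable: float
    p_dead: float
    r_yield: float = 1.0
    ssl_level: float = 1.0
    biomass_scale: float = 1.0
    budding_fraction: float = 0.0
    seed: int = 0
    n_cell_events: int = 20000
    n_ssl_base_events: int = 4000
    viable: PopulationSpec = field(default_factory=viable_spec)
    dead: PopulationSpec = field(default_factory=dead_spec)
    ssl: PopulationSpec = field(default_factory=ssl_spec)

    def __post_init__(self) -> None:
        if abs(self.p_viable + self.p_dead - 100.0) > 1e-9:
            raise ParameterError(
                f"p_viable + p_dead must equal 100, got {self.p_viable + self.p_dead}"
            )
        if not 0.0 < self.r_yield <= 1.0:
            raise ParameterError("r_yield must lie in (0, 1]")
        if self.ssl_level < 0 or self.biomass_scale <= 0:
            raise ParameterError("ssl_level must be >= 0 and biomass_scale > 0")

    def event_counts(self) -> dict[str, int]:
        """Deterministic expected event counts per population."""
        scale = self.biomass_scale * self.n_cell_events / 100.0
        n_viable = int(round(scale * self.p_viable))
        n_dead = int(round(scale * self.p_dead * self.r_yield))
        n_ssl = int(round(self.n_ssl_base_events * self.ssl_level))
        return {"viable": n_viable, "dead": n_dead, "ssl_particle": n_ssl}

    def total_concentration(self) -> float:
        """Total particle concentration (events/mL) implied by the component specs."""
        return (
            self.biomass_scale
            * (self.p_viable / 100.0 * self.viable.concentration
               + self.p_dead / 100.0 * self.r_yield * self.dead.concentration)
            + self.ssl_level * self.ssl.concentration
        )


def simulate_mixture(
    spec: MixtureSimSpec,
    sample_spacing: float = DEFAULT_SAMPLE_SPACING_UM,
    adc_max: float = DEFAULT_ADC_MAX,
) -> tuple[list[PulseEvent], pd.DataFrame]:
    """Simulate a stained mixture; returns events plus a ground-truth sidecar.

    The sidecar DataFrame has columns ``event_id``, ``label`` (viable / dead /
    background) and ``morphology`` (single / budding / n/a).  Event counts per
    population follow the deterministic composition of
    :meth:`MixtureSimSpec.event_counts`; the event order is shuffled.
    """
    counts = spec.event_counts()
    rng = np.random.default_rng(spec.seed)
    viable = replace(spec.viable, budding_fraction=spec.budding_fraction)

    all_traces: dict[str, list[np.ndarray]] = {c: [] for c in CHANNELS}
    labels: list[str] = []
    morphology: list[str] = []
    for pop_spec, label in ((viable, "viable"), (spec.dead, "dead"), (spec.ssl, "background")):
        n = counts["ssl_particle" if label == "background" else label]
        if n == 0:
            continue
        traces, is_budding = _simulate_traces(pop_spec, n, rng, sample_spacing, adc_max)
        for c in CHANNELS:
            all_traces[c].append(traces[c])
        labels += [label] * n
        if label == "viable":
            morphology += ["budding" if b else "single" for b in is_budding]
        else:
            morphology += ["n/a"] * n

    n_total = len(labels)
    if n_total == 0:
        return [], pd.DataFrame(columns=["event_id", "label", "morphology"])
    stacked = {c: np.concatenate(all_traces[c], axis=0) for c in CHANNELS}
    order = rng.permutation(n_total)
    stacked = {c: stacked[c][order] for c in CHANNELS}
    labels_arr = np.asarray(labels, dtype=object)[order]
    morph_arr = np.asarray(morphology, dtype=object)[order]

    events = _wrap_events(stacked, 0, sample_spacing, adc_max)
    truth = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "label": labels_arr,
            "morphology": morph_arr,
        }
    )
    return events, truth


def apply_instrument_limit(
    events: Sequence[PulseEvent],
    total_concentration: float,
    limit: float = 1e6,
    seed: int = 0,
) -> tuple[list[PulseEvent], bool]:
    """Emulate acquisition throttling above the instrument's particle limit.

    At particle loads above ``limit`` (events/mL) the instrument reduces data
    acquisition; we model the retained subset as *brightness-weighted* (large
    or bright events preferentially survive), so population ratios in the
    retained data become biased — the mechanism behind inaccurate counts in
    overloaded samples.  At or below the limit the events pass unchanged.

    Returns ``(events, overloaded)``.
    """
    if limit <= 0:
        raise ParameterError("limit must be > 0")
    if total_concentration < 0:
        raise ParameterError("total_concentration must be >= 0")
    events = list(events)
    if total_concentration <= limit or not events:
        return events, total_concentration > limit
    n = len(events)
    keep = max(1, int(round(n * limit / total_concentration)))
    brightness = np.array(
        [sum(float(e.channel_traces[c].max()) for c in CHANNELS) for e in events]
    )
    w = brightness ** 1.5
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=keep, replace=False, p=w / w.sum())
    idx.sort()
    return [events[i] for i in idx], True
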