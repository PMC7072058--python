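"""Pulse-shape event model and per-channel scalar feature extraction.

Pulse-shape ("scanning") flow cytometers record the full signal trace of
every particle on every detector instead of just peak/area statistics.  From
each trace we derive the three scalar features used throughout the package:

``total``
    area of the trace above baseline (a.u.), the analogue of the classic
    "integral" listmode parameter;
``maximum``
    peak height (a.u.);
``length``
    spatial extent of the pulse above a threshold, in micrometers, obtained
    from the sample count via the per-sample spacing set by the flow speed.

A saturation flag records whether the trace clipped at the detector ceiling
(``adc_max``) for a minimum number of consecutive samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical detector channels, in feature-table column order.
CHANNELS = ("FSC", "SSC", "FL_GREEN", "FL_RED")

#: Population labels a classified event may carry.
POPULATION_LABELS = ("viable", "dead", "background", "unclassified")

#: Morphology labels for viable events.
MORPHOLOGY_LABELS = ("single", "budding", "n/a")

DEFAULT_SAMPLE_SPACING_UM = 0.5
DEFAULT_ADC_MAX = 65535.0
DEFAULT_SATURATION_MIN_RUN = 2


class PulseFormatError(ValueError):
    """A pulse event or trace violates the structural contract."""


class ParameterError(ValueError):
    """An operation received an out-of-range parameter."""


@dataclass(eq=False)
class PulseEvent:
    """A single particle transit: one sampled trace per detector channel.

    All four canonical channels must be present, with equal-length,
    non-negative traces bounded by ``adc_max``.  Events compare by identity
    (traces are arrays; use the feature table for value comparisons).
    """

    event_id: int
    channel_traces: Mapping[str, np.ndarray]
    sample_spacing: float = DEFAULT_SAMPLE_SPACING_UM
    adc_max: float = DEFAULT_ADC_MAX

    def __post_init__(self) -> None:
        traces = {str(k): np.asarray(v, dtype=float) for k, v in self.channel_traces.items()}
        missing = [c for c in CHANNELS if c not in traces]
        if missing:
            raise PulseFormatError(
                f"event {self.event_id}: missing channel(s) {missing}"
            )
        lengths = {c: traces[c].size for c in CHANNELS}
        if min(lengths.values()) < 1:
            raise PulseFormatError(f"event {self.event_id}: empty trace")
        if len(set(lengths.values())) != 1:
            raise PulseFormatError(
                f"event {self.event_id}: unequal trace lengths {lengths}"
            )
        if self.sample_spacing <= 0:
            raise ParameterError("sample_spacing must be positive")
        if self.adc_max <= 0:
            raise ParameterError("adc_max must be positive")
        for c in CHANNELS:
            t = traces[c]
            if np.any(t < 0) or np.any(t > self.adc_max):
                raise PulseFormatError(
                    f"event {self.event_id}, channel {c}: samples outside [0, adc_max]"
                )
        object.__setattr__(self, "channel_traces", traces)

    @property
    def n_samples(self) -> int:
        return self.channel_traces[CHANNELS[0]].size


@dataclass(frozen=True)
class ChannelFeatures:
    """Scalar features for one event on one channel."""

    total: float
    maximum: float
    length: float
    saturated: bool


def _run_length_at_max(trace: np.ndarray, adc_max: float, min_run: int) -> bool:
    at_max = trace >= adc_max
    if min_run == 1:
        return bool(at_max.any())
    if at_max.size < min_run:
        return False
    # sliding window: any window of min_run consecutive True values
    window = np.convolve(at_max.astype(int), np.ones(min_run, dtype=int), mode="valid")
    return bool((window >= min_run).any())


def detect_saturation(
    event: PulseEvent, channel: str, min_run: int = DEFAULT_SATURATION_MIN_RUN
) -> bool:
    """True iff ``channel`` clipped at ``adc_max`` for >= ``min_run`` consecutive samples.

    Single-sample spikes at the ceiling are not counted as saturation for
    ``min_run`` >= 2, which guards against isolated ADC glitches.
    """
    if channel not in CHANNELS:
        raise ParameterError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    return _run_length_at_max(event.channel_traces[channel], event.adc_max, min_run)


def extract_features(
    event: PulseEvent,
    baseline: float = 0.0,
    length_threshold: float = 0.0,
    saturation_min_run: int = DEFAULT_SATURATION_MIN_RUN,
) -> dict[str, ChannelFeatures]:
    """Compute per-channel scalar features for one event.

    ``total`` sums the trace above ``baseline`` (negative excursions are
    clipped to zero); ``length`` counts *all* samples strictly above
    ``length_threshold`` times the sample spacing — the pulse extent for the
    mostly unimodal pulses this instrument class produces.
    """
    if baseline < 0 or length_threshold < 0:
        raise ParameterError("baseline and length_threshold must be >= 0")
    out: dict[str, ChannelFeatures] = {}
    for channel in CHANNELS:
        t = event.channel_traces[channel]
        total = float(np.maximum(t - baseline, 0.0).sum())
        maximum = float(t.max())
        length = float((t > length_threshold).sum()) * event.sample_spacing
        saturated = _run_length_at_max(t, event.adc_max, saturation_min_run)
        out[channel] = ChannelFeatures(total, maximum, length, saturated)
    return out


# ---------------------------------------------------------------------------
# Feature tables

def feature_columns() -> list[str]:
    cols = []
    for channel in CHANNELS:
        p = channel.lower()
        cols += [f"{p}_total", f"{p}_max", f"{p}_length", f"{p}_saturated"]
    return cols


@dataclass
class EventFeatureTable:
    """Per-event derived features plus optional population/morphology labels.

    Thin wrapper around a :class:`pandas.DataFrame` with one row per event,
    columns ``<channel>_total/_max/_length/_saturated`` for the four channels,
    and optional ``label`` / ``morphology`` columns.  Event ids are unique.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame())

    def __post_init__(self) -> None:
        df = self.data
        if len(df):
            if "event_id" not in df.columns:
                raise PulseFormatError("feature table requires an event_id column")
            if df["event_id"].duplicated().any():
                raise PulseFormatError("event_ids must be unique")
            for col in feature_columns():
                if col not in df.columns:
                    raise PulseFormatError(f"feature table missing column {col}")
            if "label" in df.columns:
                bad = set(df["label"].dropna()) - set(POPULATION_LABELS)
                if bad:
                    raise PulseFormatError(f"unknown population labels {sorted(bad)}")
            if "morphology" in df.columns:
                bad = set(df["morphology"].dropna()) - set(MORPHOLOGY_LABELS)
                if bad:
                    raise PulseFormatError(f"unknown morphology labels {sorted(bad)}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "EventFeatureTable":
        return EventFeatureTable(self.data.loc[np.asarray(mask)].reset_index(drop=True))


def build_feature_table(
    events: Sequence[PulseEvent] | Iterable[PulseEvent],
    baseline: float = 0.0,
    length_threshold: float = 0.0,
    saturation_min_run: int = DEFAULT_SATURATION_MIN_RUN,
    labels: Sequence[str] | None = None,
    morphology: Sequence[str] | None = None,
) -> EventFeatureTable:
    """Extract features for a collection of events into an :class:`EventFeatureTable`.

    When all events share a trace length (the common case for one acquisition)
    the per-channel math is vectorised across events.
    """
    events = list(events)
    if not events:
        return EventFeatureTable(pd.DataFrame(columns=["event_id", *feature_columns()]))
    if baseline < 0 or length_threshold < 0:
        raise ParameterError("baseline and length_threshold must be >= 0")

    n = len(events)
    same_len = len({e.n_samples for e in events}) == 1
    cols: dict[str, np.ndarray] = {"event_id": np.array([e.event_id for e in events])}
    if same_len:
        spacing = np.array([e.sample_spacing for e in events])
        adc = np.array([e.adc_max for e in events])
        for channel in CHANNELS:
            m = np.stack([e.channel_traces[channel] for e in events])
            p = channel.lower()
            cols[f"{p}_total"] = np.maximum(m - baseline, 0.0).sum(axis=1)
            cols[f"{p}_max"] = m.max(axis=1)
            cols[f"{p}_length"] = (m > length_threshold).sum(axis=1) * spacing
            at_max = m >= adc[:, None]
            if saturation_min_run == 1:
                sat = at_max.any(axis=1)
            elif at_max.shape[1] < saturation_min_run:
                sat = np.zeros(n, dtype=bool)
            else:
                k = saturation_min_run
                windows = np.lib.stride_tricks.sliding_window_view(at_max, k, axis=1)
                sat = windows.all(axis=2).any(axis=1)
            cols[f"{p}_saturated"] = sat
    else:
        rows = [extract_features(e, baseline, length_threshold, saturation_min_run) for e in events]
        for channel in CHANNELS:
            p = channel.lower()
            cols[f"{p}_total"] = np.array([r[channel].total for r in rows])
            cols[f"{p}_max"] = np.array([r[channel].maximum for r in rows])
            cols[f"{p}_length"] = np.array([r[channel].length for r in rows])
            cols[f"{p}_saturated"] = np.array([r[channel].saturated for r in rows])

    df = pd.DataFrame(cols)
    if labels is not None:
        if len(labels) != n:
            raise ParameterError("labels length must match number of events")
        df["label"] = list(labels)
    if morphology is not None:
        if len(morphology) != n:
            raise ParameterError("morphology length must match number of events")
        df["morphology"] = list(morphology)
    return EventFeatureTable(df)
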