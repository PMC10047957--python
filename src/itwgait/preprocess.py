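"""Signal conditioning and gait-cycle segmentation.

The pipeline order is fixed: raw marker *coordinates* are low-pass filtered
first (zero-phase Butterworth, fc = 12 Hz by default), joint angles are
computed from the filtered coordinates, gait events are detected on the
vertical ground-reaction force, and each foot-contact-to-foot-contact span
is resampled to 101 samples (0..100% gait cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import signal

from .gaitdata_io import (
    Condition,
    FootModel,
    GaitDataError,
    GaitEvents,
    TrialRecording,
)

__all__ = [
    "FilterSpec",
    "NormalizedCycle",
    "PCT_GRID",
    "butterworth_lowpass",
    "filter_trial",
    "detect_gait_events",
    "time_normalize",
    "cycles_to_csv",
]

#: the common % gait-cycle axis: 0, 1, ..., 100
PCT_GRID: np.ndarray = np.arange(101.0)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings.

    ``order`` is the *net* attenuation order; with ``zero_phase`` the filter
    is realized as a forward-backward pass of an order/2 design (zero lag,
    so the timing of kinematic peaks is preserved).
    """

    cutoff_hz: float = 12.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise GaitDataError("cutoff_hz must be positive")
        if self.order < 1 or (self.zero_phase and self.order % 2):
            raise GaitDataError("order must be even when zero_phase is set")


def butterworth_lowpass(
    series: np.ndarray, rate: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Low-pass filter a uniformly sampled series (along axis 0).

    Same length as the input; DC gain exactly 1.  Raises when the series is
    shorter than 3x the filter order or the cutoff is not below Nyquist.
    """
    series = np.asarray(series, dtype=float)
    if spec.cutoff_hz >= rate / 2:
        raise GaitDataError(
            f"cutoff {spec.cutoff_hz} Hz not below Nyquist ({rate / 2} Hz)"
        )
    if series.shape[0] <= 3 * spec.order:
        raise GaitDataError(
            f"series too short to filter: {series.shape[0]} <= {3 * spec.order}"
        )
    if spec.zero_phase:
        sos = signal.butter(spec.order // 2, spec.cutoff_hz, fs=rate, output="sos")
        return signal.sosfiltfilt(sos, series, axis=0)
    sos = signal.butter(spec.order, spec.cutoff_hz, fs=rate, output="sos")
    return signal.sosfilt(sos, series, axis=0)


def filter_trial(trial: TrialRecording, spec: FilterSpec = FilterSpec()) -> TrialRecording:
    """Return a copy of the trial with every marker trajectory filtered.

    Gaps (NaN spans) are preserved: each contiguous visible run is filtered
    independently; runs too short for the filter are left untouched (cycles
    overlapping a gap are discarded downstream anyway).
    """
    out: dict[str, np.ndarray] = {}
    for label, xyz in trial.markers.items():
        ok = np.isfinite(xyz).all(axis=1)
        if ok.all():
            out[label] = butterworth_lowpass(xyz, trial.marker_rate, spec)
            continue
        filt = xyz.copy()
        # filter each visible run independently
        edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start > 3 * spec.order:
                filt[start:stop] = butterworth_lowpass(
                    xyz[start:stop], trial.marker_rate, spec
                )
        out[label] = filt
    new = replace(trial, markers=out)
    return new


def detect_gait_events(
    vertical_grf: np.ndarray,
    analog_rate: float,
    marker_rate: float,
    threshold_n: float = 20.0,
    debounce_ms: float = 10.0,
) -> GaitEvents:
    """Threshold-based gait events from a vertical GRF channel.

    Foot contact is the first analog sample where the force rises above
    ``threshold_n`` and *stays* above it for at least the debounce interval;
    foot off is the first subsequent sample where it falls below and stays
    below.  Sample indices are mapped to the marker timeline by the rate
    ratio.  If the force never crosses the threshold, empty events are
    returned with a warning.
    """
    if threshold_n <= 0:
        raise GaitDataError("threshold_n must be positive")
    grf = np.asarray(vertical_grf, dtype=float)
    debounce = max(1, int(round(debounce_ms / 1000.0 * analog_rate)))
    above = grf > threshold_n

    contacts_a: list[int] = []
    offs_a: list[int] = []
    in_stance = False
    # run-length encode the above/below sequence
    change = np.flatnonzero(np.diff(above.view(np.int8)))
    starts = np.concatenate(([0], change + 1))
    stops = np.concatenate((change + 1, [len(grf)]))
    for start, stop in zip(starts, stops):
        length = stop - start
        if above[start]:
            if not in_stance and length >= debounce:
                contacts_a.append(int(start))
                in_stance = True
        else:
            if in_stance and (length >= debounce or stop == len(grf)):
                offs_a.append(int(start))
                in_stance = False
    if not contacts_a:
        warnings.warn("GRF never crossed the contact threshold; no events detected",
                      stacklevel=2)
    ratio = marker_rate / analog_rate
    contacts = [int(round(i * ratio)) for i in contacts_a]
    offs = [int(round(i * ratio)) for i in offs_a]
    # rounding to the coarser marker timeline may collapse neighbours
    contacts = sorted(set(contacts))
    offs = sorted(set(offs))
    return GaitEvents(contacts, offs, source="force_plate")


@dataclass
class NormalizedCycle:
    """A 101-sample sagittal ankle waveform on the 0..100% gait-cycle axis.

    Dorsiflexion positive, plantarflexion negative (deg).  ``stance_end_pct``
    is the foot-off instant in % gait cycle.
    """

    samples: np.ndarray
    stance_end_pct: float
    model: FootModel | None = None
    condition: Condition | None = None
    subject_id: str = ""
    cycle_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (101,):
            raise GaitDataError("a normalized cycle has exactly 101 samples")
        if not np.all(np.isfinite(self.samples)):
            raise GaitDataError("normalized cycle contains non-finite samples")
        if not 0.0 < self.stance_end_pct < 100.0:
            raise GaitDataError("stance_end_pct must lie strictly inside (0, 100)")


def time_normalize(
    angle_series: np.ndarray,
    events: GaitEvents,
    *,
    model: FootModel | None = None,
    condition: Condition | None = None,
    subject_id: str = "",
    trial_id: str = "",
) -> list[NormalizedCycle]:
    """Resample each contact-to-contact span to 101 points (linear interp).

    Cycles without exactly one enclosed foot-off, or overlapping non-finite
    angle samples (missing markers), are skipped with a warning.
    """
    series = np.asarray(angle_series, dtype=float)
    if len(events.foot_contact_frames) < 2:
        raise GaitDataError("need at least two foot contacts to form a cycle")
    cycles: list[NormalizedCycle] = []
    for k, (c0, off, c1) in enumerate(events.cycles()):
        if c1 >= len(series):
            warnings.warn(f"cycle [{c0}, {c1}] exceeds the trial length; skipped",
                          stacklevel=2)
            continue
        span = series[c0 : c1 + 1]
        if not np.all(np.isfinite(span)):
            warnings.warn(
                f"cycle [{c0}, {c1}] overlaps missing samples; skipped", stacklevel=2
            )
            continue
        x = c0 + (c1 - c0) * PCT_GRID / 100.0
        samples = np.interp(x, np.arange(c0, c1 + 1), span)
        cycles.append(
            NormalizedCycle(
                samples=samples,
                stance_end_pct=100.0 * (off - c0) / (c1 - c0),
                model=model,
                condition=condition,
                subject_id=subject_id,
                cycle_id=f"{trial_id}#{k}",
            )
        )
    return cycles


def cycles_to_csv(cycles: Iterable[NormalizedCycle], path) -> None:
    """Export normalized cycles as CSV: 101 rows, one column per cycle."""
    import csv as _csv

    cycles = list(cycles)
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["pct"] + [c.cycle_id or str(i) for i, c in enumerate(cycles)])
        for row in range(101):
            w.writerow([row] + [repr(float(c.samples[row])) for c in cycles])
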