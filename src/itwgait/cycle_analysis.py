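"""Scalar outcomes and waveform-level statistics on normalized gait cycles.

Covers the four per-cycle / per-cohort reductions used in the analysis:

* representative-trial selection: the cycle minimizing the area between its
  waveform and the pointwise median waveform of the set;
* the linear fit method (LFM): per-subject affine regression of the
  representative curve onto the cohort reference curve, with R^2 as the
  inter-subject consistency measure (consistent when mean R^2 > 0.5);
* the six clinical scalar parameters: ankle angle at foot contact, peak
  dorsiflexion during stance (value and timing), peak plantarflexion over
  the full cycle (value and timing) and their range of motion;
* rule-based rocker classification for toe-walking severity staging: a
  heel (first) rocker requires a foot-contact angle above -5 deg with a
  down-going excursion within the first 12% of the gait cycle; a premature
  forefoot (third) rocker is a stance dorsiflexion peak strictly before
  30% of the gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .gaitdata_io import GaitDataError
from .preprocess import NormalizedCycle, PCT_GRID

__all__ = [
    "AnkleParameters",
    "RockerCriteria",
    "RockerFlags",
    "LFMResult",
    "RepresentativeSelection",
    "median_waveform",
    "select_representative",
    "lfm",
    "extract_parameters",
    "classify_rockers",
    "rocker_prevalence",
]


@dataclass(frozen=True)
class AnkleParameters:
    """The six scalar outcomes of one gait cycle (deg / % gait cycle)."""

    angle_at_fc: float
    peak_df: float
    t_peak_df: float
    peak_pf: float
    t_peak_pf: float
    rom: float


@dataclass(frozen=True)
class RockerCriteria:
    """Thresholds of the rule-based rocker classification."""

    fc_angle_threshold: float = -5.0   # deg
    downgoing_window: float = 12.0     # % gait cycle
    premature_ff_threshold: float = 30.0  # % gait cycle

    def __post_init__(self) -> None:
        if not (0.0 < self.downgoing_window < 100.0):
            raise GaitDataError("downgoing_window must lie in (0, 100)")
        if not np.isfinite(self.fc_angle_threshold):
            raise GaitDataError("fc_angle_threshold must be finite")


@dataclass(frozen=True)
class RockerFlags:
    heel_rocker: bool
    premature_forefoot_rocker: bool


@dataclass
class LFMResult:
    """Linear-fit-method outcome: subject = a1 * reference + a0, with R^2."""

    a1: np.ndarray
    a0: np.ndarray
    r2: np.ndarray
    r2_mean: float
    consistent: bool  # cohort mean R^2 > 0.5


@dataclass
class RepresentativeSelection:
    """Per-cycle areas to the median waveform and the argmin index."""

    areas: np.ndarray  # deg * %GC
    chosen_index: int


def _stack(cycles: Sequence[NormalizedCycle | np.ndarray]) -> np.ndarray:
    rows = [c.samples if isinstance(c, NormalizedCycle) else np.asarray(c, float)
            for c in cycles]
    if not rows:
        raise GaitDataError("empty cycle set")
    out = np.vstack(rows)
    if out.shape[1] != 101:
        raise GaitDataError("all cycles must have 101 samples")
    return out


def median_waveform(cycles: Sequence[NormalizedCycle | np.ndarray]) -> np.ndarray:
    """Pointwise median waveform of a cycle set (midpoint rule for even counts)."""
    return np.median(_stack(cycles), axis=0)


def select_representative(
    cycles: Sequence[NormalizedCycle | np.ndarray],
) -> RepresentativeSelection:
    """Pick the cycle closest to the median waveform.

    Distance is the trapezoidal integral of |cycle - median| over
    0..100% gait cycle; ties break toward the lowest index.
    """
    data = _stack(cycles)
    if data.shape[0] < 2:
        raise GaitDataError("representative selection needs at least 2 cycles")
    med = np.median(data, axis=0)
    areas = np.trapezoid(np.abs(data - med), PCT_GRID, axis=1)
    return RepresentativeSelection(areas=areas, chosen_index=int(np.argmin(areas)))


def lfm(
    subject_cycles: Sequence[NormalizedCycle | np.ndarray],
    reference: np.ndarray | None = None,
) -> LFMResult:
    """Linear fit method over one representative cycle per subject.

    The reference defaults to the pointwise median of the set.  Each
    subject's curve is least-squares regressed onto the reference over the
    101 samples; R^2 is the squared Pearson correlation.
    """
    data = _stack(subject_cycles)
    if data.shape[0] < 2:
        raise GaitDataError("LFM needs at least 2 subjects")
    ref = median_waveform(data) if reference is None else np.asarray(reference, float)
    if np.ptp(ref) == 0:
        raise GaitDataError("zero-variance reference curve: R^2 undefined")
    a1 = np.empty(data.shape[0])
    a0 = np.empty(data.shape[0])
    r2 = np.empty(data.shape[0])
    for i, row in enumerate(data):
        res = stats.linregress(ref, row)
        a1[i], a0[i] = res.slope, res.intercept
        r2[i] = res.rvalue**2
    r2_mean = float(np.mean(r2))
    return LFMResult(a1=a1, a0=a0, r2=r2, r2_mean=r2_mean, consistent=r2_mean > 0.5)


def extract_parameters(cycle: NormalizedCycle) -> AnkleParameters:
    """The six scalar parameters of a normalized cycle.

    Peak dorsiflexion is searched over stance only (0% to foot-off), peak
    plantarflexion over the full cycle; ties take the earliest instant.
    """
    c = cycle.samples
    stance = PCT_GRID <= cycle.stance_end_pct
    i_df = int(np.argmax(c[stance]))  # stance starts at index 0: global index
    i_pf = int(np.argmin(c))
    peak_df = float(c[i_df])
    peak_pf = float(c[i_pf])
    return AnkleParameters(
        angle_at_fc=float(c[0]),
        peak_df=peak_df,
        t_peak_df=float(PCT_GRID[i_df]),
        peak_pf=peak_pf,
        t_peak_pf=float(PCT_GRID[i_pf]),
        rom=peak_df - peak_pf,
    )


def classify_rockers(
    cycle: NormalizedCycle,
    params: AnkleParameters,
    criteria: RockerCriteria = RockerCriteria(),
) -> RockerFlags:
    """Rule-based heel / premature-forefoot rocker detection.

    Heel rocker: foot-contact angle strictly above the threshold AND a
    down-going pattern inside the opening window (net excursion negative
    and the window minimum strictly after 0%).  Premature forefoot rocker:
    the stance dorsiflexion peak strictly before the timing threshold.
    """
    c = cycle.samples
    window = np.flatnonzero(PCT_GRID <= criteria.downgoing_window)
    net_down = c[window[-1]] - c[0] < 0
    min_after_start = int(np.argmin(c[window])) > 0
    heel = (params.angle_at_fc > criteria.fc_angle_threshold
            and net_down and min_after_start)
    premature = params.t_peak_df < criteria.premature_ff_threshold
    return RockerFlags(heel_rocker=bool(heel),
                       premature_forefoot_rocker=bool(premature))


def rocker_prevalence(flags: Iterable[RockerFlags]) -> dict[str, float]:
    """Percentage of cycles with each rocker flag set."""
    flags = list(flags)
    if not flags:
        raise GaitDataError("rocker_prevalence needs at least one cycle")
    n = len(flags)
    return {
        "heel_rocker_pct": 100.0 * sum(f.heel_rocker for f in flags) / n,
        "premature_forefoot_pct":
            100.0 * sum(f.premature_forefoot_rocker for f in flags) / n,
    }
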