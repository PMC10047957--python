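"""Forward-kinematic synthesis of marker-level gait trials.

The study population this package targets (children with idiopathic toe
walking, measured barefoot and with a corrective orthosis) has no public
dataset, so every pipeline stage is exercised on synthetic trials with
known ground truth.  The generator drives a lab -> tibia -> hindfoot ->
forefoot kinematic chain:

* the hindfoot-tibia sagittal angle follows a prescribed 101-sample
  waveform (toe-walking or heel-toe profile);
* a single sagittal midfoot hinge between hindfoot and forefoot carries
  the "foot intrinsic" motion that mono-segment foot models fold into the
  ankle — its amplitude is the experiment's dial;
* all model marker sets ride rigidly on their segments, with optional
  isotropic Gaussian noise;
* a stance-gated double-bump vertical GRF (1000 samples/s against
  250 samples/s kinematics) lets the event detector recover the true gait
  cycles.

Default cohort conditions: 14 subjects, ~6 cycles each (range 4-10),
barefoot trials use a toe-walking waveform with 15 deg of midfoot motion,
orthosis trials a heel-toe waveform with none.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation

from .gaitdata_io import (
    Condition,
    GaitEvents,
    ParameterError,
    Side,
    TrialRecording,
)
from .preprocess import PCT_GRID

__all__ = [
    "WaveformParams",
    "SyntheticSubjectConfig",
    "CohortEffectConfig",
    "GroundTruth",
    "SubjectData",
    "generate_ankle_waveform",
    "midfoot_waveform",
    "synthesize_trial",
    "synthesize_static",
    "generate_cohort",
]

#: dorsiflexion-positive flexion axis in the lab frame (subject's right
#: for progression along +X with +Y left): toe-up rotations are positive.
FLEXION_AXIS_LAB = np.array([0.0, -1.0, 0.0])

GRAVITY = 9.81


# ---------------------------------------------------------------------------
# waveforms

@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of a sagittal ankle waveform (deg / % gait cycle).

    ``profile`` names the gait pattern the defaults emulate: ``heel_toe``
    (orthosis-corrected) has a foot-contact angle above -5 deg and a stance
    dorsiflexion peak at or after 30% GC; ``toe_walking`` has a
    foot-contact angle below -5 deg and a premature dorsiflexion peak, so
    the rocker classifier separates the two by construction.
    """

    profile: str = "heel_toe"
    angle_at_fc: float = 0.0
    peak_df: float = 12.0
    t_peak_df: float = 45.0
    peak_pf: float = -15.0
    t_peak_pf: float = 65.0
    stance_end_pct: float = 62.0
    loading_dip_deg: float = 5.0  # first-rocker plantarflexion dip below fc
    t_dip: float = 8.0            # % GC of the dip minimum
    harmonics: int | None = None  # Fourier truncation; None = no smoothing

    def __post_init__(self) -> None:
        if self.peak_df < self.angle_at_fc:
            raise ParameterError(
                "infeasible waveform: peak_df below the foot-contact angle"
            )
        if self.peak_pf > min(self.angle_at_fc, self.peak_df):
            raise ParameterError("infeasible waveform: peak_pf is not the minimum")
        if not 0.0 < self.t_peak_df < self.t_peak_pf < 100.0:
            raise ParameterError("waveform timings must satisfy 0 < t_df < t_pf < 100")
        if not self.t_peak_df <= self.stance_end_pct < 100.0:
            raise ParameterError("peak dorsiflexion must occur during stance")
        if self.loading_dip_deg < 0:
            raise ParameterError("loading_dip_deg must be non-negative")
        if self.loading_dip_deg > 0:
            if not 0.0 < self.t_dip < self.t_peak_df:
                raise ParameterError("t_dip must precede the dorsiflexion peak")
            if self.angle_at_fc - self.loading_dip_deg <= self.peak_pf:
                raise ParameterError("loading dip must stay above peak plantarflexion")
        if self.harmonics is not None and self.harmonics < 0:
            raise ParameterError("harmonics must be non-negative")

    @classmethod
    def heel_toe(cls, **overrides) -> "WaveformParams":
        return cls(profile="heel_toe", **overrides)

    @classmethod
    def toe_walking(cls, **overrides) -> "WaveformParams":
        defaults = dict(
            angle_at_fc=-10.0, peak_df=-2.0, t_peak_df=20.0,
            peak_pf=-18.0, t_peak_pf=60.0, stance_end_pct=62.0,
            loading_dip_deg=0.0,
        )
        defaults.update(overrides)
        return cls(profile="toe_walking", **defaults)


def generate_ankle_waveform(params: WaveformParams) -> np.ndarray:
    """Smooth 101-sample periodic waveform realizing the requested landmarks.

    A shape-preserving (PCHIP) interpolant through the knots
    (0, fc), [(t_dip, fc - dip),] (t_df, peak_df), (t_pf, peak_pf),
    (100, fc) — monotone between knots, so the requested peaks are the
    global stance maximum and global minimum.  A positive
    ``loading_dip_deg`` inserts the first-rocker plantarflexion dip of
    heel-toe gait after foot contact.  ``harmonics = k`` truncates the
    Fourier series to k harmonics; ``harmonics = 0`` degenerates to a
    constant at the foot-contact angle.
    """
    if params.harmonics == 0:
        return np.full(101, params.angle_at_fc)
    knots_t = [0.0, params.t_peak_df, params.t_peak_pf, 100.0]
    knots_v = [params.angle_at_fc, params.peak_df, params.peak_pf, params.angle_at_fc]
    if params.loading_dip_deg > 0:
        knots_t.insert(1, params.t_dip)
        knots_v.insert(1, params.angle_at_fc - params.loading_dip_deg)
    wave = PchipInterpolator(knots_t, knots_v)(PCT_GRID)
    if params.harmonics is not None:
        spec = np.fft.rfft(wave[:100])
        spec[params.harmonics + 1 :] = 0.0
        smooth = np.fft.irfft(spec, 100)
        wave = np.concatenate([smooth, smooth[:1]])
    return wave


def midfoot_waveform(amplitude_deg: float) -> np.ndarray:
    """Midfoot (forefoot-vs-hindfoot) sagittal hinge angle over the cycle.

    A plantarflexion (negative) bump peaking at mid-cycle, zero at the
    cycle boundaries; mono-segment models fold it into the ankle angle.
    """
    return -amplitude_deg * 0.5 * (1.0 - np.cos(2.0 * np.pi * PCT_GRID / 100.0))


# ---------------------------------------------------------------------------
# subject geometry and configuration

@dataclass(frozen=True)
class SyntheticSubjectConfig:
    """Per-subject anatomy, waveforms and measurement-noise settings."""

    subject_id: str = "S00"
    side: Side = Side.RIGHT
    tibia_length_mm: float = 360.0
    foot_length_mm: float = 210.0  # CA to distal toe marker
    body_mass_kg: float = 37.0
    bf_waveform: WaveformParams = field(default_factory=WaveformParams.toe_walking)
    fo_waveform: WaveformParams = field(default_factory=WaveformParams.heel_toe)
    midfoot_amplitude_bf: float = 15.0
    midfoot_amplitude_fo: float = 0.0
    noise_sd_mm: float = 0.5
    cycle_duration_s: float = 1.0
    walking_speed_mm_s: float = 1100.0
    tibia_tilt_amp_deg: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tibia_length_mm <= 0 or self.foot_length_mm <= 0:
            raise ParameterError("segment lengths must be positive")
        if self.noise_sd_mm < 0:
            raise ParameterError("noise_sd_mm must be non-negative")


def _segment_templates(config: SyntheticSubjectConfig):
    """Marker positions in segment-local frames (right side, mm).

    Local frames coincide with the lab frame in the neutral pose; shank
    locals are relative to the ankle-joint centre, hindfoot locals to the
    ankle-joint centre, forefoot locals to the midfoot hinge.
    """
    fs = config.foot_length_mm / 210.0
    ts = config.tibia_length_mm / 360.0
    tl = config.tibia_length_mm
    shank = {
        "MMAL": np.array([0.0, 35.0 * ts, 0.0]),
        "LMAL": np.array([0.0, -35.0 * ts, 0.0]),
        "KNE": np.array([0.0, -45.0 * ts, tl]),
        "KNEM": np.array([0.0, 45.0 * ts, tl]),
    }
    hindfoot = {
        "CA": np.array([-60.0, 0.0, -40.0]) * fs,
        "MCA": np.array([-30.0, 25.0, -55.0]) * fs,
        "LCA": np.array([-30.0, -25.0, -55.0]) * fs,
    }
    midfoot_joint = np.array([25.0, 0.0, -50.0]) * fs
    forefoot = {
        "MT": np.array([75.0, 5.0, -5.0]) * fs,
        "TOE": np.array([125.0, 0.0, -5.0]) * fs,
    }
    if config.side is Side.LEFT:
        flip = np.array([1.0, -1.0, 1.0])
        shank = {k: v * flip for k, v in shank.items()}
        hindfoot = {k: v * flip for k, v in hindfoot.items()}
        forefoot = {k: v * flip for k, v in forefoot.items()}
        midfoot_joint = midfoot_joint * flip
    return shank, hindfoot, midfoot_joint, forefoot


@dataclass
class GroundTruth:
    """What the generator actually put into a trial."""

    hindfoot_tibia_angle: np.ndarray  # 101-sample waveform, deg
    midfoot_angle: np.ndarray         # 101-sample waveform, deg
    events: GaitEvents
    stance_end_pct: float


def _flexion_rotations(angles_deg: np.ndarray) -> np.ndarray:
    """Batch rotation matrices about the lab flexion axis (toe-up positive)."""
    rotvec = np.deg2rad(angles_deg)[:, None] * FLEXION_AXIS_LAB[None, :]
    return Rotation.from_rotvec(rotvec).as_matrix()


def _grf_profile(phase_pct: np.ndarray, stance_end_pct: float, mass_kg: float) -> np.ndarray:
    """Stance-gated double-bump vertical GRF, peak ~1.2 body weight.

    The rise/fall ramps span 2% of stance so the 20 N contact threshold is
    crossed within about one analog sample of the true event.
    """
    x = phase_pct / stance_end_pct  # fraction of stance
    in_stance = x < 1.0
    ramp = np.clip(np.minimum(x, 1.0 - x) / 0.02, 0.0, 1.0)
    bumps = 1.0 + 0.2 * np.cos(4.0 * np.pi * (x - 0.25))  # peaks 1.2 at 25/75%
    f = mass_kg * GRAVITY * ramp * bumps
    return np.where(in_stance, np.maximum(f, 0.0), 0.0)


def synthesize_trial(
    config: SyntheticSubjectConfig,
    condition: Condition,
    n_cycles: int = 6,
    *,
    marker_rate: float = 250.0,
    analog_rate: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> tuple[TrialRecording, GroundTruth]:
    """One walking trial (markers + vertical GRF) with known ground truth.

    The trial includes a quarter-cycle lead-in and tail around the
    ``n_cycles`` complete gait cycles; foot contacts fall exactly on the
    generator's bookkept frames.
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if condition is Condition.STATIC:
        raise ParameterError("use synthesize_static for the calibration trial")
    wave_params = (
        config.bf_waveform if condition is Condition.BF else config.fo_waveform
    )
    amp = (
        config.midfoot_amplitude_bf
        if condition is Condition.BF
        else config.midfoot_amplitude_fo
    )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ankle_wave = generate_ankle_waveform(wave_params)
    mid_wave = midfoot_waveform(amp)

    T = int(round(config.cycle_duration_s * marker_rate))
    lead = T // 4
    tail = T // 4
    n_frames = lead + n_cycles * T + tail
    frames = np.arange(n_frames)
    phase = ((frames - lead) % T) / T * 100.0
    theta = np.interp(phase, PCT_GRID, ankle_wave)
    mid = np.interp(phase, PCT_GRID, mid_wave)
    tibia_tilt = config.tibia_tilt_amp_deg * np.sin(2.0 * np.pi * phase / 100.0)

    shank, hindfoot, midfoot_joint, forefoot = _segment_templates(config)
    ankle_height = 0.3 * config.foot_length_mm  # neutral ankle-centre height
    t = frames / marker_rate
    ankle_centre = np.column_stack(
        [config.walking_speed_mm_s * t, np.zeros(n_frames),
         np.full(n_frames, ankle_height)]
    )

    R_tib = _flexion_rotations(tibia_tilt)
    R_hind = np.einsum("nij,njk->nik", R_tib, _flexion_rotations(theta))
    R_fore = np.einsum("nij,njk->nik", R_hind, _flexion_rotations(mid))
    joint = ankle_centre + np.einsum("nij,j->ni", R_hind, midfoot_joint)

    markers: dict[str, np.ndarray] = {}
    for label, local in shank.items():
        markers[label] = ankle_centre + np.einsum("nij,j->ni", R_tib, local)
    for label, local in hindfoot.items():
        markers[label] = ankle_centre + np.einsum("nij,j->ni", R_hind, local)
    for label, local in forefoot.items():
        markers[label] = joint + np.einsum("nij,j->ni", R_fore, local)
    if config.noise_sd_mm > 0:
        for label in markers:
            markers[label] = markers[label] + rng.normal(
                0.0, config.noise_sd_mm, markers[label].shape
            )

    n_analog = int(round(n_frames * analog_rate / marker_rate))
    a_frames = np.arange(n_analog) * marker_rate / analog_rate
    a_phase = ((a_frames - lead) % T) / T * 100.0
    grf = _grf_profile(a_phase, wave_params.stance_end_pct, config.body_mass_kg)

    contacts = [lead + k * T for k in range(n_cycles + 1)]
    offs = [
        lead + k * T + int(round(wave_params.stance_end_pct / 100.0 * T))
        for k in range(n_cycles + 1)
    ]
    offs = [f for f in offs if f < n_frames]
    trial = TrialRecording(
        trial_id=f"{config.subject_id}_{condition.value}",
        subject_id=config.subject_id,
        condition=condition,
        side=config.side,
        markers=markers,
        marker_rate=marker_rate,
        analog={"Fz": grf},
        analog_rate=analog_rate,
    )
    truth = GroundTruth(
        hindfoot_tibia_angle=ankle_wave.copy(),
        midfoot_angle=mid_wave.copy(),
        events=GaitEvents(contacts, offs, source="provided"),
        stance_end_pct=wave_params.stance_end_pct,
    )
    return trial, truth


def synthesize_static(
    config: SyntheticSubjectConfig,
    *,
    duration_s: float = 2.0,
    marker_rate: float = 250.0,
    rng: np.random.Generator | None = None,
) -> TrialRecording:
    """Standing calibration trial: neutral pose (zero ankle/midfoot angles)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n_frames = int(round(duration_s * marker_rate))
    shank, hindfoot, midfoot_joint, forefoot = _segment_templates(config)
    ankle_centre = np.array([0.0, 0.0, 0.3 * config.foot_length_mm])
    markers: dict[str, np.ndarray] = {}
    for label, local in {**shank, **hindfoot}.items():
        markers[label] = np.tile(ankle_centre + local, (n_frames, 1))
    for label, local in forefoot.items():
        markers[label] = np.tile(ankle_centre + midfoot_joint + local, (n_frames, 1))
    if config.noise_sd_mm > 0:
        for label in markers:
            markers[label] = markers[label] + rng.normal(
                0.0, config.noise_sd_mm, markers[label].shape
            )
    return TrialRecording(
        trial_id=f"{config.subject_id}_static",
        subject_id=config.subject_id,
        condition=Condition.STATIC,
        side=config.side,
        markers=markers,
        marker_rate=marker_rate,
    )


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortEffectConfig:
    """Distributions the per-subject waveforms are drawn from.

    Means loosely follow the clinical picture of barefoot toe walking
    (plantarflexed foot contact, premature dorsiflexion peak, midfoot
    compliance) versus orthosis-corrected heel-toe gait; SDs give realistic
    between-subject spread.  Setting ``bf_equals_fo`` and zeroing the
    midfoot amplitudes produces a null cohort with no model or condition
    effects beyond noise.
    """

    fc_bf: tuple[float, float] = (-10.0, 3.0)
    fc_fo: tuple[float, float] = (0.0, 2.0)
    peak_df_bf: tuple[float, float] = (0.0, 2.0)
    peak_df_fo: tuple[float, float] = (12.0, 3.0)
    t_peak_df_bf: tuple[float, float] = (20.0, 4.0)
    t_peak_df_fo: tuple[float, float] = (45.0, 4.0)
    peak_pf_bf: tuple[float, float] = (-16.0, 3.0)
    peak_pf_fo: tuple[float, float] = (-13.0, 3.0)
    loading_dip_fo: tuple[float, float] = (5.0, 1.0)
    t_peak_pf: tuple[float, float] = (65.0, 3.0)
    stance_end: tuple[float, float] = (62.0, 2.0)
    midfoot_amplitude_bf: tuple[float, float] = (15.0, 2.0)
    midfoot_amplitude_fo: tuple[float, float] = (0.0, 0.0)
    noise_sd_mm: float = 0.5
    tibia_length: tuple[float, float] = (360.0, 30.0)
    foot_length: tuple[float, float] = (210.0, 15.0)
    cycles_mean: float = 6.0
    cycles_range: tuple[int, int] = (4, 10)
    bf_equals_fo: bool = False

    @classmethod
    def null(cls) -> "CohortEffectConfig":
        """No model or condition effects: identical waveform distributions
        in both conditions and zero midfoot motion."""
        return cls(
            midfoot_amplitude_bf=(0.0, 0.0),
            midfoot_amplitude_fo=(0.0, 0.0),
            bf_equals_fo=True,
        )


@dataclass
class SubjectData:
    """One synthetic subject: config, static trial and per-condition trials."""

    config: SyntheticSubjectConfig
    static: TrialRecording
    trials: dict[Condition, TrialRecording]
    truths: dict[Condition, GroundTruth]


def _draw(rng, spec, lo=None, hi=None):
    v = rng.normal(*spec)
    if lo is not None or hi is not None:
        v = float(np.clip(v, lo if lo is not None else -np.inf,
                          hi if hi is not None else np.inf))
    return float(v)


def generate_cohort(
    n_subjects: int = 14,
    master_seed: int = 0,
    effect_config: CohortEffectConfig | None = None,
) -> list[SubjectData]:
    """Seeded cohort of synthetic subjects with BF and FO trials.

    Per-subject waveform parameters are drawn from the configured
    distributions (clipped to keep the two gait profiles well-formed);
    cycle counts are Poisson around the configured mean, clipped to the
    configured range.  Bit-reproducible for a fixed ``master_seed``.
    """
    if n_subjects < 2:
        raise ParameterError("a cohort needs at least 2 subjects")
    cfg = effect_config if effect_config is not None else CohortEffectConfig()
    root = np.random.SeedSequence(master_seed)
    cohort: list[SubjectData] = []
    for s, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        stance = _draw(rng, cfg.stance_end, 55.0, 70.0)
        t_pf = _draw(rng, cfg.t_peak_pf, stance - 5.0, 80.0)

        fc_bf = _draw(rng, cfg.fc_bf, -18.0, -5.5)
        t_df_bf = _draw(rng, cfg.t_peak_df_bf, 8.0, 28.0)
        peak_df_bf = max(fc_bf + 1.0, _draw(rng, cfg.peak_df_bf))
        peak_pf_bf = min(fc_bf - 2.0, _draw(rng, cfg.peak_pf_bf))
        bf = WaveformParams(
            profile="toe_walking", angle_at_fc=fc_bf, peak_df=peak_df_bf,
            t_peak_df=t_df_bf, peak_pf=peak_pf_bf, t_peak_pf=t_pf,
            stance_end_pct=stance, loading_dip_deg=0.0,
        )
        if cfg.bf_equals_fo:
            fo = bf
        else:
            fc_fo = _draw(rng, cfg.fc_fo, -4.0, 6.0)
            t_df_fo = _draw(rng, cfg.t_peak_df_fo, 32.0, min(55.0, stance - 2.0))
            peak_df_fo = max(fc_fo + 2.0, _draw(rng, cfg.peak_df_fo))
            dip_fo = _draw(rng, cfg.loading_dip_fo, 2.0, 8.0)
            # peak plantarflexion stays below the loading-response dip
            peak_pf_fo = min(fc_fo - dip_fo - 2.0, _draw(rng, cfg.peak_pf_fo))
            fo = WaveformParams(
                profile="heel_toe", angle_at_fc=fc_fo, peak_df=peak_df_fo,
                t_peak_df=t_df_fo, peak_pf=peak_pf_fo, t_peak_pf=t_pf,
                stance_end_pct=stance, loading_dip_deg=dip_fo,
            )
        amp_bf = _draw(rng, cfg.midfoot_amplitude_bf, 0.0, 30.0)
        amp_fo = _draw(rng, cfg.midfoot_amplitude_fo, 0.0, 30.0)
        config = SyntheticSubjectConfig(
            subject_id=f"S{s:02d}",
            tibia_length_mm=_draw(rng, cfg.tibia_length, 250.0, 450.0),
            foot_length_mm=_draw(rng, cfg.foot_length, 150.0, 260.0),
            bf_waveform=bf,
            fo_waveform=fo,
            midfoot_amplitude_bf=amp_bf,
            midfoot_amplitude_fo=amp_fo,
            noise_sd_mm=cfg.noise_sd_mm,
            cycle_duration_s=float(rng.uniform(0.9, 1.1)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        static = synthesize_static(config, rng=rng)
        trials: dict[Condition, TrialRecording] = {}
        truths: dict[Condition, GroundTruth] = {}
        for condition in (Condition.BF, Condition.FO):
            n_cycles = int(np.clip(rng.poisson(cfg.cycles_mean), *cfg.cycles_range))
            trial, truth = synthesize_trial(
                config, condition, n_cycles=n_cycles, rng=rng
            )
            trials[condition] = trial
            truths[condition] = truth
        cohort.append(SubjectData(config=config, static=static,
                                  trials=trials, truths=truths))
    return cohort
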