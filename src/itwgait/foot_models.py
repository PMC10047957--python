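"""Anatomical frames and the sagittal ankle angle for three foot models.

All three models share the shank construction (ankle-joint centre at the
inter-malleolar midpoint, longitudinal axis toward the knee centre, flexion
axis along the malleolar line) and anchor the rear of the foot axis on CA,
the posterior-calcaneus marker.  They differ in the *second* point of the
foot axis:

* mono-segment models (Plug-in-Gait, Davis) aim the axis at a forefoot
  marker, so any midfoot (forefoot-vs-hindfoot) motion is folded into the
  computed ankle angle;
* the Oxford hindfoot aims it at a *virtual* anterior calcaneal point that
  is rigid with the calcaneus, so the hindfoot-tibia angle is independent
  of the forefoot.

Frame layout: ``x`` forward along the segment, ``y`` the flexion axis
oriented so that dorsiflexion (toe-up) is a positive rotation,
``z = x cross y``; right-handed and orthonormal.  The sagittal ankle angle
is the leading rotation of a flexion-first (Y-X-Z) Euler decomposition of
the tibia-to-foot rotation, minus the static neutral offset, dorsiflexion
positive, wrapped to (-180, 180].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .gaitdata_io import (
    CalibrationError,
    FootModel,
    MarkerError,
    MARKER_SETS,
    Side,
    TrialRecording,
    validate_marker_set,
)

__all__ = [
    "SegmentFrame",
    "CalibrationOffsets",
    "AnkleAngleTrace",
    "OFM_VIRTUAL_LENGTH_MM",
    "MONO_FOREFOOT_MARKER",
    "APPLY_STATIC_OFFSET",
    "build_tibia_frame",
    "build_foot_frame_mono",
    "build_hindfoot_frame_ofm",
    "static_calibration",
    "sagittal_angle",
    "compute_ankle_trace",
]

#: length (mm) of the virtual anterior calcaneal segment of the Oxford
#: hindfoot axis, measured from CA along the intersection of the calcaneal
#: sagittal plane with the horizontal plane of the static pose.
OFM_VIRTUAL_LENGTH_MM: float = 60.0

#: which forefoot marker each mono-segment variant aims the foot axis at:
#: Plug-in-Gait the metatarsal marker, Davis the distal toe marker.
MONO_FOREFOOT_MARKER: dict[FootModel, str] = {
    FootModel.PIG: "MT",
    FootModel.DAV: "TOE",
}

#: static-offset convention per model: Plug-in-Gait and the Oxford hindfoot
#: are zeroed on the static pose, the Davis variant reports the raw
#: anatomical angle.  Editable (module-level config).
APPLY_STATIC_OFFSET: dict[FootModel, bool] = {
    FootModel.OFM: True,
    FootModel.PIG: True,
    FootModel.DAV: False,
}

_Z_LAB = np.array([0.0, 0.0, 1.0])
_EPS_DEGENERATE = 1e-6  # unit-vector norm below which geometry is degenerate
_GIMBAL_DEG = 89.0


# ---------------------------------------------------------------------------
# small batch linear algebra (arrays of shape (n, 3))

def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, v / norm, np.nan)


def _reject(v: np.ndarray, onto: np.ndarray) -> np.ndarray:
    """Component of v orthogonal to the unit vector(s) *onto*."""
    return v - np.sum(v * onto, axis=-1, keepdims=True) * onto


def _stack_frames(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Axes (n,3) each -> rotation matrices (n,3,3) with axes as columns."""
    return np.stack([x, y, z], axis=-1)


def _check_unit(v: np.ndarray, what: str) -> None:
    norm = np.linalg.norm(v, axis=-1)
    if np.any(~np.isfinite(norm)) or np.any(norm < _EPS_DEGENERATE):
        raise MarkerError(f"degenerate geometry: {what}")


@dataclass
class SegmentFrame:
    """Origin and right-handed orthonormal axes of a body segment (lab frame)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise MarkerError("segment axes are not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-9):
            raise MarkerError("segment axes are not right-handed (x cross y != z)")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are the x, y, z axes."""
        return _stack_frames(self.x_axis, self.y_axis, self.z_axis)


@dataclass
class CalibrationOffsets:
    """Per subject x model x side static-trial calibration.

    ``neutral_angle_deg`` is the time-averaged raw sagittal angle of the
    static pose; it is subtracted so the static pose reads
    ``reference_deg`` (default 0) when ``apply_offset`` is set.  For the
    Oxford hindfoot, ``ofm_virtual_local`` freezes the virtual anterior
    calcaneal point in the calcaneus technical frame.
    """

    model: FootModel
    side: Side
    neutral_angle_deg: float = 0.0
    reference_deg: float = 0.0
    apply_offset: bool = True
    ofm_virtual_local: np.ndarray | None = None

    @property
    def offset_deg(self) -> float:
        return (self.neutral_angle_deg - self.reference_deg) if self.apply_offset else 0.0


@dataclass
class AnkleAngleTrace:
    """Per-frame sagittal ankle angle (deg, dorsiflexion positive).

    NaN where a required marker is missing; ``gimbal_flags`` marks frames
    whose second Euler rotation came within 1 deg of +-90 deg.
    """

    values: np.ndarray
    model: FootModel
    trial_id: str = ""
    gimbal_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.gimbal_flags is None:
            self.gimbal_flags = np.zeros(self.values.shape, dtype=bool)


# ---------------------------------------------------------------------------
# frame builders (batch internals + single-frame public API)

def _tibia_axes(
    mmal: np.ndarray, lmal: np.ndarray, kne: np.ndarray, knem: np.ndarray, side: Side
) -> tuple[np.ndarray, np.ndarray]:
    ankle = 0.5 * (mmal + lmal)
    knee = 0.5 * (kne + knem)
    u = _unit(knee - ankle)  # longitudinal, toward the knee
    y_raw = (lmal - mmal) if side is Side.RIGHT else (mmal - lmal)
    y = _unit(_reject(y_raw, u))  # flexion axis, dorsiflexion-positive
    x = np.cross(u, y)  # anterior
    z = np.cross(x, y)
    return ankle, _stack_frames(x, y, z)


def build_tibia_frame(markers: dict[str, np.ndarray], side: Side) -> SegmentFrame:
    """Tibia/shank frame at one instant.

    Origin at the ankle-joint centre (inter-malleolar midpoint);
    longitudinal direction toward the knee centre (epicondyle midpoint);
    flexion axis along the malleolar line projected orthogonal to it.
    """
    pts = _require(markers, ("MMAL", "LMAL", "KNE", "KNEM"))
    origin, R = _tibia_axes(*(p[None, :] for p in pts), side=side)
    x, y, z = R[0, :, 0], R[0, :, 1], R[0, :, 2]
    _check_unit(y, "malleolar line collinear with the tibia longitudinal axis")
    _check_unit(R[0, :, 0], "tibia frame")
    return SegmentFrame(origin[0], x, y, z)


def _mono_axes(ca: np.ndarray, ff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = _unit(ff - ca)  # foot longitudinal axis, CA -> forefoot marker
    y = _unit(np.cross(x, np.broadcast_to(_Z_LAB, x.shape)))  # flexion axis
    z = np.cross(x, y)
    x = np.cross(y, z)  # re-orthogonalize (x already orthogonal to y)
    return ca, _stack_frames(x, y, z)


def build_foot_frame_mono(
    markers: dict[str, np.ndarray],
    variant: FootModel,
    side: Side = Side.RIGHT,
) -> SegmentFrame:
    """Mono-segment foot frame (Plug-in-Gait or Davis variant).

    The longitudinal axis runs from CA to the variant's forefoot marker;
    the sagittal plane contains that axis and the laboratory vertical.
    Only those two markers enter the construction.
    """
    if variant not in MONO_FOREFOOT_MARKER:
        raise MarkerError(f"{variant} is not a mono-segment foot model")
    ff_label = MONO_FOREFOOT_MARKER[variant]
    ca, ff = _require(markers, ("CA", ff_label))
    if np.linalg.norm(ff - ca) < 1.0:  # mm
        raise MarkerError("degenerate geometry: CA coincident with forefoot marker")
    origin, R = _mono_axes(ca[None, :], ff[None, :])
    _check_unit(R[0, :, 1], "foot axis parallel to the lab vertical")
    return SegmentFrame(origin[0], R[0, :, 0], R[0, :, 1], R[0, :, 2])


def _calcaneus_technical(
    ca: np.ndarray, mca: np.ndarray, lca: np.ndarray, side: Side
) -> tuple[np.ndarray, np.ndarray]:
    """Marker-only technical frame of the calcaneus triad.

    e1: CA toward the mid-calcaneus point; e2: mediolateral (subject-right)
    orthogonalized; e3 = e1 cross e2.  Returns (mediolateral unit, T) where
    T has columns (e1, e2, e3).
    """
    mid = 0.5 * (mca + lca)
    m = _unit((lca - mca) if side is Side.RIGHT else (mca - lca))
    e1 = _unit(mid - ca)
    e2 = _unit(_reject(m, e1))
    e3 = np.cross(e1, e2)
    return m, _stack_frames(e1, e2, e3)


def _ofm_virtual_default(
    ca: np.ndarray, mca: np.ndarray, lca: np.ndarray, side: Side
) -> np.ndarray:
    """Virtual anterior calcaneal point from the current pose.

    CA projected ``OFM_VIRTUAL_LENGTH_MM`` along the intersection of the
    calcaneal sagittal plane (normal = mediolateral direction) with the
    horizontal plane, oriented anteriorly.
    """
    mid = 0.5 * (mca + lca)
    m = _unit((lca - mca) if side is Side.RIGHT else (mca - lca))
    d = _unit(np.cross(m, np.broadcast_to(_Z_LAB, m.shape)))
    sign = np.sign(np.sum(d * (mid - ca), axis=-1, keepdims=True))
    sign = np.where(sign == 0, 1.0, sign)
    return ca + OFM_VIRTUAL_LENGTH_MM * d * sign


def _ofm_axes(
    ca: np.ndarray,
    mca: np.ndarray,
    lca: np.ndarray,
    side: Side,
    virtual_local: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    m, T = _calcaneus_technical(ca, mca, lca, side)
    if virtual_local is not None:
        v = ca + np.einsum("...ij,j->...i", T, virtual_local)
    else:
        v = _ofm_virtual_default(ca, mca, lca, side)
    x = _unit(v - ca)
    y = _unit(_reject(m, x))
    z = np.cross(x, y)
    return ca, _stack_frames(x, y, z)


def build_hindfoot_frame_ofm(
    markers: dict[str, np.ndarray],
    side: Side = Side.RIGHT,
    virtual_local: np.ndarray | None = None,
) -> SegmentFrame:
    """Oxford hindfoot frame from the calcaneus triad only.

    The sagittal plane is fitted to CA and the medial/lateral calcaneus
    markers; the longitudinal axis runs from CA to a virtual anterior
    calcaneal point inside that plane (frozen in the calcaneus technical
    frame when ``virtual_local`` comes from a static calibration).
    Forefoot markers never enter this construction.
    """
    ca, mca, lca = _require(markers, ("CA", "MCA", "LCA"))
    # collinearity check on the raw triad
    n = np.cross(mca - ca, lca - ca)
    if np.linalg.norm(n) < 1.0:  # mm^2
        raise MarkerError("degenerate geometry: calcaneus markers collinear")
    origin, R = _ofm_axes(
        ca[None, :], mca[None, :], lca[None, :], side, virtual_local
    )
    _check_unit(R[0, :, 0], "hindfoot frame")
    return SegmentFrame(origin[0], R[0, :, 0], R[0, :, 1], R[0, :, 2])


def _require(markers: dict[str, np.ndarray], labels: tuple[str, ...]):
    out = []
    for label in labels:
        if label not in markers:
            raise MarkerError(f"missing marker: {label}")
        out.append(np.asarray(markers[label], dtype=float))
    return out


# ---------------------------------------------------------------------------
# angles

def _relative_euler_yxz(Rt: np.ndarray, Rf: np.ndarray) -> np.ndarray:
    """Flexion-first intrinsic Euler angles (deg) of the tibia->foot rotation."""
    R_rel = np.einsum("...ji,...jk->...ik", Rt, Rf)
    flat = R_rel.reshape(-1, 3, 3)
    bad = ~np.isfinite(flat).all(axis=(1, 2))
    safe = flat.copy()
    safe[bad] = np.eye(3)
    eul = Rotation.from_matrix(safe).as_euler("YXZ", degrees=True)
    eul[bad] = np.nan
    return eul.reshape(R_rel.shape[:-2] + (3,))


def _wrap_deg(a):
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def sagittal_angle(
    tibia: SegmentFrame,
    foot: SegmentFrame,
    offsets: CalibrationOffsets | None = None,
) -> float:
    """Sagittal ankle angle between two frames (deg, dorsiflexion positive).

    The tibia-to-foot rotation is decomposed flexion axis first (Y-X-Z);
    the leading angle minus the static neutral offset is returned, wrapped
    to (-180, 180].  Emits a warning when the second rotation is within
    1 deg of +-90 deg (gimbal proximity).
    """
    eul = _relative_euler_yxz(tibia.rotation[None], foot.rotation[None])[0]
    if abs(eul[1]) > _GIMBAL_DEG:
        warnings.warn("gimbal proximity: second rotation within 1 deg of +-90 deg",
                      stacklevel=2)
    offset = offsets.offset_deg if offsets is not None else 0.0
    return float(_wrap_deg(eul[0] - offset))


def _trace_from_arrays(
    trial: TrialRecording,
    model: FootModel,
    side: Side,
    offsets: CalibrationOffsets | None,
) -> tuple[np.ndarray, np.ndarray]:
    mmal, lmal, kne, knem = (trial.marker(k) for k in ("MMAL", "LMAL", "KNE", "KNEM"))
    _, Rt = _tibia_axes(mmal, lmal, kne, knem, side)
    if model is FootModel.OFM:
        ca, mca, lca = (trial.marker(k) for k in ("CA", "MCA", "LCA"))
        vloc = offsets.ofm_virtual_local if offsets is not None else None
        _, Rf = _ofm_axes(ca, mca, lca, side, vloc)
        used = [mmal, lmal, kne, knem, ca, mca, lca]
    else:
        ca = trial.marker("CA")
        ff = trial.marker(MONO_FOREFOOT_MARKER[model])
        _, Rf = _mono_axes(ca, ff)
        used = [mmal, lmal, kne, knem, ca, ff]
    visible = np.logical_and.reduce(
        [np.isfinite(p).all(axis=1) for p in used]
    )
    eul = _relative_euler_yxz(Rt, Rf)
    offset = offsets.offset_deg if offsets is not None else 0.0
    angles = _wrap_deg(eul[:, 0] - offset)
    angles[~visible] = np.nan
    gimbal = np.abs(eul[:, 1]) > _GIMBAL_DEG
    gimbal &= visible
    return angles, gimbal


def compute_ankle_trace(
    trial: TrialRecording,
    model: FootModel,
    offsets: CalibrationOffsets | None = None,
    side: Side | None = None,
) -> AnkleAngleTrace:
    """Per-frame sagittal ankle angle of a trial under one foot model.

    Plug-in-Gait and Davis use the mono-segment foot frame (their variants
    differing in forefoot marker and static-offset convention), the Oxford
    model the calcaneus-only hindfoot frame.  Frames with missing required
    markers yield NaN samples.
    """
    side = side if side is not None else trial.side
    missing = validate_marker_set(trial, MARKER_SETS[model])
    if missing:
        raise MarkerError(f"missing marker: {', '.join(missing)}")
    angles, gimbal = _trace_from_arrays(trial, model, side, offsets)
    return AnkleAngleTrace(values=angles, model=model, trial_id=trial.trial_id,
                           gimbal_flags=gimbal)


# ---------------------------------------------------------------------------
# static calibration

def static_calibration(
    static_trial: TrialRecording,
    model: FootModel,
    side: Side | None = None,
    *,
    reference_deg: float = 0.0,
    apply_offset: bool | None = None,
    min_duration_s: float = 1.0,
) -> CalibrationOffsets:
    """Neutral offsets (and the Oxford virtual point) from a standing trial.

    The neutral angle is the time-average raw sagittal angle over the
    visible static frames; for the Oxford model the virtual anterior
    calcaneal point is frozen in the calcaneus technical frame of the mean
    static pose.  Raises :class:`CalibrationError` when fewer than
    ``min_duration_s`` seconds of fully visible data are available.
    """
    side = side if side is not None else static_trial.side
    missing = validate_marker_set(static_trial, MARKER_SETS[model])
    if missing:
        raise CalibrationError(f"static trial lacks markers: {', '.join(missing)}")
    labels = MARKER_SETS[model].required_labels
    finite = np.logical_and.reduce(
        [np.isfinite(static_trial.marker(k)).all(axis=1) for k in labels]
    )
    if finite.sum() < min_duration_s * static_trial.marker_rate:
        raise CalibrationError(
            f"insufficient static data: {finite.sum()} fully visible frames"
        )

    vloc = None
    if model is FootModel.OFM:
        mean = {k: np.nanmean(static_trial.marker(k)[finite], axis=0)
                for k in ("CA", "MCA", "LCA")}
        ca, mca, lca = mean["CA"], mean["MCA"], mean["LCA"]
        _, T = _calcaneus_technical(ca[None], mca[None], lca[None], side)
        v = _ofm_virtual_default(ca[None], mca[None], lca[None], side)[0]
        vloc = T[0].T @ (v - ca)

    provisional = CalibrationOffsets(
        model=model, side=side, neutral_angle_deg=0.0,
        reference_deg=0.0, apply_offset=False, ofm_virtual_local=vloc,
    )
    raw, _ = _trace_from_arrays(static_trial, model, side, provisional)
    neutral = float(np.nanmean(raw[finite]))
    if not np.isfinite(neutral):
        raise CalibrationError("static angle trace is entirely non-finite")
    if apply_offset is None:
        apply_offset = APPLY_STATIC_OFFSET[model]
    return CalibrationOffsets(
        model=model, side=side, neutral_angle_deg=neutral,
        reference_deg=reference_deg, apply_offset=apply_offset,
        ofm_virtual_local=vloc,
    )
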