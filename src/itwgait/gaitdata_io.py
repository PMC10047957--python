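"""Data model and readers/writers for gait trials.

A :class:`TrialRecording` holds the raw material of one motion-capture
trial: 3D marker trajectories in the laboratory frame (mm, nominally
250 samples/s) and optional analog channels such as the vertical
ground-reaction force (N, nominally 1000 samples/s).  Marker dropouts are
flagged as NaN rows, never zero-filled.

Laboratory frame convention (used throughout the package and by the
synthetic-data generator): right-handed, X = direction of progression,
Z = vertical up, Y = Z x X (subject's left).

Interchange formats are a plain-text fixture CSV (``frame,label,x,y,z``
plus a JSON sidecar for rates and metadata) and, when the optional
``ezc3d`` dependency is installed, binary C3D.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Condition",
    "Side",
    "FootModel",
    "TrialRecording",
    "MarkerSetSpec",
    "GaitEvents",
    "MARKER_SETS",
    "DEFAULT_ALIASES",
    "GaitDataError",
    "FormatError",
    "ConfigError",
    "EmptyTrialError",
    "MarkerError",
    "CalibrationError",
    "ParameterError",
    "normalize_labels",
    "load_alias_map",
    "read_fixture_csv",
    "write_fixture_csv",
    "read_c3d",
    "write_c3d",
    "read_events_json",
    "write_events_json",
    "validate_marker_set",
]


# ---------------------------------------------------------------------------
# errors

class GaitDataError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GaitDataError):
    """A file could not be parsed in the expected format."""


class ConfigError(GaitDataError):
    """Missing or inconsistent configuration (sidecar, alias map...)."""


class EmptyTrialError(GaitDataError):
    """A trial contains no markers."""


class MarkerError(GaitDataError):
    """A frame construction failed: missing marker or degenerate geometry."""


class CalibrationError(GaitDataError):
    """Static calibration could not be computed."""


class ParameterError(GaitDataError):
    """Inconsistent waveform or generator parameters."""


# ---------------------------------------------------------------------------
# enums

class Condition(str, Enum):
    BF = "BF"            # barefoot toe walking
    FO = "FO"            # walking with the foot orthosis
    STATIC = "STATIC"    # standing calibration trial


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class FootModel(str, Enum):
    OFM = "OFM"   # Oxford multi-segment model (hindfoot vs tibia)
    PIG = "PiG"   # Plug-in-Gait mono-segment foot
    DAV = "DAV"   # Davis mono-segment foot


# ---------------------------------------------------------------------------
# domain types

@dataclass
class TrialRecording:
    """Raw marker trajectories + analog channels for one trial.

    Parameters
    ----------
    markers
        Mapping label -> (n_frames, 3) float array of lab-frame positions
        in mm.  Frames where the marker is not visible are NaN rows.
    analog
        Mapping channel label -> 1D float array (e.g. ``"Fz"`` vertical GRF
        in N), sampled at ``analog_rate``.
    """

    trial_id: str
    subject_id: str
    condition: Condition
    side: Side
    markers: dict[str, np.ndarray]
    marker_rate: float = 250.0
    analog: dict[str, np.ndarray] = field(default_factory=dict)
    analog_rate: float | None = None

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.side = Side(self.side)
        if self.marker_rate <= 0:
            raise ConfigError("marker_rate must be positive")
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        lengths = {v.shape[0] for v in self.markers.values()}
        if len(lengths) > 1:
            raise FormatError(f"marker series lengths differ: {sorted(lengths)}")
        for k, v in self.markers.items():
            if v.ndim != 2 or v.shape[1] != 3:
                raise FormatError(f"marker {k!r} is not an (n, 3) array")
        if self.analog:
            if self.analog_rate is None:
                raise ConfigError("analog channels present but analog_rate missing")
            ratio = self.analog_rate / self.marker_rate
            if abs(ratio - round(ratio)) > 1e-9:
                raise ConfigError(
                    "analog_rate must be an integer multiple of marker_rate"
                )
            self.analog = {k: np.asarray(v, dtype=float) for k, v in self.analog.items()}

    @property
    def n_frames(self) -> int:
        if not self.markers:
            return 0
        return next(iter(self.markers.values())).shape[0]

    def marker(self, label: str) -> np.ndarray:
        try:
            return self.markers[label]
        except KeyError:
            raise MarkerError(f"missing marker: {label}") from None

    def missing_fraction(self, label: str) -> float:
        """Fraction of frames where *label* has any non-finite coordinate."""
        xyz = self.marker(label)
        return float(np.mean(~np.isfinite(xyz).all(axis=1)))


@dataclass
class MarkerSetSpec:
    """Markers a foot model needs.

    Every model anchors the rear of the foot axis on CA (posterior
    calcaneus); the multi-segment hindfoot additionally needs the medial and
    lateral calcaneus markers, the mono-segment variants a forefoot marker.
    """

    model: FootModel
    required_labels: tuple[str, ...]
    optional_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "CA" not in self.required_labels:
            raise ConfigError("CA (posterior calcaneus) is required by every model")
        if self.model is FootModel.OFM:
            calc = {"CA", "MCA", "LCA"} & set(self.required_labels)
            if len(calc) < 3:
                raise ConfigError("OFM requires at least 3 calcaneus markers")


#: shank/tibia markers shared by all models: medial/lateral malleolus and
#: medial/lateral femoral epicondyle (knee centre = epicondyle midpoint).
SHANK_LABELS: tuple[str, ...] = ("MMAL", "LMAL", "KNE", "KNEM")

MARKER_SETS: dict[FootModel, MarkerSetSpec] = {
    FootModel.OFM: MarkerSetSpec(
        FootModel.OFM,
        required_labels=SHANK_LABELS + ("CA", "MCA", "LCA"),
        optional_labels=("MT", "TOE"),
    ),
    FootModel.PIG: MarkerSetSpec(
        FootModel.PIG,
        required_labels=SHANK_LABELS + ("CA", "MT"),
        optional_labels=("TOE", "MCA", "LCA"),
    ),
    FootModel.DAV: MarkerSetSpec(
        FootModel.DAV,
        required_labels=SHANK_LABELS + ("CA", "TOE"),
        optional_labels=("MT", "MCA", "LCA"),
    ),
}

#: default marker-label alias map (Vicon/BTS dialects -> package vocabulary).
#: Shipped as an editable mapping; a user JSON file can extend/override it.
DEFAULT_ALIASES: dict[str, str] = {
    "RHEE": "CA", "LHEE": "CA", "HEE": "CA", "HEEL": "CA", "CAL": "CA",
    "RANK": "LMAL", "LANK": "LMAL", "ANK": "LMAL", "LMA": "LMAL",
    "RMMA": "MMAL", "LMMA": "MMAL", "MMA": "MMAL", "MED_MAL": "MMAL",
    "RTOE": "TOE", "LTOE": "TOE",
    "RMT2": "MT", "LMT2": "MT", "MET": "MT", "MT2": "MT",
    "RKNE": "KNE", "LKNE": "KNE",
    "RKNM": "KNEM", "LKNM": "KNEM", "KNM": "KNEM",
    "RSTL": "MCA", "LSTL": "MCA", "STL": "MCA",
    "RLCA": "LCA", "LLCA": "LCA",
}


def load_alias_map(path: str | Path | None = None) -> dict[str, str]:
    """Load a label alias map: package defaults merged with a user JSON file."""
    aliases = dict(DEFAULT_ALIASES)
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"alias config not found: {p}")
        with open(p) as fh:
            user = json.load(fh)
        if not isinstance(user, dict):
            raise ConfigError("alias config must be a JSON object {alias: label}")
        aliases.update({str(k): str(v) for k, v in user.items()})
    # idempotence: a canonical label never maps away from itself
    for target in set(aliases.values()):
        aliases.setdefault(target, target)
        if aliases[target] != target:
            raise ConfigError(f"alias target {target!r} is itself aliased")
    return aliases


def normalize_labels(
    markers: Mapping[str, np.ndarray], aliases: Mapping[str, str] | None = None
) -> dict[str, np.ndarray]:
    """Rename marker labels through the alias map (idempotent)."""
    if aliases is None:
        aliases = load_alias_map()
    out: dict[str, np.ndarray] = {}
    for label, xyz in markers.items():
        out[aliases.get(label, label)] = xyz
    return out


@dataclass
class GaitEvents:
    """Foot-contact and foot-off instants on the marker-frame timeline."""

    foot_contact_frames: list[int]
    foot_off_frames: list[int]
    source: str = "provided"  # "force_plate" | "provided"

    def __post_init__(self) -> None:
        for name in ("foot_contact_frames", "foot_off_frames"):
            seq = [int(v) for v in getattr(self, name)]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise FormatError(f"{name} must be strictly increasing")
            setattr(self, name, seq)

    def cycles(self) -> list[tuple[int, int, int]]:
        """Valid gait cycles as (contact, foot_off, next_contact) triples.

        A cycle is valid when exactly one foot-off falls strictly between
        its two delimiting foot contacts; others are skipped with a warning.
        """
        out = []
        for c0, c1 in zip(self.foot_contact_frames, self.foot_contact_frames[1:]):
            offs = [f for f in self.foot_off_frames if c0 < f < c1]
            if len(offs) != 1:
                warnings.warn(
                    f"cycle [{c0}, {c1}] skipped: {len(offs)} enclosed foot-offs",
                    stacklevel=2,
                )
                continue
            out.append((c0, offs[0], c1))
        return out


# ---------------------------------------------------------------------------
# fixture CSV (plain-text interchange)

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _analog_path(path: Path) -> Path:
    return path.with_name(path.stem + ".analog.csv")


def write_fixture_csv(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial as ``frame,label,x,y,z`` CSV + JSON sidecar.

    Missing (NaN) samples are omitted from the CSV; the sidecar records the
    total frame count so trailing gaps survive the round-trip.  Analog
    channels go to ``<stem>.analog.csv``.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "label", "x", "y", "z"])
        for label in sorted(trial.markers):
            xyz = trial.markers[label]
            ok = np.isfinite(xyz).all(axis=1)
            for f in np.flatnonzero(ok):
                w.writerow([int(f), label, repr(float(xyz[f, 0])),
                            repr(float(xyz[f, 1])), repr(float(xyz[f, 2]))])
    meta = {
        "trial_id": trial.trial_id,
        "subject_id": trial.subject_id,
        "condition": trial.condition.value,
        "side": trial.side.value,
        "marker_rate": trial.marker_rate,
        "analog_rate": trial.analog_rate,
        "n_frames": trial.n_frames,
        "analog_labels": sorted(trial.analog),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    if trial.analog:
        labels = sorted(trial.analog)
        with open(_analog_path(path), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample"] + labels)
            n = len(next(iter(trial.analog.values())))
            for i in range(n):
                w.writerow([i] + [repr(float(trial.analog[k][i])) for k in labels])


def read_fixture_csv(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> TrialRecording:
    """Read a fixture CSV written by :func:`write_fixture_csv`.

    Exact inverse of the writer to numerical round-off.  Raises
    :class:`ConfigError` when the JSON sidecar is missing and
    :class:`FormatError` on non-monotone frame numbers.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigError(f"missing sidecar JSON for {path}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    n_frames = int(meta["n_frames"])

    per_label: dict[str, list[tuple[int, float, float, float]]] = {}
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if header is None or [h.strip() for h in header[:5]] != ["frame", "label", "x", "y", "z"]:
            raise FormatError(f"unexpected fixture CSV header in {path}: {header}")
        for row in r:
            if not row:
                continue
            f = int(row[0])
            per_label.setdefault(row[1], []).append(
                (f, float(row[2]), float(row[3]), float(row[4]))
            )
    markers: dict[str, np.ndarray] = {}
    for label, rows in per_label.items():
        frames = [r0[0] for r0 in rows]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise FormatError(f"non-monotone frame numbers for marker {label!r}")
        if frames and frames[-1] >= n_frames:
            raise FormatError(f"frame {frames[-1]} out of range for marker {label!r}")
        xyz = np.full((n_frames, 3), np.nan)
        for f, x, y, z in rows:
            xyz[f] = (x, y, z)
        markers[label] = xyz
    if not markers:
        raise EmptyTrialError(f"no markers in {path}")

    analog: dict[str, np.ndarray] = {}
    apath = _analog_path(path)
    if meta.get("analog_labels") and apath.exists():
        with open(apath, newline="") as fh:
            r = csv.reader(fh)
            labels = next(r)[1:]
            cols: list[list[float]] = [[] for _ in labels]
            for row in r:
                for i, v in enumerate(row[1:]):
                    cols[i].append(float(v))
        analog = {k: np.asarray(v) for k, v in zip(labels, cols)}

    return TrialRecording(
        trial_id=meta["trial_id"],
        subject_id=meta["subject_id"],
        condition=Condition(meta["condition"]),
        side=Side(meta["side"]),
        markers=normalize_labels(markers, aliases),
        marker_rate=float(meta["marker_rate"]),
        analog=analog,
        analog_rate=meta.get("analog_rate"),
    )


# ---------------------------------------------------------------------------
# C3D (optional binary route, via ezc3d when installed)

def _require_ezc3d():
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - exercised only without ezc3d
        raise ImportError(
            "C3D support requires the optional dependency 'ezc3d' "
            "(pip install ezc3d); use the fixture-CSV format otherwise"
        ) from exc
    return ezc3d


def read_c3d(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    *,
    trial_id: str = "",
    subject_id: str = "",
    condition: Condition = Condition.BF,
    side: Side = Side.RIGHT,
) -> TrialRecording:
    """Read a C3D capture file into a :class:`TrialRecording`.

    Labels are normalized through the alias map; positions are converted to
    mm; invalid samples (residual < 0 or non-finite) are flagged NaN.
    """
    ezc3d = _require_ezc3d()
    path = Path(path)
    try:
        c3d = ezc3d.c3d(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable C3D file {path}: {exc}") from exc
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    if points.shape[1] == 0:
        raise EmptyTrialError(f"no markers in {path}")
    unit = "mm"
    try:
        unit = str(c3d["parameters"]["POINT"]["UNITS"]["value"][0]).strip().lower()
    except (KeyError, IndexError):
        pass
    scale = {"mm": 1.0, "cm": 10.0, "m": 1000.0}.get(unit, 1.0)
    residuals = c3d["data"].get("meta_points", {}).get("residuals")
    markers: dict[str, np.ndarray] = {}
    for i, label in enumerate(labels):
        xyz = points[:3, i, :].T * scale
        bad = ~np.isfinite(xyz).all(axis=1)
        if residuals is not None:
            bad |= residuals[0, i, :] < 0
        xyz = xyz.copy()
        xyz[bad] = np.nan
        markers[label] = xyz
    marker_rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    analog: dict[str, np.ndarray] = {}
    analog_rate = None
    adata = c3d["data"]["analogs"]
    if adata.size:
        alabels = [s.strip() for s in c3d["parameters"]["ANALOG"]["LABELS"]["value"]]
        analog = {lab: adata[0, i, :].copy() for i, lab in enumerate(alabels)}
        analog_rate = float(c3d["parameters"]["ANALOG"]["RATE"]["value"][0])
    return TrialRecording(
        trial_id=trial_id or path.stem,
        subject_id=subject_id,
        condition=condition,
        side=side,
        markers=normalize_labels(markers, aliases),
        marker_rate=marker_rate,
        analog=analog,
        analog_rate=analog_rate,
    )


def write_c3d(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial to C3D (requires ezc3d); NaN samples become invalid points."""
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d()
    labels = sorted(trial.markers)
    c3d["parameters"]["POINT"]["RATE"]["value"] = [trial.marker_rate]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = labels
    c3d["parameters"]["POINT"]["UNITS"]["value"] = ["mm"]
    data = np.zeros((4, len(labels), trial.n_frames))
    for i, lab in enumerate(labels):
        data[:3, i, :] = trial.markers[lab].T
        data[3, i, :] = 1.0
    c3d["data"]["points"] = data
    if trial.analog:
        alabels = sorted(trial.analog)
        c3d["parameters"]["ANALOG"]["RATE"]["value"] = [trial.analog_rate]
        c3d["parameters"]["ANALOG"]["LABELS"]["value"] = alabels
        adata = np.zeros((1, len(alabels), len(next(iter(trial.analog.values())))))
        for i, lab in enumerate(alabels):
            adata[0, i, :] = trial.analog[lab]
        c3d["data"]["analogs"] = adata
    c3d.write(str(path))


# ---------------------------------------------------------------------------
# events JSON

def write_events_json(events: GaitEvents, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "foot_contact_frames": events.foot_contact_frames,
                "foot_off_frames": events.foot_off_frames,
                "source": events.source,
            },
            fh,
        )


def read_events_json(path: str | Path) -> GaitEvents:
    with open(path) as fh:
        d = json.load(fh)
    try:
        return GaitEvents(
            foot_contact_frames=d["foot_contact_frames"],
            foot_off_frames=d["foot_off_frames"],
            source=d.get("source", "provided"),
        )
    except KeyError as exc:
        raise FormatError(f"events JSON missing key {exc}") from exc


# ---------------------------------------------------------------------------
# validation

def validate_marker_set(
    trial: TrialRecording,
    spec: MarkerSetSpec,
    max_missing_fraction: float = 0.10,
) -> list[str]:
    """Report required labels that are absent or too gappy (never raises).

    Returns an empty list iff every required label is present with fewer
    than ``max_missing_fraction`` missing samples.
    """
    missing: list[str] = []
    for label in spec.required_labels:
        if label not in trial.markers:
            missing.append(label)
        elif trial.missing_fraction(label) >= max_missing_fraction:
            missing.append(label)
    return missing
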