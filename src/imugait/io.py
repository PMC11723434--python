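"""Data model and on-disk formats for multi-IMU gait recordings.

A recording is one repetition of a walking task captured by up to five
body-worn inertial measurement units (sternum ``S``, left/right pelvis
``LP``/``RP``, left/right wrist ``LW``/``RW``), each contributing a 3-axis
accelerometer, gyroscope and magnetometer — nine channels per sensor.  The
canonical channel layout is sensor-major (S, LP, RP, LW, RW) then
component-major (acc, gyro, mag) then axis (x, y, z), so a full five-sensor
recording is an ``Ns_samples x 45`` matrix.

On disk a recording is a single CSV: ``# key: value`` metadata lines
followed by a header row of ``sensor_comp_axis`` column names and the
signal written at full float precision, so a write/read round trip is
bit-exact.  A cohort is described by a manifest CSV with one row per
recording.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GaitClass",
    "Side",
    "SENSOR_ORDER",
    "COMPONENT_ORDER",
    "AXES",
    "ValidationError",
    "FormatError",
    "IMURecording",
    "SensorSelection",
    "WindowedDataset",
    "channel_names",
    "write_recording",
    "read_recording",
    "read_manifest",
    "save_windows",
    "load_windows",
]


class GaitClass(str, enum.Enum):
    """Five-way walking-pattern label.

    WN normal, WH hemiplegic, WF equine (foot drop), WA ataxic-cerebellar,
    WP Parkinsonian.  Hemiplegic and equine gaits are simulated on either
    body side but classified without side distinction.
    """

    WN = "WN"
    WH = "WH"
    WF = "WF"
    WA = "WA"
    WP = "WP"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


SENSOR_ORDER: tuple[str, ...] = ("S", "LP", "RP", "LW", "RW")
COMPONENT_ORDER: tuple[str, ...] = ("acc", "gyro", "mag")
AXES: tuple[str, ...] = ("x", "y", "z")

#: classes whose simulation is lateralised and therefore require a side
SIDED_CLASSES = frozenset({GaitClass.WH, GaitClass.WF})

#: class label -> integer index used throughout training and evaluation
CLASS_INDEX: dict[GaitClass, int] = {c: i for i, c in enumerate(GaitClass)}


class ValidationError(ValueError):
    """A domain invariant is violated."""


class FormatError(ValueError):
    """A file does not conform to the documented layout."""


def channel_names(sensors: Sequence[str] = SENSOR_ORDER,
                  components: Sequence[str] = COMPONENT_ORDER) -> list[str]:
    """Canonical column names for the given sensors/components.

    Sensor-major, then component-major, then axis:
    ``S_acc_x, S_acc_y, ..., RW_mag_z``.
    """
    return [f"{s}_{c}_{a}" for s in sensors for c in components for a in AXES]


def _as_enum(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise ValidationError(f"invalid {enum_cls.__name__}: {value!r}") from exc


@dataclasses.dataclass
class IMURecording:
    """One repetition's raw multi-IMU signal plus metadata.

    ``signal`` has shape ``(Ns_samples, 9 * n_sensors)`` in the canonical
    layout for ``sensor_labels``; ``segment_bounds`` is the half-open
    ``(walk_start, walk_end)`` sample range of the steady walking portion,
    excluding the standing phases and the stand-to-walk / walk-to-stand
    transitions.
    """

    subject_id: str
    gait_class: GaitClass
    affected_side: Side
    repetition_index: int
    signal: np.ndarray
    segment_bounds: tuple[int, int]
    sampling_rate_hz: float = 128.0
    sensor_labels: tuple[str, ...] = SENSOR_ORDER

    def __post_init__(self) -> None:
        self.gait_class = _as_enum(self.gait_class, GaitClass)
        self.affected_side = _as_enum(self.affected_side, Side)
        self.sensor_labels = tuple(self.sensor_labels)
        unknown = set(self.sensor_labels) - set(SENSOR_ORDER)
        if unknown:
            raise ValidationError(f"unknown sensor labels: {sorted(unknown)}")
        if len(set(self.sensor_labels)) != len(self.sensor_labels):
            raise ValidationError("duplicate sensor labels")
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D matrix")
        expected = 9 * len(self.sensor_labels)
        if self.signal.shape[1] != expected:
            raise ValidationError(
                f"signal has {self.signal.shape[1]} columns, expected "
                f"{expected} (= 9 x {len(self.sensor_labels)} sensors)")
        ws, we = self.segment_bounds
        self.segment_bounds = (int(ws), int(we))
        if not (0 <= ws < we <= self.signal.shape[0]):
            raise ValidationError(
                f"segment_bounds {self.segment_bounds} invalid for "
                f"{self.signal.shape[0]} samples")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        sided = self.gait_class in SIDED_CLASSES
        if sided and self.affected_side is Side.NONE:
            raise ValidationError(
                f"{self.gait_class.value} requires an affected side")
        if not sided and self.affected_side is not Side.NONE:
            raise ValidationError(
                f"{self.gait_class.value} must have affected_side 'none'")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def columns(self) -> list[str]:
        return channel_names(self.sensor_labels)

    def walk_signal(self) -> np.ndarray:
        ws, we = self.segment_bounds
        return self.signal[ws:we]


@dataclasses.dataclass(frozen=True)
class SensorSelection:
    """A subset of sensor sites and IMU components fed to a classifier.

    The resulting channel count is ``3 * len(components) * len(sensors)``
    (three axes per component per sensor).
    """

    sensors: tuple[str, ...] = SENSOR_ORDER
    components: tuple[str, ...] = COMPONENT_ORDER

    def __post_init__(self) -> None:
        sensors = tuple(s for s in SENSOR_ORDER if s in set(self.sensors))
        components = tuple(c for c in COMPONENT_ORDER
                           if c in set(self.components))
        if len(sensors) != len(set(self.sensors)):
            raise ValidationError(
                f"unknown sensors in {self.sensors!r}; valid: {SENSOR_ORDER}")
        if len(components) != len(set(self.components)):
            raise ValidationError(
                f"unknown components in {self.components!r}; "
                f"valid: {COMPONENT_ORDER}")
        if not sensors:
            raise ValidationError("sensor selection must be non-empty")
        if not components:
            raise ValidationError("component selection must be non-empty")
        object.__setattr__(self, "sensors", sensors)
        object.__setattr__(self, "components", components)

    @property
    def n_channels(self) -> int:
        return 3 * len(self.components) * len(self.sensors)

    def column_names(self) -> list[str]:
        return channel_names(self.sensors, self.components)

    def label(self) -> str:
        return "+".join(self.sensors) + "/" + "+".join(self.components)


@dataclasses.dataclass
class WindowedDataset:
    """Fixed-length windows ready for a classifier.

    ``tensor`` has shape ``(Nw, Wl, Nch)``; ``labels`` are class indices in
    ``[0, 5)`` and ``subject_ids`` tie every window back to the subject it
    came from, which is what makes subject-disjoint splitting enforceable.
    """

    tensor: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    selection: SensorSelection

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.tensor.ndim != 3:
            raise ValidationError("tensor must have shape (Nw, Wl, Nch)")
        nw = self.tensor.shape[0]
        if self.labels.shape != (nw,) or self.subject_ids.shape != (nw,):
            raise ValidationError(
                "labels and subject_ids must have one entry per window")
        if self.tensor.shape[2] != self.selection.n_channels:
            raise ValidationError(
                f"tensor has {self.tensor.shape[2]} channels but selection "
                f"implies {self.selection.n_channels}")

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]

    def subset(self, subjects: Sequence[str]) -> "WindowedDataset":
        """Windows belonging to the given subjects (order preserved)."""
        wanted = set(subjects)
        mask = np.array([s in wanted for s in self.subject_ids])
        return WindowedDataset(self.tensor[mask], self.labels[mask],
                               self.subject_ids[mask], self.selection)


_META_FIELDS = ("subject_id", "gait_class", "affected_side",
                "repetition_index", "sampling_rate_hz", "walk_start",
                "walk_end", "sensor_labels")


def write_recording(rec: IMURecording, path, manifest_path=None) -> Path:
    """Write one recording as a self-describing CSV and log it in a manifest.

    The manifest (default ``manifest.csv`` next to the recording) gets one
    appended row; an existing row for the same path is replaced rather than
    duplicated, so rewrites are idempotent.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    ws, we = rec.segment_bounds
    meta = {
        "subject_id": rec.subject_id,
        "gait_class": rec.gait_class.value,
        "affected_side": rec.affected_side.value,
        "repetition_index": rec.repetition_index,
        "sampling_rate_hz": repr(float(rec.sampling_rate_hz)),
        "walk_start": ws,
        "walk_end": we,
        "sensor_labels": ",".join(rec.sensor_labels),
    }
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(",".join(rec.columns) + "\n")
        np.savetxt(fh, rec.signal, fmt="%.17g", delimiter=",")

    if manifest_path is None:
        manifest_path = path.parent / "manifest.csv"
    manifest_path = Path(manifest_path)
    row = {
        "subject_id": rec.subject_id,
        "gait_class": rec.gait_class.value,
        "affected_side": rec.affected_side.value,
        "repetition_index": rec.repetition_index,
        "path": path.name,
        "walk_start": ws,
        "walk_end": we,
        "sampling_rate_hz": float(rec.sampling_rate_hz),
    }
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        manifest = manifest[manifest["path"] != row["path"]]
        manifest = pd.concat([manifest, pd.DataFrame([row])],
                             ignore_index=True)
    else:
        manifest = pd.DataFrame([row])
    manifest.to_csv(manifest_path, index=False)
    return path


def _parse_meta(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, n_comment


def read_recording(path) -> IMURecording:
    """Read a recording CSV, restoring the canonical channel order.

    Accepts both files written by :func:`write_recording` and conforming
    CSVs with permuted (but fully labelled) columns.
    """
    path = Path(path)
    meta, n_comment = _parse_meta(path)
    missing = [k for k in _META_FIELDS if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")
    sensor_labels = tuple(meta["sensor_labels"].split(","))
    try:
        frame = pd.read_csv(path, skiprows=n_comment,
                            float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    expected_cols = channel_names(sensor_labels)
    missing_cols = [c for c in expected_cols if c not in frame.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing signal columns {missing_cols}")
    frame = frame[expected_cols]  # canonicalise any permutation
    if not all(np.issubdtype(d, np.number) for d in frame.dtypes):
        bad = [c for c, d in frame.dtypes.items()
               if not np.issubdtype(d, np.number)]
        raise FormatError(f"{path}: non-numeric cells in columns {bad}")
    return IMURecording(
        subject_id=meta["subject_id"],
        gait_class=GaitClass(meta["gait_class"]),
        affected_side=Side(meta["affected_side"]),
        repetition_index=int(meta["repetition_index"]),
        signal=frame.to_numpy(dtype=np.float64),
        segment_bounds=(int(meta["walk_start"]), int(meta["walk_end"])),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        sensor_labels=sensor_labels,
    )


def read_manifest(manifest_path) -> list[IMURecording]:
    """Load every recording listed in a cohort manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    root = manifest_path.parent
    return [read_recording(root / row.path) for row in manifest.itertuples()]


def save_windows(data: WindowedDataset, path) -> Path:
    """Store a WindowedDataset as an HDF5 container."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("tensor", data=data.tensor)
        fh.create_dataset("labels", data=data.labels)
        fh.create_dataset("subject_ids", data=np.array(
            [str(s) for s in data.subject_ids], dtype="S32"))
        fh.attrs["sensors"] = ",".join(data.selection.sensors)
        fh.attrs["components"] = ",".join(data.selection.components)
    return path


def load_windows(path) -> WindowedDataset:
    """Load a WindowedDataset written by :func:`save_windows`."""
    import h5py

    with h5py.File(path, "r") as fh:
        selection = SensorSelection(
            sensors=tuple(fh.attrs["sensors"].split(",")),
            components=tuple(fh.attrs["components"].split(",")))
        return WindowedDataset(
            tensor=fh["tensor"][...],
            labels=fh["labels"][...],
            subject_ids=np.array([s.decode() for s in fh["subject_ids"][...]],
                                 dtype=object),
            selection=selection)
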