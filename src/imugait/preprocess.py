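"""Walk extraction, normalization, windowing and channel selection.

The pipeline order is fixed: extract the labelled walking segment, min-max
normalize each channel of that segment to [-1, 1], cut sliding windows of
128 samples (1 s at 128 Hz) with 50% overlap, resample each window to the
target length (identity at native rate), then select the sensor/component
channels under evaluation.  Segmentation strictly precedes normalization so
that standing and transition artifacts cannot stretch the normalization
range of the walking data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io import (CLASS_INDEX, IMURecording, SensorSelection,
                 ValidationError, WindowedDataset, channel_names)

__all__ = [
    "PreprocessConfig",
    "extract_walk",
    "normalize_segment",
    "window_segment",
    "resample_window",
    "select_channels",
    "assemble_dataset",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    window_len_samples: int = 128
    overlap_fraction: float = 0.5
    normalize_range: tuple[float, float] = (-1.0, 1.0)
    resample_target: int | None = None  # None -> window_len_samples

    def __post_init__(self) -> None:
        if self.window_len_samples < 2:
            raise ValidationError("window_len_samples must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValidationError("overlap_fraction must lie in [0, 1)")
        lo, hi = self.normalize_range
        if not lo < hi:
            raise ValidationError("normalize_range must be increasing")
        if self.stride < 1:
            raise ValidationError("overlap too large: stride would be 0")

    @property
    def stride(self) -> int:
        return int(round(self.window_len_samples
                         * (1.0 - self.overlap_fraction)))

    @property
    def target_len(self) -> int:
        return (self.window_len_samples if self.resample_target is None
                else self.resample_target)


def extract_walk(rec: IMURecording) -> np.ndarray:
    """Rows of the steady walking segment, standing/transitions excluded."""
    ws, we = rec.segment_bounds
    if we <= ws:
        raise ValidationError(f"empty walking segment {rec.segment_bounds}")
    return rec.signal[ws:we]


def normalize_segment(segment: np.ndarray,
                      value_range: tuple[float, float] = (-1.0, 1.0),
                      ) -> np.ndarray:
    """Per-channel linear min-max map of a segment onto ``value_range``.

    Every non-constant channel attains both endpoints; constant channels
    map to the range midpoint.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size == 0:
        raise ValidationError("cannot normalize an empty segment")
    if not np.all(np.isfinite(segment)):
        raise ValidationError("segment contains non-finite values")
    lo, hi = value_range
    cmin = segment.min(axis=0)
    cmax = segment.max(axis=0)
    span = cmax - cmin
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    unit = (segment - cmin) / safe_span            # [0, 1]
    out = lo + unit * (hi - lo)
    mid = (lo + hi) / 2.0
    out[:, constant] = mid
    return out


def window_segment(segment: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Sliding windows of ``Wl`` rows starting at multiples of the stride.

    Returns an array of shape ``(n_windows, Wl, n_channels)``; a segment
    shorter than one window yields an empty result (with a warning), and a
    trailing partial window is discarded.
    """
    segment = np.asarray(segment)
    wl = cfg.window_len_samples
    stride = cfg.stride
    n_rows = segment.shape[0]
    if n_rows < wl:
        logger.warning("segment of %d rows shorter than window %d: "
                       "no windows produced", n_rows, wl)
        return np.empty((0, wl, segment.shape[1]), dtype=segment.dtype)
    n_windows = (n_rows - wl) // stride + 1
    return np.stack([segment[i * stride:i * stride + wl]
                     for i in range(n_windows)])


def resample_window(window: np.ndarray, target_len: int) -> np.ndarray:
    """Linear interpolation of each channel onto ``target_len`` points.

    Input and output grids both span the window uniformly, so the map is
    the identity when lengths already match and preserves affine signals
    exactly at any target length.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValidationError("cannot resample an empty window")
    if target_len < 2:
        raise ValidationError("target_len must be >= 2")
    n = window.shape[0]
    if n == target_len:
        return window.copy()
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, target_len)
    out = np.empty((target_len, window.shape[1]), dtype=np.float64)
    for ch in range(window.shape[1]):
        out[:, ch] = np.interp(x_new, x_old, window[:, ch])
    return out


def select_channels(tensor: np.ndarray, full_layout,
                    selection: SensorSelection) -> np.ndarray:
    """Slice a windowed tensor down to the selected sensors/components.

    ``full_layout`` names the sensors present in the tensor's channel axis
    (9 channels per sensor, canonical order); the output keeps canonical
    ordering and has ``3 * n_components * n_sensors`` channels.
    """
    full_layout = tuple(full_layout)
    missing = [s for s in selection.sensors if s not in full_layout]
    if missing:
        raise ValidationError(f"selected sensors not in layout: {missing}")
    if tensor.shape[-1] != 9 * len(full_layout):
        raise ValidationError(
            f"tensor has {tensor.shape[-1]} channels; layout "
            f"{full_layout} implies {9 * len(full_layout)}")
    names = channel_names(full_layout)
    index = {name: i for i, name in enumerate(names)}
    cols = [index[name] for name in selection.column_names()]
    return tensor[..., cols]


def assemble_dataset(recordings, selection: SensorSelection,
                     cfg: PreprocessConfig | None = None) -> WindowedDataset:
    """Full pipeline over a list of recordings.

    extract_walk -> normalize_segment -> window_segment -> resample_window
    -> select_channels; windows inherit their repetition's class label
    (sides merged: WH-left and WH-right are both WH) and subject id.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValidationError("recording list is empty")
    cfg = cfg or PreprocessConfig()
    rates = {rec.sampling_rate_hz for rec in recordings}
    if len(rates) > 1:
        raise ValidationError(f"mismatched sampling rates: {sorted(rates)}")

    tensors, labels, subjects = [], [], []
    for rec in recordings:
        segment = normalize_segment(extract_walk(rec), cfg.normalize_range)
        windows = window_segment(segment, cfg)
        if windows.shape[0] == 0:
            continue
        if cfg.target_len != windows.shape[1]:
            windows = np.stack([resample_window(w, cfg.target_len)
                                for w in windows])
        windows = select_channels(windows, rec.sensor_labels, selection)
        tensors.append(windows)
        labels.extend([CLASS_INDEX[rec.gait_class]] * windows.shape[0])
        subjects.extend([rec.subject_id] * windows.shape[0])

    if not tensors:
        raise ValidationError("no recording produced any window")
    return WindowedDataset(
        tensor=np.concatenate(tensors, axis=0),
        labels=np.array(labels, dtype=np.int64),
        subject_ids=np.array(subjects, dtype=object),
        selection=selection,
    )
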