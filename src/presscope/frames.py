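"""Core containers for pressure-mat data.

A sensor mattress reports interface pressure (mmHg) on a rectangular grid of
sensels. The default grid is 64 rows by 32 columns: rows run along the bed's
long axis with row 0 at the head end, columns run across the bed with column 0
at the viewer's left of the rendered image. "Left"/"right" labels elsewhere in
this package are image-frame, not patient-frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_GRID: tuple[int, int] = (64, 32)
SENSOR_MAX: float = 1000.0  # capture range of the mat, mmHg


class ValidationError(ValueError):
    """A frame or sequence violates its physical invariants."""


@dataclass
class PressureFrame:
    """One pressure map at one instant.

    Parameters
    ----------
    values
        2-D array of interface pressures in mmHg, shape (rows, cols).
        Must be finite, non-negative and no larger than ``sensor_max``.
    timestamp
        Seconds from the start of the owning sequence.
    sensor_max
        Upper bound of the sensor's capture range, mmHg.
    """

    values: np.ndarray
    timestamp: float = 0.0
    sensor_max: float = SENSOR_MAX

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"frame values must be 2-D, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("frame contains non-finite pressure values")
        if np.any(self.values < 0):
            raise ValidationError("frame contains negative pressure values")
        if np.any(self.values > self.sensor_max):
            raise ValidationError(
                f"frame exceeds sensor range [0, {self.sensor_max}] mmHg"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "PressureFrame":
        return PressureFrame(self.values.copy(), self.timestamp, self.sensor_max)

    def with_values(self, values: np.ndarray) -> "PressureFrame":
        """New frame sharing timestamp/range but holding different values."""
        return PressureFrame(values, self.timestamp, self.sensor_max)


@dataclass
class PressureSequence:
    """Ordered frames sampled at a fixed rate.

    Timestamps must increase in constant steps of ``1/sampling_hz``.
    All frames share one grid shape.
    """

    frames: list[PressureFrame]
    sampling_hz: float = 1.0
    subject_id: str = ""
    pose_id: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("a sequence must contain at least one frame")
        if self.sampling_hz <= 0:
            raise ValidationError("sampling_hz must be positive")
        shape = self.frames[0].shape
        step = 1.0 / self.sampling_hz
        for i, fr in enumerate(self.frames):
            if fr.shape != shape:
                raise ValidationError(
                    f"frame {i} shape {fr.shape} differs from {shape}"
                )
            expected = i * step
            if abs(fr.timestamp - expected) > 1e-9 * max(1.0, expected):
                raise ValidationError(
                    f"frame {i} timestamp {fr.timestamp} != {expected} "
                    f"(constant step {step} s required)"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> PressureFrame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def stack(self) -> np.ndarray:
        """All frames as one (n_frames, rows, cols) array."""
        return np.stack([f.values for f in self.frames])


def sequence_from_arrays(
    arrays: "list[np.ndarray] | np.ndarray",
    sampling_hz: float = 1.0,
    subject_id: str = "",
    pose_id: str = "",
    sensor_max: float = SENSOR_MAX,
) -> PressureSequence:
    """Build a sequence from raw arrays, assigning evenly spaced timestamps."""
    step = 1.0 / sampling_hz
    frames = [
        PressureFrame(np.asarray(a, dtype=float), i * step, sensor_max)
        for i, a in enumerate(arrays)
    ]
    return PressureSequence(frames, sampling_hz, subject_id, pose_id)
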