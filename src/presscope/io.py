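"""Plain-text matrix I/O for pressure sequences.

Two dialects are supported, matching the simple numeric formats used by
public pressure-mat datasets:

* **stacked**: one file holding the frames concatenated as rows x cols
  numeric tokens (whitespace- or comma-delimited); the total token count
  must be an exact multiple of rows*cols;
* **directory-of-frames**: a directory of such files, one frame each,
  read in sorted filename order.

Files may open with a header block of ``# key: value`` lines carrying
sequence metadata (sampling_hz, subject_id, pose_id, rows, cols).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .frames import (
    DEFAULT_GRID,
    SENSOR_MAX,
    PressureFrame,
    PressureSequence,
    ValidationError,
)

__all__ = ["read_sequence", "write_sequence", "ParseError"]


class ParseError(ValueError):
    """A file could not be parsed as pressure data."""


def _parse_file(path: Path) -> tuple[list[float], dict[str, str]]:
    """Tokenize one file, returning values and header metadata."""
    values: list[float] = []
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            for tok in stripped.replace(",", " ").split():
                try:
                    values.append(float(tok))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed numeric token {tok!r}"
                    ) from exc
    return values, meta


def _frames_from_tokens(
    tokens: list[float],
    grid_shape: tuple[int, int],
    source: Path,
    flip_rows: bool,
) -> list[np.ndarray]:
    rows, cols = grid_shape
    per_frame = rows * cols
    if len(tokens) == 0:
        raise ParseError(f"{source}: no numeric data found")
    if len(tokens) % per_frame != 0:
        raise ValidationError(
            f"{source}: token count {len(tokens)} is not a multiple of "
            f"{rows}x{cols}={per_frame}"
        )
    arr = np.asarray(tokens, dtype=float).reshape(-1, rows, cols)
    if flip_rows:
        arr = arr[:, ::-1, :]
    return list(arr)


def read_sequence(
    path: str | os.PathLike,
    grid_shape: tuple[int, int] = DEFAULT_GRID,
    sampling_hz: float = 1.0,
    sensor_max: float = SENSOR_MAX,
    flip_rows: bool = False,
    subject_id: str = "",
    pose_id: str = "",
) -> PressureSequence:
    """Read and validate a pressure sequence.

    ``path`` may be a stacked-frames file or a directory of per-frame
    files. ``flip_rows`` reverses the row order of every frame, for data
    recorded foot-to-head. Header metadata in the file overrides the
    ``sampling_hz``/``subject_id``/``pose_id`` arguments; frames violating
    the physical invariants (negative, non-finite or out-of-range values)
    are rejected rather than clamped.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    meta: dict[str, str] = {}
    arrays: list[np.ndarray] = []
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.is_file())
        if not files:
            raise ParseError(f"{p}: directory contains no frame files")
        for f in files:
            tokens, m = _parse_file(f)
            meta.update(m)
            arrays.extend(_frames_from_tokens(tokens, grid_shape, f, flip_rows))
    else:
        tokens, meta = _parse_file(p)
        if "rows" in meta and "cols" in meta:
            grid_shape = (int(meta["rows"]), int(meta["cols"]))
        arrays = _frames_from_tokens(tokens, grid_shape, p, flip_rows)
    hz = float(meta.get("sampling_hz", sampling_hz))
    step = 1.0 / hz
    frames = [
        PressureFrame(a, timestamp=i * step, sensor_max=sensor_max)
        for i, a in enumerate(arrays)
    ]
    return PressureSequence(
        frames,
        sampling_hz=hz,
        subject_id=meta.get("subject_id", subject_id),
        pose_id=meta.get("pose_id", pose_id),
    )


def write_sequence(
    seq: PressureSequence,
    path: str | os.PathLike,
    header: bool = True,
) -> None:
    """Write a sequence as a stacked-frames text file.

    Values are rendered with ``repr``-level precision so a read-back
    reproduces them bit-exactly. A commented header records the grid shape
    and sequence metadata.
    """
    rows, cols = seq.shape
    p = Path(path)
    with open(p, "w") as fh:
        if header:
            fh.write(f"# rows: {rows}\n# cols: {cols}\n")
            fh.write(f"# sampling_hz: {seq.sampling_hz!r}\n")
            if seq.subject_id:
                fh.write(f"# subject_id: {seq.subject_id}\n")
            if seq.pose_id:
                fh.write(f"# pose_id: {seq.pose_id}\n")
        for frame in seq:
            for r in range(rows):
                fh.write(" ".join(repr(float(v)) for v in frame.values[r]))
                fh.write("\n")
            fh.write("\n")
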