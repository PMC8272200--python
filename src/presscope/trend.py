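"""Savitzky-Golay trend decomposition and external-object removal.

The cleaning stage rests on one observation about in-bed pressure maps: the
body produces a strong, localized trend along each sensor line, while broad
external objects (pillows, wedges) produce low-relief plateaus whose trend
stays close to the line average. Smoothing each line with a Savitzky-Golay
(moving least-squares polynomial) filter captures the trend ``f(S)``; sensels
whose absolute trend deviation ``S' = |f(S) - avg(f(S))|`` exceeds a threshold
``th`` are kept from the raw signal, the rest are zeroed::

    b = S * (S' > th)

The SG filter is built here from first principles. For a window of 2M+1
samples on abscissae n = -M..M and a degree-k polynomial basis, the
least-squares fit coefficients are a = (A^T A)^{-1} A^T x with A the
Vandermonde design matrix; evaluating the fitted polynomial at the window
centre reduces to convolution with a fixed impulse response (the centre row
of the projection matrix A (A^T A)^{-1} A^T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _field
from functools import cached_property

import numpy as np

from .frames import PressureFrame

__all__ = [
    "SGFilterSpec",
    "DecompositionResult",
    "sg_impulse_response",
    "sg_projection_matrix",
    "sg_smooth",
    "extract_lines",
    "assemble_lines",
    "remove_external_objects",
    "grid_search_threshold",
    "default_filter_spec",
    "deviation_grid",
    "noise_floor_threshold",
    "DEFAULT_THRESHOLD",
    "rmse",
    "psnr",
    "mask_energy_fraction",
]


def _design_matrix(degree: int, half_window: int) -> np.ndarray:
    """Vandermonde design matrix on abscissae -M..M, columns n^0..n^k."""
    n = np.arange(-half_window, half_window + 1, dtype=float)
    return np.vander(n, degree + 1, increasing=True)


def sg_projection_matrix(degree: int, half_window: int) -> np.ndarray:
    """Least-squares projection P = A (A^T A)^{-1} A^T for one SG window.

    Row i of P gives the weights that evaluate the window's fitted
    polynomial at abscissa i - M; the centre row is the classic smoothing
    impulse response, the other rows handle boundary samples.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if not 0 <= degree <= 2 * half_window:
        raise ValueError(
            f"degree must satisfy 0 <= degree <= 2M (degree={degree}, M={half_window})"
        )
    a = _design_matrix(degree, half_window)
    # Solve (A^T A) H = A^T for H rather than forming an explicit inverse.
    h = np.linalg.solve(a.T @ a, a.T)
    return a @ h


def sg_impulse_response(degree: int, half_window: int) -> np.ndarray:
    """Centre-evaluation Savitzky-Golay smoothing weights, length 2M+1.

    The weights sum to one (a constant passes through unchanged) and are
    symmetric about the centre.
    """
    p = sg_projection_matrix(degree, half_window)
    return p[half_window]


@dataclass(frozen=True)
class SGFilterSpec:
    """Degree and half-window of a Savitzky-Golay smoother.

    ``degree`` is the polynomial order k (low orders, 2 or 3, suffice to
    capture a pressure-line trend); the window holds 2M+1 samples.
    """

    degree: int = 2
    half_window: int = 16

    def __post_init__(self) -> None:
        sg_projection_matrix(self.degree, self.half_window)  # validates

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1

    @cached_property
    def design_matrix(self) -> np.ndarray:
        return _design_matrix(self.degree, self.half_window)

    @cached_property
    def projection(self) -> np.ndarray:
        return sg_projection_matrix(self.degree, self.half_window)

    @cached_property
    def impulse_response(self) -> np.ndarray:
        return self.projection[self.half_window]


def default_filter_spec(
    n_cols: int = 32, degree: int = 2, eps_adjust: int = -8
) -> SGFilterSpec:
    """Default decomposition filter: M = round(r/2) + eps.

    ``r`` is the sensel count across the bed (the horizontal direction of
    the mat, 32 by default). The base rule M = r/2 sizes the window to one
    transverse line of the unfolded signal; for the default per-column
    processing the window adjustment ``eps_adjust`` (default -8, giving a
    17-tap window) restores feature-scale smoothing so that neighbouring
    body mounds along a 64-sample column are not merged into one plateau.
    """
    return SGFilterSpec(degree=degree, half_window=round(n_cols / 2) + eps_adjust)


def sg_smooth(
    signal: np.ndarray, spec: SGFilterSpec, boundary: str = "interp"
) -> np.ndarray:
    """Savitzky-Golay smoothing of a 1-D signal.

    Interior samples are the convolution of the signal with the centre
    impulse response. Boundary handling:

    ``interp`` (default)
        fit the first/last window's polynomial and evaluate it at the
        off-centre positions (rows of the projection matrix), so bed edges
        do not produce spurious trend deviations;
    ``reflect``
        pad by reflection and convolve throughout.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("sg_smooth expects a 1-D signal")
    m = spec.half_window
    w = spec.window
    if x.size < w:
        raise ValueError(
            f"signal length {x.size} shorter than filter window {w}"
        )
    if boundary == "reflect":
        xp = np.pad(x, m, mode="reflect")
        return np.convolve(xp, spec.impulse_response[::-1], mode="valid")
    if boundary != "interp":
        raise ValueError(f"unknown boundary mode {boundary!r}")
    out = np.convolve(x, spec.impulse_response[::-1], mode="same")
    p = spec.projection
    out[:m] = p[:m] @ x[:w]
    out[-m:] = p[m + 1:] @ x[-w:]
    return out


def extract_lines(frame: PressureFrame, line_axis: str = "columns") -> list[np.ndarray]:
    """Split a frame into the 1-D signals the trend filter operates on.

    ``columns``: one signal per sensor column, running head to foot (the
    long axis). ``unfolded``: the whole map as a single row-major signal.
    """
    v = frame.values
    if line_axis == "columns":
        return [v[:, c].copy() for c in range(v.shape[1])]
    if line_axis == "unfolded":
        return [v.ravel().copy()]
    raise ValueError(f"unknown line_axis {line_axis!r}")


def assemble_lines(
    lines: list[np.ndarray], shape: tuple[int, int], line_axis: str = "columns"
) -> np.ndarray:
    """Inverse of :func:`extract_lines`."""
    if line_axis == "columns":
        return np.stack(lines, axis=1)
    if line_axis == "unfolded":
        return lines[0].reshape(shape)
    raise ValueError(f"unknown line_axis {line_axis!r}")


@dataclass
class DecompositionResult:
    """Outcome of trend-based external-object removal on one frame.

    ``body_frame`` holds the raw values on the retained sensels and zero
    elsewhere; ``deviation`` is the grid of per-line absolute trend
    deviations S'; ``trend`` the per-line smoothed signal f(S) reassembled
    to grid shape; ``trend_mean`` the per-line averages avg(f(S)).
    """

    body_frame: PressureFrame
    trend: np.ndarray
    trend_mean: np.ndarray
    deviation: np.ndarray
    retained_mask: np.ndarray
    threshold: float
    filter_spec: SGFilterSpec
    line_axis: str

    _raw: np.ndarray = _field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def raw_values(self) -> np.ndarray:
        return self._raw

    @property
    def suppressed_frame(self) -> PressureFrame:
        """Raw values on the removed sensels (the suppressed residual)."""
        return self.body_frame.with_values(
            np.where(self.retained_mask, 0.0, self._raw)
        )


#: fixed fallback threshold (mmHg); the value the supervised grid search
#: returns on the default synthetic calibration scenes
DEFAULT_THRESHOLD: float = 12.0


def deviation_grid(
    frame: PressureFrame,
    spec: SGFilterSpec | None = None,
    line_axis: str = "columns",
    boundary: str = "reflect",
    mean_scope: str = "global",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trend grid, trend mean(s) and absolute-deviation grid S'.

    ``mean_scope`` controls avg(f(S)): ``global`` (default) averages the
    smoothed signal over the whole frame — the frame is mostly empty mat,
    so the average sits near the empty-bed baseline and body mounds stand
    clearly above it; ``line`` averages each processed line separately.
    """
    if spec is None:
        spec = default_filter_spec(frame.shape[1])
    lines = extract_lines(frame, line_axis)
    trends = [sg_smooth(line, spec, boundary) for line in lines]
    trend = assemble_lines(trends, frame.shape, line_axis)
    if mean_scope == "global":
        means = np.array([trend.mean()])
        dev = np.abs(trend - means[0])
    elif mean_scope == "line":
        means = np.array([t.mean() for t in trends])
        devs = [np.abs(t - mu) for t, mu in zip(trends, means)]
        dev = assemble_lines(devs, frame.shape, line_axis)
    else:
        raise ValueError(f"unknown mean_scope {mean_scope!r}")
    return trend, means, dev


def noise_floor_threshold(
    frame: PressureFrame,
    spec: SGFilterSpec | None = None,
    line_axis: str = "columns",
    boundary: str = "reflect",
    mean_scope: str = "global",
    factor: float = 2.0,
) -> float:
    """Retention threshold at the sensor-noise floor of the deviation field.

    Estimates the background deviation scale as a robust sigma (1.4826 x
    MAD) over the lower 60% of S' and returns ``factor`` times it. Suitable
    for object-free data, where removal should leave the body untouched.
    """
    _, _, dev = deviation_grid(frame, spec, line_axis, boundary, mean_scope)
    low = dev[dev <= np.percentile(dev, 60)]
    sigma = 1.4826 * float(np.median(np.abs(low - np.median(low))))
    return factor * sigma


def remove_external_objects(
    frame: PressureFrame,
    spec: SGFilterSpec | None = None,
    th: float | None = None,
    line_axis: str = "columns",
    boundary: str = "reflect",
    mean_scope: str = "global",
) -> DecompositionResult:
    """Suppress external-object sensels by thresholded trend deviation.

    trend = SG-smooth(line); S' = |trend - avg(trend)|; raw values are
    retained where S' > th and zeroed elsewhere. When no calibrated
    threshold is given (see :func:`grid_search_threshold`), a fixed default
    of ``DEFAULT_THRESHOLD`` mmHg is used.
    """
    if spec is None:
        spec = default_filter_spec(frame.shape[1])
    if th is None:
        th = DEFAULT_THRESHOLD
    if th < 0:
        raise ValueError("threshold must be non-negative")
    trend, means, dev = deviation_grid(frame, spec, line_axis, boundary, mean_scope)
    mask = dev > th
    body = np.where(mask, frame.values, 0.0)
    return DecompositionResult(
        body_frame=frame.with_values(body),
        trend=trend,
        trend_mean=means,
        deviation=dev,
        retained_mask=mask,
        threshold=float(th),
        filter_spec=spec,
        line_axis=line_axis,
        _raw=frame.values.copy(),
    )


def _f1(retained: np.ndarray, body_mask: np.ndarray) -> float:
    tp = float(np.sum(retained & body_mask))
    fp = float(np.sum(retained & ~body_mask))
    fn = float(np.sum(~retained & body_mask))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def grid_search_threshold(
    scenes,
    spec: SGFilterSpec | None = None,
    th_grid=None,
    line_axis: str = "columns",
    boundary: str = "reflect",
    mean_scope: str = "global",
) -> float:
    """Pick the retention threshold by supervised grid search.

    ``scenes`` is a list of (PressureFrame, SceneGroundTruth) pairs; the
    returned grid value maximizes the mean F1 score of the retained mask
    against the ground-truth body mask, ties broken toward the smaller
    threshold (retain more body).
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("at least one calibration scene is required")
    if th_grid is None:
        th_grid = np.arange(0.0, 51.0, 2.0)
    th_grid = np.asarray(list(th_grid), dtype=float)
    if th_grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    devs = []
    masks = []
    for frame, truth in scenes:
        _, _, dev = deviation_grid(frame, spec, line_axis, boundary, mean_scope)
        devs.append(dev)
        masks.append(np.asarray(truth.body_mask, dtype=bool))
    scores = np.array(
        [np.mean([_f1(d > th, m) for d, m in zip(devs, masks)]) for th in th_grid]
    )
    order = np.argsort(th_grid)  # ties -> smaller threshold
    best = order[np.argmax(scores[order])]
    return float(th_grid[best])


def rmse(
    reference: PressureFrame, estimate: PressureFrame, normalize: bool = False
) -> float:
    """Root-mean-square difference between two frames.

    With ``normalize`` both frames are first divided by the sensor range,
    putting the result on the [0, 1] scale used for reporting.
    """
    if reference.shape != estimate.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {estimate.shape}"
        )
    a = reference.values
    b = estimate.values
    if normalize:
        a = a / reference.sensor_max
        b = b / estimate.sensor_max
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(reference: PressureFrame, estimate: PressureFrame) -> float:
    """Peak signal-to-noise ratio in decibels.

    Computed on normalized frames as ``20 log10(peak / rmse)`` where
    ``peak`` is the maximum of the normalized reference; identical frames
    return ``inf``.
    """
    err = rmse(reference, estimate, normalize=True)
    peak = float(np.max(reference.values)) / reference.sensor_max
    if err == 0.0:
        return float("inf")
    if peak <= 0.0:
        warnings.warn("PSNR of an all-zero reference is ill-defined")
        return float("-inf")
    return float(20.0 * np.log10(peak / err))


def mask_energy_fraction(
    raw: PressureFrame, cleaned: PressureFrame, mask: np.ndarray
) -> float:
    """Fraction of the raw frame's squared energy over ``mask`` surviving
    in the cleaned frame. An empty or zero-energy mask has nothing to
    retain or suppress, so the fraction is 0.0."""
    mask = np.asarray(mask, dtype=bool)
    total = float(np.sum(raw.values[mask] ** 2))
    if total == 0.0:
        return 0.0
    kept = float(np.sum(cleaned.values[mask] ** 2))
    return kept / total
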