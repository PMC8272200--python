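"""Noise suppression and smoothing of cleaned pressure frames.

Two kernels are offered: an isotropic Gaussian (best silhouette for
visualization) and a separable 2-D Savitzky-Golay smoother (preserves
local maxima/minima, hence better for landmark detection). The default
detection chain applies SG first, then the Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import PressureFrame
from .trend import SGFilterSpec, sg_smooth

__all__ = ["EnhancementSpec", "enhance", "enhance_chain", "default_chain"]


@dataclass(frozen=True)
class EnhancementSpec:
    """One smoothing pass.

    ``gaussian``: isotropic convolution with standard deviation ``sigma``
    sensels, reflect boundary. ``savitzky_golay_2d``: the 1-D SG smoother
    applied separably along columns then rows; ``window`` is the full
    window length and is normalized to the nearest odd value >= 3 (a
    symmetric SG window must hold 2M+1 samples).
    """

    method: str = "gaussian"
    sigma: float = 1.4
    degree: int = 2
    window: int = 7

    def __post_init__(self) -> None:
        if self.method not in ("gaussian", "savitzky_golay_2d"):
            raise ValueError(f"unknown enhancement method {self.method!r}")
        if self.method == "gaussian" and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.method == "savitzky_golay_2d":
            if self.odd_window <= self.degree:
                raise ValueError("window must exceed degree")

    @property
    def odd_window(self) -> int:
        w = max(3, self.window)
        return w if w % 2 == 1 else w + 1


def enhance(frame: PressureFrame, spec: EnhancementSpec) -> PressureFrame:
    """Smooth a frame, clipping the result back to the sensor range."""
    v = frame.values
    if spec.method == "gaussian":
        if min(v.shape) < 1:
            raise ValueError("frame is empty")
        out = gaussian_filter(v, spec.sigma, mode="reflect")
    else:
        w = spec.odd_window
        if min(v.shape) < w:
            raise ValueError(
                f"frame {v.shape} smaller than SG window {w}"
            )
        sg = SGFilterSpec(degree=spec.degree, half_window=w // 2)
        out = np.apply_along_axis(sg_smooth, 0, v, sg)
        out = np.apply_along_axis(sg_smooth, 1, out, sg)
    out = np.clip(out, 0.0, frame.sensor_max)
    return frame.with_values(out)


def default_chain() -> list[EnhancementSpec]:
    """Detection-oriented chain: SG-2D (degree 2, window 7), then
    Gaussian (sigma 1.4)."""
    return [
        EnhancementSpec(method="savitzky_golay_2d", degree=2, window=7),
        EnhancementSpec(method="gaussian", sigma=1.4),
    ]


def enhance_chain(
    frame: PressureFrame, chain: "list[EnhancementSpec] | None" = None
) -> PressureFrame:
    """Apply a sequence of smoothing passes (default: :func:`default_chain`)."""
    if chain is None:
        chain = default_chain()
    for spec in chain:
        frame = enhance(frame, spec)
    return frame
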