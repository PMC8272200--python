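"""High-risk body-region detection, labelling and temporal tracking.

The regions prone to pressure injury — head, shoulders, sacrum and heels —
carry the highest interface pressures of a recumbent body. They are found
as local maxima of the enhanced pressure image: the spatial gradient field
is computed and sensels where both components cross zero from positive to
negative mark the peaks. Regions are grown from each peak by a
relative-level flood fill, cleaned morphologically, filtered by the
posture's plausible row bands, and labelled by simple spatial relations
(head topmost, feet bottommost, sacrum near mid-body, shoulders in the
upper band split left/right about the body axis).

Tracking associates same-label regions across frames by nearest centroid
within a displacement gate — patients monitored for pressure-injury risk
barely move, so a small gate suffices — and reports the mean RAW pressure
of each region per frame, keeping tracked values in physical mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .enhance import EnhancementSpec, enhance_chain
from .frames import PressureFrame, PressureSequence

__all__ = [
    "GradientField",
    "BodyRegion",
    "TrackRecord",
    "RegionParams",
    "gradient_field",
    "find_maxima",
    "grow_regions",
    "filter_regions",
    "label_regions",
    "detect_regions",
    "track_regions",
]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

REGION_LABELS = (
    "head",
    "left_shoulder",
    "right_shoulder",
    "sacrum",
    "left_foot",
    "right_foot",
    "unlabelled",
)

#: plausible fractional row bands per landmark group
ROW_BANDS = {
    "head": (0.0, 0.18),
    "shoulder": (0.15, 0.35),
    "sacrum": (0.40, 0.70),
    "foot": (0.80, 1.0),
}


@dataclass
class GradientField:
    """Spatial gradient of a pressure image: d_row = df/dy, d_col = df/dx."""

    d_row: np.ndarray
    d_col: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.d_row.shape  # type: ignore[return-value]


@dataclass(eq=False)
class BodyRegion:
    """A detected high-risk region.

    ``mean_pressure`` is always the arithmetic mean of the *raw* frame
    over the region's sensels.
    """

    label: str
    mask: np.ndarray
    centroid: tuple[float, float]
    mean_pressure: float
    seed: tuple[int, int] | None = None

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def pixels(self) -> list[tuple[int, int]]:
        rr, cc = np.where(self.mask)
        return list(zip(rr.tolist(), cc.tolist()))


@dataclass
class RegionParams:
    """Tunables of the detection/tracking chain."""

    min_height: float = 20.0  # mmHg floor for candidate maxima
    rel_level: float = 0.65  # flood-fill level relative to the seed value
    min_area: int = 4  # sensels, after morphological opening
    gate: float = 5.0  # sensels/frame association gate
    enhancement: "list[EnhancementSpec] | None" = None  # None -> default chain


def gradient_field(frame: PressureFrame) -> GradientField:
    """Central-difference gradient (one-sided at the borders)."""
    v = frame.values
    if min(v.shape) < 3:
        raise ValueError("gradient needs at least a 3x3 frame")
    d_row, d_col = np.gradient(v)
    return GradientField(d_row=d_row, d_col=d_col)


def find_maxima(
    gfield: GradientField,
    frame: PressureFrame,
    min_height: float = 20.0,
) -> list[tuple[int, int]]:
    """2-D local maxima via zero crossings of both gradient components.

    A sensel qualifies when d_row changes sign + -> - moving down its
    column and d_col changes sign + -> - moving across its row, and the
    frame value is at least ``min_height``. Plateau peaks (consecutive
    zero gradients) are resolved to the plateau centroid; flat components
    that do not rise above their surroundings are discarded.
    """
    v = frame.values
    dr, dc = gfield.d_row, gfield.d_col
    rows, cols = v.shape
    up = np.full(v.shape, 0.0)
    down = np.full(v.shape, 0.0)
    left = np.full(v.shape, 0.0)
    right = np.full(v.shape, 0.0)
    up[1:, :] = dr[:-1, :]
    down[:-1, :] = dr[1:, :]
    left[:, 1:] = dc[:, :-1]
    right[:, :-1] = dc[:, 1:]
    cand = (up >= 0) & (down <= 0) & (left >= 0) & (right <= 0)
    cand &= v >= min_height
    if not cand.any():
        return []
    labelled, n = ndimage.label(cand, structure=FOUR_CONNECTED)
    maxima: list[tuple[int, int]] = []
    for i in range(1, n + 1):
        comp = labelled == i
        ring = ndimage.binary_dilation(comp, structure=np.ones((3, 3), bool)) & ~comp
        peak = v[comp].max()
        if not ring.any() or peak <= v[ring].max():
            continue  # flat, saddle, or whole-frame component: no summit
        rr, cc = np.where(comp)
        maxima.append((int(round(rr.mean())), int(round(cc.mean()))))
    return sorted(maxima)


def grow_regions(
    frame: PressureFrame,
    maxima: list[tuple[int, int]],
    rel_level: float = 0.5,
    value_frame: PressureFrame | None = None,
) -> list[BodyRegion]:
    """Grow an (unlabelled) region around each seed maximum.

    Each region is the 4-connected component of
    ``{frame >= rel_level * frame[seed]}`` containing its seed; regions
    sharing sensels are merged, pooling their seeds. ``value_frame``
    (default: ``frame``) supplies the raw values for mean pressure.
    """
    if not 0 < rel_level < 1:
        raise ValueError("rel_level must lie in (0, 1)")
    v = frame.values
    raw = (value_frame or frame).values
    masks: list[np.ndarray] = []
    seeds: list[list[tuple[int, int]]] = []
    for r, c in maxima:
        if not (0 <= r < v.shape[0] and 0 <= c < v.shape[1]):
            raise ValueError(f"seed {(r, c)} outside the grid")
        level = rel_level * v[r, c]
        above = v >= level
        labelled, _ = ndimage.label(above, structure=FOUR_CONNECTED)
        comp = labelled == labelled[r, c]
        merged = False
        for i, m in enumerate(masks):
            if (m & comp).any():
                masks[i] = m | comp
                seeds[i].append((r, c))
                merged = True
                break
        if not merged:
            masks.append(comp)
            seeds.append([(r, c)])
    # merging may cascade
    changed = True
    while changed:
        changed = False
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if (masks[i] & masks[j]).any():
                    masks[i] |= masks[j]
                    seeds[i].extend(seeds[j])
                    del masks[j], seeds[j]
                    changed = True
                    break
            if changed:
                break
    return [_make_region(m, raw, s[0]) for m, s in zip(masks, seeds)]


def _make_region(
    mask: np.ndarray, raw: np.ndarray, seed: tuple[int, int] | None
) -> BodyRegion:
    rr, cc = np.where(mask)
    return BodyRegion(
        label="unlabelled",
        mask=mask,
        centroid=(float(rr.mean()), float(cc.mean())),
        mean_pressure=float(raw[mask].mean()),
        seed=seed,
    )


def filter_regions(
    regions: list[BodyRegion],
    min_area: int = 4,
    posture: str | None = None,
    raw: np.ndarray | None = None,
) -> list[BodyRegion]:
    """Morphological cleanup and posture-plausibility filtering.

    Each region mask is opened with a 3x3 structuring element (removing
    hand/elbow-sized specks); regions smaller than ``min_area`` sensels
    are dropped, as are regions whose centroid row falls outside every
    plausible band of the posture's template.
    """
    kept: list[BodyRegion] = []
    for reg in regions:
        opened = ndimage.binary_opening(reg.mask, structure=np.ones((3, 3), bool))
        if opened.sum() < min_area:
            continue
        if raw is None:
            # without raw values the original mean is the best available
            new = BodyRegion(
                label=reg.label,
                mask=opened,
                centroid=_centroid(opened),
                mean_pressure=reg.mean_pressure,
                seed=reg.seed,
            )
        else:
            new = _make_region(opened, raw, reg.seed)
        if posture is not None:
            rows = opened.shape[0]
            frac = new.centroid[0] / rows
            in_band = any(lo <= frac <= hi for lo, hi in ROW_BANDS.values())
            if not in_band:
                continue
        kept.append(new)
    return kept


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.where(mask)
    return (float(rr.mean()), float(cc.mean()))


def label_regions(regions: list[BodyRegion], posture: str) -> list[BodyRegion]:
    """Assign anatomical labels by spatial relations.

    Head is the topmost region; feet the bottom-band regions (two for
    supine, split about the body-axis column; one for lateral, labelled
    by the lying side); the sacrum is the region nearest the 0.55R row
    inside the mid band; shoulders are the remaining upper-band regions,
    left/right in the image frame. Anything else stays ``unlabelled``.
    """
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: r.centroid[0])
    rows = regions[0].mask.shape[0]
    axis_col = float(np.median([r.centroid[1] for r in regions]))
    remaining = list(regions)

    head = remaining.pop(0)
    head.label = "head"
    out = [head]

    feet = [
        r for r in remaining if r.centroid[0] / rows >= ROW_BANDS["foot"][0]
    ]
    for r in feet:
        remaining.remove(r)
    if posture == "supine":
        feet.sort(key=lambda r: r.centroid[1])
        if len(feet) == 1:
            feet[0].label = (
                "left_foot" if feet[0].centroid[1] <= axis_col else "right_foot"
            )
        else:
            for r in feet:
                r.label = "left_foot" if r.centroid[1] <= axis_col else "right_foot"
            # guarantee at most one of each when exactly two are present
            if len(feet) == 2 and feet[0].label == feet[1].label:
                feet[0].label, feet[1].label = "left_foot", "right_foot"
    else:
        side = "left" if posture == "left_lateral" else "right"
        for r in feet[:1]:
            r.label = f"{side}_foot"
        for r in feet[1:]:
            r.label = "unlabelled"
    out.extend(feet)

    sac_lo, sac_hi = ROW_BANDS["sacrum"]
    sac_cands = [
        r for r in remaining if sac_lo <= r.centroid[0] / rows <= sac_hi
    ]
    if sac_cands:
        sacrum = min(sac_cands, key=lambda r: abs(r.centroid[0] - 0.55 * rows))
        sacrum.label = "sacrum"
        remaining.remove(sacrum)
        out.append(sacrum)

    sh_lo, sh_hi = ROW_BANDS["shoulder"]
    shoulders = [
        r for r in remaining if sh_lo <= r.centroid[0] / rows <= sh_hi
    ]
    for r in shoulders:
        remaining.remove(r)
    if posture == "supine":
        for r in shoulders:
            r.label = (
                "left_shoulder" if r.centroid[1] <= axis_col else "right_shoulder"
            )
        if len(shoulders) == 2 and shoulders[0].label == shoulders[1].label:
            shoulders.sort(key=lambda r: r.centroid[1])
            shoulders[0].label = "left_shoulder"
            shoulders[1].label = "right_shoulder"
    else:
        side = "left" if posture == "left_lateral" else "right"
        for r in shoulders[:1]:
            r.label = f"{side}_shoulder"
        for r in shoulders[1:]:
            r.label = "unlabelled"
    out.extend(shoulders)

    for r in remaining:
        r.label = "unlabelled"
    out.extend(remaining)
    return sorted(out, key=lambda r: r.centroid[0])


def detect_regions(
    frame: PressureFrame,
    posture: str,
    params: RegionParams | None = None,
) -> list[BodyRegion]:
    """Full single-frame chain: enhance, find maxima, grow, filter, label.

    Detection runs on the enhanced frame; every region's mean pressure is
    computed on the raw input frame.
    """
    if params is None:
        params = RegionParams()
    smoothed = enhance_chain(frame, params.enhancement)
    gf = gradient_field(smoothed)
    maxima = find_maxima(gf, smoothed, params.min_height)
    regions = grow_regions(smoothed, maxima, params.rel_level, value_frame=frame)
    regions = filter_regions(
        regions, params.min_area, posture, raw=frame.values
    )
    return label_regions(regions, posture)


@dataclass
class TrackRecord:
    """Per-label time series of mean pressure and centroid."""

    label: str
    timestamps: list[float] = field(default_factory=list)
    mean_pressures: list[float] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    gaps: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.timestamps)


def track_regions(
    seq: PressureSequence,
    posture: str,
    params: RegionParams | None = None,
) -> list[TrackRecord]:
    """Detect and label regions per frame and link them over time.

    A detection joins its label's track when its centroid lies within
    ``params.gate`` sensels of the track's last position (or starts the
    track). Frames where a label is missing (or outside the gate) are
    recorded as gaps for that label.
    """
    if params is None:
        params = RegionParams()
    tracks: dict[str, TrackRecord] = {}
    seen_labels: list[str] = []
    per_frame: list[dict[str, BodyRegion]] = []
    for frame in seq:
        regs = detect_regions(frame, posture, params)
        by_label: dict[str, BodyRegion] = {}
        for r in regs:
            if r.label == "unlabelled":
                continue
            # keep the strongest candidate per label
            if r.label not in by_label or r.mean_pressure > by_label[r.label].mean_pressure:
                by_label[r.label] = r
        per_frame.append(by_label)
        for lbl in by_label:
            if lbl not in tracks:
                tracks[lbl] = TrackRecord(label=lbl)
                seen_labels.append(lbl)
    for frame, by_label in zip(seq, per_frame):
        for lbl in seen_labels:
            rec = tracks[lbl]
            reg = by_label.get(lbl)
            if reg is None:
                rec.gaps.append(frame.timestamp)
                continue
            if rec.centroids:
                last = rec.centroids[-1]
                dist = np.hypot(
                    reg.centroid[0] - last[0], reg.centroid[1] - last[1]
                )
                if dist > params.gate:
                    rec.gaps.append(frame.timestamp)
                    continue
            rec.timestamps.append(frame.timestamp)
            rec.mean_pressures.append(reg.mean_pressure)
            rec.centroids.append(reg.centroid)
    return [tracks[lbl] for lbl in seen_labels]


def tracks_to_table(tracks: list[TrackRecord]):
    """Tracks as a tidy pandas DataFrame (timestamp_s, label,
    mean_pressure_mmHg, centroid_row, centroid_col)."""
    import pandas as pd

    rows = []
    for tr in tracks:
        for t, p, (cr, cc) in zip(tr.timestamps, tr.mean_pressures, tr.centroids):
            rows.append(
                {
                    "timestamp_s": t,
                    "label": tr.label,
                    "mean_pressure_mmHg": p,
                    "centroid_row": cr,
                    "centroid_col": cc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "timestamp_s",
            "label",
            "mean_pressure_mmHg",
            "centroid_row",
            "centroid_col",
        ],
    ).sort_values(["timestamp_s", "label"], kind="stable").reset_index(drop=True)
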