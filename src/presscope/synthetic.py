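"""Seeded synthetic pressure scenes with full ground truth.

The generator emulates a 64x32 sensor mattress (range [0, 1000] mmHg,
1 Hz sampling). A scene is the sum of three layers:

* a **body** layer: squared-exponential bumps at the high-risk bony
  prominences (head, shoulders, sacrum, heels) — the load concentrations
  that dominate a recumbent pressure map. Optional broad ``support``
  components can be added for a more contiguous silhouette;
* an **object** layer: broad low-relief plateaus with softened edges,
  standing in for pillows, cushions and wedges;
* additive Gaussian sensor noise, with the sum clipped to the capture range.

Ground truth records the body and object masks, the high-risk landmark
table, and the posture label, so every downstream stage can be scored
without real recordings.

Default magnitudes are chosen to be physiologically plausible for an adult
on a standard foam mattress: peak interface pressures of 50-85 mmHg at the
bony prominences (heels and the lateral hip/shoulder at the high end),
~7-10 mmHg under broad foam positioning aids, and 5 mmHg sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import DEFAULT_GRID, SENSOR_MAX, PressureFrame, PressureSequence

POSTURES = ("supine", "left_lateral", "right_lateral")


@dataclass(frozen=True)
class Landmark:
    """One pressure bump: a named isotropic squared-exponential peak."""

    name: str
    row: float
    col: float
    peak: float  # mmHg
    spread: float  # sensels (Gaussian sigma)
    # support components may be elongated along the bed axis
    spread_col: float | None = None


@dataclass(frozen=True)
class ObjectSpec:
    """A broad low-relief plateau standing in for a pillow or wedge.

    ``footprint`` is (row0, row1, col0, col1), half-open spans. The
    footprint must be at least 4x4 sensels (objects are broad) and the
    relief must stay below the tallest landmark peak (objects are
    low-relief compared to bony prominences).
    """

    footprint: tuple[int, int, int, int]
    relief: float = 10.0  # mmHg
    edge_softness: float = 2.0  # sensels of taper


def _supine_landmarks(grid: tuple[int, int]) -> list[Landmark]:
    rows, cols = grid
    ax = cols / 2
    return [
        Landmark("head", 0.08 * rows, ax, 50.0, 2.2),
        Landmark("left_shoulder", 0.22 * rows, ax - 5.5, 55.0, 2.8),
        Landmark("right_shoulder", 0.22 * rows, ax + 5.5, 55.0, 2.8),
        Landmark("sacrum", 0.55 * rows, ax, 65.0, 4.0, spread_col=3.5),
        # heels: small contact patches with the highest peak pressures
        Landmark("left_foot", 0.92 * rows, ax - 5, 85.0, 2.0),
        Landmark("right_foot", 0.92 * rows, ax + 5, 85.0, 2.0),
    ]


def _lateral_landmarks(grid: tuple[int, int], side: str) -> list[Landmark]:
    rows, cols = grid
    sign = -1.0 if side == "left" else 1.0
    ax = cols / 2 + sign * 4
    return [
        # side-lying head contact (ear/temple) is focal, with a higher peak
        Landmark("head", 0.08 * rows, ax, 55.0, 2.5),
        Landmark(f"{side}_shoulder", 0.25 * rows, ax + sign * 3, 65.0, 3.0),
        Landmark("sacrum", 0.55 * rows, ax, 70.0, 3.5),
        Landmark(f"{side}_foot", 0.92 * rows, ax + sign * 1, 60.0, 2.0),
    ]


def default_landmarks(
    posture: str, grid: tuple[int, int] = DEFAULT_GRID
) -> list[Landmark]:
    """High-risk landmark layout for a posture (ground-truth peaks only)."""
    if posture == "supine":
        return _supine_landmarks(grid)
    if posture == "left_lateral":
        return _lateral_landmarks(grid, "left")
    if posture == "right_lateral":
        return _lateral_landmarks(grid, "right")
    raise ValueError(f"unknown posture {posture!r}")


def default_side_cushion(grid: tuple[int, int] = DEFAULT_GRID) -> ObjectSpec:
    """A positioning cushion placed beside the patient's trunk and hip.

    Its relief (~7 mmHg) reflects its own light weight plus partial load
    transfer, spread over a large foam footprint.
    """
    rows, _ = grid
    return ObjectSpec(
        footprint=(int(0.30 * rows), int(0.75 * rows), 1, 8),
        relief=7.0,
        edge_softness=2.0,
    )


def default_leg_wedge(grid: tuple[int, int] = DEFAULT_GRID) -> ObjectSpec:
    """A leg-elevation wedge under the calves, spanning most of the width.

    Wedges sharing columns with strong body signal are only partially
    removable by trend decomposition (the method needs the body to dominate
    the line trend); this object is provided to exercise that limitation.
    """
    rows, cols = grid
    return ObjectSpec(
        footprint=(int(0.62 * rows), int(0.84 * rows), 3, cols - 3),
        relief=10.0,
        edge_softness=2.0,
    )


@dataclass
class SceneSpec:
    """Complete recipe for one synthetic scene.

    ``landmarks`` lists the high-risk peaks recorded in ground truth;
    ``support`` the broad silhouette components (part of the body layer but
    not tracked as landmarks); ``objects`` the external artefacts.
    """

    posture: str = "supine"
    landmarks: list[Landmark] = field(default_factory=list)
    support: list[Landmark] = field(default_factory=list)
    objects: list[ObjectSpec] = field(default_factory=list)
    noise_sd: float = 5.0  # mmHg
    seed: int = 0
    grid: tuple[int, int] = DEFAULT_GRID
    sensor_max: float = SENSOR_MAX
    # contact-mask contour: interface pressures above ~20 mmHg are the
    # clinically loaded region
    mask_level: float = 20.0

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        rows, cols = self.grid
        for lm in list(self.landmarks) + list(self.support):
            if not (0 <= lm.row < rows and 0 <= lm.col < cols):
                raise ValueError(f"landmark {lm.name!r} lies off the grid")
            if not 0 < lm.peak <= self.sensor_max:
                raise ValueError(f"landmark {lm.name!r} peak outside (0, max]")
            if lm.spread < 1:
                raise ValueError(f"landmark {lm.name!r} spread < 1 sensel")
        max_peak = max((lm.peak for lm in self.landmarks), default=self.sensor_max)
        for obj in self.objects:
            r0, r1, c0, c1 = obj.footprint
            if r1 - r0 < 4 or c1 - c0 < 4:
                raise ValueError("object footprint must span at least 4x4 sensels")
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError("object footprint outside the grid")
            if self.landmarks and obj.relief >= max_peak:
                raise ValueError("object relief must stay below landmark peaks")
            if obj.relief <= 0:
                raise ValueError("object relief must be positive")

    def with_seed(self, seed: int) -> "SceneSpec":
        return replace(self, seed=seed)


def default_scene_spec(
    posture: str = "supine",
    with_object: bool = False,
    noise_sd: float = 5.0,
    seed: int = 0,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> SceneSpec:
    """The standard study scene: default body, optional side cushion,
    5 mmHg sensor noise."""
    return SceneSpec(
        posture=posture,
        landmarks=default_landmarks(posture, grid),
        objects=[default_side_cushion(grid)] if with_object else [],
        noise_sd=noise_sd,
        seed=seed,
        grid=grid,
    )


@dataclass
class SceneGroundTruth:
    """Everything a test oracle needs about a generated scene."""

    body_mask: np.ndarray
    object_mask: np.ndarray
    landmarks: list[Landmark]
    posture: str
    body_values: np.ndarray  # noise-free body layer
    object_values: np.ndarray  # noise-free object layer
    object_under_body: bool = False

    @property
    def object_only_mask(self) -> np.ndarray:
        return self.object_mask & ~self.body_mask

    @property
    def clean_frame(self) -> PressureFrame:
        """Noise-free body-only frame (removal target)."""
        return PressureFrame(self.body_values.copy())


def _render_bump(grid: tuple[int, int], lm: Landmark) -> np.ndarray:
    rows, cols = grid
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    s_r = lm.spread
    s_c = lm.spread_col if lm.spread_col is not None else lm.spread
    return lm.peak * np.exp(
        -((r - lm.row) ** 2) / (2 * s_r**2) - ((c - lm.col) ** 2) / (2 * s_c**2)
    )


def _render_object(grid: tuple[int, int], obj: ObjectSpec) -> np.ndarray:
    base = np.zeros(grid)
    r0, r1, c0, c1 = obj.footprint
    base[r0:r1, c0:c1] = obj.relief
    if obj.edge_softness > 0:
        base = gaussian_filter(base, obj.edge_softness, mode="constant")
    return base


def generate_scene(spec: SceneSpec) -> tuple[PressureFrame, SceneGroundTruth]:
    """Render one scene: clip(body + objects + noise, 0, sensor_max)."""
    body = np.zeros(spec.grid)
    for lm in list(spec.landmarks) + list(spec.support):
        body += _render_bump(spec.grid, lm)
    objects = np.zeros(spec.grid)
    for obj in spec.objects:
        objects += _render_object(spec.grid, obj)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, spec.grid) if spec.noise_sd > 0 else 0.0
    values = np.clip(body + objects + noise, 0.0, spec.sensor_max)
    body_mask = body >= spec.mask_level
    # an object's mask outlines its own footprint even when its relief is
    # below the body contact level
    if spec.objects:
        obj_level = min(spec.mask_level, 0.5 * max(o.relief for o in spec.objects))
    else:
        obj_level = spec.mask_level
    object_mask = objects >= obj_level
    truth = SceneGroundTruth(
        body_mask=body_mask,
        object_mask=object_mask,
        landmarks=list(spec.landmarks),
        posture=spec.posture,
        body_values=body,
        object_values=objects,
        object_under_body=bool(np.any(body_mask & object_mask)),
    )
    return PressureFrame(values, sensor_max=spec.sensor_max), truth


def generate_sequence(
    spec: SceneSpec,
    n_frames: int,
    drift_sd: float = 0.0,
    sampling_hz: float = 1.0,
) -> tuple[PressureSequence, SceneGroundTruth]:
    """Static body observed over time: fresh noise per frame plus a slow
    random-walk drift of the global mean (``drift_sd`` mmHg per step)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    noiseless = replace(spec, noise_sd=0.0)
    base_frame, truth = generate_scene(noiseless)
    base = base_frame.values
    rng = np.random.default_rng(spec.seed)
    frames = []
    offset = 0.0
    step = 1.0 / sampling_hz
    for i in range(n_frames):
        if drift_sd > 0:
            offset += rng.normal(0.0, drift_sd)
        noise = (
            rng.normal(0.0, spec.noise_sd, spec.grid) if spec.noise_sd > 0 else 0.0
        )
        values = np.clip(base + offset + noise, 0.0, spec.sensor_max)
        frames.append(PressureFrame(values, i * step, spec.sensor_max))
    seq = PressureSequence(frames, sampling_hz, pose_id=spec.posture)
    return seq, truth


@dataclass(frozen=True)
class JitterSpec:
    """Spec-perturbation ranges for dataset generation.

    Subject-level jitter (consistent across a subject's frames) models
    morphology; frame-level noise models the sensor. All-zero jitter makes
    same-class frames identical.
    """

    position: float = 1.5  # sensels, per-landmark uniform jitter
    axis: float = 2.0  # sensels, whole-body column shift per subject
    peak_frac: float = 0.10  # relative peak jitter
    spread_frac: float = 0.15  # relative spread jitter
    noise_sd: float = 5.0  # mmHg per-frame sensor noise

    @classmethod
    def none(cls) -> "JitterSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class LabelledSample:
    frame: PressureFrame
    label: str
    subject_id: str


def _jitter_landmark(lm: Landmark, jit: JitterSpec, rng: np.random.Generator,
                     grid: tuple[int, int], dcol_axis: float) -> Landmark:
    rows, cols = grid
    row = lm.row + rng.uniform(-jit.position, jit.position)
    col = lm.col + dcol_axis + rng.uniform(-jit.position, jit.position)
    peak = lm.peak * (1 + rng.uniform(-jit.peak_frac, jit.peak_frac))
    spread = max(1.0, lm.spread * (1 + rng.uniform(-jit.spread_frac, jit.spread_frac)))
    return replace(
        lm,
        row=float(np.clip(row, 0, rows - 1)),
        col=float(np.clip(col, 0, cols - 1)),
        peak=float(np.clip(peak, 1.0, SENSOR_MAX)),
        spread=float(spread),
    )


def labelled_dataset(
    n_per_posture: int,
    jitter: JitterSpec | None = None,
    seed: int = 0,
    n_subjects: int = 10,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> list[LabelledSample]:
    """Balanced three-class dataset of single frames with subject structure.

    Each synthetic subject has a consistent morphology (axis shift, landmark
    jitter) applied to every posture; frames then differ only by sensor
    noise. Frames are distributed round-robin over subjects so each class
    has exactly ``n_per_posture`` samples.
    """
    if n_per_posture < 1:
        raise ValueError("n_per_posture must be >= 1")
    if jitter is None:
        jitter = JitterSpec()
    root = np.random.SeedSequence([int(seed), n_per_posture, n_subjects])
    subj_seeds = root.spawn(n_subjects)
    # subject morphologies
    morphs = []
    for s in range(n_subjects):
        rng = np.random.default_rng(subj_seeds[s])
        dax = rng.uniform(-jitter.axis, jitter.axis)
        per_posture = {}
        for posture in POSTURES:
            per_posture[posture] = [
                _jitter_landmark(lm, jitter, rng, grid, dax)
                for lm in default_landmarks(posture, grid)
            ]
        morphs.append(per_posture)
    samples: list[LabelledSample] = []
    frame_seeds = root.spawn(3 * n_per_posture)
    counter = 0
    for posture in POSTURES:
        for i in range(n_per_posture):
            s = i % n_subjects
            lms = morphs[s][posture]
            spec = SceneSpec(
                posture=posture,
                landmarks=lms,
                noise_sd=jitter.noise_sd,
                seed=int(frame_seeds[counter].generate_state(1)[0] % 2**31),
                grid=grid,
            )
            frame, _ = generate_scene(spec)
            samples.append(LabelledSample(frame, posture, f"S{s:02d}"))
            counter += 1
    return samples
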