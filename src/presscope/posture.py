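"""In-bed posture classification from HOG features.

Frames are cleaned/enhanced, upsampled, and described by a histogram of
oriented gradients (HOG); a conventional classifier (RBF-kernel SVM,
k-nearest-neighbour with k=10, or a random forest) separates supine from
left- and right-lateral lying. Features can be taken from the whole frame
or from the sacrum band only — the pelvis region that stays in contact
with the mat in all three postures.

The training protocol is subject-wise: 20% of subjects are held out for
testing (no subject appears on both sides), and the model report carries
a grouped k-fold cross-validation on the training portion (10 folds, or
one per subject when fewer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import hog as _sk_hog
from skimage.transform import rescale
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .enhance import enhance_chain
from .frames import PressureFrame

__all__ = [
    "HOGConfig",
    "PostureModel",
    "POSTURE_LABELS",
    "crop_sacrum",
    "extract_hog",
    "featurize_dataset",
    "train_posture_model",
    "predict_posture",
]

POSTURE_LABELS = ("supine", "left_lateral", "right_lateral")

#: fractional row band of the pelvis/sacrum crop
SACRUM_BAND = (0.45, 0.65)


@dataclass(frozen=True)
class HOGConfig:
    """HOG hyperparameters.

    ``upsample`` is an integer bicubic zoom applied before gradient
    extraction — pressure maps are low-resolution, and HOG cells need
    enough pixels to form stable orientation histograms.
    """

    orientations: int = 8
    cell: int = 8
    block: int = 2
    upsample: int = 4

    def __post_init__(self) -> None:
        if self.orientations < 2:
            raise ValueError("orientations must be >= 2")
        if min(self.cell, self.block, self.upsample) < 1:
            raise ValueError("cell, block and upsample must be >= 1")


def crop_sacrum(frame: PressureFrame) -> PressureFrame:
    """Fixed fractional pelvis band: rows [0.45R, 0.65R), all columns.

    Applying the crop twice re-applies the fractions to the crop (the
    operation is not idempotent by design).
    """
    rows = frame.shape[0]
    r0 = int(SACRUM_BAND[0] * rows)
    r1 = int(SACRUM_BAND[1] * rows)
    return frame.with_values(frame.values[r0:r1].copy())


def extract_hog(frame: PressureFrame, config: HOGConfig | None = None) -> np.ndarray:
    """HOG feature vector of one frame.

    Standard pipeline: bicubic upsampling, gradient orientation
    histograms per cell, L2 block normalization over overlapping blocks.
    A constant frame has zero gradients everywhere and maps to the zero
    vector. Feature length is fixed for fixed shape and config.
    """
    if config is None:
        config = HOGConfig()
    img = frame.values
    if config.upsample > 1:
        img = rescale(img, config.upsample, order=3, preserve_range=True)
    if min(img.shape) < config.cell:
        raise ValueError(
            f"frame {img.shape} smaller than one {config.cell}x{config.cell} cell"
        )
    return _sk_hog(
        img,
        orientations=config.orientations,
        pixels_per_cell=(config.cell, config.cell),
        cells_per_block=(config.block, config.block),
        block_norm="L2",
        feature_vector=True,
    )


@dataclass
class PostureModel:
    """A fitted posture classifier plus its training report."""

    model_type: str
    feature_scope: str
    hog_config: HOGConfig
    pipeline: Pipeline
    frame_shape: tuple[int, int]
    preprocess: bool
    report: dict = field(default_factory=dict)

    def features(self, frame: PressureFrame) -> np.ndarray:
        if frame.shape != self.frame_shape:
            raise ValueError(
                f"frame shape {frame.shape} differs from training shape "
                f"{self.frame_shape}"
            )
        return _featurize(
            frame, self.feature_scope, self.hog_config, self.preprocess
        )


def _featurize(
    frame: PressureFrame, scope: str, config: HOGConfig, preprocess: bool
) -> np.ndarray:
    if preprocess:
        frame = enhance_chain(frame)
    if scope == "sacrum":
        frame = crop_sacrum(frame)
    elif scope != "whole_body":
        raise ValueError(f"unknown feature scope {scope!r}")
    return extract_hog(frame, config)


def _make_estimator(model_type: str, seed: int) -> Pipeline:
    if model_type == "svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", random_state=seed)
        )
    if model_type == "knn":
        # HOG blocks are already contrast-normalized; standardizing the many
        # near-constant dimensions would let noise dominate the distances
        return make_pipeline(KNeighborsClassifier(n_neighbors=10))
    if model_type == "random_forest":
        return make_pipeline(
            RandomForestClassifier(n_estimators=100, random_state=seed)
        )
    raise ValueError(f"unknown model type {model_type!r}")


def subject_split(
    subjects: list[str], test_fraction: float, seed: int
) -> tuple[set[str], set[str]]:
    """Deterministic subject-wise train/test partition."""
    unique = sorted(set(subjects))
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    n_test = max(1, int(round(test_fraction * len(unique))))
    if n_test >= len(unique):
        raise ValueError("not enough subjects for a held-out split")
    return set(order[n_test:]), set(order[:n_test])


def featurize_dataset(
    dataset,
    feature_scope: str = "whole_body",
    hog_config: HOGConfig | None = None,
    preprocess: bool = True,
):
    """Features, labels, subject groups and frame shape for a dataset.

    Useful when several model types are trained on the same features.
    """
    if hog_config is None:
        hog_config = HOGConfig()
    records = [
        (s.frame, s.label, s.subject_id) if hasattr(s, "frame") else tuple(s)
        for s in dataset
    ]
    if not records:
        raise ValueError("empty dataset")
    frame_shape = records[0][0].shape
    feats = np.stack(
        [_featurize(f, feature_scope, hog_config, preprocess) for f, _, _ in records]
    )
    y = np.array([lbl for _, lbl, _ in records])
    groups = np.array([sid for _, _, sid in records])
    return feats, y, groups, frame_shape


def train_posture_model(
    dataset,
    model_type: str = "svm",
    feature_scope: str = "whole_body",
    hog_config: HOGConfig | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    cv_folds: int = 10,
    preprocess: bool = True,
    precomputed=None,
) -> PostureModel:
    """Fit a posture classifier with the subject-wise protocol.

    ``dataset`` is an iterable of (frame, label, subject_id) triples (the
    ``LabelledSample`` records from the synthetic generator work
    directly). ``precomputed`` may carry the output of
    :func:`featurize_dataset` to avoid re-extracting features. The report
    carries grouped CV accuracies on the training portion, overall and
    per-class held-out accuracy, and the split.
    """
    if hog_config is None:
        hog_config = HOGConfig()
    if precomputed is None:
        precomputed = featurize_dataset(dataset, feature_scope, hog_config, preprocess)
    feats, y, groups, frame_shape = precomputed
    labels = sorted(set(y))
    if len(labels) < 2:
        raise ValueError("training requires at least two posture classes")

    train_subj, test_subj = subject_split(list(groups), test_fraction, seed)
    tr = np.isin(groups, sorted(train_subj))
    te = ~tr

    est = _make_estimator(model_type, seed)
    n_train_subjects = len(set(groups[tr]))
    folds = min(cv_folds, n_train_subjects)
    if folds < cv_folds:
        warnings.warn(
            f"only {n_train_subjects} training subjects; "
            f"reducing CV folds from {cv_folds} to {folds}"
        )
    cv_scores = cross_val_score(
        est, feats[tr], y[tr], groups=groups[tr], cv=GroupKFold(n_splits=folds)
    )
    est.fit(feats[tr], y[tr])
    pred = est.predict(feats[te])
    per_class = {
        lbl: float(np.mean(pred[y[te] == lbl] == lbl))
        for lbl in labels
        if np.any(y[te] == lbl)
    }
    report = {
        "cv_scores": [float(s) for s in cv_scores],
        "cv_mean": float(np.mean(cv_scores)),
        "holdout_accuracy": float(np.mean(pred == y[te])),
        "holdout_per_class": per_class,
        "train_subjects": sorted(map(str, train_subj)),
        "test_subjects": sorted(map(str, test_subj)),
        "n_train": int(tr.sum()),
        "n_test": int(te.sum()),
    }
    return PostureModel(
        model_type=model_type,
        feature_scope=feature_scope,
        hog_config=hog_config,
        pipeline=est,
        frame_shape=frame_shape,
        preprocess=preprocess,
        report=report,
    )


def predict_posture(model: PostureModel, frame: PressureFrame) -> str:
    """Predict the posture label of one frame (deterministic per model)."""
    feats = model.features(frame).reshape(1, -1)
    return str(model.pipeline.predict(feats)[0])
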