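"""Random-forest pixel classification from sparse brushstroke annotations.

The estimator follows scikit-learn conventions: hyper-parameters are
constructor arguments, ``fit`` learns from data, fitted state lives in
trailing-underscore attributes, and ``get_params``/``set_params`` work for
model selection.  Supervision is sparse — only the annotated pixels are used
for training, mirroring the interactive brushstroke workflow — and every run
is seeded; an unseeded mode is deliberately not offered so that re-analysis of
the same images always reproduces the same segmentation.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .errors import DomainError, ModelIOError, TrainingError
from .features import FeatureConfig, compute_features
from .io import AnnotationMap, ClassTable, RasterImage, default_class_table

FORMAT_VERSION = "osteoseg-model-1"


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities, (H, W, K); rows sum to 1."""

    probs: np.ndarray
    class_table: ClassTable
    calibration_um: float

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 3 or p.shape[2] != len(self.class_table):
            raise DomainError(f"expected (H, W, {len(self.class_table)}) grid, got {p.shape}")
        if (p < -1e-12).any() or np.abs(p.sum(axis=2) - 1.0).max() > 1e-6:
            raise DomainError("probabilities must be non-negative and sum to 1 per pixel")
        self.probs = p


@dataclass
class SegmentationMap:
    """Dense per-pixel class assignment with inherited spatial calibration."""

    labels: np.ndarray  # (H, W) class ids, no zeros
    class_table: ClassTable
    calibration_um: float

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise DomainError(f"labels must be 2D, got shape {lab.shape}")
        present = set(np.unique(lab).tolist())
        if not present <= set(self.class_table.ids):
            raise DomainError(f"invalid class ids in segmentation: {sorted(present - set(self.class_table.ids))}")
        if not self.calibration_um > 0:
            raise DomainError("calibration must be positive")
        self.labels = lab.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def segment(probs: ProbabilityMap) -> SegmentationMap:
    """Per-pixel argmax; ties break toward the lowest class id."""
    idx = np.argmax(probs.probs, axis=2)  # first maximum, i.e. lowest id on ties
    ids = np.asarray(probs.class_table.ids, dtype=np.uint8)
    return SegmentationMap(ids[idx], probs.class_table, probs.calibration_um)


class PixelClassifier(BaseEstimator, ClassifierMixin):
    """Four-class pixel classifier for TRAP-stained osteoclast micrographs.

    Parameters
    ----------
    feature_config : FeatureConfig, optional
        Multi-scale feature bank specification; defaults to the full bank
        (six filter groups at seven scales on all three colour channels).
    n_trees : int, default 100
        Forest size; trees are grown to purity with gini splits and √F
        candidate features per split.
    random_state : int, default 0
        Seed for forest construction; recorded in the model manifest.
    class_table : ClassTable, optional
        Semantic classes; defaults to dentine / pre-osteoclast / resorption /
        osteoclast.

    Attributes
    ----------
    forest_ : RandomForestClassifier
    mean_, scale_ : ndarray of shape (F,)
        Per-feature training-set standardisation (constant features get
        scale 1).
    manifest_ : dict
        Version, seed, per-class training-pixel counts, feature config.
    """

    def __init__(self, feature_config=None, n_trees=100, random_state=0, class_table=None):
        self.feature_config = feature_config
        self.n_trees = n_trees
        self.random_state = random_state
        self.class_table = class_table

    # -- helpers -------------------------------------------------------
    def _config(self) -> FeatureConfig:
        return self.feature_config if self.feature_config is not None else FeatureConfig()

    def _classes(self) -> ClassTable:
        return self.class_table if self.class_table is not None else default_class_table()

    # -- estimator API -------------------------------------------------
    def fit(self, images, annotations):
        """Train from sparse annotations on one or more images.

        ``images`` and ``annotations`` are equal-length sequences of
        :class:`RasterImage` and :class:`AnnotationMap`; only non-zero
        annotation pixels contribute training samples.
        """
        images = list(images)
        annotations = list(annotations)
        if len(images) != len(annotations) or not images:
            raise DomainError("images and annotations must be equal-length, non-empty lists")
        table = self._classes()
        config = self._config()
        if int(self.n_trees) < 1:
            raise DomainError("n_trees must be positive")

        X_parts, y_parts = [], []
        counts = {cid: 0 for cid in table.ids}
        for img, ann in zip(images, annotations):
            if img.shape != ann.labels.shape:
                raise DomainError(
                    f"annotation shape {ann.labels.shape} does not match image shape {img.shape}"
                )
            mask = ann.labels > 0
            if not mask.any():
                continue
            stack = compute_features(img, config)
            X_parts.append(stack.values[mask])
            y_parts.append(ann.labels[mask].astype(np.int64))
            for cid in table.ids:
                counts[cid] += int(np.sum(ann.labels == cid))
        for cid, n in counts.items():
            if n == 0:
                raise TrainingError(f"class {table.name_of(cid)!r} has no annotations")

        X = np.concatenate(X_parts, axis=0)
        y = np.concatenate(y_parts, axis=0)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xz = (X - self.mean_) / self.scale_

        self.forest_ = RandomForestClassifier(
            n_estimators=int(self.n_trees),
            criterion="gini",
            max_features="sqrt",
            random_state=int(self.random_state),
            n_jobs=1,
        )
        self.forest_.fit(Xz, y)
        self.classes_ = self.forest_.classes_
        self.class_table_ = table
        self.feature_config_ = config
        self.manifest_ = {
            "format": FORMAT_VERSION,
            "seed": int(self.random_state),
            "n_trees": int(self.n_trees),
            "training_pixels_per_class": {table.name_of(c): counts[c] for c in table.ids},
            "feature_config": json.loads(config.to_json()),
            "classes": [
                {"id": e.id, "name": e.name, "display_colour": list(e.display_colour)}
                for e in table
            ],
        }
        return self

    def _check_fitted(self):
        if not hasattr(self, "forest_"):
            raise DomainError("classifier is not fitted")

    def predict_proba(self, image: RasterImage) -> ProbabilityMap:
        """Per-pixel class probabilities for one image (pure function of model and image)."""
        self._check_fitted()
        if not isinstance(image, RasterImage):
            raise DomainError("expected a RasterImage")
        stack = compute_features(image, self.feature_config_)
        h, w, _ = stack.values.shape
        Xz = (stack.as_matrix() - self.mean_) / self.scale_
        probs = self.forest_.predict_proba(Xz).reshape(h, w, len(self.class_table_))
        return ProbabilityMap(probs, self.class_table_, image.calibration_um)

    def predict(self, image: RasterImage) -> SegmentationMap:
        """Dense argmax segmentation of one image."""
        return segment(self.predict_proba(image))

    # -- persistence ---------------------------------------------------
    def save(self, path: str) -> str:
        """Persist as a single-file archive: forest blob + JSON manifest."""
        self._check_fitted()
        blob = _io.BytesIO()
        joblib.dump({"forest": self.forest_, "mean": self.mean_, "scale": self.scale_}, blob)
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("manifest.json", json.dumps(self.manifest_, sort_keys=True, indent=1))
            zf.writestr("forest.joblib", blob.getvalue())
        return path

    @classmethod
    def load(cls, path: str) -> "PixelClassifier":
        try:
            with zipfile.ZipFile(path, "r") as zf:
                manifest = json.loads(zf.read("manifest.json"))
                blob = zf.read("forest.joblib")
        except (zipfile.BadZipFile, KeyError, OSError, json.JSONDecodeError) as exc:
            raise ModelIOError(f"cannot load model from {path}: {exc}") from exc
        version = manifest.get("format")
        if version != FORMAT_VERSION:
            raise ModelIOError(f"unsupported model format {version!r} (expected {FORMAT_VERSION})")
        try:
            payload = joblib.load(_io.BytesIO(blob))
        except Exception as exc:
            raise ModelIOError(f"corrupt forest payload in {path}: {exc}") from exc
        from .io import ClassEntry  # local import to avoid cycle at module load

        table = ClassTable(
            tuple(
                ClassEntry(c["id"], c["name"], tuple(c["display_colour"]))
                for c in manifest["classes"]
            )
        )
        config = FeatureConfig(
            tuple(manifest["feature_config"]["scales"]),
            tuple(manifest["feature_config"]["groups"]),
            manifest["feature_config"]["channel_policy"],
        )
        model = cls(
            feature_config=config,
            n_trees=manifest["n_trees"],
            random_state=manifest["seed"],
            class_table=table,
        )
        model.forest_ = payload["forest"]
        model.mean_ = payload["mean"]
        model.scale_ = payload["scale"]
        model.classes_ = model.forest_.classes_
        model.class_table_ = table
        model.feature_config_ = config
        model.manifest_ = manifest
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers


def train(images, annotations, config=None, n_trees=100, seed=0) -> PixelClassifier:
    """Train a :class:`PixelClassifier` (functional form)."""
    return PixelClassifier(
        feature_config=config, n_trees=n_trees, random_state=seed
    ).fit(images, annotations)


def predict_probabilities(model: PixelClassifier, image: RasterImage) -> ProbabilityMap:
    return model.predict_proba(image)


def save_model(model: PixelClassifier, path: str) -> str:
    return model.save(path)


def load_model(path: str) -> PixelClassifier:
    return PixelClassifier.load(path)
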