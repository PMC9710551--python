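"""Feature assembly, PCA + RBF-SVM training, calibration and prediction.

The classifier pipeline is: optional standardization -> PCA (fitted on
training rows only, default 2400 components) -> RBF-kernel SVM. The raw SVM
decision score drives the class call (pathogenic iff score >= 0); an
isotonic regression fitted on pooled out-of-fold scores maps scores to a
calibrated pathogenicity probability, from which an integer reliability
index in 0..10 is derived as round(20 * |p - 0.5|).
"""

from __future__ import annotations

import hashlib
import io
import json
import math
import zipfile
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.isotonic import IsotonicRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from savpath.embeddings import PositionalEncoding
from savpath.go_encoding import FunctionEncoding
from savpath.variant_data import Label, VariantRecord

MODEL_FORMAT_VERSION = 1
DEFAULT_PCA_COMPONENTS = 2400


@dataclass
class FeatureVector:
    """One variant's full encoding: positional blocks then function blocks."""

    values: np.ndarray
    layout: list[tuple[str, int]]

    def __len__(self) -> int:
        return self.values.shape[0]

    def block(self, name: str) -> np.ndarray:
        offset = 0
        for block_name, length in self.layout:
            if block_name == name:
                return self.values[offset : offset + length]
            offset += length
        raise KeyError(name)


def layout_checksum(layout: Sequence[tuple[str, int]]) -> str:
    return hashlib.sha256(repr([tuple(b) for b in layout]).encode()).hexdigest()[:16]


def assemble_features(pos: PositionalEncoding, func: FunctionEncoding) -> FeatureVector:
    """Concatenate positional and function encodings into one vector.

    Non-finite values are rejected with an error naming the offending block.
    """
    for name, block in [("positional", pos.values), ("function", func.values)]:
        if not np.all(np.isfinite(block)):
            raise ValueError(f"non-finite values in {name} encoding block")
    layout = list(pos.layout) + [
        (f"go_{ns}", func.block_dim) for ns in ("MF", "CC", "BP")
    ]
    return FeatureVector(
        values=np.concatenate([pos.values, func.values]), layout=layout
    )


@dataclass
class PipelineConfig:
    pca_components: int = DEFAULT_PCA_COMPONENTS
    svm_C: float = 10.0
    svm_gamma: float | str = "scale"
    decision_threshold: float = 0.0
    standardize: bool = True
    class_weight: str | None = None  # None or "balanced"
    seed: int = 0
    grid_pca_components: tuple[int, ...] = (1200, 2400)
    grid_C: tuple[float, ...] = (1.0, 10.0, 100.0)
    grid_gamma: tuple[float | str, ...] = ("scale", 1e-3, 1e-4)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("grid_pca_components", "grid_C", "grid_gamma"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def fit_pca(X: np.ndarray, n_components: int) -> PCA:
    """Centred PCA projecting to min(n_components, n_samples, n_features)."""
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    effective = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=effective, svd_solver="full")
    pca.fit(X)
    return pca


def reliability_index(p: float) -> int:
    """RI = round(20 * |p - 0.5|), half away from zero; 0 at p=0.5, 10 at p in {0,1}."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability {p} outside [0, 1]")
    return int(math.floor(20.0 * abs(p - 0.5) + 0.5))


@dataclass
class Prediction:
    variant: VariantRecord | None
    score: float
    probability: float
    label: Label
    reliability_index: int


def _labels_to_binary(y: Sequence[Label]) -> np.ndarray:
    return np.array([1 if label is Label.PLP else 0 for label in y], dtype=int)


class _FittedStages:
    """Scaler (optional) + PCA + SVC fitted on one training split."""

    def __init__(self, config: PipelineConfig, X: np.ndarray, y01: np.ndarray) -> None:
        if len(np.unique(y01)) < 2:
            raise ValueError("training data contains a single class")
        self.scaler = None
        Xt = X
        if config.standardize:
            self.scaler = StandardScaler()
            Xt = self.scaler.fit_transform(X)
        self.pca = fit_pca(Xt, config.pca_components)
        Z = self.pca.transform(Xt)
        self.svc = SVC(
            kernel="rbf",
            C=config.svm_C,
            gamma=config.svm_gamma,
            class_weight=config.class_weight,
            random_state=config.seed,
        )
        self.svc.fit(Z, y01)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Xt = self.scaler.transform(X) if self.scaler is not None else X
        return self.svc.decision_function(self.pca.transform(Xt))


@dataclass
class TrainedPipeline:
    """Deployable model: fitted stages + calibrator + configuration."""

    stages: _FittedStages
    calibrator: IsotonicRegression
    config: PipelineConfig
    feature_layout: list[tuple[str, int]]

    @property
    def n_features(self) -> int:
        return sum(length for _, length in self.feature_layout)

    @property
    def projected_dim(self) -> int:
        return self.stages.pca.n_components_

    def _check_width(self, X: np.ndarray) -> None:
        if X.shape[-1] != self.n_features:
            raise ValueError(
                f"feature length mismatch: pipeline expects {self.n_features}, "
                f"received {X.shape[-1]}"
            )

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_width(X)
        return self.stages.decision_scores(X)

    def predict_batch(
        self, X: np.ndarray, variants: Sequence[VariantRecord] | None = None
    ) -> list[Prediction]:
        scores = self.decision_scores(X)
        probs = np.clip(self.calibrator.predict(scores), 0.0, 1.0)
        out = []
        for i, (s, p) in enumerate(zip(scores, probs)):
            label = Label.PLP if s >= self.config.decision_threshold else Label.BLB
            out.append(
                Prediction(
                    variant=variants[i] if variants is not None else None,
                    score=float(s),
                    probability=float(p),
                    label=label,
                    reliability_index=reliability_index(float(p)),
                )
            )
        return out

    def predict_one(self, fv: FeatureVector, variant: VariantRecord | None = None) -> Prediction:
        pred = self.predict_batch(fv.values[None, :], [variant] if variant else None)[0]
        return pred

    # -- persistence: zip archive of a joblib payload + plain-text manifest --

    def save(self, path: str | Path) -> None:
        payload = io.BytesIO()
        joblib.dump(
            {
                "scaler": self.stages.scaler,
                "pca": self.stages.pca,
                "svc": self.stages.svc,
                "calibrator": self.calibrator,
            },
            payload,
        )
        manifest = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": self.config.to_dict(),
            "feature_layout": [list(b) for b in self.feature_layout],
            "layout_checksum": layout_checksum(self.feature_layout),
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            info = zipfile.ZipInfo("manifest.json", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, json.dumps(manifest, indent=2, sort_keys=True))
            info = zipfile.ZipInfo("model.joblib", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, payload.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPipeline":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest["format_version"] != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model format version {manifest['format_version']}"
                )
            layout = [tuple(b) for b in manifest["feature_layout"]]
            if layout_checksum(layout) != manifest["layout_checksum"]:
                raise ValueError("feature-layout checksum mismatch in model archive")
            parts = joblib.load(io.BytesIO(zf.read("model.joblib")))
        config = PipelineConfig.from_dict(manifest["config"])
        stages = _FittedStages.__new__(_FittedStages)
        stages.scaler = parts["scaler"]
        stages.pca = parts["pca"]
        stages.svc = parts["svc"]
        return cls(
            stages=stages,
            calibrator=parts["calibrator"],
            config=config,
            feature_layout=layout,
        )


def _fold_indices(fold_ids: Sequence[str]) -> dict[str, np.ndarray]:
    folds: dict[str, list[int]] = {}
    for i, f in enumerate(fold_ids):
        folds.setdefault(f, []).append(i)
    return {f: np.array(idx) for f, idx in folds.items()}


def grid_search_cv(
    X: np.ndarray,
    y: Sequence[Label],
    fold_ids: Sequence[str],
    config: PipelineConfig,
) -> tuple[PipelineConfig, list[dict]]:
    """Grid search over (pca_components, C, gamma) by mean validation MCC.

    For every grid point and every fold, the scaler and PCA are refitted on
    the fold's training part only. Ties break toward smaller pca_components,
    then smaller C, then grid order of gamma.
    """
    from savpath.evaluation import confusion, metrics  # local import to avoid cycle

    folds = _fold_indices(fold_ids)
    if len(folds) < 2:
        raise ValueError("grid search needs at least 2 folds")
    grid = [
        (n, C, gamma)
        for n in config.grid_pca_components
        for C in config.grid_C
        for gamma in config.grid_gamma
    ]
    if not grid:
        raise ValueError("empty hyperparameter grid")

    y01 = _labels_to_binary(y)
    results = []
    for gi, (n_comp, C, gamma) in enumerate(grid):
        point = replace(config, pca_components=n_comp, svm_C=C, svm_gamma=gamma)
        fold_mccs = []
        for fold, val_idx in folds.items():
            train_idx = np.concatenate([idx for f, idx in folds.items() if f != fold])
            stages = _FittedStages(point, X[train_idx], y01[train_idx])
            scores = stages.decision_scores(X[val_idx])
            pred = [Label.PLP if s >= point.decision_threshold else Label.BLB for s in scores]
            true = [y[i] for i in val_idx]
            m = metrics(confusion(true, pred))
            if m.mcc is not None:
                fold_mccs.append(m.mcc)
        mean_mcc = float(np.mean(fold_mccs)) if fold_mccs else float("-inf")
        results.append(
            {
                "pca_components": n_comp,
                "svm_C": C,
                "svm_gamma": gamma,
                "mean_mcc": mean_mcc,
                "grid_index": gi,
            }
        )
    best = max(
        results,
        key=lambda r: (
            r["mean_mcc"],
            -r["pca_components"],
            -r["svm_C"],
            -r["grid_index"],
        ),
    )
    best_config = replace(
        config,
        pca_components=best["pca_components"],
        svm_C=best["svm_C"],
        svm_gamma=best["svm_gamma"],
    )
    return best_config, results


def train(
    X: np.ndarray,
    y: Sequence[Label],
    fold_ids: Sequence[str],
    config: PipelineConfig,
    feature_layout: Sequence[tuple[str, int]] | None = None,
) -> TrainedPipeline:
    """Fit the final pipeline on all rows and calibrate on out-of-fold scores.

    Each fold is scored by stages trained on the remaining folds; the pooled
    out-of-fold (score, binary label) pairs fit one isotonic calibrator,
    clipped to [0, 1] and clamping out-of-range scores to boundary values.
    """
    X = np.asarray(X, dtype=float)
    y01 = _labels_to_binary(y)
    if len(np.unique(y01)) < 2:
        raise ValueError("training data contains a single class")
    folds = _fold_indices(fold_ids)
    if len(folds) < 2:
        raise ValueError("calibration-in-cross-validation needs at least 2 folds")

    oof_scores = np.empty(X.shape[0])
    for fold, val_idx in folds.items():
        train_idx = np.concatenate([idx for f, idx in folds.items() if f != fold])
        stages = _FittedStages(config, X[train_idx], y01[train_idx])
        oof_scores[val_idx] = stages.decision_scores(X[val_idx])

    calibrator = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    calibrator.fit(oof_scores, y01)

    final_stages = _FittedStages(config, X, y01)
    if feature_layout is None:
        feature_layout = [("features", X.shape[1])]
    return TrainedPipeline(
        stages=final_stages,
        calibrator=calibrator,
        config=config,
        feature_layout=list(feature_layout),
    )
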