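"""Trimap generation and two-stage self-training over a pluggable backend.

Pseudo masks carry label noise. The two-stage scheme distills them: a
stage-one model is trained on the pseudo masks; its own predictions on the
training set are XOR-ed against the pseudo masks to build a trimap whose
disagreement pixels are marked IGNORE; a stage-two model — warm-started
from stage one — is then trained with the IGNORE pixels excluded from the
loss, so only label pixels both sources agree on supervise the second pass.

The deep segmentation networks this scheme normally drives are an
extension point behind the ``SegmentationBackend`` protocol; the shipped
``ToyPixelBackend`` is a per-pixel logistic classifier over depth-derived
features, sufficient to exercise the orchestration end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import scipy.ndimage as ndi

from .errors import DimensionError, ParameterError
from .imgio import IGNORE, validate_mask
from .metrics import iou
from .thresholding import normalize_depth

__all__ = [
    "make_trimap",
    "SegmentationBackend",
    "ToyPixelBackend",
    "ToyState",
    "TrainingReport",
    "two_stage_train",
]


def make_trimap(pseudo: np.ndarray, inferred: np.ndarray) -> np.ndarray:
    """Ternary stage-two label: IGNORE where the two masks disagree.

    Where pseudo and inferred masks agree the pseudo label is kept; where
    they disagree (elementwise XOR) the pixel is marked IGNORE. The IGNORE
    count therefore equals the Hamming distance between the masks.
    """
    pseudo = validate_mask(pseudo)
    inferred = validate_mask(inferred)
    if pseudo.shape != inferred.shape:
        raise DimensionError(f"shape mismatch {pseudo.shape} vs {inferred.shape}")
    out = pseudo.copy()
    out[pseudo != inferred] = IGNORE
    return out


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract a trainer must satisfy to drive the two-stage loop.

    ``fit`` consumes (features, label) pairs where labels may be binary
    masks or trimaps — IGNORE pixels must be excluded from the loss — and
    an optional warm start state. ``predict`` must be deterministic given
    a state and features.
    """

    def fit(self, samples: Sequence[tuple[np.ndarray, np.ndarray]],
            warm_start: object | None = None) -> object: ...

    def predict(self, state: object, features: np.ndarray) -> np.ndarray: ...

    @property
    def supports_warm_start(self) -> bool: ...


def depth_features(depth: np.ndarray) -> np.ndarray:
    """Per-pixel features of a depth map: intensity, normalized depth, local mean.

    Returns an HxWx3 stack scaled to [0, 1]-ish ranges; this is what the
    toy backend consumes in place of RGB imagery.
    """
    depth = np.asarray(depth, dtype=float)
    dn = normalize_depth(depth)
    local = ndi.uniform_filter(depth, size=9, mode="reflect")
    return np.stack([depth / 255.0, dn / 255.0, local / 255.0], axis=-1)


@dataclass(frozen=True)
class ToyState:
    """Trained state of the toy backend: logistic weights and intercept."""

    weights: np.ndarray
    bias: float

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "bias": self.bias}

    @classmethod
    def from_dict(cls, d: dict) -> "ToyState":
        return cls(weights=np.asarray(d["weights"], dtype=float), bias=float(d["bias"]))


@dataclass
class ToyPixelBackend:
    """Per-pixel logistic classifier over depth-derived features.

    A deliberately small stand-in for a segmentation network: each pixel is
    classified independently by a logistic model trained with a fixed
    budget of full-batch gradient-descent epochs. IGNORE-labeled pixels are
    dropped from the loss; warm starting continues descent from the given
    state. Training is deterministic (zero initialization, fixed epoch
    count), so identical inputs give identical states.
    """

    learning_rate: float = 2.0
    epochs: int = 150
    l2: float = 1e-4
    seed: int = 0

    @property
    def supports_warm_start(self) -> bool:
        return True

    def _stack(
        self, samples: Sequence[tuple[np.ndarray, np.ndarray]]
    ) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for feats, label in samples:
            label = np.asarray(label)
            keep = label != IGNORE
            xs.append(np.asarray(feats, dtype=float)[keep])
            ys.append(label[keep].astype(float))
        x = np.concatenate(xs, axis=0)
        y = np.concatenate(ys, axis=0)
        if x.size == 0:
            raise ParameterError("no labeled (non-IGNORE) pixels to fit on")
        return x, y

    def fit(
        self,
        samples: Sequence[tuple[np.ndarray, np.ndarray]],
        warm_start: ToyState | None = None,
    ) -> ToyState:
        if len(samples) == 0:
            raise ParameterError("need at least one training sample")
        x, y = self._stack(samples)
        if np.unique(y).size < 2:
            raise ParameterError("training labels are single-class; cannot fit")
        w = np.zeros(x.shape[1]) if warm_start is None else warm_start.weights.copy()
        b = 0.0 if warm_start is None else warm_start.bias
        n = y.size
        for _ in range(self.epochs):
            z = np.clip(x @ w + b, -500, 500)
            grad = 1.0 / (1.0 + np.exp(-z)) - y
            w -= self.learning_rate * (x.T @ grad / n + self.l2 * w)
            b -= self.learning_rate * float(grad.mean())
        return ToyState(weights=w, bias=b)

    def predict(self, state: ToyState, features: np.ndarray) -> np.ndarray:
        feats = np.asarray(features, dtype=float)
        flat = feats.reshape(-1, feats.shape[-1])
        pred = (flat @ state.weights + state.bias) > 0
        return pred.reshape(feats.shape[:2]).astype(np.uint8)


@dataclass
class TrainingReport:
    """Per-stage diagnostics of one two-stage run."""

    ignore_fraction: list[float] = field(default_factory=list)
    stage1_iou: list[float] = field(default_factory=list)
    stage2_iou: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d: dict = {"ignore_fraction": self.ignore_fraction}
        if self.stage1_iou:
            d["stage1_iou"] = self.stage1_iou
            d["stage1_mean_iou"] = float(np.mean(self.stage1_iou))
        if self.stage2_iou:
            d["stage2_iou"] = self.stage2_iou
            d["stage2_mean_iou"] = float(np.mean(self.stage2_iou))
        return d


def two_stage_train(
    backend: SegmentationBackend,
    samples: Sequence[tuple[np.ndarray, np.ndarray]],
    ground_truth: Sequence[np.ndarray] | None = None,
) -> tuple[object, object, TrainingReport]:
    """Run the two-stage self-training loop over (features, pseudo mask) pairs.

    Stage one fits on the pseudo masks; each sample's stage-one prediction
    and pseudo mask are merged into a trimap; stage two fits on the trimaps
    with IGNORE honored, warm-started from the stage-one state (backends
    without warm-start support are rejected). When ground-truth masks are
    supplied, both stages' per-sample training IoU is recorded.
    """
    if len(samples) == 0:
        raise ParameterError("need at least one training sample")
    if not backend.supports_warm_start:
        raise ParameterError("backend must support warm start for stage two")

    try:
        stage1 = backend.fit(samples)
    except Exception as exc:
        raise type(exc)(f"stage-one training failed: {exc}") from exc

    report = TrainingReport()
    trimap_samples = []
    for feats, pseudo in samples:
        inferred = backend.predict(stage1, feats)
        trimap = make_trimap(pseudo, inferred)
        report.ignore_fraction.append(float((trimap == IGNORE).mean()))
        trimap_samples.append((feats, trimap))

    try:
        stage2 = backend.fit(trimap_samples, warm_start=stage1)
    except Exception as exc:
        raise type(exc)(f"stage-two training failed: {exc}") from exc

    if ground_truth is not None:
        for (feats, _), gt in zip(samples, ground_truth):
            report.stage1_iou.append(iou(backend.predict(stage1, feats), gt))
            report.stage2_iou.append(iou(backend.predict(stage2, feats), gt))
    return stage1, stage2, report
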