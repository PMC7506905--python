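"""Probabilistic-classifier backends for the active-learning loop.

Three things live here:

* :class:`ArchitectureSpec` / :func:`build_default_spec` — the buildable
  description of the residual network used for hyperspectral cubes: a first
  channel-mixing convolution, 27 residual blocks (three stages of nine,
  16/32/64 filters, stride-2 at stage boundaries — the canonical small-image
  residual layout), global average pooling and a softmax head, ReLU
  activations with batch normalization before each activation, cross-entropy
  loss and a momentum optimizer.

* :class:`ReferenceClassifier` — a deterministic nearest-prototype model
  on spatial-spectral features.  Fast enough for CPU-only tests and
  end-to-end experiments, it implements the exact same fit/predict
  contract as any network backend, so the loop is backend-agnostic.

* :class:`ScriptedClassifier` — a backend that replays fixed probability
  tables.  It trains nothing and exists so set bookkeeping, cost ledgers
  and schedules can be tested in isolation from any learning.

The feature used by the reference classifier deserves a note.  Per-image
per-channel standardization fixes every channel's spatial mean to 0 and
variance to 1, so marginal channel statistics carry no class signal on
preprocessed cubes.  What survives is spatial-spectral structure: which
spatial patterns the channels share and how each channel expresses them.
The feature therefore has three blocks:

1. *common-pattern loadings* — the projection of each channel onto the
   image's centered, unit-norm cross-channel mean map m0 (on raw cubes
   this reduces to a scaled mean transmittance spectrum);
2. *residual covariance* — after removing the common pattern from every
   channel, the channel-by-channel second-moment matrix of the residual,
   trace-normalized.  This is a region-covariance descriptor: a localized
   region whose spectral contrast differs between classes shows up as a
   class-specific rank-one component, with no sign ambiguity;
3. *orientation probe* — the projection of each channel onto one fixed
   spatially asymmetric template.  Deterministic feature maps built
   covariantly from the image alone are exactly invariant under the
   flip/rotation augmentations, which would make all augmented variants
   of a sample perfectly tied in every certainty ranking; a trained
   network has no such exact symmetry.  This small block breaks the tie
   the way a network's asymmetry would, without informing the class
   decision.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .acquisition import PredictionMatrix
from .hypercube_io import HyperCube, ValidationError

__all__ = [
    "ArchitectureSpec",
    "build_default_spec",
    "ClassifierState",
    "ReferenceClassifier",
    "ScriptedClassifier",
    "BACKENDS",
    "save_state",
    "load_state",
]


# ---------------------------------------------------------------------------
# Residual-network architecture description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the residual network.

    ``stages`` is a tuple of (blocks, filters) pairs; the residual-block
    count is their sum.  Batch normalization is placed before each ReLU
    activation; the head is global average pooling followed by a fully
    connected softmax layer of width ``n_classes``.
    """

    input_size: int = 32
    input_channels: int = 71
    n_classes: int = 2
    first_conv_filters: int = 16
    stages: tuple[tuple[int, int], ...] = ((9, 16), (9, 32), (9, 64))
    stage_stride: int = 2
    activation: str = "relu"
    batch_norm: str = "pre_activation"
    head: str = "global_average_pool+fc_softmax"
    loss: str = "cross_entropy"
    optimizer: str = "momentum"
    momentum: float = 0.9
    learning_rate: float = 0.1
    batch_size: int = 32
    epochs_per_iteration: int = 10

    def __post_init__(self) -> None:
        if self.input_channels < 1 or self.n_classes < 1:
            raise ValidationError("input_channels and n_classes must be >= 1")
        if self.n_residual_blocks < 1:
            raise ValidationError("need at least one residual block")

    @property
    def n_residual_blocks(self) -> int:
        return sum(b for b, _ in self.stages)

    @property
    def softmax_width(self) -> int:
        return self.n_classes


def build_default_spec(input_channels: int = 71, classes: int = 2) -> ArchitectureSpec:
    """Default 27-residual-block spec for 32x32 multichannel inputs."""
    return ArchitectureSpec(input_channels=input_channels, n_classes=classes)


# ---------------------------------------------------------------------------
# Classifier state and backends
# ---------------------------------------------------------------------------


@dataclass
class ClassifierState:
    """Opaque trained parameters plus shape metadata.

    ``params`` is backend-specific; prediction from a fixed state is
    deterministic.  ``n_fit_calls`` counts fine-tuning rounds.
    """

    backend: str
    n_classes: int
    params: dict = field(default_factory=dict)
    input_shape: tuple[int, int, int] | None = None
    n_fit_calls: int = 0


def _cube_array(cube) -> np.ndarray:
    return cube.pixels if isinstance(cube, HyperCube) else np.asarray(cube)


def _cube_id(cube, fallback: int) -> str:
    return cube.sample_id if isinstance(cube, HyperCube) else str(fallback)


class ReferenceClassifier:
    """Deterministic nearest-prototype classifier on spatial-spectral
    features (see the module docstring for the feature blocks).

    Fit computes per-class prototype feature vectors and a within-class
    scatter scale.  Fine-tuning a network to convergence makes it fit the
    *current* training set, with earlier weights surviving only where the
    new data is silent; the prototype analogue implemented here is that a
    warm-started fit recomputes the prototype of every class present in
    the batch and keeps the previous prototype only for classes the batch
    lacks.  Prediction is a softmax over negative squared prototype
    distances divided by the scatter scale; ``temperature`` rescales the
    logits and never changes the per-sample class ranking.

    ``logit_jitter`` adds a small, *content-keyed* deterministic
    perturbation to the logits (a fixed pseudo-random draw seeded from the
    feature bytes).  A network trained by SGD gives slightly different
    posteriors to the augmented variants of one sample; an exactly
    symmetric prototype model gives them identical posteriors, which would
    leave every certainty ranking tied within augmentation groups.  The
    jitter reproduces the network's tie-breaking behaviour while staying
    bit-reproducible: the same cube always receives the same perturbation,
    independent of batch order or classifier state.
    """

    name = "reference"

    # relative weights of the three feature blocks
    _W_COMMON = 0.3
    _W_COV = 2.0
    _W_ORIENT = 0.3

    def __init__(self, temperature: float = 1.0, logit_jitter: float = 0.05):
        if temperature <= 0:
            raise ValidationError("temperature must be positive")
        if logit_jitter < 0:
            raise ValidationError("logit_jitter must be >= 0")
        self.temperature = float(temperature)
        self.logit_jitter = float(logit_jitter)

    # -- features ---------------------------------------------------------
    @staticmethod
    def _orientation_template(h: int, w: int) -> np.ndarray:
        # fixed asymmetric pattern; distinct under every flip/rotation
        yy = np.linspace(-1.0, 1.0, h)[:, None] * np.ones((1, w))
        xx = np.ones((h, 1)) * np.linspace(-1.0, 1.0, w)[None, :]
        t = xx + 0.5 * yy + 0.25 * xx * yy
        t -= t.mean()
        return t / np.sqrt((t * t).sum())

    @classmethod
    def features(cls, cube) -> np.ndarray:
        x = _cube_array(cube).astype(np.float64)
        h, w, c = x.shape
        scale = np.sqrt(h * w)
        m = x.mean(axis=2)
        m0 = m - m.mean()
        nrm = np.sqrt((m0 * m0).sum())
        if nrm < 1e-12:
            # spatially flat image: only the mean spectrum is informative
            return np.concatenate(
                [cls._W_COMMON * x.mean(axis=(0, 1)), np.zeros(c * c), np.zeros(c)]
            )
        m0 /= nrm
        common = np.tensordot(x, m0, axes=([0, 1], [0, 1]))
        resid = (x - m0[:, :, None] * common[None, None, :]).reshape(-1, c)
        cov = (resid.T @ resid) / (h * w)
        tr = np.trace(cov)
        if tr > 1e-12:
            cov = cov / tr
        orient = np.tensordot(x, cls._orientation_template(h, w), axes=([0, 1], [0, 1]))
        return np.concatenate(
            [
                cls._W_COMMON * common / scale,
                cls._W_COV * cov.reshape(-1),
                cls._W_ORIENT * orient / scale,
            ]
        )

    def _feature_matrix(self, cubes: Sequence) -> np.ndarray:
        return np.stack([self.features(c) for c in cubes])

    # -- fit --------------------------------------------------------------
    def fit(
        self,
        cubes: Sequence,
        labels: Sequence[int],
        state: ClassifierState | None = None,
        warm_start: bool = False,
        n_classes: int | None = None,
        seed: int = 0,
    ) -> ClassifierState:
        if len(cubes) == 0:
            raise ValidationError("cannot fit on an empty training set")
        if len(cubes) != len(labels):
            raise ValidationError(f"{len(cubes)} cubes but {len(labels)} labels")
        y = np.asarray(labels, dtype=np.int64)
        present = np.unique(y)
        if n_classes is None:
            n_classes = state.n_classes if state is not None else None
        if n_classes is None:
            if present.size < 2:
                raise ValidationError(
                    "training set contains a single class; pass n_classes to "
                    "fit with missing classes"
                )
            n_classes = int(present.max()) + 1
        if int(present.max()) >= n_classes:
            raise ValidationError(
                f"label {int(present.max())} out of range for {n_classes} classes"
            )

        feats = self._feature_matrix(cubes)
        d = feats.shape[1]
        if warm_start and state is not None and state.params:
            old = state.params["prototypes"]
            if old.shape != (n_classes, d):
                raise ValidationError(
                    f"warm start shape mismatch: state holds {old.shape}, "
                    f"data implies {(n_classes, d)}"
                )
            proto = old.copy()
            counts = state.params["counts"].copy()
        else:
            proto = np.full((n_classes, d), np.nan)
            counts = np.zeros(n_classes)

        # classes present in the batch are refit from the batch; classes
        # absent keep their previous prototype (fine-tuning semantics)
        for c in present:
            fc = feats[y == c]
            proto[c] = fc.mean(axis=0)
            counts[c] = len(fc)

        # within-class scatter of this batch sets the logit scale
        sq = np.array([((feats[i] - proto[y[i]]) ** 2).sum() for i in range(len(y))])
        scale = max(float(sq.mean()), 1e-12)

        cube0 = _cube_array(cubes[0])
        return ClassifierState(
            backend=self.name,
            n_classes=n_classes,
            params={"prototypes": proto, "counts": counts, "scale": scale},
            input_shape=tuple(cube0.shape),
            n_fit_calls=(state.n_fit_calls + 1) if state is not None else 1,
        )

    @staticmethod
    def _content_jitter(feature: np.ndarray, m: int) -> np.ndarray:
        """Fixed pseudo-random logit offsets seeded from the feature bytes."""
        key = zlib.crc32(np.ascontiguousarray(feature).tobytes())
        return np.random.default_rng(key).standard_normal(m)

    # -- predict ----------------------------------------------------------
    def predict_proba(self, state: ClassifierState, cubes: Sequence) -> PredictionMatrix:
        if state is None or not state.params:
            raise ValidationError("classifier state is unfitted")
        if len(cubes) == 0:
            raise ValidationError("cannot predict on an empty batch")
        feats = self._feature_matrix(cubes)
        proto = state.params["prototypes"]
        if feats.shape[1] != proto.shape[1]:
            raise ValidationError(
                f"cube channel count {feats.shape[1]} does not match fitted "
                f"feature size {proto.shape[1]}"
            )
        d2 = ((feats[:, None, :] - proto[None, :, :]) ** 2).sum(axis=2)
        # classes never seen get a distance beyond any observed one
        seen = ~np.isnan(proto).any(axis=1)
        if not seen.all():
            worst = np.nanmax(np.where(np.isfinite(d2), d2, np.nan)) if seen.any() else 1.0
            d2 = np.where(seen[None, :], d2, worst + 10.0 * state.params["scale"])
        logits = -d2 / (2.0 * state.params["scale"])
        if self.logit_jitter > 0:
            logits = logits + self.logit_jitter * np.stack(
                [self._content_jitter(feats[i], proto.shape[0]) for i in range(len(feats))]
            )
        logits = logits / self.temperature
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        ids = tuple(_cube_id(c, i) for i, c in enumerate(cubes))
        return PredictionMatrix(probabilities=p, ids=ids)


class ScriptedClassifier:
    """Backend that replays a fixed table of class posteriors by sample id.

    ``table`` maps sample_id -> probability row, or is a callable
    ``(sample_id, n_fit_calls) -> row`` for iteration-dependent scripts.
    ``fit`` only increments the fine-tune counter.
    """

    name = "scripted"

    def __init__(self, table, n_classes: int = 2):
        self.table = table
        self.n_classes = int(n_classes)

    def fit(
        self,
        cubes: Sequence,
        labels: Sequence[int],
        state: ClassifierState | None = None,
        warm_start: bool = False,
        n_classes: int | None = None,
        seed: int = 0,
    ) -> ClassifierState:
        if len(cubes) == 0:
            raise ValidationError("cannot fit on an empty training set")
        return ClassifierState(
            backend=self.name,
            n_classes=n_classes or self.n_classes,
            params={"scripted": True},
            n_fit_calls=(state.n_fit_calls + 1) if state is not None else 1,
        )

    def _row(self, sid: str, k: int) -> np.ndarray:
        if callable(self.table):
            return np.asarray(self.table(sid, k), dtype=np.float64)
        return np.asarray(self.table[sid], dtype=np.float64)

    def predict_proba(self, state: ClassifierState, cubes: Sequence) -> PredictionMatrix:
        if len(cubes) == 0:
            raise ValidationError("cannot predict on an empty batch")
        k = state.n_fit_calls if state is not None else 0
        ids = tuple(_cube_id(c, i) for i, c in enumerate(cubes))
        rows = np.stack([self._row(sid, k) for sid in ids])
        return PredictionMatrix(probabilities=rows, ids=ids)


BACKENDS = {
    "reference": ReferenceClassifier,
    "scripted": ScriptedClassifier,
}


def save_state(state: ClassifierState, path) -> "Path":
    """Persist a classifier state as one .npz archive with a metadata entry."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = {k: v for k, v in state.params.items() if isinstance(v, np.ndarray)}
    scalars = {k: v for k, v in state.params.items() if not isinstance(v, np.ndarray)}
    meta = {
        "backend": state.backend,
        "n_classes": state.n_classes,
        "input_shape": state.input_shape,
        "n_fit_calls": state.n_fit_calls,
        "scalars": scalars,
    }
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_state(path) -> ClassifierState:
    """Restore a classifier state written by :func:`save_state`."""
    import json

    with np.load(path) as archive:
        meta = json.loads(archive["_meta"].tobytes().decode())
        params = {k: archive[k] for k in archive.files if k != "_meta"}
    params.update(meta["scalars"])
    shape = meta["input_shape"]
    return ClassifierState(
        backend=meta["backend"],
        n_classes=int(meta["n_classes"]),
        params=params,
        input_shape=None if shape is None else tuple(shape),
        n_fit_calls=int(meta["n_fit_calls"]),
    )
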