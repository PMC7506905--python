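"""The active-learning loop: pseudo-fraction schedule, set bookkeeping,
the augmentation image pool, the annotation-cost ledger and learning-curve
output.

Two loop variants are provided.  The plain variant charges the annotation
oracle for K samples every iteration: rank the unlabeled pool by certainty,
pseudo-label the top N_pseudo(k) = floor(N_train * p(k)), send the bottom K
to the annotator, fine-tune on the union, grow p by the stride schedule
p(k+1) = p(k) + delta*k (capped), and return the pseudo-labeled samples to
the unlabeled pool — pseudo labels are transient and re-derived from the
newest model each round.

The pool variant exploits augmentation groups: all variants of one physical
sample share its label, so when a sample is manually annotated its
associates' labels come for free.  Those associates are banked in an image
pool; whenever the pool holds at least K images, the next iteration draws K
of them at random *instead of* paying the annotator.  The cost ledger
(`manual_count`) counts only oracle charges, never pool draws or pseudo
labels.

Annotation percentages are reported against the original, pre-augmentation
training-set size: a pool draw's label was already paid for when its parent
was annotated.  Because the plain variant pays per augmented image, its
percentage can exceed 100% on an augmented training set — that is precisely
the waste the pool removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .acquisition import (
    PredictionMatrix,
    pseudo_label,
    rank_by_certainty,
    resolve_criterion,
    split_selection,
)
from .classifier import ClassifierState
from .hypercube_io import HyperCube, SampleManifest, ValidationError, load_cube

__all__ = [
    "LoopConfig",
    "LoopState",
    "LoopResult",
    "AnnotationOracle",
    "n_pseudo",
    "update_p",
    "initialize",
    "iterate",
    "run",
    "evaluate",
    "annotation_curve",
]


class AnnotationOracle(Protocol):
    """Contract for the (simulated) human annotator.

    ``label`` returns a class index and charges one annotation;
    ``free_label`` returns the same class without charge and is used only
    for pool-banked associates whose label is implied by an already-paid
    annotation.  ``charges`` is the monotone charge counter.
    """

    def label(self, sample_id: str) -> int: ...
    def free_label(self, sample_id: str) -> int: ...
    @property
    def charges(self) -> int: ...


@dataclass
class LoopConfig:
    """Loop hyperparameters.

    ``K`` is the number of manual annotations per iteration (defaults to
    ceil(0.05 * N_train) when left None).  ``p0`` and ``delta`` drive the
    pseudo-fraction schedule p(k+1) = p(k) + delta*k, capped at ``p_max``.
    ``algorithm`` selects the plain loop ("alg1") or the image-pool loop
    ("alg2").  ``criterion`` is one of least_confidence/margin/entropy or
    "random" for the control arm.  ``manual_budget`` bounds the total
    number of oracle charges; None means unbounded.
    """

    K: int | None = None
    p0: float = 0.05
    delta: float = 0.01
    p_max: float = 0.95
    max_iterations: int = 50
    criterion: str = "entropy"
    algorithm: str = "alg1"
    seed: int = 0
    warm_start: bool = True
    manual_budget: int | None = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        if self.K is not None and self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if not 0.0 <= self.p0 < 1.0:
            raise ValidationError(f"p0 must lie in [0, 1), got {self.p0}")
        if self.delta < 0:
            raise ValidationError(f"delta must be >= 0, got {self.delta}")
        if not 0.0 <= self.p_max <= 1.0:
            raise ValidationError(f"p_max must lie in [0, 1], got {self.p_max}")
        if self.max_iterations < 0:
            raise ValidationError("max_iterations must be >= 0")
        if self.algorithm not in ("alg1", "alg2"):
            raise ValidationError(f"unknown algorithm '{self.algorithm}'")
        self.criterion = resolve_criterion(self.criterion)


@dataclass
class LoopState:
    """Mutable loop bookkeeping.

    ``xm``/``xp`` map sample ids to labels (manual and pseudo); ``xu`` is
    the ordered unlabeled pool; ``pool`` the ordered bank of augmentation
    associates awaiting a free draw.  ``manual_count`` counts oracle
    charges only.  ``history`` collects one record per completed training
    round (the initialization round included).
    """

    k: int
    p: float
    xm: dict[str, int]
    xp: dict[str, int]
    xu: list[str]
    pool: list[str]
    manual_count: int
    n_train: int
    n_train_orig: int
    n_classes: int
    train_order: list[str]
    history: list[dict] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng, repr=False)

    def check_invariants(self) -> None:
        xm, xp = set(self.xm), set(self.xp)
        xu, pool = set(self.xu), set(self.pool)
        sets = [("xm", xm), ("xp", xp), ("xu", xu), ("pool", pool)]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                inter = sets[i][1] & sets[j][1]
                if inter:
                    raise ValidationError(
                        f"{sets[i][0]} and {sets[j][0]} intersect: {sorted(inter)[:3]}"
                    )
        if (xm | xp | xu | pool) - set(self.train_order):
            raise ValidationError("loop sets contain ids outside the training set")


@dataclass
class LoopResult:
    """Output block of a loop run: the fine-tuned classifier state, the
    manually-labeled set, and the per-iteration history."""

    classifier: ClassifierState
    xm: dict[str, int]
    history: pd.DataFrame
    state: LoopState


def n_pseudo(n_train: int, p: float) -> int:
    """Number of pseudo-labeled images this iteration: floor(N_train * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"pseudo fraction must lie in [0, 1], got {p}")
    return math.floor(n_train * p)


def update_p(p: float, k: int, delta: float, p_max: float = 0.95) -> float:
    """Stride schedule p(k+1) = p(k) + delta * k, capped at p_max."""
    return min(p + delta * k, p_max)


# ---------------------------------------------------------------------------
# Loop steps
# ---------------------------------------------------------------------------


def _load_cubes(manifest: SampleManifest) -> dict[str, HyperCube]:
    return {sid: load_cube(manifest.path_of(sid)) for sid in manifest.ids()}


def _ordered(ids, order: Sequence[str]) -> list[str]:
    wanted = set(ids)
    return [i for i in order if i in wanted]


def _fit_training_set(state, config, backend, clf_state, cubes):
    train_ids = list(state.xm) + list(state.xp)
    labels = [state.xm.get(i, state.xp.get(i)) for i in train_ids]
    return backend.fit(
        [cubes[i] for i in train_ids],
        labels,
        state=clf_state,
        warm_start=config.warm_start and clf_state is not None,
        n_classes=state.n_classes,
        seed=config.seed,
    )


def _record(state: LoopState, accuracy: float, xp_size: int, charged: int) -> None:
    state.history.append(
        {
            "k": state.k,
            "n_manual": len(state.xm),
            "n_pseudo": xp_size,
            "n_unlabeled": len(state.xu),
            "n_pool": len(state.pool),
            "manual_count": state.manual_count,
            "charged_this_iter": charged,
            "p": state.p,
            "accuracy": accuracy,
            "n_train": state.n_train,
            "n_train_orig": state.n_train_orig,
            "seed": -1,  # filled by run()
        }
    )


def initialize(
    manifest: SampleManifest,
    config: LoopConfig,
    oracle: AnnotationOracle,
    backend,
    cubes: dict[str, HyperCube] | None = None,
) -> tuple[LoopState, ClassifierState]:
    """Seed the loop: K random manual annotations, one initial fit."""
    if cubes is None:
        cubes = _load_cubes(manifest)
    train_ids = manifest.ids("train")
    if not train_ids:
        raise ValidationError("training split is empty")
    K = config.K if config.K is not None else math.ceil(0.05 * len(train_ids))
    if K > len(train_ids):
        raise ValidationError(f"K={K} exceeds training-set size {len(train_ids)}")
    rng = np.random.default_rng(config.seed)
    picked = rng.choice(len(train_ids), size=K, replace=False)
    xm_ids = _ordered((train_ids[i] for i in picked), train_ids)
    xm = {sid: oracle.label(sid) for sid in xm_ids}
    n_classes = config.n_classes if config.n_classes is not None else manifest.n_classes()
    state = LoopState(
        k=0,
        p=config.p0,
        xm=xm,
        xp={},
        xu=[i for i in train_ids if i not in xm],
        pool=[],
        manual_count=K,
        n_train=len(train_ids),
        n_train_orig=manifest.n_groups("train"),
        n_classes=n_classes,
        train_order=train_ids,
        rng=rng,
    )
    clf_state = _fit_training_set(state, config, backend, None, cubes)
    acc, _ = evaluate(backend, clf_state, manifest, cubes)
    _record(state, acc, 0, K)
    return state, clf_state


def _rank_unlabeled(state, config, backend, clf_state, cubes):
    """Ranked unlabeled ids (certainty high-to-low) and their posteriors."""
    if not state.xu:
        return [], None
    probs = backend.predict_proba(clf_state, [cubes[i] for i in state.xu])
    if config.criterion == "random":
        order = state.rng.permutation(len(state.xu))
        ranked = [state.xu[i] for i in order]
    else:
        ranked = list(rank_by_certainty(probs, criterion=config.criterion).ids)
    return ranked, probs


def iterate(
    state: LoopState,
    config: LoopConfig,
    oracle: AnnotationOracle,
    backend,
    clf_state: ClassifierState,
    cubes: dict[str, HyperCube],
    manifest: SampleManifest,
    groups: dict[str, list[str]] | None = None,
) -> ClassifierState:
    """One loop iteration (plain or pool variant per ``config.algorithm``).

    Mutates ``state`` in place and returns the fine-tuned classifier state.
    """
    if not state.xu and not (config.algorithm == "alg2" and state.pool):
        raise ValidationError("nothing left to select: unlabeled pool (and pool) empty")
    K = config.K if config.K is not None else math.ceil(0.05 * state.n_train)
    ranked, probs = _rank_unlabeled(state, config, backend, clf_state, cubes)

    n_p = n_pseudo(state.n_train, state.p)
    charged = 0
    free_draw = config.algorithm == "alg2" and (
        len(state.pool) >= K or (not ranked and state.pool)
    )
    if free_draw:
        # free draw: K random pool members join XM without charge
        # (fewer when draining a sub-K remainder after XU is exhausted)
        pseudo_ids, _ = split_selection(ranked, n_p, 0) if ranked else ([], [])
        draw = state.rng.choice(len(state.pool), size=min(K, len(state.pool)), replace=False)
        drawn = [state.pool[i] for i in sorted(draw)]
        for sid in drawn:
            state.xm[sid] = oracle.free_label(sid)
        state.pool = [i for i in state.pool if i not in set(drawn)]
        manual_ids: list[str] = []
    else:
        K_eff = min(K, len(ranked))
        pseudo_ids, manual_ids = split_selection(ranked, n_p, K_eff)
        for sid in manual_ids:
            state.xm[sid] = oracle.label(sid)
        charged = len(manual_ids)
        state.manual_count += charged
        if config.algorithm == "alg2":
            # bank every still-unlabeled associate of the manual set (the
            # initial annotations included, the first time through)
            if groups is None:
                groups = manifest.groups("train")
            consumed = set(state.xm) | set(pseudo_ids)
            xu_set = set(state.xu)
            banked: list[str] = []
            for sid in state.xm:
                gid = manifest.group_of(sid)
                for assoc in groups.get(gid, []):
                    if assoc in xu_set and assoc not in consumed:
                        banked.append(assoc)
                        xu_set.discard(assoc)
            state.pool.extend(_ordered(banked, state.train_order))

    # pseudo labels are assigned from the current model and leave XU for
    # the duration of this training round only
    state.xp = dict(pseudo_label(probs, pseudo_ids)) if pseudo_ids else {}
    if config.algorithm == "alg2":
        remove = set(state.xm) | set(state.xp) | set(state.pool)
    else:
        remove = set(state.xm) | set(state.xp)
    state.xu = [i for i in state.train_order if i in set(state.xu) - remove]

    state.check_invariants()
    clf_state = _fit_training_set(state, config, backend, clf_state, cubes)

    xp_size = len(state.xp)
    state.p = update_p(state.p, state.k, config.delta, config.p_max)
    state.k += 1
    # line "XU <- XU union XP": pseudo ids return to the unlabeled pool
    returned = set(state.xu) | set(state.xp)
    state.xu = [i for i in state.train_order if i in returned]
    state.xp = {}

    acc, _ = evaluate(backend, clf_state, manifest, cubes)
    _record(state, acc, xp_size, charged)
    return clf_state


def run(
    manifest: SampleManifest,
    config: LoopConfig,
    oracle: AnnotationOracle,
    backend,
    cubes: dict[str, HyperCube] | None = None,
) -> LoopResult:
    """Run the full loop until no unlabeled work remains, the manual budget
    is spent, or ``max_iterations`` is reached."""
    if cubes is None:
        cubes = _load_cubes(manifest)
    groups = manifest.groups("train")
    state, clf_state = initialize(manifest, config, oracle, backend, cubes)
    while state.k < config.max_iterations:
        work_left = bool(state.xu) or (config.algorithm == "alg2" and bool(state.pool))
        if not work_left:
            break
        if config.manual_budget is not None and state.manual_count >= config.manual_budget:
            break
        clf_state = iterate(
            state, config, oracle, backend, clf_state, cubes, manifest, groups
        )
    history = pd.DataFrame(state.history)
    history["seed"] = config.seed
    return LoopResult(classifier=clf_state, xm=dict(state.xm), history=history, state=state)


# ---------------------------------------------------------------------------
# Evaluation and learning curves
# ---------------------------------------------------------------------------


def evaluate(
    backend,
    clf_state: ClassifierState,
    manifest: SampleManifest,
    cubes: dict[str, HyperCube] | None = None,
) -> tuple[float, np.ndarray]:
    """Test-set accuracy and the m x m confusion-count matrix
    (rows = true class, columns = predicted)."""
    test_ids = manifest.ids("test")
    if not test_ids:
        raise ValidationError("test split is empty")
    if cubes is None:
        cubes = {sid: load_cube(manifest.path_of(sid)) for sid in test_ids}
    probs = backend.predict_proba(clf_state, [cubes[i] for i in test_ids])
    pred = probs.probabilities.argmax(axis=1)
    truth = np.array([manifest.label_of(i) for i in test_ids])
    m = max(clf_state.n_classes, int(truth.max()) + 1)
    confusion = np.zeros((m, m), dtype=np.int64)
    np.add.at(confusion, (truth, pred), 1)
    accuracy = float((pred == truth).mean())
    return accuracy, confusion


def annotation_curve(history: pd.DataFrame | LoopResult) -> pd.DataFrame:
    """Learning curve: manual-annotation percentage of the original
    (pre-augmentation) training set versus test accuracy, one row per
    iteration.  The percentage column is monotone non-decreasing."""
    df = history.history if isinstance(history, LoopResult) else history
    if df.empty:
        raise ValidationError("history is empty")
    out = pd.DataFrame(
        {
            "k": df["k"],
            "manual_count": df["manual_count"],
            "manual_pct": 100.0 * df["manual_count"] / df["n_train_orig"],
            "accuracy": df["accuracy"],
        }
    )
    return out.reset_index(drop=True)
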