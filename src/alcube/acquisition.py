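"""Uncertainty-sampling acquisition: certainty criteria, ranking, selection.

Given the current classifier's class-posterior matrix over the unlabeled
pool, each criterion assigns every sample a *certainty* score — high means
the model is confident, low means the sample is informative:

* least confidence:  C_i = max_j p_ij                       (range [1/m, 1])
* margin:            C_i = p_(1) - p_(2), top two classes   (range [0, 1])
* entropy:           C_i = sum_j p_ij ln p_ij, 0 ln 0 := 0  (range [-ln m, 0])

The entropy criterion is the *negative* Shannon entropy, so it too is a
certainty score and all three obey one uniform rule: sort high-to-low,
pseudo-label the top, send the bottom to the human annotator.  For binary
problems the three criteria induce the same ranking — each is a monotone
function of |p_i1 - 0.5|.

Natural log is used for the entropy criterion; the base only rescales
scores and never changes a ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hypercube_io import ValidationError

__all__ = [
    "PredictionMatrix",
    "CertaintyRanking",
    "certainty_least_confidence",
    "certainty_margin",
    "certainty_entropy",
    "CRITERIA",
    "resolve_criterion",
    "rank_by_certainty",
    "split_selection",
    "pseudo_label",
]

_ROW_SUM_TOL = 1e-6


@dataclass
class PredictionMatrix:
    """N x m class-posterior rows aligned with a list of sample ids.

    Rows must be nonnegative and sum to 1 within 1e-6; at least two
    classes are required.
    """

    probabilities: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        self.ids = tuple(str(i) for i in self.ids)
        p = self.probabilities
        if p.ndim != 2:
            raise ValidationError(f"probabilities must be 2-D, got shape {p.shape}")
        if p.shape[1] < 2:
            raise ValidationError(f"need at least 2 classes, got m={p.shape[1]}")
        if len(self.ids) != p.shape[0]:
            raise ValidationError(
                f"{len(self.ids)} ids for {p.shape[0]} probability rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sample ids in prediction matrix")
        _check_rows(p)

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[1]

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    def row_of(self, sample_id: str) -> np.ndarray:
        try:
            return self.probabilities[self.ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample id '{sample_id}'") from None


def _check_rows(p: np.ndarray) -> None:
    if np.any(p < -_ROW_SUM_TOL):
        raise ValidationError("negative class probabilities")
    sums = p.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
    if bad.size:
        raise ValidationError(
            f"probability row {bad[0]} sums to {sums[bad[0]]:.8f}, not 1"
        )


def _as_probs(probs) -> np.ndarray:
    if isinstance(probs, PredictionMatrix):
        return probs.probabilities
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValidationError(f"expected an N x m matrix with m >= 2, got {p.shape}")
    _check_rows(p)
    return p


def certainty_least_confidence(probs) -> np.ndarray:
    """Posterior of the most likely class per sample."""
    return _as_probs(probs).max(axis=1)


def certainty_margin(probs) -> np.ndarray:
    """Gap between the top two class posteriors per sample."""
    p = np.sort(_as_probs(probs), axis=1)
    return p[:, -1] - p[:, -2]


def certainty_entropy(probs) -> np.ndarray:
    """Negative Shannon entropy, sum_j p ln p with 0 ln 0 := 0."""
    p = _as_probs(probs)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(p), 0.0)
    return terms.sum(axis=1)


CRITERIA = {
    "least_confidence": certainty_least_confidence,
    "margin": certainty_margin,
    "entropy": certainty_entropy,
}

_ALIASES = {
    "lc": "least_confidence",
    "ms": "margin",
    "margin_sampling": "margin",
    "en": "entropy",
}


def resolve_criterion(name: str) -> str:
    """Map a criterion name or short alias to its canonical name."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in CRITERIA and key != "random":
        raise ValidationError(
            f"unknown criterion '{name}' "
            f"(expected one of {sorted(CRITERIA) + ['random']} or aliases lc/ms/en)"
        )
    return key


@dataclass
class CertaintyRanking:
    """Sample ids sorted high-to-low by certainty score.

    The sort is stable and ties keep the original id order, so rankings are
    reproducible bit-for-bit.
    """

    ids: tuple[str, ...]
    scores: np.ndarray
    criterion: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.ids) != self.scores.size:
            raise ValidationError("ranking ids and scores differ in length")
        if self.scores.size and np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.ids)


def rank_by_certainty(
    probs: PredictionMatrix,
    ids: Sequence[str] | None = None,
    criterion: str = "entropy",
) -> CertaintyRanking:
    """Stable descending sort of samples by a criterion's certainty score."""
    name = resolve_criterion(criterion)
    if name == "random":
        raise ValidationError("random selection has no certainty ranking; shuffle ids instead")
    if ids is None:
        if not isinstance(probs, PredictionMatrix):
            raise ValidationError("ids are required when probs is a bare array")
        ids = probs.ids
    p = _as_probs(probs)
    if len(ids) != p.shape[0]:
        raise ValidationError(f"{len(ids)} ids for {p.shape[0]} probability rows")
    scores = CRITERIA[name](p)
    order = np.argsort(-scores, kind="stable")
    return CertaintyRanking(
        ids=tuple(str(ids[i]) for i in order),
        scores=scores[order],
        criterion=name,
    )


def split_selection(
    ranking: CertaintyRanking | Sequence[str],
    n_pseudo: int,
    n_manual: int,
) -> tuple[list[str], list[str]]:
    """Top ``n_pseudo`` ids for pseudo-labeling, bottom ``n_manual`` for
    manual annotation; the two sets are disjoint.

    When the ranking is too short to honour both quotas, the manual quota
    wins and the pseudo quota shrinks to ``N - n_manual`` — annotation is
    the budgeted resource the loop optimizes, pseudo labels are free.
    """
    ids = list(ranking.ids) if isinstance(ranking, CertaintyRanking) else [str(i) for i in ranking]
    n = len(ids)
    if n_pseudo < 0 or n_manual < 0:
        raise ValidationError("selection counts must be nonnegative")
    if n_manual > n:
        raise ValidationError(f"n_manual={n_manual} exceeds ranking size {n}")
    n_pseudo = min(n_pseudo, n - n_manual)
    manual = ids[n - n_manual :] if n_manual else []
    return ids[:n_pseudo], manual


def pseudo_label(probs: PredictionMatrix, ids: Sequence[str]) -> list[tuple[str, int]]:
    """Label each selected id with its argmax class; ties go to the
    smaller class index."""
    return [(str(i), int(np.argmax(probs.row_of(str(i))))) for i in ids]
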