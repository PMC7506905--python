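"""Desk-scale annotation-budget experiments.

Utilities to reproduce, on synthetic data, the study's central comparison:
accuracy as a function of the manual-annotation percentage, for the plain
loop versus the image-pool loop and for the three uncertainty criteria
versus random selection, all against the fully annotated baseline.

The benchmark problem size is deliberately reduced — 2 classes, 60 samples
per class, 40-50 px cubes with 120 spectral channels — so a full multi-seed
comparison runs in seconds per seed on one CPU while keeping every
structural property of the full-scale pipeline (fractionally matched
spectral window, 6x augmentation, identical loop mechanics).
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .active_loop import LoopConfig, LoopResult, annotation_curve, evaluate, run
from .classifier import ReferenceClassifier
from .hypercube_io import SampleManifest, load_cube
from .preprocess import PreprocessConfig, preprocess_dataset
from .synthdata import SynthConfig, generate_dataset, make_oracle, scaled_preprocess_config

__all__ = [
    "benchmark_config",
    "prepare_benchmark",
    "baseline_accuracy",
    "reach_percentage",
    "annotation_experiment",
    "annotation_study",
]

# (algorithm, criterion) arms covering the plain-vs-pool and
# criteria-vs-random comparisons
DEFAULT_CONDITIONS = (
    ("alg1", "entropy"),
    ("alg2", "entropy"),
    ("alg2", "least_confidence"),
    ("alg2", "margin"),
    ("alg2", "random"),
)


def benchmark_config(
    n_per_class: int = 60, separation: float = 3.0, seed: int = 0
) -> tuple[SynthConfig, PreprocessConfig]:
    """Reduced-size generator + matching preprocessing constants."""
    synth = SynthConfig(
        n_per_class=n_per_class,
        height=(40, 50),
        width=(40, 50),
        n_channels=120,
        separation=separation,
        seed=seed,
    )
    return synth, scaled_preprocess_config(synth.n_channels)


def prepare_benchmark(
    synth: SynthConfig, pcfg: PreprocessConfig, augment: bool = True
) -> tuple[SampleManifest, dict]:
    """Generate, preprocess (train split augmented 6x) and load into memory."""
    with tempfile.TemporaryDirectory() as tmp:
        raw = generate_dataset(synth, Path(tmp) / "raw")
        processed = preprocess_dataset(raw, pcfg, Path(tmp) / "proc", augment_train=augment)
        cubes = {sid: load_cube(processed.path_of(sid)) for sid in processed.ids()}
    return processed, cubes


def baseline_accuracy(manifest: SampleManifest, cubes: dict, backend=None) -> float:
    """Accuracy of the model trained on the entire (augmented) training
    split with every label manually annotated."""
    backend = backend or ReferenceClassifier()
    train = manifest.ids("train")
    labels = [manifest.label_of(i) for i in train]
    state = backend.fit([cubes[i] for i in train], labels)
    acc, _ = evaluate(backend, state, manifest, cubes)
    return acc


def reach_percentage(curve: pd.DataFrame, target_accuracy: float) -> float:
    """Smallest manual-annotation percentage at which the curve's accuracy
    meets ``target_accuracy``; inf if it never does."""
    hit = curve[curve["accuracy"] >= target_accuracy - 1e-9]
    return float(hit["manual_pct"].iloc[0]) if len(hit) else math.inf


def annotation_experiment(
    seed: int,
    n_per_class: int = 60,
    separation: float = 3.0,
    conditions=DEFAULT_CONDITIONS,
    max_iterations: int = 80,
) -> dict:
    """One seed's full comparison.

    Returns a dict with the baseline accuracy and, per (algorithm,
    criterion) arm, its learning curve, peak accuracy, the percentage at
    which the peak occurs, and the percentage at which it first reaches
    the baseline accuracy.
    """
    synth, pcfg = benchmark_config(n_per_class=n_per_class, separation=separation, seed=seed)
    manifest, cubes = prepare_benchmark(synth, pcfg)
    backend = ReferenceClassifier()
    base_acc = baseline_accuracy(manifest, cubes, backend)

    arms: dict[tuple[str, str], dict] = {}
    for algorithm, criterion in conditions:
        config = LoopConfig(
            algorithm=algorithm,
            criterion=criterion,
            seed=seed,
            max_iterations=max_iterations,
        )
        oracle = make_oracle(manifest, label_noise=synth.label_noise, seed=seed)
        result: LoopResult = run(manifest, config, oracle, backend, cubes)
        curve = annotation_curve(result)
        peak_i = int(curve["accuracy"].idxmax())
        arms[(algorithm, criterion)] = {
            "curve": curve,
            "history": result.history,
            "peak_accuracy": float(curve["accuracy"].iloc[peak_i]),
            "peak_pct": float(curve["manual_pct"].iloc[peak_i]),
            "reach_pct": reach_percentage(curve, base_acc),
            "final_accuracy": float(curve["accuracy"].iloc[-1]),
            "manual_count": int(curve["manual_count"].iloc[-1]),
        }
    return {
        "seed": seed,
        "baseline_accuracy": base_acc,
        "n_train": len(manifest.ids("train")),
        "n_train_orig": manifest.n_groups("train"),
        "arms": arms,
    }


def annotation_study(seeds, n_per_class: int = 60, separation: float = 3.0) -> dict:
    """Multi-seed annotation-budget study.

    Runs :func:`annotation_experiment` for every seed and aggregates the
    two headline comparisons: how often the image-pool loop reaches the
    baseline accuracy strictly cheaper than the plain loop, and how often
    each uncertainty criterion reaches it at most as expensively as random
    selection (both under the pool loop).  Returns per-seed records plus
    the aggregate counts and means.
    """
    seeds = list(seeds)
    records = []
    pool_wins = 0
    crit_wins = {c: 0 for c in ("entropy", "least_confidence", "margin")}
    for seed in seeds:
        res = annotation_experiment(seed, n_per_class=n_per_class, separation=separation)
        arms = res["arms"]
        rec = {
            "seed": seed,
            "baseline_accuracy": res["baseline_accuracy"],
            "alg1_entropy_reach_pct": arms[("alg1", "entropy")]["reach_pct"],
            "alg2_entropy_reach_pct": arms[("alg2", "entropy")]["reach_pct"],
            "alg2_random_reach_pct": arms[("alg2", "random")]["reach_pct"],
            "alg2_entropy_peak_accuracy": arms[("alg2", "entropy")]["peak_accuracy"],
            "alg1_entropy_peak_accuracy": arms[("alg1", "entropy")]["peak_accuracy"],
        }
        pool_wins += rec["alg2_entropy_reach_pct"] < rec["alg1_entropy_reach_pct"]
        for c in crit_wins:
            crit_wins[c] += arms[("alg2", c)]["reach_pct"] <= rec["alg2_random_reach_pct"]
        records.append(rec)
    n = len(seeds)
    return {
        "n_seeds": n,
        "records": records,
        "pool_cheaper_than_plain": pool_wins,
        "criterion_not_worse_than_random": crit_wins,
        "baseline_accuracy_mean": float(np.mean([r["baseline_accuracy"] for r in records])),
        "alg1_entropy_reach_pct_mean": float(np.mean([r["alg1_entropy_reach_pct"] for r in records])),
        "alg2_entropy_reach_pct_mean": float(np.mean([r["alg2_entropy_reach_pct"] for r in records])),
        "alg2_random_reach_pct_mean": float(np.mean([r["alg2_random_reach_pct"] for r in records])),
        "alg2_entropy_peak_accuracy_mean": float(
            np.mean([r["alg2_entropy_peak_accuracy"] for r in records])
        ),
    }
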