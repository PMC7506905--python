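"""Schedule arithmetic, set bookkeeping, cost ledger, both loop variants."""

import math

import numpy as np
import pandas as pd
import pytest

from alcube import (
    HyperCube,
    LoopConfig,
    SampleManifest,
    ScriptedClassifier,
    ValidationError,
    annotation_curve,
    evaluate,
    initialize,
    n_pseudo,
    run,
    update_p,
)
from alcube.classifier import ClassifierState
from alcube.synthdata import make_oracle


def scripted_setup(n_groups=8, group_size=6, n_test=4):
    """Manifest of augmentation groups plus a scripted backend whose
    certainty is a fixed, known function of the sample id."""
    rows, table = [], {}
    idx = 0
    for g in range(n_groups):
        for m in range(group_size):
            sid = f"g{g}.{m}"
            rows.append(
                dict(sample_id=sid, file_path=sid, label=g % 2, split="train",
                     group_id=f"g{g}")
            )
            eps = 0.4 * (idx + 1) / (n_groups * group_size + n_test + 1)
            table[sid] = [0.5 + eps, 0.5 - eps]  # certainty grows with idx
            idx += 1
    for t in range(n_test):
        sid = f"te{t}"
        rows.append(dict(sample_id=sid, file_path=sid, label=t % 2, split="test"))
        table[sid] = [0.9, 0.1] if t % 2 == 0 else [0.1, 0.9]
        idx += 1
    manifest = SampleManifest.from_rows(rows)
    cubes = {
        sid: HyperCube(pixels=np.zeros((2, 2, 2), dtype=np.float32), sample_id=sid)
        for sid in manifest.ids()
    }
    return manifest, cubes, ScriptedClassifier(table)


class TestSchedule:
    @pytest.mark.parametrize(
        "n,p,expected", [(460, 0.1, 46), (123, 0.0, 0), (100, 0.333, 33), (7, 1.0, 7)]
    )
    def test_pseudo_count_is_the_floor(self, n, p, expected):
        assert n_pseudo(n, p) == expected

    def test_pseudo_fraction_bounds(self):
        with pytest.raises(ValidationError):
            n_pseudo(10, 1.5)

    @pytest.mark.parametrize(
        "p,k,delta,expected",
        [(0.05, 0, 0.02, 0.05), (0.11, 3, 0.02, 0.17), (0.94, 5, 0.1, 0.95)],
    )
    def test_stride_update_with_cap(self, p, k, delta, expected):
        assert update_p(p, k, delta, p_max=0.95) == pytest.approx(expected)

    def test_update_grid_matches_hand_computation(self):
        for p0 in (0.0, 0.05, 0.3):
            for delta in (0.0, 0.01, 0.05):
                p = p0
                for k in range(8):
                    expected = min(p + delta * k, 0.95)
                    assert update_p(p, k, delta) == pytest.approx(expected)
                    p = expected


class TestInitialize:
    def test_seeds_k_charged_annotations(self):
        manifest, cubes, backend = scripted_setup()
        oracle = make_oracle(manifest)
        config = LoopConfig(K=5, seed=3, criterion="entropy")
        state, _ = initialize(manifest, config, oracle, backend, cubes)
        assert len(state.xm) == 5
        assert len(state.xu) == 48 - 5
        assert state.manual_count == 5 == oracle.charges
        assert len(state.history) == 1

    def test_same_seed_selects_the_same_samples(self):
        manifest, cubes, backend = scripted_setup()
        picks = []
        for _ in range(2):
            state, _ = initialize(
                manifest, LoopConfig(K=6, seed=9), make_oracle(manifest), backend, cubes
            )
            picks.append(sorted(state.xm))
        assert picks[0] == picks[1]

    def test_k_larger_than_training_set_rejected(self):
        manifest, cubes, backend = scripted_setup(n_groups=1)
        with pytest.raises(ValidationError, match="exceeds"):
            initialize(manifest, LoopConfig(K=7), make_oracle(manifest), backend, cubes)


class TestPlainLoop:
    def test_bookkeeping_and_cost_ledger(self):
        manifest, cubes, backend = scripted_setup()
        oracle = make_oracle(manifest)
        config = LoopConfig(K=5, p0=0.1, delta=0.01, seed=0, algorithm="alg1",
                            criterion="entropy", max_iterations=4)
        result = run(manifest, config, oracle, backend, cubes)
        h = result.history
        # one init row plus one row per iteration; K charges each round
        assert len(h) == 5
        np.testing.assert_array_equal(h["manual_count"], 5 * (np.arange(5) + 1))
        assert oracle.charges == int(h["manual_count"].iloc[-1])
        # pseudo set is transient: empty at the end of every iteration
        assert result.state.xp == {}
        # plain loop never banks anything
        assert result.state.pool == []

    def test_two_runs_are_bit_identical(self):
        traces = []
        for _ in range(2):
            manifest, cubes, backend = scripted_setup()
            config = LoopConfig(K=4, seed=12, algorithm="alg1", max_iterations=6)
            result = run(manifest, config, make_oracle(manifest), backend, cubes)
            traces.append(result.history)
        pd.testing.assert_frame_equal(traces[0], traces[1])

    def test_selection_follows_the_scripted_certainty(self):
        """Bottom-of-ranking ids (lowest scripted certainty) are annotated
        first; the loop's behaviour is fully determined by the prediction
        matrix it is fed."""
        manifest, cubes, backend = scripted_setup()
        config = LoopConfig(K=3, p0=0.0, delta=0.0, seed=1, algorithm="alg1",
                            criterion="least_confidence", max_iterations=1)
        oracle = make_oracle(manifest)
        state, clf = initialize(manifest, config, oracle, backend, cubes)
        least_certain = [i for i in manifest.ids("train") if i not in state.xm][:3]
        from alcube import iterate

        iterate(state, config, oracle, backend, clf, cubes, manifest)
        assert set(least_certain) <= set(state.xm)

    def test_exhaustion_terminates_with_empty_pool(self):
        manifest, cubes, backend = scripted_setup(n_groups=3)
        config = LoopConfig(K=4, seed=2, algorithm="alg1", max_iterations=50)
        result = run(manifest, config, make_oracle(manifest), backend, cubes)
        assert result.state.xu == []
        assert len(result.xm) == 18

    def test_zero_iterations_returns_the_initial_model(self):
        manifest, cubes, backend = scripted_setup()
        config = LoopConfig(K=4, seed=2, max_iterations=0)
        result = run(manifest, config, make_oracle(manifest), backend, cubes)
        assert len(result.history) == 1
        assert result.classifier.n_fit_calls == 1

    def test_manual_budget_stops_the_loop(self):
        manifest, cubes, backend = scripted_setup()
        config = LoopConfig(K=5, seed=2, algorithm="alg1", max_iterations=50,
                            manual_budget=15)
        result = run(manifest, config, make_oracle(manifest), backend, cubes)
        assert int(result.history["manual_count"].iloc[-1]) == 15


class TestPoolLoop:
    def test_associates_are_banked_and_draws_are_free(self):
        manifest, cubes, backend = scripted_setup(n_groups=8)
        oracle = make_oracle(manifest)
        config = LoopConfig(K=4, p0=0.0, delta=0.0, seed=0, algorithm="alg2",
                            criterion="entropy", max_iterations=6)
        result = run(manifest, config, oracle, backend, cubes)
        h = result.history
        # at least one iteration drew from the pool without charging
        free_iters = h[(h["charged_this_iter"] == 0) & (h["k"] > 0)]
        assert len(free_iters) > 0
        # the ledger counts only oracle charges
        assert oracle.charges == int(h["manual_count"].iloc[-1])
        # free draws carry the true group label into XM
        for sid, label in result.xm.items():
            assert label == manifest.label_of(sid)

    def test_pool_disjoint_from_working_sets_every_iteration(self):
        manifest, cubes, backend = scripted_setup(n_groups=10)
        config = LoopConfig(K=4, seed=7, algorithm="alg2", max_iterations=20)
        oracle = make_oracle(manifest)
        state, clf = initialize(manifest, config, oracle, backend, cubes)
        from alcube import iterate

        groups = manifest.groups("train")
        for _ in range(12):
            if not state.xu and not state.pool:
                break
            clf = iterate(state, config, oracle, backend, clf, cubes, manifest, groups)
            assert not set(state.pool) & set(state.xu)
            assert not set(state.pool) & set(state.xm)

    def test_pool_variant_never_costs_more_than_plain(self):
        """Under identical seeds and configs the image-pool loop's charge
        ledger is dominated by the plain loop's at every iteration."""
        histories = {}
        for algorithm in ("alg1", "alg2"):
            manifest, cubes, backend = scripted_setup(n_groups=8)
            config = LoopConfig(K=4, seed=5, algorithm=algorithm, criterion="entropy",
                                max_iterations=10)
            result = run(manifest, config, make_oracle(manifest), backend, cubes)
            histories[algorithm] = result.history["manual_count"].to_numpy()
        shared = min(len(histories["alg1"]), len(histories["alg2"]))
        assert np.all(histories["alg2"][:shared] <= histories["alg1"][:shared])

    def test_partition_of_the_training_set_is_maintained(self):
        manifest, cubes, backend = scripted_setup(n_groups=6)
        config = LoopConfig(K=4, seed=3, algorithm="alg2", max_iterations=30)
        result = run(manifest, config, make_oracle(manifest), backend, cubes)
        state = result.state
        train = set(manifest.ids("train"))
        assert set(state.xm) | set(state.xu) | set(state.pool) <= train
        # run ended by exhaustion: every sample was resolved into XM
        assert set(state.xm) == train


class TestEvaluate:
    def test_perfect_predictor_scores_one(self):
        manifest, cubes, backend = scripted_setup()
        state = backend.fit([cubes[i] for i in manifest.ids("train")[:4]], [0, 1, 0, 1])
        acc, confusion = evaluate(backend, state, manifest, cubes)
        assert acc == 1.0
        assert confusion.sum() == 4

    def test_one_class_predictor_on_balanced_test_scores_half(self):
        manifest, cubes, _ = scripted_setup()
        constant = ScriptedClassifier({sid: [1.0, 0.0] for sid in manifest.ids()})
        state = ClassifierState(backend="scripted", n_classes=2, params={"scripted": True})
        acc, confusion = evaluate(constant, state, manifest, cubes)
        assert acc == 0.5
        assert confusion[:, 0].sum() == confusion.sum()

    def test_empty_test_split_rejected(self):
        manifest, cubes, backend = scripted_setup()
        train_only = manifest.subset(manifest.ids("train"))
        state = backend.fit([cubes[i] for i in train_only.ids("train")[:2]], [0, 1])
        with pytest.raises(ValidationError, match="test"):
            evaluate(backend, state, train_only, cubes)


class TestAnnotationCurve:
    def test_percentage_arithmetic_and_monotonicity(self):
        manifest, cubes, backend = scripted_setup()
        config = LoopConfig(K=4, seed=4, algorithm="alg1", max_iterations=5)
        result = run(manifest, config, make_oracle(manifest), backend, cubes)
        curve = annotation_curve(result)
        orig = manifest.n_groups("train")
        np.testing.assert_allclose(
            curve["manual_pct"], 100.0 * curve["manual_count"] / orig
        )
        assert np.all(np.diff(curve["manual_pct"]) >= 0)
        # plain loop: constant K-sized increments until exhaustion
        increments = np.diff(curve["manual_count"])
        assert set(increments[:-1].tolist()) <= {4}

    def test_pool_draws_show_as_flat_steps(self):
        manifest, cubes, backend = scripted_setup(n_groups=8)
        config = LoopConfig(K=4, p0=0.0, delta=0.0, seed=0, algorithm="alg2",
                            max_iterations=8)
        result = run(manifest, config, make_oracle(manifest), backend, cubes)
        curve = annotation_curve(result)
        assert (np.diff(curve["manual_count"]) == 0).any()

    def test_empty_history_rejected(self):
        with pytest.raises(ValidationError):
            annotation_curve(pd.DataFrame())


def test_end_to_end_on_separable_data(separable_dataset):
    """The full loop on well-separated synthetic data finishes at the
    fully annotated model's accuracy level."""
    manifest, cubes = separable_dataset
    from alcube import ReferenceClassifier

    config = LoopConfig(seed=0, algorithm="alg2", criterion="entropy", max_iterations=60)
    result = run(manifest, config, make_oracle(manifest), ReferenceClassifier(), cubes)
    assert float(result.history["accuracy"].iloc[-1]) >= 0.9
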