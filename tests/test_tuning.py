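"""Fold stratification, the density-at-estimate objective, tuning and CV."""

import numpy as np
import pytest

from skyline._records import EstimateSet, ImageRecord
from skyline.ground_truth import fit_density
from skyline.tuning import (
    DEFAULT_SPACES,
    ParamSpace,
    TuneBudget,
    cross_validate,
    estimate_horizon,
    objective,
    stratified_folds,
    tune,
)


def _spike_corpus(n, position=0.55, seed=0, classes=("coast", "city")):
    """Tiny corpus whose densities are identical floor-bandwidth spikes."""
    rng = np.random.default_rng(seed)
    corpus = []
    for i in range(n):
        px = rng.integers(0, 256, (48, 64, 3), dtype=np.uint8)
        rec = ImageRecord(
            f"img{i:03d}", px, classes[i % len(classes)], position
        )
        est = EstimateSet(rec.id, [position] * 12)
        corpus.append((rec, est))
    densities = {rec.id: fit_density(est) for rec, est in corpus}
    return corpus, densities


class TestStratifiedFolds:
    def test_equal_fold_sizes(self, small_corpus, small_densities):
        folds = stratified_folds(small_corpus, small_densities, k=5, seed=0)
        sizes = [len(folds.fold_ids(f)) for f in range(5)]
        assert sizes == [4] * 5
        assert sorted(folds.assignments) == sorted(
            r.id for r, _ in small_corpus
        )

    def test_two_class_balance_reaches_exact_split(self):
        corpus, densities = _spike_corpus(20)
        folds = stratified_folds(corpus, densities, k=2, seed=3,
                                 n_iterations=2000)
        for f in range(2):
            classes = [
                c for (r, _), c in zip(
                    corpus, (r.scene_class for r, _ in corpus)
                )
                if folds.assignments[r.id] == f
            ]
            assert classes.count("coast") == 5
            assert classes.count("city") == 5
        # identical spike densities: the class term can reach 0, so the
        # exhaustively attainable optimum J = 0 is reached
        assert folds.report["cost"] == pytest.approx(0.0, abs=1e-12)

    def test_hill_climb_never_worse_than_initial(
        self, small_corpus, small_densities
    ):
        initial = stratified_folds(
            small_corpus, small_densities, k=4, seed=9, n_iterations=0
        )
        improved = stratified_folds(
            small_corpus, small_densities, k=4, seed=9, n_iterations=1500
        )
        assert improved.report["cost"] <= initial.report["cost"] + 1e-12

    def test_deterministic(self, small_corpus, small_densities):
        a = stratified_folds(small_corpus, small_densities, k=4, seed=2)
        b = stratified_folds(small_corpus, small_densities, k=4, seed=2)
        assert a.assignments == b.assignments

    def test_k_below_two_rejected(self, small_corpus, small_densities):
        with pytest.raises(ValueError):
            stratified_folds(small_corpus, small_densities, k=1)


class TestObjective:
    def test_spike_density_at_forced_position(self):
        corpus, densities = _spike_corpus(1, position=0.5)
        # dum2 with zero spread always answers its mean
        val = objective(
            "dum2", "none", {"center": 0.5, "spread": 0.0},
            [corpus[0][0]], densities,
        )
        assert val == pytest.approx(79.79, abs=0.01)

    def test_far_estimates_give_negligible_objective(self):
        corpus, densities = _spike_corpus(3, position=0.9)
        val = objective(
            "dum2", "none", {"center": 0.05, "spread": 0.0},
            [r for r, _ in corpus], densities,
        )
        assert val < 1e-10

    def test_mean_of_two_hand_computed_confidences(self):
        from skyline.ground_truth import confidence

        corpus, densities = _spike_corpus(2, position=0.6)
        val = objective(
            "dum2", "none", {"center": 0.58, "spread": 0.0},
            [r for r, _ in corpus], densities,
        )
        want = np.mean(
            [confidence(densities[r.id], 0.58) for r, _ in corpus]
        )
        assert val == pytest.approx(want, rel=1e-9)

    def test_missing_density_rejected(self, small_corpus, small_densities):
        rec = small_corpus[0][0]
        with pytest.raises(ValueError, match="density"):
            objective("lin", "L", {}, [rec], {})


class TestEstimateHorizon:
    def test_lin_finds_coast_horizon(self):
        from skyline.scene_synth import SceneSpec, make_scene

        rec = make_scene(
            SceneSpec("coast", 0.5, width=64, height=64, texture_noise_sd=0.0)
        )
        y = estimate_horizon("lin", "L", {"smoothing_sigma": 0.5}, rec)
        assert abs(y - 0.5) <= 2 / 64

    def test_condition_maps_back_to_full_coordinates(self):
        from skyline.scene_synth import SceneSpec, make_scene

        rec = make_scene(
            SceneSpec("coast", 0.5, width=66, height=66, texture_noise_sd=0.0)
        )
        y_norm = estimate_horizon("lin", "L", {"smoothing_sigma": 0.5}, rec)
        y_low = estimate_horizon(
            "lin", "L", {"smoothing_sigma": 0.5}, rec, condition="lower"
        )
        assert abs(y_low - y_norm) <= 2 / 44  # window has 44 rows

    def test_dummies_never_read_pixels(self):
        # image argument is ignored entirely for the dummies
        corpus, _ = _spike_corpus(1)
        a = estimate_horizon(
            "dum1", "none", {"center": 0.4, "spread": 0.1}, corpus[0][0],
            seed=5,
        )
        other = ImageRecord(
            "x", np.zeros((8, 8, 3), np.uint8), "coast", 0.5
        )
        b = estimate_horizon(
            "dum1", "none", {"center": 0.4, "spread": 0.1}, other, seed=5
        )
        assert a == b


class TestParamSpace:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            ParamSpace({"x": (2.0, 1.0, False, False)})
        with pytest.raises(ValueError):
            ParamSpace({"x": (0.0, 1.0, True, False)})

    def test_vector_round_trip(self, rng):
        space = DEFAULT_SPACES["van"]
        p = space.sample(rng)
        q = space.from_vector(space.to_vector(p))
        for name in space.names:
            assert q[name] == pytest.approx(p[name], rel=1e-9)

    def test_integer_parameters_are_integral(self, rng):
        space = DEFAULT_SPACES["van"]
        for _ in range(20):
            p = space.sample(rng)
            assert p["n_lines"] == int(p["n_lines"])


class TestTune:
    def test_dum2_recovers_planted_spike(self):
        corpus, densities = _spike_corpus(6, position=0.55)
        folds = stratified_folds(corpus, densities, k=2, seed=0)
        result = tune(
            "dum2", "none", folds, corpus, densities,
            budget=TuneBudget(n_random=60, n_refine_starts=2,
                              refine_max_iter=80),
            seed=1,
        )
        for f in range(2):
            assert result.best_params[f]["center"] == pytest.approx(
                0.55, abs=0.01
            )
            lo = DEFAULT_SPACES["dum2"].bounds["spread"][0]
            assert result.best_params[f]["spread"] <= lo + 0.02

    def test_budget_accounting(self):
        corpus, densities = _spike_corpus(4)
        folds = stratified_folds(corpus, densities, k=2, seed=0)
        result = tune(
            "dum1", "none", folds, corpus, densities,
            budget=TuneBudget(n_random=1, n_refine_starts=0),
            seed=0,
        )
        assert all(
            result.trace[f]["n_evaluations"] == 1 for f in range(folds.k)
        )

    def test_refinement_never_below_best_random(self):
        corpus, densities = _spike_corpus(6)
        folds = stratified_folds(corpus, densities, k=2, seed=0)
        result = tune(
            "dum2", "none", folds, corpus, densities,
            budget=TuneBudget(n_random=10, n_refine_starts=1,
                              refine_max_iter=30),
            seed=4,
        )
        for f in range(2):
            best_random = max(
                e["objective"] for e in result.trace[f]["evaluations"]
            )
            assert result.best_objective[f] >= best_random - 1e-12

    def test_reproducible(self):
        corpus, densities = _spike_corpus(4)
        folds = stratified_folds(corpus, densities, k=2, seed=0)
        kw = dict(budget=TuneBudget(n_random=5, n_refine_starts=0), seed=7)
        a = tune("dum1", "none", folds, corpus, densities, **kw)
        b = tune("dum1", "none", folds, corpus, densities, **kw)
        assert a.best_params == b.best_params
        assert a.trace == b.trace


@pytest.fixture(scope="module")
def tuned():
    corpus, densities = _spike_corpus(12)
    folds = stratified_folds(corpus, densities, k=3, seed=0)
    result = tune(
        "dum2", "none", folds, corpus, densities,
        budget=TuneBudget(n_random=5, n_refine_starts=0), seed=2,
    )
    return corpus, densities, folds, result


class TestCrossValidate:
    def test_each_image_scored_exactly_once(self, tuned):
        corpus, densities, folds, result = tuned
        table = cross_validate(
            "dum2", "none", folds, result, corpus, densities
        )
        assert len(table) == 12
        assert sorted(table.image_id) == sorted(r.id for r, _ in corpus)

    def test_norm_condition_equals_default(self, tuned):
        corpus, densities, folds, result = tuned
        a = cross_validate("dum2", "none", folds, result, corpus, densities,
                           seed=3)
        b = cross_validate("dum2", "none", folds, result, corpus, densities,
                           condition="norm", seed=3)
        assert a.equals(b)

    def test_no_leakage_provenance(self, tuned):
        corpus, densities, folds, result = tuned
        for image_id, fold in folds.assignments.items():
            assert image_id not in result.training_ids[fold]

    def test_missing_fold_params_rejected(self, tuned):
        corpus, densities, folds, result = tuned
        broken = type(result)(
            algorithm=result.algorithm,
            channel=result.channel,
            best_params={0: result.best_params[0]},
            best_objective={0: result.best_objective[0]},
            trace={},
            training_ids={},
        )
        with pytest.raises(ValueError, match="folds"):
            cross_validate("dum2", "none", folds, broken, corpus, densities)


def test_gst_objective_runs_inner_cv():
    """A gst parameter evaluation trains mixtures behind an inner 3-fold
    split and yields a finite mean confidence."""
    from skyline.scene_synth import make_corpus
    from skyline.ground_truth import fit_density, remove_outliers

    corpus = make_corpus(12, width=48, height=48, seed=3)
    densities = {
        r.id: fit_density(remove_outliers(e)) for r, e in corpus
    }
    val = objective(
        "gst", "all", {"K": 1, "pca_dim": 8},
        [r for r, _ in corpus], densities,
    )
    assert np.isfinite(val) and val >= 0
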