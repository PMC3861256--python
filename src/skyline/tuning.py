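"""Stratified fold partitioning and per-fold hyperparameter tuning.

The corpus is split into k folds that balance both scene-class proportions
and mean ground-truth density peaks (a proxy for image difficulty), by
hill-climbing pairwise swaps from a seeded random equal split. For each
fold, each algorithm/channel pair is tuned on the union of the other k-1
folds — random search over the parameter space followed by Nelder–Mead
refinement from the best starts — and then evaluated exactly once per image
on the left-out fold, so no image's test parameters were ever fitted on its
own fold.

The training objective is the mean *confidence*: the per-image ground-truth
density evaluated at the winner-takes-all estimate (or, for the holistic
``gst`` pathway, at the mixture prediction; each ``gst`` parameter
evaluation wraps an internal 3-fold cross-validation because scoring a
parameter setting requires training a regressor). The image-blind dummies
are averaged over 10 seeded runs to integrate out their randomness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import estimators as est
from . import gist_regressor as gist
from .ground_truth import GroundTruthDensity, confidence
from .imagery import ConditionSpec, apply_condition, to_full_coords, to_lab

__all__ = [
    "ALGORITHMS",
    "DEFAULT_SPACES",
    "FoldPartition",
    "ParamSpace",
    "TuneBudget",
    "TuneResult",
    "stratified_folds",
    "estimate_horizon",
    "objective",
    "tune",
    "cross_validate",
]

logger = logging.getLogger("skyline")

ALGORITHMS = ("div", "-div", "lin", "gab", "van", "gst", "dum1", "dum2")


# ---------------------------------------------------------------------------
# Parameter spaces


@dataclass
class ParamSpace:
    """Searchable box per parameter: (low, high, log-scale?, integer?)."""

    bounds: dict[str, tuple[float, float, bool, bool]]

    def __post_init__(self) -> None:
        for name, (lo, hi, is_log, _) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r}: lower must be < upper")
            if is_log and lo <= 0:
                raise ValueError(f"log-scale bounds for {name!r} must be > 0")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name, (lo, hi, is_log, is_int) in self.bounds.items():
            if is_log:
                v = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            else:
                v = rng.uniform(lo, hi)
            out[name] = round(v) if is_int else v
        return out

    def to_vector(self, params: dict[str, float]) -> np.ndarray:
        return np.array(
            [
                math.log(params[n]) if self.bounds[n][2] else params[n]
                for n in self.names
            ]
        )

    def from_vector(self, vec: np.ndarray) -> dict[str, float]:
        """Integers stay relaxed during refinement and are rounded here,
        at evaluation; values are clipped back into their boxes."""
        out = {}
        for n, v in zip(self.names, vec):
            lo, hi, is_log, is_int = self.bounds[n]
            if is_log:
                v = math.exp(v)
            v = min(max(float(v), lo), hi)
            out[n] = round(v) if is_int else v
        return out


DEFAULT_SPACES: dict[str, ParamSpace] = {
    "div": ParamSpace(
        {"smoothing_sigma": (0.1, 5.0, True, False),
         "local_weight": (0.0, 1.0, False, False)}
    ),
    "-div": ParamSpace(
        {"smoothing_sigma": (0.1, 5.0, True, False),
         "local_weight": (0.0, 1.0, False, False)}
    ),
    "lin": ParamSpace({"smoothing_sigma": (0.1, 5.0, True, False)}),
    "gab": ParamSpace(
        {"wavelength": (4.0, 32.0, True, False),
         "bandwidth": (0.5, 2.0, False, False),
         "selectivity": (0.2, 1.0, False, False)}
    ),
    "van": ParamSpace(
        {"canny_sigma": (1.0, 4.0, True, False),
         "canny_low": (0.5, 3.0, False, False),
         "canny_gap": (1.0, 8.0, False, False),
         "exponent_rho": (1.0, 4.0, False, False),
         "n_lines": (5, 40, False, True)}
    ),
    "gst": ParamSpace(
        {"K": (1, 5, False, True), "pca_dim": (8, 64, True, True)}
    ),
    "dum1": ParamSpace(
        {"center": (0.0, 1.0, False, False),
         "spread": (0.01, 0.5, False, False)}
    ),
    "dum2": ParamSpace(
        {"center": (0.0, 1.0, False, False),
         "spread": (0.005, 0.3, False, False)}
    ),
}


# ---------------------------------------------------------------------------
# Stratified folds


@dataclass
class FoldPartition:
    assignments: dict[str, int]
    k: int
    report: dict = field(default_factory=dict)

    def fold_of(self, image_id: str) -> int:
        return self.assignments[image_id]

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]


def _partition_cost(
    fold_idx: np.ndarray, classes: np.ndarray, peaks_std: np.ndarray, k: int,
    class_labels: np.ndarray, global_props: np.ndarray,
) -> float:
    cost = 0.0
    for f in range(k):
        mask = fold_idx == f
        props = np.array(
            [(classes[mask] == c).mean() for c in class_labels]
        )
        cost += np.abs(props - global_props).sum()
        cost += abs(peaks_std[mask].mean())  # global standardized mean is 0
    return cost


def stratified_folds(
    corpus,
    densities: dict[str, GroundTruthDensity],
    k: int = 10,
    seed: int = 0,
    n_iterations: int = 2000,
) -> FoldPartition:
    """Split the corpus into k folds balanced in class mix and difficulty.

    Starts from a seeded random equal-size split (fold sizes differ by at
    most one) and hill-climbs over pairwise swaps that decrease the combined
    cost: the L1 deviation of per-fold class proportions from the global
    proportions plus, with equal weight after standardization, the absolute
    per-fold mean of standardized density peaks.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    records = [rec for rec, *_ in (
        (item if isinstance(item, tuple) else (item,)) for item in corpus
    )]
    n = len(records)
    if n < k:
        raise ValueError(f"corpus size {n} smaller than k={k}")
    ids = np.array([r.id for r in records])
    classes = np.array([r.scene_class for r in records])
    peaks = np.array([densities[r.id].peak for r in records])
    sd = peaks.std()
    peaks_std = (peaks - peaks.mean()) / (sd if sd > 0 else 1.0)
    class_labels = np.unique(classes)
    global_props = np.array(
        [(classes == c).mean() for c in class_labels]
    )

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_idx = np.empty(n, dtype=int)
    fold_idx[order] = np.arange(n) % k

    cost = _partition_cost(
        fold_idx, classes, peaks_std, k, class_labels, global_props
    )
    for _ in range(n_iterations):
        i, j = rng.integers(0, n, size=2)
        if fold_idx[i] == fold_idx[j]:
            continue
        fold_idx[i], fold_idx[j] = fold_idx[j], fold_idx[i]
        new_cost = _partition_cost(
            fold_idx, classes, peaks_std, k, class_labels, global_props
        )
        if new_cost < cost:
            cost = new_cost
        else:
            fold_idx[i], fold_idx[j] = fold_idx[j], fold_idx[i]

    report = {"cost": cost, "per_fold": {}}
    for f in range(k):
        mask = fold_idx == f
        report["per_fold"][f] = {
            "size": int(mask.sum()),
            "class_proportions": {
                str(c): float((classes[mask] == c).mean())
                for c in class_labels
            },
            "mean_peak_density": float(peaks[mask].mean()),
        }
    return FoldPartition(
        assignments=dict(zip(ids.tolist(), fold_idx.tolist())), k=k,
        report=report,
    )


# ---------------------------------------------------------------------------
# Estimation dispatch


def _build_profile(
    algorithm: str, channel_array: np.ndarray, params: dict[str, float]
) -> est.ConfidenceProfile:
    if algorithm in ("div", "-div"):
        p = est.DivParams(
            smoothing_sigma=params.get("smoothing_sigma", 1.0),
            local_weight=params.get("local_weight", 0.5),
        )
        polarity = "light_above" if algorithm == "div" else "dark_above"
        return est.profile_div(channel_array, p, polarity)
    if algorithm == "lin":
        return est.profile_lin(
            channel_array, params.get("smoothing_sigma", 1.0)
        )
    if algorithm == "gab":
        p = est.GaborParams(
            wavelength=params.get("wavelength", 8.0),
            bandwidth=params.get("bandwidth", 1.0),
            selectivity=params.get("selectivity", 0.5),
        )
        return est.profile_gab(channel_array, p)
    if algorithm == "van":
        low = params.get("canny_low", 1.0)
        p = est.VanParams(
            canny_sigma=params.get("canny_sigma", 2.0),
            canny_low=low,
            canny_high=low + params.get("canny_gap", 4.0),
            exponent_rho=params.get("exponent_rho", 2.0),
            n_lines=int(params.get("n_lines", 20)),
        )
        return est.profile_van(channel_array, p)
    raise ValueError(f"unknown profile algorithm {algorithm!r}")


def _conditioned_lab(image, condition: str, condition_seed: int):
    """Lab channels of the conditioned image, memoized on the record.

    The conversion is deterministic in (condition, seed), and tuning
    evaluates the same conditioned image hundreds of times, so the cache
    turns an O(evaluations) cost into O(conditions).
    """
    key = (condition, condition_seed)
    cache = getattr(image, "_lab_cache", None)
    if cache is None:
        cache = {}
        try:
            object.__setattr__(image, "_lab_cache", cache)
        except AttributeError:  # non-cacheable image object
            pass
    if key not in cache:
        cond, cmap = apply_condition(
            image, ConditionSpec(condition, seed=condition_seed)
        )
        cache[key] = (to_lab(cond), cmap)
    return cache[key]


def estimate_horizon(
    algorithm: str,
    channel: str,
    params: dict[str, float],
    image,
    condition: str = "norm",
    seed: int = 0,
    condition_seed: int = 0,
) -> float:
    """Estimate one image's horizon in full-image normalized coordinates.

    Applies the condition transform, runs the algorithm on the requested
    L*a*b* channel of the conditioned image, and maps the winner-takes-all
    estimate back through the condition's coordinate map.
    """
    if algorithm in ("dum1", "dum2"):
        p = est.DummyParams(
            kind="uniform" if algorithm == "dum1" else "normal",
            center=params.get("center", 0.5),
            spread=params.get("spread", 0.25),
        )
        return est.dummy_estimate(p, seed)
    lab, cmap = _conditioned_lab(image, condition, condition_seed)
    profile = _build_profile(algorithm, lab.channel(channel), params)
    y_window = est.winner_takes_all(profile)
    y_full, _ = to_full_coords(y_window, cmap)
    return y_full


# ---------------------------------------------------------------------------
# Objective


def _gst_targets(images, densities) -> np.ndarray:
    """Regression targets: mean retained estimate per image."""
    return np.array(
        [float(np.mean(densities[im.id].sample_points)) for im in images]
    )


def _gst_descriptor(image, condition: str, condition_seed: int = 0):
    """Spatial-envelope descriptor of the conditioned image, memoized."""
    key = ("gist", condition, condition_seed)
    cache = getattr(image, "_lab_cache", None)
    if cache is not None and key in cache:
        return cache[key]
    lab, _ = _conditioned_lab(image, condition, condition_seed)
    desc = gist.gist_descriptor(lab)
    cache = getattr(image, "_lab_cache", None)
    if cache is not None:
        cache[key] = desc
    return desc


def _gst_objective(
    params: dict[str, float],
    images,
    densities,
    condition: str,
    seed: int,
    inner_folds: int = 3,
) -> float:
    """Mean held-out confidence of the mixture under an inner 3-fold CV."""
    descriptors = [_gst_descriptor(im, condition) for im in images]
    targets = _gst_targets(images, densities)
    n = len(images)
    K = int(params.get("K", 4))
    pca_dim = int(params.get("pca_dim", 64))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [order[f::inner_folds] for f in range(inner_folds)]
    total = 0.0
    for f in range(inner_folds):
        test_idx = folds[f]
        train_idx = np.concatenate(
            [folds[g] for g in range(inner_folds) if g != f]
        )
        if train_idx.size < 2 * K:
            return 0.0
        try:
            mix = gist.fit_mixture(
                [descriptors[i] for i in train_idx],
                targets[train_idx],
                K=K,
                n_restarts=1,
                seed=seed,
                pca_dim=pca_dim,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("gst fit failed for params %s: %s", params, exc)
            return 0.0
        for i in test_idx:
            total += confidence(
                densities[images[i].id], gist.predict(mix, descriptors[i])
            )
    return total / n


def objective(
    algorithm: str,
    channel: str,
    params: dict[str, float],
    images,
    densities: dict[str, GroundTruthDensity],
    condition: str = "norm",
    seed: int = 0,
) -> float:
    """Training objective: mean ground-truth-density confidence of the
    algorithm's estimates over the given images.

    Estimator failures contribute 0 for the affected image and are logged.
    Dummy objectives are averaged over 10 seeded runs; ``gst`` evaluation
    wraps an inner 3-fold cross-validation (training is part of scoring).
    """
    images = list(images)
    if not images:
        raise ValueError("objective needs at least one image")
    for im in images:
        if im.id not in densities:
            raise ValueError(f"no density for image {im.id!r}")
    if algorithm == "gst":
        return _gst_objective(params, images, densities, condition, seed)
    if algorithm in ("dum1", "dum2"):
        rng = np.random.default_rng(seed)
        runs = []
        for _ in range(10):
            run_seed = int(rng.integers(0, 2**31 - 1))
            total = 0.0
            for i, im in enumerate(images):
                y = estimate_horizon(
                    algorithm, channel, params, im, condition,
                    seed=run_seed + i,
                )
                total += confidence(densities[im.id], y)
            runs.append(total / len(images))
        return float(np.mean(runs))
    total = 0.0
    for im in images:
        try:
            y = estimate_horizon(
                algorithm, channel, params, im, condition, seed=seed
            )
            total += confidence(densities[im.id], y)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning(
                "%s failed on image %s: %s (contributes 0)",
                algorithm, im.id, exc,
            )
    return total / len(images)


# ---------------------------------------------------------------------------
# Tuning


@dataclass
class TuneBudget:
    n_random: int = 500
    n_refine_starts: int = 3
    refine_max_iter: int = 200


@dataclass
class TuneResult:
    algorithm: str
    channel: str
    best_params: dict[int, dict[str, float]]  # fold -> params
    best_objective: dict[int, float]
    trace: dict[int, dict]  # fold -> {n_evaluations, seed, evaluations}
    training_ids: dict[int, list[str]]  # provenance: fold -> tuned-on ids


def tune(
    algorithm: str,
    channel: str,
    folds: FoldPartition,
    corpus,
    densities: dict[str, GroundTruthDensity],
    space: ParamSpace | None = None,
    budget: TuneBudget | None = None,
    seed: int = 0,
    condition: str = "norm",
) -> TuneResult:
    """Per-fold hyperparameter search: random sampling then Nelder–Mead.

    For each fold f, the objective is evaluated on the union of the other
    folds (f's training set) at ``budget.n_random`` seeded samples of the
    space; simplex refinement then starts from the best
    ``budget.n_refine_starts`` samples. Refinement never returns a worse
    objective than its starting point. Deterministic for a fixed seed.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if space is None:
        space = DEFAULT_SPACES[algorithm]
    if not space.bounds:
        raise ValueError("empty parameter space")
    if budget is None:
        budget = TuneBudget()
    if budget.n_random < 1:
        raise ValueError("budget.n_random must be >= 1")

    records = {r.id: r for r, *_ in (
        (item if isinstance(item, tuple) else (item,)) for item in corpus
    )}
    rng = np.random.default_rng(seed)
    best_params: dict[int, dict[str, float]] = {}
    best_obj: dict[int, float] = {}
    trace: dict[int, dict] = {}
    training_ids: dict[int, list[str]] = {}

    for f in range(folds.k):
        train_ids = [
            i for i, ff in folds.assignments.items() if ff != f
        ]
        train_imgs = [records[i] for i in train_ids]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        fold_rng = np.random.default_rng(fold_seed)

        evaluations: list[tuple[dict, float]] = []
        for _ in range(budget.n_random):
            p = space.sample(fold_rng)
            val = objective(
                algorithm, channel, p, train_imgs, densities, condition,
                seed=fold_seed,
            )
            evaluations.append((p, val))

        evaluations.sort(key=lambda e: -e[1])
        best_p, best_v = evaluations[0]
        for start_p, start_v in evaluations[: budget.n_refine_starts]:
            x0 = space.to_vector(start_p)

            def neg(vec: np.ndarray) -> float:
                return -objective(
                    algorithm, channel, space.from_vector(vec), train_imgs,
                    densities, condition, seed=fold_seed,
                )

            res = minimize(
                neg, x0, method="Nelder-Mead",
                options={"maxiter": budget.refine_max_iter,
                         "xatol": 1e-3, "fatol": 1e-4},
            )
            refined_p = space.from_vector(res.x)
            refined_v = -res.fun
            # best-so-far contract: keep the start if refinement regressed
            cand_p, cand_v = (
                (refined_p, refined_v)
                if refined_v >= start_v
                else (start_p, start_v)
            )
            if cand_v > best_v:
                best_p, best_v = cand_p, cand_v
        best_params[f] = best_p
        best_obj[f] = best_v
        trace[f] = {
            "n_evaluations": len(evaluations),
            "seed": fold_seed,
            "evaluations": [
                {"params": p, "objective": v} for p, v in evaluations
            ],
        }
        training_ids[f] = train_ids
        logger.info(
            "tuned %s/%s fold %d: objective %.4f", algorithm, channel, f,
            best_v,
        )
    return TuneResult(
        algorithm=algorithm,
        channel=channel,
        best_params=best_params,
        best_objective=best_obj,
        trace=trace,
        training_ids=training_ids,
    )


def cross_validate(
    algorithm: str,
    channel: str,
    folds: FoldPartition,
    tune_result: TuneResult,
    corpus,
    densities: dict[str, GroundTruthDensity],
    condition: str = "norm",
    seed: int = 0,
) -> pd.DataFrame:
    """Score every image exactly once with its fold's left-out parameters.

    Each fold's images are scored with the parameter set tuned on the other
    folds; the condition transform is applied before estimation and the
    estimate mapped back to full coordinates. Returns a table with columns
    image_id, algorithm, channel, condition, fold, scene_class, position,
    confidence.
    """
    missing = [f for f in range(folds.k) if f not in tune_result.best_params]
    if missing:
        raise ValueError(f"tune_result lacks parameters for folds {missing}")
    records = {r.id: r for r, *_ in (
        (item if isinstance(item, tuple) else (item,)) for item in corpus
    )}
    rows = []
    rng = np.random.default_rng(seed)
    for f in range(folds.k):
        params = tune_result.best_params[f]
        mixture = None
        if algorithm == "gst":
            train_imgs = [
                records[i] for i, ff in folds.assignments.items() if ff != f
            ]
            descs = [_gst_descriptor(im, "norm") for im in train_imgs]
            mixture = gist.fit_mixture(
                descs,
                _gst_targets(train_imgs, densities),
                K=int(params.get("K", 4)),
                n_restarts=1,
                seed=seed,
                pca_dim=int(params.get("pca_dim", 64)),
            )
        for image_id in folds.fold_ids(f):
            im = records[image_id]
            if algorithm == "gst":
                _, cmap = _conditioned_lab(im, condition, 0)
                desc = _gst_descriptor(im, condition)
                y_window = gist.predict(mixture, desc)
                y, _ = to_full_coords(y_window, cmap)
            else:
                y = estimate_horizon(
                    algorithm, channel, params, im, condition,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            rows.append(
                dict(
                    image_id=image_id,
                    algorithm=algorithm,
                    channel=channel,
                    condition=condition,
                    fold=f,
                    scene_class=im.scene_class,
                    position=y,
                    confidence=confidence(densities[image_id], y),
                )
            )
    return pd.DataFrame(rows)
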