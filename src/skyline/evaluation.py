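"""Aggregation of confidences and human-machine comparison statistics.

Three pieces: group means of confidences by condition and scene type (with
standard errors), the Pearson correlation of two "behavior patterns" — the
labeled vector of 6 per-condition means followed by 7 per-scene-type means
(a 6 x 7 crossed variant is available behind a flag) — and the Shrout-Fleiss
two-way random-effects intraclass correlations ICC(2,1) and ICC(2,k) that
quantify inter-rater reliability.

Because no human data ship with this package, a simulated quick-viewing
rater population is provided as a clearly synthetic stand-in for the human
reference pattern: per-scene-class estimate spreads inflated by
per-condition factors chosen to mirror the reported ordering (inverted and
blurred hurt most, the middle subwindow least).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ground_truth import GroundTruthDensity, confidence
from .imagery import CONDITIONS
from .scene_synth import DEFAULT_ESTIMATE_SD, SCENE_CLASSES

__all__ = [
    "BehaviorPattern",
    "RatingsMatrix",
    "mean_confidence_by",
    "behavior_pattern",
    "behavior_correlation",
    "icc",
    "simulated_human_confidences",
    "CONDITION_SPREAD_FACTOR",
]

# Spread inflation of simulated quick-viewing raters per condition, relative
# to the unlimited-time per-class spread. Synthetic stand-in values encoding
# the reported ordering: inverted/blurred degrade estimates most, the middle
# subwindow least.
CONDITION_SPREAD_FACTOR = {
    "norm": 1.2,
    "inverted": 2.0,
    "blurred": 1.8,
    "lower": 1.25,
    "middle": 1.1,
    "upper": 1.5,
}


@dataclass
class BehaviorPattern:
    """Labeled vector of mean confidences: 6 condition cells then 7 scene
    type cells (or the 6 x 7 crossed cells when built with crossed=True)."""

    labels: list[str]
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError("labels and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("behavior pattern cells must all be finite")


@dataclass
class RatingsMatrix:
    """Items x raters matrix of normalized positions with a missing mask."""

    values: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D items x raters matrix")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask must match the ratings shape")

    def complete_rows(self) -> np.ndarray:
        """Items rated by every rater (incomplete items are omitted)."""
        keep = ~self.missing.any(axis=1)
        return self.values[keep]


def mean_confidence_by(
    confidences: pd.DataFrame, grouping: str = "condition"
) -> pd.DataFrame:
    """Group means and standard errors of the confidence column.

    ``grouping`` is one of ``condition``, ``scene_type`` or
    ``condition×scene_type``. Standard error is ``sd / sqrt(n)`` (sample
    sd); single-member groups report a missing SE, and empty groups are
    absent rather than zero.
    """
    if confidences.empty:
        raise ValueError("confidence table is empty")
    df = confidences.rename(columns={"scene_class": "scene_type"})
    cols = {
        "condition": ["condition"],
        "scene_type": ["scene_type"],
        "condition×scene_type": ["condition", "scene_type"],
        "condition x scene_type": ["condition", "scene_type"],
    }.get(grouping)
    if cols is None:
        raise ValueError(f"unknown grouping {grouping!r}")
    grouped = df.groupby(cols, observed=True)["confidence"]
    out = grouped.agg(
        mean="mean",
        se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="size",
    ).reset_index()
    return out


def behavior_pattern(
    confidences: pd.DataFrame, source: str = "", crossed: bool = False
) -> BehaviorPattern:
    """Build the 13-cell behavior pattern (6 condition marginal means
    followed by 7 scene-type marginal means), or the 42 crossed cells."""
    df = confidences.rename(columns={"scene_class": "scene_type"})
    labels: list[str] = []
    values: list[float] = []
    if crossed:
        for cond in CONDITIONS:
            for cls in SCENE_CLASSES:
                sub = df[(df.condition == cond) & (df.scene_type == cls)]
                if sub.empty:
                    raise ValueError(f"no confidences for cell {cond}/{cls}")
                labels.append(f"{cond}:{cls}")
                values.append(float(sub.confidence.mean()))
    else:
        for cond in CONDITIONS:
            sub = df[df.condition == cond]
            if sub.empty:
                raise ValueError(f"no confidences for condition {cond!r}")
            labels.append(f"condition:{cond}")
            values.append(float(sub.confidence.mean()))
        for cls in SCENE_CLASSES:
            sub = df[df.scene_type == cls]
            if sub.empty:
                raise ValueError(f"no confidences for scene type {cls!r}")
            labels.append(f"scene:{cls}")
            values.append(float(sub.confidence.mean()))
    return BehaviorPattern(labels=labels, values=np.array(values),
                           source=source)


def behavior_correlation(
    pattern_a: BehaviorPattern, pattern_b: BehaviorPattern
) -> float:
    """Pearson correlation of two behavior patterns across matching cells.

    Returns NaN (missing) when either pattern has zero variance.
    """
    if pattern_a.labels != pattern_b.labels:
        raise ValueError("behavior patterns have mismatching cell labels")
    a, b = pattern_a.values, pattern_b.values
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def icc(ratings: RatingsMatrix, form: str = "single") -> float:
    """Shrout–Fleiss two-way random-effects intraclass correlation.

    ``form='single'`` gives ICC(2,1), the reliability of a single rater;
    ``form='average'`` gives ICC(2,k), the reliability of the k-rater mean.
    Items with any missing rating are dropped first. With n items, k raters
    and row/column/error mean squares MSR/MSC/MSE:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)
    """
    if form not in ("single", "average"):
        raise ValueError(f"form must be 'single' or 'average', got {form!r}")
    x = ratings.complete_rows()
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(
            f"need at least 2 complete items and 2 raters, got {n} x {k}"
        )
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (msc - mse) / n
    return float((msr - mse) / denom)


def plot_mean_confidence(
    confidences: pd.DataFrame, grouping: str, path
) -> None:
    """Bar plot of group mean confidences with standard-error bars (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = mean_confidence_by(confidences, grouping)
    label_cols = [c for c in table.columns if c not in ("mean", "se", "n")]
    labels = table[label_cols].astype(str).agg("/".join, axis=1)
    fig, ax = plt.subplots(figsize=(max(4, 0.7 * len(table)), 3.2))
    ax.bar(labels, table["mean"], yerr=table["se"].fillna(0.0), capsize=3)
    ax.set_ylabel("mean confidence")
    ax.set_xlabel(grouping)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def simulated_human_confidences(
    corpus,
    densities: dict[str, GroundTruthDensity],
    conditions=CONDITIONS,
    n_raters: int = 18,
    seed: int = 0,
) -> pd.DataFrame:
    """Confidence table for a synthetic quick-viewing rater population.

    A stand-in for human reference behavior: per-image estimates are drawn
    from a truncated normal around the true horizon with the class spread
    inflated by the condition factor, then scored against the ground-truth
    densities. Columns match :func:`skyline.tuning.cross_validate` output
    with algorithm='human'.
    """
    from .scene_synth import simulate_estimates

    rng = np.random.default_rng(seed)
    rows = []
    for item in corpus:
        rec = item[0] if isinstance(item, tuple) else item
        for cond in conditions:
            sd = DEFAULT_ESTIMATE_SD[rec.scene_class] * (
                CONDITION_SPREAD_FACTOR[cond]
            )
            ests = simulate_estimates(
                rec.true_horizon, sd, n=n_raters, contamination=0.02,
                seed=int(rng.integers(0, 2**31 - 1)), image_id=rec.id,
            )
            for pos in ests.positions:
                rows.append(
                    dict(
                        image_id=rec.id,
                        algorithm="human",
                        channel="",
                        condition=cond,
                        scene_class=rec.scene_class,
                        position=float(pos),
                        confidence=confidence(densities[rec.id], float(pos)),
                    )
                )
    return pd.DataFrame(rows)
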