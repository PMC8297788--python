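"""One-vs-all random-forest classification of window features.

Each behavior is predicted against the union of all others.  Rare classes
(drinking, sleeping in a typical cohort) are up-sampled threefold with
concomitant down-sampling of the majority class; the common classes are
balanced 1:1 by down-sampling negatives only.  Three validation schemes
mirror the study design: a stratified 70/30 holdout, 5-fold stratified
cross-validation, and leave-one-animal-out (LOOA), which probes
between-animal generalization.

Note on fidelity: consecutive 120 s windows overlap by 119.5 s, so row-level
random splitting shares nearly identical windows between train and test and
measures within-session interpolation rather than generalization.  That
replicates the original design; ``make_split(..., scheme="holdout_70_30",
by_block=True)`` splits by contiguous session blocks instead for an honest
out-of-sample estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from rumipress.evaluation import (
    METRIC_COLUMNS,
    ConfusionMatrix,
    PerformanceMetrics,
    confusion,
    metrics,
)

__all__ = [
    "BalanceConfig",
    "ForestSpec",
    "SplitPlan",
    "default_balance",
    "balance_classes",
    "make_split",
    "train_one_vs_all",
    "predict",
    "run_validation",
]

_SCHEMES = ("holdout_70_30", "scv_5fold", "looa")


@dataclass(frozen=True)
class BalanceConfig:
    """Class rebalancing for one one-vs-all problem."""

    target_behavior: str
    upsample_factor: int = 1
    balance_ratio: float = 1.0  # negatives : positives after balancing

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.balance_ratio <= 0:
            raise ValueError("balance_ratio must be positive")


def default_balance(behavior: str) -> BalanceConfig:
    """Threefold up-sampling for the rare classes, plain 1:1 otherwise."""
    factor = 3 if behavior in ("drinking", "sleeping") else 1
    return BalanceConfig(target_behavior=behavior, upsample_factor=factor)


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest hyperparameters (conventional defaults, config-exposed)."""

    n_trees: int = 500
    features_per_split: int = 5  # floor(sqrt(30))
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.features_per_split <= 30:
            raise ValueError("features_per_split must be in 1..30")


@dataclass(frozen=True)
class SplitPlan:
    """Row-to-fold assignment for one validation scheme.

    ``folds`` maps fold id -> integer row positions of that fold's **test**
    rows.  For the holdout scheme there is a single fold ``0`` (the 30%
    test set); for SCV five folds; for LOOA one per cow (keyed by cow_id).
    """

    scheme: str
    folds: dict[object, np.ndarray]
    seed: int


def balance_classes(
    features: pd.DataFrame, config: BalanceConfig, seed: int = 0
) -> pd.DataFrame:
    """Up-sample positives and down-sample negatives to the target ratio.

    Every original positive row is kept at least once; with
    ``upsample_factor`` f > 1, a further (f-1)*n_pos positives are drawn with
    replacement.  Negatives are then down-sampled without replacement to
    ``balance_ratio`` x the positive count, and the result is shuffled
    deterministically.
    """
    rng = np.random.default_rng(seed)
    is_pos = (features["label"] == config.target_behavior).to_numpy()
    pos = features.loc[is_pos]
    neg = features.loc[~is_pos]
    if len(pos) == 0:
        raise ValueError(f"no rows labeled {config.target_behavior!r} to balance")
    parts = [pos]
    extra = (config.upsample_factor - 1) * len(pos)
    if extra:
        parts.append(pos.iloc[rng.integers(0, len(pos), size=extra)])
    n_pos_out = len(pos) * config.upsample_factor
    n_neg_out = int(round(config.balance_ratio * n_pos_out))
    if n_neg_out > len(neg):
        n_neg_out = len(neg)  # cannot invent negatives
    parts.append(neg.iloc[rng.choice(len(neg), size=n_neg_out, replace=False)])
    out = pd.concat(parts, ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


def make_split(
    features: pd.DataFrame, scheme: str, seed: int = 0, by_block: bool = False
) -> SplitPlan:
    """Build the fold plan for one of the three validation schemes.

    Stratification uses the (multiclass) ``label`` column so every fold
    preserves behavior prevalence; LOOA folds are one per distinct cow.
    ``by_block`` (holdout only) assigns each cow's last 30% of windows, in
    time order, to the test set instead of sampling rows — overlapping
    windows then never leak between train and test.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    y = features["label"].to_numpy()
    folds: dict[object, np.ndarray] = {}
    if scheme == "holdout_70_30":
        if by_block:
            test_parts = []
            for cow in sorted(set(features["cow_id"].astype(str))):
                rows = np.flatnonzero(features["cow_id"].astype(str) == cow)
                order = rows[np.argsort(features["window_end_s"].iloc[rows].to_numpy(),
                                        kind="stable")]
                n_test = int(round(0.30 * len(order)))
                test_parts.append(order[len(order) - n_test:])
            folds[0] = np.sort(np.concatenate(test_parts))
        else:
            splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.30,
                                              random_state=seed)
            _, test_idx = next(splitter.split(np.zeros(len(y)), y))
            folds[0] = np.sort(test_idx)
    elif scheme == "scv_5fold":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        for i, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            folds[i] = np.sort(test_idx)
    else:  # looa
        cows = features["cow_id"].astype(str).to_numpy()
        unique = sorted(set(cows))
        if len(unique) < 2:
            raise ValueError("leave-one-animal-out needs at least 2 distinct cows")
        for cow in unique:
            folds[cow] = np.flatnonzero(cows == cow)
    return SplitPlan(scheme=scheme, folds=folds, seed=seed)


def _feature_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns
            if c not in ("label", "cow_id", "window_end_s")]


def train_one_vs_all(
    train: pd.DataFrame, target_behavior: str, spec: ForestSpec | None = None
) -> RandomForestClassifier:
    """Fit a random forest for one behavior against all others."""
    spec = spec or ForestSpec()
    cols = _feature_columns(train)
    y = (train["label"] == target_behavior).to_numpy()
    if y.all() or not y.any():
        raise ValueError(
            f"training data contains a single class for {target_behavior!r}"
        )
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.features_per_split,
        min_samples_leaf=spec.min_leaf,
        random_state=spec.seed,
        n_jobs=1,
    )
    clf.fit(train[cols].to_numpy(), y)
    clf.feature_names_ = list(cols)
    return clf


def predict(clf: RandomForestClassifier, features: pd.DataFrame) -> np.ndarray:
    """Per-row binary predictions: majority vote over trees, ties negative.

    Columns bind by name, so column order in ``features`` is irrelevant.
    """
    cols = getattr(clf, "feature_names_", None)
    if cols is None:
        raise ValueError("classifier was not trained by train_one_vs_all")
    missing = set(cols) - set(features.columns)
    if missing:
        raise ValueError(f"missing feature column(s): {sorted(missing)}")
    proba = clf.predict_proba(features[cols].to_numpy())
    pos_col = int(np.flatnonzero(clf.classes_)[0])
    return proba[:, pos_col] > 0.5


def run_validation(
    features: pd.DataFrame,
    target_behavior: str,
    scheme: str,
    balance: BalanceConfig | None = None,
    spec: ForestSpec | None = None,
    seed: int = 0,
    by_block: bool = False,
) -> tuple[list[tuple[object, ConfusionMatrix, PerformanceMetrics]], pd.DataFrame]:
    """Balance, split, train and score one behavior under one scheme.

    Balancing is applied to the full feature set before splitting (the
    default, matching resampled count reporting); per-fold metrics are
    returned together with a mean/SD aggregate across folds.
    """
    balance = balance or default_balance(target_behavior)
    spec = spec or ForestSpec(seed=seed)
    if by_block:
        # resampling duplicates overlapping windows across blocks; keep the
        # original rows so the block boundary stays meaningful
        balanced = features.reset_index(drop=True)
    else:
        balanced = balance_classes(features, balance, seed=seed)
    plan = make_split(balanced, scheme, seed=seed, by_block=by_block)
    all_rows = np.arange(len(balanced))
    results = []
    for fold_id, test_idx in plan.folds.items():
        train_idx = np.setdiff1d(all_rows, test_idx)
        clf = train_one_vs_all(balanced.iloc[train_idx], target_behavior, spec)
        pred = predict(clf, balanced.iloc[test_idx])
        truth = (balanced.iloc[test_idx]["label"] == target_behavior).to_numpy()
        cm = confusion(pred, truth)
        results.append((fold_id, cm, metrics(cm)))
    per_fold = pd.DataFrame(
        [{"fold": fid, "TP": cm.tp, "FP": cm.fp, "TN": cm.tn, "FN": cm.fn,
          **m.as_dict()} for fid, cm, m in results]
    )
    agg = pd.DataFrame({
        "metric": METRIC_COLUMNS,
        "mean": [per_fold[c].mean() for c in METRIC_COLUMNS],
        "sd": [per_fold[c].std(ddof=1) if len(per_fold) > 1 else float("nan")
               for c in METRIC_COLUMNS],
    })
    return results, agg
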