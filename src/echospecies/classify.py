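"""Random-forest species classification with fish-level grouping.

The ten responses of one fish are strongly correlated, so validation splits
are made at the fish level: in no cross-validation repeat does a fish
contribute responses to both the fit and the validation sets.  Response-level
("naive") splitting is also provided to demonstrate how leakage of
within-fish correlation inflates apparent accuracy.

The forest follows the reference configuration: 5000 trees, ``m`` predictors
sampled per split with the default ``m = round(sqrt(p))``, species assigned
by majority vote across trees, and per-predictor importance measured as the
average decrease in Gini node impurity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .io import amplitude_columns, predictor_columns

__all__ = [
    "ForestConfig",
    "CVConfig",
    "CVResult",
    "FittedForest",
    "ClassifierReport",
    "split_by_day",
    "fit_forest",
    "predict_species",
    "grouped_cv",
    "naive_cv",
    "gini_importance",
    "confusion_matrix_from_predictions",
    "confusion_metrics",
    "compare_test_accuracy",
    "compare_cv_accuracy",
    "evaluate_test",
]

SPECIES_ORDER = ("stickleback", "whitefish")


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings; ``m_try=None`` means round(sqrt(p))."""

    n_trees: int = 5000
    m_try: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.m_try is not None and self.m_try < 1:
            raise ValueError("m_try must be at least 1")

    def resolve_m_try(self, p: int) -> int:
        if self.m_try is not None:
            if self.m_try > p:
                raise ValueError(f"m_try={self.m_try} exceeds predictor count {p}")
            return self.m_try
        return max(1, int(np.floor(np.sqrt(p) + 0.5)))


@dataclass(frozen=True)
class CVConfig:
    """Repeated leave-fish-out cross-validation settings."""

    n_repeats: int = 30
    holdout_fraction_of_fish: float = 0.10
    stratify_by_species: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction_of_fish < 1.0:
            raise ValueError("holdout fraction must lie strictly between 0 and 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


@dataclass
class CVResult:
    accuracies: np.ndarray
    held_out_fish: list[list[str]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


@dataclass
class FittedForest:
    model: RandomForestClassifier
    feature_names: list[str]
    classes: tuple[str, ...]


@dataclass
class ClassifierReport:
    """Full evaluation of one predictor representation (FRC or NFD)."""

    predictor_kind: str
    cv: CVResult | None
    test_accuracy: float
    confusion: pd.DataFrame
    ppv: dict[str, float]
    sensitivity: dict[str, float]
    importance: pd.DataFrame


def split_by_day(
    table: pd.DataFrame,
    train_days: tuple[int, ...] = (1, 3),
    test_days: tuple[int, ...] = (2,),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split responses into training and testing sets by experimental day."""
    if "day" not in table.columns or table["day"].isna().any():
        raise ValueError("every row needs a day label")
    train = table[table["day"].isin(train_days)].reset_index(drop=True)
    test = table[table["day"].isin(test_days)].reset_index(drop=True)
    overlap = set(train["fish_id"]) & set(test["fish_id"])
    if overlap:
        raise ValueError(f"fish present in both train and test days: {sorted(overlap)[:5]}")
    if test.empty:
        warnings.warn("test day subset is empty", stacklevel=2)
    return train, test


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = predictor_columns(table)
    return table[cols].to_numpy(dtype=float), table["species"].to_numpy(), cols


def fit_forest(train: pd.DataFrame, config: ForestConfig = ForestConfig()) -> FittedForest:
    """Fit the random forest on a training table (FRC or NFD format)."""
    x, y, cols = _xy(train)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("training set must contain both species")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.resolve_m_try(x.shape[1]),
        random_state=int(config.seed) % (2**31),
        n_jobs=1,
    )
    model.fit(x, y)
    return FittedForest(model=model, feature_names=cols, classes=classes)


def predict_species(forest: FittedForest, rows: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Majority-vote predictions and per-class vote fractions.

    Ties are broken deterministically in favor of the lexicographically
    first species label.
    """
    x = rows[forest.feature_names].to_numpy(dtype=float)
    votes = forest.model.predict_proba(x)
    order = np.argsort(forest.model.classes_)  # lexicographic class order
    classes = forest.model.classes_[order]
    votes = votes[:, order]
    labels = classes[np.argmax(votes, axis=1)]  # argmax takes first on ties
    return labels, pd.DataFrame(votes, columns=classes)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _sample_fish(rng, fish_by_species, fraction, stratify):
    held = []
    if stratify:
        for sp in sorted(fish_by_species):
            fish = fish_by_species[sp]
            k = max(1, _round_half_up(fraction * len(fish)))
            held.extend(rng.choice(fish, size=k, replace=False))
    else:
        fish = sorted(f for group in fish_by_species.values() for f in group)
        k = max(1, _round_half_up(fraction * len(fish)))
        held.extend(rng.choice(fish, size=k, replace=False))
    return sorted(held)


def grouped_cv(
    table: pd.DataFrame,
    forest_config: ForestConfig = ForestConfig(),
    cv_config: CVConfig = CVConfig(),
) -> CVResult:
    """Repeated leave-fish-out cross-validation.

    Per repeat, ~10% of fish (stratified by species, at least one per
    species) are withheld with all their responses; the forest is fit on the
    remaining fish and accuracy is the fraction of withheld responses
    predicted correctly.
    """
    fish_by_species = {
        sp: sorted(sub["fish_id"].unique()) for sp, sub in table.groupby("species")
    }
    if any(len(f) < 2 for f in fish_by_species.values()):
        raise ValueError("need at least 2 fish per species for grouped CV")
    seeds = np.random.SeedSequence(cv_config.seed).spawn(cv_config.n_repeats)
    accuracies, held_lists = [], []
    for r, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        held = _sample_fish(
            rng, fish_by_species, cv_config.holdout_fraction_of_fish,
            cv_config.stratify_by_species,
        )
        held_mask = table["fish_id"].isin(held)
        fit_set, val_set = table[~held_mask], table[held_mask]
        if fit_set["species"].nunique() < 2 or val_set.empty:
            raise ValueError("degenerate CV split: a species vanished from the fit set")
        forest = fit_forest(
            fit_set, ForestConfig(forest_config.n_trees, forest_config.m_try,
                                  seed=forest_config.seed + r)
        )
        labels, _ = predict_species(forest, val_set)
        accuracies.append(float(np.mean(labels == val_set["species"].to_numpy())))
        held_lists.append(held)
    return CVResult(accuracies=np.asarray(accuracies), held_out_fish=held_lists)


def naive_cv(
    table: pd.DataFrame,
    forest_config: ForestConfig = ForestConfig(),
    cv_config: CVConfig = CVConfig(),
) -> CVResult:
    """Response-level cross-validation that ignores fish identity.

    Withholds ~10% of individual responses at random, so the same fish's
    other responses remain in the fit set.  Provided only to demonstrate the
    optimistic bias this leakage causes relative to :func:`grouped_cv`.
    """
    n = len(table)
    seeds = np.random.SeedSequence(cv_config.seed).spawn(cv_config.n_repeats)
    accuracies = []
    for r, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        k = max(1, _round_half_up(cv_config.holdout_fraction_of_fish * n))
        held_idx = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[held_idx] = True
        fit_set, val_set = table[~mask], table[mask]
        forest = fit_forest(
            fit_set, ForestConfig(forest_config.n_trees, forest_config.m_try,
                                  seed=forest_config.seed + r)
        )
        labels, _ = predict_species(forest, val_set)
        accuracies.append(float(np.mean(labels == val_set["species"].to_numpy())))
    return CVResult(accuracies=np.asarray(accuracies), held_out_fish=[])


def gini_importance(forest: FittedForest, freq_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Per-predictor Gini importance, against frequency (FRC) or feature names."""
    imp = forest.model.feature_importances_
    if freq_grid is not None:
        return pd.DataFrame({"frequency_hz": np.asarray(freq_grid, float), "importance": imp})
    return pd.DataFrame({"feature": forest.feature_names, "importance": imp})


def confusion_matrix_from_predictions(
    true_labels: np.ndarray, predicted_labels: np.ndarray,
    classes: tuple[str, ...] = SPECIES_ORDER,
) -> pd.DataFrame:
    """Confusion matrix with rows = true species, columns = predicted species."""
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true_labels, predicted_labels):
        cm[index[t], index[p]] += 1
    return pd.DataFrame(cm, index=list(classes), columns=list(classes))


def confusion_metrics(cm: pd.DataFrame | np.ndarray) -> dict:
    """Accuracy, per-species PPV and sensitivity from a confusion matrix.

    Exact integer arithmetic: accuracy = trace/total; PPV of a species is
    its diagonal count over its column total; sensitivity the diagonal count
    over its row total.  A zero column total leaves that PPV as NaN (flagged).
    """
    if isinstance(cm, pd.DataFrame):
        labels = list(cm.index)
        counts = cm.to_numpy()
    else:
        counts = np.asarray(cm)
        labels = list(SPECIES_ORDER[: counts.shape[0]])
    if counts.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    total = int(counts.sum())
    accuracy = float(np.trace(counts)) / total
    ppv, sens = {}, {}
    for i, lab in enumerate(labels):
        col = counts[:, i].sum()
        row = counts[i, :].sum()
        ppv[lab] = float(counts[i, i] / col) if col > 0 else float("nan")
        sens[lab] = float(counts[i, i] / row) if row > 0 else float("nan")
    return {"accuracy": accuracy, "ppv": ppv, "sensitivity": sens, "total": total}


def compare_test_accuracy(cm_a: pd.DataFrame | np.ndarray, cm_b: pd.DataFrame | np.ndarray) -> float:
    """Two-sided Fisher exact test on correct/incorrect counts of two methods."""
    a = np.asarray(cm_a if not isinstance(cm_a, pd.DataFrame) else cm_a.to_numpy())
    b = np.asarray(cm_b if not isinstance(cm_b, pd.DataFrame) else cm_b.to_numpy())
    if a.sum() != b.sum():
        raise ValueError("both confusion matrices must cover the same response set")
    table = [
        [int(np.trace(a)), int(a.sum() - np.trace(a))],
        [int(np.trace(b)), int(b.sum() - np.trace(b))],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def compare_cv_accuracy(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sided t-test on two CV accuracy distributions -> (t, df, p)."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 accuracy values per group")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        # degenerate: no variance in either group
        equal = np.isclose(a.mean(), b.mean())
        return (0.0 if equal else np.inf * np.sign(a.mean() - b.mean()),
                float(a.size + b.size - 2), 1.0 if equal else 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def evaluate_test(
    forest: FittedForest, test: pd.DataFrame, predictor_kind: str = "frc",
    cv: CVResult | None = None, freq_grid: np.ndarray | None = None,
) -> ClassifierReport:
    """Predict the test set and assemble the full report."""
    labels, _ = predict_species(forest, test)
    cm = confusion_matrix_from_predictions(test["species"].to_numpy(), labels)
    metrics = confusion_metrics(cm)
    return ClassifierReport(
        predictor_kind=predictor_kind,
        cv=cv,
        test_accuracy=metrics["accuracy"],
        confusion=cm,
        ppv=metrics["ppv"],
        sensitivity=metrics["sensitivity"],
        importance=gini_importance(forest, freq_grid),
    )
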