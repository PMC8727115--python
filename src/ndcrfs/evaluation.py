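"""Benchmarking harness: CV accuracy curves, Jaccard subset comparison,
wins/ties/losses summaries.

The protocol mirrors the standard filter-method benchmark: rank features
once, then for each subset size K report the stratified 5-fold
cross-validated accuracy (percent) of a downstream classifier trained on the
top-K features.  Discretization schemes are fitted on training folds only
and applied to test folds, so no information leaks across the split; a
``discretize_once`` switch reproduces the laxer fit-on-everything protocol.

Two feature subsets are compared with the Jaccard index |S1 n S2|/|S1 u S2|
(1 = identical, 0 = disjoint), and accuracy lists are summarized as
wins/ties/losses at 3-decimal precision, matching how such results are
conventionally tabulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import Dataset
from .discretization import discretize_dataset, fit_scheme, apply as apply_scheme
from .errors import InputError
from .selection import RankedSubset, greedy_select

__all__ = [
    "jaccard_difference",
    "wins_ties_losses",
    "summarize_table",
    "cross_validated_accuracy",
    "make_classifier",
    "BenchmarkReport",
    "benchmark",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("knn", "tree", "svm")


def jaccard_difference(s1, s2) -> float:
    """Jaccard index |S1 n S2| / |S1 u S2| of two feature-identifier sets."""
    a, b = set(s1), set(s2)
    if not a and not b:
        raise InputError("both subsets are empty; the Jaccard index is undefined")
    return len(a & b) / len(a | b)


def wins_ties_losses(reference, competitor, decimals: int = 3) -> tuple[int, int, int]:
    """Count reference > / = / < competitor, compared at printed precision."""
    ref = list(reference)
    comp = list(competitor)
    if len(ref) != len(comp):
        raise InputError("wins_ties_losses needs equal-length value lists")
    wins = ties = losses = 0
    for r, c in zip(ref, comp):
        r, c = round(float(r), decimals), round(float(c), decimals)
        if r > c:
            wins += 1
        elif r == c:
            ties += 1
        else:
            losses += 1
    return wins, ties, losses


def summarize_table(values) -> float:
    """Column mean rounded to 3 decimals (the tables' Average row)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise InputError("cannot average an empty list")
    return float(np.round(vals.mean(), 3))


def make_classifier(name: str, seed: int = 42, **params):
    """Reference classifier adapters (scikit-learn under the hood).

    ``knn`` (3 neighbours), ``tree`` (CART as the C4.5 stand-in) and ``svm``
    (RBF kernel).  Hyperparameters are exposed because the benchmark
    protocol itself fixes none.
    """
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 3), **params)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "svm":
        return SVC(kernel=params.pop("kernel", "rbf"), **params)
    raise InputError(f"unknown classifier {name!r}; available: {CLASSIFIER_NAMES}")


def _fold_matrices(
    dataset: Dataset,
    features: list[str],
    train_idx,
    test_idx,
    discretization: str,
    n_bins: int,
    discretize_once: bool,
    fit_spy=None,
):
    """Integer design matrices for one fold; schemes fitted on train rows only."""
    frame = dataset.frame
    labels_train = dataset.subset_rows(train_idx).class_labels
    cols_train, cols_test = [], []
    for f in features:
        raw = frame[f].to_numpy()
        if dataset.is_discrete(f):
            codes = dataset.column(f).values
            cols_train.append(codes[train_idx])
            cols_test.append(codes[test_idx])
        else:
            fit_rows = slice(None) if discretize_once else train_idx
            fit_values = raw[fit_rows]
            if fit_spy is not None:
                fit_spy(f, np.asarray(fit_values))
            scheme = fit_scheme(
                fit_values,
                dataset.class_labels if discretize_once else labels_train,
                discretization,
                n_bins,
            )
            cols_train.append(apply_scheme(scheme, raw[train_idx]).values)
            cols_test.append(apply_scheme(scheme, raw[test_idx]).values)
    return np.column_stack(cols_train), np.column_stack(cols_test)


def cross_validated_accuracy(
    dataset: Dataset,
    ranking: RankedSubset,
    classifier="knn",
    folds: int = 5,
    seed: int = 42,
    *,
    k_max: int | None = None,
    discretization: str = "caim",
    discretize_once: bool = False,
    classifier_params: dict | None = None,
    _fit_spy=None,
) -> np.ndarray:
    """Mean test-fold accuracy (percent) for each subset size K = 1..k_max.

    Folds are stratified on the class and fixed by ``seed``; the curve is
    invariant to feature order within each prefix because the classifier
    sees an unordered design matrix.
    """
    unknown = [f for f in ranking.order if f not in dataset.feature_names]
    if unknown:
        raise InputError(f"ranking refers to features absent from the dataset: {unknown}")
    k_max = len(ranking.order) if k_max is None else min(k_max, len(ranking.order))
    y = dataset.class_labels.values
    class_counts = np.bincount(y)
    if class_counts.min() < folds:
        raise InputError(
            f"stratification impossible: rarest class has {class_counts.min()} sample(s) "
            f"for {folds} folds"
        )
    proto = (
        make_classifier(classifier, seed, **(classifier_params or {}))
        if isinstance(classifier, str)
        else classifier
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    features = list(ranking.order[:k_max])
    acc = np.zeros((folds, k_max))
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        x_train, x_test = _fold_matrices(
            dataset, features, train_idx, test_idx,
            discretization, 5, discretize_once, _fit_spy,
        )
        for k in range(1, k_max + 1):
            model = clone(proto)
            model.fit(x_train[:, :k], y[train_idx])
            acc[fold_i, k - 1] = np.mean(model.predict(x_test[:, :k]) == y[test_idx])
    return acc.mean(axis=0) * 100.0


@dataclass
class BenchmarkReport:
    """Per-criterion accuracy curves plus subset-difference statistics."""

    curves: dict[str, list[float]]           # criterion -> accuracy (%) at K=1..k_max
    best: dict[str, tuple[float, int]]       # criterion -> (best accuracy, smallest best K)
    rankings: dict[str, list[str]]           # criterion -> selection order (first k_max)
    jaccard: dict[str, dict[str, float]]     # pairwise Jaccard at the final K
    wtl_vs_reference: dict[str, tuple[int, int, int]]
    reference: str
    classifier: str
    folds: int
    seed: int
    k_max: int
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "curves": self.curves,
            "best": {k: {"accuracy": v[0], "k": v[1]} for k, v in self.best.items()},
            "rankings": self.rankings,
            "jaccard_at_final_k": self.jaccard,
            "wins_ties_losses_vs_reference": {
                k: list(v) for k, v in self.wtl_vs_reference.items()
            },
            "reference": self.reference,
            "classifier": self.classifier,
            "folds": self.folds,
            "seed": self.seed,
            "k_max": self.k_max,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        names = list(self.curves)
        lines = [
            f"| K | {' | '.join(names)} |",
            f"|---|{'---|' * len(names)}",
        ]
        for k in range(self.k_max):
            row = " | ".join(f"{self.curves[n][k]:.3f}" for n in names)
            lines.append(f"| {k + 1} | {row} |")
        lines.append("")
        lines.append("Best accuracy (%, smallest best K):")
        for n in names:
            acc, k = self.best[n]
            lines.append(f"- {n}: {acc:.3f} at K={k}")
        return "\n".join(lines)

    def curves_to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"K": k + 1, "criterion": name, "accuracy_percent": v}
            for name, curve in self.curves.items()
            for k, v in enumerate(curve)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def benchmark(
    dataset: Dataset,
    criteria,
    k_max: int = 10,
    classifier: str = "knn",
    folds: int = 5,
    seed: int = 42,
    *,
    beta: float = 0.5,
    discretization: str = "caim",
    discretize_once: bool = False,
    reference: str = "ndcrfs",
    classifier_params: dict | None = None,
) -> BenchmarkReport:
    """Full harness: rank with each criterion, score accuracy curves, compare subsets.

    Rankings are computed on the (once-)discretized full table, as the
    published filter protocol does; the classifier stage re-fits
    discretization per training fold unless ``discretize_once`` is set.
    """
    criteria = list(criteria)
    discrete, _ = discretize_dataset(dataset, discretization)
    k_max = min(k_max, discrete.n_features)
    curves: dict[str, list[float]] = {}
    rankings: dict[str, list[str]] = {}
    for name in criteria:
        ranked = greedy_select(discrete, name, k_max, beta=beta)
        rankings[name] = list(ranked.order)
        curve = cross_validated_accuracy(
            dataset,
            ranked,
            classifier,
            folds,
            seed,
            k_max=k_max,
            discretization=discretization,
            discretize_once=discretize_once,
            classifier_params=classifier_params,
        )
        curves[name] = [float(v) for v in curve]
    best = {}
    for name, curve in curves.items():
        arr = np.asarray(curve)
        k_best = int(arr.argmax())  # smallest argmax
        best[name] = (float(arr[k_best]), k_best + 1)
    jaccard = {
        a: {b: round(jaccard_difference(rankings[a], rankings[b]), 3) for b in criteria}
        for a in criteria
    }
    wtl = {
        name: wins_ties_losses(curves[reference], curves[name])
        for name in criteria
        if reference in curves and name != reference
    }
    return BenchmarkReport(
        curves=curves,
        best=best,
        rankings=rankings,
        jaccard=jaccard,
        wtl_vs_reference=wtl,
        reference=reference,
        classifier=classifier if isinstance(classifier, str) else type(classifier).__name__,
        folds=folds,
        seed=seed,
        k_max=k_max,
        config={
            "criteria": criteria,
            "beta": beta,
            "discretization": discretization,
            "discretize_once": discretize_once,
            "classifier_params": classifier_params or {},
        },
    )
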