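"""Class-aware discretization of continuous columns.

The default scheme is CAIM (class-attribute interdependence maximization):
boundaries are added greedily from the midpoints between consecutive distinct
values, each step keeping the cut that maximizes

    caim = (1 / n_intervals) * sum_r  max_class_count_r ** 2 / total_r

over the quanta matrix, and the search stops once the score no longer
improves and at least as many intervals exist as classes.  Unsupervised
equal-width and equal-frequency binning (default 5 bins) are available as
explicitly labeled fallbacks so results never silently depend on the CAIM
reconstruction.

Cut-point semantics: a value's code is the number of cut-points strictly
below it, so out-of-range values clamp to the edge bins and coding is
monotone in the value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import Dataset
from .errors import InputError
from .info_theory import DiscreteColumn

__all__ = [
    "DiscretizationScheme",
    "fit_caim",
    "fit_equal_width",
    "fit_equal_frequency",
    "fit_scheme",
    "apply",
    "discretize_dataset",
    "schemes_to_json",
    "schemes_from_json",
]

METHODS = ("caim", "equal_width", "equal_frequency")


@dataclass(frozen=True)
class DiscretizationScheme:
    """Ascending cut-points for one column; ``bins = len(cut_points) + 1``."""

    method: str
    cut_points: tuple[float, ...]

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cut_points, dtype=float)
        if cuts.size and np.any(np.diff(cuts) <= 0):
            raise InputError("cut-points must be strictly increasing")

    @property
    def bins(self) -> int:
        return len(self.cut_points) + 1


def apply(scheme: DiscretizationScheme, values) -> DiscreteColumn:
    """Code each value as the number of cut-points strictly below it."""
    v = np.asarray(values, dtype=float)
    codes = np.searchsorted(np.asarray(scheme.cut_points, dtype=float), v, side="left")
    return DiscreteColumn(codes.astype(np.int64), scheme.bins)


def _caim_value(codes: np.ndarray, labels: np.ndarray, n_bins: int, n_classes: int) -> float:
    quanta = np.zeros((n_bins, n_classes), dtype=np.int64)
    np.add.at(quanta, (codes, labels), 1)
    totals = quanta.sum(axis=1)
    occupied = totals > 0
    maxima = quanta[occupied].max(axis=1).astype(float)
    return float(np.sum(maxima**2 / totals[occupied]) / n_bins)


def fit_caim(values, labels: DiscreteColumn) -> DiscretizationScheme:
    """Greedy CAIM fit of cut-points for one continuous column.

    A constant column yields a single-bin scheme; fewer samples than classes
    is rejected.  Candidate boundaries are the midpoints between consecutive
    sorted distinct values, so every trained interval is non-empty.
    """
    v = np.asarray(values, dtype=float)
    y = labels.values
    if v.ndim != 1 or v.size != y.size:
        raise InputError("values and labels must be equal-length 1-D sequences")
    n_classes = labels.alphabet_size
    if v.size < n_classes:
        raise InputError(f"need at least {n_classes} samples (one per class), got {v.size}")
    distinct = np.unique(v)
    if distinct.size < 2:
        return DiscretizationScheme("caim", ())
    candidates = list((distinct[:-1] + distinct[1:]) / 2.0)
    chosen: list[float] = []
    best_global = 0.0
    while candidates:
        scored = []
        for c in candidates:
            cuts = np.sort(np.asarray(chosen + [c]))
            codes = np.searchsorted(cuts, v, side="left")
            scored.append((_caim_value(codes, y, cuts.size + 1, n_classes), c))
        caim, cut = max(scored, key=lambda t: t[0])
        if caim > best_global or len(chosen) + 1 < n_classes:
            chosen.append(cut)
            candidates.remove(cut)
            best_global = caim
        else:
            break
    return DiscretizationScheme("caim", tuple(sorted(chosen)))


def fit_equal_width(values, n_bins: int = 5) -> DiscretizationScheme:
    """Evenly spaced cut-points between the observed min and max."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi or n_bins < 2:
        return DiscretizationScheme("equal_width", ())
    cuts = np.linspace(lo, hi, n_bins + 1)[1:-1]
    return DiscretizationScheme("equal_width", tuple(np.unique(cuts)))


def fit_equal_frequency(values, n_bins: int = 5) -> DiscretizationScheme:
    """Quantile cut-points (duplicates collapsed)."""
    v = np.asarray(values, dtype=float)
    qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    cuts = np.unique(qs)
    cuts = cuts[(cuts > v.min()) & (cuts <= v.max())]
    return DiscretizationScheme("equal_frequency", tuple(cuts))


def fit_scheme(
    values, labels: DiscreteColumn | None, method: str = "caim", n_bins: int = 5
) -> DiscretizationScheme:
    """Dispatch on the method name (``caim`` needs class labels)."""
    if method == "caim":
        if labels is None:
            raise InputError("CAIM is class-aware; labels are required")
        return fit_caim(values, labels)
    if method == "equal_width":
        return fit_equal_width(values, n_bins)
    if method == "equal_frequency":
        return fit_equal_frequency(values, n_bins)
    raise InputError(f"unknown discretization method {method!r}; available: {METHODS}")


def discretize_dataset(
    dataset: Dataset,
    method: str = "caim",
    n_bins: int = 5,
    *,
    schemes: dict[str, DiscretizationScheme] | None = None,
) -> tuple[Dataset, dict[str, DiscretizationScheme]]:
    """Replace every continuous column by its discrete codes.

    When ``schemes`` is given (e.g. fitted on a training fold) they are
    applied as-is; otherwise a scheme is fitted per continuous column on
    this dataset.  Already-discrete columns pass through untouched.
    """
    frame = dataset.frame.copy()
    fitted: dict[str, DiscretizationScheme] = {}
    labels = dataset.class_labels
    for name in dataset.feature_names:
        if dataset.is_discrete(name):
            continue
        scheme = (schemes or {}).get(name)
        if scheme is None:
            scheme = fit_scheme(frame[name].to_numpy(), labels, method, n_bins)
        fitted[name] = scheme
        frame[name] = apply(scheme, frame[name].to_numpy()).values
    kinds = {name: "discrete" for name in dataset.feature_names}
    return (
        Dataset(frame, dataset.class_column, kinds=kinds, provenance=dataset.provenance),
        fitted,
    )


def schemes_to_json(schemes: dict[str, DiscretizationScheme], path) -> None:
    """Serialize column -> {method, cut_points, bins} as JSON."""
    payload = {
        name: {"method": s.method, "cut_points": list(s.cut_points), "bins": s.bins}
        for name, s in schemes.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def schemes_from_json(path) -> dict[str, DiscretizationScheme]:
    payload = json.loads(Path(path).read_text())
    return {
        name: DiscretizationScheme(entry["method"], tuple(entry["cut_points"]))
        for name, entry in payload.items()
    }
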