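"""Plug-in (maximum-likelihood) information estimators for discrete variables.

Everything here works on integer-coded categorical vectors and is reported in
bits (log base 2).  Probabilities are raw frequency counts with no smoothing;
``0 * log 0`` contributes nothing.  These are the primitives the selection
criteria are built from:

* Shannon entropy ``H(X)`` and conditional entropy ``H(X|Y)``
* mutual information ``I(X;Y)``
* conditional mutual information ``I(X;Y|Z)``
* interaction information ``I(X;Y) - I(X;Y|C)`` (positive = redundancy with
  respect to the class, negative = synergy)
* the CU information-gain factor ``2 / (H(f_select|C) + H(f_k|C))`` used by
  the NDCRFS criterion to normalize its interaction penalty

Tiny negative MI/CMI estimates produced by floating-point cancellation
(above ``-1e-9``) are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "DiscreteColumn",
    "ContingencyCounts",
    "tabulate",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
    "cu_factor",
    "joint_column",
]

#: denominators below this are treated as zero (degenerate CU factor)
EPS = 1e-12
#: negative MI/CMI estimates above this are floating-point noise, clamped to 0
NEG_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class DiscreteColumn:
    """An integer-coded categorical vector with its category alphabet.

    ``values`` holds non-negative codes, each strictly below
    ``alphabet_size``.  The alphabet may be larger than the set of codes that
    actually occur (unobserved categories simply carry zero probability).
    """

    values: np.ndarray
    alphabet_size: int

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(self.values, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise InputError("DiscreteColumn requires a non-empty 1-D sequence")
        if self.alphabet_size < 1:
            raise InputError("alphabet_size must be >= 1")
        if arr.min() < 0 or arr.max() >= self.alphabet_size:
            raise InputError(
                f"codes must lie in [0, {self.alphabet_size}); "
                f"saw range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_values(cls, values, alphabet_size: int | None = None) -> "DiscreteColumn":
        """Build a column, inferring the alphabet as ``max(code) + 1`` if not given."""
        arr = np.asarray(values, dtype=np.int64)
        if alphabet_size is None:
            alphabet_size = int(arr.max()) + 1 if arr.size else 0
        return cls(arr, alphabet_size)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True, eq=False)
class ContingencyCounts:
    """Joint occurrence counts over one to three discrete variables."""

    cell_counts: np.ndarray
    total: int

    @property
    def axis_arities(self) -> tuple[int, ...]:
        return tuple(self.cell_counts.shape)

    def marginal(self, keep_axes: tuple[int, ...]) -> "ContingencyCounts":
        """Marginalize onto ``keep_axes`` (a lower-order table over those variables)."""
        drop = tuple(i for i in range(self.cell_counts.ndim) if i not in keep_axes)
        return ContingencyCounts(self.cell_counts.sum(axis=drop), self.total)


def tabulate(*cols: DiscreteColumn) -> ContingencyCounts:
    """Count joint occurrences of 1-3 equal-length discrete columns."""
    if not 1 <= len(cols) <= 3:
        raise InputError("tabulate takes between one and three columns")
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise InputError("all columns must have identical length")
    shape = tuple(c.alphabet_size for c in cols)
    flat = np.ravel_multi_index(tuple(c.values for c in cols), shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return ContingencyCounts(counts, n)


def _h(counts: np.ndarray, total: int) -> float:
    """Entropy in bits of the empirical distribution counts/total.

    Counts are sorted before summation so the result is invariant to the
    axis order of the table — this is what makes I(X;Y) == I(Y;X) exact,
    not merely up to float rounding.
    """
    c = np.sort(counts[counts > 0].astype(np.float64).ravel())
    p = c / total
    return float(-np.sum(p * np.log2(p)))


def _clamp(value: float) -> float:
    return 0.0 if -NEG_TOL < value < 0.0 else value


def entropy(x: DiscreteColumn) -> float:
    """Shannon entropy H(X) in bits."""
    t = tabulate(x)
    return _h(t.cell_counts, t.total)


def conditional_entropy(x: DiscreteColumn, given: DiscreteColumn) -> float:
    """H(X|Y) = H(X,Y) - H(Y), in bits."""
    t = tabulate(x, given)
    return max(0.0, _h(t.cell_counts, t.total) - _h(t.cell_counts.sum(axis=0), t.total))


def mutual_information(x: DiscreteColumn, y: DiscreteColumn) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), in bits."""
    t = tabulate(x, y)
    joint = t.cell_counts
    mi = _h(joint.sum(axis=1), t.total) + _h(joint.sum(axis=0), t.total) - _h(joint, t.total)
    return _clamp(mi)


def conditional_mutual_information(
    x: DiscreteColumn, y: DiscreteColumn, z: DiscreteColumn
) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z), in bits."""
    t = tabulate(x, y, z)
    c = t.cell_counts
    n = t.total
    cmi = _h(c.sum(axis=1), n) + _h(c.sum(axis=0), n) - _h(c.sum(axis=(0, 1)), n) - _h(c, n)
    return _clamp(cmi)


def interaction_information(x: DiscreteColumn, y: DiscreteColumn, c: DiscreteColumn) -> float:
    """I(X;Y) - I(X;Y|C): positive = redundancy w.r.t. C, negative = synergy."""
    return mutual_information(x, y) - conditional_mutual_information(x, y, c)


def cu_factor(f_sel: DiscreteColumn, f_cand: DiscreteColumn, c: DiscreteColumn) -> float:
    """Information-gain normalizer 2 / (H(f_sel|C) + H(f_cand|C)).

    When both features are deterministic given the class the denominator
    vanishes; the factor is then defined as 0 so the interaction penalty
    disappears and such candidates are ranked by relevance alone.
    """
    denom = conditional_entropy(f_sel, c) + conditional_entropy(f_cand, c)
    if denom < EPS:
        return 0.0
    return 2.0 / denom


def joint_column(x: DiscreteColumn, y: DiscreteColumn) -> DiscreteColumn:
    """The pair (X, Y) coded as a single column over the product alphabet."""
    if len(x) != len(y):
        raise InputError("columns must have identical length")
    codes = x.values * y.alphabet_size + y.values
    return DiscreteColumn(codes, x.alphabet_size * y.alphabet_size)
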