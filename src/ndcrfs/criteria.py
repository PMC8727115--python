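"""The eight greedy forward-selection criteria.

All criteria score a candidate feature ``f_k`` against the class ``C`` and
the already-selected set ``S``, using only plug-in information estimates:

====================  =======================================================
``mim``               I(f_k;C)
``cife``              I(f_k;C) - sum_S [I(f_k;s) - I(f_k;s|C)]
``jmi``               I(f_k;C) - (1/|S|) sum_S [I(f_k;s) - I(f_k;s|C)]
``cmim``              I(f_k;C) - max_S [I(f_k;s) - I(f_k;s|C)]
``dwfs``              multiplicative weight, W *= 2*(I(f_k;C|s)-I(f_k;C))
                      / (H(f_k)+H(C)) + 1; ranked by W * I(f_k;C)
``drjmim``            min_S I(f_k;s;C) * [I(f_k;C) + C_Ratio(f_k,s)*I(s;C)]
``dwur``              weight, W *= (1 - beta*I(f_k;s))
                      * (I(f_k;C) + C_Ratio(f_k,s)*I(s;C))
``ndcrfs``            I(f_k;C) - max_S CU(s,f_k) * (I(f_k;s|C) - I(s;C))
====================  =======================================================

with ``C_Ratio(f_k,s) = 2*(I(f_k;C|s) - I(f_k;C)) / (H(f_k)+H(C))`` and
``CU(s,f_k) = 2/(H(s|C)+H(f_k|C))``.  Empty sums/maxima/minima are defined as
0 (resp. reduce the score to I(f_k;C)), so every criterion picks the same,
maximally relevant first feature.

Scores of ``mim``/``cife``/``jmi``/``cmim``/``drjmim``/``ndcrfs`` are in
bits; ``dwfs``/``dwur`` scores are dimensionless weights.  The two kinds are
never compared across criteria.

Scoring never mutates the :class:`SelectionState`; only the ``*_update``
weight recurrences and the selection driver do.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import Dataset
from .errors import DegenerateInputError, InputError, UnknownFeatureError
from .info_theory import EPS, _clamp, _h, tabulate

__all__ = [
    "SelectionState",
    "CriterionScore",
    "Criterion",
    "CRITERION_NAMES",
    "make_criterion",
    "score_mim",
    "score_cife",
    "score_jmi",
    "score_cmim",
    "score_drjmim",
    "score_ndcrfs",
    "score_dwfs",
    "score_dwur",
    "c_ratio",
    "dwfs_update",
    "dwur_update",
]


@dataclass(frozen=True)
class CriterionScore:
    """A per-candidate criterion value (bits, or a dimensionless weight)."""

    feature_id: str
    score: float
    criterion_name: str


@dataclass(frozen=True)
class _PairStats:
    """All pairwise statistics of (f, g, C), from a single 3-way tabulation."""

    mi: float                # I(f;g)
    cmi_given_class: float   # I(f;g|C)  (symmetric in f, g)
    cmi_class_given_g: float  # I(f;C|g)
    cmi_class_given_f: float  # I(g;C|f)


class SelectionState:
    """Shared state of a greedy forward search: F, S, weights and caches.

    ``candidates`` and ``selected`` partition the examined features;
    ``weights`` carry the DWFS/DWUR multiplicative weights (initialized 1).
    Unary and pairwise information statistics are memoized; the number of
    distinct pairwise tabulations actually computed is counted in
    ``pair_evals`` (it is bounded by T*n for a T-step search over n
    features, matching the advertised O(Tmn) cost).
    """

    def __init__(self, dataset: Dataset, *, beta: float = 0.5, use_cache: bool = True):
        self.dataset = dataset
        self.selected: list[str] = []
        self.candidates: list[str] = list(dataset.feature_names)
        self.weights: dict[str, float] = {f: 1.0 for f in self.candidates}
        self.beta = float(beta)
        self._use_cache = use_cache
        self._class = dataset.class_labels
        self._h_class = _entropy_of(self._class)
        self._unary: dict[str, tuple[float, float, float]] = {}
        self._pairs: dict[tuple[str, str], _PairStats] = {}
        self.pair_evals = 0

    # -- column access -----------------------------------------------------
    def _col(self, f: str):
        return self.dataset.column(f)

    def _check_known(self, f: str) -> None:
        if f not in self.weights:
            raise UnknownFeatureError(f"unknown feature {f!r}")

    # -- unary statistics ----------------------------------------------------
    def _unary_stats(self, f: str) -> tuple[float, float, float]:
        """(H(f), H(f|C), I(f;C)) from one 2-way tabulation."""
        hit = self._unary.get(f)
        if hit is not None and self._use_cache:
            return hit
        t = tabulate(self._col(f), self._class)
        n = t.total
        h_joint = _h(t.cell_counts, n)
        h_f = _h(t.cell_counts.sum(axis=1), n)
        h_f_given_c = max(0.0, h_joint - self._h_class)
        mi = _clamp(h_f - h_f_given_c)
        stats = (h_f, h_f_given_c, mi)
        self._unary[f] = stats
        return stats

    def h(self, f: str) -> float:
        """H(f) in bits."""
        return self._unary_stats(f)[0]

    def h_given_class(self, f: str) -> float:
        """H(f|C) in bits."""
        return self._unary_stats(f)[1]

    def mi_class(self, f: str) -> float:
        """I(f;C) in bits."""
        return self._unary_stats(f)[2]

    @property
    def h_class(self) -> float:
        """H(C) in bits."""
        return self._h_class

    # -- pairwise statistics -------------------------------------------------
    def _pair_stats(self, f: str, g: str) -> _PairStats:
        key = (f, g) if f <= g else (g, f)
        hit = self._pairs.get(key)
        if hit is None or not self._use_cache:
            self.pair_evals += 1
            a, b = key
            t = tabulate(self._col(a), self._col(b), self._class)
            c3 = t.cell_counts
            n = t.total
            h_abc = _h(c3, n)
            h_ab = _h(c3.sum(axis=2), n)
            h_ac = _h(c3.sum(axis=1), n)
            h_bc = _h(c3.sum(axis=0), n)
            h_a = _h(c3.sum(axis=(1, 2)), n)
            h_b = _h(c3.sum(axis=(0, 2)), n)
            hit = _PairStats(
                mi=_clamp(h_a + h_b - h_ab),
                cmi_given_class=_clamp(h_ac + h_bc - self._h_class - h_abc),
                cmi_class_given_g=_clamp(h_ab + h_bc - h_b - h_abc),  # I(a;C|b)
                cmi_class_given_f=_clamp(h_ab + h_ac - h_a - h_abc),  # I(b;C|a)
            )
            self._pairs[key] = hit
        if (f, g) == key:
            return hit
        return _PairStats(hit.mi, hit.cmi_given_class, hit.cmi_class_given_f,
                          hit.cmi_class_given_g)

    def mi(self, f: str, g: str) -> float:
        """I(f;g) in bits."""
        return self._pair_stats(f, g).mi

    def cmi_given_class(self, f: str, g: str) -> float:
        """I(f;g|C) in bits (symmetric)."""
        return self._pair_stats(f, g).cmi_given_class

    def cmi_class_given(self, f: str, g: str) -> float:
        """I(f;C|g) in bits."""
        return self._pair_stats(f, g).cmi_class_given_g

    def interaction(self, f: str, g: str) -> float:
        """Interaction information I(f;g) - I(f;g|C)."""
        s = self._pair_stats(f, g)
        return s.mi - s.cmi_given_class

    # -- state transitions ---------------------------------------------------
    def select(self, f: str) -> None:
        """Move a candidate into the selected set."""
        self.candidates.remove(f)  # raises ValueError if absent
        self.selected.append(f)


def _entropy_of(col) -> float:
    t = tabulate(col)
    return _h(t.cell_counts, t.total)


def _require_candidate(state: SelectionState, f_k: str) -> None:
    state._check_known(f_k)
    if f_k not in state.candidates:
        raise UnknownFeatureError(f"feature {f_k!r} is not a candidate (already selected?)")


# ---------------------------------------------------------------------------
# scoring functions
# ---------------------------------------------------------------------------

def score_mim(state: SelectionState, f_k: str) -> CriterionScore:
    """Relevance only: I(f_k;C), independent of the selected set."""
    _require_candidate(state, f_k)
    return CriterionScore(f_k, state.mi_class(f_k), "mim")


def score_cife(state: SelectionState, f_k: str) -> CriterionScore:
    """Relevance minus summed class-conditional redundancy."""
    _require_candidate(state, f_k)
    penalty = sum(state.interaction(f_k, s) for s in state.selected)
    return CriterionScore(f_k, state.mi_class(f_k) - penalty, "cife")


def score_jmi(state: SelectionState, f_k: str) -> CriterionScore:
    """CIFE with the redundancy sum averaged over |S|."""
    _require_candidate(state, f_k)
    score = state.mi_class(f_k)
    if state.selected:
        score -= sum(state.interaction(f_k, s) for s in state.selected) / len(state.selected)
    return CriterionScore(f_k, score, "jmi")


def score_cmim(state: SelectionState, f_k: str) -> CriterionScore:
    """Max-min criterion: only the worst redundancy term is charged."""
    _require_candidate(state, f_k)
    penalty = max((state.interaction(f_k, s) for s in state.selected), default=0.0)
    return CriterionScore(f_k, state.mi_class(f_k) - penalty, "cmim")


def c_ratio(state: SelectionState, f_k: str, f_sel: str) -> float:
    """Normalized conditional-relevance gain 2*(I(f_k;C|f_sel)-I(f_k;C))/(H(f_k)+H(C)).

    Positive values flag interaction relevance (the selected feature reveals
    class information in the candidate); negative values flag redundancy.
    """
    state._check_known(f_k)
    state._check_known(f_sel)
    denom = state.h(f_k) + state.h_class
    if denom < EPS:
        raise DegenerateInputError(
            f"H({f_k})+H(C) is zero (constant feature and constant class)"
        )
    return 2.0 * (state.cmi_class_given(f_k, f_sel) - state.mi_class(f_k)) / denom


def score_drjmim(state: SelectionState, f_k: str) -> CriterionScore:
    """min over selected s of I(f_k;s;C) * [I(f_k;C) + C_Ratio(f_k,s)*I(s;C)].

    The minimum is taken over the whole product.  With S empty the score
    reduces to I(f_k;C).
    """
    _require_candidate(state, f_k)
    if not state.selected:
        return CriterionScore(f_k, state.mi_class(f_k), "drjmim")
    rel = state.mi_class(f_k)
    score = min(
        state.interaction(f_k, s) * (rel + c_ratio(state, f_k, s) * state.mi_class(s))
        for s in state.selected
    )
    return CriterionScore(f_k, score, "drjmim")


def score_ndcrfs(state: SelectionState, f_k: str) -> CriterionScore:
    """NDCRFS: I(f_k;C) - max over selected s of CU(s,f_k)*(I(f_k;s|C)-I(s;C)).

    CU(s,f_k) = 2/(H(s|C)+H(f_k|C)) normalizes the interaction term; a
    vanishing denominator (both features deterministic given C) sets CU to 0
    so the candidate falls back to pure relevance.  The empty max is 0, so
    the first step is plain MIM.
    """
    _require_candidate(state, f_k)
    h_k = state.h_given_class(f_k)

    def term(s: str) -> float:
        denom = state.h_given_class(s) + h_k
        cu = 0.0 if denom < EPS else 2.0 / denom
        return cu * (state.cmi_given_class(f_k, s) - state.mi_class(s))

    penalty = max((term(s) for s in state.selected), default=0.0)
    return CriterionScore(f_k, state.mi_class(f_k) - penalty, "ndcrfs")


def dwfs_update(state: SelectionState, f_k: str, f_new: str) -> float:
    """DWFS weight recurrence after ``f_new`` enters S.

    W(f_k) *= 2*(I(f_k;C|f_new) - I(f_k;C)) / (H(f_k)+H(C)) + 1.  The "+1"
    keeps the multiplier at exactly 1 when the new feature leaves the
    candidate's relevance unchanged.
    """
    state._check_known(f_k)
    state.weights[f_k] *= c_ratio(state, f_k, f_new) + 1.0
    return state.weights[f_k]


def dwur_update(state: SelectionState, f_k: str, f_new: str, beta: float | None = None) -> float:
    """DWUR weight recurrence: DWFS's conditional-relevance ratio plus an
    explicit (1 - beta*I(f_k;f_new)) redundancy discount."""
    state._check_known(f_k)
    b = state.beta if beta is None else float(beta)
    mult = (1.0 - b * state.mi(f_k, f_new)) * (
        state.mi_class(f_k) + c_ratio(state, f_k, f_new) * state.mi_class(f_new)
    )
    state.weights[f_k] *= mult
    return state.weights[f_k]


def score_dwfs(state: SelectionState, f_k: str) -> CriterionScore:
    """Current DWFS weight times the candidate's base relevance."""
    _require_candidate(state, f_k)
    return CriterionScore(f_k, state.weights[f_k] * state.mi_class(f_k), "dwfs")


def score_dwur(state: SelectionState, f_k: str) -> CriterionScore:
    """Current DWUR weight (base relevance before any update)."""
    _require_candidate(state, f_k)
    if not state.selected:
        return CriterionScore(f_k, state.mi_class(f_k), "dwur")
    return CriterionScore(f_k, state.weights[f_k], "dwur")


# ---------------------------------------------------------------------------
# criterion registry
# ---------------------------------------------------------------------------

class Criterion:
    """A named scoring rule, optionally with a post-selection weight update."""

    name: str = ""

    def __init__(self, scorer, name: str, updater=None):
        self._scorer = scorer
        self.name = name
        self._updater = updater

    def score(self, state: SelectionState, f_k: str) -> float:
        return self._scorer(state, f_k).score

    def on_select(self, state: SelectionState, f_new: str) -> None:
        """Hook run by the driver right after ``f_new`` moves into S."""
        if self._updater is not None:
            for f in list(state.candidates):
                self._updater(state, f, f_new)


_SCORERS = {
    "mim": score_mim,
    "cife": score_cife,
    "jmi": score_jmi,
    "cmim": score_cmim,
    "dwfs": score_dwfs,
    "drjmim": score_drjmim,
    "dwur": score_dwur,
    "ndcrfs": score_ndcrfs,
}
_UPDATERS = {"dwfs": dwfs_update, "dwur": dwur_update}

CRITERION_NAMES: tuple[str, ...] = tuple(_SCORERS)


def make_criterion(name: str) -> Criterion:
    """Look up a criterion by its registry name."""
    if name not in _SCORERS:
        raise InputError(
            f"unknown criterion {name!r}; available: {', '.join(CRITERION_NAMES)}"
        )
    return Criterion(_SCORERS[name], name, _UPDATERS.get(name))
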