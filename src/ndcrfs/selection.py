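"""Greedy forward search producing a ranked feature subset.

Each step moves the highest-scoring candidate from the candidate pool into
the selected set, then lets the criterion update any per-candidate weights.
Ties are broken by the lowest feature index (original column order), so runs
are fully deterministic.  Candidates whose score comes out non-finite are
ranked last — an undefined penalty never wins a selection step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .criteria import Criterion, SelectionState, make_criterion
from .data import Dataset
from .errors import DegenerateInputError, InputError

__all__ = ["RankedSubset", "greedy_select", "rank_all", "write_ranking", "read_ranking"]


@dataclass(frozen=True)
class RankedSubset:
    """Features in selection order with the criterion value at each step."""

    order: tuple[str, ...]
    step_scores: tuple[float, ...]
    criterion_name: str
    k_requested: int

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> tuple[str, ...]:
        return self.order[:k]


def greedy_select(
    dataset: Dataset,
    criterion: str | Criterion,
    k: int,
    *,
    beta: float = 0.5,
    state: SelectionState | None = None,
) -> RankedSubset:
    """Select up to ``k`` features by greedy forward search.

    Parameters
    ----------
    dataset
        A fully discrete dataset (run discretization first otherwise).
    criterion
        Registry name (``mim``, ``cife``, ``jmi``, ``cmim``, ``dwfs``,
        ``drjmim``, ``dwur``, ``ndcrfs``) or a :class:`Criterion` instance.
    k
        Number of features to select; capped at the feature count.
    beta
        DWUR redundancy coefficient in [0, 1] (ignored by other criteria).
    state
        Optional pre-built state (used by tests to instrument caching).
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if not dataset.is_fully_discrete:
        cont = [f for f in dataset.feature_names if not dataset.is_discrete(f)]
        raise InputError(
            f"dataset has continuous columns {cont}; discretize them first "
            "(ndcrfs.discretization.discretize_dataset)"
        )
    if dataset.class_labels.alphabet_size < 2:
        raise DegenerateInputError("class column is constant; nothing to separate")
    crit = make_criterion(criterion) if isinstance(criterion, str) else criterion
    if state is None:
        state = SelectionState(dataset, beta=beta)

    order: list[str] = []
    step_scores: list[float] = []
    steps = min(k, len(state.candidates))
    for _ in range(steps):
        best_f = None
        best_key = -math.inf
        best_raw = math.nan
        for f in state.candidates:  # original column order => lowest-index tie-break
            raw = crit.score(state, f)
            key = raw if math.isfinite(raw) else -math.inf
            if best_f is None or key > best_key:
                best_f, best_key, best_raw = f, key, raw
        state.select(best_f)
        crit.on_select(state, best_f)
        order.append(best_f)
        step_scores.append(best_raw)
    return RankedSubset(tuple(order), tuple(step_scores), crit.name, k)


def rank_all(
    dataset: Dataset, criterion: str | Criterion, *, beta: float = 0.5
) -> RankedSubset:
    """Rank every feature (greedy_select with k = number of features)."""
    return greedy_select(dataset, criterion, dataset.n_features, beta=beta)


def write_ranking(ranked: RankedSubset, path, metadata: dict | None = None) -> None:
    """Write a ranking as TSV (rank, feature, score, criterion).

    A leading ``#`` comment line carries a JSON reproducibility block
    (criterion, requested k, any caller-supplied config).
    """
    block = {"criterion": ranked.criterion_name, "k_requested": ranked.k_requested}
    if metadata:
        block.update(metadata)
    lines = ["# " + json.dumps(block, sort_keys=True), "rank\tfeature\tscore\tcriterion"]
    for i, (feat, score) in enumerate(zip(ranked.order, ranked.step_scores), start=1):
        lines.append(f"{i}\t{feat}\t{score!r}\t{ranked.criterion_name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ranking(path) -> RankedSubset:
    """Read a TSV ranking written by :func:`write_ranking`."""
    order: list[str] = []
    scores: list[float] = []
    name = ""
    k_requested = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            try:
                block = json.loads(line[1:].strip())
                k_requested = int(block.get("k_requested", 0))
            except json.JSONDecodeError:
                pass
            continue
        cells = line.split("\t")
        if cells[0] == "rank":
            continue
        if len(cells) < 4:
            raise InputError(f"{path}: malformed ranking line {line!r}")
        order.append(cells[1])
        scores.append(float(cells[2]))
        name = cells[3]
    if not order:
        raise InputError(f"{path}: no ranking rows found")
    return RankedSubset(tuple(order), tuple(scores), name, k_requested or len(order))
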