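"""Synthetic classification tables with planted feature roles.

The generator emulates the taxonomy the selection criteria are designed to
tell apart:

* **relevant** features copy the class label, each value independently
  re-sampled uniformly over the alphabet with probability ``relevance_noise``;
* **redundant** features are noisy copies of designated relevant features
  (``redundancy_noise`` is the probability of replacing a value by a
  different category);
* **interacting pairs** are (trigger X, partner = class - X mod n_classes,
  i.e. XOR for two classes), so the pair is jointly informative while each
  member alone is (near-)independent of the class; an optional trigger bias
  (binary only) lets the partner leak a small marginal signal, which is what
  makes the pair discoverable by a forward search at all;
* **irrelevant** features are uniform noise.

Every column's role ships in a JSON sidecar, never inside the CSV, so a
pipeline cannot accidentally peek.  Generation is fully reproducible from
the design's seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, save_table
from .errors import InputError

__all__ = ["PlantedDesign", "generate", "expected_mi", "save_synthetic"]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of a planted-role table.

    Defaults are the package's standard small-sample benchmark condition:
    500 samples, binary class, 5 relevant features at 10% relevance noise,
    5 redundant copies at 5% corruption, one unbiased XOR pair, 20 noise
    features.
    """

    n_samples: int = 500
    n_classes: int = 2
    n_relevant: int = 5
    n_redundant: int = 5
    n_interacting_pairs: int = 1
    n_irrelevant: int = 20
    relevance_noise: float = 0.1
    redundancy_noise: float = 0.05
    interaction_noise: float = 0.0
    interaction_trigger_bias: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_relevant,
            self.n_redundant,
            self.n_interacting_pairs,
            self.n_irrelevant,
        )
        if any(c < 0 for c in counts):
            raise InputError("feature counts must be non-negative")
        if self.n_relevant + self.n_redundant + 2 * self.n_interacting_pairs + self.n_irrelevant < 1:
            raise InputError("design must plant at least one feature")
        if self.n_redundant > 0 and self.n_relevant == 0:
            raise InputError("redundant copies require at least one relevant feature")
        if self.n_samples < 2 or self.n_classes < 2:
            raise InputError("need at least 2 samples and 2 classes")
        if not 0.0 <= self.relevance_noise < 0.5:
            raise InputError("relevance_noise must lie in [0, 0.5)")
        for name in ("redundancy_noise", "interaction_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.interaction_trigger_bias < 1.0:
            raise InputError("interaction_trigger_bias must lie in (0, 1)")


def _corrupt(values: np.ndarray, rate: float, n_classes: int, rng) -> np.ndarray:
    """Replace each value, with probability ``rate``, by a *different* category."""
    out = values.copy()
    mask = rng.random(values.size) < rate
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, n_classes, mask.sum())) % n_classes
    return out


def generate(design: PlantedDesign) -> tuple[Dataset, dict]:
    """Draw a table from the design; returns the dataset and role metadata."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    n, k = design.n_samples, design.n_classes
    c = rng.integers(0, k, n)

    columns: dict[str, np.ndarray] = {}
    roles: dict[str, dict] = {}

    relevant_names: list[str] = []
    for i in range(design.n_relevant):
        name = f"rel_{i + 1}"
        vals = c.copy()
        resample = rng.random(n) < design.relevance_noise
        vals[resample] = rng.integers(0, k, int(resample.sum()))
        columns[name] = vals
        roles[name] = {"role": "relevant"}
        relevant_names.append(name)

    for i in range(design.n_redundant):
        name = f"red_{i + 1}"
        source = relevant_names[i % len(relevant_names)]
        columns[name] = _corrupt(columns[source], design.redundancy_noise, k, rng)
        roles[name] = {"role": "redundant", "source": source}

    for i in range(design.n_interacting_pairs):
        a, b = f"xor_a_{i + 1}", f"xor_b_{i + 1}"
        if k == 2:
            trigger = (rng.random(n) < design.interaction_trigger_bias).astype(np.int64)
        else:
            trigger = rng.integers(0, k, n)
        partner = _corrupt((c - trigger) % k, design.interaction_noise, k, rng)
        columns[a] = trigger
        columns[b] = partner
        roles[a] = {"role": "interaction_trigger", "partner": b}
        roles[b] = {"role": "interaction_partner", "partner": a}

    for i in range(design.n_irrelevant):
        name = f"irr_{i + 1}"
        columns[name] = rng.integers(0, k, n)
        roles[name] = {"role": "irrelevant"}

    columns["class"] = c
    frame = pd.DataFrame(columns)
    kinds = {name: "discrete" for name in frame.columns}
    dataset = Dataset(frame, "class", kinds=kinds, provenance=f"synthetic seed={design.seed}")
    metadata = {"design": asdict(design), "roles": roles}
    return dataset, metadata


def _h_bits(*probs: float) -> float:
    return float(-sum(p * np.log2(p) for p in probs if p > 0))


def expected_mi(design: PlantedDesign, role: str) -> float:
    """Closed-form I(f;C) in bits for a planted role (binary class only).

    Derived by writing out the 2x2 joint of the noise mixture: a relevant
    feature disagrees with the class with probability rho/2 (uniform
    resampling hits the wrong category half the time), a redundant copy
    composes that channel with its own corruption rate, and an interaction
    partner disagrees with the class whenever trigger XOR corruption is 1.
    """
    if design.n_classes != 2:
        raise NotImplementedError("closed-form expected MI is defined for binary designs")
    q = design.relevance_noise / 2.0  # P(relevant != C)
    if role == "relevant":
        flip = q
    elif role == "redundant":
        r = design.redundancy_noise
        flip = q * (1 - r) + (1 - q) * r
    elif role in ("irrelevant", "interaction_trigger"):
        return 0.0
    elif role == "interaction_partner":
        b = design.interaction_trigger_bias
        eta = design.interaction_noise
        flip = b * (1 - eta) + (1 - b) * eta
    else:
        raise InputError(f"unknown role {role!r}")
    return 1.0 - _h_bits(flip, 1.0 - flip)


def save_synthetic(design: PlantedDesign, csv_path, sidecar_path=None) -> tuple[Path, Path]:
    """Generate and write the CSV table plus its JSON role sidecar."""
    dataset, metadata = generate(design)
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".roles.json")
    save_table(dataset, csv_path)
    sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return csv_path, sidecar
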