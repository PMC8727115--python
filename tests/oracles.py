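"""Independent brute-force oracles: the information definitions written out
literally as sums over full probability tables.  Deliberately slow and
dumb — they never share code with the package implementation."""

import itertools
import math

import numpy as np


def _p(counts: dict, total: int, key) -> float:
    return counts.get(key, 0) / total


def oracle_entropy(x) -> float:
    x = np.asarray(x)
    n = len(x)
    return -sum(
        (np.sum(x == v) / n) * math.log2(np.sum(x == v) / n)
        for v in np.unique(x)
    )


def oracle_mi(x, y) -> float:
    """I(X;Y) = sum_xy p(x,y) log2 p(x,y)/(p(x)p(y))."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for vx in np.unique(x):
        for vy in np.unique(y):
            pxy = np.sum((x == vx) & (y == vy)) / n
            if pxy == 0:
                continue
            px = np.sum(x == vx) / n
            py = np.sum(y == vy) / n
            total += pxy * math.log2(pxy / (px * py))
    return total


def oracle_cmi(x, y, z) -> float:
    """I(X;Y|Z) = sum_z p(z) sum_xy p(x,y|z) log2 p(x,y|z)/(p(x|z)p(y|z))."""
    x, y, z = np.asarray(x), np.asarray(y), np.asarray(z)
    n = len(x)
    total = 0.0
    for vz in np.unique(z):
        mask = z == vz
        pz = mask.sum() / n
        xs, ys = x[mask], y[mask]
        m = mask.sum()
        inner = 0.0
        for vx in np.unique(xs):
            for vy in np.unique(ys):
                pxy = np.sum((xs == vx) & (ys == vy)) / m
                if pxy == 0:
                    continue
                px = np.sum(xs == vx) / m
                py = np.sum(ys == vy) / m
                inner += pxy * math.log2(pxy / (px * py))
        total += pz * inner
    return total


def oracle_conditional_entropy(x, given) -> float:
    """H(X|Y) = sum_y p(y) H(X|Y=y)."""
    x, given = np.asarray(x), np.asarray(given)
    n = len(x)
    total = 0.0
    for vy in np.unique(given):
        mask = given == vy
        total += (mask.sum() / n) * oracle_entropy(x[mask])
    return total
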