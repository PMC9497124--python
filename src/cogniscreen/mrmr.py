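"""Mutual information and minimum-redundancy–maximum-relevance ranking.

Features are ranked by greedy forward selection: the first pick
maximizes relevance (mutual information with the class label); each
subsequent pick maximizes the relevance/redundancy quotient (MIQ, the
default) or difference (MID), where redundancy is the normalized sum of
mutual information between the candidate and the already-selected set.

Mutual information is the plug-in estimate from joint counts in log
base 2 (bits); continuous features are discretized by equal-frequency
binning fitted on the data at hand (training folds, in the CV harness).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MIEstimate",
    "MRMRRanking",
    "mutual_information",
    "relevance",
    "redundancy",
    "mrmr_rank",
]


@dataclass
class MIEstimate:
    """A mutual-information value in bits with estimator provenance."""

    value: float
    estimator: str  # "discrete" | "binned"
    bins: int


@dataclass
class MRMRRanking:
    """Greedy MRMR selection trace."""

    features: list[str]
    theta: np.ndarray  # relevance of the pick at each step
    delta: np.ndarray  # redundancy of the pick at each step
    score: np.ndarray  # criterion value of the pick at each step
    k: int
    criterion: str = "miq"


def _is_discrete(v: np.ndarray, n_bins: int) -> bool:
    vals = v[~pd.isna(v)]
    uniq = np.unique(vals)
    if uniq.size <= max(n_bins, 2):
        return True
    return bool(np.issubdtype(np.asarray(vals).dtype, np.integer))


def _discretize(v: np.ndarray, n_bins: int) -> tuple[np.ndarray, bool]:
    """Map a variable to integer codes; equal-frequency bins if continuous."""
    v = np.asarray(v)
    if _is_discrete(v, n_bins):
        _, codes = np.unique(v, return_inverse=True)
        return codes, True
    qs = np.quantile(v.astype(float), np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, v, side="right"), False


def _plugin_mi(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in MI (bits) from integer-coded variables."""
    n = cx.size
    kx = cx.max() + 1
    ky = cy.max() + 1
    # integer counts keep marginals exact, so the estimate is exactly
    # symmetric in X and Y (the sorted summation fixes the order too)
    counts = np.bincount(cx * ky + cy, minlength=kx * ky).reshape(kx, ky)
    rx = counts.sum(axis=1)
    ry = counts.sum(axis=0)
    nz = counts > 0
    ratio = counts[nz].astype(float) * n / (rx[:, None] * ry[None, :])[nz]
    terms = (counts[nz] / n) * np.log2(ratio)
    mi = float(np.sort(terms).sum())
    return max(mi, 0.0)  # clip numerical noise


def mutual_information(
    x: np.ndarray, y: np.ndarray, estimator: str = "auto", n_bins: int = 8
) -> MIEstimate:
    """Mutual information M(X, Y) in bits.

    ``estimator`` is ``"discrete"`` (use values as categories),
    ``"binned"`` (equal-frequency binning into ``n_bins``), or
    ``"auto"`` (binned only for continuous-looking variables).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if estimator == "discrete":
        cx = np.unique(x, return_inverse=True)[1]
        cy = np.unique(y, return_inverse=True)[1]
        kind = "discrete"
    elif estimator == "binned":
        cx, _ = _discretize(x.astype(float), n_bins)
        cy, _ = _discretize(y.astype(float), n_bins)
        kind = "binned"
    elif estimator == "auto":
        cx, dx = _discretize(x, n_bins)
        cy, dy = _discretize(y, n_bins)
        kind = "discrete" if (dx and dy) else "binned"
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return MIEstimate(value=_plugin_mi(cx, cy), estimator=kind, bins=n_bins)


def relevance(candidates: pd.DataFrame, labels, n_bins: int = 8) -> float:
    """Mean MI between each feature in the set and the class label."""
    if candidates.shape[1] == 0:
        raise ValueError("empty candidate set")
    y = np.asarray(labels)
    vals = [
        mutual_information(candidates[c].to_numpy(), y, n_bins=n_bins).value
        for c in candidates.columns
    ]
    return float(np.mean(vals))


def redundancy(omega: list[str], f_i: str, table: pd.DataFrame, n_bins: int = 8) -> float:
    """Normalized pairwise MI between ``f_i`` and the other set members.

    Delta = (1/|Omega|^2) * sum over f_j in Omega, f_j != f_i of M(f_i, f_j).
    """
    if len(omega) == 0:
        raise ValueError("empty set")
    xi = table[f_i].to_numpy()
    total = sum(
        mutual_information(xi, table[f_j].to_numpy(), n_bins=n_bins).value
        for f_j in omega
        if f_j != f_i
    )
    return float(total) / len(omega) ** 2


def mrmr_rank(
    table: pd.DataFrame,
    labels,
    k: int = 20,
    criterion: str = "miq",
    n_bins: int = 8,
) -> MRMRRanking:
    """Greedy MRMR feature ranking.

    Step 1 picks the most relevant feature; each later step picks the
    candidate maximizing relevance/redundancy (``"miq"``) or relevance
    minus redundancy (``"mid"``), with redundancy computed against the
    already-selected set.  Ties break by column order.  Constant
    columns are skipped with a warning; ``k`` larger than the feature
    count is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if criterion not in ("miq", "mid"):
        raise ValueError(f"criterion must be 'miq' or 'mid', got {criterion!r}")
    y = np.asarray(labels)

    cols: list[str] = []
    for c in table.columns:
        if np.ptp(table[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"constant feature column {c!r} skipped", stacklevel=2)
        else:
            cols.append(c)
    if not cols:
        raise ValueError("no non-constant features")
    if k > len(cols):
        warnings.warn(f"k={k} exceeds feature count {len(cols)}; truncated", stacklevel=2)
        k = len(cols)

    codes = {c: _discretize(table[c].to_numpy(), n_bins)[0] for c in cols}
    ycodes = np.unique(y, return_inverse=True)[1]
    rel = {c: _plugin_mi(codes[c], ycodes) for c in cols}

    pair_cache: dict[tuple[str, str], float] = {}

    def pair_mi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = _plugin_mi(codes[a], codes[b])
        return pair_cache[key]

    selected: list[str] = []
    thetas, deltas, scores = [], [], []
    remaining = list(cols)
    while len(selected) < k:
        best_c, best_score, best_theta, best_delta = None, -np.inf, 0.0, 0.0
        for c in remaining:
            theta = rel[c]
            # Omega = selected set plus the candidate itself
            omega_size = len(selected) + 1
            delta = sum(pair_mi(c, s) for s in selected) / omega_size**2
            if criterion == "miq":
                score = theta / max(delta, 1e-12)
            else:
                score = theta - delta
            if score > best_score:  # strict: ties keep earlier column
                best_c, best_score, best_theta, best_delta = c, score, theta, delta
        selected.append(best_c)
        remaining.remove(best_c)
        thetas.append(best_theta)
        deltas.append(best_delta)
        scores.append(best_score)
    return MRMRRanking(
        features=selected,
        theta=np.array(thetas),
        delta=np.array(deltas),
        score=np.array(scores),
        k=k,
        criterion=criterion,
    )
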