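"""Fast contingency counting and decomposable BIC/log-likelihood scores.

Discrete BN scores decompose over families (a node plus its parents);
both the evaluation metrics and the score-based learners share these
primitives.  Counting uses mixed-radix encoding of the selected columns
followed by ``np.bincount``, which keeps a single G2 test or family
score at O(n) with small constants.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .dataset import DiscreteDataset

__all__ = ["joint_counts", "family_counts", "family_ll", "family_dim", "FamilyScoreCache"]


def joint_counts(codes: np.ndarray, cols: Sequence[int], cards: Sequence[int]) -> np.ndarray:
    """Contingency table over the given columns, shape = their cardinalities."""
    cols = list(cols)
    dims = [int(cards[c]) for c in cols]
    if not cols:
        return np.array(codes.shape[0], dtype=np.int64)
    flat = np.zeros(codes.shape[0], dtype=np.int64)
    for c, d in zip(cols, dims):
        flat = flat * d + codes[:, c]
    counts = np.bincount(flat, minlength=int(np.prod(dims)))
    return counts.reshape(dims)


def family_counts(
    codes: np.ndarray, child: int, parents: Sequence[int], cards: Sequence[int]
) -> np.ndarray:
    """Counts N[parent-config, child-state], parent configs mixed-radix."""
    parents = list(parents)
    r = int(cards[child])
    q = 1
    flat = np.zeros(codes.shape[0], dtype=np.int64)
    for p in parents:
        d = int(cards[p])
        flat = flat * d + codes[:, p]
        q *= d
    flat = flat * r + codes[:, child]
    counts = np.bincount(flat, minlength=q * r)
    return counts.reshape(q, r)


def family_ll(counts: np.ndarray) -> float:
    """Maximum-likelihood log-likelihood contribution of one family.

    ``sum N_ijk * ln(N_ijk / N_ij)`` with the 0*ln(0) := 0 convention.
    """
    counts = np.asarray(counts, dtype=np.float64)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * (np.log(counts) - np.log(row))
    return float(np.nansum(np.where(counts > 0, term, 0.0)))


def family_dim(child_card: int, parent_cards: Sequence[int]) -> int:
    """Free parameters of one family: (r-1) * prod(parent cardinalities)."""
    q = 1
    for c in parent_cards:
        q *= int(c)
    return (int(child_card) - 1) * q


class FamilyScoreCache:
    """Memoised family BIC scores for structure search over one dataset.

    ``score(child, parents)`` returns the BIC contribution
    ``LL_family - dim/2 * ln(n)`` of that family; higher is better.
    """

    def __init__(self, data: DiscreteDataset):
        self.codes = data.codes
        self.cards = data.cardinalities
        self.n = data.n
        self._log_n = math.log(self.n)
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def score(self, child: int, parents: frozenset[int]) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        counts = family_counts(self.codes, child, sorted(parents), self.cards)
        dim = family_dim(self.cards[child], [self.cards[p] for p in parents])
        val = family_ll(counts) - 0.5 * dim * self._log_n
        self._cache[key] = val
        return val
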