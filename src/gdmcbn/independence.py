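"""Conditional-independence testing for discrete data.

The G2 (likelihood-ratio chi-square) test is the workhorse of the
constraint-based learners: for variables X, Y and conditioning set Z it
compares observed cell counts in each Z-stratum against the
independence expectation and refers ``G2 = 2 * sum O*ln(O/E)`` to a
chi-square distribution.  Degrees of freedom are
``(r_x - 1)(r_y - 1)`` per *non-empty* stratum, the usual adjustment
for sparse strata in clinical-scale tables.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2

from .dataset import DiscreteDataset
from .scoring import joint_counts

__all__ = ["G2Result", "ci_test_g2"]


class G2Result(NamedTuple):
    statistic: float
    dof: int
    p: float
    uninformative: bool = False


def ci_test_g2(
    data: DiscreteDataset, x: str, y: str, cond: Sequence[str] = ()
) -> G2Result:
    """Test X independent of Y given ``cond`` with the G2 statistic.

    Returns ``(statistic, dof, p, uninformative)``.  A variable with a
    single observed state makes the test uninformative; it is reported
    with p = 1 and the ``uninformative`` flag set rather than raising.
    """
    cond = list(cond)
    if x == y:
        raise ValueError("x and y must differ")
    if x in cond or y in cond:
        raise ValueError("conditioning set must exclude x and y")

    xi = data.column_index(x)
    yi = data.column_index(y)
    ci = [data.column_index(c) for c in cond]
    cards = data.cardinalities

    if len(np.unique(data.codes[:, xi])) < 2 or len(np.unique(data.codes[:, yi])) < 2:
        return G2Result(0.0, 0, 1.0, uninformative=True)

    counts = joint_counts(data.codes, ci + [xi, yi], cards)
    rx, ry = int(cards[xi]), int(cards[yi])
    table = counts.reshape(-1, rx, ry).astype(np.float64)  # strata x X x Y

    totals = table.sum(axis=(1, 2))
    nonempty = totals > 0
    if not nonempty.any():
        return G2Result(0.0, 0, 1.0, uninformative=True)
    t = table[nonempty]
    tot = totals[nonempty][:, None, None]
    expected = t.sum(axis=2, keepdims=True) * t.sum(axis=1, keepdims=True) / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        term = t * (np.log(t) - np.log(expected))
    g2 = 2.0 * float(np.where(t > 0, term, 0.0).sum())
    dof = int(nonempty.sum()) * (rx - 1) * (ry - 1)
    if dof <= 0:
        return G2Result(g2, 0, 1.0, uninformative=True)
    p = float(chi2.sf(g2, dof))
    return G2Result(g2, dof, p, uninformative=False)
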