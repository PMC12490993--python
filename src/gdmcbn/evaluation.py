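"""Graph evaluation: seven criteria against a reference DAG.

Given a learned graph, a reference graph over the same nodes, and the
cohort data, the criteria are: structural Hamming distance (SHD),
number of independent graphical fragments, number of free parameters,
BIC, log-likelihood, F1, and the balanced scoring function

    BSF = 0.5 * (TP/a + TN/i - FP/i - FN/a),

where ``a`` is the number of reference edges and ``i`` the number of
reference non-adjacencies (``|V|(|V|-1)/2 - a``).  BSF is bounded in
[-1, 1]; both the empty and the fully connected learned graph score
exactly 0, and perfect recovery scores 1.  Optional percentile
bootstrap confidence intervals resample the node-pair universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .dataset import DiscreteDataset
from .graphs import Dag, Pdag
from .scoring import family_counts, family_dim, family_ll
from .schema import VariableSpec

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "shd",
    "f1",
    "bsf",
    "log_likelihood",
    "count_free_parameters",
    "bic",
    "count_fragments",
    "bootstrap_ci",
    "evaluate_all",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge-level confusion counts of a learned DAG against a reference.

    ``a`` = reference edges, ``i`` = reference non-adjacent pairs;
    TP + FN = a and TN + FP = i hold by construction.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    a: int
    i: int

    def __post_init__(self):
        if self.tp + self.fn != self.a or self.tn + self.fp != self.i:
            raise ValueError("inconsistent confusion counts")
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative count")


def _pair_universe(nodes: set[str]) -> list[tuple[str, str]]:
    srt = sorted(nodes)
    return [(srt[i], srt[j]) for i in range(len(srt)) for j in range(i + 1, len(srt))]


def _classify_pair(learned: Dag, reference: Dag, u: str, v: str) -> str:
    """One of 'tp', 'fn', 'fp', 'tn' for the unordered pair (u, v)."""
    ref_adj = reference.adjacent(u, v)
    lrn_adj = learned.adjacent(u, v)
    if ref_adj:
        if (u, v) in reference.directed:
            return "tp" if (u, v) in learned.directed else "fn"
        return "tp" if (v, u) in learned.directed else "fn"
    return "fp" if lrn_adj else "tn"


def confusion(learned: Dag, reference: Dag) -> ConfusionCounts:
    """TP: reference edges recovered with the right orientation; FN:
    reference edges missing or reversed; FP: learned adjacencies where
    the reference has none; TN: pairs non-adjacent in both."""
    if learned.nodes != reference.nodes:
        raise ValueError("node sets differ")
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for u, v in _pair_universe(reference.nodes):
        counts[_classify_pair(learned, reference, u, v)] += 1
    a = len(reference.directed)
    n_pairs = len(reference.nodes) * (len(reference.nodes) - 1) // 2
    return ConfusionCounts(counts["tp"], counts["tn"], counts["fp"], counts["fn"],
                           a, n_pairs - a)


def shd(learned: Pdag, reference: Pdag) -> int:
    """Structural Hamming distance: each node pair with a missing or
    extra adjacency, or a different orientation, contributes exactly 1."""
    if learned.nodes != reference.nodes:
        raise ValueError("node sets differ")
    total = 0
    for u, v in _pair_universe(reference.nodes):
        total += _pair_differs(learned, reference, u, v)
    return total


def _pair_differs(learned: Pdag, reference: Pdag, u: str, v: str) -> int:
    def kind(g: Pdag) -> str:
        if (u, v) in g.directed:
            return ">"
        if (v, u) in g.directed:
            return "<"
        if g.adjacent(u, v):
            return "-"
        return "."

    return int(kind(learned) != kind(reference))


def f1(counts: ConfusionCounts) -> float:
    """F1 = 2RP/(R+P) with R = TP/a, P = TP/(TP+FP); 0 when TP = 0."""
    if counts.a == 0:
        return math.nan  # not applicable without reference edges
    if counts.tp == 0:
        return 0.0
    recall = counts.tp / counts.a
    precision = counts.tp / (counts.tp + counts.fp)
    return 2 * recall * precision / (recall + precision)


def bsf(counts: ConfusionCounts, literal_i: bool = False) -> float:
    """Balanced scoring function, bounded in [-1, 1].

    ``literal_i=True`` uses i = |V|(|V|-1)/2 (all pairs) instead of the
    non-adjacent pairs; that variant loses the empty/complete-graph
    fixed points and is provided for comparison only.
    """
    a = counts.a
    i = (counts.i + counts.a) if literal_i else counts.i
    if a == 0 or i == 0:
        return math.nan
    return 0.5 * (counts.tp / a + counts.tn / i - counts.fp / i - counts.fn / a)


def count_free_parameters(dag: Dag, schema: list[VariableSpec]) -> int:
    """Sum over nodes of (r - 1) * product of parent cardinalities,
    counting every state including the missing category."""
    card = {s.name: s.cardinality for s in schema}
    total = 0
    for node in dag.nodes:
        total += family_dim(card[node], [card[p] for p in dag.parents(node)])
    return total


def log_likelihood(dag: Dag, data: DiscreteDataset) -> float:
    """Maximum-likelihood fit of the DAG on the data (0*ln 0 := 0)."""
    missing = dag.nodes - set(data.names)
    if missing:
        raise ValueError(f"DAG nodes absent from data: {sorted(missing)}")
    cards = data.cardinalities
    total = 0.0
    for node in sorted(dag.nodes):
        ci = data.column_index(node)
        pi = sorted(data.column_index(p) for p in dag.parents(node))
        total += family_ll(family_counts(data.codes, ci, pi, cards))
    return total


def bic(dag: Dag, data: DiscreteDataset) -> float:
    """BIC = LL - |theta|/2 * ln(n); higher is better."""
    theta = count_free_parameters(dag, data.schema)
    return log_likelihood(dag, data) - 0.5 * theta * math.log(data.n)


def count_fragments(graph: Pdag) -> int:
    """Weakly connected components, isolated nodes included."""
    import networkx as nx

    return nx.number_connected_components(graph.to_networkx_skeleton())


# ------------------------------------------------------------- bootstrap

def _counts_from_classes(classes: np.ndarray) -> ConfusionCounts:
    tp = int((classes == 0).sum())
    fn = int((classes == 1).sum())
    fp = int((classes == 2).sum())
    tn = int((classes == 3).sum())
    return ConfusionCounts(tp, tn, fp, fn, tp + fn, tn + fp)


_CLASS_CODE = {"tp": 0, "fn": 1, "fp": 2, "tn": 3}


def bootstrap_ci(
    metric: str | Callable[[ConfusionCounts], float],
    learned: Dag,
    reference: Dag,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval over resampled node pairs.

    The comparison universe (all unordered node pairs) is resampled
    with replacement B times; the metric — ``"shd"`` or a callable on
    :class:`ConfusionCounts` — is recomputed on each resample.
    Resamples on which the metric is undefined are redrawn.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if learned.nodes != reference.nodes:
        raise ValueError("node sets differ")
    pairs = _pair_universe(reference.nodes)
    classes = np.array(
        [_CLASS_CODE[_classify_pair(learned, reference, u, v)] for u, v in pairs]
    )
    diffs = np.array([_pair_differs(learned, reference, u, v) for u, v in pairs])
    rng = np.random.default_rng(seed)
    n_pairs = len(pairs)
    values = []
    attempts = 0
    while len(values) < B:
        attempts += 1
        if attempts > 20 * B:
            raise RuntimeError("metric undefined on almost every resample")
        idx = rng.integers(0, n_pairs, size=n_pairs)
        if metric == "shd":
            values.append(float(diffs[idx].sum()))
            continue
        try:
            counts = _counts_from_classes(classes[idx])
        except ValueError:
            continue
        val = metric(counts)  # type: ignore[operator]
        if isinstance(val, float) and math.isnan(val):
            continue
        values.append(float(val))
    lo, hi = np.quantile(values, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


# ------------------------------------------------------------- reports

@dataclass
class MetricsReport:
    """All seven criteria for one graph, with optional 95% CIs."""

    name: str
    shd: float
    f1: float
    bsf: float
    ll: float
    bic: float
    free_parameters: int
    fragments: int
    shd_ci: tuple[float, float] | None = None
    f1_ci: tuple[float, float] | None = None
    bsf_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "Algorithm": self.name,
            "SHD": self.shd,
            "F1": self.f1,
            "BSF": self.bsf,
            "LL": self.ll,
            "BIC": self.bic,
            "FreeParams": self.free_parameters,
            "Fragments": self.fragments,
        }
        for label, ci in (("SHD", self.shd_ci), ("F1", self.f1_ci), ("BSF", self.bsf_ci)):
            if ci is not None:
                out[f"{label}_lo"] = ci[0]
                out[f"{label}_hi"] = ci[1]
        return out


def evaluate_all(
    learned: list[tuple[str, Dag]],
    reference: Dag,
    data: DiscreteDataset,
    ci_bootstrap: int | None = None,
    seed: int = 0,
) -> list[MetricsReport]:
    """One report per graph; pass ``ci_bootstrap=B`` for bootstrap CIs."""
    reports = []
    for name, g in learned:
        counts = confusion(g, reference)
        rep = MetricsReport(
            name=name,
            shd=float(shd(g, reference)),
            f1=f1(counts),
            bsf=bsf(counts),
            ll=log_likelihood(g, data),
            bic=bic(g, data),
            free_parameters=count_free_parameters(g, data.schema),
            fragments=count_fragments(g),
        )
        if ci_bootstrap:
            rep.shd_ci = bootstrap_ci("shd", g, reference, ci_bootstrap, seed=seed)
            rep.f1_ci = bootstrap_ci(f1, g, reference, ci_bootstrap, seed=seed + 1)
            rep.bsf_ci = bootstrap_ci(bsf, g, reference, ci_bootstrap, seed=seed + 2)
        reports.append(rep)
    return reports


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
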