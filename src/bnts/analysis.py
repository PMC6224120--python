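"""Family-level analytics over learned Boolean networks.

A learning run produces a *family* of co-optimal networks per biological
context (e.g. cell line).  This module aggregates families by hyper-edge
frequency, compares families through the Jaccard index on hyper-edge
sets, validates specificity against randomised data, scores downstream
sets against a canonical pathway via TPR/FPR and AUROC, and measures
node centrality in aggregated networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from bnts.core import BooleanNetwork, clause_str
from bnts.learn import discrete_rmse, optimal_trace_cost
from bnts.pkn import PKN
from bnts.timeseries import PerturbationDataset, clamping

__all__ = [
    "BNFamily",
    "AggregatedNetwork",
    "hyperedge_frequencies",
    "aggregate",
    "jaccard",
    "family_similarity",
    "similarity_matrix",
    "rmse_ratio",
    "random_validation",
    "downstream_set",
    "tpr_fpr",
    "family_auroc",
    "node_centrality",
]


@dataclass(frozen=True)
class BNFamily:
    """A non-empty family of networks over one node universe."""

    label: str
    networks: tuple
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "networks", tuple(self.networks))
        if not self.networks:
            raise ValueError("a family must contain at least one network")
        universe = set(self.networks[0].nodes)
        for bn in self.networks:
            if set(bn.nodes) != universe:
                raise ValueError("all networks must share one node universe")

    def __len__(self):
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)


@dataclass(frozen=True)
class AggregatedNetwork:
    """Hyper-edges kept at frequency strictly above the threshold."""

    hyperedges: Mapping  # (target, clause) -> frequency in (0,1]
    threshold: float

    def __post_init__(self):
        for he, freq in self.hyperedges.items():
            if not 0 < freq <= 1:
                raise ValueError(f"frequency {freq} outside (0,1]")
            if freq <= self.threshold:
                raise ValueError(
                    f"hyper-edge {he} at frequency {freq} <= threshold"
                )

    def hyperedge_set(self) -> frozenset:
        return frozenset(self.hyperedges)

    @property
    def nodes(self) -> frozenset:
        out = set()
        for target, clause in self.hyperedges:
            out.add(target)
            out.update(r for r, _ in clause)
        return frozenset(out)

    def to_digraph(self) -> nx.DiGraph:
        """Plain regulator -> target graph induced by the hyper-edges."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for target, clause in self.hyperedges:
            for reg, sign in clause:
                g.add_edge(reg, target)
        return g

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"target": t, "clause": clause_str(c), "frequency": f}
            for (t, c), f in sorted(
                self.hyperedges.items(), key=lambda kv: (kv[0][0], clause_str(kv[0][1]))
            )
        ]
        return pd.DataFrame(rows, columns=["target", "clause", "frequency"])

    def to_dot(self, roles: Mapping | None = None) -> str:
        """Graphviz description with nodes colored by experimental role."""
        colors = {
            "stimulus": "palegreen",
            "inhibitor": "lightcoral",
            "readout": "lightblue",
            "inhibitor_and_readout": "plum",
            "unobserved": "white",
        }
        lines = ["digraph aggregated {"]
        for v in sorted(self.nodes):
            color = colors.get((roles or {}).get(v, "unobserved"), "white")
            lines.append(f'  "{v}" [style=filled, fillcolor={color}];')
        for (target, clause), freq in sorted(
            self.hyperedges.items(), key=lambda kv: (kv[0][0], clause_str(kv[0][1]))
        ):
            for reg, sign in sorted(clause):
                arrow = "normal" if sign > 0 else "tee"
                lines.append(
                    f'  "{reg}" -> "{target}" [arrowhead={arrow}, label="{freq:.2f}"];'
                )
        lines.append("}")
        return "\n".join(lines)


def hyperedge_frequencies(family: BNFamily) -> dict:
    """Fraction of the family's networks containing each hyper-edge."""
    counts: dict = {}
    for bn in family:
        for he in bn.hyperedges():
            counts[he] = counts.get(he, 0) + 1
    size = len(family)
    return {he: c / size for he, c in counts.items()}


def aggregate(family: BNFamily, threshold: float = 0.3) -> AggregatedNetwork:
    """Keep hyper-edges with family frequency strictly above ``threshold``."""
    freqs = hyperedge_frequencies(family)
    kept = {he: f for he, f in freqs.items() if f > threshold}
    return AggregatedNetwork(kept, threshold)


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets are identical (1.0)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def family_similarity(gold: Iterable, family: BNFamily) -> float:
    """Mean Jaccard similarity of each family member to a gold-standard set.

    The gold standard is a hyper-edge set — typically the (thresholded)
    aggregate of a family, either the family's own (within-family
    diversity) or another family's (cross-context comparison).
    """
    gold = set(gold)
    return float(
        np.mean([jaccard(gold, bn.hyperedges()) for bn in family])
    )


def similarity_matrix(
    families: Sequence, threshold: float = 0.3
) -> pd.DataFrame:
    """All-pairs family similarity with gold = row family's aggregate.

    Entry (row, col) scores the column family against the aggregate of
    the row family, so the matrix is not symmetric in general; the
    diagonal measures within-family homogeneity.
    """
    golds = {f.label: aggregate(f, threshold).hyperedge_set() for f in families}
    data = {
        row.label: [
            family_similarity(golds[row.label], col) for col in families
        ]
        for row in families
    }
    return pd.DataFrame(
        data, index=[f.label for f in families]
    ).T.loc[[f.label for f in families], [f.label for f in families]]


def rmse_ratio(discrete: float, model: float) -> float:
    """Discrete over model RMSE; 1 means exact discrete recovery.

    A zero model RMSE forces a zero discrete RMSE (the discrete error is
    a floor), in which case the fit is perfect and the ratio is 1.
    """
    if model == 0:
        if discrete == 0:
            return 1.0
        raise ValueError("model RMSE below the discrete floor is impossible")
    return discrete / model


def random_validation(
    bn_family: BNFamily,
    data: PerturbationDataset,
    n_samples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Specificity check: RMSE ratios of the family on randomised data.

    Each sample redraws every readout value at every timepoint uniformly
    in [0,1], keeping the perturbation design.  For each sample the best
    model RMSE attainable by any network in the family (trace search
    with the network fixed) and the sample's own discrete RMSE give one
    ratio.  Structured data the family was learned from yields ratio 1;
    random data should fall strictly below.
    """
    rng = np.random.default_rng(seed)
    clamps = [
        clamping(p, data.stimuli, data.inhibitors) for p in data.perturbations
    ]
    denom = data.m * data.k * data.n_perturbations
    cache: dict = {}
    ratios = []
    for _ in range(int(n_samples)):
        mats = tuple(
            rng.uniform(0.0, 1.0, size=(data.k, data.m)) for _ in data.series
        )
        sample = PerturbationDataset(
            data.observed_nodes,
            data.timepoints,
            data.perturbations,
            mats,
            data.stimuli,
            data.inhibitors,
        )
        d = discrete_rmse(sample)
        best_cost = min(
            optimal_trace_cost(bn, sample, clamps, adjacency_cache=cache)
            for bn in bn_family
        )
        model = math.sqrt(best_cost / denom)
        ratios.append(rmse_ratio(d, model))
    return np.asarray(ratios)


def _as_digraph(network) -> nx.DiGraph:
    if isinstance(network, AggregatedNetwork):
        return network.to_digraph()
    if isinstance(network, PKN):
        g = nx.DiGraph()
        g.add_nodes_from(sorted(network.nodes))
        for s, t, _ in sorted(network.edges):
            g.add_edge(s, t)
        return g
    if isinstance(network, BooleanNetwork):
        g = nx.DiGraph()
        g.add_nodes_from(network.nodes)
        for target, clause in network.hyperedges():
            for reg, _ in clause:
                g.add_edge(reg, target)
        return g
    raise TypeError(f"unsupported network type {type(network)!r}")


def downstream_set(network, root) -> frozenset:
    """Nodes reachable from ``root`` by directed traversal, root excluded."""
    g = _as_digraph(network)
    if root not in g:
        raise ValueError(f"root {root!r} not in network")
    return frozenset(nx.descendants(g, root))


def tpr_fpr(standard: Iterable, inferred: Iterable, universe: Iterable) -> tuple:
    """True/false positive rates of an inferred node set vs a standard set.

    TP/FP/FN/TN are set cardinalities within ``universe``: TPR is
    TP/(TP+FN) = |standard ∩ inferred| / |standard|, FPR is FP/(FP+TN) =
    |inferred \\ standard| / |universe \\ standard|.
    """
    standard, inferred, universe = set(standard), set(inferred), set(universe)
    if not standard <= universe or not inferred <= universe:
        raise ValueError("standard and inferred must be subsets of the universe")
    if not standard:
        raise ValueError("TPR undefined for an empty standard set")
    negatives = universe - standard
    if not negatives:
        raise ValueError("FPR undefined when the universe equals the standard")
    tpr = len(standard & inferred) / len(standard)
    fpr = len(inferred - standard) / len(negatives)
    return tpr, fpr


def family_auroc(points: Iterable) -> float:
    """Area under the ROC point cloud (one (fpr, tpr) point per network).

    Points are sorted by FPR, reduced to the upper envelope at duplicate
    FPRs, anchored at (0,0) and (1,1), and integrated by trapezoids.
    Invariant to point order and duplication.
    """
    pts = [(float(f), float(t)) for f, t in points]
    for f, t in pts:
        if not (0 <= f <= 1 and 0 <= t <= 1):
            raise ValueError("ROC points must lie in the unit square")
    pts += [(0.0, 0.0), (1.0, 1.0)]
    envelope: dict = {}
    for f, t in pts:
        envelope[f] = max(envelope.get(f, 0.0), t)
    xs = sorted(envelope)
    ys = [envelope[f] for f in xs]
    return float(np.trapezoid(ys, xs))


def node_centrality(network, node) -> float:
    """Betweenness of ``node``: fraction of shortest s-t paths through it.

    Normalized by the number of ordered source-target pairs (excluding
    the node) that are connected at all, so the middle of a directed
    chain scores 1 and terminal nodes score 0.
    """
    g = _as_digraph(network)
    if node not in g:
        raise ValueError(f"node {node!r} not in network")
    raw = nx.betweenness_centrality(g, normalized=False)[node]
    connected_pairs = 0
    for s in g:
        if s == node:
            continue
        for t in nx.descendants(g, s):
            if t != node and t != s:
                connected_pairs += 1
    if connected_pairs == 0:
        return 0.0
    return raw / connected_pairs
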