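"""Optimizing search for Boolean networks fitting binarized time series.

The learning problem: given a PKN and a normalized multi-perturbation
dataset, find Boolean networks B (one DNF function per node, drawn from
the PKN's clause space) together with binary trajectories Y_P (one full
network state per observed timepoint, clamp-respecting, consecutive
states support-consistent) minimizing the RMSE between the continuous
data and Y restricted to the observed nodes.  Data points where the
optimal Y disagrees with the binarized data are the *penalized points*;
adopting Y's value there yields the corrected dataset handed to the
model checker.

The search is organised around an exact decomposition of the objective:
binarizing the data gives the *discrete RMSE* floor, and any candidate
trajectory's squared error equals the floor plus a fixed penalty per
point where it deviates from the binarized value.  Deviation sets are
therefore enumerated in non-decreasing total penalty (a best-first
subset walk), and for each set the clause space is searched depth-first
for networks that admit support-consistent traces through the corrected
observations.  The first penalty level with any feasible network is the
global optimum; all networks found at that level (up to ``max_models``)
are returned, so every result is identically optimal.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from bnts.core import (
    BooleanNetwork,
    ConsistencyChecker,
    upstream_closure,
)
from bnts.pkn import PKN, ClauseSpace, clause_space
from bnts.timeseries import (
    BinarizedDataset,
    PerturbationDataset,
    binarize,
    clamping,
)

__all__ = [
    "LearnConfig",
    "FitResult",
    "LearnOutput",
    "rmse",
    "discrete_rmse",
    "learn",
    "optimal_trace_cost",
]


@dataclass(frozen=True)
class LearnConfig:
    """Caps and knobs of the learning search.

    ``max_clause_size``/``max_clauses_per_node`` bound the candidate
    function space per node; ``max_models`` bounds how many co-optimal
    networks are collected; ``max_flip_sets`` bounds how many equal-cost
    correction sets are examined before flagging truncation.  ``mode``
    selects between the pruned search (``branch-and-bound``) and a plain
    ``exhaustive`` enumeration useful for cross-checks at toy scale;
    both are complete and return the same optimum.
    """

    max_clause_size: int = 2
    max_clauses_per_node: int = 3
    max_models: int = 200
    seed: int = 0
    threshold: float = 0.5
    mode: str = "branch-and-bound"
    max_flip_sets: int = 20000

    def __post_init__(self):
        if min(self.max_clause_size, self.max_clauses_per_node, self.max_models) < 1:
            raise ValueError("caps must be >= 1")
        if self.mode not in ("branch-and-bound", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FitResult:
    """One optimal network with its over-approximated trajectories."""

    bn: BooleanNetwork
    traces: tuple  # per perturbation: k full states over bn.nodes
    clampings: tuple  # per perturbation: node -> 0/1
    discrete_rmse: float
    model_rmse: float
    penalized_points: tuple  # (perturbation, time index, node)
    corrected_dataset: BinarizedDataset

    def observations(self) -> tuple:
        """Per perturbation, the k corrected binary observation maps."""
        ds = self.corrected_dataset
        out = []
        for p in range(ds.n_perturbations):
            seq = []
            for j in range(ds.k):
                seq.append(
                    {
                        node: int(ds.series[p][j, i])
                        for i, node in enumerate(ds.observed_nodes)
                    }
                )
            out.append(tuple(seq))
        return tuple(out)


class LearnOutput(Sequence):
    """Ordered co-optimal :class:`FitResult` list plus run metadata."""

    def __init__(self, results, objective, discrete, truncated):
        self.results = list(results)
        self.objective = objective
        self.discrete_rmse = discrete
        self.truncated = truncated

    def __getitem__(self, i):
        return self.results[i]

    def __len__(self):
        return len(self.results)


# ---------------------------------------------------------------------------
# objective


def rmse(observed: PerturbationDataset, predicted) -> float:
    """Root mean square error between data and binary predictions.

    ``predicted`` holds one k x m array per perturbation, aligned with
    the dataset's observed nodes; the normalizer is m * k * |P|.
    """
    mats = [np.asarray(m, dtype=float) for m in predicted]
    if len(mats) != observed.n_perturbations:
        raise ValueError("prediction count does not match perturbations")
    total = 0.0
    for obs, pred in zip(observed.series, mats):
        if pred.shape != obs.shape:
            raise ValueError(
                f"prediction shape {pred.shape} does not match data {obs.shape}"
            )
        total += float(((obs - pred) ** 2).sum())
    denom = observed.m * observed.k * observed.n_perturbations
    if denom == 0:
        raise ValueError("empty dataset")
    return math.sqrt(total / denom)


def discrete_rmse(observed: PerturbationDataset, threshold: float = 0.5) -> float:
    """Error floor imposed by discretization: RMSE against own binarization."""
    b = binarize(observed, threshold)
    return rmse(observed, [mat for mat in b.series])


# ---------------------------------------------------------------------------
# trace feasibility for a fixed network


def _layer_states(nodes, clamp, observed_vals):
    """Full states over ``nodes`` matching clamp + observations, free elsewhere.

    Returns [] when an observed value contradicts the clamping.
    """
    template = []
    free_pos = []
    for i, v in enumerate(nodes):
        if v in clamp:
            if v in observed_vals and observed_vals[v] != clamp[v]:
                return []
            template.append(clamp[v])
        elif v in observed_vals:
            template.append(observed_vals[v])
        else:
            template.append(0)
            free_pos.append(i)
    out = []
    for assign in itertools.product((0, 1), repeat=len(free_pos)):
        state = list(template)
        for pos, val in zip(free_pos, assign):
            state[pos] = val
        out.append(tuple(state))
    return out


def _feasible_trace(checker, layers):
    """Shortest-witness DP through observation layers; None if infeasible.

    ``layers[j]`` lists the admissible full states at timepoint j; an edge
    exists when the earlier state is support-consistent with the later.
    """
    if not layers or not layers[0]:
        return None
    parent = [{s: None for s in layers[0]}]
    for j in range(1, len(layers)):
        cur = {}
        for s in layers[j]:
            items = tuple(enumerate(s))
            for prev in parent[j - 1]:
                if checker.pair(prev, items):
                    cur[s] = prev
                    break
        if not cur:
            return None
        parent.append(cur)
    # reconstruct one witness
    state = next(iter(parent[-1]))
    path = [state]
    for j in range(len(layers) - 1, 0, -1):
        state = parent[j][path[-1]]
        path.append(state)
    return tuple(reversed(path))


def optimal_trace_cost(
    bn: BooleanNetwork,
    data: PerturbationDataset,
    clamps: Sequence,
    adjacency_cache: dict | None = None,
    return_traces: bool = False,
):
    """Minimum squared-error sum attainable by ``bn`` on ``data``.

    With the network fixed, the best binary trajectory per perturbation
    is found by dynamic programming over full states (restricted to the
    cone of influence of the observed nodes): state costs are the squared
    distances to the continuous observations, and transitions require
    support consistency.  Returns the summed squared error; divide by
    m * k * |P| and take the root for the model RMSE.  With
    ``return_traces`` the per-perturbation argmin trajectories (full
    states over ``bn.nodes``, non-cone nodes frozen at clamp or 0) are
    returned alongside.
    """
    cone = sorted(upstream_closure(bn, [v for v in data.observed_nodes if v in set(bn.nodes)]))
    sub = bn.restrict(cone)
    obs_pos = [
        (i, cone.index(v))
        for i, v in enumerate(data.observed_nodes)
        if v in set(cone)
    ]
    total = 0.0
    witnesses = []
    for p in range(data.n_perturbations):
        clamp = {v: val for v, val in clamps[p].items() if v in set(cone)}
        key = (sub.hyperedges(), tuple(sorted(clamp.items())))
        if adjacency_cache is not None and key in adjacency_cache:
            checker, states, edges = adjacency_cache[key]
        else:
            checker = ConsistencyChecker(sub, clamp)
            states = _layer_states(tuple(cone), clamp, {})
            edges = {
                s: [t for t in states if checker.pair(s, tuple(enumerate(t)))]
                for s in states
            }
            if adjacency_cache is not None:
                adjacency_cache[key] = (checker, states, edges)

        def state_cost(j, s):
            return sum(
                (data.series[p][j, i] - s[pos]) ** 2 for i, pos in obs_pos
            )

        # any observed node outside the bn contributes its best-case error
        base = 0.0
        outside = [
            i for i, v in enumerate(data.observed_nodes) if v not in set(cone)
        ]
        for j in range(data.k):
            for i in outside:
                t = data.series[p][j, i]
                base += min(t**2, (t - 1.0) ** 2)

        cost = {s: state_cost(0, s) for s in states}
        parents = [{s: None for s in states}]
        for j in range(1, data.k):
            nxt, par = {}, {}
            for s, c in cost.items():
                for t in edges[s]:
                    cand = c + state_cost(j, t)
                    if cand < nxt.get(t, math.inf):
                        nxt[t] = cand
                        par[t] = s
            cost, _ = nxt, parents.append(par)
        total += min(cost.values()) + base
        if return_traces:
            state = min(cost, key=lambda s: (cost[s], s))
            path = [state]
            for j in range(data.k - 1, 0, -1):
                state = parents[j][path[-1]]
                path.append(state)
            path.reverse()
            cone_pos = {v: i for i, v in enumerate(cone)}
            full = []
            for s in path:
                full.append(
                    tuple(
                        s[cone_pos[v]]
                        if v in cone_pos
                        else clamps[p].get(v, 0)
                        for v in bn.nodes
                    )
                )
            witnesses.append(tuple(full))
    if return_traces:
        return total, tuple(witnesses)
    return total


# ---------------------------------------------------------------------------
# learning


def _flip_subsets(deltas):
    """Yield (total penalty, index tuple) over all subsets, best first."""
    yield 0.0, ()
    n = len(deltas)
    if n == 0:
        return
    heap = [(deltas[0], (0,))]
    while heap:
        total, tup = heapq.heappop(heap)
        yield total, tup
        last = tup[-1]
        if last + 1 < n:
            heapq.heappush(heap, (total + deltas[last + 1], tup + (last + 1,)))
            heapq.heappush(
                heap,
                (total - deltas[last] + deltas[last + 1], tup[:-1] + (last + 1,)),
            )


def _can_output(clauses, value, clamp_vals) -> bool:
    """Can the DNF ``clauses`` output ``value`` with clamped regulators fixed?

    Free regulators range over {0,1}.  The empty function (identity)
    cannot produce a value change, hence returns False for both values.
    """
    if not clauses:
        return False
    regs = sorted({r for c in clauses for r, _ in c})
    free = [r for r in regs if r not in clamp_vals]
    for assign in itertools.product((0, 1), repeat=len(free)):
        vals = dict(zip(free, assign))
        vals.update({r: clamp_vals[r] for r in regs if r in clamp_vals})
        sat = any(
            all(vals[r] == (1 if s > 0 else 0) for r, s in c) for c in clauses
        )
        if int(sat) == value:
            return True
    return False


class _Problem:
    """Shared context of one learn() run."""

    def __init__(self, pkn, data, cfg):
        self.pkn = pkn
        self.data = data
        self.cfg = cfg
        missing = (
            (set(data.stimuli) | set(data.inhibitors) | set(data.observed_nodes))
            - pkn.nodes
        )
        if missing:
            raise ValueError(
                f"dataset nodes absent from the PKN: {sorted(missing)}"
            )
        self.space = clause_space(pkn, cfg.max_clause_size)
        self.clamps = tuple(
            clamping(p, data.stimuli, data.inhibitors) for p in data.perturbations
        )
        # cone of influence: PKN-ancestors of the observed nodes
        cone = set(data.observed_nodes)
        frontier = list(cone)
        while frontier:
            v = frontier.pop()
            for s, _ in pkn.predecessors(v):
                if s not in cone:
                    cone.add(s)
                    frontier.append(s)
        self.cone = tuple(sorted(cone))
        self.candidates = {
            v: self.space.functions(v, cfg.max_clauses_per_node) for v in self.cone
        }
        if not self.cone or not all(self.candidates.values()):
            raise ValueError("empty candidate space")

    def local_ok(self, node, clauses, targets) -> bool:
        """Sound per-node filter: every observed change must be producible.

        If the corrected observations require ``node`` to switch to value
        v under some perturbation, the function must be able to output v
        given that perturbation's clamped regulators (free regulators
        unrestricted); otherwise no trace can widen the node to v.
        """
        if node not in self.data.observed_nodes:
            return True
        i = self.data.node_index(node)
        for p, clamp in enumerate(self.clamps):
            if node in clamp:
                continue  # clamped nodes never change; conflicts surface in the DP
            col = targets[p][:, i]
            clamp_regs = {
                r: clamp[r]
                for c in clauses
                for r, _ in c
                if r in clamp
            }
            for j in range(1, len(col)):
                if col[j] != col[j - 1] and not _can_output(
                    clauses, int(col[j]), clamp_regs
                ):
                    return False
        return True

    def layers_for(self, p, targets):
        coneset = set(self.cone)
        clamp = {k: v for k, v in self.clamps[p].items() if k in coneset}
        layers = []
        for j in range(self.data.k):
            vals = {
                v: int(targets[p][j, i])
                for i, v in enumerate(self.data.observed_nodes)
                if v in coneset
            }
            layers.append(_layer_states(self.cone, clamp, vals))
        return layers

    def feasible(self, functions, targets, free_nodes=()):
        """Witness traces for a (possibly partial) function assignment.

        ``free_nodes`` are treated optimistically: any value reachable.
        Returns per-perturbation witnesses, or None if some perturbation
        admits no support-consistent trace.
        """
        funcs = dict(functions)
        for v in free_nodes:
            funcs[v] = ()
        bn = BooleanNetwork(self.cone, funcs)
        witnesses = []
        free_idx = frozenset(self.cone.index(v) for v in free_nodes)
        for p in range(self.data.n_perturbations):
            clamp = {k: v for k, v in self.clamps[p].items() if k in set(self.cone)}
            checker = ConsistencyChecker(bn, clamp)
            if free_idx:
                checker.dyn.free = free_idx  # optimistic images, see _Compiled
            layers = self.layers_for(p, targets)
            wit = _feasible_trace(checker, layers)
            if wit is None:
                return None
            witnesses.append(wit)
        return tuple(witnesses)


def _search_networks(problem: _Problem, targets, cap: int):
    """DFS over per-node function choices; yields (functions, witnesses).

    Candidate order per node is canonical (clause-space order), so the
    produced networks come out in a deterministic lexicographic order.
    In branch-and-bound mode each partial assignment is checked with the
    unassigned nodes treated optimistically, pruning subtrees that cannot
    be completed; exhaustive mode checks leaves only.
    """
    cfg = problem.cfg
    nodes = list(problem.cone)
    prune = cfg.mode == "branch-and-bound"
    cands = {}
    for v in nodes:
        opts = problem.candidates[v]
        if prune:
            opts = [f for f in opts if problem.local_ok(v, f, targets)]
        if not opts:
            return
        cands[v] = opts
    found = 0
    assignment: dict = {}

    def rec(depth):
        nonlocal found
        if found >= cap:
            return
        if depth == len(nodes):
            wit = problem.feasible(assignment, targets)
            if wit is not None:
                found += 1
                yield dict(assignment), wit
            return
        v = nodes[depth]
        for f in cands[v]:
            assignment[v] = f
            if prune and depth + 1 < len(nodes):
                if problem.feasible(assignment, targets, free_nodes=nodes[depth + 1 :]) is None:
                    del assignment[v]
                    continue
            yield from rec(depth + 1)
            if found >= cap:
                del assignment[v]
                return
            del assignment[v]

    yield from rec(0)


def learn(pkn: PKN, data: PerturbationDataset, cfg: LearnConfig | None = None) -> LearnOutput:
    """Learn all (up to a cap) RMSE-optimal networks compatible with the PKN.

    ``data`` must be normalized and quality-controlled.  The result's
    networks all attain the same, globally minimal RMSE; ``truncated``
    reports whether the enumeration was cut by ``max_models`` (or by the
    flip-set cap) before the co-optimal family was exhausted.
    """
    cfg = cfg or LearnConfig()
    if data.n_perturbations == 0 or data.k == 0 or data.m == 0:
        raise ValueError("empty dataset")
    stacked = data.stacked()
    if np.nanmin(stacked) < 0 or np.nanmax(stacked) > 1:
        raise ValueError("data must be normalized to [0,1] before learning")
    problem = _Problem(pkn, data, cfg)
    binar = binarize(data, cfg.threshold)
    denom = data.m * data.k * data.n_perturbations
    s0 = sum(
        float(((obs - b) ** 2).sum())
        for obs, b in zip(data.series, binar.series)
    )
    d_rmse = math.sqrt(s0 / denom)

    # flip penalties: extra squared error for deviating from the binarized value
    points = []
    for p in range(data.n_perturbations):
        for j in range(data.k):
            for i, node in enumerate(data.observed_nodes):
                t = data.series[p][j, i]
                b = binar.series[p][j, i]
                points.append(((p, j, node), (t - (1 - b)) ** 2 - (t - b) ** 2))
    order = sorted(range(len(points)), key=lambda q: (points[q][1], q))
    deltas = [points[q][1] for q in order]

    best: list = []
    truncated = False
    examined = 0
    group_total = None
    subset_iter = _flip_subsets(deltas)
    for total, tup in subset_iter:
        if best and group_total is not None and total > group_total + 1e-9:
            break
        examined += 1
        if examined > cfg.max_flip_sets:
            truncated = True
            break
        flips = tuple(points[order[q]][0] for q in tup)
        flipped = binar.flip(flips)
        targets = [mat for mat in flipped.series]
        room = cfg.max_models + 1 - len(best)
        if room <= 0:
            truncated = True
            break
        for functions, witnesses in _search_networks(problem, targets, room):
            if group_total is None:
                group_total = total
            best.append((functions, witnesses, flips, flipped, total))
            if len(best) > cfg.max_models:
                truncated = True
                break
        if truncated and best:
            break
    if not best:
        # Heavily corrected data (many flips needed) makes best-first
        # flip enumeration explode; fall back to the complete per-network
        # route: scan the candidate space and price each network by its
        # optimal trace (cost-aware DP), which is exact at any noise.
        truncated = False
        best_cost = math.inf
        pool: list = []
        nodes = list(problem.cone)
        for combo in itertools.product(
            *(problem.candidates[v] for v in nodes)
        ):
            functions = dict(zip(nodes, combo))
            bn_cone = BooleanNetwork(tuple(nodes), functions)
            cost = optimal_trace_cost(bn_cone, data, problem.clamps)
            if cost < best_cost - 1e-12:
                best_cost = cost
                pool = [(functions, bn_cone)]
            elif cost <= best_cost + 1e-12:
                pool.append((functions, bn_cone))
            if len(pool) > cfg.max_models and best_cost <= s0 + 1e-12:
                break  # already at the floor with a full quota
        for functions, bn_cone in pool[: cfg.max_models + 1]:
            _, witnesses = optimal_trace_cost(
                bn_cone, data, problem.clamps, return_traces=True
            )
            flips = []
            cone_pos = {v: i for i, v in enumerate(nodes)}
            for p, wit in enumerate(witnesses):
                for j, state in enumerate(wit):
                    for i, node in enumerate(data.observed_nodes):
                        if state[cone_pos[node]] != binar.series[p][j, i]:
                            flips.append((p, j, node))
            flips = tuple(flips)
            flipped = binar.flip(flips)
            best.append(
                (functions, witnesses, flips, flipped, best_cost - s0)
            )
        if len(best) > cfg.max_models:
            truncated = True
    if not best:
        raise RuntimeError(
            "no support-consistent trace exists for any candidate network"
        )

    objective = math.sqrt((s0 + best[0][4]) / denom)
    # canonical order over networks; drop duplicates found via different flips
    seen_bns = set()
    results = []
    all_nodes = tuple(sorted(pkn.nodes))
    for functions, witnesses, flips, flipped, total in best[: cfg.max_models]:
        bn = BooleanNetwork(
            all_nodes,
            {v: functions.get(v, ()) for v in all_nodes},
        )
        key = bn.hyperedges()
        if key in seen_bns:
            continue
        seen_bns.add(key)
        traces = []
        for p, wit in enumerate(witnesses):
            clamp = problem.clamps[p]
            seq = []
            for state in wit:
                by_node = dict(zip(problem.cone, state))
                seq.append(
                    tuple(
                        clamp.get(v, by_node.get(v, 0)) for v in all_nodes
                    )
                )
            traces.append(tuple(seq))
        results.append(
            FitResult(
                bn=bn,
                traces=tuple(traces),
                clampings=tuple(dict(c) for c in problem.clamps),
                discrete_rmse=d_rmse,
                model_rmse=objective,
                penalized_points=tuple(flips),
                corrected_dataset=flipped,
            )
        )
    return LearnOutput(results, objective, d_rmse, truncated)
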