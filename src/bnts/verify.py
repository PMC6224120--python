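"""Exact certification of learned networks against corrected traces.

Support consistency is only a necessary condition for reachability, so
every network surviving the learning step must still be checked exactly.
A network is *true positive* (TP) when, for every perturbation, the
corrected binary observation sequence can be realised by an actual path
in the state graph: there are full states s_1, ..., s_k matching the
observations (unobserved components free, clamped components fixed) with
s_{j+1} reachable from s_j.  This is the explicit-state equivalent of
the nested CTL query EF(s_1 ∧ EF(s_2 ∧ ...)).  Networks that fail are
*false positive* (FP) — they exhibit exactly the gap between the
over-approximation and true reachability.

Before checking, the network is restricted to the cone of influence of
the observed nodes (nodes with a regulatory path to an observation),
which preserves verdicts while shrinking the state space.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from bnts.core import BooleanNetwork, _Compiled, upstream_closure

__all__ = ["Verdict", "verify", "triage"]

DEFAULT_BUDGET = 2**20


@dataclass(frozen=True)
class Verdict:
    """Outcome of exact model checking for one network.

    ``status`` is TP when every perturbation's observation sequence is
    exactly realisable, FP when some transition provably fails, and
    undecided only when the exploration budget was exhausted first.
    ``per_perturbation`` holds one record per perturbation with its
    pass/fail status and, on failure, the 1-based index of the first
    transition that cannot be realised (0 when already the initial
    observation is unsatisfiable).
    """

    bn_id: object
    status: str
    per_perturbation: tuple
    states_explored: int
    budget_hit: bool = False

    def __post_init__(self):
        if self.status not in ("TP", "FP", "undecided"):
            raise ValueError(f"invalid status {self.status!r}")


def _check_perturbation(bn, observations, clamp, budget):
    """(status, failing transition index or None, states explored)."""
    dyn = _Compiled(bn, clamp)
    idx = dyn.idx
    for obs in observations:
        for v in obs:
            if v not in idx:
                raise ValueError(f"observation references unknown node {v!r}")

    def matching_states(obs, pool=None):
        items = [(idx[v], val) for v, val in obs.items()]
        if pool is not None:
            return {s for s in pool if all(s[i] == val for i, val in items)}
        # enumerate all states consistent with obs + clamp
        fixed = dict(dyn.clamp)
        for i, val in items:
            if fixed.get(i, val) != val:
                return set()
            fixed[i] = val
        free = [i for i in range(dyn.n) if i not in fixed]
        out = set()
        for code in range(1 << len(free)):
            s = [0] * dyn.n
            for i, val in fixed.items():
                s[i] = val
            for b, i in enumerate(free):
                s[i] = (code >> b) & 1
            out.add(tuple(s))
        return out

    explored = 0
    frontier = matching_states(observations[0])
    explored += len(frontier)
    if not frontier:
        return "fail", 0, explored
    for j in range(1, len(observations)):
        # forward closure of the frontier under the any-subset schedule
        seen = set(frontier)
        queue = deque(frontier)
        while queue:
            cur = queue.popleft()
            diff = [
                i
                for i in range(dyn.n)
                if i not in dyn.clamp and dyn.target(i, cur) != cur[i]
            ]
            for code in range(1, 1 << len(diff)):
                nxt = list(cur)
                for b, i in enumerate(diff):
                    if (code >> b) & 1:
                        nxt[i] = 1 - nxt[i]
                nxt = tuple(nxt)
                if nxt not in seen:
                    seen.add(nxt)
                    explored += 1
                    if explored > budget:
                        return "undecided", None, explored
                    queue.append(nxt)
        frontier = matching_states(observations[j], pool=seen)
        if not frontier:
            return "fail", j, explored
    return "pass", None, explored


def verify(
    bn: BooleanNetwork,
    corrected: Sequence,
    clamps: Sequence,
    budget: int = DEFAULT_BUDGET,
    bn_id=None,
) -> Verdict:
    """Model-check one network against corrected observation sequences.

    ``corrected[p]`` is the sequence of per-timepoint observation maps
    (node -> 0/1) of perturbation p; ``clamps[p]`` its clamping.  The
    budget counts explored states across all perturbations, so verdicts
    are deterministic; exceeding it yields ``undecided``, never FP.
    """
    if len(corrected) != len(clamps):
        raise ValueError("one clamping per perturbation required")
    observed = sorted({v for seq in corrected for obs in seq for v in obs})
    for v in observed:
        if v not in set(bn.nodes):
            raise ValueError(f"observation references unknown node {v!r}")
    cone = upstream_closure(bn, observed)
    sub = bn.restrict(cone)
    total = 0
    details = []
    status = "TP"
    for p, (seq, clamp) in enumerate(zip(corrected, clamps)):
        subclamp = {v: val for v, val in clamp.items() if v in cone}
        st, fail_at, explored = _check_perturbation(
            sub, seq, subclamp, budget - total
        )
        total += explored
        details.append(
            {"perturbation": p, "status": st, "failing_transition": fail_at}
        )
        if st == "fail":
            status = "FP"
            break
        if st == "undecided":
            status = "undecided"
            break
    return Verdict(
        bn_id=bn_id,
        status=status,
        per_perturbation=tuple(details),
        states_explored=total,
        budget_hit=status == "undecided",
    )


def triage(
    results: Sequence,
    budget_per_bn: int = DEFAULT_BUDGET,
    wall_budget: int = 50 * DEFAULT_BUDGET,
) -> tuple:
    """Verify learner results in order until the wall budget runs out.

    The wall budget is counted in explored states (deterministic, unlike
    wall-clock); networks not reached before exhaustion are undecided.
    Returns (TP, FP, undecided) lists of :class:`Verdict`.
    """
    tps, fps, und = [], [], []
    remaining = wall_budget
    for i, fit in enumerate(results):
        if remaining <= 0:
            und.append(
                Verdict(
                    bn_id=i,
                    status="undecided",
                    per_perturbation=(),
                    states_explored=0,
                    budget_hit=True,
                )
            )
            continue
        verdict = verify(
            fit.bn,
            fit.observations(),
            fit.clampings,
            budget=min(budget_per_bn, remaining),
            bn_id=i,
        )
        remaining -= verdict.states_explored
        {"TP": tps, "FP": fps, "undecided": und}[verdict.status].append(verdict)
    return tps, fps, und
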