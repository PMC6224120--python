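"""Boolean network semantics.

A Boolean network (BN) is a set of nodes, each with a regulatory function
written in disjunctive normal form: a disjunction of *clauses*, where a
clause is a conjunction of signed literals over the node's regulators.
One (node ← clause) pair is a *hyper-edge*.

The update schedule is the most permissive one: at every step an arbitrary
non-empty subset of non-clamped nodes is updated simultaneously.  Both the
synchronous and the asynchronous schedules are sub-relations of it, so any
reachability certificate obtained here is schedule-robust.

Exact reachability in the 2^n state graph is PSPACE-hard in general, so
this module also implements the cheap necessary condition used to
pre-filter candidate networks during learning: *meta-states* (one value
set per node among {0}, {1}, {0,1}) over-approximate sets of states, the
widening relation between meta-states over-approximates reachability, and
*support consistency* refines it with per-component conditions.  If a
state y is exactly reachable from x, then x is support-consistent with y;
the converse may fail, which is exactly why learned networks must still be
certified by exact model checking.
"""

from __future__ import annotations

import enum
import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Clause",
    "clause_str",
    "parse_clause",
    "clause_sort_key",
    "BooleanNetwork",
    "ReachResult",
    "successors",
    "reachable",
    "meta_successors",
    "support_consistent",
    "ConsistencyChecker",
    "upstream_closure",
]

#: A clause is a frozen set of signed literals (regulator, sign) with
#: sign +1 (plain) or -1 (negated).  It evaluates to 1 on a state iff
#: every positive regulator is 1 and every negated regulator is 0.
Clause = frozenset


def clause_sort_key(clause: Clause):
    """Canonical ordering of clauses: by size, then by sorted literals."""
    return (len(clause), tuple(sorted(clause)))


def clause_str(clause: Clause) -> str:
    """Render a clause as ``a&!b`` (negation marked with ``!``)."""
    return "&".join(
        ("" if sign > 0 else "!") + reg for reg, sign in sorted(clause)
    )


def parse_clause(text: str) -> Clause:
    """Parse ``a&!b`` into a clause; inverse of :func:`clause_str`."""
    lits = []
    for tok in text.split("&"):
        tok = tok.strip()
        if not tok:
            raise ValueError(f"empty literal in clause {text!r}")
        if tok.startswith("!"):
            lits.append((tok[1:].strip(), -1))
        else:
            lits.append((tok, +1))
    clause = frozenset(lits)
    regs = [r for r, _ in lits]
    if len(set(regs)) != len(regs):
        raise ValueError(f"clause {text!r} repeats a regulator")
    return clause


@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean network: ordered nodes plus one DNF function per node.

    ``functions[v]`` is a tuple of clauses whose disjunction drives ``v``.
    An empty tuple means ``v`` has no regulatory function: it keeps its
    current value (identity), which is the semantics used for source and
    unconstrained nodes.  Clamped nodes are handled by the dynamics, not
    by the function table.
    """

    nodes: tuple
    functions: Mapping

    def __post_init__(self):
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        funcs = {}
        for v in self.nodes:
            clauses = tuple(self.functions.get(v, ()))
            if len(set(clauses)) != len(clauses):
                raise ValueError(f"duplicate hyper-edge on node {v!r}")
            for c in clauses:
                for reg, sign in c:
                    if reg not in nodeset:
                        raise ValueError(
                            f"clause regulator {reg!r} of node {v!r} is not a declared node"
                        )
                    if sign not in (+1, -1):
                        raise ValueError(f"bad literal sign {sign!r}")
                if (reg_set := {r for r, _ in c}) and len(reg_set) != len(c):
                    raise ValueError(
                        f"clause on {v!r} carries both polarities of one regulator"
                    )
            funcs[v] = tuple(sorted(clauses, key=clause_sort_key))
        object.__setattr__(self, "functions", funcs)

    # -- structure ---------------------------------------------------------

    def regulators(self, node) -> frozenset:
        return frozenset(r for c in self.functions[node] for r, _ in c)

    def hyperedges(self) -> frozenset:
        """The set of (target, clause) pairs defining this network."""
        return frozenset(
            (v, c) for v in self.nodes for c in self.functions[v]
        )

    def index(self) -> Mapping:
        return {v: i for i, v in enumerate(self.nodes)}

    def restrict(self, keep: Iterable) -> "BooleanNetwork":
        """Sub-network on ``keep``; clauses using dropped regulators are removed."""
        keep = [v for v in self.nodes if v in set(keep)]
        keepset = set(keep)
        funcs = {
            v: tuple(
                c for c in self.functions[v] if {r for r, _ in c} <= keepset
            )
            for v in keep
        }
        return BooleanNetwork(tuple(keep), funcs)

    # -- text round-trip ---------------------------------------------------

    def to_lines(self) -> list:
        """One ``target <- clause`` line per hyper-edge, canonically ordered."""
        out = []
        for v in self.nodes:
            for c in self.functions[v]:
                out.append(f"{v} <- {clause_str(c)}")
        return out

    @classmethod
    def from_lines(cls, lines: Iterable, nodes: Sequence | None = None) -> "BooleanNetwork":
        funcs: dict = {}
        seen = []
        for lineno, raw in enumerate(lines, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "<-" not in line:
                raise ValueError(f"line {lineno}: expected 'target <- clause'")
            tgt, rhs = (part.strip() for part in line.split("<-", 1))
            clause = parse_clause(rhs)
            funcs.setdefault(tgt, []).append(clause)
            seen.append(tgt)
            seen.extend(r for r, _ in clause)
        if nodes is None:
            nodes = tuple(dict.fromkeys(seen))
        return cls(tuple(nodes), {v: tuple(c) for v, c in funcs.items()})


class ReachResult(enum.Enum):
    """Tri-state outcome of a bounded exact reachability query."""

    TRUE = "true"
    FALSE = "false"
    BUDGET_EXCEEDED = "budget_exceeded"

    def __bool__(self):  # pragma: no cover - convenience only
        if self is ReachResult.BUDGET_EXCEEDED:
            raise ValueError("budget_exceeded has no boolean value")
        return self is ReachResult.TRUE


# ---------------------------------------------------------------------------
# compiled dynamics


class _Compiled:
    """Index-based view of a BN under a fixed clamping, for fast evaluation."""

    def __init__(self, bn: BooleanNetwork, clamp: Mapping | None):
        clamp = dict(clamp or {})
        for v, val in clamp.items():
            if v not in set(bn.nodes):
                raise ValueError(f"clamped node {v!r} is not in the network")
            if val not in (0, 1):
                raise ValueError(f"clamp value for {v!r} must be 0/1")
        self.bn = bn
        self.idx = bn.index()
        self.n = len(bn.nodes)
        self.clamp = {self.idx[v]: val for v, val in clamp.items()}
        #: indices treated optimistically (image always {0,1}); used by the
        #: learner to prune partial candidate assignments soundly
        self.free: frozenset = frozenset()
        # per node: list of clauses, each a tuple of (reg_index, sign)
        self.clauses = []
        self.regs = []
        for v in bn.nodes:
            cs = [
                tuple(sorted((self.idx[r], s) for r, s in c))
                for c in bn.functions[v]
            ]
            self.clauses.append(cs)
            self.regs.append(sorted({i for c in cs for i, _ in c}))
        self._image_memo: dict = {}

    def check_state(self, x):
        if len(x) != self.n:
            raise ValueError("state length does not match network size")
        for i, val in self.clamp.items():
            if x[i] != val:
                raise ValueError(
                    f"state violates clamping on node {self.bn.nodes[i]!r}"
                )

    def target(self, i: int, x) -> int:
        """f_i(x) with identity semantics for function-free nodes."""
        if i in self.clamp:
            return self.clamp[i]
        cs = self.clauses[i]
        if not cs:
            return x[i]
        for c in cs:
            if all(x[j] == (1 if s > 0 else 0) for j, s in c):
                return 1
        return 0

    def image(self, i: int, x, widened: frozenset) -> frozenset:
        """{f_i(z) : z in u} for the meta-state u fixing x outside ``widened``.

        Clamped regulators are pinned at their clamp value even when listed
        in ``widened``.
        """
        if i in self.clamp:
            return frozenset((self.clamp[i],))
        if i in self.free:
            return _BOTH
        cs = self.clauses[i]
        if not cs:
            # identity: image equals the node's own component of u
            return frozenset((0, 1)) if i in widened else frozenset((x[i],))
        free = [
            j for j in self.regs[i] if j in widened and j not in self.clamp
        ]
        base = tuple(
            (j, self.clamp.get(j, x[j])) for j in self.regs[i] if j not in free
        )
        key = (i, tuple(free), base)
        hit = self._image_memo.get(key)
        if hit is not None:
            return hit
        vals = dict(base)
        out = set()
        for assign in itertools.product((0, 1), repeat=len(free)):
            vals.update(zip(free, assign))
            sat = any(
                all(vals[j] == (1 if s > 0 else 0) for j, s in c) for c in cs
            )
            out.add(1 if sat else 0)
            if len(out) == 2:
                break
        res = frozenset(out)
        self._image_memo[key] = res
        return res


def _as_clamp_free_subsets(diff):
    """All non-empty subsets of ``diff`` (indices), deterministic order."""
    for r in range(1, len(diff) + 1):
        yield from itertools.combinations(diff, r)


def successors(bn: BooleanNetwork, x, clamp: Mapping | None = None) -> set:
    """All states produced by updating any non-empty subset of free nodes.

    Updating node i sets it to f_i(x); the state itself is excluded, so
    only subsets of the disagreeing nodes produce new states.  Clamped
    nodes never change.
    """
    dyn = _Compiled(bn, clamp)
    dyn.check_state(x)
    diff = [
        i
        for i in range(dyn.n)
        if i not in dyn.clamp and dyn.target(i, x) != x[i]
    ]
    out = set()
    for subset in _as_clamp_free_subsets(diff):
        y = list(x)
        for i in subset:
            y[i] = 1 - y[i]
        out.add(tuple(y))
    return out


def reachable(
    bn: BooleanNetwork,
    x,
    goal: Mapping,
    clamp: Mapping | None = None,
    budget: int = 2**20,
) -> ReachResult:
    """Exact bounded reachability of a (possibly partial) goal state.

    Breadth-first search of the any-subset state graph from ``x``; the goal
    constrains only the nodes it mentions.  Exhausting the reachable set
    without a match is FALSE; visiting more than ``budget`` states is
    reported as BUDGET_EXCEEDED, never conflated with FALSE.
    """
    dyn = _Compiled(bn, clamp)
    dyn.check_state(x)
    idx = dyn.idx
    for v in goal:
        if v not in idx:
            raise ValueError(f"goal constrains unknown node {v!r}")
    goal_items = [(idx[v], val) for v, val in goal.items()]

    def matches(state):
        return all(state[i] == val for i, val in goal_items)

    x = tuple(x)
    if matches(x):
        return ReachResult.TRUE
    seen = {x}
    queue = deque([x])
    while queue:
        cur = queue.popleft()
        diff = [
            i
            for i in range(dyn.n)
            if i not in dyn.clamp and dyn.target(i, cur) != cur[i]
        ]
        for subset in _as_clamp_free_subsets(diff):
            nxt = list(cur)
            for i in subset:
                nxt[i] = 1 - nxt[i]
            nxt = tuple(nxt)
            if nxt in seen:
                continue
            if matches(nxt):
                return ReachResult.TRUE
            seen.add(nxt)
            if len(seen) > budget:
                return ReachResult.BUDGET_EXCEEDED
            queue.append(nxt)
    return ReachResult.FALSE


# ---------------------------------------------------------------------------
# meta-states


_ZERO = frozenset((0,))
_ONE = frozenset((1,))
_BOTH = frozenset((0, 1))


def meta_successors(bn: BooleanNetwork, u: Sequence, clamp: Mapping | None = None) -> set:
    """Single-step widenings of meta-state ``u``.

    For each free component i the image of f_i over u is joined into u_i;
    a successor is emitted whenever the join strictly grows the component.
    ``u`` is a sequence of frozensets among {0}, {1}, {0,1} aligned with
    ``bn.nodes``; clamped components must be the clamp singleton and are
    never widened.
    """
    dyn = _Compiled(bn, clamp)
    if len(u) != dyn.n:
        raise ValueError("meta-state length does not match network size")
    u = tuple(frozenset(c) for c in u)
    for i, comp in enumerate(u):
        if not comp or not comp <= _BOTH:
            raise ValueError("meta-state components must be non-empty subsets of {0,1}")
        if i in dyn.clamp and comp != frozenset((dyn.clamp[i],)):
            raise ValueError("clamped component must equal its clamp value")
    # express u as base point + widened set so _Compiled.image applies
    base = tuple(min(c) for c in u)
    widened = frozenset(i for i, c in enumerate(u) if c == _BOTH)
    out = set()
    for i in range(dyn.n):
        if i in dyn.clamp:
            continue
        img = dyn.image(i, base, widened)
        joined = u[i] | img
        if joined != u[i]:
            v = list(u)
            v[i] = joined
            out.add(tuple(v))
    return out


class ConsistencyChecker:
    """Memoized support-consistency queries for one network and clamping.

    Support consistency of x with y requires a meta-state u, reachable
    from the singleton meta-state of x by zero or more widenings, with
    y ∈ u and, for every constrained component i, one of:

    (a) y_i differs from x_i (the widening covers the change), or
    (b) y_i equals x_i and u_i is still the singleton, or
    (c) y_i equals x_i, u_i was widened, and some z ∈ u has f_i(z) = y_i.

    Because widening only ever grows components, every meta-state reachable
    from a singleton is described by its set of widened components, and the
    search space is the (union-closed) family of constructible widened
    sets.
    """

    def __init__(self, bn: BooleanNetwork, clamp: Mapping | None = None):
        self.dyn = _Compiled(bn, clamp)
        self._pair_memo: dict = {}
        self._widen_memo: dict = {}

    def _widenable(self, i, x, widened):
        if i in self.dyn.clamp:
            return False
        key = (i, x, widened)
        hit = self._widen_memo.get(key)
        if hit is None:
            hit = (1 - x[i]) in self.dyn.image(i, x, widened)
            self._widen_memo[key] = hit
        return hit

    def pair(self, x, y_items) -> bool:
        """Is x support-consistent with the partial state y (as items)?"""
        key = (tuple(x), tuple(sorted(y_items)))
        hit = self._pair_memo.get(key)
        if hit is not None:
            return hit
        res = self._search(tuple(x), dict(y_items))
        self._pair_memo[key] = res
        return res

    def _search(self, x, y) -> bool:
        dyn = self.dyn
        need = frozenset(i for i, val in y.items() if val != x[i])
        if any(i in dyn.clamp for i in need):
            return False
        same = [i for i in y if y[i] == x[i]]

        def ok(widened):
            if not need <= widened:
                return False
            for i in same:
                if i in widened and y[i] not in dyn.image(i, x, widened):
                    return False
            return True

        start = frozenset()
        if ok(start):
            return True
        seen = {start}
        queue = deque([start])
        while queue:
            w = queue.popleft()
            for i in range(dyn.n):
                if i in w or not self._widenable(i, x, w):
                    continue
                nw = w | {i}
                if nw in seen:
                    continue
                if ok(nw):
                    return True
                seen.add(nw)
                queue.append(nw)
        return False


def support_consistent(
    bn: BooleanNetwork,
    x,
    y,
    clamp: Mapping | None = None,
) -> bool:
    """Necessary condition for exact reachability of y from x.

    ``y`` is either a full state aligned with ``bn.nodes`` or a mapping
    constraining a subset of nodes.  Soundness: reachable(x, y) = TRUE
    implies support_consistent(x, y); the converse can fail.
    """
    checker = ConsistencyChecker(bn, clamp)
    checker.dyn.check_state(x)
    idx = checker.dyn.idx
    if isinstance(y, Mapping):
        for v in y:
            if v not in idx:
                raise ValueError(f"target constrains unknown node {v!r}")
        items = tuple((idx[v], val) for v, val in y.items())
    else:
        if len(y) != len(bn.nodes):
            raise ValueError("full target state has wrong length")
        items = tuple(enumerate(y))
    return checker.pair(tuple(x), items)


def upstream_closure(bn: BooleanNetwork, targets: Iterable) -> frozenset:
    """Targets plus every node with a directed regulatory path to them.

    Nodes outside this *cone of influence* can be frozen at an arbitrary
    value without affecting reachability or support consistency of
    observations on the targets.
    """
    want = set(targets)
    frontier = list(want)
    while frontier:
        v = frontier.pop()
        for r in bn.regulators(v):
            if r not in want:
                want.add(r)
                frontier.append(r)
    return frozenset(want)
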