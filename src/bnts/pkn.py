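"""Prior knowledge network (PKN) I/O and the clause space it admits.

The PKN is a signed directed graph over proteins with a role partition:
stimuli (experimentally set to 0/1), inhibitors (clamped to 0 when the
inhibiting drug is applied), readouts (measured in [0,1]) and unobserved
nodes.  A protein can be an inhibitor and a readout at the same time; all
other role pairs are disjoint.

A candidate Boolean function for node v must be *compatible* with the
PKN: it is a disjunction of clauses over direct PKN predecessors of v,
and each literal's polarity matches the sign of the corresponding edge
(+1 gives a plain literal, -1 a negated one).  :func:`clause_space`
enumerates all such clauses up to a size cap, canonically ordered so that
candidate enumeration downstream is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from bnts.core import Clause, clause_sort_key

__all__ = [
    "ROLES",
    "PKN",
    "ClauseSpace",
    "read_sif",
    "write_sif",
    "read_roles",
    "clause_space",
]

ROLES = (
    "stimulus",
    "inhibitor",
    "readout",
    "inhibitor_and_readout",
    "unobserved",
)

_POS_TOKENS = {"1", "+1", "activate"}
_NEG_TOKENS = {"-1", "inhibit"}


@dataclass(frozen=True)
class PKN:
    """Signed directed prior network with node roles.

    ``edges`` are (source, target, sign) triples with sign in {+1, -1};
    parallel edges of opposite sign between the same pair are allowed.
    ``roles`` maps every node to one of :data:`ROLES`; nodes absent from
    the role table passed to the constructor default to ``unobserved``.
    """

    nodes: frozenset
    edges: frozenset
    roles: Mapping

    def __post_init__(self):
        roles = dict(self.roles)
        for s, t, sign in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge ({s!r}, {t!r}) endpoint not in nodes")
            if sign not in (+1, -1):
                raise ValueError(f"edge ({s!r}, {t!r}) has invalid sign {sign!r}")
        for v, role in roles.items():
            if v not in self.nodes:
                raise ValueError(f"role given for unknown node {v!r}")
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for node {v!r}")
        for v in self.nodes:
            roles.setdefault(v, "unobserved")
        object.__setattr__(self, "roles", roles)

    # -- role views --------------------------------------------------------

    @property
    def stimuli(self) -> frozenset:
        return frozenset(v for v, r in self.roles.items() if r == "stimulus")

    @property
    def inhibitors(self) -> frozenset:
        return frozenset(
            v
            for v, r in self.roles.items()
            if r in ("inhibitor", "inhibitor_and_readout")
        )

    @property
    def readouts(self) -> frozenset:
        return frozenset(
            v
            for v, r in self.roles.items()
            if r in ("readout", "inhibitor_and_readout")
        )

    @property
    def unobserved(self) -> frozenset:
        return frozenset(v for v, r in self.roles.items() if r == "unobserved")

    # -- queries -----------------------------------------------------------

    def predecessors(self, node) -> list:
        """Sorted (source, sign) pairs of direct regulators of ``node``."""
        if node not in self.nodes:
            raise KeyError(node)
        return sorted((s, sign) for s, t, sign in self.edges if t == node)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for v in sorted(self.nodes):
            g.nodes[v]["role"] = self.roles[v]
        for s, t, sign in sorted(self.edges):
            g.add_edge(s, t, sign=sign)
        return g


def _parse_sign(token: str, lineno: int) -> int:
    if token in _POS_TOKENS:
        return +1
    if token in _NEG_TOKENS:
        return -1
    raise ValueError(f"line {lineno}: cannot parse sign token {token!r}")


def read_sif(path, roles: Mapping | None = None) -> PKN:
    """Read a SIF-style file: one ``source sign target`` triple per line.

    Fields are whitespace- or tab-separated; sign tokens ``1``/``+1``/
    ``activate`` mean +1 and ``-1``/``inhibit`` mean -1.  ``roles`` maps a
    subset of the nodes to their experimental role; unlisted nodes become
    ``unobserved``.
    """
    text = Path(path).read_text()
    nodes, edges = set(), set()
    n_data_lines = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 1:
            # standard SIF: a bare name declares an isolated node
            nodes.add(parts[0])
            n_data_lines += 1
            continue
        if len(parts) != 3:
            raise ValueError(
                f"line {lineno}: expected 'source sign target', got {raw!r}"
            )
        src, sign_tok, tgt = parts
        sign = _parse_sign(sign_tok, lineno)
        nodes.update((src, tgt))
        edges.add((src, tgt, sign))
        n_data_lines += 1
    if n_data_lines == 0:
        raise ValueError(f"{path}: no interaction lines found")
    return PKN(frozenset(nodes), frozenset(edges), dict(roles or {}))


def write_sif(pkn: PKN, path) -> None:
    """Write the canonical SIF form read back by :func:`read_sif`.

    Nodes that touch no edge are emitted as bare single-name lines so
    the round-trip preserves the full node set.
    """
    lines = [f"{s}\t{sign:+d}\t{t}" for s, t, sign in sorted(pkn.edges)]
    touched = {v for s, t, _ in pkn.edges for v in (s, t)}
    lines += sorted(pkn.nodes - touched)
    Path(path).write_text("\n".join(lines) + "\n")


def read_roles(path) -> dict:
    """Read a 2-column (node, role) whitespace-separated table."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'node role'")
        node, role = parts
        if role not in ROLES:
            raise ValueError(f"line {lineno}: unknown role {role!r}")
        out[node] = role
    return out


@dataclass(frozen=True)
class ClauseSpace:
    """Admissible clauses per node, derived from PKN sign consistency.

    ``clauses[v]`` is the canonically ordered tuple of all clauses over
    direct predecessors of v with edge-matching polarities and size at
    most ``max_clause_size``.  Nodes without predecessors get an empty
    tuple: they can only be clamped or keep their value.
    """

    clauses: Mapping
    max_clause_size: int

    def __getitem__(self, node):
        return self.clauses[node]

    def nodes(self):
        return sorted(self.clauses)

    def functions(self, node, max_clauses: int) -> list:
        """Candidate functions for ``node``: antichain clause subsets.

        Returns every subset of the node's clauses of size at most
        ``max_clauses`` in which no clause subsumes another (a clause
        whose literals contain another clause's is redundant in a
        disjunction, so dropping such subsets loses no Boolean function).
        The empty subset — no regulation, node keeps its value — is
        included and comes first; the order is deterministic.
        """
        if max_clauses < 1:
            raise ValueError("max_clauses must be >= 1")
        cs = self.clauses[node]
        out = [()]
        for r in range(1, min(max_clauses, len(cs)) + 1):
            for combo in itertools.combinations(range(len(cs)), r):
                sel = [cs[i] for i in combo]
                if any(
                    a < b or b < a
                    for a, b in itertools.combinations(sel, 2)
                ):
                    continue
                out.append(tuple(sel))
        return out


def clause_space(pkn: PKN, max_clause_size: int = 2) -> ClauseSpace:
    """Enumerate every PKN-compatible clause per node up to a size cap.

    For a node with predecessor edges {(p, s)}, a clause picks a non-empty
    subset of distinct regulators and, for each, one of its available edge
    signs; a clause never carries both polarities of one regulator.  With
    no double-signed predecessors this yields sum_{s<=cap} C(d, s) clauses
    for in-degree d.
    """
    if max_clause_size < 1:
        raise ValueError("max_clause_size must be >= 1")
    table = {}
    for v in sorted(pkn.nodes):
        preds = pkn.predecessors(v)
        by_reg: dict = {}
        for src, sign in preds:
            by_reg.setdefault(src, set()).add(sign)
        regs = sorted(by_reg)
        clauses = []
        for r in range(1, min(max_clause_size, len(regs)) + 1):
            for combo in itertools.combinations(regs, r):
                for signs in itertools.product(
                    *(sorted(by_reg[reg], reverse=True) for reg in combo)
                ):
                    clauses.append(Clause(zip(combo, signs)))
        table[v] = tuple(sorted(set(clauses), key=clause_sort_key))
    return ClauseSpace(table, max_clause_size)
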