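"""Synthetic benchmark generator.

Produces random prior networks, ground-truth Boolean networks drawn from
their clause space, and simulated multi-perturbation time series, so the
whole learning pipeline is testable without any experimental download.

The emission model maps hidden binary states to continuous readings the
way normalized phosphoproteomic intensities behave: each (perturbation,
protein) pair draws a low level (inactive) and a high level (active)
once, the trajectory emits the level matching the hidden bit at every
timepoint, and Gaussian measurement noise is added before clipping to
[0,1].  With the default bands the 0.5 binarization threshold recovers
the hidden states exactly at zero noise and is increasingly stressed
from noise_sd ≈ 0.15.  Hidden trajectories are random walks in the
network's own any-subset transition system, so consecutive sampled
states are truly reachable and the generating network is certifiable as
a true positive at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from bnts.core import BooleanNetwork, successors
from bnts.pkn import PKN, clause_space, write_sif
from bnts.timeseries import PerturbationDataset, clamping, write_midas

__all__ = [
    "SimConfig",
    "generate_pkn",
    "sample_true_bn",
    "default_perturbations",
    "simulate",
    "write_bundle",
]

#: emission bands for hidden 0 and 1 (uniform draws)
LOW_BAND = (0.05, 0.35)
HIGH_BAND = (0.65, 0.95)

#: minute grid of the standard 4-hour perturbation screen
TIME_GRID = (0, 5, 15, 30, 60, 120, 240, 480, 960, 1920)


@dataclass(frozen=True)
class SimConfig:
    """Shape and noise of the synthetic study.

    Defaults emulate a small perturbation screen: a ten-protein network
    with three stimuli, one (measured) inhibitor and four readouts,
    five perturbations observed at the standard seven-timepoint minute
    grid, with mild measurement noise.
    """

    n_nodes: int = 10
    edge_density: float = 0.2
    n_stimuli: int = 3
    n_inhibitors: int = 1
    n_readouts: int = 4
    n_perturbations: int = 5
    k_timepoints: int = 7
    noise_sd: float = 0.05
    n_feedback_edges: int = 1
    max_clause_size: int = 2
    max_clauses_per_node: int = 3
    missing_t0: bool = False
    duplicate_timepoint: bool = False
    inhibitor_dynamic: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_stimuli + self.n_inhibitors + self.n_readouts > self.n_nodes:
            raise ValueError("role counts exceed the number of nodes")
        if self.n_stimuli < 1 or self.n_stimuli >= self.n_nodes:
            raise ValueError("need at least one stimulus and one non-stimulus")
        if self.k_timepoints < 2:
            raise ValueError("need at least two timepoints")
        if self.noise_sd < 0 or not 0 < self.edge_density <= 1:
            raise ValueError("invalid noise or density")


def generate_pkn(cfg: SimConfig) -> PKN:
    """Seeded random signed DAG-plus-feedback prior with roles assigned.

    Stimuli are sources (no parents); every other node has at least one
    parent among earlier nodes; every readout is reachable from some
    stimulus; a few feedback edges close cycles among non-stimuli.
    Inhibitors are also measured (role ``inhibitor_and_readout``), as is
    typical when the inhibited protein is on the assay panel.
    """
    rng = np.random.default_rng(cfg.seed)
    stimuli = [f"s{i+1}" for i in range(cfg.n_stimuli)]
    inhibitors = [f"i{i+1}" for i in range(cfg.n_inhibitors)]
    readouts = [f"r{i+1}" for i in range(cfg.n_readouts)]
    n_unobs = cfg.n_nodes - cfg.n_stimuli - cfg.n_inhibitors - cfg.n_readouts
    unobserved = [f"u{i+1}" for i in range(n_unobs)]
    rest = inhibitors + unobserved + readouts
    rng.shuffle(rest)
    order = stimuli + rest

    edges = set()
    for pos in range(cfg.n_stimuli, len(order)):
        v = order[pos]
        parents = [
            order[q] for q in range(pos) if rng.random() < cfg.edge_density
        ]
        if not parents:
            parents = [order[int(rng.integers(0, pos))]]
        for u in parents:
            sign = +1 if rng.random() < 0.75 else -1
            edges.add((u, v, sign))

    non_stim = order[cfg.n_stimuli :]
    for _ in range(cfg.n_feedback_edges):
        if len(non_stim) >= 2:
            a, b = rng.choice(len(non_stim), size=2, replace=False)
            src, tgt = non_stim[max(a, b)], non_stim[min(a, b)]
            edges.add((src, tgt, +1 if rng.random() < 0.75 else -1))

    # guarantee stimulus -> readout reachability
    adj: dict = {}
    for s, t, _ in edges:
        adj.setdefault(s, set()).add(t)

    def reachable_from(starts):
        seen = set(starts)
        stack = list(starts)
        while stack:
            for t in adj.get(stack.pop(), ()):
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        return seen

    covered = reachable_from(stimuli)
    for r in readouts:
        if r not in covered:
            s = stimuli[int(rng.integers(0, len(stimuli)))]
            edges.add((s, r, +1))
            adj.setdefault(s, set()).add(r)
            covered = reachable_from(stimuli)

    roles = {v: "stimulus" for v in stimuli}
    roles.update({v: "inhibitor_and_readout" for v in inhibitors})
    roles.update({v: "readout" for v in readouts})
    roles.update({v: "unobserved" for v in unobserved})
    return PKN(frozenset(order), frozenset(edges), roles)


def sample_true_bn(pkn: PKN, cfg: SimConfig) -> BooleanNetwork:
    """Uniformly sample one network from the PKN's candidate space.

    Every node with regulators receives a non-empty disjunction drawn
    uniformly from the same canonical function space the learner
    enumerates (so the truth is always recoverable under equal caps);
    regulator-free nodes keep their value.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    space = clause_space(pkn, cfg.max_clause_size)
    nodes = tuple(sorted(pkn.nodes))
    funcs = {}
    for v in nodes:
        options = space.functions(v, cfg.max_clauses_per_node)[1:]  # skip empty
        funcs[v] = (
            options[int(rng.integers(0, len(options)))] if options else ()
        )
    return BooleanNetwork(nodes, funcs)


def default_perturbations(pkn: PKN, n: int, seed: int = 0) -> tuple:
    """A canonical perturbation panel: single-stimulus designs first.

    The panel starts with each stimulus toggled on alone (inhibitors
    untreated) — the design under which the generating network is
    identifiable at zero noise — followed by the all-stimuli baseline
    and, for each inhibitor, the all-stimuli design with that inhibitor
    applied; any further perturbations are random treatment vectors.
    """
    rng = np.random.default_rng(seed + 3)
    stimuli = sorted(pkn.stimuli)
    inhibitors = sorted(pkn.inhibitors)
    panel = []
    for s in stimuli:
        p = {x: 0 for x in stimuli + inhibitors}
        p[s] = 1
        panel.append(p)
    panel.append({**{s: 1 for s in stimuli}, **{i: 0 for i in inhibitors}})
    for i in inhibitors:
        p = {**{s: 1 for s in stimuli}, **{x: 0 for x in inhibitors}}
        p[i] = 1
        panel.append(p)
    while len(panel) < n:
        p = {
            x: int(rng.integers(0, 2)) for x in stimuli + inhibitors
        }
        if p not in panel:
            panel.append(p)
    return tuple(panel[:n])


def simulate(
    bn: BooleanNetwork, pkn: PKN, perturbations: Sequence, cfg: SimConfig
) -> tuple:
    """Simulate a noisy dataset; returns (dataset, hidden binary traces).

    Per perturbation a random walk under the perturbation's clamping
    records ``k_timepoints`` states (each one 0 or 1 steps after the
    previous); the PKN's readouts are emitted through the band/noise
    model.  Configured QC defects are injected afterwards.  The hidden
    full-state traces are returned alongside for oracle tests.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    nodes = bn.nodes
    stim_cols = sorted(pkn.stimuli)
    inh_cols = sorted(pkn.inhibitors)
    observed = sorted(pkn.readouts)
    k = cfg.k_timepoints
    timepoints = list(TIME_GRID[:k])

    hidden_all, series = [], []
    for pert in perturbations:
        clamp = clamping(pert, stim_cols, inh_cols)
        state = tuple(
            clamp.get(v, int(rng.integers(0, 2))) for v in nodes
        )
        hidden = [state]
        for _ in range(k - 1):
            succ = sorted(successors(bn, state, clamp))
            if succ and rng.random() < 0.8:
                state = succ[int(rng.integers(0, len(succ)))]
            hidden.append(state)
        hidden_all.append(tuple(hidden))

        levels = {
            v: (rng.uniform(*LOW_BAND), rng.uniform(*HIGH_BAND))
            for v in observed
        }
        mat = np.zeros((k, len(observed)))
        node_pos = {v: i for i, v in enumerate(nodes)}
        for j in range(k):
            for c, v in enumerate(observed):
                bit = hidden[j][node_pos[v]]
                val = levels[v][bit] + rng.normal(0.0, cfg.noise_sd)
                mat[j, c] = min(1.0, max(0.0, val))
        series.append(mat)

    # inject defects
    if cfg.duplicate_timepoint:
        dup_at = 1
        timepoints.insert(dup_at + 1, timepoints[dup_at])
        for p in range(len(series)):
            extra = series[p][dup_at, :] + rng.normal(
                0.0, max(cfg.noise_sd, 0.01), size=len(observed)
            )
            series[p] = np.insert(
                series[p], dup_at + 1, np.clip(extra, 0, 1), axis=0
            )
        hidden_all = [
            h[: dup_at + 1] + (h[dup_at],) + h[dup_at + 1 :] for h in hidden_all
        ]
    if cfg.missing_t0:
        series[0][0, 0] = np.nan
    if cfg.inhibitor_dynamic:
        target = None
        for p, pert in enumerate(perturbations):
            treated = [
                v for v in inh_cols if pert.get(v, 0) == 1 and v in observed
            ]
            if treated:
                target = (p, observed.index(treated[0]))
                break
        if target is None:
            raise ValueError(
                "inhibitor_dynamic defect needs a perturbation with a "
                "measured, treated inhibitor"
            )
        p, c = target
        col = series[p][:, c].copy()
        col[::2], col[1::2] = 0.1, 0.9
        series[p][:, c] = col

    ds = PerturbationDataset(
        tuple(observed),
        tuple(timepoints),
        tuple(dict(p) for p in perturbations),
        tuple(series),
        tuple(stim_cols),
        tuple(inh_cols),
    )
    return ds, tuple(hidden_all)


def write_bundle(directory, pkn: PKN, bn: BooleanNetwork, dataset: PerturbationDataset) -> dict:
    """Write a fixture bundle (SIF, roles, MIDAS, truth BN); returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": directory / "pkn.sif",
        "roles": directory / "roles.tsv",
        "midas": directory / "data.csv",
        "truth": directory / "truth.bn",
    }
    write_sif(pkn, paths["sif"])
    paths["roles"].write_text(
        "\n".join(f"{v}\t{r}" for v, r in sorted(pkn.roles.items())) + "\n"
    )
    write_midas(dataset, paths["midas"])
    paths["truth"].write_text("\n".join(bn.to_lines()) + "\n")
    return paths
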