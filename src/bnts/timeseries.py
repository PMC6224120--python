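"""Multi-perturbation time-series containers, normalization, QC.

A :class:`PerturbationDataset` holds, for each perturbation (a 0/1
treatment assignment over stimuli and inhibitors), a k x m matrix of
measurements of m readout proteins at k shared timepoints.  Values live
in [0,1] after max-based normalization; missing entries are NaN.

Quality control mirrors the standard cleaning sequence for perturbation
screens of this kind: fill missing time-0 readings from unperturbed
controls, collapse duplicated timepoints, drop perturbations in which an
inhibited protein's own readout is nevertheless dynamic, and finally
drop perturbations with incomplete series.  Every repair is recorded in
a replayable report.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PerturbationDataset",
    "BinarizedDataset",
    "QCReport",
    "normalize",
    "binarize",
    "qc_repair",
    "clamping",
    "read_midas",
    "write_midas",
    "read_long",
]

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class PerturbationDataset:
    """Aligned multi-perturbation time series.

    ``series[p][j, i]`` is the value of ``observed_nodes[i]`` at
    ``timepoints[j]`` under ``perturbations[p]``; NaN marks a missing
    reading.  ``stimuli`` and ``inhibitors`` name the treated columns so
    that clampings can be derived without consulting the PKN.
    """

    observed_nodes: tuple
    timepoints: tuple
    perturbations: tuple
    series: tuple
    stimuli: tuple = ()
    inhibitors: tuple = ()

    def __post_init__(self):
        k, m = len(self.timepoints), len(self.observed_nodes)
        if len(self.series) != len(self.perturbations):
            raise ValueError("one series per perturbation required")
        mats = []
        for mat in self.series:
            arr = np.asarray(mat, dtype=float)
            if arr.shape != (k, m):
                raise ValueError(
                    f"series shape {arr.shape} does not match (k={k}, m={m})"
                )
            arr = arr.copy()
            arr.setflags(write=False)
            mats.append(arr)
        object.__setattr__(self, "series", tuple(mats))
        object.__setattr__(
            self, "perturbations", tuple(dict(p) for p in self.perturbations)
        )

    @property
    def k(self) -> int:
        return len(self.timepoints)

    @property
    def m(self) -> int:
        return len(self.observed_nodes)

    @property
    def n_perturbations(self) -> int:
        return len(self.perturbations)

    def node_index(self, node) -> int:
        return self.observed_nodes.index(node)

    def stacked(self) -> np.ndarray:
        """All series stacked to a (|P|, k, m) array."""
        return np.stack(self.series) if self.series else np.zeros((0, self.k, self.m))


@dataclass(frozen=True)
class BinarizedDataset(PerturbationDataset):
    """A :class:`PerturbationDataset` whose values are exactly 0 or 1."""

    def __post_init__(self):
        super().__post_init__()
        for mat in self.series:
            if not np.isin(mat, (0.0, 1.0)).all():
                raise ValueError("binarized values must be 0 or 1")

    def flip(self, points) -> "BinarizedDataset":
        """Return a copy with each (perturbation, time, node) point flipped."""
        mats = [mat.copy() for mat in self.series]
        for p, j, node in points:
            i = self.node_index(node)
            mats[p][j, i] = 1.0 - mats[p][j, i]
        return replace(self, series=tuple(mats))


def clamping(perturbation: Mapping, stimuli, inhibitors) -> dict:
    """Derive the Boolean clamping imposed by one perturbation.

    Stimuli are held at their 0/1 treatment value for the whole
    trajectory.  An inhibitor treated with 1 means the drug is applied,
    so the protein is held inactive (0); an untreated inhibitor is free.
    """
    clamp = {}
    for s in stimuli:
        clamp[s] = int(perturbation.get(s, 0))
    for i in inhibitors:
        if int(perturbation.get(i, 0)) == 1:
            clamp[i] = 0
    return clamp


# ---------------------------------------------------------------------------
# normalization / binarization


def normalize(raw: PerturbationDataset) -> PerturbationDataset:
    """Max-based normalization: divide each protein by its global maximum.

    The maximum is taken over every perturbation and timepoint, so after
    normalization each observed protein with any positive reading attains
    the value 1 somewhere.  Idempotent; missing entries stay missing.
    A protein whose global maximum is zero (or that has no readings at
    all) cannot be scaled and raises.
    """
    stacked = raw.stacked()
    if (stacked[~np.isnan(stacked)] < 0).any():
        raise ValueError("raw values must be non-negative")
    mats = [mat.copy() for mat in raw.series]
    for i, node in enumerate(raw.observed_nodes):
        col = stacked[:, :, i]
        if np.isnan(col).all():
            raise ValueError(f"node {node!r} has no readings to normalize")
        peak = np.nanmax(col)
        if peak == 0:
            raise ValueError(
                f"node {node!r} has global maximum 0; normalization undefined"
            )
        for mat in mats:
            mat[:, i] /= peak
    return replace(raw, series=tuple(mats))


def binarize(
    norm: PerturbationDataset, threshold: float = DEFAULT_THRESHOLD
) -> BinarizedDataset:
    """Threshold normalized values to {0,1}; ties (== threshold) map to 1."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0,1)")
    mats = []
    for p, mat in enumerate(norm.series):
        if np.isnan(mat).any():
            j, i = map(int, np.argwhere(np.isnan(mat))[0])
            raise ValueError(
                "cannot binarize missing entry at "
                f"(perturbation {p}, time {norm.timepoints[j]!r}, "
                f"node {norm.observed_nodes[i]!r})"
            )
        mats.append((mat >= threshold).astype(float))
    return BinarizedDataset(
        norm.observed_nodes,
        norm.timepoints,
        norm.perturbations,
        tuple(mats),
        norm.stimuli,
        norm.inhibitors,
    )


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    """Exhaustive log of QC repairs; replaying it reconstructs the output."""

    entries: list = field(default_factory=list)

    def __bool__(self):
        return bool(self.entries)

    def add(self, rule: str, **details):
        self.entries.append({"rule": rule, **details})

    def by_rule(self, rule: str) -> list:
        return [e for e in self.entries if e["rule"] == rule]

    def replay(self, raw: PerturbationDataset) -> PerturbationDataset:
        """Apply the recorded repairs to ``raw`` again."""
        mats = [mat.copy() for mat in raw.series]
        for e in self.by_rule("step-2"):
            i = raw.node_index(e["node"])
            mats[e["perturbation"]][0, i] = e["value"]
        keep_rows = sorted(
            set(range(raw.k))
            - {j for e in self.by_rule("step-3") for j in e["dropped_rows"]}
        )
        timepoints = tuple(raw.timepoints[j] for j in keep_rows)
        mats = [mat[keep_rows, :] for mat in mats]
        dropped = {
            e["perturbation"]
            for e in self.by_rule("step-4") + self.by_rule("step-5")
        }
        keep_p = [p for p in range(raw.n_perturbations) if p not in dropped]
        return replace(
            raw,
            timepoints=timepoints,
            perturbations=tuple(raw.perturbations[p] for p in keep_p),
            series=tuple(mats[p] for p in keep_p),
        )


def qc_repair(
    raw: PerturbationDataset,
    control: Mapping | None = None,
    tolerance: float = 0.1,
) -> tuple:
    """Clean a raw dataset; returns (clean dataset, replayable report).

    Applied in order:

    * step-2 — a missing time-0 reading is filled from the unperturbed
      control value of that protein, when a control is given;
    * step-3 — duplicated timepoint labels are collapsed by keeping the
      first occurrence in file order;
    * step-4 — a perturbation in which an inhibited protein is also
      measured and its own trace varies by more than ``tolerance``
      (max - min, ignoring missing values) contradicts the experimental
      setting and is dropped;
    * step-5 — perturbations with remaining missing readings are dropped.

    Nothing raises: every issue becomes a report entry, and an empty
    surviving dataset is reported rather than an error.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    report = QCReport()
    mats = [mat.copy() for mat in raw.series]

    # step 2: control readings stand in for missing time-0 values
    if control:
        for p in range(raw.n_perturbations):
            for i, node in enumerate(raw.observed_nodes):
                if np.isnan(mats[p][0, i]) and node in control:
                    mats[p][0, i] = float(control[node])
                    report.add(
                        "step-2",
                        perturbation=p,
                        node=node,
                        value=float(control[node]),
                    )

    # step 3: collapse duplicated timepoints, first occurrence wins
    seen: dict = {}
    keep_rows, dropped_rows = [], {}
    for j, label in enumerate(raw.timepoints):
        if label in seen:
            dropped_rows.setdefault(label, []).append(j)
        else:
            seen[label] = j
            keep_rows.append(j)
    for label, rows in dropped_rows.items():
        report.add(
            "step-3", timepoint=label, kept_row=seen[label], dropped_rows=rows
        )
    timepoints = tuple(raw.timepoints[j] for j in keep_rows)
    mats = [mat[keep_rows, :] for mat in mats]

    # step 4: inhibited-but-dynamic readouts invalidate the perturbation
    surviving = []
    for p, pert in enumerate(raw.perturbations):
        bad = None
        for node in raw.inhibitors:
            if int(pert.get(node, 0)) != 1 or node not in raw.observed_nodes:
                continue
            trace = mats[p][:, raw.node_index(node)]
            vals = trace[~np.isnan(trace)]
            if vals.size and float(vals.max() - vals.min()) > tolerance:
                bad = (node, float(vals.max() - vals.min()))
                break
        if bad is None:
            surviving.append(p)
        else:
            report.add(
                "step-4", perturbation=p, node=bad[0], range=bad[1]
            )

    # step 5: only complete series are kept
    complete = []
    for p in surviving:
        if np.isnan(mats[p]).any():
            report.add("step-5", perturbation=p)
        else:
            complete.append(p)
    if not complete:
        report.add("empty-dataset")

    clean = replace(
        raw,
        timepoints=timepoints,
        perturbations=tuple(raw.perturbations[p] for p in complete),
        series=tuple(mats[p] for p in complete),
    )
    return clean, report


# ---------------------------------------------------------------------------
# file formats


def write_midas(ds: PerturbationDataset, path) -> None:
    """Write the MIDAS-dialect table read back by :func:`read_midas`."""
    rows = []
    for p, pert in enumerate(ds.perturbations):
        for j, t in enumerate(ds.timepoints):
            row = {}
            for s in ds.stimuli:
                row[f"TR:{s}:Stimuli"] = int(pert.get(s, 0))
            for i in ds.inhibitors:
                row[f"TR:{i}i"] = int(pert.get(i, 0))
            row["DA:ALL"] = t
            for idx, node in enumerate(ds.observed_nodes):
                val = ds.series[p][j, idx]
                row[f"DV:{node}"] = "" if np.isnan(val) else val
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_midas(path) -> PerturbationDataset:
    """Read a MIDAS-dialect CSV into a :class:`PerturbationDataset`.

    Treatment columns ``TR:<name>:Stimuli`` and ``TR:<name>i`` carry the
    0/1 perturbation, ``DA:ALL`` the time label, and ``DV:<name>`` the
    measurements.  Perturbations appear in order of first occurrence and
    must share one timepoint grid (duplicated labels are preserved for QC
    to resolve).
    """
    df = pd.read_csv(path)
    stimuli = [
        c.split(":")[1] for c in df.columns if c.startswith("TR:") and c.endswith(":Stimuli")
    ]
    inhibitors = [
        c[3:-1]
        for c in df.columns
        if c.startswith("TR:") and c.endswith("i") and not c.endswith(":Stimuli")
    ]
    readouts = [c[3:] for c in df.columns if c.startswith("DV:")]
    if "DA:ALL" not in df.columns:
        raise ValueError("MIDAS table lacks the DA:ALL time column")
    tr_cols = [f"TR:{s}:Stimuli" for s in stimuli] + [f"TR:{i}i" for i in inhibitors]
    perts, series, timepoints = [], [], None
    for key, grp in df.groupby(tr_cols, sort=False):
        key = (key,) if len(tr_cols) == 1 else key
        pert = {name: int(val) for name, val in zip(stimuli + inhibitors, key)}
        labels = tuple(grp["DA:ALL"].tolist())
        if timepoints is None:
            timepoints = labels
        elif labels != timepoints:
            raise ValueError(
                f"perturbation {pert!r} has timepoints {labels}, expected {timepoints}"
            )
        mat = grp[[f"DV:{r}" for r in readouts]].to_numpy(dtype=float)
        perts.append(pert)
        series.append(mat)
    if timepoints is None:
        raise ValueError("MIDAS table has no data rows")
    return PerturbationDataset(
        tuple(readouts),
        timepoints,
        tuple(perts),
        tuple(series),
        tuple(stimuli),
        tuple(inhibitors),
    )


def read_long(values_path, perturbations_path) -> PerturbationDataset:
    """Read the long-format pair of tables.

    ``values_path``: columns (perturbation_id, time, node, value).
    ``perturbations_path``: columns (perturbation_id, node, kind, value)
    with kind in {stimulus, inhibitor}.  Produces the same dataset a
    MIDAS table with equal content would.
    """
    vals = pd.read_csv(values_path)
    perts_df = pd.read_csv(perturbations_path)
    stimuli = sorted(perts_df.loc[perts_df["kind"] == "stimulus", "node"].unique())
    inhibitors = sorted(perts_df.loc[perts_df["kind"] == "inhibitor", "node"].unique())
    observed = sorted(vals["node"].unique())
    pert_ids = list(dict.fromkeys(vals["perturbation_id"]))
    timepoints = None
    perts, series = [], []
    for pid in pert_ids:
        sub = perts_df[perts_df["perturbation_id"] == pid]
        pert = {row["node"]: int(row["value"]) for _, row in sub.iterrows()}
        for name in stimuli + inhibitors:
            pert.setdefault(name, 0)
        block = vals[vals["perturbation_id"] == pid]
        labels = tuple(dict.fromkeys(block["time"]))
        if timepoints is None:
            timepoints = labels
        elif labels != timepoints:
            raise ValueError(f"perturbation {pid!r} disagrees on timepoints")
        mat = np.full((len(labels), len(observed)), np.nan)
        tindex = {t: j for j, t in enumerate(labels)}
        for _, row in block.iterrows():
            mat[tindex[row["time"]], observed.index(row["node"])] = row["value"]
        perts.append(pert)
        series.append(mat)
    return PerturbationDataset(
        tuple(observed),
        timepoints or (),
        tuple(perts),
        tuple(series),
        tuple(stimuli),
        tuple(inhibitors),
    )
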