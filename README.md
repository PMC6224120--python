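# bnts — Boolean networks from perturbation time series

`bnts` infers families of Boolean networks (BNs) of protein signaling
from multi-perturbation phosphoproteomic time series, constrained by a
prior knowledge network (PKN).  It is aimed at systems biologists who
have a literature-derived signed interaction graph and a perturbation
screen (stimuli toggled, inhibitors applied, readouts measured over
time) and want executable logic models that provably reproduce the
discretized data — plus honest bookkeeping of which data points had to
be corrected to make that possible.

## The method

A PKN is a signed digraph (V, E, σ) with node roles: stimuli S,
inhibitors I, readouts R, unobserved U.  A candidate BN gives each node
a DNF function over its PKN predecessors with edge-matching signs; each
(node ← clause) pair is a hyper-edge.  Each perturbation P ⊆ S ∪ I
clamps stimuli at their treatment value and applied inhibitors at 0.
Dynamics update any non-empty subset of free nodes at once, so results
hold for synchronous and asynchronous schedules alike.

Learning minimizes the root mean square error between the observed
series T and a binary trajectory Y (one full state per timepoint,
consecutive states linked by the dynamics):

    RMSE = sqrt( (1 / (m·k·|P|)) Σ_i Σ_j Σ_P ( (t_P^j)_i − (y_P^j)_i )² )

Because exact reachability between successive states is PSPACE-hard,
the search instead requires *support consistency* — a necessary
condition built from meta-states over {{0},{1},{0,1}} that widen one
component's image at a time.  The *discrete RMSE* (data vs. its own
binarization) is the floor of this objective; points where the optimal
Y deviates from the binarized data are *penalized points* and are
corrected before verification.  Every returned network attains the
same, globally minimal RMSE.  Exact model checking (nested frontier
reachability, the explicit-state form of EF(s₁ ∧ EF(s₂ ∧ …)))
then certifies each network as *true positive* (reproduces all
corrected trajectories exactly) or *false positive* (an artifact of the
over-approximation).  Family analytics aggregate hyper-edges by
frequency (> 0.3 by default), compare families by mean Jaccard
similarity against a gold aggregate, score downstream sets by TPR/FPR
and ROC area, and check specificity by re-fitting 100 uniform-random
resamples of the readouts (RMSE ratio = discrete/model, which is 1 on
recovered data and falls below 1 on noise).

A synthetic module generates random PKNs, ground-truth BNs from their
clause space, and noisy simulated screens (with injectable QC defects),
so the whole pipeline is testable without any external dataset.

## Worked example

```python
from bnts.synthetic import (SimConfig, generate_pkn, sample_true_bn,
                            default_perturbations, simulate)
from bnts.timeseries import qc_repair, normalize
from bnts.learn import LearnConfig, learn
from bnts.verify import triage

cfg = SimConfig(seed=1, noise_sd=0.0)          # 10 proteins, 5 perturbations, k=7
pkn = generate_pkn(cfg)
truth = sample_true_bn(pkn, cfg)
data, hidden = simulate(truth, pkn, default_perturbations(pkn, 5, 1), cfg)
norm = normalize(qc_repair(data)[0])
out = learn(pkn, norm, LearnConfig(max_models=5))
tps, fps, und = triage(out)
print(f"{len(out)} co-optimal networks, objective {out.objective:.4f} "
      f"(discrete floor {out.discrete_rmse:.4f}), "
      f"{len(tps)} TP / {len(fps)} FP")
print(out[0].bn.to_lines())
```

prints

```
5 co-optimal networks, objective 0.1983 (discrete floor 0.1983), 5 TP / 0 FP
['i1 <- r4', 'r1 <- !r2&s3', 'r2 <- u1', 'r3 <- s2', 'r4 <- s3', 'u1 <- !s2']
```

The objective equals the discrete floor with no penalized points, so
every learned network reproduces the binarized trajectories exactly,
and model checking certifies all five as true positives; the first
network's hyper-edges (`target <- clause`, `!` = NOT, `&` = AND,
repeated targets = OR) recover the generating logic.

The same pipeline is available from the shell:

```sh
bnts simulate --seed 1 --noise-sd 0.0 --out fixture/
bnts preprocess --data fixture/data.csv --out pre/
bnts learn --pkn fixture/pkn.sif --roles fixture/roles.tsv \
           --data pre/clean.csv --max-models 5 --out learned/
bnts verify --pkn fixture/pkn.sif --roles fixture/roles.tsv \
            --data pre/clean.csv --out verified/
bnts aggregate --bn-dir learned/ --out agg/
bnts validate --bn-dir learned/ --data pre/clean.csv --out val/
```

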