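# Methods

## The inference problem

`bnts` learns Boolean networks (BNs) of protein signaling from
multi-perturbation phosphoproteomic time series, constrained by a prior
knowledge network (PKN).  The PKN is a signed directed graph
(V, E, σ) whose nodes are partitioned into stimuli S (experimentally
held at 0/1), inhibitors I (held at 0 while the drug is applied),
readouts R (measured in [0,1] after normalization) and unobserved nodes
U; I and R may overlap (an inhibited protein can also be on the assay
panel).  A perturbation is one 0/1 treatment assignment over S ∪ I,
inducing a *clamping* — stimuli fixed at their treatment value,
applied inhibitors fixed at 0 — that holds for the whole trajectory.

A candidate BN gives each node a regulatory function in disjunctive
normal form whose clauses draw signed literals from the node's direct
PKN predecessors with edge-matching polarity (a +1 edge contributes a
plain literal, a −1 edge a negated one).  One (node ← clause) pair is a
*hyper-edge*.  The per-node candidate space is capped by
`max_clause_size` (default 2 literals per AND gate) and
`max_clauses_per_node` (default 3 OR-terms); within those caps the
enumeration keeps only antichains of clauses, because a clause whose
literal set contains another clause's is redundant in a disjunction —
this canonicalizes the space without losing any Boolean function.  A
node may also receive no function at all; such nodes (and unobserved
sources in general) keep their current value.  These caps are
configuration, not biological claims; they keep desk-scale search exact.

## Dynamics and the over-approximation

States are Boolean vectors over all nodes.  The update schedule is the
most permissive one: any non-empty subset of non-clamped nodes may
update simultaneously to its function value.  Synchronous and
asynchronous dynamics are both sub-relations, so certificates are
schedule-robust.  Exact reachability in this 2^n graph is the
PSPACE-hard bottleneck, so candidate filtering uses *meta-states*:
vectors over {{0}, {1}, {0,1}} that over-approximate sets of states
componentwise.  A widening step joins one component's image
{f_i(x) : x ∈ u} into u_i; components only ever grow, so every
meta-state reachable from a state's singleton meta-state is described
by its set of widened components, chains have length ≤ n, and the
search space is the union-closed family of constructible widened sets.

x is *support-consistent* with y when some reachable meta-state u
contains y and each component satisfies one of: (a) y_i ≠ x_i; (b)
y_i = x_i with u_i still a singleton; (c) y_i = x_i, u_i = {0,1}, and
some z ∈ u has f_i(z) = y_i.  Exact reachability implies support
consistency (tested exhaustively at small n and on seeded random
networks); the converse fails — such gaps are exactly the
false-positive networks the verifier later rejects.  The implementation
searches widened sets breadth-first with memoized per-node image
tables; images are computed by enumerating only the free regulators of
one node, so each query is cheap at the in-degrees the caps allow.

## Learning as exact optimization

Given normalized data T and threshold θ (default 0.5, ties to 1 — the
midpoint of the normalized scale), the learner searches pairs (B, Y) of
a candidate network and binary trajectories (one full state per
observed timepoint, clamp-respecting, consecutive states
support-consistent, unobserved components free) minimizing

    RMSE = sqrt( (1 / (m·k·|P|)) Σ_i Σ_j Σ_P (t_ij^P − y_ij^P)² )

over the observed entries.  Binarizing T gives the *discrete RMSE*, the
floor any binary fit can attain; a trajectory's squared error equals
that floor plus a fixed penalty per *penalized point* where Y deviates
from the binarized value.  The search therefore enumerates deviation
sets best-first by total penalty (a heap-driven subset walk) and, per
set, runs a depth-first search over per-node function choices for
networks admitting support-consistent traces through the corrected
observations.  Trace feasibility per perturbation is a layered dynamic
program over full states restricted to the cone of influence of the
observed nodes (their regulatory ancestors); nodes outside the cone
cannot affect observations and are left unregulated.  Two sound pruning
rules keep the DFS small: a function that cannot output an observed
value change under the perturbation's clamping is locally impossible,
and a partial assignment is abandoned when even the optimistic
relaxation (unassigned nodes treated as able to take any value) admits
no trace.  The first penalty level with any feasible network is the
global optimum, so all returned networks are identically optimal; the
output is truncated at `max_models` (default 200) and flagged.

When the data require many corrections (high noise), the best-first
subset walk degenerates; past a cap on examined deviation sets the
learner switches to the complete per-network route: scan the candidate
space and price each network by a cost-aware Viterbi DP over the same
layered state graph.  Both routes are exact; they were cross-checked
against a brute-force minimum over the full (network × trace) space on
randomized small instances.  Worst-case cost is exponential in the cone
size and candidate space — inherent to the problem — so practical use
relies on sparse priors and the caps above.

Corrections adopt the optimal trajectory's value at each penalized
point ("correct the data to the model"), and the corrected dataset is
what the verifier checks; the alternative (correcting to the flipped
binarization) is identical here because penalized points are defined as
exactly those disagreements.

## Certification (model checking)

Support consistency is necessary, not sufficient, so every optimal
network is certified by exact nested reachability: per perturbation,
the frontier of full states matching the first corrected observation
(unobserved components free — consistent with the learner's existential
trace variables) is closed forward under the any-subset schedule, the
next observation is intersected with the closure, and so on; the
network is a *true positive* (TP) when every perturbation's sequence
survives to the end, *false positive* (FP) when some frontier empties,
with the 1-based index of the first failing transition reported.
Budgets are counted in explored states, not wall-clock, so verdicts are
deterministic; exceeding a budget yields `undecided`, never FP.  The
network is first restricted to the observation cone, which preserves
verdicts while shrinking the state space.  `triage` processes a learned
family in enumeration order under a per-network and a total budget.

## Family analytics

Hyper-edge frequency is the fraction of a family's networks containing
the hyper-edge; aggregation keeps frequencies strictly above a
threshold (default 0.3).  Similarity between a gold-standard hyper-edge
set and a family is the mean Jaccard index over members; cross-family
comparisons use one family's (thresholded) aggregate as gold, so the
matrix is not symmetric and both orientations are reported.  The
RMSE ratio (discrete / model, ≤ 1 by the floor invariant) equals 1
exactly when the family recovers the binarized data; random-data
validation redraws every readout value uniformly in [0,1] (keeping the
perturbation design), re-prices the best attainable model RMSE with the
networks fixed, and reports the ratio distribution — specificity shows
up as ratios strictly below the structured-data value of 1.  Downstream
sets are directed reachability (root excluded) on the graph induced by
hyper-edges; TPR/FPR are set-cardinality rates against a canonical
standard within a node universe, and the family ROC area sorts the
per-network points by FPR, takes the upper envelope at duplicate FPRs,
anchors (0,0) and (1,1), and integrates by trapezoids (the construction
from a point cloud is under-determined; this choice is order- and
duplication-invariant).  Node centrality is directed betweenness
normalized by the number of connected source–target pairs, so the
middle of a chain scores 1.

## Synthetic studies

The generator emulates a small perturbation screen.  Defaults (chosen
once, as the package's study conditions): 10 proteins — 3 stimuli, 1
inhibitor that is also measured, 4 readouts, 2 unobserved — edge
density 0.2 over a topologically ordered prior with one feedback edge
(≈1.4 edges per node, the sparsity of curated signaling maps), 5
perturbations (each stimulus alone, all stimuli, all-stimuli plus
inhibitor), 7 timepoints on the 0/5/15/30/60/120/240-minute grid, and
Gaussian measurement noise with sd 0.05.  Ground-truth networks are
drawn uniformly from the same candidate space the learner enumerates,
so recovery is well-posed.  Hidden trajectories are random walks in the
truth network's own transition system under each clamping; hence
consecutive recorded states are genuinely reachable and the truth is
certifiable as TP.  Emission draws one low level (U(0.05, 0.35)) and
one high level (U(0.65, 0.95)) per perturbation–protein pair, emits the
level matching the hidden bit, adds noise and clips to [0,1]; levels
are drawn once per trajectory so that a clamped protein's trace is flat
up to noise, as in a real inhibition experiment.  At zero noise the 0.5
threshold recovers hidden states exactly; from sd ≈ 0.15 binarization
errors appear and exercise the correction machinery.  QC defects
(missing time-0 reading, duplicated timepoint, inhibited-but-dynamic
readout) can be injected individually.

What the generator does not emulate: replicate structure, correlated
or heteroscedastic noise, unmodeled proteins outside the prior, and
prior networks that miss true edges.  Passing recovery tests therefore
shows the search and certification machinery is correct under the
model's own assumptions, not that real screens are this benign.

## Quality control

Four repairs run in order on raw data, each logged in a replayable
report: missing time-0 readings are filled from unperturbed controls;
duplicated timepoint labels collapse to the first occurrence;
perturbations whose inhibited-and-measured protein varies by more than
a tolerance (max − min of the normalized trace, default 0.1 — the rule
had to be made numeric somewhere, and 0.1 separates assay noise from
genuine dynamics under the default emission model) are dropped as
contradicting the experimental setting; perturbations with remaining
missing readings are dropped rather than imputed.  Normalization
divides each protein by its global maximum over all perturbations and
timepoints, is idempotent, and refuses all-zero proteins.

## Numerical choices and limitations

Penalty ties are grouped with absolute tolerance 1e-9 when closing an
optimal penalty level; optimality comparisons in the fallback use
1e-12.  Binarization maps ties at the threshold to 1.  Enumeration
order everywhere is canonical (sorted nodes, clause-space order), so
equal-seed runs are byte-identical.  Default budgets: 2^20 explored
states per verification, 200 models, 20000 deviation sets before the
fallback route.  The verifier and learner are explicit-state and
exponential in the observation cone; they are meant for desk-scale
networks (cones up to ~15–20 free nodes), not for symbolic-scale
problems.  Learned structure is identifiable only up to the data: with
few perturbations many networks are co-optimal, which is why the output
is a family and the analytics operate on families.
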