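# Methods

`ci_immunize` implements three algorithms for *optimal percolation*: finding
a minimal set of nodes whose removal (or immunization) fragments a network's
giant connected component into non-extensive pieces.  All three descend from
the observation that the giant component of a sparse, locally tree-like
graph survives exactly while the largest eigenvalue of its non-backtracking
(NB) matrix exceeds 1, so influential nodes are those whose removal lowers
that eigenvalue the most.

## Collective Influence (CI) attack

**Score.** For a present node *i* with live degree *k_i*,

    CI_l(i) = (k_i - 1) * sum_{j in dB(i, l)} (k_j - 1),

where `dB(i, l)` is the set of present nodes at shortest-path distance
exactly *l* from *i*.  `CI_l` is the weight of the NB walks leaving the
ball of radius *l*; its sum over nodes estimates the NB eigenvalue raised
to the power *l*+1.  `l = 0` degenerates to degree; we expose that limit as
the separate high-degree-adaptive (HDA) baseline and require `l >= 1` for
CI itself.

**Adaptive removal in O(N log N).** Scores live in an indexed binary
max-heap (node -> slot index, bottom-up build, localized re-heapification).
Removing node *i* perturbs only nodes within distance *l*+1 of *i*
(distances measured just before the removal):

* distance <= *l*: recomputed from scratch by a depth-*l* BFS;
* distance exactly *l*+1: node *j* loses `(k_j - 1)` for **each** neighbor
  *m* of *i* that lies on *j*'s *l*-frontier.  On a tree that multiplicity
  is 1, recovering the textbook `(k_j - 1)` decrement; counting it (by a
  depth-*l* BFS from each neighbor of *i*) makes the localized update exact
  on loopy graphs as well.  Consequently the heap attack reproduces the
  naive recompute-everything reference *exactly*, for every radius, on
  every graph — the oracle-equivalence tests exploit this.

Updates on tree-like structure only lower scores (sift-down); a sift-up
fallback guards the rare increases on loopy graphs.  Ties between equal
scores are broken arbitrarily by heap order, or by smallest node id when
`deterministic_ties` is set (used by all reproducibility and oracle tests).

**Stopping rule.** Instead of an O(N) component check per removal, the
attack monitors

    lambda(l; q) = [ sum_i CI_l(i) / (N<k>) ]^(1/(l+1)),

maintained incrementally from running sums.  Here `N<k>` is the **live**
degree sum (twice the surviving edge count).  With that normalization
`lambda(l; 0) = kappa - 1` with `kappa = <k^2>/<k>` on tree-like random
graphs, and along the attack `lambda` tracks the remnant's `kappa - 1`; the
attack stops at the first step with `lambda <= 1`.  (Normalizing by the
*initial* `N<k>` instead deflates lambda by `(2E_live / N<k>_0)^(1/(l+1))`
and stops the attack while the remnant is still supercritical — measured on
ER `<k>`=3.5 at N=10^5: stop at q=0.19 with the giant still at 58%.  The
live normalization is therefore the one consistent with "lambda reaches 1
when the giant component vanishes".)

Finite-*l*, finite-N bias: lambda estimates the remnant eigenvalue through
degree moments of *l*-step neighborhoods; the attack itself induces
negative degree correlations, so lambda slightly overshoots the true NB
radius near the transition.  At N=10^5, `<k>`=3.5, l=5 the lambda stop
lands ~0.01 in q *after* the second-largest-cluster peak.  The gap shrinks
with N and with *l*.

**Components on a thinned grid.** Giant and second-largest cluster sizes
are measured every `max(1, N/1000)` removals (plus once at the stop), which
is fine enough to locate the second-cluster peak to dq = 0.001 at N=10^5.

## Reinsertion

Below the percolation point the question becomes: what is the best G
achievable with a budget of qN removals?  Starting from the attacked state,
still-removed nodes are added back in batches of 0.2% of N; each batch
takes the candidates whose present neighbors span the *fewest distinct
clusters* (cluster sizes are deliberately ignored; ties by smallest id).
Reinsertion restores only edges to present neighbors, so after the full
pass the original graph is recovered exactly.  Cluster merging uses
union-find; candidate counts are recomputed per batch.

Two desk-scale caveats, both measured at N = 5x10^3 - 3x10^4 on ER
`<k>`=3.5: (1) in a narrow window just below the threshold
(q > ~0.92 q_c) the size-blind criterion can merge the largest clusters
early and the rebuilt curve crosses slightly above the forward-attack
curve; far below q_c it is far below it.  (2) Point-wise in q, the G values
for batch fractions 0.002 vs 0.001 can differ by a few % of N near the
threshold (the merge order there is chaotic), but the curves are
indistinguishable *horizontally*: the budget q needed to reach any given G
level agrees to 0.001.  The insensitivity test therefore compares budgets.

## CI propagation (CI_P)

The `l -> infinity` limit.  Left/right messages on the 2M directed edges,

    L_{i->j} <- sum_{k in di \ j} L_{k->i},
    R_{i->j} <- sum_{k in dj \ i} R_{j->k},

are power-iterated with per-sweep normalization to unit sum; the
pre-normalization growth factor, averaged over the last 10 sweeps to damp
even/odd oscillation, estimates the NB eigenvalue `lambda_max` (trees are
nilpotent: 0; a single cycle: 1; random k-regular: k-1).  First-order
eigenvalue perturbation for removing node *i* zeroes the NB entries of the
edge pairs through *i*, giving the score

    CI_P(i) = sum_{j != k in di} L_{j->i} R_{i->k}
            = (sum_j L_{j->i})(sum_k R_{i->k}) - sum_j L_{j->i} R_{i->j};

the left/right eigenvector overlap that normalizes the perturbation is the
same for every node and is dropped.  The attack removes the current argmax
(ties: smallest id), zeroes the removed node's messages, re-converges with
a warm start (a handful of sweeps per removal in practice), and stops at
`lambda_max <= 1`.  Convergence tolerance 1e-7 on the L1 change of the
normalized vectors, 1000-sweep cap; hitting the cap is recorded in the
trace and iteration proceeds with the last state.

On random 3-regular graphs CI_P stops at the exact optimal threshold
q_c = 1/4.  A geometric note: that stopping point is a *decycling* set —
the survivor graph is a forest with NB radius <= 1, but it may retain an
extensive giant *tree* (measured at N=2000: cyclomatic number 1 at the
stop, giant tree ~ 0.69N).  Eigenvalue-based and cluster-size-based notions
of "destroyed" separate at finite N; see the immunization threshold below.

## Collective immunization (CI_BP)

SIR epidemics with seed density gamma and transmission probability beta on
a tree-like graph obey the cavity equations

    nu_{i->j} = (1 - gamma) prod_{k in di \ j} [1 - beta n_k (1 - nu_{k->i})],

with `nu_{i->j}` the probability that *i* ends susceptible when *j* is
absent and `n_k = 0` marking immunized (non-transmitting) neighbors.  The
optimal immunization set minimizes

    E(n) = sum_i n_i (1 - nu_i) + mu sum_i (1 - n_i),

the expected outbreak plus a chemical potential mu per immunized node.

**General (beta, gamma): scalar min-sum.**  With the cavity messages frozen
at the current configuration, E is a sum of local factors
`a_i(n_i, n_di)`; min-sum messages (scalar cost differences, exact subset
enumeration over up to 14 cavity neighbors per factor) are iterated with
damping 0.5 to tolerance 1e-6, the node field `h_i` (cost of keeping minus
cost of removing) collects the incoming messages plus the mu term, and
`sigma_i = sign(h_i)` (ties keep the node) decides.  The outer loop
alternates nu-convergence and h-convergence until the spins are stable;
when min-sum oscillates, a reinforcement self-field integrating the running
marginal (rate 1e-3 per sweep) forces convergence; the lowest-energy
configuration over 3 random restarts is kept, scored by a canonical
evaluator (fresh nu fixed point per candidate).  On trees this minimizes
the frozen-nu surrogate exactly; the residual gap to the true energy (the
surrogate cannot see that immunizing a node protects nodes two or more
hops away) is what the exhaustive-enumeration oracle quantifies — the
measured exact-minimum rate on 8-9-node instances over the
(beta, gamma, mu) grid is ~90-92%.

**Percolation limit (beta -> 1, gamma = 1/N): size-resolved min-sum.**  In
this limit the cavity probability collapses to
`nu_{i->j} = (1 - gamma)^(S_{i->j})` with `S_{i->j}` the cavity cluster
size, and the energy groups by cluster:

    E = sum_clusters f(s) + mu |immunized|,   f(s) = s (1 - (1-gamma)^s).

The frozen-nu scalar scheme degenerates here (at a supercritical
configuration nu ~ 0 in the giant and the surrogate turns into an
independent-set objective; measured: it immunizes ~55% of a random cubic
graph).  The percolation solver therefore passes *size-resolved* messages
`m_{i->j}(y)`, y = 0 (immunized) or 1..C (present, heading a cavity cluster
of y nodes), paying cluster costs incrementally at each merge —
`f(1 + sum y_k) - sum f(y_k)` — which telescopes to exactly one `f` per
cluster on a tree.  Sizes saturate at a cap C (default `4 ln N`); beyond
the cap the cost continues *affinely* with slope `f(C) - f(C-1)`, tracked
exactly through the convolutions by a saturated bucket.  A hard cap with no
slope would make an extensive cluster locally free (its single cluster-cost
sits infinitely far away) and the solver would never fragment anything; the
affine tail keeps a positive marginal cost per node, at the price of an
O(C^2/N) over-estimate of splitting gains that mu absorbs.  Quenched random
node fields (amplitude mu/10) seed symmetry breaking on regular graphs, and
a reinforcement field integrating the keep/remove gap (rate 0.02 per sweep
after a 30-sweep warmup) polarizes the run; decisions need `gap > 1e-6`
(ties keep).  Messages are swept with damping 0.7 for up to 600 sweeps (at
least 2C, so size information can propagate).

**mu-bisection and trim.**  The immunized fraction is fixed implicitly by
mu, so a 20-step bisection on [0, 1] finds the smallest immunized fraction
whose residual giant is at most `2 ln N` nodes (sub-extensive).  Feasible
solutions get a reverse-greedy polish: immunized nodes whose reinsertion
would merge present clusters to at most the threshold are returned,
smallest merged size first — this only sheds provably redundant nodes and
never violates the threshold.

**Thresholds at finite N.**  On random cubic graphs the optimal percolation
threshold is q_c = 1/4 and is achieved by a decycling set; but a decycled
forest may keep a giant tree, and cutting trees into pieces of at most
`2 ln N` nodes costs extra removals of order `0.75 N / (2 ln N)` — about
0.04 N at N = 5000 (an edge-counting bound puts the true optimum for that
task at >= 0.27 N).  The residual-giant criterion therefore yields
immunized fractions around 0.28-0.30 at desk sizes, approaching 1/4 only
as N grows and the sub-extensive allowance widens.  CI_P, which stops on
the eigenvalue itself, hits 0.25 directly.

## Graphs, generators, I/O

Graphs are CSR adjacency plus a presence mask and live degrees; removal
flips the mask and decrements neighbor degrees (never deletes edges), so
reinsertion can restore exactly.  Erdős–Rényi graphs use the G(n, M) model
with `M = round(n <k> / 2)` so the mean degree is exact; random regular
graphs use the pairing model with full restart on collisions (acceptance
rate ~ exp(-(k^2-1)/4), fine for small k).  Both are bit-reproducible for
a fixed seed.  Edge lists are whitespace-separated integer pairs, one per
line, `#` comments allowed; arbitrary labels map to dense ids (sorted
order) and the mapping is retained for writing.  Isolated nodes are not
representable in the format.  Attack traces are TSV
(step, node_removed, q, giant, second, lambda) with a small `#`-prefixed
header; component columns are NaN off the measurement grid.

## Problem sizes used by the test suite

Chosen so the whole suite runs on one CPU in minutes: oracle-equivalence
and spectral cross-checks on graphs of up to 200 nodes; the eigenvalue
stopping rule and the CI-vs-HDA comparison on ER `<k>`=3.5 at N = 10^5;
CI_P threshold on random cubic graphs at N = 5000; the BP immunization
bisection at N = 2000 in the tests and N = 5000 in the acceptance script;
exhaustive BP oracles on 8-9-node graphs.  Synthetic generators match the
graph families the algorithms were designed for (sparse, tree-like); none
of the tests exercise heavy-tailed degree distributions, degree
correlations, or clustering, so passing them says nothing about dense or
highly clustered real networks, where the tree-like (Bethe) assumptions
behind both lambda and the cavity equations degrade.

## Known limitations

* `lambda(l; q)` overshoots the transition by ~0.01 in q at N = 10^5 with
  l = 5 (attack-induced degree correlations); use CI_P when the exact
  eigenvalue matters.
* The reinsertion criterion ignores cluster sizes (by design); just below
  q_c it can briefly underperform the forward curve.
* The scalar CI_BP solver is a frozen-nu surrogate: near-exact on trees,
  ~90% exact-minimum rate on small loopy instances, and not suitable for
  the percolation limit (use the size-resolved solver, which
  `percolation_immunize` does automatically).
* The size cap C trades fidelity for O(2M C^2) sweep cost; clusters are
  indistinguishable beyond C.
* Immunized fractions from the residual-giant criterion carry a
  +O(1/ln N) finite-size offset relative to the eigenvalue threshold.
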