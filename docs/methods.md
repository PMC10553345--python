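# Methods

This note records the models behind `netpattern`, the defaults that matter,
the choices made where the design was genuinely open, and what the synthetic
generators do and do not establish.

## The graph currency and the four measures

Every system is reduced to a **simple undirected unweighted graph**: directed
inputs are symmetrized, parallel edges and self-loops dropped, and isolated
nodes retained in `|V|` for every average. This is deliberate — the point of
the comparison is a profile that applies identically to a wiring diagram, a
fired-neuron subgraph, a co-occurrence network and a random draw, so any
weight or direction information that only some systems carry is discarded.

- **Average degree** `2|E|/|V|`. Undefined (error) on an empty node set.
- **Average PageRank.** Damped PageRank (damping 0.85, tolerance 1e-10 on
  the L1 change, max 200 sweeps, dangling and teleport mass spread
  uniformly), computed by sparse power iteration. On any graph the masses
  sum to one, so the *mean* is exactly `1/|V|` — the measure is reported
  because its trajectory encodes network size, and the mean is computed (not
  assigned) so normalization is exercised. Damping is a convention choice:
  the undamped formulation has no unique stationary vector on disconnected
  graphs, and the only cross-checkable consequence (mean = 1/|V|) is
  damping-invariant. Non-convergence raises a warning, never a silent
  result.
- **Average clustering.** Mean over *all* nodes of
  `2·Tri(v)/(deg(v)(deg(v)−1))`, with nodes of degree < 2 contributing 0
  rather than being excluded; this keeps the mean defined on every graph and
  is negligible at the densities profiled here.
- **Average triangles.** Mean per-node triangle *membership*, i.e. `3T/|V|`
  for `T` distinct triangles — each triangle counts once per member node.
  This is the reading consistent with the worm-matched null value (~8.6 at
  n=281, p=0.0611, vs the closed form `C(280,2)p³ ≈ 8.9`; the distinct-
  triangle reading `T/|V|` would give ≈ 3).

Triangle counts are computed by a blocked sparse product:
`(A_rows @ A) ∘ A_rows` row-summed gives twice the per-node membership; the
row-block size adapts so the intermediate fill stays near 2·10⁷ entries,
which keeps a fruit-fly-scale graph (n = 21,733, ≈ 2.9M edges) under a
minute and well inside memory. Small-graph results are property-tested
against exhaustive triple enumeration, and PageRank against an independent
dense power iteration and networkx.

## Random-graph models

`ba_graph(n, e)` (preferential attachment; `|E| = e(n−e)` by construction),
`er_gnp(n, p)`, `er_gnm(n, m)` and `random_regular(n, d)` (pairing model;
requires `3 ≤ d < n`, `n·d` even). G(n,m) samples uniformly over *labeled*
edge sets: uniform sampling over non-isomorphic classes is computationally
unreasonable and the four measures are label-invariant anyway. G(n,p) is a
vectorized pair-index sampler (binomial edge count, rejection sampling of
distinct indices, exact integer inversion of the upper-triangle
linearization), so connectome-scale draws take seconds.

The growth experiment regenerates a model at `n_k = k · step_nodes` for
`k = 1..iterations` (defaults 20 × 200, 20 replicate draws averaged; G(n,p)
uses p = 0.015, the budgeted models e = m/n = d = 20). G(n,m) and the
regular model keep a fixed per-node budget (`m_k = e·n_k`), so their average
degree is static during expansion and only G(n,p) — the one model whose
edge count scales with the pair population — shows rising degree and
triangles. G(n,p) clustering is theoretically flat (≈ p), and its direction
is deliberately left unasserted in the comparison summary.

## Trained-network fired patterns

The classifier is a feed-forward MLP — input layer of side² pixel neurons,
sigmoid hidden layers (default 80/40/20; the desk profile uses 40/20/10 at
8×8 input), softmax output — trained with mini-batch Adam (lr 1e-3,
β₁ 0.9, β₂ 0.999, ε 1e-8, batch 32) on sparse categorical cross-entropy,
implemented directly in numpy since per-neuron outputs are needed anyway.

For one input, the **fired** set is every neuron with output strictly
greater than 0.5 (strict because the definition says "greater than"; a
zero-weight network, whose hidden sigmoids are exactly 0.5, fires nothing).
Input neurons participate with the normalized pixel intensity as their
output. The **active** set uses the strict 0.1 background threshold.
The edge universe on a neuron set is configurable:

- `adjacent` — pairs in consecutive layers only (the physical weight
  topology); such graphs are multipartite and triangle-free;
- `cross` (default) — every pair in *different* layers; the default must be
  cross-layer for the triangle trajectory to be non-degenerate;
- `all` — every pair.

**Cohesion** = fired-subgraph edges / active-subgraph edges, with the
denominator requiring *both* endpoints active (keeps the ratio in [0,1]
since fired ⊆ active); an `either` mode (at least one endpoint active,
other endpoint drawn from the full universe) is available behind a flag
because the background-threshold notation is ambiguous on this point.

The epoch sweep trains for 100 epochs, recording at epochs 1–10 and every
10th thereafter (19 checkpoints) the held-out accuracy plus the four
measures and cohesion averaged over `eval_n` (default 100) held-out inputs;
an input whose fired set is empty contributes an all-zero profile.

### What the sweep does and does not reproduce

On the synthetic image task the degree and triangle trajectories are almost
perfectly correlated (Pearson ≈ 0.995–0.999; both are driven by the fired
count), and PageRank/clustering are flat-to-jagged — matching the reported
behaviour of those two measures. The *downward* drift of degree and
triangles seen on real handwritten-digit training does **not** reproduce:
on a prototype-separable task the hidden fired counts freeze near half the
layer widths once the loss collapses, and the output neuron crossing 0.5 as
softmax confidence grows adds an upward transient, so the two directional
cells classify Flat/Up. The corresponding assertions are kept at their
stated directions and fail; this is a known, documented gap of the
synthetic stand-in, not of the measure implementation.

## Topic networks

A publication record is one paper's (year, topic-set); topics in one paper
form a clique, and the network at year y is the union of all cliques up to
y (cumulative, so node and edge sets are monotone). Repeat co-occurrence
does not add weight. Years without records inherit the previous year's
graph, keeping trajectories on a contiguous year axis. Records with empty
topic sets are rejected with a logged count; the CSV dialect is
`year,topic1;topic2;…`.

## Connectomes and the animal projection

The worm-dialect reader consumes (neuron1, neuron2, type, count) rows,
drops the Receiving/Receiving-Poly rows (types R, Rp — duplicates of the
send-side rows of the same synapses), ignores multiplicities and direction,
and collapses to a simple graph. Unknown type tokens are kept with a logged
warning; malformed rows fail with their line number.

A **matched null** is a G(n, p) draw at the connectome's node count and
edge-completion ratio `p = 2|E|/(|V|(|V|−1))` — worm p = 0.061134,
fruit-fly p = 0.012164. The projection sweep covers a roster of eight
animals with estimated neuron counts (200–18,000) × ten densities, linearly
spaced *inclusive* of both endpoints (the sources do not state
inclusivity; linspace is the natural reading). Two trajectory readings are
reported:

- **fixed-density**: profile vs neuron count at one p. Degree, triangles
  (∝ C(n−1,2)p³) and 1/n-PageRank move with n; clustering is ≈ p
  independent of n, so its direction is asserted Flat here and left out of
  the summary assertion.
- **density-matched diagonal**: the k-th animal (ascending n) paired with
  the k-th *descending* density, emulating the empirical fall in synaptic
  density from worm to fruit fly. This reading reproduces the full
  Up/Down/Down/Up direction vector and matches the topic-network row —
  the cross-system commonality the comparison is after.

The default test profile caps the roster at n ≤ 5,600 with a few seeds;
the full sweep (n = 18,000 at worm density ≈ 10M edges) runs behind
explicit flags.

## Trend classification

A series is classified by the sign of its least-squares slope against the
0-based index, normalized by the series' mean absolute value; a normalized
magnitude under `flat_tol` (default 0.01 per index step) is Flat, and an
all-zero series is Flat. Slope-sign with a flat band was chosen over
first-vs-last comparison for robustness to the jagged PageRank/clustering
trajectories; the rule is antisymmetric under negation and reversal, and is
applied identically to every system. Series shorter than 3 are rejected.
Expected-pattern files may assert `Up`/`Down`/`Flat`, the weak forms
`NotDown`/`NotUp`, or the wildcard `-`.

## Synthetic data

**Images.** One fixed uniform-random prototype per class in [0,1]^(side²);
samples add clipped Gaussian pixel noise. The separability invariant
(min pairwise prototype distance > 4·noise_sd) is validated at build time.
Defaults mirror the handwritten-digit corpus layout (10 classes, 28×28,
60,000/10,000); the desk profile is 8×8 with 4,000/800 samples at
noise_sd 0.5, a noise level chosen so held-out accuracy rises through the
high 90s across the full 100-epoch window instead of saturating at 1.0
within a few epochs — i.e., so the *maturation* being profiled actually
spans the window. These are learnable stand-ins, not visual imitations:
passing tests show the pipeline mechanics and the measure trajectories on a
separable 784-dimensional task, not behaviour on real image statistics.

**Publications.** A Price-style stream: yearly volume grows 5%/year (the
literature's empirical multi-decade doubling), a constant ~30 brand-new
topics enter per year (cumulative vocabulary near-linear in time), each
paper lists Poisson(4) topics (≥ 2), drawn with probability ∝
(3 + past uses)^0.6. The initial-attractiveness term and sublinear bias
spread reuse beyond a closed hub core; this diversification is what makes
a topic's partners outgrow their interconnections, reproducing the falling
mean clustering alongside rising degree/triangles and super-linear edge
growth (node/edge growth correlation > 0.95). Parameters are realism
defaults, not fits to any particular journal.

**Toy wiring tables.** A planted G(n,p) edge set written in the worm
dialect with synthetic Send/junction type tokens and optional duplicate
Receiving rows, so the reader's filtering is testable against ground truth.

All generators are seed-deterministic and emit exactly the text dialects
the readers consume.

## Numerical and scale choices

- All randomness flows through integer seeds; child seeds derive from
  `numpy.random.SeedSequence` over (seed, stage, repetition) keys and stay
  below 2³¹.
- The default `run-all` configuration is the test-scale profile (desk image
  profile, 12 × 200-node G(n,p) growth with 5 replicates, animal roster
  capped at 5,600 neurons with 3 seeds); it completes in a few minutes on
  one CPU. Full-scale settings are plain config overrides.
- Degenerate inputs fail loudly: empty graphs (measures), empty record
  streams, malformed rows, invalid model parameters (e ≥ n, odd n·d,
  m > C(n,2)) all raise typed errors.

## Known limitations

- The trained-network directional cells (degree/triangles Down) are not
  reproduced by the synthetic image task; see above.
- G(n,p) growth clustering and fixed-density animal clustering have no
  meaningful direction (theory: flat) and are excluded from summary
  assertions.
- Fired-pattern extraction loops over evaluation inputs; at the full
  28×28/100-epoch scale a sweep is minutes-to-hours, which is why the desk
  profile is the default.
- The wiring-table reader trusts its four-column dialect; it is not a
  general connectome-format parser.
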