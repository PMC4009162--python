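# Methods

## Model

A gene-regulatory network is represented as a synchronous Boolean network:
`n` named genes, each with a Boolean update rule over the others written in
the `& | !` dialect with parentheses and the constants `0`/`1` (a
BoolNet-compatible subset; an equivalent JSON dialect carries link
knockouts).  All genes update simultaneously from the pre-update state, so
the deterministic map D sends each of the 2^n states to a unique successor.
Every trajectory therefore ends on a cycle — an attractor — which is the
model's notion of a stable cell type: a point attractor is a fixed
expression profile, a cyclic attractor an oscillating one.  Asynchronous
and probabilistic-Boolean update schemes are out of scope.

State encoding: the first declared gene is the least significant bit of
the integer state index (`index = Σ bits[k]·2^k`).  This convention is
arbitrary but fixed, and every exported artifact uses gene names rather
than raw indices.

Attractor enumeration exhausts all 2^n start states with a shared
visited-state memo (linear in the state-space size) and is guarded at
n ≤ 24 by default.  Attractors are canonically rotated to start at their
smallest state index and numbered by that index, so ids are stable across
runs.  An independent brute-force oracle (simulate each start state until
a repeat) cross-checks the enumeration in the test-suite for n ≤ 8.

## Noise model and transition kernel

Expression noise is modeled as independent per-gene bit flips with
probability `p` per gene per update step.  The per-step composition
follows the standard perturbed-Boolean-network convention: with
probability (1−p)^n no gene flips and the deterministic update fires;
otherwise the state jumps to the flipped state (flips preempt the update
that step).  The one-step kernel from state x to z at Hamming distance h
is therefore

    P(x, z) = [h ≥ 1]·p^h·(1−p)^(n−h) + [z = D(x)]·(1−p)^n

with two disjoint routes into z — an aggregate of bit flips, or the
deterministic target with no flips — and exact row sums of 1.  The kernel
is materialized densely up to n = 14 and generated row-by-row above that.

`p` is user-configurable everywhere and defaults to 0.01 (one spurious
flip per gene per hundred update steps — small enough that attractors are
long-lived, large enough that transitions are observable); it is recorded
in all output metadata.  The number of flips per step is Binomial(n, p),
which `flip_probability` exposes directly.

Two cheaper barrier measures are included for comparison: the Hamming
distance between states, and the single-bit-flip measure (each one-bit
perturbation of each attractor state is relaxed deterministically and the
receiving attractor recorded).  The single-bit-flip matrix is normalized
per source attractor by the number of perturbations performed
(period_i × n), which makes each row an exact probability distribution
over receiving attractors; the counts matrix is also exposed so callers
can renormalize differently.

## Mean first passage time

MFPT(x → T) is the expected number of update steps until the perturbed
chain, started at x, first visits any state of the target set T.  Three
independent routes are implemented:

1. **Exact**: first-step analysis.  With Q the kernel restricted to
   non-target states, solve (I − Q)k = 1; dense LAPACK factorization up
   to the dense-kernel limit, matrix-free GMRES above it.
2. **Series**: the first-passage probabilities F_k (probability that the
   first visit happens exactly at step k) satisfy F_1 = one-step
   absorption mass and F_k = Q F_{k−1}; the MFPT is Σ k·F_k.
   `fk_series` returns the explicit truncated distribution (useful for
   plotting passage-time curves); `series_mfpt` accumulates the partial
   sums by matrix doubling, growing the truncation K until the residual
   tail mass drops below a tolerance (default 1e−6), and reports the tail
   so truncation error can be bounded: the partial sum plus K·tail is a
   lower bound on the exact value.
3. **Monte-Carlo**: seeded vectorized simulation of noisy walks;
   censored walks (still running at `max_steps`) are reported, never
   silently dropped, and the estimate carries its standard error.

Between attractors, the destination is treated as a *state set* (first
arrival at any state of the target cycle), which makes target-side
averaging moot; the averaging applies to the *source* cycle's states with
uniform weights, as no phase distribution is specified for a cyclic
attractor.  A source state already inside the target has hitting time 0,
and the diagonal of the MFPT matrix is 0 by this first-passage convention
(not the mean recurrence time).  For 0 < p < 1 the perturbed chain
reaches every state with positive probability, so all off-diagonal MFPTs
are finite and positive.

## Separation, flux, direction, classification

separation(i, j) = min(MFPT(i, j), MFPT(j, i)) is symmetric;
flux(i, j) = MFPT(i, j) − MFPT(j, i) is antisymmetric; the edge of an
unordered pair points i → j when MFPT(i, j) < MFPT(j, i).  Exact ties
carry no arrow.  Because exact symmetry (e.g. the two-attractor identity
network) reaches the linear solver as permuted systems that come back
differing at rounding level, ties are judged at a relative tolerance of
1e−9 rather than bit-for-bit.

The landscape-capacity formula 2m − log₂(m+1) − 1 (the maximum number of
transitions a classic ridge-and-valley landscape can show for m cell
types) is exact when m+1 is a power of two — a perfect binary lineage
tree — and the log term is floored for general m.

Lineage classification consumes attractor *labels* and a rooted cell-type
tree (newick with named internal nodes, or a child/parent TSV).  The five
kinds are: sink a descendant of source → spontaneous-differentiation;
sink an ancestor → spontaneous-dedifferentiation; otherwise off-path:
both leaves → transdifferentiation; sink at least as deep as source →
off-differentiation; sink shallower → off-dedifferentiation.  The
equal-depth off-path case between non-leaves is deliberately classed as
off-differentiation.  Attractors without a tree label are reported as
"unclassified" rather than guessed.

## 3-D layout

Coordinates minimize the raw stress Σ_{i<j} (‖x_i − x_j‖ − sep(i, j))²
by SMACOF-style iterative majorization (Guttman transform, uniform
weights), which guarantees monotone non-increasing stress per iteration —
asserted at run time.  Defaults: 8 restarts from seeded uniform starts in
a cube scaled to the median separation, convergence at relative stress
change < 1e−9 or 2 000 iterations, centroid recentered at the origin.
m = 1 places the node at the origin and m = 2 uses the exact closed form.
Because MFPT-derived separations can span orders of magnitude, a `log`
scale mode (embedding log(1 + sep)) is offered for legibility; the default
is `linear`, matching the stress objective literally, and the mode is
recorded in output metadata.  scikit-learn's SMACOF implementation, which
minimizes the same raw-stress objective, serves as an independent
cross-check in the test-suite, never as the implementation.

## Rendering

The scene writer emits VRML97 ("#VRML V2.0 utf8"): one sphere per
attractor (radius defaulting to 5% of the largest pairwise layout
distance; colors from a user map or a fixed 12-color palette keyed by
attractor order) and one arrow per favored direction — a cylinder shaft
plus a cone head at the sink end.  Arrow widths map |flux| linearly onto
[0.2, 1.0] of the sphere radius.  Pairs with no favored direction are
never drawn; pairs with |flux| below a threshold (default 10% of the
scene's maximum |flux|, always overridable and recorded in metadata) are
hidden for legibility.  GraphML and JSON exports mirror the scene with
full per-edge MFPT/separation/flux/classification attributes; all writers
are deterministic (identical inputs give byte-identical documents).

## Synthetic data

Property tests and the acceptance script draw Kauffman-style NK random
Boolean networks: each gene reads k distinct inputs chosen uniformly and
each truth-table output is true with probability `bias` (defaults
k = 2, bias = 0.5 — the critical NK regime, which yields networks with a
handful of attractors at n ≤ 8).  Generated rules serialize to the text
dialect as sums of minterms, so every generated network round-trips
through the parser.

The bundled 11-gene myeloid demonstration network is a **synthetic
stand-in**: it uses the canonical myeloid transcription factors and an
interaction topology in their spirit, with author-chosen Boolean logic
tuned so that the synchronous dynamics produce exactly seven point
attractors whose expression profiles match the simplified myeloid lineage
(CMP root; MEP, GMP progenitors; ERY, MEG, MON, GRA terminal types).  The
core antagonisms are the GATA-1/PU.1 and EKLF/Fli-1 mutual exclusions and
the Gfi-1/EgrNab switch; GATA-2 marks the MEP progenitor and self-extinguishes
once lineage-committed factors rise, and Gfi-1 requires its own expression
(so the granulocyte program must be entered, not drifted into).  What
passing tests on this network show is that the *pipeline* behaves
correctly at realistic scale (2 048 states, seven labeled cell types, all
42 ordered transitions, all five transition kinds observed); they make no
claim that the demo's specific MFPT values reproduce any experimentally
inferred myeloid network, whose published form does not include usable
Boolean rules.

## Problem sizes and numerical choices

Defaults chosen for the bundled analyses: exact MFPT via dense solves up
to n = 14 (the demo's 7 targets × 2 041-unknown systems solve in a few
seconds); the random-ensemble cross-validation uses 50 networks with
n ∈ {3..6}, p ∈ {0.01, 0.1}, 300 Monte-Carlo walks per pair with
`max_steps` set to 100× the exact value; the one-gene analytic check uses
10 000 walks.  Series truncation tolerance 1e−6 tail mass; linear-solve
guard rejects negative expectations; layout tolerance 1e−9 relative.
Monte-Carlo agreement is judged at 3 standard errors, which for 300 walks
of an approximately geometric passage time is a generous but honest band.

## Known limitations

- Exhaustive enumeration and dense kernels limit exact analysis to a few
  dozen genes at most (the intended scale of logical differentiation
  models); no SAT/BDD symbolic attractor detection.
- Synchronous determinism only; no gene-specific or asymmetric noise
  rates.
- Labeling requires exact/wildcard pattern matches; there is no
  nearest-pattern assignment, so a pattern that matches no attractor
  simply leaves it unassigned.
- The layout is a local optimizer with restarts; for pathological
  (strongly non-metric) separation matrices different seeds can find
  different local minima, though the stress value is reported and
  recomputable.
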