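# Methods

## Model and scope

The package decomposes the one-step (Markovian) information flow of a
two-part stochastic process.  The only object the decomposition consumes is
the joint distribution of the stacked vector (X¹_t, X²_t, X¹_{t+1},
X²_{t+1}), represented either as

* a finite joint pmf on arbitrary per-slot alphabets
  (`DiscreteDynSystem`), or
* the 4×4 covariance of a zero-mean stationary Gaussian process
  (`GaussianDynSystem`).

Whether that distribution comes from an analytic construction, a stationary
AR(1) solution, or estimation from data is orthogonal to the decomposition
itself.  Parts are univariate; multivariate (coarse-grained) parts and
lags > 1 embeddings are out of scope — for multivariate data the package
decomposes variable *pairs* (`pairwise_decompose`).

## Lattice and Möbius inversion

Antichains of nonempty subsets of {1..N} are enumerated by brute force
(all collections of the 2^N−1 nonempty subsets filtered for pairwise
incomparability); this is exact and instantaneous for the N ≤ 3 sizes the
package targets (counts 1, 4, 18).  The decomposition lattice is the
Cartesian product of the past and future antichain lattices under the
componentwise order α⪯β iff every member of β contains a member of α, with
containment taken non-strictly so the order is reflexive and the structure
a genuine lattice.  For N = 2 this gives 16 nodes, labelled
`<past>-><future>` with tokens `red` ({1}{2}), `un1` ({1}), `un2` ({2}),
`syn` ({12}).

Atoms are computed by bottom-up recursion over a topological sort of the
node list (ordered by strict-down-set size, ties broken by label), not by
matrix inversion: atom(n) = redundancy(n) − Σ atoms strictly below n.  The
round trip (inversion followed by down-set summation) is exact to ~1e-12 on
arbitrary real tables and is property-tested.  Enumeration works for any N;
numeric atom semantics and labels are asserted only for N = 2.

## Redundancy backends

**MMI.**  The redundancy at node α→β is min over (a ∈ α, b ∈ β) of
I(Xᵃ_t ; Xᵇ_{t+1}), where Xᵃ is the joint variable of the parts in a.
Minimizing over *joint-group* mutual informations is the only reading
consistent with the compatibility requirement (single-member nodes must
reduce to plain MI) and with the closed-form revised-Φ expression
min_{i,j} I(Xⁱ_t ; Xʲ_{t+1}).  MMI tables are monotone along the lattice
order (larger nodes minimize over dominating pairs), which is also tested.

**CCS.**  A pointwise (per-state) measure for discrete systems.  For two
sources S₁, S₂ and one target T, the local co-information
c = i(S₁;T) + i(S₂;T) − i(S₁S₂;T) is credited as redundancy at a state only
when i(S₁;T), i(S₂;T), i(S₁S₂;T) and c all share one strict sign; the
redundancy is the pmf-weighted sum of credited terms.  Nodes with a single
composite past (future) antichain and two future (past) members use the
same rule with the roles of past and future exchanged (mutual information
is symmetric, so the "backward" decomposition needs no new machinery).  The
bottom node uses the double co-information

    c = i(x₁;y₁) + i(x₁;y₂) + i(x₂;y₁) + i(x₂;y₂)
        − i(x₁;Y) − i(x₂;Y) − i(X;y₁) − i(X;y₂) + i(X;Y)

credited when the four pairwise local terms, i(X;Y) and c share one sign.
This inclusion–exclusion form is forced by subset-equality: when the two
future parts are duplicates the double node must collapse to the
single-target rule, and it does so exactly (tested).  CCS on Gaussian
systems is refused rather than silently switched to MMI.

Both backends satisfy compatibility by construction (singleton-member nodes
are evaluated as plain MI), which is why the aggregate identities below
hold for *any* backend the package ships.

## Derived measures

Classical measures are computed from direct mutual-information expressions
(numerically robust, independent of the inversion) and cross-checked in the
tests against their atom aggregates:

| measure | direct definition | atom aggregate |
|---|---|---|
| TDMI | I(X_t;X_{t+1}) | sum of all 16 atoms |
| AIS(1) | I(X¹_t;X¹_{t+1}) | red->red + red->un1 + un1->red + un1->un1 |
| TE(1→2) | I(X¹_t;X²_{t+1}\|X²_t) | un1->red + un1->un2 + syn->red + syn->un2 |
| Φ_WMS | TDMI − ΣAIS | −red->red + transfer + all syn atoms |
| Φ_R | Φ_WMS + bottom redundancy | — |
| uCD | TE(1→2)+TE(2→1) | corrected CD = uCD − syn->red |

The six-mode taxonomy (storage 4, copy 2, transfer 2, erasure 2, downward
3, upward 3 atoms) partitions the 16 atoms, so the modes also sum to TDMI.
These identities are verified on ensembles of 200 random discrete systems
(Dirichlet-uniform pmfs, both backends) and 200 random stationary Gaussian
systems (random stable coupling, random SPD innovations) to |error| < 1e-9.

## Numerical choices

* Log base 2 everywhere; all outputs in bits.
* Discrete information quantities are plug-in (maximum-likelihood) values
  on marginal tables; zero-mass states contribute zero.
* Gaussian mutual information is ½·log₂(det Σ_a det Σ_b / det Σ_ab) via
  `slogdet`; if a required submatrix is numerically non-positive a 1e-10
  diagonal jitter is tried once, and failure after jitter raises rather
  than returning NaN.  Mutual informations are clipped at zero; conditional
  MI is the difference I(a;b∪c) − I(a;c).
* The stationary AR(1) covariance solves S = A·S·Aᵀ + Σ with
  `scipy.linalg.solve_discrete_lyapunov`; spectral radius ≥ 1 raises.
* Estimators: sample covariance with denominator n−1 (Gaussian) and
  empirical pair counts (discrete), lag 1 by default.  A `step` keyword
  strides the pair start times: series emitted as i.i.d. (past, future)
  row pairs must be counted with `step=2`, because sliding pairs would mix
  in spurious future→next-past transitions that belong to no trajectory.
* Atom values below 1e-10 in magnitude are reported as-is; the
  `AtomTable.nonzero` view applies the 1e-10 threshold used by the
  "single nonzero atom" checks.  Negative atoms (possible under MMI) are
  reported without flooring.

## Synthetic systems

The generators produce the study conditions the rest of the package is
validated under:

* **Logic gates** — copy transfer, downward XOR, parity-preserving random
  (PPR): 8-state equiprobable pmfs built directly from their defining
  rules.  Each has Φ_WMS = 1 bit and a single nonzero MMI atom
  (`un1->un2`, `syn->un1`, `syn->syn` respectively).
* **Pure-atom systems** — one binary construction per atom label (ten base
  constructions plus part-swapped mirrors, covering all 16 labels), each
  verified at build time against the MMI decomposition: exactly one atom of
  1 bit, all others below 1e-10.  These back the sign table of Φ_WMS
  (−1 on red->red, +1 on transfer and syn atoms, 0 elsewhere).
* **AR family** — couplings all equal to a (default of interest a = 0.4),
  unit-variance innovations with correlation c; |2a| < 1 required.  The
  c-sweep reproduces the qualitative signature that Φ_WMS decreases through
  zero as noise correlation grows while Φ_R stays nonnegative.
* **Samplers** — `sample_transition_pairs` draws i.i.d. (past, future)
  pairs rather than rolling out a chain, because systems like PPR conserve
  a quantity along trajectories: a single rollout would condition on one
  conserved class and no longer sample the stated one-step joint.  AR
  rollouts start from the stationary distribution so finite-sample
  estimates carry no transient bias.

What the generators do *not* emulate: non-Markovian dependence, nonlinear
continuous dynamics, heavy-tailed noise, or measurement artifacts.  Tests
passing on these systems show the decomposition machinery and estimators
are correct under their stated models, not that Gaussian or plug-in
estimates are adequate for arbitrary real data.

## The storage–transfer analysis

`ais_te_analysis` correlates per-source AIS with per-ordered-pair TE across
all variable pairs of a dataset, then reports the first-order partial
correlation after removing the duplication atom `un1->red` that both
measures contain.  The validation library uses a three-channel binary
construction in which duplication, self-storage and synergistic-transfer
strengths are independent dials and the `un1->red` atom equals the
duplication channel's capacity exactly; with duplication dominating, the
AIS–TE correlation is ≈ 1 and collapses once the atom is partialled out.
A literal one-atom library (duplication and nothing else) makes AIS, TE and
the atom identical, so the partial correlation is undefined there — the
three-channel construction is the nearest well-posed setting.  Simulation
scale: libraries of ~24 analytic systems and 6000-step Gaussian series,
which keep sampling noise on the reported correlations near ±0.05.

## Problem sizes used in validation

Property ensembles use 200 random systems per family; estimator-consistency
checks use T = 100,000 AR steps (atoms recovered within ±0.01 bits of the
analytic solution); discrete pmf recovery uses 50,000 sampled transition
pairs (±0.02 per cell).  All are comfortably within desk-scale runtimes.

## Known limitations

* Numeric atoms are defined for two univariate parts only; antichain and
  lattice enumeration is general-N but no atom naming or computation is
  offered beyond N = 2.
* The decomposition is one-step (lag selectable, but a single lag): systems
  with longer memory need an embedding the package does not construct.
* MMI redundancy is a hard minimum: measured atoms are continuous but not
  smooth in the underlying distribution, which matters when differencing
  atoms across similar systems.
* CCS is discrete-only, and like all pointwise sign-gated measures it is
  not additive over independent subsystems in general.
* Estimated decompositions inherit plug-in estimator bias; no bias
  correction or significance testing of atoms is provided.
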