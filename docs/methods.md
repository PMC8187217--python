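# Methods

## Model

A reaction network is the triple (S, C, R): species, complexes (nonnegative
integer vectors over the species), and reactions ν → ν′ between distinct
complexes, each with a rate constant κ > 0. The stochastic semantics is the
continuous-time Markov chain on Z^n_{≥0} that jumps x → x + ν′ − ν at
intensity κ·x!/(x−ν)! (mass action) or, for general kinetics,
κ·∏_i ∏_{j=0}^{ν_i−1} θ_i(x_i − j) with per-species rate laws θ_i
satisfying θ_i(x) = 0 iff x ≤ 0. Mass action is θ(x) = x; Hill type I is
x^m/(k^m + x^m); Hill type II is k1^m/(k2^m + x^m). The Hill-II formula does
not vanish at 0 on its own, so every rate law is clamped to 0 for x ≤ 0 and
uses its formula for x ≥ 1 — the clamped function is what the intensity
product needs, and it reduces to the falling factorial for mass action.

A stationary distribution on an irreducible component Γ solves the master
equation (πQ = 0 restricted to Γ). *Generalized balance* refines this: a
set of tuples (L_i, R_i) of reaction subsets whose L's and R's each
partition R, such that inflow through L_i balances outflow through R_i at
every state. Any generalized-balance certificate implies stationarity;
the classical special cases (detailed/reaction balance, per-complex balance,
per-jump-vector balance) are provided as named partition constructors. For
the per-complex case the balance equation pairs the *inflow* reactions
(ν′ = C, evaluated at the shifted states) against the *outflow* reactions
(ν = C): that orientation is the one a complex-balanced Poisson
distribution satisfies (verified in the test suite on an irreversible
3-cycle, where the opposite pairing fails).

## Decomposition and assembly

The driver looks for a reaction-disjoint split G = G₁ ∪ ... ∪ G_s with
every part *essential* (each reactant complex is accessible from its
product complex, the practical characterization of "every state sits in an
irreducible component"). Essentiality of the parts guarantees that the
projection of a joint component onto a part's species is a disjoint union
of that part's components, which is the state-space half of the assembly
hypothesis. Parts are solved by three registered solvers:

1. **complex_balanced** — weakly reversible parts with a point of complex
   balance c (solved in log space from the per-complex flow equations with
   scale-invariant relative residuals, so a collapse of c toward 0 or ∞
   cannot fake a solution; acceptance threshold 1e−10 relative). Factors
   are Poisson-type, c_i^x/∏_{l≤x} θ_i(l).
2. **motif** — two-species parts whose jumps are all ±(e_A − e_B) and whose
   aggregate up/down rates factor as up(x) = θ_B(x_B)·U(x_A),
   down(x) = θ_A(x_A)·D(x_A − 1). Each conservation line is then a
   birth–death chain and the factors are f_A(x) = d^x ∏ U(l−1)/D(l−1) / ∏θ_A(l),
   f_B(x) = d^x/∏ θ_B(l). This covers S1 ⇌ S2, the exchange motif
   2S1 ⇌ S1+S2, and the autocatalytic conversions S2+(m−1)S1 → mS1 in one
   code path. The factorization is checked numerically on a grid
   (refusing, e.g., reactants with two copies of the partner species) and
   U, D remain analytically evaluable at any x, so the factors extend to
   infinite components and to tail-ratio estimates.
3. **direct_factorize** — small conservative parts (≤ 2000 projected
   states): the projected components are each solved exactly and one set of
   per-species log-factors is fitted jointly across all of them by least
   squares (one free constant per component). A joint max log-residual
   below 1e−8 verifies numerically that a single product form serves every
   projected component — exactly the distributional half of the hypothesis.

**Matching.** Conservative parts own a free exponential tilt
f_i ↦ d^{c_i x} f_i along their conservation vector; non-conservative parts
have none. For every species shared by two parts the condition
α_i f_i^j = f_i^k must hold on the species' observed range. In log space
this is linear in the log-tilts, so all constraints over all leaf parts are
solved as one least-squares system; a max residual above 1e−8 means no
choice of free constants makes the factors proportional and the assembly is
*refused* (the proportionality hypothesis is exact, so refusal — not
approximation — is the correct outcome; a `force` flag builds the
mismatched product anyway for diagnostic use, and the test suite checks
that such a product violates the master equation). Parts whose conservation
space has dimension > 1 get a single tilt direction; a genuinely
multi-dimensional gauge would need a tilt per conservation law and is a
known limitation (none of the bundled fixtures require it).

**Search.** Bipartitions are enumerated deterministically (subsets
containing the smallest reaction index, by size then lexicographically),
filtered by a memoized essentiality test with a cheap pre-filter
(reversible or weakly reversible ⇒ essential), and recursed; the first
split whose sub-solutions match is kept. Accessibility queries decompose
across species-disjoint reaction groups (independent chains) before any
state enumeration, which keeps unbounded but decoupled directions from
forcing truncation. Exhaustive search is refused above 16 reactions
(configurable): the bipartition count is 2^|R| − 1 and the method is aimed
at networks assembled from small motifs. Only reaction-disjoint splits are
searched; unions that glue over shared reactions (summed rates) are
supported by the union constructor but the space of such decompositions is
a continuum and is not enumerable.

When no decomposition assembles, a finite closed component falls back to
the direct null-space solve (flagged in the provenance report); an
infinite component raises an error rather than guessing.

## Numerics

- Product-form factors are stored via successive ratios with f(0) = 1 and
  evaluated as cumulative log sums; factorials underflow near x ≈ 170 in
  double precision while the normalized distributions are still meaningful.
- The direct solver replaces one row of the transposed generator with the
  normalization constraint: dense LU up to 2000 states, sparse LU beyond.
  Residual ‖πQ‖∞ is recorded on every solve; a singular system or negative
  probabilities signal a non-simple null space and raise instead of being
  silently clipped (only round-off at −1e−8 relative is tolerated).
- Deficiency uses the exact rational rank of the stoichiometric matrix;
  conservation vectors come from an LP over a rational nullspace basis
  (positivity imposed as c ≥ 1) and are re-verified in exact arithmetic
  after rounding, so a reported conservation law is orthogonal to every
  reaction vector exactly.
- Exploration bounds: conservative networks use the exact cap
  x_i ≤ ⟨c, x₀⟩/c_i, so reachability and essentiality verdicts are exact;
  otherwise a seed-plus-margin cap (default 10) applies and any suppressed
  jump marks the result truncated/inconclusive rather than wrong.
- The ratio-test summability verdict estimates the tail ratio limit at
  x = 10^6 and 10^7 for analytic factors; limits inside (1−1e−6, 1+1e−6)
  and table-backed factors are deliberately *inconclusive*.
- Tie-breaks are deterministic throughout: species order is first
  appearance, reactions keep file order (also the SSA selection order),
  subset enumeration is by size then lexicographic, and the first valid
  decomposition in that order is reported.

Default tolerances (all overridable via `Settings` or a `key = value`
config file): master-equation residual 1e−10, generalized-balance residual
1e−9 (relative to the largest flow term), proportionality 1e−10 relative,
factorization and matching 1e−8 on log scale.

## Simulation

The SSA uses one named numpy generator seeded from the trajectory config;
waiting times are exponential in the total intensity and the reaction is
chosen by cumulative-sum inversion in file order, so trajectories are
bit-reproducible. Stationary estimates are time-weighted occupancies after
a burn-in fraction (default 0.2) of the observation window — π is the law
of time averages, so holding times are weighted, not event counts. Standard
errors are binomial-style with the post-burn-in event count as a crude
effective sample size; they are indicative, not calibrated for
autocorrelation.

## Synthetic fixtures and what passing tests show

The fixture module reproduces the small benchmark networks with recorded
ground truth (the three-species double motif with deficiency 2, the
deficiency-one pair of detailed-balanced parts, the gene-expression network
that is essential but admits no essential split, the non-essential chain
with an irreversible source, the motif ∪ birth–death join with infinite
components, the autocatalytic conversion family, the five-species join of
an autocatalytic-type part with a triple exchange) and two random families:
star-glued motifs sharing one hub species (rates log-uniform on [0.1, 10],
component sizes N ∈ {3..6}) whose assembly succeeds for every rate draw,
and double motifs glued through the rate-dependent species whose second
block is proportional by construction — the one-rate perturbations of that
family are the refusal benchmark. These fixtures exercise exactly the
regime the theory covers: low copy numbers, a handful of species, factors
that are ratios of affine functions of the rates. Passing tests show the
assembly calculus and its verification are correct there; they do not probe
large networks (the search is exponential by design), stiff rate
separations beyond two orders of magnitude, or non-product stationary
distributions, which the method refuses rather than approximates. Problem
sizes in the test and acceptance runs (components up to a few thousand
states, 100 random fixtures, 10^5 SSA events) were chosen so the direct
null-space oracle is cheap and exact alongside every assembled answer.
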