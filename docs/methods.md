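# Methods

## Model class and assumptions

`causalinfo` works with discrete probability models on chain graphs.  A
chain graph has directed and undirected edges and no semi-directed cycle;
its maximal undirected-connected sets are the chain components τ, and a
DAG is the special case where every component is a singleton.  The joint
distribution factorises over components,

    P(V) = ∏_τ P(τ | pa(τ)),        pa(τ) = ∪_{X∈τ} pa(X) ∖ τ,

and the model is parameterised directly by one conditional table per
component.  For chain graphs this takes the component conditionals as
given equilibria of the within-component generative process; the package
does not verify that an undirected pairwise kernel with that equilibrium
exists, because interventions and all information measures depend only on
the conditionals themselves.

Interventions follow truncated factorisation.  For `do(Y = y)`, every
component τ that intersects Y contributes `P(τ∖Y | pa(τ), τ∩Y)` evaluated
at y, and the intervened nodes carry point mass.  On a DAG the replaced
factor is the constant 1 (the factor is dropped), so a single
implementation serves both graph classes, and the chain-graph definition
demonstrably reduces to the DAG one when components are singletons.

The model class is Markovian: all common causes are represented as nodes.
Positivity ("no modelled event has probability zero") is *reported* (the
`positive` flag), not enforced, so deterministic limits — the ε → 0
noisy-copy chain — stay representable.  Conditioning on a
probability-zero event raises an error naming the event; an adjustment
stratum of probability zero raises a positivity error naming the cell.

## Information measures

All functionals are exact summations over joint tables (no estimation):

- entropy, KL divergence, and (conditional) mutual information, the latter
  computed as `D( P(A,B,Z) ‖ P(A|Z)P(B|Z)P(Z) )` over support points; an
  independent entropy-form recomputation is kept in the test suite;
- weighted Jensen–Shannon divergence
  `JSD(q‖r) = H[π_q q + π_r r] − π_q H[q] − π_r H[r]`;
- directed information `I(A→B) = E log [ P(A|B) / P(A|do(B)) ]`, with the
  *second* argument as the do() target, and its conditional version with
  the intervention applied *before* conditioning:
  `P(A|do(B),Z) = P(A,Z|do(B)) / P(Z|do(B))`.

Conventions: `0·log 0 := 0`; sums run over support points of the
observational distribution, matching the measure-theoretic expectation; a
support point with zero interventional mass yields a flagged infinite
value rather than an exception.  The default base is bits
(`options.log_base`); every identity is base-invariant and the nats/bits
ratio is tested.  "Equals zero" decisions use an absolute tolerance of
1e-9 bits (`options.zero_tol`), which absorbs only float round-off since
nothing is estimated.  Probabilities are stored in linear space;
logarithms appear only inside the measures.

## The two-step pipeline

Step 1 tests `I(Y→X) = 0` (no confounding of the ordered pair (X, Y));
failing that, it searches the subsets of the non-descendants of X
(excluding X and Y) for the smallest Z with `I(Y→X|Z) = 0`, tie-broken
lexicographically by node name — valid adjustment sets are not ranked by
the theory, so the tie-break is a reproducibility device, not a claim.
The search can run on the information-theoretic route, the graphical
back-door route, or both with a hard consistency check; the two are
provably equivalent on this model class and the equivalence is exercised
in the tests.  The back-door criterion itself is evaluated pairwise over
(x, y) through the standard delete-outgoing-edges d-separation
equivalence, with "descendant of X" meaning descendant of any member;
d-separation is delegated to networkx and cross-checked against an
exhaustive path-enumeration oracle in the test suite.

Step 2 computes the effect only after step 1 succeeds — calling the
quantification with a confounded, unadjusted pair is a pipeline-order
error, because mutual-information-type quantities have a causal reading
only in the unconfounded setting.  For a binary cause the package emits
the Jensen–Shannon cross-check (aggregate and per-stratum, including the
per-z identity against the z-stratum KL divergence); for a non-binary
cause it reports MI/CMI alone and flags the report.  ACE requires the
outcome's numeric coding to be *declared* (`numeric` flag); ordinal
coercion is never silent.  SCE additionally requires the stratifying set
to be non-descendants of the cause.

## Canonical time-series models

The builders emulate the standard graphs used to compare time-series
definitions of directed information; series are named `X.1..X.n`, etc., so
the closed forms can locate them programmatically.

- `g1`: 2n nodes in a total order (X and Y interleaved), every forward
  arrow.  The general definition reduces to the with-present sum
  `Σ_i I(X^i ; Y_i | Y^{i−1})`.
- `g2`: aligned series, all strictly-forward arrows, none at equal times;
  reduces to the no-present sum `Σ_i I(X^{i−1} ; Y_i | Y^{i−1})`.
- `g2z`, `h1z`: a third, confounding series Z.  Z is exogenous — `Z.i`
  receives arrows only from earlier Z, while X and Y receive from all
  earlier nodes of all three series.  This choice makes the conditional
  closed form `Σ_i I(X^{i−1};Y_i | Y^{i−1}, Z^{i−1})` equal the general
  conditional definition (verified to 1e-16 at n = 2, 3); the alternative
  with arrows from X, Y into Z breaks the identity and so cannot be the
  intended topology.
- `h1`: `g2` plus an undirected edge inside every pair {X.i, Y.i}, making
  those pairs chain components — instantaneous coupling without a causal
  direction.  The chain-graph interventional definition again yields the
  no-present sum.
- `bidirectional`: arrows `X.{i−1}→Y.i` and `Y.{i−1}→X.i` only.  With
  `epsilon` set, every arrow is a binary symmetric channel with flip
  probability ε and uniform initial states — a discrete realisation of
  the Gaussian noisy-copy counterexample.  The discrete stand-in is valid
  for the structural claims because the vanishing of
  `I(Y_n → X^{n−1})` is factorisation-driven (it holds for *any*
  conditional tables, which the tests check with Dirichlet-seeded CPTs
  and across ε), and ε → 0 maps to deterministic copying.  The Gaussian
  version is out of scope.

Boundary conventions, applied uniformly to the i = 1 terms: a conditional
mutual information with an empty first or second argument is 0; an empty
conditioning set means unconditional.

Two deliberate departures from a naive reading of the counterexample
literature, both verified numerically:

- The structural zero is `I(Y_n → X^{n−1})` with Y_n the *present* sample
  only.  Conditioning on the whole Y series is not zero — `Y.1` is a
  parent of `X.2`, so the full-series variant opens a back door and is
  strictly positive (≈0.14 bits on the seed-7 chain); the suite asserts
  both facts.
- Transfer entropy on the bidirectional chain vanishes at *both* ε = 0
  (deterministic copies: `Y_n` is a function of `Y^{n−1}`) and ε = 0.5
  (pure noise), peaking near ε ≈ 0.12 for n = 4.  The monotone decrease
  to zero therefore holds on a grid near the deterministic limit
  ({0.12, 0.1, 0.08, 0.05, 0.02, 0.01, 0}), which is the grid the property
  test uses; monotonicity over a wide grid like {0.4 … 0} is false.

## Synthetic inputs and what the tests show

There are no external datasets: inputs are the canonical graphs above,
small hand-specified tables, and Dirichlet(1)-seeded conditional tables
(each row's generator is seeded by (seed, component index, row index), so
editing one table never reshuffles others).  Dirichlet(1) rows are almost
surely strictly positive and non-degenerate, which is exactly the regime
the identities require; they do not emulate real-data features such as
sampling noise, sparsity, or near-deterministic structure except where a
test constructs those deliberately (ε-channels, zero rows).  Passing tests
therefore certify the *exact* identities and the correctness of the
machinery, not finite-sample behaviour; the sampling/fitting layer is
tested separately against binomial standard-error bounds at n = 10⁵–2×10⁵.

## Numerical choices and problem sizes

- Row-stochasticity tolerance 1e-9 (absolute) per conditional row; every
  produced joint table is checked to sum to 1 within 1e-9.
- Exact enumeration is refused beyond ~4×10⁶ assignments with a resource
  error: this is a desk-scale, exact tool by contract.
- Directed information with do-target B costs one interventional joint
  per assignment of B; the suite and the acceptance script therefore use
  n ≤ 3–4 time points (≤ 2⁹-state joints), where every identity is
  checked to 1e-9 in well under a second.
- Enumerations (back-door sets, adjustment-set search) are ordered by
  size then lexicographically by node name, so outputs are reproducible.
- Empirical fitting sets never-observed parent rows to uniform and
  records them (`meta['uniform_rows']`).

## Known limitations

- Markovian models only: no latent confounders, no ADMGs/ancestral
  graphs, no front-door identification.
- Chain-graph support is factorisation-level: component conditionals in,
  interventions and measures out; no c-separation/Markov-property
  machinery and no Gibbs-equilibrium simulation of component kernels.
- Exact tables only: no approximate inference; the state-space cap is a
  hard refusal, not a fallback to sampling.
- ACE/SCE and the Jensen–Shannon cross-check are defined for a binary
  cause (domain {0, 1}) as in the underlying identities; non-binary
  causes get MI/CMI without the cross-check.
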