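# Methods

## Model and assumptions

The core object is a scaffold S with L independent binding sites, one per
ligand (kinase) species; the canonical parameterization has L = 3 for
Raf/MEK/ERK, but nothing is hardcoded to three. Assumptions:

- **Pairwise equilibria.** Each ligand X binds its site with its own K_D;
  site occupancies do not interact (no cooperativity, no allostery, no
  phosphorylation dynamics, no membrane states). The bound amount SX is the
  physical root of `SX² − (S_T + X_T + K_D)·SX + S_T·X_T = 0`.
- **Independence product.** The full-complex level is
  `S_T · Π p_i`, with `p_i = SX_i / S_T`. For truly independent sites this
  is not an approximation in the deterministic limit: the steady state of
  the complete mass-action system over all 2^L occupancy patterns
  factorizes, which the ODE oracle confirms to ~1e−6 relative (limited by
  integration tolerances, not by the model).
- **Units.** All amounts are dimensionless-consistent: totals and K_D must
  share units (arbitrary concentration or copies per unit volume). No
  conversion happens inside the core; copies↔molar conversion is available
  but always demands an explicit cell volume, because the literature gives
  scaffold abundance in copies per cell and kinase abundance in molarity
  without fixing a volume.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| titration grid | 200 log points, 0.01×–100× max ligand total | scaffold amount | spans both prozone flanks |
| plateau threshold | 0.95 | fraction of peak | the plateau edge is not defined quantitatively anywhere authoritative; the tight-binding closed form `[min, second-min]` is exposed separately so nothing scientific depends on this choice |
| boundary refinement | brentq between grid neighbours, rel. 1e−9 | — | makes reported edges grid-independent to ≲1e−6 |
| enumeration guard | 30 copies per species | copies | falling-factorial sums are computed in log-space (gammaln) below the guard; beyond it the SSA is the intended tool |
| SSA burn-in | 20% of horizon | time | discards the relaxation transient from the empty initial state |
| SSA batches | 20 | — | batch means give the standard errors used in 3-SE concordance checks |
| steady-state tolerance | max derivative < 1e−10 × max totals | amount/time | algebraic residual check after stiff (LSODA) integration over geometrically growing spans, robust for K_D spanning 1e−2–1e1 |
| configuration states/site | 3 | — | empty / bound / bound-phosphorylated, reproducing 27 configurations for a three-site monomer and 729 for a dimer; fully parameterized since other state decompositions are defensible |

## Discrete placement semantics

The integer-copy oracle places, independently per ligand type,
`min(n_scaffold, copies)` copies on *distinct* scaffolds, uniformly at
random (one site per type per scaffold). This is the reading under which
the worked example behaves as stated: with 5 scaffolds and (2, 5, 10)
copies both possible full complexes always form; with 6 scaffolds exactly
one lacks MEK, a designated Raf copy hits it with probability 1/6 (any Raf
with probability 1/3), and that branch yields exactly one full complex.
Both hit-probability readings are exposed
(`designated_scaffold_hit_probability(..., form=...)`) and neither is
treated as the "right" one in user-facing output. The full-complex
distribution is computed by folding hypergeometric intersection laws in
exact rational arithmetic; an exhaustive enumerator over all joint
placements serves as its brute-force cross-check and handles conditioning.

At finite K_D the per-ligand bound-count pmf uses partition-function
weights `w(b) ∝ C(n, b) · c!/(c−b)! · κ^b`, κ = 1/K_D in copies per unit
volume with volume 1, so the discrete and analytic parameterizations
coincide numerically. Expected full complexes are
`Π E[b_i] / n^(L−1)` (uniform placement given counts, independent types).

## What the synthetic scenarios emulate — and what they do not

`generate_scenarios` draws scaffold and ligand totals and K_Ds log-uniformly
within configured ranges, mirroring the structure of the canonical
stoichiometry panels: one scaffold titrated against ligand pools of
different abundance with a shared or per-ligand affinity. It does **not**
emulate correlated expression between kinases, cell-to-cell variability,
competing binding partners, phosphatases, or activation dynamics — so
passing tests demonstrate correctness of the equilibrium model, not
predictive accuracy for any real signaling system. The seven fixed presets
(ligand sets (2,2,2) and (2,10,20) at K_D ∈ {0.01, 1}, (2,100,200) at
K_D ∈ {0.1, 10}, plus the discrete (2,5,10) copy set) are pinned by a
checksum test.

## Numerical choices

- **Root selection.** Always the smaller quadratic root (the larger exceeds
  min(S_T, X_T) and is unphysical), in the form
  `2·S_T·X_T / (b + √(b² − 4·S_T·X_T))` to avoid cancellation at small K_D;
  K_D = 0 is special-cased to `min(S_T, X_T)` exactly rather than left to
  limiting numerics.
- **Degenerate inputs.** `S_T = 0` yields an all-zero occupancy result for
  levels but a domain error for probabilities (undefined); an all-zero
  titration curve is a domain error for range extraction; a conditioning
  event of probability zero (e.g. no scaffold can lack the partner ligand)
  is a domain error rather than a silent empty distribution.
- **Ties and edges.** Plateau membership uses `≥ threshold·max·(1−1e−12)`;
  if an edge falls outside the grid it is reported at the grid end;
  bisection falls back to the qualifying grid point if the bracket does not
  change sign (flat tight-binding plateaus).

## Design choices where the design was open

- **Per-ligand K_D** is allowed to differ even though the canonical panels
  use one value per panel — generalization at zero cost; presets pin equal
  values.
- **Threshold semantics** for "optimal range": ≥ threshold × peak, default
  0.95, with the analytic frame exposed separately (see table).
- **HeLa-like scenario**: Raf 13 nM, MEK = ERK = 1 μM; scaffold totals are
  supplied as copies per cell plus an explicit volume. Site affinities of
  KSR1 for its kinases are not established numbers, so `hela_scenario`
  *requires* user K_Ds and never defaults them.
- **SSA method**: direct method with one global event clock; with koff = 0
  the chain absorbs at full occupancy and the remaining horizon is credited
  to the absorbed state.

## Known limitations

- The finite-size gap between the discrete expectation (per volume) and the
  analytic level scales like 1/N in the per-species copy numbers: it
  shrinks monotonically under ×2/×4/×8 scaling everywhere we test, but its
  magnitude at the enumeration guard depends on affinity — ~1.8% for weak
  binding (K_D ≈ 5 at equal abundances of 3), ~2.4% at K_D ≈ 1, and 0
  exactly at K_D = 0. Systems with min copies of 1–2 deviate by tens of
  percent; that is physics, not error.
- Plateau *curtailment* with rising K_D (narrower optimal range at weaker
  affinity) holds while K_D stays below the scarcest ligand total. In the
  deep weak-binding regime the whole curve flattens and the *relative*
  90%-plateau broadens again; the monotonicity property is therefore only
  claimed, and tested, in the strong-to-moderate affinity regime.
- The tight-binding plateau ratio for a (2, 100, 200) pool is 50× (100/2),
  which is the model's quantitative form of the qualitative "a ~100-fold
  change in scaffold expression does not impair signaling" framing; both
  ratio conventions (upper/lower of the plateau vs. kinase-pool ratio) are
  reported by the stoichiometry scan and neither is asserted as the other.
- No phosphatases, no scaffold oligomerization kinetics (only the static
  configuration count), no trans-activation between partially occupied
  scaffolds, no feedback.
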