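# prozone

Equilibrium scaffold-occupancy modeling for kinase cascades: prozone
titration curves, optimal scaffold-concentration ranges, and exact
finite-copy-number oracles.

## The problem

Scaffold proteins such as KSR1 (mammalian MAPK pathway) or Ste5 (yeast
mating pathway) carry one binding site per kinase of a cascade — Raf, MEK
and ERK in the canonical case — and assemble them into a single signaling
complex. Too little scaffold means too few complexes; too much scaffold
titrates the kinases apart into *incomplete* complexes (one scaffold holding
only MEK, another only ERK). This decline at scaffold excess is the prozone
effect, also called combinatorial inhibition. A long-standing conclusion was
that signaling therefore requires a narrowly tuned scaffold concentration.
This package implements the counter-analysis: because cellular kinase pools
are very unequal (Raf ≈ 13 nM vs. MEK, ERK ≈ 1 μM in HeLa cells), the
full-complex level is maximal over a broad *range* of scaffold
concentrations, framed by the two least abundant kinases.

## The model

A scaffold S binds each kinase X reversibly and independently of its other
sites. Mass balance for one site,

```
(S_T − SX)(X_T − SX) = K_D · SX ,      K_D = k_off / k_on ,
```

is a quadratic in the complex SX whose physical root (the smaller one,
computed in a cancellation-free form) gives the occupancy probability
p(X bound) = SX / S_T. With independent sites, the concentration of
scaffolds carrying the complete cascade is the product

```
full_complex(S_T) = S_T · Π_i p_i(S_T) .
```

In the tight-binding limit (K_D → 0) with sorted kinase totals
x₁ ≤ x₂ ≤ …, this curve is piecewise-exact: it rises as S_T below x₁,
plateaus at x₁ for x₁ ≤ S_T ≤ x₂, and declines as x₁x₂/S_T beyond — hence
the optimal range [x₁, x₂].

Four independent oracles validate the analytic model:

- **exact placement combinatorics** (tight binding, integer copies):
  the full distribution of the number of complete complexes, by folding
  hypergeometric intersections in exact rational arithmetic;
- **exact finite-K_D enumeration** via partition-function weights
  `w(b) ∝ C(n,b) · c!/(c−b)! · K_D^(−b)` for b bound copies;
- **stochastic simulation** of binding/unbinding events (direct-method SSA)
  with batch-mean standard errors;
- **mass-action ODEs** over all 2^L site-occupancy patterns, whose steady
  state matches the quadratic product to ~1e−6 relative (independence is
  exact in the deterministic limit).

## Worked example

```python
import prozone as pz

sc = pz.canonical_presets()["mid_highaffinity"]   # 2 Raf, 10 MEK, 20 ERK, K_D = 0.01
curve = pz.titration_curve(sc)                  # 200 log-spaced scaffold totals
rng = pz.optimal_range_from_curve(curve, threshold=0.95)
print("peak full complexes:", f"{rng.peak_value:.3f}")
print(f"optimal range (95% of peak): [{rng.lower:.3f}, {rng.upper:.3f}]")
```

prints

```
peak full complexes: 1.989
optimal range (95% of peak): [2.069, 10.375]
```

The peak is limited by the scarcest kinase (2 Raf; binding at K_D = 0.01 is
strong but not perfect, hence 1.989), and the 95% plateau spans
essentially [2, 10] — the Raf and MEK totals — as the tight-binding closed
form `pz.tight_binding_range((2, 10, 20))` predicts exactly ([2, 10]).

The discrete intuition, at integer scale:

```python
dist = pz.tight_binding_placement(6, (2, 5, 10))
print(dist.values, dist.probs, dist.expectation)
# (1, 2) (0.333..., 0.666...) 1.666...
```

With 6 scaffolds and 5 MEK, one scaffold lacks MEK; a given Raf copy lands
on it with probability 1/6 (`designated_scaffold_hit_probability(6, 2)`),
some Raf copy with probability 1/3, in which case only 1 of the 2 possible
full complexes forms — so the expectation drops from 2 to 5/3 as soon as
scaffold exceeds the second-scarcest kinase.

Command-line equivalents:

```
prozone titrate --totals 2,10,20 --kd 0.01 --smin 0.02 --smax 2000 --points 200 --out curve.csv
prozone range --totals 2,5,10 --tight --format json
prozone discrete --scaffolds 6 --copies 2,5,10 --tight --format json
prozone enumerate-configs --sites 3 --states 3 --order 2
prozone run discrete_worked --outdir report/ --oracles
```

## Layout

- `src/prozone/model.py` — the whole model, in the order the analysis runs
  (equilibrium core → oracles → range analysis → scenarios/I-O/pipeline)
- `src/prozone/__main__.py` — the CLI
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations
- `tests/` — unit, property (hypothesis) and end-to-end scientific tests
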