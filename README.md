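# tailsplit

When is it statistically *better* to dichotomize an ordinal scale than to
keep its raw values?  `tailsplit` studies this question for measures with
**asymmetric reliability** — scales whose inter-rater agreement is much
tighter at one extreme of the range than elsewhere.  The motivating case
is the Alda score of lithium responsiveness in bipolar disorder: an
ordinal 0–10 scale, conventionally dichotomized at 7 into "responders"
(≥ 7) and "non-responders", whose high scores are reachable through far
fewer item combinations (79 of 2673) than low scores (2159 yield ≤ 3)
and are therefore rated far more consistently.

The package is aimed at biostatisticians and psychiatric-genetics
researchers who use such scales as target variables and need to decide
between regression on the raw score and classification on its
dichotomization.

## What it computes

**Empirical stage** (`tailsplit.rating_model`).  Given inter-rater data
(raters × vignettes, with consensus gold-standard scores), the counts
n⁽ᵏ⁾ of observed scores per gold score *k* are modelled as multinomial
with a symmetric Dirichlet(α) prior, smoothed by the MAP estimate

θ̂ᵢ = max(0, α + nᵢ − 1) / Σⱼ max(0, α + nⱼ − 1).

α plays the role of a-priori observation noise.  The same construction
applied to the 2×2 class-collapsed counts, with concentration
ξ = 11α/2 (equal total prior mass), gives the dichotomized analogue.
Mutual information I[x_o ; x*] between observed and gold labels is
computed for both representations along an α-grid, and
`crossover_alpha` finds the noise level beyond which the dichotomized
scale retains *more* information than the raw one.

**Theoretical stage** (`tailsplit.synthetic_reliability`,
`tailsplit.mi_estimation`, `tailsplit.power_analysis`).  A continuous
generator y = ω·f(x) + (1−ω)·U(0,10) with diagonal noise U(−σ,σ) —
optionally scaled by the logistic profile 1/(1+e^(−0.75x+5)) to make
reliability asymmetric — feeds (a) mutual-information comparisons
between a Gaussian-KDE estimate on the continuous data and the exact
2×2 MI after thresholding at τ, and (b) analytic power comparisons
between the Pearson correlation test (Fisher-Z approximation,
Φ(√(n−3)|ζ(ρ̂)| − z_{1−α/2})) and Fisher's exact test (noncentral
hypergeometric survival functions) at a median split (τ = 5) and a tail
split (τ = 3).

## Worked example

```python
import numpy as np
from tailsplit import (build_count_tables, impute_missing_counts,
                       generate_rating_fixture, mi_curves)

# 59 synthetic raters of the 12 standard vignettes, with tighter
# agreement on gold scores >= 7 (sd 0.8) than below (sd 2.0)
matrix = generate_rating_fixture(n_raters=59, seed=101)
tables = impute_missing_counts(build_count_tables(matrix))
curve = mi_curves(tables, np.geomspace(0.5, 100, 60))
print(f"crossover alpha: {curve.crossover_alpha:.2f}")
for a in (1.0, 10.0):
    i = int(np.argmin(np.abs(curve.alpha_grid - a)))
    print(f"alpha={curve.alpha_grid[i]:5.2f}  "
          f"raw MI={curve.mi_raw[i]:.4f}  binary MI={curve.mi_binary[i]:.4f}")
```

prints

```
crossover alpha: 4.82
alpha= 1.03  raw MI=0.7366  binary MI=0.3836
alpha= 9.68  raw MI=0.1842  binary MI=0.2714
```

Read: with little prior noise (α ≈ 1) the raw 11-point scale carries
almost twice the information of the responder/non-responder split
(0.74 vs 0.38 nats), but once observation noise exceeds α ≈ 4.8 the
ordering reverses — at α ≈ 10 the dichotomized representation retains
more information about the gold standard (0.27 vs 0.18 nats).  That is
the core phenomenon: coarsening throws away detail, but what it keeps
is the part of the scale that raters agree on.

The same stages are available from the shell:

```sh
tailsplit alda-combos --min 7 --max 10          # -> 79
tailsplit make-fixture --n-raters 59 --seed 1 --out ratings.csv
tailsplit empirical-mi --ratings ratings.csv --out curve.csv
tailsplit power-experiment --runs 100 --seed 1 --out power.csv
tailsplit reproduce --seed 1 --out results/
```

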