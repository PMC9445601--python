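# foliar

Shoot-level leaf-area allometry for plant ecophysiologists: the foliage
length-times-width model, the line fits it calls for, and a synthetic-shoot
generator for validating the whole chain by parameter recovery.

## The model

Within a species, an individual lamina's area is proportional to its length
times its width (the Montgomery equation, `A_leaf = c · L_leaf · W_leaf`):
different-sized leaves of one species are *affine*. The same idea extends to
whole shoots. Detach a shoot's laminas and lay them side by side; the
resulting *foliage* has

```
L_f = Σ W_leaf          (foliage length: sum of lamina widths)
W_f = max L_leaf        (foliage width: maximum lamina length)
A_shoot = Σ A_leaf      (total shoot leaf area)
```

If different-sized foliages of a species are affine, then

```
A_shoot ∝ L_f · W_f
```

and if the two foliage dimensions follow a power law `L_f ∝ W_f^β` with
β > 1 (bigger shoots carry disproportionately more leaves), the classic
empirical relationships all follow with exponents fixed by β:

| relationship | form | exponent |
|---|---|---|
| area from max leaf length | `A_shoot ∝ W_f^(β+1)` | β + 1 > 2 |
| size–number allometry | `A_shoot ∝ N^α` | α = (β+1)/(β−1) > 1 |
| Heerema–Spann–Teobaldelli | `A_shoot/W_f ∝ N^γ` | γ = β/(β−1) > 1 |
| mean leaf area vs total | `A_shoot/N ∝ A_shoot^λ` | λ = 2/(β+1) ∈ (0, 1) |
| Sun | `A_shoot ∝ N · max A_leaf` | — |
| Lopes–Pinto | `A_shoot = k · N · (min A_leaf + max A_leaf)/2` | constant k |

Exponents are estimated by standardized major axis (SMA) regression on
log10 scales (slope = sign(r)·sd(y)/sd(x)); predictive relations use OLS
with adjusted R². The package fits all of the above per species, reports
the regression table, and checks the fitted α, γ, λ against the values
predicted from the fitted β.

No field data ship with the package; the `simulate` module generates shoot
collections under the affine model with known β so every fitted exponent
can be compared with its ground truth.

## Worked example

```
$ foliar simulate --beta 2 --seed 11 --n-shoots 60 --out demo.csv
INFO wrote 60 shoots (5196 leaves) to demo.csv; true beta=2 alpha=3 gamma=2 lambda=0.666667
$ foliar analyze --input demo.csv
species=synthetic n_shoots=60 beta=1.986 alpha=2.992 gamma=1.987 lambda=0.6658 k=0.8158
```

The generating exponent was β = 2, so the model predicts α = 3, γ = 2,
λ = 2/3; the fitted values (1.986, 2.992, 1.987, 0.666) recover them to
well under one percent despite the 1 % multiplicative measurement noise.
`foliar analyze --out report.json` writes the full regression table
(slopes, intercepts, adjusted R², 95 % CIs) as JSON or, with
`--format csv`, one row per relationship and method. `foliar check` prints
the exponent-consistency report (confidence-interval inclusion of each
predicted exponent).

The same analysis is available in-library, sklearn-style:

```python
from foliar import SpeciesAllometry, generate_shoots, default_config

shoots, truth = generate_shoots(default_config())
est = SpeciesAllometry().fit(shoots)
est.exponents_.beta      # fitted SMA slope of log10 L_f on log10 W_f
est.report_              # full per-species report
```

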