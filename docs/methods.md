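# Methods

## Model and scope

The package implements the foliage length-times-width model of total shoot
leaf area. A shoot is a single current-year stem with its leaves; only the
leaf laminas are modelled (no petioles, stems, buds or reproductive
organs), and only simple, flat laminas are in scope — compound leaves,
needles and succulent leaves are not. Units are fixed at cm and cm²
throughout; there is no conversion layer.

Per shoot the package computes foliage length `L_f` (sum of lamina widths),
foliage width `W_f` (maximum lamina length), total area `A_shoot`, leaf
count `N`, and the minimum/maximum individual lamina area. For a single
leaf the foliage dimensions collapse onto the leaf's own width and length.
Ties for the longest leaf are resolved on values; which leaf attains the
maximum is never used. Leaf areas come either from direct measurement or
from the Montgomery relation `A = c·L·W` with a species-specific
coefficient (e.g. 0.7169 for *Cardiocrinum cordatum*); the area policy is
explicit so the two workflows cannot be mixed silently.

## Fitting protocol

All log-scale fits use base-10 logarithms. OLS (scipy's `linregress`, via
`ols_fit`/`OLSLine`) is used where one variable predicts the other; its R²
is adjusted for the single predictor, `1 − (1 − R²)(n − 1)/(n − 2)`, and is
not clamped, so it may be negative. The intercept is always estimated, even
for relations that are theoretically proportional. SMA (`sma_fit`/
`SMALine`) is used for mutual allometric relationships: slope magnitude
sd(y)/sd(x) with the sign of the Pearson correlation, r² reported as the
squared correlation. The 95 % SMA slope interval uses the standard
allometry-literature expression: with `B = F₀.₉₅(1, n−2)·(1 − r²)/(n − 2)`,
the bounds are `b·(√(B+1) ∓ √B)`. p-values are the two-sided test of zero
correlation for both methods. Fits require n ≥ 3, non-zero variance in
each fitted variable and (for SMA) a non-zero correlation; violations raise
typed errors rather than returning NaNs.

The per-species pipeline fits nine relationships (see the README table plus
the leaf-level Montgomery fit), each with the method set it is
conventionally reported with (SMA only for the foliage length–width
exponent β; OLS only for the four proportionality relations; both
otherwise). The exponent set is assembled from the SMA slopes (β, α, γ),
the SMA slope of log10(A_shoot/N) on log10(A_shoot) (λ), and the
Lopes–Pinto OLS slope (k). `min_n_filter` (default 1: all shoots are kept)
excludes shoots with few leaves from the shoot-level fits only; it exists
because shoots with N ≤ 3 sit visibly off the size–number regression line —
their totals are dominated by a single leaf — and users may want to
quantify that. Each relation records its own sample size.

Exponent consistency is reported, not asserted: the α, γ, λ predicted from
the fitted β are flagged by inclusion in the fitted exponents' 95 % CIs.
On very tight fits (noise-free simulations, or large field samples) the
CIs shrink to a few thousandths and the check routinely flags tiny,
scientifically irrelevant discrepancies; treat `overall_pass` as a strict
screen, and the fitted-vs-predicted magnitudes as the substantive answer.

## Synthetic data

The generator exists because the model's field datasets are not released;
it simulates the affine model with known ground truth so the pipeline can
be validated by parameter recovery. Per shoot it draws a size scale `W*`
(log10-normal), sets `N = max(1, round(n0·W*^(β−1)))` — leafing intensity
`n0` is the number of leaves per cm^(β−1) — and generates leaves from a
within-shoot profile that declines linearly from the largest leaf either in
length (`linear_length(f_min)`) or in area (`linear_area(g_min)`). Widths
are lengths divided by a species-constant aspect ratio; areas follow the
Montgomery relation. Multiplicative log-normal noise (`10^N(0, σ)` with σ
in log10 units) is applied independently to every dimension of every leaf,
including the largest, and the foliage dimensions are recomputed from the
realized leaves, so their defining identities hold exactly under noise.

Defaults: β = 2, 200 shoots, log10 W* ~ N(0.9, 0.25), n0 = 10, aspect
ratio 2.5, Montgomery coefficient 0.7, `linear_length(0.3)`, σ = 0.01,
seed 20220330. These give shoot areas spanning roughly three orders of
magnitude, comparable to within-species field collections of the species
the model was developed on, though with generally higher leaf counts than
the 1–22 per shoot seen in those collections. The linear profiles are
admitted modelling choices, not claims about any species' real within-shoot
size distribution; likewise the generator ignores phyllotaxis, light
environment, herbivory and between-species covariation, so recovery on
synthetic data demonstrates correctness of the estimation chain under the
model's assumptions, not robustness to real-world violations of them.

`theoretical_k` gives the Lopes–Pinto constant implied by a profile at a
given leaf count (mean relative area over midrange). For `linear_area` it
is exactly 1 at any N — equally spaced areas make the mean equal the
midrange — which is the regime in which the original empirical k = 1 was
reported. For `linear_length` it depends weakly on N; the ground-truth
value attached to a generated dataset is the large-N limit, evaluated at
N = 10001 (convergence is O(1/N); ≈ 0.850 for the default floor 0.3).

## Numerical behaviour and known limitations

- Recovery accuracy (noise-free, defaults): fitted β within 0.001 of
  truth, α/γ within 0.01, the length-times-width adjusted R² ≥ 0.9999;
  residual deviations come solely from integer rounding of N.
- With per-leaf noise, the realized `W_f` is a maximum over N noisy
  lengths and acquires an upward extreme-value bias ≈ σ√(2 ln N) that
  grows with shoot size. This deflates the fitted β by roughly
  σ·√(2 ln 10)·(β−1)/(2√(log10 N)) per unit slope — about 1 % at β = 2 and
  3–4 % at β = 3 for σ = 0.02 under the default leaf counts. Users
  simulating steep-β species at appreciable noise should expect this bias;
  it is a property of max-statistics under noise, not of the fitters.
- The Lopes–Pinto OLS slope is attenuated a few percent below
  `theoretical_k` at even modest noise, because noise inflates the
  observed maximum (and deflates the minimum) leaf area in the regressor.
- Equality-constrained edge cases (all shoots identical, zero variance,
  zero correlation) raise typed errors early rather than propagating NaNs.
- Problem sizes: the shipped tests and the acceptance script use 100–200
  shoots per dataset (the generator's default), with 10 replicate seeds
  for the noisy-recovery study; each complete run takes seconds on one
  core.
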