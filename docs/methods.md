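# Methods

This note records the statistical model behind `cannorm`, the conventions and
numerical choices the implementation commits to, and what the synthetic-data
generator does and does not emulate.

## Shape and size scoring

**Landmark input.** TPS records (`LM=`/`LM<n>=` headers, optional `ID=`,
`IMAGE=`, `SCALE=`) are read as ordered 2-D configurations; `SCALE` is applied
multiplicatively, converting pixels to millimetres. The image y-axis is kept
as stored: every downstream statistic is similarity-invariant, so the
convention has no geometric consequence. Landmark roles (fixed vs.
semilandmark), bilateral pairing and midline membership are not part of the
TPS format and are supplied by a YAML sidecar schema with 1-based indices.
Semilandmarks are placed at equal arc-length spacing along digitized curves
and are afterwards treated exactly like fixed landmarks — no sliding — so
that all point types enter the analysis on the same footing.

**Symmetrization (dorsal head).** Bilateral pairs are replaced by the average
of each point with the mirror image of its partner across the body axis; the
axis is the total-least-squares line through the midline points, or the
configuration's principal axis when fewer than two midline points exist.
Symmetrization is applied to the raw configurations before superimposition.
The full two-sided symmetric configuration provides the head centroid size
(HeadCS = √Σᵢ‖pᵢ − p̄‖²); one side plus the midline enters the shape
analysis, halving the redundant coordinate count.

**Superimposition.** Full generalized Procrustes analysis: every
configuration is centred, scaled to unit centroid size, and rotated by least
squares onto an iteratively re-estimated consensus. Reflections are excluded
by default (specimens have handedness); a flag allows them. Convergence is
declared when the consensus stops moving (max coordinate change < 1e-10,
limit 100 iterations); judging convergence on consensus movement rather than
on the objective matters because the objective is quadratic near the optimum
and would stall at ~1e-5 consensus precision. Procrustes distances are full
Procrustes distances between unit-size centred configurations.

**Integration and score axes.** Escoufier's
RV = tr(S_AB·S_BA)/√(tr(S_AA²)·tr(S_BB²)) and two-block PLS (SVD of the
between-block covariance matrix) both use centred, *unstandardized*
covariance matrices — the standard choice for Procrustes coordinates, and the
convention that reproduces the packaged census-table worked examples exactly.
Permutation tests shuffle the row correspondence of one block and use the
add-one estimator p = (b + 1)/(n + 1), so p is never exactly zero. The PLS1
score plane (dorsal, lateral) and the SVL–HeadCS plane are each summarized by
the dominant axis of an unstandardized PCA of the two score columns — a major
axis line. Axis signs are pinned by covariates: `PC1_shape` is oriented so
cannibal-labelled specimens score low (tetragonal head, shallow fin at the
low end), `PC1_size` so larger animals score high.

## Population statistics

Each high-density tank is a population with census vector **X** = (x₁, x₂)
(cannibals among survivors, victims = initial − survivors). Solitary
specimens are pooled into a single hypothetical zero-interaction population
(`sol`, x₁ = x₂ = 0). Per population, **Y** = (y₁, y₂, y₃) collects the
Pearson correlation of the joint (PC1_size, PC1_shape) distribution and the
moment skewness of each margin. Skewness defaults to the population form
g₁ = m₃/m₂^{3/2} with 1/n moments; a bias-corrected variant
(√(n(n−1))/(n−2)·g₁) is available, since the two are not distinguishable
against the published per-tank values without the raw specimen data.

**SMA.** The standardized major axis slope is sign(cov)·SD(y)/SD(x) through
the bivariate mean (the true major axis is also provided; the published
census line is reproduced by the SMA form, which is therefore the default
reproduction path). The common-slope test minimizes
−Σnᵢ·ln(1 − corr²(y − bx, y + bx)) over b (bounded scalar minimization,
tolerance 1e-10, ≤ 200 iterations) and refers the minimum to χ²(g−1). The
elevation test is a Wald test of aᵢ = ȳᵢ − b·x̄ᵢ given the common slope; the
elevation covariance matrix includes the off-diagonal terms
x̄ᵢx̄ⱼ·var(b̂) induced by the shared slope estimate — omitting them makes the
test severely conservative (empirical size ~0.4% instead of 5%).

**Planned-contrast ANOVA.** One-way ANOVA across victim-count-keyed
populations, with two decompositions of the among-group SS: (i) a 1-df
group-size-weighted linear regression of group means on victim count plus
the (g−2)-df deviation from regression, the regression term being tested
against the deviation mean square and all other terms against the
within-group mean square (the mixed testing scheme of the original analysis);
(ii) the 1-df Solitary-vs-rest contrast plus the (g−2)-df variation among
nonzero-victim groups. SS additivity within each decomposition is exact by
construction (the remainder is computed as a difference).

## Model selection

All fits are Gaussian least squares with
AIC = n·ln(2π·RSS/n) + n + 2(k + 1), where k counts mean-structure
coefficients as reported in comparison tables and the +1 is the residual
variance; ΔAIC and Akaike weights are invariant to this constant. RSS is
floored at n·(1e-9·max|y|)² before the logarithm: models that interpolate
the data to machine precision would otherwise be ranked by the accidental
ordering of floating-point residues rather than by parsimony.

Nonlinear curves (asymptotic a + b(1 − e^{−c·x₂}) and power a + b·x₂^c, with
0^c ≡ 0) are fitted by bounded trust-region least squares from a grid of 25
starts over c ∈ [0.01, 5], with the b sign seeded from the data trend. The
six exploitation/interference models are OLS fits on the covariates listed
in the README; the "largest cannibal" per tank is the maximum `PC1_size`
holder. Censuses in which a design is unidentifiable (e.g. constant cannibal
counts making the x₁ column collinear with the intercept) drop that model
from the comparison with a warning.

A property worth knowing when reading the recovery tests: for generating
models that are nested inside a competitor (Models 3 and 4 are nested in
Models 5/6), plain AIC over-selects the larger competitor with a
probability that does not shrink with the noise level (it is the scale-free
tail probability of the incremental F statistic crossing the 2-point
penalty, roughly 16–22% per nesting competitor at n = 10 tanks). Recovery
is therefore near-certain only for exact responses or non-nested generating
models (Model 6); under noise the nested scenarios recover at ~60%, which
the test suite documents rather than hides.

## Cannibal screen

Hard evidence (a conspecific visible in the stomach; the enlarged-jaw visual
call) fixes cannibal seeds. Self-training starts from the seeds plus
provisional calls from the classical jaw-width/head-width rule
(JW1/HW > 0.9, strict inequality) and iterates a linear discriminant on the
seven head dimensions, SVL, JW1/HW and HW/SVL until labels stabilize
(≤ 20 rounds); provisional calls may flip, seeds may not. Balanced class
priors are used because the seeds are a sparse, biased sample of the
cannibal class — frequency priors would anchor the boundary at the seed
rate. With no seeds at all the ratio rule decides alone. The classifier
backend is pluggable (any `fit`/`predict_proba` object).

## Synthetic-data generator

The generator emulates the density-manipulation design: 10 tanks × 30
larvae plus 30 pooled solitary animals (defaults). Per tank it draws the
victim count x₂ uniformly on 1–9 (matching the observed range and
approximately the observed mean/SD), recruits cannibals as
x₁ = 1 + Binomial(x₂ − 1, 0.35) capped at 6 (yielding the observed 1–6 range
and a positive x₁–x₂ coupling), and partitions victims among cannibals by a
Dirichlet-multinomial with concentration 0.5 — small concentrations give one
dominant consumer, mirroring the exclusive-exploitation regime, and the
parameter spans egalitarian → fully exclusive so the model-selection stage
can be tested against known ground truth.

Two latent scores drive each specimen. Size s is standard normal plus
1.2 per victim consumed; under the high-density integration rule
shape = 0.2 − 0.4·s + N(0, 0.45²), so larger animals express a more
cannibal-like shape and tanks with more victims develop stronger negative
size–shape correlation and right-skewed size — the published sign pattern
emerges rather than being imposed. Solitary specimens draw shape
independently of size (mean −0.1, SD 0.3, between the cannibal and
noncannibal means). Landmarks are template outlines (dorsal: 19 bilateral
pairs + 1 midline point, 9 fixed + 10 semilandmark pairs; lateral: 20
points, 8 fixed + 12 semilandmarks) deformed along two fixed basis vectors —
anterior head widening and dorsal-fin shallowing — by the negated shape
score (plus an independent per-view deviation, SD 0.35, so dorsal–lateral
integration is strong but not perfect), scaled by 10 mm·(1 + 0.06·s), with
isotropic digitizing noise (SD 0.004 template units). The linear
measurements (HW, JW1 … SVL) are read geometrically off the deformed
landmarks, so landmark and measurement views of a specimen are consistent
by construction.

What the generator does *not* emulate: temporal attack sequences and growth
trajectories (only the end-state census and morphology), caudal-fin damage,
digitizing operator error beyond isotropic noise, measurement-landmark
mismatch, and between-clutch genetic structure. Passing recovery tests
therefore show that the pipeline's statistics recover the latent
integration structure they target under the stated noise model — not that
real photographs would be digitized consistently.

## Problem sizes used in the test suite

Simulation-based tests use 100–500 replicates per claim (500 for test-size
calibration of the SMA identity tests and the ANOVA contrasts, 200 for
permutation-null uniformity, selection consistency and screen recovery),
with permutation counts of 49–999 inside replicates; the packaged
census-table computations are exact single evaluations. These sizes give
Monte-Carlo standard errors comfortably below the asserted tolerances
(e.g. ±1% on a 5% rejection rate at 500 replicates).

## Known limitations

- Procrustes-coordinate CVA requires dimension reduction; the default
  (axes covering 95% variance, capped at n − g − 1) is a pragmatic
  MorphoJ-style choice, and canonical structure close to the cap is
  unstable.
- The elevation test's slope-variance term uses the large-sample SMA
  variance; at very small group sizes (< ~15) the test runs slightly
  conservative.
- The screen's monotonicity in jaw width holds for the rule path and
  empirically for well-separated clusters, but is not a formal guarantee of
  the LDA path.
- The order of operations fixes symmetrization before superimposition;
  symmetrizing aligned coordinates instead would give slightly different
  Procrustes distances, and no published value is available to discriminate
  between the two orders.
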