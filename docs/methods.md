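# Methods

## The compositional model

A participant's day is a 4-part composition of minutes in sleep, sedentary
time (SED), light physical activity (LPA) and moderate-to-vigorous physical
activity (MVPA), closed to 1440. All analysis happens in Aitchison geometry:
closure (rescaling to a fixed total), perturbation (part-wise product),
the compositional geometric mean as the centre, and the variation matrix
$t_{ij} = \operatorname{var}[\ln(x_i/x_j)]$ as the co-dependence summary
(sample variance with the $n-1$ denominator, matching common CoDA software).
Zero minutes in any behaviour are a hard error in the core layer; an
explicit multiplicative-replacement pre-step (default floor 1 min) is
offered in the processing layer for datasets that need it.

ILR pivot coordinates map the simplex isometrically to $\mathbb{R}^{3}$.
With parts in pivot order, coordinate $k$ contrasts part $k$ against the
geometric mean of the parts after it; the first coordinate is therefore
"pivot behaviour vs all remaining behaviours", and a positive value means
relatively more time in the pivot. Rotating each behaviour into the pivot
slot yields four orthonormal bases of the same 3-dimensional space; any two
are related by an orthogonal map, which is why fitted values, residuals,
$R^2$ and joint tests are rotation-invariant and only the coefficient
vector's expression changes. The canonical part order is
(sleep, SED, LPA, MVPA); under rotation the pivot moves to the front and
the remaining parts keep canonical order — only the first coordinate is
interpreted, so the tail order is a reproducibility convention, not a
modelling choice.

## Movement processing

Intensity is classified from ENMO (milli-g) with adolescent wrist
cut-points: SED < 35.6, LPA [35.6, 201.4), MPA [201.4, 707.0),
VPA ≥ 707.0; MVPA = MPA + VPA. Published versions of these cut-points
sometimes print 707.7 for the MPA/VPA boundary; we read that as a
typographical variant of 707.0 and use left-closed upper intervals
throughout so the classifier is a total monotone step function. A day is
valid iff wear time ≥ 16 h and sleep > 0 min; a participant is retained iff
≥ 3 valid days. The analysed composition averages raw minutes across valid
days *first* and closes to 1440 afterwards, so arithmetic means stay on the
raw-minute scale used descriptively. Days run midnight-to-midnight, and
sleep arrives as a per-day field (upstream sleep-detection algorithms are
out of scope). Exclusions are tallied in a flow object whose counts always
reconcile (enrolled = final + Σ exclusions). An optional flag to accept
upstream-imputed full weeks instead of valid-days-only exists at the
ingestion boundary; the default is valid-days-only.

## Wellbeing scoring

EPOCH has 20 positively-worded items on a 1–5 frequency scale, four per
domain; each domain score is the plain item mean (no reverse coding), hence
bounded in [1, 5] and monotone in every item. Any missing or out-of-range
item invalidates the whole sheet — participants are excluded, not imputed,
matching the inclusion-flow semantics. Some published tables describe the
scale range as 0–5; we code 1–5, consistent with the five labelled response
options. The item→domain mapping ships as configuration because instrument
item order varies across administrations; the default is a clearly-labelled
synthetic placeholder (items 1–4 → engagement, …, 17–20 → happiness).

## Synthetic cohort

The generator's defaults are the study conditions the package is built
around: n = 124 analysed adolescents in 7 school clusters, ages ~N(14.8,
1.0) clipped to [13, 17], gender mix 49.2% male / 46.0% female / 4.8% other
(the "other" category is excluded from regression, as such studies do).
Compositions are logistic-normal — ILR coordinates drawn from a
multivariate normal centred at the ILR image of the published centre day
(sleep 473.0, SED 680.9, LPA 250.7, MVPA 35.3 min) — the natural generative
conjugate of the linear-in-ILR analysis model. The ILR covariance is
constructed from a target variation matrix via
$\Sigma_{\mathrm{clr}} = -\tfrac12 G T G$: the three sleep/SED/LPA pairs use
the published log-ratio variances (0.054, 0.063, 0.088) and the MVPA pairs,
unpublished, are set to 0.38–0.46 — large enough to keep MVPA the most
compositionally distinct behaviour and consistent with the published
arithmetic-vs-geometric MVPA gap (42.1 vs 35.3 min).

Outcomes follow
$y = \mu_d + (z - \bar z)^\top\beta_z + (a - \bar a)\beta_{\text{age}}
+ (\text{female} - p_f)\beta_{\text{sex}} + u_{\text{school}} + \varepsilon$,
with domain means at published levels (3.39–4.35), $\beta_{\text{age}} =
-0.05$/yr, $\beta_{\text{sex}} = -0.10$, school random intercepts
(SD 0.15) on outcomes only, and residual SD 0.60 (chosen to put domain SDs
near the published 0.7–0.9 once compositional and covariate variance is
added). Covariates are centred so the configured domain means are the
population means regardless of effect sizes. The default compositional
effect is null for four domains; for happiness the centred (clr-scale)
gradient is (−0.23, −0.96, +1.04, +0.15) over (sleep, SED, LPA, MVPA) — the
sum-zero projection of plausible pivot-scale coefficients. This plants the
qualitative structure the pipeline should detect (LPA up, SED down, others
null); magnitudes are illustrative, not calibrated to any dataset. Item
responses are the domain score plus N(0, 0.25) noise, rounded and clipped
to 1–5, which leaves ~99% of rescored domain means within half a scale
point of their target. All randomness flows through
`numpy.random.default_rng` (PCG64); a seed fixes every emitted file
bit-for-bit.

What the generator does *not* emulate: measurement error in the
accelerometer pipeline (epoch misclassification, non-wear misdetection),
compositional confounding by school or demographics (compositions are drawn
independently of both), item-level factor structure beyond a common domain
mean, and selection effects in who fails the wear criteria (excluded
participants are drawn from the same composition distribution). Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated model — not that the model captures every
feature of field data.

## Estimation and inference

Point estimates are OLS. Inference uses the CR1 cluster-robust sandwich by
school with small-sample scaling, referenced to $t_{G-1}$ (G = number of
schools), the standard few-cluster correction; a mixed-effects alternative
is deliberately out of scope. The joint "model p" is the cluster-robust
Wald test of all non-intercept coefficients. Naive OLS standard errors are
retained alongside for comparison. Significance is two-sided α = 0.05 with
no multiplicity correction — conventional in this literature, and a known
limitation given 4 rotations × 5 outcomes and 60 reallocation cells.
Design-matrix rank is checked before fitting (collinear columns are named);
gender enters as a two-level indicator (reference male) after dropping
other categories with a logged count; models require ≥ 2 clusters, ≥ 2
gender levels and parameters + 2 complete cases. Residual diagnostics
(Shapiro–Wilk, Breusch–Pagan, VIFs) are reported but never trigger
refitting.

In simulation at the defaults, this machinery is well calibrated: type-I
error of the pivot coefficient ≈ 5% at the study's own scale (n = 124,
7 schools, school effects present), and 95% CI coverage ≈ 95% in the
large-sample/many-cluster regime (n = 2000, 25 schools) — both recomputed
by `scripts/acceptance.py` (1000 and 200 replicates respectively; sizes
chosen to keep Monte-Carlo error a fraction of the tolerance while the full
suite stays fast).

## Reallocation

The engine moves δ minutes (default 30) from one behaviour to another at a
base composition, by convention the analysed sample's compositional
geometric mean closed to 1440 — the standard reference day. The predicted
difference is the inner product of the ILR displacement with the fitted ILR
coefficients (covariates cancel); its variance is the quadratic form in the
cluster-robust coefficient covariance, and CIs use the same $t_{G-1}$
reference as the fit. Feasibility requires δ < the donor part's minutes.
Because the ILR map is nonlinear, A→B and B→A differences are antisymmetric
only to first order in δ (the mismatch shrinks ~quadratically as δ → 0);
this is a property, not a bug, and is tested rather than "corrected". The
grid reports all 12 ordered pairs × 5 domains, flags cells whose CI
excludes zero, and emits both the per-δ and per-minute scales, since
published tables in this literature are not always explicit about which
scale a cell is on.

## Numerical conventions

Closure tolerance 1e-9 relative; ILR round-trips are exact to ~1e-13 in
practice and tested at 1e-9/1e-10. Display rounding is 1 d.p. for minutes
and percentages, 3 d.p. for coefficients; JSON payloads keep full
precision. PSD covariance factors use an eigendecomposition with negative
eigenvalues below −1e-10 rejected (so a zero covariance — degenerate but
legal — generates a point mass at the centre). Percentage shares after
1-d.p. rounding may sum to 100.0 ± 0.1; no largest-remainder adjustment is
applied.
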