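# Methods

## The model

`bcfkit` analyses uptake-phase bioconcentration experiments on small aquatic
organisms (the design it targets: zebrafish eleutheroembryos exposed to a
mixture of ionizable pharmaceuticals for 48 h under semi-static renewal).
The body burden `Cf` (ng/g wet weight) of an organism in water at
concentration `Cw` (ug/L) is modelled as a single well-mixed compartment
with first-order exchange:

    dCf/dt = k1 * Cw(t) - k2 * Cf,        Cf(0) = 0

with `k1` the uptake rate constant (L kg^-1 h^-1) and `k2` the elimination
rate constant (h^-1).  Under the standard constant-water assumption the
uptake phase has the closed form `Cf(t) = (k1/k2) Cw (1 - e^(-k2 t))` and
the depuration phase `Cf(t) = Cf0 e^(-k2 t)`.  Two bioconcentration factors
follow, both in L/kg because of the ng/g-over-ug/L unit convention:

* `BCF_k = k1/k2` — the kinetic estimate, valid whether or not the exposure
  reaches steady state;
* `BCF_48h = Cf(t_end) / mean(Cw)` — the end-of-exposure ratio, which equals
  `BCF_k` only once the plateau is reached (the two agree within ~1% when
  `k2 * t_end >= 5`).

The `k2 -> 0` limit is handled by the exact series limit (`Cf = k1 Cw t`),
never by dividing by zero, and `BCF_k` is reported as undefined (a dedicated
error) when `k2 = 0`.

## Fitting

For fixed `k2` the model is linear in `k1`, so the least-squares problem is
solved by variable projection: `k1(k2)` has a closed form (clipped at 0) and
the fit reduces to a 1-D minimization of the profiled SSE over `log k2`.  A
coarse log-spaced grid (default 60 points over `k2 in [1e-5, 10] /h`) seeds
a bounded Brent refinement (`xatol = 1e-12` on `log k2`).  Grid ties resolve
to the lowest SSE and then to the lowest `k2`; an optimum pinned at a search
boundary is reported with `converged=False`, never silently.  This search
cannot diverge, recovers noise-free parameters to ~1e-9 relative, and is
fast enough to sit inside a bootstrap inside a Monte-Carlo study.

Choices that matter:

* **Water concentration during fitting.**  Default `cw_mode="mean"`: `Cw`
  is held at the arithmetic mean of the uncensored water measurements over
  the exposure, matching the usual reporting convention (`Cw` as mean ± sd).
  `cw_mode="stepwise"` instead integrates the model against a previous-value
  step interpolation of the measured profile (segment-analytic, exact for
  genuinely piecewise-constant water).  Note that sampling the medium just
  before each renewal makes the step profile miss the renewal jumps, so
  stepwise mode is not automatically less biased on sawtooth-driven data.
* **Weighting.**  Unweighted residuals on raw concentrations, all replicate
  points entering individually (no pre-averaging).  A `1/yhat` weighting
  option exists (refined with derivative-based least squares started from
  the unweighted optimum) for strongly heteroscedastic data.
* **Censoring.**  Below-LOD body burdens are excluded from the fit;
  below-LOQ-but-above-LOD values are kept, flagged.  Measured t=0 samples
  are controls/QC material, never fit data — the model pins `Cf(0) = 0`.
* **Known mismatch bias.**  Fitting the constant-`Cw` closed form to data
  driven by a decaying sawtooth profile inflates `k1` and `k2` together
  (about +16% each at a decay of 0.01/h) while their ratio `BCF_k` stays
  nearly unbiased (about -2%).  The ratio is what the 48-h design
  identifies robustly; reported `k1`, `k2` should be read with this in
  mind when the water profile is visibly non-constant.

## Uncertainty

`bootstrap_uncertainty` case-resamples, with replacement, the replicate
measurement points of *both* series: the body-burden points that enter the
fit and the uncensored water measurements behind the mean exposure
concentration.  The water component matters: `BCF_k` scales as `1/Cw`, and
with five water samples at 10% CV the mean carries ~4.5% relative error —
omitting it produces severely anticonservative intervals (measured coverage
drops from ~92% to ~65%).  Each resample is refit (single-start, coarser
grid, seeded from the resample RNG); degenerate resamples (fewer than two
distinct positive times) are skipped and counted.  Percentile intervals at
the requested level (default 90%) are reported for `k1`, `k2`, `BCF_k`;
`B < 100` triggers a warning.  Everything is deterministic under a fixed
seed.

## Steady-state detection

An exposure is declared steady when (1) the replicate-mean burdens at the
last two sampling times differ by at most the tolerance (default 20%,
relative to the earlier mean), and (2) whenever at least three positive-time
means exist, a shape-only fit of `B (1 - e^(-k2 t))` estimates a plateau
fraction `1 - e^(-k2 t_end)` of at least one minus the tolerance.  The
second condition guards against slow, nearly linear uptake whose late
samples happen to lie close together while the curve is still far from its
plateau (e.g. `k2 = 0.005/h` gives a 5.9% last-interval change but only 21%
of plateau at 48 h).  With only two sampling times the guard cannot be
evaluated and the first condition decides alone.

## Speciation and classification

All analytes are treated as monoprotic bases (the amine chemistry of SSRIs
and their N-desmethyl metabolites): the neutral fraction at pH `p` is
`1/(1 + 10^(pKa - p))` and the distribution coefficient is
`log D = log Kow + log10(neutral fraction)`.  The built-in panel carries the
published pKa / log Kow constants for the seven analytes; at the assay pH of
7.8 the computed log D column reproduces the published values to two
decimals for six of them.  The seventh (desmethylcitalopram) is a known
inconsistency in the source data: its own constants (pKa 10.54, log Kow
3.38) give log D 0.64, not the printed 0.14; the formula is treated as
authoritative and the discrepancy is asserted in the tests rather than
papered over.  Regulatory classification is strict: `BCF > 2000` L/kg is
"bioaccumulative", the boundary value itself is not.

## Trend testing

Metabolite-to-parent ratios are computed on replicate means per sampling
time (one ratio per time point, matching how such tables are reported);
a time point with a censored or non-positive parent mean yields an
*undefined* ratio, flagged, never fabricated, while a fully censored
metabolite counts as concentration zero.  Monotone trend is assessed with
the Mann-Kendall test.  P-values are exact where it matters: with no ties
the null distribution of S comes from the inversion-count recurrence (any
n); with ties and `n <= 8` it is enumerated over all orderings of the
observed multiset; larger tied samples use the tie-corrected normal
approximation with continuity correction.  The direction call uses the
exact one-sided tail toward the observed S at alpha = 0.05: with the usual
four sampling times a perfectly monotone course reaches p = 1/24 one-sided,
whereas no four-point course can reach p < 0.05 two-sided (minimum 1/12) —
so any claimed "significant increase" at n = 4 is necessarily a one-sided
statement.  Kendall's tau-b is reported (0 by convention for an all-tied
sequence).

## Synthetic experiments

The generator emulates the study design, and its defaults are the study
conditions: nominal exposure 300 or 80 ug/L; medium refreshed every 24 h
with exponential loss (default 0.01/h) between renewals — the sawtooth is
sampled *before* each refresh; sampling at {0, 6, 24, 45, 48} h; three
replicate pools of 20 individuals; multiplicative lognormal measurement
noise with mean exactly 1 and 10% CV (anchored to the analytical method's
~10% reproducibility); LOD/LOQ censoring at 0.3/1 ug/L (water) and 6/21
ng/g (organisms).  True body burdens are the segment-analytic solution of
the governing ODE against the noise-free sawtooth (no discretization
error); metabolite burdens add a first-order internal conversion
`dM/dt = conversion_k * Cf_parent - k2_met * M` integrated numerically at
tight tolerance.  The conversion mechanism is test scaffolding for ratio
kinetics, not a calibrated biotransformation model.  Per-analyte true
(k1, k2) defaults are set to the magnitudes the study reports (BCF_k ~150
for sertraline down to ~0.7 for desmethylcitalopram), with only sertraline
eliminating fast enough (`k2 = 0.08/h`) to approach its plateau within 48 h.

What the generator does *not* emulate — hence what passing recovery tests do
not show about real data: inter-individual variability within a pool,
organism growth over the exposure, saturable (concentration-dependent)
uptake of ionizable compounds, pH drift, matrix effects on recovery, or
correlated analytical errors between analytes measured in one run.

The Monte-Carlo recovery study runs 200 simulated experiments under the
design above with truth `k1 = 20, k2 = 0.1` (BCF_k = 200, ~99% of plateau
at 48 h) and 200 bootstrap resamples per experiment — sizes chosen to give
~2-percentage-point Monte-Carlo error on coverage while the whole study
completes in well under a minute on one CPU.  Typical results: median
absolute BCF_k error ~4%, 90%-interval coverage ~92%.

## Numerical details

* `(1 - e^(-k2 t))/k2` is computed with `expm1`; `k2 = 0` takes the exact
  limit `t`.
* Lognormal noise uses `sigma^2 = ln(1 + cv^2)` with mean correction, so the
  noise factor has mean exactly 1 at any CV.
* The exact Mann-Kendall null uses integer (object-dtype) convolution, so
  counts are exact at any n where it is invoked.
* OLS outlier flagging short-circuits on numerically perfect fits
  (SSR <= 1e-12 * SS_tot), where studentized residuals are 0/0 noise; nan
  studentized residuals map to "not an outlier", +/-inf to "outlier".
* All stochastic operations take a single integer seed; nothing reads
  global RNG state.  Reports carry a config hash + seed + version
  provenance block and are byte-identical across reruns.

## Limitations

Depuration-phase fitting is out of scope (the closed form is implemented
for simulation and testing only); growth dilution and lipid normalization
corrections are not applied; speciation is monoprotic-base only; the
regression of log BCF_k on log D pools whatever fitted records are supplied
and does not model exposure level as a covariate.
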