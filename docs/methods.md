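# Methods

`tracerkin` analyses dual-isotope, terminal-sampling tracer studies of the
kind used to characterise the circulation time and tissue influx of peptide
therapeutics in rodents: a radiolabelled ligand (~1e6 cpm) is co-injected
intravenously with a vascular marker (radiolabelled albumin, ~5e5 cpm), each
animal contributes one terminal serum sample (cpm/ml, with the injected dose
recorded) and paired tissue samples (cpm/g) at a single time between 0.5 and
225 min, and the concentration–time curve is assembled across animals.

## Noncompartmental terminal phase

Serum activity is expressed as percent of injected dose per ml
(%Inj/ml = 100·activity/dose) for display; fits use raw cpm/ml because the
log-linear slope is scale-invariant. The terminal phase is estimated by
unweighted OLS of log10(C) on time within a window:

    t_half = log10(2) / |m|  =  ln 2 / k,     k = |m|·ln 10,

with the constant carried at full floating precision (0.301 and 0.693 are its
3-decimal roundings). Two-point fits are allowed with an explicit warning
flag (short early windows are common for rapidly cleared ligands); they carry
no residual degrees of freedom, so the slope SE is NaN. Window selection is
normally manual (windows are always echoed in output); an automated surrogate
returns the longest suffix of distinct times whose fit has negative slope and
r² above a threshold (suffixes are nested, so the choice is deterministic).

Animals sharing a nominal time can be pooled before the fit (geometric mean,
i.e. averaging after log transformation) or regressed individually
(equivalent slope when groups are balanced, but times with more animals get
more weight). The default regresses individual animals; both are exposed
because the averaging order is a genuine free choice in this design.

## Exposure time and Patlak multiple-time regression

For unidirectional uptake, tissue activity per gram follows
Am(t) = Ki·∫₀ᵗCp dτ + Vi·Cp(t). Dividing by Cp linearises it on the
clearance-corrected time axis Expt(t) = ∫₀ᵗCp dτ / Cp(t):

    Am/Cp = Ki·Expt + Vi,

with Ki in µl/(g·min) (serum cleared into tissue) and Vi in µl/g (vascular
space plus rapid reversible binding). Tissue/serum ratios are reported in
µl/g (ml/g × 1000). The co-injected marker is assumed not to cross the
barrier (Ki = 0); subtracting its ratio — same animal by default, same
nominal time (marker ratios averaged) as a fallback — gives the delta T/S
that is regressed. Negative deltas are retained; truncation would bias Vi.

Because sampling is cross-sectional, Expt is computed from the pooled group
serum curve, not per animal. Two routes are provided:

- **trapezoid** (default): the pooled curve (geometric aggregation over
  duplicate times) is interpolated log-linearly (exponential segments,
  appropriate for concentrations spanning orders of magnitude), Cp is
  back-extrapolated to t = 0 from the first two samples (a bolus dose has
  finite Cp(0); disable with `extrapolate_t0=False`, which starts the
  integral at the first sample), and the AUC is a trapezoid sum on a dense
  grid (step = min(0.01 min, smallest gap/100)). Robust for arbitrary curve
  shapes; on a biexponential sampled at 8 points its interpolation error is
  of order 0.1–1%, which propagates into Ki at a similar size.
- **fitted-model**: a mono/biexponential input function is fitted to all
  individual serum points by least squares on log concentrations
  (curve-peeling initialisation, Levenberg–Marquardt polish) and integrated
  in closed form. On data that are truly (bi)exponential this is essentially
  exact — noise-free simulated studies recover Ki and Vi to machine
  precision — and it is the route used for the reproducibility script.

The Patlak fit itself is unweighted OLS of delta T/S on Expt within an
exposure-time window (the "linear portion"; an automated surrogate takes the
longest prefix with r² above a threshold, since saturation or efflux bends
the late points). Simple regression is computed with centered normal
equations rather than a generic QR solver so that degenerate limits are
exact: a flat (marker-like) response yields slope exactly 0.0 with zero
residuals. The test suite cross-checks all outputs against an independent
library OLS and longhand textbook formulas.

### Uncertainty of Ki and Vi

When the input function is estimated from the same study, its uncertainty
shifts every Expt value coherently — an error no residual-based SE can see.
With the fitted-model route the log-parameter covariance of the input
function (standard nonlinear-LS covariance on the log-domain residuals) is
propagated into the exposure times and then, by the delta method, into the
slope and intercept; this term is added in quadrature to the textbook OLS
SEs. It vanishes for noise-free data. In simulation (10% multiplicative
noise, 4 animals per time, 8 times) the resulting 95% CI for Ki attains
~94–96% empirical coverage, versus ~86% for the naive residual-only SE.

Known residual limitations: the tissue/serum ratio of lognormal counts
carries a small multiplicative bias (E[e^(εA−εC)] = e^(σ²) ≈ +1% at 10% CV)
that propagates into Ki; late points have proportionally larger noise
(heteroscedasticity) that unweighted OLS does not exploit; and the group
comparison tests below ignore input-function uncertainty.

## Comparing two Patlak fits

Fits carry their sufficient statistics (n, means, Sxx, Sxy, Syy, RSS), so
two fits — including fits re-loaded from JSON — can be compared without raw
data, following the textbook tests that commercial curve-fitting software
documents for comparing regression lines:

- slopes: t = (Ki_A − Ki_B)/SE with pooled residual variance,
  df = n_A + n_B − 4;
- intercepts: from the common-slope (ANCOVA) model, df = n_A + n_B − 3,
  flagged *conditional* when the slopes already differ at α (default 0.05),
  because the common-slope premise is then rejected by the data;
- correlations: Fisher z with SE = √(1/(n_A−3) + 1/(n_B−3)); omitted with a
  flag when either n = 3 or |r| = 1 in only one group.

Noise-free degenerate limits are reported explicitly: identical fits give
t = 0, p = 1; different exact lines have zero pooled variance, reported as
p = 0 with an infinite-t flag. Exact equivalence to any specific commercial
implementation is not claimed.

## Pharmacodynamic quantification

Phospho/total signal ratios are normalized to the arithmetic mean ratio of
the reference-time (t = 0) samples, pooled across treatment arms by default
(per-arm pooling is an option and errors if an arm lacks baseline samples).
Normalization is idempotent. Tolerance tests are summarised as the total
trapezoidal AUC of glucose versus time (mg·min/dl) over the measured
interval, with no baseline subtraction; times must be strictly increasing.

## The simulator and what it does (not) emulate

`simulate_study` generates a full dual-tracer study with known ground truth:
biexponential serum decay Cp(t) = A1·e^(−λ1 t) + A2·e^(−λ2 t) in %Inj/ml
(A2 = 0 for monoexponential), tissue uptake from the forward model
Am = (Ki·AUC + Vi·Cp)/1000 cpm/g using the closed-form antiderivative, a
marker arm with Ki = 0, cross-sectional sampling (each animal appears at
exactly one time; the tissue rows reuse that animal's serum realization as
their denominator, as one serum sample serves both purposes in a terminal
study), and mean-unbiased multiplicative lognormal noise: each measured
quantity is multiplied by e^ε, ε ~ N(−σ²/2, σ²), σ² = ln(1 + cv²). An
optional Poisson stage models gamma-counting noise on raw cpm. All
randomness flows from one seed; identical configs give byte-identical CSVs.

Two preset conditions mirror the in-vivo designs the analysis targets:

- `insulin_like_config`: biexponential (48.9, 0.1 min; 1.1, 1.8 min) %Inj/ml,
  sampled at 0.5–10 min. The amplitude split places the apparent (0.5–3 min)
  half-life near 1 min and the 1.5–3 min window near the 1.8 min slow phase.
- `slow_ligand_config`: biexponential (39.2, 4 min; 2.8, 556 min), sampled at
  8 times over 0.5–225 min, 4 animals per time, 10% noise, Ki = 0.5
  µl/(g·min) and Vi = 10 µl/g for whole brain, marker Vi = 10 µl/g. The
  split places the full-window apparent half-life near 58 min with a
  terminal (slow-phase) half-life of 556 min (~9.3 h).

Defaults (dose 1e6 cpm ligand / 5e5 cpm marker, Cp(0) ≈ 50%Inj/ml ≈ dose
distributed in ~2 ml plasma, albumin marker t½ 1600 min) are chosen to be
physiologically plausible for a mouse study of this type.

What the simulator does **not** emulate: per-animal biological variation in
kinetic parameters or vascular volume (noise is purely multiplicative
measurement error, so by-animal and by-time marker pairing give identical
point estimates here, which is not guaranteed in real data); efflux,
saturation or metabolism (uptake is strictly unidirectional, so linear-
portion selection is only exercised on synthetic plateaus); subcutaneous
absorption; whole-body physiology. Passing tests therefore demonstrate
correctness of the estimators under the stated error model, not robustness
to model misspecification in real data.

A caution illustrated by the simulator: with only three sampling times at or
beyond 60 min, the terminal slope of a 556-min phase spans only ~0.09 log10
units, so at 10% measurement noise the terminal half-life estimate from one
32-animal study scatters widely (roughly 300–600 min across seeds). The
apparent (full-window) half-life, the Patlak Ki and the PD quantities are
much more stable.

## Numerical choices

- Exposure-time grid: step = min(0.01 min, smallest gap/100); knots and
  evaluation times are inserted into the grid so interpolation at them is
  exact. Expt(0) = 0 by definition.
- Input-function fitting accepts a monoexponential outright when its maximum
  log-residual is below 1e-10, and falls back from biexponential to
  monoexponential when the extra phase does not reduce the maximum
  log-residual; optimizer overflow excursions are penalised, not raised.
- Duplicate nominal times: geometric aggregation by default everywhere a
  single-valued curve is required; single-point groups pass through
  unchanged (bit-exact).
- JSON outputs carry full round-trip precision; human summaries round to 3
  decimals. Every CLI analysis output embeds a run manifest (command line,
  SHA-256 of inputs, seed, package version, timestamp — the only field that
  varies between identical runs).
- Problem sizes in the test suite and reproducibility script (500 simulated
  replicate studies for the recovery experiment, 100 seeded datasets for the
  oracle-equivalence checks) keep each run in seconds on a single core while
  leaving Monte-Carlo error on the reported medians/coverages well below the
  widths of the bands being checked.
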