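# Methods

## The quantification model

The measured quantity for each analyte in each injected sample is the
**isotope-dilution response**

    R = A(12C) / A(13C ISTD),

the ratio of the analyte's quantifier-transition peak area to the area of a
co-analyzed uniformly ¹³C-labeled internal standard. Because both species
co-elute and ionize together, matrix suppression/enhancement and
injection-to-injection variability are common-mode and cancel in the ratio.
Analytes that are too low-abundance in labeled cell extract to give a usable
¹³C channel (NCA, 1-mNAM, NMN, ADPR) are ratioed against the ¹³C channel of a
structurally similar, closest-eluting panel member instead (NAM, NR, NAMN and
NADH respectively); NAAD is monitored but not quantified (see Crosstalk).

**Matrix-matched calibration.** External standards are prepared in pooled
biological matrix, so every standard carries the matrix's endogenous analyte
signal. The mean response of matrix-only blanks is subtracted per analyte
from the standard responses before regression (mean rather than median: the
subtraction then commutes with the least-squares fit, and a constant
background provably leaves slope and intercept unchanged). Negative
corrected responses are clipped to zero and flagged. Unknown samples are
*not* blank-subtracted — their endogenous signal is the measurand.

**Calibration fit.** Response vs nominal added concentration over twelve
levels spanning 50–10,000 nM, duplicate injections retained as individual
points. The default is 1/x-weighted least squares. MRM area noise is close
to constant-CV, so residual variance grows with concentration; over a
200-fold range an unweighted fit lets the top standards dominate and leaves
the intercept uncertain by tens of nM on the concentration scale — enough to
swamp low-abundance analytes and inflate low-QC imprecision (in our
simulations, unweighted fitting raised the 250 nM QC recovery CV from 5.4%
to 8.9% at a 5% technical CV and turned a 4 nM NMN signal into 11 ± 15 nM;
1/x weighting restores both). Ordinary least squares remains available via
`weighting="none"`. R² and the residual SD are reported unweighted. Curves
with non-positive slope are marked rejected and refuse back-calculation.

**Sensitivity (ICH slope method).** LOD = 3.3 σ/S and LOQ = 10 σ/S, with S
the slope and σ the residual standard deviation (n−2 denominator) of a
separate low-range regression (0.78–100 nM, prepared in solvent + ISTD,
fitted unweighted — the response variance is near-constant there). σ is
taken as the residual SD of that regression, the most common reading of the
"standard deviation of the response" in the guideline; it is configurable.
LOQ/LOD = 10/3.3 ≈ 3.03 by construction; the published panel values satisfy
this identity to the printed precision, which the acceptance suite checks.

**Back-calculation and censoring.** x = (R − intercept)/S; negative values
are reported as 0 with a flag. Concentrations below the analyte's LOQ are
censored at the extract (nM) level — LOQ is an instrument-domain quantity,
so censoring happens before any biology-domain conversion — and reported as
`<LOQ`, excluded from means and tests.

**Normalization to biomass.** With dilution factor d, extraction volume
V_e (L), sampled broth volume V_b (L) and cell dry weight X (g/L):

    pool [nmol/gCDW] = (c_extract [nM] · d · V_e) / (X · V_b).

Linear in concentration and dilution; inversely proportional to biomass.

**Outlier screening.** Two-tailed Dixon's Q test (r₁₀ statistic, 95%
confidence) per technical-replicate group, n = 3–30, critical values from
the standard published two-tailed table embedded as constants. One suspect
value maximum per group per pass (the test is defined for a single suspect);
outliers stay in the matrix flagged, excluded from summaries.

## Isotopologue crosstalk

Natural-abundance isotopologue distributions are computed by exact
convolution of per-element multinomial isotope profiles (¹³C 1.07%, ²H
0.0115%, ¹⁵N 0.364%, ¹⁷O 0.038%, ¹⁸O 0.205%, P monoisotopic — IUPAC
representative values, overridable), collapsed to nominal mass shifts
because a unit-resolution triple quadrupole cannot see fine structure. For
NAD⁺ (C₂₁H₂₇N₇O₁₄P₂) the M+1/M+0 ratio is 26.1% — 22.7% from carbon alone,
the rest mostly ¹⁵N — i.e. "about a quarter" of the main signal.

The crosstalk scan flags ordered analyte pairs whose parent ions collide
after a +k nominal shift (k ≤ 3 by default: M+2 covers the NADP⁺-type
collisions, M+3 is negligible) within an m/z tolerance and an RT window,
reporting the source's M+k/M+0 ratio as the predicted interference. The
screen is deliberately parent-m/z-only (conservative): actual bleed-through
also requires a shared product ion, which monitored transitions cannot
decide (NAD⁺ does fragment at 136.1 — the NAAD quantifier — even though
136.1 is not one of NAD⁺'s own monitored products). The pipeline does not
attempt to unmix flagged channels; the compromised channel (NAAD) is
monitor-only.

## Validation metrics

%CV = 100·s/mean (n−1 denominator) and bias% = 100·(mean − nominal)/nominal
per analyte × QC level, intraday per day and interday pooled across days
(mean-of-daily-means available). Acceptance ±20% for both. Bias is skipped
where the calibration matrix's endogenous level exceeds the QC level
(strict inequality) — true for NAD⁺ and NADH against the 250 nM low QC —
because the nominal spike is then not the dominant signal. Stability is
recovery = 100·after/before on paired means; acceptance 75–120%
(freeze–thaw convention), with the narrower 75–115% band annotated for
24 h autosampler storage. Both bands are kept condition-specific rather
than reconciled.

## Kinetics

µ is the OLS slope of ln(biomass) vs time over ≥3 points (exact on
exponential data). Specific rates divide the volumetric rate by the
time-average biomass: the logarithmic mean (x₂−x₁)/ln(x₂/x₁) during
exponential growth (the exact time-average of an exponential; equal
endpoints return the limit), the arithmetic mean during linear growth under
oxygen limitation/anaerobiosis. The same averaging is applied to q_s as to
q_p for consistency. Yield is product formed per glucose consumed between
sampling points, clipped at zero (flagged) for decreasing products. RQ is
CER/OUR from inlet/outlet off-gas fractions, by default under an
equal-dry-flow assumption with an inert (N₂) balance correction available;
RQ is undefined (flagged) when O₂ uptake is not positive, as in an
N₂-sparged anaerobic phase.

## Statistics

Fold changes first average technical replicates within each biological
replicate; log₂FC = log₂(mean_tp / mean_ref) on biological-replicate means,
defined only when both means are positive. Significance: per-analyte
one-way ANOVA, then Tukey HSD pairwise contrasts. Pairwise p-values use the
studentized-range distribution via the standard table interpolation
(statsmodels `psturng`; accurate to ~10⁻³ in the decision region, clipped
to [0.001, 0.9]) — the exact statsmodels implementation is two orders of
magnitude slower and serves as the cross-check oracle in the test suite.
BH-FDR is applied across analytes within each timepoint contrast (the
family is configurable; this choice treats each contrast's panel-wide
screen as one family). Stars: * ≤0.05, ** ≤0.01, *** ≤0.001.

PCA operates on autoscaled data: mean-centered, divided by the
per-variable SD (default) or by √SD (softer, Pareto-like; offered because
both conventions circulate). Zero-variance variables are dropped with a
warning, missing values mean-imputed per variable with a warning; the
decomposition is full-rank, so variance-explained sums to 100%.

Dixon's Q and the redox ratios operate on uncensored, non-outlier records
only; a ratio is skipped for a sample when either member is censored or the
denominator is zero.

## The synthetic generator

The generator emulates the data this pipeline is designed for, with ground
truth exported for recovery tests:

* **Calibration batch**: 3 matrix blanks; 12 standard levels, geometric
  between 50 and 10,000 nM (range and count are the assay design; the exact
  ladder spacing is a generator choice), duplicate injections; QCs at
  250/2500/7500 nM in matrix; low series 0.78–100 nM in solvent.
* **Matrix**: endogenous extract concentrations with NAD⁺ (1200 nM) and
  NADH (400 nM) well above the low QC, precursors low — the configuration
  that makes the bias-skip rule and background subtraction matter.
* **Experiment**: 5 timepoints × 2 biological × 5 technical replicates.
  Baseline pools place the cofactors in the hundreds of nmol/gCDW and the
  precursors ≤100 (NAD⁺ 800, NADH 300, NADP⁺ 150, NADPH 120, FAD 200;
  NMN 1 — deliberately below LOQ to exercise censoring; 1-mNAM 0 —
  undetectable). Planted effects: NADP⁺/NADPH ×0.5 from T2, NCA/NR ×3 from
  T2, ADPR ×2 from T3, NAM ×1.5 at T5, NAD⁺/NADH unchanged.
* **Noise**: multiplicative lognormal (areas are positive and
  heteroscedastic), all unit-mean. A per-sample injection factor (CV 3%)
  multiplies every channel and cancels in the ID ratio; the analyte channel
  carries the technical CV (5%), so the *response* CV equals the configured
  technical CV — keeping "configured CV" interpretable end-to-end.
  Biological CV (10%) perturbs true pools per biological replicate.
  Technical-replicate variance magnitudes in real runs are assay-specific;
  these defaults are design values, not estimates of any particular run.
* **Crosstalk**: when enabled, the NAD⁺ M+1 fraction of the realized NAD⁺
  area is added to the NAAD channel (the physically grounded pair — shared
  136.1 fragment, 0.3 min apart); signal injection is exact, so at zero
  noise the NAAD channel equals NAD⁺ area × M+1/M+0 identically.
* **Physiology**: exponential growth (µ = 0.61 h⁻¹) over the first
  sampling interval, then linear growth; glucose and mixed-acid products
  integrate the configured q_s/q_p against the biomass trajectory
  analytically (sampling boundaries are included in the time grid exactly),
  so the kinetics module recovers the configured rates to numerical
  precision on noiseless data; off-gas fractions encode the per-interval RQ
  (1.0 aerobic, 0.9 at the onset of limitation, undefined when N₂-sparged).

What the generator does **not** emulate: chromatographic trace shape and
integration error, carryover, detector saturation, RT drift within a batch,
real between-day drift, and any correlation structure between analytes
beyond the shared injection factor. Passing recovery tests therefore
demonstrates the correctness of the computational chain under the stated
noise model, not the analytical performance of any instrument.

## Numerical choices and degenerate inputs

* Identical (config, seed) pairs produce byte-identical outputs
  (`numpy.random.default_rng` throughout).
* Censoring uses strict `< LOQ`; a value exactly at the LOQ is
  quantifiable. The bias-skip rule uses strict `>`.
* Dixon's test: zero range → no test; n < 3 → warning, values unchanged;
  ties at the suspect value remove exactly one occurrence.
* ANOVA with zero within-group variance: p = 1 when all means agree,
  p = 0 otherwise (handled explicitly, no division by zero).
* Back-calculation clips negatives to zero; a zero-baseline analyte
  therefore back-calculates to 0 (or floating-point crumbs), and fold
  changes are undefined (NaN) when either group mean is non-positive.
* `exp_average_biomass(x, x)` returns x (the continuous limit).

## Problem sizes

The simulation-based acceptance checks use 100 seeded replicates of the
full design (one calibration batch + one 50-sample experiment per seed,
~1 s each) and 1000 null simulations for the ANOVA type-I check; both sizes
give binomial confidence intervals tight enough for the stated bounds while
keeping the default test run around a minute.

## Known limitations

* Crosstalk is flagged and simulated but never deconvolved; quantification
  of a compromised channel requires a chromatographic or transition fix,
  not arithmetic.
* The LOD/LOQ regression assumes near-constant response variance in the
  low range; strongly heteroscedastic low-range data would bias σ.
* Dixon critical values are tabulated for α = 0.05 only (the confidence
  level the workflow specifies).
* Interday precision pools replicates across days by default; with strong
  day effects the mean-of-daily-means option is more appropriate.
* The off-gas balance assumes ideal gas and, by default, equal dry molar
  in/out flow; use the inert-balance option when RQ is far from 1.
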