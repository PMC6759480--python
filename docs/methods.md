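# Methods

This note documents the models, conventions and numerical choices behind
`rumenferm`, in the order the pipeline uses them.

## Design arithmetic

Crude protein (CP) follows the N × 6.25 convention and is carried as a
fraction of dry matter (DM). Isonitrogenous dosing solves
`dose × cp_target = dose_ref × cp_ref`. BCAA amounts are tracked in mmol
per vessel; conversions between mmol and mass-percent-of-protein use the
molar masses of the **free** amino acids (Val 117.15, Ile/Leu
131.17 g/mol), not residue masses. The free-acid convention is the one
under which published mmol dosing tables and amino-acid-as-%-of-protein
figures are mutually consistent, which the test suite checks; residue
masses would understate each acid's share of protein mass by ~14%.

When a treatment carries both an assayed supplement composition (mg amino
acid per g protein) and explicit per-dose mmol amounts, the two are
cross-checked at 5% relative tolerance. The tolerance is deliberately
loose: dosing tables printed to 3 decimal places in mmol alone carry ~2%
rounding error at the smallest doses.

## The conversion estimator

Stoichiometry is fixed at 1 mol BCAA → 1 mol BCVFA (oxidative deamination
+ decarboxylation). No correction is applied for incorporation of BCAA or
BCVFA into microbial biomass: the assay design counters that bias by
overdosing protein, and the required maximal growth stimulation occurs at
BCVFA concentrations (~0.2 mM) far below the signals analyzed.

Control subtraction uses the **mean** of the control replicates at the
matching timepoint, applied to each treatment replicate individually, so
replicate-level standard errors can be attached to every treatment
estimate. Negative conversions (treatment below control) are reported
as-is with a flag, never truncated — truncation would bias dose–response
comparisons. A supplement contributing zero of some BCAA gets a *missing*
(not zero) per-acid conversion.

Two aggregates are reported: the molar-sum conversion (total ΔBCVFA moles
over total BCAA moles, identically the BCAA-mole-weighted mean of per-acid
conversions) and the unweighted mean of the three per-acid values. The
molar-sum value is the headline statistic and defines RUP = 100 − conv;
when only a published BCVFA *total* is available (as in the packaged
treatment-mean fixture) it is the only computable aggregate. Vessel volume
cancels from the estimator; it enters only to express amounts in mmol.

## Fermentation summaries

"Total VFA" = acetic + propionic + butyric + valeric + the three BCVFAs;
lactic acid — a transient fermentation intermediate — is excluded. This
definition is verified arithmetically against the packaged fixture's
printed totals. Ammonia is carried in mM as a schema convention; all
NH₃-based conclusions are comparative, not absolute. Gas is cumulative
volume at ambient pressure (no ideal-gas normalization). Bacterial density
is 16S gene copies/mL, log₁₀-transformed for analysis; doublings between
two timepoints are log₂ of the density ratio. Missing analytes propagate
as missing, never as zero.

## Statistical layer

Vessels are destructively sampled (each vessel is opened at exactly one
timepoint), so timepoints are independent groups and the model is a
per-analyte, per-timepoint one-way ANOVA with treatment (all 10 levels,
control included) as the single factor. The 10-level layout, rather than a
source × dose factorial, is the one that can assign a superscript to the
control. The degenerate 0/0 case (identical constant groups) is reported
as F = 0, p = 1.

All-pairs comparisons use Tukey HSD, generalizing to Tukey–Kramer under
unequal n, with p-values from the studentized-range distribution
(via `scipy.stats.tukey_hsd`). Letters come from the insert-and-absorb
compact-letter-display algorithm: start with one column holding all
groups; each significant pair splits every column containing both; columns
that become subsets are absorbed. Letter order follows descending group
means with ties broken by input order. The default letter tier uses
α = 0.05; a secondary α = 0.10 tier can be requested. No multiplicity
correction is applied across analytes or timepoints.

Correlation tables are pairwise-complete Pearson: each cell drops rows
missing either variable and reports r, the two-sided p from the t
transform (n − 2 df), and the n used; cells with fewer than 3 complete
pairs are reported missing.

## The synthetic generator

The generator emulates the reference batch-culture study: 10 treatments ×
18 vessels, 6 withdrawn at each of 4, 10 and 24 h, each vessel contributing
exactly one observation.

**Control trajectories.** Each analyte's control curve is a
shape-preserving (PCHIP) interpolant through anchors at 0/4/10/24 h. The
4/10/24-h acid-panel anchors are the published control means, so the
noise-free control reproduces them exactly; the 0-h anchors are plausible
carry-over levels from the 10% rumen-fluid inoculum. Ammonia and gas
anchors are free parameters (no tabulated values exist) shaped to the
described kinetics: NH₃ dips from 4 to 10 h (assimilation-dominated) then
rises to 24 h; gas rises monotonically. Bacteria follow lagged logistic
growth (N₀ = 10¹⁰, K = 3.6 × 10¹¹ copies/mL, r = 0.56 h⁻¹, 2-h lag),
passing ≈3 × 10¹⁰ at 4 h and ≈3 × 10¹¹ at 10 h (~3 doublings) before
plateauing.

**Protein signal.** Degradation of supplement s is first-order with an
optional lag: conv(t) = f_s·(1 − exp(−k_s·max(t − lag_s, 0))). Each BCVFA
rises above baseline by conv(t) × (partner BCAA mmol)/V. The default
kinetics are calibrated to the published control-subtracted BCVFA pattern:
whey f = 0.62 (k = 0.33 h⁻¹, lag 9.5 h), soybean meal f = 0.50 (k = 0.25,
lag 10), yeast-derived protein f = 0.13 (k = 0.25, lag 10). The long lags
reflect the observation that BCVFA barely exceed control before 10 h —
structured feed proteins need proteolysis before deamination products
appear. Ammonia gains a fixed residual fraction (default 0.25) of the
nitrogen deaminated, f_s·conv-weighted CP dose /(6.25 × 14 g/mol).

**Activity signal.** Straight-chain VFAs and gas are scaled
multiplicatively by 1 + c_s · (non-protein supplement mass / basal DM) ·
(1 − exp(−0.15·t)); lactic acid by an analogous early-transient factor.
Coefficients c_s (soybean meal 2.2, yeast protein 1.5) reproduce the
published 24-h total-VFA ratios. The protein and activity signals are
decoupled **by construction**: BCVFA and NH₃ never depend on c_s. The
generator therefore does not emulate one real-data feature — carbon from
degraded whey protein feeding VFA production (whey's published ~20% VFA
rise despite negligible carbohydrate); whey's coefficient is simply set
low (0.5). Passing correlation-structure tests consequently demonstrate
that the *pipeline* separates the two marker blocks when they are truly
independent, not that real fermentations are this clean. Likewise the
generator omits vessel-to-vessel inoculum variation, animal-to-animal
variation and pH dynamics.

**Noise.** Every analyte of every vessel receives independent
multiplicative Gaussian noise, value × (1 + CV·z), truncated at zero,
default CV 5% — chosen to give treatment-mean standard errors of the
magnitude printed in the reference study's summary table. Because each
acid is measured (and perturbed) independently, derived totals have a
smaller effective CV than single analytes, as in a real GC panel. Noise
draws are consumed in a fixed order independent of kinetic parameters, so
two configurations differing only in activity coefficients yield
bit-identical BCVFA columns under the same seed. All randomness flows from
the config seed (default 20190918); runs are bit-reproducible.

## Problem sizes used in tests and the acceptance script

Stochastic checks use: parameter recovery at f ∈ {0.1, 0.3, 0.5, 0.7} with
200 simulated experiments each (control + one high-dose supplement, n = 6,
CV 5%, k = 0.25 h⁻¹ with no lag so 24-h truth ≈ 100·f); ANOVA calibration
over 1000 null datasets of 10 groups × 6; compact-letter-display
invariants over 500 random layouts; Monte-Carlo bias checks with 150–300
repeats. These sizes give Monte-Carlo standard errors comfortably below
the tolerances asserted.

## Known limitations

- RUP here is the direct complement of 24-h *in vitro* conversion; no
  passage-rate correction or in vivo extrapolation is attempted, so values
  rank supplements rather than predict absolute ruminal escape.
- The estimator is undefined for treatments introducing no BCAA (controls)
  and noisy at very small doses, where the BCVFA increment is comparable
  to control-level variation.
- The published-fixture path carries only BCVFA totals, so per-acid
  conversions from it are unavailable by construction.
- NH₃ scales in the generator are conventions, not calibrated values; no
  conclusion in the package depends on their absolute magnitude.
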