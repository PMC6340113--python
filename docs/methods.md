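# Methods

## Assay model

The package analyses a two-dimensional titration: a 384-well plate whose
16 rows each hold one buffered free Ca²⁺ concentration and whose 24
columns form a serial dilution of the titrant protein (calmodulin or an
isolated CaM domain) against a fixed ~50 nM TAMRA-labelled peptide.  Two
orthogonal readouts come from the same plate:

1. **Row-wise**: anisotropy versus total protein at one [Ca²⁺] → a
   protein–peptide K_D at that [Ca²⁺]; repeating over rows gives the
   K_D-versus-Ca²⁺ profile.
2. **Column-wise**: anisotropy versus [Ca²⁺] at one protein concentration
   (a fixed protein:peptide ratio) → the apparent Ca²⁺ affinity
   (appK_D) of the preformed complex, by a Hill fit.

### Binding isotherm

Binding is 1:1 mass action.  Because K_D values down to ~1 nM are
measured against 50 nM peptide, the bound fraction of titrant is not
negligible (ligand depletion) and the exact quadratic isotherm is used.
The physical (smaller) root is evaluated in the Citardauq form
`2·P·C/(b + sqrt(b² − 4·P·C))` with `b = K_D + P + C`; the textbook
`(b − sqrt(…))/2` form loses all significant digits when K_D ≪ P and is
rejected by a dedicated stability test against the mass-action oracle.

An independent equilibrium oracle (bracketed bisection on free protein,
no shared code with the closed form) backs every isotherm test; the two
agree to 1e-10 over a 10³-point grid spanning 1 pM–1 mM in all three
concentrations.

### Two-mode model

Rows that a single site cannot describe (historically, the weakest
peptide at elevated Ca²⁺) can be fit with a sum of two hyperbolas with
dissociation constants K_DI ≤ K_DII, valid where free ≈ total protein.
As written the saturation ranges over [0, 2) while the FA mixture treats
it as a fraction; no normalization is defined for this model, so the
fitted bound-state amplitude is an *effective* amplitude, not a per-site
signal.  This is deliberate and matches how the model is used: only
K_DI is reported as the headline affinity, with the ratio r = K_DII/K_DI
recorded.  The ratio is parameterized as log₁₀r ∈ [0, 3] so the ordering
holds by construction.

Model choice is automated: the two-mode fit is accepted over the
one-site fit only when the one-extra-parameter F-test on the residual
sum of squares is significant (default α = 0.05) **and** the fitted
ratio is ≥ 5 (well-separated modes).  Measured on synthetic data at the
default noise (σ = 3): type-I rate 1.2% on one-site truth (1000 seeds),
power 90% on two-mode truth with K_DI = 2 µM, K_DII = 20 µM (200 seeds).
Separately, the two-mode fit carries a `two-mode-unsupported` diagnostic
flag when the ratio collapses to 1 or the asymptotic log₁₀K_DII interval
spans more than four decades; the 4-decade width was calibrated on
simulation so the flag fires on ~⅔ of one-site-generated rows but on
<1% of genuinely two-mode rows (a 2-decade gate would falsely flag ~25%
of true two-mode fits, because K_DII above the top titrant concentration
is intrinsically weakly determined).

### Fitting and uncertainty

All fits are unweighted nonlinear least squares on the raw anisotropy
signal (`scipy.optimize.least_squares`, TRF, tolerances 1e-14).  K_D and
appK_D are fitted as log₁₀ values — the natural scale for a geometric
dilution design — with bounds [1e-12, 1e-3] M (K_D) and [1e-12, 1e-2] M
(appK_D); FA endpoints are bounded to [0, 500] anisotropy units.
Initialization: K_D at the geometric mean of the titrant concentrations,
endpoints at the observed signal extremes; the Hill midpoint at the Ca²⁺
of half signal range, n at 1.5.

Confidence intervals are asymptotic: σ̂² = RSS/(n−p), covariance
σ̂²·(JᵀJ)⁻¹ at the optimum, Student-t quantile on n−p degrees of
freedom; intervals on log-scale parameters are exponentiated (hence
asymmetric on the molar scale).  Measured coverage of the 95% K_D
interval is 92–97% across true K_D ∈ [1 nM, 5 µM] at σ = 3, with median
relative bias under 8% everywhere (worst at 1 nM, where the titration is
nearly stoichiometric).  Across replicate plates, profiles report the
geometric-mean K_D per Ca²⁺ condition with a t-based 95% CI on log₁₀K_D;
a single replicate passes through its own asymptotic interval.  Whether
one should instead pool replicate wells into a single fit is a genuinely
open design choice; per-replicate fitting was chosen because it exposes
plate-to-plate variation, and both the per-fit and across-replicate
summaries are exported.

### Reliability flagging

- **Measurable window**: fits with K_D outside ~[1 nM, 5 µM] are marked
  unreliable — below, the curve shape is set by stoichiometry, not
  affinity; above, the 30 µM top concentration no longer approaches
  saturation.  On simulation, out-of-window truths (0.1 nM, 50 µM) are
  flagged in >90% of seeds.
- **No binding**: after fitting, the model-predicted FA span across the
  sampled concentrations is compared with 3× the noise estimate (the
  larger of the residual σ̂ and a robust first-difference estimate); a
  smaller span flags the row `no-binding/unresolvable` and suppresses
  the K_D.  The predicted span, not the raw data span, is used because
  the extreme-value range of pure noise over 24 wells (~4σ) would defeat
  a raw-span rule.  Fits whose bound endpoint does not exceed the free
  endpoint are likewise rejected.  The Hill fit parameterizes the bound
  endpoint as baseline + nonnegative amplitude, so Ca²⁺-unresponsive or
  decreasing columns surface as a `no Ca2+ response` flag rather than an
  inverted fit.

### Hill (appK_D) analysis

The extracted column is chosen as the nearest in log space to the target
protein:peptide ratio (≈4 full-length, ≈40 isolated domains; an explicit
column override exists).  The Hill coefficient is fitted freely within
[0.5, 4]; synthetic generation uses n = 2 by default (two EF-hands per
CaM domain) — an assumption, since no reference n values are available.
A ratio ≤ 1 triggers a warning: the readout presumes the complex is
formed throughout the Ca²⁺ series.  Note the fitted n of a column
extracted from a plate is an *apparent* steepness — it convolves the
generating K_D(Ca²⁺) transition with the depletion isotherm — so only
appK_D, not n, is compared against generating values in tests.

## Free-Ca²⁺ buffering

Conditional stability constants use the Schwarzenbach proton
side-reaction factor with two protonations for EGTA (pKa 9.40, 8.79;
log K_Ca 10.86) and one for NTA (pKa 9.73; log K_Ca 6.41), NIST-style
values at I ≈ 0.15 M, 25 °C, configurable and recorded in the run
metadata.  1:1 Ca:chelator complexes only; Mg²⁺ competition, ternary
CaHL species, activity-coefficient and temperature corrections are out
of scope.  Free Ca²⁺ solves the multi-chelator mass balance by Brent's
method on [0, Ca_tot] plus Newton polish (relative residual < 1e-12; in
practice ~1e-16).  The 16-row gradient is designed inversely: 16
log-spaced free-Ca²⁺ targets over 0.3 nM–400 µM are mapped to mixing
fractions of the 0 / 3 mM-total-Ca stocks by root-finding.  With 0.5 mM
EGTA + 2 mM NTA the achievable ceiling is ~790 µM free Ca²⁺, so the full
target range is reachable; targets outside it raise an error naming the
achievable interval.  The row free-Ca values are treated as exact in the
downstream fits — the empirical recalibration of buffer series against a
Ca²⁺ sensor that a wet lab would perform has no synthetic counterpart.

## Synthetic plate generator

Defaults (all configurable, all logged in run metadata):

| parameter | default | rationale |
|---|---|---|
| stock_conc | 680 µM | within the 600–1200 µM practice range; gives a round 30 µM top concentration after 3 µl into 65 µl |
| dilution | 38:68 per column | transfer geometry of the robot protocol |
| peptide_conc | 50 nM | working concentration of the labelled peptide |
| fa_free / fa_bound | 150 / 250 | bound plateau anchored to the observed 240–260 range; the free baseline is not documented and 150 is a typical TAMRA-peptide anisotropy |
| noise_sd | 3 units | read noise giving visible scatter yet successful recovery; not documented for the instrument |
| pipette_cv | 2% | per-transfer volume CV, compounded down the series as real serial dilutions do |
| K_D profile | log-logistic, 390 nM → 1 nM, midpoint 60 nM, slope 2 | smooth monotone stand-in for the empirical K_D(Ca²⁺) curves of the high-affinity peptide |

One seeded `numpy` generator drives a whole plate: identical seeds give
bit-identical tables.  The generator does **not** emulate: the
fluorescence-intensity enhancement of the probe upon binding (FA is
treated as a pure mole-fraction-weighted mixture), instrument G-factor /
gain / flash statistics, evaporation or edge effects, or row-buffer
composition errors.  Passing recovery tests therefore demonstrate the
estimator's statistical behaviour under the stated noise model, not
robustness to every instrumental systematic of real plates.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks use 200 replicates per condition (1000 for the
model-selection type-I rate), 24-point rows, and 16-point Ca²⁺ curves —
enough for ~±3.5% binomial precision on coverage-style rates while
keeping the full suite under a minute.

## Known limitations

- Asymptotic CIs undercover slightly at the stoichiometric edge of the
  window (1 nM) and say nothing about systematic errors (peptide
  concentration, label effects).
- The two-mode model's saturation is used as printed (range [0, 2)),
  so its FA amplitude is effective, not physical.
- appK_D from a plate column depends weakly on which column (ratio) is
  extracted; the package reports the column and realized ratio with
  every fit.
- No global (linkage-constrained) fit across rows; each row is
  independent, matching the original per-row analysis.
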