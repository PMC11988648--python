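# Methods

## The monitoring problem

Probiotic fermentation of a fruit-juice blend is tracked by two reference
measurements — pH and viable cell count (log₁₀ CFU/mL) — and, indirectly,
by NIR transmission spectra of the juice in the first overtone of water
(1300–1600 nm). Acidification and cell growth both perturb the water
hydrogen-bonding network and the medium's turbidity, so the spectra carry
a low-rank signature of the process state. The package implements the
standard chemometric readout of that signature: PCA for structure,
PCA-LDA for fermentation-time classification, PLSR for pH/cell-count
calibration, and aquagrams for an interpretable water-band summary.

## Generative model of the campaign

The simulator is first-class code, not a fixture: it defines the study
conditions every downstream test and metric is computed under.

**Design.** Three cultures (BL, LS, MC) sampled at 0/4/8/16/24 h in
3 replicates, 3 consecutive scans per replicate. The unfermented 0 h juice
is a single shared group (labelled `JUICE`) reused by every per-strain
subset: 3·4 + 1 = 13 sample groups, 117 scan rows, 45 rows per strain
subset. The three 0 h replicates are treated as splits of one juice batch.

**Reference trajectories.** pH follows exponential decay
`pH(t) = pH_end + (pH0 − pH_end)·exp(−k·t)` with pH0 = 6.5 and
pH_end = 4.0 for all cultures; k = 0.20 h⁻¹ (BL), 0.12 (LS), 0.22 (MC).
The slower LS rate keeps its pH moving between every pair of sampling
points while BL/MC are near-stationary after 16 h. Cell counts are
piecewise-parametric shape families rather than mechanistic kinetics,
because only the shapes are constrained: BL a normalized logistic rise
from log₁₀ CFU = 7.0 to a 9.0 plateau (midpoint 6 h, rate 0.5 h⁻¹); LS a
smoothstep rise hitting log₁₀(2×10⁹) ≈ 9.30 exactly at 8 h, then a linear
decline of 0.15 log/h; MC a lagged logistic (midpoint 8 h, rate 0.7 h⁻¹,
plateau 9.2) with a 0.10 log/h decline after 16 h. All curves pass through
7.0 at t = 0 (the 5 % inoculum at ~10⁷ CFU/mL).

**Spectra.** On a 1300–1600 nm grid with 0.5 nm step (601 points; the
instrument's sampling interval is a free choice),

```
A(λ) = baseline(λ) + Σₖ aₖ·G(λ; cₖ, σₖ) + slope·(λ − λmid) + offset + ε
```

with a broad water hump baseline (Gaussian at 1445 nm, σ = 45 nm,
amplitude 1.10, plus 0.25 offset — plausible for 1 mm transmission),
twelve Gaussian bands (σ = 9 nm) at the WAMAC centers
1342…1512 nm, and band amplitudes affine in the state:
`aₖ = c_pH,ₖ·(6.5 − pH) + c_cfu,ₖ·(logcfu − 7)`. The pH couplings are
positive for the 1342–1452 nm coordinates (peaking at 1412/1440 nm, so
difference spectra crest inside 1400–1450 nm) and negative above 1462 nm,
encoding the displacement from strongly hydrogen-bonded toward freer water
states as acids accumulate; the cell-count couplings follow the same sign
pattern at roughly a fifth of the magnitude. Turbidity enters as a
multiplicative-scatter term whose offset (0.010 per log unit) and tilt
(2×10⁻⁵ per nm per log unit) grow with log₁₀ CFU.

**Noise.** Replicate (biological) noise — per-band amplitude sd 5×10⁻⁴
plus an offset sd 5×10⁻⁴, shared by all scans of a replicate — dominates
scan (instrumental) noise (iid sd 1×10⁻⁴ per wavelength, plus small
per-scan offset/tilt jitter). Reference noise: pH sd 0.02, log-count sd
0.15 (plate counting repeats poorly). Spectra are generated from the same
noisy replicate values the reference table records, so optical signal and
reference are coherent. These defaults were set by a separability
analysis performed before any model fitting: the smallest inter-class
spectral contrast in the design (BL, 16 h vs 24 h, ΔpH ≈ 0.08) is then a
4–6σ gap relative to within-class spread, i.e. the "well-separated"
regime in which perfect time classification is the expected outcome.
What the defaults do **not** emulate: wavelength-correlated instrument
drift, temperature fluctuation of the water spectrum, or chemical
interferents beyond the two latent factors — so passing tests demonstrate
correctness of the machinery under a two-factor world, not performance on
real juice spectra.

One integer seed drives independent child streams (reference, spectra,
cell-count fold assignment); with all noise sds zero the output is
deterministic and seed-invariant.

## Pretreatment

Savitzky–Golay smoothing/derivatives (2nd-order polynomial default;
`mode="interp"` so edges are served by the terminal polynomial fits and
the grid is preserved; derivatives scaled per nm), per-spectrum polynomial
detrending (degree 2 default — the degree is a free parameter since only
"polynomial baseline tendencies" is prescribed), SNV with the n−1
standard deviation, and MSC against the set-mean reference — both common
chemometric conventions. Recipes are ordered lists (`PretreatmentSpec`)
validated for odd windows > polyorder, derivative order ∈ {1, 2}, and at
most one of MSC/SNV. The per-analysis presets (43-point smoothing +
detrend for the global PCA; 21-point smoothing / detrend / MSC for the
BL / LS / MC time classifiers; detrend / SNV / SNV for the pH
calibrations; 21-point smoothing + MSC for the averaged cell-count model;
21-point smoothing + SNV before aquagrams) follow the best-model
treatments of the underlying campaign. Difference spectra are computed on
(culture × time) averages against the 0 h average, with the baseline row
kept as an explicit zero spectrum.

## Chemometrics

**PCA** is the SVD of the column-centered matrix; explained-variance
ratios are relative to total variance; sign fixed by making each
loading's largest-magnitude element positive (bit-reproducibility).

**Grouped cross-validation.** The unit of independence is the
(sample, replicate) scan block. The fold plan assigns fold = replicate,
giving three folds of 39 rows (full set) or 15 rows (strain subset); a
no-split assertion runs inside every CV loop. Non-three replicate counts
fall back to a warned round-robin.

**PCA-LDA.** Per fold, PCA is refit on training rows only (no leakage)
and a linear discriminant with pooled within-class covariance and equal
priors (balanced design) classifies the validation scores; a ridge of
1e-8 × mean diagonal is added only if the pooled covariance fails its
Cholesky factorization. NrPC selection scans 1..30 (capped with a warning
at training-fold rank) and picks, in order: highest pooled validation
accuracy, smallest |calibration − validation| gap, smallest NrPC — the
two stated criteria given a precedence, with the full candidate table
returned for audit. Calibration accuracy is the fold-mean training
accuracy; validation accuracy is pooled over held-out predictions; both
resubstitution and cross-validated numbers are always reported. Canonical
scores for plotting come from an all-data model's Fisher axes.

**PLSR.** Univariate NIPALS with mean centering; deflation stops early
when the residual rank is exhausted, so the requested NrLV is an upper
bound on noiseless data. The regression vector is reconstructed as
`W(PᵀW)⁻¹q`, and `fitted = (x − x̄)·b + ȳ` is asserted to 1e-8. R²CV and
RMSECV are computed from pooled held-out predictions (single-number
comparability), not per-fold averages; RMSEC ≤ RMSECV is deliberately not
asserted. NrLV selection takes the RMSECV argmin, exact ties broken
toward fewer components; on noiseless data successive candidates tie at
numerical precision and the selected count may exceed the generating
rank — the fitted model is identical, so this is cosmetic. Cell-count
calibration uses (culture × time) averaged fermented spectra (n = 12,
because replicate-level plate counts are too noisy); since averaging
destroys the replicate blocks, its three folds are a seeded
culture-stratified assignment of averaged rows, flagged in the report.

## Aquagrams

Classic normalization, chosen because the design has no temperature
perturbation: pretreat (21-point smoothing + SNV by default), average per
display group, then per WAMAC standardize across the displayed groups,
`(A_g − μ)/σ` — so each coordinate's values sum to zero over the groups
and a zero spread raises an error naming the coordinate. Coordinates
resolve to the nearest grid wavelength (band-mean over a range available
behind a flag). The nominal set {1342, 1364, 1374, 1384, 1412, 1426,
1440, 1452, 1462, 1476, 1488, 1512} nm is the conventional C1–C12
registry and is fully overridable — it is a convention, not a claim.
Difference aquagrams subtract the 0 h group's values, mapping the
baseline to the zero vector.

## Problem sizes and determinism

All analyses run at the native campaign size (117 × 601; strain subsets
45 × 601; averaged cell-count set 12 × 601), which keeps the entire test
suite and the acceptance script in the tens-of-seconds range. Fixed
inputs give bit-identical models; rerunning the pipeline with the same
configuration reproduces identical metric JSONs.

## Known limitations

* Two latent factors (pH, log count) generate all spectral variation;
  real fermentations have more (sugars, organic-acid speciation,
  temperature), which is why the simulated calibrations are cleaner than
  field ones.
* The scatter model is a per-scan linear tilt + offset; no wavelength-
  dependent (e.g. Mie) scattering curvature.
* LDA assumes shared within-class covariance; with 30-row training folds
  and up to 29 PCs the pooled estimate is rank-limited, mitigated but not
  cured by the ridge.
* No instrument-native file formats; CSV only.
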