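# Methods

This note documents the models, the numerical choices, and the limits of
what the tests establish. It is the package's own account; all numbers
quoted here are computed by the test suite or the acceptance script.

## 1. The analysis chain

### Preprocessing

Stages run in a fixed order — drop initial volumes, Gaussian smoothing,
linear detrend + band-pass, nuisance regression, FD scrubbing — enforced by
`preprocess_run`. Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_drop` | 10 | equilibration volumes removed (240 acquired → 230 analyzed) |
| `fwhm_mm` | 4.0 | isotropic smoothing kernel; σ = FWHM / √(8 ln 2), reflect boundaries (sum-conserving) |
| `band_low_hz`, `band_high_hz` | 0.01, 0.08 | pass band; frequency-domain mask with raised-cosine edges of half-width `taper_hz` = 0.002 Hz, applied after least-squares detrending |
| nuisance design | Friston-24 + WM + CSF (+ global) | Friston-24 = [p, p², p_{t−1}, p_{t−1}²] per rigid-body parameter; lag rows zero-filled at t = 0; intercept always included; rank checked via QR with collinear columns named |
| `fd_threshold` | 0.2 | Power FD = Σ\|Δtrans\| + 50 mm · Σ\|Δrot\|; FD₁ = 0 |
| `scrub_before`, `scrub_after` | 1, 2 | deletion windows, clipped at run boundaries, union over flagged volumes |
| exclusion limits | 2 mm / 2° | "or" rule by default (either limit excludes); an "and" variant is exposed because the convention is ambiguous in practice |

WM/CSF signals: synthetic runs carry designated nuisance series; for real
NIfTI input the mean series within user-supplied WM/CSF masks would play the
same role. Scrubbing is applied last, by deletion (not interpolation), after
filtering and regression.

### Degree mapping

Within-mask Pearson correlations, streamed in row blocks (memory is
O(block × n_voxels), never the full matrix). Edges must *exceed*
`r_threshold` = 0.2 (strict inequality, documented for reproducibility);
negative correlations contribute nothing. `mode` selects binary counting or
weighted summation — the default is weighted, the "connectivity strength"
reading; both exist because the two phrasings circulate in the literature.
Zero-variance voxels get degree 0 with a warning. Standardization defaults
to the in-mask z-score; `fisher_then_sum` instead applies atanh to each
retained correlation before summation (a z-score of a *count* through atanh
would be ill-defined for values above 1), then z-scores. Correlations are
clipped at 1 − 1e−7 before atanh so duplicated series stay finite.

### Group statistics

Per-voxel OLS of `degree ~ 1 + group + covariates`, group coded patient = 1
(so positive t = "increase"), covariates defaulting to mean FD, age, sex
(binary-coded), HAMD and HAMA. With no covariates the t statistic equals
the classical pooled two-sample t exactly (tested at 1e−8).

Residual smoothness: residual maps are normalized per voxel to unit sum of
squares; the mean squared first difference v along each axis estimates
2(1 − ρ(1)) of the spatial autocorrelation, inverted under a Gaussian ACF
as FWHM = √(2 ln 2 / −ln ρ(1)) and floored at one voxel. This inversion is
unbiased on Gaussian-kernel fields (a 6 mm kernel is recovered within the
tests' 15% band with ≈1% bias) where the first-order formula √(4 ln 2 / v)
overestimates by ≈10% at 1.3-voxel smoothness.

Cluster correction: resel counts R₀..R₃ from Worsley's lattice counting of
in-mask points/edges/faces/cubes scaled by 1/FWHM; expected cluster count
E[m] from the t-field Euler-characteristic densities; expected cluster size
E[n] = S·P(T>u) / E[m]; extent tail P(n ≥ k) = exp(−β k^{2/3}) with
β = (Γ(5/2)/E[n])^{2/3}; corrected p = 1 − exp(−tails · E[m] · P(n ≥ k)).
Two-tailed testing is two one-tailed excursions at `voxel_p` each, with the
familywise rate controlled jointly by doubling the Poisson rate — E[n] is a
one-excursion-set quantity and must *not* be divided by the doubled rate
(doing so halves the expected cluster size and made the corrected p
anti-conservative by ≈2.5× in Monte Carlo; this was caught and fixed by the
calibration tests). Cluster labeling uses 26-connectivity by default
(6/18 configurable) and matches an exhaustive flood-fill oracle.

### Clinical associations

Partial correlation = Pearson correlation of residuals after projecting
both variables on [1, covariates]; p from t = r√(df/(1−r²)), df = n −
n_cov − 2. The cluster screen runs patients only, covarying sex, age,
illness duration and education, with Bonferroni over the full
(clusters × variables) family — the family choice is exposed because the
convention varies. The voxel-wise variant converts per-voxel partial r to t
and reuses the GRF machinery, with smoothness from the full-model residuals.

### Classification

Per-cluster mean standardized degree as features; RBF SVM (linear
available); leave-one-out cross-validation with per-training-fold z-scaling
(no leakage); exhaustive grid over log2 c ∈ [−5, 15] and log2 g ∈ [−15, 3]
step 2 (the common LIBSVM grid), ties broken toward smallest c then
smallest g, making the procedure fully deterministic. The grid criterion is
LOOCV accuracy; a sensitivity + specificity criterion is available because
the published description of the stopping rule is ambiguous. The
"excluded subject pairs" phrasing sometimes seen for LOOCV is nonstandard;
standard single-subject LOOCV is implemented. Permutation test:
p = (1 + #{perm ≥ observed}) / (n_perm + 1); by default every permutation
honestly repeats the full grid search (a fixed-parameter fast path exists
and is flagged anti-conservative).

### Demographics

Pooled-variance t (raw vectors or printed mean/SD/n) and Pearson chi-square
without continuity correction — the variants that reproduce the emulated
cohort table's printed statistics (e.g. HAMA t = 9.00, sex χ² = 0.026).
Welch and Yates variants sit behind flags. Several of that table's printed
p-values are inconsistent with its own statistics (age p = 0.71 at
t = 0.05); p-values here are always recomputed from the statistic and df.

## 2. The synthetic cohort

The generator states a world, calibrated once and then frozen:

| parameter | default | rationale |
|---|---|---|
| grid, voxel | 12³, 3 mm | desk-scale grid at the acquisition's resampled voxel size |
| volumes, TR | 240, 2 s | the emulated acquisition (230 analyzed after the drop) |
| cohort | 40 / 38 | patients / controls (tests use 20 + 20 for Monte Carlo) |
| `n_networks` | 6 | latent band-limited signals, *spatially distributed* membership |
| `base_coupling` | 0.04 | post-preprocessing same-network correlations ≈ 0.3–0.5, straddling the 0.2 edge threshold |
| `n_hub_voxels` | 27 | 3³ block, ≈2.7% of the mask — the desk-scale analog of reported cluster sizes |
| `effect_strength` | 0.25 | patient hub-coupling increment; 0 = null cohort; 0.75 = the "strong" implant used in recovery tests |
| `noise_smooth_fwhm_vox` | 2.0 | intrinsic spatial correlation of voxel noise (real BOLD noise is spatially smooth) |
| `motion_sd` | 0.01 mm | random-walk step (rotations 100× slower); gives mean FD ≈ 0.04, matching the emulated cohort |
| `spike_prob` | 0.02 | per-volume chance of a persistent 0.5–2 mm translation jump |

Three of these were corrected during development because pilot Monte Carlo
showed the first-draft world defeated its own design goals, and the reasons
are instructive:

* **Coupling must be set post-preprocessing.** Band-pass (≈72% of white
  noise power removed at TR 2 s) and 4 mm smoothing together shrink noise
  variance ≈10×, so correlations measured *after* preprocessing are far
  higher than the generative coupling. A base coupling of 0.3 saturates the
  graph (nearly every edge r ≈ 0.9) and erases any hub contrast.
* **Noise needs intrinsic spatial correlation.** With iid voxel noise the
  degree-map residuals are nearly white (FWHM ≈ 1.1 voxel), exactly the
  lattice regime where cluster-extent theory has a discreteness cliff
  (the smallest attainable familywise rate jumps from ≈0.01 to ≈0.15).
* **Networks must be distributed, not contiguous.** A contiguous slab gives
  every network's sampling fluctuation a contiguous footprint in each
  subject's degree map — long-range common modes that no local-smoothness
  correction can calibrate (familywise rate ≈ 0.15 regardless of other
  settings). Distributed membership (as real resting-state networks are)
  restores ≈ nominal calibration. Six networks rather than three halves the
  between-subject variance of control hub degree, which is what bounds the
  attainable effect size; with three networks the group effect saturates at
  d ≈ 1.2 no matter how strong the implant.

Phenotypes: truncated normals at instrument bounds matched to the group
means/SDs of the emulated cohort; patients satisfy the eligibility screen
(Y-BOCS total > 16, HAMD < 18); illness duration is log-normal matched by
moments to 66.68 ± 75.54 months; sex follows the 27/40 and 25/38 male
fractions. Every draw is a pure function of (config, seed); identical
inputs give bit-identical cohorts.

What the generator does **not** emulate: hemodynamic response shapes,
scanner noise spectra (1/f, physiological cycles), anatomy or templates,
multi-site effects, or realistic between-region coupling topography. A
green calibration test therefore establishes that the statistical machinery
is correct *under the stated world's assumptions* (stationary local
smoothness, Gaussian-ish residuals) — not that GRF correction is calibrated
on real BOLD data, where nonstationarity and heavy-tailed ACFs are known to
inflate cluster false positives. The scrubbing burden (≈8% of volumes at
the default spike rate) is deliberately heavier than the emulated study
reports (≈0.5%), so the scrubbing code path does real work in every run.

## 3. Degenerate inputs and tie-breaks

Zero-variance voxels → degree 0 + warning. All-volumes-scrubbed → subject
unusable (error naming the subject). Rank-deficient designs → error naming
the collinear columns. Constant residuals in partial correlation → error
(checked against rounding noise at 1e−10 relative). Grid ties in the SVM →
smallest c, then smallest g. Equal-accuracy features in the single-region
screen → lowest column index. Cluster peak ties → first voxel in C order
via argmax.

## 4. Known limitations

* GRF cluster inference at desk scale sits close to its small-sample limits;
  the calibration band (familywise rate within the binomial 95% CI of 0.05
  over 200 cohorts) is met, but the extent approximation is visibly light
  for 2–3-voxel clusters and the implementation relies on the cluster-forming
  threshold p ≤ 0.001 regime.
* The permutation test re-runs the grid search honestly, which is O(grid ×
  n² SVM fits) per permutation; the published 10,000 permutations are
  practical only with the fast fixed-parameter path or patience.
* Real-data ingestion is limited to NIfTI + text motion files on a common
  grid; registration, slice timing and realignment are out of scope.
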