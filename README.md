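# fcdegree

Voxel-wise degree centrality (functional connectivity strength) analysis of
resting-state fMRI for two-group case-control studies, built around the
pipeline used in obsessive-compulsive disorder (OCD) imaging: nuisance
preprocessing with motion scrubbing, whole-mask degree mapping, Gaussian
random field (GRF) cluster statistics, clinical partial correlations, and
support-vector-machine discrimination — plus a synthetic-cohort generator
with known ground truth so every stage is testable without any patient data.

## Who this is for

Neuroimaging methodologists and students who want a transparent, tested
reference implementation of the degree-centrality case-control workflow:
each stage is a plain function over numpy arrays and NIfTI files, and the
statistical machinery (residual smoothness estimation, GRF cluster-extent
p-values, leave-one-out SVM permutation testing) is written out rather than
hidden inside a toolbox.

## The method

For each subject, the preprocessed BOLD run yields a degree map: for voxel
*i* inside a gray-matter mask,

```
deg(i) = Σ_{j≠i}  r_ij · 1[r_ij > 0.2]          (weighted, default)
deg(i) = Σ_{j≠i}  1[r_ij > 0.2]                 (binary)
```

where `r_ij` is the Pearson correlation between voxel time series; negative
correlations are set to zero, and maps are z-scored within the mask
(`atanh`-transformed edge sums are available as `fisher_then_sum`).
Preprocessing follows the fixed order: drop initial volumes → 4 mm FWHM
Gaussian smoothing → linear detrend + 0.01–0.08 Hz band-pass → regression of
Friston-24 motion parameters, white-matter and CSF signals (global signal
optional) → framewise-displacement scrubbing (FD > 0.2, one volume before
and two after, by deletion).

Group inference is a per-voxel linear model `degree ~ intercept + group +
covariates` with t statistics for the group contrast, cluster-formed at
voxel p < 0.001 and corrected at cluster p < 0.05 using random-field theory
(resel counts from the mask lattice, Euler-characteristic cluster rate, and
the exponential cluster-extent approximation). Surviving clusters feed
partial-correlation screens against clinical scores (Bonferroni over the
full screen) and a leave-one-out SVM with a LIBSVM-style `(log2 c, log2 g)`
grid search and label-permutation testing.

## Worked example

```python
import dataclasses
from fcdegree import SimulationConfig, analyze_synthetic_cohort, hub_voxel_mask

sim = SimulationConfig(n_patients=20, n_controls=20,
                       effect_strength=0.75, seed=5000)
result = analyze_synthetic_cohort(sim)
print(result["table"][["n_voxels", "peak_t", "direction", "corrected_p"]])
```

prints the recovered cluster table for a cohort with an implanted 27-voxel
hub (patients' hub-network coupling 0.79 vs 0.04 in controls):

```
   n_voxels    peak_t direction  corrected_p
0        28  7.079068  increase     0.000004
```

a single surviving "increase" cluster (patients > controls) of 28 voxels
covering the implant (Dice 0.98 against the 27-voxel ground truth), with a
familywise-corrected cluster p of 4e-6. On null cohorts
(`effect_strength=0`) the same pipeline detects a cluster in ≈5% of
cohorts — the nominal familywise rate.

The same stages are scriptable from the shell:

```bash
fcdegree run-all --output myrun --seed 7
fcdegree report demographics --phenotypes myrun/simulate/phenotypes.csv
fcdegree classify --features features.tsv --labels group --permutations 10000
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a synthetic effect cohort and runs the complete pipeline
(simulation → preprocessing/QC → degree maps → GRF cluster report →
clinical screen → LOOCV SVM with permutation test → demographics report)
in a temporary directory, then writes the results JSON to `--out`. It takes
a few minutes on one CPU.
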