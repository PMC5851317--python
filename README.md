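# dynapet

Simulation and quantification pipeline for **dynamic ¹¹C-acetate cardiac
PET**. The package lets methods researchers exercise, end to end and with
known ground truth, the full chain used to compare reconstruction
algorithms in clinical kinetic studies: a 2D cardiac phantom whose regions
follow a 1-tissue-compartment model, Poisson count simulation through a
factored system operator (attenuation, normalization, optional
time-of-flight and point-spread-function factors), four reconstruction
methods — FBP, OSEM, TOF-OSEM and TOF+PSF-OSEM — ROI/TAC/SUV extraction
with CV/contrast image-quality metrics, kinetic fitting with LV/RV
spillover correction, and cohort-level comparison statistics.

## The models at the core

**Ordinary-Poisson OSEM.** With prompts p, randoms/scatter expectations
r, s, system matrix A and angular subsets S_q, the update is

    f_j ← f_j / (Σ_{i∈S_q} A_ij) · Σ_{i∈S_q} A_ij p_i / (Σ_l A_il f_l + r_i + s_i)

with r and s kept inside the denominator. TOF adds a Gaussian positional
kernel along each line of response as an extra sinogram dimension; PSF adds
a radial Gaussian detector factor. FBP pre-subtracts r + s, divides by
attenuation/normalization, ramp-filters and backprojects. Convergence is
bookkept in EM-equivalent iterations = iterations × subsets.

**Kinetics.** Myocardial tissue follows
dC_t/dt = K₁·C_P − k₂·C_t (K₁ ∝ perfusion, k₂ ∝ oxidative clearance for
acetate), driven by the image-derived LV blood curve. The measured
myocardial TAC is fitted as
(1 − v_lv − v_rv)·C_t + v_lv·C_LV + v_rv·C_RV by bounded weighted least
squares, recovering K₁, k₂ and the two spillover fractions.

**Comparison.** For every method pair: OLS regression (slope, intercept,
r²) of per-subject parameters, paired-t and Welch-t p-values at α = 0.05,
and per-method group summaries — the standard method-agreement tables.

## Worked example

```python
from dynapet.pipeline import ExperimentConfig, run_subject, subject_seed

cfg = ExperimentConfig()          # 64x64 phantom, 53-frame 40-min protocol
res = run_subject(cfg, subject_seed(1, 0))
print(res.truth_params)
print(res.fits[["method", "K1", "k2", "v_lv"]])
```

prints (seed shown):

```
{'K1': 0.8502491542924276, 'k2': 0.21144566070970217}
  method        K1        k2      v_lv
0    FBP  0.700269  0.179694  0.040898
1   OSEM  0.711842  0.243928  0.078387
2    TOF  0.739388  0.235480  0.044650
3   TPSF  0.772927  0.219534  0.017650
```

The phantom's true myocardial uptake for this subject is
K₁ = 0.85 mL/min/mL with washout k₂ = 0.211 min⁻¹. Each row is the kinetic
fit from one reconstruction of the same noisy sinograms: all four methods
recover the right magnitudes, with the residual underestimation of K₁
reflecting partial-volume losses of the thin myocardial wall at PET
resolution — the effect the spillover fractions v only partly absorb. The
TOF-based methods sit closest to the truth, consistent with their faster,
more noise-robust convergence.

The same machinery is scriptable from the shell:

```sh
dynapet simulate --out truth.nii.gz
dynapet recon --method tof --iterations 10 --subsets 10 --seed 1 --out tof.nii.gz
dynapet run-all --config exp.yaml --out report/
```

## Layout

| module | contents |
|---|---|
| `dynapet.phantom` | frame schedules, input functions, phantom rasterization, dynamic ground truth |
| `dynapet.projection` | system operator (geometry/attenuation/PSF/TOF), subsets, Poisson count simulation |
| `dynapet.reconstruction` | OP-OSEM family, FBP, post-filtering, decay-corrected activity conversion |
| `dynapet.roi_tac` | ROI masks, TAC extraction, CV/contrast, SUV |
| `dynapet.kinetics` | 1-tissue-compartment solver, spillover model, fitting, convergence tables |
| `dynapet.compare` | regressions, paired/Welch tests, cohort reports |
| `dynapet.pipeline` / `dynapet.cli` | experiment orchestration and the `dynapet` command |

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
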