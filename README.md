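# dcepk

Direct pharmacokinetic (PK) map estimation for dynamic contrast-enhanced
MRI (DCE-MRI), built for perfusion researchers who want to study — and
stress-test — the reliability of PK mapping without access to patient data.

DCE-MRI quantifies tumor microvasculature by fitting the extended Tofts
model

    Ct(t) = vp·Cp(t) + Ktrans ∫₀ᵗ Cp(τ) e^(−kep(t−τ)) dτ,   kep = Ktrans/Ve

voxel by voxel, where `Cp` is the arterial input function (AIF).  The AIF
must be selected from a handful of vessel voxels in a noisy T1 series, and
that choice propagates into every parameter map — the classic reliability
problem of DCE-MRI.  `dcepk` implements both routes around this problem:

* **Conventional pathway** — semi-automatic AIF extraction (with a seeded
  inter-rater perturbation model) and bounded voxelwise nonlinear
  least-squares fitting, via a variable-projection scan over `kep`.
* **Network pathway** — a two-stage spatiotemporal model that bypasses the
  AIF entirely: a per-voxel temporal convolutional network condenses the
  60-frame curve into three feature maps, and a probabilistic U-Net with a
  diagonal-Gaussian latent space turns them into Ktrans/Ve/Vp maps.
  Sampling the latent yields multiple plausible map sets, whose voxelwise
  standard deviation is an **uncertainty map**.
* **Digital reference objects** — glioma-like phantoms (enhancing rim,
  necrotic core, non-enhancing infiltration, vessel) rendered through the
  full SPGR signal physics with Rician noise, plus labelled cohorts (WHO
  grade, IDH status) whose class information lives only in the PK
  distributions.
* **Evaluation battery** — masked SSIM and NRMSE, ICC(A,1) reliability
  comparison (AIF raters vs latent samples), Bland–Altman limits of
  agreement, and AUROC with DeLong confidence intervals and paired tests.

The networks run on a compact numpy autodiff engine inside the package, so
the whole loop — simulate, fit, train, predict, evaluate — runs on one CPU
in minutes.  See `docs/methods.md` for the model details and design
choices.

## Worked example

`examples/01_forward_model.py` simulates one tumor-rim voxel through the
full physics:

```
AIF peak: 6.04 mM at t = 35 s
tissue concentration peak: 0.423 mM; final frame 0.241 mM
signal enhancement: baseline 95.1 -> peak 239.6 (a.u.)
round-trip max error: 1.78e-14 mM (0 non-invertible frames)
```

The AIF bolus peaks at 6 mM 35 s after injection; a voxel with
Ktrans = 0.15 min⁻¹, Ve = 0.35, Vp = 0.06 accumulates ~0.42 mM of contrast,
which raises the SPGR signal 2.5-fold; inverting the signal recovers the
concentration to machine precision, confirming the physics is exactly
self-consistent.

`examples/03_simulate_cohort.py` draws a 200-subject labelled cohort and
scores the two diagnostic tasks from the mean rim Ktrans:

```
AUROC mean-rim-ktrans vs grade: 0.822 (95% CI 0.765-0.879)
AUROC mean-rim-ktrans vs idh: 0.784 (95% CI 0.721-0.848)
```

Both land in the good-discrimination band: the grade effect on the rim
distributions is larger than the IDH effect, so grade separates better.

The other examples cover the conventional fit with rater variability
(`02`), training and sampling the network with uncertainty maps (`04`),
and the full reliability report (`05`).  A thin CLI mirrors the stages:

```bash
dcepk simulate --out-dir cohort --n-subjects 12 --seed 0
dcepk fit-tofts --dce cohort/sub-0000/dce.nii.gz \
    --vessel-mask cohort/sub-0000/mask_vessel.nii.gz \
    --brain-mask cohort/sub-0000/mask_brain.nii.gz --out-dir fits
dcepk run-all --out-dir run --seed 0
```

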