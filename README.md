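# ballstick

Ball-and-stick diffusion-MRI phantom simulation, Bayesian MCMC estimation
with serial/parallel engine variants, and statistical comparison of the
resulting posterior sample sets.

## The problem

Bayesian multi-fibre estimation from diffusion-weighted MRI produces, for
every brain voxel, posterior distributions of diffusion parameters rather
than point estimates: the mean diffusivity *d*, the baseline signal *S0*,
fibre volume fractions *f₁*, *f₂* and fibre orientations in spherical
polar angles (φ₁, θ₁), (φ₂, θ₂).  Production implementations exist in both
serial (per-voxel CPU) and massively parallel (GPU) forms, which differ in
operation order, random-number streaming and floating-point accumulation
precision.  Whether those implementation differences change the *shape* of
the per-voxel posteriors — and hence downstream probabilistic tractography
— is an empirical question.

This package provides the full desk-scale machinery to study it:

- **phantom** — synthetic single-shell acquisitions (b = 1000 s/mm², 64
  directions + 6 b0) from the ball-and-stick forward model

  μ = S0 [ (1 − Σⱼ fⱼ) e^(−b d) + Σⱼ fⱼ e^(−b d (g·vⱼ)²) ],

  over four tissue compartments (CSF, grey matter, single-fibre and
  crossing-fibre white matter) with Gaussian or Rician noise and an
  optional spatial SNR profile;
- **inference** — per-voxel Levenberg–Marquardt initialization followed by
  Metropolis MCMC with an automatic-relevance-determination (ARD) prior on
  the second fibre, a 2250/1250/25 recording schedule (50 samples per
  trial, 20 trials merged to 1000 samples per posterior) and two engine
  variants: `sequential` (one RNG stream, voxel by voxel, double
  precision) and `phase_parallel` (all initializations first, per-voxel
  RNG substreams, optional single-precision accumulation);
- **compare** — per-voxel two-sample Kolmogorov–Smirnov tests with
  Bonferroni familywise control, S-score binning (0.1–0.2, 0.2–0.3,
  0.3–0.4, >0.4) and initialization-difference maps;
- **angular** — axial directional statistics: dyadic-mean principal
  diffusion directions, angular differences with antiparallel equivalence,
  percentile cones of angular uncertainty, and the f₂>f₁ label-switch
  swap correction;
- **report** — tissue-class localization of significant voxels and the
  headline roll-up over all six compared distributions per voxel.

## Worked example

Fit one noisy single-fibre white-matter voxel (truth f₁ = 0.7, stick along
+x, SNR 20):

```sh
$ python examples/02_fit_single_voxel.py
L-M init : d=9.68e-04  S0=98.1  f1=0.256  f2=0.546
posterior: d=9.24e-04  S0=98.5  f1=0.729  f2=0.037  (50 recorded samples)
truth    : d=9.00e-04  S0=100.0  f1=0.700  f2=0.000
orientation error: 1.6 deg (axial, antiparallel-equivalent)
```

The least-squares initialization splits the fraction arbitrarily between
the two (here aligned) sticks; during sampling the ARD prior drains the
unsupported second fraction to ≈0 while f₁ concentrates near the truth,
and the posterior mean orientation lands within 2° of the planted axis.

Compare the two engine variants on a small phantom:

```sh
$ python examples/03_compare_engines.py
768 comparisons over 128 voxels
not significantly different: 99.9% (voxel-level pair convention)
initialization differences above 1% of the mean: 347 voxel-parameter entries
```

Single- vs double-precision least-squares fits differ visibly at the
initialization stage (mostly in the weakly identified second-fibre
parameters), while the merged posteriors remain statistically
indistinguishable almost everywhere.

The other examples cover phantom construction (`01`), directional
statistics and the arccos(0.05) ≈ 87.13° uniform-axes cone (`04`), and
label switching with the swap correction (`05`).  A thin CLI mirrors the
workflow (`ballstick simulate|fit|compare|angles|report|pipeline`).

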