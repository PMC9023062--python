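# Methods

## Forward model

The diffusion-weighted signal in a voxel is modelled as one isotropic
compartment ("ball") plus K = 2 perfectly anisotropic compartments
("sticks"):

    mu(b, g) = S0 [ (1 - f1 - f2) exp(-b d)
                    + f1 exp(-b d (g . v1)^2)
                    + f2 exp(-b d (g . v2)^2) ]

with b the diffusion weighting (s/mm^2), g the unit gradient direction,
d a single mean diffusivity shared by all compartments (mm^2/s), S0 the
non-diffusion-weighted signal, f_j in [0, 1] the stick fractions
(f1 + f2 <= 1) and v_j the unit stick orientations.  Spherical convention,
fixed package-wide: v = (sin th cos ph, sin th sin ph, cos th), th in
[0, pi] measured from +z, ph in [-pi, pi].  Note (th, ph) and
(pi - th, ph + pi) denote antipodal vectors, i.e. the same fibre *axis*:
orientations are axial data, and all angular statistics treat v and -v as
identical.

## Synthetic phantom

`build_phantom` assigns ground-truth parameters on a rectangular grid with
a 10% in-plane border outside the mask and four equal quadrant
compartments (values chosen inside physiological ranges at b = 1000):

| compartment  | d (mm^2/s) | fractions        | orientations        |
|--------------|-----------|-------------------|---------------------|
| CSF          | 3.0e-3    | none              | —                   |
| grey matter  | 0.8e-3    | f1 = 0.1          | in-plane            |
| WM single    | 0.9e-3    | f1 = 0.7          | +x                  |
| WM crossing  | 0.9e-3    | f1 = 0.45, f2 = 0.40 | +x and +y (90 deg) |

S0 = 100 everywhere.  The gradient scheme is a deterministic spherical
Fibonacci spiral (64 directions + 6 b0 by default); its minimum pairwise
angular separation at 64 directions is ~22 degrees.

Noise defaults to Rician at SNR 20 on S0 (sd = S0/snr; `gaussian` and
`none` are available, and a spatial `snr_profile` multiplier can emulate a
head-coil sensitivity pattern).  The phantom reproduces the statistical
structure of a real acquisition — two fibre populations, per-voxel mean
orientations, tissue-dependent diffusivity — but none of its anatomical
geometry, spatial noise correlation, motion or eddy-current artifacts:
tests passing on the phantom validate the estimation and comparison
machinery, not claims about any particular brain dataset.

## Likelihood, priors, initialization

The per-voxel likelihood is Gaussian with the noise variance marginalized
under a Jeffreys prior, log L = -(N/2) log RSS with RSS the residual sum
of squares over the N volumes (floored at 1e-300 so noiseless data stay
finite).  This avoids sampling a noise parameter; it is slightly
mis-specified for Rician data at low SNR, which biases fractions by a few
hundredths at SNR 20 (both engines see the same bias, so comparisons are
unaffected).

Priors: improper uniform on d > 0 and S0 > 0; sin(th_j) per stick
(uniform on the sphere); flat on f1; and for the second fibre an ARD
shrinkage term -log(max(f2, 0.001)).  The cap at f_floor = 0.001 keeps
the density proper (the pure 1/f form is not integrable at 0, which makes
the chain sink indefinitely and mix pathologically) while preserving the
shrink-to-zero behaviour: on single-fibre or isotropic data the posterior
mean of f2 stays well below 0.05.

Initialization is a Levenberg-Marquardt least-squares fit of all eight
parameters, seeded from a log-linear diffusion-tensor regression (S0 from
the mean b0 signal; d and the first orientation from the tensor
eigensystem; f1 from a fractional-anisotropy-like measure; a small
perpendicular second stick at f2 = 0.05).  The fitted vector is clipped
into the support afterwards.  In single-precision mode the residual
pipeline runs in 32-bit float with a finite-difference step matched to
float32 machine epsilon; the resulting fits differ from the double-
precision ones mostly in weakly identified parameters (f2 and the
second-stick angles), by amounts that frequently exceed 1% of the
posterior mean.

## Sampler

Metropolis with single-site Normal proposals over the eight parameters,
in fixed order d, S0, f1, f2, th1, ph1, th2, ph2.  theta proposals are
reflected into [0, pi], phi wrapped into [-pi, pi]; invalid states
(negative d or S0, fractions outside [0, 1] or summing above 1) are
rejected outright.  Proposal standard deviations start at 10% of each
parameter's plausible range and are adapted every 40 iterations toward
~50% acceptance during burn-in only (multiplied by 1.1 or 0.9, clamped to
[0.01, 10] times the initial value); freezing after burn-in preserves
detailed balance over the recording window.

Three auxiliary moves address multimodality that single-site updates
cannot traverse; all are exact Metropolis moves with symmetric proposals:

1. **Fraction exchange** — shift weight between the sticks at fixed
   f1 + f2.  When the sticks are nearly aligned the likelihood is flat
   along this ridge; the move lets the ARD prior drain the secondary
   fraction instead of leaving the chain to diffuse.
2. **Label swap** — exchange (f1, th1, ph1) with (f2, th2, ph2)
   wholesale.  The likelihood is invariant, so acceptance reduces to the
   ARD prior ratio; this frees chains trapped in the label-switched mode
   (dominant fraction on the penalized second stick).
3. **Antipodal flip** — per stick, replace (th, ph) by (pi - th,
   ph + pi) with probability 1/2.  Likelihood and prior are invariant, so
   the flip is always accepted; it keeps the two equivalent
   representations of each axis equally occupied, making raw angle
   marginals independent of which representation a chain settles in.

Without these moves, independent chains trap in per-voxel modes for whole
trials and two runs of the *same* engine with different seeds produce
strongly significant KS differences — the comparison stage would then
measure sampler pathology rather than engine differences.  With them, the
null calibration (same engine, two seeds) yields no Bonferroni-significant
voxel and a near-nominal uncorrected rejection rate.

Recording: of `n_iterations` total (default 2250), the final
`n_record_window` (default 1250) are eligible, one full parameter vector
every `thin` = 25 iterations, giving 50 samples per trial; burn-in is the
difference (1000 by default).  Default `n_trials` = 20 independent trials
are merged into 1000 samples per posterior.  Desk-scale runs in the tests
and the acceptance script use 750/250/25 with 5 trials (50 merged
samples) on a 20x20x5 phantom; these sizes keep a full three-engine study
within minutes on one CPU while leaving every distributional property
testable.

## Engine variants

`sequential` emulates a serial per-voxel implementation: one RNG stream
per trial, consumed voxel-by-voxel in scan order, double-precision
accumulation.  `phase_parallel` emulates a parallel implementation: all
initializations first, then all chains, each voxel on an independent
substream keyed by (seed base, trial, voxel); with
`precision_mode="single_accumulate"` the residual accumulation in both
the initialization and the MCMC likelihood is rounded to 32-bit float at
every addition.  The L-M initialization is deterministic given the
precision mode, so equal-precision engines initialize identically
(their samples still differ through RNG streaming), while the
single-precision engine differs at the initialization stage in essentially
every voxel — the three discrepancy sources (starting points, operation
order, math-library precision) are thereby individually switchable.
Trial seeds derive from numpy SeedSequence; identical configurations
reproduce bit-identical output.

## Comparison stage

Per voxel and per compared parameter (f1, f2, ph1, th1, ph2, th2) the two
engines' merged sample vectors are compared with the two-sample
Kolmogorov-Smirnov statistic S = sup |ECDF_A - ECDF_B| (scipy; exact
p-value when n*m <= 1e4, asymptotic otherwise).  Significance defaults to
Bonferroni over all voxels x 6 tests at alpha = 0.05 (per-parameter
correction and uncorrected mode available).  Significant tests are binned
by S into [0.1, 0.2), [0.2, 0.3), [0.3, 0.4), [0.4, 1]; at 1000 merged
samples the Bonferroni-critical S is ~0.136, so significant tests below
the lowest edge cannot occur at full sample size.  Merged MCMC samples
are autocorrelated; the pipeline applies KS to them as-is (a fidelity
choice, not a statistical endorsement), while the null-calibration check
thins by an extra factor 2 to approximate independence.

Angular summaries are computed over voxels whose [phi, theta] pair is
significant (either angle; the pair's S is the larger of the two).  The
mean principal diffusion direction is the principal eigenvector of the
mean dyadic tensor mean(v v^T) — the standard axial-data mean, invariant
to antiparallel flips; the cone of angular uncertainty is the 95th
percentile (linear interpolation) of axial deviations from the
same-engine mean PDD.  The label-switch correction swaps
(f1, ph1, th1) <-> (f2, ph2, th2) per sample wherever f2 > f1 (per-voxel
mean-based swapping available); it is idempotent and is applied to both
engines before re-testing.

The roll-up reports the fraction of comparisons with no significant
difference under two labelled conventions: the voxel-level pair
convention (each fibre's angle pair counts once per voxel, denominator
voxels x 6) and the strict per-distribution convention (all six
distributions counted individually); the strict significant count is
always at least the pair count.

## Numerical and degenerate-input choices

- All-zero voxel signals raise a degenerate-input error; non-positive
  mean b0 likewise.
- RSS is floored at 1e-300 before taking logarithms.
- mean_pdd fixes the eigenvector sign by making its largest-magnitude
  component positive; a degenerate top eigenvalue pair resolves
  deterministically to the highest eigenvector index.
- Masked-out voxels hold 0 in all written volumes.
- On-disk layouts are plain NIfTI + whitespace text (FSL-style bvals/
  bvecs), written in float64 so read-back is bit-exact.

## Known limitations

- Two fibres only; no multi-shell or non-monoexponential decay models.
- The Gaussian marginalized likelihood ignores the Rician noise floor;
  at SNR 20 this biases f1 downward by ~0.05 in dense white matter.
- The engine variants emulate the *mechanisms* of serial/parallel
  implementation differences (ordering, streaming, precision); they do
  not reproduce any particular production binary's RNG or sample values.
- Tissue-class localization percentages depend entirely on the phantom
  layout; only the computation, not any real-data percentage, is
  reproducible here.
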