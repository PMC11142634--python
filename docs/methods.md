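# Methods

This note documents the models, estimators and design choices behind
`crossfc`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, which defaults matter, and what the
synthetic cohorts do and do not emulate.

## 1. Connectome construction

### fMRI

Region-averaged BOLD series (R×T) are processed in a fixed order:
**nuisance regression → band-pass → scrubbing → Pearson correlation.**
Regression removes an intercept, CSF, white-matter and global gray-matter
signals and the six motion parameters by per-region OLS. The band-pass is
a zero-phase (forward–backward) second-order-sections Butterworth filter,
order 2 per pass, 0.009–0.08 Hz; its contract is stated as gain bounds
(≥ 0.9 at 0.04 Hz, ≤ 0.1 at 0.2 Hz and at DC on 500-volume probes at
TR = 2 s) rather than coefficients, and the tests enforce exactly that.
Scrubbing censors volumes whose Power-style framewise displacement
(sum of absolute translation increments plus rotation increments projected
on a 50 mm sphere; FD of the first volume defined as 0) exceeds 0.5 mm.
Scrubbing runs after filtering because the filter needs contiguous
samples. Fewer than 10 surviving volumes raises an error as a
subject-exclusion signal; the minimum is only enforced when the recording
itself had at least 10 volumes, so toy inputs remain analyzable.
Zero-variance regions yield zeroed edges (with a warning) instead of NaNs,
keeping every matrix finite.

### EEG

Region-level source series are cut into non-overlapping segments of one
fMRI TR. Per segment, cross-spectra are estimated with Hann windows of
`fs/2` samples, giving 2-Hz resolution; the FFT is zero-padded to one
second so the spectrum is evaluated exactly at the bin centers
1, 3, …, 59 Hz. Sub-windows do **not** overlap by default. The reason is
the analytic significance rule: for white Gaussian noise the DFT
coefficients of disjoint Hann windows are independent complex Gaussians,
which makes the Goodman/Schelter null

    p(|C|²) = (1 − |C|²)^((dof − 2)/2),   dof = 2 · n_windows

*exactly* calibrated — the acceptance suite verifies the 5% rejection rate
at dof = 8 to within Monte-Carlo error. With 50% overlap (available via the
`overlap` argument) the effective dof falls below `2 n` and the analytic p
becomes mildly anticonservative.

Per bin, the corrected imaginary coherency (lagged coherence)
`ciCoh = sqrt(Im C² / (1 − Re C²))` is computed, defined as 0 where
`Re C² = 1`; values are clipped to [0, 1]. Bins that fail the analytic
significance test at α = 0.05 are set to 0 per segment. Bins are averaged
into bands by bin center (δ gets centers 1 and 3 Hz; band intervals are
half-open with γ closed at 60 Hz; the partition is 2/2/2/9/15 bins), then
segments are averaged, zeros included, with no threshold on the final
matrix. Bins whose auto-power is zero or below 1e−12 of the region's
strongest bin are treated as incoherent rather than 0/0.

Segment rejection implements two site-specific rules: `sd4` drops segments
in which any region exceeds its whole-recording mean by more than 4
whole-recording standard deviations, and `amp300` drops segments crossing
±300 µV (it refuses data whose units are not declared as µV). Note that
the 4-SD rule targets transient artifacts in real recordings; on unbounded
Gaussian surrogates a >4-SD sample occurs in almost every long segment, so
synthetic pipelines use the amplitude rule (or none).

## 2. Group statistics

**Cross-modal spatial correlation.** Pearson correlation across the
canonical upper-triangle edge vector (row-major, 0-based pairs
(0,1), (0,2), …; E = R(R−1)/2, i.e. 2,278 edges for R = 68 — the edge
count is always derived from R) between a group-mean EEG band matrix and
the group-mean fMRI matrix. Group contrasts use the statistic
`r_b − r_a` against the null obtained by randomly switching group labels
and re-averaging (group sizes preserved); p-values use the add-one
estimator `(1 + #{null ≥ obs})/(1 + n_perm)` so p = 0 never occurs.
Directions are fixed a priori (rTLE > controls, lTLE < controls).

**Split-half reliability.** Even group sizes below 16 are enumerated
exhaustively, counting each unordered partition once (the first subject is
pinned to side A); otherwise `n_iter` random balanced splits are drawn,
and odd groups drop one random subject per split.

**Contribution decomposition.** With z-vectors normalized to unit sum of
squares, `r = Σ z_x z_y` exactly, and `c_i = z_x,i z_y,i / r` satisfies
`Σ c_i = 1` to 1e−9 (an algebraic identity the tests check on random
pairs). Contributions are undefined (error) at r = 0.

**Subnetwork battery.** Intra-network edge masks (both endpoints in the
ICN) for the seven canonical networks; each (band, network) cell gets the
coupling contrast and the contrast of network-summed whole-brain
contributions, both by label permutation, at the Bonferroni cell threshold
α/(n_bands · n_networks) — 0.05/35 ≈ 0.0014 for the full battery. The
threshold adapts to the battery actually run. Networks with fewer than two
regions are skipped with a warning.

**Bootstrap models.** Each iteration resamples subjects with replacement
(multinomial weights), producing a coupling `r` and iteration-averaged
covariates; OLS of `r` on the averaged covariates across iterations is fit
with statsmodels. Covariate significance compares the observed t to a null
in which the bootstrap distribution is rebuilt with that covariate permuted
across subjects. One fresh bootstrap distribution per null iteration is
shared by all covariates (each covariate permuted independently against
it), which preserves the null's independence while avoiding a per-covariate
rebuild. Covariates are left on natural scales (sex, site, group and HS as
0/1 dummies); constant covariates are excluded with a warning, and
rank-deficient bootstrap designs are redrawn (error after 50 consecutive
failures). The depth of the permuted-covariate null is a free parameter
(`n_perm_null`) since conventions differ between implementations.

**NBS.** Edge-wise OLS (intercept, group, age, sex, site) via the normal
equations, vectorized over edges; one-sided t contrasts at first-level
threshold T = 2; component size = number of suprathreshold edges in a
connected component of the region graph (extent, not intensity); the null
permutes raw group labels only (no residual permutation), and corrected
p-values compare each observed component to the permutation distribution
of the maximum component size. fMRI responses are Fisher z-transformed
(values at ±1 clipped to ±(1−1e−7) with a warning); EEG responses enter raw.

**Sensitivity analyses.** Filters `ied_le_1` (drop patients above 1
interictal discharge/min), `hs_only`, `non_hs_only` (controls always
pass; emptying a patient group is an error); hemisphere-restricted
coupling on intra-hemispheric edge masks; edge-weight-versus-centroid-
distance correlation; and an individual-level variant that compares
per-subject coupling between groups by one-sided Welch t tests at
Bonferroni α/5.

## 3. The synthetic cohort generator

The generator emulates the study design the statistics were built for:
two sites (TR 2.0 s, ~150 volumes, 1 kHz EEG vs. TR 3.6 s, 350 volumes,
250 Hz EEG), three groups, 68 regions, five bands. Defaults (all set
before any group statistic was run, and documented here as the package's
reference conditions):

* **Latent topology.** Edge weights `exp(−λ d_ij)` plus N(0, 0.05²)
  jitter, rescaled to [0, 1]; λ = 0.012 /mm reproduces the strong negative
  distance–connectivity relationship of cortical FC (weights halve over
  ~58 mm).
* **Coupling model.** A subject's fMRI edge vector is
  `tanh(0.3 + 0.35·(u + τ ε)/√(1+τ²))`; the EEG band vector is
  `expit(−1.6 + 0.8·(w u + √(1−w²) v_b + τ η)/√(1+τ²))`, where `u` is the
  standardized latent, `v_b` a band-specific latent, and ε, η iid
  edge-level subject noise. The squashers keep fMRI in (−1, 1) and EEG in
  (0, 1) at realistic levels (ciCoh mostly 0.05–0.45).
* **Calibration.** The mixture weight `w` is bisected until the expected
  realized correlation between group-mean matrices — evaluated by internal
  Monte-Carlo with common random numbers across groups — hits the target.
  Common random numbers make groups with equal targets receive (nearly)
  identical weights, so unflagged contrasts are exactly null. Band latents
  are decorrelated from `u` within every intra-ICN edge block (block-wise
  Gram–Schmidt with spread matching), so the planted coupling holds
  uniformly across subnetwork masks instead of drifting by ±1/√(mask size)
  from one latent draw to the next. Targets whose required weight exceeds
  1 raise a calibration error; the noise-free target of exactly 1 returns
  the rank-identical limit.
* **Noise level.** τ (= `noise_sd`) = 1.0 per modality. This puts the
  model's split-half reliability at `1/(1 + 2τ²/n)` ≈ 0.78–0.89 for group
  sizes 14–33 and per-subject cross-modal coupling near 0.2 — matching the
  reliability range and the low individual-level coupling reported for
  real concurrent recordings.
* **Default coupling targets.** 0.40 for all groups and bands, 0.55 for
  rTLE in δ–β; for lTLE-β the intra-DMN edges are attenuated by the
  multiplier `dmn_decoupling` = 0.75. The attenuation is applied relative
  to the coupling the base weight would realize on the DMN mask (estimated
  with a dedicated high-repetition masked calibration), so the planted
  *gap* is consistent across cohorts.
* **Covariates.** age ~ U(18, 60); sex ~ Bernoulli(0.5); patients get
  duration ~ U(1, 30) years, HS ~ Bernoulli(0.5) and IED rate ~
  Exponential(mean 0.3 /min); controls carry explicit missing values.
  A small site effect (+0.1 pre-squash mean for the 64-channel site)
  keeps the site covariate meaningful.
* **Time-series mode.** BOLD is multivariate Gaussian with the subject's
  target matrix as covariance (eigenvalue-clipped to PSD), plus linear
  drift, a 0.15 Hz physiological component, CSF/WM/global-gray leakage and
  motion-spike glitches; the motion table is a smooth random walk with
  spikes (rate 0.02/volume) that trip FD scrubbing. EEG superposes
  narrow-band Gaussian background per band (amplitudes 4/3/3/2/1 scaled to
  ~37 µV total), quarter-cycle-lagged common drivers on the strongest 1%
  of target edges (an exact 90° lag via the analytic signal), an
  instantaneous symmetric mixing component (strength 0.3) as a
  volume-conduction surrogate, and occasional ±350–500 µV artifact
  segments. All randomness derives from the design seed through fixed
  stream keys, so cohorts regenerate bit-identically.

**What the generator does not emulate.** No hemodynamic forward model, no
sensor-space EEG, leadfields or artifact morphology; coupling is induced
at the edge level, not through joint neural dynamics, so time-series mode
demonstrates estimator behavior (lagged-coupling detection, zero-lag
suppression, scrubbing, rejection), not physiology. Subject noise is iid
across edges, whereas real connectome deviations are spatially structured.
Passing tests therefore certify the statistics and estimators, not the
biology.

## 4. Problem sizes and known limitations

Test and acceptance runs use deliberately small problem sizes: null
calibrations at R = 30 with 15 subjects/group and 500 permutations over
200 replicates; pipeline demonstrations at R = 8–10 with 30–40 segments;
the pattern-recovery study at the reference sizes n = 17/17/16 with 2,000
(whole-brain) and 5,000 (subnetwork) permutations.

Under those reference conditions the whole-brain pattern (rTLE > controls
in δ/θ/α/β at p < 0.01, γ null) is recovered essentially always, but the
single-cell DMN×β detection at the 0.0014 Bonferroni threshold is
underpowered: the planted gap is (1 − 0.75) × 0.40 = 0.10 in correlation
units, while the permutation null of a difference of correlations on a
153-edge mask with 16–17 subjects per group and split-half-faithful noise
has a one-sided 0.0014 quantile of a similar magnitude. The
`pattern_recovery_fraction` reported by `scripts/acceptance.py` makes this
visible (well below 1); detecting the cell reliably at that threshold
would need larger groups, a stronger planted attenuation, or less
measurement noise than concurrent EEG-fMRI reliability supports.

Other limitations: the bundled atlas ships standard Desikan labels but
synthetic centroid coordinates and a hand-built Yeo-7 assignment (true
centroids are subject-level FreeSurfer output); the NBS implements the
extent statistic only; permutation schemes shuffle raw labels (no
Freedman–Lane residualization); and the EEG significance mask assumes
Gaussian segments, so heavy-tailed artifacts should be rejected before
estimation.
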