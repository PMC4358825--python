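# Methods

## Signal model and its central assumption

The phantom simulator treats a ¹⁹F magnitude image as strictly proportional to
local spin density: the noiseless value of a voxel holding `s` spins is
`gain · s · r(Δf)`, where `gain` (signal units per spin) is an arbitrary scanner
scale and `r(Δf) ∈ [0, 1]` is the excitation response at the compartment's
chemical-shift offset.  Relaxation and flip-angle dependence of the underlying
balanced-SSFP acquisition are deliberately **not** modeled: the quantification
chain's validity rests on the pellet and reference compartments sharing one
proportionality constant, so that assumption is promoted to the simulator's
contract rather than buried in sequence physics.  Consequently the noise-free
phantom is an exact oracle: the full chain must return the true cell count to
machine precision for *any* gain and *any* reference concentration, and the
test suite enforces a relative error below 10⁻⁹.

Compartments are voxelized by center-inclusion (a voxel belongs to a sphere or
cylinder iff its center does).  There is no sub-voxel partial volume in this
version; that choice is what keeps the noise-free oracle exact, at the cost of
not exercising edge-voxel effects.  Coordinates are continuous in mm, voxel
indices 0-based, and the world position of a voxel center is
`(index + 0.5) · voxel_size`.

## Noise

Magnitude reconstruction of complex Gaussian channel noise gives Rician voxel
statistics; signal-free voxels are Rayleigh with mode σ.  The simulator adds
noise as `|clean + n₁ + i·n₂|` with `n₁, n₂ ~ N(0, σ)`; a Kolmogorov–Smirnov
property test checks the Rayleigh law on 10⁵ empty voxels.  The default
σ = 50 signal units (with the default gain of 10⁻¹² units/spin and mid-range
loading) puts the smallest pellet of the validation series at an ROI SNR of
roughly 10–20 — comfortably detectable but visibly noisy, a realistic regime
for a 2×10⁵-cell deposit.  Rician bias slightly inflates low-signal ROI sums;
at the default settings the effect is well under a percent and the linearity
study absorbs it.

## Geometry defaults

Grid 32×32×16 voxels at 1×1×2 mm (the fluorine acquisition resolution), so
each voxel is 2 μL.  One spherical pellet (radius 3 mm, ≈57 voxels) and one
cylindrical reference tube (radius 2 mm, length 16 mm) per phantom; the series
2×10⁵, 4×10⁵, 6×10⁵, 8×10⁵, 1×10⁶, 2×10⁶ cells shares geometry across sizes —
only the spin load changes, which mirrors how pellet phantoms are actually
built and keeps the regression free of geometric confounds.  The default
reference concentration is 2.6×10¹⁶ spins/μL; 7.3×10¹⁶ is accepted anywhere a
`C_ref` is taken (published protocols quote either value, and the chain is
invariant to the choice as long as generator and quantifier agree).

## Excitation-bandwidth model

Pulse bandwidth follows the fixed time-bandwidth product `B·T = 2.0 kHz·ms`,
which maps the two canonical pulse widths (1.32 ms plain sinc, 0.66 ms
Gaussian-filtered sinc) onto ≈1.5 kHz and ≈3 kHz bands.  The plain sinc's
approximately rectangular passband is realized as a sixth-order supergaussian
`exp(−ln2 · (2Δf/B)⁶)` — flat to ≥ 0.9 inside |Δf| ≤ B/4, exactly 0.5 at B/2,
and negligible beyond; the filtered sinc's response is a Gaussian with FWHM B,
`exp(−4 ln2 (Δf/B)²)`.  (A Gaussian with FWHM B is mathematically 2^(−1/4) ≈ 0.84
at B/4, so the "flat passband" guarantee applies to the rectangular profile
only.)  The off-resonance compartment defaults to Δf = 1.2 kHz — inside the
3 kHz band but outside the 1.5 kHz band, reproducing the observed behavior that
a narrow pulse eliminates the isoflurane background while a broad pulse lets it
contaminate quantification.  No k-space simulation, banding, or coil
sensitivity is attempted.

## NMR calibration

Peak areas are trapezoidal integrals over explicit windows after removing a
linear baseline through the window edges; each edge level is the mean over a
short edge segment (5% of the window per side) so a single noisy sample cannot
tilt the baseline across the whole window.  Windows are inputs,
not auto-detected: in calibration practice the cell and reference resonances
are known, and automated peak-picking is out of scope.  The spectrum simulator
places two Gaussian peaks (SD 0.3 kHz, 6 kHz apart, 4096 points over ±8 kHz)
with areas proportional to `n_cells · Y` and `N_ref`; round-trip recovery is
exact to discretization (< 0.5%) at zero noise and biased < 3% at spectrum SNR
50 over 100 seeds.  Phasing, apodization and PFPE multiplet fine structure are
not modeled; the loading range 8.2×10¹⁰–2.4×10¹¹ spins/cell bounds the sampled
truth values.

## Quantification conventions

* The background constant *x* is the minimum over the **entire dataset**
  including the reference tube; with magnitude noise the minimum is near zero,
  and at σ = 0 it is exactly zero, so correction is a no-op on clean phantoms.
* `N̂` is reported as a continuous value, never rounded — apparent cell number
  is a ratio of physical quantities, and integerizing it would discard
  information the longitudinal statistics use.
* Detectability uses the Rose criterion: SNR = mean corrected ROI signal over
  the SD of corrected signal-free background voxels, detectable iff SNR ≥ 5
  (inclusive; threshold configurable).  A noise-free positive ROI reports +∞.
* The convenience auto-ROI thresholds at background mean + 3·SD (the offset is
  measured from the Rayleigh floor, which is not zero) and keeps the largest
  26-connected component after excluding the reference tube.  Hand-drawn-
  equivalent masks from NIfTI files remain the primary path.

## Repeated-measures statistics

The one-way repeated-measures ANOVA decomposes within-subject variation into a
time effect and a subject×time residual: `F = MS_time / MS_error` with nominal
df `(k−1)` and `(k−1)(n−1)`.  Sphericity violations are handled with the
Greenhouse–Geisser estimate computed from the double-centered covariance `S̃`
of the timepoint columns, `ε̂ = tr(S̃)² / ((k−1)·tr(S̃²))`, clipped to
`[1/(k−1), 1]`; the p-value uses the scaled df `(ε̂(k−1), ε̂(k−1)(n−1))`.
Greenhouse–Geisser was chosen over Huynh–Feldt because it is the conservative
default of the common statistics packages and reproduces the fractional-df
structure such analyses print; note `df2/df1 = n−1` exactly, so the number of
complete cases can be read off any reported F(df1, df2).  Tests verify the
implementation against a loop-based sums-of-squares oracle with an
eigenvalue-form ε̂ (10⁻⁸ agreement on 100 random tables) and against pingouin.

Tukey post-hoc comparisons use `q = |Δmean| / √(MS_error/n)` against the
studentized-range distribution with k means and the uncorrected error df
(GG-corrected df available by flag); with k = 2 this reduces exactly to the
paired t-test, which the suite checks.  Missing timepoints trigger
complete-case exclusion with a warning — a zero count is a valid observation
(undetectable ≠ missing), and all outputs carry the analysis n explicitly.

## Synthetic cohorts

The longitudinal demo simulates per-subject exponential clearance
`N(t) = N₀·exp(−k_s t)` with `k_s` log-normal across subjects (defaults:
N₀ = 2×10⁶ cells, days 0/3/9/16, median k = 0.25/day for the fast
immune-competent-like cohort and 0.08/day for the slow immune-compromised-like
cohort, log-SD 0.4).  This is a fixture standing in for unmodeled clearance
biology, not a biological claim: it exists so the detectability ordering (the
fast cohort loses detectable subjects no later than the slow one), the
percent-remaining bookkeeping and the ANOVA plumbing can be exercised on data
with known structure.  What passing these tests shows is that the *pipeline*
behaves correctly; it says nothing about real implant survival, bystander
label transfer, or in-vivo noise fields, none of which the generator emulates.

## Problem sizes and determinism

Default studies are deliberately small — 18 phantom images for the linearity
study, ≤ 16k-voxel grids, 100-table oracle sweeps — so every study reruns in
seconds.  All randomness flows through explicit integer seeds (replicates vary
only the noise seed, matching repeat scan sessions); fixed seeds reproduce
images bit-identically and report files byte-identically (JSON with sorted
keys).
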