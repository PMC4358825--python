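# fluoroquant

Absolute cell-count quantification for fluorine-19 MRI cell tracking.

Cells labeled with a perfluorocarbon (PFC/PFPE) emulsion carry ¹⁹F nuclei into
tissue that otherwise has no detectable fluorine, so any ¹⁹F-MRI signal comes
from the labeled cells (or from ¹⁹F-containing anesthetic, see below).  Because
the magnitude signal is proportional to the number of ¹⁹F spins, an image can be
converted into an **absolute cell count** by comparing it to a reference tube of
known spin concentration.  `fluoroquant` implements that quantification chain as
a tested, reusable pipeline, together with a synthetic phantom generator that
provides exact ground truth, an NMR-based loading calibration, and the
repeated-measures statistics used to follow implanted cells over time.

Intended users: imaging scientists developing or validating ¹⁹F cell-tracking
protocols, and anyone who needs a fully seeded synthetic test bed for
ROI-based absolute quantification.

## The method

For an ROI drawn over a cell deposit in a background-corrected magnitude image:

1. **Background correction** — subtract the dataset-wide minimum voxel value
   *x* from every voxel, left-shifting the intensity distribution to zero.
2. **Total spins** — with reference concentration `C_ref` (spins/μL) and voxel
   volume `V` (μL):

   `X = (Σ_ROI S_i / mean_ref S_j) · C_ref · V`

   i.e. the ROI signal expressed in reference-voxel equivalents, each carrying
   `C_ref · V` spins.
3. **Cellular loading** — comparative NMR on a known number of the same cells
   next to a standard of known spin count gives `Y` (spins per cell) from the
   peak-area ratio: `Y = (A_cell / A_ref) · N_ref / n_cells`.
4. **Cell count** — `N̂ = X / Y`.

Because both the ROI and the reference are scaled by the same unknown image
gain, `N̂` is gain-invariant — the property that makes absolute counting
possible without knowing scanner units, and the property the noise-free
synthetic phantoms verify to machine precision.

The longitudinal module analyzes subject × timepoint count tables with a
one-way repeated-measures ANOVA using Greenhouse–Geisser corrected fractional
degrees of freedom (`df1 = ε̂(k−1)`, `df2 = ε̂(k−1)(n−1)`), Tukey HSD pairwise
comparisons via the studentized-range distribution, percent-of-baseline
summaries and per-timepoint detectability tallies (Rose criterion, SNR ≥ 5).

The phantom generator also models RF excitation bandwidth: a pulse of
time-domain FWHM `T` (ms) excites a band of width `B = 2/T` (kHz), so a long
plain sinc (1.32 ms → ≈1.5 kHz) leaves a 1.2 kHz off-resonance compartment
(an isoflurane stand-in) essentially unexcited, while a short Gaussian-filtered
sinc (0.66 ms → ≈3 kHz) excites it and inflates any ROI it overlaps.

## Worked example

```python
import fluoroquant as fq

# simulate a 1e6-cell pellet + reference tube, quantify it with ground-truth masks
spec = fq.build_pellet_series((1_000_000,), spins_per_cell=1.5e11)[0]
img, masks = fq.generate_fluorine_image(spec, fq.AcquisitionParams(noise_sd=50.0, seed=7))
res = fq.quantify_image(
    img,
    fq.RoiMask(masks["pellet_0"], spec.grid),
    fq.RoiMask(masks["reference"], spec.grid),
    c_ref=2.6e16,
    spins_per_cell=1.5e11,
)
print(f"N = {res.cell_count:.0f} cells, SNR = {res.snr:.1f}, detectable = {res.detectable}")
```

prints

```
N = 999506 cells, SNR = 95.7, detectable = True
```

— the estimate is within 0.05% of the true 10⁶ cells at this noise level, and
the pellet is far above the SNR ≥ 5 detection threshold.  The same chain is
available from the shell:

```sh
fluoroquant validate-linearity --replicates 3 --seed 0 --out linearity.json
```

which simulates the six-pellet series (2×10⁵ … 2×10⁶ cells) on three imaging
occasions and reports the regression of estimated on true counts
(`r_squared`, `pearson_r`, `slope`, per-pellet mean ± SD).  Other subcommands:
`simulate`, `calibrate`, `quantify`, `longitudinal`, `demo-cohort`.

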