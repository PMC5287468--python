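# poremark

Quantitative image analysis of ring-shaped membrane pore complexes — such as
the nuclear-pore-like structures found in the internal membranes of the
planctomycete bacterium *Gemmata obscuriglobus* — in 2D electron micrographs,
together with a fully ground-truthed synthetic-micrograph generator that makes
every stage of the analysis verifiable without access to original image data.

## Who it is for

Microscopists and method developers who need to (i) detect ring pores on
membrane sheets and estimate their areal density, (ii) measure plug /
inner-ring / outer-ring diameters from radial intensity profiles, (iii) test
for n-fold rotational symmetry by Markham rotational reinforcement with a
proper statistical control, and (iv) quantify immunogold labelling by a
distance-association rule with a permutation null.

## The core methods

**Markham reinforcement.** An image `I` of a putatively symmetric particle is
rotated about its refined centre by increments of 360°/n (45.0° for n = 8,
51.4° for n = 7) and superimposed; true n-fold features reinforce while noise
averages out. poremark scores a candidate order by the mean Pearson
correlation over an annular band,

    score(n) = mean_{k=1..n-1}  corr( I, R_{k·360/n} I ),

compares it against the same statistic at seeded random control angles, and
selects the order with the largest standardized reinforcement gap
`z(n) = (score(n) − control mean) · √(n−1) / σ_noise`; standardization
resolves the divisor degeneracy (for a perfect 8-fold image, n = 2 and 4 tie
with n = 8 in raw score) and equalizes sampling variance across orders.
Scoring always runs on raw images — the bandpass filter included here is for
display only. Tilt-foreshortened (elliptical) pores are rectified first via a
second-moment ellipse fit of the outer ridge.

**Radial morphometry.** Ring diameters are twice the radius of the annulus
intensity ridge in the radial profile (3-point parabolic sub-bin
localization); the central plug diameter is the full width at half contrast
of the central dark disk. Missing features are flagged, never guessed.

**Density.** Pores are detected by normalized cross-correlation against
zero-mean Gaussian annulus templates over a radius grid, with greedy
non-maximum suppression; density = count / membrane-mask area with a Poisson
95% interval.

**Immunogold association.** A particle is associated when its distance to
the nearest pore's outer-ring edge, `max(0, |x − c| − r_outer)`, does not
exceed 20 nm (inclusive). A permutation test (uniform placement in the
membrane mask, `p = (1 + #{frac_b ≥ frac_obs}) / (B + 1)`) supplies the null.

**Synthetic generator.** Pores are rendered analytically: erf-edged dark
plug, Gaussian-profile bright inner and dark outer annuli, the outer ring
modulated by `1 + a·cos(n·θ)`, optional cos-tilt foreshortening, Gaussian PSF
and additive Gaussian noise (SNR ≡ |outer-ring contrast| / noise σ). Sheets
place pores by hard-core rejection sampling at a stated density. Defaults
follow the published geometry: d_outer/d_inner/d_plug = 33.5/17.5/9.5 nm,
8-fold subunits, 0.69 nm/px, densities 87 and 200 pores/μm².

## Worked example

```python
from poremark import (LARGE_PORE, render_pore_patch, noise_sigma_for_snr,
                      refine_center, radial_profile, measure_rings,
                      assess_symmetry)

sigma = noise_sigma_for_snr(LARGE_PORE, 3.0)          # SNR 3
patch = render_pore_patch(LARGE_PORE, noise_sigma=sigma, seed=42)

scan = assess_symmetry(patch, n_max=12, seed=42)
print("selected order:", scan.selected_n)             # -> selected order: 8

m = measure_rings(radial_profile(patch, refine_center(patch)))
print(f"outer {m.d_outer_nm:.1f} inner {m.d_inner_nm:.1f} plug {m.d_plug_nm:.1f} nm")
# -> outer 33.3 inner 17.8 plug 8.7 nm
```

The scan selects 8-fold symmetry (the generator's ground truth), and the
measured diameters recover the model geometry (33.5 / 17.5 / 9.5 nm) to
single-pore precision; cohort means over 50 pores land within ±0.4 nm.

A full pipeline run (simulate → detect → measure → symmetry → gold → report):

```bash
poremark all --preset study-lysed-sheet --seed 11 --outdir run/
# run/report.json then contains e.g.
#   detect.density_per_um2   ≈ 87.9   (87 /μm² simulated)
#   symmetry.selected_n      = 8
#   gold.fraction            = 0.90, p_value = 0.005
```

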