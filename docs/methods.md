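# Methods

## The measurement problem

Ring-shaped pore complexes on membrane sheets appear en face in 2D electron
micrographs as a dark central plug, a thin brighter inner ring and a thicker
dark outer ring, sometimes with visible subunits on the outer ring. The
package quantifies four things: pore geometry (three diameters), areal pore
density, the rotational symmetry order of the subunit arrangement, and the
spatial association of immunogold labels with pores. Because the original
micrographs behind the published measurements are not publicly deposited,
every estimator is validated by parameter recovery on synthetic micrographs
generated at the published values; the generator is therefore first-class,
tested code.

## Synthetic micrograph model

A pore at the origin contributes, before blurring,

    f(r, θ) = c_p · ½ erfc((r − r_p)/(s_p√2))                      (plug)
            + c_i · exp(−(r − r_i)²/2s_i²)                         (inner ring)
            + c_o · (1 + a cos n(θ − φ)) · exp(−(r − r_o)²/2s_o²)  (outer ring)

with ridge radii r = d/2, widths given as FWHM (s = FWHM/2.355), and signed
contrasts relative to the membrane background (intensity = brightness;
electron-dense = dark, so the plug and outer ring are negative, the inner
ring positive — the negative-stain appearance). The plug diameter is defined
as the full width at half contrast of the central disk; ring diameters refer
to the ridge (peak) line. Generator and estimators share these conventions,
so recovery is exact in the noiseless limit; this is a deliberate design
choice because the published prose does not fix a measurement rule.

Defaults (the study conditions):

| parameter | default | note |
|---|---|---|
| d_outer, d_inner, d_plug | 33.5, 17.5, 9.5 nm | large pore class |
| medium class | ring 14.5 nm, centre 5 nm | no inner ring described; a zero-contrast placeholder keeps the type invariant and is flagged "missing" downstream |
| small class | 6 nm | metadata-grade preset |
| n_fold, subunit amplitude | 8, 0.5 | amplitude is not a published number; 0.5 gives clearly visible but non-saturating subunits |
| ring widths (FWHM) | 2 / 3 / 5 nm | plug edge, inner, outer |
| contrasts | −0.25 / +0.15 / −0.25 | background 0.5 (membrane), 0.3 (exterior) |
| pixel size | 0.69 nm/px | detector value |
| PSF | Gaussian, σ = 1 nm | no CTF; morphometry and symmetry operate at scales where a Gaussian envelope suffices |
| noise | i.i.d. Gaussian; SNR ≡ \|c_o\|/σ | stated with every fixture |
| densities | 87 and 200 pores/μm² | lysed-cell and fraction-3 preparations |
| tilt | affine compression by cos(tilt) along one axis | in-plane proxy for out-of-plane tilt; observed tilts < 10° |
| basket depth | metadata only | 3D feature, never rendered |

Sheets place `round(density × area)` pore centres by sequential hard-core
rejection sampling (uniform proposals, minimum separation 35 nm, at most
100× target attempts; feasible below packing fraction 0.55). Gold particles
are placed with a controlled associated fraction: edge distance uniform on
[0, 20] nm for associated particles, strictly > 20 nm otherwise.

What the generator does **not** emulate: CTF oscillations, stain granularity
and correlated noise, membrane curvature and folding, partial/overlapping
pores, the "reverse (basket-side) view" interpretation of the medium class,
and 3D projection through tilted specimens (tilt is a 2D affine proxy).
Passing recovery tests therefore demonstrates estimator correctness under
the stated image-formation model, not performance on arbitrary real
micrographs.

## Morphometry

The pore centre is refined as the centre of 2-fold point symmetry: the
cross-correlation peak between the patch and its 180°-rotated copy sits at
twice the centre offset; the peak is found by zero-padded FFT correlation
with per-axis parabolic interpolation, and a slow integer-grid search serves
as the independent oracle in tests. Radial profiles use contiguous annular
bins (default width = 1 px = 0.69 nm) about the refined centre.

Feature extraction from the profile: the baseline is the mean of the
outermost 20% of bins (default patches extend to 1.1 × d_outer so this
region is ring-free). A lightly smoothed copy (Gaussian, σ = 1 bin;
symmetric, so peak and half-crossing positions are unbiased) is used for
segmentation: the plug extent is the contiguous run above half the central
contrast, the inner ring is the strongest bright local maximum beyond the
plug, the outer ring the strongest dark local maximum beyond the inner.
Ridge positions are refined with a 3-point parabola; the plug radius is the
steepest half-contrast down-crossing inside the innermost detected ring
(noise produces shallow spurious crossings; ring flanks are excluded by the
search bound). Features below 8% of the strongest profile amplitude are
flagged missing. Reported uncertainty is half a bin width combined in
quadrature with the parabola shift.

Known bias: the PSF shrinks the apparent half-contrast radius of the curved
plug edge by roughly σ_PSF²/d ≈ 0.1–0.3 nm; this is inherent to the
definition and well inside the ±0.8 nm tolerance used in recovery tests.
Ordering (plug < inner < outer) is enforced by flagging, not by clamping.

## Symmetry analysis

Reinforcement score: mean Pearson correlation between the raw patch and its
k·(360/n)-degree rotations (bilinear, about the refined centre) over the
annular band [0.5·r_plug, 1.1·r_outer]. The control evaluates the same
correlation at m = 99 seeded random angles (≥ 1° away from any commensurate
increment). Tilt: if the outer-ridge second-moment ellipse has axis ratio
< 0.97 the patch is first stretched by 1/ratio along the minor axis.

Selecting the order needs a noise scale that is not inflated by the signal:
the self-correlation of a symmetric object varies deterministically with
angle (harmonics of its symmetry), so the raw control s.d. mixes signal
structure with sampling noise. The controls are therefore regressed on
integer angular harmonics up to n_max; the residual s.d. σ_noise estimates
the sampling noise of a single correlation, floored at 0.005 (the
bilinear-interpolation error scale, below which exactly-commensurate
rotations — 90°/180°/270° are interpolation-free — would reach spurious
significance on nearly rotation-invariant images).

An order n qualifies when its gap `g(n) = score(n) − control mean` exceeds
all of: 0.02 (absolute floor; a circular object's gap is pure interpolation
error), 0.15 · (1 − control mean) (relative floor: the fraction of variance
not already shared under arbitrary rotation that n-fold rotation explains —
pure noise shows incidental angular structure with absolute gaps up to
~0.08, but never explains more than a small fraction of its own entirely
unshared variance), and 3σ_noise/√(n−1) (score(n) averages n−1
correlations). Among qualifiers the largest standardized gap
z(n) = g(n)·√(n−1)/σ_noise wins, ties to the larger n. Standardization does
double duty: score(2) is a single noisy correlation while score(8) averages
seven, so raw-score comparison favours small orders by sampling variance;
and for a perfect n-fold image every divisor of n ties at the maximum raw
score, where the √(n−1) factor resolves the degeneracy toward n itself.
If nothing qualifies the result is "none".

The angular power spectrum (azimuthal profile on ≥ 360 bins in the same
band; dominant non-DC harmonic up to n_max) is computed alongside as an
independent cross-check; on synthetic SNR-3 pores the two agree in ≥ 95% of
seeded trials. n_max = 12 guards against aliasing at no cost. All rotations
are bilinear by default; bicubic is available by flag and must agree on the
selected order.

The bandpass filter (Fourier-domain difference of Gaussians, half-power
feature sizes at the 40 px / 3 px cutoffs, DC restored) exists for display
only; its output carries a provenance tag and symmetry scoring warns if it
ever receives one.

## Detection and density

Templates are zero-mean dark Gaussian annuli (width = the generator's outer
ring FWHM) over a ridge-radius grid (default 14.75/16.75/18.75 nm);
`skimage.feature.match_template` provides the normalized cross-correlation,
making detection exactly invariant to affine intensity changes. Peaks above
0.35 inside the membrane mask are pruned by greedy NMS (descending score,
ties by row then column; 30 nm exclusion). Detections nearer the mask
boundary than their ridge radius are flagged "edge" but kept — density uses
all detections, as no edge rule is published. Membrane masks come from the
ground truth for synthetic scenes or from Otsu + closing + largest component
for real images. Density is count/area with the Poisson interval
count ± 1.96√count scaled by area.

## Immunogold association

Distance is measured to the outer-ring edge by default (size-independent
across pore classes; centre-distance mode by flag, membrane traces via
polyline or mask distance). The 20 nm rule is inclusive ("does not
exceed"). The permutation null redraws all particle positions uniformly in
the membrane mask B times (default 999); p = (1 + #{replicate fraction ≥
observed})/(B + 1), minimum attainable 1/(B+1). Background-category
exclusion (e.g. cell-wall particles) is supported as an optional mask and
off by default. The published tallies (397/45, 549/60) cannot be recomputed
without the original micrographs; they enter the tests only as fraction
arithmetic and boundary-semantics fixtures.

## Problem sizes and numerical choices

Recovery experiments use 50 patches per cohort, 1–2 μm² sheets, 99 control
angles, B = 99–999 permutations, and 100-seed concordance runs — sizes at
which every quantity is stable to well inside its tolerance. Determinism:
every stage seed derives from the global seed via `SeedSequence`; identical
config + seed reproduce bit-identical images, tables and report.json (stage
timings go to the log, not the report). Coordinates are 0-based (row, col)
with physical position = index × pixel size; public tables use x = col·ps,
y = row·ps. MRC I/O uses the EM cell/grid convention for the pixel size;
TIFF carries a JSON sidecar. Images are never rescaled on read; a missing
pixel size is an error, not a default.

## Limitations

Single-image symmetry testing cannot distinguish a faint true symmetry from
incidental angular structure in noise below a relative reinforcement gap of
~0.15; at SNR ≤ 2 the selector returns "none" rather than guessing. The
2D tilt model breaks down above ~20°. The detector assumes the outer-ring
polarity of the negative-stain convention; freeze-fracture shadowing is out
of scope, as are 3D reconstruction, CTF simulation and basket measurement.
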