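# Methods

`histophantom` builds two-dimensional microstructural acoustic phantoms
from (real or synthetic) histology images, simulates plane-wave ultrasound
of those phantoms with a modeled linear array, and quantifies how realistic
the resulting speckle is. This note documents the models, the numerical
choices, and what the bundled synthetic data can and cannot show.

## Phantom model

A histology image is segmented into two microstructural components —
collagen and cells — plus background. Density is assigned per component as

    rho(x, z) = rho_global * ( M_background + mu_component * M_microstructure )

where `mu_component` is a unitless local heterogeneity multiplier
(`mu_collagen`, `mu_cell`). Component sound speed follows the empirical
Mast relation for soft tissue,

    c_local = (rho_global * mu + 349) / 0.893,

applied as an offset about the tissue's global sound speed so that the
background keeps its literature value:

    c(x, z) = c_global + (c_local - c_global) * M_microstructure.

Global properties per tissue (density, sound speed, power-law absorption
prefactor in dB/(MHz^y cm); exponent y = 1.1 everywhere):

| tissue | rho [kg/m^3] | c [m/s] | alpha0 |
|--------|-----|------|-------|
| artery | 1085 | 1565 | 0.6 |
| fat    | 911  | 1440 | 1.1 |
| muscle | 1085 | 1585 | 0.6 |
| skin   | 1100 | 1600 | 0.8 |
| water  | 1000 | 1480 | 2.2e-3 |

Estimated heterogeneity multipliers shipped as presets: fat 1.14 / 1.035,
artery 1.05 / 1.035, muscle 1.07 / 1.005, skin 1.15 / 1.020
(collagen / cell), with baseline speckle intensities 2.49e-8, 2.70e-8,
4.73e-8 and 3.40e-7 respectively. Skin phantoms are layered: the epidermis
and dermis rows carry the skin parameters and the hypodermis the adipose
fat parameters; the boundary is horizontal and its depth a config value
(default 2 mm) since no thickness is prescribed by the data the presets
derive from.

The isotropic *baseline* phantom replaces structure with an i.i.d. Gaussian
relative-density perturbation: `rho = rho_global * (1 + eps)`,
`eps ~ N(0, speckle_intensity)`. The mapping between "speckle intensity"
and a density IQR is not uniquely fixed; the builder accepts either a
dimensionless variance (the interpretation used for the preset values) or
a target density IQR, which it realizes exactly on the drawn sample. Sound
speed again follows the Mast relation as an offset about `c_global` — a
deliberate choice so that a baseline phantom declared to have, say,
c = 1504 m/s really has that background speed.

## Segmentation

k-means (k-means++ init, fixed seed) clusters the CIELAB chromaticity
channels (a, b); lightness is excluded because it varies with section
thickness and illumination rather than stain. Clusters are merged into
components either by explicit id sets or automatically: the reddest
cluster (highest mean a) becomes collagen, the yellowest (highest mean b)
cells, the lightest (highest mean L) background; leftovers join the cell
component (nuclei are merged into cells). The collagen mask is cleaned by
morphological opening then closing with disc structuring elements
(defaults 2 um radius; per-tissue cluster counts default to 4 for fat and
muscle, 3 for artery and skin — all overridable, since the optimal
per-tissue settings are sample-dependent).

Masks are anti-alias downsampled to the simulation grid: each mask becomes
a real occupancy field, low-pass filtered with a Gaussian whose -6 dB point
sits near the target Nyquist, resampled, and re-binarized around the 0.5
level with an area-preserving rank rule (keep the highest-occupancy pixels
until the source microstructure area fraction is matched). The rank rule
coincides with plain 0.5-thresholding except in degenerate cases (fields
everywhere ~0.5, e.g. sub-resolution checkerboards), where a fixed
threshold would collapse the area fraction to 0 or 1. Collagen wins ties
against cells, being the stronger scatterer.

## Synthetic histology

The generator emulates picrosirius-red stained sections (collagen red,
cytoplasm/muscle yellow, nuclei gray-brown dots): fat as a Voronoi
tessellation of adipocytes with collagen borders of prescribed thickness
(the border is the exact band around the Voronoi bisectors, so border area
= ridge length x thickness up to boundary effects) and an optional fascia
band; muscle as fascicle bands at a configurable fibre orientation with
wobbled perimysium lines (cosine-mode wobble, making 0 and 90 degree
slides exact transposes); artery as lumen / intima / media / adventitia
layers; skin as epidermis / dermis strata over a fat hypodermis. Default
scale mirrors 10x magnification (0.43 um/pixel, 2048^2). Masks are exact
ground truth by construction.

What this does **not** emulate: stain variability and bleed-through,
sectioning artifacts, out-of-plane structure, nucleus-level chromatin
texture. Passing segmentation tests on synthetic slides therefore shows
algorithmic correctness of the clustering/morphology chain, not robustness
to real staining variation.

## Wave solver

First-order linear acoustics are advanced by a k-space pseudospectral
scheme: spectral derivatives on a spatially staggered grid, the temporal
correction kappa = sinc(c_ref k dt / 2) (c_ref = max sound speed), and
split-field PML (20 points, quadratic profile, alpha_max = 2 nepers per
grid point; standard pseudospectral practice). Power-law absorption of
exponent y uses fractional-Laplacian absorption and dispersion terms with
tau = -2 alpha0 c^(y-1), eta = 2 alpha0 c^y tan(pi y / 2); y = 1 exactly is
rejected (tan singularity). Grid spacing is lambda/8 at the centre
frequency (24.7 um for the 7.6 MHz L11-5v at 1500 m/s; 10.4 um for the
18 MHz L22-14v) and the time step uses CFL 0.3 against the maximum sound
speed. Grid dimensions are rounded up to FFT-friendly sizes. State arrays
default to float32; float64 is used for the tightest conservation checks.

Elements are normal-velocity sources on the first interior row, each
represented by samples of the band-limited indicator of its width (the
rectangle convolved with the grid sinc kernel, truncated at 1e-3 of peak)
to avoid staircasing; receive is the aperture-weighted pressure sum per
element, then band-limited decimation to ~4 f0. The transmit waveform is a
Gaussian toneburst at f0 with 65% fractional bandwidth — a generic model
of a two-way array response, since measured proprietary waveforms are not
redistributable. Volume-injection point sources scale the density
increment by the local density, which makes source/receiver pairs exactly
reciprocal in heterogeneous media.

Numerical notes established by the test suite: in homogeneous media the
scheme's dispersion error is below 0.5% at 8 points per wavelength
(differential travel times); the leapfrog shadow energy (potential term
p_n p_{n+1}, not p_n^2) is conserved to ~1e-16 per 1000 steps in closed
lossless domains; RF is exactly linear in source amplitude. Absolute
envelope arrival times carry a few-nanosecond skew from finite-aperture
diffraction — a physics effect, not grid error.

## Beamforming

Delay-and-sum with the plane-wave delay law
t_tx = (z cos theta + x sin theta)/c plus the steering offset for
zero-normalized element delays; receive delays are geometric with the
aperture limited by a fixed f-number (half-aperture = depth / (2 F),
default F = 3.7) and rectangular apodization (no apodization is applied,
as none is prescribed). Angle images are summed coherently; the envelope
is the analytic-signal magnitude along depth. Reconstruction grids of 50
and 15 um and reconstruction speeds of 1500 m/s (fat, artery) / 1540 m/s
(muscle, skin) are the preset values. Because the axial RF carrier period
(c / 2 f0, ~99 um at 7.6 MHz) can fall at or below the display grid's
Nyquist, delays are evaluated on an internally oversampled axial grid, the
envelope is detected there, and then decimated to the requested spacing
(the envelope is band-limited well below the display Nyquist; skipping
this aliases the carrier and visibly corrupts envelope statistics). B-mode
display normalizes to the 99th percentile with a 60 dB dynamic range.

The autofocus estimator beamforms at candidate speeds and maximizes mean
envelope power. Its region of interest is gated in *time* (the central
fraction of the recorded span), not depth: a fixed-depth ROI maps to
earlier, less-attenuated echoes as the candidate speed grows and biases
the estimate high, whereas a time gate integrates the same physical echoes
for every candidate so only the coherent-summation gain differs. The
solver's staggered velocity source sits half a cell proud of the receive
row; the RF time origin is compensated accordingly. On point targets the
focus objective is sharp and maximizes at the true speed; on speckle the
objective is shallow and its maximum wanders by ~1% for a reduced
(32-element, ~10 mm) acquisition, tightening as aperture and ROI count
grow. The receive aperture edge is feathered over one pitch: with a hard
edge, shallow apertures of only a few elements switch element sets
discretely across the image and ripple the lateral PSF by tens of
micrometres.

## Speckle metrics

*First-order statistics.* Envelope ROIs are normalized to their 99th
percentile and histogrammed with bin width 0.03 — the Freedman-Diaconis
width (2 IQR n^(-1/3)) evaluated on the minimum ROI of 25 x 25 wavelengths
at the 50 um grid. Dissimilarity is the Jensen-Shannon divergence with
base-2 logs (bounded [0, 1]), convention 0 log(0/x) = 0; search areas are
tiled into ROIs with 20% overlap and summarized by the median JSD.
Normalization happens in the envelope domain (pre-log).

*Texture.* The texture anisotropy index low-pass filters a dB-domain ROI
with an isotropic radial fourth-order Butterworth magnitude response
(|H|^2 = 1 / (1 + (f/fc)^8)) at cutoffs (16 lambda)^-1 ... (2 lambda)^-1,
takes 3x3 Sobel gradients along the image axes, forms the gradient
covariance C = Wc' Wc / (N - 1), and reports TAI = 1 - lambda_min /
lambda_max (0 for a constant ROI, flagged). TAI is invariant to offset,
positive rescaling, and 90-degree rotation.

*Speckle size.* The mean-removed envelope autocovariance is computed
spectrally with zero padding (a true linear autocovariance), normalized at
zero lag; the 0.5-level contour of the central peak is extracted by
sub-pixel bilinear contouring and fit by least squares to an axis-aligned
ellipse (no tilt), whose full axes are the axial/lateral speckle FWHM.
Depth profiles tile square 20 x 20 wavelength ROIs with 80% axial overlap.

*Attenuation.* A least-squares line through log mean RF intensity versus
depth (z = c t / 2); half the round-trip slope divided by f0 in MHz gives
dB/(MHz cm). No diffraction compensation is applied, so the estimator is
meant for depth ranges where geometric spreading is secondary.

## Heterogeneity search

(mu_collagen, mu_cell) is estimated by exhaustive grid search (defaults
1.00-1.20 step 0.01 and 1.000-1.050 step 0.005, matching the precision of
the shipped presets) minimizing the median envelope-histogram JSD between
a simulated ROI (centre crop, avoiding simulator edge roll-off) and the
reference search area. Two simulators plug in: the full-wave pipeline, and
a convolutional surrogate (envelope of a Gaussian-enveloped two-way PSF
convolved with the impedance-gradient reflectivity) for fast parameter-
recovery experiments. One subtlety the surrogate experiments expose: with
percentile normalization, noiseless speckle statistics are invariant to a
global rescaling of heterogeneity, so the *magnitude* of mu is anchored by
the acquisition noise floor; the surrogate therefore models an absolute
electronic noise level (tests use ~-12 dB of the mean envelope), as a real
acquisition would provide. Recovery experiments regenerate a reference at
known (mu_collagen, mu_cell) with independent noise and jitter and require
recovery within one grid step over multiple seeds.

## CT-fused scenes

A CT slice is 10x oversampled, converted from HU to mass density by the
five-segment piecewise-linear stoichiometric calibration (water ~1018
kg/m^3 at HU 0; the raw published segments dip slightly at the seams near
14 and 100 HU, so each segment is floored at the running maximum of the
previous endpoints to keep the mapping monotone), and to sound speed by
the Mast relation pixel-wise. Tissues outside the four histology types get
class labels from half-open density intervals (an editable table; the
shipped bands are broad fat / soft tissue / muscle / connective / bone
defaults) with per-class absorption and speckle intensity scaled x50.
Transition edges between speckle-power regions are found by Sobel
magnitude thresholding and assigned connective tissue (1026 kg/m^3,
1545 m/s, 1.17 dB/(MHz cm)); the printed edge thickness (1.23 um) is below
the oversampled spacing (2.47 um), so edges are one pixel on that grid. A
delineated thyroid is smoothed with a Gaussian (sigma = 2.96 um) and set
to (1050 kg/m^3, 1500 m/s, 1.2 dB/(MHz cm), intensity 5e-7). Histology
phantoms are embedded with their mu deviations rescaled (factor 0.5 for
fat and muscle); artery-wall strips are warped onto an annulus of inner
radius 2.5 mm (lateral -> angle, depth -> radius, nearest-neighbour so
exclusivity survives); regions larger than the available microstructure
are covered by mirror tiling (replacing manual clone-stamp extension).

## Problem sizes used by the test suite

Full-scale acquisitions (40 x 40 mm, 128 elements, 41 angles) are
hours-scale on a single core, so the suite exercises the identical chain
at reduced scale, chosen as the smallest configurations that still develop
fully formed speckle: the PVA speckle-size check uses a 32-element
L11-5v aperture (9.6 mm), ~10 mm depth and 11 compounding angles at
+/-20 degrees, asserting the median axial/lateral speckle FWHM within
+/-25% of the full-scale in silico medians (172/278 um); point-target and
physics checks use 6-10 mm domains. Reproducing the full-scale medians
(and the L22-14v pair, whose 10.4 um grid is ~4x the cost) is an overnight
run of the same code via the CLI.

## Known limitations

Two-dimensional propagation only (no elevational spread — the known cause
of lateral speckle-size overestimates in vitro vs in silico); linear
acoustics (no B/A); no transducer electrical impulse-response
identification; the surrogate simulator ignores diffraction, multiple
scattering and attenuation and is for testing, not inference on real
data; the density-interval table and Schneider segment constants are
editable approximations, not calibrated to any particular scanner.
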