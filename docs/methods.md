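# Methods

This note documents the models behind `spectiq`, the parameters that
matter, the numerical choices, and what the synthetic study can and cannot
say about a physical scanner.

## Digital phantom

The NEMA IEC body phantom is voxelized by a voxel-center-inside-surface
test on three co-registered grids: activity (MBq/ml), linear attenuation
(cm⁻¹) and integer labels (0 outside, 1 background, 2–7 the spheres,
largest first). The D-shaped interior cross-section is composed of a
150 mm half-disc on top of an 80 mm slab with 80 mm rounded bottom corners
(300 × 230 mm overall, ≈10.2 L over the 180 mm axial extent — a shell-less
approximation of the published interior). The six spheres (37, 28, 22, 17,
13, 10 mm inner diameter) sit at 60° spacing on a 114.4 mm circle in one
transverse plane. Sphere shells and the central low-density insert are not
modelled (the insert hook exists as geometry but is off by default, since
no metric uses it).

Fills: the hot-sphere concentration `a_H` and the target-to-background
ratio define the background as exactly `a_B = a_H / (T/B)`; the four study
fills use `a_H` = 0.20, 0.11, 0.06 and 0.03 MBq/ml at 32:1, 16:1, 8:1 and
4:1. Decay calibration multiplies a concentration by `2^(−t/T½)` with the
Tc-99m half-life T½ = 6.0058 h (configurable). Attenuation is water at
140 keV inside the body (μ = 0.154 cm⁻¹), zero outside.

Grids: full-scale default is 128×128×64 at 3.3 mm isotropic. The desk
study profile used by the sweeps, tests and acceptance script is 64×64×32
at 5.5 mm with the body trimmed axially to 160 mm so it fits the axial
field of view; at that pitch the 10 mm sphere spans only ~3 voxels, which
is deliberately harsh on partial-volume behaviour but keeps a full
reconstruction under half a minute. A 1 mm (and 0.5 mm) reference grid is
used only in geometry tests, where voxelized compartment volumes agree
with the analytic sphere volumes to 2 %.

## Acquisition model

Step-and-shoot, 360° in 60 views of 6°, detector bins at the voxel pitch,
axes (view, transaxial bin, axial bin). The projector is rotation-based:
per view the activity grid is rotated in-plane about the axial axis by a
precomputed sparse bilinear matrix and summed along the ray axis. The
transport matrix is column-normalized so every voxel deposits exactly its
content into the view (count conservation to machine precision); the
μ-map is resampled with the plain interpolating rotation, since the
Beer–Lambert factor `exp(−∫μ dl)` needs values, not mass. Attenuation per
voxel uses the cumulative μ from the voxel center to the detector with a
half-voxel self term. The collimator-detector response is a
depth-dependent Gaussian, FWHM(d) = 4.0 mm + 0.045·d (d = distance to the
detector face at the edge of the field of view), applied plane-by-plane at
the rotated orientation. Planes are grouped into 16 depth bins sharing one
kernel; within a group the planes are summed before blurring, which is
exact for a shared kernel and cuts the filter count 4×. Blurs use
zero-padded convolution, so each per-view operator has an exact transpose
— the backprojector is that transpose, giving the matched operator pair
OSEM assumes.

Energy model: the detector records a Gaussian photopeak at 140 keV with
6 % FWHM energy resolution (CZT-like). Window efficiency is the Gaussian
mass inside the window bounds (0.997 for 140 keV ± 7.5 %, ~1.0 for
± 10 %). Scatter in the photopeak window is a stationary 2-D Gaussian blur
(σ = 30 mm) of the primary sinogram, globally scaled so that
scatter/(scatter+primary) equals 0.25 for the 15 % window or 0.32 for the
20 % window; the 120 keV ± 5 % scatter window records 1.1× the photopeak
scatter. This generative scatter model is intentionally different from the
dual-energy-window model the reconstruction uses to remove it, so
correction studies are not an inverse crime: the DEW estimate
`0.5·(21/12)·C_sc ≈ 0.96 × true scatter` slightly under-corrects at the
15 % window and over-corrects (`0.5·(28/12)·1.1 ≈ 1.28×`) at the 20 %
window, reproducing the direction of the published window comparison.

Counting noise is per-bin Poisson with child seeds spawned
deterministically from the acquisition seed; photopeak and scatter windows
are independent given their expectations (the physical system re-bins one
list-mode stream, so its windows share events — a known divergence).
System sensitivity defaults to 140 counts·s⁻¹·MBq⁻¹, giving ≈10⁶
photopeak counts per 120 s view for the 32:1 fill. List-mode re-framing
to shorter times is binomial thinning with retention `t/120`, i.e. a
sub-sample of the same event stream, not an independent acquisition;
marginally the thinned counts are again Poisson.

## Reconstruction

OSEM maximizes the Poisson likelihood of `y ~ Poisson(Ax + s)` by the
multiplicative update `x ← x/(Aᵀ1)·Aᵀ(y/(Ax+s))` cycled over angular
subsets formed by stride (maximally spread angles; sizes differ by ≤1 when
the subset count does not divide 60). One subset is exactly MLEM. `A`
contains the true μ-map when AC is on and the depth-dependent PSF when RR
is on; RR off is a deliberate model mismatch, as clinically. `s` is the
DEW estimate (k = 0.5) when SC is on, else zero; scatter is handled
additively inside the forward model, which preserves Poisson statistics
and nonnegativity — a pre-subtraction mode (`y − s` clipped at zero) is
available for fidelity to older DEW practice. Initialization is a uniform
image restricted to the body support (μ > 0) when AC is on. Guards: bins
with zero forward value contribute a zero ratio; voxels whose subset
sensitivity is below 1e-8 of its maximum are frozen. Calibration
(voxel volume × sensitivity × frame time × window efficiency) is folded
into `A`, so the estimate is in MBq/ml throughout; this is algebraically
identical to reconstructing in count units and converting once at the end.

The Gaussian post-filter (FWHM 0.7–6.99 mm in the protocol) is applied in
the Fourier domain with the exact Gaussian transfer function. Rationale:
at 5.5 mm desk voxels a truncated spatial kernel with sub-voxel σ
degenerates to the identity, which would flatten the RC-versus-FWHM curve
at its small end; the Fourier filter is strictly contractive on every
non-DC frequency for any σ > 0, preserves the mean exactly, and keeps the
monotone RC decline the filter study measures. Its periodic boundary is
immaterial for objects inside the body.

## Quantification

Sphere VOIs are the ground-truth label masks (the CT-guided "inner edge"
delineation, adopted as a design limitation); means use all masked voxels
and SDs the n−1 denominator. Background ROIs follow the NEMA NU 2 layout:
for each sphere size, one circle of that diameter at each of 12 positions
on a 100 mm ring, on the central sphere plane and the slices nearest
±1 cm and ±2 cm — 60 ROIs per size, each required to stay ≥15 mm from the
body edge and clear of every sphere, with an explicit placement error
otherwise. RC, percent contrast and COV are computed from the same
reconstructed volume (the contrast and COV ratios are scale-invariant, so
counts versus MBq/ml is immaterial). The VOI SD is voxel-wise within the
mask; an SD across repeated noise realizations is available by re-running
with different seeds (the published triplicate measurement is
deterministic here).

## Sweeps and statistics

The sequential protocol starts from 6 subsets, no filter, AC+SC+RR,
120 s/frame, 15 % window, and evaluates iterations → subsets → filter
FWHM → correction combination → energy window → acquisition time,
freezing each step's optimum (mean RC closest to 100 %; the filter step
keeps "no filter" since a post-filter only ever lowers RC). Shared work is
cached: the iterations sweep reconstructs once and records per-iteration
recovery curves through a callback; the FWHM sweep filters one unfiltered
reconstruction; the time sweep thins one full-length acquisition.

Statistics are two-sided throughout with α = 0.05 and no multiple-testing
correction. "Correlation" is product-moment Pearson (r with a t-based p on
n−2 df); rank correlation is available but unused by the protocol.
Regression is ordinary least squares; the paired t-test uses df = n−1.
Iteration statistics are reported separately for ranges 1–35 and 35–90
with the boundary iteration in both, matching the published table layout.
"Converged at iteration n" is not defined in the source protocol; here it
is the smallest n whose next 10 iterations gain less than 1 RC percentage
point — both knobs configurable and reported with results.

## What the synthetic study shows — and does not

The generator emulates attenuation, depth-dependent resolution, broad
scatter, window-dependent scatter fractions and Poisson counting at
realistic count levels, so qualitative findings transfer: EM convergence
ordering by sphere size, the early/late iteration regression-coefficient
gap, the strict RC decline with filter FWHM, the correction ordering
AC+RR ≥ AC+SC+RR ≥ AC+SC with contrast favouring AC+SC+RR, and the decay
of RC noise with frame time. Absolute RC values are scanner-specific —
they depend on the vendor's proprietary OSEM, collimator and energy
response — so the published tables are bundled as reference data for exact
statistical recomputation, not as targets for the simulator. Not modelled:
Monte-Carlo photon transport, septal penetration, detector dead time, CZT
charge sharing and low-energy tailing, CT imaging and Hounsfield-to-μ
conversion (the μ-map is ground truth), sphere shells, and any
partial-volume correction.

## Reproducibility and problem sizes

Every stochastic stage consumes an explicit seed; study- and script-level
seeds spawn per-stage children through `numpy.random.SeedSequence`. The
test suite and the acceptance script use the desk profile (64×64×32 at
5.5 mm, 60 views, 16 iterations × 12 subsets for noisy studies, a 200
iteration × 30 subset deep run for the noiseless recovery check, 5 noise
seeds for the correction comparison and 10 for the acquisition-time noise
study) — sizes chosen so the whole suite runs in minutes on one CPU while
every qualitative property remains measurable.
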