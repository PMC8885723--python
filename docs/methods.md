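# Methods

## Acquisition model and unit conventions

All protocol arithmetic flows through one module (`tadmri.protocol`).  For
rectangular pulsed gradients of width δ and separation Δ the effective
diffusion weighting is b = (γ_H g δ)²(Δ − δ/3), with the proton
gyromagnetic ratio γ_H = 2.675×10⁸ rad s⁻¹ T⁻¹ (configurable).  Two
q conventions are first-class citizens and never mixed silently:
`radian` (q = γ_H g δ, used by the stretched-exponential models) and
`cyclic` (q = γ_H g δ / 2π, used by q-space imaging, so that attenuation
and displacement profile form an ordinary Fourier pair).  Internally g is
mT/m, δ and Δ ms, b s/mm², q rad/mm or 1/mm, displacements and compartment
widths mm (micrometres at the reporting surface).  Images are (z, y, x[,
volume]) with 0-based indices and voxel size in mm.

Protocol factories encode the four pulsed-gradient stimulated-echo
experiments used throughout: a γ ramp (3 orthogonal directions × 17
effective b from 61.2 to 8521.2/8521.2/9496.6 s/mm², Δ = 40 ms), an α ramp
(Δ ∈ {40, 60, 80, 150, 300, 500, 800} ms at constant g ≈ 80.8 mT/m, with
receiver gains {64, 64, 64, 64, 421.147, 855.654, 2801.08}), a 6-direction
single-shell tensor protocol, and a 31-shell q-space ramp reaching
q ≈ 95.5 mm⁻¹ (b = 14171 s/mm²).  Stored b values are validated against
the gradient arithmetic to 0.5%; "effective" gradients are taken as given
(imaging-gradient cross-terms are not recomputed).

## Voxel models

All nonlinear fits use SciPy's bounded trust-region-reflective least
squares (tolerance 1e-10, ≤ 400 iterations), are deterministic (no random
restarts), and report convergence, residual norm and bound-pinning flags.

**Pseudo-superdiffusion (γ).**  S(q)/S₀ = p₁·exp((−p₂q^{p₃} − D₀q₀²)Δ) +
p₄ with p₄ fixed at 0.15 (the value four-parameter pilot fits converge to
on magnitude data; re-estimation is a non-default option), initialization
(1, 1e-10, 1.8) and bounds [0,0,0]–[∞,∞,2]; γ = p₃/2.  Two numerical
choices matter.  First, the conventional initialization p₂ = 1e-10 is
meaningful only in SI units, so the model works in rad/m and seconds
internally.  Second, p₂ spans many decades between that initialization and
its optimum; it is optimized as ln p₂ (the linear parameterization stalls
the trust-region scaling and does not reach the optimum even at tight
tolerances).  The D₀q₀² term compensates attenuation already present in
the lowest-shell reference used as S₀; because p₁ is free the term is a
constant factor absorbed into the amplitude — it changes p₁, never γ
(tested as an invariance).  D₀ defaults to 0 at the voxel surface;
`fit_gamma_map` accepts a mean-diffusivity map or per-tissue scalar.

**Transient subdiffusion (α).**  ln S(Δ) = ln p₁ [− Δ/T1] − p₂q₀²Δ^{p₃}
with bounds [0,0,0.5]–[∞,∞,1.1], amplitude initialized at max S and p₂ at
the tissue's mean diffusivity (`fit_alpha_map` takes per-tissue medians;
the spinal cord is segmented into WM and GM+fluid and fitted per class).
q₀ is the constant q of the experiment (the separately acquired b0 volume,
which has a different effective gradient, is not part of the fit — the
amplitude is free).  The exponent is linear in p₂, matching the defining
signal model; the squared-p₂ reading of the fit expression is available
behind `squared_dgen=True`.  Because the receiver-gain schedule makes the
RG-corrected log-noise heteroscedastic by a factor ≈ 40 across the Δ grid,
log-residuals are weighted by each sample's known relative precision
(RG × signal) by default; the unweighted fit is `weighting=None`.  The
weighting brings the estimator from a median |α̂ − α| ≈ 0.05 to ≈ 0.025 at
SNR 30, close to the Cramér–Rao bound (≈ 0.028) for this design.

The optional T1 factor divides out the known longitudinal decay over the
stimulated-echo mixing time (TM ≈ Δ; T1 ≈ 760 ms in fixed WM, 600 ms GM).
A structural caveat the test suite documents explicitly: the −Δ/T1 term is
algebraically absorbable by the stretched term only at α = 1 (where
Δ^α ∝ Δ).  Away from that limit, fitting T1-decayed data *without* the
factor biases α upward (≈ +0.15 at α = 0.7, ≈ +0.05 at α = 0.9 under this
protocol), so "corrected and uncorrected fits agree on α" holds exactly in
the Gaussian limit and only approximately near it.  The corrected fit
recovers α exactly in all regimes.

**Q-space.**  The low-q biexponential S(q) = p₁e^{−2π²p₂²q²} +
(1−p₁)e^{−2π²p₃²q²} + p₄ fixes p₄ = 0.2, initializes at
(0.7·max S, 5 μm, 1.5 μm) and bounds widths to 10 mm.  The likelihood is
symmetric under (f → 1−f, widths swapped); after fitting, compartments are
relabeled so Z_ecs ≥ Z_ics and f refers to the wider one, which makes the
fraction-initialization indetermination (0.3 vs 0.7 give identical
residual norms) invisible to callers.  Fits with coinciding widths are
flagged single-compartment.  The published initialization for the
intracellular width exceeds its own bound under any unit reading; the
default here is 1.5 μm, the tissue-plausible scale.

**Displacement profile.**  The attenuation is resampled onto a uniform q
grid anchored at 0 (the measured grid starts at the lowest shell; the
attenuation is extended flat below it), mirrored evenly, discretely
Fourier transformed (no zero-padding by default; a padding factor is
exposed), and the real part's central 11 points are kept — the tails
fluctuate with noise.  The profile is fitted with L(x) = p₁ +
(1/π)p₂/(x² + p₂²); p₂ = y₀ is the half width at half maximum and
FWHM = 2y₀ identically (stored, never recomputed).  With q_max ≈
95.5 mm⁻¹ the displacement resolution is 1/(2q_max) ≈ 5.2 μm, so
micrometre-scale widths are resolution-broadened; width recovery is
therefore assessed FWHM-against-FWHM (pipeline FWHM vs the generator
propagator's true FWHM, 2√(2 ln 2)·Z for a Gaussian compartment of width
Z), the commensurate comparison, which recovers a 1.5 μm restriction scale
to ≈ 3% at SNR 30.  Comparing the fitted half-width against the Gaussian
σ-scale instead mixes two width conventions (HWHM vs σ) and misleads by
construction.

**DTI and relaxometry.**  Ordinary log-linear least squares on the six
unique tensor elements plus ln S₀ (weights exposed, off by default);
eigenvalues sorted descending; FA = √(3/2)·‖λ − MD‖/‖λ‖; D∥ = λ₁,
D⊥ = (λ₂+λ₃)/2.  Relaxometry fits S = S₀e^{−TE/T2} (log-linear start,
nonlinear refinement); non-decaying voxels are flagged with R2* = 0 rather
than extrapolated.

**Exponent invariants.**  M = mean, A = 3Σ(eᵢ−M)²/(2Σeᵢ²), par = e₁,
ort = (e₂+e₃)/2.  A is computed on max-normalized components (it is
scale-invariant, and this keeps it finite for extreme inputs), lies in
[0, 1] for non-negative triplets, and is NaN (with a mask update) for
all-zero voxels — not 0, which would fake isotropy.  The formula is used
exactly as defined, without the square root of the FA-style analog; the
rooted variant is available for comparison.

## Synthetic data

The generators exist to make every pipeline stage testable without scanner
or microscope data; their forward models are exactly the fit expressions
above, so what they establish is estimator correctness (forward-inverse
consistency, noise robustness), *not* biophysical validity — there is no
restricted-diffusion Monte-Carlo, no orientation dispersion, no crossing
fibers, and the γ generator's exponent q^{2γ} is the fitted
parameterization itself.

The cord phantom is a parametric cross-section: fluid-filled capillary,
GM butterfly (two mirrored ellipse lobes), and a WM rim cut into six
angular sectors carrying tract labels.  Default tissue parameters: fluid
γ = α = 1 (Gaussian), isotropic tensor 2.0e-3 mm²/s, T1 = 2000 ms; GM
γ = 0.85, α = 0.9, Dgen 0.9e-3, T1 = 600 ms; WM tracts γ_par 0.9→0.7,
γ_ort = γ_par − 0.1, α 0.85→0.75, Dgen 0.5e-3 mm²/s^α, prolate tensor
(1.4, 0.3, 0.3)e-3, T1 = 760 ms, Z_ics 1.0–2.0 μm — fixed-tissue values a
practitioner would call typical for ex-vivo cord.  Magnitude noise is
Rician (independent Gaussian noise in both quadrature channels), with SNR
defined against the reference S₀; a signal-free background is then
Rayleigh, so the plain ROI-mean/background-SD ratio overestimates the
channel SNR by 1/√(2−π/2) ≈ 1.53 — the SNR recovery test applies that
conversion.  γ-series include a noise-floor offset fraction (default 0.15,
matching the fixed fit offset); q-space series an additive 0.2 for the
same reason; α-series are scaled by their receiver gain before noise, so
that RG correction also rescales the noise — the reason the schedule
exists.

Micrographs are rendered by random sequential adsorption of
non-overlapping disks (axoplasm) wrapped in myelin annuli of fixed g-ratio
0.7, on an extracellular background, at 0.033 μm/pixel by default, with
Gaussian diameters truncated at 3 pixels and four distinct gray levels
(myelin darkest).  Debris objects deliberately violate the selection
rules: sub-threshold speckles, ≥10:1 bars, and mottled blobs.  The
clustered/dispersed free-space layouts hold axon count and diameters fixed
while moving the empty space, isolating what ELD is meant to detect.
Packing targets above ≈ 35% outer-disk area fraction approach the RSA
limit and raise a PackingError that reports the achieved count.

## Morphometry

Preprocessing is a pixel-wise adaptive Wiener filter over a 0.2 μm window:
local mean plus (1 − noise/local-variance)₊ times the deviation, computed
on reflective-boundary local statistics (zero padding would darken edges
and violate mean preservation; the implementation is verified against a
brute-force windowed oracle).  Segmentation digitizes intensities at three
cut points (manual or multi-Otsu) into myelin/ICS/ECS/other; fractions are
computed over the ROI and sum to one exactly.  Candidate axons are
8-connected components of the ICS mask, rejected by the conjunction of
three order-independent rules: area below 10 px (user-adjustable — the
threshold is deliberately delegated), perimeter/√area > 6.2, σ/μ > 0.5.
Perimeters use the Crofton estimator (4 directions): the weighted
boundary-step estimator overshoots digitized disks (ratio → 3.71 rather
than 2√π ≈ 3.545), and with a cut at 6.2 between disk (3.545) and 10:1 bar
(≈ 6.6 Crofton / 6.96 ideal) the estimator choice is load-bearing.
Diameters are equivalent-circle diameters from area, the robust measured
primitive.  AxDens = f_axon/(π(AxDiam/2)²); note this defining ratio
equals count density times E[d²]/d̄² = 1 + CV², so at the default diameter
scatter (CV = 0.2) it sits ≈ 4% above the count density by construction.
ELD is operationalized as kept-axon count divided by the area of the
kept-axon regions dilated by 2×AxDiam (distance-transform implementation),
intersected with the ROI — density over axon-occupied neighborhoods,
ignoring free regions.  Absolute ELD values are convention-dependent and
not comparable across implementations; only orderings (clustered >
dispersed free space) are meaningful, and only those are tested.

## Validation statistics

ROIs are MD-threshold bands (fluid/GM/WM splits), with interface bands
(e.g. gm-wm) defined as the intersection of 2-voxel dilations of the two
tissues.  ROI summaries exclude invalid voxels and count them.  Pearson r
with two-tailed P from the t distribution (n − 2 df) over matched ROI
rows; significance stars at 0.05/0.01/0.005/0.001; no multiple-comparison
correction is applied, mirroring the validation design this package
follows.  The γ-vs-R2* relation is ordinary least squares across ROI
means.  Area fractions are compared with a pooled two-proportion z-test.

## Validation studies (acceptance surface)

`tadmri.studies` wires the above into self-contained studies whose
numbers `scripts/acceptance.py` recomputes from a seed: protocol-arithmetic
cross-checks of all printed effective b values; invariant algebra over 1e5
random triplets; γ recovery on the 17-shell × 3-direction grid
(γ ∈ {0.6, 0.8, 1.0}, 100 noise seeds each, pooled median |error| — the
noiseless fits are exact to < 1e-3, and γ = 1 pins p₃ at its bound of 2);
α recovery with the printed RG schedule (α ∈ {0.7, 0.9}); the α T1
with/without comparison (see the caveat above — reported as measured);
noiseless biexponential recovery with the 0.3/0.7 initialization check;
Lorentzian-pipeline width recovery at a 1.5 μm restriction scale;
morphometry recovery on a 500-axon, 80 μm field at 0.033 μm/pixel
(diameters 1.5 ± 0.3 μm, ≈ 29% outer packing, 6 debris objects); the
clustered-vs-dispersed ELD ordering at 90 axons; and a six-tract
end-to-end study in which ground-truth γ increases linearly with tract
axon diameter (0.9–1.9 μm) and the pipeline's Pearson table must recover
the strong positive Mγ–AxDiam association.  Problem sizes (a 40×40 cord
slice, 20 μm tract micrographs) are chosen so the whole battery runs in
well under a minute while leaving each estimate's Monte-Carlo error an
order of magnitude below the margins being tested.

## Known limitations

Three orthogonal directions give a first-order characterization of the
exponent anisotropy; estimating the intrinsic anomalous-diffusion frame
would need ≥ 12 directions and is out of scope, as are orientation
dispersion, crossing fibers, denoising/Gibbs-unringing preprocessing,
multi-component T2, and biophysically generative diffusion simulation.
Absolute ELD values are implementation-defined.  The displacement-profile
resolution is q_max-limited; widths below ≈ 5 μm are recovered only in the
FWHM-vs-FWHM sense described above.
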