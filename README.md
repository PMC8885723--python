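# tadmri

Transient anomalous diffusion (tAD) MRI analysis for ex-vivo spinal cord,
with the histology morphometry and statistics needed to validate diffusion
contrasts against tissue microstructure.

Water diffusion in white matter is only approximately Gaussian.  Two
stretched-exponential acquisitions probe the departures:

* **γ-imaging (pseudo-superdiffusion)** ramps the gradient strength *g* at
  constant diffusion time Δ and fits

  S(q)/S₀ = p₁ · exp((−p₂ q^{p₃} − D₀q₀²)·Δ) + p₄,  γ = p₃/2 ∈ [0, 1],

  with q = γ_H·g·δ.  γ < 1 reflects magnetic-susceptibility inhomogeneity
  (myelin/ECS interfaces), not true superdiffusion.
* **α-imaging (transient subdiffusion)** ramps Δ at constant *g* and fits

  ln S(Δ) = ln p₁ − p₂ q₀² Δ^{p₃},  α = p₃ ∈ [0.5, 1.1],

  where α < 1 quantifies the local disorder a water molecule explores as
  its diffusion length grows.

Alongside these the package implements **q-space imaging** (low-q
biexponential compartment fit S(q) = f·e^{−2π²q²Z_ecs²} +
(1−f)·e^{−2π²q²Z_ics²} + p₄, and the displacement-profile route: mirror
the attenuation, Fourier transform, fit a Lorentzian whose FWHM = 2y₀
tracks the restriction scale), **DTI** (log-linear tensor fit: MD, FA,
D∥ = λ₁, D⊥ = (λ₂+λ₃)/2) and **T2*/T2 relaxometry** (R2* = 1/T2*).
Directional exponent triplets are summarized by their mean, anisotropy
A = 3Σ(eᵢ−M)²/(2Σeᵢ²) ∈ [0, 1], parallel and orthogonal components.

The validation side re-implements the quantitative histology used to
ground these contrasts: adaptive Wiener filtering, four-class threshold
segmentation (myelin/ICS/ECS/other with fractions summing to one),
axon selection rules (area, perimeter/√area ≤ 6.2, σ/μ ≤ 0.5), and the
per-tract summaries AxDiam, SD_ax.diam, AxDens = f_axon/(π·(AxDiam/2)²),
and the effective local density ELD (density over axon-occupied
neighborhoods only).  Pearson tables, an R2* regression and a
two-proportion z-test connect the MRI and histology arms.

Because no imaging data are shipped, every stage is exercised end-to-end
on synthetic phantoms: a parametric spinal-cord cross-section driven by
each acquisition protocol (with Rician magnitude noise and the published
receiver-gain schedule), and toluidine-blue-like micrographs of packed
myelinated axons with known diameters, density and debris.

## Worked example

Fit one voxel of a simulated γ-imaging shell ramp (17 effective b-values,
61.2 → 8521.2 s/mm², Δ = 40 ms, Rician SNR 30):

```python
import numpy as np
from tadmri import (GammaDecayModel, gamma_protocol, q_from_b,
                    add_rician_noise, exponent_invariants)

proto = gamma_protocol()                      # three orthogonal directions
vols = proto.volumes()
sub = vols[vols.direction_index == 0]
q = q_from_b(sub["b_s_mm2"].to_numpy(), proto.delta, 40.0, "radian")

dgen = 3.0 / ((q.max() * 1e3) ** (2 * 0.8) * 0.040)   # ground truth gamma=0.8
S = 0.85 * np.exp(-dgen * (q * 1e3) ** (2 * 0.8) * 0.040) + 0.15
est = GammaDecayModel().fit(q, add_rician_noise(S, snr=30, seed=7))
print(f"gamma_ = {est.gamma_:.3f}  dgen_ = {est.dgen_:.3e}")
# gamma_ = 0.774  dgen_ = 1.246e-07

print(exponent_invariants(0.82, 0.71, 0.69))
# {'mean': 0.74, 'anisotropy': 0.0089, 'par': 0.82, 'ort': 0.7}
```

`gamma_` lands within the Monte-Carlo scatter of the true exponent 0.8 at
this SNR (median |error| ≈ 0.03 over the full grid), and the invariant
triplet shows a nearly isotropic voxel (anisotropy ≪ 1) with the parallel
exponent highest, as expected along coherent fibers.

All estimators are scikit-learn compatible (`fit`/`predict`,
`get_params`/`set_params`, trailing-underscore attributes);
`tadmri.maps.fit_*_map` applies them voxel-wise over masked 4D stacks and
returns named parametric maps, written to NIfTI via `tadmri.stack`.
A thin `tadmri` CLI covers the common shell workflows
(`tadmri convert-b`, `tadmri simulate dwi|histo`,
`tadmri fit gamma|alpha|qsi|dti`, `tadmri metrics`, `tadmri morpho`,
`tadmri correlate`).

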