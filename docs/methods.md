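# Methods

## The problem

Refractive-index (RI) tomography reconstructs a sample's 3D refractive index
n(r) from complex fields u(r, k_in) measured under plane-wave illumination at
many incidence angles.  Linear (Born/Rytov-type) inversions are fast but
assume weak scattering; in thick multicellular samples two effects break
them: multiple scattering (MS), which buries singly scattered light in a
diffuse background, and sample-induced aberration (SIA), the slowly varying
wavefront distortion accumulated on the way through the sample.  Both arise
from the same physical quantity — RI inhomogeneity — so a sufficiently
accurate partial RI map can be used to *computationally undo* them.

`silicoclear` implements that idea as in-silico clearing: the reconstruction
volume is split along the optical axis into blocks of length l_b; starting
from the block nearest the detection lens (whose view is not yet degraded),
each block is reconstructed from optically sectioned phase-gradient data,
and the measured fields are then numerically backpropagated *through the
reconstructed slab*, stripping the distortion it caused, before the next
(deeper) block is processed.

## Forward model

Scattering potential: V(r) = k_b²[(n(r)/n_b)² − 1], k_b = 2π n_b/λ0.  The
multi-slice beam propagation method (BPM) alternates non-paraxial angular-
spectrum diffraction over one slice pitch Δz with a per-slice phase screen

    u(z + Δz) = O(z + Δz) · P_Δz{u(z)},
    P_Δz = F⁻¹ exp(i √(k_b² − |k_t|²) Δz) F,
    O = exp(i k0 δn(r_t, z) α Δz),   α = 1/cos θ_in,

where the obliquity factor α corrects the phase accumulated by an obliquely
incident wave.  Backpropagation applies the exact algebraic inverse
(conjugate screens in reverse order with the inverted propagator).

Numerical choices:

* **Evanescent policy.**  |k_t| > k_b components are zeroed by the
  propagator.  This makes backpropagation stable but irreversible for field
  content scattered beyond the band: the forward-backward identity is exact
  (≈1e-14 in tests) only when the screens generate no out-of-band content,
  i.e. for spectrally band-limited slabs probed well inside the aperture.
  The test suite constructs that regime explicitly (contrast band-limited to
  k_b/4, illumination NA 0.3); for general slabs the identity degrades
  gracefully with the out-of-band energy.
* **Lateral boundaries** are FFT-periodic everywhere (simulation, QPGI
  synthesis, reconstruction kernel), so wrap-around is a consistent
  convention rather than an artifact.  An optional cosine taper (applied to
  the object contrast, keeping the slice operators unitary) is available for
  non-periodic inputs but off by default.
* **Illumination grids** are squares in k-space clipped to the illumination
  NA, with each wavevector snapped to the nearest lateral FFT bin of the
  window so every incident wave is exactly periodic.  Illumination counts
  therefore depend on window size and are never asserted as constants.
* **Detection** is modelled as a hard circular low-pass at NA_det·k0.

A volumetric Lippmann–Schwinger solver (u = u_in + G*(Vu), LGMRES, guarded
to ≤ 64³ voxels) serves as the independent full-wave reference.  Its
Green's kernel is the radially truncated real-space Helmholtz kernel
e^{ik_b r}/4πr evaluated on a 2× zero-padded grid (exact aperiodic
convolution; the singular voxel carries the analytic ball average).  The
damped spectral form 1/(k_b² − |k|² − iε) is available as an option but the
damping needed to kill wrap-around also attenuates the in-volume scattered
field by tens of percent, which is why truncation is the default.  BPM and
Lippmann–Schwinger exit fields agree to ~0.1–1% relative L2 on weak-contrast
spheres, comfortably inside the 5% gate the cross-check asserts.

## QPGI synthesis

With carriers removed, ū = u·exp(−i k_in·r), the sheared incoherent
accumulation

    W̄(r) = (1/N_in) Σ_j ū_j(r) ū_j*(r + δr)

gives the quantitative phase gradient image ψ = arg W̄.  Because the terms
are intensity-like, the sum is incoherent and optically sectioned: refocused
to a stack of z-planes, a scatterer contributes only near its own depth
(measured axial FWHM for a 2λ0 sphere at NA 1.0: 2.8λ0 versus 4.0λ0 for
single-field QPI on the same data — the sectioning contrast the pipeline
relies on).  Shears default to one lateral voxel pitch per axis (smallest
resolvable shear; keeps the phase-gradient relation linear); shifts use
Fourier interpolation so sub-voxel shears are exact for band-limited fields.
Phases are principal values — no unwrapping is ever needed because QPGI
values are small by construction.  The shear is applied one-sided, matching
the accumulation formula as written.

## Linear inversion

The QPGI stacks respond linearly to the scattering potential through a pair
of shift-invariant 3D kernels.  The default kernel is **calibrated**: a
single-voxel scatterer with contrast 1e-4 (Born regime; a >1% nonlinearity
between the response at ε and ε/2 raises an error) is pushed through the
exact measurement pipeline — first-order Born scattering to the detection
plane, NA filter, refocusing, sheared accumulation — and the response,
normalized by the scatterer's potential, is the impulse response.  The
calibration registers the scatterer the way the BPM discretization does
(slice iz acts at field plane (iz+1)Δz, at field sample coordinates); this
registration matters — a half-voxel mismatch costs ~20% model error, the
registered kernel predicts BPM-simulated stacks of a weak sphere to ~2%.
An analytic Ewald-shell construction is provided as an alternative
provenance; it neglects the refocus-side conjugate term and is not the
default.

The inverse problem

    min_{x≥0} ½‖C G_x x − ψ_x‖² + ½‖C G_y x − ψ_y‖² + τ‖x‖₁ + ξ‖Ψx‖₁

is solved in scaled-form ADMM with two auxiliary blocks (z₁ = x for ℓ1 +
non-negativity, z₂ = Ψx for anisotropic TV with forward differences and
Neumann boundaries); the x-update solves the ρ-regularized normal equations
with warm-started conjugate gradients (default cap 20, tol 1e-6).  x is the
*potential* — the operator acts naturally on V — and is converted to RI on
return.  The operator is zero-padded axially to ≥ 2× the block depth (true
linear convolution in z) and kept FFT-periodic laterally, consistent with
the periodic field physics; lateral zero-padding would introduce model
mismatch here, not remove it.

Defaults τ = 7.5e-2, ξ = 0.1, ρ = 1, 50 iterations follow the reference
protocol.  The synthetic-recovery tests use weak phantoms (δn = 0.002) whose
potentials are ~0.2 in λ0 units, and accordingly set τ ≈ 1e-6, ξ ≈ 1e-5,
ρ ≈ 1e-3 (ADMM converges best with ρ near the operator's spectral scale,
mean |H|² ≈ 3e-4 for these geometries).  On a 96×96×48 grid with 37 angles
the full simulate → QPGI → ADMM chain recovers the mean contrast of a 6λ0
sphere to ~9% with background artifacts below 0.1% of the contrast outside
a PSF-sized shell; the shell exclusion matters because the diffraction-
limited edge spread is resolution, not artifact.

## The clearing loop and baselines

Blocks are processed detection-side first; fields are carried at block
boundaries, never re-propagated from the camera.  Within a block the
refocusing is homogeneous-medium (the block's own RI is unknown at that
point).  The remainder block sits on the illumination side so the most
trusted blocks keep the nominal length.  Per-block kernels are cached by
block depth and freed with the loop; nothing 4D is held.  Diagnostics record
the circular variance of the normalized fields' phase before and after each
backpropagation — in every strongly scattering run this flatness improves
monotonically block by block, which is the mechanism of the method made
visible.

The no-clearing baseline is a single stack over the full extent and one
inversion.  The conventional-Rytov baseline is classical diffraction
tomography: per-angle complex Rytov phase (2D unwrapped), Fourier mapping
onto Ewald shells with nearest-bin gridding (rounding phases re-referenced
to the grid center — without that compensation a centered object is
incoherently attenuated by ~35%), Hermitian symmetrization, then the same
ℓ1+TV+non-negativity ADMM on the sampled spectrum.  Suspected unwrapping
failures are warned about and the reconstruction still returned.

## Synthetic phantoms — what they emulate and what they do not

* The **spheroid phantom** reproduces the simulated-spheroid geometry:
  cells on a BCC lattice (one corner site anchored at the spheroid center —
  the anchoring that yields exactly 331 cells for D = 122λ0, a = 18λ0; a
  cell is included iff its center lies inside the radius), each with
  cytoplasm 1.370 / nucleus 1.355 / nucleolus 1.370 / vesicles 1.410 in a
  1.333 medium and a per-cell random rigid rotation.  Organelle sizes are
  not published; defaults are nucleus 0.6, nucleolus 0.2, vesicles 0.1 of
  the cell diameter with 5 vesicles per cell, all configurable.  Voxels
  belong to a sphere iff their center is inside — deterministic, no
  antialiasing.
* The **two-layer phantom** places a dense vesicle slab on the detection
  side above a weak test layer, isolating the depth-degradation mechanism.
* What passing these tests does *not* show: real cells are not spheres, real
  measurements carry camera noise and calibration drift, and real media are
  not laterally periodic.  The phantoms probe the reconstruction physics,
  not instrument robustness.

## Depth-ordering evaluation

The flagship qualitative result — with clearing the deepest layer
reconstructs better than without, and conventional Rytov is worst — is
reproduced at reduced scale on a vesicle-laden spheroid: D = 18λ0, 27 cells
(5λ0 cells, 6λ0 lattice, nucleus fraction 0.3, 24 vesicles of 1.5λ0 per
cell), 96×96×56 voxels at (λ0/5, λ0/5, 2λ0/5), 37 illuminations at NA 1.0,
l_b = 9.6λ0 (3 blocks), layers one lattice constant thick.  The vesicle load
was chosen so the exit wavefront is genuinely in the multiple-scattering
regime (circular variance ≈ 0.74, ~4% amplitude nulls) — the regime the
comparison is about; at weak scattering all three methods converge and the
ordering between the two baselines is not diagnostic.  Measured deepest-
layer NRE in this configuration: clearing 8.0e-5 < no-clearing 1.8e-4 <
Rytov 2.2e-4.  Problem sizes throughout the suite (48³ Lippmann–Schwinger
cross-checks, 96×96×48 recovery, 96×96×56 ordering) are the package's
chosen desk-scale study conditions; tolerances and orderings are asserted
unchanged at those sizes.

NRE, PSNR and SSIM follow the standard definitions (squared-norm ratio;
10·log10(L²/MSE) with L the truth dynamic range; uniform 7×7×7-window SSIM
with C1 = (0.01L)², C2 = (0.03L)², valid-mode borders).  Layer-wise
evaluation tiles z (no overlap) and takes L per layer from the truth, so
layers are comparable among themselves.

## Downstream analysis

Morphology thresholds: foreground n > 1.340, high-RI n > 1.375; equivalent
diameter d_eq = 2(3V/4π)^(1/3).  The fragmentation filter sums, over the
three axes, a 1D fourth-derivative-of-Gaussian (σ = 138 nm lateral, 400 nm
axial on physical grids) combined with plain Gaussians on the other axes,
takes the magnitude, and intersects the thresholded response with the
foreground; derivative kernels are normalized to exactly zero sum so a
constant volume never fragments.  The threshold default is Otsu's value on
the in-foreground response (the published analysis does not print a rule;
an absolute override is provided for reproducibility).  Hill fits use
bounded nonlinear least squares with deterministic initialization (plateaus
from the extreme concentrations, EC50 at the geometric mid-concentration,
H = 1); C = 0 points enter the residual at the model's C→0 limit E0.

## Known limitations

* The calibrated kernel is a faithful numerical surrogate for the
  linearized QPGI relation; the closed-form derivation of the original
  operator is not published here, so exact coefficient-level identity with
  the authors' kernel cannot be asserted — only the ≤20% full-wave
  agreement gate and the end-to-end recovery tests.
* Axial resolution suffers the usual missing-cone anisotropy; the ℓ1/TV
  prior compensates only partially (unconstrained least squares recovers
  ~65% of a weak sphere's interior contrast; the constrained solver ~90%).
* Block boundaries can leave faint seams in strongly scattering runs, the
  known price of block-wise sectioning.
* CPU-only; the implementation streams over blocks but is FFT-bound.
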