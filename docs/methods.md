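# Methods

## Light-propagation model

Photon transport in highly scattering, weakly absorbing tissue is modelled by
the diffusion approximation.  Two coupled elliptic PDEs describe the
excitation fluence Φ_x and the fluorescence emission fluence Φ_m:

    -∇·(D_x ∇Φ_x) + k_x Φ_x = S_x
    -∇·(D_m ∇Φ_m) + k_m Φ_m = α Φ_x

with nodal coefficients

    D_{x,m} = 1 / (3 (μ_a,i + μ_a,f + μ'_s))     [mm]
    k_{x,m} = iω/c + μ_a,i + μ_a,f               [1/mm]
    α       = η μ_axf / (1 − iωτ)                [1/mm]

per band (x = excitation, m = emission wavelength).  Absorption splits into an
intrinsic chromophore part μ_a,i and a fluorophore part μ_a,f; η is the
fluorescence quantum efficiency, τ the lifetime (ns).  The angular modulation
frequency ω is in rad/ns and defaults to 0 (continuous wave): amplitude-only
data, real arithmetic, and real symmetric positive-definite systems.  The
complex path (ω > 0) is implemented and unit-tested; c defaults to the speed
of light over a tissue refractive index of 1.4.

Boundary: Robin condition Φ + 2AD ∂Φ/∂n = 0, so the weak-form boundary
integrand is b = 1/(2A).  The internal-reflection parameter defaults to
A_x = A_m = 1 (matched boundary) and is configurable.

Collimated sources are modelled the standard way: isotropic point sources
placed one transport mean free path 1/μ'_s inside the boundary, distributed to
the containing element's nodes by barycentric weights.  Detectors sample Φ_m on
the closest boundary facet by barycentric interpolation.

## Discretization

Galerkin P1 finite elements on conforming simplicial meshes (triangles/
tetrahedra).  Element stiffness, mass and boundary-facet matrices use the
exact P1 integrals; nodal coefficient fields are element-averaged before
integration, consistent with the Jacobian's nodal parameterization.  Systems
are factorized once per band with a sparse LU and reused across all sources,
detectors and adjoint solves.

Built-in generators: a ring-structured Delaunay disc triangulation, and a
cylinder built by extruding the disc into prism layers, each split into three
tetrahedra with quad-face diagonals chosen through the smallest global vertex
index (conforming across neighbouring prisms, well-shaped elements).
Adaptive refinement is conforming longest-edge bisection of every element
intersecting a dilated prior region, in rounds, stopping before a round would
exceed the node budget; picking each element's longest marked edge (ties by
vertex index) makes the induced facet splits identical on both sides of every
shared face, which preserves conformity in 2D and 3D.  Node positions are
never moved, so node sets are nested and rasterized truth maps are
refinement-consistent.

Validation: on a homogeneous cylinder the CW solution for a centred point
source matches the infinite-medium Green's function exp(−μ_eff r)/(4πDr)
within 10% at nodes ≥ 3 mm from the source and ≥ 5 mm from the boundary
(0.6 mm mesh), and source–detector reciprocity holds to 1e-8.

## Inverse problem

The unknown image x is the nodal μ_axf map alone; every other tissue map is
held at its true value.  One Gauss–Newton step solves the Tikhonov normal
equations K Δx = b with K = JᵀJ + ξI, b = JᵀΔy, ξ = 0.001.  The Jacobian is
assembled by the adjoint method with all three dependency paths of μ_axf
(through k_x, D_x and α): one excitation solve per source plus one emission
and one excitation adjoint solve per detector.  A brute-force central-
difference Jacobian is kept as an independent oracle; the two agree to better
than 1e-5 (relative Frobenius) on every test mesh, in 2D and 3D, CW and
frequency domain.

**System normalization.**  Raw fluence units are arbitrary, so J and Δy are
scaled by γ/‖y_meas‖ before the normal equations are formed.  With ξ fixed at
0.001, the dimensionless gain γ controls how aggressively a full step fits
the current data relative to the Tikhonov penalty (scaling both J and Δy by γ
is equivalent to regularizing with ξ/γ²).  The default γ = 0.03 was
calibrated once on the one-inclusion phantom as the largest gain at which the
full-step iteration remains stable under 10 dB measurement noise; gains an
order of magnitude larger make the step amplify noise far beyond the image
scale and the clamped iteration diverges.  Noiseless convergence studies,
where stability is not a concern, raise γ to recover the weakly-determined
interior modes (the README example uses γ = 300).

After each update the image is clamped at zero (full step, no line search).
Complex residuals (ω > 0) are handled by stacking real and imaginary parts
into real rows.

## Accelerated inner solver

The compressed solve of K Δx = b proceeds in four steps: (1) transform with
an orthonormal single-level discrete wavelet matrix W (default Haar;
periodized orthogonal filters, zero-padding to the next power of two) and
keep the approximation–approximation block K̂₁ = (W K Wᵀ)₁₁ and b̂₁; (2)
project onto the leading principal components of K̂₁'s column covariance
(covariance centred by the column mean, projection applied to the uncentred
block; retained rank q from a 95% eigenvalue-mass rule by default) and solve
the q × n₁ system by minimum-norm least squares; (3) prolongate with zeros to
the padded length; (4) inverse-transform and use the result to warm-start
conjugate gradients on the full system (tolerance 1e-8, cap 10·N iterations).
The compression changes the path, not the fixed point: the final iterate
agrees with a dense factorization of K Δx = b to 1e-6, and with q = n₁ the
reduced solve is an exact rotation of the block system.

Nodal vectors have no natural 1D order, so before transforming, nodes are
permuted by breadth-first traversal from the node nearest the domain centroid,
which makes spatially adjacent nodes index-adjacent and the wavelet
approximation meaningful.

At the extreme conditioning of high-gain noiseless studies (ξ/γ² ~ 1e-9),
scipy's CG can stall just short of the 1e-8 tolerance at the iteration cap;
such studies use the direct Cholesky inner solve (same fixed point) instead.

## Outer iteration with source rotation

Iteration i illuminates with the source ring rotated by θ = i·β, where β
defaults to half the inter-source angle (45° for 4 sources, 30° for the 3D
case's 6 per ring).  At each angle the measurement vector is simulated from
the truth phantom once and cached, so revisited angles reuse identical noisy
data; the noise seed of an angle derives deterministically from (base seed,
angle).  The loop relinearizes at the current image with the rotated sources,
updates, and stops when the relative residual ‖y − F(x)‖/‖y‖ of the current
angle's data drops below δ = 0.02 or at the iteration cap.  The residual
threshold is interpreted relatively because the data are in arbitrary units
(a flag restores the bare norm).

Method variants share this loop and differ only in the inner solve:
`proposed` (wavelet-PCA compressed solve, rotation on), `conventional`
(direct Tikhonov solve, rotation off — the fixed-source baseline),
`wavelet_only` (approximation-block solve without PCA and without the full
polish), `pca_only` (PCA projection of the uncompressed system).  The two
ablations keep the rotation schedule so the comparison isolates the inner
solver.

## Phantoms, noise and metric

Three built-in phantoms define the experiments.  2D: a 25 mm-radius disc,
background μ_axf = 0.006 mm⁻¹, with either one 5 mm inclusion at (10, 0) mm
(μ_axf = 0.04) or two 5 mm inclusions at (−10, 5) and (10, −5) mm (0.03 and
0.04); intrinsic absorption 0.003, reduced scattering 0.4 mm⁻¹ — standard
soft-tissue NIR optics giving an optical diameter of about five attenuation
lengths.  (The coefficient tables these phantoms follow are per-cm figures;
read per-mm they would make the disc ~52 attenuation lengths deep, a regime
in which boundary data carry no interior information at any noise level.)
3D: a cylinder of radius 10 mm and height 40 mm, background
μ_axf = 0.005 mm⁻¹, with a cylindrical inclusion of radius 2 mm and height
6 mm (μ_axf = 0.01) centred at (5, 0, 20) mm; measurements on the planes
z = 15, 20, 25 mm with six sources and sixteen detectors per plane, coupled
within each plane.

Noise is additive Gaussian on each measurement component with
σ = rms(y)·10^(−SNR/20); the standard experiments use 10 dB (σ ≈ 0.32·rms).
Image quality is the nodal mean squared error MSE = (1/N) Σ (x_rec − x_act)²,
evaluated on the reconstruction mesh.

## Experiment design and problem sizes

The 2D benchmark experiments use prior-refined meshes (coarse disc refined
toward the inclusion support dilated by 2 mm) at the 122/148-node reference
scale, 12 outer iterations, and ≥ 10 noise seeds; the 3D experiment uses a
uniform ~855-node tetrahedral mesh, 8 outer iterations, 5 seeds.  At 10 dB
the relative residual cannot fall below the noise floor (≈ 0.32), so δ never
triggers and the iteration cap fixes the work per run; the caps above keep a
full benchmark pass around a minute on one CPU.

The noiseless recovery study (README example) uses a uniform 3 mm disc mesh
rather than the prior-refined one: the MSE metric weights every node equally,
and the refined mesh concentrates most of its nodes exactly where the image
is hardest to determine (the inclusion interior and rim), which caps the
achievable MSE reduction there at about 7× — a property of the metric and
mesh, not of the solver.

## What the simulations do and do not show

Data are simulated with the same finite-element model and mesh used for
reconstruction (the classical committed inverse crime); real measurements add
model error, geometric uncertainty and non-diffusive transport near sources.
The noise model is white and signal-level-proportional only through its
global rms; real detectors have per-channel noise floors.  Passing benchmarks
therefore demonstrates correctness of the solvers and the relative merits of
the method variants under the stated study conditions, not clinical imaging
performance.  Known limitations: the termination threshold δ = 0.02 is
unreachable at 10 dB (the cap governs); localization at 10 dB with 12
iterations is unreliable even when the MSE ordering is stable; and at this
noise level the cruder ablation solvers can match or slightly beat the exact
combined solve on MSE because they absorb less measurement noise per step.
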