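# fmtwave

Fluorescence molecular tomography (FMT) reconstructs the spatial map of a
fluorophore's absorption coefficient μ_axf inside tissue from light
measurements on the boundary.  `fmtwave` implements a complete simulation and
reconstruction pipeline for this problem:

- a **P1 finite-element forward model** of the coupled frequency-domain
  diffusion equations for the excitation and emission fluences,

      -∇·(D_x ∇Φ_x) + k_x Φ_x = S_x,
      -∇·(D_m ∇Φ_m) + k_m Φ_m = α Φ_x,      α = η μ_axf / (1 − iωτ),

  with Robin boundary conditions Φ + 2AD ∂Φ/∂n = 0, on built-in disc and
  cylinder meshes (Gmsh/VTK import–export included);
- an **adjoint Jacobian** of the boundary measurements with respect to the
  nodal μ_axf map (all three dependency paths: excitation absorption k_x,
  excitation diffusion D_x, and the emission source coefficient α) feeding
  Tikhonov-regularized Gauss–Newton updates, K Δx = b with
  K = JᵀJ + ξI and b = JᵀΔy;
- an **accelerated inner solver** that compresses (K, b) with an orthonormal
  single-level wavelet transform, reduces the approximation block by
  principal-component projection, solves the reduced system, and polishes the
  zero-padded, back-transformed result with warm-started conjugate gradients;
- an **outer iteration with rotated-source illumination**: every iteration the
  excitation source ring is rotated by half the inter-source angle
  (β = 360°/2n), so fresh measurement geometry enters each relinearization at
  no extra per-iteration cost.

Synthetic phantoms (one- and two-inclusion discs, a 3D cylinder with a small
cylindrical inclusion), Gaussian measurement noise at a configurable SNR, and
the nodal mean-squared-error metric used to score reconstructions are all part
of the package, so every experiment runs from scratch with no external data.

## Worked example

Noiseless parameter recovery on the one-inclusion disc phantom (25 mm disc,
5 mm inclusion at (10, 0) mm, 6.7:1 fluorophore contrast), reconstructed from
4 rotating sources and 30 detectors:

```python
import numpy as np
from fmtwave import (DetectorSet, ReconConfig, SourceSet, build_disc_mesh,
                     mse, phantom_one_inclusion, rasterize)
from fmtwave.experiments import ExperimentSetup, run_reconstruction

phantom = phantom_one_inclusion()
mesh = build_disc_mesh(25.0, 3.0)
props_truth, x_true = rasterize(phantom, mesh)
x0 = np.full(mesh.N, phantom.background["mu_axf"])
setup = ExperimentSetup(
    name="recovery", phantom=phantom, mesh=mesh, props_truth=props_truth,
    props_background=props_truth.with_mu_axf(x0), x_true=x_true,
    sources=SourceSet(angles_deg=[0, 90, 180, 270], boundary_radius_mm=25.0,
                      offset_depth_mm=2.5),
    detectors=DetectorSet(angles_deg=np.arange(30) * 12 + 6.0,
                          boundary_radius_mm=25.0),
)
config = ReconConfig(variant="conventional", beta_deg=45.0, max_outer_iters=250,
                     delta=1e-12, system_gain=300.0)
result, err = run_reconstruction(setup, "conventional", seed=1, snr_db=None,
                                 config=config)
```

which prints

```
mesh: 237 nodes; initial MSE 3.414e-05 mm^-2
final MSE 3.319e-06 mm^-2 (10.3x reduction)
recovered peak mu_axf = 0.0524 mm^-1 at [9.38 0.  ] mm (truth: 0.04 mm^-1 inside a 5 mm disc at (10, 0) mm)
```

The reconstruction reduces the nodal MSE more than tenfold and places the
recovered absorption peak 0.6 mm from the true inclusion centre.  At the
standard 10 dB noise level, the rotating-source method keeps the median MSE at
or below its starting value while the fixed-source baseline degrades — the
ordering the benchmark experiments quantify.

## Command line

The same pipeline is scriptable:

```bash
fmtwave simulate    --config config.yaml --out run/
fmtwave reconstruct --config config.yaml --measurements run/measurements.h5 \
                    --variant proposed --out run/
fmtwave evaluate    --result run/result_proposed.h5 --config config.yaml
fmtwave bench       --config config.yaml --seeds 5 --out comparison.csv
```

`config.yaml` needs only the keys you want to override; the defaults are the
standard study conditions (ξ = 0.001, δ = 0.02, 10 dB noise, rotation by half
the source spacing).  Variants: `proposed` (wavelet-PCA + rotation),
`conventional` (fixed sources, direct Tikhonov), `wavelet_only`, `pca_only`.

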