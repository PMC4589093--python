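"""Canned experiment setups at the standard problem scales.

Each setup builds the phantom, a prior-refined (2D) or uniform (3D) mesh at
the reference node count, the source/detector rings and the ground truth,
and can run any reconstruction variant against freshly simulated noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .forward import DetectorSet, SourceSet, TissueProperties
from .mesh import Mesh, adaptive_refine, build_cylinder_mesh, build_disc_mesh
from .phantoms import (
    Phantom,
    mse,
    phantom_cylinder_3d,
    phantom_one_inclusion,
    phantom_two_inclusion,
    prior_from_phantom,
    rasterize,
)
from .reconstruct import (
    ReconConfig,
    ReconResult,
    SimulatedMeasurements,
    reconstruct,
)

__all__ = ["ExperimentSetup", "build_experiment", "run_reconstruction", "EXPERIMENTS"]

EXPERIMENTS = ("one_inclusion", "two_inclusion", "cylinder_3d")

#: reference mesh node budgets for the three experiments
NODE_BUDGETS = {"one_inclusion": 122, "two_inclusion": 148, "cylinder_3d": 858}


@dataclass
class ExperimentSetup:
    name: str
    phantom: Phantom
    mesh: Mesh
    props_truth: TissueProperties
    props_background: TissueProperties
    x_true: np.ndarray
    sources: SourceSet
    detectors: DetectorSet
    omega: float = 0.0


def _uniform_angles(n: int, start: float = 0.0) -> np.ndarray:
    return (start + 360.0 * np.arange(n) / n) % 360.0


def build_experiment(
    name: str,
    n_sources: int | None = None,
    node_budget: int | None = None,
    coarse_edge_mm: float | None = None,
) -> ExperimentSetup:
    """Assemble one of the reference experiments.

    2D discs: a coarse triangulation adaptively refined toward the inclusion
    prior (dilated 2 mm) up to the reference node budget; 4 sources and 30
    detectors uniformly on the boundary.  3D cylinder: a uniform tetrahedral
    mesh at the ~858-node scale; 6 sources and 16 detectors on each of the
    planes z = 15, 20, 25 mm.  Sources sit one transport mean free path
    (1/mu_sx') inside the boundary.
    """
    if name not in EXPERIMENTS:
        raise ConfigurationError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    budget = node_budget or NODE_BUDGETS[name]

    if name in ("one_inclusion", "two_inclusion"):
        phantom = phantom_one_inclusion() if name == "one_inclusion" else phantom_two_inclusion()
        radius = phantom.geometry["radius_mm"]
        base = build_disc_mesh(radius, coarse_edge_mm or 8.0)
        prior = prior_from_phantom(phantom, dilation_mm=2.0)
        mesh = adaptive_refine(base, prior, node_budget=budget)
        props_truth, x_true = rasterize(phantom, mesh)
        offset = 1.0 / float(np.max(props_truth.mu_sx_prime))
        sources = SourceSet(
            angles_deg=_uniform_angles(n_sources or 4),
            boundary_radius_mm=radius,
            offset_depth_mm=offset,
        )
        detectors = DetectorSet(
            angles_deg=_uniform_angles(30, start=6.0),
            boundary_radius_mm=radius,
        )
    else:
        phantom = phantom_cylinder_3d()
        radius = phantom.geometry["radius_mm"]
        height = phantom.geometry["height_mm"]
        mesh = build_cylinder_mesh(radius, height, coarse_edge_mm or 2.8)
        props_truth, x_true = rasterize(phantom, mesh)
        offset = 1.0 / float(np.max(props_truth.mu_sx_prime))
        planes = phantom.geometry["measurement_planes_mm"]
        nsp = n_sources or phantom.geometry["sources_per_plane"]
        ndp = phantom.geometry["detectors_per_plane"]
        src_angles, src_z, src_plane = [], [], []
        det_angles, det_z, det_plane = [], [], []
        for p, z in enumerate(planes):
            src_angles.extend(_uniform_angles(nsp))
            src_z.extend([z] * nsp)
            src_plane.extend([p] * nsp)
            det_angles.extend(_uniform_angles(ndp, start=360.0 / (2 * ndp)))
            det_z.extend([z] * ndp)
            det_plane.extend([p] * ndp)
        sources = SourceSet(
            angles_deg=np.array(src_angles),
            boundary_radius_mm=radius,
            offset_depth_mm=offset,
            z_mm=np.array(src_z),
            plane=np.array(src_plane),
        )
        detectors = DetectorSet(
            angles_deg=np.array(det_angles),
            boundary_radius_mm=radius,
            z_mm=np.array(det_z),
            plane=np.array(det_plane),
        )

    # the unknown is mu_axf alone: the reconstruction model holds every other
    # map at its true value and resets mu_axf to the homogeneous background
    props_background = props_truth.with_mu_axf(
        np.full(mesh.N, float(phantom.background["mu_axf"]))
    )
    return ExperimentSetup(
        name=name,
        phantom=phantom,
        mesh=mesh,
        props_truth=props_truth,
        props_background=props_background,
        x_true=x_true,
        sources=sources,
        detectors=detectors,
    )


def run_reconstruction(
    setup: ExperimentSetup,
    variant: str = "proposed",
    seed: int = 0,
    snr_db: float | None = 10.0,
    config: ReconConfig | None = None,
) -> tuple[ReconResult, float]:
    """Simulate noisy data from the truth and reconstruct; returns (result, MSE)."""
    if config is None:
        config = ReconConfig(variant=variant)
    elif config.variant != variant:
        config = replace(config, variant=variant)
    meas = SimulatedMeasurements(
        setup.mesh,
        setup.props_truth,
        setup.sources,
        setup.detectors,
        omega=setup.omega,
        snr_db=snr_db,
        seed=seed,
    )
    result = reconstruct(
        meas,
        setup.mesh,
        setup.props_background,
        setup.sources,
        setup.detectors,
        config=config,
        x_true=setup.x_true,
        omega=setup.omega,
    )
    return result, mse(result.x, setup.x_true)
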