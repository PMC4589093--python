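import numpy as np
import pytest

from fmtwave import (
    DetectorSet,
    SourceSet,
    TissueProperties,
    build_disc_mesh,
    build_cylinder_mesh,
)


@pytest.fixture(scope="session")
def small_disc():
    """Coarse 2D disc (N ~ 40) for fast FEM/Jacobian checks."""
    return build_disc_mesh(10.0, 3.5)


@pytest.fixture(scope="session")
def small_cylinder():
    """Coarse 3D cylinder (N ~ 40) for fast FEM/Jacobian checks."""
    return build_cylinder_mesh(5.0, 10.0, 3.4)


def tissue(mesh, **over):
    base = dict(
        mu_axi=0.003, mu_axf=0.006, mu_sx_prime=0.4,
        mu_ami=0.002, mu_amf=0.0005, mu_sm_prime=0.3,
        eta=0.2, tau=0.6,
    )
    base.update(over)
    return TissueProperties(n_nodes=mesh.N, **base)


@pytest.fixture(scope="session")
def disc_setup(small_disc):
    """Mesh + props + 2 sources + 6 detectors on the small disc."""
    props = tissue(small_disc)
    srcs = SourceSet(
        angles_deg=[0.0, 180.0], boundary_radius_mm=10.0, offset_depth_mm=2.5
    )
    dets = DetectorSet(
        angles_deg=np.arange(0, 360, 60) + 15.0, boundary_radius_mm=10.0
    )
    return small_disc, props, srcs, dets


@pytest.fixture(scope="session")
def cylinder_setup(small_cylinder):
    props = tissue(small_cylinder)
    srcs = SourceSet(
        angles_deg=[0.0, 120.0, 240.0], boundary_radius_mm=5.0,
        offset_depth_mm=1.0, z_mm=[5.0] * 3, plane=[0] * 3,
    )
    dets = DetectorSet(
        angles_deg=np.arange(0, 360, 90) + 10.0, boundary_radius_mm=5.0,
        z_mm=[5.0] * 4, plane=[0] * 4,
    )
    return small_cylinder, props, srcs, dets
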