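"""Synthetic phantoms, measurement noise and the image-error metric.

The built-in phantoms are the standard test objects for this reconstruction
problem: a 25 mm disc with one or two circular fluorophore inclusions, and a
10 x 40 mm cylinder with a small cylindrical inclusion.  Optical values are
tabulated per region; ``rasterize`` turns a phantom into nodal tissue maps
on a mesh plus the ground-truth mu_axf vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, InvalidParameterError
from .forward import TissueProperties
from .mesh import Circle, CylinderRegion, Mesh, PriorImage

__all__ = [
    "InclusionSpec",
    "Phantom",
    "phantom_one_inclusion",
    "phantom_two_inclusion",
    "phantom_cylinder_3d",
    "rasterize",
    "prior_from_phantom",
    "add_noise",
    "mse",
]

# Background optical values shared by the disc phantoms, in mm^-1 (lifetime
# in ns).  The tabulated coefficients for these phantoms are per-cm values
# (e.g. background mu_axi = 0.03 cm^-1-scale, mu_s' = 4.0 cm^-1): read per
# mm they would put the 50 mm disc at ~52 attenuation lengths, an optically
# opaque regime in which no boundary measurement carries interior
# information.  Converted to mm^-1 they are standard soft-tissue NIR optics
# (total absorption ~0.009 mm^-1, reduced scattering 0.4 mm^-1, optical
# diameter ~5 attenuation lengths) and match the 3D phantom's per-mm
# background fluorophore absorption of 0.005 mm^-1.
_DISC_BACKGROUND = {
    "mu_axf": 0.006,
    "mu_axi": 0.003,
    "mu_sx_prime": 0.4,
    "mu_amf": 0.0005,
    "mu_ami": 0.002,
    "mu_sm_prime": 0.3,
    "eta": 0.2,
    "tau": 0.6,
}


@dataclass(frozen=True)
class InclusionSpec:
    """One inclusion: a shape plus property overrides (at least mu_axf)."""

    shape: object  # Circle or CylinderRegion
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shape.radius <= 0:
            raise InvalidParameterError("inclusion radius must be > 0")
        if any(v < 0 for v in self.overrides.values()):
            raise InvalidParameterError("property overrides must be >= 0")


@dataclass
class Phantom:
    """Geometry + background properties + inclusions."""

    name: str
    geometry: dict  # {"kind": "disc", "radius_mm": ...} or cylinder
    background: dict
    inclusions: list

    def to_json(self) -> str:
        def shape_dict(s):
            if isinstance(s, Circle):
                return {"kind": "circle", "center": list(s.center), "radius": s.radius}
            return {
                "kind": "cylinder",
                "center": list(s.center),
                "radius": s.radius,
                "height": s.height,
            }

        return json.dumps(
            {
                "name": self.name,
                "geometry": self.geometry,
                "background": self.background,
                "inclusions": [
                    {"shape": shape_dict(i.shape), "overrides": i.overrides}
                    for i in self.inclusions
                ],
            },
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "Phantom":
        d = json.loads(text)
        incl = []
        for i in d["inclusions"]:
            s = i["shape"]
            if s["kind"] == "circle":
                shape = Circle(tuple(s["center"]), s["radius"])
            else:
                shape = CylinderRegion(tuple(s["center"]), s["radius"], s["height"])
            incl.append(InclusionSpec(shape, i["overrides"]))
        return Phantom(d["name"], d["geometry"], d["background"], incl)


def phantom_one_inclusion() -> Phantom:
    """25 mm disc with a single 5 mm circular inclusion at (10, 0) mm.

    Background mu_axf = 0.006 mm^-1, inclusion mu_axf = 0.04 mm^-1 (a 6.7:1
    fluorophore contrast); quantum efficiency 0.2, lifetime 0.6 ns.
    """
    incl = InclusionSpec(
        Circle((10.0, 0.0), 5.0), {"mu_axf": 0.04, "mu_amf": 0.02}
    )
    return Phantom(
        name="one_inclusion",
        geometry={"kind": "disc", "radius_mm": 25.0},
        background=dict(_DISC_BACKGROUND),
        inclusions=[incl],
    )


def phantom_two_inclusion() -> Phantom:
    """25 mm disc with two 5 mm inclusions (mu_axf 0.03 and 0.04 mm^-1)."""
    bg = dict(_DISC_BACKGROUND)
    bg["mu_amf"] = 0.0003
    return Phantom(
        name="two_inclusion",
        geometry={"kind": "disc", "radius_mm": 25.0},
        background=bg,
        inclusions=[
            InclusionSpec(Circle((-10.0, 5.0), 5.0), {"mu_axf": 0.03, "mu_amf": 0.002}),
            InclusionSpec(Circle((10.0, -5.0), 5.0), {"mu_axf": 0.04, "mu_amf": 0.003}),
        ],
    )


def phantom_cylinder_3d() -> Phantom:
    """Cylinder (radius 10 mm, height 40 mm) with a 2 x 6 mm inclusion.

    Background mu_axf = 0.005, inclusion mu_axf = 0.01 centred at
    (5, 0, 20) mm; measurements are taken on the planes z = 15, 20, 25 mm
    with six sources and sixteen detectors per plane.
    """
    bg = dict(_DISC_BACKGROUND)
    bg["mu_axf"] = 0.005
    incl = InclusionSpec(
        CylinderRegion((5.0, 0.0, 20.0), 2.0, 6.0), {"mu_axf": 0.01}
    )
    return Phantom(
        name="cylinder_3d",
        geometry={
            "kind": "cylinder",
            "radius_mm": 10.0,
            "height_mm": 40.0,
            "measurement_planes_mm": [15.0, 20.0, 25.0],
            "sources_per_plane": 6,
            "detectors_per_plane": 16,
        },
        background=bg,
        inclusions=[incl],
    )


_PROPERTY_KEYS = (
    "mu_axf", "mu_axi", "mu_ami", "mu_amf", "mu_sx_prime", "mu_sm_prime",
    "eta", "tau",
)


def rasterize(phantom: Phantom, mesh: Mesh):
    """Nodal tissue maps and the ground-truth mu_axf vector on a mesh."""
    dim = 2 if phantom.geometry["kind"] == "disc" else 3
    if mesh.dimension != dim:
        raise ContractError(
            f"mesh dimension {mesh.dimension} does not match phantom geometry"
        )
    r_dom = phantom.geometry["radius_mm"]
    r_nodes = np.linalg.norm(mesh.nodes[:, :2], axis=1)
    if r_nodes.max() > r_dom * (1 + 1e-6):
        raise ContractError("mesh extends beyond phantom geometry")

    fields = {
        k: np.full(mesh.N, float(phantom.background[k])) for k in _PROPERTY_KEYS
    }
    for inc in phantom.inclusions:
        inside = inc.shape.contains(mesh.nodes)
        for k, v in inc.overrides.items():
            fields[k][inside] = v
    props = TissueProperties(n_nodes=mesh.N, **fields)
    return props, fields["mu_axf"].copy()


def prior_from_phantom(phantom: Phantom, dilation_mm: float = 0.0) -> PriorImage:
    """Prior image marking the inclusion supports, dilated by a margin."""
    return PriorImage(
        regions=[i.shape.dilated(dilation_mm) for i in phantom.inclusions],
        dilation_mm=0.0,
    )


def add_noise(y: np.ndarray, snr_db: float | None, seed) -> np.ndarray:
    """Additive Gaussian noise at a given amplitude signal-to-noise ratio.

    sigma = rms(y) * 10**(-snr_db / 20), applied independently to the real
    and imaginary components; ``snr_db=None`` means noiseless.
    """
    y = np.asarray(y)
    if snr_db is None or np.isinf(snr_db):
        return y.copy()
    if not np.isfinite(snr_db):
        raise InvalidParameterError("snr_db must be finite or None")
    rms = float(np.sqrt(np.mean(np.abs(y) ** 2)))
    if rms == 0.0:
        raise InvalidParameterError("SNR undefined for an all-zero signal")
    sigma = rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=y.shape)
    if np.iscomplexobj(y):
        noise = noise + 1j * rng.normal(0.0, sigma, size=y.shape)
    return y + noise


def mse(x_rec: np.ndarray, x_act: np.ndarray) -> float:
    """Mean squared nodal error between reconstructed and true maps."""
    x_rec = np.asarray(x_rec, dtype=float)
    x_act = np.asarray(x_act, dtype=float)
    if x_rec.shape != x_act.shape:
        raise ContractError(f"length mismatch: {x_rec.shape} vs {x_act.shape}")
    return float(np.mean((x_rec - x_act) ** 2))
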