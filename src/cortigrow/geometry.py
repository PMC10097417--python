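"""Quarter-annulus computational domain and proliferative-zone fields.

The reference configuration is an annular sector in the first quadrant
(theta in [0, pi/2], radius in [r, R]) representing a slab of the fetal
frontal lobe at gestational week 11. Zone boundaries (VZ, ISVZ, OSVZ,
cortical plate) are *material* surfaces: they are expressed in the
material radial coordinate ``ri`` stored per node, so they convect with
the growing tissue rather than staying fixed in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constitutive import smooth_heaviside

__all__ = [
    "GeometryParams",
    "Mesh",
    "build_quarter_annulus",
    "reference_fiber_direction",
    "osvz_outer_radius",
    "zone_weight_vz",
    "zone_weight_osvz",
    "apply_boundary_perturbation",
]


@dataclass(frozen=True)
class GeometryParams:
    """Reference geometry (mm) and the MST expansion speed of the OSVZ."""

    R: float = 2.0        # outer brain radius
    r: float = 0.4        # inner (ventricular) radius
    r_vz: float = 0.5     # outer boundary of the ventricular zone
    r_isvz: float = 0.8   # outer boundary of the inner SVZ
    r_cp: float = 1.8     # inner boundary of the cortical plate
    m_mst: float = 0.02   # OSVZ boundary speed, mm/day

    def __post_init__(self):
        if not (0 < self.r < self.r_vz < self.r_isvz < self.r_cp < self.R):
            raise ValueError(
                "geometry radii must satisfy 0 < r < r_vz < r_isvz < r_cp < R"
            )
        if self.m_mst < 0:
            raise ValueError("m_mst must be >= 0")

    def with_(self, **kw) -> "GeometryParams":
        return replace(self, **kw)


@dataclass
class Mesh:
    """Structured quadrilateral mesh with boundary tags.

    ``nodes`` are reference coordinates (possibly including the seeded
    symmetry-breaking perturbation); ``material_radius`` is the
    unperturbed radial coordinate used for all zone and profile fields.
    For annulus meshes the generating 1D coordinate arrays are kept in
    ``radial_coords`` / ``theta_coords`` to support fast structured
    interpolation (empty for ad-hoc meshes).
    """

    nodes: np.ndarray                 # (n, 2)
    elements: np.ndarray              # (ne, 4) CCW quads
    boundary: dict                    # name -> ordered node-index array
    material_radius: np.ndarray       # (n,)
    radial_coords: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta_coords: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def copy(self) -> "Mesh":
        return Mesh(
            self.nodes.copy(),
            self.elements.copy(),
            {k: v.copy() for k, v in self.boundary.items()},
            self.material_radius.copy(),
            self.radial_coords.copy(),
            self.theta_coords.copy(),
        )


def _radial_grading(geom: GeometryParams, n_radial: int, min_cortex_layers: int = 4):
    """Radial node positions with the cortex band [r_cp, R] guaranteed at
    least ``min_cortex_layers`` element layers (when n_radial allows)."""
    frac = (geom.R - geom.r_cp) / (geom.R - geom.r)
    n_cortex = int(round(n_radial * frac))
    n_cortex = max(min(min_cortex_layers, n_radial - 2), n_cortex)
    n_cortex = min(n_cortex, n_radial - 2)
    n_sub = n_radial - n_cortex
    rs = np.concatenate(
        [
            np.linspace(geom.r, geom.r_cp, n_sub + 1),
            np.linspace(geom.r_cp, geom.R, n_cortex + 1)[1:],
        ]
    )
    return rs


def build_quarter_annulus(
    geom: GeometryParams,
    n_radial: int,
    n_circumferential: int,
    grading: bool = True,
) -> Mesh:
    """Structured quad mesh of the sector theta in [0, pi/2], radius in [r, R].

    Nodes are ordered radially-major: node(ir, it) = ir * (n_c + 1) + it.
    Boundary tags: ``inner`` (radius r), ``outer`` (radius R), ``edge_y0``
    (the edge on the x-axis, y = 0), ``edge_x0`` (the edge on the y-axis,
    x = 0).
    """
    if n_radial < 2 or n_circumferential < 2:
        raise ValueError("need at least 2 elements in each direction")
    if geom.r >= geom.R:
        raise ValueError("inner radius must be smaller than outer radius")
    if grading:
        rs = _radial_grading(geom, n_radial)
    else:
        rs = np.linspace(geom.r, geom.R, n_radial + 1)
    thetas = np.linspace(0.0, np.pi / 2.0, n_circumferential + 1)
    Rg, Tg = np.meshgrid(rs, thetas, indexing="ij")
    nodes = np.column_stack([(Rg * np.cos(Tg)).ravel(), (Rg * np.sin(Tg)).ravel()])
    nt = n_circumferential + 1

    def nid(ir, it):
        return ir * nt + it

    elems = []
    for ir in range(len(rs) - 1):
        for it in range(n_circumferential):
            # CCW in (r, theta): positive Jacobian
            elems.append([nid(ir, it), nid(ir + 1, it), nid(ir + 1, it + 1), nid(ir, it + 1)])
    elements = np.asarray(elems, dtype=np.int64)

    boundary = {
        "inner": np.array([nid(0, it) for it in range(nt)], dtype=np.int64),
        "outer": np.array([nid(len(rs) - 1, it) for it in range(nt)], dtype=np.int64),
        "edge_y0": np.array([nid(ir, 0) for ir in range(len(rs))], dtype=np.int64),
        "edge_x0": np.array(
            [nid(ir, n_circumferential) for ir in range(len(rs))], dtype=np.int64
        ),
    }
    material_radius = Rg.ravel().copy()
    return Mesh(nodes, elements, boundary, material_radius, rs.copy(), thetas.copy())


def reference_fiber_direction(point):
    """Radial unit vector N = X / ||X|| in the reference configuration.

    Accepts a single point or an array of points (..., 2).
    """
    p = np.asarray(point, dtype=float)
    nrm = np.linalg.norm(p, axis=-1)
    if np.any(nrm == 0):
        raise ValueError("fiber direction undefined at the origin")
    return p / nrm[..., None]


def osvz_outer_radius(t, geom: GeometryParams):
    """Material outer boundary of the OSVZ, min(r_isvz + m_mst t, r_cp).

    MST translocation of outer radial glial cells pushes the OSVZ boundary
    outward linearly in time; it is capped at the cortical plate radius.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return np.minimum(geom.r_isvz + geom.m_mst * t, geom.r_cp)


def zone_weight_vz(ri, geom: GeometryParams = GeometryParams()):
    """VZ indicator 1 - H(ri - r_vz; 50), smooth in the material radius."""
    return 1.0 - smooth_heaviside(np.asarray(ri, dtype=float) - geom.r_vz, 50.0)


def zone_weight_osvz(ri, t, geom: GeometryParams = GeometryParams()):
    """OSVZ indicator H(ri - r_isvz; 50) - H(ri - r_osvz(t); 50).

    Zero width at t = 0 (the two logistic steps cancel); the tiny negative
    tail from the difference of logistics is clamped at 0.
    """
    ri = np.asarray(ri, dtype=float)
    ro = osvz_outer_radius(t, geom)
    w = smooth_heaviside(ri - geom.r_isvz, 50.0) - smooth_heaviside(ri - ro, 50.0)
    return np.clip(w, 0.0, 1.0)


def apply_boundary_perturbation(
    mesh: Mesh,
    amplitude: float,
    mode_count: int = 8,
    seed: int = 0,
    geom: GeometryParams = GeometryParams(),
) -> Mesh:
    """Seeded multi-mode radial perturbation of the cortical band.

    Breaks the rotational symmetry so the wrinkling bifurcation is
    triggered reproducibly. Node radii in the cortex band get
    ``amplitude * sum_k a_k cos(2 k theta)`` with seeded coefficients
    ``a_k = cos(phi_k)``, ``phi_k ~ U(0, 2 pi)``; the modes ``cos(2 k
    theta)`` have zero slope at both symmetry edges so the perturbed
    boundary stays compatible with the symmetry constraints. The
    perturbation ramps from 0 at material radius r_cp to full size at R.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = mesh.copy()
    if amplitude == 0.0:
        return out
    rng = np.random.default_rng(seed)
    coeff = np.cos(rng.uniform(0.0, 2.0 * np.pi, size=mode_count))
    theta = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    ramp = np.clip(
        (mesh.material_radius - geom.r_cp) / (geom.R - geom.r_cp), 0.0, 1.0
    )
    modes = sum(
        coeff[k] * np.cos(2.0 * (k + 1) * theta) for k in range(mode_count)
    )
    drho = amplitude * ramp * modes
    radius = np.linalg.norm(mesh.nodes, axis=1)
    scale = (radius + drho) / radius
    out.nodes = mesh.nodes * scale[:, None]
    return out
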