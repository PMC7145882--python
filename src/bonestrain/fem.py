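"""2D plane-stress linear elasticity on vertebral meshes.

The vertebra is modelled as a thin slab of uniform thickness loaded in its
plane: 3-node constant-strain triangles (CST), element stiffness
``k_e = t * A * B^T D B`` with the plane-stress elasticity matrix D built
from a BMD-dependent elastic modulus, the patient-specific compressive load
distributed as a uniform traction over the upper boundary, and the lower
boundary fixed.  The assembled system is sparse, symmetric and positive
definite after constraint elimination and is solved directly; the residual
must satisfy ||K u - f|| <= 1e-8 ||f||.

Per-element strains follow from ``eps = B u``; the scalar summary is the von
Mises equivalent strain of the full 3D tensor implied by plane stress
(eps_zz = -nu/(1-nu) (eps_xx + eps_yy)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import GeometryError, SolverError
from .mesh import TriMesh

__all__ = ["MaterialModel", "BoundaryConditions", "StrainField",
           "identify_surfaces", "make_boundary_conditions",
           "assemble_stiffness", "assemble_and_solve", "compute_strains",
           "DEFAULT_MATERIAL", "DEFAULT_THICKNESS_MM"]

DEFAULT_THICKNESS_MM = 30.0


@dataclass(frozen=True)
class MaterialModel:
    """Power-law BMD -> elastic modulus map with a positive floor.

    E(b) = max(floor, E_ref * (b / bmd_ref)^gamma).  The defaults
    (8000 MPa at 1.0 g/cm^2, gamma = 2, nu = 0.3, floor = 10 MPa) are
    documented modelling assumptions: density-modulus exponents of about 2
    are typical for trabecular bone, and the floor keeps near-void elements
    numerically benign.
    """

    E_ref: float = 8000.0
    bmd_ref: float = 1.0
    gamma: float = 2.0
    poisson: float = 0.3
    floor: float = 10.0

    def __post_init__(self) -> None:
        if self.E_ref <= 0 or self.bmd_ref <= 0 or self.floor <= 0:
            raise ValueError("E_ref, bmd_ref and floor must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if not 0.0 <= self.poisson <= 0.49:
            raise ValueError("poisson must lie in [0, 0.49]")

    def modulus(self, bmd) -> np.ndarray:
        b = np.asarray(bmd, dtype=float)
        return np.maximum(self.floor, self.E_ref * (b / self.bmd_ref) ** self.gamma)


DEFAULT_MATERIAL = MaterialModel()


@dataclass
class BoundaryConditions:
    """Nodal loads on the upper surface and fixed supports on the lower one.

    ``node_forces`` maps node index -> (fx, fy) in newtons;
    ``constrained_dofs`` are global degree-of-freedom indices (2*node for x,
    2*node+1 for y) held at zero displacement.
    """

    node_forces: dict
    constrained_dofs: np.ndarray
    thickness_mm: float = DEFAULT_THICKNESS_MM
    total_force_n: float | None = None

    def __post_init__(self) -> None:
        self.constrained_dofs = np.asarray(sorted(set(int(d) for d in
                                                      self.constrained_dofs)),
                                           dtype=np.int64)
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if not self.node_forces or self.constrained_dofs.size == 0:
            raise ValueError("loaded and constrained sets must be non-empty")
        loaded = set(self.node_forces)
        constrained = set(int(d) // 2 for d in self.constrained_dofs)
        if loaded & constrained:
            raise ValueError("loaded and constrained node sets must be disjoint")
        if self.total_force_n is not None:
            applied = float(np.sum(np.linalg.norm(
                np.asarray(list(self.node_forces.values()), dtype=float), axis=1)))
            if abs(applied - abs(self.total_force_n)) > 1e-9 * max(abs(self.total_force_n), 1.0):
                raise ValueError("nodal forces do not sum to the prescribed load")

    @property
    def loaded_nodes(self) -> np.ndarray:
        return np.asarray(sorted(self.node_forces), dtype=np.int64)

    @property
    def constrained_nodes(self) -> np.ndarray:
        return np.unique(self.constrained_dofs // 2)


@dataclass
class StrainField:
    """Per-element strain state of one solved vertebra."""

    exx: np.ndarray
    eyy: np.ndarray
    gxy: np.ndarray
    eq: np.ndarray          # von Mises equivalent strain, >= 0
    area_mm2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.exx)
        for name in ("eyy", "gxy", "eq", "area_mm2"):
            if len(getattr(self, name)) != n:
                raise ValueError("strain component arrays must share one length")
        if np.any(self.eq < 0):
            raise ValueError("equivalent strain must be nonnegative")


def identify_surfaces(mesh: TriMesh, band_fraction: float = 0.08):
    """Upper- and lower-surface boundary node sets of a vertebra.

    Boundary nodes whose y coordinate (y grows downward) lies within
    ``band_fraction`` of the vertical extent from the top belong to the upper
    surface; symmetrically at the bottom for the lower surface.
    """
    if not 0.0 < band_fraction < 0.5:
        raise ValueError("band_fraction must lie in (0, 0.5)")
    bnodes = mesh.boundary_nodes()
    y = mesh.nodes[bnodes, 1]
    ymin, ymax = y.min(), y.max()
    extent = ymax - ymin
    if extent <= 0:
        raise GeometryError("mesh has zero vertical extent")
    upper = bnodes[y <= ymin + band_fraction * extent + 1e-12]
    lower = bnodes[y >= ymax - band_fraction * extent - 1e-12]
    if upper.size == 0 or lower.size == 0:
        raise GeometryError("empty upper or lower surface node set")
    return upper, lower


def make_boundary_conditions(mesh: TriMesh, total_force_n: float,
                             band_fraction: float = 0.08,
                             thickness_mm: float = DEFAULT_THICKNESS_MM,
                             constraint: str = "fixed") -> BoundaryConditions:
    """Distribute a compressive load over the upper surface and fix the lower.

    The load acts in +y (downward, image convention) as a uniform vertical
    pressure over the upper-surface band: each boundary edge contributes its
    sub-segment inside the band, weighted by horizontal projection and lumped
    consistently onto the edge nodes.  ``constraint`` is
    ``fixed`` (both components of every lower node) or ``roller``
    (frictionless: y only, plus x of one node to remove the lateral
    rigid-body mode).
    """
    upper, lower = identify_surfaces(mesh, band_fraction)

    # the loaded region is the geometric band, not a node set: each boundary
    # edge contributes the sub-segment lying inside the band, so the applied
    # traction is independent of the mesh resolution
    bnodes = mesh.boundary_nodes()
    yb = mesh.nodes[bnodes, 1]
    y_cut = yb.min() + band_fraction * (yb.max() - yb.min()) + 1e-12

    edges = mesh.boundary_edges()
    ya = mesh.nodes[edges[:, 0], 1]
    yc = mesh.nodes[edges[:, 1], 1]
    covered = []            # (i, j, sub-length, mean parameter of sub-segment)
    for (i, j), y0, y1 in zip(edges, ya, yc):
        if y0 <= y_cut and y1 <= y_cut:
            t0, t1 = 0.0, 1.0
        elif y0 <= y_cut < y1:
            t0, t1 = 0.0, (y_cut - y0) / (y1 - y0)
        elif y1 <= y_cut < y0:
            t0, t1 = (y_cut - y0) / (y1 - y0), 1.0
        else:
            continue
        # weight by the horizontal projection: a uniform vertical pressure
        # loads a surface element in proportion to its projected width, so
        # near-vertical flanks inside the band carry (almost) nothing
        L = abs(mesh.nodes[j, 0] - mesh.nodes[i, 0]) * (t1 - t0)
        if L > 0:
            covered.append((int(i), int(j), L, 0.5 * (t0 + t1)))
    if not covered:
        raise GeometryError("no boundary edge intersects the upper band")
    total_len = sum(c[2] for c in covered)

    node_forces: dict = {}
    for i, j, L, tbar in covered:
        share = total_force_n * L / total_len
        for n_, w in ((i, 1.0 - tbar), (j, tbar)):
            fx, fy = node_forces.get(n_, (0.0, 0.0))
            node_forces[n_] = (fx, fy + share * w)

    if constraint == "fixed":
        dofs = np.concatenate([2 * lower, 2 * lower + 1])
    elif constraint == "roller":
        anchor = lower[np.argmin(mesh.nodes[lower, 0])]
        dofs = np.concatenate([2 * lower + 1, [2 * anchor]])
    else:
        raise ValueError(f"unknown constraint style {constraint!r}")

    return BoundaryConditions(node_forces=node_forces, constrained_dofs=dofs,
                              thickness_mm=thickness_mm,
                              total_force_n=total_force_n)


def _element_B_and_area(nodes: np.ndarray, tri: np.ndarray):
    """Strain-displacement matrices B (m, 3, 6) and areas (m,) for CSTs."""
    p = nodes[tri]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    # signed area; positive for the CCW orientation TriMesh guarantees
    area = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                  - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    m = len(tri)
    B = np.zeros((m, 3, 6))
    inv2A = 1.0 / (2.0 * area)
    for k in range(3):
        B[:, 0, 2 * k] = b[:, k] * inv2A
        B[:, 1, 2 * k + 1] = c[:, k] * inv2A
        B[:, 2, 2 * k] = c[:, k] * inv2A
        B[:, 2, 2 * k + 1] = b[:, k] * inv2A
    return B, area


def assemble_stiffness(mesh: TriMesh, thickness_mm: float,
                       poisson: float) -> sparse.csr_matrix:
    """Global stiffness matrix (N/mm) for a mesh with assigned moduli."""
    if mesh.element_modulus is None:
        raise ValueError("mesh has no moduli; call assign_materials first")
    E = np.asarray(mesh.element_modulus, dtype=float)
    nu = poisson
    B, area = _element_B_and_area(mesh.nodes, mesh.triangles)
    # plane-stress D, factored as E_e * D0
    D0 = np.array([[1.0, nu, 0.0],
                   [nu, 1.0, 0.0],
                   [0.0, 0.0, (1.0 - nu) / 2.0]]) / (1.0 - nu ** 2)
    ke = np.einsum("mki,kl,mlj->mij", B, D0, B) \
        * (E * area * thickness_mm)[:, None, None]

    dof = np.empty((len(mesh.triangles), 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    n_dof = 2 * len(mesh.nodes)
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)),
                          shape=(n_dof, n_dof)).tocsr()
    return K


def assemble_and_solve(mesh: TriMesh, bcs: BoundaryConditions,
                       poisson: float = DEFAULT_MATERIAL.poisson,
                       residual_tol: float = 1e-8) -> np.ndarray:
    """Solve K u = f with the given boundary conditions.

    Fixed dofs are eliminated by reduction to the free set; the reduced
    system is symmetric positive definite and solved directly.  Returns the
    full nodal displacement vector (mm), zero at constrained dofs.
    """
    K = assemble_stiffness(mesh, bcs.thickness_mm, poisson)
    n_dof = K.shape[0]
    f = np.zeros(n_dof)
    for node, (fx, fy) in bcs.node_forces.items():
        f[2 * node] += fx
        f[2 * node + 1] += fy

    fixed = bcs.constrained_dofs
    free = np.setdiff1d(np.arange(n_dof), fixed, assume_unique=False)
    Kff = K[np.ix_(free, free)].tocsc()
    with np.errstate(all="ignore"):
        uf = spsolve(Kff, f[free])
    if not np.all(np.isfinite(uf)):
        raise SolverError(
            "singular stiffness matrix: a rigid-body mode (translation or "
            "rotation) is unconstrained — check the lower-surface supports")

    u = np.zeros(n_dof)
    u[free] = uf
    resid = np.linalg.norm(Kff @ uf - f[free])
    fnorm = np.linalg.norm(f)
    if fnorm > 0 and resid > residual_tol * fnorm:
        raise SolverError(
            f"solver residual {resid:.3e} exceeds {residual_tol:.1e} * ||f||: "
            "the system is singular or nearly so (an unconstrained rigid-body "
            "mode, or a degenerate mesh)")
    return u


def compute_strains(mesh: TriMesh, displacements: np.ndarray,
                    poisson: float = DEFAULT_MATERIAL.poisson) -> StrainField:
    """Constant per-element strain tensor and von Mises equivalent strain.

    The out-of-plane normal strain implied by plane stress,
    eps_zz = -nu/(1-nu) (eps_xx + eps_yy), enters the deviatoric invariant so
    that a pure volumetric in-plane state still reports its true distortion.
    """
    u = np.asarray(displacements, dtype=float).ravel()
    if u.size != 2 * len(mesh.nodes):
        raise ValueError("displacement vector length must be 2 x node count")
    B, area = _element_B_and_area(mesh.nodes, mesh.triangles)
    dof = np.empty((len(mesh.triangles), 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    eps = np.einsum("mij,mj->mi", B, u[dof])
    exx, eyy, gxy = eps[:, 0], eps[:, 1], eps[:, 2]

    ezz = -poisson / (1.0 - poisson) * (exx + eyy)
    exy = gxy / 2.0
    mean = (exx + eyy + ezz) / 3.0
    dxx, dyy, dzz = exx - mean, eyy - mean, ezz - mean
    eq = np.sqrt(2.0 / 3.0 * (dxx ** 2 + dyy ** 2 + dzz ** 2 + 2.0 * exy ** 2))
    return StrainField(exx=exx, eyy=eyy, gxy=gxy, eq=eq, area_mm2=area)
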