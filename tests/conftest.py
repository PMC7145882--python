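import numpy as np
import pytest

from bonestrain.fem import assemble_stiffness, make_boundary_conditions
from bonestrain.mesh import BMDImage, VertebraROI, extract_contour, triangulate
from bonestrain.phantom import PhantomSpec, generate_vertebra_image


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noiseless default phantom: image plus analytic ROIs."""
    spec = PhantomSpec(noise_sd_g_cm2=0.0)
    image, rois = generate_vertebra_image(spec)
    return spec, image, rois


@pytest.fixture(scope="session")
def segmented_rois(quiet_phantom):
    _, image, _ = quiet_phantom
    return extract_contour(image)


@pytest.fixture(scope="session")
def default_mesh(segmented_rois):
    """Default-resolution mesh of the topmost vertebra."""
    return triangulate(segmented_rois[0], 3.0)


@pytest.fixture()
def unit_square_roi():
    return VertebraROI(level="SQ", contour=np.array(
        [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture(scope="session")
def square_10mm_mesh():
    roi = VertebraROI(level="SQ", contour=np.array(
        [[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]))
    return triangulate(roi, 2.0)


class UniformModulus:
    """Material stub: constant modulus regardless of BMD."""

    def __init__(self, E=5000.0, poisson=0.3):
        self.E = E
        self.poisson = poisson
        self.floor = 1.0

    def modulus(self, bmd):
        return np.full_like(np.asarray(bmd, dtype=float), self.E)


@pytest.fixture()
def uniform_material():
    return UniformModulus()


def external_work_and_strain_energy(mesh, bcs, u, poisson):
    """Both sides of the energy balance, computed independently."""
    K = assemble_stiffness(mesh, bcs.thickness_mm, poisson)
    f = np.zeros(2 * len(mesh.nodes))
    for n, (fx, fy) in bcs.node_forces.items():
        f[2 * n] += fx
        f[2 * n + 1] += fy
    return 0.5 * f @ u, 0.5 * u @ (K @ u)


def solve_square_compression(mesh, material, p_mpa=2.0, thickness=30.0,
                             constraint="roller", width=10.0):
    """Uniaxial compression of a square; returns (u, strain field, bcs)."""
    from bonestrain.fem import assemble_and_solve, compute_strains
    from bonestrain.mesh import assign_materials

    img = BMDImage(values=np.full((16, 16), 0.8), pixel_spacing_mm=1.0)
    mesh = assign_materials(mesh, img, material)
    F = p_mpa * width * thickness
    bcs = make_boundary_conditions(mesh, F, band_fraction=0.05,
                                   thickness_mm=thickness, constraint=constraint)
    u = assemble_and_solve(mesh, bcs, poisson=material.poisson)
    return mesh, u, compute_strains(mesh, u, poisson=material.poisson), bcs
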