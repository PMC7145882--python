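import numpy as np
import pytest

from bonestrain.errors import SolverError
from bonestrain.fem import (BoundaryConditions, MaterialModel,
                            assemble_and_solve, assemble_stiffness,
                            compute_strains, identify_surfaces,
                            make_boundary_conditions)
from bonestrain.mesh import BMDImage, TriMesh, VertebraROI, assign_materials, triangulate

from conftest import (UniformModulus, external_work_and_strain_energy,
                      solve_square_compression)


# ---------------------------------------------------------------------------
# Surface identification
# ---------------------------------------------------------------------------

def test_unit_square_surfaces(unit_square_roi):
    mesh = triangulate(unit_square_roi, 0.5)
    upper, lower = identify_surfaces(mesh, band_fraction=0.1)
    assert np.allclose(mesh.nodes[upper, 1], 0.0)     # y down: top is y=0
    assert np.allclose(mesh.nodes[lower, 1], 1.0)
    assert not set(upper) & set(lower)


def test_band_below_half_keeps_sets_disjoint(default_mesh):
    for band in (0.05, 0.2, 0.45):
        upper, lower = identify_surfaces(default_mesh, band_fraction=band)
        assert not set(upper) & set(lower)
        assert upper.size and lower.size


def test_rotating_mesh_180_swaps_surfaces(default_mesh):
    upper, lower = identify_surfaces(default_mesh, band_fraction=0.1)
    centre = default_mesh.nodes.mean(axis=0)
    rotated = TriMesh(nodes=2 * centre - default_mesh.nodes,
                      triangles=default_mesh.triangles, level="rot")
    up2, lo2 = identify_surfaces(rotated, band_fraction=0.1)
    assert set(up2) == set(lower)
    assert set(lo2) == set(upper)


def test_invalid_band_fraction(default_mesh):
    with pytest.raises(ValueError):
        identify_surfaces(default_mesh, band_fraction=0.6)


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

def test_zero_load_zero_displacement(square_10mm_mesh, uniform_material):
    img = BMDImage(values=np.full((16, 16), 0.8), pixel_spacing_mm=1.0)
    mesh = assign_materials(square_10mm_mesh, img, uniform_material)
    bcs = make_boundary_conditions(mesh, 0.0, band_fraction=0.05)
    u = assemble_and_solve(mesh, bcs, poisson=0.3)
    assert np.allclose(u, 0.0, atol=1e-15)


@pytest.mark.parametrize("target_edge", [5.0, 2.0, 1.0])
def test_patch_test_exact_for_cst(target_edge, uniform_material):
    """Uniform uniaxial compression: eyy = -p/E, exx = nu p/E, exact."""
    roi = VertebraROI(level="SQ", contour=np.array(
        [[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]))
    mesh = triangulate(roi, target_edge)
    p = 2.0
    _, u, field, _ = solve_square_compression(mesh, uniform_material, p_mpa=p)
    E, nu = uniform_material.E, uniform_material.poisson
    assert np.max(np.abs(field.eyy + p / E)) <= 1e-10 * p / E
    assert np.max(np.abs(field.exx - nu * p / E)) <= 1e-10 * p / E
    assert np.max(np.abs(field.gxy)) <= 1e-10 * p / E
    # uniform state: equivalent strain identical in every element
    assert field.eq.std() <= 1e-12 * field.eq.mean()


def test_two_material_strip_in_series(uniform_material):
    """Stacked soft/stiff layers match the 1D springs-in-series compliance."""
    roi = VertebraROI(level="ST", contour=np.array(
        [[0.0, 0.0], [10.0, 0.0], [10.0, 20.0], [0.0, 20.0]]))
    mesh = triangulate(roi, 1.0)
    E1, E2 = 8000.0, 2000.0         # top half, bottom half

    class TwoLayer:
        poisson = 0.0               # suppress lateral coupling for the 1D oracle
        floor = 1.0

        def modulus(self, bmd):
            return np.asarray(bmd, dtype=float)

    img_values = np.full((24, 12), E2, dtype=float)
    img_values[:10, :] = E1         # rows 0-9 -> y in [0, 10) mm
    img = BMDImage(values=img_values, pixel_spacing_mm=1.0)
    mesh = assign_materials(mesh, img, TwoLayer())

    p, t = 1.0, 30.0
    F = p * 10.0 * t
    bcs = make_boundary_conditions(mesh, F, band_fraction=0.02,
                                   thickness_mm=t, constraint="roller")
    u = assemble_and_solve(mesh, bcs, poisson=0.0)
    top_nodes, _ = identify_surfaces(mesh, band_fraction=0.02)
    end_disp = np.mean(u[2 * top_nodes + 1])
    expected = p * (10.0 / E1 + 10.0 / E2)   # compression toward +y
    assert end_disp == pytest.approx(expected, rel=0.02)


def test_rigid_translation_has_zero_strain(default_mesh):
    u = np.tile([0.3, -0.7], len(default_mesh.nodes))
    field = compute_strains(default_mesh, u)
    assert np.allclose(field.exx, 0.0, atol=1e-12)
    assert np.allclose(field.eq, 0.0, atol=1e-12)


def test_energy_balance_on_phantom_solves(segmented_rois, quiet_phantom):
    _, image, _ = quiet_phantom
    material = MaterialModel()
    for roi in segmented_rois:
        mesh = assign_materials(triangulate(roi, 3.0), image, material)
        bcs = make_boundary_conditions(mesh, 400.0)
        u = assemble_and_solve(mesh, bcs, poisson=material.poisson)
        work, energy = external_work_and_strain_energy(mesh, bcs, u,
                                                       material.poisson)
        assert abs(energy - work) <= 1e-8 * abs(work)


def test_linearity_in_load(segmented_rois, quiet_phantom):
    _, image, _ = quiet_phantom
    material = MaterialModel()
    mesh = assign_materials(triangulate(segmented_rois[0], 3.0), image, material)
    u1 = assemble_and_solve(mesh, make_boundary_conditions(mesh, 300.0),
                            poisson=material.poisson)
    u2 = assemble_and_solve(mesh, make_boundary_conditions(mesh, 600.0),
                            poisson=material.poisson)
    f1 = compute_strains(mesh, u1, material.poisson)
    f2 = compute_strains(mesh, u2, material.poisson)
    assert np.allclose(f2.eq, 2.0 * f1.eq, rtol=1e-9)
    assert np.allclose(f2.exx, 2.0 * f1.exx, rtol=1e-9, atol=1e-18)


def test_strains_scale_inversely_with_moduli(segmented_rois, quiet_phantom):
    _, image, _ = quiet_phantom
    from dataclasses import replace as dc_replace
    mesh = assign_materials(triangulate(segmented_rois[1], 3.0), image,
                            MaterialModel())
    k = 2.5
    stiffer = dc_replace(mesh, element_modulus=k * mesh.element_modulus)
    bcs = make_boundary_conditions(mesh, 450.0)
    f1 = compute_strains(mesh, assemble_and_solve(mesh, bcs), 0.3)
    f2 = compute_strains(stiffer, assemble_and_solve(stiffer, bcs), 0.3)
    assert np.allclose(f2.eq, f1.eq / k, rtol=1e-9)


def test_stiffness_symmetric(default_mesh, quiet_phantom):
    _, image, _ = quiet_phantom
    mesh = assign_materials(default_mesh, image, MaterialModel())
    K = assemble_stiffness(mesh, 30.0, 0.3)
    assert abs(K - K.T).max() <= 1e-9 * abs(K).max()


def test_solution_invariant_under_node_permutation(segmented_rois, quiet_phantom):
    _, image, _ = quiet_phantom
    mesh = assign_materials(triangulate(segmented_rois[2], 3.0), image,
                            MaterialModel())
    bcs = make_boundary_conditions(mesh, 420.0)
    ref = compute_strains(mesh, assemble_and_solve(mesh, bcs), 0.3)

    rng = np.random.default_rng(8)
    perm = rng.permutation(len(mesh.nodes))
    inv = np.argsort(perm)
    pmesh = TriMesh(nodes=mesh.nodes[perm], triangles=inv[mesh.triangles],
                    element_bmd=mesh.element_bmd,
                    element_modulus=mesh.element_modulus)
    pbcs = BoundaryConditions(
        node_forces={int(inv[n]): f for n, f in bcs.node_forces.items()},
        constrained_dofs=np.concatenate(
            [[2 * inv[d // 2] + d % 2] for d in bcs.constrained_dofs]),
        thickness_mm=bcs.thickness_mm, total_force_n=bcs.total_force_n)
    got = compute_strains(pmesh, assemble_and_solve(pmesh, pbcs), 0.3)
    assert np.allclose(np.sort(got.eq), np.sort(ref.eq), rtol=1e-9)


def test_unconstrained_system_raises(square_10mm_mesh, uniform_material):
    img = BMDImage(values=np.full((16, 16), 0.8), pixel_spacing_mm=1.0)
    mesh = assign_materials(square_10mm_mesh, img, uniform_material)
    bcs = make_boundary_conditions(mesh, 100.0)
    # constrain a single dof: rotation and translation modes remain
    crippled = BoundaryConditions(node_forces=bcs.node_forces,
                                  constrained_dofs=bcs.constrained_dofs[:1],
                                  thickness_mm=30.0)
    with pytest.raises(SolverError, match="rigid-body|singular"):
        assemble_and_solve(mesh, crippled)


def test_mesh_convergence_of_mean_equivalent_strain(segmented_rois, quiet_phantom):
    _, image, _ = quiet_phantom
    material = MaterialModel()
    means = []
    for target in (3.0, 1.5):
        mesh = assign_materials(triangulate(segmented_rois[0], target),
                                image, material)
        bcs = make_boundary_conditions(mesh, 450.0)
        f = compute_strains(mesh, assemble_and_solve(mesh, bcs), material.poisson)
        means.append(np.sum(f.eq * f.area_mm2) / np.sum(f.area_mm2))
    assert abs(means[1] - means[0]) / means[0] < 0.01


def test_disjointness_enforced_in_boundary_conditions():
    with pytest.raises(ValueError, match="disjoint"):
        BoundaryConditions(node_forces={0: (0.0, 1.0)},
                           constrained_dofs=[0, 1])


def test_force_sum_validated(default_mesh):
    bcs = make_boundary_conditions(default_mesh, 500.0)
    total = sum(fy for _, fy in bcs.node_forces.values())
    assert total == pytest.approx(500.0, rel=1e-12)
    with pytest.raises(ValueError, match="sum"):
        BoundaryConditions(node_forces={0: (0.0, 1.0)},
                           constrained_dofs=[10, 11], total_force_n=2.0)
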