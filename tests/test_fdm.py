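"""Finite-difference forward solver: stencil, solves, lead fields, current density."""

import numpy as np
import pytest

from tesplan.analytic import DipoleSource, analytic_shell_potential
from tesplan.cortex import CorticalPatch
from tesplan.fdm import (
    InjectionPattern,
    assemble_fdm_system,
    current_density,
    dipole_scalp_voltages,
    lead_field_from_reciprocity,
    solve_injection,
    solve_monopoles,
)
from tesplan.phantom import (
    DEFAULT_CONDUCTIVITIES,
    ShellSpec,
    TISSUES,
    VoxelHeadModel,
    assign_conductivities,
    build_shell_phantom,
)


def block_model(shape, tissue="scalp", spacing=2.0):
    """A conducting block surrounded by one voxel of air."""
    full = tuple(s + 2 for s in shape)
    labels = np.zeros(full, dtype=np.int8)
    labels[1:-1, 1:-1, 1:-1] = TISSUES.index(tissue)
    m = VoxelHeadModel(labels=labels, spacing_mm=spacing, conductivity=np.zeros(full))
    return assign_conductivities(m, DEFAULT_CONDUCTIVITIES)


class TestAssembly:
    def test_row_sums_vanish_on_homogeneous_block(self):
        sys_ = assemble_fdm_system(block_model((3, 3, 3)))
        rows = np.asarray(sys_.laplacian.sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 0.0, atol=1e-15)

    def test_harmonic_mean_face_conductance(self):
        # scalp voxel next to a skull voxel
        labels = np.zeros((4, 3, 3), dtype=np.int8)
        labels[1, 1, 1] = TISSUES.index("scalp")
        labels[2, 1, 1] = TISSUES.index("skull")
        m = VoxelHeadModel(labels=labels, spacing_mm=2.0, conductivity=np.zeros((4, 3, 3)))
        assign_conductivities(m, DEFAULT_CONDUCTIVITIES)
        sys_ = assemble_fdm_system(m)
        a = sys_.index[1, 1, 1]
        b = sys_.index[2, 1, 1]
        expect = 2.0 / (1 / 0.44 + 1 / 0.018) * 2e-3  # sigma_face * h
        assert sys_.laplacian[a, b] == pytest.approx(-expect, rel=1e-12)

    def test_air_faces_have_zero_coupling(self):
        sys_ = assemble_fdm_system(block_model((2, 2, 2)))
        # every voxel of a 2x2x2 block touches 3 conducting and 3 air faces:
        # couplings exist only for the conducting faces (Neumann at air)
        L = sys_.laplacian.toarray()
        g = 0.44 * 2e-3  # face conductance within the homogeneous block
        for i in range(8):
            assert np.count_nonzero(L[i]) == 4  # self + 3 conducting neighbors
            assert L[i, i] == pytest.approx(3 * g, rel=1e-12)
        np.testing.assert_allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0, atol=1e-15)

    def test_disconnected_region_reports_component_sizes(self):
        labels = np.zeros((7, 3, 3), dtype=np.int8)
        labels[1, 1, 1] = TISSUES.index("scalp")
        labels[4:6, 1, 1] = TISSUES.index("scalp")
        m = VoxelHeadModel(labels=labels, spacing_mm=2.0, conductivity=np.zeros((7, 3, 3)))
        assign_conductivities(m, DEFAULT_CONDUCTIVITIES)
        with pytest.raises(ValueError, match=r"2 components.*\[2, 1\]"):
            assemble_fdm_system(m)


class TestSolve:
    def test_zero_pattern_gives_zero_potential(self, homog_world):
        w = homog_world
        phi = solve_injection(w.system, w.electrodes, InjectionPattern(np.zeros(len(w.electrodes))))
        vals = phi.values[w.model.conducting_mask]
        np.testing.assert_array_equal(vals, 0.0)

    def test_nonzero_sum_pattern_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            InjectionPattern(np.array([100.0, -50.0]))

    def test_linearity_under_negation(self, homog_world):
        w = homog_world
        pat = np.zeros(len(w.electrodes))
        pat[0], pat[-1] = 100.0, -100.0
        a = solve_injection(w.system, w.electrodes, InjectionPattern(pat), tol=1e-10)
        b = solve_injection(w.system, w.electrodes, InjectionPattern(-pat), tol=1e-10)
        mask = w.model.conducting_mask
        np.testing.assert_allclose(a.values[mask], -b.values[mask], atol=1e-12 * np.abs(a.values[mask]).max())

    def test_antipodal_antisymmetry_on_homogeneous_sphere(self):
        model = build_shell_phantom(ShellSpec(((60.0, "scalp"),)), spacing_mm=4.0)
        sys_ = assemble_fdm_system(model)
        c = model._center_mm
        top = c + [0, 0, 58.0]
        bot = c - [0, 0, 58.0]
        phi = solve_monopoles(sys_, np.array([top, bot]), np.array([1e-3, -1e-3]), tol=1e-10)
        v = np.nan_to_num(phi.values)
        # sources sit on the same x/y voxel column, so the solution is
        # antisymmetric under the z-index reflection
        flipped = -v[:, :, ::-1]
        denom = np.abs(v).max()
        assert np.abs(v - flipped).max() / denom < 1e-6

    def test_average_reference_and_conservation(self, homog_world):
        w = homog_world
        pat = np.zeros(len(w.electrodes))
        pat[0], pat[3] = 150.0, -150.0
        phi = solve_injection(w.system, w.electrodes, InjectionPattern(pat), tol=1e-10)
        vals = phi.values[tuple(w.system.voxels.T)]
        assert abs(vals.mean()) < 1e-12 * np.abs(vals).max()
        # discrete conservation: residual of the solved system is tiny
        b = np.zeros(w.system.n_unknowns)
        b[w.system.node_of_point(w.electrodes.positions_mm[0])] += 150e-6
        b[w.system.node_of_point(w.electrodes.positions_mm[3])] -= 150e-6
        resid = w.system.laplacian @ vals - b
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(b)


class TestLeadField:
    def test_reciprocity_against_direct_dipole_solves(self, homog_world, rng):
        w = homog_world
        picks = rng.choice(len(w.parcellation.patches), 4, replace=False)
        for pi in picks:
            patch = w.parcellation.patches[pi]
            volts = dipole_scalp_voltages(
                w.system, w.electrodes, patch.centroid_mm, patch.normal, tol=1e-10
            )
            col = w.lfm.column(patch.id)
            assert np.linalg.norm(volts - col) / np.linalg.norm(col) < 0.02

    def test_moment_linearity(self, homog_world):
        w = homog_world
        patch = w.parcellation.patches[0]
        v1 = dipole_scalp_voltages(w.system, w.electrodes, patch.centroid_mm, patch.normal, 1.0)
        v2 = dipole_scalp_voltages(w.system, w.electrodes, patch.centroid_mm, patch.normal, 2.0)
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-9)

    def test_columns_average_referenced(self, four_shell_world):
        M = four_shell_world.lfm.matrix
        np.testing.assert_allclose(M.mean(axis=0), 0.0, atol=1e-18 + 1e-12 * np.abs(M).max())

    def test_central_radial_dipole_matches_series(self, homog_world):
        # scalp pattern of a central radial dipole correlates > 0.99 with the
        # analytic solution
        w = homog_world
        from types import SimpleNamespace

        patch = CorticalPatch(
            id=0,
            triangles=np.array([0]),
            area_cm2=1.0,
            centroid_mm=w.center + [0.0, 0.0, 20.0],
            normal=np.array([0.0, 0.0, 1.0]),
        )
        parc = SimpleNamespace(patches=[patch])
        lfm = lead_field_from_reciprocity(w.system, w.electrodes, parc, tol=1e-10)
        col = lfm.matrix[:, 0]
        phi_an = analytic_shell_potential(
            ShellSpec(((92.0, "scalp"),)),
            DipoleSource((0.0, 0.0, 20.0), (0.0, 0.0, 1.0)),
            w.electrodes.positions_mm - w.center,
        )
        r = np.corrcoef(col, phi_an)[0, 1]
        assert r > 0.99

    def test_patch_in_air_rejected(self, homog_world):
        from types import SimpleNamespace

        w = homog_world
        far = CorticalPatch(
            id=7,
            triangles=np.array([0]),
            area_cm2=1.0,
            centroid_mm=np.array([0.0, 0.0, 0.0]),  # grid corner: air
            normal=np.array([0.0, 0.0, 1.0]),
        )
        with pytest.raises(ValueError, match="patch 7"):
            lead_field_from_reciprocity(w.system, w.electrodes, SimpleNamespace(patches=[far]))


class TestCurrentDensity:
    def test_constant_potential_gives_zero(self):
        m = block_model((4, 4, 4))
        from tesplan.fdm import PotentialField

        phi = PotentialField(values=np.full(m.shape, 3.7), spacing_mm=m.spacing_mm)
        J = current_density(m, phi).values
        np.testing.assert_array_equal(J, 0.0)

    def test_negation_linearity_and_air_zero(self, homog_world):
        w = homog_world
        pat = np.zeros(len(w.electrodes))
        pat[0], pat[5] = 120.0, -120.0
        phi = solve_injection(w.system, w.electrodes, InjectionPattern(pat), tol=1e-10)
        J1 = current_density(w.model, phi).values
        phi.values = -phi.values
        J2 = current_density(w.model, phi).values
        np.testing.assert_allclose(J1, -J2, atol=1e-12 * np.abs(J1).max())
        assert np.all(J1[~w.model.conducting_mask] == 0.0)

    def test_reference_shift_leaves_current_density_unchanged(self, homog_world):
        w = homog_world
        pat = np.zeros(len(w.electrodes))
        pat[1], pat[4] = 80.0, -80.0
        phi = solve_injection(w.system, w.electrodes, InjectionPattern(pat), tol=1e-10)
        J1 = current_density(w.model, phi).values
        phi.values = phi.values + 0.123
        J2 = current_density(w.model, phi).values
        np.testing.assert_allclose(J1, J2, atol=1e-9 * np.abs(J1).max())

    def test_bar_resistor_ohms_law(self):
        # homogeneous bar with end electrodes: interior |J| = I / A within 5%
        labels = np.zeros((10, 10, 34), dtype=np.int8)
        labels[2:8, 2:8, 2:32] = TISSUES.index("scalp")
        bar = VoxelHeadModel(labels=labels, spacing_mm=2.0, conductivity=np.zeros(labels.shape))
        assign_conductivities(bar, DEFAULT_CONDUCTIVITIES)
        sys_ = assemble_fdm_system(bar)
        I = 1e-3
        ends = np.array([(np.array([5, 5, 2]) + 0.5) * 2.0, (np.array([5, 5, 31]) + 0.5) * 2.0])
        phi = solve_monopoles(sys_, ends, np.array([I, -I]), tol=1e-10)
        J = current_density(bar, phi).values
        interior = np.linalg.norm(J, axis=-1)[2:8, 2:8, 12:22]
        area = (6 * 2e-3) ** 2
        assert np.all(np.abs(interior - I / area) / (I / area) < 0.05)
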