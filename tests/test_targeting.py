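"""Ranked-weighting montage construction, sham montages, montage evaluation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tesplan.cortex import nearest_patch
from tesplan.fdm import LeadFieldMatrix
from tesplan.phantom import ElectrodeSet
from tesplan.targeting import (
    Montage,
    SafetyLimits,
    TargetSpec,
    balance_and_cap,
    build_sham_montage,
    evaluate_montage,
    plan_montage,
    project_target_to_scalp,
    select_and_weight,
)

LIMITS = SafetyLimits()


class TestSelectAndWeight:
    def test_worked_example(self):
        v = np.array([10.0, 8.0, 6.0, -9.0, -3.0, -1.0])
        m = select_and_weight(v, 2, 2, LIMITS)
        np.testing.assert_allclose(
            m.currents_ua, [200.0, 160.0, 0.0, -200.0, -200.0 / 3.0, 0.0], atol=1e-9
        )

    def test_equal_magnitudes_hit_the_cap(self):
        v = np.array([5.0, 5.0, -5.0, -5.0])
        m = select_and_weight(v, 2, 2, LIMITS)
        np.testing.assert_allclose(np.abs(m.currents_ua), 200.0)

    def test_scale_invariance(self):
        v = np.array([10.0, 8.0, 6.0, -9.0, -3.0, -1.0])
        m1 = select_and_weight(v, 2, 2, LIMITS)
        m2 = select_and_weight(2 * v, 2, 2, LIMITS)
        np.testing.assert_array_equal(m1.currents_ua, m2.currents_ua)

    def test_ties_prefer_lower_electrode_index(self):
        v = np.array([5.0, 7.0, 7.0, -4.0, -4.0])
        m = select_and_weight(v, 2, 1, LIMITS)
        # both 7.0-electrodes selected over 5.0; the tied sinks pick index 3
        assert m.currents_ua[1] == 200.0 and m.currents_ua[2] == 200.0
        assert m.currents_ua[0] == 0.0
        assert m.currents_ua[3] == -200.0 and m.currents_ua[4] == 0.0

    def test_insufficient_polarity_raises(self):
        with pytest.raises(ValueError, match="insufficient polarity"):
            select_and_weight(np.array([1.0, 2.0, 3.0, -1.0]), 2, 2, LIMITS)


class TestBalanceAndCap:
    def test_worked_example_balancing(self):
        pre = Montage(["a", "b", "c", "d"], [200.0, 160.0, -200.0, -200.0 / 3.0])
        out = balance_and_cap(pre, 2.0, LIMITS)
        np.testing.assert_allclose(
            out.currents_ua, [148.148148, 118.518519, -200.0, -66.666667], atol=1e-2
        )
        assert out.net_current_ua() == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_montage_unchanged(self):
        pre = Montage(["a", "b"], [200.0, -200.0])
        out = balance_and_cap(pre, 2.0, LIMITS)
        np.testing.assert_array_equal(out.currents_ua, [200.0, -200.0])

    def test_requested_total_halves_currents(self):
        pre = Montage(
            [f"e{i}" for i in range(16)], [200.0] * 8 + [-200.0] * 8
        )  # balanced side sum 1.6 mA
        out = balance_and_cap(pre, 0.8, LIMITS)
        np.testing.assert_allclose(out.currents_ua, [100.0] * 8 + [-100.0] * 8)

    def test_nonpositive_request_rejected(self):
        pre = Montage(["a", "b"], [200.0, -200.0])
        with pytest.raises(ValueError, match="positive"):
            balance_and_cap(pre, 0.0, LIMITS)

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.data(),
        n_el=st.integers(6, 24),
        requested=st.floats(0.1, 2.0),
    )
    def test_safety_invariants_always_hold(self, data, n_el, requested):
        v = np.array(
            data.draw(
                st.lists(
                    st.floats(-10, 10).filter(lambda x: abs(x) > 1e-3),
                    min_size=n_el,
                    max_size=n_el,
                )
            )
        )
        n_pos, n_neg = int(np.sum(v > 0)), int(np.sum(v < 0))
        if n_pos == 0 or n_neg == 0:
            return
        N = data.draw(st.integers(1, n_pos))
        M = data.draw(st.integers(1, n_neg))
        out = balance_and_cap(select_and_weight(v, N, M, LIMITS), requested, LIMITS)
        assert np.abs(out.currents_ua).max() <= 200.0 + 1e-9
        assert out.total_source_ua <= min(requested, 2.0) * 1000.0 + 1e-9
        assert abs(out.net_current_ua()) <= 1e-9 * max(1.0, np.abs(out.currents_ua).max())
        assert out.n_sources == N and out.n_sinks == M


class TestProjection:
    @staticmethod
    def synthetic_lfm(rng, n_el=20, n_patch=6):
        M = rng.normal(size=(n_el, n_patch))
        M -= M.mean(axis=0, keepdims=True)
        return LeadFieldMatrix(M, [f"E{i:03d}" for i in range(n_el)], list(range(n_patch)))

    def test_cathodal_is_negated_anodal(self, rng):
        lfm = self.synthetic_lfm(rng)
        a = project_target_to_scalp(lfm, 2, "cortical_surface_anodal")
        c = project_target_to_scalp(lfm, 2, "cortical_surface_cathodal")
        np.testing.assert_array_equal(a, -c)

    def test_voltages_sum_to_zero(self, rng):
        lfm = self.synthetic_lfm(rng)
        v = project_target_to_scalp(lfm, 1)
        assert abs(v.sum()) < 1e-12 * np.abs(v).max()

    def test_missing_patch_raises(self, rng):
        lfm = self.synthetic_lfm(rng)
        with pytest.raises(KeyError, match="99"):
            project_target_to_scalp(lfm, 99)

    def test_polarity_antisymmetry_of_full_plan(self, rng):
        lfm = self.synthetic_lfm(rng)
        a = plan_montage(lfm, 3, "cortical_surface_anodal", 3, 3, 1.5)
        c = plan_montage(lfm, 3, "cortical_surface_cathodal", 3, 3, 1.5)
        np.testing.assert_array_equal(a.currents_ua, -c.currents_ua)

    def test_vertex_electrode_dominates_radial_dipole_column(self, four_shell_world):
        # raw lead-field column of the patch under the vertex: the electrode
        # straight above carries the largest (positive) voltage
        w = four_shell_world
        top_patch = nearest_patch(w.parcellation, w.center + [0.0, 0.0, 70.0])
        col = w.lfm.column(top_patch)
        dist_to_vertex = np.linalg.norm(
            w.electrodes.positions_mm - (w.center + [0.0, 0.0, 92.0]), axis=1
        )
        best = int(np.argmax(col))
        assert col[best] > 0
        assert dist_to_vertex[best] <= np.sort(dist_to_vertex)[2] + 1e-9


class TestTargetSpec:
    def test_request_above_cap_rejected(self):
        with pytest.raises(ValueError, match="safety"):
            TargetSpec(patch_id=0, polarity="cortical_surface_anodal", requested_total_ma=3.0)

    def test_bad_polarity_rejected(self):
        with pytest.raises(ValueError, match="polarity"):
            TargetSpec(patch_id=0, polarity="up", requested_total_ma=1.0)


class TestSham:
    @staticmethod
    def line_electrodes(xs):
        return ElectrodeSet(
            ids=[f"L{i}" for i in range(len(xs))],
            positions_mm=np.column_stack([xs, np.zeros(len(xs)), np.zeros(len(xs))]),
        )

    def test_adjacent_partners_on_line_geometry(self):
        xs = np.array([0.0, 10.0, 25.0, 30.0, 40.0, 55.0])
        electrodes = self.line_electrodes(xs)
        active = Montage(electrodes.ids, [180.0, 120.0, 0.0, 0.0, -140.0, -160.0])
        sham = build_sham_montage(active, electrodes)
        # source anchor L1 (lowest source current) pairs with nearest L0;
        # sink anchor L4 pairs with nearest L3 (brute-force distance check)
        expect = {"L1": 100.0, "L0": -100.0, "L4": -100.0, "L3": 100.0}
        got = {k: v for k, v in sham.to_dict().items() if v != 0.0}
        assert got == expect

    def test_total_and_zero_sum(self, rng):
        xs = np.arange(8) * 9.0
        electrodes = self.line_electrodes(xs)
        active = Montage(electrodes.ids, [200.0, 150.0, 0, 0, 0, 0, -250.0, -100.0])
        sham = build_sham_montage(active, electrodes)
        assert sham.total_source_ua == pytest.approx(200.0)
        assert sham.net_current_ua() == pytest.approx(0.0, abs=1e-12)
        assert sham.n_sources == 2 and sham.n_sinks == 2

    def test_opposite_side_neighbor_skipped_with_warning(self):
        xs = np.array([0.0, 10.0, 20.0, 30.0])
        electrodes = self.line_electrodes(xs)
        active = Montage(electrodes.ids, [200.0, -150.0, -50.0, 0.0])
        with pytest.warns(UserWarning, match="opposite side|already used"):
            sham = build_sham_montage(active, electrodes)
        sham.validate()
        assert sham.total_source_ua == pytest.approx(200.0)


class TestEvaluate:
    def test_superposition_matches_direct_solve(self, homog_world):
        w = homog_world
        v = w.lfm.column(w.parcellation.patches[0].id) * -1.0
        montage = balance_and_cap(select_and_weight(v, 3, 3, LIMITS), 1.0, LIMITS)
        direct = evaluate_montage(
            w.model, w.electrodes, montage, w.parcellation, system=w.system, tol=1e-10
        )
        fast = w.evaluator.evaluate(montage)
        np.testing.assert_allclose(
            direct["normal_a_per_m2"].to_numpy(),
            fast["normal_a_per_m2"].to_numpy(),
            rtol=1e-4,
            atol=1e-9,
        )

    def test_negated_montage_negates_normal_components(self, homog_world):
        w = homog_world
        montage = plan_montage(w.lfm, w.parcellation.patches[0].id, "cortical_surface_anodal", 3, 3, 1.0)
        a = w.evaluator.evaluate(montage)["normal_a_per_m2"].to_numpy()
        b = w.evaluator.evaluate(montage.negated())["normal_a_per_m2"].to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-15)

    def test_anodal_drives_positive_normal_density(self, four_shell_world):
        w = four_shell_world
        tp = nearest_patch(w.parcellation, w.center + [0.0, 0.0, 70.0])
        montage = plan_montage(w.lfm, tp, "cortical_surface_anodal", 8, 8, 2.0)
        assert w.evaluator.target_normal_density(montage, tp) > 0

    def test_requested_total_scales_target_density_linearly(self, four_shell_world):
        w = four_shell_world
        tp = nearest_patch(w.parcellation, w.center + [0.0, 0.0, 70.0])
        m1 = plan_montage(w.lfm, tp, "cortical_surface_anodal", 8, 8, 0.4)
        m2 = plan_montage(w.lfm, tp, "cortical_surface_anodal", 8, 8, 0.8)
        j1 = w.evaluator.target_normal_density(m1, tp)
        j2 = w.evaluator.target_normal_density(m2, tp)
        assert j2 / j1 == pytest.approx(m2.total_source_ua / m1.total_source_ua, rel=1e-9)

    def test_unknown_electrodes_rejected(self, homog_world):
        w = homog_world
        bad = Montage(["X1", "X2"], [100.0, -100.0])
        with pytest.raises(ValueError, match="unknown electrodes"):
            evaluate_montage(w.model, w.electrodes, bad, w.parcellation, system=w.system)

    def test_display_thresholding_masks_half(self, homog_world):
        w = homog_world
        montage = plan_montage(w.lfm, w.parcellation.patches[0].id, "cortical_surface_anodal", 3, 3, 1.0)
        df = evaluate_montage(
            w.model, w.electrodes, montage, w.parcellation, system=w.system, threshold_lowest=0.5
        )
        assert 0.4 <= df["display"].mean() <= 0.6
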