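"""Reduced-order equilibrium model: body building, solving, outputs."""

import numpy as np
import pytest
from scipy.optimize import brentq, check_grad

from spinetape.exceptions import BodyModelError, ConvergenceError
from spinetape.foam import FoundationLaw, load_material
from spinetape.mechanics import (
    GRAVITY,
    SEGMENT_MASS_FRACTIONS,
    BodySegmentModel,
    EquilibriumResult,
    SupportSurface,
    _column_groups,
    _energy_and_grad,
    build_default_body,
    contact_area,
    contact_pressure_profile,
    ivd_peak_stress,
    percent_change,
    pillow_footprint_area_cm2,
    solve_equilibrium,
)


@pytest.fixture(scope="module")
def body():
    return build_default_body(176.0, 74.0)


@pytest.fixture(scope="module")
def mm_surface():
    return SupportSurface.from_names("MM")


@pytest.fixture(scope="module")
def mm_result(body, mm_surface):
    return solve_equilibrium(body, mm_surface)


def single_node_body(mass=10.0, width=200.0):
    return BodySegmentModel(
        names=("blob",), x=np.array([500.0]),
        rest_offset=np.array([0.0]), mass=np.array([mass]),
        width=np.array([width]),
        k_axial=np.zeros(0), k_bend=np.zeros(1), lig_k=np.zeros(0),
        disc_levels={}, disc_area={},
    )


class TestBuildBody:
    def test_masses_sum_to_total(self, body):
        assert body.total_mass == pytest.approx(74.0, abs=1e-6)
        assert np.all(body.mass > 0)

    def test_head_mass_fraction(self, body):
        assert body.mass[0] == pytest.approx(74.0 * SEGMENT_MASS_FRACTIONS["head"])

    def test_height_scales_geometry(self):
        a = build_default_body(160.0, 74.0)
        b = build_default_body(176.0, 74.0)
        assert np.allclose(np.diff(b.x), np.diff(a.x) * 176.0 / 160.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(BodyModelError):
            build_default_body(120.0, 74.0)
        with pytest.raises(BodyModelError):
            build_default_body(176.0, 200.0)

    def test_disc_levels_cover_cervical_to_lumbosacral(self, body):
        assert "C5-C6" in body.disc_levels
        assert "L5-S1" in body.disc_levels
        assert len(body.disc_levels) == 23


class TestSolve:
    def test_energy_gradient_consistent(self, body, mm_surface):
        x = body.x
        h = mm_surface.surface_height(x)
        groups = _column_groups(mm_surface.columns(x))
        areas = body.tributary_lengths() * body.width
        rest = body.rest_offset
        rng = np.random.default_rng(1)
        y = rest + 150.0 + rng.normal(0, 5, body.n)
        f = lambda v: _energy_and_grad(v, body, groups, h, areas, rest, GRAVITY)
        err = check_grad(lambda v: f(v)[0], lambda v: f(v)[1], y)
        scale = np.linalg.norm(f(y)[1])
        assert err / scale < 1e-4

    def test_force_balance(self, mm_result):
        assert mm_result.force_balance_error < 5e-3
        assert mm_result.total_contact_force == pytest.approx(
            74.0 * GRAVITY, rel=5e-3
        )

    def test_energy_trace_non_increasing(self, mm_result):
        assert np.all(np.diff(mm_result.energy_trace) <= 1e-9)

    def test_zero_gravity_rest_shape_zero_pressure(self, body, mm_surface):
        r = solve_equilibrium(body, mm_surface, g=0.0)
        assert np.all(r.pressure == 0.0)
        assert np.allclose(np.diff(r.y), np.diff(body.rest_offset), atol=1e-6)

    def test_single_node_matches_scalar_oracle(self):
        """m g = p(w) A for one point mass on one foam column."""
        from spinetape.mechanics import _TabulatedColumn

        body = single_node_body(mass=10.0, width=200.0)
        mat = load_material("MM")
        law = FoundationLaw.single(mat, 200.0)
        surface = SupportSurface(law, pillow=None)
        r = solve_equilibrium(body, surface)
        area_mm2 = 200.0 * 200.0
        # oracle on the identical tabulated column the solver integrates
        col = _TabulatedColumn(law)
        w = brentq(
            lambda d: col.pressure(d) * area_mm2 * 1e-3 - 10.0 * GRAVITY,
            1e-9, 180.0,
        )
        assert r.deflection[0] == pytest.approx(w, abs=1e-6)
        # and against the exact (untabulated) law within the grid resolution
        w_exact = brentq(
            lambda d: mat.law(d / 200.0) * area_mm2 * 1e-3 - 10.0 * GRAVITY,
            0.0, 180.0,
        )
        assert r.deflection[0] == pytest.approx(w_exact, abs=0.01)

    def test_rigid_foundation_limit(self, body, mm_result):
        rigid = SupportSurface(
            FoundationLaw.single(load_material("HM").scaled(1e6), 200.0),
            FoundationLaw.single(load_material("pillow").scaled(1e6), 90.0),
        )
        r = solve_equilibrium(body, rigid)
        assert r.deflection.max() < 0.5
        assert r.torso_sink_angle_deg() < mm_result.torso_sink_angle_deg()

    def test_deterministic(self, body, mm_surface, mm_result):
        again = solve_equilibrium(body, mm_surface)
        assert np.array_equal(again.y, mm_result.y)


class TestOutputs:
    def test_region_peaks_are_nodal_maxima(self, mm_result):
        pressures, peaks = contact_pressure_profile(mm_result)
        names = list(mm_result.body.names)
        heel = pressures[names.index("heel")]
        assert peaks["heel"] == pytest.approx(heel)
        assert peaks["buttock"] == pytest.approx(
            max(pressures[names.index(n)] for n in ("L4", "L5", "sacrum"))
        )

    def test_zero_gravity_zero_peaks_and_area(self, body, mm_surface):
        r = solve_equilibrium(body, mm_surface, g=0.0)
        _, peaks = contact_pressure_profile(r)
        assert all(v == 0.0 for v in peaks.values())
        assert contact_area(r)["total"] == 0.0

    def test_tiny_threshold_recovers_footprint(self, mm_result):
        a = contact_area(mm_result, threshold_kpa=1e-9)
        in_contact = mm_result.pressure > 1e-9
        footprint = mm_result.tributary_area[in_contact].sum() / 100.0
        assert a["total"] == pytest.approx(footprint)
        assert a["pillow"] + a["mattress"] == pytest.approx(a["total"])

    def test_negative_threshold_rejected(self, mm_result):
        with pytest.raises(ValueError):
            contact_area(mm_result, threshold_kpa=-1.0)

    def test_unconverged_result_rejected(self, mm_result):
        import dataclasses

        broken = dataclasses.replace(mm_result, converged=False)
        with pytest.raises(ConvergenceError):
            contact_pressure_profile(broken)

    def test_ivd_pure_axial_formula(self, body, mm_result):
        """With moments zeroed the proxy is exactly |F|/A."""
        import dataclasses

        r = dataclasses.replace(mm_result, node_moment=np.zeros(body.n))
        per_level, _ = ivd_peak_stress(r)
        j = body.disc_levels["C5-C6"]
        expected = abs(r.joint_force[j]) / body.disc_area["C5-C6"] * 1e3
        got = per_level.set_index("level").loc["C5-C6", "stress_kPa"]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_load_zero_stress(self, body, mm_surface):
        r = solve_equilibrium(body, mm_surface, g=0.0)
        per_level, peaks = ivd_peak_stress(r)
        assert np.allclose(per_level.stress_kPa, 0.0, atol=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in peaks.values())

    def test_stiffer_pillow_raises_cervical_proxy(self, body):
        mm = load_material("MM")
        peaks = []
        for scale in (0.5, 1.0, 2.0):
            surface = SupportSurface(
                FoundationLaw.single(mm, 200.0),
                FoundationLaw.single(load_material("pillow").scaled(scale), 90.0),
            )
            _, disc_peaks = ivd_peak_stress(solve_equilibrium(body, surface))
            peaks.append(disc_peaks["cervical"])
        assert peaks[0] < peaks[1] < peaks[2]


class TestMonotonicity:
    def test_softer_mattress_more_area_lower_buttock_peak(self, body):
        mm = load_material("MM")
        pillow = FoundationLaw.single(load_material("pillow"), 90.0)
        soft = solve_equilibrium(
            body, SupportSurface(FoundationLaw.single(mm.scaled(0.5), 200.0), pillow)
        )
        hard = solve_equilibrium(
            body, SupportSurface(FoundationLaw.single(mm.scaled(2.0), 200.0), pillow)
        )
        assert contact_area(soft)["total"] >= contact_area(hard)["total"]
        assert (
            contact_pressure_profile(soft)[1]["buttock"]
            <= contact_pressure_profile(hard)[1]["buttock"]
        )


class TestPercentChange:
    def test_cervical_peak_worked_example(self):
        rounded, raw = percent_change(316.0, 212.0)
        assert rounded == 49
        assert raw == pytest.approx((316 - 212) / 212 * 100)

    def test_lumbar_peak_worked_example(self):
        assert percent_change(119.0, 93.0)[0] == 28

    def test_no_change(self):
        assert percent_change(5.0, 5.0) == (0, 0.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    def test_pillow_footprint_area(self):
        assert pillow_footprint_area_cm2(550.0, 350.0) == pytest.approx(1925.0)
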