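"""Tape element model: classification, arc fitting, chaining, resampling, IO."""

import io
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinetape.exceptions import (
    ChainError,
    InvalidElementError,
    MustBeLineError,
    ResampleError,
    TapeParseError,
)
from spinetape.geometry import hausdorff_distance, point_line_distance, rotate
from spinetape.tape import (
    ArcElement,
    SpinalCurve,
    chain_elements,
    classify_element,
    element_arclength,
    fit_arc,
    read_tape_csv,
    read_tape_json,
    resample_curve,
    sample_element,
    write_tape_csv,
    write_tape_json,
)


class TestClassify:
    @pytest.mark.parametrize(
        "mid, expected",
        [
            ((1.0, 0.0), "line"),        # exactly collinear
            ((1.0, 1.0), "arc"),         # 1 mm off the chord
            ((1.0, 0.01), "line"),       # 0.01 mm off, below the 0.05 tolerance
        ],
    )
    def test_three_point_classification(self, mid, expected):
        e = ArcElement((0.0, 0.0), mid, (2.0, 0.0))
        # independent check of the off-chord distance driving the decision
        assert point_line_distance(mid, (0, 0), (2, 0)) == pytest.approx(abs(mid[1]))
        assert classify_element(e, tol_line=0.05) == expected

    def test_degenerate_element_rejected(self):
        with pytest.raises(InvalidElementError):
            ArcElement((0.0, 0.0), (1.0, 1.0), (0.0, 0.0))


class TestFitArc:
    @pytest.mark.parametrize("my, below", [(1.0, False), (-1.0, True)])
    def test_symmetric_half_circle(self, my, below):
        e = ArcElement((0.0, 0.0), (1.0, my), (2.0, 0.0))
        center, radius, a0, a1 = fit_arc(e)
        assert np.allclose(center, (1.0, 0.0), atol=1e-12)
        assert radius == pytest.approx(1.0)
        # the sweep traverses the midpoint: its angle lies inside [a0, a1]
        mid_angle = np.arctan2(my - center[1], 1.0 - center[0])
        lo, hi = sorted([a0, a1])
        assert lo <= mid_angle <= hi or lo <= mid_angle + 2 * np.pi * np.sign(a1 - a0) <= hi
        pts = sample_element(e, 5)
        assert (pts[2][1] < 0) == below

    def test_matches_perpendicular_bisector_oracle(self, rng):
        for _ in range(50):
            pts = rng.uniform(-50, 50, (3, 2))
            e = ArcElement(pts[0], pts[1], pts[2])
            if classify_element(e) == "line":
                continue
            center, radius, *_ = fit_arc(e)
            # oracle: intersect the two perpendicular bisectors directly
            m1, d1 = (pts[0] + pts[1]) / 2, pts[1] - pts[0]
            m2, d2 = (pts[1] + pts[2]) / 2, pts[2] - pts[1]
            A = np.array([d1, d2])
            b = np.array([d1 @ m1, d2 @ m2])
            oracle = np.linalg.solve(A, b)
            assert np.allclose(center, oracle, atol=1e-6)
            for p in pts:
                assert np.hypot(*(p - center)) == pytest.approx(radius, rel=1e-9)

    def test_collinear_input_rejected(self):
        e = ArcElement((0.0, 0.0), (1.0, 0.0), (2.0, 0.0))
        with pytest.raises(MustBeLineError):
            fit_arc(e)


class TestArclength:
    def test_straight_chord(self):
        e = ArcElement((0.0, 0.0), (1.0, 0.0), (2.0, 0.0))
        assert element_arclength(e) == pytest.approx(2.0)

    def test_half_unit_circle(self):
        e = ArcElement((0.0, 0.0), (1.0, 1.0), (2.0, 0.0))
        assert element_arclength(e) == pytest.approx(np.pi)

    def test_semicircle_against_dense_polyline_oracle(self):
        # semicircle of radius 100 given by its three defining points
        e = ArcElement((-100.0, 0.0), (0.0, 100.0), (100.0, 0.0))
        theta = np.linspace(0, np.pi, 20001)
        oracle = np.sum(
            np.hypot(*np.diff(100 * np.column_stack([np.cos(theta), np.sin(theta)]), axis=0).T)
        )
        assert element_arclength(e) == pytest.approx(100 * np.pi, rel=1e-9)
        assert element_arclength(e) == pytest.approx(oracle, rel=1e-6)


class TestChain:
    def test_native_straight_tape_length(self, straight_tape):
        curve = chain_elements(straight_tape)
        assert curve.length == pytest.approx(870.0, rel=1e-6)
        assert np.allclose(curve.points[:, 1], 0.0)

    def test_gap_repair_emits_warning(self):
        e0 = ArcElement((0.0, 0.0), (15.0, 0.0), (30.0, 0.0), 0)
        e1 = ArcElement((30.0, 0.8), (45.0, 0.8), (60.0, 0.8), 1)  # 0.8 mm gap
        with pytest.warns(UserWarning, match="repaired by translation"):
            curve = chain_elements([e0, e1], gap_tol=0.5)
        # continuity restored: no jump bigger than the sampling spacing
        assert np.max(np.hypot(*np.diff(curve.points, axis=0).T)) < 2.0

    def test_small_gap_closed_silently(self):
        e0 = ArcElement((0.0, 0.0), (15.0, 0.0), (30.0, 0.0), 0)
        e1 = ArcElement((30.3, 0.0), (45.0, 0.0), (60.0, 0.0), 1)  # 0.3 mm gap
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            curve = chain_elements([e0, e1], gap_tol=0.5)
        assert curve.length == pytest.approx(59.7, rel=1e-3)

    def test_chain_matches_analytic_curve(self, sine_curve):
        """Elements cut from an analytic curve chain back onto it."""
        from spinetape.synthetic import sample_tape

        elements = sample_tape(sine_curve, 29, noise_mm=0.0)
        rec = resample_curve(chain_elements(elements), 0.5)
        dense = resample_curve(sine_curve, 0.5)
        assert hausdorff_distance(rec.points, dense.points) < 0.1

    def test_length_conservation(self, rng):
        """Chained curve length equals the element arclength sum (0.1%)."""
        for _ in range(10):
            elements = []
            p = np.zeros(2)
            direction = 0.0
            for i in range(10):
                direction += rng.uniform(-0.3, 0.3)
                d = np.array([np.cos(direction), np.sin(direction)])
                end = p + 30.0 * d
                sag = rng.uniform(-2, 2)
                normal = np.array([-d[1], d[0]])
                mid = (p + end) / 2 + sag * normal
                elements.append(ArcElement(p, mid, end, i))
                p = end
            curve = chain_elements(elements)
            total = sum(element_arclength(e) for e in elements)
            assert curve.length == pytest.approx(total, rel=1e-3)

    @given(
        angle=st.floats(-0.6, 0.6),
        tx=st.floats(-500, 500),
        ty=st.floats(-500, 500),
    )
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_equivariance(self, angle, tx, ty):
        base = [
            ArcElement((30.0 * i, 0.0), (30.0 * i + 15.0, 3.0), (30.0 * (i + 1), 0.0), i)
            for i in range(5)
        ]
        moved = [
            ArcElement(
                rotate(e.p_start, angle) + (tx, ty),
                rotate(e.p_mid, angle) + (tx, ty),
                rotate(e.p_end, angle) + (tx, ty),
                e.index,
            )
            for e in base
        ]
        ref = rotate(chain_elements(base).points, angle) + (tx, ty)
        assert np.allclose(chain_elements(moved).points, ref, atol=1e-9)

    def test_empty_and_misordered_rejected(self, straight_tape):
        with pytest.raises(ChainError):
            chain_elements([])
        with pytest.raises(ChainError):
            chain_elements(straight_tape[::-1])


class TestResample:
    def test_straight_line_spacing(self):
        curve = SpinalCurve.from_points(
            np.column_stack([np.linspace(0, 870, 30), np.zeros(30)])
        )
        res = resample_curve(curve, 10.0)
        assert len(res.points) == 88
        assert np.allclose(np.diff(res.points[:, 0]), 10.0, atol=1e-9)

    def test_arc_length_preserved(self, circle_curve):
        res = resample_curve(circle_curve, 1.0)
        assert res.length == pytest.approx(circle_curve.length, rel=1e-3)
        assert np.allclose(res.points[0], circle_curve.points[0])
        assert np.allclose(res.points[-1], circle_curve.points[-1])

    def test_idempotent(self, sine_curve):
        once = resample_curve(sine_curve, 5.0)
        twice = resample_curve(once, 5.0)
        assert np.allclose(once.points, twice.points, atol=1e-6)

    def test_bad_spacing_rejected(self, sine_curve):
        with pytest.raises(ResampleError):
            resample_curve(sine_curve, 1e6)
        with pytest.raises(ResampleError):
            resample_curve(sine_curve, 0.0)


class TestSerialization:
    def test_csv_round_trip(self, straight_tape, tmp_path):
        path = tmp_path / "tape.csv"
        write_tape_csv(straight_tape, path)
        back = read_tape_csv(path)
        assert len(back) == 29
        for a, b in zip(straight_tape, back):
            assert a.index == b.index
            assert np.allclose(a.p_start, b.p_start)
            assert np.allclose(a.p_mid, b.p_mid)
            assert np.allclose(a.p_end, b.p_end)

    def test_json_round_trip(self, straight_tape, tmp_path):
        path = tmp_path / "tape.json"
        write_tape_json(straight_tape, path)
        back = read_tape_json(path)
        assert len(back) == 29
        assert np.allclose(back[7].p_mid, straight_tape[7].p_mid)

    def test_unexpected_count_warns(self, straight_tape, tmp_path):
        path = tmp_path / "tape.csv"
        write_tape_csv(straight_tape[:28], path)
        with pytest.warns(UserWarning, match="expected 29"):
            back = read_tape_csv(path)
        assert len(back) == 28

    def test_parse_errors_name_the_row(self, straight_tape, tmp_path):
        path = tmp_path / "tape.csv"
        write_tape_csv(straight_tape[:3], path)
        text = path.read_text().splitlines()
        text[2] = text[2].replace("45.0", "")   # empty y-ish cell in row 1
        path.write_text("\n".join(text))
        with pytest.raises(TapeParseError, match="row 1"):
            read_tape_csv(path, expected_count=3)

    def test_duplicate_index_rejected(self, straight_tape, tmp_path):
        path = tmp_path / "tape.csv"
        dup = straight_tape[:2] + [
            ArcElement((60.0, 0), (75.0, 0), (90.0, 0), index=1)
        ]
        write_tape_csv(dup, path)
        with pytest.raises(TapeParseError, match="duplicate"):
            read_tape_csv(path, expected_count=3)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "tape.csv"
        path.write_text("element_id,x_start,y_start\n0,0,0\n")
        with pytest.raises(TapeParseError, match="missing column"):
            read_tape_csv(path)
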