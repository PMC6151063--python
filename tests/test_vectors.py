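"""Unit and property tests for the Alpins vector mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astigvec.vectors import (
    CylinderReading,
    EyeRecord,
    PolarVector,
    RectVector,
    analyze_eye,
    classify_orientation,
    compute_ci,
    compute_dv,
    compute_sia,
    compute_tia,
    mirror_os_axis,
    polar_to_rect,
    rect_to_polar,
    summarize_ci,
    summarize_vectors,
    to_positive_cylinder,
    wrap_axis,
)

polar_vectors = st.builds(
    PolarVector,
    magnitude=st.floats(0.01, 10.0),
    axis=st.floats(0.001, 180.0),
)


class TestNotationConversion:
    @pytest.mark.parametrize(
        "reading, expected",
        [
            ((-2.00, 90), (2.00, 180)),   # printed worked example
            ((-1.00, 180), (1.00, 90)),   # printed worked example
            ((0.75, 88), (0.75, 88)),     # already positive: identity
            ((2.00, 0), (2.00, 180)),     # 0 deg meridian reported as 180
            ((0.0, 0), (0.0, 180)),
        ],
    )
    def test_positive_cylinder_conversion(self, reading, expected):
        v = to_positive_cylinder(CylinderReading(*reading))
        assert v.magnitude == pytest.approx(expected[0], abs=1e-12)
        assert v.axis == pytest.approx(expected[1], abs=1e-12)

    @given(mag=st.floats(0.0, 10.0), axis=st.floats(0.0, 180.0))
    @settings(max_examples=200)
    def test_idempotent_on_positive_input(self, mag, axis):
        once = to_positive_cylinder(CylinderReading(mag, axis))
        twice = to_positive_cylinder(CylinderReading(once.magnitude, once.axis))
        assert twice == once

    @given(mag=st.floats(-10.0, 10.0), axis=st.floats(0.0, 180.0))
    @settings(max_examples=200)
    def test_mirror_commutes_with_conversion(self, mag, axis):
        """Mirror-then-convert equals convert-then-mirror (axis maps mod 180)."""
        conv = to_positive_cylinder(CylinderReading(mag, axis))
        a = mirror_os_axis(conv.axis, "OS")
        # compare as meridians (mod 180) to avoid the 0/180 seam
        b = to_positive_cylinder(
            CylinderReading(mag, wrap_axis(180.0 - axis))
        ).axis
        assert math.isclose(a % 180.0, b % 180.0, abs_tol=1e-9) or \
            math.isclose(abs(a % 180.0 - b % 180.0), 180.0, abs_tol=1e-9)


class TestMirror:
    @pytest.mark.parametrize(
        "axis, eye, expected",
        [(88, "OS", 92), (90, "OS", 90), (45, "OD", 45), (180, "OS", 180)],
    )
    def test_examples(self, axis, eye, expected):
        assert mirror_os_axis(axis, eye) == pytest.approx(expected)

    @given(axis=st.floats(0.001, 180.0))
    @settings(max_examples=200)
    def test_involution(self, axis):
        assert mirror_os_axis(mirror_os_axis(axis, "OS"), "OS") == pytest.approx(
            axis, abs=1e-9
        )


class TestDoubleAngleRoundTrip:
    @pytest.mark.parametrize(
        "polar, rect",
        [
            ((1.00, 90), (-1.00, 0.00)),
            ((1.00, 45), (0.00, 1.00)),
            ((2.00, 180), (2.00, 0.00)),
        ],
    )
    def test_known_decompositions(self, polar, rect):
        r = polar_to_rect(PolarVector(*polar))
        assert r.x == pytest.approx(rect[0], abs=1e-12)
        assert r.y == pytest.approx(rect[1], abs=1e-12)
        back = rect_to_polar(r)
        assert back.magnitude == pytest.approx(polar[0], abs=1e-12)
        assert back.axis == pytest.approx(polar[1], abs=1e-12)

    def test_zero_vector_convention(self):
        assert rect_to_polar(RectVector(0.0, 0.0)) == PolarVector(0.0, 180.0)

    def test_round_trip_bulk(self):
        """10^4 random vectors survive polar->rect->polar to 1e-9."""
        rng = np.random.default_rng(7)
        mags = rng.uniform(0.001, 12.0, 10_000)
        axes = rng.uniform(1e-6, 180.0, 10_000)
        for m, a in zip(mags, axes):
            back = rect_to_polar(polar_to_rect(PolarVector(m, a)))
            assert math.isclose(back.magnitude, m, abs_tol=1e-9)
            assert math.isclose(back.axis, a, abs_tol=1e-7)


class TestSurgicalVectors:
    def test_tia_is_preop_under_emmetropia(self):
        for v in (PolarVector(2.0, 90.0), PolarVector(0.0, 180.0)):
            assert compute_tia(v) is v

    def test_full_correction_gives_sia_equal_preop(self):
        sia = compute_sia(PolarVector(2.0, 90.0), PolarVector(0.0, 180.0))
        assert sia.magnitude == pytest.approx(2.0, abs=1e-12)
        assert sia.axis == pytest.approx(90.0, abs=1e-9)

    def test_no_change_gives_zero_sia(self):
        v = PolarVector(1.25, 37.0)
        assert compute_sia(v, v).magnitude == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_axes_combine(self):
        # law of cosines oracle: M1=M2=1, delta-theta=90 deg -> magnitude 2
        sia = compute_sia(PolarVector(1.0, 90.0), PolarVector(1.0, 180.0))
        assert sia.magnitude == pytest.approx(2.0, abs=1e-12)
        assert sia.axis == pytest.approx(90.0, abs=1e-9)

    def test_sia_magnitude_matches_law_of_cosines(self):
        """10^4 random eye pairs against the closed-form magnitude."""
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            m1, m2 = rng.uniform(0.0, 8.0, 2)
            a1, a2 = rng.uniform(1e-6, 180.0, 2)
            sia = compute_sia(PolarVector(m1, a1), PolarVector(m2, a2))
            expected = math.sqrt(
                max(0.0, m1 * m1 + m2 * m2
                    - 2.0 * m1 * m2 * math.cos(math.radians(2.0 * (a1 - a2))))
            )
            assert math.isclose(sia.magnitude, expected, abs_tol=1e-9)

    def test_dv_by_hand_rectangular_subtraction(self):
        dv = compute_dv(PolarVector(1.0, 90.0), PolarVector(1.0, 180.0))
        assert dv.magnitude == pytest.approx(2.0, abs=1e-12)
        assert dv.axis == pytest.approx(90.0, abs=1e-9)

    def test_dv_null_for_perfect_outcome(self):
        v = PolarVector(1.5, 105.0)
        assert compute_dv(v, v).magnitude == pytest.approx(0.0, abs=1e-12)

    @given(preop=polar_vectors, postop=polar_vectors)
    @settings(max_examples=300)
    def test_dv_equals_postop_under_emmetropia(self, preop, postop):
        """TIA - (preop - postop) = postop, an exact algebraic identity."""
        tia = compute_tia(preop)
        dv = compute_dv(tia, compute_sia(preop, postop))
        assert math.isclose(dv.magnitude, postop.magnitude, abs_tol=1e-9)
        if postop.magnitude > 1e-6:
            d = abs(dv.axis - postop.axis) % 180.0
            assert min(d, 180.0 - d) * postop.magnitude < 1e-6


class TestCorrectionIndex:
    def test_optimal_outcome_is_one(self):
        assert compute_ci(PolarVector(2.0, 90.0), PolarVector(2.0, 90.0)) == 1.0

    def test_undercorrection_ratio(self):
        assert compute_ci(PolarVector(1.0, 90.0), PolarVector(2.0, 90.0)) == 0.5

    def test_zero_tia_is_undefined(self):
        assert compute_ci(PolarVector(1.0, 90.0), PolarVector(0.0, 180.0)) is None


class TestSummaries:
    def test_single_vector_is_its_own_mean(self):
        v = PolarVector(1.75, 63.0)
        s = summarize_vectors([v])
        assert s.n == 1 and s.sd_x == 0.0 and s.sd_y == 0.0
        assert s.vector_mean.magnitude == pytest.approx(v.magnitude, abs=1e-12)
        assert s.vector_mean.axis == pytest.approx(v.axis, abs=1e-9)

    def test_antipodal_pair_cancels(self):
        s = summarize_vectors([PolarVector(1.0, 45.0), PolarVector(1.0, 135.0)])
        assert s.vector_mean.magnitude == pytest.approx(0.0, abs=1e-12)
        assert s.arith_mean_magnitude == pytest.approx(1.0)

    def test_matches_componentwise_oracle(self):
        """1000 random vectors vs independent numpy accumulation."""
        rng = np.random.default_rng(5)
        mags = rng.uniform(0.0, 6.0, 1000)
        axes = rng.uniform(1e-6, 180.0, 1000)
        xs = mags * np.cos(np.radians(2 * axes))
        ys = mags * np.sin(np.radians(2 * axes))
        s = summarize_vectors([PolarVector(m, a) for m, a in zip(mags, axes)])
        assert s.mean_x == pytest.approx(xs.mean(), abs=1e-9)
        assert s.mean_y == pytest.approx(ys.mean(), abs=1e-9)
        assert s.sd_x == pytest.approx(xs.std(ddof=1), abs=1e-9)
        assert s.sd_y == pytest.approx(ys.std(ddof=1), abs=1e-9)
        assert s.vector_mean.magnitude == pytest.approx(
            math.hypot(xs.mean(), ys.mean()), abs=1e-9
        )

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            summarize_vectors([])

    @pytest.mark.parametrize(
        "cis, expected",
        [([1.0, 1.0, 1.0], 1.0), ([0.5, 2.0], 1.0), ([0.9] * 7, 0.9)],
    )
    def test_ci_geometric_mean(self, cis, expected):
        s = summarize_ci(cis)
        assert s.geometric_mean == pytest.approx(expected, abs=1e-12)
        assert s.n_defined == len(cis) and s.n_excluded == 0

    def test_ci_exclusions_counted(self):
        s = summarize_ci([1.0, None, 0.0, 0.8])
        assert s.n_defined == 2 and s.n_excluded == 2

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError, match="excluded"):
            summarize_ci([None, 0.0])


class TestOrientationClassifier:
    @pytest.mark.parametrize(
        "axis, label",
        [(90, "WTR"), (10, "ATR"), (170, "ATR"), (180, "ATR"),
         (45, "oblique"), (135, "oblique"),
         (30, "oblique"), (60, "oblique"), (120, "oblique"), (150, "oblique")],
    )
    def test_sector_labels(self, axis, label):
        assert classify_orientation(axis) == label

    def test_shaded_boundary_policy(self):
        assert classify_orientation(30, boundary="shaded") == "ATR"
        assert classify_orientation(60, boundary="shaded") == "WTR"

    def test_partition_is_total_and_exclusive(self):
        """Every meridian gets exactly one label; counts sum to the grid size."""
        grid = np.linspace(0.05, 180.0, 3600)
        labels = [classify_orientation(a) for a in grid]
        counts = {lab: labels.count(lab) for lab in ("ATR", "WTR", "oblique")}
        assert sum(counts.values()) == len(grid)
        assert all(counts[lab] > 0 for lab in counts)

    def test_integer_grid_totality(self):
        labels = [classify_orientation(a) for a in range(1, 181)]
        assert len(labels) == 180


class TestPerEyePipeline:
    def test_perfect_full_correction(self):
        r = analyze_eye(EyeRecord("OD", CylinderReading(2.0, 90), CylinderReading(0.0, 0)))
        assert r.tia == PolarVector(2.0, 90.0)
        assert r.sia.magnitude == pytest.approx(2.0, abs=1e-12)
        assert r.dv.magnitude == pytest.approx(0.0, abs=1e-12)
        assert r.ci == pytest.approx(1.0, abs=1e-12)

    def test_os_negative_cylinder_trace(self):
        # -2.00 x 90 converts to +2.00 x 180; the OS mirror fixes 180.
        r = analyze_eye(EyeRecord("OS", CylinderReading(-2.0, 90), CylinderReading(0.0, 0)))
        assert r.tia.magnitude == pytest.approx(2.0, abs=1e-12)
        assert r.tia.axis == pytest.approx(180.0, abs=1e-9)
        assert r.ci == pytest.approx(1.0, abs=1e-12)

    def test_collinear_undercorrection(self):
        r = analyze_eye(EyeRecord("OD", CylinderReading(2.0, 90), CylinderReading(1.0, 90)))
        assert r.ci == pytest.approx(0.5, abs=1e-12)

    @given(
        mag1=st.floats(0.25, 6.0), ax1=st.floats(0.5, 179.5),
        mag2=st.floats(0.0, 6.0), ax2=st.floats(0.5, 179.5),
    )
    @settings(max_examples=300)
    def test_swapping_eye_labels_preserves_magnitudes(self, mag1, ax1, mag2, ax2):
        """Relabeling OD<->OS with mirrored axes changes no magnitude or CI."""
        od = analyze_eye(EyeRecord("OD", CylinderReading(mag1, ax1), CylinderReading(mag2, ax2)))
        os_ = analyze_eye(EyeRecord(
            "OS", CylinderReading(mag1, 180.0 - ax1), CylinderReading(mag2, 180.0 - ax2)
        ))
        assert math.isclose(od.tia.magnitude, os_.tia.magnitude, abs_tol=1e-9)
        assert math.isclose(od.sia.magnitude, os_.sia.magnitude, abs_tol=1e-9)
        assert math.isclose(od.dv.magnitude, os_.dv.magnitude, abs_tol=1e-9)
        if od.ci is None:
            assert os_.ci is None
        else:
            assert math.isclose(od.ci, os_.ci, abs_tol=1e-9)


class TestValidation:
    def test_out_of_range_magnitude_rejected(self):
        with pytest.raises(ValueError):
            CylinderReading(35.0, 90)

    def test_out_of_range_axis_rejected(self):
        with pytest.raises(ValueError):
            CylinderReading(1.0, 200)

    def test_bad_eye_label_rejected(self):
        with pytest.raises(ValueError):
            EyeRecord("LEFT", CylinderReading(1.0, 90), CylinderReading(0.0, 0))
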