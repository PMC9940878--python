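import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignoquant.io_core import Outline, ValidationError
from lignoquant.morphology import (
    LineProfile,
    convexity,
    extract_profile,
    normalize_to_cml,
    smooth_outline,
    swelling_table,
)
from lignoquant.synthetic import dense_convexity, gen_line_profile, gen_vessel_outline

from oracles import convexity_dense, random_star_polygon


class TestSmoothOutline:
    def test_zero_bandwidth_identity(self, unit_square_outline):
        out = smooth_outline(unit_square_outline, 0.0)
        np.testing.assert_allclose(out.vertices, unit_square_outline.vertices)

    def test_regular_polygon_near_fixed_point(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        o = Outline("circle", np.column_stack([np.cos(theta), np.sin(theta)]))
        sm = smooth_outline(o, 0.02)
        assert np.abs(np.hypot(*sm.vertices.T) - np.hypot(*o.vertices.T)).max() < 1e-2
        assert len(sm.vertices) == len(o.vertices)

    def test_staircase_noise_removed(self):
        """A square with one-pixel staircase edges smooths back to the clean
        square's area within 2%."""
        side = 20.0
        edges = []
        for k in range(4):
            t = np.arange(0, side, 1.0)
            stair = np.where(t.astype(int) % 2 == 0, -0.25, 0.25)  # zero-mean pixelation
            if k == 0:
                pts = np.column_stack([t, stair])
            elif k == 1:
                pts = np.column_stack([side - stair, t])
            elif k == 2:
                pts = np.column_stack([side - t, side - stair])
            else:
                pts = np.column_stack([stair, side - t])
            edges.append(pts)
        o = Outline("stairs", np.vstack(edges))
        sm = smooth_outline(o, 0.02)
        from oracles import shoelace_area

        assert abs(shoelace_area(sm.vertices) - side**2) / side**2 < 0.02


class TestConvexity:
    def test_unit_square(self, unit_square_outline):
        m = convexity(unit_square_outline, smooth=False)
        assert m.convexity == pytest.approx(1.0, abs=1e-9)

    def test_l_shape_hand_values(self, l_shape_outline):
        m = convexity(l_shape_outline, smooth=False)
        assert m.area == pytest.approx(3.0, abs=1e-12)
        assert m.hull_area == pytest.approx(3.5, abs=1e-12)
        assert m.convexity == pytest.approx(6.0 / 7.0, abs=1e-12)

    def test_collapsed_vessel_matches_dense_oracle(self):
        for a in (0.0, 0.3, 0.5, 0.7):
            o, truth = gen_vessel_outline(1, collapse=a)
            m = convexity(o, smooth=False)
            assert abs(m.convexity - truth) / truth < 0.01

    def test_oracle_equivalence_random_polygons(self, rng):
        """Seeded random simple polygons agree with the independent
        shoelace/monotone-chain implementation to 1e-9."""
        for _ in range(200):
            n = int(rng.integers(8, 65))
            v = random_star_polygon(rng, n)
            m = convexity(Outline("p", v), smooth=False)
            assert abs(m.convexity - convexity_dense(v)) < 1e-9

    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 50),
        tx=st.floats(-100, 100),
        reverse=st.booleans(),
    )
    @settings(max_examples=25, deadline=None)
    def test_similarity_invariance(self, angle, scale, tx, reverse):
        o, _ = gen_vessel_outline(3, collapse=0.4)
        base = convexity(o, smooth=False).convexity
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        v = (o.vertices @ R.T) * scale + np.array([tx, 1.5])
        if reverse:
            v = v[::-1]
        assert convexity(Outline("t", v), smooth=False).convexity == pytest.approx(base, abs=1e-9)

    def test_convexity_in_unit_interval(self, rng):
        for _ in range(50):
            v = random_star_polygon(rng, int(rng.integers(8, 32)))
            c = convexity(Outline("p", v), smooth=False).convexity
            assert 0.0 < c <= 1.0 + 1e-12

    def test_raw_metric_co_reported(self):
        o, _ = gen_vessel_outline(2, collapse=0.5)
        m = convexity(o, smooth=True)
        assert m.smoothed and 0 < m.raw_convexity <= 1.0


class TestExtractProfile:
    def test_constant_field(self):
        img = np.full((10, 10), 7.0)
        p = extract_profile(img, (1.0, 1.0), (8.0, 1.0), step=0.5)
        np.testing.assert_allclose(p.intensities, 7.0)

    def test_linear_ramp(self):
        img = np.tile(np.arange(20.0), (5, 1))
        p = extract_profile(img, (2.0, 2.0), (17.0, 2.0), step=1.0)
        np.testing.assert_allclose(p.intensities, 2.0 + p.positions, atol=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            extract_profile(np.zeros((5, 5)), (1, 1), (1, 1), 0.5)

    def test_blurred_step_plateaus(self):
        """A blurred two-level step sampled across the edge keeps its plateau
        means within 3% of the injected levels."""
        from scipy.ndimage import gaussian_filter

        img = np.zeros((20, 40))
        img[:, :20] = 100.0
        img[:, 20:] = 60.0
        img = gaussian_filter(img, 2.0)
        p = extract_profile(img, (2.0, 10.0), (37.0, 10.0), step=0.25)
        left = p.intensities[p.positions < 10]
        right = p.intensities[p.positions > 25]
        assert abs(left.mean() - 100.0) / 100.0 < 0.03
        assert abs(right.mean() - 60.0) / 60.0 < 0.03


class TestNormalizeToCml:
    def test_arithmetic(self):
        p = LineProfile([0.0, 1.0, 2.0], [100.0, 200.0, 300.0], ["CML", "CML", "CC"])
        n = normalize_to_cml(p, min_cml=2)
        np.testing.assert_allclose(n.intensities, [2 / 3, 4 / 3, 2.0])

    def test_idempotent_and_scale_invariant(self):
        prof, _ = gen_line_profile(4)
        n1 = normalize_to_cml(prof)
        n2 = normalize_to_cml(n1)
        np.testing.assert_allclose(n1.intensities, n2.intensities, rtol=1e-12)
        scaled = LineProfile(prof.positions, prof.intensities * 13.7, prof.layer_labels)
        np.testing.assert_allclose(
            normalize_to_cml(scaled).intensities, n1.intensities, rtol=1e-12
        )

    def test_cml_mean_exactly_one(self):
        prof, _ = gen_line_profile(8, noise_sd=3.0)
        n = normalize_to_cml(prof)
        assert n.intensities[n.layer_labels == "CML"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_cc_cml_ratio_recovered_under_blur_and_noise(self):
        prof, truth = gen_line_profile(9, noise_sd=2.0)
        n = normalize_to_cml(prof)
        cc = n.intensities[n.layer_labels == "CC"].mean()
        assert abs(cc - truth.true_cc_over_cml.iloc[0]) / truth.true_cc_over_cml.iloc[0] < 0.03

    def test_requires_cml(self):
        p = LineProfile([0.0, 1.0], [1.0, 2.0], ["CC", "CC"])
        with pytest.raises(ValidationError):
            normalize_to_cml(p)


class TestSwelling:
    def test_ratios(self):
        df = pd.DataFrame(
            {
                "wall_id": ["w1"] * 3,
                "state": ["fresh", "dried", "rehydrated"],
                "thickness_um": [6.0, 2.0, 5.5],
            }
        )
        out = swelling_table(df)
        assert out.swelling_fresh_over_dried[0] == pytest.approx(3.0)
        assert out.swelling_rehydrated_over_dried[0] == pytest.approx(2.75)

    def test_equal_states_ratio_one(self):
        df = pd.DataFrame(
            {"wall_id": ["w"] * 3, "state": ["fresh", "dried", "rehydrated"], "thickness_um": [4.0] * 3}
        )
        out = swelling_table(df)
        assert out.swelling_fresh_over_dried[0] == 1.0

    def test_endpoint_distance(self):
        df = pd.DataFrame(
            {
                "wall_id": ["w", "w"],
                "state": ["fresh", "dried"],
                "x1_um": [0.0, 0.0],
                "y1_um": [0.0, 0.0],
                "x2_um": [3.0, 1.0],
                "y2_um": [4.0, 0.0],
            }
        )
        out = swelling_table(df)
        assert out.fresh[0] == pytest.approx(5.0)

    def test_missing_state_left_empty(self):
        df = pd.DataFrame({"wall_id": ["w"], "state": ["fresh"], "thickness_um": [4.0]})
        out = swelling_table(df)
        assert np.isnan(out.dried[0]) and np.isnan(out.swelling_fresh_over_dried[0])

    def test_duplicate_rejected(self):
        df = pd.DataFrame(
            {"wall_id": ["w", "w"], "state": ["fresh", "fresh"], "thickness_um": [4.0, 5.0]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            swelling_table(df)


def test_dense_convexity_oracle_consistency():
    """The generator's dense truth agrees with the independent oracle."""
    o, truth = gen_vessel_outline(5, collapse=0.4, n_vertices=2000)
    assert abs(convexity_dense(o.vertices) - truth) < 5e-3
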