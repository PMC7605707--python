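import numpy as np
import pytest

import spinemetrics as sm
from spinemetrics.errors import (
    CanalNotFoundError,
    EmptyBoundaryError,
    ForamenNotFoundError,
    RegionAbsentError,
)
from spinemetrics.landmarks import (
    LandmarkSet,
    Measurements,
    _m_ivd,
    centroid_IVD,
    classify_herniation,
    derive_p_qprime,
    extract_important_boundaries,
    locate_BM,
    locate_foraminal_points,
    locate_q,
    measure,
    ts_column_extent,
)


class TestClassifyHerniation:
    @pytest.mark.parametrize("r,expected", [
        (1.15, "normal"),
        (1.1, "normal"),       # boundary inclusive for normal
        (0.95, "minor"),
        (1.0999, "minor"),
        (0.8001, "minor"),
        (0.8, "severe"),       # boundary inclusive for severe
        (0.5, "severe"),
        (0.0, "severe"),
    ])
    def test_thresholds(self, r, expected):
        assert classify_herniation(r) == expected

    def test_partition_of_nonnegative_ratios(self):
        grid = np.linspace(0.0, 2.0, 4001)
        cats = [classify_herniation(float(r)) for r in grid]
        assert all(c in ("normal", "minor", "severe") for c in cats)
        # each grade occupies one contiguous run: severe, minor, normal
        changes = [i for i in range(1, len(cats)) if cats[i] != cats[i - 1]]
        assert len(changes) == 2

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_invalid_ratio(self, bad):
        with pytest.raises(ValueError):
            classify_herniation(bad)

    def test_custom_thresholds(self):
        assert classify_herniation(0.9, severe_threshold=0.95) == "severe"


class TestExtractBoundaries:
    def test_region_absent(self):
        lab = np.full((6, 6), 6, dtype=np.int16)
        with pytest.raises(RegionAbsentError):
            extract_important_boundaries({}, lab)

    def test_empty_important_boundary(self):
        # IVD block surrounded only by Other: A2 = E23 u E24 u E25 is empty
        lab = np.full((8, 8), 6, dtype=np.int16)
        lab[2:4, 2:4] = 2
        lab[6:8, 2:4] = 3
        pair_points = {(2, 6): np.array([[1.5, 2.0]]),
                       (3, 6): np.array([[5.5, 2.0]])}
        with pytest.raises(EmptyBoundaryError):
            extract_important_boundaries(pair_points, lab)

    def test_phantom_flank_membership(self, phantom_96):
        """Every A2 point comes from a pair {2, x} with x in {3,4,5}; A3
        from {3, x} with x in {2,4,5} (checked via pair provenance)."""
        from spinemetrics.evolve import boundary_points_by_pair
        from spinemetrics.grid import build_boundary_grid, build_sparse, compute_gradients

        rep = build_sparse(build_boundary_grid(
            phantom_96.label, compute_gradients(phantom_96.t1)))
        pts = boundary_points_by_pair(rep, sm.IMPORTANT_PAIRS, level=0)
        boundaries = extract_important_boundaries(pts, phantom_96.label)
        assert boundaries.A2.source_pairs <= {(2, 3), (2, 4), (2, 5)}
        assert boundaries.A3.source_pairs <= {(2, 3), (3, 4), (3, 5)}
        # A2 equals the brute-force union over adjacency tests
        expected = set()
        lab = phantom_96.label
        h, w = lab.shape
        for r in range(h):
            for c in range(w):
                if lab[r, c] != 2:
                    continue
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and lab[rr, cc] in (3, 4, 5):
                        expected.add((r + dr / 2.0, c + dc / 2.0))
        got = {tuple(p) for p in boundaries.A2.points}
        assert got == expected


class TestCentroid:
    def test_single_pixel(self):
        lab = np.full((30, 30), 6, dtype=np.int16)
        lab[10, 20] = 2
        np.testing.assert_array_equal(centroid_IVD(lab), [10.0, 20.0])

    def test_symmetric_block(self):
        lab = np.full((12, 12), 6, dtype=np.int16)
        lab[4:7, 4:7] = 2
        np.testing.assert_array_equal(centroid_IVD(lab), [5.0, 5.0])

    def test_largest_component_wins(self):
        lab = np.full((20, 20), 6, dtype=np.int16)
        lab[10:15, 5:15] = 2        # 50 pixels
        lab[1, 17:20] = 2           # 3 pixels
        np.testing.assert_array_equal(centroid_IVD(lab), [12.0, 9.5])

    def test_region_absent(self):
        with pytest.raises(RegionAbsentError):
            centroid_IVD(np.full((4, 4), 6, dtype=np.int16))


class TestForaminalPoints:
    def test_mirror_symmetric_truth(self, phantom_160):
        m = phantom_160.truth_measurements
        assert m.d_L == pytest.approx(m.d_R, abs=1e-9)

    def test_designed_gap_recovered(self):
        spec = sm.PhantomSpec.scaled(200, gap_left=6.0, gap_right=9.0)
        st = sm.generate_phantom(spec)
        res = sm.run_slice(st.composite, st.label,
                           sm.RunConfig(mm_per_pixel=spec.mm_per_pixel))
        d_l_px = res.measurements.d_L / spec.mm_per_pixel
        d_r_px = res.measurements.d_R / spec.mm_per_pixel
        assert 5.0 <= d_l_px <= 7.0
        assert 8.0 <= d_r_px <= 10.0

    def test_matches_brute_force_min_pair(self, rng):
        for _ in range(10):
            a2 = rng.random((40, 2)) * 20
            a3 = rng.random((40, 2)) * 20 + [25, 0]
            T, B = locate_foraminal_points(a2, a3, "left", None, midline_col=25.0)
            best = None
            for t in a2:
                if t[1] >= 25.0:
                    continue
                for b in a3:
                    if b[1] >= 25.0:
                        continue
                    d = np.hypot(*(t - b))
                    key = (d, abs(t[1] - b[1]), t[0])
                    if best is None or key < best[0]:
                        best = (key, t, b)
            np.testing.assert_allclose(T, best[1])
            np.testing.assert_allclose(B, best[2])

    def test_no_candidates(self):
        a2 = np.array([[0.0, 10.0]])
        a3 = np.array([[5.0, 10.0]])
        with pytest.raises(ForamenNotFoundError):
            locate_foraminal_points(a2, a3, "left", None, midline_col=5.0)


class TestLocateBM:
    def test_phantom_canal_apex(self, phantom_160):
        lm = phantom_160.truth_landmarks
        from spinemetrics.phantom import _Geometry

        geo = _Geometry(phantom_160.spec)
        apex_col = geo.c_mid
        apex_row = geo.t_pe(np.array([apex_col]))[0]
        assert abs(lm.B_M[0] - apex_row) <= 1.0
        assert abs(lm.B_M[1] - apex_col) <= 1.0

    def test_flat_boundary_tie_breaks_to_midpoint(self):
        a3 = np.column_stack([np.full(11, 7.0), np.arange(11, dtype=float)])
        bm = locate_BM(a3, np.array([7.0, 0.0]), np.array([7.0, 10.0]))
        np.testing.assert_allclose(bm, [7.0, 5.0])

    def test_matches_brute_force_scan(self, rng):
        a3 = np.column_stack([rng.random(50) * 30, rng.random(50) * 60])
        B_L, B_R = np.array([0.0, 10.0]), np.array([0.0, 50.0])
        bm = locate_BM(a3, B_L, B_R)
        inside = [p for p in a3 if 10.0 < p[1] < 50.0]
        best = max(inside, key=lambda p: (p[0], -abs(p[1] - 30.0)))
        np.testing.assert_allclose(bm, best)

    def test_no_point_in_interval(self):
        a3 = np.array([[3.0, 0.0], [3.0, 10.0]])
        with pytest.raises(CanalNotFoundError):
            locate_BM(a3, np.array([0.0, 4.0]), np.array([0.0, 6.0]))


class TestLocateQ:
    def test_matches_brute_force(self, rng):
        T_L, T_R = np.array([10.0, 0.0]), np.array([10.0, 40.0])
        B_M = np.array([25.0, 20.0])
        for _ in range(10):
            arc = rng.random((60, 2)) * [20, 40]
            q = locate_q(arc, T_L, T_R, B_M)
            chord = T_R - T_L
            normal = np.array([-chord[1], chord[0]]) / np.hypot(*chord)
            scores = [abs((z - T_L) @ normal) - np.hypot(*(z - B_M)) for z in arc]
            np.testing.assert_allclose(q, arc[int(np.argmax(scores))])

    def test_symmetric_semicircle_apex(self):
        theta = np.linspace(0, np.pi, 181)
        arc = np.column_stack([10 - 8 * np.sin(theta), 20 + 8 * np.cos(theta)])
        q = locate_q(arc, np.array([10.0, 12.0]), np.array([10.0, 28.0]),
                     B_M=np.array([30.0, 20.0]))
        np.testing.assert_allclose(q, [2.0, 20.0], atol=1e-9)

    def test_single_point(self):
        q = locate_q(np.array([[3.0, 4.0]]), np.array([0.0, 0.0]),
                     np.array([0.0, 8.0]), np.array([10.0, 4.0]))
        np.testing.assert_array_equal(q, [3.0, 4.0])

    def test_degenerate_chord(self):
        with pytest.raises(ValueError):
            locate_q(np.array([[1.0, 1.0]]), np.array([0.0, 0.0]),
                     np.array([0.0, 0.0]), np.array([5.0, 5.0]))


class TestDeriveP:
    def test_perpendicular_axes(self):
        p, q_prime, _ = derive_p_qprime(
            q=np.array([2.0, 1.0]),
            T_L=np.array([0.0, -5.0]), T_R=np.array([0.0, 5.0]),
            B_M=np.array([10.0, 0.0]), D_C=np.array([-10.0, 0.0]),
        )
        np.testing.assert_allclose(p, [0.0, 0.0], atol=1e-12)

    def test_projection_identity_on_line(self):
        B_M, D_C = np.array([10.0, 0.0]), np.array([0.0, 5.0])
        q = B_M + 0.3 * (D_C - B_M)
        _, q_prime, _ = derive_p_qprime(q, np.array([0.0, -5.0]),
                                        np.array([2.0, 5.0]), B_M, D_C)
        np.testing.assert_allclose(q_prime, q, atol=1e-12)

    def test_matches_vector_algebra(self, rng):
        for _ in range(20):
            T_L, T_R, B_M, D_C, q = rng.random((5, 2)) * 20
            u, v = T_R - T_L, D_C - B_M
            if abs(u[0] * v[1] - u[1] * v[0]) < 1e-6 or np.hypot(*v) < 1e-6:
                continue
            p, q_prime, _ = derive_p_qprime(q, T_L, T_R, B_M, D_C)
            # independent solve: T_L + t u = B_M + s v
            ts = np.linalg.solve(np.column_stack([u, -v]), B_M - T_L)
            np.testing.assert_allclose(p, T_L + ts[0] * u, atol=1e-9)
            np.testing.assert_allclose(
                q_prime, B_M + ((q - B_M) @ v) / (v @ v) * v, atol=1e-9)

    def test_parallel_lines_rejected(self):
        with pytest.raises(ValueError):
            derive_p_qprime(np.zeros(2), np.array([0.0, 0.0]), np.array([0.0, 4.0]),
                            np.array([5.0, 0.0]), np.array([5.0, 4.0]))

    def test_warning_outside_segment(self):
        _, _, warnings = derive_p_qprime(
            q=np.array([0.0, 20.0]),
            T_L=np.array([0.0, 0.0]), T_R=np.array([0.0, 1.0]),
            B_M=np.array([10.0, 10.0]), D_C=np.array([5.0, 10.0]),
        )
        assert any("outside" in w for w in warnings)


def make_landmarks(**overrides):
    base = dict(
        T_L=[0.0, -5.0], T_R=[0.0, 5.0], B_L=[8.0, -6.0], B_R=[8.0, 6.0],
        B_M=[10.0, 0.0], D_C=[-10.0, 0.0], p=[0.0, 0.0], q=[-2.0, 0.0],
        q_prime=[-2.0, 0.0],
    )
    base.update(overrides)
    return LandmarkSet(**{k: np.asarray(v, float) for k, v in base.items()})


class TestMeasure:
    def test_spacing_scales_widths(self):
        lm = make_landmarks(T_L=[0.0, 0.0], B_L=[10.0, 0.0])
        m = measure(lm, sm.PixelSpacing(0.5))
        assert m.d_L == pytest.approx(5.0)

    def test_severe_example(self):
        lm = make_landmarks(B_M=[0.0, 0.0], q_prime=[0.0, 8.0], p=[0.0, 10.0],
                            D_C=[0.0, 20.0], T_L=[-5.0, 10.0], T_R=[5.0, 10.0],
                            q=[0.0, 8.0])
        m = measure(lm, sm.PixelSpacing(1.0))
        assert m.d_AP == pytest.approx(8.0)
        assert m.r == pytest.approx(0.8)
        assert m.category == "severe"

    def test_q_prime_at_p_is_minor(self):
        lm = make_landmarks(q_prime=[0.0, 0.0])  # q' == p
        m = measure(lm, sm.PixelSpacing(1.0))
        assert m.r == pytest.approx(1.0)
        assert m.category == "minor"

    def test_zero_dp_rejected(self):
        lm = make_landmarks(p=[10.0, 0.0])  # p == B_M
        with pytest.raises(ValueError):
            measure(lm, sm.PixelSpacing(1.0))

    def test_scale_equivariance(self, rng):
        lm = make_landmarks()
        m1 = measure(lm, sm.PixelSpacing(0.6))
        factor = 3.0
        scaled = LandmarkSet(**{
            name: getattr(lm, name) * factor
            for name in ("T_L", "T_R", "B_L", "B_R", "B_M", "D_C", "p", "q", "q_prime")
        })
        m2 = measure(scaled, sm.PixelSpacing(0.6 / factor))
        assert m1.d_L == pytest.approx(m2.d_L)
        assert m1.d_AP == pytest.approx(m2.d_AP)
        assert m1.r == pytest.approx(m2.r)


class TestLandmarkSet:
    def test_nine_points_round_trip(self):
        lm = make_landmarks()
        back = LandmarkSet.from_dict(lm.to_dict())
        for name in ("T_L", "T_R", "B_L", "B_R", "B_M", "D_C", "p", "q", "q_prime"):
            np.testing.assert_array_equal(getattr(lm, name), getattr(back, name))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            make_landmarks(B_M=[float("nan"), 0.0])


class TestMIvdArc:
    def test_picks_posterior_arc(self, phantom_160):
        res = sm.run_slice(phantom_160.composite, phantom_160.label,
                           sm.RunConfig(mm_per_pixel=phantom_160.spec.mm_per_pixel))
        arc = _m_ivd(res.boundaries.A2, res.landmarks.T_L, res.landmarks.T_R,
                     res.landmarks.B_M)
        # the measurement arc hugs the canal: closer to B_M than the full curve
        d_arc = np.sqrt(((arc - res.landmarks.B_M) ** 2).sum(axis=1)).mean()
        d_all = np.sqrt(
            ((res.boundaries.A2.points - res.landmarks.B_M) ** 2).sum(axis=1)).mean()
        assert d_arc < d_all


def test_ts_column_extent(phantom_96):
    extent = ts_column_extent(phantom_96.label, pad=1.0)
    cols = np.nonzero((phantom_96.label == 4).any(axis=0))[0]
    assert extent == (cols.min() - 1.0, cols.max() + 1.0)
    assert ts_column_extent(np.full((4, 4), 6, dtype=np.int16)) is None
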