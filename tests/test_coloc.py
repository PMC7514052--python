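import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fociq import (FieldGeometry, NNResult, compartment_counts,
                   nearest_neighbor_distances, pairing_summary,
                   poisson_nn_fraction_beyond, random_null, rotation_null,
                   segment_nuclei)
from fociq.coloc import NullSpec, field_fractions_beyond

GEOM = FieldGeometry()   # 694 x 520 um


class TestNearestNeighborDistances:
    def test_identical_sets_give_zero_distances(self):
        pts = [(10, 10), (50, 80), (200, 300)]
        res = nearest_neighbor_distances(pts, pts)
        np.testing.assert_array_equal(res.distances_um, 0.0)

    def test_three_four_five(self):
        res = nearest_neighbor_distances([(0.0, 0.0)], [(3.0, 4.0)])
        assert res.distances_um[0] == 5.0

    def test_one_distance_per_source(self):
        res = nearest_neighbor_distances([(0, 0), (1, 1)], [(5, 5)] * 7)
        assert len(res.distances_um) == 2

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            nearest_neighbor_distances([], [(1, 1)])
        with pytest.raises(ValueError):
            nearest_neighbor_distances([(1, 1)], [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(r1=st.floats(0, 50), r2=st.floats(0, 50))
    def test_fraction_within_is_a_cdf(self, r1, r2):
        rng = np.random.default_rng(3)
        res = NNResult("pooled", rng.uniform(0, 40, size=200))
        lo, hi = sorted((r1, r2))
        assert 0.0 <= res.fraction_within(lo) <= res.fraction_within(hi) <= 1.0
        assert res.fraction_within(1e9) == 1.0
        assert res.fraction_beyond(r1) == pytest.approx(
            1.0 - res.fraction_within(r1))


class TestRotationNull:
    def test_field_centre_is_fixed_point(self):
        centre = [(GEOM.width_um / 2, GEOM.height_um / 2)]
        out = rotation_null(centre, GEOM)
        np.testing.assert_allclose(out, centre)

    def test_four_rotations_are_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform((0, 0), (GEOM.width_um, GEOM.height_um), (50, 2))
        out = pts
        for _ in range(4):
            out = rotation_null(out, GEOM)
        np.testing.assert_allclose(out, pts, atol=1e-9)

    def test_count_preserved_and_in_field(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform((0, 0), (GEOM.width_um, GEOM.height_um), (200, 2))
        out = rotation_null(pts, GEOM)
        assert out.shape == pts.shape
        assert (out[:, 0] >= 0).all() and (out[:, 0] <= GEOM.width_um).all()
        assert (out[:, 1] >= 0).all() and (out[:, 1] <= GEOM.height_um).all()

    def test_normalized_distance_multiset_preserved(self):
        # in unit-square coordinates the rotation is rigid, so the
        # inter-point distance multiset is exactly preserved there
        rng = np.random.default_rng(2)
        pts = rng.uniform((0, 0), (GEOM.width_um, GEOM.height_um), (40, 2))
        out = rotation_null(pts, GEOM)

        def norm_dists(p):
            q = p / [GEOM.width_um, GEOM.height_um]
            d = np.hypot(q[:, None, 0] - q[None, :, 0],
                         q[:, None, 1] - q[None, :, 1])
            return np.sort(d[np.triu_indices(len(q), 1)])

        np.testing.assert_allclose(norm_dists(out), norm_dists(pts),
                                   atol=1e-12)

    def test_out_of_bounds_points_rejected(self):
        with pytest.raises(ValueError):
            rotation_null([(GEOM.width_um + 1, 0)], GEOM)


class TestRandomNull:
    def test_dense_target_pairs_every_source(self):
        # density limit: against a very dense target set, every source
        # focus finds a neighbour within 1 um
        rng = np.random.default_rng(0)
        src = rng.uniform((0, 0), (GEOM.width_um, GEOM.height_um), (50, 2))
        tgt = rng.uniform((0, 0), (GEOM.width_um, GEOM.height_um),
                          (300_000, 2))
        res = nearest_neighbor_distances(src, tgt)
        assert res.fraction_within(1.0) > 0.9

    def test_published_beyond_30um_fractions(self):
        # ~5% of pairings beyond 30 um at 400 points, ~25% at 200
        r400 = random_null(400, 400, GEOM, n_fields=300, seed=5)
        assert r400.fraction_beyond(30.0) == pytest.approx(0.05, abs=0.01)
        r200 = random_null(200, 200, GEOM, n_fields=300, seed=5)
        assert r200.fraction_beyond(30.0) == pytest.approx(0.25, abs=0.04)
        r800 = random_null(800, 800, GEOM, n_fields=300, seed=5)
        assert r800.fraction_beyond(30.0) < 0.01

    def test_toroidal_matches_poisson_closed_form(self):
        # P(D > r) = exp(-lambda pi r^2) without edges, within 3 MC sigma
        for n in (200, 400, 800):
            for r in (5.0, 10.0, 30.0):
                fracs = field_fractions_beyond(n, n, GEOM, r, n_fields=150,
                                               seed=n + int(r),
                                               boundary="toroidal")
                sigma = fracs.std(ddof=1) / np.sqrt(len(fracs))
                expected = poisson_nn_fraction_beyond(n, GEOM, r)
                assert abs(fracs.mean() - expected) <= max(3 * sigma, 5e-4)

    def test_bounded_field_lengthens_distances(self):
        for n in (200, 400):
            bounded = random_null(n, n, GEOM, n_fields=150, seed=9)
            toroidal = random_null(n, n, GEOM, n_fields=150, seed=9,
                                   boundary="toroidal")
            assert bounded.fraction_beyond(30.0) >= \
                toroidal.fraction_beyond(30.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            random_null(0, 10, GEOM)
        with pytest.raises(ValueError):
            random_null(10, 10, GEOM, boundary="mirror")
        with pytest.raises(ValueError):
            NullSpec(kind="shuffle")


class TestPairingSummary:
    def test_observed_equal_to_random_has_no_excess(self):
        obs = random_null(200, 200, GEOM, n_fields=20, seed=1)
        rand = random_null(200, 200, GEOM, n_fields=200, seed=2)
        table = pairing_summary(obs, {"random": rand})
        excess = table.loc[table.model == "observed",
                           "excess_within_vs_random"]
        assert np.abs(excess).max() < 0.03

    def test_wt_field_pairing_recovers_planted_fraction(self, wt_field,
                                                        wt_summary):
        # ~40% of sarcoplasmic foci planted as <=1 um pairs
        geom = wt_field.config.geometry
        src = [f.centroid_um for f in wt_summary.foci[("5p", "sarcoplasmic")]
               if f.size_class == "small"]
        tgt = [f.centroid_um for f in wt_summary.foci[("3p", "sarcoplasmic")]
               if f.size_class == "small"]
        obs = {
            "5p_to_3p": nearest_neighbor_distances(src, tgt, "5p_to_3p"),
            "3p_to_5p": nearest_neighbor_distances(tgt, src, "3p_to_5p"),
        }
        rot = nearest_neighbor_distances(src, rotation_null(tgt, geom))
        rand = random_null(len(src), len(tgt), geom, n_fields=100, seed=3)
        table = pairing_summary(obs, {"rotation": rot, "random": rand})
        get = lambda m, r: float(
            table.loc[(table.model == m) & (table.threshold_um == r),
                      "fraction_within"].iloc[0])
        assert get("observed", 1.0) == pytest.approx(0.40, abs=0.08)
        # nulls are consistent with chance pairing, far below observed
        assert get("rotation", 1.0) < 0.1
        assert get("random", 1.0) < 0.1
        # all pairings below 4 um are over-represented vs random
        assert get("observed", 4.0) > get("random", 4.0)

    def test_mdx_field_far_pairings_match_random(self, mdx_field,
                                                 mdx_summary):
        geom = mdx_field.config.geometry
        src = [f.centroid_um for f in mdx_summary.foci[("5p", "sarcoplasmic")]
               if f.size_class == "small"]
        tgt = [f.centroid_um for f in mdx_summary.foci[("3p", "sarcoplasmic")]
               if f.size_class == "small"]
        obs = nearest_neighbor_distances(src, tgt)
        rand = random_null(len(src), len(tgt), geom, n_fields=200, seed=4)
        # most opposite-probe distances are long, comparable with chance
        assert obs.fraction_beyond(30.0) > 0.2
        assert obs.fraction_beyond(30.0) == pytest.approx(
            rand.fraction_beyond(30.0), abs=0.15)
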