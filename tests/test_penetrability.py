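"""The central statistic: histogram, normalization, alignment, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucolab.penetrability import (
    DistanceDistribution,
    DistanceSet,
    aggregate_mouse,
    build_distance_histogram,
    compute_penetrability,
    median_curve,
    normalize_and_align,
    penetrability_auc,
    thickness_from_beads,
)


class TestHistogram:
    @pytest.mark.parametrize(
        "d, b, expected_counts, expected_edges",
        [
            ([10, 10, 10], 5, [0, 0, 3], [0, 5, 10, 15]),
            ([2, 7, 12], 5, [1, 1, 1], [0, 5, 10, 15]),
        ],
    )
    def test_direct_binning(self, d, b, expected_counts, expected_edges):
        h = build_distance_histogram(DistanceSet(np.array(d, float)), b)
        np.testing.assert_array_equal(h.counts, expected_counts)
        np.testing.assert_allclose(h.bin_edges_um, expected_edges)

    def test_below_tissue_clamped_and_reported(self):
        h = build_distance_histogram(DistanceSet(np.array([-3.0, 2.0, 7.0])), 5)
        assert h.n_clamped_below == 1
        assert h.counts[0] == 2  # clamped bead joins the first bin
        assert h.n_beads == 3

    def test_counts_conserve_beads_uniform_draws(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0, 50, 10_000)
        h = build_distance_histogram(DistanceSet(d), 5)
        assert h.n_beads == 10_000
        # each of 10 bins within the 99% multinomial interval around 1000
        half = 2.576 * np.sqrt(10_000 * 0.1 * 0.9)
        assert np.all(np.abs(h.counts - 1000) < half)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="no beads"):
            build_distance_histogram(DistanceSet(np.zeros(0)), 5)


class TestNormalizeAlign:
    def test_single_occupied_bin_collapses_to_surface_point(self):
        dist = DistanceDistribution(np.array([0, 5, 10, 15.0]), np.array([0, 0, 5.0]))
        nd = normalize_and_align(dist)
        assert nd.surface_bin_distance_um == 12.5
        np.testing.assert_array_equal(nd.x_um, [0.0])
        np.testing.assert_array_equal(nd.f, [1.0])
        assert nd.n_cropped_above == 0

    def test_three_rule_hand_example(self):
        # modal bin (count 100) anchors the surface; the 7 beads above it
        # are cropped; frequencies are scaled to the modal count
        dist = DistanceDistribution(
            np.array([0, 5, 10, 15, 20.0]), np.array([10, 1, 100, 7.0])
        )
        nd = normalize_and_align(dist)
        assert nd.surface_bin_distance_um == 12.5
        np.testing.assert_allclose(nd.x_um, [0, 5, 10])
        np.testing.assert_allclose(nd.f, [1.0, 0.01, 0.1])
        assert nd.n_cropped_above == 7

    def test_scale_invariance_of_max_normalization(self):
        counts = np.array([10, 1, 100, 7.0])
        edges = np.array([0, 5, 10, 15, 20.0])
        a = normalize_and_align(DistanceDistribution(edges, counts))
        b = normalize_and_align(DistanceDistribution(edges, counts * 3))
        np.testing.assert_array_equal(a.x_um, b.x_um)
        np.testing.assert_array_equal(a.f, b.f)
        assert a.surface_bin_distance_um == b.surface_bin_distance_um

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_align(
                DistanceDistribution(np.array([0, 5.0]), np.array([0.0]))
            )


class TestAUC:
    def test_single_point_curve_scores_zero(self):
        dist = DistanceDistribution(np.array([0, 5, 10.0]), np.array([0, 9.0]))
        assert penetrability_auc(normalize_and_align(dist)) == 0.0

    def test_flat_curve_rectangle_area(self):
        # ten equal bins, b = 5: exact ties anchor at the outermost bin and
        # the flat unit curve integrates to (k - 1) * b = 45
        dist = DistanceDistribution(np.arange(11) * 5.0, np.full(10, 7.0))
        nd = normalize_and_align(dist)
        assert penetrability_auc(nd) == pytest.approx(45.0)

    def test_manual_trapezoid_sum(self):
        dist = DistanceDistribution(
            np.arange(6) * 5.0, np.array([10, 10, 10, 10, 100.0])
        )
        nd = normalize_and_align(dist)
        np.testing.assert_allclose(nd.f, [1.0, 0.1, 0.1, 0.1, 0.1])
        # 0.55*5 + 0.1*15
        assert penetrability_auc(nd) == pytest.approx(4.25)


class TestThickness:
    @pytest.mark.parametrize(
        "d, expected", [([30, 30, 30], 30.0), ([10, 20, 30, 40], 25.0)]
    )
    def test_mean_distance(self, d, expected):
        assert thickness_from_beads(DistanceSet(np.array(d, float))) == expected

    def test_impenetrable_phantom_recovers_layer_thickness(self):
        import mucolab as m

        model = m.MucusModel(thickness_um=80.0, penetration_fraction=0.0)
        ds = m.sample_bead_distances(model, 500, seed=0)
        assert thickness_from_beads(ds) == pytest.approx(80.0)


class TestAggregateMouse:
    def _stack(self, d, stack_id):
        res, nd = compute_penetrability(DistanceSet(np.asarray(d, float),
                                                    "m1", stack_id), 5)
        return res, nd

    def test_single_stack_identity(self):
        res, nd = self._stack([2, 7, 12, 42, 42, 42], "s1")
        agg = aggregate_mouse([res], [nd])
        assert agg.auc_um == res.auc_um
        assert agg.n_stacks == 1

    def test_median_of_aucs(self):
        import mucolab as m

        rng = np.random.default_rng(0)
        results, curves = [], []
        for i, p in enumerate([0.1, 0.9, 0.4]):
            model = m.MucusModel(thickness_um=50.0, penetration_fraction=p)
            ds = m.sample_bead_distances(model, 2000, seed=i)
            res, nd = compute_penetrability(ds, 5)
            results.append(res)
            curves.append(nd)
        agg = aggregate_mouse(results, curves)
        assert agg.auc_um == np.median([r.auc_um for r in results])

    def test_median_curve_matches_explicit_padding(self):
        # curves of unequal extent: brute-force zero-padding + per-x median
        res1, nd1 = self._stack([42.0, 42.0, 42.0], "s1")  # 1 point
        res2, nd2 = self._stack([2, 7, 12, 42, 42, 42], "s2")
        res3, nd3 = self._stack([7, 7, 42, 42, 42, 42, 17], "s3")
        agg = aggregate_mouse([res1, res2, res3], [nd1, nd2, nd3])
        n = max(c.f.size for c in (nd1, nd2, nd3))
        padded = np.zeros((3, n))
        for i, c in enumerate((nd1, nd2, nd3)):
            padded[i, : c.f.size] = c.f
        np.testing.assert_allclose(agg.median_curve_f, np.median(padded, axis=0))
        np.testing.assert_allclose(agg.median_curve_x_um, np.arange(n) * 5.0)

    def test_mismatched_bin_widths_rejected(self):
        _, nd1 = self._stack([10.0, 10.0], "s1")
        res2, _ = compute_penetrability(DistanceSet(np.array([10.0, 10.0])), 2)
        _, nd2 = compute_penetrability(DistanceSet(np.array([10.0, 10.0])), 2)
        with pytest.raises(ValueError, match="bin width"):
            median_curve([nd1, nd2])


class TestInvariants:
    @given(
        counts=st.lists(st.integers(0, 50), min_size=2, max_size=12).filter(
            lambda c: sum(c) > 0
        ),
        k=st.integers(2, 9),
    )
    @settings(max_examples=100, deadline=None)
    def test_bead_count_invariance_exact(self, counts, k):
        """Multiplying every count by k leaves the curve and AUC unchanged."""
        counts = np.array(counts, float)
        edges = np.arange(counts.size + 1) * 5.0
        a = normalize_and_align(DistanceDistribution(edges, counts))
        b = normalize_and_align(DistanceDistribution(edges, counts * k))
        np.testing.assert_array_equal(a.x_um, b.x_um)
        np.testing.assert_array_equal(a.f, b.f)
        assert penetrability_auc(a) == penetrability_auc(b)

    @given(
        d=st.lists(st.floats(0.0, 100.0), min_size=3, max_size=60),
        m=st.integers(1, 6),
    )
    @settings(max_examples=100, deadline=None)
    def test_surface_offset_invariance_exact(self, d, m):
        """A thicker overlying buffer (shift by whole bins) changes nothing."""
        b = 5.0
        base = compute_penetrability(DistanceSet(np.array(d)), b)
        shifted = compute_penetrability(DistanceSet(np.array(d) + m * b), b)
        assert base[0].auc_um == shifted[0].auc_um
        np.testing.assert_array_equal(base[1].f, shifted[1].f)
        np.testing.assert_array_equal(base[1].x_um, shifted[1].x_um)

    @given(d=st.lists(st.floats(-20.0, 120.0), min_size=1, max_size=80))
    @settings(max_examples=100, deadline=None)
    def test_bead_conservation_through_the_chain(self, d):
        """Every bead is in the cropped curve, above it, or clamped below."""
        ds = DistanceSet(np.array(d))
        hist = build_distance_histogram(ds, 5.0)
        nd = normalize_and_align(hist)
        peak = hist.counts.max()
        in_curve = float(nd.f.sum() * peak)
        # trailing trimmed bins are empty, so the curve sum is exact
        assert in_curve + nd.n_cropped_above == pytest.approx(len(ds))
        assert hist.n_beads == len(ds)
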