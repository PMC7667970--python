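"""Generators: surfaces, bead populations, renders, series, cohorts, oracle."""

import numpy as np
import pytest
from scipy import ndimage, stats

import mucolab as m
from mucolab.penetrability import compute_penetrability
from mucolab.synthetic import _sample_depths


class TestTissueSurface:
    def test_zero_amplitude_is_constant(self):
        surf = m.generate_tissue_surface(
            m.SurfaceConfig(grid_nx=8, grid_ny=6, amplitude_um=0.0, mean_z_um=50.0)
        )
        np.testing.assert_array_equal(surf.surface_z_um, 50.0)
        assert surf.valid_mask.all()

    def test_deterministic_under_seed(self):
        cfg = m.SurfaceConfig(amplitude_um=5.0, mean_z_um=50.0, seed=7)
        a = m.generate_tissue_surface(cfg)
        b = m.generate_tissue_surface(cfg)
        np.testing.assert_array_equal(a.surface_z_um, b.surface_z_um)

    def test_heights_bounded_by_amplitude(self):
        surf = m.generate_tissue_surface(
            m.SurfaceConfig(amplitude_um=5.0, mean_z_um=50.0, seed=1)
        )
        assert surf.surface_z_um.min() >= 35.0
        assert surf.surface_z_um.max() <= 65.0

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            m.SurfaceConfig(grid_nx=0)


@pytest.fixture(scope="module")
def flat_surface():
    return m.generate_tissue_surface(
        m.SurfaceConfig(grid_nx=32, grid_ny=32, pixel_size_um=4.0,
                        mean_z_um=50.0, amplitude_um=0.0)
    )


class TestBeadPopulation:

    def test_impenetrable_all_beads_at_surface(self, flat_surface):
        model = m.MucusModel(thickness_um=80.0, penetration_fraction=0.0)
        beads = m.generate_bead_population(flat_surface, model, 200, seed=0)
        np.testing.assert_array_equal(beads.depth_um, 0.0)
        assert set(beads.label) == {"surface"}
        np.testing.assert_allclose(beads.true_distance_um, 80.0)

    def test_fully_penetrant_uniform_depth_moments(self, flat_surface):
        model = m.MucusModel(thickness_um=80.0, penetration_fraction=1.0)
        beads = m.generate_bead_population(flat_surface, model, 100_000, seed=1)
        se = 80.0 / np.sqrt(12) / np.sqrt(100_000)
        assert abs(beads.depth_um.mean() - 40.0) < 3 * se

    def test_penetrant_fraction_within_binomial_interval(self, flat_surface):
        model = m.MucusModel(thickness_um=80.0, penetration_fraction=0.5)
        beads = m.generate_bead_population(flat_surface, model, 10_000, seed=2)
        frac = np.mean(beads.label == "penetrant")
        half = 2.576 * np.sqrt(0.25 / 10_000)
        assert abs(frac - 0.5) < half

    @pytest.mark.parametrize("law,kwargs", [
        ("uniform", {}),
        ("exponential", {"depth_scale_um": 20.0}),
    ])
    def test_depth_law_distribution_ks(self, law, kwargs):
        """Empirical penetrant depths follow the configured truncated law."""
        model = m.MucusModel(thickness_um=80.0, penetration_fraction=1.0,
                             depth_law=law, **kwargs)
        rng = np.random.default_rng(3)
        depth, _ = _sample_depths(model, 10_000, rng)
        if law == "uniform":
            cdf = stats.uniform(0, 80).cdf
        else:
            s, T = 20.0, 80.0
            cdf = lambda x: (1 - np.exp(-np.asarray(x) / s)) / (1 - np.exp(-T / s))
        assert stats.kstest(depth, cdf).pvalue > 0.01

    def test_exponential_law_requires_scale(self):
        with pytest.raises(ValueError):
            m.MucusModel(depth_law="exponential")


class TestRenderZstack:
    def test_empty_bead_channel_is_noise_only(self):
        surf = m.generate_tissue_surface(
            m.SurfaceConfig(grid_nx=16, grid_ny=16, mean_z_um=30.0)
        )
        model = m.MucusModel(thickness_um=40.0)
        beads = m.generate_bead_population(surf, model, 1, seed=0)
        # drop the single bead to render an empty bead field
        for attr in ("x_um", "y_um", "z_um", "depth_um", "label", "surface_z_um"):
            setattr(beads, attr, getattr(beads, attr)[:0])
        rendered = m.render_zstack(
            surf, beads, m.RenderConfig(background_noise_sigma=1.0, seed=1),
            n_z=30,
        )
        assert rendered.stack.channel("beads").max() < 50.0

    def test_single_bead_argmax_at_known_voxel(self):
        surf = m.generate_tissue_surface(
            m.SurfaceConfig(grid_nx=16, grid_ny=16, pixel_size_um=2.0,
                            mean_z_um=20.0)
        )
        model = m.MucusModel(thickness_um=40.0, penetration_fraction=0.0)
        beads = m.generate_bead_population(surf, model, 1, seed=5)
        rendered = m.render_zstack(surf, beads, m.RenderConfig(z_step_um=2.0))
        ch = rendered.stack.channel("beads")
        k, j, i = np.unravel_index(np.argmax(ch), ch.shape)
        assert abs((i + 0.5) * 2.0 - beads.x_um[0]) <= 2.0 * np.sqrt(3)
        assert abs((j + 0.5) * 2.0 - beads.y_um[0]) <= 2.0 * np.sqrt(3)
        assert abs((k + 0.5) * 2.0 - beads.z_um[0]) <= 2.0 * np.sqrt(3)

    def test_connected_components_count_nonoverlapping(self, rendered_phantom):
        _, beads, rendered = rendered_phantom
        mask = rendered.stack.channel("beads") >= 50.0
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == len(beads)

    def test_out_of_volume_bead_reported_not_dropped(self):
        surf = m.generate_tissue_surface(
            m.SurfaceConfig(grid_nx=8, grid_ny=8, mean_z_um=20.0)
        )
        model = m.MucusModel(thickness_um=40.0, penetration_fraction=0.0)
        beads = m.generate_bead_population(surf, model, 3, seed=0)
        beads.z_um[1] = 500.0  # way above the rendered volume
        rendered = m.render_zstack(surf, beads, m.RenderConfig(), n_z=40)
        assert list(rendered.clipped_bead_ids) == [1]


class TestThicknessSeries:
    def test_noiseless_constant(self):
        ts = m.generate_thickness_series(350.0, 0.0, 0.0)
        assert len(ts) == 20  # 5 locations x 4 times
        np.testing.assert_array_equal(ts["thickness_um"], 350.0)

    def test_noiseless_linear_evaluation(self):
        ts = m.generate_thickness_series(400.0, 2.0, 0.0)
        for t, expected in [(0, 400), (15, 430), (30, 460), (45, 490)]:
            vals = ts.loc[ts["time_min"] == t, "thickness_um"]
            assert len(vals) == 5
            np.testing.assert_array_equal(vals, float(expected))

    def test_deterministic_under_seed(self):
        a = m.generate_thickness_series(400.0, 2.0, 5.0, seed=9)
        b = m.generate_thickness_series(400.0, 2.0, 5.0, seed=9)
        assert a.equals(b)


def _two_group_config(p_lean=0.1, p_ob=0.7, housing="separated", n=5, **kw):
    def grp(label, p, rate):
        return m.GroupConfig(
            label=label, n=n, body_weight_g=(30, 3),
            fasting_glucose_mM=(8, 1), fasting_insulin_uU_ml=(10, 3),
            mucus=m.MucusModel(thickness_um=80.0, penetration_fraction=p),
            growth_rate_um_min=(rate, 0.3), initial_thickness_um=(400, 40),
        )

    return m.CohortConfig(groups=(grp("lean", p_lean, 2.0), grp("ob", p_ob, 1.0)),
                          housing=housing, **kw)


class TestCohort:
    def test_table_shape_and_balance(self):
        cohort = m.generate_cohort(_two_group_config(n=5))
        assert len(cohort.table) == 10
        assert cohort.table["group"].value_counts().tolist() == [5, 5]
        assert set(cohort.distance_sets) == set(cohort.table["mouse"])

    def test_separated_groups_keep_their_penetration_fractions(self):
        cohort = m.generate_cohort(_two_group_config(p_lean=0.1, p_ob=0.7))
        means = cohort.table.groupby("group")["true_penetration_fraction"].mean()
        assert means["ob"] - means["lean"] == pytest.approx(0.6)

    def test_cohoused_ground_truth_converges(self):
        cohort = m.generate_cohort(_two_group_config(housing="cohoused"))
        assert cohort.table["true_penetration_fraction"].nunique() == 1
        assert cohort.table["true_penetration_fraction"].iloc[0] == pytest.approx(0.4)

    def test_partial_convergence_knob(self):
        cohort = m.generate_cohort(
            _two_group_config(housing="cohoused", convergence=0.5)
        )
        means = cohort.table.groupby("group")["true_penetration_fraction"].mean()
        assert means["ob"] - means["lean"] == pytest.approx(0.3)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            _two_group_config(n=1)


class TestExpectedPenetrability:
    def test_impenetrable_scores_zero(self):
        model = m.MucusModel(thickness_um=50.0, penetration_fraction=0.0)
        assert m.expected_penetrability(model, 5.0) == 0.0

    def test_fully_penetrant_flat_curve(self):
        model = m.MucusModel(thickness_um=50.0, penetration_fraction=1.0)
        assert m.expected_penetrability(model, 5.0) == pytest.approx(45.0)

    def test_closed_form_matches_monte_carlo(self):
        model = m.MucusModel(thickness_um=50.0, penetration_fraction=0.5)
        expected = m.expected_penetrability(model, 5.0)
        ds = m.sample_bead_distances(model, 10**6, seed=12)
        res, _ = compute_penetrability(ds, 5.0)
        assert res.auc_um == pytest.approx(expected, rel=0.01)

    def test_exponential_law_monte_carlo(self):
        model = m.MucusModel(thickness_um=50.0, penetration_fraction=0.6,
                             depth_law="exponential", depth_scale_um=15.0)
        expected = m.expected_penetrability(model, 5.0)
        ds = m.sample_bead_distances(model, 10**6, seed=13)
        res, _ = compute_penetrability(ds, 5.0)
        assert res.auc_um == pytest.approx(expected, rel=0.01)

    def test_monotone_in_penetration_fraction_while_surface_modal(self):
        # the surface spike stays modal up to p = k/(k+1); beyond that the
        # anchor moves (flagged as a regime change) and monotonicity ends
        aucs = [
            m.expected_penetrability(
                m.MucusModel(thickness_um=50.0, penetration_fraction=p), 5.0
            )
            for p in np.linspace(0, 0.9, 10)
        ]
        assert np.all(np.diff(aucs) >= 0)

    def test_regime_change_warned_when_surface_not_modal(self):
        model = m.MucusModel(thickness_um=50.0, penetration_fraction=0.95)
        with pytest.warns(UserWarning, match="regime"):
            m.expected_penetrability(model, 5.0)

    def test_bin_width_must_divide_thickness(self):
        model = m.MucusModel(thickness_um=52.0, penetration_fraction=0.5)
        with pytest.raises(ValueError, match="integer multiple"):
            m.expected_penetrability(model, 5.0)

    def test_jitter_flagged_as_approximate(self):
        model = m.MucusModel(thickness_um=50.0, penetration_fraction=0.5,
                             surface_jitter_um=2.0)
        with pytest.warns(UserWarning, match="jitter"):
            m.expected_penetrability(model, 5.0)
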