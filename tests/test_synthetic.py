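"""Synthetic tissue, proportion-field and transition-chain generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from plastmap import plasticity, synthetic
from plastmap.io import read_spot_table, write_spot_table


class TestGenSpots:
    def test_annulus_containment(self):
        geom = synthetic.TissueGeometry(r_inner=300, r_outer=600, spot_spacing=20)
        spots, _ = synthetic.gen_spots(geom, smear_fraction=0.0, seed=0)
        r = np.hypot(*(spots.coords - np.array(geom.center)).T)
        assert np.all((r >= 300) & (r <= 600))

    def test_deterministic_given_seed(self):
        geom = synthetic.TissueGeometry(r_inner=300, r_outer=450, spot_spacing=25,
                                        jitter_sd=2.0)
        a, ta = synthetic.gen_spots(geom, smear_fraction=0.05, seed=7)
        b, tb = synthetic.gen_spots(geom, smear_fraction=0.05, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert (a.counts != b.counts).nnz == 0
        pd.testing.assert_frame_equal(ta.spots, tb.spots)

    def test_smear_count_and_halo_placement(self, half_annulus_geom):
        spots, _ = synthetic.gen_spots(half_annulus_geom, smear_fraction=0.1, seed=3)
        tissue = spots.table[~spots.table["is_smear"]]
        smears = spots.table[spots.table["is_smear"]]
        n = len(tissue)
        # Binomial(n, 0.1): allow 5 sigma around the mean
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(len(smears) - 0.1 * n) <= 5 * sd
        r = np.hypot(smears["x"], smears["y"])
        assert np.all(r > half_annulus_geom.r_outer + half_annulus_geom.spot_spacing)
        assert np.all(smears["total_counts"] <= 50)

    def test_total_counts_match_count_matrix(self, half_annulus):
        spots, _ = half_annulus
        row_sums = np.asarray(spots.counts.sum(axis=1)).ravel()
        assert np.array_equal(row_sums, spots.table["total_counts"].to_numpy())

    def test_boundary_rings_subset_members_and_disjoint(self, half_annulus):
        spots, _ = half_annulus
        mask = spots.region_mask()
        members = set(mask.members)
        for ring in (mask.inner, mask.outer, mask.upper, mask.bottom):
            assert set(ring) <= members
        assert not (set(mask.inner) & set(mask.outer))

    def test_degenerate_annulus_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            synthetic.TissueGeometry(r_inner=600, r_outer=300)

    def test_invalid_parameters_rejected(self):
        geom = synthetic.TissueGeometry()
        with pytest.raises(ValueError):
            synthetic.gen_spots(geom, mean_depth=0)
        with pytest.raises(ValueError):
            synthetic.gen_spots(geom, smear_fraction=1.0)

    def test_wedge_spots_inside_triangle(self, wedge_geom):
        spots, truth = synthetic.gen_spots(wedge_geom, seed=1)
        t = wedge_geom.apex[1] - spots.table["y"]
        halfwidth = 0.5 * wedge_geom.base_width * t / wedge_geom.height
        assert np.all(np.abs(spots.table["x"] - wedge_geom.apex[0]) <= halfwidth + 1e-9)
        ax = truth.spots["axial_fraction"]
        assert ax.between(0, 1).all()

    def test_roundtrip_through_tsv_and_mtx(self, half_annulus, tmp_path):
        spots, _ = half_annulus
        write_spot_table(spots, tmp_path)
        back = read_spot_table(tmp_path)
        pd.testing.assert_frame_equal(spots.table, back.table)
        assert (spots.counts != back.counts).nnz == 0
        assert back.genes == spots.genes


class TestGenProportionField:
    def test_step_profiles_separate_inner_and_outer(self, half_annulus):
        spots, truth = half_annulus
        profiles = {
            "A": synthetic.LogisticProfile(midpoint=0.5, slope=80.0),
            "B": synthetic.LogisticProfile(midpoint=0.5, slope=-80.0),
        }
        ab, truth2 = synthetic.gen_proportion_field(spots, truth, profiles, noise_sd=0.0)
        rf = truth.spots.loc[ab.index, "radial_fraction"]
        inner = rf > 0.55
        assert np.all(ab.loc[inner, "A"] > ab.loc[inner, "B"])

    def test_constant_profiles_give_half_half(self, half_annulus):
        spots, truth = half_annulus
        flat = synthetic.LogisticProfile(slope=0.0, low=1.0, high=1.0)
        _, truth2 = synthetic.gen_proportion_field(spots, truth, {"A": flat, "B": flat})
        assert np.allclose(truth2.type_proportions.to_numpy(), 0.5)

    def test_logistic_profile_tracks_radial_fraction(self, half_annulus):
        spots, truth = half_annulus
        profiles = {
            "A": synthetic.LogisticProfile(midpoint=0.5, slope=10.0),
            "B": synthetic.LogisticProfile(midpoint=0.5, slope=-10.0),
        }
        ab, truth2 = synthetic.gen_proportion_field(spots, truth, profiles, noise_sd=0.0)
        props = ab.div(ab.sum(axis=1), axis=0)
        rho = spearmanr(props["A"], truth.spots.loc[ab.index, "radial_fraction"]).statistic
        assert rho > 0.99

    def test_truth_rows_sum_to_one(self, half_annulus):
        spots, truth = half_annulus
        profiles = {
            "A": synthetic.LogisticProfile(slope=5.0),
            "B": synthetic.LogisticProfile(slope=-3.0),
            "C": synthetic.LogisticProfile(slope=0.0, low=0.2, high=0.2),
        }
        _, truth2 = synthetic.gen_proportion_field(spots, truth, profiles, noise_sd=0.1, seed=2)
        assert np.allclose(truth2.type_proportions.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_profiles_rejected(self, half_annulus):
        spots, truth = half_annulus
        zero = synthetic.LogisticProfile(slope=0.0, low=0.0, high=0.0)
        with pytest.raises(ValueError):
            synthetic.gen_proportion_field(spots, truth, {"A": zero, "B": zero})

    def test_single_profile_rejected(self, half_annulus):
        spots, truth = half_annulus
        with pytest.raises(ValueError):
            synthetic.gen_proportion_field(spots, truth, {"A": synthetic.LogisticProfile()})


class TestGenTransitionChain:
    def test_noise_free_transitions_run_forward_only(self):
        res = synthetic.gen_transition_chain([10, 10], ["immature", "mature"], noise_p=0.0, seed=0)
        T = res.transition.tocoo()
        stages = res.cells["stage"].to_numpy()
        assert np.all(stages[T.row] == 0)
        assert np.all(stages[T.col] == 1)

    def test_terminal_stage_has_zero_outflow(self, three_stage_chain):
        res = three_stage_chain
        row_sums = np.asarray(res.transition.sum(axis=1)).ravel()
        terminal = res.cells["stage"] == res.cells["stage"].max()
        assert np.all(row_sums[terminal] == 0)

    def test_net_flow_strictly_decreasing_along_chain(self, three_stage_chain):
        res = three_stage_chain
        nf = plasticity.net_flow(res.transition)
        means = pd.Series(nf.raw).groupby(res.cells["stage"].values).mean()
        assert means[0] > means[1] > means[2]

    def test_velocity_magnitude_decreases_to_zero_at_sink(self, three_stage_chain):
        res = three_stage_chain
        norms = np.linalg.norm(res.velocities, axis=1)
        by_stage = pd.Series(norms).groupby(res.cells["stage"].values).mean()
        assert by_stage[0] > by_stage[1] > by_stage[2] == 0.0

    def test_roles_mark_source_and_sink(self, three_stage_chain):
        roles = three_stage_chain.truth.roles
        assert roles["immature"] == "source"
        assert roles["transitional"] == "intermediate"
        assert roles["mature"] == "sink"

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_transition_chain([5, 0], ["a", "b"])

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_transition_chain([5, 5], ["a", "b"], forward_p=0.3, noise_p=0.4)
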