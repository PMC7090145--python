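"""Generator determinism, noise-free limits and ground-truth closure."""

import numpy as np
import pytest

from phenokit import (DielSimParams, GrowthModel, SimConfig, StomataSimParams,
                      render_leaf_scene, simulate_diel_trace, simulate_growth,
                      simulate_physio, simulate_stomata)
from phenokit.growth import GrowthDomainError
from phenokit.synthetic import SceneSizingError, diel_template, physio_targets


class TestRenderScene:
    def test_empty_scene_has_only_the_reference(self):
        scene = render_leaf_scene([], px_per_cm=30, seed=0)
        assert scene.truth["area_cm2"] == 0.0
        assert scene.green_mask.sum() == 0
        assert scene.reference_mask.sum() == 900

    def test_unit_area_equals_reference_count(self):
        scene = render_leaf_scene([1.0], px_per_cm=50, seed=1)
        assert scene.green_mask.sum() == 2500
        assert scene.reference_mask.sum() == 2500

    def test_total_green_count_is_rounded_sum(self):
        scene = render_leaf_scene([2.5, 0.7], px_per_cm=40, seed=0)
        assert scene.green_mask.sum() == round(3.2 * 40 * 40)  # 5120

    def test_seeded_determinism(self):
        a = render_leaf_scene([1.0, 0.5], px_per_cm=40, seed=9)
        b = render_leaf_scene([1.0, 0.5], px_per_cm=40, seed=9)
        assert np.array_equal(a.image, b.image)

    def test_canvas_too_small_raises(self):
        with pytest.raises(SceneSizingError):
            render_leaf_scene([5.0], px_per_cm=50, seed=0, canvas_shape=(80, 80))

    def test_shapes_never_overlap(self):
        scene = render_leaf_scene([1.0, 1.0, 1.0], px_per_cm=40, seed=4)
        assert not (scene.green_mask & scene.reference_mask).any()


class TestSimulateGrowth:
    def test_noise_free_reproduces_model(self):
        model = GrowthModel(29.7391, 1.0830)
        table = simulate_growth(model, (-21, 14))
        assert table.loc[0, "area_cm2"] == 0.0  # D = -21
        d0 = table[table["day"] == 0]["area_cm2"].item()
        assert d0 == pytest.approx(29.7391 * (1.0830 ** 21 - 1), rel=1e-12)

    def test_zero_noise_kills_seed_dependence(self):
        model = GrowthModel(10.0, 1.05)
        a = simulate_growth(model, (-5, 10), noise_sd=0.0, seed=1)
        b = simulate_growth(model, (-5, 10), noise_sd=0.0, seed=2)
        assert a.equals(b)

    def test_negative_model_area_names_day(self):
        model = GrowthModel(29.7391, 1.0830, 5.7849, 1.2998,
                            salt_term_offset=21.0)
        with pytest.raises(GrowthDomainError):
            simulate_growth(model, (0, 14))

    def test_truth_sidecar_present(self):
        table = simulate_growth(GrowthModel(10.0, 1.05), (-5, 5))
        assert table.attrs["truth"]["model"]["a1"] == 10.0


class TestSimulateDiel:
    def test_noiseless_control_nights_sit_at_night_level(self, noiseless_params):
        trace = simulate_diel_trace(SimConfig(seed=0, n_days=4), noiseless_params)
        nights = trace.assimilation[~trace.light_on]
        assert np.all(nights == noiseless_params.night_level)

    def test_noiseless_template_matches_direct_template(self, noiseless_params):
        cfg = SimConfig(seed=0, n_days=3, group="salt")
        trace = simulate_diel_trace(cfg, noiseless_params)
        np.testing.assert_array_equal(trace.assimilation,
                                      diel_template(cfg, noiseless_params))

    def test_seeded_determinism(self):
        a = simulate_diel_trace(SimConfig(seed=5, group="salt"))
        b = simulate_diel_trace(SimConfig(seed=5, group="salt"))
        assert np.array_equal(a.assimilation, b.assimilation)

    def test_control_max_daytime_sample_below_printed_ceiling(self, control_trace):
        assert control_trace.assimilation[control_trace.light_on].max() <= 12.0

    def test_trace_length_and_schedule(self, salt_trace):
        assert len(salt_trace) == 14 * 2880
        assert salt_trace.light_on.sum() == len(salt_trace) // 2

    def test_truth_records_transition(self, salt_trace):
        assert salt_trace.truth["transition_night_zero_day"] == 8
        assert salt_trace.truth["spikes_from_day"] == 9


class TestSimulateStomata:
    def test_control_day_open_night_closed_every_day(self):
        table = simulate_stomata(SimConfig(seed=2, group="control"))
        means = table.groupby(["day", "timepoint"])["aperture_um"].mean().unstack()
        assert (means["4pm"] > means["4am"]).all()

    def test_apertures_positive_and_within_union_of_ranges(self, salt_stomata):
        ap = salt_stomata["aperture_um"]
        assert (ap > 0).all()
        assert ap.between(0.7, 1.1).sum() + ap.between(1.7, 3.0).sum() == len(ap)

    def test_inversion_day_bounds_checked(self):
        with pytest.raises(ValueError, match="inversion_day"):
            simulate_stomata(SimConfig(seed=0, n_days=5, group="salt"),
                             StomataSimParams(inversion_day=7))

    def test_row_count_and_determinism(self, salt_stomata):
        assert len(salt_stomata) == 14 * 2 * 150
        again = simulate_stomata(SimConfig(seed=7, group="salt"))
        assert salt_stomata.equals(again)


class TestSimulatePhysio:
    def test_weight_ordering_invariant(self, physio_table):
        assert (physio_table["tw_g"] > physio_table["fw_g"]).all()
        assert (physio_table["fw_g"] > physio_table["dw_g"]).all()
        assert (physio_table["dw_g"] > 0).all()

    def test_day0_succulence_near_baseline(self, physio_table):
        day0 = physio_table[(physio_table["day"] == 0)
                            & (physio_table["group"] == "control")]
        succ = (day0["fw_g"] / day0["area_cm2"]).mean()
        assert succ == pytest.approx(0.12, rel=0.1)

    def test_same_seed_identical_tables(self):
        a = simulate_physio(SimConfig(seed=4))
        b = simulate_physio(SimConfig(seed=4))
        assert a.equals(b)

    def test_targets_cover_reported_trajectories(self):
        assert physio_targets(0, "control")["succulence_g_cm2"] == 0.12
        assert physio_targets(5, "control")["succulence_g_cm2"] == 0.16
        assert physio_targets(11, "salt")["succulence_g_cm2"] == pytest.approx(0.18)
        assert physio_targets(0, "control")["rwc_pct"] == 62.5
        assert physio_targets(14, "control")["rwc_pct"] == 80.0

    def test_truth_sidecar_mirrors_targets(self, physio_table):
        truth = physio_table.attrs["truth"]
        assert truth["targets"]["salt"][7]["mda_nmol_g"] == 1.75
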