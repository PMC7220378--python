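"""Generators: kinematics, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from calpharm import (
    EMGenParams,
    LocoGenParams,
    ProtocolParams,
    ROISceneParams,
    StimGenParams,
    annulus_density_profile,
    gen_em_sample,
    gen_locomotion_block,
    gen_roi_scene,
    gen_speed_trace,
    gen_stim_dataset,
)
from calpharm.em import PSDSample
from calpharm.synthetic import protocol_position


class TestSpeedTrace:
    def test_kinematic_values(self):
        trace = gen_speed_trace()
        t = trace.time_s
        assert trace.speed_cm_s[np.searchsorted(t, 8.5)] == pytest.approx(5.0)
        assert trace.speed_cm_s[np.searchsorted(t, 15.0)] == pytest.approx(10.0)
        # motor off outside [7, 26)
        assert np.all(trace.speed_cm_s[t < 7.0] == 0)
        assert np.all(trace.speed_cm_s[t >= 26.0] == 0)

    def test_motorized_distance_is_160_cm(self):
        p = ProtocolParams()
        assert protocol_position(26.0, p) - protocol_position(7.0, p) == pytest.approx(160.0)
        assert protocol_position(p.t_total, p) == pytest.approx(160.0)

    def test_position_is_integral_of_speed(self):
        trace = gen_speed_trace()
        approx = np.concatenate(
            [[0], np.cumsum((trace.speed_cm_s[1:] + trace.speed_cm_s[:-1]) / 2) / 30.0]
        )
        assert np.allclose(approx, trace.position_cm, atol=0.06)

    def test_speed_continuous_at_segment_boundaries(self):
        trace = gen_speed_trace()
        max_step = ProtocolParams().accel / 30.0
        assert np.max(np.abs(np.diff(trace.speed_cm_s))) <= max_step + 1e-12

    def test_inconsistent_protocol_rejected(self):
        with pytest.raises(ValueError):
            ProtocolParams(t_accel_start=5.0, t_free_end=6.0)
        with pytest.raises(ValueError):
            ProtocolParams(accel=0.1)  # v_max never reached


class TestLocomotionBlock:
    def test_deterministic_under_seed(self, small_loco_params):
        b1, t1 = gen_locomotion_block(small_loco_params)
        b2, t2 = gen_locomotion_block(small_loco_params)
        for r1, r2 in zip(b1, b2):
            assert r1.soma.equals(r2.soma)
            assert r1.neuropil.equals(r2.neuropil)
        assert np.array_equal(b1.masks["pre_drug"], b2.masks["pre_drug"])
        assert t1.baseline.equals(t2.baseline)

    def test_distinct_seeds_differ(self, small_loco_params):
        b1, _ = gen_locomotion_block(small_loco_params)
        b2, _ = gen_locomotion_block(
            LocoGenParams(**{**small_loco_params.__dict__, "seed": small_loco_params.seed + 1})
        )
        assert not b1.recordings[0].soma.equals(b2.recordings[0].soma)

    def test_zero_effect_zero_decay_gives_equal_designed_values(self):
        p = LocoGenParams(
            n_rois=5, n_pre=3, n_post=4, effect_slope=0.0, effect_noise_sd=0.0, decay_B=0.0, seed=3
        )
        _, truth = gen_locomotion_block(p)
        # decay collapses to the constant A, so every recording shares b_i + A
        expected = truth.baseline + p.decay_A
        for j in truth.designed_L.index:
            assert np.allclose(truth.designed_L.loc[j], expected)
        assert np.allclose(truth.change, 0.0)

    def test_percentile_exact_without_jitter(self):
        p = LocoGenParams(n_rois=4, n_pre=3, n_post=4, jitter_sd=0.0, seed=11)
        block, truth = gen_locomotion_block(p)
        rec = block.recordings[0]
        corrected = rec.soma - p.neuropil_scale * rec.neuropil
        dff = (corrected - truth.f_rest.values) / truth.f_rest.values
        window = dff.iloc[300:750]
        got = np.percentile(window, 75, axis=0)
        assert np.allclose(got, truth.designed_L.loc[1].to_numpy(), atol=1e-12)

    def test_percentile_exact_with_jitter(self):
        """The jitter is re-centred so the windowed 75th percentile is exact."""
        p = LocoGenParams(n_rois=4, n_pre=3, n_post=4, jitter_sd=0.2, seed=11)
        block, truth = gen_locomotion_block(p)
        for rec in block.recordings[:2]:
            corrected = rec.soma - p.neuropil_scale * rec.neuropil
            dff = (corrected - truth.f_rest.values) / truth.f_rest.values
            got = np.percentile(dff.iloc[300:750], 75, axis=0)
            assert np.allclose(got, truth.designed_L.loc[rec.index].to_numpy(), atol=1e-9)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LocoGenParams(baseline_sd=0.0)
        with pytest.raises(ValueError):
            LocoGenParams(n_post=3)

    def test_population_r_formula(self):
        p = LocoGenParams()
        rho = p.effect_slope * p.baseline_sd / np.sqrt(
            (p.effect_slope * p.baseline_sd) ** 2 + p.effect_noise_sd**2
        )
        assert p.population_r == pytest.approx(rho)
        assert p.population_r == pytest.approx(-0.547, abs=5e-4)


class TestRoiScene:
    def test_no_shift_no_perturbation_gives_identity_overlap(self):
        a, b, shift, truth = gen_roi_scene(
            ROISceneParams(n_rois=9, shift_px=(0, 0), seed=2)
        )
        assert shift == (0, 0)
        assert np.allclose(truth["ratio"], 1.0)
        assert truth["should_match"].all()

    def test_truth_matches_direct_mask_geometry(self):
        params = ROISceneParams(n_rois=9, shift_px=(4, -3), perturb_radius_frac=0.3, seed=5)
        a, b, shift, truth = gen_roi_scene(params)
        # re-derive one ratio by brute force from the label images
        row = truth.iloc[0]
        ma = a == row["label_a"]
        mb = b == row["label_b"]
        src = np.argwhere(mb)
        aligned = np.zeros_like(mb)
        aligned[src[:, 0] - shift[1], src[:, 1] - shift[0]] = True
        ratio = np.logical_and(ma, aligned).sum() / np.logical_or(ma, aligned).sum()
        assert ratio == pytest.approx(row["ratio"])

    def test_roi_leaving_field_rejected(self):
        with pytest.raises(ValueError):
            gen_roi_scene(ROISceneParams(n_rois=4, field_px=(40, 40), shift_px=(30, 0)))


class TestStimDataset:
    def test_zero_multiplier_gives_unit_ratios(self):
        table, truth = gen_stim_dataset(StimGenParams(drug_component_multiplier=0.0, seed=1))
        wide = table.pivot(index="cell", columns="condition", values="peak_dff")
        assert np.allclose(wide["drug"] / wide["control"], 1.0)
        assert truth["mean_ratio"] == 1.0

    def test_worked_multiplier(self):
        m = 1.1277
        table, truth = gen_stim_dataset(
            StimGenParams(drug_component_multiplier=m, peak_noise_sd=0.0, seed=1)
        )
        wide = table.pivot(index="cell", columns="condition", values="peak_dff")
        assert np.allclose(wide["drug"] / wide["control"], 1.0 / (1.0 + m))
        assert truth["mean_ratio"] == pytest.approx(0.470, abs=5e-4)

    def test_large_multiplier_limit(self):
        table, truth = gen_stim_dataset(
            StimGenParams(drug_component_multiplier=1e6, peak_noise_sd=0.0, seed=1)
        )
        wide = table.pivot(index="cell", columns="condition", values="peak_dff")
        assert (wide["drug"] / wide["control"] < 1e-5).all()


class TestEmGenerator:
    def test_uniform_profile_is_flat(self):
        sample, truth = gen_em_sample(
            EMGenParams(particle_count=4000, radial_profile="uniform", seed=3)
        )
        profile = annulus_density_profile(
            PSDSample(sample["psd_polygon"], sample["particles"])
        )
        dens = profile.densities
        expected = truth["expected_density_per_um2"].iloc[0]
        # Poisson counting error per band ~ 1/sqrt(count)
        for count, d in zip(profile.table["count"], dens):
            assert d == pytest.approx(expected, rel=4 / np.sqrt(max(count, 1)))

    def test_all_mass_in_first_band(self):
        sample, _ = gen_em_sample(
            EMGenParams(particle_count=80, radial_profile=(50.0, 0, 0, 0, 0), seed=4)
        )
        from calpharm.em import particle_distances

        dist = particle_distances(PSDSample(sample["psd_polygon"], sample["particles"]))
        assert (dist["distance_nm"] < 50.0).all()
        assert not dist["inside_psd"].any()

    def test_zero_particles(self):
        sample, _ = gen_em_sample(EMGenParams(particle_count=0, seed=5))
        assert sample["particles"].shape == (0, 2)
        profile = annulus_density_profile(PSDSample(sample["psd_polygon"], sample["particles"]))
        assert profile.table["count"].sum() == 0
        assert profile.total == 0
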