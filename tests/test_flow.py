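"""Pulse-shape metrics: worked values, invariants and generator recovery."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pelletmetrics as pm
from pelletmetrics.flow import NoParticleError
from pelletmetrics.synthetic import PulseGenParams, generate_pulse_profile

from conftest import make_profile, plateau_pulse, triangle_pulse

REL = 1e-9


class TestDetectExtent:
    def test_rectangular_pulse_length(self, rect_profile):
        start, end, length = pm.detect_extent(rect_profile)
        assert start == pytest.approx(10.0, rel=REL)
        assert end == pytest.approx(110.0, rel=REL)
        assert length == pytest.approx(100.0, rel=REL)

    def test_all_baseline_raises(self):
        x = np.arange(0.0, 50.0)
        with pytest.raises(NoParticleError):
            pm.detect_extent(make_profile(x, np.full_like(x, 50.0)))

    def test_synthetic_sphere_within_two_spacings(self):
        params = PulseGenParams(pellet_diameter_um=180.0, seed=5)
        profile, truth = generate_pulse_profile(params)
        _, _, length = pm.detect_extent(profile)
        assert abs(length - truth["diameter_um"]) <= 2 * params.sample_spacing_um


class TestClassification:
    def _profile(self, length, saturated):
        x = np.arange(0.0, length + 21.0)
        level = 2000.0 if saturated else 1500.0
        fsc = plateau_pulse(x, 9.5, 10.5 + length, level)
        return make_profile(x, fsc, saturation_mv=2000.0)

    @pytest.mark.parametrize("length,saturated,expected", [
        (120, True, "pellet"),   # rule as stated: saturation AND > 80 μm
        (60, True, "small"),     # saturated but too short
        (120, False, "large"),   # long but never saturates
        (70, False, "small"),
    ])
    def test_rule(self, length, saturated, expected):
        assert pm.classify_particle(self._profile(length, saturated)) == expected


class TestCompactness:
    def test_rectangular_ssc_is_one(self, rect_profile):
        assert pm.compactness(rect_profile) == pytest.approx(1.0, rel=REL)

    def test_triangular_ssc_is_half(self):
        x = np.arange(0.0, 121.0)
        fsc = plateau_pulse(x, 9.5, 110.5, 3000.0)
        ssc = triangle_pulse(x, 10, 110, 900.0)
        assert pm.compactness(make_profile(x, fsc, ssc=ssc)) == \
            pytest.approx(0.5, rel=REL)

    def test_flat_ssc_raises(self, rect_profile):
        flat = dataclasses.replace(rect_profile,
                                   ssc_mv=np.full_like(rect_profile.ssc_mv, 30.0))
        with pytest.raises(ValueError, match="flat SSC"):
            pm.compactness(flat)

    def test_projected_sphere_near_root3_over_2(self):
        d = 200.0
        p, _ = generate_pulse_profile(PulseGenParams(
            pellet_diameter_um=d, noise_sd_mv=0.0, sample_spacing_um=d / 250))
        assert pm.compactness(p) == pytest.approx(math.sqrt(3) / 2, abs=0.01)


class TestViableLayers:
    def test_fda_arithmetic(self, rect_profile):
        # FLG exactly a quarter of FSC pointwise -> area ratio 1/4, L = 100
        p = dataclasses.replace(rect_profile, flg_mv=0.25 * rect_profile.fsc_mv)
        assert pm.viable_layer_fda(p) == pytest.approx(0.5 * 0.25 * 100.0, rel=REL)

    def test_fda_zero_and_full(self, rect_profile):
        assert pm.viable_layer_fda(rect_profile) == pytest.approx(0.0, abs=1e-12)
        full = dataclasses.replace(rect_profile, flg_mv=rect_profile.fsc_mv)
        assert pm.viable_layer_fda(full) == pytest.approx(50.0, rel=REL)

    def test_pi_flat_flr_gives_full_radius(self, rect_profile):
        assert pm.viable_layer_pi(rect_profile) == pytest.approx(50.0, rel=REL)

    def test_pi_flr_everywhere_gives_zero(self, rect_profile):
        x = rect_profile.position_um
        flr = plateau_pulse(x, 2, 118, 900.0)
        p = dataclasses.replace(rect_profile, flr_mv=flr)
        assert pm.viable_layer_pi(p) == 0.0

    def test_pi_recovers_dead_core_complement(self):
        params = PulseGenParams(pellet_diameter_um=100.0,
                                dead_core_diameter_um=60.0,
                                viable_shell_um=20.0, noise_sd_mv=0.0, seed=3)
        p, _ = generate_pulse_profile(params)
        expected = 0.5 * (100.0 - 60.0)
        assert pm.viable_layer_pi(p) == pytest.approx(
            expected, abs=params.sample_spacing_um)

    def test_fda_matches_shell_closed_form(self):
        # chord-projection shell: vl = R (1-(1-t/R)^2) (g_flg/g_fsc)
        d, shell = 180.0, 30.0
        params = PulseGenParams(pellet_diameter_um=d, viable_shell_um=shell,
                                noise_sd_mv=0.0, saturation_mv=1e9,
                                sample_spacing_um=d / 250)
        p, _ = generate_pulse_profile(params)
        R = d / 2
        expected = R * (1 - (1 - shell / R) ** 2) * (params.flg_gain / params.fsc_gain)
        assert pm.viable_layer_fda(p) == pytest.approx(expected, rel=0.02)

    def test_monotone_in_shell_thickness(self):
        vls = []
        for shell in [5.0, 15.0, 30.0, 50.0, 80.0]:
            p, _ = generate_pulse_profile(PulseGenParams(
                pellet_diameter_um=160.0, viable_shell_um=shell,
                noise_sd_mv=0.0, seed=0))
            vls.append(pm.viable_layer_fda(p))
        assert all(b >= a for a, b in zip(vls, vls[1:]))


class TestFactors:
    @pytest.mark.parametrize("vl,length,expected", [
        (15.0, 120.0, 0.25), (60.0, 120.0, 1.0), (0.0, 120.0, 0.0)])
    def test_viability_factor_arithmetic(self, vl, length, expected):
        assert pm.viability_factor(vl, length) == pytest.approx(expected, rel=REL)

    def test_viability_factor_rejects_bad_input(self):
        with pytest.raises(ValueError):
            pm.viability_factor(10.0, 0.0)
        with pytest.raises(ValueError):
            pm.viability_factor(70.0, 120.0)  # above the radius

    def test_autofluorescence_arithmetic(self, rect_profile):
        p = dataclasses.replace(rect_profile, flg_mv=0.21 * rect_profile.fsc_mv)
        assert pm.autofluorescence_factor(p) == pytest.approx(0.21, rel=REL)
        assert pm.autofluorescence_factor(rect_profile) == pytest.approx(0.0, abs=1e-12)
        full = dataclasses.replace(rect_profile, flg_mv=rect_profile.fsc_mv)
        assert pm.autofluorescence_factor(full) == pytest.approx(1.0, rel=REL)


class TestInvariances:
    def test_common_gain_leaves_ratios_unchanged(self):
        p, _ = generate_pulse_profile(PulseGenParams(
            noise_sd_mv=0.0, saturation_mv=1e9, seed=2))
        scaled = dataclasses.replace(
            p, fsc_mv=3.0 * p.fsc_mv, ssc_mv=3.0 * p.ssc_mv,
            flg_mv=3.0 * p.flg_mv, flr_mv=3.0 * p.flr_mv)
        assert pm.compactness(scaled) == pytest.approx(pm.compactness(p), rel=0.01)
        assert pm.viable_layer_fda(scaled) == pytest.approx(
            pm.viable_layer_fda(p), rel=0.01)
        assert pm.autofluorescence_factor(scaled) == pytest.approx(
            pm.autofluorescence_factor(p), rel=1e-12)

    def test_position_translation_changes_nothing(self):
        p, _ = generate_pulse_profile(PulseGenParams(seed=4))
        shifted = dataclasses.replace(p, position_um=p.position_um + 137.5)
        for fn in (pm.compactness, pm.viable_layer_fda, pm.viable_layer_pi,
                   pm.autofluorescence_factor):
            assert fn(shifted) == pytest.approx(fn(p), rel=1e-12)
        assert pm.detect_extent(shifted)[2] == pytest.approx(
            pm.detect_extent(p)[2], rel=1e-12)


class TestPopulation:
    def test_identical_pellets_have_zero_sd(self):
        p, _ = generate_pulse_profile(PulseGenParams(noise_sd_mv=0.0, seed=0))
        profiles = [dataclasses.replace(p, particle_id=f"p{i}") for i in range(100)]
        s = pm.summarize_population(profiles, min_pellets=50)
        assert s["n_pellets"] == 100
        assert s["signal_length_um"][1] == pytest.approx(0.0, abs=1e-9)
        assert s["compactness"][1] == pytest.approx(0.0, abs=1e-9)

    def test_counts_only_pellets(self):
        big, _ = generate_pulse_profile(PulseGenParams(
            pellet_diameter_um=160.0, noise_sd_mv=0.0, seed=0))
        small, _ = generate_pulse_profile(PulseGenParams(
            pellet_diameter_um=50.0, viable_shell_um=10.0,
            dead_core_diameter_um=20.0, noise_sd_mv=0.0, seed=0))
        s = pm.summarize_population([big] * 18 + [small] * 2, min_pellets=10)
        assert s["n_pellets"] == 18
        assert s["n_particles"] == 20

    def test_seeded_population_means_recover_truth(self):
        profiles, truth = pm.generate_pulse_population(n=60, seed=11)
        s = pm.summarize_population(profiles, min_pellets=10)
        assert s["signal_length_um"][0] == pytest.approx(
            truth["diameter_um"].mean(), rel=0.05)

    def test_low_count_flagged(self):
        p, _ = generate_pulse_profile(PulseGenParams(seed=0))
        s = pm.summarize_population([p] * 5, min_pellets=50)
        assert any("low reliability" in w for w in s["warnings"])


class TestProfileIO:
    @pytest.mark.parametrize("fmt", ["jsonl", "csvdir"])
    def test_roundtrip(self, tmp_path, fmt):
        profiles, _ = pm.generate_pulse_population(n=3, seed=9)
        target = tmp_path / ("batch.jsonl" if fmt == "jsonl" else "batch")
        pm.write_profiles(profiles, target, fmt=fmt)
        back = pm.read_profiles(target)
        assert len(back) == 3
        for a, b in zip(profiles, back):
            np.testing.assert_allclose(b.position_um, a.position_um)
            np.testing.assert_allclose(b.fsc_mv, a.fsc_mv)
            assert b.particle_id == a.particle_id
            assert b.saturation_mv == a.saturation_mv


@settings(deadline=None, max_examples=25)
@given(st.floats(1.0, 400.0), st.floats(0.0, 1.0))
def test_viability_factor_stays_in_unit_interval(length, frac):
    vl = frac * length / 2
    assert 0.0 <= pm.viability_factor(vl, length) <= 1.0 + 1e-12
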