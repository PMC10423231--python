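"""Synthetic-data generators: statistical structure, determinism, validation."""

import numpy as np
import pytest

from flimcrowd.decay import InstrumentResponse, convolve_model_with_irf
from flimcrowd.simulate import (
    CondensateSpec,
    DecaySimSpec,
    DiffusingSpecies,
    FcsSimSpec,
    FlimSceneSpec,
    ToyTrajectorySpec,
    generate_calibration_table,
    generate_toy_trajectory,
    simulate_anisotropy_decays,
    simulate_fcs_trajectory,
    simulate_flim_scene,
    simulate_tcspc_decay,
)

from conftest import WINDOW_NS


class TestDecaySimulator:
    def test_mean_arrival_time_single_component(self):
        tau, n = 1.5, 200_000
        spec = DecaySimSpec(
            component_lifetimes=[tau],
            component_amplitudes=[1.0],
            irf_fwhm=0.0,
            irf_t0=0.0,
            n_photons=n,
            seed=1,
        )
        h = simulate_tcspc_decay(spec)
        mean_t = np.sum(h.bin_centers * h.counts) / h.total_photons
        assert abs(mean_t - tau) < 3 * tau / np.sqrt(n)

    def test_default_instrument_constants(self):
        spec = DecaySimSpec(component_lifetimes=[1.5], component_amplitudes=[1.0])
        assert spec.irf_fwhm == 0.1  # 100 ps FWHM pulse
        assert spec.repetition_window == 50.0  # 20 MHz repetition rate

    def test_histogram_matches_analytic_model_chi2(self, irf):
        """1e6-photon bi-exponential realizations against the closed-form
        convolved model: Pearson chi-square per dof ~ 1 on populated bins."""
        chis = []
        for seed in range(3):
            spec = DecaySimSpec(
                component_lifetimes=[0.5, 2.0],
                component_amplitudes=[0.5, 0.5],
                n_photons=1_000_000,
                seed=seed,
            )
            h = simulate_tcspc_decay(spec)
            # simulator amplitudes weight photons: scale each component to
            # unit photon mass before mixing
            model = np.zeros(512)
            for tau, f in [(0.5, 0.5), (2.0, 0.5)]:
                comp = convolve_model_with_irf(
                    [tau], [1.0], irf, h.bin_edges, repetition_window=WINDOW_NS
                )
                model += f * comp / comp.sum()
            expected = model * spec.n_photons
            sel = expected >= 10
            chi2 = np.sum((h.counts[sel] - expected[sel]) ** 2 / expected[sel])
            chis.append(chi2 / sel.sum())
        assert 0.9 < np.mean(chis) < 1.1

    def test_determinism(self):
        spec = DecaySimSpec(
            component_lifetimes=[1.0], component_amplitudes=[1.0], seed=9,
            n_photons=10_000,
        )
        h1, h2 = simulate_tcspc_decay(spec), simulate_tcspc_decay(spec)
        assert np.array_equal(h1.counts, h2.counts)

    @pytest.mark.parametrize(
        "field,kwargs",
        [
            ("component_lifetimes", dict(component_lifetimes=[-1.0])),
            ("repetition_window", dict(repetition_window=0.5)),
            ("n_photons", dict(n_photons=0)),
            ("background_rate", dict(background_rate=-1.0)),
        ],
    )
    def test_validation_names_offending_field(self, field, kwargs):
        base = dict(component_lifetimes=[1.5], component_amplitudes=[1.0])
        base.update(kwargs)
        with pytest.raises(ValueError, match=field):
            DecaySimSpec(**base)


class TestFlimScene:
    def test_zero_budget_empty_stream(self):
        spec = FlimSceneSpec(image_shape=(8, 8), photon_budget=0.0, seed=0)
        stream, truth = simulate_flim_scene(spec)
        assert len(stream) == 0
        assert truth.shape == (8, 8)

    def test_photon_conservation(self):
        spec = FlimSceneSpec(image_shape=(16, 16), photon_budget=50.0, seed=3)
        stream, _ = simulate_flim_scene(spec)
        per_pixel = stream.groupby(["y", "x"]).size().sum()
        assert per_pixel == len(stream)

    def test_overlap_later_condensate_wins(self):
        spec = FlimSceneSpec(
            image_shape=(16, 16),
            condensates=[
                CondensateSpec(center=(8, 8), radius=5, lifetimes=(1.0,)),
                CondensateSpec(center=(8, 8), radius=3, lifetimes=(2.0,)),
            ],
            seed=0,
        )
        truth = spec.ground_truth_map()
        assert truth[8, 8] == 2.0
        assert truth[8, 8 - 4] == 1.0

    def test_out_of_bounds_condensate_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            FlimSceneSpec(
                image_shape=(8, 8),
                condensates=[CondensateSpec(center=(20, 20), radius=2)],
            )

    def test_determinism(self):
        spec = FlimSceneSpec(image_shape=(8, 8), photon_budget=20.0, seed=5)
        s1, _ = simulate_flim_scene(spec)
        s2, _ = simulate_flim_scene(spec)
        assert s1.equals(s2)


class TestFcsSimulator:
    def test_zero_brightness_all_zero(self):
        spec = FcsSimSpec(
            species=[DiffusingSpecies(1.0, 1.0, 0.0)],
            duration=1.0,
            bin_time=1e-3,
            seed=0,
        )
        counts, _ = simulate_fcs_trajectory(spec)
        assert counts.sum() == 0

    def test_ground_truth_diffusion_times(self):
        spec = FcsSimSpec(
            species=[DiffusingSpecies(1.5625, 1.0, 1e4)],
            focus_waists=(0.25, 1.25),
            duration=1.0,
            bin_time=1e-3,
            seed=0,
        )
        np.testing.assert_allclose(spec.diffusion_times, [0.01])

    def test_bleaching_gives_decaying_trend(self):
        from flimcrowd.fcs import IntensityTrajectory, fit_photobleaching

        spec = FcsSimSpec(
            species=[DiffusingSpecies(1.5625, 1.0, 3e4)],
            duration=5.0,
            bin_time=1e-3,
            mean_occupancy=3.0,
            bleach_rate_per_excursion=100.0,
            seed=2,
        )
        counts, _ = simulate_fcs_trajectory(spec)
        bleach = fit_photobleaching(IntensityTrajectory(counts, 1e-3))
        assert bleach.decaying

    def test_invalid_bin_time(self):
        with pytest.raises(ValueError, match="bin_time"):
            FcsSimSpec(
                species=[DiffusingSpecies(1.0, 1.0, 1.0)],
                duration=1.0,
                bin_time=0.0,
            )

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="fractions"):
            FcsSimSpec(
                species=[DiffusingSpecies(1.0, 0.3, 1.0)],
                duration=1.0,
                bin_time=1e-3,
            )


class TestAnisotropySimulator:
    def test_r0_cap_enforced(self):
        with pytest.raises(ValueError, match="0.4"):
            simulate_anisotropy_decays(0.41, [(10.0, 1.0)], lifetime=1.5)

    def test_frozen_rotation_limit_constant_r(self):
        from flimcrowd.anisotropy import anisotropy_decay

        par, perp = simulate_anisotropy_decays(
            0.38, [(np.inf, 1.0)], lifetime=2.0, n_photons=5_000_000, seed=4
        )
        dec = anisotropy_decay(par, perp, min_denominator_counts=200)
        r = dec.r[dec.valid]
        assert abs(np.mean(r) - 0.38) < 0.01
        assert np.std(r[: r.size // 2]) < 0.05

    def test_determinism(self):
        a1 = simulate_anisotropy_decays(0.3, [(5.0, 1.0)], 1.5, seed=2, n_photons=1000)
        a2 = simulate_anisotropy_decays(0.3, [(5.0, 1.0)], 1.5, seed=2, n_photons=1000)
        assert np.array_equal(a1[0].counts, a2[0].counts)
        assert np.array_equal(a1[1].counts, a2[1].counts)


class TestToyTrajectory:
    def test_static_spec_is_constant(self):
        spec = ToyTrajectorySpec(
            n_residues=24,
            n_frames=6,
            pocket_residue_indices=[0, 5, 13, 20],
            pocket_expansion_per_state=(0.0,),
            thermal_noise_sd=0.0,
            seed=0,
        )
        coords, _ = generate_toy_trajectory(spec)
        assert np.all(coords == coords[0])

    def test_expansion_increases_pocket_volume(self):
        from flimcrowd.pocket import PocketDefinition, Trajectory, pocket_volume

        pocket_idx = [0, 1, 2, 13, 14, 15, 25, 26, 27]
        spec = ToyTrajectorySpec(
            n_residues=36,
            n_frames=4,
            pocket_residue_indices=pocket_idx,
            pocket_expansion_per_state=(0.0, 1.0),
            state_sequence=[0, 0, 1, 1],
            thermal_noise_sd=0.0,
            seed=0,
        )
        coords, _ = generate_toy_trajectory(spec)
        traj = Trajectory.from_calpha(coords[0:1])
        pocket = PocketDefinition([], np.array(pocket_idx))
        v_compact = pocket_volume(coords[0], traj.atoms, pocket)
        v_expanded = pocket_volume(coords[2], traj.atoms, pocket)
        assert v_expanded > v_compact > 0

    def test_determinism_bit_identical(self):
        spec = ToyTrajectorySpec(
            n_residues=20, n_frames=5, pocket_residue_indices=[1],
            thermal_noise_sd=0.3, seed=12,
        )
        c1, _ = generate_toy_trajectory(spec)
        c2, _ = generate_toy_trajectory(spec)
        assert c1.tobytes() == c2.tobytes()

    def test_pocket_indices_validated(self):
        with pytest.raises(ValueError, match="pocket_residue_indices"):
            ToyTrajectorySpec(n_residues=5, n_frames=4, pocket_residue_indices=[7])


class TestCalibrationTable:
    def test_noiseless_plateau_below_onset(self):
        tab = generate_calibration_table(
            30.0, 1.45, -0.01, [0, 10, 20, 30, 40, 50], noise_sd=0.0
        )
        below = tab[tab.fvo_percent <= 30]["mean_lifetime_ns"]
        assert np.all(below == 1.45)
        above = tab[tab.fvo_percent > 30]["mean_lifetime_ns"]
        assert np.all(np.diff(above) < 0)

    def test_onset_round_trip(self):
        from flimcrowd.calibration import detect_reduction_onset

        tab = generate_calibration_table(
            30.0, 1.45, -0.01, np.arange(0, 51, 2.5), noise_sd=0.0
        )
        fit = detect_reduction_onset(tab, bootstrap=0)
        assert abs(fit.onset - 30.0) < 0.05

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_calibration_table(30.0, 1.45, -0.01, [0, 10, 20, 30, 40], -0.1)
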