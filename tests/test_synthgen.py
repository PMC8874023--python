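"""Unit and property tests for the surrogate EEG/EOG generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import blinkclean as bc
from blinkclean.config import GeneratorConfig
from blinkclean.synthgen import render_blink_signal, train_val_split


class TestReferenceSpectrum:
    def test_zero_window_gives_zero_coefficients(self):
        spec = bc.derive_reference_spectrum(np.zeros(512), 512)
        assert np.all(spec.coefficients == 0)

    def test_pure_sine_concentrates_energy_in_its_bins(self):
        # oracle: direct DFT summation at every frequency bin
        t = np.arange(512) / 512.0
        window = np.sin(2 * np.pi * 10 * t)
        spec = bc.derive_reference_spectrum(window, 512)
        n = 512
        k = np.arange(n)
        oracle = np.array([np.sum(window * np.exp(-2j * np.pi * kk * np.arange(n) / n))
                           for kk in k])
        assert np.allclose(spec.coefficients, oracle, atol=1e-8)
        power = np.abs(spec.coefficients) ** 2
        in_bins = power[10] + power[n - 10]
        assert in_bins / power.sum() > 0.999

    def test_one_second_window_length(self, gen_config):
        # 512 samples at 512 Hz cover exactly one second
        assert gen_config.window_samples == round(gen_config.sampling_rate)
        with pytest.raises(ValueError, match="512 samples"):
            bc.derive_reference_spectrum(np.zeros(511), 512)

    def test_nonfinite_input_rejected(self):
        bad = np.zeros(512)
        bad[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            bc.derive_reference_spectrum(bad, 512)


class TestPinkReference:
    def test_deterministic_under_fixed_seed(self, gen_config):
        a = bc.pink_reference(gen_config, 42)
        b = bc.pink_reference(gen_config, 42)
        assert np.array_equal(a, b)

    def test_average_log_spectrum_slope_is_negative(self, gen_config):
        # oracle: least-squares slope of the averaged periodogram in log-log
        rng = np.random.default_rng(0)
        psd = np.zeros(257)
        for _ in range(200):
            w = bc.pink_reference(gen_config, rng)
            psd += np.abs(np.fft.rfft(w)) ** 2
        psd /= 200
        f = np.arange(1, 257, dtype=float)
        slope = np.polyfit(np.log(f), np.log(psd[1:]), 1)[0]
        assert slope < -0.5

    def test_statistics_inside_configured_ranges(self, gen_config):
        rng = np.random.default_rng(5)
        for _ in range(50):
            w = bc.pink_reference(gen_config, rng)
            assert 5.0 <= np.std(w) <= 15.0
            assert 45.0 <= np.ptp(w) <= 100.0


class TestCleanWindow:
    def test_zero_jitter_reproduces_reference(self, gen_config):
        config = GeneratorConfig(spectrum_jitter=0.0)
        ref = bc.pink_reference(config, 3)
        spec = bc.derive_reference_spectrum(ref, 512)
        out = bc.generate_clean_window(spec, config, 3)
        assert np.allclose(out, ref, atol=1e-10)

    def test_perturbations_bounded_by_jitter(self, gen_config):
        rng = np.random.default_rng(4)
        ref = bc.pink_reference(gen_config, rng)
        spec = bc.derive_reference_spectrum(ref, 512)
        for _ in range(20):
            info = {}
            bc.generate_clean_window(spec, gen_config, rng, info)
            assert np.max(np.abs(info["perturbations"])) <= gen_config.spectrum_jitter

    def test_hermitian_symmetry_leaves_negligible_imag_residue(self, gen_config):
        # oracle: perturbed coefficient array must invert to a real signal
        from blinkclean.synthgen import perturb_spectrum
        rng = np.random.default_rng(6)
        ref = bc.pink_reference(gen_config, rng)
        spec = bc.derive_reference_spectrum(ref, 512)
        coeff, _ = perturb_spectrum(spec, gen_config, rng)
        residue = np.max(np.abs(np.fft.ifft(coeff).imag))
        assert residue <= 1e-9

    def test_spectrum_length_mismatch_rejected(self, gen_config):
        from blinkclean.recording import ReferenceSpectrum
        bad = ReferenceSpectrum(np.zeros(256, dtype=complex), 512.0)
        with pytest.raises(ValueError, match="does not match"):
            bc.generate_clean_window(bad, gen_config, 1)

    def test_spectral_fidelity_to_reference(self, gen_config):
        # log-amplitude spectra of generated and reference windows correlate
        rng = np.random.default_rng(7)
        for _ in range(25):
            ref = bc.pink_reference(gen_config, rng)
            spec = bc.derive_reference_spectrum(ref, 512)
            gen = bc.generate_clean_window(spec, gen_config, rng)
            la = np.log(np.abs(np.fft.rfft(ref))[1:] + 1e-12)
            lg = np.log(np.abs(np.fft.rfft(gen))[1:] + 1e-12)
            assert np.corrcoef(la, lg)[0, 1] >= 0.9


class TestStitching:
    def test_single_window_identity(self, gen_config):
        w = bc.pink_reference(gen_config, 8)
        assert np.array_equal(bc.stitch_windows([w], gen_config), w)

    def test_empty_list_rejected(self, gen_config):
        with pytest.raises(ValueError, match="at least one"):
            bc.stitch_windows([], gen_config)

    def test_junction_jumps_bounded_and_length_preserved(self, gen_config):
        rng = np.random.default_rng(9)
        windows = [bc.pink_reference(gen_config, rng) for _ in range(50)]
        out = bc.stitch_windows(windows, gen_config)
        assert out.shape == (50 * 512,)
        jumps = np.abs(out[512::512] - out[511:-1:512])
        assert np.max(jumps) <= 7.0 + 1e-9


class TestBlinks:
    def test_zero_amplitude_gives_zero_pulse(self):
        assert np.all(bc.blink_waveform(0.0, 0.3, 512) == 0)

    def test_peak_equals_amplitude_and_pulse_is_symmetric(self):
        # oracle: direct evaluation of the Gaussian-window formula
        pulse = bc.blink_waveform(300.0, 0.3, 512)
        assert pulse.max() == pytest.approx(300.0)
        assert np.argmax(pulse) == (len(pulse) - 1) // 2
        assert np.allclose(pulse, pulse[::-1])
        sigma = 0.15
        t = (np.arange(len(pulse)) - (len(pulse) - 1) // 2) / 512.0
        assert np.allclose(pulse, 300.0 * np.exp(-0.5 * (t / sigma) ** 2))

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            bc.blink_waveform(100.0, 0.0, 512)

    def test_zero_duration_train_is_empty(self, gen_config):
        assert len(bc.sample_blink_train(0.0, gen_config, 1)) == 0

    def test_gaps_and_amplitudes_within_stated_ranges(self, gen_config):
        rng = np.random.default_rng(10)
        for _ in range(50):
            train = bc.sample_blink_train(60.0, gen_config, rng)
            onsets = train.onsets
            gaps = np.diff(np.concatenate([[0.0], onsets]))
            assert np.all(gaps >= 0.5) and np.all(gaps <= 4.0)
            assert np.all(train.amplitudes >= 0.0)
            assert np.all(train.amplitudes <= 650.0)

    def test_mean_event_count_matches_renewal_simulation(self, gen_config):
        # oracle: independent Monte-Carlo renewal simulation of the count
        rng = np.random.default_rng(11)
        counts = [len(bc.sample_blink_train(60.0, gen_config, rng))
                  for _ in range(1000)]
        oracle_rng = np.random.default_rng(99)
        oracle_counts = []
        for _ in range(1000):
            t, n = 0.0, 0
            while True:
                t += oracle_rng.uniform(0.5, 4.0)
                if t >= 60.0:
                    break
                oracle_rng.uniform(0.0, 650.0)
                oracle_rng.uniform(0.2, 0.4)
                n += 1
            oracle_counts.append(n)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - np.mean(oracle_counts)) < 3 * np.sqrt(2) * se


class TestPropagation:
    def test_zero_and_unit_gains(self):
        blink = bc.blink_waveform(200.0, 0.3, 512)
        art = bc.propagate_blinks(blink, np.array([0.0, 1.0]))
        assert np.all(art[0] == 0)
        assert np.array_equal(art[1], blink)

    @given(st.integers(0, 2**32 - 1))
    def test_propagation_is_linear(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 64))
        gains = rng.uniform(-1, 1, size=5)
        left = bc.propagate_blinks(a, gains) + bc.propagate_blinks(b, gains)
        right = bc.propagate_blinks(a + b, gains)
        assert np.allclose(left, right, atol=1e-12)

    def test_gain_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bc.propagate_blinks(np.zeros((2, 3)), np.zeros(2))


class TestRecording:
    def test_contamination_is_strictly_additive(self, gen_config, recording_pair):
        clean, cont, train = recording_pair
        gains = np.array([cont.meta["realized_gains"][c]
                          for c in cont.channel_names])
        blink = render_blink_signal(train, cont.n_samples, 512.0)
        artifact = bc.propagate_blinks(blink, gains)
        assert np.allclose(cont.data - clean.data, artifact, atol=1e-9)
        # subtracting the known artifact recovers the clean recording
        assert np.allclose(cont.data - artifact, clean.data, atol=1e-9)

    def test_reference_row_carries_largest_artifact(self, recording_pair):
        clean, cont, _ = recording_pair
        artifact = cont.data - clean.data
        peak_per_channel = np.abs(artifact).max(axis=1)
        ref_idx = cont.channel_index("Fp1")
        assert np.argmax(peak_per_channel) == ref_idx

    def test_fixed_seed_reproduces_recording(self, gen_config):
        a = bc.generate_recording(5, gen_config, 21)
        b = bc.generate_recording(5, gen_config, 21)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert a[2].events == b[2].events

    def test_non_integral_duration_rejected(self, gen_config):
        with pytest.raises(ValueError, match="whole number"):
            bc.generate_recording(2.5, gen_config, 1)

    def test_stitched_channels_respect_boundary_limit(self, recording_pair):
        clean, _, _ = recording_pair
        for row in clean.data:
            jumps = np.abs(row[512::512] - row[511:-1:512])
            assert np.max(jumps) <= 7.0 + 1e-9


class TestDataset:
    def test_empty_dataset(self, gen_config):
        ds = bc.generate_dataset(0, gen_config, 1)
        assert len(ds) == 0

    def test_structure_and_bookkeeping(self, gen_config):
        ds = bc.generate_dataset(120, gen_config, 13, recording_duration=4.0)
        assert ds.inputs.shape == (120, 512, 2)
        assert ds.targets.shape == (120, 512)
        assert len(ds.train_indices) == 96 and len(ds.val_indices) == 24
        assert set(ds.train_indices) | set(ds.val_indices) == set(range(120))
        # examples cycle over the 15 non-reference electrodes
        assert ds.channel_labels[:15] == [c for c in gen_config.channel_names
                                          if c != "Fp1"]

    def test_examples_reconstruct_from_generator_bookkeeping(self, gen_config):
        # oracle: regenerate the source recording from its recorded seed and
        # verify contaminated - clean = gain x blink trace for every example
        ds = bc.generate_dataset(45, gen_config, 17, recording_duration=3.0)
        seed = ds.meta["recording_seeds"][0]
        clean, cont, train = bc.generate_recording(
            3.0, gen_config, np.random.default_rng(seed))
        blink = render_blink_signal(train, cont.n_samples, 512.0)
        for i in range(45):
            w, ch = divmod(i, 15)
            label = ds.channel_labels[i]
            sl = slice(w * 512, (w + 1) * 512)
            gain = ds.meta["example_gains"][i]
            diff = ds.inputs[i, :, 1] - ds.targets[i]
            assert np.allclose(diff, gain * blink[sl], atol=1e-9)
            assert np.allclose(ds.inputs[i, :, 0], cont.channel("Fp1")[sl])
            assert np.allclose(ds.targets[i], clean.channel(label)[sl])

    def test_default_full_scale_split_bookkeeping(self):
        # the default call is sized at 70,000 windows split 56,000/14,000
        import inspect
        default_n = inspect.signature(bc.generate_dataset).parameters["n_windows"].default
        assert default_n == 70_000
        tr, va = train_val_split(default_n, 0.8, np.random.default_rng(0))
        assert len(tr) == 56_000 and len(va) == 14_000
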