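"""Stimulus-generation contracts: kinematics, ranges, determinism, spectra."""

import numpy as np
import pytest

from msinrf import (InvalidParameterError, StimulusSequence, apply_dog_lgn,
                    apply_optical_blur, compound_grating, contrast_modulated,
                    drifting_grating, masked_grating, moving_bar,
                    random_pattern, square_wave_sequence)
from msinrf.stimuli import StimulusRecipe


class TestMovingBar:
    def test_polarity_swap_inverts_luminance(self):
        white = moving_bar(polarity="white").frames
        black = moving_bar(polarity="black").frames
        np.testing.assert_array_equal(black, 1.0 - white)

    def test_leftward_is_mirror_of_rightward(self):
        right = moving_bar(direction=1).frames
        left = moving_bar(direction=-1).frames
        np.testing.assert_array_equal(left, right[:, :, ::-1])

    def test_kinematics_at_printed_speed(self):
        # 2 deg/s at 120 Hz: 0.2 deg = 40 px accumulated over 12 frames
        seq = moving_bar(speed_deg_s=2.0)
        prof = seq.profile()
        np.testing.assert_array_equal(prof[12], np.roll(prof[0], 40))

    def test_invalid_width(self):
        with pytest.raises(InvalidParameterError):
            moving_bar(width_deg=0.0)


class TestDriftingGrating:
    def test_zero_contrast_is_uniform(self):
        seq = drifting_grating(contrast=0.0)
        np.testing.assert_array_equal(seq.frames, 0.5)

    def test_michelson_contrast(self):
        seq = drifting_grating(contrast=0.4, sf_cpd=2.0)
        prof = seq.profile()[0]
        assert prof.max() - prof.min() == pytest.approx(0.4, abs=1e-4)
        assert prof.mean() == pytest.approx(0.5, abs=1e-3)

    def test_quarter_period_frame_is_cosine_phase(self):
        # at t = 1/(4 f_t) the sine has advanced by pi/2 (a whole frame at 5 Hz)
        tf = 5.0
        seq = drifting_grating(contrast=0.4, sf_cpd=2.0, tf_hz=tf, phase=0.0)
        frame_idx = int(round(120 / (4 * tf)))
        ref = drifting_grating(contrast=0.4, sf_cpd=2.0, tf_hz=tf, phase=-np.pi / 2)
        np.testing.assert_allclose(seq.profile()[frame_idx], ref.profile()[0],
                                   atol=1e-12)

    def test_phase_shift_is_cyclic_translation(self):
        # one spatial period of the 2 c/deg grating is 100 px; shifting the
        # phase by 2*pi*sf*(10 px) translates frames by 10 px
        base = drifting_grating(0.4, 2.0, 4.0, phase=0.0).profile()
        shift_px = 10
        shifted = drifting_grating(
            0.4, 2.0, 4.0, phase=2 * np.pi * 2.0 * shift_px * 0.005
        ).profile()
        np.testing.assert_allclose(shifted[:, : 400 - shift_px],
                                   base[:, shift_px:], atol=1e-9)

    def test_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            drifting_grating(sf_cpd=150.0)


class TestMaskedGrating:
    def test_zero_noise_equals_signal(self):
        masked = masked_grating(2.5, noise_contrast=0.0, seed=0)
        signal = drifting_grating(0.4, 2.5, 10.0)
        np.testing.assert_allclose(masked.frames, signal.frames, atol=1e-12)

    def test_same_seed_same_sequence(self):
        a = masked_grating(5.0, seed=7).frames
        b = masked_grating(5.0, seed=7).frames
        np.testing.assert_array_equal(a, b)

    def test_phase_jitter_block_structure(self):
        # 120 Hz / 10 Hz: the noise phase is held for exactly 12 frames
        seq = masked_grating(5.0, seed=3, signal_contrast=0.0)
        prof = seq.profile()
        for block in range(10):
            np.testing.assert_array_equal(
                prof[12 * block: 12 * (block + 1)],
                np.broadcast_to(prof[12 * block], (12, 400)),
            )
        changed = [not np.array_equal(prof[12 * b], prof[12 * b + 12])
                   for b in range(9)]
        assert any(changed)


class TestRandomPattern:
    def test_zero_speed_is_static(self):
        seq = random_pattern(speed_deg_s=0.0, seed=1)
        np.testing.assert_array_equal(seq.frames, np.broadcast_to(
            seq.frames[0], seq.frames.shape))

    def test_reverse_phi_inverts_odd_frames(self):
        phi = random_pattern(seed=4).profile()
        rphi = random_pattern(reverse_phi=True, seed=4).profile()
        np.testing.assert_array_equal(rphi[0::2], phi[0::2])
        np.testing.assert_array_equal(rphi[1::2], 1.0 - phi[1::2])

    def test_integer_shift_schedule(self):
        # 8.5 deg/s -> 14.1667 px/frame; displacements are rounded cumulative
        seq = random_pattern(seed=2)
        prof = seq.profile()
        for t in (1, 5, 11):
            expect = np.roll(prof[0], round(t * 8.5 / 0.005 / 120))
            np.testing.assert_array_equal(prof[t], expect)

    def test_contrast_levels(self):
        prof = random_pattern(contrast=0.9, seed=0).profile()
        assert set(np.round(np.unique(prof), 6)) == {0.05, 0.95}


class TestSquareWave:
    def test_missing_fundamental_identity(self):
        # at a contrast where Fourier synthesis never clips, the MF stimulus
        # equals the square wave minus its fundamental, frame by frame
        kw = dict(contrast=0.7, phase=0.3)
        sq = square_wave_sequence(**kw).profile()
        mf = square_wave_sequence(missing_fundamental=True, **kw).profile()
        x = np.arange(400) * 0.005
        disp = (1.0 / 1.5 / 4.0) * (np.arange(120) // 8)
        fundamental = (0.7 / 2) * (4 / np.pi) * np.sin(
            2 * np.pi * 1.5 * (x[None, :] - disp[:, None]) + 0.3
        )
        np.testing.assert_allclose(sq - mf, fundamental, atol=1e-9)

    def test_quarter_cycle_jump_blocks(self):
        # 66 ms jumps round to 8 frames at 120 Hz; four jumps close a period
        prof = square_wave_sequence().profile()
        np.testing.assert_array_equal(prof[:8], np.broadcast_to(prof[0], (8, 400)))
        assert not np.array_equal(prof[0], prof[8])
        np.testing.assert_allclose(prof[0], prof[32], atol=1e-9)

    def test_smooth_mode_drifts_continuously(self):
        prof = square_wave_sequence(smooth=True).profile()
        assert not np.array_equal(prof[0], prof[1])

    def test_clipping_fraction_is_recorded_and_small(self):
        seq = square_wave_sequence()
        assert 0 < seq.meta["clipped_fraction"] < 0.02


class TestContrastModulated:
    def test_luminance_range_from_printed_depths(self):
        # local contrast spans [0.06, 0.54] -> luminance within [0.23, 0.77]
        seq = contrast_modulated(seed=0)
        assert seq.frames.min() >= 0.5 - 0.54 / 2 - 1e-9
        assert seq.frames.max() <= 0.5 + 0.54 / 2 + 1e-9

    def test_time_averaged_luminance_near_mean(self):
        seq = contrast_modulated(seed=1)
        pixel_means = seq.profile().mean(axis=0)
        assert np.abs(pixel_means - 0.5).max() < 0.08  # Monte-Carlo tolerance

    def test_envelope_bound_validated(self):
        with pytest.raises(InvalidParameterError):
            contrast_modulated(depth=0.6, env_contrast=0.8)

    def test_no_net_directional_energy(self):
        # seed-averaged x-t amplitude spectrum is mirror-symmetric in temporal
        # frequency: leftward and rightward luminance energy balance out
        def directional_imbalance(profiles):
            spec = np.zeros((120, 400))
            for prof in profiles:
                spec += np.abs(np.fft.fft2(prof - prof.mean()))
            half_t, half_x = 60, 200
            right = spec[1:half_t, 1:half_x].sum() + spec[half_t + 1:, half_x + 1:].sum()
            left = spec[1:half_t, half_x + 1:].sum() + spec[half_t + 1:, 1:half_x].sum()
            return abs(right - left) / (right + left)

        second_order = [contrast_modulated(seed=s).profile() for s in range(12)]
        assert directional_imbalance(second_order) < 0.05
        # sanity contrast: a luminance grating is strongly directional
        first_order = [drifting_grating(0.4, 2.0, 4.0).profile()]
        assert directional_imbalance(first_order) > 0.5


class TestCompoundGrating:
    def test_zero_second_component_is_single_grating(self):
        comp = compound_grating(2.0, 4.0, 8.5, 1.0, c_each=(0.4, 0.0))
        single = drifting_grating(0.4, 2.0, 4.0)
        np.testing.assert_allclose(comp.frames, single.frames, atol=1e-12)

    def test_component_order_commutes(self):
        a = compound_grating(2.0, 4.0, 8.5, 1.0, 0.4)
        b = compound_grating(8.5, 1.0, 2.0, 4.0, 0.4)
        np.testing.assert_allclose(a.frames, b.frames, atol=1e-12)
        # peak modulation bounded by the component sum (0.8 at c_each = 0.4)
        assert np.abs(a.frames - 0.5).max() <= 0.8 + 1e-9

    def test_overrange_rejected(self):
        with pytest.raises(InvalidParameterError):
            compound_grating(2.0, 4.0, c_each=0.6)


class TestPreFilters:
    def test_dog_uniform_gain(self):
        seq = StimulusSequence(np.full((8, 64, 64), 0.6))
        out = apply_dog_lgn(seq)
        np.testing.assert_allclose(out.frames, 0.6 * (1 - 1 / 5), rtol=1e-7)

    def test_dog_linearity(self, rng):
        a = StimulusSequence(rng.random((7, 64, 64)))
        b = StimulusSequence(rng.random((7, 64, 64)))
        mix = StimulusSequence(0.3 * a.frames + 0.7 * b.frames)
        direct = apply_dog_lgn(mix).frames
        combined = 0.3 * apply_dog_lgn(a).frames + 0.7 * apply_dog_lgn(b).frames
        np.testing.assert_allclose(direct, combined, atol=1e-12)

    def test_dog_isotropy(self):
        # a radial pattern rotated by 90 deg commutes with the filter
        y, x = np.mgrid[:65, :65] - 32
        blob = np.exp(-((x - 8) ** 2 + y**2) / 50.0)
        seq = StimulusSequence(blob[None, :, :] * np.ones((3, 1, 1)))
        rot = StimulusSequence(np.rot90(seq.frames, axes=(1, 2)).copy())
        out = apply_dog_lgn(seq).frames
        out_rot = apply_dog_lgn(rot).frames
        np.testing.assert_allclose(np.rot90(out, axes=(1, 2)), out_rot, atol=1e-12)

    def test_dog_fast_path_matches_full(self, rng):
        prof = rng.random((6, 64))
        fast = StimulusSequence(np.broadcast_to(prof[:, None, :], (6, 64, 64)))
        full = StimulusSequence(fast.frames.copy())
        np.testing.assert_allclose(apply_dog_lgn(fast).frames,
                                   apply_dog_lgn(full).frames, atol=1e-10)

    def test_blur_identity_and_smoothing(self, rng):
        seq = StimulusSequence(rng.random((3, 64, 64)))
        assert apply_optical_blur(seq, 0.0) is seq
        blurred = apply_optical_blur(seq, 0.02)
        assert blurred.frames.mean() == pytest.approx(seq.frames.mean(), abs=1e-6)
        assert blurred.frames.var() < seq.frames.var()


class TestSequenceContract:
    def test_defaults(self):
        seq = drifting_grating()
        assert seq.shape == (120, 400, 400)
        assert seq.fps == 120.0 and seq.deg_per_px == pytest.approx(0.005)

    def test_out_of_range_luminance_rejected(self):
        with pytest.raises(InvalidParameterError):
            StimulusSequence(np.full((3, 8, 8), 1.5))

    def test_custom_recipe_geometry(self):
        recipe = StimulusRecipe("g", {}, fps=60.0, duration_s=0.5, size_px=128,
                                deg_per_px=0.01)
        seq = drifting_grating(0.4, 2.0, 4.0, recipe=recipe)
        assert seq.shape == (30, 128, 128)
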