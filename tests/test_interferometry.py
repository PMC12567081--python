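"""Off-axis recording and Fourier-sideband demodulation."""

import numpy as np
import pytest

from jtez.interferometry import (
    DemodulationError,
    InterferogramSet,
    demodulate,
    estimate_carrier,
    rephase,
    synthesize,
)

GRID = (96, 96)


def identity_field(shape=GRID):
    return np.broadcast_to(np.eye(2, dtype=complex), shape + (2, 2)).copy()


class TestSynthesize:
    def test_two_beam_fringe_closed_form(self):
        r = 2.0
        igs = synthesize(identity_field(), carrier=(0.2, 0.2), reference_amplitude=r, bit_depth=None)
        a = np.arange(GRID[0])[:, None]
        b = np.arange(GRID[1])[None, :]
        expected = 1 + r**2 / 2 + np.sqrt(2) * r * np.cos(2 * np.pi * 0.2 * (a + b))
        np.testing.assert_allclose(igs.images[(0, 0)], expected, atol=1e-10)

    def test_zero_reference_is_fringe_free(self):
        igs = synthesize(identity_field(), reference_amplitude=0.0, bit_depth=None)
        np.testing.assert_allclose(igs.images[(0, 0)], 1.0, atol=1e-12)
        np.testing.assert_allclose(igs.images[(0, 90)], 0.0, atol=1e-12)

    def test_cross_channel_sees_only_reference(self):
        r = 2.0
        igs = synthesize(identity_field(), reference_amplitude=r, bit_depth=None)
        np.testing.assert_allclose(igs.images[(0, 90)], r**2 / 2, atol=1e-10)

    def test_carrier_beyond_nyquist(self):
        with pytest.raises(ValueError):
            synthesize(identity_field(), carrier=(0.6, 0.2))

    def test_quantization_bounded(self):
        igs = synthesize(identity_field(), bit_depth=16)
        for im in igs.images.values():
            assert im.dtype == np.uint16

    def test_intensities_validated(self):
        igs = synthesize(identity_field(), bit_depth=None)
        bad = {k: v.copy() for k, v in igs.images.items()}
        bad[(0, 0)][0, 0] = -1.0
        with pytest.raises(ValueError):
            InterferogramSet(images=bad, carrier=igs.carrier, reference_amplitude=2.0, bit_depth=None)


class TestDemodulate:
    def test_identity_round_trip(self):
        igs = synthesize(identity_field(), bit_depth=None)
        rec = demodulate(igs)
        err = np.abs(rec.w - identity_field())[rec.mask]
        assert np.sqrt(np.mean(err**2)) < 0.01

    def test_phantom_round_trip(self, single_layer):
        jones, _ = single_layer
        rec = demodulate(synthesize(jones, bit_depth=None))
        m = rec.mask
        rel = np.sqrt(np.mean(np.abs(rec.w - jones)[m] ** 2)) / np.sqrt(np.mean(np.abs(jones[m]) ** 2))
        assert rel < 0.02

    def test_all_zero_images_fail(self):
        zeros = {(s, o): np.zeros(GRID) for s in (0, 90) for o in (0, 90)}
        igs = InterferogramSet(images=zeros, carrier=(0.2, 0.2), reference_amplitude=2.0, bit_depth=None)
        with pytest.raises(DemodulationError):
            demodulate(igs)

    def test_estimate_carrier_finds_peak(self):
        igs = synthesize(identity_field(), carrier=(0.2, 0.15), bit_depth=None)
        u, v = estimate_carrier(igs.images[(0, 0)])
        assert abs(u - 0.2) < 0.02 and abs(v - 0.15) < 0.02

    def test_missing_carrier_metadata_estimated(self):
        from dataclasses import replace

        igs = synthesize(identity_field(), carrier=(0.25, 0.25), bit_depth=None)
        rec = demodulate(replace(igs, carrier=None))
        assert abs(rec.carrier[0] - 0.25) < 0.02
        err = np.abs(np.abs(rec.w[..., 0, 0]) - 1.0)[rec.mask]
        assert np.sqrt(np.mean(err**2)) < 0.02

    def test_sideband_power_parseval_bound(self):
        igs = synthesize(identity_field(), bit_depth=None)
        I = igs.intensity((0, 0))
        F = np.fft.fft2(I)
        fu = np.fft.fftfreq(I.shape[0])[:, None]
        fv = np.fft.fftfreq(I.shape[1])[None, :]
        keep = (np.abs(fu - 0.2) <= 0.1) & (np.abs(fv - 0.2) <= 0.1)
        assert np.sum(np.abs(F[keep]) ** 2) <= np.sum(np.abs(F) ** 2)

    def test_noise_degrades_monotonically(self, single_layer):
        jones, _ = single_layer
        rmse = []
        for sd in (0.0, 0.01, 0.05):
            rec = demodulate(synthesize(jones, bit_depth=None, noise_sd=sd, seed=5))
            rmse.append(np.sqrt(np.mean(np.abs(rec.w - jones)[rec.mask] ** 2)))
        assert rmse[0] < rmse[1] < rmse[2]


class TestRephase:
    def test_idempotent(self, single_layer):
        jones, _ = single_layer
        rec = demodulate(synthesize(jones, bit_depth=None))
        once = rephase(rec)
        twice = rephase(once)
        np.testing.assert_allclose(twice.w, once.w, atol=1e-12)

    def test_restores_global_piston(self, single_layer):
        jones, _ = single_layer
        rec = rephase(demodulate(synthesize(jones, bit_depth=None)))
        shifted = rec.copy()
        shifted.w = shifted.w * np.exp(1j * np.pi / 3)
        back = rephase(shifted)
        np.testing.assert_allclose(back.w, rec.w, atol=1e-10)

    def test_relative_component_phases_preserved(self, single_layer):
        jones, _ = single_layer
        rec = demodulate(synthesize(jones, bit_depth=None))
        out = rephase(rec)
        m = rec.mask & (np.abs(rec.w[..., 1, 0]) > 0.05) & (np.abs(rec.w[..., 0, 0]) > 0.05)
        before = np.angle(rec.w[..., 1, 0][m] / rec.w[..., 0, 0][m])
        after = np.angle(out.w[..., 1, 0][m] / out.w[..., 0, 0][m])
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_w11_anchor_available(self, single_layer):
        jones, _ = single_layer
        rec = demodulate(synthesize(jones, bit_depth=None))
        out = rephase(rec, anchor="w11")
        assert abs(np.angle(out.w[..., 0, 0][out.mask].mean())) < 1e-10

    def test_empty_mask_rejected(self):
        rec = demodulate(synthesize(identity_field(), bit_depth=None))
        rec.mask[:] = False
        with pytest.raises(ValueError):
            rephase(rec)
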