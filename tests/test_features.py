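"""Feature bank: DoG size tuning, steerable energies, opponency,
competition and pooling."""

import numpy as np
import pytest

from scsaliency.features import (DEFAULT_SPEEDS, ORIENTATIONS, ScaleSpace,
                                 competition_operator, dog_disk_response,
                                 eccentricity_size_law, make_dog, opponent_motion,
                                 pool_activation_field, preferred_disk_size,
                                 spatiotemporal_energy)
from scsaliency.steerable import SteerableBank, direction_vector


class TestSizeLaw:
    @pytest.mark.parametrize("R,S", [(0.0, 0.75), (40.0, 5.0), (20.0, 2.875)])
    def test_anchors_and_midpoint(self, R, S):
        assert eccentricity_size_law(R) == pytest.approx(S)


class TestDoG:
    def test_ratio_exact(self):
        spec = make_dog(2.0, 6.7)
        assert spec.sigma_s / spec.sigma_c == pytest.approx(6.7)

    def test_uniform_field_zero(self):
        spec = make_dog(1.5, 6.7)
        ss = ScaleSpace(np.full((64, 64), 0.8))
        v = (ss.sample([32.0], [32.0], [spec.sigma_c * 4])
             - ss.sample([32.0], [32.0], [spec.sigma_s * 4]))[0]
        assert abs(v) < 1e-9

    @pytest.mark.parametrize("S,K", [(1.0, 6.7), (3.0, 3.2)])
    def test_disk_sweep_peaks_at_S(self, S, K):
        # the defining property of the size equations: the numerical
        # argmax over disk diameters recovers S
        spec = make_dog(S, K)
        assert preferred_disk_size(spec) == pytest.approx(S, rel=0.05)

    def test_analytic_response_argmax(self):
        spec = make_dog(2.5, 6.7)
        d = np.linspace(0.3, 10.0, 400)
        r = [spec.disk_response(x) for x in d]
        assert d[int(np.argmax(r))] == pytest.approx(2.5, rel=0.02)

    def test_size_tuning_prefers_matched_disk(self):
        spec = make_dog(2.0, 6.7)
        assert dog_disk_response(spec, 2.0) > dog_disk_response(spec, 6.0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_dog(-1.0, 6.7)
        with pytest.raises(ValueError):
            make_dog(1.0, 0.9)


def _grating_stack(theta_deg, v_px, n=9, size=64, sf=0.15, phase=0.0):
    t = np.arange(n)[:, None, None]
    y, x = np.mgrid[0:size, 0:size]
    th = np.deg2rad(theta_deg)
    return np.cos(2 * np.pi * sf * (x * np.cos(th) + y * np.sin(th) - v_px * t) + phase)


class TestSpatiotemporal:
    def test_static_uniform_all_zero(self):
        en = spatiotemporal_energy(np.full((9, 32, 32), 0.5))
        c = 16
        for m in en.orientation.values():
            assert m[c, c] == pytest.approx(0.0, abs=1e-6)
        assert en.flicker[c, c] == pytest.approx(0.0, abs=1e-6)

    def test_static_grating_orientation_selective(self):
        en = spatiotemporal_energy(_grating_stack(45.0, 0.0))
        c = 32
        assert en.orientation[(45.0, 0)][c, c] > 5 * en.orientation[(135.0, 0)][c, c]
        # motion maps stay small for a static pattern
        assert en.motion_fwd[(4.0, 45.0, 0)][c, c] < en.orientation[(45.0, 0)][c, c]

    def test_drifting_grating_direction_selective(self):
        en = spatiotemporal_energy(_grating_stack(0.0, 2.0))
        c = 32
        fwd = en.motion_fwd[(1.0, 0.0, 0)][c, c]
        bwd = en.motion_bwd[(1.0, 0.0, 0)][c, c]
        assert fwd > 2 * bwd

    def test_counts(self):
        en = spatiotemporal_energy(_grating_stack(0.0, 1.0))
        assert len(en.orientation) == 8          # 4 orientations x 2 scales
        assert len(en.motion_fwd) == 24          # 3 speeds x 4 orientations x 2 scales
        assert len(en.motion_bwd) == 24
        opp = opponent_motion(en.motion_fwd, en.motion_bwd)
        assert len(opp) == 48

    def test_underfull_buffer_rejected(self):
        with pytest.raises(ValueError):
            spatiotemporal_energy(np.zeros((5, 16, 16)))


class TestOpponentMotion:
    def test_cancellation(self):
        m = {("a",): np.full((4, 4), 2.0)}
        opp = opponent_motion(m, {("a",): np.full((4, 4), 2.0)})
        assert np.allclose(opp[("a", "pos")], 0.0)
        assert np.allclose(opp[("a", "neg")], 0.0)

    def test_rectified_one_sided(self):
        fwd = {("a",): np.full((2, 2), 3.0)}
        bwd = {("a",): np.full((2, 2), 1.0)}
        opp = opponent_motion(fwd, bwd)
        assert np.allclose(opp[("a", "pos")], 2.0)
        assert np.allclose(opp[("a", "neg")], 0.0)


class TestCompetition:
    def test_zero_map_fixed(self):
        assert np.allclose(competition_operator(np.zeros((50, 50))), 0.0)

    def test_isolated_peak_survives_in_place(self):
        m = np.zeros((80, 80))
        m[40, 40] = 1.0
        out = competition_operator(m)
        assert out.min() >= 0.0
        assert np.unravel_index(out.argmax(), out.shape) == (40, 40)
        assert out[40, 40] > 0.5

    def test_many_equal_peaks_suppressed_vs_single(self):
        single = np.zeros((90, 90))
        single[45, 45] = 1.0
        many = np.zeros((90, 90))
        many[10::12, 10::12] = 1.0
        out_s = competition_operator(single)
        out_m = competition_operator(many)
        assert out_m.max() < out_s.max()

    def test_output_nonnegative(self, rng):
        out = competition_operator(rng.random((60, 60)))
        assert out.min() >= 0.0


class TestPooling:
    def test_impulse_disc_footprint(self):
        m = np.zeros((21, 21))
        m[10, 10] = 1.0
        out = pool_activation_field(m, radius=3)
        yy, xx = np.mgrid[-10:11, -10:11]
        disc = (yy**2 + xx**2 <= 9)
        assert np.array_equal(out > 0, disc)

    def test_uniform_times_count(self):
        out = pool_activation_field(np.ones((30, 30)), radius=3)
        n_disc = int((np.hypot(*np.mgrid[-3:4, -3:4]) <= 3).sum())
        assert out[15, 15] == pytest.approx(n_disc)


class TestDoubleOpponency:
    def test_sign_swap_invariance(self):
        # |DoG| responds equally to red-on-green and green-on-red
        y, x = np.mgrid[0:64, 0:64]
        disk = (np.hypot(y - 32, x - 32) < 6).astype(float)
        plane = disk - 0.5 * (1 - disk)   # centre +, surround -
        spec = make_dog(2.0, 6.7)
        def resp(img):
            ss = ScaleSpace(img)
            return abs((ss.sample([32.0], [32.0], [spec.sigma_c * 4])
                        - ss.sample([32.0], [32.0], [spec.sigma_s * 4]))[0])
        assert resp(plane) == pytest.approx(resp(-plane), rel=1e-9)
        assert resp(plane) > 0.01


class TestSteerableQuadrature:
    def test_phase_invariance(self):
        bank = SteerableBank()
        w = direction_vector(0.0, 2.0, bank.sigma_x, bank.sigma_t)
        es = [bank.energy(bank.basis(_grating_stack(0.0, 2.0, phase=p)), w)[32, 32]
              for p in np.linspace(0, np.pi, 5)]
        assert max(es) < 1.6 * min(es)

    def test_energy_rotation_consistency(self):
        # steering is exact: energy for a 45 deg grating measured by the
        # 45 deg-steered filter matches the 0 deg case by symmetry
        bank = SteerableBank()
        e0 = bank.energy(bank.basis(_grating_stack(0.0, 0.0)),
                         direction_vector(0.0, 0.0, bank.sigma_x, bank.sigma_t))[32, 32]
        e90 = bank.energy(bank.basis(_grating_stack(90.0, 0.0)),
                          direction_vector(90.0, 0.0, bank.sigma_x, bank.sigma_t))[32, 32]
        assert e0 == pytest.approx(e90, rel=0.05)
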