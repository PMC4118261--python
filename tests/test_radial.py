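import numpy as np
import pytest

from lungfavc import (
    BinaryRegion,
    GridError,
    TransformCenter,
    cp_ratio,
    fractional_radius,
    radial_register,
    shell_decomposition,
    transform_center,
)
from lungfavc.favc import FAVCMap
from lungfavc.radial import ShellProfile, _fractional_radii

from conftest import digital_ball


def ball_center(ball):
    env, c = ball
    return TransformCenter((float(c),) * 3, (c,) * 3, float(c))


class TestTransformCenter:
    def _envelope_with_row(self, x_extent=(5, 41), hy=20, hz=30):
        m = np.zeros((50, 40, 60), dtype=bool)
        m[x_extent[0]:x_extent[1], 10:30, 10:50] = True
        return BinaryRegion(m, (1.0,) * 3)

    def test_midpoint_between_hilum_and_lateral_edge(self):
        env = self._envelope_with_row()
        c = transform_center(env, (10, 20, 30), lateral_sign=+1)
        assert c.p_x == 40.0
        assert c.o == (25.0, 20.0, 30.0)

    def test_hilum_on_edge_degenerates_to_hilum(self):
        env = self._envelope_with_row()
        c = transform_center(env, (40, 20, 30), lateral_sign=+1)
        assert c.o == (40.0, 20.0, 30.0)

    def test_y_z_copy_hilum_regardless_of_edge(self):
        env = self._envelope_with_row()
        for sign in (-1, +1):
            c = transform_center(env, (10, 20, 30), lateral_sign=sign)
            assert c.o[1] == 20.0 and c.o[2] == 30.0

    def test_lateral_sign_selects_edge(self):
        env = self._envelope_with_row()
        c = transform_center(env, (10, 20, 30), lateral_sign=-1)
        assert c.p_x == 5.0

    def test_no_envelope_on_ray_raises(self):
        env = self._envelope_with_row()
        with pytest.raises(GridError):
            transform_center(env, (10, 2, 2), lateral_sign=+1)

    def test_literal_mode(self):
        env = self._envelope_with_row()
        c = transform_center(env, (10, 20, 30), lateral_sign=+1, literal=True)
        assert c.o[0] == 10 + 40.0 / 2


class TestFractionalRadius:
    def test_zero_at_center(self, ball20):
        env, c = ball20
        assert fractional_radius(env, (float(c),) * 3, (c, c, c)) == 0.0

    @pytest.mark.parametrize("offset, expected", [(20, 1.0), (10, 0.5)])
    def test_axis_points_on_digital_ball(self, ball20, offset, expected):
        env, c = ball20
        f = fractional_radius(env, (float(c),) * 3, (c + offset, c, c))
        assert f == pytest.approx(expected, abs=0.05)

    def test_monotone_along_ray(self, ball20):
        env, c = ball20
        o = np.array([float(c)] * 3)
        direction = np.array([2.0, 1.0, 1.0])
        direction /= np.linalg.norm(direction)
        pts = o[None, :] + direction[None, :] * np.linspace(1, 19, 10)[:, None]
        f = _fractional_radii(env.mask, o, pts)
        assert np.all(np.diff(f) >= -1e-12)

    def test_center_outside_envelope_rejected(self, ball20):
        env, c = ball20
        with pytest.raises(GridError):
            fractional_radius(env, (0.0, 0.0, 0.0), (c, c, c))


class TestShells:
    def test_uniform_ball_shell_fractions(self, ball20):
        env, c = ball20
        fm = FAVCMap(np.full(env.mask.shape, 0.68), (1.0,) * 3)
        prof = shell_decomposition(fm, env, (c, c, c), 10)
        frac = prof.counts / env.count
        analytic = np.array(
            [(i / 10) ** 3 - ((i - 1) / 10) ** 3 for i in range(1, 11)]
        )
        assert np.abs(frac - analytic).max() < 0.02
        assert frac[-1] == pytest.approx(0.271, abs=0.02)

    def test_constant_favc_in_every_shell(self, ball20):
        env, c = ball20
        fm = FAVCMap(np.full(env.mask.shape, 0.42), (1.0,) * 3)
        prof = shell_decomposition(fm, env, (c, c, c), 10)
        nonempty = prof.counts > 0
        np.testing.assert_allclose(prof.mean_favc[nonempty], 0.42)

    def test_shells_partition_envelope_and_conserve_air(self, ball20):
        env, c = ball20
        rng = np.random.default_rng(0)
        vals = np.where(env.mask, rng.uniform(0.3, 0.9, env.mask.shape), 0.0)
        fm = FAVCMap(vals, (1.0,) * 3)
        prof = shell_decomposition(fm, env, (c, c, c), 10)
        assert prof.counts.sum() == env.count
        direct = vals[env.mask].sum() * fm.voxel_volume_ml
        assert prof.total_air_ml == pytest.approx(direct, rel=1e-9)

    def test_too_few_shells_rejected(self, ball20):
        env, c = ball20
        fm = FAVCMap(np.zeros(env.mask.shape), (1.0,) * 3)
        with pytest.raises(GridError):
            shell_decomposition(fm, env, (c, c, c), 1)


class TestCpRatio:
    def test_equal_shells_give_unity(self):
        prof = ShellProfile(np.ones(10), np.ones(10), np.ones(10, int))
        assert cp_ratio(prof) == 1.0

    def test_direct_sum(self):
        v = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2], float)
        prof = ShellProfile(v, v, np.ones(10, int))
        assert cp_ratio(prof) == 0.5

    def test_centered_uniform_ball_is_one_seventh(self, ball20):
        env, c = ball20
        fm = FAVCMap(np.full(env.mask.shape, 1.0), (1.0,) * 3)
        prof = shell_decomposition(fm, env, (c, c, c), 10)
        assert cp_ratio(prof) == pytest.approx(1 / 7, abs=0.01)

    def test_zero_peripheral_volume_rejected(self):
        v = np.array([1.0] * 5 + [0.0] * 5)
        prof = ShellProfile(v, v, np.ones(10, int))
        with pytest.raises(GridError):
            cp_ratio(prof)


class TestRegistration:
    def test_identity_when_subject_equals_template(self, ball20):
        env, c = ball20
        tc = ball_center(ball20)
        rng = np.random.default_rng(1)
        vals = np.where(env.mask, rng.uniform(0.2, 0.9, env.mask.shape), 0.0)
        fm = FAVCMap(vals, (1.0,) * 3)
        reg, flags = radial_register(fm, env, tc, env, tc)
        np.testing.assert_array_equal(reg.values[env.mask], vals[env.mask])
        assert flags.sum() == 0

    def test_constant_subject_maps_to_constant(self, ball20):
        env, c = ball20
        small = digital_ball(10, n=25)
        fm = FAVCMap(np.full(small[0].mask.shape, 0.57), (1.0,) * 3)
        reg, _ = radial_register(
            fm, small[0], ball_center(small), env, ball_center(ball20)
        )
        np.testing.assert_allclose(reg.values[env.mask], 0.57)

    def test_value_multiset_preserved(self, ball20):
        env, c = ball20
        small_env, cs = digital_ball(10, n=25)
        rng = np.random.default_rng(2)
        vals = np.where(small_env.mask,
                        rng.uniform(0.2, 0.9, small_env.mask.shape), 0.0)
        fm = FAVCMap(vals, (1.0,) * 3)
        reg, _ = radial_register(
            fm, small_env, ball_center((small_env, cs)),
            env, ball_center(ball20),
        )
        subject_values = set(vals[small_env.mask])
        assert set(reg.values[env.mask]) <= subject_values

    def test_radial_gradient_transfers_by_fractional_radius(self, ball20):
        env, c = ball20
        small_env, cs = digital_ball(10, n=25)
        idx = np.indices(small_env.mask.shape)
        r = np.sqrt(sum((idx[i] - cs) ** 2 for i in range(3))) / 10.0
        vals = np.where(small_env.mask, 0.5 + 0.3 * np.clip(r, 0, 1), 0.0)
        fm = FAVCMap(vals, (1.0,) * 3)
        reg, _ = radial_register(
            fm, small_env, ball_center((small_env, cs)),
            env, ball_center(ball20),
        )
        pts = np.argwhere(env.mask)
        f_t = _fractional_radii(env.mask, np.array([float(c)] * 3), pts)
        expected = 0.5 + 0.3 * np.clip(f_t, 0, 1)
        rms = np.sqrt(np.mean((reg.values[tuple(pts.T)] - expected) ** 2))
        assert rms < 0.02

    def test_empty_envelope_rejected(self, ball20):
        env, c = ball20
        empty = BinaryRegion(np.zeros(env.mask.shape, bool), (1.0,) * 3)
        fm = FAVCMap(np.zeros(env.mask.shape), (1.0,) * 3)
        tc = ball_center(ball20)
        with pytest.raises(GridError):
            radial_register(fm, empty, tc, env, tc)
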