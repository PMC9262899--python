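"""Hill-type musculotendon model: curves, equilibrium, affine MTU force."""

import numpy as np
import pytest

from coordsim.hill import (
    DEFAULT_CURVES,
    CurveSet,
    MusculotendonParams,
    eval_curves,
    mtu_force,
    pennation,
    rigid_tendon_fiber,
    solve_fiber_equilibrium,
)

MUSCLE = MusculotendonParams("test", f_o_m=1000.0, l_o_m=0.10, l_s_t=0.25,
                             alpha_o=0.2)
PENNATELESS = MusculotendonParams("flat", f_o_m=500.0, l_o_m=0.08, l_s_t=0.20,
                                  alpha_o=0.0)


class TestCurves:
    def test_characteristic_points(self):
        f_l, f_pe, f_t = eval_curves(DEFAULT_CURVES, 1.0, 1.0)
        assert f_l == pytest.approx(1.0)
        assert f_t == 0.0
        f_l, f_pe, _ = eval_curves(DEFAULT_CURVES, 0.9, 1.01)
        assert f_pe == 0.0

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            eval_curves(DEFAULT_CURVES, 0.0, 1.0)
        with pytest.raises(ValueError):
            eval_curves(DEFAULT_CURVES, 1.0, -0.5)

    def test_tendon_curve_shape(self):
        x = np.linspace(0.8, 1.1, 200)
        f = DEFAULT_CURVES.tendon_fl(x)
        assert np.all(f[x <= 1.0] == 0.0)
        above = f[x > 1.0001]
        assert np.all(np.diff(above) > 0)  # strictly increasing past slack
        # carries one F_o at the nominal strain
        assert DEFAULT_CURVES.tendon_fl(
            1.0 + DEFAULT_CURVES.tendon_strain_at_fom
        ) == pytest.approx(1.0)

    def test_active_curve_peaks_at_optimal(self):
        x = np.linspace(0.4, 1.6, 300)
        f = DEFAULT_CURVES.active_fl(x)
        assert np.all(f >= 0)
        assert np.argmax(f) == np.argmin(np.abs(x - 1.0))

    def test_passive_curve_nondecreasing(self):
        x = np.linspace(0.7, 1.7, 200)
        f = DEFAULT_CURVES.passive_fl(x)
        assert np.all(f[x <= 1.0] == 0.0)
        assert np.all(np.diff(f) >= 0)


class TestEquilibrium:
    def test_zero_force_configuration(self):
        l_mtu = MUSCLE.l_s_t + MUSCLE.l_o_m * np.cos(MUSCLE.alpha_o)
        fs = solve_fiber_equilibrium(MUSCLE, DEFAULT_CURVES, 0.0, l_mtu)
        assert fs.l_m == pytest.approx(MUSCLE.l_o_m, rel=1e-9)
        assert abs(fs.equilibrium_residual) < 1e-8 * MUSCLE.f_o_m

    @pytest.mark.parametrize("a_prev", [0.0, 0.2, 0.5, 1.0])
    @pytest.mark.parametrize("stretch", [0.995, 1.0, 1.02, 1.05])
    def test_residual_oracle(self, a_prev, stretch):
        """Plugging the returned fiber length back into the equilibrium
        equation gives a residual below 1e-8 of maximal isometric force."""
        for p in (MUSCLE, PENNATELESS):
            l_mtu = (p.l_s_t + p.l_o_m * np.cos(p.alpha_o)) * stretch
            fs = solve_fiber_equilibrium(p, DEFAULT_CURVES, a_prev, l_mtu)
            alpha = pennation(p, fs.l_m)
            f_l, f_pe, f_t = eval_curves(
                DEFAULT_CURVES, fs.l_m / p.l_o_m, fs.l_t / p.l_s_t
            )
            resid = p.f_o_m * (-f_t + (a_prev * f_l + f_pe) * np.cos(alpha))
            assert abs(resid) < 1e-8 * p.f_o_m
            assert fs.l_m * np.cos(fs.alpha) + fs.l_t == pytest.approx(l_mtu)

    def test_stiff_tendon_limit_matches_rigid(self):
        """As tendon stiffness grows, the compliant solution approaches the
        rigid-tendon fiber length (within 1% at 100x nominal stiffness)."""
        stiff = CurveSet(tendon_strain_at_fom=0.049 / 100.0)
        l_mtu = MUSCLE.l_s_t + MUSCLE.l_o_m * np.cos(MUSCLE.alpha_o) * 1.03
        rigid = rigid_tendon_fiber(MUSCLE, l_mtu)
        compliant = solve_fiber_equilibrium(MUSCLE, stiff, 0.7, l_mtu)
        assert compliant.l_m == pytest.approx(rigid.l_m, rel=0.01)
        # and stiffer is closer than the nominal tendon
        nominal = solve_fiber_equilibrium(MUSCLE, DEFAULT_CURVES, 0.7, l_mtu)
        assert abs(compliant.l_m - rigid.l_m) < abs(nominal.l_m - rigid.l_m)

    def test_tendon_force_monotone_in_activation(self):
        l_mtu = MUSCLE.l_s_t + MUSCLE.l_o_m * np.cos(MUSCLE.alpha_o) * 1.01
        forces = []
        for a in np.linspace(0, 1, 11):
            fs = solve_fiber_equilibrium(MUSCLE, DEFAULT_CURVES, a, l_mtu)
            forces.append(
                MUSCLE.f_o_m * DEFAULT_CURVES.tendon_fl(fs.l_t / MUSCLE.l_s_t)
            )
        assert np.all(np.diff(forces) >= -1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_fiber_equilibrium(MUSCLE, DEFAULT_CURVES, 1.5, 0.36)
        with pytest.raises(ValueError):
            solve_fiber_equilibrium(MUSCLE, DEFAULT_CURVES, 0.5, 0.1)


class TestFixedHeightPennation:
    def test_height_conserved(self):
        h = MUSCLE.l_o_m * np.sin(MUSCLE.alpha_o)
        for l_m in np.linspace(0.5, 1.5, 7) * MUSCLE.l_o_m:
            assert l_m * np.sin(pennation(MUSCLE, l_m)) == pytest.approx(h)

    def test_cap(self):
        assert pennation(MUSCLE, 1e-6) == pytest.approx(np.deg2rad(84.0))


class TestRigidTendon:
    def test_no_pennation_geometry(self):
        fs = rigid_tendon_fiber(PENNATELESS, 0.27)
        assert fs.l_m == pytest.approx(0.27 - PENNATELESS.l_s_t)
        assert fs.l_t == PENNATELESS.l_s_t

    def test_optimal_configuration(self):
        l_mtu = MUSCLE.l_s_t + MUSCLE.l_o_m * np.cos(MUSCLE.alpha_o)
        fs = rigid_tendon_fiber(MUSCLE, l_mtu)
        assert fs.l_m == pytest.approx(MUSCLE.l_o_m)

    def test_slack_violation_raises(self):
        with pytest.raises(ValueError):
            rigid_tendon_fiber(MUSCLE, MUSCLE.l_s_t)


class TestMTUForce:
    def test_zero_and_maximal(self):
        l_mtu = (PENNATELESS.l_s_t
                 + PENNATELESS.l_o_m * np.cos(PENNATELESS.alpha_o))
        fs = rigid_tendon_fiber(PENNATELESS, l_mtu)
        f0, _, _ = mtu_force(PENNATELESS, DEFAULT_CURVES, 0.0, fs)
        f1, _, _ = mtu_force(PENNATELESS, DEFAULT_CURVES, 1.0, fs)
        assert f0 == 0.0
        assert f1 == pytest.approx(PENNATELESS.f_o_m)

    def test_affine_in_activation(self):
        """force(a) is exactly affine: midpoint equals mean of endpoints."""
        fs = solve_fiber_equilibrium(MUSCLE, DEFAULT_CURVES, 0.4, 0.355)
        f0, c0, c1 = mtu_force(MUSCLE, DEFAULT_CURVES, 0.0, fs)
        fh, _, _ = mtu_force(MUSCLE, DEFAULT_CURVES, 0.5, fs)
        f1, _, _ = mtu_force(MUSCLE, DEFAULT_CURVES, 1.0, fs)
        assert fh == pytest.approx((f0 + f1) / 2.0, abs=1e-12)
        assert f0 == pytest.approx(c0, abs=1e-12)
        assert f1 == pytest.approx(c0 + c1, abs=1e-12)
        assert c1 >= 0
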