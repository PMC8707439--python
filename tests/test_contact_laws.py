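import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcdem.contact_laws import (
    HERTZIAN,
    ContactModelParams,
    ContactState,
    effective_properties,
    hertz_normal_force,
    hysteretic_normal_force,
    multicontact_normal_force,
    plastic_overlap,
    rolling_torque,
    tangential_force,
    unloading_stiffness,
)
from mcdem.materials import MCC_A, STEEL_WALL


R50 = 112.3e-6  # radius of a volume-median coarse-MCC particle


def _sweep(pair, params, overlaps):
    """Evaluate the hysteretic law along an overlap sequence."""
    state = ContactState()
    forces = []
    for dn in overlaps:
        f, state = hysteretic_normal_force(state, dn, pair, params)
        forces.append(f)
    return np.array(forces), state


class TestEffectiveProperties:
    def test_equal_spheres_effective_radius(self):
        pair = effective_properties(MCC_A, R50, MCC_A, R50)
        assert pair.effective_radius == pytest.approx(R50 / 2)

    def test_particle_particle_effective_young(self):
        # oracle: direct evaluation of the reciprocal sum
        e, nu = 2.58e8, 0.30
        expected = 1.0 / (2 * (1 - nu**2) / e)
        pair = effective_properties(MCC_A, R50, MCC_A, R50)
        assert pair.effective_young == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.4176e8, rel=1e-3)

    def test_particle_wall_dominated_by_soft_side(self):
        inv = (1 - 0.30**2) / 2.58e8 + (1 - 0.31**2) / 7.62e10
        pair = effective_properties(MCC_A, R50, STEEL_WALL)
        assert pair.effective_radius == pytest.approx(R50)
        assert pair.effective_young == pytest.approx(1.0 / inv, rel=1e-12)
        assert pair.effective_young == pytest.approx(2.835e8, rel=1e-2)

    def test_wall_contact_uses_pw_friction(self):
        pair = effective_properties(MCC_A, R50, STEEL_WALL)
        assert pair.sliding_friction == MCC_A.sliding_friction_pw
        assert pair.rolling_friction == MCC_A.rolling_friction_pw

    def test_k1_is_hertz_stiffness(self, mcc_a_pair):
        k_expected = 4 / 3 * mcc_a_pair.effective_young * math.sqrt(mcc_a_pair.effective_radius)
        assert mcc_a_pair.k1 == pytest.approx(k_expected, rel=1e-12)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            effective_properties(MCC_A, -1e-6, MCC_A, 1e-6)


class TestHertz:
    def test_zero_overlap_zero_force(self, mcc_a_pair):
        assert hertz_normal_force(0.0, 1.0, mcc_a_pair) == 0.0
        assert hertz_normal_force(-1e-6, 0.0, mcc_a_pair) == 0.0

    def test_median_pair_force_at_one_micron(self, mcc_a_pair):
        # oracle: (4/3) E* sqrt(R*) dn^{3/2} with table inputs
        expected = (4 / 3) * 1.41758e8 * math.sqrt(56.15e-6) * (1e-6) ** 1.5
        assert hertz_normal_force(1e-6, 0.0, mcc_a_pair) == pytest.approx(expected, rel=1e-4)
        assert expected == pytest.approx(1.416e-3, rel=1e-3)

    def test_power_law_scaling(self, mcc_a_pair):
        f1 = hertz_normal_force(1e-6, 0.0, mcc_a_pair)
        f2 = hertz_normal_force(2e-6, 0.0, mcc_a_pair)
        assert f2 / f1 == pytest.approx(2**1.5, rel=1e-12)

    def test_damping_never_makes_force_attractive(self, mcc_a_pair):
        pair = replace(mcc_a_pair, normal_damping=1.0)
        assert hertz_normal_force(1e-9, -1e3, pair) == 0.0


class TestPlasticOverlap:
    def test_elastic_limit_no_residual(self):
        assert plastic_overlap(1e-5, 1.0, 1.0) == 0.0

    def test_table_stiffness_ratio(self):
        # (1 - 1/120)^{2/3} = 0.99444...
        assert plastic_overlap(1.0, 1.0, 120.0) == pytest.approx((119 / 120) ** (2 / 3))
        assert plastic_overlap(1.0, 1.0, 120.0) == pytest.approx(0.99444, abs=1e-5)

    def test_perfectly_plastic_limit(self):
        assert plastic_overlap(1e-5, 1.0, 1e12) == pytest.approx(1e-5, rel=1e-6)

    def test_invalid_stiffness_rejected(self):
        with pytest.raises(ValueError):
            plastic_overlap(1e-5, 2.0, 1.0)


class TestUnloadingStiffness:
    def test_endpoints(self, mcc_a_pair):
        params = ContactModelParams()
        assert unloading_stiffness(0.0, mcc_a_pair, params) == pytest.approx(mcc_a_pair.k1)
        dstar = 120 / 119 * 0.99 * 2 * mcc_a_pair.effective_radius
        assert unloading_stiffness(dstar, mcc_a_pair, params) == pytest.approx(mcc_a_pair.k2)
        assert unloading_stiffness(2 * dstar, mcc_a_pair, params) == pytest.approx(mcc_a_pair.k2)

    def test_plastic_flow_limit_and_midpoint(self, mcc_a_pair):
        # oracle: dmax* = k2/(k2-k1) phi_f 2R* with table parameters
        params = ContactModelParams()
        dstar = 120 / 119 * 0.99 * 2 * 56.15e-6
        assert dstar == pytest.approx(1.1214e-4, rel=1e-3)
        k2s = unloading_stiffness(dstar / 2, mcc_a_pair, params)
        assert k2s == pytest.approx(60.5 * mcc_a_pair.k1, rel=1e-9)

    def test_continuous_and_nondecreasing(self, mcc_a_pair):
        params = ContactModelParams()
        dmaxes = np.linspace(0, 2e-4, 400)
        vals = [unloading_stiffness(d, mcc_a_pair, params) for d in dmaxes]
        assert np.all(np.diff(vals) >= -1e-9)


class TestHystereticLaw:
    def test_virgin_loading_is_k1_branch(self, mcc_a_pair):
        params = ContactModelParams(pull_off_force=0.0)
        overlaps = np.linspace(0, 5e-6, 100)[1:]
        forces, state = _sweep(mcc_a_pair, params, overlaps)
        assert np.allclose(forces, mcc_a_pair.k1 * overlaps**1.5, rtol=1e-12)
        assert state.branch == "loading"

    def test_unloading_crosses_zero_at_plastic_overlap(self, mcc_a_pair):
        params = ContactModelParams()
        dmax = 5e-6
        _, state = _sweep(mcc_a_pair, params, np.linspace(0, dmax, 50)[1:])
        k2s = unloading_stiffness(dmax, mcc_a_pair, params)
        d0 = plastic_overlap(dmax, mcc_a_pair.k1, k2s)
        f_at_d0, _ = hysteretic_normal_force(state, d0, mcc_a_pair, params)
        assert f_at_d0 == pytest.approx(0.0, abs=1e-12)

    def test_adhesive_minimum_at_delta_min(self, mcc_a_pair):
        # brute-force sweep oracle: the k2*/adhesive branch intersection of
        # the three-branch law sits at dmin = ((k2*-k1)/(k2*+kc))^{2/3} dmax
        # with F_min = -kc dmin^{3/2} (solving k2*(d^1.5 - d0^1.5) = -kc d^1.5)
        params = ContactModelParams()
        dmax = 2.3e-4  # beyond dmax*, so k2* = k2
        dmin_expected = (119 / 120.5) ** (2 / 3) * dmax
        grid = np.linspace(dmax, 1e-9, 20001)
        forces, _ = _sweep(mcc_a_pair, params, np.concatenate([[dmax], grid]))
        k = int(np.argmin(forces))
        assert grid[k - 1] == pytest.approx(dmin_expected, rel=1e-3)
        assert forces[k] == pytest.approx(-mcc_a_pair.kc * dmin_expected**1.5, rel=1e-3)
        assert (119 / 120.5) ** (2 / 3) == pytest.approx(0.991684, abs=1e-6)

    def test_elastic_special_case_matches_hertz_exactly(self, mcc_a_pair):
        pair = replace(mcc_a_pair, k2=mcc_a_pair.k1, kc=0.0)
        params = HERTZIAN
        rng = np.random.default_rng(0)
        path = np.abs(np.cumsum(rng.normal(0, 5e-7, 300)))
        forces, _ = _sweep(pair, params, path)
        hertz = np.array([hertz_normal_force(d, 0.0, pair) for d in path])
        assert np.array_equal(forces, hertz)

    def test_reload_follows_k2_branch_until_virgin_rejoin(self, mcc_a_pair):
        params = ContactModelParams()
        dmax = 5e-6
        _, state = _sweep(mcc_a_pair, params, np.linspace(0, dmax, 50)[1:])
        # unload part-way (staying above the adhesive switch), then reload
        down = np.linspace(dmax, 0.9 * dmax, 30)[1:]
        up = np.linspace(0.9 * dmax, dmax * 0.9999, 30)
        for dn in down:
            _, state = hysteretic_normal_force(state, dn, mcc_a_pair, params)
        branches = set()
        for dn in up:
            _, state = hysteretic_normal_force(state, dn, mcc_a_pair, params)
            branches.add(state.branch)
        assert branches == {"unload_reload"}
        f, state = hysteretic_normal_force(state, dmax * 1.01, mcc_a_pair, params)
        assert state.branch == "loading"

    def test_contact_loss_resets_history(self, mcc_a_pair):
        params = ContactModelParams()
        _, state = _sweep(mcc_a_pair, params, [1e-6, 2e-6])
        f, state = hysteretic_normal_force(state, 0.0, mcc_a_pair, params)
        assert f == 0.0
        assert state.branch == "broken"
        assert state.max_overlap == 0.0
        assert np.all(state.tangential_spring == 0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        k2r=st.floats(1.0, 500.0),
        kcr=st.floats(0.0, 5.0),
        phif=st.floats(0.05, 1.0),
        dmax_frac=st.floats(0.01, 2.0),
    )
    def test_force_continuity_along_arbitrary_paths(self, k2r, kcr, phif, dmax_frac):
        """The branch-selected force is continuous in the overlap."""
        params = ContactModelParams(k2_over_k1=k2r, kc_over_k1=kcr, plasticity_depth=phif)
        pair = effective_properties(MCC_A, R50, MCC_A, R50, params)
        dmax = dmax_frac * pair.effective_radius
        path = np.concatenate(
            [
                np.linspace(0, dmax, 200)[1:],
                np.linspace(dmax, dmax * 0.3, 200)[1:],
                np.linspace(dmax * 0.3, dmax * 0.8, 200)[1:],
            ]
        )
        forces, _ = _sweep(pair, params, path)
        # continuity: force increments bounded by the stiffest branch slope
        df = np.abs(np.diff(forces))
        dpow = np.abs(np.diff(path**1.5))
        bound = 1.0001 * (pair.k2 + pair.kc) * dpow + 1e-12
        assert np.all(df <= bound)

    def test_hysteresis_loop_dissipates_energy(self):
        params = ContactModelParams(kc_over_k1=0.0)
        mcc_a_pair = effective_properties(MCC_A, R50, MCC_A, R50, params)
        dmax = 5e-6
        # the k2* unloading interval spans <1% of dmax: resolve it finely
        up = np.linspace(0, dmax, 20000)[1:]
        down = np.linspace(dmax, 0, 20000)[1:]
        f_up, state = _sweep(mcc_a_pair, params, up)
        f_down = []
        for dn in down:
            f, state = hysteretic_normal_force(state, dn, mcc_a_pair, params)
            f_down.append(f)
        work_in = np.trapezoid(f_up, up)
        work_out = -np.trapezoid(f_down, down)
        assert work_in > work_out > 0
        # elastic limit: no dissipation
        pair_el = replace(mcc_a_pair, k2=mcc_a_pair.k1, kc=0.0)
        f_up, state = _sweep(pair_el, HERTZIAN, up)
        f_down = []
        for dn in down:
            f, state = hysteretic_normal_force(state, dn, pair_el, HERTZIAN)
            f_down.append(f)
        # grids differ by one endpoint panel, so allow quadrature error
        assert np.trapezoid(f_up, up) == pytest.approx(-np.trapezoid(f_down, down), rel=1e-3)


class TestTangential:
    def test_no_motion_no_force(self, mcc_a_pair):
        state = ContactState()
        f, _ = tangential_force(state, np.zeros(3), 1e-9, 1e-3, mcc_a_pair)
        assert np.all(f == 0.0)

    def test_coulomb_cap_with_table_friction(self, mcc_a_pair):
        # mu_s(pp) = 0.561; a large accumulated spring must sit exactly on the cap
        state = ContactState(tangential_spring=np.array([1e-4, 0.0, 0.0]))
        f, new = tangential_force(state, np.zeros(3), 1e-9, 1e-3, mcc_a_pair)
        assert np.linalg.norm(f) == pytest.approx(0.561e-3, rel=1e-9)
        # spring rescaled onto the cap
        kt = mcc_a_pair.tangential_stiffness
        assert np.linalg.norm(new.tangential_spring) == pytest.approx(
            (0.561e-3 / kt) ** (2 / 3), rel=1e-9
        )

    def test_reversing_velocity_unwinds_spring(self, mcc_a_pair):
        state = ContactState()
        v = np.array([1e-3, 0, 0])
        for _ in range(10):
            _, state = tangential_force(state, v, 1e-6, 1.0, mcc_a_pair)
        for _ in range(10):
            _, state = tangential_force(state, -v, 1e-6, 1.0, mcc_a_pair)
        assert np.linalg.norm(state.tangential_spring) == pytest.approx(0.0, abs=1e-18)

    def test_tensile_contact_resets_spring(self, mcc_a_pair):
        state = ContactState(tangential_spring=np.array([1e-6, 0, 0]))
        f, new = tangential_force(state, np.zeros(3), 1e-9, -1e-3, mcc_a_pair)
        assert np.all(f == 0.0)
        assert np.all(new.tangential_spring == 0.0)


class TestRollingTorque:
    def test_zero_rotation_zero_torque(self, mcc_a_pair):
        assert np.all(rolling_torque(np.zeros(3), 1e-3, mcc_a_pair) == 0.0)

    def test_cdt_magnitude_with_table_friction(self):
        # oracle: mu_r R_r |Fn| = 0.3 * 56.15e-6 * 1e-3
        pair = effective_properties(MCC_A, R50, MCC_A, R50)
        tau = rolling_torque(np.array([0, 0, 2.0]), 1e-3, pair)
        assert np.linalg.norm(tau) == pytest.approx(0.3 * 56.15e-6 * 1e-3, rel=1e-3)
        assert np.linalg.norm(tau) == pytest.approx(1.6845e-8, rel=1e-3)

    def test_torque_opposes_rotation_and_is_odd(self, mcc_a_pair):
        w = np.array([1.0, -2.0, 0.5])
        t1 = rolling_torque(w, 1e-3, mcc_a_pair)
        t2 = rolling_torque(-w, 1e-3, mcc_a_pair)
        assert np.dot(t1, w) < 0
        assert np.allclose(t1, -t2)


class TestMultiContact:
    def test_beta_zero_reduces_to_hysteretic(self, mcc_a_pair):
        params = ContactModelParams(beta=0.0)
        state = ContactState()
        f_h, _ = hysteretic_normal_force(state, 2e-6, mcc_a_pair, params)
        f_mc, _ = multicontact_normal_force(state, 2e-6, mcc_a_pair, params, 1e-9, 1e7)
        assert f_mc == f_h

    def test_point_contact_has_no_correction(self, mcc_a_pair):
        params = ContactModelParams(beta=1.3)
        state = ContactState()
        f_h, _ = hysteretic_normal_force(state, 2e-6, mcc_a_pair, params)
        f_mc, _ = multicontact_normal_force(state, 2e-6, mcc_a_pair, params, 0.0, 1e7)
        assert f_mc == f_h

    def test_correction_arithmetic(self, mcc_a_pair):
        # beta nu A P = 1.3 * 0.3 * 1e-9 * 1e7 = 3.9e-3 N
        params = ContactModelParams(beta=1.3)
        state = ContactState()
        f_h, _ = hysteretic_normal_force(state, 2e-6, mcc_a_pair, params)
        f_mc, _ = multicontact_normal_force(state, 2e-6, mcc_a_pair, params, 1e-9, 1e7)
        assert f_mc - f_h == pytest.approx(3.9e-3, rel=1e-12)

    def test_negative_area_rejected(self, mcc_a_pair):
        with pytest.raises(ValueError):
            multicontact_normal_force(
                ContactState(), 1e-6, mcc_a_pair, ContactModelParams(), -1e-9, 1e7
            )


class TestContactModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k2_over_k1": 0.5},
            {"kc_over_k1": -0.1},
            {"plasticity_depth": 0.0},
            {"plasticity_depth": 1.5},
            {"beta": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContactModelParams(**kwargs)
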