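"""Unit and property tests for the two-cell lateral-inhibition core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from angioswitch.li_core import (
    SPECIES,
    FeedbackParams,
    Trajectory,
    TwoCellState,
    classify,
    derivatives,
    effective_vegf,
    initial_state,
    simulate,
    simulate_to_equilibrium,
)

# --------------------------------------------------------------- helpers


def _random_state(rng, params, v_max=3.0):
    """Random physical state respecting the receptor and Notch pools."""
    a = np.zeros(len(SPECIES))
    b = np.zeros(len(SPECIES))
    for arr in (a, b):
        vr = rng.uniform(0, params.receptor_total)
        dn = rng.uniform(0, params.notch_total)
        arr[:] = [params.receptor_total - vr, vr, rng.uniform(0, 1.5),
                  params.notch_total - dn, dn, rng.uniform(0, 1),
                  rng.uniform(0, 1), rng.uniform(0, 1)]
    return TwoCellState(a=a, b=b, V_a=rng.uniform(0, v_max),
                        V_b=rng.uniform(0, v_max))


# --------------------------------------------------------- effective_vegf


@pytest.mark.parametrize("V, P, k6, n, expected", [
    (1.0, 0.0, 7.3, 2.0, 1.0),   # zero feedback species -> identity
    (1.0, 2.0, 1.0, 2.0, 5.0),   # direct substitution 1*(1+1*4)
    (0.0, 5.0, 3.0, 2.0, 0.0),   # zero VEGF annihilates
    (2.0, 1.0, 0.0, 2.0, 2.0),   # zero gain -> identity
])
def test_effective_vegf_values(V, P, k6, n, expected):
    assert effective_vegf(V, P, k6, n) == pytest.approx(expected)


@settings(deadline=None, derandomize=True)
@given(
    V=st.floats(0, 10), P=st.floats(0, 10), dV=st.floats(0, 5),
    dP=st.floats(0, 5), k6=st.floats(0, 100), n=st.floats(1, 4),
)
def test_effective_vegf_monotone(V, P, dV, dP, k6, n):
    base = effective_vegf(V, P, k6, n)
    assert effective_vegf(V + dV, P, k6, n) >= base
    assert effective_vegf(V, P + dP, k6, n) >= base


def test_effective_vegf_rejects_negative_input():
    with pytest.raises(ValueError):
        effective_vegf(-1.0, 0.0, 1.0, 2.0)
    with pytest.raises(ValueError):
        effective_vegf(1.0, -0.1, 1.0, 2.0)


def test_params_validation():
    with pytest.raises(ValueError):
        FeedbackParams(dll4_prod=-1.0)
    with pytest.raises(ValueError):
        FeedbackParams(n_exp=0.5)
    with pytest.raises(ValueError):
        FeedbackParams(repress_site="nowhere")


# ------------------------------------------------------------ derivatives


def test_zero_state_has_zero_rates(bif_params):
    zero = TwoCellState(a=np.zeros(8), b=np.zeros(8), V_a=0.0, V_b=0.0)
    assert np.all(derivatives(zero, bif_params) == 0.0)


def test_mirror_symmetric_state_gives_mirror_symmetric_rates(bif_params, rng):
    st_ = _random_state(rng, bif_params)
    sym = TwoCellState(a=st_.a.copy(), b=st_.a.copy(), V_a=st_.V_a,
                       V_b=st_.V_a)
    dy = derivatives(sym, bif_params)
    np.testing.assert_allclose(dy[:8], dy[8:], rtol=0, atol=0)


def test_swapping_cells_swaps_rates(bif_params, rng):
    st_ = _random_state(rng, bif_params)
    dy = derivatives(st_, bif_params)
    dy_sw = derivatives(st_.swapped(), bif_params)
    np.testing.assert_allclose(dy_sw, np.concatenate([dy[8:], dy[:8]]))


def test_derivatives_match_finite_difference_of_simulate(bif_params, rng):
    """Central finite differences of short integrations reproduce the
    analytic rate vector at random states."""
    dt = 1e-4
    for _ in range(10):
        st_ = _random_state(rng, bif_params)
        traj = simulate(st_, bif_params, t_end=dt, dt_out=dt / 4,
                        rtol=1e-12, atol=1e-14, method="DOP853")
        # two central differences around y(dt/2), Richardson-extrapolated
        d_full = (traj.y[4] - traj.y[0]) / dt
        d_half = (traj.y[3] - traj.y[1]) / (dt / 2)
        fd = (4.0 * d_half - d_full) / 3.0
        mid = TwoCellState.from_vector(traj.y[2], st_.V_a, st_.V_b)
        expected = derivatives(mid, bif_params)
        scale = np.max(np.abs(expected)) + 1.0
        np.testing.assert_allclose(fd, expected, rtol=1e-6,
                                   atol=1e-6 * scale)


# --------------------------------------------------------------- simulate


def test_zero_vegf_zero_initial_stays_zero(bif_params):
    zero = TwoCellState(a=np.zeros(8), b=np.zeros(8), V_a=0.0, V_b=0.0)
    traj = simulate(zero, bif_params, t_end=50.0)
    assert np.all(traj.y == 0.0)


def test_symmetric_start_remains_symmetric(bif_params):
    """Without a perturbation the deterministic ODE cannot pattern."""
    st_ = initial_state(bif_params, 3.0, 3.0, eps=0.0)
    traj = simulate(st_, bif_params, t_end=100.0)
    np.testing.assert_allclose(traj.y[:, :8], traj.y[:, 8:],
                               rtol=0, atol=1e-9)


def test_receptor_nudge_decides_the_winner(bif_params):
    """With feedback on, an epsilon advantage in free receptor makes that
    cell the high-DLL4 (tip) cell at steady state."""
    st_ = initial_state(bif_params, 3.0, 3.0)  # nudge on cell A
    final, info = simulate_to_equilibrium(st_, bif_params)
    assert info["converged"]
    assert final["A", "DLL4"] > final["B", "DLL4"]
    assert final["A", "DLL4"] > 10 * final["B", "DLL4"]


def test_exchange_symmetry_of_trajectories(bif_params, rng):
    st_ = _random_state(rng, bif_params)
    traj = simulate(st_, bif_params, t_end=50.0)
    traj_sw = simulate(st_.swapped(), bif_params, t_end=50.0)
    np.testing.assert_allclose(
        traj_sw.y, np.concatenate([traj.y[:, 8:], traj.y[:, :8]], axis=1),
        rtol=0, atol=1e-7)


def test_conservation_and_nonnegativity(bif_params, rng):
    atol = 1e-10
    st_ = _random_state(rng, bif_params)
    traj = simulate(st_, bif_params, t_end=100.0, atol=atol)
    assert traj.y.min() >= -10 * atol
    for off in (0, 8):
        rt = traj.y[:, off + 0] + traj.y[:, off + 1]
        nt = traj.y[:, off + 3] + traj.y[:, off + 4]
        np.testing.assert_allclose(rt, rt[0], rtol=1e-7)
        np.testing.assert_allclose(nt, nt[0], rtol=1e-7)


def test_feedback_free_trajectories_match_reference_implementation(bif_params):
    """fb_prod = 0 (or k6 = 0) must reproduce a independently written
    feedback-free model of the same reaction scheme to 1e-8."""
    p = bif_params

    def reference_rhs(_t, y):
        # 7 species/cell, no feedback factor: R, VR, D, Nf, DN, NICD, HE
        out = np.empty(14)
        for i, j in ((0, 7), (7, 0)):
            R, VR, D, Nf, DN, NICD, HE = y[i:i + 7]
            Dj, DNj, Nfj = y[j + 2], y[j + 4], y[j + 3]
            V = 3.0
            sig = 1.0 / (1.0 + (p.repress_gain * HE) ** p.repress_exp)
            b = p.vegf_bind_on * V * R - p.vegf_bind_off * VR
            out[i + 0] = -b
            out[i + 1] = b
            out[i + 2] = (p.dll4_prod * VR * sig - p.deg_dll4 * D
                          - p.notch_bind_on * D * Nfj + p.notch_bind_off * DNj)
            tr = p.notch_bind_on * Dj * Nf
            out[i + 3] = -tr + (p.notch_bind_off + p.nicd_cat) * DN
            out[i + 4] = tr - (p.notch_bind_off + p.nicd_cat) * DN
            out[i + 5] = p.nicd_cat * DN - p.deg_nicd * NICD
            out[i + 6] = p.he_prod * NICD - p.deg_he * HE
        return out

    for variant in (dict(fb_prod=0.0), dict(k6=0.0),
                    dict(fb_prod=0.0, k6=0.0)):
        from dataclasses import replace
        p_var = replace(p, **variant)
        st_ = initial_state(p_var, 3.0, 3.0)
        traj = simulate(st_, p_var, t_end=50.0, rtol=1e-10, atol=1e-12)
        y0 = np.concatenate([st_.a[:7], st_.b[:7]])
        ref = solve_ivp(reference_rhs, (0, 50.0), y0, t_eval=traj.t,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        got = np.concatenate([traj.y[:, 0:7], traj.y[:, 8:15]], axis=1)
        np.testing.assert_allclose(got, ref.y.T, rtol=0, atol=1e-8)


def test_winning_cell_dll4_monotone_in_its_vegf(matrix_params):
    """Steady-state winner DLL4 is non-decreasing in the winner's VEGF."""
    vb = 0.01
    values = []
    for va in np.linspace(0.05, 0.25, 10):
        final, _ = simulate_to_equilibrium(
            initial_state(matrix_params, va, vb), matrix_params)
        values.append(final["A", "DLL4"])
    diffs = np.diff(values)
    assert np.all(diffs >= -1e-8)


def test_simulate_input_validation(bif_params):
    with pytest.raises(ValueError):
        simulate(initial_state(bif_params, 1, 1), bif_params, t_end=-1.0)


# --------------------------------------------------------------- classify


def _traj_from_dll4(t, d_a, d_b):
    y = np.zeros((len(t), 16))
    y[:, 2] = d_a
    y[:, 10] = d_b
    return Trajectory(t=np.asarray(t, float), y=y, V_a=1.0, V_b=1.0,
                      params=FeedbackParams())


def test_classify_flatline_zero_is_unresolved_pair():
    t = np.arange(0, 51.0)
    out = classify(_traj_from_dll4(t, np.zeros_like(t), np.zeros_like(t)),
                   tip_threshold=0.3, inhibited_threshold=0.1, hold_time=10)
    assert out.labels == ("inhibited", "inhibited")
    assert not out.resolved
    assert out.patterning_time is None


def test_classify_step_functions_patterning_time():
    """A crosses tip at t=5 and stays; B drops below inhibited at t=7:
    the pair locks in at t=7."""
    t = np.arange(0, 31.0)
    d_a = np.where(t >= 5, 0.5, 0.0)
    d_b = np.where(t >= 7, 0.05, 0.5)
    out = classify(_traj_from_dll4(t, d_a, d_b), 0.3, 0.1, hold_time=10)
    assert out.resolved
    assert out.labels == ("tip", "inhibited")
    assert out.patterning_time == pytest.approx(7.0)


def test_classify_recrossing_is_unresolved():
    t = np.arange(0, 41.0)
    d_a = 0.5 + 0.3 * np.sin(t)  # oscillates through the tip threshold
    d_b = np.zeros_like(t)
    out = classify(_traj_from_dll4(t, d_a, d_b), 0.3, 0.1, hold_time=10)
    assert out.label_a == "unresolved"
    assert not out.resolved


def test_classify_hold_time_not_met():
    t = np.arange(0, 12.0)
    d_a = np.where(t >= 5, 0.5, 0.0)  # only 6 time units above threshold
    out = classify(_traj_from_dll4(t, d_a, np.zeros_like(t)), 0.3, 0.1,
                   hold_time=10)
    assert out.label_a == "unresolved"


def test_classify_rejects_inverted_thresholds(bif_params):
    t = np.arange(0, 5.0)
    with pytest.raises(ValueError):
        classify(_traj_from_dll4(t, t * 0, t * 0), 0.1, 0.3, hold_time=1)
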