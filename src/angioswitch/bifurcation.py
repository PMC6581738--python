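"""Steady-state, hysteresis and cusp analyses of the two-cell switch.

The positive-feedback loop makes the VEGF response of each cell bistable
over a window of VEGF input: a quasi-static upward sweep switches the
winning cell to the active (high-DLL4) state at a higher VEGF level than
the one at which the downward sweep lets it go -- hysteresis.  Mapping the
number of coexisting stable steady states over a (VEGF, feedback) grid
traces the cusp-shaped bistable region; without feedback the system is
monostable everywhere on the modeled range.

Continuation is implemented as quasi-static sweeping plus multi-start
damped root finding on the mass-action right-hand side (no pseudo-arclength
machinery): fold points are located at grid resolution, which is how the
switch thresholds are reported.

Steady-state search runs in reduced coordinates that eliminate the two
conserved pools per cell (receptor, Notch), so the Jacobian used for the
stability labels has no structural zero modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import root

from .li_core import (
    N_SPECIES,
    SPECIES,
    _IDX,
    _rhs,
    FeedbackParams,
    TwoCellState,
    initial_state,
    simulate,
    simulate_to_equilibrium,
)

__all__ = [
    "SteadyState",
    "HysteresisResult",
    "CuspRegion",
    "find_steady_states",
    "sweep_hysteresis",
    "map_cusp",
    "vegf_path",
    "bistable_interval",
]

# reduced per-cell coordinates: conserved R_free and Notch_free eliminated
_RED = ("VR", "DLL4", "DN", "NICD", "HE", "P")
N_RED = len(_RED)


def _full_from_reduced(z: np.ndarray, p: FeedbackParams) -> np.ndarray:
    y = np.empty(2 * N_SPECIES)
    for c in range(2):
        zc = z[c * N_RED:(c + 1) * N_RED]
        yc = y[c * N_SPECIES:(c + 1) * N_SPECIES]
        for k, name in enumerate(_RED):
            yc[_IDX[name]] = zc[k]
        yc[_IDX["R_free"]] = p.receptor_total - zc[_RED.index("VR")]
        yc[_IDX["Notch_free"]] = p.notch_total - zc[_RED.index("DN")]
    return y


def _reduced_from_full(y: np.ndarray) -> np.ndarray:
    z = np.empty(2 * N_RED)
    for c in range(2):
        yc = y[c * N_SPECIES:(c + 1) * N_SPECIES]
        for k, name in enumerate(_RED):
            z[c * N_RED + k] = yc[_IDX[name]]
    return z


def _reduced_rhs(z: np.ndarray, V_a: float, V_b: float,
                 p: FeedbackParams) -> np.ndarray:
    dy = _rhs(_full_from_reduced(z, p), V_a, V_b, p)
    return _reduced_from_full(dy)


def _reduced_jacobian(z: np.ndarray, V_a: float, V_b: float,
                      p: FeedbackParams, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the reduced system."""
    n = z.size
    J = np.empty((n, n))
    for k in range(n):
        h = rel_step * max(abs(z[k]), 1.0)
        zp, zm = z.copy(), z.copy()
        zp[k] += h
        zm[k] -= h
        J[:, k] = (_reduced_rhs(zp, V_a, V_b, p)
                   - _reduced_rhs(zm, V_a, V_b, p)) / (2 * h)
    return J


@dataclass
class SteadyState:
    """An equilibrium of the two-cell system with its stability label."""

    state: TwoCellState
    residual: float
    stable: bool
    leading_eig: float

    @property
    def winning_dll4(self) -> float:
        return max(self.state["A", "DLL4"], self.state["B", "DLL4"])


def _start_points(p: FeedbackParams, n_starts: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    RT, NT = p.receptor_total, p.notch_total
    d_scale = p.dll4_prod * RT / max(p.deg_dll4, 1e-12)
    p_scale = p.fb_prod * RT / max(p.deg_p, 1e-12)
    lo = np.zeros(2 * N_RED)
    # deterministic anchors: trivial, both-active, and the two mixed states
    def cell(vr, d):
        dn = NT * d / (d + 2.0) if d > 0 else 0.0
        nicd = dn
        he = nicd
        return [vr * RT, d * d_scale, min(dn, NT), nicd, he, vr * p_scale]
    anchors = [
        lo,
        np.array(cell(0.9, 0.5) + cell(0.9, 0.05)),
        np.array(cell(0.9, 0.05) + cell(0.9, 0.5)),
        np.array(cell(0.9, 0.3) + cell(0.9, 0.3)),
        np.array(cell(0.05, 0.05) + cell(0.05, 0.05)),
    ]
    starts = anchors[:]
    while len(starts) < n_starts:
        z = rng.uniform(0.0, 1.0, 2 * N_RED)
        scale = np.array([RT, d_scale, NT, NT, NT * p.he_prod / max(p.deg_he, 1e-12),
                          p_scale] * 2)
        starts.append(z * scale)
    return starts[:n_starts]


def find_steady_states(
    params: FeedbackParams,
    V_a: float,
    V_b: float,
    n_starts: int = 12,
    seed: int = 0,
    resid_tol: float = 1e-8,
    dedup_tol: float = 1e-6,
    verify: bool = True,
) -> list[SteadyState]:
    """Multi-start damped root finding on the mass-action derivatives.

    Returns deduplicated steady states (L-inf distance < ``dedup_tol``),
    each labeled stable/unstable from the reduced Jacobian's leading
    eigenvalue and verified by a short re-integration staying within 1e-6.
    Raises ``RuntimeError`` if no start converges.
    """
    if n_starts < 8:
        raise ValueError(f"n_starts must be >= 8, got {n_starts}")
    if V_a < 0 or V_b < 0:
        raise ValueError("VEGF inputs must be >= 0")
    rng = np.random.default_rng(seed)
    found: list[np.ndarray] = []
    for z0 in _start_points(params, n_starts, rng):
        sol = root(_reduced_rhs, z0, args=(V_a, V_b, params), method="hybr",
                   tol=1e-12)
        z = sol.x
        if not sol.success:
            continue
        resid = float(np.max(np.abs(_reduced_rhs(z, V_a, V_b, params))))
        if resid > resid_tol:
            continue
        # physicality: non-negative species, pools respected (tiny slack)
        y = _full_from_reduced(z, params)
        if np.min(y) < -1e-9:
            continue
        if any(np.max(np.abs(z - z2)) < dedup_tol for z2 in found):
            continue
        found.append(z)
    if not found:
        raise RuntimeError(
            f"no steady state converged at V=({V_a}, {V_b}) "
            f"with {n_starts} starts"
        )
    out = []
    for z in found:
        y = np.clip(_full_from_reduced(z, params), 0.0, None)
        if verify:
            st0 = TwoCellState.from_vector(y, V_a, V_b)
            traj = simulate(st0, params, t_end=1.0, dt_out=0.5)
            drift = float(np.max(np.abs(traj.y[-1] - y)))
            if drift > 1e-6:
                continue
        J = _reduced_jacobian(z, V_a, V_b, params)
        lead = float(np.max(np.linalg.eigvals(J).real))
        resid = float(np.max(np.abs(_reduced_rhs(z, V_a, V_b, params))))
        out.append(SteadyState(
            state=TwoCellState.from_vector(y, V_a, V_b),
            residual=resid,
            stable=lead < 0.0,
            leading_eig=lead,
        ))
    if not out:
        raise RuntimeError(
            f"steady-state candidates at V=({V_a}, {V_b}) all failed "
            "re-integration verification"
        )
    return out


def vegf_path(v_max: float, v_step: float, v_min: float = 0.0) -> np.ndarray:
    """Quasi-static VEGF path: ``v_min`` up to ``v_max`` then back down."""
    up = np.arange(v_min, v_max + 0.5 * v_step, v_step)
    return np.concatenate([up, up[::-1][1:]])


@dataclass
class HysteresisResult:
    """Winning-cell DLL4 along an up-then-down quasi-static VEGF sweep."""

    v_up: np.ndarray
    dll4_up: np.ndarray
    v_down: np.ndarray
    dll4_down: np.ndarray
    tip_threshold: float
    switch_on_vegf: Optional[float]
    switch_off_vegf: Optional[float]

    @property
    def bistable(self) -> bool:
        return (self.switch_on_vegf is not None
                and self.switch_off_vegf is not None
                and self.switch_off_vegf < self.switch_on_vegf)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "leg": ["up"] * len(self.v_up) + ["down"] * len(self.v_down),
            "V": np.concatenate([self.v_up, self.v_down]),
            "winning_dll4": np.concatenate([self.dll4_up, self.dll4_down]),
        })


def sweep_hysteresis(
    params: FeedbackParams,
    v_path: Sequence[float],
    tip_threshold: float = 0.3,
    eps: Optional[float] = None,
    tol_eq: float = 1e-7,
) -> HysteresisResult:
    """Quasi-static up-then-down VEGF sweep of the two-cell system.

    At each VEGF level the system is re-equilibrated from the previous
    endpoint (both cells see the same V).  A deterministic symmetry-breaking
    nudge (``eps``, default ``1e-4 * receptor_total``) is re-applied to cell
    A's free receptor at every step so that equal-input patterning can
    resolve; without a perturbation the deterministic ODE would stay on the
    symmetric manifold for ever.

    ``switch_on_vegf`` is the first up-leg V at which the winning cell's
    DLL4 crosses ``tip_threshold``; ``switch_off_vegf`` the lowest down-leg
    V at which the active state persists.
    """
    v_path = np.asarray(v_path, dtype=float)
    if v_path.ndim != 1 or v_path.size < 3:
        raise ValueError("v_path must be a 1-D up-then-down grid")
    turn = int(np.argmax(v_path))
    up, down = v_path[:turn + 1], v_path[turn:]
    if np.any(np.diff(up) <= 0) or np.any(np.diff(down) >= 0):
        raise ValueError("v_path must ascend monotonically then descend")
    if eps is None:
        eps = 1e-4 * params.receptor_total

    state = initial_state(params, up[0], up[0], eps=eps)
    dll4_up = np.empty(up.size)
    for i, V in enumerate(up):
        state = TwoCellState(a=state.a.copy(), b=state.b.copy(), V_a=V, V_b=V)
        state.a[_IDX["R_free"]] += eps
        state, _info = simulate_to_equilibrium(state, params, tol_eq=tol_eq)
        dll4_up[i] = max(state["A", "DLL4"], state["B", "DLL4"])
    dll4_down = np.empty(down.size)
    for i, V in enumerate(down):
        state = TwoCellState(a=state.a.copy(), b=state.b.copy(), V_a=V, V_b=V)
        state.a[_IDX["R_free"]] += eps
        state, _info = simulate_to_equilibrium(state, params, tol_eq=tol_eq)
        dll4_down[i] = max(state["A", "DLL4"], state["B", "DLL4"])

    on_idx = np.nonzero(dll4_up >= tip_threshold)[0]
    switch_on = float(up[on_idx[0]]) if on_idx.size else None
    switch_off = None
    for V, d in zip(down, dll4_down):
        if d >= tip_threshold:
            switch_off = float(V)
        else:
            break
    return HysteresisResult(
        v_up=up, dll4_up=dll4_up, v_down=down, dll4_down=dll4_down,
        tip_threshold=tip_threshold,
        switch_on_vegf=switch_on, switch_off_vegf=switch_off,
    )


@dataclass
class CuspRegion:
    """Stable-steady-state counts over a (VEGF, feedback-production) grid."""

    v_grid: np.ndarray
    fb_grid: np.ndarray
    n_stable: np.ndarray  # shape (n_fb, n_v)
    bistable: np.ndarray  # bool, count >= 2
    failed: np.ndarray    # bool, steady-state search failed at this point

    def to_dataframe(self):
        import pandas as pd
        fb, v = np.meshgrid(self.fb_grid, self.v_grid, indexing="ij")
        return pd.DataFrame({
            "fb_prod": fb.ravel(),
            "V": v.ravel(),
            "n_stable_states": self.n_stable.ravel(),
            "bistable": self.bistable.ravel(),
            "failed": self.failed.ravel(),
        })


def map_cusp(
    params: FeedbackParams,
    v_range: Sequence[float],
    fb_range: Sequence[float],
    n_starts: int = 12,
    seed: int = 0,
) -> CuspRegion:
    """Count distinct stable steady states on a (VEGF, fb_prod) grid.

    Per-point failures are recorded in the ``failed`` mask rather than
    aborting the whole map.  A grid point is bistable iff at least two
    distinct stable states are found.  Bistability here is assessed on the
    per-cell activation level (winning-cell VR), so the count distinguishes
    the inactive and active branches of the switch rather than the
    tip/stalk relabelling of the same activation state.
    """
    v_grid = np.asarray(v_range, dtype=float)
    fb_grid = np.asarray(fb_range, dtype=float)
    n_stable = np.zeros((fb_grid.size, v_grid.size), dtype=int)
    failed = np.zeros_like(n_stable, dtype=bool)
    from dataclasses import replace
    for i, fb in enumerate(fb_grid):
        p_i = replace(params, fb_prod=float(fb))
        for j, V in enumerate(v_grid):
            try:
                states = find_steady_states(p_i, V, V, n_starts=n_starts,
                                            seed=seed)
            except RuntimeError:
                failed[i, j] = True
                continue
            # distinct activation levels among stable states
            levels: list[float] = []
            for s in states:
                if not s.stable:
                    continue
                # tip/stalk relabellings of the same activation branch sit
                # within ~1e-3 RT of each other; branches are ~RT apart
                x = max(s.state["A", "VR"], s.state["B", "VR"])
                if not any(abs(x - l) < 0.01 * max(1.0, params.receptor_total)
                           for l in levels):
                    levels.append(x)
            n_stable[i, j] = len(levels)
    bistable = n_stable >= 2
    return CuspRegion(v_grid=v_grid, fb_grid=fb_grid, n_stable=n_stable,
                      bistable=bistable, failed=failed)


def bistable_interval(cusp: CuspRegion, fb_value: float) -> Optional[tuple]:
    """(V_lo, V_hi) of the bistable mask in the row nearest ``fb_value``."""
    i = int(np.argmin(np.abs(cusp.fb_grid - fb_value)))
    idx = np.nonzero(cusp.bistable[i])[0]
    if idx.size == 0:
        return None
    return (float(cusp.v_grid[idx[0]]), float(cusp.v_grid[idx[-1]]))
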