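"""Two-cell VEGF-Delta-Notch lateral-inhibition model with positive feedback.

Two adjacent endothelial cells compete for the motile "tip" identity.  In
each cell, VEGF reversibly binds a fixed receptor pool; the active
VEGF-receptor complex drives production of the Notch ligand DLL4 and of a
positive-feedback factor P.  DLL4 of one cell trans-binds free Notch of the
*other* cell; the bound complex is irreversibly cleaved to NICD, which
induces a consolidated transcriptional repressor (HE) that attenuates the
cell's own VEGFR pathway output.  P closes a positive-feedback loop by
amplifying the VEGF input seen by the receptor:

    V_eff = V * (1 + k6 * P**n)

With feedback, small inter-cell differences in receptor activity are
amplified into a fast, switch-like, bistable tip/stalk decision; without it
lateral inhibition is slow and needs much more VEGF.

All concentrations are dimensionless (c.u.); time is in model units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "FeedbackParams",
    "TwoCellState",
    "Trajectory",
    "PatterningOutcome",
    "SimulationError",
    "effective_vegf",
    "derivatives",
    "simulate",
    "simulate_to_equilibrium",
    "classify",
    "initial_state",
]

#: Per-cell species, in state-vector order.
SPECIES = ("R_free", "VR", "DLL4", "Notch_free", "DN", "NICD", "HE", "P")
_IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails; carries solver diagnostics."""


@dataclass(frozen=True)
class FeedbackParams:
    """Kinetic constants of the two-cell reaction network.

    Every rate is non-negative and dimensionless.  ``fb_prod = 0`` (or
    ``k6 = 0``) recovers the feedback-free model exactly.

    Parameters
    ----------
    vegf_bind_on, vegf_bind_off
        Reversible VEGF-receptor binding (per c.u. per time; per time).
    dll4_prod
        DLL4 production rate per unit active receptor complex.
    notch_bind_on, notch_bind_off
        Reversible trans-binding of neighbour DLL4 to free Notch.
    nicd_cat
        Irreversible NICD release from the DLL4-Notch complex; the receptor
        stub is recycled to the free-Notch pool so the per-cell Notch pool
        is conserved.
    he_prod
        HE (consolidated HES/HEY/HER repressor) production per NICD.
    repress_gain, repress_exp
        Strength and cooperativity of HE repression of VEGFR pathway
        output: sigma(HE) = 1 / (1 + (repress_gain * HE)**repress_exp).
    repress_site
        ``"output"`` (default): sigma multiplies DLL4 production (HE
        represses receptor signalling *activity*); ``"binding"``: sigma
        multiplies ``vegf_bind_on`` (HE represses receptor availability).
    fb_prod
        Production rate of the feedback species P per unit active receptor
        complex -- the knob swept as "P" in the bistability analyses.
    k6, n_exp
        Positive-feedback gain and nonlinearity of the effective-VEGF law.
    deg_dll4, deg_nicd, deg_he, deg_p
        First-order degradation rates.
    receptor_total, notch_total
        Fixed per-cell pools (set via the initial condition; the dynamics
        conserve them).
    """

    vegf_bind_on: float = 1.0
    vegf_bind_off: float = 1.0
    dll4_prod: float = 1.0
    notch_bind_on: float = 1.0
    notch_bind_off: float = 1.0
    nicd_cat: float = 1.0
    he_prod: float = 1.0
    repress_gain: float = 8.0
    repress_exp: float = 2.0
    repress_site: Literal["output", "binding"] = "output"
    fb_prod: float = 0.0
    k6: float = 0.0
    n_exp: float = 2.0
    deg_dll4: float = 1.0
    deg_nicd: float = 1.0
    deg_he: float = 1.0
    deg_p: float = 1.0
    receptor_total: float = 1.0
    notch_total: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "vegf_bind_on", "vegf_bind_off", "dll4_prod", "notch_bind_on",
            "notch_bind_off", "nicd_cat", "he_prod", "repress_gain",
            "fb_prod", "k6", "deg_dll4", "deg_nicd", "deg_he", "deg_p",
            "receptor_total", "notch_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_exp < 1:
            raise ValueError(f"n_exp must be >= 1, got {self.n_exp}")
        if self.repress_exp < 1:
            raise ValueError(f"repress_exp must be >= 1, got {self.repress_exp}")
        if self.repress_site not in ("output", "binding"):
            raise ValueError(f"unknown repress_site {self.repress_site!r}")

    def without_feedback(self) -> "FeedbackParams":
        """The same parameter set with the positive-feedback loop removed."""
        return replace(self, fb_prod=0.0, k6=0.0)


@dataclass
class TwoCellState:
    """Per-cell species concentrations plus the external VEGF inputs."""

    a: np.ndarray
    b: np.ndarray
    V_a: float = 0.0
    V_b: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (N_SPECIES,) or self.b.shape != (N_SPECIES,):
            raise ValueError(f"each cell needs {N_SPECIES} species {SPECIES}")
        if self.V_a < 0 or self.V_b < 0:
            raise ValueError("VEGF inputs must be >= 0")

    def vector(self) -> np.ndarray:
        return np.concatenate([self.a, self.b])

    @classmethod
    def from_vector(cls, y: np.ndarray, V_a: float, V_b: float) -> "TwoCellState":
        y = np.asarray(y, dtype=float)
        return cls(a=y[:N_SPECIES], b=y[N_SPECIES:], V_a=V_a, V_b=V_b)

    def swapped(self) -> "TwoCellState":
        """Exchange cells A and B (and their VEGF inputs)."""
        return TwoCellState(a=self.b.copy(), b=self.a.copy(),
                            V_a=self.V_b, V_b=self.V_a)

    def __getitem__(self, key: tuple) -> float:
        cell, species = key
        arr = self.a if cell in ("a", "A", 0) else self.b
        return float(arr[_IDX[species]])


def initial_state(
    params: FeedbackParams,
    V_a: float,
    V_b: float,
    eps: Optional[float] = None,
) -> TwoCellState:
    """Standard pre-patterning initial condition.

    Full free receptor and Notch pools, every other species zero.  ``eps``
    (default ``1e-4 * receptor_total``) is a deterministic symmetry-breaking
    nudge added to cell A's free receptor; pass ``eps=0`` for an exactly
    symmetric start.
    """
    if eps is None:
        eps = 1e-4 * params.receptor_total
    a = np.zeros(N_SPECIES)
    b = np.zeros(N_SPECIES)
    a[_IDX["R_free"]] = params.receptor_total + eps
    b[_IDX["R_free"]] = params.receptor_total
    a[_IDX["Notch_free"]] = params.notch_total
    b[_IDX["Notch_free"]] = params.notch_total
    return TwoCellState(a=a, b=b, V_a=V_a, V_b=V_b)


def effective_vegf(V, P_level, k6: float, n_exp: float = 2.0):
    """Feedback-amplified VEGF input, ``V * (1 + k6 * P**n_exp)``.

    Monotone non-decreasing in each argument; ``P = 0`` or ``k6 = 0``
    reduce it to the identity on ``V``.  Accepts scalars or arrays.
    """
    V = np.asarray(V, dtype=float)
    P_level = np.asarray(P_level, dtype=float)
    if np.any(V < 0) or np.any(P_level < 0) or k6 < 0 or n_exp < 0:
        raise ValueError("effective_vegf requires non-negative inputs")
    out = V * (1.0 + k6 * P_level ** n_exp)
    return float(out) if out.ndim == 0 else out


def _rhs(y: np.ndarray, V_a: float, V_b: float, p: FeedbackParams) -> np.ndarray:
    """Mass-action right-hand side on the full 16-dim state vector."""
    dy = np.empty_like(y)
    for (i0, j0, V) in ((0, N_SPECIES, V_a), (N_SPECIES, 0, V_b)):
        R, VR, D, Nf, DN, NICD, HE, P = y[i0:i0 + N_SPECIES]
        D_other = y[j0 + _IDX["DLL4"]]
        DN_other = y[j0 + _IDX["DN"]]
        Nf_other = y[j0 + _IDX["Notch_free"]]

        sigma = 1.0 / (1.0 + (p.repress_gain * max(HE, 0.0)) ** p.repress_exp)
        kon = p.vegf_bind_on * (sigma if p.repress_site == "binding" else 1.0)
        veff = V * (1.0 + p.k6 * max(P, 0.0) ** p.n_exp)
        bind = kon * veff * R
        unbind = p.vegf_bind_off * VR

        out_rep = sigma if p.repress_site == "output" else 1.0

        # this cell's DLL4 is consumed/released by binding the *other*
        # cell's Notch (trans), while this cell's Notch binds neighbour DLL4
        dy[i0 + _IDX["R_free"]] = -bind + unbind
        dy[i0 + _IDX["VR"]] = bind - unbind
        dy[i0 + _IDX["DLL4"]] = (
            p.dll4_prod * VR * out_rep
            - p.deg_dll4 * D
            - p.notch_bind_on * D * Nf_other
            + p.notch_bind_off * DN_other
        )
        trans = p.notch_bind_on * D_other * Nf
        dy[i0 + _IDX["Notch_free"]] = -trans + (p.notch_bind_off + p.nicd_cat) * DN
        dy[i0 + _IDX["DN"]] = trans - (p.notch_bind_off + p.nicd_cat) * DN
        dy[i0 + _IDX["NICD"]] = p.nicd_cat * DN - p.deg_nicd * NICD
        dy[i0 + _IDX["HE"]] = p.he_prod * NICD - p.deg_he * HE
        dy[i0 + _IDX["P"]] = p.fb_prod * VR - p.deg_p * P
    return dy


def derivatives(state: TwoCellState, params: FeedbackParams) -> np.ndarray:
    """Mass-action rate vector for the 16 species (cell A then cell B).

    DLL4 of each cell drives Notch binding of the other cell; HE represses
    the cell's own VEGFR pathway output; P feeds back through
    :func:`effective_vegf`.
    """
    return _rhs(state.vector(), state.V_a, state.V_b, params)


@dataclass
class Trajectory:
    """Time-resolved solution of the two-cell system.

    Concentrations are kept as the solver produced them (tiny negative
    undershoots within tolerance are possible); they are clipped to zero
    only at write-out (:meth:`to_dataframe`).
    """

    t: np.ndarray
    y: np.ndarray  # shape (n_times, 16)
    V_a: float
    V_b: float
    params: FeedbackParams
    success: bool = True
    message: str = ""
    rtol: float = 1e-8
    atol: float = 1e-10

    def species(self, cell: str, name: str) -> np.ndarray:
        offset = 0 if cell in ("a", "A") else N_SPECIES
        return self.y[:, offset + _IDX[name]]

    def state_at(self, i: int) -> TwoCellState:
        return TwoCellState.from_vector(self.y[i], self.V_a, self.V_b)

    @property
    def final_state(self) -> TwoCellState:
        return self.state_at(-1)

    def to_dataframe(self):
        """Tidy (time, cell, species, value) frame, clipped at zero."""
        import pandas as pd

        frames = []
        for cell, offset in (("A", 0), ("B", N_SPECIES)):
            for k, name in enumerate(SPECIES):
                frames.append(pd.DataFrame({
                    "time": self.t,
                    "cell": cell,
                    "species": name,
                    "value": np.clip(self.y[:, offset + k], 0.0, None),
                }))
        return pd.concat(frames, ignore_index=True)


def simulate(
    initial: TwoCellState,
    params: FeedbackParams,
    t_end: float,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the stiff two-cell system to ``t_end``.

    Deterministic given its inputs.  Raises :class:`SimulationError` with
    solver diagnostics on failure -- never returns silent NaNs.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if dt_out <= 0:
        raise ValueError(f"dt_out must be > 0, got {dt_out}")
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    if t_eval[-1] > t_end:
        t_eval[-1] = t_end
    sol = solve_ivp(
        lambda _t, y: _rhs(y, initial.V_a, initial.V_b, params),
        (0.0, t_end),
        initial.vector(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(
            f"integration failed: {sol.message} "
            f"(t reached {sol.t[-1] if sol.t.size else 0.0:.3g}/{t_end}, "
            f"nfev={sol.nfev}, V=({initial.V_a}, {initial.V_b}))"
        )
    return Trajectory(t=sol.t, y=sol.y.T, V_a=initial.V_a, V_b=initial.V_b,
                      params=params, success=True, message=sol.message,
                      rtol=rtol, atol=atol)


def simulate_to_equilibrium(
    initial: TwoCellState,
    params: FeedbackParams,
    tol_eq: float = 1e-7,
    window: float = 10.0,
    t_chunk: float = 50.0,
    t_max: float = 5000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[TwoCellState, dict]:
    """Integrate until max |rate| < ``tol_eq`` over a trailing window.

    Returns the equilibrated state and an info dict (time used, residual,
    converged flag).  The residual is the largest |dy/dt| component sampled
    across the trailing ``window`` time units.
    """
    state = initial
    t_used = 0.0
    residual = np.inf
    while t_used < t_max:
        traj = simulate(state, params, t_end=t_chunk, dt_out=window / 4.0,
                        rtol=rtol, atol=atol)
        state = traj.final_state
        t_used += t_chunk
        tail = traj.y[traj.t >= traj.t[-1] - window]
        residual = max(
            float(np.max(np.abs(_rhs(row, state.V_a, state.V_b, params))))
            for row in tail
        )
        if residual < tol_eq:
            return state, {"t_used": t_used, "residual": residual,
                           "converged": True}
    return state, {"t_used": t_used, "residual": residual, "converged": False}


@dataclass
class PatterningOutcome:
    """Tip/inhibited labels and the time at which the pattern locked in."""

    label_a: str
    label_b: str
    resolved: bool
    patterning_time: Optional[float] = None

    @property
    def labels(self) -> tuple[str, str]:
        return (self.label_a, self.label_b)


def _stable_from(t: np.ndarray, ok: np.ndarray, hold_time: float) -> Optional[float]:
    """Earliest time from which ``ok`` holds through the end, if that
    terminal stretch is at least ``hold_time`` long."""
    if not ok[-1]:
        return None
    bad = np.nonzero(~ok)[0]
    start = t[bad[-1] + 1] if bad.size else t[0]
    if t[-1] - start >= hold_time:
        return float(start)
    return None


def classify(
    traj: Trajectory,
    tip_threshold: float,
    inhibited_threshold: float,
    hold_time: float,
) -> PatterningOutcome:
    """Label each cell tip / inhibited / unresolved from its DLL4 trace.

    A cell is *tip* iff its DLL4 stays at or above ``tip_threshold``
    continuously through the end of the trajectory for at least
    ``hold_time``; *inhibited* iff DLL4 stays at or below
    ``inhibited_threshold`` likewise.  The pair is resolved only as a
    complementary tip/inhibited pair; ``patterning_time`` is the earliest
    time from which both conditions hold continuously.
    """
    if tip_threshold <= inhibited_threshold:
        raise ValueError(
            f"tip_threshold ({tip_threshold}) must exceed "
            f"inhibited_threshold ({inhibited_threshold})"
        )
    labels = {}
    times = {}
    for cell in ("A", "B"):
        d = traj.species(cell, "DLL4")
        t_tip = _stable_from(traj.t, d >= tip_threshold, hold_time)
        t_inh = _stable_from(traj.t, d <= inhibited_threshold, hold_time)
        if t_tip is not None:
            labels[cell], times[cell] = "tip", t_tip
        elif t_inh is not None:
            labels[cell], times[cell] = "inhibited", t_inh
        else:
            labels[cell], times[cell] = "unresolved", None
    resolved = sorted(labels.values()) == ["inhibited", "tip"]
    pt = max(times["A"], times["B"]) if resolved else None
    return PatterningOutcome(label_a=labels["A"], label_b=labels["B"],
                             resolved=resolved, patterning_time=pt)
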