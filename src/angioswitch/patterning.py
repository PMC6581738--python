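"""Patterning-speed matrices over paired per-cell VEGF inputs.

For every (V_A, V_B) pair on a low-VEGF grid, the two-cell system is run
from the standard epsilon-perturbed initial state and the outcome is
classified: the entry records the patterning time (time from which a
stable tip/inhibited pair holds) or a failure flag.  Comparing the
feedback-off and feedback-on matrices localizes the VEGF regime in which
lateral inhibition can only pattern when the positive feedback is enabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .li_core import FeedbackParams, classify, initial_state, simulate

__all__ = ["PatterningMatrix", "scan_matrix", "threshold_boundary"]


@dataclass
class PatterningMatrix:
    """Grid of patterning times (NaN where unresolved) for one feedback
    setting; entry [i, j] is the pair (V_A = v_grid[i], V_B = v_grid[j])."""

    v_grid: np.ndarray
    times: np.ndarray     # shape (n, n), NaN = failure
    resolved: np.ndarray  # bool, shape (n, n)
    feedback_on: bool
    horizon: float

    def to_dataframe(self):
        import pandas as pd
        va, vb = np.meshgrid(self.v_grid, self.v_grid, indexing="ij")
        return pd.DataFrame({
            "V_A": va.ravel(),
            "V_B": vb.ravel(),
            "feedback": self.feedback_on,
            "patterning_time": self.times.ravel(),
            "resolved": self.resolved.ravel(),
        })


def scan_matrix(
    params: FeedbackParams,
    v_grid: Sequence[float],
    feedback_on: bool,
    horizon: float = 500.0,
    tip_threshold: float = 0.3,
    inhibited_threshold: float = 0.1,
    hold_time: float = 10.0,
    dt_out: float = 1.0,
    eps: Optional[float] = None,
) -> PatterningMatrix:
    """Simulate and classify every VEGF pair on ``v_grid``.

    ``feedback_on=False`` removes the positive-feedback loop
    (``fb_prod = k6 = 0``) from ``params``.  The deterministic epsilon
    tie-break on cell A's receptor is applied with the same sign across the
    whole scan, so equal-input pairs resolve reproducibly (and the matrix
    is transpose-symmetric only up to that tie-break).
    """
    v_grid = np.asarray(v_grid, dtype=float)
    p = params if feedback_on else params.without_feedback()
    deg_rates = [p.deg_dll4, p.deg_nicd, p.deg_he, p.deg_p, p.vegf_bind_off]
    char_time = 1.0 / max(min(r for r in deg_rates if r > 0), 1e-12)
    if horizon < 10 * char_time:
        warnings.warn(
            f"horizon {horizon} is below 10 characteristic times "
            f"({10 * char_time:.3g}); unresolved flags may reflect the "
            "horizon rather than the dynamics",
            stacklevel=2,
        )
    n = v_grid.size
    times = np.full((n, n), np.nan)
    resolved = np.zeros((n, n), dtype=bool)
    for i, Va in enumerate(v_grid):
        for j, Vb in enumerate(v_grid):
            traj = simulate(initial_state(p, Va, Vb, eps=eps), p,
                            t_end=horizon, dt_out=dt_out)
            out = classify(traj, tip_threshold, inhibited_threshold,
                           hold_time)
            resolved[i, j] = out.resolved
            if out.resolved:
                times[i, j] = out.patterning_time
    return PatterningMatrix(v_grid=v_grid, times=times, resolved=resolved,
                            feedback_on=feedback_on, horizon=horizon)


def threshold_boundary(
    matrix_off: PatterningMatrix,
    matrix_on: PatterningMatrix,
) -> Optional[float]:
    """Upper VEGF bound of the feedback-only patterning regime.

    Returns the largest grid value V such that every pair with both inputs
    <= V fails without feedback and resolves with feedback, or ``None`` if
    no grid value qualifies (no feedback-only regime).
    """
    if matrix_off.v_grid.shape != matrix_on.v_grid.shape or not np.allclose(
            matrix_off.v_grid, matrix_on.v_grid):
        raise ValueError("matrices must share the same VEGF grid")
    v = matrix_off.v_grid
    boundary = None
    for vb in np.sort(v):
        mask = (v[:, None] <= vb) & (v[None, :] <= vb)
        if not mask.any():
            continue
        if (~matrix_off.resolved[mask]).all() and matrix_on.resolved[mask].all():
            boundary = float(vb)
    return boundary
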