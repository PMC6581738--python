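"""Lattice tip-selection competition for an 8-cell vessel row.

A deliberately simplified, fixed-geometry re-implementation of the
membrane-agent ("memAgent") selection competition: eight endothelial cells
sit in a row on a 3-D grid, each represented by a fixed set of surface
memAgents, below a static VEGF field that increases along the y axis.
Per timestep each memAgent activates its receptors against the VEGF
available in its 26 neighbouring environment sites after a fixed sink
(mimicking the decoy receptor Flt1) has depleted them; summed activation
upregulates the cell's Dll4, which Notch-inhibits the receptor level of the
two row-adjacent neighbours on the next step (lateral inhibition with a
one-step expression lag).  No springs, filopodia, migration or shape change
are modelled: the object of study is purely how many cells stabilise as
tips, and how fast, under control, VEGF-inhibited and flt1-knockdown
conditions.

The sink enters subtractively: available VEGF per environment site is
``max(0, E - vsink * sink_unit / 26)``, so receptor activation strictly
decreases as ``vsink`` rises whenever any site retains VEGF -- lowering the
sink (flt1 knockdown) increases activation and selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CellAgent",
    "LatticeConfig",
    "ConditionSpec",
    "LatticeState",
    "SelectionEnsemble",
    "activate_receptors",
    "neighborhood_vegf",
    "build_lattice",
    "step",
    "run_ensemble",
    "count_selected",
    "standard_conditions",
]


@dataclass(frozen=True)
class CellAgent:
    """One cell's membrane-agent bookkeeping (uniform across its agents).

    ``vm`` is the receptor level carried by each memAgent, bounded by the
    cell's receptor capacity ``vmax``; ``mtot`` (the number of memAgents)
    is constant over a run because the geometry is fixed.
    """

    mtot: int
    vmax: float
    vm: float
    dll4: float = 0.0
    notch_in: float = 0.0

    def __post_init__(self) -> None:
        if self.mtot < 1:
            raise ValueError("mtot must be >= 1")
        if not (0.0 <= self.vm <= self.vmax):
            raise ValueError(f"vm must lie in [0, vmax], got {self.vm}")


def activate_receptors(
    agent: CellAgent,
    local_vegf: Sequence[float],
    vsink: float,
    sink_unit: float = 0.1,
) -> float:
    """Receptor activation Vm' of one memAgent.

    The 26 neighbouring environment sites each offer
    ``max(0, E_n - vsink * sink_unit / 26)`` of VEGF after sink depletion;
    activation is linear in the memAgent's receptor level::

        Vm' = vm * (mtot / vmax) * sum_n max(0, E_n - vsink*sink_unit/26)

    Strictly decreasing in ``vsink`` while any site retains VEGF, and
    linear in ``vm``.
    """
    local_vegf = np.asarray(local_vegf, dtype=float)
    if local_vegf.shape != (26,):
        raise ValueError("local_vegf must supply the 26 neighbouring sites")
    if np.any(local_vegf < 0) or vsink < 0:
        raise ValueError("VEGF values and vsink must be >= 0")
    avail = np.clip(local_vegf - vsink * sink_unit / 26.0, 0.0, None)
    return float(agent.vm * (agent.mtot / agent.vmax) * avail.sum())


@dataclass(frozen=True)
class LatticeConfig:
    """Fixed 8-cell row geometry, VEGF field and update-rule constants."""

    n_cells: int = 8
    cell_span: int = 4          # grid sites per cell along x
    nz: int = 2                 # grid sites per cell across z
    ny: int = 8                 # VEGF field depth along y
    vegf_amplitude: float = 0.04   # control field scale (c.u. per site)
    vegf_y_gradient: float = 0.1   # field grows as amplitude*(0.9 + grad*y)
    sink_unit: float = 0.1
    vmax: float = 80.0          # receptor capacity per cell
    dll4_cap: float = 1.0
    dll4_k: float = 0.25        # half-saturation of Dll4 induction (Hill-2)
    notch_strength: float = 6.0
    notch_exp: float = 2.0
    vm_relax: float = 0.12      # per-step receptor relaxation fraction
    vm_init_frac: float = 0.1   # initial receptor level / baseline
    jitter: float = 0.05        # uniform +/- fraction on per-cell baseline
    tip_signal_threshold: float = 0.14
    n_steps: int = 200
    n_replicates: int = 100
    hold_steps: int = 10        # consecutive tip steps to count as selected
    window: tuple = (20, 60)    # early selection window (timesteps)
    seed: int = 0

    @property
    def mtot(self) -> int:
        return self.cell_span * self.nz


@dataclass(frozen=True)
class ConditionSpec:
    """A named perturbation of the VEGF field amplitude and/or sink."""

    label: str
    vegf_amplitude: Optional[float] = None  # None -> config reference field
    vsink: float = 9.0

    def __post_init__(self) -> None:
        if self.vegf_amplitude is not None and self.vegf_amplitude < 0:
            raise ValueError("vegf_amplitude must be >= 0")
        if self.vsink < 0:
            raise ValueError("vsink must be >= 0")


def standard_conditions() -> dict[str, ConditionSpec]:
    """Control (Vsink = 9), VEGF-inhibited (field = 0.038) and flt1
    knockdown (Vsink = 8)."""
    return {
        "control": ConditionSpec("control", vegf_amplitude=None, vsink=9.0),
        "vegf_inhibited": ConditionSpec("vegf_inhibited",
                                        vegf_amplitude=0.038, vsink=9.0),
        "flt1_kd": ConditionSpec("flt1_kd", vegf_amplitude=None, vsink=8.0),
    }


def _field_value(cfg: LatticeConfig, amplitude: float, y: int) -> float:
    """VEGF at an environment site; defined for y >= 1 above the cell row."""
    if y < 1 or y >= cfg.ny:
        return 0.0
    return amplitude * (0.9 + cfg.vegf_y_gradient * y)


def neighborhood_vegf(cfg: LatticeConfig, amplitude: float,
                      site: tuple[int, int, int]) -> np.ndarray:
    """VEGF in the 26 sites surrounding one memAgent site.

    Sites outside the grid, on the cell row (y = 0) or below it carry no
    VEGF.
    """
    x, y, z = site
    nx = cfg.n_cells * cfg.cell_span
    vals = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                xs, ys, zs = x + dx, y + dy, z + dz
                if 0 <= xs < nx and 0 <= zs < cfg.nz:
                    vals.append(_field_value(cfg, amplitude, ys))
                else:
                    vals.append(0.0)
    return np.asarray(vals)


def build_lattice(cfg: LatticeConfig, condition: ConditionSpec) -> np.ndarray:
    """Per-cell receptor drive: summed sink-depleted neighbourhood VEGF
    over the cell's memAgents (constant over a run; the field is static)."""
    amplitude = (cfg.vegf_amplitude if condition.vegf_amplitude is None
                 else condition.vegf_amplitude)
    sink = condition.vsink * cfg.sink_unit / 26.0
    drive = np.zeros(cfg.n_cells)
    for c in range(cfg.n_cells):
        for sx in range(c * cfg.cell_span, (c + 1) * cfg.cell_span):
            for sz in range(cfg.nz):
                env = neighborhood_vegf(cfg, amplitude, (sx, 0, sz))
                drive[c] += np.clip(env - sink, 0.0, None).sum()
    return drive


@dataclass
class LatticeState:
    """Mutable per-cell state of one run."""

    vm: np.ndarray        # per-memAgent receptor level, uniform within cell
    vm_base: np.ndarray   # jittered per-cell baseline receptor level
    dll4: np.ndarray
    signal: np.ndarray    # summed memAgent activation Vm' per cell
    tip: np.ndarray       # bool


def step(state: LatticeState, cfg: LatticeConfig,
         drive: np.ndarray) -> LatticeState:
    """One discrete timestep of the selection competition.

    Receptor activation per cell is the memAgent sum
    ``signal = vm * (mtot/vmax) * drive`` (``drive`` already aggregates the
    sink-depleted neighbourhood VEGF over the cell's memAgents); Dll4 is
    induced from the summed activation with saturation; Notch inhibition
    from the two row neighbours downregulates the receptor baseline on the
    *next* step (one-step gene-expression lag).  Deterministic.
    """
    signal = state.vm * (cfg.mtot / cfg.vmax) * drive
    s2 = signal ** 2
    dll4 = cfg.dll4_cap * s2 / (s2 + cfg.dll4_k ** 2)
    # mean (not sum) over the existing row neighbours, so a uniform state
    # is an invariant of the dynamics and symmetric inputs stalemate
    inhib = np.zeros_like(dll4)
    nn = np.zeros_like(dll4)
    inhib[:-1] += dll4[1:]
    inhib[1:] += dll4[:-1]
    nn[:-1] += 1
    nn[1:] += 1
    inhib = inhib / nn
    target = state.vm_base / (1.0 + (cfg.notch_strength * inhib) ** cfg.notch_exp)
    vm = (1.0 - cfg.vm_relax) * state.vm + cfg.vm_relax * target
    tip = signal >= cfg.tip_signal_threshold
    return LatticeState(vm=vm, vm_base=state.vm_base, dll4=dll4,
                        signal=signal, tip=tip)


@dataclass
class SelectionEnsemble:
    """Per-replicate, per-timestep, per-cell tip records for one condition."""

    condition: ConditionSpec
    config: LatticeConfig
    tips: np.ndarray     # bool, (n_replicates, n_steps, n_cells)
    signal: np.ndarray   # (n_replicates, n_steps, n_cells)
    dll4: np.ndarray     # (n_replicates, n_steps, n_cells)

    def to_dataframe(self):
        import pandas as pd
        r, t, c = np.meshgrid(
            np.arange(self.tips.shape[0]),
            np.arange(self.tips.shape[1]),
            np.arange(self.tips.shape[2]),
            indexing="ij",
        )
        return pd.DataFrame({
            "replicate": r.ravel(), "t": t.ravel(), "cell": c.ravel(),
            "tip": self.tips.ravel(),
            "signal": self.signal.ravel(), "dll4": self.dll4.ravel(),
        })


def _initial_state(cfg: LatticeConfig, rng: np.random.Generator,
                   jitter: Optional[float] = None) -> LatticeState:
    j = cfg.jitter if jitter is None else jitter
    base = (cfg.vmax / cfg.mtot) * (1.0 + rng.uniform(-j, j, cfg.n_cells))
    vm = cfg.vm_init_frac * base
    zeros = np.zeros(cfg.n_cells)
    return LatticeState(vm=vm, vm_base=base, dll4=zeros.copy(),
                        signal=zeros.copy(), tip=zeros.astype(bool))


def run_ensemble(cfg: LatticeConfig, condition: ConditionSpec) -> SelectionEnsemble:
    """Seeded replicate runs (default 100 x up to 200 timesteps).

    Per-replicate initial receptor baselines are jittered by seeded uniform
    noise; the full per-timestep time series is retained.  Bit-for-bit
    reproducible from ``cfg.seed``.
    """
    n_r, n_t, n_c = cfg.n_replicates, cfg.n_steps, cfg.n_cells
    drive = build_lattice(cfg, condition)
    tips = np.zeros((n_r, n_t, n_c), dtype=bool)
    signal = np.zeros((n_r, n_t, n_c))
    dll4 = np.zeros((n_r, n_t, n_c))
    for r in range(n_r):
        rng = np.random.default_rng([cfg.seed, r])
        state = _initial_state(cfg, rng)
        for t in range(n_t):
            state = step(state, cfg, drive)
            tips[r, t] = state.tip
            signal[r, t] = state.signal
            dll4[r, t] = state.dll4
    return SelectionEnsemble(condition=condition, config=cfg, tips=tips,
                             signal=signal, dll4=dll4)


def count_selected(
    ensemble: SelectionEnsemble,
    window: Optional[tuple[int, int]] = None,
    hold_steps: Optional[int] = None,
) -> tuple[float, float]:
    """Mean +/- SEM of cells selected per replicate in an early window.

    A cell counts as selected in a replicate if it held tip state for at
    least ``hold_steps`` consecutive timesteps ending inside ``window``.
    SEM is the sample standard deviation over replicates divided by
    sqrt(n_replicates).
    """
    cfg = ensemble.config
    if window is None:
        window = cfg.window
    if hold_steps is None:
        hold_steps = cfg.hold_steps
    lo, hi = window
    n_t = ensemble.tips.shape[1]
    if not (0 <= lo <= hi < n_t):
        raise ValueError(f"window {window} outside simulated span [0, {n_t})")
    tips = ensemble.tips
    runs = np.zeros_like(tips, dtype=int)
    runs[:, 0] = tips[:, 0]
    for t in range(1, n_t):
        runs[:, t] = np.where(tips[:, t], runs[:, t - 1] + 1, 0)
    selected = (runs[:, lo:hi + 1] >= hold_steps).any(axis=1)
    counts = selected.sum(axis=1).astype(float)
    mean = float(counts.mean())
    sem = (float(counts.std(ddof=1) / np.sqrt(counts.size))
           if counts.size > 1 else 0.0)
    return mean, sem
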