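"""Synthetic imaging-style cohorts and the quantification procedures.

The in-vivo observable is a per-vessel record of when endothelial cells
are selected to sprout, whether they proliferate, where their nuclei sit
dorsally over time, and how strongly they signal.  This module generates
such records under a simple, explicit generative model -- a homogeneous
Poisson selection process truncated at a Notch-dependent window-closure
time, Bernoulli proliferation, linear dorsal migration plus a shared embryo
drift -- and implements the quantifiers applied to them: selection counts
over time, vessel cellularity distributions, drift-corrected track
normalisation against the dorsal-aorta reference, an in-silico
receptor-inhibition robustness protocol on the two-cell model, and the
deterministic transcript-ratio candidate filter.

Control defaults are calibrated so that the mean number of selections per
vessel by the 24-hpf mark is ~2; genotype variants encode direction only
(loss of Notch closure keeps the window open; reduced VEGF signalling
lowers the selection rate; flt1 loss raises it).

All distributional choices are model conveniences, not measurements: see
docs/methods.md for what they do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .li_core import FeedbackParams, initial_state, simulate_to_equilibrium

__all__ = [
    "CohortParams",
    "VesselRecord",
    "FilterThresholds",
    "gen_cohort",
    "quantify_selection",
    "quantify_cellularity",
    "normalize_tracks",
    "estimate_selection_rate",
    "estimate_closure_time",
    "robustness_protocol",
    "filter_candidates",
    "make_toy_transcript_table",
    "GENOTYPES",
]

#: Direction-only genotype effects on the selection rate and the closure
#: window (effect sizes are figure-borne in vivo, so these encode sign).
GENOTYPES = {
    "control": dict(rate_multiplier=1.0, close_window=True, prolif_prob=None),
    "dll4_kd": dict(rate_multiplier=1.0, close_window=False, prolif_prob=0.6),
    "flt1_kd": dict(rate_multiplier=1.5, close_window=True, prolif_prob=None),
    "vegfr_inhibited": dict(rate_multiplier=0.5, close_window=True,
                            prolif_prob=None),
    "tm4sf18_mut": dict(rate_multiplier=0.6, close_window=True,
                        prolif_prob=None),
}


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for a synthetic vessel cohort.

    Times are in hours post-fertilisation (hpf); positions in micrometres.
    Control defaults give ``rate * (24 - t_start) = 2`` selections per
    vessel by 24 hpf.
    """

    rate: float = 0.4            # selection events / vessel / hour
    t_start: float = 19.0        # observation / selection onset (hpf)
    window_close: Optional[float] = 25.0  # T_c; None = never closes
    t_end: float = 34.0          # observation end (hpf)
    prolif_prob: float = 0.3     # Bernoulli per selected EC per window
    track_dt: float = 0.3        # imaging interval (h)
    dorsal_speed: float = 10.0   # EC dorsal migration (um/h)
    drift_amplitude: float = 3.0 # embryo drift random-walk scale (um/step)
    track_noise: float = 0.5     # per-timepoint positional noise (um)
    readout_sigma: float = 0.3   # lognormal sigma of signalling readouts
    genotype: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.window_close is not None and self.window_close <= self.t_start:
            raise ValueError("window_close must exceed t_start")
        if not 0.0 <= self.prolif_prob <= 1.0:
            raise ValueError("prolif_prob must be a probability")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @classmethod
    def for_genotype(cls, genotype: str, seed: int = 0,
                     **overrides) -> "CohortParams":
        """Control defaults adjusted for a named genotype/condition."""
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}; "
                             f"choose from {sorted(GENOTYPES)}")
        eff = GENOTYPES[genotype]
        base = cls(seed=seed, genotype=genotype)
        kw = dict(rate=base.rate * eff["rate_multiplier"])
        if not eff["close_window"]:
            kw["window_close"] = None
        if eff["prolif_prob"] is not None:
            kw["prolif_prob"] = eff["prolif_prob"]
        kw.update(overrides)
        return replace(base, **kw)


@dataclass
class VesselRecord:
    """One vessel's synthetic observation record."""

    vessel_id: int
    genotype: str
    selection_times: np.ndarray      # hpf, sorted
    proliferation_times: np.ndarray  # hpf
    track_times: np.ndarray          # shared imaging grid (hpf)
    tracks: np.ndarray               # (n_ecs, n_t) raw dorsal positions (um)
    reference_track: np.ndarray      # dorsal-aorta position (n_t,), same grid
    readouts: np.ndarray             # per-EC signalling intensity (a.u.)

    @property
    def cellularity(self) -> int:
        """Final EC count: selections plus surviving proliferations."""
        return len(self.selection_times) + len(self.proliferation_times)


def gen_cohort(params: CohortParams, n_vessels: int) -> list[VesselRecord]:
    """Draw a synthetic cohort of ``n_vessels`` vessel records.

    Selection times follow a homogeneous Poisson process at ``params.rate``
    truncated at the closure time (no truncation when ``window_close`` is
    None, emulating loss of Notch-mediated closure).  Each selected EC
    migrates dorsally at constant speed on top of a shared random-walk
    embryo drift, sampled on the imaging grid, with i.i.d. positional
    noise; per-EC signalling readouts are lognormal.
    """
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    rng = np.random.default_rng(params.seed)
    t_close = (params.t_end if params.window_close is None
               else min(params.window_close, params.t_end))
    times = np.arange(params.t_start, params.t_end + 0.5 * params.track_dt,
                      params.track_dt)
    vessels = []
    for v in range(n_vessels):
        # Poisson process on [t_start, t_close)
        n_sel = rng.poisson(params.rate * (t_close - params.t_start))
        sel = np.sort(rng.uniform(params.t_start, t_close, n_sel))
        prolif_mask = rng.random(n_sel) < params.prolif_prob
        prolif = np.array([
            rng.uniform(t, params.t_end) for t in sel[prolif_mask]
        ])
        # shared embryo drift: random walk on the imaging grid
        drift = np.concatenate([
            [0.0],
            np.cumsum(rng.normal(0.0, params.drift_amplitude,
                                 times.size - 1)),
        ])
        tracks = np.empty((n_sel, times.size))
        for k, t0 in enumerate(sel):
            motion = params.dorsal_speed * np.clip(times - t0, 0.0, None)
            tracks[k] = (motion + drift
                         + rng.normal(0.0, params.track_noise, times.size))
        reference = drift + rng.normal(0.0, params.track_noise, times.size)
        readouts = rng.lognormal(0.0, params.readout_sigma, n_sel)
        vessels.append(VesselRecord(
            vessel_id=v, genotype=params.genotype,
            selection_times=sel, proliferation_times=prolif,
            track_times=times, tracks=tracks, reference_track=reference,
            readouts=readouts,
        ))
    return vessels


def quantify_selection(cohort: Sequence[VesselRecord],
                       timepoints: Sequence[float]) -> pd.DataFrame:
    """Mean +/- SEM selections per vessel at each timepoint.

    Counts selection events at or before each timepoint, averaged over
    vessels; SEM over vessels.  Invariant to vessel ordering.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    counts = np.array([
        [(v.selection_times <= t).sum() for t in timepoints]
        for v in cohort
    ], dtype=float)
    mean = counts.mean(axis=0)
    sem = (counts.std(axis=0, ddof=1) / np.sqrt(len(cohort))
           if len(cohort) > 1 else np.zeros_like(mean))
    return pd.DataFrame({"timepoint": timepoints, "mean": mean, "sem": sem})


def quantify_cellularity(cohort: Sequence[VesselRecord]) -> dict:
    """Distribution of vessel cellularity over {1, 2, >=3} and the mean.

    Vessels with zero ECs (no selection before closure) never form a
    scorable vessel and are excluded, mirroring how only existing vessels
    can be scored in vivo.
    """
    cells = np.array([v.cellularity for v in cohort])
    cells = cells[cells >= 1]
    if cells.size == 0:
        raise ValueError("no vessels with at least one EC")
    fractions = {
        "1": float((cells == 1).mean()),
        "2": float((cells == 2).mean()),
        "3+": float((cells >= 3).mean()),
    }
    return {"fractions": fractions, "mean": float(cells.mean()),
            "n_vessels": int(cells.size)}


def normalize_tracks(tracks: np.ndarray,
                     reference_track: np.ndarray) -> np.ndarray:
    """Drift-corrected dorsal movement relative to the dorsal aorta.

    Subtracts the reference (dorsal-aorta) position at each timepoint from
    every track sharing the same time grid; output is micrometres relative
    to the DA.
    """
    tracks = np.atleast_2d(np.asarray(tracks, dtype=float))
    reference_track = np.asarray(reference_track, dtype=float)
    if tracks.shape[-1] != reference_track.shape[-1]:
        raise ValueError("tracks and reference must share the time grid")
    return tracks - reference_track[None, :]


def estimate_closure_time(cohort: Sequence[VesselRecord]) -> float:
    """Plateau (window-closure) time estimated as the latest selection
    event observed in the cohort; accurate to the sampling interval once
    the cohort carries enough events."""
    latest = [v.selection_times[-1] for v in cohort
              if v.selection_times.size]
    if not latest:
        raise ValueError("cohort contains no selection events")
    return float(max(latest))


def estimate_selection_rate(cohort: Sequence[VesselRecord],
                            t_start: float,
                            t_close: Optional[float] = None) -> float:
    """Selection rate (events/vessel/hour) before window closure.

    ``t_close`` defaults to :func:`estimate_closure_time` on the same
    cohort.
    """
    if t_close is None:
        t_close = estimate_closure_time(cohort)
    if t_close <= t_start:
        raise ValueError("t_close must exceed t_start")
    n_events = sum((v.selection_times <= t_close).sum() for v in cohort)
    return float(n_events / (len(cohort) * (t_close - t_start)))


def robustness_protocol(
    params: FeedbackParams,
    inhibition_levels: Sequence[float],
    feedback_on: bool = True,
    v_ref: float = 3.0,
    tip_threshold: float = 0.3,
    eps: Optional[float] = None,
) -> pd.DataFrame:
    """In-silico graded receptor-inhibition of the patterned two-cell state.

    The system is first equilibrated at the reference VEGF with the chosen
    feedback setting; each inhibition level then scales receptor activation
    (``vegf_bind_on * (1 - level)``) and the system is re-equilibrated from
    the active baseline state.  Returns the winning-cell DLL4 (pathway
    output) per level plus an ``active`` flag against ``tip_threshold``.
    With feedback the output is retained near baseline until the bistable
    region is exited; without feedback it declines gradedly from the start.
    """
    levels = np.asarray(inhibition_levels, dtype=float)
    if np.any((levels < 0) | (levels >= 1)):
        raise ValueError("inhibition levels must lie in [0, 1)")
    p = params if feedback_on else params.without_feedback()
    base_state, info = simulate_to_equilibrium(
        initial_state(p, v_ref, v_ref, eps=eps), p)
    rows = []
    for lvl in levels:
        p_l = replace(p, vegf_bind_on=p.vegf_bind_on * (1.0 - float(lvl)))
        st = base_state.__class__(a=base_state.a.copy(),
                                  b=base_state.b.copy(),
                                  V_a=v_ref, V_b=v_ref)
        st, _ = simulate_to_equilibrium(st, p_l)
        out = max(st["A", "DLL4"], st["B", "DLL4"])
        rows.append({"inhibition": float(lvl), "winning_dll4": out,
                     "active": out >= tip_threshold})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FilterThresholds:
    """Printed cut-offs of the transcript candidate filter."""

    background_floor: float = 100.0   # raw green processed signal
    su5416_ratio_max: float = 0.4     # SU5416 / DMSO
    dapt_ratio_min: float = 1.5       # DAPT / DMSO
    su_dapt_ratio_max: float = 1.0    # SU5416+DAPT / DMSO

    def __post_init__(self) -> None:
        for name in ("background_floor", "su5416_ratio_max",
                     "dapt_ratio_min", "su_dapt_ratio_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


FILTER_COLUMNS = ("raw_signal", "ratio_su5416", "ratio_dapt", "ratio_su_dapt")


def filter_candidates(
    table: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Deterministic VEGFR-activated / Notch-repressed transcript filter.

    Keeps rows with raw signal at or above the background floor, a
    VEGFR-inhibition (SU5416) ratio below 0.4, a Notch-inhibition (DAPT)
    ratio above 1.5 and a double-treatment ratio below 1.
    """
    missing = [c for c in FILTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    keep = (
        (table["raw_signal"] >= thresholds.background_floor)
        & (table["ratio_su5416"] < thresholds.su5416_ratio_max)
        & (table["ratio_dapt"] > thresholds.dapt_ratio_min)
        & (table["ratio_su_dapt"] < thresholds.su_dapt_ratio_max)
    )
    return table.loc[keep].copy()


def make_toy_transcript_table(n_rows: int = 50, seed: int = 0,
                              n_planted: int = 5) -> pd.DataFrame:
    """Random toy per-probe table with a few planted pass-all rows.

    Synthetic stand-in for a per-probe expression-ratio table; column
    semantics match :data:`FILTER_COLUMNS`.
    """
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "transcript": [f"probe_{i:04d}" for i in range(n_rows)],
        "raw_signal": rng.lognormal(5.0, 1.5, n_rows),
        "ratio_su5416": rng.lognormal(0.0, 0.6, n_rows),
        "ratio_dapt": rng.lognormal(0.0, 0.6, n_rows),
        "ratio_su_dapt": rng.lognormal(0.0, 0.6, n_rows),
    })
    planted = rng.choice(n_rows, size=min(n_planted, n_rows), replace=False)
    table.loc[planted, "raw_signal"] = rng.uniform(200, 2000, planted.size)
    table.loc[planted, "ratio_su5416"] = rng.uniform(0.05, 0.35, planted.size)
    table.loc[planted, "ratio_dapt"] = rng.uniform(1.6, 4.0, planted.size)
    table.loc[planted, "ratio_su_dapt"] = rng.uniform(0.3, 0.95, planted.size)
    return table
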