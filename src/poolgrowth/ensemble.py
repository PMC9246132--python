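"""Trajectory- and distribution-level phenomenology.

Covers the stochastic signatures that distinguish the growth regimes:
residence times in the branches of a bistable size distribution, the
no-growth / shoulder / bistable state diagram, the two-structure coexistence
phase map, anticorrelation of sizes on the limiting-pool line, and stochastic
selection of a single dominant structure (polarity establishment) under
autocatalytic growth.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import FeedbackParams, PoolConfig
from .master_equation import (StationaryDistribution, count_modes,
                              stationary_joint_two, stationary_single)
from .ssa import SimulationSpec, Trajectory, gillespie_run

__all__ = [
    "ResidenceTimeStats",
    "DynamicState",
    "DynamicStateLabel",
    "SelectionResult",
    "residence_times",
    "high_state_residence",
    "classify_dynamic_state",
    "coexistence_phase",
    "anticorrelation",
    "windowed_anticorrelation",
    "polarity_selection",
]


@dataclass
class ResidenceTimeStats:
    """Dwell-time statistics between the low and high branches.

    State assignment uses two-threshold hysteresis on the occupied fraction
    n_i / N_current: the high state is entered at >= hi_frac, the low state
    at <= lo_frac, and in-between samples keep the previous state, which
    suppresses spurious switch counts from small fluctuations.  When no
    completed switch is observed, tau_R is a censored lower bound.
    """

    tau_R: float
    dwell_samples: np.ndarray
    dwell_states: np.ndarray     # +1 (high) / -1 (low) per completed dwell
    n_transitions: int
    lo_frac: float
    hi_frac: float
    censored: bool
    final_dwell: float = 0.0     # ongoing stay at the end of the run
    final_state: int = 0         # state of the ongoing stay

    @property
    def n_dwells(self) -> int:
        return self.dwell_samples.size

    @property
    def tau_R_censoring_aware(self) -> float:
        """Mean dwell including the ongoing final stay as a lower bound.

        At large pools the structure may never leave its selected state
        within the run; dropping that ongoing stay would bias tau_R low, so
        it enters the mean as a censored sample.
        """
        if self.dwell_samples.size == 0:
            return self.final_dwell
        return float(np.append(self.dwell_samples, self.final_dwell).mean())

    def state_dwells(self, state: int, include_final: bool = True) -> np.ndarray:
        """Dwell samples of one state (+1 high / -1 low).

        With ``include_final`` the ongoing last stay enters as a censored
        (lower-bound) sample when it belongs to the requested state.
        """
        d = self.dwell_samples[self.dwell_states == state]
        if include_final and self.final_state == state:
            d = np.append(d, self.final_dwell)
        return d


def high_state_residence(p: FeedbackParams, N: int, V: float, t_max: float,
                         seeds: Sequence[int], lo_frac: float = 0.25,
                         hi_frac: float = 0.75,
                         record_dt: float | None = None) -> np.ndarray:
    """Per-seed survival time of the large state, censored at t_max.

    Starts each run with the structure holding essentially the whole pool
    and measures the first dwell in the high state — the time until the
    large structure first collapses below ``lo_frac`` of the pool.  Runs in
    which no collapse occurs contribute the full observation window as a
    censored lower bound, so the estimate saturates rather than drops when
    the large state becomes effectively permanent.
    """
    dt = record_dt if record_dt is not None else max(t_max / 300000.0, 0.5)
    out = []
    for seed in seeds:
        cfg = PoolConfig(N_total=N, V=V, M=1)
        spec = SimulationSpec(cfg=cfg, params=[p], seed=int(seed) % 2**31,
                              t_max=t_max, record_dt=dt,
                              init_sizes=[max(N - 1, 0)])
        st = residence_times(gillespie_run(spec), 0, lo_frac, hi_frac)
        d = st.state_dwells(1)
        out.append(float(d[0]) if d.size else 0.0)
    return np.asarray(out)


class DynamicState(str, enum.Enum):
    NO_GROWTH = "no_growth"
    SHOULDER = "shoulder"
    BISTABLE = "bistable"
    MONOSTABLE_LARGE = "monostable_large"


@dataclass
class DynamicStateLabel:
    value: DynamicState
    criteria_record: dict


def residence_times(tr: Trajectory, structure: int = 0,
                    lo_frac: float = 0.25, hi_frac: float = 0.75
                    ) -> ResidenceTimeStats:
    """Mean residence time of one structure between its low and high states."""
    if not 0 < lo_frac < hi_frac < 1:
        raise ValueError("need 0 < lo_frac < hi_frac < 1")
    frac = tr.sizes[:, structure] / np.maximum(tr.N_current, 1)
    times = tr.times
    state = 0              # 0 undetermined, +1 high, -1 low
    entry_t = times[0] if times.size else 0.0
    dwells: list[float] = []
    dwell_states: list[int] = []
    for k in range(frac.size):
        new = state
        if frac[k] >= hi_frac:
            new = 1
        elif frac[k] <= lo_frac:
            new = -1
        if new != state:
            if state != 0:
                dwells.append(times[k] - entry_t)
                dwell_states.append(state)
            state = new
            entry_t = times[k]
    dwell_arr = np.asarray(dwells, dtype=float)
    state_arr = np.asarray(dwell_states, dtype=np.int64)
    n_trans = dwell_arr.size
    final_dwell = (tr.t_end - entry_t) if state != 0 else tr.t_end - times[0]
    if n_trans == 0:
        # censored: never saw a completed stay; tau_R is a lower bound
        return ResidenceTimeStats(tau_R=float(final_dwell),
                                  dwell_samples=dwell_arr,
                                  dwell_states=state_arr, n_transitions=0,
                                  lo_frac=lo_frac, hi_frac=hi_frac,
                                  censored=True, final_dwell=float(final_dwell),
                                  final_state=state)
    return ResidenceTimeStats(tau_R=float(dwell_arr.mean()),
                              dwell_samples=dwell_arr, dwell_states=state_arr,
                              n_transitions=n_trans,
                              lo_frac=lo_frac, hi_frac=hi_frac, censored=False,
                              final_dwell=float(final_dwell),
                              final_state=state)


def classify_dynamic_state(p: FeedbackParams, N: int, V: float = 1.0,
                           small_mode_max: int = 2,
                           tail_factor: float = 3.0,
                           tail_mass_threshold: float = 0.01
                           ) -> DynamicStateLabel:
    """Label the growth regime from the exact stationary distribution.

    Decision rule (thresholds recorded in the returned criteria):
    two modes -> bistable; one mode located at n <= 2 with more than 1% of
    mass beyond 3x the mean -> shoulder (near-exponential body with a long
    tail); one small mode with CV >= 1 and no such tail -> no_growth;
    otherwise monostable_large.
    """
    d = stationary_single(p, N, V)
    modes = count_modes(d)
    mode_loc = int(np.argmax(d.probs))
    mean, cv = d.mean, d.cv
    tail_mass = float(d.probs[d.support > tail_factor * mean].sum()) \
        if mean > 0 else 0.0
    rec = {"modes": modes, "mode_location": mode_loc, "mean": mean, "cv": cv,
           "tail_mass": tail_mass, "small_mode_max": small_mode_max,
           "tail_factor": tail_factor,
           "tail_mass_threshold": tail_mass_threshold,
           "kappa": p.kappa, "alpha": p.alpha, "beta": p.beta, "N": N, "V": V}
    if modes >= 2:
        label = DynamicState.BISTABLE
    elif mode_loc <= small_mode_max and tail_mass > tail_mass_threshold:
        label = DynamicState.SHOULDER
    elif mode_loc <= small_mode_max and cv >= 1.0:
        label = DynamicState.NO_GROWTH
    else:
        label = DynamicState.MONOSTABLE_LARGE
    return DynamicStateLabel(value=label, criteria_record=rec)


def coexistence_phase(alpha_beta_values: Sequence[float],
                      kappa1_values: Sequence[float],
                      kappa2: float, N: int, V: float = 1.0):
    """Coexistence phase map of two competing structures.

    For each (alpha+beta, kappa1) grid cell the exact joint law gives both
    marginal means; the pair coexists when both means exceed one subunit.
    Returns (coexist boolean array, mean1 array, mean2 array), each of shape
    (len(alpha_beta_values), len(kappa1_values)).
    """
    ab_vals = np.asarray(alpha_beta_values, dtype=float)
    k1_vals = np.asarray(kappa1_values, dtype=float)
    shape = (ab_vals.size, k1_vals.size)
    coexist = np.zeros(shape, dtype=bool)
    mean1 = np.zeros(shape)
    mean2 = np.zeros(shape)
    for a, ab in enumerate(ab_vals):
        for b, k1 in enumerate(k1_vals):
            p1 = FeedbackParams.from_kappa(0.0, ab, k1)
            p2 = FeedbackParams.from_kappa(0.0, ab, kappa2)
            j = stationary_joint_two(p1, p2, N, V)
            m1, m2 = j.marginal_mean(1), j.marginal_mean(2)
            mean1[a, b], mean2[a, b] = m1, m2
            coexist[a, b] = (m1 > 1.0) and (m2 > 1.0)
    return coexist, mean1, mean2


def anticorrelation(tr: Trajectory, burn_in: float | None = None) -> float:
    """Holding-time-weighted Pearson correlation of the two structure sizes."""
    if tr.M != 2:
        raise ValueError("anticorrelation requires an M=2 trajectory")
    sub = tr.after(tr.burn_in_time() if burn_in is None else burn_in)
    w = sub.holding_weights()
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("empty post-burn-in window")
    x = sub.sizes[:, 0].astype(float)
    y = sub.sizes[:, 1].astype(float)
    mx, my = (x * w).sum() / wsum, (y * w).sum() / wsum
    sx = math.sqrt(((x - mx) ** 2 * w).sum() / wsum)
    sy = math.sqrt(((y - my) ** 2 * w).sum() / wsum)
    if sx == 0 or sy == 0:
        return float("nan")
    cov = ((x - mx) * (y - my) * w).sum() / wsum
    return float(cov / (sx * sy))


def windowed_anticorrelation(tr: Trajectory, window: float,
                             burn_in: float | None = None) -> float:
    """Time-averaged within-window Pearson correlation of the two sizes.

    In a growing cell the common upward trend of both structures masks the
    anticorrelated fluctuations of pool competition; correlating inside
    windows short against the growth timescale (but long against the
    structure dynamics) removes the trend.  Windows with degenerate variance
    are skipped; the result is the duration-weighted mean over windows.
    """
    if tr.M != 2:
        raise ValueError("windowed anticorrelation requires M=2")
    sub = tr.after(tr.burn_in_time() if burn_in is None else burn_in)
    t0, t1 = sub.times[0], sub.t_end
    corrs, weights = [], []
    lo = t0
    while lo < t1:
        hi = min(lo + window, t1)
        m = (sub.times >= lo) & (sub.times < hi)
        if m.sum() >= 10:
            x = sub.sizes[m, 0].astype(float)
            y = sub.sizes[m, 1].astype(float)
            if x.std() > 0 and y.std() > 0:
                corrs.append(float(np.corrcoef(x, y)[0, 1]))
                weights.append(hi - lo)
        lo = hi
    if not corrs:
        return float("nan")
    return float(np.average(corrs, weights=weights))


@dataclass
class SelectionResult:
    """Outcome of stochastic single-structure selection across seeds."""

    winners: list            # per-seed dominant index at t_max, or None
    persisted: list          # per-seed: dominance held over the final window
    flicker_counts: list     # per-seed distinct dominant identities over time
    single_winner_fraction: float
    winner_counts: np.ndarray
    chi2_pvalue: float


def _dominant(sizes_row: np.ndarray) -> int | None:
    consumed = sizes_row.sum()
    if consumed <= 0:
        return None
    i = int(np.argmax(sizes_row))
    return i if sizes_row[i] > 0.5 * consumed else None


def polarity_selection(M: int, p: FeedbackParams, N: int, V: float,
                       t_max: float, seeds: Sequence[int],
                       record_dt: float | None = None,
                       final_window: float = 0.1) -> SelectionResult:
    """Stochastic selection of one dominant structure among M competitors.

    Runs one seeded SSA per entry of ``seeds``; a structure is dominant when
    it holds more than half of the consumed pool.  Reports the final winner
    per seed, whether its dominance persisted over the last ``final_window``
    fraction of the run, how many distinct dominants appeared (flickering),
    and a chi-square test of winner uniformity across structures.
    """
    from scipy.stats import chisquare

    cfg = PoolConfig(N_total=N, V=V, M=M)
    dt = record_dt if record_dt is not None else t_max / 2000.0
    winners, persisted, flickers = [], [], []
    for seed in seeds:
        spec = SimulationSpec(cfg=cfg, params=[p] * M, seed=int(seed) % 2**31,
                              t_max=t_max, record_dt=dt)
        tr = gillespie_run(spec)
        doms = [_dominant(row) for row in tr.sizes]
        w = doms[-1]
        winners.append(w)
        tail = [d for t, d in zip(tr.times, doms)
                if t >= (1.0 - final_window) * t_max]
        persisted.append(w is not None and all(d == w for d in tail))
        flickers.append(len({d for d in doms if d is not None}))
    wins = [w for w in winners if w is not None]
    counts = np.bincount(wins, minlength=M) if wins else np.zeros(M, dtype=int)
    if len(wins) >= M and counts.sum() > 0:
        pval = float(chisquare(counts).pvalue)
    else:
        pval = float("nan")
    frac = sum(w is not None for w in winners) / max(len(winners), 1)
    return SelectionResult(winners=winners, persisted=persisted,
                           flicker_counts=flickers,
                           single_winner_fraction=frac,
                           winner_counts=counts, chi2_pvalue=pval)
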