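"""Exact stochastic simulation (Gillespie) of M competing structures.

Each step draws two uniforms in fixed order: r1 sets the waiting time
tau = log(1/r1) / sum(R_i), r2 selects the reaction channel by
cumulative-propensity inversion.  The 2M assembly/disassembly channels use
the core rate laws; two optional channels extend the model:

* subunit production at propensity r_p * (Delta_N - deltaN), replenishing the
  available pool after an amputation-like loss of Delta_N subunits (the mean
  of the produced count follows Delta_N * (1 - exp(-r_p t)));
* linear cell growth as a unit-Poisson channel of constant propensity g, each
  firing adding one subunit to the pool and dV to the volume, so that
  E[N(t)] = N0 + g t and E[V(t)] = V0 + g dV t.

The growth law of the cell is stochasticized as a jump channel rather than a
deterministic drift between reactions: propensities stay time-homogeneous,
the algorithm stays exact, and the ensemble means match the linear growth
law.  Stationary statistics weight each visited state by its holding time;
event-count histograms are biased and not offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .core import FeedbackParams, PoolConfig, PoolMode
from .master_equation import StationaryDistribution, empirical_distribution

__all__ = [
    "ProductionSpec",
    "GrowthSpec",
    "SimulationSpec",
    "Trajectory",
    "gillespie_run",
    "run_with_production",
    "run_with_cell_growth",
    "stationary_histogram",
]

_EVENT_ABSORBED = -1


@dataclass(frozen=True)
class ProductionSpec:
    """Replenishment channel: propensity r_p * (Delta_N - produced so far)."""

    r_p: float
    Delta_N: int

    def __post_init__(self) -> None:
        if self.r_p < 0 or self.Delta_N < 0:
            raise ValueError("r_p and Delta_N must be >= 0")


@dataclass(frozen=True)
class GrowthSpec:
    """Linear cell growth channel: rate g, each firing adds (1 subunit, dV)."""

    g: float
    dV: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be >= 0")


@dataclass
class SimulationSpec:
    """Complete, reproducible description of one SSA run."""

    cfg: PoolConfig
    params: Sequence[FeedbackParams]
    seed: int
    t_max: float | None = None
    max_events: int | None = None
    record_dt: float | None = None   # None -> record every event
    burn_in: float | None = None     # None -> 20% of simulated time
    production: ProductionSpec | None = None
    growth: GrowthSpec | None = None
    init_sizes: Sequence[int] | None = None
    init_N_av: int | None = None     # override pool after e.g. amputation

    def __post_init__(self) -> None:
        if len(self.params) != self.cfg.M:
            raise ValueError("need one FeedbackParams per structure")
        if (self.t_max is None) == (self.max_events is None):
            raise ValueError("set exactly one of t_max / max_events")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


@dataclass
class Trajectory:
    """Recorded sample path: one row per event (or per thinning interval)."""

    times: np.ndarray            # strictly increasing
    sizes: np.ndarray            # (R, M) integer counts
    N_av: np.ndarray
    N_current: np.ndarray
    V: np.ndarray
    events: np.ndarray           # channel index fired to *leave* each row
    t_end: float
    n_events: int
    absorbed: bool
    spec: SimulationSpec
    produced: int = 0            # cumulative production-channel firings

    @property
    def M(self) -> int:
        return self.sizes.shape[1]

    def holding_weights(self) -> np.ndarray:
        """Sojourn time of each recorded state, closing the last at t_end."""
        dt = np.diff(np.append(self.times, self.t_end))
        return np.clip(dt, 0.0, None)

    def after(self, t0: float) -> "Trajectory":
        """Restrict to rows with time >= t0 (keeps spec and t_end)."""
        m = self.times >= t0
        if not m.any():
            raise ValueError(f"no recorded states after t = {t0}")
        return Trajectory(self.times[m], self.sizes[m], self.N_av[m],
                          self.N_current[m], self.V[m], self.events[m],
                          self.t_end, self.n_events, self.absorbed, self.spec,
                          self.produced)

    def burn_in_time(self) -> float:
        b = self.spec.burn_in
        return 0.2 * self.t_end if b is None else b

    def weighted_mean_sizes(self, burn_in: float | None = None) -> np.ndarray:
        tr = self.after(self.burn_in_time() if burn_in is None else burn_in)
        w = tr.holding_weights()
        return (tr.sizes * w[:, None]).sum(axis=0) / w.sum()

    def conservation_residuals(self) -> np.ndarray:
        return self.N_current - self.N_av - self.sizes.sum(axis=1)

    def summary(self) -> dict:
        tr = self.after(self.burn_in_time())
        w = tr.holding_weights()
        wsum = w.sum()
        mean = (tr.sizes * w[:, None]).sum(axis=0) / wsum
        var = ((tr.sizes - mean) ** 2 * w[:, None]).sum(axis=0) / wsum
        sd = np.sqrt(var)
        cv = np.where(mean > 0, sd / np.maximum(mean, 1e-300), np.inf)
        x = tr.sizes - mean
        cov = (x[:, :, None] * x[:, None, :] * w[:, None, None]).sum(axis=0) / wsum
        denom = np.outer(sd, sd)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, cov / denom, np.nan)
        return {
            "mean": mean.tolist(), "sd": sd.tolist(), "cv": cv.tolist(),
            "correlation": corr.tolist(), "seed": self.spec.seed,
            "t_end": self.t_end, "n_events": self.n_events,
            "absorbed": self.absorbed,
            "params": [p.to_dict() for p in self.spec.params],
            "pool": self.spec.cfg.to_dict(),
        }

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        for i in range(self.M):
            data[f"n_{i + 1}"] = self.sizes[:, i]
        data["N_av"] = self.N_av
        data["N_total"] = self.N_current
        data["V"] = self.V
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@njit(cache=True)
def _ssa_kernel(alpha, beta, kplus, kminus, limiting, rho,
                n0, N_av0, N_cur0, V0,
                t_max, max_events,
                prod_on, r_p, Delta_N,
                growth_on, g, dV,
                record_dt,
                rec_t, rec_sizes, rec_Nav, rec_Ncur, rec_V, rec_ev,
                seed):
    np.random.seed(seed)
    M = n0.size
    n = n0.copy()
    N_av = N_av0
    N_cur = N_cur0
    V = V0
    t = 0.0
    deltaN = 0
    events = 0
    absorbed = False
    cap = rec_t.size
    nrec = 0
    # initial state
    rec_t[0] = 0.0
    for i in range(M):
        rec_sizes[0, i] = n[i]
    rec_Nav[0] = N_av
    rec_Ncur[0] = N_cur
    rec_V[0] = V
    rec_ev[0] = -2
    nrec = 1
    next_rec = record_dt if record_dt > 0.0 else 0.0

    props = np.empty(2 * M + 2)
    while events < max_events and nrec < cap:
        total = 0.0
        for i in range(M):
            if limiting:
                a = kplus[i] * N_av * np.exp(-alpha[i] * np.log1p(n[i])) / V
            else:
                a = kplus[i] * rho * np.exp(-alpha[i] * np.log1p(n[i]))
            if n[i] == 0:
                b = 0.0
            else:
                b = kminus[i] * np.exp(beta[i] * np.log(n[i]))
            props[2 * i] = a
            props[2 * i + 1] = b
            total += a + b
        pr = r_p * (Delta_N - deltaN) if prod_on else 0.0
        gr = g if growth_on else 0.0
        props[2 * M] = pr
        props[2 * M + 1] = gr
        total += pr + gr
        if total <= 0.0:
            absorbed = True
            break
        r1 = np.random.random()
        r2 = np.random.random()
        tau = np.log(1.0 / r1) / total
        t_new = t + tau
        if t_max > 0.0 and t_new > t_max:
            t = t_max
            break
        # thinned recording of the pre-event state
        if record_dt > 0.0:
            while next_rec <= t_new and nrec < cap:
                rec_t[nrec] = next_rec
                for i in range(M):
                    rec_sizes[nrec, i] = n[i]
                rec_Nav[nrec] = N_av
                rec_Ncur[nrec] = N_cur
                rec_V[nrec] = V
                rec_ev[nrec] = -2
                nrec += 1
                next_rec += record_dt
            if nrec >= cap:
                t = t_new
                break
        t = t_new
        # channel selection by cumulative-propensity inversion
        thresh = r2 * total
        acc = 0.0
        j = -1
        for c in range(2 * M + 2):
            acc += props[c]
            if thresh < acc:
                j = c
                break
        if j < 0:
            # fp fallthrough: take the highest-index active channel
            for c in range(2 * M + 1, -1, -1):
                if props[c] > 0.0:
                    j = c
                    break
        if j < 2 * M:
            i = j // 2
            if j % 2 == 0:
                n[i] += 1
                if limiting:
                    N_av -= 1
            else:
                n[i] -= 1
                if limiting:
                    N_av += 1
        elif j == 2 * M:
            deltaN += 1
            N_av += 1
            N_cur += 1
        else:
            N_av += 1
            N_cur += 1
            V += dV
        events += 1
        if record_dt <= 0.0:
            rec_t[nrec] = t
            for i in range(M):
                rec_sizes[nrec, i] = n[i]
            rec_Nav[nrec] = N_av
            rec_Ncur[nrec] = N_cur
            rec_V[nrec] = V
            rec_ev[nrec] = j
            nrec += 1
    return nrec, events, t, absorbed, deltaN


def gillespie_run(spec: SimulationSpec) -> Trajectory:
    """Run the exact SSA described by ``spec``; bit-for-bit seed reproducible."""
    cfg = spec.cfg
    M = cfg.M
    alpha = np.array([p.alpha for p in spec.params])
    beta = np.array([p.beta for p in spec.params])
    kplus = np.array([p.k_plus for p in spec.params])
    kminus = np.array([p.k_minus for p in spec.params])
    limiting = cfg.mode is PoolMode.LIMITING_POOL

    n0 = (np.zeros(M, dtype=np.int64) if spec.init_sizes is None
          else np.asarray(spec.init_sizes, dtype=np.int64))
    if (n0 < 0).any():
        raise ValueError("initial sizes must be non-negative")
    if limiting:
        N_av0 = (cfg.N_total - int(n0.sum()) if spec.init_N_av is None
                 else int(spec.init_N_av))
        if N_av0 < 0:
            raise ValueError("initial sizes exceed the total pool")
        N_cur0 = N_av0 + int(n0.sum())
    else:
        N_av0, N_cur0 = 0, int(n0.sum())

    t_max = -1.0 if spec.t_max is None else float(spec.t_max)
    max_events = np.iinfo(np.int64).max if spec.max_events is None \
        else int(spec.max_events)

    record_dt = 0.0 if spec.record_dt is None else float(spec.record_dt)
    if record_dt > 0.0:
        if spec.t_max is None:
            raise ValueError("thinned recording requires t_max")
        cap = int(math.ceil(t_max / record_dt)) + 2
    else:
        if spec.max_events is None:
            raise ValueError(
                "event-resolved recording requires max_events; use record_dt "
                "for long t_max runs")
        cap = max_events + 1

    rec_t = np.empty(cap)
    rec_sizes = np.empty((cap, M), dtype=np.int64)
    rec_Nav = np.empty(cap, dtype=np.int64)
    rec_Ncur = np.empty(cap, dtype=np.int64)
    rec_V = np.empty(cap)
    rec_ev = np.empty(cap, dtype=np.int64)

    prod = spec.production
    grow = spec.growth
    nrec, events, t_end, absorbed, produced = _ssa_kernel(
        alpha, beta, kplus, kminus, limiting, float(cfg.rho),
        n0, N_av0, N_cur0, float(cfg.V),
        t_max, max_events,
        prod is not None, 0.0 if prod is None else prod.r_p,
        0 if prod is None else prod.Delta_N,
        grow is not None, 0.0 if grow is None else grow.g,
        0.0 if grow is None else grow.dV,
        record_dt,
        rec_t, rec_sizes, rec_Nav, rec_Ncur, rec_V, rec_ev,
        spec.seed)

    return Trajectory(
        times=rec_t[:nrec].copy(), sizes=rec_sizes[:nrec].copy(),
        N_av=rec_Nav[:nrec].copy(), N_current=rec_Ncur[:nrec].copy(),
        V=rec_V[:nrec].copy(), events=rec_ev[:nrec].copy(),
        t_end=float(t_end), n_events=int(events), absorbed=bool(absorbed),
        spec=spec, produced=int(produced))


def run_with_production(spec: SimulationSpec) -> Trajectory:
    """SSA run with the subunit-production channel armed."""
    if spec.production is None:
        raise ValueError("spec.production must be set")
    return gillespie_run(spec)


def run_with_cell_growth(spec: SimulationSpec) -> Trajectory:
    """SSA run with the linear cell-growth channel armed."""
    if spec.growth is None:
        raise ValueError("spec.growth must be set")
    return gillespie_run(spec)


def stationary_histogram(tr: Trajectory, burn_in: float | None = None,
                         structure: int = 0,
                         n_max: int | None = None) -> StationaryDistribution:
    """Occupancy-weighted stationary histogram of one structure's size."""
    t0 = tr.burn_in_time() if burn_in is None else burn_in
    if t0 >= tr.t_end:
        raise ValueError("burn-in leaves an empty window")
    sub = tr.after(t0)
    w = sub.holding_weights()
    return empirical_distribution(sub.sizes[:, structure], w, n_max=n_max)
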