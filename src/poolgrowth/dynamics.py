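"""Mean-field rate equations: integration, fixed points, stability, scaling.

The continuum model relaxes the integer sizes to real n_i >= 0 obeying

    dn_i/dt = k_plus_i * (N - sum_j n_j) * (1 + n_i)**(-alpha_i) / V
              - k_minus_i * n_i**beta_i,

or the buffered-concentration analogue with (N - sum n)/V replaced by rho.
These equations are an approximate deterministic model — they are not the
exact first-moment equations of the master equation, whose mean couples to
higher moments for general exponents.

Closed-form steady states for the two canonical negative-feedback motifs:

    (alpha, beta) = (0, 1):  n* = kappa N / (kappa M + V) = kappa rho0 V / (kappa M + V)
    (alpha, beta) = (1, 0):  n* = (kappa rho0 - 1) V / (kappa M + V)   (0 if kappa rho0 <= 1)

With the overall density rho0 = N/V held fixed, these interpolate between
linear size scaling with cell volume (kappa M >> V, n* ~ rho0 V / M) and a
saturated size independent of V and M (kappa M << V, n* ~ kappa rho0 or
kappa rho0 - 1).

For beta < 0 the disassembly law diverges at n = 0; the ODE domain is
restricted to n >= EPS_BOUNDARY and the origin is examined separately as a
regularized boundary state (disassembly switched off exactly at n = 0).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import FeedbackParams, PoolConfig, PoolMode

__all__ = [
    "EPS_BOUNDARY",
    "FixedPointClass",
    "FixedPoint",
    "SteadyState",
    "ScalingCurve",
    "ode_rhs",
    "ode_jacobian",
    "integrate",
    "fixed_points",
    "steady_state_formula",
    "scaling_sweep",
]

EPS_BOUNDARY = 1e-9


class FixedPointClass(str, enum.Enum):
    STABLE_NODE = "stable_node"
    UNSTABLE_NODE = "unstable_node"
    SADDLE = "saddle"
    MARGINAL = "marginal"
    BOUNDARY_REGULARIZED = "boundary_regularized"


@dataclass
class FixedPoint:
    location: np.ndarray
    eigenvalues: np.ndarray
    classification: FixedPointClass

    @property
    def is_stable(self) -> bool:
        return self.classification in (FixedPointClass.STABLE_NODE,
                                       FixedPointClass.BOUNDARY_REGULARIZED)


class SteadyState(tuple):
    """(n_star, no_growth) pair from a closed-form steady-state formula."""

    def __new__(cls, n_star: float, no_growth: bool = False):
        return super().__new__(cls, (float(n_star), bool(no_growth)))

    @property
    def n_star(self) -> float:
        return self[0]

    @property
    def no_growth(self) -> bool:
        return self[1]


@dataclass
class ScalingCurve:
    """Steady size across a sweep of cell volume V or structure count M."""

    axis: str                    # "V" or "M"
    grid: np.ndarray
    n_star: np.ndarray
    regime: list                 # "linear_scaling" (kappa M > V) or "saturated"
    meta: dict = field(default_factory=dict)


def _pool_term(sizes: np.ndarray, cfg: PoolConfig) -> float:
    if cfg.mode is PoolMode.LIMITING_POOL:
        return (cfg.N_total - float(sizes.sum())) / cfg.V
    return cfg.rho


def ode_rhs(sizes: np.ndarray, params: Sequence[FeedbackParams],
            cfg: PoolConfig) -> np.ndarray:
    """Right-hand side of the continuum rate equations at ``sizes``."""
    n = np.asarray(sizes, dtype=float)
    pool = _pool_term(n, cfg)
    out = np.empty_like(n)
    for i, p in enumerate(params):
        ni = n[i]
        if p.beta < 0:
            ni_off = max(ni, EPS_BOUNDARY)
            off = p.k_minus * ni_off ** p.beta
        else:
            off = p.k_minus * ni ** p.beta if ni > 0 else (
                p.k_minus if p.beta == 0 else 0.0)
        on = p.k_plus * pool * math.exp(-p.alpha * math.log1p(max(ni, 0.0)))
        out[i] = on - off
    return out


def ode_jacobian(sizes: np.ndarray, params: Sequence[FeedbackParams],
                 cfg: PoolConfig) -> np.ndarray:
    """Analytic Jacobian of :func:`ode_rhs`."""
    n = np.asarray(sizes, dtype=float)
    M = n.size
    pool = _pool_term(n, cfg)
    limiting = cfg.mode is PoolMode.LIMITING_POOL
    J = np.zeros((M, M))
    for i, p in enumerate(params):
        ni = max(n[i], 0.0)
        fb = math.exp(-p.alpha * math.log1p(ni))
        dpool = -1.0 / cfg.V if limiting else 0.0
        for j in range(M):
            J[i, j] = p.k_plus * dpool * fb
        J[i, i] += p.k_plus * pool * (-p.alpha) * fb / (1.0 + ni)
        ni_off = max(ni, EPS_BOUNDARY)
        if p.beta != 0:
            J[i, i] -= p.k_minus * p.beta * ni_off ** (p.beta - 1.0)
    return J


def integrate(init: Sequence[float], params: Sequence[FeedbackParams],
              cfg: PoolConfig, t_grid: np.ndarray,
              rtol: float = 1e-10, atol: float = 1e-12):
    """Integrate the rate equations over ``t_grid`` (stiff-capable).

    Sizes are clipped at zero from below.  Returns (t, y) with y of shape
    (len(t), M).
    """
    y0 = np.asarray(init, dtype=float)
    if (y0 < 0).any():
        raise ValueError("initial sizes must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(_t, y):
        return ode_rhs(np.clip(y, 0.0, None), params, cfg)

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol.t, np.clip(sol.y.T, 0.0, None)


def _classify(eigvals: np.ndarray, tol: float = 1e-9) -> FixedPointClass:
    re = eigvals.real
    if (np.abs(re) <= tol).any():
        return FixedPointClass.MARGINAL
    if (re < 0).all():
        return FixedPointClass.STABLE_NODE
    if (re > 0).all():
        return FixedPointClass.UNSTABLE_NODE
    return FixedPointClass.SADDLE


def fixed_points(params: Sequence[FeedbackParams], cfg: PoolConfig,
                 search_box: tuple[float, float] | None = None,
                 grid_points: int = 200, dedupe_tol: float = 1e-6
                 ) -> list[FixedPoint]:
    """All fixed points of the rate equations inside the search box.

    Interior roots are found by dense grid seeding plus Newton polishing with
    the analytic Jacobian; the boundary hyperplanes n_i = 0 are examined
    separately under the K_off(0) = 0 regularization.  For M > 2 the search
    is restricted to the symmetric subspace n_1 = ... = n_M.
    """
    M = cfg.M
    lo, hi = (0.0, float(cfg.N_total)) if search_box is None else search_box
    if hi <= lo:
        raise ValueError("empty search box")

    if M > 2:
        return _symmetric_fixed_points(params, cfg, (lo, hi), grid_points)

    npts = grid_points if M == 1 else min(grid_points, 60)
    axes = [np.linspace(lo, hi, npts)] * M
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    resid = np.array([np.abs(ode_rhs(p, params, cfg)).max() for p in pts])
    order = np.argsort(resid)
    seeds = pts[order[: 40 * M]]

    found: list[np.ndarray] = []
    for s in seeds:
        sol = root(lambda y: ode_rhs(y, params, cfg), s,
                   jac=lambda y: ode_jacobian(y, params, cfg))
        # hybr may report slow progress at a converged root: accept on residual
        x = sol.x
        if (x < lo - 1e-8).any() or (x > hi + 1e-8).any():
            continue
        if np.abs(ode_rhs(x, params, cfg)).max() > 1e-8:
            continue
        if any(np.allclose(x, f, atol=dedupe_tol, rtol=dedupe_tol) for f in found):
            continue
        found.append(x)

    out = []
    for x in found:
        ev = np.linalg.eigvals(ode_jacobian(x, params, cfg))
        out.append(FixedPoint(location=x, eigenvalues=ev,
                              classification=_classify(ev)))

    out.extend(_boundary_fixed_points(params, cfg, (lo, hi), out))
    out.sort(key=lambda fp: tuple(fp.location))
    return out


def _boundary_fixed_points(params, cfg, box, interior) -> list[FixedPoint]:
    """Regularized equilibria on the n_i = 0 boundary (beta_i < 0 only).

    With disassembly switched off exactly at zero, n_i = 0 is an attracting
    boundary state when the divergent disassembly dominates assembly on the
    positive side, i.e. when dn_i/dt < 0 at n_i = EPS_BOUNDARY.
    """
    M = cfg.M
    out: list[FixedPoint] = []
    if not any(p.beta < 0 for p in params):
        return out
    # all-zero corner
    corner = np.zeros(M)
    probe = np.full(M, EPS_BOUNDARY)
    drift = ode_rhs(probe, params, cfg)
    if all(params[i].beta < 0 and drift[i] < 0 for i in range(M)):
        out.append(FixedPoint(location=corner,
                              eigenvalues=np.array([]),
                              classification=FixedPointClass.BOUNDARY_REGULARIZED))
    if M == 2:
        for zero_i in (0, 1):
            other = 1 - zero_i
            if params[zero_i].beta >= 0:
                continue
            # solve the surviving 1-D problem with n_zero held at 0
            sub_cfg = PoolConfig(N_total=cfg.N_total, V=cfg.V, M=1,
                                 mode=cfg.mode, rho=cfg.rho)
            for fp in fixed_points([params[other]], sub_cfg, box):
                if fp.classification is FixedPointClass.BOUNDARY_REGULARIZED:
                    continue
                y = np.zeros(M)
                y[other] = fp.location[0]
                y[zero_i] = EPS_BOUNDARY
                if ode_rhs(y, params, cfg)[zero_i] < 0:
                    loc = y.copy()
                    loc[zero_i] = 0.0
                    out.append(FixedPoint(
                        location=loc, eigenvalues=fp.eigenvalues,
                        classification=FixedPointClass.BOUNDARY_REGULARIZED))
    return out


def _symmetric_fixed_points(params, cfg, box, grid_points) -> list[FixedPoint]:
    p = params[0]
    M = cfg.M

    def f(n):
        y = np.full(M, max(n, 0.0))
        return ode_rhs(y, params, cfg)[0]

    lo, hi = box
    grid = np.linspace(lo, hi, grid_points)
    vals = np.array([f(g) for g in grid])
    out = []
    for i in np.nonzero(np.diff(np.sign(vals)) != 0)[0]:
        from scipy.optimize import brentq

        n_star = brentq(f, grid[i], grid[i + 1], xtol=1e-12)
        y = np.full(M, n_star)
        ev = np.linalg.eigvals(ode_jacobian(y, params, cfg))
        out.append(FixedPoint(location=y, eigenvalues=ev,
                              classification=_classify(ev)))
    return out


def steady_state_formula(model: str, kappa: float, rho0: float, V: float,
                         M: int) -> SteadyState:
    """Closed-form per-structure steady size for the two canonical motifs.

    ``model`` is ``"(0,1)"`` (size-proportional disassembly) or ``"(1,0)"``
    (inverse-size assembly).  The (1,0) motif has no growing solution when
    kappa * rho0 <= 1; the formula then returns 0 with the no-growth flag.
    """
    if kappa <= 0 or rho0 < 0 or V <= 0 or M < 1:
        raise ValueError("parameters must be positive (rho0 >= 0)")
    key = model.replace(" ", "")
    if key == "(0,1)":
        return SteadyState(kappa * rho0 * V / (kappa * M + V))
    if key == "(1,0)":
        if kappa * rho0 <= 1:
            return SteadyState(0.0, no_growth=True)
        return SteadyState((kappa * rho0 - 1.0) * V / (kappa * M + V))
    raise ValueError('model must be "(0,1)" or "(1,0)"')


def scaling_sweep(model: str, kappa: float, rho0: float,
                  V_grid: Sequence[float] | None = None,
                  M_grid: Sequence[int] | None = None,
                  V: float | None = None, M: int | None = None) -> ScalingCurve:
    """Steady size across a sweep of cell volume or structure count.

    The overall density rho0 = N/V is held fixed across the sweep.  Each
    point is tagged ``linear_scaling`` when kappa M > V (size tracks cell
    volume) or ``saturated`` when kappa M < V (size independent of V and M),
    with the crossover at kappa M = V.
    """
    if (V_grid is None) == (M_grid is None):
        raise ValueError("provide exactly one of V_grid / M_grid")
    if V_grid is not None:
        if M is None:
            raise ValueError("sweeping V requires a fixed M")
        grid = np.asarray(V_grid, dtype=float)
        n_star = np.array([steady_state_formula(model, kappa, rho0, v, M).n_star
                           for v in grid])
        regime = ["linear_scaling" if kappa * M > v else "saturated"
                  for v in grid]
        return ScalingCurve("V", grid, n_star, regime,
                            meta={"model": model, "kappa": kappa,
                                  "rho0": rho0, "M": M})
    if V is None:
        raise ValueError("sweeping M requires a fixed V")
    grid = np.asarray(M_grid, dtype=float)
    n_star = np.array([steady_state_formula(model, kappa, rho0, V, int(m)).n_star
                       for m in grid])
    regime = ["linear_scaling" if kappa * m > V else "saturated" for m in grid]
    return ScalingCurve("M", grid, n_star, regime,
                        meta={"model": model, "kappa": kappa,
                              "rho0": rho0, "V": V})
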