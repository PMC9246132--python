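"""Exact stationary size distributions of the growth master equation.

For a single structure of size ``n`` drawing on a finite pool of ``N``
subunits, detailed balance between adjacent sizes,

    k_minus * n**beta * P(n) = (k_plus / V) * (N - n + 1) * n**(-alpha) * P(n-1),

closes the birth-death chain and yields the stationary distribution

    P(n) ∝ (kappa / V)**n * N! / [ (N - n)! * (n!)**(alpha + beta) ],

with kappa = k_plus / k_minus.  The distribution is written for unit volume
in the source model; a general volume enters only through the substitution
kappa -> kappa / V, which this module applies throughout.

Two structures sharing the pool have the joint stationary law

    P(n1, n2) ∝ kappa1**n1 * kappa2**n2 * N! /
                [ (n1!)**(a+b) * (n2!)**(a+b) * (N - n1 - n2)! ]

on the simplex n1 + n2 <= N.  When the cell instead buffers the free-subunit
concentration at rho, the structures decouple and each has weight
(kappa * rho)**n / (n!)**(a+b), which is normalizable only when the weight
ratio eventually falls below one (always true for a + b > 0; for a + b = 0 it
requires kappa * rho < 1).

All weights are computed with log-gamma in log space and normalized by
log-sum-exp: N!/(N-n)! overflows double precision near N = 171.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import FeedbackParams

__all__ = [
    "StationaryDistribution",
    "JointDistribution",
    "KappaThresholds",
    "stationary_single",
    "stationary_joint_two",
    "marginalize",
    "stationary_const_conc",
    "moments",
    "count_modes",
    "find_kappa0",
    "bistable_window",
    "empirical_distribution",
]


@dataclass
class StationaryDistribution:
    """Exact (or empirical) probability vector over integer sizes."""

    support: np.ndarray          # integer sizes, contiguous from support[0]
    probs: np.ndarray
    log_weights: np.ndarray | None = None
    log_normalizer: float = 0.0  # log C_N
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != self.support.shape:
            raise ValueError("support and probs must have equal length")
        if (self.probs < -1e-15).any():
            raise ValueError("negative probabilities")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    @property
    def sd(self) -> float:
        m = self.mean
        var = float(np.dot((self.support - m) ** 2, self.probs))
        return math.sqrt(max(var, 0.0))

    @property
    def cv(self) -> float:
        m = self.mean
        return self.sd / m if m > 0 else float("inf")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"n": self.support, "probability": self.probs})


@dataclass
class JointDistribution:
    """Joint stationary law of two structures on the simplex n1 + n2 <= N.

    ``probs`` is an (N+1, N+1) array, zero outside the simplex.
    """

    N: int
    probs: np.ndarray
    log_P00: float               # log of the normalization constant P(0, 0)
    meta: dict = field(default_factory=dict)

    def marginal(self, which: int) -> StationaryDistribution:
        return marginalize(self, which)

    def marginal_mean(self, which: int) -> float:
        return self.marginal(which).mean

    def covariance(self) -> float:
        """Cov(n1, n2) under the exact joint law."""
        n = np.arange(self.N + 1, dtype=float)
        p1 = self.probs.sum(axis=1)
        p2 = self.probs.sum(axis=0)
        m1, m2 = float(n @ p1), float(n @ p2)
        e12 = float(n @ self.probs @ n)
        return e12 - m1 * m2

    def correlation(self) -> float:
        """Pearson correlation of (n1, n2) under the exact joint law."""
        d1, d2 = self.marginal(1), self.marginal(2)
        s1, s2 = d1.sd, d2.sd
        if s1 == 0 or s2 == 0:
            return float("nan")
        return self.covariance() / (s1 * s2)

    def to_frame(self):
        import pandas as pd

        idx = np.arange(self.N + 1)
        n1, n2 = np.meshgrid(idx, idx, indexing="ij")
        mask = (n1 + n2) <= self.N
        return pd.DataFrame({"n1": n1[mask], "n2": n2[mask],
                             "probability": self.probs[mask]})


@dataclass(frozen=True)
class KappaThresholds:
    """Characteristic growth-rate thresholds of a single structure.

    ``kappa0`` is the growth rate at which the size CV crosses 1 (below it
    the structure barely grows and fluctuations dominate); ``kappa_star`` and
    ``kappa_c`` bound the window of bimodal stationary distributions for
    autocatalytic growth (alpha + beta < 0).  NaN marks an absent threshold.
    """

    kappa0: float
    kappa_star: float
    kappa_c: float

    @property
    def has_bistable_window(self) -> bool:
        return math.isfinite(self.kappa_star) and math.isfinite(self.kappa_c)


def _single_log_weights(alpha: float, beta: float, kappa: float, N: int,
                        V: float) -> np.ndarray:
    n = np.arange(N + 1, dtype=float)
    ab = alpha + beta
    return (n * math.log(kappa / V) + gammaln(N + 1.0) - gammaln(N - n + 1.0)
            - ab * gammaln(n + 1.0))


def stationary_single(p: FeedbackParams, N: int, V: float = 1.0) -> StationaryDistribution:
    """Exact stationary size distribution of one structure on a finite pool."""
    if N < 0:
        raise ValueError("N must be >= 0")
    if V <= 0:
        raise ValueError("V must be > 0")
    lw = _single_log_weights(p.alpha, p.beta, p.kappa, N, V)
    log_C = float(logsumexp(lw))
    probs = np.exp(lw - log_C)
    return StationaryDistribution(
        support=np.arange(N + 1), probs=probs, log_weights=lw,
        log_normalizer=log_C,
        meta={"alpha": p.alpha, "beta": p.beta, "kappa": p.kappa, "N": N,
              "V": V, "volume_convention": "kappa/V"})


def stationary_joint_two(p1: FeedbackParams, p2: FeedbackParams, N: int,
                         V: float = 1.0) -> JointDistribution:
    """Exact joint stationary law of two structures sharing one pool.

    The closed form is derived for structures sharing one (alpha, beta)
    pair; differing exponents are accepted but flagged as an extension in
    the output metadata.
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    n = np.arange(N + 1, dtype=float)
    ab1 = p1.alpha + p1.beta
    ab2 = p2.alpha + p2.beta
    w1 = n * math.log(p1.kappa / V) - ab1 * gammaln(n + 1.0)
    w2 = n * math.log(p2.kappa / V) - ab2 * gammaln(n + 1.0)
    lw = w1[:, None] + w2[None, :] + gammaln(N + 1.0)
    tot = n[:, None] + n[None, :]
    with np.errstate(invalid="ignore"):
        lw = lw - gammaln(N - tot + 1.0)
    lw[tot > N] = -np.inf
    log_Z = float(logsumexp(lw))
    probs = np.exp(lw - log_Z)
    probs[tot > N] = 0.0
    return JointDistribution(
        N=N, probs=probs, log_P00=float(lw[0, 0] - log_Z),
        meta={"kappa1": p1.kappa, "kappa2": p2.kappa, "alpha_beta": (ab1, ab2),
              "V": V, "volume_convention": "kappa/V",
              "extension_distinct_exponents": ab1 != ab2})


def marginalize(j: JointDistribution, which: int) -> StationaryDistribution:
    """Marginal size distribution of structure 1 or 2 from the joint law."""
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    probs = j.probs.sum(axis=2 - which)
    return StationaryDistribution(support=np.arange(j.N + 1), probs=probs,
                                  meta=dict(j.meta, marginal_of=which))


def _const_conc_log_weights(kappa_rho: float, ab: float,
                            n_max: int) -> np.ndarray:
    n = np.arange(n_max + 1, dtype=float)
    if kappa_rho == 0:
        lw = np.full(n_max + 1, -np.inf)
        lw[0] = 0.0
        return lw
    return n * math.log(kappa_rho) - ab * gammaln(n + 1.0)


def _const_conc_marginal(p: FeedbackParams, rho: float, n_max: int | None):
    """One structure's weight vector under a buffered concentration.

    Returns (distribution or None, normalizable flag).  Doubling truncation
    until the appended tail mass is < 1e-10, or until a non-normalizability
    certificate fires: the weight ratio w(n+1)/w(n) = kappa*rho / (n+1)**(a+b)
    is persistently >= 1, which happens iff a+b < 0, or a+b = 0 with
    kappa*rho >= 1.
    """
    ab = p.alpha + p.beta
    kr = p.kappa * rho
    # analytic certificate: ratio tends to kr * (n+1)^(-ab)
    if ab < 0 and kr > 0:
        return None, False
    if ab == 0 and kr >= 1:
        return None, False
    nmax = 64 if n_max is None else int(n_max)
    adaptive = n_max is None
    while True:
        lw = _const_conc_log_weights(kr, ab, nmax)
        log_Z = float(logsumexp(lw))
        tail = float(np.exp(logsumexp(lw[-8:]) - log_Z))
        if tail < 1e-10:
            probs = np.exp(lw - log_Z)
            d = StationaryDistribution(
                support=np.arange(nmax + 1), probs=probs, log_weights=lw,
                log_normalizer=log_Z,
                meta={"alpha": p.alpha, "beta": p.beta, "kappa": p.kappa,
                      "rho": rho, "mode": "constant_concentration"})
            return d, True
        if not adaptive:
            raise ValueError(
                f"truncation n_max={nmax} leaves tail mass {tail:.2e} >= 1e-10; "
                "increase n_max")
        if nmax > 2 ** 22:
            raise ValueError("truncation exceeded 2**22 without convergence")
        nmax *= 2


def stationary_const_conc(p1: FeedbackParams, p2: FeedbackParams, rho: float,
                          n_max: int | None = None):
    """Stationary marginals of two structures at buffered free concentration.

    The joint law factorizes into independent marginals.  Returns
    ``(d1, d2, normalizable)``; the distributions are ``None`` when the
    weights are not normalizable (unbounded growth).
    """
    d1, ok1 = _const_conc_marginal(p1, rho, n_max)
    d2, ok2 = _const_conc_marginal(p2, rho, n_max)
    return d1, d2, ok1 and ok2


def moments(d: StationaryDistribution) -> tuple[float, float, float]:
    """(mean, sd, cv) of a normalized distribution; cv = inf at mean 0."""
    return d.mean, d.sd, d.cv


def count_modes(d: StationaryDistribution) -> int:
    """Number of local maxima of the exact probability vector.

    Consecutive equal values are merged into one plateau before counting;
    endpoints are eligible.  No smoothing is applied — the input is an exact
    distribution, not a histogram.
    """
    p = d.probs
    # merge plateaus
    keep = np.concatenate(([True], p[1:] != p[:-1]))
    q = p[keep]
    if q.size == 1:
        return 1
    modes = 0
    for i in range(q.size):
        left_ok = i == 0 or q[i - 1] < q[i]
        right_ok = i == q.size - 1 or q[i + 1] < q[i]
        if left_ok and right_ok:
            modes += 1
    return modes


def _cv_of_kappa(kappa: float, alpha: float, beta: float, N: int,
                 V: float) -> float:
    p = FeedbackParams.from_kappa(alpha, beta, kappa)
    return stationary_single(p, N, V).cv


def find_kappa0(alpha: float, beta: float, N: int, V: float = 1.0,
                bracket: tuple[float, float] = (1e-8, 1e4),
                tol: float = 1e-6) -> float:
    """Growth rate at which the stationary size CV crosses 1.

    Locates the smallest crossing of CV(kappa) = 1 inside ``bracket`` by a
    log-spaced scan followed by bisection, to |CV - 1| < ``tol``.
    """
    from scipy.optimize import brentq

    lo, hi = bracket
    grid = np.geomspace(lo, hi, 200)
    f = np.array([_cv_of_kappa(k, alpha, beta, N, V) - 1.0 for k in grid])
    sign_change = np.nonzero(np.diff(np.sign(f)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError(
            f"CV - 1 does not change sign in bracket {bracket}: "
            f"endpoints CV = {f[0] + 1:.4g}, {f[-1] + 1:.4g}")
    i = int(sign_change[0])
    k0 = brentq(lambda k: _cv_of_kappa(k, alpha, beta, N, V) - 1.0,
                grid[i], grid[i + 1], xtol=1e-14, rtol=1e-12)
    cv = _cv_of_kappa(k0, alpha, beta, N, V)
    if abs(cv - 1.0) > tol:
        raise RuntimeError(f"bisection failed: CV({k0}) = {cv}")
    return float(k0)


def _n_modes_at(kappa: float, alpha: float, beta: float, N: int,
                V: float) -> int:
    p = FeedbackParams.from_kappa(alpha, beta, kappa)
    return count_modes(stationary_single(p, N, V))


def bistable_window(alpha: float, beta: float, N: int, V: float = 1.0,
                    kappa_range: tuple[float, float] = (1e-8, 1e4),
                    grid_points: int = 600,
                    rel_tol: float = 1e-6) -> KappaThresholds:
    """Bimodality window [kappa_star, kappa_c] of the exact distribution.

    Only autocatalytic growth (alpha + beta < 0) can be bimodal; the window
    endpoints are located by a log-spaced scan for a 2-mode region followed
    by bisection on each edge.  An empty window is reported as NaN endpoints.
    """
    if alpha + beta >= 0:
        try:
            k0 = find_kappa0(alpha, beta, N, V, kappa_range)
        except ValueError:
            k0 = float("nan")
        return KappaThresholds(kappa0=k0, kappa_star=float("nan"),
                               kappa_c=float("nan"))
    grid = np.geomspace(*kappa_range, grid_points)
    bimodal = np.array([_n_modes_at(k, alpha, beta, N, V) >= 2 for k in grid])
    if not bimodal.any():
        k_star = k_c = float("nan")
    else:
        idx = np.nonzero(bimodal)[0]
        lo_i, hi_i = int(idx[0]), int(idx[-1])

        def bisect_edge(k_out: float, k_in: float) -> float:
            # k_in is bimodal, k_out is not; return the bimodal-side edge
            while abs(k_in - k_out) > rel_tol * k_in:
                mid = math.sqrt(k_in * k_out)
                if _n_modes_at(mid, alpha, beta, N, V) >= 2:
                    k_in = mid
                else:
                    k_out = mid
            return k_in

        k_star = grid[lo_i] if lo_i == 0 else bisect_edge(grid[lo_i - 1], grid[lo_i])
        k_c = grid[hi_i] if hi_i == grid.size - 1 else bisect_edge(grid[hi_i + 1], grid[hi_i])
    try:
        k0 = find_kappa0(alpha, beta, N, V, kappa_range)
    except ValueError:
        k0 = float("nan")
    return KappaThresholds(kappa0=k0, kappa_star=float(k_star),
                           kappa_c=float(k_c))


def empirical_distribution(values: np.ndarray, weights: np.ndarray,
                           n_max: int | None = None) -> StationaryDistribution:
    """Occupancy-weighted empirical distribution over integer sizes."""
    values = np.asarray(values, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("no weighted samples to build a distribution from")
    top = int(values.max()) if n_max is None else int(n_max)
    counts = np.bincount(values, weights=weights, minlength=top + 1)
    probs = counts / counts.sum()
    return StationaryDistribution(support=np.arange(top + 1), probs=probs,
                                  meta={"empirical": True})
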