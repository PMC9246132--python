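"""Core parameterization and rate laws for size-dependent growth.

A structure of size ``n`` (in subunit counts) assembles from a shared pool of
``N_av`` free subunits with propensity

    K_on(n)  = k_plus * N_av * (1 + n)**(-alpha) / V      (limiting pool)
    K_on(n)  = k_plus * rho  * (1 + n)**(-alpha)          (constant concentration)

and disassembles with propensity

    K_off(n) = k_minus * n**beta        for n >= 1
    K_off(0) = 0                        always (boundary regularization)

The exponents ``alpha`` and ``beta`` set the strength of size-dependent
feedback on assembly and disassembly.  Their sum decides the qualitative
regime: ``alpha + beta > 0`` gives net negative feedback and robust size
control, ``alpha + beta = 0`` is the degenerate limiting-pool class with no
individual size regulation, and ``alpha + beta < 0`` gives autocatalytic
growth with bistability.  ``K_off(0) = 0`` regularizes the divergence of
``n**beta`` at the origin for ``beta < 0`` and prevents negative sizes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FeedbackParams",
    "PoolConfig",
    "PoolMode",
    "SystemState",
    "Regime",
    "classify_regime",
    "assembly_propensity",
    "disassembly_propensity",
    "size_feedback_factor",
]


class PoolMode(str, enum.Enum):
    """How the free-subunit pool is bookkept."""

    LIMITING_POOL = "limiting_pool"
    CONSTANT_CONCENTRATION = "constant_concentration"


class Regime(str, enum.Enum):
    """Qualitative growth regime, a pure function of ``alpha + beta``."""

    NEGATIVE_FEEDBACK = "negative_feedback"      # alpha + beta > 0
    LIMITING_POOL_LINE = "limiting_pool_line"    # alpha + beta == 0
    POSITIVE_FEEDBACK = "positive_feedback"      # alpha + beta < 0


@dataclass(frozen=True)
class FeedbackParams:
    """Per-structure growth law: feedback exponents and bare rates.

    Parameters
    ----------
    alpha
        Feedback exponent on assembly (dimensionless).  ``alpha > 0`` means
        the assembly rate decreases with size.
    beta
        Feedback exponent on disassembly (dimensionless).  ``beta > 0`` means
        the disassembly rate increases with size.
    k_plus
        Bare assembly rate (volume / time), strictly positive.
    k_minus
        Bare disassembly rate (1 / time), strictly positive.
    """

    alpha: float
    beta: float
    k_plus: float = 1.0
    k_minus: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")
        if not (self.k_plus > 0 and self.k_minus > 0):
            raise ValueError("k_plus and k_minus must be > 0")

    @property
    def kappa(self) -> float:
        """Net growth rate ratio kappa = k_plus / k_minus."""
        return self.k_plus / self.k_minus

    @property
    def regime(self) -> Regime:
        return classify_regime(self.alpha, self.beta)

    @classmethod
    def from_kappa(cls, alpha: float, beta: float, kappa: float,
                   k_minus: float = 1.0) -> "FeedbackParams":
        """Build params with a given kappa at unit disassembly rate."""
        return cls(alpha=alpha, beta=beta, k_plus=kappa * k_minus, k_minus=k_minus)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta,
                "k_plus": self.k_plus, "k_minus": self.k_minus}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeedbackParams":
        return cls(alpha=float(d["alpha"]), beta=float(d["beta"]),
                   k_plus=float(d.get("k_plus", 1.0)),
                   k_minus=float(d.get("k_minus", 1.0)))


@dataclass(frozen=True)
class PoolConfig:
    """Global pool bookkeeping: total subunits, volume, structure count, mode.

    In ``limiting_pool`` mode the total amount ``N_total`` is conserved
    (``N = N_av + sum_i n_i``) and ``rho`` is unused.  In
    ``constant_concentration`` mode the cell buffers the free-subunit
    concentration at ``rho`` and ``N_total`` is unused.
    """

    N_total: int = 0
    V: float = 1.0
    M: int = 1
    mode: PoolMode = PoolMode.LIMITING_POOL
    rho: float = 0.0

    def __post_init__(self) -> None:
        mode = PoolMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if self.V <= 0:
            raise ValueError("V must be > 0")
        if self.M < 1:
            raise ValueError("M must be a positive integer")
        if mode is PoolMode.LIMITING_POOL and self.N_total < 0:
            raise ValueError("N_total must be >= 0 in limiting_pool mode")
        if mode is PoolMode.CONSTANT_CONCENTRATION and self.rho < 0:
            raise ValueError("rho must be >= 0 in constant_concentration mode")

    @property
    def rho0(self) -> float:
        """Overall subunit density N_total / V (limiting-pool mode)."""
        return self.N_total / self.V

    def to_dict(self) -> dict:
        return {"N_total": self.N_total, "V": self.V, "M": self.M,
                "mode": self.mode.value, "rho": self.rho}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PoolConfig":
        return cls(N_total=int(d.get("N_total", 0)), V=float(d.get("V", 1.0)),
                   M=int(d.get("M", 1)),
                   mode=PoolMode(d.get("mode", "limiting_pool")),
                   rho=float(d.get("rho", 0.0)))


@dataclass
class SystemState:
    """Instantaneous state of the growing system.

    ``N_current`` may exceed the initial total under subunit production or
    cell growth; the conservation identity ``N_current = N_av + sum(sizes)``
    holds at every event in limiting-pool mode.
    """

    t: float
    sizes: np.ndarray            # integer counts n_i, shape (M,)
    N_av: int
    V_current: float
    N_current: int

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.t < 0:
            raise ValueError("time must be >= 0")
        if (self.sizes < 0).any():
            raise ValueError("sizes must be non-negative")
        if self.N_av < 0:
            raise ValueError("N_av must be non-negative")
        if self.V_current <= 0:
            raise ValueError("V_current must be > 0")

    @classmethod
    def initial(cls, cfg: PoolConfig,
                sizes: Sequence[int] | None = None) -> "SystemState":
        """State at t=0; structures start empty unless sizes are given."""
        n = np.zeros(cfg.M, dtype=np.int64) if sizes is None else \
            np.asarray(sizes, dtype=np.int64)
        if cfg.mode is PoolMode.LIMITING_POOL:
            n_av = cfg.N_total - int(n.sum())
            if n_av < 0:
                raise ValueError("initial sizes exceed the total pool")
            return cls(t=0.0, sizes=n, N_av=n_av, V_current=cfg.V,
                       N_current=cfg.N_total)
        return cls(t=0.0, sizes=n, N_av=0, V_current=cfg.V, N_current=0)

    def conservation_residual(self) -> int:
        return self.N_current - self.N_av - int(self.sizes.sum())


def classify_regime(alpha: float, beta: float) -> Regime:
    """Classify the growth regime from the exact sign of ``alpha + beta``.

    The exponents are user-supplied model constants, not estimates, so the
    comparison with zero is exact (no tolerance).
    """
    s = alpha + beta
    if not math.isfinite(s):
        raise ValueError("alpha + beta must be finite")
    if s > 0:
        return Regime.NEGATIVE_FEEDBACK
    if s < 0:
        return Regime.POSITIVE_FEEDBACK
    return Regime.LIMITING_POOL_LINE


def size_feedback_factor(n: float, alpha: float) -> float:
    """(1 + n)**(-alpha), evaluated in log space for robustness."""
    return math.exp(-alpha * math.log1p(n))


def assembly_propensity(state: SystemState, i: int, p: FeedbackParams,
                        cfg: PoolConfig) -> float:
    """Assembly propensity K_on of structure ``i`` in the current state."""
    if not 0 <= i < cfg.M:
        raise IndexError(f"structure index {i} out of range for M={cfg.M}")
    n = int(state.sizes[i])
    if n < 0 or state.N_av < 0:
        raise ValueError("contract violation: negative n_i or N_av")
    if cfg.mode is PoolMode.LIMITING_POOL:
        if state.N_av == 0:
            return 0.0
        return p.k_plus * state.N_av * size_feedback_factor(n, p.alpha) / state.V_current
    return p.k_plus * cfg.rho * size_feedback_factor(n, p.alpha)


def disassembly_propensity(state: SystemState, i: int, p: FeedbackParams) -> float:
    """Disassembly propensity K_off of structure ``i``; exactly 0 at n=0."""
    n = int(state.sizes[i])
    if n < 0:
        raise ValueError("contract violation: negative n_i")
    if n == 0:
        return 0.0
    return p.k_minus * math.exp(p.beta * math.log(n))
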