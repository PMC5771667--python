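"""Closed-form population genetics of beneficial mutants and duplications.

Competition between two genotypes in a serial-dilution regime follows
r(t) = r0 * 2^(S t) with t in generations; the effective population size of
a culture bottlenecked by dilution factor D is the geometric mean
<N> = N / sqrt(D).  Fixation statistics are Haldane-style closed forms,
dispatched by regime:

* punctual  -- a single beneficial mutant: P_fix = 2S,
  t_fix = log2(<N>^2)/S, t_half = t_fix/2.
* neutral   -- P_fix = 1/<N>, t_fix = 2<N>.
* recurrent -- mutants resupplied at rate mu_b: P_fix = 1,
  t_fix = log2(<N> S / mu_b)/S.
* duplication -- duplicates form at mu_c and are deleted at mu_d; the
  deletion flux acts as an effective selection penalty S' = S - mu_d and
  fixation requires S > mu_d.

Duplication formation-deletion balance gives a standing duplicate
frequency mu_c/(mu_c + mu_d) under neutrality (reached in about 3/mu_d
generations) and mu_c/(mu_c + mu_d - S) when the duplicate is deleterious.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PopGenParams",
    "Trajectory",
    "FixationStats",
    "competition_dynamics",
    "fixation_stats",
    "recurrent_mutant_dynamics",
    "successive_fixation_time",
    "duplication_balance",
    "DuplicationBalance",
    "duplication_frequency_dynamics",
    "effective_population_size",
    "concurrence_and_global_fixation",
    "mutant_supply",
]


@dataclass(frozen=True)
class PopGenParams:
    """Population and rate parameters of a serial-dilution culture."""

    N: float = 1e5                 # maximal population size (cells)
    D: float = 100.0               # dilution factor
    mu: float = 1e-10              # per-base mutation rate (mut/bp/gen)
    mu_b: float = 1e-9             # beneficial-mutation rate (mut/gen)
    mu_c: float = 3e-4             # duplication formation rate (dup/gene/gen)
    mu_d: float = 4.4e-2           # duplication deletion rate (1/gene/gen)
    S: float = 0.0                 # selection coefficient
    N_eff: Optional[float] = None  # override; default N / sqrt(D)

    def __post_init__(self) -> None:
        if self.N <= 0 or self.D <= 0:
            raise ValueError("N and D must be > 0")
        for r in ("mu", "mu_b", "mu_c", "mu_d"):
            if getattr(self, r) < 0:
                raise ValueError(f"{r} must be >= 0")
        if self.N_eff is None:
            object.__setattr__(self, "N_eff", self.N / math.sqrt(self.D))
        elif self.N_eff <= 0:
            raise ValueError("N_eff must be > 0")

    @property
    def S_eff(self) -> float:
        """Effective selection coefficient of a duplicate, S - mu_d."""
        return self.S - self.mu_d


@dataclass
class Trajectory:
    """Genotype ratio r(t) and advantaged-genotype frequency f = 1/(1+1/r)."""

    t: np.ndarray
    r: np.ndarray
    delay: Optional[float] = None  # generations before the first mutant (if any)

    @property
    def f(self) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            return np.where(np.isinf(self.r), 1.0, self.r / (1.0 + self.r))


def ratio_from_frequency(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return f / (1.0 - f)


def competition_dynamics(r0: float, S: float, t) -> Trajectory:
    """Deterministic competition r(t) = r0 * 2^(S t)."""
    if r0 <= 0:
        raise ValueError("initial ratio r0 must be > 0")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    with np.errstate(over="ignore"):
        r = r0 * np.exp2(S * t)
    return Trajectory(t=t, r=r)


@dataclass(frozen=True)
class FixationStats:
    P_fix: float
    t_fix: float
    t_half: float
    regime: str
    fixable: bool = True


def fixation_stats(
    S: float,
    N_eff: float,
    regime: str = "punctual",
    mu_b: float | None = None,
    mu_c: float | None = None,
    mu_d: float | None = None,
) -> FixationStats:
    """Fixation probability and characteristic times, by regime."""
    if N_eff <= 0:
        raise ValueError("N_eff must be > 0")
    if regime == "neutral":
        return FixationStats(1.0 / N_eff, 2.0 * N_eff, N_eff, regime)
    if regime == "punctual":
        if S <= 0:
            raise ValueError("punctual regime requires S > 0")
        t_fix = math.log2(N_eff**2) / S
        return FixationStats(2.0 * S, t_fix, t_fix / 2.0, regime)
    if regime == "recurrent":
        if S <= 0:
            raise ValueError("recurrent regime requires S > 0")
        if mu_b is None or mu_b <= 0:
            raise ValueError("recurrent regime requires mu_b > 0")
        t_fix = math.log2(N_eff * S / mu_b) / S
        return FixationStats(1.0, t_fix, t_fix / 2.0, regime)
    if regime == "duplication":
        if mu_d is None or mu_d < 0:
            raise ValueError("duplication regime requires mu_d >= 0")
        S_eff = S - mu_d
        if S_eff <= 0:
            return FixationStats(0.0, math.inf, math.inf, regime, fixable=False)
        t_fix = math.log2(N_eff**2) / S_eff
        return FixationStats(2.0 * S_eff, t_fix, t_fix / 2.0, regime)
    raise ValueError(f"unknown regime {regime!r}")


def recurrent_mutant_dynamics(
    mu_b: float, N: float, D: float, S: float, t
) -> Trajectory:
    """Invasion dynamics when beneficial mutants are resupplied at mu_b.

    Large supply (mu_b*N > 1): r = mu_b * 2^(S t) / S (many mutants per
    passage; no establishment delay).  Small supply: a punctual mutant with
    mean waiting time T = log2(D)/(mu_b*N) generations,
    r = 2^(S (t-T)) / <N>.
    """
    if S <= 0:
        raise ValueError("S must be > 0")
    if mu_b <= 0 or N <= 0 or D <= 0:
        raise ValueError("mu_b, N, D must be > 0")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    N_eff = N / math.sqrt(D)
    if mu_b * N > 1:
        r = mu_b * np.exp2(S * t) / S
        return Trajectory(t=t, r=r)
    T = math.log2(D) / (mu_b * N)
    r = np.exp2(S * (t - T)) / N_eff
    return Trajectory(t=t, r=r, delay=T)


def successive_fixation_time(
    S_list: Sequence[float], N_eff: float, regime: str = "punctual", **kw
) -> float:
    """Total generations to stack m successive fixations.

    The last mutation pays its full fixation time; each earlier one only
    needs to reach 50% before the next can start:
    t = t_fix(m) + t_half(m-1) + ... + t_half(1).
    """
    if any(S <= 0 for S in S_list):
        raise ValueError("all S must be > 0")
    if len(S_list) == 0:
        return 0.0
    stats = [fixation_stats(S, N_eff, regime, **kw) for S in S_list]
    return stats[-1].t_fix + sum(st.t_half for st in stats[:-1])


@dataclass(frozen=True)
class DuplicationBalance:
    r_eq: float
    f_eq: float
    t_eq: float
    is_equilibrium: bool = True


def duplication_balance(mu_c: float, mu_d: float, S: float = 0.0) -> DuplicationBalance:
    """Stationary duplicate frequency under formation-deletion balance.

    Neutral (S = 0): r_eq = mu_c/mu_d, f_eq = mu_c/(mu_c + mu_d).
    Deleterious (S < 0): r_eq = mu_c/(mu_d - S), f_eq = mu_c/(mu_c + mu_d - S).
    The transient lasts about t_eq = 3/mu_d generations.  S > mu_d means the
    duplicate escapes the balance and fixes (no equilibrium).
    """
    if mu_c <= 0 or mu_d <= 0:
        raise ValueError("mu_c and mu_d must be > 0")
    t_eq = 3.0 / mu_d
    if S > mu_d:
        return DuplicationBalance(math.inf, 1.0, t_eq, is_equilibrium=False)
    r_eq = mu_c / (mu_d - S)
    f_eq = mu_c / (mu_c + mu_d - S)
    return DuplicationBalance(r_eq, f_eq, t_eq)


def duplication_frequency_dynamics(
    mu_c: float, mu_d: float, S: float, f0: float, t_max: int
) -> Trajectory:
    """Per-generation two-class recurrence for the duplicate frequency.

    Each generation the duplicate class grows by a relative factor (1 + S),
    a fraction mu_d of it loses the second copy, and a fraction mu_c of
    singletons gains one; frequencies are renormalized.  The stationary
    point is exactly mu_c/(mu_c + mu_d) at S = 0 and matches the
    closed-form deleterious balance to first order in the rates.  With
    mu_c = mu_d = 0 the recurrence is pure competition with per-generation
    growth (1 + S), i.e. competition_dynamics at S' = log2(1 + S).
    """
    if not (0 <= mu_c < 1 and 0 <= mu_d < 1):
        raise ValueError("rates must be in [0, 1)")
    if not (0 <= f0 <= 1):
        raise ValueError("f0 must be in [0, 1]")
    f = np.empty(t_max + 1)
    f[0] = f0
    for i in range(t_max):
        fd, fs = f[i], 1.0 - f[i]
        m_dup = fd * (1.0 + S) * (1.0 - mu_d) + fs * mu_c
        m_sin = fs * (1.0 - mu_c) + fd * (1.0 + S) * mu_d
        f[i + 1] = m_dup / (m_dup + m_sin)
    t = np.arange(t_max + 1, dtype=float)
    with np.errstate(divide="ignore"):
        r = np.where(f < 1.0, f / (1.0 - f), np.inf)
    return Trajectory(t=t, r=r)


def effective_population_size(G: float) -> float:
    """Genome-size scaling of the effective population size: 3e9 / G^1.44."""
    if G <= 0:
        raise ValueError("G must be > 0")
    return 3e9 / G**1.44


def concurrence_and_global_fixation(
    n_mut: float, mu_c: float, S: float, mu_d: float
):
    """Two-step path: promoter mutation halving expression, then duplication.

    ``n_mut`` is the expected number of half-expression promoter mutants
    present per generation; ``mu_c`` the per-generation probability that a
    given cell carries/gains a duplicate.  The probability that both concur
    in the same cell in a generation (duplication after the mutation) is
    p_concur = n_mut * mu_c / 2, and the global fixation probability is
    2 (S - mu_d) * p_concur (zero, flagged, when S <= mu_d).
    Returns ``(p_concur, P_fix_global, fixable)``.
    """
    if n_mut < 0 or mu_c < 0 or mu_d < 0:
        raise ValueError("inputs must be >= 0")
    p_concur = n_mut * mu_c / 2.0
    if S <= mu_d:
        return p_concur, 0.0, False
    return p_concur, 2.0 * (S - mu_d) * p_concur, True


def mutant_supply(mu: float, n_sites: float, N_eff: float):
    """Expected mutants per generation: mu_b = n_sites*mu; supply = mu_b*<N>."""
    if mu < 0 or n_sites < 0 or N_eff < 0:
        raise ValueError("inputs must be >= 0")
    mu_b = n_sites * mu
    return mu_b, mu_b * N_eff
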