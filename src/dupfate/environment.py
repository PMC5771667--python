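"""Synthetic generators for the two external inputs of the analysis.

1. Fluctuating lactose environments: doses are log-normal around a median
   ``x_median`` with amplitude ``delta_x`` = SD of ln(x) (``delta_x = 0``
   means a constant dose).

2. Promoter-mutant maximal activities: single-point mutations of the lac
   promoter mostly leave maximal expression near the wild-type level but a
   left tail of weakened promoters exists, including a cluster around 50%
   expression.  The empirical distribution is emulated here by a calibrated
   mixture: a scaled-Beta bulk whose mode is pinned at the wild-type
   activity, plus a narrow Gaussian cluster at half expression.  The two
   free parameters (Beta concentration and cluster weight) are solved from
   analytic mixture moments so that the distribution reproduces the target
   skewness and half-expression fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "EnvironmentSpec",
    "PromoterMutantSpec",
    "ConfigurationError",
    "sample_lactose",
    "sample_promoter_activity",
]


class ConfigurationError(ValueError):
    """A generator spec whose constraints cannot be satisfied."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """Constant or log-normally fluctuating lactose dose.

    ``x_median`` is the median dose in mM; ``delta_x`` the SD of ln(x).
    """

    x_median: float = 0.13
    delta_x: float = 1.0

    def __post_init__(self) -> None:
        if self.x_median < 0 or self.delta_x < 0:
            raise ValueError("x_median and delta_x must be >= 0")

    @property
    def mode(self) -> str:
        return "constant" if self.delta_x == 0 else "fluctuating"


@dataclass(frozen=True)
class PromoterMutantSpec:
    """Targets for the promoter-mutant activity distribution.

    ``frac_half_expression=None`` drops the half-expression cluster and
    calibrates the bulk alone (needed e.g. for a symmetric override).
    """

    target_skewness: float = -0.68
    frac_half_expression: Optional[float] = 0.10
    mode_activity: float = 1.0

    def __post_init__(self) -> None:
        if self.target_skewness > 0:
            raise ValueError("target skewness must be <= 0")
        if self.frac_half_expression is not None and not (
            0 < self.frac_half_expression < 1
        ):
            raise ValueError("frac_half_expression must be in (0, 1)")
        if self.mode_activity <= 0:
            raise ValueError("mode_activity must be > 0")


def sample_lactose(
    spec: EnvironmentSpec, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` doses; ln(x/x_median) ~ Normal(0, delta_x)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.delta_x == 0:
        return np.full(n, spec.x_median)
    rng = np.random.default_rng() if rng is None else rng
    return spec.x_median * np.exp(rng.normal(0.0, spec.delta_x, size=n))


# --- promoter-activity mixture calibration ---------------------------------

_UPPER_FACTOR = 1.3  # bulk support is (0, 1.3 * mode_activity]
_CLUSTER_CENTER = 0.5
_CLUSTER_SD = 0.05


def _beta_for_mode(alpha: float) -> float:
    """Beta shape b such that the scaled mode sits at mode/upper."""
    mode_frac = 1.0 / _UPPER_FACTOR
    return 2.0 + (alpha - 1.0) / mode_frac - alpha


def _mixture_moments(alpha: float, w: float, mode: float):
    """Raw moments 1..3, the skewness, and the [0.4, 0.6] mass."""
    beta_b = _beta_for_mode(alpha)
    c = _UPPER_FACTOR * mode
    # raw moments of c * Beta(alpha, beta_b)
    m_bulk = []
    prod = 1.0
    for j in range(3):
        prod *= (alpha + j) / (alpha + beta_b + j)
        m_bulk.append(c ** (j + 1) * prod)
    mu_c, sd_c = _CLUSTER_CENTER * mode, _CLUSTER_SD * mode
    m_cl = [mu_c, mu_c**2 + sd_c**2, mu_c**3 + 3 * mu_c * sd_c**2]
    m = [(1 - w) * mb + w * mc for mb, mc in zip(m_bulk, m_cl)]
    mean = m[0]
    var = m[1] - mean**2
    third = m[2] - 3 * mean * m[1] + 2 * mean**3
    skew = third / var**1.5
    lo, hi = 0.4 * mode, 0.6 * mode
    bulk_mass = stats.beta.cdf(hi / c, alpha, beta_b) - stats.beta.cdf(
        lo / c, alpha, beta_b
    )
    cl_mass = stats.norm.cdf(hi, mu_c, sd_c) - stats.norm.cdf(lo, mu_c, sd_c)
    frac = (1 - w) * bulk_mass + w * cl_mass
    return skew, frac


def _calibrate(spec: PromoterMutantSpec):
    """Solve (alpha, cluster weight) for the spec's targets."""
    if spec.frac_half_expression is None:
        # bulk alone: skewness is U-shaped in alpha with a tail rising to 0-;
        # solve on the monotone branch, accepting the alpha -> inf limit for
        # targets indistinguishable from symmetric
        grid = np.logspace(np.log10(1.6), 8, 80)
        skews = np.array(
            [_mixture_moments(a, 0.0, spec.mode_activity)[0] for a in grid]
        )
        i_min = int(np.argmin(skews))
        if spec.target_skewness < skews[i_min] - 1e-3:
            raise ConfigurationError(
                f"bulk skewness cannot reach {spec.target_skewness}"
            )
        if spec.target_skewness >= skews[-1]:
            alpha = grid[-1]
        else:
            alpha = optimize.brentq(
                lambda a: _mixture_moments(a, 0.0, spec.mode_activity)[0]
                - spec.target_skewness,
                grid[i_min],
                grid[-1],
            )
        return alpha, _beta_for_mode(alpha), 0.0
    else:

        def resid(p):
            alpha, w = np.exp(p[0]), p[1]
            skew, frac = _mixture_moments(alpha, w, spec.mode_activity)
            return [skew - spec.target_skewness, frac - spec.frac_half_expression]

        sol = optimize.least_squares(
            resid, x0=[np.log(6.0), 0.08], bounds=([0.5, 0.0], [12.0, 0.5])
        )
        alpha, w = float(np.exp(sol.x[0])), float(sol.x[1])
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-4:
        raise ConfigurationError(
            f"promoter-activity targets infeasible (residual {sol.fun})"
        )
    return alpha, _beta_for_mode(alpha), w


def sample_promoter_activity(
    spec: PromoterMutantSpec = PromoterMutantSpec(),
    n: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` mutant maximal activities (y_max values).

    The distribution is unimodal with mode near ``mode_activity``, left
    skewed with sample skewness near ``target_skewness``, and carries
    ``frac_half_expression`` of its mass in the half-expression band
    [0.4, 0.6] (in units of the wild-type activity).
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    alpha, beta_b, w = _calibrate(spec)
    c = _UPPER_FACTOR * spec.mode_activity
    from_cluster = rng.random(n) < w
    out = c * rng.beta(alpha, beta_b, size=n)
    n_cl = int(from_cluster.sum())
    if n_cl:
        cl = rng.normal(
            _CLUSTER_CENTER * spec.mode_activity,
            _CLUSTER_SD * spec.mode_activity,
            size=n_cl,
        )
        out[from_cluster] = np.clip(cl, 1e-9, c)
    return out
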