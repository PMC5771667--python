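"""Stochastic expression of singleton and duplicated gene copies.

A cell's normalized expression follows a Hill response to the inducer,
perturbed by multiplicative log-normal noise acting on the effective dose.
Intrinsic noise (SD eta_in of ln z_i) is drawn independently per gene copy;
extrinsic noise (SD eta_ex of ln z0) is shared by all copies in the cell:

    y = sum_i  y_max_i * (x z_i z0)^n / (x0^n + (x z_i z0)^n)

Duplication with dosage sharing (y_max = [0.5, 0.5]) averages two
independent intrinsic draws and therefore halves the intrinsic variance
while leaving extrinsic fluctuations untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .fitness import DEFAULT_PARAMS, FitnessParams, optimal_expression

__all__ = [
    "NoiseParams",
    "CopySpec",
    "NoiseDraw",
    "SINGLETON",
    "SHARING_DUPLICATE",
    "DOUBLING_DUPLICATE",
    "deterministic_response",
    "stochastic_response",
    "sample_expression",
    "expression_cv",
    "median_dose_response",
    "hill_slope_at_x0",
    "curve_deviation_test",
]


@dataclass(frozen=True)
class NoiseParams:
    """SDs of natural-log intrinsic (per copy) and extrinsic (shared) noise."""

    eta_in: float = 0.0
    eta_ex: float = 0.0

    def __post_init__(self) -> None:
        if self.eta_in < 0 or self.eta_ex < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class CopySpec:
    """Per-copy maximal expression levels of a genotype."""

    y_max: tuple = (1.0,)

    def __post_init__(self) -> None:
        ym = tuple(float(v) for v in self.y_max)
        if len(ym) == 0 or any(v <= 0 for v in ym):
            raise ValueError("y_max must be a non-empty list of positive levels")
        object.__setattr__(self, "y_max", ym)

    @property
    def n_copies(self) -> int:
        return len(self.y_max)

    @property
    def total(self) -> float:
        return float(sum(self.y_max))


SINGLETON = CopySpec((1.0,))
SHARING_DUPLICATE = CopySpec((0.5, 0.5))
DOUBLING_DUPLICATE = CopySpec((1.0, 1.0))


@dataclass(frozen=True)
class NoiseDraw:
    """One cell's noise multipliers: shared z0 and per-copy z_i."""

    z0: float
    z: tuple


def _hill(u, params: FitnessParams):
    un = u ** params.n
    return un / (params.x0 ** params.n + un)


def deterministic_response(
    x, params: FitnessParams = DEFAULT_PARAMS, copies: CopySpec = SINGLETON
):
    """Noise-free expression: ``(sum y_max_i) * x^n / (x0^n + x^n)``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    y = copies.total * _hill(x, params)
    return float(y) if y.ndim == 0 else y


def stochastic_response(
    x: float,
    params: FitnessParams = DEFAULT_PARAMS,
    copies: CopySpec = SINGLETON,
    noise: NoiseParams = NoiseParams(),
    rng: np.random.Generator | None = None,
):
    """One cell's steady-state expression and the noise draw behind it.

    Returns ``(y, NoiseDraw)``.  See :func:`sample_expression` for the
    vectorized batch sampler used by all downstream Monte Carlo.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    z0 = float(np.exp(rng.normal(0.0, noise.eta_ex)))
    z = np.exp(rng.normal(0.0, noise.eta_in, size=copies.n_copies))
    y = float(
        np.sum(np.asarray(copies.y_max) * _hill(x * z * z0, params))
    )
    return y, NoiseDraw(z0=z0, z=tuple(float(v) for v in z))


def sample_expression(
    x,
    n_samples: int | None = None,
    params: FitnessParams = DEFAULT_PARAMS,
    copies: CopySpec = SINGLETON,
    noise: NoiseParams = NoiseParams(),
    rng: np.random.Generator | None = None,
    z0: np.ndarray | None = None,
):
    """Vectorized batch of stochastic responses.

    ``x`` may be a scalar (with ``n_samples`` draws at that dose) or an
    array of per-cell doses.  ``z0`` optionally injects pre-drawn extrinsic
    multipliers, which lets callers share the extrinsic state between
    genotypes living in the same cell.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        if n_samples is None:
            raise ValueError("n_samples required for scalar dose")
        x = np.full(n_samples, float(x))
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    m = x.shape[0]
    if z0 is None:
        z0 = np.exp(rng.normal(0.0, noise.eta_ex, size=m))
    y = np.zeros(m)
    for y_max_i in copies.y_max:
        zi = np.exp(rng.normal(0.0, noise.eta_in, size=m))
        y += y_max_i * _hill(x * zi * z0, params)
    return y


def expression_cv(
    x: float,
    params: FitnessParams = DEFAULT_PARAMS,
    copies: CopySpec = SINGLETON,
    noise: NoiseParams = NoiseParams(),
    n_samples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Coefficient of variation (SD/mean) of expression at a fixed dose.

    Returns NaN when the mean is zero (x = 0, where nothing is expressed).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    y = sample_expression(x, n_samples, params, copies, noise, rng)
    mean = y.mean()
    if mean == 0:
        return float("nan")
    return float(y.std(ddof=1) / mean)


def median_dose_response(
    doses,
    params: FitnessParams = DEFAULT_PARAMS,
    copies: CopySpec = SINGLETON,
    noise: NoiseParams = NoiseParams(),
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-dose median expression over ``n_samples`` stochastic draws.

    The median is the population-level readout: for symmetric log-noise it
    is preserved by the monotone Hill map, so a singleton's median curve
    coincides with the deterministic one while a duplicate's is flattened.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(np.diff(doses) < 0) or np.any(doses < 0):
        raise ValueError("doses must be sorted and non-negative")
    rng = np.random.default_rng() if rng is None else rng
    med = np.empty_like(doses)
    for i, x in enumerate(doses):
        if noise.eta_in == 0 and noise.eta_ex == 0:
            med[i] = deterministic_response(x, params, copies)
        else:
            med[i] = np.median(
                sample_expression(x, n_samples, params, copies, noise, rng)
            )
    return pd.DataFrame({"x": doses, "y_median": med})


def hill_slope_at_x0(curve: pd.DataFrame, params: FitnessParams = DEFAULT_PARAMS):
    """Fit a Hill function to a median dose-response curve.

    Least-squares fit of ``y = Y * x^m / (K^m + x^m)`` (free Y, m, K)
    initialized at the deterministic values.  Returns
    ``(n_eff, slope)`` where ``n_eff = m`` is the effective Hill
    coefficient and ``slope = m*Y/4`` is the slope of y vs normalized
    dose x/K at the fitted midpoint (for the deterministic wild type this
    is n/4 = 1).
    """
    x = np.asarray(curve["x"], dtype=float)
    y = np.asarray(curve["y_median"], dtype=float)
    if x.max() / max(x.min(), 1e-30) < 10:
        raise ValueError("curve must span at least one decade around x0")

    def model(x, Y, m, K):
        return Y * x ** m / (K ** m + x ** m)

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=[max(y.max(), 1e-6), params.n, params.x0],
            bounds=([1e-9, 0.1, 1e-9], [np.inf, 50.0, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise ValueError(f"Hill fit failed (non-sigmoidal curve?): {exc}")
    Y, m, K = popt
    return float(m), float(m * Y / 4.0)


def curve_deviation_test(
    x0_range=(0.01, 1.0),
    m: int = 1000,
    params: FitnessParams = DEFAULT_PARAMS,
    dose_grid=None,
    rng: np.random.Generator | None = None,
) -> float:
    """How special is the wild-type EC50 relative to random alternatives?

    Samples ``m`` EC50 values log-uniformly from ``x0_range``, computes the
    Euclidean distance between each candidate deterministic dose-response
    curve and the optimal-expression curve over ``dose_grid`` (default: 50
    log-spaced doses in [0.001, 10] mM), and returns the fraction of
    candidates at least as close as the wild type.  A small p says the
    wild-type regulatory constant is nearly the best match to the optimum.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if dose_grid is None:
        dose_grid = np.logspace(-3, 1, 50)
    dose_grid = np.asarray(dose_grid, dtype=float)
    y_opt = optimal_expression(dose_grid, params)

    def dist(x0_val: float) -> float:
        from dataclasses import replace

        p = replace(params, x0=x0_val)
        y = deterministic_response(dose_grid, p, SINGLETON)
        return float(np.linalg.norm(y - y_opt))

    d_wt = dist(params.x0)
    lo, hi = np.log(x0_range[0]), np.log(x0_range[1])
    candidates = np.exp(rng.uniform(lo, hi, size=m))
    d = np.array([dist(c) for c in candidates])
    return float(np.mean(d <= d_wt))
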