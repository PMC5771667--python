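"""Cost-benefit fitness model for an inducible catabolic enzyme.

Growth rate is modelled as ``W = W0 * (1 + B - C)`` where the benefit of
expressing the enzyme at normalized level ``y`` under inducer (lactose)
concentration ``x`` follows Michaelis-Menten kinetics, ``B = a*y*x/(k+x)``,
and the cost of sequestering cellular resources diverges as expression
approaches the resource ceiling ``h``, ``C = b*y/(h-y)``.  Above the ceiling
(``y > h``) the cell is assumed inviable (``W = 0``).

All parameters default to the experimentally fitted E. coli lac operon
values.  Doses are in mM, growth rates in 1/h, expression is dimensionless
(wild-type maximal expression = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "FitnessParams",
    "fitness_components",
    "fitness",
    "optimal_expression",
    "optimal_slope_at",
    "selection_coefficient",
    "scale_to_genome",
]

#: sentinel returned for the cost at/above the resource ceiling (pole of C)
COST_UNDEFINED = float("inf")


@dataclass(frozen=True)
class FitnessParams:
    """Fitted constants of the growth-rate model.

    Attributes
    ----------
    W0 : basal growth rate in absence of lactose (1/h).
    a : benefit scale (growth-rate gain from lactose utilization).
    k : Michaelis constant of the benefit term (mM).
    b : cost scale (growth-rate loss per unit expression).
    h : resource ceiling; cost diverges as y -> h.
    x0 : inducer EC50 of the regulatory response (mM).
    n : Hill coefficient of the regulatory response.
    G : haploid genome size in Mbp (optional bookkeeping; see
        :func:`scale_to_genome`).
    """

    W0: float = 1.0
    a: float = 0.17
    k: float = 0.40
    b: float = 0.036
    h: float = 1.80
    x0: float = 0.13
    n: float = 4.0
    G: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("W0", "a", "k", "b", "h", "x0", "n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")
        if self.G is not None and self.G <= 0:
            raise ValueError("genome size G must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessParams":
        """Build from a flat config block (YAML/JSON); missing keys default."""
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown fitness parameter(s): {sorted(unknown)}")
        return cls(**known)


DEFAULT_PARAMS = FitnessParams()


def _validate_xy(x, y) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError("lactose concentration x must be >= 0")
    if np.any(np.asarray(y) < 0):
        raise ValueError("expression y must be >= 0")


def fitness_components(x, y, params: FitnessParams = DEFAULT_PARAMS):
    """Benefit and cost of expressing at level ``y`` under dose ``x``.

    Returns ``(B, C)``.  The cost is reported as ``inf`` at and above the
    pole ``y = h`` where the model ceases to be meaningful (fitness is 0
    there by convention).  Accepts scalars or arrays.
    """
    _validate_xy(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    B = params.a * y * x / (params.k + x)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(y < params.h, params.b * y / (params.h - y), COST_UNDEFINED)
    if B.ndim == 0:
        return float(B), float(C)
    return B, C


def fitness(x, y, params: FitnessParams = DEFAULT_PARAMS):
    """Growth rate ``W = W0*(1 + B - C)``, floored at 0; ``W = 0`` for y > h.

    The floor covers expression just below the ceiling, where the cost pole
    would otherwise drive the growth rate negative.  Vectorized.
    """
    _validate_xy(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    B = params.a * y * x / (params.k + x)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(y < params.h, params.b * y / (params.h - y), np.inf)
    W = np.where(y <= params.h, np.maximum(params.W0 * (1.0 + B - C), 0.0), 0.0)
    if W.ndim == 0:
        return float(W)
    return W


def optimal_expression(x, params: FitnessParams = DEFAULT_PARAMS):
    """Expression level maximizing W at dose ``x`` (dW/dy = 0).

    Closed form ``y_opt = h - sqrt(b*h*(k+x)/(a*x))``, clamped to [0, h]:
    at low doses the unclamped optimum is negative, and since W is then
    monotone decreasing in y the biological optimum is zero expression.
    ``x = 0`` returns 0 by the same convention.  Vectorized.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("lactose concentration x must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = params.h - np.sqrt(
            params.b * params.h * (params.k + x) / (params.a * x)
        )
    y = np.where(x > 0, np.clip(raw, 0.0, params.h), 0.0)
    if y.ndim == 0:
        return float(y)
    return y


def optimal_slope_at(x: float, params: FitnessParams = DEFAULT_PARAMS) -> float:
    """Slope of the optimal dose-response curve vs normalized dose at ``x``.

    Returns ``x0 * d(y_opt)/dx`` from the closed-form derivative
    ``d(y_opt)/dx = sqrt(b*h/a) * k / (2 x^2 sqrt((k+x)/x))``.  In the
    clamped region (y_opt = 0) the slope is 0 (a warning is not raised;
    the caller can test ``optimal_expression(x) > 0``).
    """
    if x <= 0:
        raise ValueError("x must be > 0")
    if optimal_expression(x, params) <= 0.0:
        return 0.0
    g = (params.k + x) / x
    dy_dx = (
        math.sqrt(params.b * params.h / params.a)
        * params.k
        / (2.0 * x * x * math.sqrt(g))
    )
    return params.x0 * dy_dx


def selection_coefficient(W_adv, W_ref):
    """Selection coefficient ``S = W_adv / W_ref - 1``.

    ``W_ref`` must be positive (a reference genotype that does not grow has
    no defined relative fitness).  ``W_adv = 0`` gives S = -1.  Vectorized.
    """
    W_adv = np.asarray(W_adv, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    if np.any(W_ref <= 0):
        raise ValueError("reference fitness W_ref must be > 0")
    S = W_adv / W_ref - 1.0
    if S.ndim == 0:
        return float(S)
    return S


def scale_to_genome(G: float, params: FitnessParams = DEFAULT_PARAMS) -> FitnessParams:
    """Rescale the resource ceiling to a genome of ``G`` Mbp: ``h = 0.36*G``.

    Larger genomes proxy for cells with more expression resources, so the
    cost of an extra gene copy shrinks with G (G ~ 5 recovers the E. coli
    default h = 1.8).
    """
    if G <= 0:
        raise ValueError("genome size G must be > 0")
    return replace(params, h=0.36 * G, G=G)
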