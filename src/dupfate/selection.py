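"""Monte Carlo selection-coefficient analyses of duplicate vs singleton.

Each trial compares two genotypes living in distinct cells that experience
the same environmental dose but independent expression noise (both
intrinsic and extrinsic draws are genotype-private; only the dose is
shared).  The per-trial selection coefficient is S = W_chal / W_ref - 1
and summaries report its mean and Fisher-Pearson skewness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .environment import EnvironmentSpec, sample_lactose
from .expression import (
    CopySpec,
    DOUBLING_DUPLICATE,
    NoiseParams,
    SHARING_DUPLICATE,
    SINGLETON,
    sample_expression,
)
from .fitness import DEFAULT_PARAMS, FitnessParams, fitness, scale_to_genome
from .popgen import effective_population_size

__all__ = [
    "GenotypePair",
    "SelectionSummary",
    "selection_distribution",
    "mean_selection_landscape",
    "dosage_selection_curve",
    "imbalance_selection_curve",
    "promoter_mutant_selection",
    "neutral_region",
]

MODERATE_NOISE = NoiseParams(0.3, 0.3)
HIGH_NOISE = NoiseParams(1.0, 1.0)


@dataclass(frozen=True)
class GenotypePair:
    """Challenger (e.g. duplicate) vs reference (e.g. singleton)."""

    challenger: CopySpec = SHARING_DUPLICATE
    reference: CopySpec = SINGLETON
    noise: NoiseParams = NoiseParams()
    params: FitnessParams = DEFAULT_PARAMS


@dataclass
class SelectionSummary:
    mean_S: float
    skewness: float
    n: int
    n_excluded: int = 0
    samples: Optional[np.ndarray] = None

    @property
    def mean_S_sem(self) -> float:
        """Monte Carlo standard error of mean_S."""
        if self.samples is None or len(self.samples) < 2:
            return float("nan")
        return float(self.samples.std(ddof=1) / np.sqrt(len(self.samples)))


def selection_distribution(
    pair: GenotypePair,
    env: EnvironmentSpec,
    n: int = 10_000,
    rng: np.random.Generator | None = None,
    keep_samples: bool = True,
) -> SelectionSummary:
    """Distribution of per-response S over n shared-dose trials.

    Trials in which the reference genotype does not grow (W_ref = 0,
    possible only when its expression can exceed the resource ceiling) are
    excluded and counted.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    x = sample_lactose(env, n, rng)
    y_ref = sample_expression(
        x, params=pair.params, copies=pair.reference, noise=pair.noise, rng=rng
    )
    y_chal = sample_expression(
        x, params=pair.params, copies=pair.challenger, noise=pair.noise, rng=rng
    )
    W_ref = fitness(x, y_ref, pair.params)
    W_chal = fitness(x, y_chal, pair.params)
    ok = W_ref > 0
    n_excl = int((~ok).sum())
    if n_excl:
        warnings.warn(f"excluded {n_excl} trials with W_ref = 0", stacklevel=2)
    S = W_chal[ok] / W_ref[ok] - 1.0
    return SelectionSummary(
        mean_S=float(S.mean()),
        skewness=float(stats.skew(S)) if S.std() > 0 else 0.0,
        n=int(ok.sum()),
        n_excluded=n_excl,
        samples=S if keep_samples else None,
    )


def mean_selection_landscape(
    x_medians: Sequence[float],
    eta_in_grid: Sequence[float],
    eta_ex: float = 0.3,
    pair: GenotypePair | None = None,
    n: int = 10_000,
    delta_x: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """<S> over a (median dose) x (intrinsic noise) grid at fixed eta_ex.

    Returns a matrix of shape (len(eta_in_grid), len(x_medians)).
    """
    if len(x_medians) == 0 or len(eta_in_grid) == 0:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    base = pair or GenotypePair()
    out = np.empty((len(eta_in_grid), len(x_medians)))
    for i, eta_in in enumerate(eta_in_grid):
        p = GenotypePair(
            challenger=base.challenger,
            reference=base.reference,
            noise=NoiseParams(eta_in, eta_ex),
            params=base.params,
        )
        for j, xm in enumerate(x_medians):
            env = EnvironmentSpec(x_median=xm, delta_x=delta_x)
            out[i, j] = selection_distribution(
                p, env, n, rng, keep_samples=False
            ).mean_S
    return out


def dosage_selection_curve(
    x_grid: Sequence[float],
    noise: NoiseParams = MODERATE_NOISE,
    params: FitnessParams = DEFAULT_PARAMS,
    n: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """<S>(x) of expression-doubling duplication ([1,1] vs [1]) at constant dose.

    At x = 0 nothing is expressed by either genotype, so the duplication is
    strictly neutral (S = 0 exactly, no sampling).
    """
    rng = np.random.default_rng() if rng is None else rng
    pair = GenotypePair(DOUBLING_DUPLICATE, SINGLETON, noise, params)
    out = np.empty(len(x_grid))
    for j, x in enumerate(x_grid):
        if x == 0:
            out[j] = 0.0
            continue
        env = EnvironmentSpec(x_median=x, delta_x=0.0)
        out[j] = selection_distribution(pair, env, n, rng, keep_samples=False).mean_S
    return out


def imbalance_selection_curve(
    ratio_grid: Sequence[float],
    x: float = 0.13,
    noise: NoiseParams = HIGH_NOISE,
    params: FitnessParams = DEFAULT_PARAMS,
    n: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """<S>(y_max1/y_max2) of a duplicate with total expression 1 vs a singleton.

    The duplicate splits unit expression as (r/(1+r), 1/(1+r)); a balanced
    split (ratio 1) buffers intrinsic noise best, and an extreme ratio
    degenerates to the singleton (S -> 0).
    """
    rng = np.random.default_rng() if rng is None else rng
    env = EnvironmentSpec(x_median=x, delta_x=0.0)
    out = np.empty(len(ratio_grid))
    for j, r in enumerate(ratio_grid):
        if r <= 0:
            raise ValueError("ratios must be > 0")
        y1 = r / (1.0 + r)
        pair = GenotypePair(CopySpec((y1, 1.0 - y1)), SINGLETON, noise, params)
        out[j] = selection_distribution(pair, env, n, rng, keep_samples=False).mean_S
    return out


def promoter_mutant_selection(
    y_max_values: Sequence[float],
    with_duplication: bool,
    env: EnvironmentSpec,
    noise: NoiseParams = HIGH_NOISE,
    params: FitnessParams = DEFAULT_PARAMS,
    n: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """<S> of each promoter mutant (optionally after duplication) vs wild type.

    Without duplication the mutant is a singleton at activity y_max; with
    duplication it carries two copies at y_max each (so y_max = 0.5
    recovers the ancestral total expression with two copies).
    """
    rng = np.random.default_rng() if rng is None else rng
    out = np.empty(len(y_max_values))
    for j, ym in enumerate(y_max_values):
        if ym <= 0:
            raise ValueError("y_max values must be > 0")
        chal = CopySpec((ym, ym)) if with_duplication else CopySpec((ym,))
        pair = GenotypePair(chal, SINGLETON, noise, params)
        out[j] = selection_distribution(pair, env, n, rng, keep_samples=False).mean_S
    return out


def neutral_region(
    y_grid: Sequence[float],
    G_grid: Sequence[float],
    noise: NoiseParams = MODERATE_NOISE,
    params: FitnessParams = DEFAULT_PARAMS,
    n: int = 2_000,
    dose_factor: float = 100.0,
    rng: np.random.Generator | None = None,
):
    """Effective neutrality of expression-doubling duplication: |<N><S>| < 1.

    For each (expression level y, genome size G): the cost ceiling is
    rescaled to h = 0.36 G, the benefit is switched off (a -> 0 limit via
    a tiny value, isolating the cost of duplication), and <S> of [y, y] vs
    [y] is measured at a saturating dose (dose_factor * x0), where the
    realized expression equals y_max and noise is effectively inert.  The
    effective population size is 3e9 / G^1.44.  Returns
    ``(neutral_mask, S_matrix)`` with shape (len(G_grid), len(y_grid)).
    """
    from dataclasses import replace

    rng = np.random.default_rng() if rng is None else rng
    S_mat = np.empty((len(G_grid), len(y_grid)))
    neutral = np.empty_like(S_mat, dtype=bool)
    for i, G in enumerate(G_grid):
        if G <= 0:
            raise ValueError("genome sizes must be > 0")
        # a tiny benefit scale stands in for a = 0 (FitnessParams requires > 0)
        p = replace(scale_to_genome(G, params), a=1e-300)
        N_eff = effective_population_size(G)
        x = dose_factor * p.x0
        for j, y in enumerate(y_grid):
            if y < 0:
                raise ValueError("expression levels must be >= 0")
            if y == 0:
                S_mat[i, j] = 0.0
            elif y >= p.h:
                # the singleton itself is inviable at this ceiling
                S_mat[i, j] = -1.0
            else:
                pair = GenotypePair(CopySpec((y, y)), CopySpec((y,)), noise, p)
                env = EnvironmentSpec(x_median=x, delta_x=0.0)
                S_mat[i, j] = selection_distribution(
                    pair, env, n, rng, keep_samples=False
                ).mean_S
            neutral[i, j] = abs(N_eff * S_mat[i, j]) < 1.0
    return neutral, S_mat
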