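"""Agent-based in silico serial-dilution evolution of two genotypes.

A culture of carrying capacity N is grown from N/D founders and diluted
D-fold once per passage (one day); the lactose dose is redrawn each
passage.  Every cell's growth rate W comes from its own stochastic
expression draw, its volume grows as 2^(W t), and growth stops at the
common time t* when the total volume reaches N (so a passage spans about
log2(D) generations).  Within a passage, growth is simulated as
synchronous generation steps of one doubling time each, with expression
noise redrawn per cell per step; the final fractional step is solved by
bisection so the total volume lands exactly on N.  Dilution keeps the
deterministic volume ratio dominant while retaining binomial sampling
noise in the founders, which is what produces replicate-to-replicate
variability.  No mutations occur: genotype frequencies change only through
selection and drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .environment import EnvironmentSpec, sample_lactose
from .expression import CopySpec, NoiseParams, SHARING_DUPLICATE, SINGLETON, sample_expression
from .fitness import DEFAULT_PARAMS, FitnessParams, fitness
from .popgen import competition_dynamics, ratio_from_frequency

__all__ = ["SimConfig", "EvolutionTrajectory", "run_passage", "run_evolution",
           "theory_comparison", "TheoryComparison"]

MAX_HOURS_PER_PASSAGE = 24.0


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a serial-dilution competition experiment."""

    N: int = 100_000
    D: float = 100.0
    duplicate: CopySpec = SHARING_DUPLICATE
    singleton: CopySpec = SINGLETON
    noise: NoiseParams = NoiseParams(0.5, 0.0)
    env: EnvironmentSpec = EnvironmentSpec(x_median=0.13, delta_x=1.0)
    params: FitnessParams = DEFAULT_PARAMS
    f0: float = 0.5
    n_passages: int = 151
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N / self.D < 10:
            raise ValueError("need at least 10 founders per passage (N/D >= 10)")
        if not (0 <= self.f0 <= 1):
            raise ValueError("f0 must be in [0, 1]")
        if self.n_passages < 1 or self.replicates < 1:
            raise ValueError("n_passages and replicates must be >= 1")

    @property
    def founders(self) -> int:
        return int(round(self.N / self.D))

    @property
    def generations_per_passage(self) -> float:
        return math.log2(self.D)


@dataclass
class EvolutionTrajectory:
    """Per-passage records (replicate, passage, generation, f, dose)."""

    data: pd.DataFrame
    config: SimConfig

    def mean_sd(self) -> pd.DataFrame:
        """Replicate mean and SD of the duplicate frequency per generation."""
        g = self.data.groupby("generation")["f"]
        return pd.DataFrame(
            {"f_mean": g.mean(), "f_sd": g.std(ddof=1)}
        ).reset_index()

    def f_at(self, generation: float) -> pd.Series:
        """Per-replicate f at the recorded generation closest to ``generation``."""
        gens = self.data["generation"].unique()
        closest = gens[np.argmin(np.abs(gens - generation))]
        sel = self.data[self.data["generation"] == closest]
        return sel.set_index("replicate")["f"]


class ExtinctionError(RuntimeError):
    """Every cell in the culture stopped growing."""


def _grow_step(
    counts: tuple[int, int],
    dose: float,
    tau: float,
    config: SimConfig,
    rng: np.random.Generator,
):
    """One synchronous step: per-cell W draws, volume factors 2^(W tau).

    Returns per-genotype end-of-step volumes (duplicate, singleton) and the
    raw per-cell growth factors for fractional-step solving.
    """
    vols = []
    Ws = []
    for copies, n_cells in zip((config.duplicate, config.singleton), counts):
        if n_cells == 0:
            Ws.append(np.empty(0))
            vols.append(0.0)
            continue
        y = sample_expression(
            dose, n_cells, config.params, copies, config.noise, rng
        )
        W = fitness(np.full(n_cells, dose), y, config.params)
        Ws.append(np.atleast_1d(W))
        vols.append(float(np.exp2(W * tau).sum()))
    return vols, Ws


def _solve_saturation_time(W: np.ndarray, N: float) -> float:
    """Common time tau in (0, 1] at which sum_i 2^(W_i tau) reaches N."""
    # 1e-4 precision in tau is far below the sampling noise of the passage
    lo, hi = 0.0, 1.0
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if float(np.exp2(W * mid).sum()) < N:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _stochastic_round(v: float, rng: np.random.Generator) -> int:
    base = int(v)
    return base + (1 if rng.random() < v - base else 0)


def run_passage(
    founders: tuple[int, int],
    dose: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Grow one passage from ``founders`` = (n_duplicate, n_singleton).

    Returns the founders of the next passage, sampled binomially with
    probability proportional to the end-of-passage genotype volumes.
    """
    if sum(founders) != config.founders:
        raise ValueError("founders must total N/D")
    counts = tuple(founders)
    hours = 0.0
    total_volume = float(sum(counts))
    end_vols = [float(counts[0]), float(counts[1])]
    while hours < MAX_HOURS_PER_PASSAGE and total_volume < config.N:
        vols, Ws = _grow_step(counts, dose, 1.0, config, rng)
        if all(len(W) == 0 or np.all(W == 0) for W in Ws):
            raise ExtinctionError("all cells have zero growth rate")
        step_total = sum(vols)
        if step_total >= config.N:
            # fractional final step: solve sum 2^(W tau) = N, no redraw
            W_all = np.concatenate([W for W in Ws if len(W)])
            tau = _solve_saturation_time(W_all, config.N)
            end_vols = [float(np.exp2(W * tau).sum()) for W in Ws]
            hours += tau
            break
        # complete step: rebin volumes into unit cells for the next round
        end_vols = vols
        counts = tuple(_stochastic_round(v, rng) for v in vols)
        total_volume = float(sum(counts))
        hours += 1.0
    v_dup, v_sin = end_vols
    total = v_dup + v_sin
    n_found = config.founders
    n_dup = int(rng.binomial(n_found, v_dup / total))
    return n_dup, n_found - n_dup


def run_evolution(config: SimConfig) -> EvolutionTrajectory:
    """Run the full serial-dilution experiment over all replicates.

    The generation counter advances by log2(D) per passage; the dose is
    redrawn from the environment each passage and shared by all cells.
    """
    records = []
    root = np.random.default_rng(config.seed)
    for rep in range(config.replicates):
        rng = np.random.default_rng(root.integers(2**31))
        n_dup = int(round(config.f0 * config.founders))
        counts = (n_dup, config.founders - n_dup)
        gen = 0.0
        records.append((rep, 0, gen, counts[0] / config.founders, np.nan))
        for passage in range(1, config.n_passages + 1):
            dose = float(sample_lactose(config.env, 1, rng)[0])
            counts = run_passage(counts, dose, config, rng)
            gen += config.generations_per_passage
            records.append((rep, passage, gen, counts[0] / config.founders, dose))
    data = pd.DataFrame(
        records, columns=["replicate", "passage", "generation", "f", "dose"]
    )
    return EvolutionTrajectory(data=data, config=config)


@dataclass
class TheoryComparison:
    max_abs_residual: float
    within_envelope: bool      # strict: every checkpoint inside mean +/- 2 SD
    frac_within: float         # fraction of checkpoints inside the envelope
    n_checked: int


def theory_comparison(
    trajectory: EvolutionTrajectory, S_mean: float
) -> TheoryComparison:
    """Compare replicate-mean f(t) with the logistic prediction at <S>.

    The prediction is f(t) = 1/(1 + (1/f0 - 1) 2^(-<S> t)).  Reports the
    maximum absolute residual of the replicate mean and whether the
    analytic curve stays inside the mean +/- 2 SD envelope at every
    recorded generation (SD across replicates; requires >= 2 replicates).
    """
    if trajectory.config.replicates < 2:
        raise ValueError("theory comparison needs >= 2 replicates")
    ms = trajectory.mean_sd()
    r0 = ratio_from_frequency(trajectory.config.f0)
    pred = competition_dynamics(float(r0), S_mean, ms["generation"].values).f
    resid = ms["f_mean"].values - pred
    inside = np.abs(resid) <= 2.0 * ms["f_sd"].values + 1e-12
    return TheoryComparison(
        max_abs_residual=float(np.max(np.abs(resid))),
        within_envelope=bool(np.all(inside)),
        frac_within=float(np.mean(inside)),
        n_checked=len(ms),
    )
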