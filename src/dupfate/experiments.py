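"""Configuration-driven experiment runners.

Each experiment regenerates one figure-level dataset of the analysis from a
seed and optional parameter overrides, writes tidy CSV plus a summary JSON
with the headline statistics, and records a manifest (config + seed +
package version) so any run is reproducible from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Callable, Dict

import numpy as np
import pandas as pd

from . import __version__
from .environment import (
    EnvironmentSpec,
    PromoterMutantSpec,
    sample_lactose,
    sample_promoter_activity,
)
from .expression import (
    DOUBLING_DUPLICATE,
    NoiseParams,
    SHARING_DUPLICATE,
    SINGLETON,
    curve_deviation_test,
    deterministic_response,
    hill_slope_at_x0,
    median_dose_response,
    sample_expression,
)
from .fitness import DEFAULT_PARAMS, FitnessParams, optimal_expression, optimal_slope_at
from .information import mi_significance, mutual_information
from .popgen import (
    duplication_balance,
    duplication_frequency_dynamics,
    effective_population_size,
    fixation_stats,
)
from .selection import (
    GenotypePair,
    HIGH_NOISE,
    MODERATE_NOISE,
    dosage_selection_curve,
    imbalance_selection_curve,
    mean_selection_landscape,
    neutral_region,
    promoter_mutant_selection,
    selection_distribution,
)
from .evolution import SimConfig, run_evolution, theory_comparison

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    seed: int = 0
    out_dir: str = "results"
    overrides: Dict[str, Any] = field(default_factory=dict)


def _write(config: ExperimentConfig, tables: Dict[str, pd.DataFrame], summary: dict):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out / f"{config.experiment}_{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "overrides": config.overrides,
        "version": __version__,
    }
    (out / f"{config.experiment}_summary.json").write_text(
        json.dumps({"summary": summary, "manifest": manifest}, indent=2, default=float)
    )
    return summary


def _ov(config: ExperimentConfig, key: str, default):
    return config.overrides.get(key, default)


def _exp_tradeoff_curves(config: ExperimentConfig):
    """Deterministic, optimal and median dose-response curves and slopes."""
    rng = np.random.default_rng(config.seed)
    params = DEFAULT_PARAMS
    doses = np.logspace(np.log10(params.x0 / 30), np.log10(params.x0 * 30), 40)
    det = median_dose_response(doses, params, SINGLETON, NoiseParams())
    noise = NoiseParams(_ov(config, "eta_in", 0.5), _ov(config, "eta_ex", 0.0))
    n_samp = _ov(config, "n_samples", 2000)
    med_dup = median_dose_response(doses, params, SHARING_DUPLICATE, noise, n_samp, rng)
    n_det, slope_det = hill_slope_at_x0(det, params)
    n_dup, slope_dup = hill_slope_at_x0(med_dup, params)
    p_dev = curve_deviation_test(m=_ov(config, "m_deviation", 1000), rng=rng)
    curves = det.rename(columns={"y_median": "y_deterministic"})
    curves["y_optimal"] = optimal_expression(doses, params)
    curves["y_median_duplicate"] = med_dup["y_median"]
    summary = {
        "slope_deterministic": slope_det,
        "n_eff_deterministic": n_det,
        "slope_duplicate_median": slope_dup,
        "n_eff_duplicate_median": n_dup,
        "slope_optimal_at_x0": optimal_slope_at(params.x0, params),
        "p_curve_deviation": p_dev,
    }
    return _write(config, {"curves": curves}, summary)


def _exp_selection_distribution(config: ExperimentConfig):
    """Per-response S of the dosage-sharing duplicate (fluctuating dose)."""
    rng = np.random.default_rng(config.seed)
    noise = NoiseParams(_ov(config, "eta_in", 0.5), _ov(config, "eta_ex", 0.0))
    env = EnvironmentSpec(
        x_median=_ov(config, "x_median", DEFAULT_PARAMS.x0),
        delta_x=_ov(config, "delta_x", 1.0),
    )
    n = _ov(config, "n", 10_000)
    summ = selection_distribution(GenotypePair(noise=noise), env, n, rng)
    table = pd.DataFrame({"S": summ.samples})
    return _write(
        config,
        {"samples": table},
        {"mean_S": summ.mean_S, "skewness": summ.skewness, "n": summ.n,
         "mean_S_sem": summ.mean_S_sem},
    )


def _exp_mi_transfer(config: ExperimentConfig):
    """Mutual information of the singleton and duplicate channels."""
    rng = np.random.default_rng(config.seed)
    noise = NoiseParams(_ov(config, "eta_in", 0.5), _ov(config, "eta_ex", 0.0))
    env = EnvironmentSpec(
        x_median=_ov(config, "x_median", DEFAULT_PARAMS.x0),
        delta_x=_ov(config, "delta_x", 1.0),
    )
    n = _ov(config, "n", 10_000)
    bins = _ov(config, "bins", 32)
    x = sample_lactose(env, n, rng)
    y_s = sample_expression(x, copies=SINGLETON, noise=noise, rng=rng)
    y_d = sample_expression(x, copies=SHARING_DUPLICATE, noise=noise, rng=rng)
    I_s = mutual_information(x, y_s, bins)
    I_d = mutual_information(x, y_d, bins)
    z, p = mi_significance(I_s.I, I_d.I, n)
    table = pd.DataFrame({"x": x, "y_singleton": y_s, "y_duplicate": y_d})
    return _write(
        config,
        {"samples": table},
        {"I_singleton": I_s.I, "I_duplicate": I_d.I, "z": z, "p": p,
         "bins": bins, "n": n},
    )


def _exp_selection_landscape(config: ExperimentConfig):
    """<S> over median dose x intrinsic noise at fixed extrinsic noise."""
    rng = np.random.default_rng(config.seed)
    x_medians = np.asarray(_ov(config, "x_medians", np.logspace(-2, 0.5, 6)))
    eta_in_grid = np.asarray(_ov(config, "eta_in_grid", [0.0, 0.25, 0.5, 0.75, 1.0]))
    eta_ex = _ov(config, "eta_ex", 0.3)
    n = _ov(config, "n", 5_000)
    M = mean_selection_landscape(x_medians, eta_in_grid, eta_ex, None, n, rng=rng)
    rows = [
        {"x_median": xm, "eta_in": ei, "mean_S": M[i, j], "n": n}
        for i, ei in enumerate(eta_in_grid)
        for j, xm in enumerate(x_medians)
    ]
    table = pd.DataFrame(rows)
    return _write(
        config,
        {"landscape": table},
        {"max_mean_S": float(M.max()),
         "argmax_x_median": float(x_medians[M.max(axis=0).argmax()]),
         "eta_ex": eta_ex},
    )


def _exp_evolve_sweep(config: ExperimentConfig):
    """Serial-dilution evolution vs the analytic prediction."""
    rng = np.random.default_rng(config.seed)
    noise = NoiseParams(_ov(config, "eta_in", 0.5), _ov(config, "eta_ex", 0.0))
    env = EnvironmentSpec(
        x_median=_ov(config, "x_median", DEFAULT_PARAMS.x0),
        delta_x=_ov(config, "delta_x", 1.0),
    )
    sim = SimConfig(
        N=_ov(config, "N", 100_000),
        D=_ov(config, "D", 100.0),
        noise=noise,
        env=env,
        f0=_ov(config, "f0", 0.5),
        n_passages=_ov(config, "n_passages", 151),
        replicates=_ov(config, "replicates", 3),
        seed=config.seed,
    )
    traj = run_evolution(sim)
    summ = selection_distribution(
        GenotypePair(noise=noise), env, _ov(config, "n_S", 100_000), rng,
        keep_samples=False,
    )
    cmp = theory_comparison(traj, summ.mean_S)
    f_end = traj.f_at(1000.0)
    return _write(
        config,
        {"trajectory": traj.data},
        {"mean_S": summ.mean_S, "f_1000_mean": float(f_end.mean()),
         "f_1000_sd": float(f_end.std(ddof=1)),
         "max_abs_residual": cmp.max_abs_residual,
         "within_envelope": cmp.within_envelope},
    )


def _exp_dosage_curves(config: ExperimentConfig):
    """<S> of expression-doubling duplication across constant doses."""
    rng = np.random.default_rng(config.seed)
    x_grid = np.asarray(_ov(config, "x_grid", [0.0, 0.001, 0.01, 0.05, 0.13, 0.5, 2.0]))
    n = _ov(config, "n", 10_000)
    rows = []
    for label, noise in (("moderate", MODERATE_NOISE), ("high", HIGH_NOISE),
                         ("none", NoiseParams())):
        S = dosage_selection_curve(x_grid, noise, DEFAULT_PARAMS, n, rng)
        rows += [{"x": x, "noise": label, "mean_S": s} for x, s in zip(x_grid, S)]
    table = pd.DataFrame(rows)
    none = table[(table.noise == "none") & (table.x == 0.13)]["mean_S"]
    return _write(
        config,
        {"curve": table},
        {"S_no_noise_at_x0": float(none.iloc[0]) if len(none) else None},
    )


def _exp_duplication_balance(config: ExperimentConfig):
    """Formation-deletion balance and its transient dynamics."""
    mu_c = _ov(config, "mu_c", 3e-4)
    mu_d = _ov(config, "mu_d", 4.4e-2)
    S = _ov(config, "S", 0.0)
    bal = duplication_balance(mu_c, mu_d, S)
    t_max = _ov(config, "t_max", 300)
    traj = duplication_frequency_dynamics(mu_c, mu_d, S, _ov(config, "f0", 0.0), t_max)
    table = pd.DataFrame({"t": traj.t, "f": traj.f})
    return _write(
        config,
        {"dynamics": table},
        {"f_eq": bal.f_eq, "t_eq": bal.t_eq, "is_equilibrium": bal.is_equilibrium,
         "f_final": float(traj.f[-1])},
    )


def _exp_promoter_path(config: ExperimentConfig):
    """Mutation-then-duplication path: mutant activities and their <S>."""
    rng = np.random.default_rng(config.seed)
    spec = PromoterMutantSpec()
    n_mut = _ov(config, "n_mutants", 200)
    y_max = sample_promoter_activity(spec, max(n_mut, 100), rng)[:n_mut]
    env = EnvironmentSpec(
        x_median=_ov(config, "x_median", DEFAULT_PARAMS.x0),
        delta_x=_ov(config, "delta_x", 0.0),
    )
    n = _ov(config, "n", 4_000)
    S_single = promoter_mutant_selection(y_max, False, env, HIGH_NOISE, n=n, rng=rng)
    S_dup = promoter_mutant_selection(y_max, True, env, HIGH_NOISE, n=n, rng=rng)
    table = pd.DataFrame(
        {"y_max": y_max, "S_mutant": S_single, "S_mutant_duplicated": S_dup}
    )
    # the half-expression-then-duplicate genotype, at the printed conditions
    S_half = promoter_mutant_selection(
        [0.5], True, env, HIGH_NOISE, n=_ov(config, "n_half", 100_000), rng=rng
    )[0]
    fix = fixation_stats(S_half, 2e8, "duplication", mu_d=4.1e-4)
    return _write(
        config,
        {"mutants": table},
        {"mean_S_half_duplicated": S_half, "P_fix": fix.P_fix,
         "fixable": fix.fixable},
    )


def _exp_neutral_region(config: ExperimentConfig):
    """Effectively neutral (|<N><S>| < 1) duplication across (y, G)."""
    rng = np.random.default_rng(config.seed)
    y_grid = np.asarray(_ov(config, "y_grid", [0.0, 0.05, 0.2, 0.5, 1.0, 2.0]))
    G_grid = np.asarray(_ov(config, "G_grid", [1.0, 5.0, 30.0, 300.0, 3000.0]))
    mask, S = neutral_region(y_grid, G_grid, n=_ov(config, "n", 2000), rng=rng)
    rows = [
        {"G": G, "y": y, "mean_S": S[i, j], "neutral": bool(mask[i, j]),
         "N_eff": effective_population_size(G)}
        for i, G in enumerate(G_grid)
        for j, y in enumerate(y_grid)
    ]
    table = pd.DataFrame(rows)
    return _write(
        config,
        {"region": table},
        {"n_neutral": int(mask.sum()), "n_cells": int(mask.size)},
    )


EXPERIMENTS: Dict[str, Callable[[ExperimentConfig], dict]] = {
    "tradeoff_curves": _exp_tradeoff_curves,
    "selection_distribution": _exp_selection_distribution,
    "mi_transfer": _exp_mi_transfer,
    "selection_landscape": _exp_selection_landscape,
    "evolve_sweep": _exp_evolve_sweep,
    "dosage_curves": _exp_dosage_curves,
    "duplication_balance": _exp_duplication_balance,
    "promoter_path": _exp_promoter_path,
    "neutral_region": _exp_neutral_region,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one named experiment; returns its summary dict."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; "
            f"choose from {sorted(EXPERIMENTS)}"
        )
    return EXPERIMENTS[config.experiment](config)
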