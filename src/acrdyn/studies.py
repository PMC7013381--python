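"""Reusable study computations over the model and the synthetic assays.

These are the computations the analysis drivers, the test suite and the
acceptance script all share: an independent fixed-step integration
oracle, the reference mixed/clonal infection runs, the anti-CRISPR
strength sweeps, the type-I-error calibration of the fitness test, and
the (phi, gamma) parameter-recovery study.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .experiments import (
    ExperimentDesign,
    default_gamma_inv_grid,
    default_phi_grid,
    mixed_infection_design,
    run_design,
    sweep_gamma_inv,
    sweep_phi,
)
from .model import ModelParameters, PopulationState, _rhs, simulate
from .stats import competition_fitness, one_sample_test
from .synth import (
    NoiseModel,
    fit_phi_gamma,
    generate_competition,
    generate_noisy_trajectory,
)


def rk4_reference(initial: PopulationState, params: ModelParameters,
                  sample_times: Sequence[float], h: float = 1e-4) -> np.ndarray:
    """Classic fixed-step fourth-order Runge-Kutta integration.

    Deliberately independent of the adaptive integrator behind
    :func:`acrdyn.model.simulate`; used only as a verification oracle.
    Returns densities of shape (len(sample_times), 5).
    """
    sample_times = np.asarray(list(sample_times), dtype=float)
    y = initial.as_array()
    t = float(sample_times[0])
    out = [y.copy()]
    for t_next in sample_times[1:]:
        n_steps = max(1, int(round((t_next - t) / h)))
        dt = (t_next - t) / n_steps
        for _ in range(n_steps):
            k1 = _rhs(y, params)
            k2 = _rhs(y + 0.5 * dt * k1, params)
            k3 = _rhs(y + 0.5 * dt * k2, params)
            k4 = _rhs(y + dt * k3, params)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = float(t_next)
        out.append(y.copy())
    return np.vstack(out)


def max_rel_error_vs_rk4(params: ModelParameters | None = None,
                         initial: PopulationState | None = None,
                         t_end: float = 5.0, n_samples: int = 11,
                         h: float = 1e-4) -> float:
    """Worst relative disagreement between the adaptive integration and
    the fixed-step RK4 oracle over [0, t_end]."""
    params = params or ModelParameters()
    initial = initial or PopulationState(W=1e3, V1=100.0, V2=100.0)
    times = np.linspace(0.0, t_end, n_samples)
    traj = simulate(initial, params, t_end, times)
    oracle = rk4_reference(initial, params, times, h=h)
    scale = np.maximum(np.abs(oracle), 1.0)
    return float(np.max(np.abs(traj.densities - oracle) / scale))


def reference_infections(t_end: float = 30.0) -> dict:
    """The reference infection experiments: mixed infection of sensitive
    hosts, clonal infections of each phage type, and the two host
    backgrounds for the Acr-positive phage."""
    params = ModelParameters()
    designs = {
        "mixed_sensitive": mixed_infection_design(params, t_end=t_end),
        "clonal_acr_negative": ExperimentDesign(
            host_type="sensitive", v1_0=0.0, v2_0=100.0, params=params,
            t_end=t_end),
        "clonal_acr_positive_wt": ExperimentDesign(
            host_type="sensitive", v1_0=100.0, v2_0=0.0, params=params,
            t_end=t_end),
        "clonal_acr_positive_ko": ExperimentDesign(
            host_type="crispr_ko", v1_0=100.0, v2_0=0.0, params=params,
            t_end=t_end),
        "no_phage_control": ExperimentDesign(
            host_type="sensitive", v1_0=0.0, v2_0=0.0, params=params,
            t_end=t_end, no_phage_control=True),
    }
    return {name: run_design(d) for name, d in designs.items()}


def default_sweeps():
    """The two anti-CRISPR strength sweeps at the default grids."""
    base = mixed_infection_design()
    return (sweep_phi(base, default_phi_grid()),
            sweep_gamma_inv(base, default_gamma_inv_grid()))


def monotone_fraction(values: np.ndarray, increasing: bool) -> float:
    """Fraction of adjacent grid steps in the required direction
    (ties count as satisfying either direction)."""
    diffs = np.diff(np.asarray(values, dtype=float))
    ok = diffs >= 0 if increasing else diffs <= 0
    return float(np.mean(ok))


def type1_error_study(n_experiments: int = 1000, alpha: float = 0.05,
                      seed: int = 0, n_replicates: int = 6,
                      noise: NoiseModel = NoiseModel()) -> dict:
    """Empirical type-I error of the log-scale one-sample fitness test.

    Simulates competition assays with true fitness exactly 1 and counts
    how often the two-sided test (vs 1) rejects at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_experiments):
        table = generate_competition(true_fitness=1.0,
                                     n_replicates=n_replicates,
                                     timepoints=(0.0, 3.0), noise=noise,
                                     seed=rng)
        fits = competition_fitness(table, focal="focal", t0=0.0, tx=3.0)
        result = one_sample_test(fits, null_value=1.0, tail="two-sided",
                                 log_scale=True)
        if result.p < alpha:
            rejections += 1
    rate = rejections / n_experiments
    mc_se = math.sqrt(alpha * (1.0 - alpha) / n_experiments)
    return {"rate": rate, "alpha": alpha, "mc_se": mc_se,
            "n_experiments": n_experiments}


def _recovery_design(t_end: float = 30.0) -> ExperimentDesign:
    return mixed_infection_design(t_end=t_end)


def noise_free_recovery(true_phi: float = 0.3,
                        true_gamma: float = 1.0) -> dict:
    """Fit (phi, gamma) to a noise-free synthetic trajectory."""
    design = _recovery_design()
    truth = ModelParameters(phi=true_phi, gamma=true_gamma)
    obs = generate_noisy_trajectory(truth, design,
                                    noise=NoiseModel(sigma_log=0.0),
                                    sample_times=np.linspace(0.0, 30.0, 20),
                                    seed=0)
    fit = fit_phi_gamma(obs, known=ModelParameters(), design=design)
    return {"fit": fit,
            "phi_rel_err": abs(fit.phi - true_phi) / true_phi,
            "gamma_rel_err": abs(fit.gamma - true_gamma) / true_gamma}


def recovery_study(n_seeds: int = 100, sigma_log: float = 0.1,
                   true_phi: float = 0.3, true_gamma: float = 1.0,
                   seed: int = 0, n_times: int = 20) -> dict:
    """Parameter-recovery simulation at a fixed measurement-noise level.

    Generates ``n_seeds`` independent noisy trajectories from the same
    truth and refits (phi, gamma) to each; reports median absolute errors
    of phi and of log gamma.
    """
    design = _recovery_design()
    truth = ModelParameters(phi=true_phi, gamma=true_gamma)
    times = np.linspace(0.0, 30.0, n_times)
    rng = np.random.default_rng(seed)
    phi_err, log_gamma_err = [], []
    for _ in range(n_seeds):
        obs = generate_noisy_trajectory(truth, design,
                                        noise=NoiseModel(sigma_log=sigma_log),
                                        sample_times=times, seed=rng)
        fit = fit_phi_gamma(obs, known=ModelParameters(), design=design)
        phi_err.append(abs(fit.phi - true_phi))
        log_gamma_err.append(abs(math.log(fit.gamma) - math.log(true_gamma)))
    return {"median_abs_phi_err": float(np.median(phi_err)),
            "median_abs_log_gamma_err": float(np.median(log_gamma_err)),
            "phi_err": phi_err, "log_gamma_err": log_gamma_err,
            "n_seeds": n_seeds, "sigma_log": sigma_log}
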