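"""Synthetic competition-assay, plaque-assay and trajectory data.

Emulates the statistical structure of the bench assays so the measurement
statistics and the model-fitting layer can be exercised end-to-end
without any external data: six biological replicates, multiplicative
(log-normal) measurement noise on titres and qPCR quantities, and Poisson
counting noise for plate/plaque counts after serial dilution.

Every generator is a pure function of (truth, noise model, seed): the
same inputs regenerate the same table bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .experiments import ExperimentDesign
from .model import ModelParameters

logger = logging.getLogger(__name__)

#: Detection limit applied before taking logs of simulated observables —
#: the bench assays cannot measure below roughly one particle per culture
#: volume, so both simulated data and model predictions are floored here
#: (matching the extinction threshold).  This keeps collapsed
#: compartments from dominating log-scale fitting losses.
LOG_FLOOR = 1e-3


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for simulated assays.

    ``sigma_log`` is the standard deviation of mean-zero Gaussian noise
    on natural-log quantities (multiplicative noise on the original
    scale); it models replicate-to-replicate titre/qPCR variability.
    ``poisson_counts`` additionally replaces each quantity by a Poisson
    plate count taken after dilution by ``plate_dilution`` and scaled
    back up, modelling colony/plaque counting error.
    """

    sigma_log: float = 0.2
    poisson_counts: bool = False
    plate_dilution: float = 1e-5

    def __post_init__(self):
        if self.sigma_log < 0:
            raise ValueError(f"sigma_log must be >= 0, got {self.sigma_log}")
        if not 0 < self.plate_dilution <= 1:
            raise ValueError("plate_dilution must lie in (0, 1]")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _measure(rng: np.random.Generator, expected: float,
             noise: NoiseModel) -> float:
    """One noisy quantity measurement."""
    q = expected * math.exp(rng.normal(0.0, noise.sigma_log)) \
        if noise.sigma_log > 0 else expected
    if noise.poisson_counts:
        q = rng.poisson(q * noise.plate_dilution) / noise.plate_dilution
    return q


def generate_competition(true_fitness: float,
                         n_replicates: int = 6,
                         timepoints: Sequence[float] = (0.0, 1.0, 3.0),
                         noise: NoiseModel = NoiseModel(),
                         seed=0,
                         initial_fraction: float = 0.5,
                         total_quantity: float = 1e7,
                         competitors: tuple = ("focal", "reference"),
                         ) -> pd.DataFrame:
    """Simulate a two-competitor competition assay.

    The focal competitor's odds grow by a factor ``true_fitness`` per day
    (so the odds-ratio fitness between day 0 and day ``t`` is
    ``true_fitness ** t``); each competitor's quantity at each timepoint
    is then measured with the given noise model.  Returns a long-form
    table with columns replicate, timepoint, competitor, quantity.
    """
    if true_fitness <= 0:
        raise ValueError(f"true_fitness must be > 0, got {true_fitness}")
    if n_replicates < 2:
        raise ValueError(f"need >= 2 replicates, got {n_replicates}")
    if not 0 < initial_fraction < 1:
        raise ValueError("initial_fraction must lie in (0, 1)")
    rng = _rng(seed)
    odds0 = initial_fraction / (1.0 - initial_fraction)
    rows = []
    for rep in range(1, n_replicates + 1):
        for t in timepoints:
            odds = odds0 * true_fitness ** t
            f = odds / (1.0 + odds)
            for comp, frac in zip(competitors, (f, 1.0 - f)):
                rows.append({
                    "replicate": rep,
                    "timepoint": float(t),
                    "competitor": comp,
                    "quantity": _measure(rng, total_quantity * frac, noise),
                })
    return pd.DataFrame(rows)


def generate_ecoi(true_phi: float,
                  ecoi_ko: float = 0.8,
                  counts_scale: int = 10_000,
                  moi: float = 1.0,
                  seed=0) -> pd.DataFrame:
    """Simulate a paired efficiency-of-centres-of-infection assay.

    ``counts_scale`` pre-adsorbed cells per host are challenged at the
    given MOI; centres of infection are Poisson with expectation
    ``ecoi_ko * cells * moi`` on the CRISPR-knockout host and
    ``true_phi * ecoi_ko * cells * moi`` on the resistant (single-spacer
    BIM) host.  Returns a table with columns host, centres, cells, moi.
    """
    if not 0.0 <= true_phi <= 1.0:
        raise ValueError(f"true_phi must lie in [0, 1], got {true_phi}")
    if not 0.0 < ecoi_ko <= 1.0:
        raise ValueError(f"ecoi_ko must lie in (0, 1], got {ecoi_ko}")
    if counts_scale < 1:
        raise ValueError("counts_scale must be >= 1")
    rng = _rng(seed)
    cells = float(counts_scale)
    rows = []
    for host, eff in (("crispr_ko", ecoi_ko), ("bim1", true_phi * ecoi_ko)):
        centres = int(rng.poisson(eff * cells * moi))
        rows.append({"host": host, "centres": centres, "cells": cells,
                     "moi": float(moi)})
    return pd.DataFrame(rows)


def generate_noisy_trajectory(params: ModelParameters,
                              design: ExperimentDesign,
                              noise: NoiseModel = NoiseModel(sigma_log=0.1),
                              sample_times: Sequence[float] | None = None,
                              seed=0,
                              observables: Sequence[str] = ("N", "V1", "V2"),
                              ) -> pd.DataFrame:
    """Simulate the model under ``design`` (with ``params`` substituted)
    and emit noisy log-density observations.

    By default only the bench-observable totals are reported: total
    bacteria N and the two phage titres V1, V2 (the W/R/S split is not
    observable without clone typing).  i.i.d. Gaussian noise with sd
    ``noise.sigma_log`` is added to each natural-log density.  Returns a
    long table with columns time, observable, log_density.
    """
    rng = _rng(seed)
    design = design.replace(params=params)
    if sample_times is None:
        sample_times = np.linspace(0.0, design.t_end, 20)
    sample_times = np.asarray(list(sample_times), dtype=float)
    # Sample exactly at the requested observation times.
    from .model import simulate
    traj = simulate(design.initial_state, design.effective_params,
                    design.t_end, sample_times,
                    transfers=design.transfers or None,
                    extinction_threshold=design.extinction_threshold)
    rows = []
    for name in observables:
        log_true = np.log(np.maximum(traj.column(name), LOG_FLOOR))
        eps = (rng.normal(0.0, noise.sigma_log, size=log_true.size)
               if noise.sigma_log > 0 else np.zeros_like(log_true))
        for t, v in zip(traj.times, log_true + eps):
            rows.append({"time": float(t), "observable": name,
                         "log_density": float(v)})
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    """Outcome of fitting (phi, gamma) to noisy trajectory observations."""

    phi: float
    gamma: float
    loss: float
    converged: bool
    identifiable: bool
    message: str = ""
    grid_losses: np.ndarray | None = field(default=None, repr=False)

    @property
    def gamma_inv(self) -> float:
        return 1.0 / self.gamma


def _prediction_loss(phi: float, gamma: float, obs: pd.DataFrame,
                     known: ModelParameters, design: ExperimentDesign,
                     rtol: float) -> float:
    from .model import simulate

    params = known.replace(phi=float(phi), gamma=float(gamma))
    times = np.unique(obs["time"].to_numpy(dtype=float))
    d = design.replace(params=params)
    traj = simulate(d.initial_state, d.effective_params,
                    max(d.t_end, times[-1]), times,
                    transfers=d.transfers or None, rtol=rtol, atol=1e-8)
    loss = 0.0
    time_index = {t: i for i, t in enumerate(traj.times)}
    for name, grp in obs.groupby("observable"):
        pred = np.log(np.maximum(traj.column(name), LOG_FLOOR))
        idx = [time_index[t] for t in grp["time"].to_numpy(dtype=float)]
        resid = grp["log_density"].to_numpy(dtype=float) - pred[idx]
        loss += float(np.sum(resid ** 2))
    return loss


def fit_phi_gamma(observations: pd.DataFrame,
                  known: ModelParameters,
                  design: ExperimentDesign | None = None,
                  gamma_max: float = 100.0,
                  grid_size: int = 5,
                  rtol: float = 1e-6,
                  n_starts: int = 2) -> FitResult:
    """Estimate the lysis probability phi and the reversion rate gamma
    from noisy log-density observations, all other parameters known.

    Minimises squared error on log densities over
    (phi, gamma) in (0, 1) x (0, gamma_max] via a ``grid_size`` x
    ``grid_size`` multi-start coarse grid (log-spaced in gamma) followed
    by bounded local minimisation from the best ``n_starts`` grid points.
    A flat loss surface or a boundary solution is flagged as
    non-identifiable rather than silently returned.
    """
    required = {"time", "observable", "log_density"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    if observations["time"].nunique() < 10:
        raise ValueError("need >= 10 distinct observation timepoints")
    if "V1" not in set(observations["observable"]):
        raise ValueError("observations must include the Acr-positive "
                         "phage titre V1")
    if design is None:
        from .experiments import mixed_infection_design
        design = mixed_infection_design()

    phi_grid = np.linspace(0.05, 0.95, grid_size)
    gamma_grid = np.logspace(math.log10(0.05), math.log10(gamma_max),
                             grid_size)

    def loss_fn(x):
        phi = min(max(x[0], 1e-6), 1.0 - 1e-6)
        gamma = math.exp(x[1])
        return _prediction_loss(phi, gamma, observations, known, design, rtol)

    grid_losses = np.empty((grid_size, grid_size))
    for i, phi in enumerate(phi_grid):
        for j, gamma in enumerate(gamma_grid):
            grid_losses[i, j] = _prediction_loss(phi, gamma, observations,
                                                 known, design, rtol)

    # Identifiability screen on the coarse grid: a parameter whose axis
    # leaves the loss essentially unchanged cannot be estimated.
    scale = max(abs(grid_losses).max(), 1e-12)
    phi_effect = float(np.ptp(grid_losses, axis=0).max()) / scale
    gamma_effect = float(np.ptp(grid_losses, axis=1).max()) / scale
    flat_tol = 1e-9
    flags = []
    if phi_effect < flat_tol:
        flags.append("phi")
    if gamma_effect < flat_tol:
        flags.append("gamma")
    if flags:
        i, j = np.unravel_index(np.argmin(grid_losses), grid_losses.shape)
        return FitResult(phi=float(phi_grid[i]), gamma=float(gamma_grid[j]),
                         loss=float(grid_losses[i, j]), converged=False,
                         identifiable=False,
                         message=f"flat loss in {', '.join(flags)}: "
                                 "non-identifiable",
                         grid_losses=grid_losses)

    order = np.argsort(grid_losses, axis=None)
    bounds = [(1e-4, 1.0 - 1e-4),
              (math.log(1e-3), math.log(gamma_max))]
    best = None
    converged = False
    for flat_idx in order[:n_starts]:
        i, j = np.unravel_index(flat_idx, grid_losses.shape)
        x0 = [float(phi_grid[i]), math.log(float(gamma_grid[j]))]
        res = minimize(loss_fn, x0, method="L-BFGS-B", bounds=bounds,
                       options={"eps": 1e-7, "ftol": 1e-14, "gtol": 1e-10,
                                "maxiter": 60})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    phi_hat = float(min(max(best.x[0], bounds[0][0]), bounds[0][1]))
    gamma_hat = float(math.exp(best.x[1]))

    at_boundary = (phi_hat in (bounds[0][0], bounds[0][1])
                   or best.x[1] in (bounds[1][0], bounds[1][1]))
    message = "boundary solution" if at_boundary else "ok"
    if at_boundary:
        logger.warning("fit reached a parameter boundary: phi=%.4g "
                       "gamma=%.4g", phi_hat, gamma_hat)
    return FitResult(phi=phi_hat, gamma=gamma_hat, loss=float(best.fun),
                     converged=converged and not at_boundary,
                     identifiable=not at_boundary, message=message,
                     grid_losses=grid_losses)
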