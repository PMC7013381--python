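"""Declarative in-silico experiment designs and parameter sweeps.

An :class:`ExperimentDesign` encodes a host background (initially
sensitive, CRISPR-knockout, or a pre-immunised BIM), a phage inoculum
(clonal or mixed), the model parameters, and a sampling schedule.  Sweeps
vary either the lysis probability ``phi`` or the immunosuppression
duration ``1/gamma`` point-by-point, holding everything else fixed, and
collect the final Acr-positive : Acr-negative phage ratio plus summaries
of the immunosuppressed compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import (
    COMPARTMENTS,
    DEFAULT_EXTINCTION_THRESHOLD,
    ModelError,
    ModelParameters,
    PhageRatio,
    PopulationState,
    Trajectory,
    final_phage_ratio,
    simulate,
)

HOST_TYPES = ("sensitive", "crispr_ko", "bim")

#: Resistance presets for bacteriophage-insensitive mutants: resistance
#: (the probability the phage genome is cleaved before acr expression)
#: increases with the number of targeting spacers.  Package conventions;
#: only the one-spacer value is a reference parameterisation.
BIM_RHO_PRESETS = {"bim1": 0.5, "bim2": 0.9}

DEFAULT_HOST_DENSITY = 1e3
DEFAULT_T_END = 30.0
DEFAULT_N_SAMPLES = 301


@dataclass(frozen=True)
class ExperimentDesign:
    """One infection experiment: host background, inoculum, parameters,
    schedule.

    ``host_type`` is ``sensitive`` (wild-type, all cells in W),
    ``crispr_ko`` (spacer acquisition disabled, A forced to 0) or ``bim``
    (pre-immunised: all cells start resistant, with ``rho`` taken from
    ``bim_preset`` unless the supplied parameters already override it).
    """

    host_type: str = "sensitive"
    v1_0: float = 0.0
    v2_0: float = 0.0
    params: ModelParameters = field(default_factory=ModelParameters)
    host_density: float = DEFAULT_HOST_DENSITY
    t_end: float = DEFAULT_T_END
    n_samples: int = DEFAULT_N_SAMPLES
    transfers: tuple = ()
    bim_preset: str = "bim1"
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD
    no_phage_control: bool = False

    def __post_init__(self):
        if self.host_type not in HOST_TYPES:
            raise ModelError(
                f"host_type must be one of {HOST_TYPES}, got {self.host_type!r}")
        if self.v1_0 < 0 or self.v2_0 < 0:
            raise ModelError("phage inocula must be >= 0")
        if self.host_density <= 0:
            raise ModelError("host_density must be > 0")
        if self.v1_0 == 0 and self.v2_0 == 0 and not self.no_phage_control:
            raise ModelError(
                "no phage inoculum: set no_phage_control=True for an "
                "uninfected control")
        if self.host_type == "bim" and self.bim_preset not in BIM_RHO_PRESETS:
            raise ModelError(
                f"unknown BIM preset {self.bim_preset!r}; "
                f"choose from {sorted(BIM_RHO_PRESETS)}")

    @property
    def effective_params(self) -> ModelParameters:
        if self.host_type == "crispr_ko":
            return self.params.replace(A=0.0)
        if self.host_type == "bim":
            return self.params.replace(rho=BIM_RHO_PRESETS[self.bim_preset])
        return self.params

    @property
    def initial_state(self) -> PopulationState:
        if self.host_type == "bim":
            return PopulationState(t=0.0, W=0.0, R=self.host_density, S=0.0,
                                   V1=self.v1_0, V2=self.v2_0)
        return PopulationState(t=0.0, W=self.host_density, R=0.0, S=0.0,
                               V1=self.v1_0, V2=self.v2_0)

    def replace(self, **changes) -> "ExperimentDesign":
        return replace(self, **changes)


def run_design(design: ExperimentDesign, **simulate_kwargs) -> Trajectory:
    """Simulate one design.  Deterministic: identical designs give
    identical trajectories."""
    sample_times = np.linspace(0.0, design.t_end, design.n_samples)
    return simulate(design.initial_state, design.effective_params,
                    design.t_end, sample_times,
                    transfers=design.transfers or None,
                    extinction_threshold=design.extinction_threshold,
                    **simulate_kwargs)


@dataclass
class SweepResult:
    """Outcome of a 1-D parameter sweep.

    One entry per grid point: the final phage ratio (with extinction
    flags), per-compartment extinction flags at the final sample, the
    time-integral of the immunosuppressed density and its peak, and the
    exact parameters used.
    """

    parameter: str                      # "phi" or "gamma_inv"
    grid: np.ndarray
    ratios: list                        # list[PhageRatio]
    extinct: list                       # list[dict[str, bool]] at t_end
    integral_S: np.ndarray
    peak_S: np.ndarray
    params_per_point: list              # list[ModelParameters]

    def __post_init__(self):
        n = len(self.grid)
        if not (len(self.ratios) == len(self.extinct) == n
                == len(self.integral_S) == len(self.peak_S)
                == len(self.params_per_point)):
            raise ModelError("sweep result lengths are inconsistent")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "grid_value": np.asarray(self.grid, dtype=float),
            "ratio": [r.value for r in self.ratios],
            "log_ratio": [r.log_value for r in self.ratios],
            "v1_extinct": [e["V1"] for e in self.extinct],
            "v2_extinct": [e["V2"] for e in self.extinct],
            "integral_S": self.integral_S,
            "peak_S": self.peak_S,
        })

    @property
    def ordering_keys(self) -> np.ndarray:
        """Log-ratios with extinction sentinels mapped to +/- infinity."""
        return np.array([r.ordering_key for r in self.ratios])


def _summarise(traj: Trajectory) -> tuple:
    ratio = final_phage_ratio(traj)
    thr = traj.extinction_threshold
    extinct = {name: bool(traj.densities[-1, j] < thr)
               for j, name in enumerate(COMPARTMENTS)}
    s = traj.column("S")
    integral_s = float(np.trapezoid(s, traj.times))
    return ratio, extinct, integral_s, float(s.max())


def _sweep(base: ExperimentDesign, parameter: str, grid,
           params_for, **simulate_kwargs) -> SweepResult:
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ModelError("sweep grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ModelError("sweep grid must be strictly increasing")
    ratios, extinct, integrals, peaks, per_point = [], [], [], [], []
    for value in grid:
        p = params_for(value)
        traj = run_design(base.replace(params=p), **simulate_kwargs)
        ratio, ext, integral_s, peak_s = _summarise(traj)
        ratios.append(ratio)
        extinct.append(ext)
        integrals.append(integral_s)
        peaks.append(peak_s)
        per_point.append(traj.parameters)
    return SweepResult(parameter=parameter, grid=grid, ratios=ratios,
                       extinct=extinct, integral_S=np.array(integrals),
                       peak_S=np.array(peaks), params_per_point=per_point)


def sweep_phi(base: ExperimentDesign, phi_grid: Sequence[float],
              **simulate_kwargs) -> SweepResult:
    """Vary the lysis probability phi over an increasing grid in [0, 1]."""
    for v in phi_grid:
        if not 0.0 <= v <= 1.0:
            raise ModelError(f"phi grid value {v} outside [0, 1]")
    return _sweep(base, "phi", phi_grid,
                  lambda v: base.params.replace(phi=float(v)),
                  **simulate_kwargs)


def sweep_gamma_inv(base: ExperimentDesign, gamma_inv_grid: Sequence[float],
                    **simulate_kwargs) -> SweepResult:
    """Vary the immunosuppression duration 1/gamma over an increasing
    positive grid (gamma = 1/value at each point)."""
    for v in gamma_inv_grid:
        if v <= 0.0:
            raise ModelError(f"gamma_inv grid value {v} must be > 0")
    return _sweep(base, "gamma_inv", gamma_inv_grid,
                  lambda v: base.params.replace(gamma=1.0 / float(v)),
                  **simulate_kwargs)


def default_phi_grid() -> np.ndarray:
    return np.linspace(0.05, 0.95, 11)


def default_gamma_inv_grid() -> np.ndarray:
    return np.logspace(np.log10(0.1), np.log10(10.0), 11)


def mixed_infection_design(params: ModelParameters | None = None,
                           inoculum: float = 100.0,
                           **changes) -> ExperimentDesign:
    """The reference mixed-infection experiment: initially sensitive hosts
    infected with an equal mix of Acr-positive and Acr-negative phage."""
    return ExperimentDesign(host_type="sensitive", v1_0=inoculum,
                            v2_0=inoculum,
                            params=params or ModelParameters(),
                            **changes)
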