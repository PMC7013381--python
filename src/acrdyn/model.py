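"""Compartment model of anti-CRISPR phage / bacteria population dynamics.

The model tracks five densities: sensitive bacteria ``W``, CRISPR-resistant
bacteria ``R``, immunosuppressed bacteria ``S``, free Acr-positive phage
``V1`` and free Acr-negative phage ``V2``.  Bacteria grow logistically
(maximal rate ``r``, density dependence ``k``) and die at rate ``m``.  Free
phages adsorb to any cell at rate ``a``.  On a sensitive cell the phage
either lyses it (releasing ``B`` particles) or, with probability ``A``, the
cell acquires CRISPR resistance and the phage genome is destroyed.  On a
resistant cell an Acr-negative phage is always destroyed; an Acr-positive
phage is destroyed with probability ``rho``, completes lysis with
probability ``(1 - rho) * phi``, or — with probability
``(1 - rho) * (1 - phi)`` — fails but leaves enough anti-CRISPR protein to
push the cell into a transient immunosuppressed state that reverts at rate
``gamma``.  Immunosuppressed cells are open to productive infection by
either phage type.

With N = W + R + S and V = V1 + V2 the dynamics are

    dW/dt  = r W (1 - k N) - (a V1 + a V2 + m) W
    dR/dt  = A a V W + r R (1 - k N) - (a (1 - rho) V1 + m) R + gamma S
    dS/dt  = a (1 - rho) (1 - phi) V1 R - (a V + m + gamma) S
    dV1/dt = a (1 - rho) phi B V1 R + a B V1 (S + (1 - A) W) - a N V1
    dV2/dt = a B V2 (S + (1 - A) W) - a N V2
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

#: Compartment order used throughout the package.
COMPARTMENTS = ("W", "R", "S", "V1", "V2")

#: Densities below this are reported as extinct (roughly "less than one
#: particle per notional culture volume"); the ODE keeps integrating the
#: raw value regardless.
DEFAULT_EXTINCTION_THRESHOLD = 1e-3

# Post-step densities in (-CLIP_TOLERANCE, 0) are integrator round-off and
# are clipped to zero; anything at or below -CLIP_TOLERANCE is treated as
# integration failure.
CLIP_TOLERANCE = 1e-9


class ModelError(ValueError):
    """Invalid model inputs (parameters, states, schedules)."""


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state and time."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ModelError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParameters:
    """Rate and probability constants of the infection model.

    Defaults follow the package's reference parameterisation: the printed
    constants a=0.001, A=0.2, B=5, rho=0.5 with a moderately strong
    anti-CRISPR (phi=0.3, mean immunosuppression duration 1/gamma = 1),
    and host-growth constants r=1, k=1e-6, m=0.1 chosen to give logistic
    growth to a carrying density of ~9e5 in arbitrary model-time units.
    """

    a: float = 0.001      # adsorption rate (per phage per cell-density per time)
    A: float = 0.2        # P(sensitive cell acquires CRISPR resistance on infection)
    B: float = 5.0        # burst size
    rho: float = 0.5      # P(Acr-positive genome destroyed on R before acr expression)
    phi: float = 0.3      # P(lysis | Acr expression succeeds on R)
    gamma: float = 1.0    # reversion rate S -> R; 1/gamma = immunosuppression duration
    r: float = 1.0        # maximal bacterial growth rate
    k: float = 1e-6       # intensity of density dependence
    m: float = 0.1        # bacterial mortality rate

    def __post_init__(self):
        for name in ("A", "rho", "phi"):
            v = _check_finite(name, getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name} must lie in [0, 1], got {v}")
        for name in ("a", "B", "gamma", "r", "k", "m"):
            v = _check_finite(name, getattr(self, name))
            if v < 0.0:
                raise ModelError(f"{name} must be >= 0, got {v}")
        if self.gamma == 0.0 and self.phi < 1.0 and self.rho < 1.0:
            # Permitted, but immunosuppressed cells then never revert.
            logger.warning(
                "gamma = 0 with phi < 1 and rho < 1: immunosuppressed cells "
                "accumulate without reversion"
            )

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("a", "A", "B", "rho", "phi", "gamma", "r", "k", "m")}


@dataclass(frozen=True)
class PopulationState:
    """Densities of the five compartments at one instant.

    ``N`` (total bacteria) and ``V`` (total phage) are derived, never
    stored.
    """

    t: float = 0.0
    W: float = 0.0
    R: float = 0.0
    S: float = 0.0
    V1: float = 0.0
    V2: float = 0.0

    def __post_init__(self):
        _check_finite("t", self.t)
        for name in COMPARTMENTS:
            v = _check_finite(name, getattr(self, name))
            if v < 0.0:
                raise ModelError(f"{name} must be >= 0, got {v}")

    @property
    def N(self) -> float:
        return self.W + self.R + self.S

    @property
    def V(self) -> float:
        return self.V1 + self.V2

    def as_array(self) -> np.ndarray:
        return np.array([self.W, self.R, self.S, self.V1, self.V2], dtype=float)

    @classmethod
    def from_array(cls, t: float, y: Sequence[float]) -> "PopulationState":
        W, R, S, V1, V2 = (float(v) for v in y)
        return cls(t=t, W=W, R=R, S=S, V1=V1, V2=V2)


@dataclass(frozen=True)
class Event:
    """A marker on a trajectory: a serial transfer or a compartment
    falling below the extinction threshold."""

    time: float
    kind: str               # "transfer" or "extinction"
    detail: str = ""        # compartment name, or dilution factor

    def as_dict(self) -> dict:
        return {"time": self.time, "kind": self.kind, "detail": self.detail}


@dataclass
class Trajectory:
    """Sampled solution of the model: times, a (n, 5) density array in
    compartment order, event markers and the parameters used."""

    times: np.ndarray
    densities: np.ndarray           # shape (len(times), 5)
    parameters: ModelParameters
    events: list = field(default_factory=list)
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (self.times.size, 5):
            raise ModelError(
                f"densities shape {self.densities.shape} does not match "
                f"{self.times.size} sample times"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ModelError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def state(self, i: int) -> PopulationState:
        return PopulationState.from_array(self.times[i], self.densities[i])

    @property
    def states(self) -> list:
        return [self.state(i) for i in range(len(self))]

    @property
    def final_state(self) -> PopulationState:
        return self.state(-1)

    def column(self, name: str) -> np.ndarray:
        if name == "N":
            return self.densities[:, :3].sum(axis=1)
        if name == "V":
            return self.densities[:, 3:].sum(axis=1)
        return self.densities[:, COMPARTMENTS.index(name)]

    def to_frame(self):
        import pandas as pd

        data = {"t": self.times}
        for i, name in enumerate(COMPARTMENTS):
            data[name] = self.densities[:, i]
        data["N"] = self.column("N")
        data["V"] = self.column("V")
        return pd.DataFrame(data)


def rhs(state: PopulationState, params: ModelParameters):
    """Time derivatives (dW, dR, dS, dV1, dV2) at one state.

    Pure function; rejects non-finite inputs naming the offending field.
    """
    if not isinstance(state, PopulationState):
        state = PopulationState(*state)  # pragma: no cover - convenience
    return tuple(_rhs(state.as_array(), params))


def _rhs(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Vectorised right-hand side on a raw (5,) array; no validation."""
    W, R, S, V1, V2 = y
    N = W + R + S
    V = V1 + V2
    aV1 = p.a * V1
    dW = p.r * W * (1.0 - p.k * N) - (aV1 + p.a * V2 + p.m) * W
    dR = (p.A * p.a * V * W + p.r * R * (1.0 - p.k * N)
          - (p.a * (1.0 - p.rho) * V1 + p.m) * R + p.gamma * S)
    dS = (p.a * (1.0 - p.rho) * (1.0 - p.phi) * V1 * R
          - (p.a * V + p.m + p.gamma) * S)
    dV1 = (p.a * (1.0 - p.rho) * p.phi * p.B * V1 * R
           + p.a * p.B * V1 * (S + (1.0 - p.A) * W) - p.a * N * V1)
    dV2 = p.a * p.B * V2 * (S + (1.0 - p.A) * W) - p.a * N * V2
    return np.array([dW, dR, dS, dV1, dV2])


def _jac(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the right-hand side; speeds up the stiff
    integrator, which would otherwise difference the RHS."""
    W, R, S, V1, V2 = y
    N = W + R + S
    V = V1 + V2
    a, A, B, rho, phi = p.a, p.A, p.B, p.rho, p.phi
    gamma, r, k, m = p.gamma, p.r, p.k, p.m
    return np.array([
        [r * (1 - k * N) - r * W * k - (a * V + m),
         -r * W * k, -r * W * k, -a * W, -a * W],
        [A * a * V - r * R * k,
         r * (1 - k * N) - r * R * k - (a * (1 - rho) * V1 + m),
         -r * R * k + gamma,
         A * a * W - a * (1 - rho) * R,
         A * a * W],
        [0.0,
         a * (1 - rho) * (1 - phi) * V1,
         -(a * V + m + gamma),
         a * (1 - rho) * (1 - phi) * R - a * S,
         -a * S],
        [a * B * (1 - A) * V1 - a * V1,
         a * (1 - rho) * phi * B * V1 - a * V1,
         a * B * V1 - a * V1,
         a * (1 - rho) * phi * B * R + a * B * (S + (1 - A) * W) - a * N,
         0.0],
        [a * B * (1 - A) * V2 - a * V2,
         -a * V2,
         a * B * V2 - a * V2,
         0.0,
         a * B * (S + (1 - A) * W) - a * N],
    ])


def _validate_transfers(transfers, t_end: float):
    """Transfers are (time, dilution) pairs, strictly increasing times,
    dilution factors in (0, 1]."""
    if transfers is None:
        return []
    out = []
    last = 0.0
    for time, dilution in transfers:
        time = float(time)
        dilution = float(dilution)
        if not 0.0 < time < t_end:
            raise ModelError(f"transfer time {time} outside (0, t_end)")
        if time <= last and out:
            raise ModelError("transfer times must be strictly increasing")
        if not 0.0 < dilution <= 1.0:
            raise ModelError(f"dilution factor {dilution} outside (0, 1]")
        out.append((time, dilution))
        last = time
    return out


def _clip_roundoff(t: float, y: np.ndarray,
                   band: float = CLIP_TOLERANCE) -> np.ndarray:
    """Clip small negative round-off to zero; abort on genuine blow-up.

    The round-off band scales with the integrator's absolute tolerance
    (it equals CLIP_TOLERANCE at the default atol).
    """
    if np.any(y <= -band):
        raise IntegrationError(
            f"density fell below -{band:g} at t={t:.6g} "
            f"(values {y.tolist()})", t, y)
    return np.clip(y, 0.0, None)


def simulate(initial: PopulationState,
             params: ModelParameters,
             t_end: float,
             sample_times: Iterable[float] | None = None,
             transfers: Sequence[tuple] | None = None,
             *,
             rtol: float = 1e-8,
             atol: float = 1e-10,
             extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model forward to ``t_end``.

    ``sample_times`` defaults to 301 evenly spaced points.  ``transfers``
    is an optional schedule of (time, dilution) pairs; at each transfer
    every compartment is multiplied by the dilution factor (a serial
    passage into fresh medium) and a ``transfer`` event is recorded.
    Extinction events mark the first sample at which a previously live
    compartment falls below ``extinction_threshold``; they are reporting
    markers only and do not alter the dynamics.
    """
    t_end = float(t_end)
    if not t_end > 0.0:
        raise ModelError(f"t_end must be > 0, got {t_end}")
    if sample_times is None:
        sample_times = np.linspace(0.0, t_end, 301)
    sample_times = np.asarray(list(sample_times), dtype=float)
    if sample_times.size == 0:
        raise ModelError("sample_times must be nonempty")
    if np.any(np.diff(sample_times) <= 0):
        raise ModelError("sample_times must be strictly increasing")
    if sample_times[0] < 0.0 or sample_times[-1] > t_end:
        raise ModelError("sample_times must lie within [0, t_end]")
    schedule = _validate_transfers(transfers, t_end)
    clip_band = max(CLIP_TOLERANCE, 10.0 * atol)

    events: list[Event] = []
    y = initial.as_array()
    out_times = [0.0] if sample_times[0] == 0.0 else []
    out_states = [y.copy()] if out_times else []
    pending = sample_times[sample_times > 0.0]

    seg_start = 0.0
    boundaries = [t for t, _ in schedule] + [t_end]
    dilutions = [d for _, d in schedule] + [None]
    for seg_end, dilution in zip(boundaries, dilutions):
        take = pending[(pending > seg_start) & (pending <= seg_end)]
        if y.max() == 0.0:
            # Empty system: exactly stationary; skip the integrator.
            for t in take:
                out_times.append(t)
                out_states.append(y.copy())
        else:
            sol = solve_ivp(lambda t, yy: _rhs(yy, params),
                            (seg_start, seg_end), y,
                            method=method, rtol=rtol, atol=atol,
                            jac=lambda t, yy: _jac(yy, params),
                            dense_output=True)
            if not sol.success:
                raise IntegrationError(
                    f"integration failed in [{seg_start:g}, {seg_end:g}]: "
                    f"{sol.message}", sol.t[-1], sol.y[:, -1])
            for t in take:
                yt = _clip_roundoff(t, sol.sol(t), clip_band)
                out_times.append(t)
                out_states.append(yt)
            y = _clip_roundoff(seg_end, sol.sol(seg_end), clip_band)
        if dilution is not None:
            y = y * dilution
            events.append(Event(time=seg_end, kind="transfer",
                                detail=f"dilution={dilution:g}"))
        seg_start = seg_end

    times = np.array(out_times)
    densities = np.vstack(out_states)

    # First crossing below the extinction threshold, per compartment that
    # was ever alive.
    for j, name in enumerate(COMPARTMENTS):
        col = densities[:, j]
        alive = col >= extinction_threshold
        if not alive.any():
            continue
        first_alive = int(np.argmax(alive))
        dead_after = np.nonzero(~alive[first_alive:])[0]
        if dead_after.size:
            i = first_alive + int(dead_after[0])
            events.append(Event(time=float(times[i]), kind="extinction",
                                detail=name))
    events.sort(key=lambda e: e.time)

    return Trajectory(times=times, densities=densities, parameters=params,
                      events=events, extinction_threshold=extinction_threshold)


@dataclass(frozen=True)
class PhageRatio:
    """V1/V2 at the final sample, with extinction flags.

    ``status`` is one of ``ok``, ``v1_extinct``, ``v2_extinct`` (infinite
    advantage of the Acr-positive phage) or ``both_extinct`` (undefined
    ratio).  ``ordering_key`` maps the flags onto the extended real line
    so sweeps can be ordered: +inf when only V2 is extinct, -inf when only
    V1 is, log(ratio) otherwise, NaN when both are extinct.
    """

    value: float
    log_value: float
    status: str
    v1_final: float
    v2_final: float

    @property
    def ordering_key(self) -> float:
        if self.status == "v2_extinct":
            return math.inf
        if self.status == "v1_extinct":
            return -math.inf
        if self.status == "both_extinct":
            return math.nan
        return self.log_value


def final_phage_ratio(traj: Trajectory,
                      threshold: float | None = None) -> PhageRatio:
    """Ratio of Acr-positive to Acr-negative phage at the last sample."""
    if len(traj) == 0:
        raise ModelError("trajectory is empty")
    if threshold is None:
        threshold = traj.extinction_threshold
    v1 = float(traj.densities[-1, 3])
    v2 = float(traj.densities[-1, 4])
    v1_dead = v1 < threshold
    v2_dead = v2 < threshold
    if v1_dead and v2_dead:
        return PhageRatio(math.nan, math.nan, "both_extinct", v1, v2)
    if v2_dead:
        return PhageRatio(math.inf, math.inf, "v2_extinct", v1, v2)
    ratio = v1 / v2
    status = "v1_extinct" if v1_dead else "ok"
    log_value = math.log(ratio) if ratio > 0.0 else -math.inf
    return PhageRatio(ratio, log_value, status, v1, v2)
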