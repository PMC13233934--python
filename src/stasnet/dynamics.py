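"""Firing-rate dynamics: sigmoidal units driven by recurrence and noise.

Each neuron is a rate unit

    tau_M dr/dt = -r + Phi(I(t)),      Phi(I) = 1 / (1 + exp(beta (I0 - I)))

with total input I_post = sum_pre w_post,pre r_pre - I_ext, where I_ext is an
approximation of Gaussian white noise drawn independently per neuron and per
time step.  Integration is forward Euler at dt = 1 ms; with dt <= tau_M every
Euler step is a convex combination of r and Phi(I), so rates stay in [0, 1].
A warm-up period is simulated and discarded before recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numpy.typing import ArrayLike, NDArray

from .connectivity import Connectome

__all__ = [
    "NeuronParams",
    "NoiseParams",
    "SimConfig",
    "RateTrace",
    "transfer_function",
    "total_input",
    "simulate",
]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane time constant (ms), sigmoid steepness, half-activation input."""

    tau_m: float = 12.0
    beta: float = 0.25
    i0: float = 50.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """External Gaussian drive: mean, standard deviation, seed, correlation.

    The drive is sampled independently for every neuron.  ``mode`` selects
    its temporal structure:

    - ``"ou"`` (default): an AR(1)/Ornstein-Uhlenbeck process with
      stationary standard deviation ``sigma_ext`` and correlation time
      ``tau_noise`` (ms) — a band-limited approximation of Gaussian white
      noise.  Excursions persist long enough (relative to the membrane time
      constant) to nucleate collective activity.
    - ``"white"``: one i.i.d. draw per neuron per step;
      ``scale_sqrt_dt`` switches to diffusion-style sqrt(dt) scaling.
    - ``"quenched"``: one frozen draw per neuron per run.
    """

    mu_ext: float = 0.0
    sigma_ext: float = 30.0
    seed: int = 0
    mode: str = "ou"
    tau_noise: float = 10.0
    scale_sqrt_dt: bool = False

    def __post_init__(self) -> None:
        if self.sigma_ext < 0:
            raise ValueError("sigma_ext must be >= 0")
        if self.mode not in ("ou", "white", "quenched"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.mode == "ou" and self.tau_noise <= 0:
            raise ValueError("tau_noise must be positive for OU noise")

    def with_seed(self, seed: int) -> "NoiseParams":
        from dataclasses import replace

        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimConfig:
    """Simulated duration, warm-up, step (ms) and number of noise seeds."""

    t_sim: float = 4000.0
    t_warmup: float = 400.0
    dt: float = 1.0
    n_seeds: int = 8

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("t_sim", "t_warmup"):
            t = getattr(self, name)
            if abs(round(t / self.dt) - t / self.dt) > 1e-9:
                raise ValueError(f"{name}={t} is not a multiple of dt={self.dt}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_sim / self.dt))

    @property
    def n_warmup(self) -> int:
        return int(round(self.t_warmup / self.dt))


@dataclass(frozen=True)
class RateTrace:
    """Recorded rates, shape ``(n_steps, n_neurons)``, warm-up excluded.

    ``times`` are in ms measured from the end of warm-up.  ``mean_recurrent``
    is the time-and-population mean of the recurrent input term (diagnostic
    for the inhibition-dominated regime).
    """

    rates: NDArray[np.float32] = field(repr=False)
    config: SimConfig = None  # type: ignore[assignment]
    noise_seed: int = 0
    mean_recurrent: float = float("nan")

    @property
    def times(self) -> NDArray[np.float64]:
        return np.arange(self.rates.shape[0]) * self.config.dt


def transfer_function(i: ArrayLike, params: NeuronParams = NeuronParams()) -> NDArray:
    """Sigmoid rate Phi(I), strictly increasing, saturating in (0, 1).

    Phi(I0) = 0.5 exactly; the exponent is clipped to keep the evaluation
    finite at extreme inputs.
    """
    x = params.beta * (params.i0 - np.asarray(i, dtype=float))
    out = 1.0 / (1.0 + np.exp(np.clip(x, -500.0, 500.0)))
    return out


def total_input(
    rates: NDArray, connectome: Connectome, ext: NDArray | float = 0.0
) -> NDArray:
    """Total input per neuron: recurrent weighted sum minus the external term."""
    rates = np.asarray(rates)
    if rates.shape[-1] != connectome.n_total:
        raise ValueError(
            f"rate vector length {rates.shape[-1]} does not match "
            f"connectome size {connectome.n_total}"
        )
    return connectome.weights @ rates - ext


def simulate(
    connectome: Connectome,
    neuron_params: NeuronParams = NeuronParams(),
    noise_params: NoiseParams = NoiseParams(),
    sim_config: SimConfig = SimConfig(),
    record: str = "all",
    r0: NDArray | None = None,
) -> RateTrace:
    """Integrate the network with forward Euler and record post-warm-up rates.

    ``record`` selects which population's rates are stored ("all" or "exc");
    the state always covers the whole network.  The trace is deterministic
    for a fixed noise seed.  ``r0`` sets the initial rate state (default
    zeros) — useful for seeding activity bumps in controlled experiments;
    with a nonzero ``r0`` one usually runs without a warm-up.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite (reported with the step index).
    """
    rng = np.random.default_rng(noise_params.seed)
    n = connectome.n_total
    n_rec = connectome.n_exc if record == "exc" else n
    W = sp.csr_matrix(connectome.weights)
    dt, tau = sim_config.dt, neuron_params.tau_m
    alpha = dt / tau
    sigma = noise_params.sigma_ext

    if noise_params.mode == "quenched":
        frozen = noise_params.mu_ext + sigma * rng.standard_normal(n)
    elif noise_params.mode == "ou":
        a = np.exp(-dt / noise_params.tau_noise)
        b = sigma * np.sqrt(1.0 - a * a)
        ou_state = sigma * rng.standard_normal(n)  # stationary init
    else:  # white
        white_scale = sigma * (np.sqrt(dt) if noise_params.scale_sqrt_dt else 1.0)

    if r0 is None:
        r = np.zeros(n)
    else:
        r = np.asarray(r0, dtype=float).copy()
        if r.shape != (n,) or r.min() < 0 or r.max() > 1:
            raise ValueError("r0 must be an (n_total,) array of rates in [0, 1]")
    n_total_steps = sim_config.n_warmup + sim_config.n_steps
    out = np.empty((sim_config.n_steps, n_rec), dtype=np.float32)
    recurrent_sum = 0.0
    for step in range(n_total_steps):
        if noise_params.mode == "quenched":
            i_ext = frozen
        elif noise_params.mode == "ou":
            ou_state = a * ou_state + b * rng.standard_normal(n)
            i_ext = noise_params.mu_ext + ou_state
        else:
            i_ext = noise_params.mu_ext + white_scale * rng.standard_normal(n)
        recurrent = W @ r
        i_total = recurrent - i_ext
        r = r + alpha * (-r + transfer_function(i_total, neuron_params))
        if not np.all(np.isfinite(r)):
            raise FloatingPointError(f"non-finite rate state at step {step}")
        if step >= sim_config.n_warmup:
            out[step - sim_config.n_warmup] = r[:n_rec]
            recurrent_sum += recurrent.mean()
    mean_recurrent = recurrent_sum / max(sim_config.n_steps, 1)
    return RateTrace(
        rates=out,
        config=sim_config,
        noise_seed=noise_params.seed,
        mean_recurrent=float(mean_recurrent),
    )
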