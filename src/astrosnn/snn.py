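"""Unsupervised single-layer spiking network: LIF dynamics, homeostasis,
trace-based STDP, soft winner-take-all lateral inhibition, Poisson encoding.

The architecture is the classic cortical-microcircuit layout for unsupervised
digit recognition: an input layer (one Poisson neuron per pixel) fully
connected through plastic excitatory synapses to a layer of leaky
integrate-and-fire neurons with adaptive thresholds, which inhibit each other
through static recurrent synapses.

Update ordering within a 1 ms step (fixed, and relied upon by the oracle
tests): integrate membranes -> detect spikes -> queue lateral inhibition for
the next step -> advance spike traces (a spike sets the owner's trace to 1
after decay) -> apply the plasticity rule using the current-step traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LifParams",
    "LifState",
    "WeightMatrix",
    "StdpTraces",
    "NetworkConfig",
    "lif_step",
    "threshold_step",
    "trace_step",
    "stdp_update",
    "normalize_weights",
    "poisson_encode",
    "run_batch",
]


@dataclass
class LifParams:
    """Leaky integrate-and-fire and adaptive-threshold parameters (ms / mV)."""

    tau_mem: float = 100.0      # membrane time constant
    v_rest: float = -65.0       # resting potential
    v_reset: float = -60.0      # reset potential
    theta0: float = -52.0       # base threshold
    theta_plus: float = 0.05    # per-spike threshold increment
    tau_theta: float = 1e7      # adaptive-threshold time constant
    delta_ref: float = 5.0      # refractory period
    dt: float = 1.0             # integration step

    def __post_init__(self) -> None:
        if not (self.theta0 > self.v_rest and self.theta0 > self.v_reset):
            raise ValueError("theta0 must exceed v_rest and v_reset")
        for name in ("tau_mem", "tau_theta", "delta_ref", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class LifState:
    """Membrane state of the output layer.

    ``v``, ``refrac_remaining`` and ``spiked`` are private per batch replica
    (shape ``(batch, n_neurons)``); ``theta`` is the shared homeostasis memory
    of the network (shape ``(n_neurons,)``) and persists across images.
    """

    v: np.ndarray
    theta: np.ndarray
    refrac_remaining: np.ndarray
    spiked: np.ndarray

    @classmethod
    def resting(cls, batch: int, n_neurons: int, params: LifParams,
                theta: np.ndarray | None = None) -> "LifState":
        th = np.zeros(n_neurons) if theta is None else np.asarray(theta, dtype=float).copy()
        return cls(
            v=np.full((batch, n_neurons), params.v_rest, dtype=float),
            theta=th,
            refrac_remaining=np.zeros((batch, n_neurons)),
            spiked=np.zeros((batch, n_neurons), dtype=bool),
        )

    def reset_membranes(self, params: LifParams) -> None:
        """Reset per-replica state between images; theta persists."""
        self.v[...] = params.v_rest
        self.refrac_remaining[...] = 0.0
        self.spiked[...] = False


@dataclass
class WeightMatrix:
    """Bounded input->output weights with a persistent fault mask.

    ``fault_mask`` is True for live synapses.  Dead synapses carry weight 0 and
    are never updated.  ``w_recurrent`` is the static (negative) lateral
    inhibition weight among output neurons.
    """

    w: np.ndarray                       # (n_input, n_neurons)
    w_max: float = 1.0
    w_norm: float = 78.4
    w_recurrent: float = -120.0
    fault_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.fault_mask is None:
            self.fault_mask = np.ones(self.w.shape, dtype=bool)
        self.fault_mask = np.asarray(self.fault_mask, dtype=bool)
        if self.fault_mask.shape != self.w.shape:
            raise ValueError("fault_mask shape must match w")
        if self.w_recurrent > 0:
            raise ValueError("w_recurrent must be <= 0 (inhibitory)")

    @property
    def n_input(self) -> int:
        return self.w.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.w.shape[1]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.w.copy(), self.w_max, self.w_norm,
                            self.w_recurrent, self.fault_mask.copy())

    @classmethod
    def random(cls, n_input: int, n_neurons: int, rng: np.random.Generator,
               w_max: float = 1.0, w_norm: float = 78.4,
               w_recurrent: float = -120.0) -> "WeightMatrix":
        w = rng.uniform(0.0, w_max, size=(n_input, n_neurons))
        return cls(w, w_max, w_norm, w_recurrent)


@dataclass
class StdpTraces:
    """Pre/post spike traces and the STDP learning rates.

    A trace is set to exactly 1 when its owner spikes and decays exponentially
    with ``tau_trace`` otherwise, so every trace lives in [0, 1].
    """

    x_pre: np.ndarray   # (batch, n_input)
    x_post: np.ndarray  # (batch, n_neurons)
    tau_trace: float = 20.0
    eta_pre: float = 1e-4
    eta_post: float = 1e-2

    @classmethod
    def zeros(cls, batch: int, n_input: int, n_neurons: int,
              tau_trace: float = 20.0, eta_pre: float = 1e-4,
              eta_post: float = 1e-2) -> "StdpTraces":
        return cls(np.zeros((batch, n_input)), np.zeros((batch, n_neurons)),
                   tau_trace, eta_pre, eta_post)

    def reset(self) -> None:
        self.x_pre[...] = 0.0
        self.x_post[...] = 0.0


@dataclass
class NetworkConfig:
    """Input encoding and simulation layout."""

    n_input: int
    n_neurons: int
    exposure_ms: float = 350.0
    max_rate_hz: float = 63.75
    batch_size: int = 16
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_input", "n_neurons", "exposure_ms", "max_rate_hz",
                     "batch_size", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.exposure_ms / self.dt))


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def lif_step(state: LifState, input_current: np.ndarray, params: LifParams) -> LifState:
    """One Euler step of the membrane equation, in place.

    ``input_current`` is the per-step synaptic drive (weighted input-spike sum
    plus negative lateral-inhibition current), added directly to the membrane
    potential.  Refractory neurons are held at ``v_reset`` and ignore inputs.
    """
    drive = np.asarray(input_current, dtype=float)
    if not np.all(np.isfinite(drive)):
        bad = np.argwhere(~np.isfinite(drive))[0]
        raise FloatingPointError(f"non-finite input drive at neuron index {tuple(bad)}")
    refractory = state.refrac_remaining > 0
    dv = (params.dt / params.tau_mem) * (params.v_rest - state.v) + drive
    state.v = np.where(refractory, params.v_reset, state.v + dv)
    state.refrac_remaining = np.maximum(state.refrac_remaining - params.dt * refractory, 0.0)
    v_th = params.theta0 + state.theta
    state.spiked = ~refractory & (state.v >= v_th)
    state.v = np.where(state.spiked, params.v_reset, state.v)
    state.refrac_remaining = np.where(state.spiked, params.delta_ref,
                                      state.refrac_remaining)
    return state


def threshold_step(state: LifState, params: LifParams, frozen: bool = False) -> LifState:
    """Advance the adaptive threshold: exponential decay, then +theta_plus per
    spike (summed over batch replicas, since theta is shared network state).

    With ``frozen=True`` (evaluation) theta is left untouched.
    """
    if frozen:
        return state
    state.theta = state.theta * np.exp(-params.dt / params.tau_theta)
    state.theta = state.theta + params.theta_plus * state.spiked.sum(axis=0)
    return state


def trace_step(traces: StdpTraces, pre_spiked: np.ndarray, post_spiked: np.ndarray,
               dt: float = 1.0) -> StdpTraces:
    """Decay all traces, then set spiking entities' traces to exactly 1."""
    decay = np.exp(-dt / traces.tau_trace)
    traces.x_pre = traces.x_pre * decay
    traces.x_post = traces.x_post * decay
    traces.x_pre = np.where(pre_spiked, 1.0, traces.x_pre)
    traces.x_post = np.where(post_spiked, 1.0, traces.x_post)
    return traces


def stdp_update(w: WeightMatrix, traces: StdpTraces, pre_spiked: np.ndarray,
                post_spiked: np.ndarray,
                astdp: tuple[float, float] | None = None) -> WeightMatrix:
    """Apply one step of the pair-based trace STDP rule, in place.

    On each post-synaptic spike the incoming synapses potentiate by
    ``eta_post * x_pre``; on each pre-synaptic spike the outgoing synapses
    depress by ``eta_pre * x_post``.  Batch replicas' contributions are summed.
    ``astdp`` optionally carries ``(w_alpha, sigma)``: the potentiation branch
    is then scaled per synapse by ``(w / w_alpha)**sigma`` evaluated at the
    *current* weight (the astrocyte-augmented rule); the depression branch is
    never scaled.  Weights are clipped to ``[0, w_max]`` and dead synapses
    stay exactly 0.
    """
    pre_f = np.asarray(pre_spiked, dtype=float)
    post_f = np.asarray(post_spiked, dtype=float)
    if pre_f.ndim == 1:
        pre_f = pre_f[None, :]
        post_f = post_f[None, :]
        x_pre = np.atleast_2d(traces.x_pre)
        x_post = np.atleast_2d(traces.x_post)
    else:
        x_pre, x_post = traces.x_pre, traces.x_post
    dw = np.zeros_like(w.w)
    if post_f.any():
        pot = traces.eta_post * (x_pre.T @ post_f)
        if astdp is not None:
            w_alpha, sigma = astdp
            if w_alpha <= 0:
                raise RuntimeError("w_alpha floor guard violated (w_alpha <= 0)")
            pot = pot * (w.w / w_alpha) ** sigma
        dw += pot
    if pre_f.any():
        dw -= traces.eta_pre * (pre_f.T @ x_post)
    w.w = np.clip(w.w + dw, 0.0, w.w_max)
    w.w *= w.fault_mask
    return w


def normalize_weights(w: WeightMatrix) -> WeightMatrix:
    """Rescale each output neuron's live incoming weights so they sum to
    ``w_norm``, in place.

    The rescaling is multiplicative, so whenever no weight would exceed
    ``w_max`` the column sums equal ``w_norm`` exactly.  Weights are bounded
    physical quantities, so values pushed past ``w_max`` are clipped there;
    after heavy fault injection (few live synapses per neuron) the bound wins
    and the achieved sum falls short of ``w_norm`` — this clipping loss is
    precisely what re-training recovers.  Neurons whose live incoming weights
    are all zero are skipped with a warning.
    """
    sums = w.w.sum(axis=0)
    dead_cols = sums <= 0.0
    if dead_cols.any():
        logger.warning("normalize_weights: skipping %d all-zero neuron(s)",
                       int(dead_cols.sum()))
    scale = np.where(dead_cols, 1.0, w.w_norm / np.where(dead_cols, 1.0, sums))
    w.w *= scale[None, :]
    np.clip(w.w, 0.0, w.w_max, out=w.w)
    w.w *= w.fault_mask
    return w


def poisson_encode(image: np.ndarray, config: NetworkConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Encode an intensity image as a Bernoulli spike raster.

    Each pixel fires independently per step with probability
    ``max_rate_hz * intensity / 255 * dt``, i.e. the firing rate is
    proportional to pixel intensity.  Returns a boolean ``(n_steps, n_input)``
    raster.
    """
    flat = np.asarray(image, dtype=float).reshape(-1)
    if flat.size != config.n_input:
        raise ValueError(f"image has {flat.size} pixels, expected {config.n_input}")
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("pixel intensities must lie in [0, 255]")
    p = (config.max_rate_hz * flat / 255.0) * (config.dt / 1000.0)
    return rng.random((config.n_steps, config.n_input)) < p


# ---------------------------------------------------------------------------
# Batched simulation
# ---------------------------------------------------------------------------

def _present(rasters: np.ndarray, w: WeightMatrix, state: LifState,
             traces: StdpTraces, params: LifParams, learning: bool,
             astdp: tuple[float, float] | None) -> np.ndarray:
    """Present one image per replica simultaneously; returns spike counts."""
    B, T, _ = rasters.shape
    n_out = w.n_neurons
    counts = np.zeros((B, n_out))
    inhib = np.zeros((B, n_out))
    w_mat = w.w
    for t in range(T):
        pre = rasters[:, t, :]
        pre_f = pre.astype(float)
        drive = pre_f @ w_mat + inhib
        lif_step(state, drive, params)
        threshold_step(state, params, frozen=not learning)
        spk = state.spiked
        counts += spk
        tot = spk.sum(axis=1, keepdims=True)
        inhib = w.w_recurrent * (tot - spk)
        trace_step(traces, pre, spk, params.dt)
        if learning:
            stdp_update(w, traces, pre_f, spk.astype(float), astdp)
            w_mat = w.w
    return counts


def run_batch(rasters: np.ndarray, w: WeightMatrix, state: LifState,
              traces: StdpTraces, params: LifParams, *, learning: bool = False,
              astdp: tuple[float, float] | None = None,
              backend: str = "auto") -> np.ndarray:
    """Simulate one mini-batch of encoded images.

    ``rasters`` has shape ``(batch, n_steps, n_input)``; replicas share the
    weights (per-step weight deltas are summed across the batch) and theta,
    but keep private membrane and trace state, which is reset to rest before
    the presentation.  Returns per-replica output spike counts
    ``(batch, n_neurons)``.  With ``learning=False`` weights and theta are
    untouched (evaluation freezes homeostasis).

    ``backend``: ``"numba"`` (jitted event-driven loop), ``"numpy"`` (the
    composition of the public per-step operations) or ``"auto"``.
    """
    from . import _kernels

    if rasters.ndim != 3:
        raise ValueError("rasters must be (batch, n_steps, n_input)")
    if rasters.shape[2] != w.n_input:
        raise ValueError(
            f"raster input dimension {rasters.shape[2]} != weights {w.n_input}")
    if rasters.shape[0] != state.v.shape[0]:
        raise ValueError("batch size mismatch between rasters and state")
    if backend == "auto":
        backend = "numba" if _kernels.HAVE_NUMBA else "numpy"
    if backend not in ("numba", "numpy"):
        raise ValueError(f"unknown backend {backend!r}")
    state.reset_membranes(params)
    traces.reset()
    if backend == "numpy":
        return _present(rasters, w, state, traces, params, learning, astdp)
    use_astdp = astdp is not None
    w_alpha, sigma = astdp if use_astdp else (1.0, 0.0)
    if use_astdp and w_alpha <= 0:
        raise RuntimeError("w_alpha floor guard violated (w_alpha <= 0)")
    counts = np.zeros((rasters.shape[0], w.n_neurons))
    raster_b = np.ascontiguousarray(rasters, dtype=bool)
    _kernels.present_kernel(
        raster_b, w.w, w.fault_mask, state.theta, state.v,
        state.refrac_remaining, traces.x_pre, traces.x_post, counts,
        params.dt, params.tau_mem, params.v_rest, params.v_reset,
        params.theta0, params.theta_plus, params.tau_theta, params.delta_ref,
        w.w_max, w.w_recurrent, traces.tau_trace, traces.eta_pre,
        traces.eta_post, learning, use_astdp, float(w_alpha), float(sigma))
    state.spiked = np.zeros_like(counts, dtype=bool)  # per-step detail not retained
    return counts
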