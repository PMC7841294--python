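"""Fault injection and the astrocyte-augmented STDP (A-STDP) repair rule.

Faults model synapses stuck at zero: each input->output synapse of a trained
weight matrix is independently deleted with probability ``p_del``.  Repair
re-trains the faulty network with a plasticity rule whose potentiation branch
is scaled per synapse by ``(w / w_alpha)**sigma``, where ``w_alpha`` is the
weight value at the alpha-th percentile of the network's pooled weight
distribution.  ``w_alpha`` collapses when faults are injected and creeps back
toward ``w_max`` as the surviving strong synapses relearn, so it acts as a
class-independent surrogate signal for repair progress: healthy synapses
(``w > w_alpha``) relearn aggressively, weak ones barely move, and the
enhancement switches itself off as ``w_alpha`` saturates.  The depression
branch is the plain STDP one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snn import (LifParams, LifState, NetworkConfig, StdpTraces, WeightMatrix,
                  normalize_weights, run_batch, stdp_update)

__all__ = [
    "FaultSpec",
    "AstdpParams",
    "RepairTrace",
    "inject_faults",
    "compute_w_alpha",
    "astdp_update",
    "repair_run",
]


@dataclass
class FaultSpec:
    """I.i.d. Bernoulli deletion of input->output synapses."""

    p_del: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_del <= 1.0):
            raise ValueError("p_del must lie in [0, 1]")


@dataclass
class AstdpParams:
    """Hyperparameters of the A-STDP repair rule.

    ``alpha`` is the weight percentile defining the surrogate signal;
    ``sigma`` the non-linearity exponent (``sigma=0`` reduces the rule to
    plain STDP).  ``w_alpha_floor`` guards the division when nearly every
    weight is zero; ``include_dead`` controls whether deleted synapses enter
    the percentile pool as zeros (default: they do).
    """

    alpha: float = 98.0
    sigma: float = 2.0
    w_alpha_floor: float | None = None
    recompute_every: int = 1
    include_dead: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 100.0):
            raise ValueError("alpha must lie in (0, 100)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.recompute_every < 1:
            raise ValueError("recompute_every must be >= 1")

    def floor_for(self, w: WeightMatrix) -> float:
        return self.w_alpha_floor if self.w_alpha_floor is not None else 1e-3 * w.w_max


@dataclass
class RepairTrace:
    """Batch-indexed log of the repair process."""

    log: pd.DataFrame                 # columns: batch, w_alpha
    accuracy: pd.DataFrame            # columns: epoch, accuracy
    n_deleted: int
    n_alive: int
    best_accuracy: float | None = None
    best_epoch: int | None = None


def inject_faults(w: WeightMatrix, spec: FaultSpec) -> WeightMatrix:
    """Return a copy of *w* with synapses deleted i.i.d. with ``p_del``.

    Deleted synapses get weight 0 and a permanent dead flag; the recurrent
    inhibitory weight is untouched.  Already-dead synapses stay dead.
    """
    rng = np.random.default_rng(spec.seed)
    out = w.copy()
    keep = rng.random(out.w.shape) >= spec.p_del
    out.fault_mask = out.fault_mask & keep
    out.w = out.w * out.fault_mask
    return out


def compute_w_alpha(w: WeightMatrix, params: AstdpParams) -> float:
    """Weight value at the alpha-th percentile of the pooled distribution.

    Linear interpolation between order statistics; dead synapses enter the
    pool as zeros unless ``params.include_dead`` is False.  The result is
    floored at ``w_alpha_floor`` so the ``w / w_alpha`` ratio stays finite.
    """
    if w.w.size == 0:
        raise ValueError("empty weight matrix")
    pool = w.w if params.include_dead else w.w[w.fault_mask]
    if pool.size == 0:
        return params.floor_for(w)
    value = float(np.percentile(pool, params.alpha, method="linear"))
    return max(value, params.floor_for(w))


def potentiation_scale(w: WeightMatrix, w_alpha: float,
                       params: AstdpParams) -> np.ndarray:
    """Per-synapse potentiation multiplier ``(w / w_alpha)**sigma``."""
    if w_alpha <= 0:
        raise RuntimeError("w_alpha floor guard violated (w_alpha <= 0)")
    return (w.w / w_alpha) ** params.sigma


def astdp_update(w: WeightMatrix, traces: StdpTraces, pre_spiked, post_spiked,
                 w_alpha: float, params: AstdpParams) -> WeightMatrix:
    """One step of the A-STDP rule.

    Potentiation on a post-synaptic spike is
    ``eta_post * x_pre * (w / w_alpha)**sigma`` (current weight ``w``);
    depression on a pre-synaptic spike is the unmodified STDP branch.  Clipped
    to ``[0, w_max]``; dead synapses are untouched.
    """
    if w_alpha <= 0:
        raise RuntimeError("w_alpha floor guard violated (w_alpha <= 0)")
    return stdp_update(w, traces, pre_spiked, post_spiked,
                       astdp=(w_alpha, params.sigma))


def repair_run(w_faulty: WeightMatrix, batches, rule: str,
               lif_params: LifParams, net_config: NetworkConfig,
               traces: StdpTraces, params: AstdpParams | None = None, *,
               theta: np.ndarray | None = None, epochs: int = 1,
               eval_fn=None, eval_every: int = 20, select: str | None = None,
               normalize_each_batch: bool = True, log_every: int = 1):
    """Re-train a faulty weight matrix with ``stdp`` or ``astdp``.

    Parameters
    ----------
    batches : callable
        ``batches(epoch)`` yields encoded rasters ``(B, T, n_input)`` for one
        re-training epoch (a fresh pass over the training stream).
    rule : {"stdp", "astdp"}
        Plasticity rule; ``astdp`` refreshes ``w_alpha`` every
        ``params.recompute_every`` batches and logs it after each batch.
    theta :
        Trained adaptive-threshold offsets; homeostasis keeps running during
        re-training (hyperparameters unchanged from training).
    eval_fn : callable, optional
        ``eval_fn(weights, theta) -> accuracy``; called every ``eval_every``
        batches and at every epoch end.
    select : {"best", "final"}, optional
        Which checkpoint to return: the maximum-accuracy one seen during
        re-training (the A-STDP reporting convention) or the final state
        (the sole-STDP convention, reported after a fixed epoch budget).
        Defaults to ``"best"`` when ``eval_fn`` is given, else ``"final"``.
    normalize_each_batch :
        Keep the per-batch weight normalization of the training loop running
        during re-training (hyperparameters/procedure unchanged).

    Weight normalization is applied once before the first batch (and skipped
    entirely in the degenerate zero-batch case, which returns the input
    unchanged).  Returns ``(w_out, theta_out, RepairTrace)``.
    """
    if rule not in ("stdp", "astdp"):
        raise ValueError(f"unknown plasticity rule {rule!r}")
    if select is None:
        select = "best" if eval_fn is not None else "final"
    if select not in ("best", "final"):
        raise ValueError(f"unknown checkpoint selection {select!r}")
    if select == "best" and eval_fn is None:
        raise ValueError("select='best' requires eval_fn")
    params = params or AstdpParams()
    n_alive = int(w_faulty.fault_mask.sum())
    n_deleted = int(w_faulty.fault_mask.size - n_alive)

    w = w_faulty.copy()
    th = np.zeros(w.n_neurons) if theta is None else np.asarray(theta, float).copy()
    log_rows: list[tuple[int, float]] = []
    acc_rows: list[tuple[int, float]] = []
    best = (None, None, w.copy(), th.copy())  # (acc, batch, w, theta)

    last_eval = -1

    def _maybe_checkpoint(batch_idx):
        nonlocal best, last_eval
        if batch_idx == last_eval:
            return
        last_eval = batch_idx
        acc = float(eval_fn(w, th))
        acc_rows.append((batch_idx, acc))
        if best[0] is None or acc > best[0]:
            best = (acc, batch_idx, w.copy(), th.copy())

    normalized = False
    w_alpha = None
    batch_idx = 0
    for epoch in range(epochs):
        for rasters in batches(epoch):
            if not normalized:
                normalize_weights(w)
                normalized = True
            state = LifState.resting(rasters.shape[0], w.n_neurons, lif_params,
                                     theta=th)
            if rule == "astdp":
                if w_alpha is None or batch_idx % params.recompute_every == 0:
                    w_alpha = compute_w_alpha(w, params)
                astdp_arg = (w_alpha, params.sigma)
            else:
                astdp_arg = None
            run_batch(rasters, w, state, traces, lif_params, learning=True,
                      astdp=astdp_arg)
            th = state.theta
            if normalize_each_batch:
                normalize_weights(w)
            if rule == "astdp" and batch_idx % log_every == 0:
                log_rows.append((batch_idx, compute_w_alpha(w, params)))
            batch_idx += 1
            if eval_fn is not None and batch_idx % eval_every == 0:
                _maybe_checkpoint(batch_idx)
        if eval_fn is not None:
            _maybe_checkpoint(batch_idx)

    if not normalized:  # zero re-training batches: no-op contract
        out = (None, None, w_faulty.copy(), th)
    elif select == "best" and best[0] is not None:
        out = best
    else:
        out = (acc_rows[-1][1] if acc_rows else None, batch_idx, w, th)

    trace = RepairTrace(
        log=pd.DataFrame(log_rows, columns=["batch", "w_alpha"]),
        accuracy=pd.DataFrame(acc_rows, columns=["batch", "accuracy"]),
        n_deleted=n_deleted, n_alive=n_alive,
        best_accuracy=best[0], best_epoch=best[1],
    )
    return out[2], out[3], trace
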