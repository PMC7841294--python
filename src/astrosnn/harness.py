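"""Class assignment, prediction, accuracy and the full experiment protocol.

The protocol mirrors the standard unsupervised-SNN evaluation: output neurons
are assigned the class they respond to most strongly on (a subset of) the
training set; a test example is predicted as the class whose assigned neurons
fire most on average.  The experiment pipeline is
train -> inject faults -> normalize -> re-train (sole STDP and A-STDP) with
per-phase accuracies aggregated over independent runs, plus the alpha/sigma
ablation sweep on a 5:1 train/validation split.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import Dataset, SynthSpec, generate
from .repair import AstdpParams, FaultSpec, inject_faults, repair_run
from .snn import (LifParams, LifState, NetworkConfig, StdpTraces, WeightMatrix,
                  normalize_weights, run_batch)

__all__ = [
    "NeuronLabeling",
    "ExperimentConfig",
    "ExperimentRecord",
    "assign_classes",
    "predict",
    "evaluate",
    "response_counts",
    "train_snn",
    "run_experiment",
    "ablate",
]

ABSTAIN = -1

PHASES = ["baseline", "post_fault", "post_norm", "stdp_repair", "astdp_repair"]


@dataclass
class NeuronLabeling:
    """Per-neuron class assignment from highest mean response."""

    labels: np.ndarray        # (n_neurons,) class index
    response: np.ndarray      # (n_neurons, n_classes) mean spike count
    inactive: np.ndarray      # (n_neurons,) True if zero spikes everywhere


def assign_classes(spike_counts: np.ndarray, example_labels: np.ndarray,
                   n_classes: int) -> NeuronLabeling:
    """Label each neuron with the class maximizing its mean response.

    Ties break toward the lowest class index.  Neurons that never spiked on
    the labeling set are still labeled (class 0 by the tie rule) but flagged
    inactive and excluded from prediction.
    """
    counts = np.asarray(spike_counts, dtype=float)
    labels = np.asarray(example_labels)
    if counts.shape[0] != labels.shape[0]:
        raise ValueError("spike_counts and example_labels length mismatch")
    if not np.isin(np.arange(n_classes), labels).all():
        raise ValueError("labeling set must cover every class")
    response = np.stack([counts[labels == c].mean(axis=0)
                         for c in range(n_classes)], axis=1)
    return NeuronLabeling(
        labels=response.argmax(axis=1),
        response=response,
        inactive=counts.sum(axis=0) == 0,
    )


def predict(spike_counts: np.ndarray, labeling: NeuronLabeling) -> np.ndarray:
    """Predict classes from output spike counts.

    The score of class *c* is the mean spike count over the active neurons
    labeled *c*; the argmax wins (ties toward the lowest index).  Examples
    whose class scores are all zero — in particular when no neuron is active —
    yield the abstain sentinel ``-1`` (counted as an error).
    """
    counts = np.atleast_2d(np.asarray(spike_counts, dtype=float))
    n_classes = labeling.response.shape[1]
    active = ~labeling.inactive
    scores = np.full((counts.shape[0], n_classes), -np.inf)
    for c in range(n_classes):
        members = active & (labeling.labels == c)
        if members.any():
            scores[:, c] = counts[:, members].mean(axis=1)
    pred = np.where(np.isfinite(scores).any(axis=1), scores.argmax(axis=1), ABSTAIN)
    finite_max = np.where(np.isfinite(scores), scores, 0.0).max(axis=1)
    pred = np.where(finite_max <= 0, ABSTAIN, pred)
    return pred if np.asarray(spike_counts).ndim > 1 else int(pred[0])


def _encode_block(images: np.ndarray, net: NetworkConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Poisson-encode a block of images into a (B, T, n_input) raster."""
    flat = images.reshape(len(images), -1)
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("pixel intensities must lie in [0, 255]")
    p = (net.max_rate_hz * flat / 255.0) * (net.dt / 1000.0)
    return rng.random((len(images), net.n_steps, net.n_input)) < p[:, None, :]


def response_counts(images: np.ndarray, w: WeightMatrix, theta: np.ndarray,
                    net: NetworkConfig, lif: LifParams, traces: StdpTraces,
                    rng: np.random.Generator) -> np.ndarray:
    """Output spike counts per image, learning off and homeostasis frozen."""
    out = np.zeros((len(images), w.n_neurons))
    for start in range(0, len(images), net.batch_size):
        block = images[start:start + net.batch_size]
        rasters = _encode_block(block, net, rng)
        state = LifState.resting(len(block), w.n_neurons, lif, theta=theta)
        tr = StdpTraces.zeros(len(block), w.n_input, w.n_neurons,
                              traces.tau_trace, traces.eta_pre, traces.eta_post)
        out[start:start + len(block)] = run_batch(
            rasters, w, state, tr, lif, learning=False)
    return out


def evaluate(images: np.ndarray, labels: np.ndarray, w: WeightMatrix,
             theta: np.ndarray, labeling: NeuronLabeling, net: NetworkConfig,
             lif: LifParams, traces: StdpTraces,
             rng: np.random.Generator) -> float:
    """Test accuracy in percent (abstentions count as errors)."""
    if len(images) == 0:
        raise ValueError("empty evaluation dataset")
    counts = response_counts(images, w, theta, net, lif, traces, rng)
    pred = predict(counts, labeling)
    return 100.0 * float(np.mean(pred == np.asarray(labels)))


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Desk-scale defaults for the full self-repair experiment.

    The network hyperparameters follow the cortical-microcircuit conventions
    (100 ms membranes, adaptive thresholds, trace STDP with
    eta_post=1e-2 / eta_pre=1e-4, strong static lateral inhibition); the
    normalization target scales with input dimensionality (78.4 for 784-pixel
    images -> 25.6 for the 256-pixel synthetic task).
    """

    synth: SynthSpec = field(default_factory=SynthSpec)
    net: NetworkConfig = field(default_factory=lambda: NetworkConfig(
        n_input=256, n_neurons=50))
    lif: LifParams = field(default_factory=LifParams)
    tau_trace: float = 20.0
    eta_pre: float = 1e-4
    eta_post: float = 1e-2
    w_max: float = 1.0
    w_norm: float = 25.6
    w_recurrent: float = -120.0
    astdp: AstdpParams = field(default_factory=AstdpParams)
    train_epochs: int = 2
    stdp_repair_epochs: int = 1
    astdp_repair_epochs: int = 2
    p_del_levels: tuple = (0.5, 0.8)
    fault_only_levels: tuple = (0.9,)
    n_runs: int = 5
    labeling_subset: int = 500
    val_fraction: float = 1.0 / 6.0
    seed: int = 0

    def traces_template(self, batch: int = 1) -> StdpTraces:
        return StdpTraces.zeros(batch, self.net.n_input, self.net.n_neurons,
                                self.tau_trace, self.eta_pre, self.eta_post)


@dataclass
class ExperimentRecord:
    """Per-phase accuracies with mean +- std across runs, plus diagnostics."""

    table: pd.DataFrame             # p_del x phase summary (mean, std)
    runs: pd.DataFrame              # long form: run, p_del, phase, accuracy
    w_alpha_traces: dict            # (run, p_del) -> DataFrame(batch, w_alpha)
    correlations: pd.DataFrame      # run, p_del, rule, median_corr
    config: dict
    seeds: list
    neuron_correlations: dict = field(default_factory=dict)
    # (run, p_del, rule) -> per-neuron correlation vector (NaN where degenerate)

    def gain(self) -> pd.Series:
        """Accuracy gain of A-STDP over sole-STDP re-training, per p_del."""
        mean = self.table["mean"].unstack("phase")
        return mean["astdp_repair"] - mean["stdp_repair"]

    def to_markdown(self) -> str:
        mean = self.table["mean"].unstack("phase")
        std = self.table["std"].unstack("phase")
        cols = [p for p in PHASES if p in mean.columns]
        lines = ["| Fault probability | " + " | ".join(cols) + " | gain |",
                 "|" + "---|" * (len(cols) + 2)]
        for p_del, row in mean.iterrows():
            cells = [f"{row[c]:.2f} ± {std.loc[p_del, c]:.2f}"
                     if np.isfinite(row[c]) else "—" for c in cols]
            g = (row.get("astdp_repair", np.nan) - row.get("stdp_repair", np.nan))
            cells.append(f"{g:.2f}" if np.isfinite(g) else "—")
            lines.append(f"| {p_del:.0%} | " + " | ".join(cells) + " |")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(out / "phase_accuracies.csv", index=False)
        self.table.to_csv(out / "summary.csv")
        self.correlations.to_csv(out / "repair_correlations.csv", index=False)
        (out / "summary.md").write_text(self.to_markdown() + "\n")
        for (run, p_del), tr in self.w_alpha_traces.items():
            tr.to_csv(out / f"w_alpha_run{run}_p{int(round(100 * p_del))}.csv",
                      index=False)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch_stream(images: np.ndarray, net: NetworkConfig, ss: np.random.SeedSequence):
    """Factory of per-epoch encoded mini-batch generators (shuffled)."""
    def batches(epoch: int):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=ss.spawn_key + (epoch,)))
        order = rng.permutation(len(images))
        # full mini-batches only (replica count is part of the protocol)
        for start in range(0, len(images) - net.batch_size + 1, net.batch_size):
            block = images[order[start:start + net.batch_size]]
            yield _encode_block(block, net, rng)
    return batches


def train_snn(images: np.ndarray, cfg: ExperimentConfig,
              ss: np.random.SeedSequence, *, epochs: int | None = None,
              eval_fn=None):
    """Train the unsupervised network with trace STDP.

    Weights are renormalized to ``w_norm`` after every mini-batch (the
    cortical-microcircuit convention); theta accumulates across the whole run.
    If ``eval_fn(w, theta) -> accuracy`` is given, the best-scoring epoch
    checkpoint is returned, otherwise the final one.
    Returns ``(w, theta, history_df)``.
    """
    epochs = cfg.train_epochs if epochs is None else epochs
    ss_init, ss_enc = np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=ss.spawn_key).spawn(2)
    rng_init = np.random.default_rng(ss_init)
    w = WeightMatrix.random(cfg.net.n_input, cfg.net.n_neurons, rng_init,
                            w_max=cfg.w_max, w_norm=cfg.w_norm,
                            w_recurrent=cfg.w_recurrent)
    normalize_weights(w)
    theta = np.zeros(cfg.net.n_neurons)
    traces = cfg.traces_template(cfg.net.batch_size)
    batches = _batch_stream(images, cfg.net, ss_enc)
    history = []
    best = (None, w.copy(), theta.copy())
    for epoch in range(epochs):
        for rasters in batches(epoch):
            state = LifState.resting(rasters.shape[0], cfg.net.n_neurons,
                                     cfg.lif, theta=theta)
            tr = (traces if rasters.shape[0] == cfg.net.batch_size
                  else cfg.traces_template(rasters.shape[0]))
            run_batch(rasters, w, state, tr, cfg.lif, learning=True)
            theta = state.theta
            normalize_weights(w)
        if eval_fn is not None:
            acc = float(eval_fn(w, theta))
            history.append({"epoch": epoch, "accuracy": acc})
            if best[0] is None or acc > best[0]:
                best = (acc, w.copy(), theta.copy())
    if eval_fn is None:
        best = (None, w.copy(), theta.copy())
    return best[1], best[2], pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def _child(ss: np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + key)


def _rng(ss: np.random.SeedSequence, *key: int) -> np.random.Generator:
    return np.random.default_rng(_child(ss, *key))


class _Evaluator:
    """Bundles labeling + accuracy measurement for one run."""

    def __init__(self, data: Dataset, cfg: ExperimentConfig,
                 ss: np.random.SeedSequence, label_idx: np.ndarray,
                 val_idx: np.ndarray):
        self.data = data
        self.cfg = cfg
        self.ss = ss
        self.label_idx = label_idx
        self.val_idx = val_idx
        self.traces = cfg.traces_template()

    # Evaluation encoding noise is drawn from fixed streams (not advanced
    # between calls) so phase accuracies within a run are paired and any
    # evaluation is exactly reproducible in isolation.
    def _labeling(self, w, theta) -> NeuronLabeling:
        rng = _rng(self.ss, 900)
        counts = response_counts(self.data.train_images[self.label_idx], w,
                                 theta, self.cfg.net, self.cfg.lif,
                                 self.traces, rng)
        return assign_classes(counts, self.data.train_labels[self.label_idx],
                              self.data.n_classes)

    def _acc(self, images, labels, w, theta, labeling) -> float:
        rng = _rng(self.ss, 901)
        return evaluate(images, labels, w, theta, labeling, self.cfg.net,
                        self.cfg.lif, self.traces, rng)

    def test_accuracy(self, w, theta) -> float:
        lab = self._labeling(w, theta)
        return self._acc(self.data.test_images, self.data.test_labels, w,
                         theta, lab)

    def val_accuracy(self, w, theta) -> float:
        lab = self._labeling(w, theta)
        return self._acc(self.data.train_images[self.val_idx],
                         self.data.train_labels[self.val_idx], w, theta, lab)


def _live_correlation(w_before: WeightMatrix, w_after: WeightMatrix) -> float:
    """Median per-neuron Pearson correlation between weight maps, live
    synapses of the repaired matrix only."""
    corrs = []
    for j in range(w_before.n_neurons):
        alive = w_after.fault_mask[:, j]
        if alive.sum() < 3:
            continue
        a, b = w_before.w[alive, j], w_after.w[alive, j]
        if a.std() == 0 or b.std() == 0:
            continue
        corrs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.median(corrs)) if corrs else np.nan


def per_neuron_correlations(w_before: WeightMatrix, w_after: WeightMatrix) -> np.ndarray:
    """Per-neuron Pearson correlations (live synapses only), NaN where
    degenerate."""
    out = np.full(w_before.n_neurons, np.nan)
    for j in range(w_before.n_neurons):
        alive = w_after.fault_mask[:, j]
        a, b = w_before.w[alive, j], w_after.w[alive, j]
        if alive.sum() >= 3 and a.std() > 0 and b.std() > 0:
            out[j] = np.corrcoef(a, b)[0, 1]
    return out


def run_experiment(cfg: ExperimentConfig | None = None, *,
                   data: Dataset | None = None,
                   progress: bool = False) -> ExperimentRecord:
    """Execute the full train/fault/normalize/repair protocol.

    For each of ``cfg.n_runs`` seeds: train for ``train_epochs`` and keep the
    best validation-accuracy checkpoint; then for every fault level inject
    faults, record post-fault and post-normalization test accuracy, re-train
    with sole STDP (``stdp_repair_epochs``) and with A-STDP (best validation
    checkpoint over ``astdp_repair_epochs``), recording test accuracy and the
    ``w_alpha`` trajectory.  Levels in ``fault_only_levels`` record only the
    post-fault accuracy.
    """
    cfg = cfg or ExperimentConfig()
    data = data if data is not None else generate(cfg.synth)
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    traces_by_run = {}
    corr_rows = []
    neuron_corrs = {}
    seeds = []

    for run in range(cfg.n_runs):
        ss = _child(root, run)
        seeds.append(int(np.random.default_rng(ss).integers(2**31)))
        rng_split = _rng(ss, 1)
        n_train = len(data.train_images)
        perm = rng_split.permutation(n_train)
        n_val = int(round(cfg.val_fraction * n_train))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        label_idx = fit_idx[:min(cfg.labeling_subset, len(fit_idx))]
        ev = _Evaluator(data, cfg, ss, label_idx, val_idx)

        if progress:
            print(f"[run {run}] training baseline ...", flush=True)
        w0, theta0, _ = train_snn(data.train_images[fit_idx], cfg,
                                  _child(ss, 2), eval_fn=ev.val_accuracy)
        acc_base = ev.test_accuracy(w0, theta0)
        rows.append({"run": run, "p_del": 0.0, "phase": "baseline",
                     "accuracy": acc_base})

        all_levels = [(p, False) for p in cfg.p_del_levels] + \
                     [(p, True) for p in cfg.fault_only_levels]
        for p_del, fault_only in all_levels:
            if progress:
                print(f"[run {run}] p_del={p_del} ...", flush=True)
            fs = FaultSpec(p_del, seed=int(
                np.random.default_rng(_child(ss, 3, int(p_del * 100))).integers(2**31)))
            wf = inject_faults(w0, fs)
            acc_fault = ev.test_accuracy(wf, theta0)
            rows.append({"run": run, "p_del": p_del, "phase": "post_fault",
                         "accuracy": acc_fault})
            if fault_only:
                continue

            wn = normalize_weights(wf.copy())
            acc_norm = ev.test_accuracy(wn, theta0)
            rows.append({"run": run, "p_del": p_del, "phase": "post_norm",
                         "accuracy": acc_norm})

            stream = _batch_stream(data.train_images[fit_idx], cfg.net,
                                   _child(ss, 4, int(p_del * 100)))
            traces = cfg.traces_template(cfg.net.batch_size)
            # sole-STDP convention: report the state after a fixed epoch budget
            w_stdp, th_stdp, _ = repair_run(
                wf, stream, "stdp", cfg.lif, cfg.net, traces, cfg.astdp,
                theta=theta0, epochs=cfg.stdp_repair_epochs, select="final")
            acc_stdp = ev.test_accuracy(w_stdp, th_stdp)
            rows.append({"run": run, "p_del": p_del, "phase": "stdp_repair",
                         "accuracy": acc_stdp})

            traces = cfg.traces_template(cfg.net.batch_size)
            # A-STDP convention: maximum validation accuracy over re-training
            w_astdp, th_astdp, rtrace = repair_run(
                wf, stream, "astdp", cfg.lif, cfg.net, traces, cfg.astdp,
                theta=theta0, epochs=cfg.astdp_repair_epochs,
                eval_fn=ev.val_accuracy, select="best")
            acc_astdp = ev.test_accuracy(w_astdp, th_astdp)
            rows.append({"run": run, "p_del": p_del, "phase": "astdp_repair",
                         "accuracy": acc_astdp})
            traces_by_run[(run, p_del)] = rtrace.log

            corr_rows.append({"run": run, "p_del": p_del, "rule": "stdp",
                              "median_corr": _live_correlation(w0, w_stdp)})
            corr_rows.append({"run": run, "p_del": p_del, "rule": "astdp",
                              "median_corr": _live_correlation(w0, w_astdp)})
            neuron_corrs[(run, p_del, "stdp")] = per_neuron_correlations(w0, w_stdp)
            neuron_corrs[(run, p_del, "astdp")] = per_neuron_correlations(w0, w_astdp)

    runs_df = pd.DataFrame(rows)
    table = (runs_df.groupby(["p_del", "phase"])["accuracy"]
             .agg(["mean", "std"]))
    return ExperimentRecord(table=table, runs=runs_df,
                            w_alpha_traces=traces_by_run,
                            correlations=pd.DataFrame(corr_rows),
                            config=_config_snapshot(cfg), seeds=seeds,
                            neuron_correlations=neuron_corrs)


def _config_snapshot(cfg: ExperimentConfig) -> dict:
    snap = asdict(cfg)
    return snap


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

def ablate(cfg: ExperimentConfig, alphas, sigmas, *, p_del: float = 0.9,
           repair_epochs: int = 1) -> pd.DataFrame:
    """Grid sweep of the A-STDP hyperparameters alpha and sigma.

    Trains one baseline, injects faults at ``p_del``, splits the training set
    5:1 into retraining and validation subsets by random sampling, re-trains
    the faulty network for each (alpha, sigma) on the retraining subset and
    scores it on validation.  Returns a tidy DataFrame with an ``is_best``
    flag on the argmax pair.
    """
    data = generate(cfg.synth)
    root = np.random.SeedSequence(cfg.seed)
    ss = _child(root, 0)
    rng_split = _rng(ss, 1)
    n_train = len(data.train_images)
    perm = rng_split.permutation(n_train)
    n_val = n_train // 6
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if np.intersect1d(val_idx, fit_idx).size:
        raise RuntimeError("train/validation split overlaps")
    label_idx = fit_idx[:min(cfg.labeling_subset, len(fit_idx))]
    ev = _Evaluator(data, cfg, ss, label_idx, val_idx)

    w0, theta0, _ = train_snn(data.train_images[fit_idx], cfg, _child(ss, 2),
                              eval_fn=ev.val_accuracy)
    fs = FaultSpec(p_del, seed=int(_rng(ss, 3).integers(2**31)))
    wf = inject_faults(w0, fs)

    rows = []
    for alpha in alphas:
        for sigma in sigmas:
            params = replace(cfg.astdp, alpha=alpha, sigma=sigma)
            stream = _batch_stream(data.train_images[fit_idx], cfg.net,
                                   _child(ss, 4))
            traces = cfg.traces_template(cfg.net.batch_size)
            w_r, th_r, _ = repair_run(wf, stream, "astdp", cfg.lif, cfg.net,
                                      traces, params, theta=theta0,
                                      epochs=repair_epochs)
            acc = ev.val_accuracy(w_r, th_r)
            rows.append({"alpha": alpha, "sigma": sigma, "val_accuracy": acc})
    grid = pd.DataFrame(rows)
    grid["is_best"] = False
    grid.loc[grid["val_accuracy"].idxmax(), "is_best"] = True
    return grid
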