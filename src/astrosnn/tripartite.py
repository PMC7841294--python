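"""Tripartite-synapse self-repair simulator.

A small toy network — a handful of leaky integrate-and-fire post-neurons, each
driven by its own pool of Poisson pre-neurons through stochastic synapses — is
coupled to a single astrocyte.  Every post-synaptic spike releases the
endocannabinoid 2-AG, which acts along two pathways:

* **direct** (local): 2-AG binding at the pre-synaptic terminal depresses the
  neuron's own synapses (DSE, depolarization-induced suppression of
  excitation), linearly in the 2-AG level;
* **indirect** (global): 2-AG binding on the astrocyte process drives IP3
  production; IP3-gated calcium release from the endoplasmic reticulum
  (Li-Rinzel dynamics) produces cytosolic Ca2+ oscillations, and each upward
  threshold crossing releases a bolus of glutamate, which sustains a slow,
  astrocyte-wide potentiating signal (e-SP) broadcast to *all* synapses.

Each synapse's probability of release is
``PR = PR0 * (1 + (DSE + eSP) / 100)``, clipped to [0, 1].  In the fault-free
network DSE and e-SP settle into a dynamic equilibrium that pins PR at its
initial value.  When a fraction of a neuron's synapses die (PR forced to 0),
that neuron's firing — and hence its 2-AG and |DSE| — collapses while the
global e-SP persists, so the surviving synapses' PR climbs and the firing rate
recovers toward its pre-fault value.

The Li-Rinzel constants follow the standard published parameterization; the
coupling and scale factors (2-AG -> IP3 drive, DSE/e-SP gains, synaptic kick)
are packaged defaults calibrated once so the fault-free two-neuron scenario
sits at the dynamic equilibrium described above, with firing rates in the
tens-of-Hz band.  All of them can be overridden through ``AstroParams``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .snn import LifParams

__all__ = [
    "LiRinzelParams",
    "Ip3Params",
    "AstroParams",
    "TripartiteState",
    "ToyNetworkConfig",
    "ToyRecord",
    "step_ag",
    "li_rinzel_step",
    "step_gliotransmission",
    "compute_dse",
    "update_pr",
    "simulate_toy",
]


class IntegrationError(FloatingPointError):
    """A state variable became non-finite during integration."""


@dataclass
class LiRinzelParams:
    """Standard Li-Rinzel IP3-gated Ca2+ constants (concentrations in uM,
    rates in 1/s or uM/s)."""

    v1: float = 6.0       # max channel flux rate (1/s)
    v2: float = 0.11      # leak rate (1/s)
    v3: float = 0.9       # max SERCA pump rate (uM/s)
    k3: float = 0.1       # pump half-activation (uM)
    d1: float = 0.13      # IP3 dissociation constant (uM)
    d2: float = 1.049     # inactivation dissociation constant (uM)
    d3: float = 0.9434    # IP3 dissociation (h gate) (uM)
    d5: float = 0.08234   # Ca2+ activation dissociation (uM)
    a2: float = 0.2       # inactivation binding rate (1/(uM s))
    c0: float = 2.0       # total free Ca2+ per cytosol volume (uM)
    c1: float = 0.185     # ER/cytosol volume ratio


@dataclass
class Ip3Params:
    """First-order IP3 kinetics driven by bound 2-AG (CB1R binding)."""

    ip3_star: float = 0.45   # baseline IP3 (uM): spontaneously oscillatory
    tau_ip3: float = 7.0     # IP3 relaxation time constant (s)
    r_ip3: float = 0.0035    # IP3 production per unit total 2-AG (uM/s)


@dataclass
class AstroParams:
    """Time constants and gains of the retrograde signalling loop.

    Times are in seconds; 2-AG and glutamate quantities are dimensionless,
    with DSE/e-SP expressed on the percent scale that enters
    ``PR = PR0 (1 + (DSE + eSP)/100)``.
    """

    tau_ag: float = 10.0        # 2-AG decay time constant (s)
    r_ag: float = 0.01          # 2-AG production per post-spike
    tau_glu: float = 20.0       # glutamate decay time constant (s)
    r_glu: float = 1.0          # glutamate per Ca2+ threshold-crossing event
    tau_esp: float = 40.0       # e-SP relaxation time constant (s)
    m_esp: float = 200.0        # e-SP scaling factor (percent per glutamate unit)
    k_ag: float = 245.0         # DSE scaling factor (percent per 2-AG unit)
    ca_threshold: float = 0.3   # Ca2+ level triggering glutamate release (uM)
    li_rinzel: LiRinzelParams = field(default_factory=LiRinzelParams)
    ip3: Ip3Params = field(default_factory=Ip3Params)
    dt: float = 1e-3            # integration step (s)

    def __post_init__(self) -> None:
        for name in ("tau_ag", "tau_glu", "tau_esp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("r_ag", "r_glu", "m_esp", "k_ag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.dt < min(self.tau_ag, self.tau_glu, self.tau_esp) / 100):
            raise ValueError("dt must be small relative to the time constants")


@dataclass
class TripartiteState:
    """Astrocyte + per-neuron retrograde-signal state.

    ``ag`` is per post-neuron; ``ca``, ``ip3``, ``h_gate``, ``glu`` and
    ``esp`` are astrocyte-global scalars.  ``ca_prev`` retains the previous
    Ca2+ sample for upward-crossing detection.
    """

    ag: np.ndarray
    ca: float = 0.07
    ip3: float = 0.16
    h_gate: float = 0.79
    glu: float = 0.0
    esp: float = 0.0
    ca_prev: float = 0.07

    @classmethod
    def initial(cls, n_post: int) -> "TripartiteState":
        return cls(ag=np.zeros(n_post))

    @property
    def dse(self) -> np.ndarray:
        raise AttributeError("use compute_dse(state.ag, params.k_ag)")


@dataclass
class ToyNetworkConfig:
    """Scenario description for the toy self-repair simulation.

    ``fault_schedule`` is a list of ``(time_s, post_neuron, spec)`` entries
    where ``spec`` is either a fraction in [0, 1] (the first
    ``round(frac * n_pre)`` synapses die, deterministically) or an explicit
    sequence of synapse indices.  ``pr0`` may be a scalar or an
    ``(n_post, n_pre)`` array of initial release probabilities.
    """

    n_post: int = 2
    n_pre_per_post: int = 10
    pre_rate: float = 10.0          # Hz per pre-neuron
    duration: float = 400.0         # s
    fault_schedule: list = field(default_factory=list)
    pr0: float | np.ndarray = 0.5
    seed: int = 0
    sample_every: float = 0.1       # s between recorded samples
    rate_window: float = 10.0       # s sliding window for firing rates
    kick_mv: float = 14.0           # membrane kick per transmitted spike (mV)
    lif: LifParams = field(default_factory=lambda: LifParams(
        tau_mem=15.0, theta_plus=0.0, delta_ref=50.0))

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.rate_window <= 0 or self.rate_window > self.duration:
            raise ValueError("rate_window must lie in (0, duration]")
        for t_f, neuron, spec in self.fault_schedule:
            if not (0 <= t_f < self.duration):
                raise ValueError("fault times must fall inside the simulation")
            if not (0 <= neuron < self.n_post):
                raise ValueError("fault neuron index out of range")
            if np.isscalar(spec) and not (0 <= spec <= 1):
                raise ValueError("fault fraction must lie in [0, 1]")

    def pr0_matrix(self) -> np.ndarray:
        pr0 = np.broadcast_to(np.asarray(self.pr0, dtype=float),
                              (self.n_post, self.n_pre_per_post)).copy()
        if pr0.min() < 0 or pr0.max() > 1:
            raise ValueError("pr0 must lie in [0, 1]")
        return pr0


@dataclass
class ToyRecord:
    """Uniformly sampled trajectories from :func:`simulate_toy`.

    ``rate`` is a sliding-window firing-rate estimate (Hz); ``pr`` carries the
    per-synapse release probabilities; ``esp`` is the astrocyte-global
    potentiation signal and ``dse`` the per-neuron depression signal (both in
    percent).
    """

    times: np.ndarray          # (S,)
    rate: np.ndarray           # (n_post, S)
    dse: np.ndarray            # (n_post, S)
    esp: np.ndarray            # (S,)
    pr: np.ndarray             # (n_post, n_pre, S)
    ca: np.ndarray             # (S,)
    ip3: np.ndarray            # (S,)
    glu: np.ndarray            # (S,)
    spike_counts: np.ndarray   # (n_post, S) spikes per sampling bin
    faulty: np.ndarray         # (n_post, n_pre) final fault mask
    config: ToyNetworkConfig = None  # type: ignore[assignment]

    def to_frame(self):
        """Tidy (time, variable, entity, value) DataFrame."""
        import pandas as pd

        rows = []
        for i in range(self.rate.shape[0]):
            rows.append(pd.DataFrame({"time": self.times, "variable": "rate",
                                      "entity": f"N{i+1}", "value": self.rate[i]}))
            rows.append(pd.DataFrame({"time": self.times, "variable": "dse",
                                      "entity": f"N{i+1}", "value": self.dse[i]}))
            for j in range(self.pr.shape[1]):
                rows.append(pd.DataFrame({"time": self.times, "variable": "pr",
                                          "entity": f"N{i+1}S{j}",
                                          "value": self.pr[i, j]}))
        for name, series in [("esp", self.esp), ("ca", self.ca),
                             ("ip3", self.ip3), ("glu", self.glu)]:
            rows.append(pd.DataFrame({"time": self.times, "variable": name,
                                      "entity": "astro", "value": series}))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Elementary steps (forward Euler, dt in seconds)
# ---------------------------------------------------------------------------

def step_ag(state: TripartiteState, post_spiked: np.ndarray,
            params: AstroParams) -> TripartiteState:
    """Advance 2-AG: exponential decay plus ``r_ag`` per post-synaptic spike."""
    if not np.all(np.isfinite(state.ag)):
        raise IntegrationError("non-finite value in state variable 'ag'")
    state.ag = state.ag + params.dt * (-state.ag / params.tau_ag)
    state.ag = state.ag + params.r_ag * np.asarray(post_spiked, dtype=float)
    return state


def _li_rinzel_fluxes(ca: float, ip3: float, h: float, p: LiRinzelParams):
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca / (ca + p.d5)
    free_er = p.c0 - (1.0 + p.c1) * ca
    j_chan = p.v1 * (m_inf * n_inf * h) ** 3 * free_er
    j_leak = p.v2 * free_er
    j_pump = p.v3 * ca * ca / (p.k3 * p.k3 + ca * ca)
    return j_chan, j_leak, j_pump


def li_rinzel_step(state: TripartiteState, params: AstroParams,
                   ag_total: float | None = None) -> TripartiteState:
    """Advance IP3, cytosolic Ca2+ and the channel gating variable.

    IP3 relaxes toward its baseline and is driven by total bound 2-AG;
    Ca2+ integrates the channel/leak/pump fluxes; the gate follows its
    standard inactivation kinetics.  A negative Ca2+ excursion (step size too
    coarse) is clamped to 0 with a warning.
    """
    for name in ("ca", "ip3", "h_gate"):
        if not np.isfinite(getattr(state, name)):
            raise IntegrationError(f"non-finite value in state variable '{name}'")
    p = params.li_rinzel
    ip3p = params.ip3
    if ag_total is None:
        ag_total = float(np.sum(state.ag))
    state.ca_prev = state.ca
    j_chan, j_leak, j_pump = _li_rinzel_fluxes(state.ca, state.ip3, state.h_gate, p)
    q2 = p.d2 * (state.ip3 + p.d1) / (state.ip3 + p.d3)
    dh = p.a2 * (q2 * (1.0 - state.h_gate) - state.ca * state.h_gate)
    dip3 = (ip3p.ip3_star - state.ip3) / ip3p.tau_ip3 + ip3p.r_ip3 * ag_total
    state.ca = state.ca + params.dt * (j_chan + j_leak - j_pump)
    state.h_gate = min(max(state.h_gate + params.dt * dh, 0.0), 1.0)
    state.ip3 = state.ip3 + params.dt * dip3
    if state.ca < 0.0:
        warnings.warn("Ca2+ went negative; clamped to 0 (integration step too "
                      "coarse)", RuntimeWarning, stacklevel=2)
        state.ca = 0.0
    return state


def step_gliotransmission(state: TripartiteState, params: AstroParams) -> TripartiteState:
    """Advance glutamate and e-SP.

    Glutamate gains ``r_glu`` on each *upward* crossing of ``ca_threshold``
    (one release per oscillation peak) and decays with ``tau_glu``; e-SP
    relaxes toward ``m_esp * glu`` with time constant ``tau_esp``.
    """
    crossed = state.ca_prev < params.ca_threshold <= state.ca
    state.glu = state.glu + params.dt * (-state.glu / params.tau_glu)
    if crossed:
        state.glu += params.r_glu
    state.esp = state.esp + (params.dt / params.tau_esp) * (
        -state.esp + params.m_esp * state.glu)
    return state


def compute_dse(ag, k_ag: float):
    """Depression signal: linear in the 2-AG level, ``DSE = -AG * K_AG``."""
    ag_arr = np.asarray(ag, dtype=float)
    if np.any(ag_arr < 0):
        raise ValueError("AG must be non-negative")
    out = -ag_arr * k_ag
    return out if out.ndim else float(out)


def update_pr(pr0, dse, esp, faulty=None):
    """Release probability ``PR = PR0 + PR0 * (DSE + eSP)/100``, clipped to
    [0, 1]; faulty synapses bypass the rule and stay exactly 0."""
    pr0_arr = np.asarray(pr0, dtype=float)
    pr = pr0_arr + pr0_arr * (np.asarray(dse) + np.asarray(esp)) / 100.0
    pr = np.clip(pr, 0.0, 1.0)
    if faulty is not None:
        pr = np.where(faulty, 0.0, pr)
    return pr if pr.ndim else float(pr)


# ---------------------------------------------------------------------------
# Full toy simulation
# ---------------------------------------------------------------------------

def _fault_indices(spec, n_pre: int) -> np.ndarray:
    if np.isscalar(spec):
        k = int(round(float(spec) * n_pre))
        return np.arange(k)
    return np.asarray(spec, dtype=int)


def _reference_chunk(u_pre, u_trans, pr0, faulty, pr, state, v, refrac,
                     config, params, lif, spike_counts, rec, start_step,
                     sample_stride):
    """Advance one chunk with the public per-step operations (numpy path)."""
    rec_dse, rec_esp, rec_pr, rec_ca, rec_ip3, rec_glu = rec
    p_pre = config.pre_rate * params.dt
    n_samples = rec_esp.shape[0]
    for k in range(u_pre.shape[0]):
        t = start_step + k
        pre_spk = u_pre[k] < p_pre                     # (n_post, n_pre)
        transmitted = pre_spk & (u_trans[k] < pr)
        n_trans = transmitted.sum(axis=1)

        # toy LIF post-neurons (delta-kick synapses)
        refractory = refrac > 0
        v[:] = np.where(refractory, lif.v_reset,
                        v + (lif.dt / lif.tau_mem) * (lif.v_rest - v)
                        + config.kick_mv * n_trans)
        refrac[:] = np.maximum(refrac - lif.dt * refractory, 0.0)
        spiked = ~refractory & (v >= lif.theta0)
        v[:] = np.where(spiked, lif.v_reset, v)
        refrac[:] = np.where(spiked, lif.delta_ref, refrac)

        # astrocyte / retrograde signalling
        step_ag(state, spiked, params)
        li_rinzel_step(state, params)
        step_gliotransmission(state, params)
        dse = compute_dse(state.ag, params.k_ag)
        pr[:] = update_pr(pr0, dse[:, None], state.esp, faulty)

        s = t // sample_stride
        if s < n_samples:
            spike_counts[:, s] += spiked
        if (t + 1) % sample_stride == 0 and s < n_samples:
            rec_dse[:, s] = dse
            rec_esp[s] = state.esp
            rec_pr[:, :, s] = pr
            rec_ca[s] = state.ca
            rec_ip3[s] = state.ip3
            rec_glu[s] = state.glu


def simulate_toy(config: ToyNetworkConfig, params: AstroParams | None = None,
                 backend: str = "auto") -> ToyRecord:
    """Simulate the toy tripartite network and record sampled trajectories.

    Pre-synaptic inputs are independent Poisson trains; each pre-spike is
    transmitted with Bernoulli probability PR and adds a fixed ``kick_mv``
    depolarization to its post-neuron.  Faults listed in
    ``config.fault_schedule`` force the selected synapses' PR to 0 from the
    scheduled time onward.  Every post-neuron owns private RNG streams for its
    input and transmission draws, so fault experiments replay identically on
    the unaffected neurons' streams.

    ``backend`` selects the inner loop: ``"numba"`` (jitted), ``"numpy"``
    (the reference composition of the public step operations) or ``"auto"``
    (numba when available).  Both consume identical RNG streams.
    """
    from . import _kernels

    params = params or AstroParams()
    if backend == "auto":
        backend = "numba" if _kernels.HAVE_NUMBA else "numpy"
    if backend not in ("numba", "numpy"):
        raise ValueError(f"unknown backend {backend!r}")
    n_post, n_pre = config.n_post, config.n_pre_per_post
    dt = params.dt
    n_steps = int(round(config.duration / dt))
    sample_stride = max(1, int(round(config.sample_every / dt)))
    n_samples = n_steps // sample_stride
    if n_samples < 1:
        raise ValueError("duration too short for the sampling interval")

    pr0 = config.pr0_matrix()
    faulty = np.zeros((n_post, n_pre), dtype=bool)
    fault_steps = sorted(
        (int(round(t / dt)), neuron, _fault_indices(spec, n_pre))
        for t, neuron, spec in config.fault_schedule)
    fault_queue = list(fault_steps)

    state = TripartiteState.initial(n_post)
    lif = replace(config.lif, dt=dt * 1e3)  # LIF params are in ms
    v = np.full(n_post, lif.v_rest)
    refrac = np.zeros(n_post)
    pr = update_pr(pr0, compute_dse(state.ag, params.k_ag)[:, None], state.esp,
                   faulty)

    # one RNG stream per post-neuron; fixed per-step consumption
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(n_post)]

    times = (np.arange(n_samples) + 1) * sample_stride * dt
    rec_dse = np.empty((n_post, n_samples))
    rec_esp = np.empty(n_samples)
    rec_pr = np.empty((n_post, n_pre, n_samples))
    rec_ca = np.empty(n_samples)
    rec_ip3 = np.empty(n_samples)
    rec_glu = np.empty(n_samples)
    spike_counts = np.zeros((n_post, n_samples))
    rec = (rec_dse, rec_esp, rec_pr, rec_ca, rec_ip3, rec_glu)

    # chunk edges at fault events so both backends draw identical streams
    chunk = 20000
    edges = sorted({0, n_steps} | {min(max(fs[0], 0), n_steps)
                                   for fs in fault_steps}
                   | set(range(0, n_steps, chunk)))
    lr, ip = params.li_rinzel, params.ip3
    packed = np.array([
        params.dt, params.tau_ag, params.r_ag, params.tau_glu, params.r_glu,
        params.tau_esp, params.m_esp, params.k_ag, params.ca_threshold,
        lr.v1, lr.v2, lr.v3, lr.k3, lr.d1, lr.d2, lr.d3, lr.d5, lr.a2,
        lr.c0, lr.c1, ip.ip3_star, ip.tau_ip3, ip.r_ip3,
        config.pre_rate * dt, config.kick_mv, lif.tau_mem, lif.v_rest,
        lif.v_reset, lif.theta0, lif.delta_ref, lif.dt])
    astro = np.array([state.ca, state.ip3, state.h_gate, state.glu,
                      state.esp, state.ca_prev])

    for lo, hi in zip(edges[:-1], edges[1:]):
        while fault_queue and fault_queue[0][0] <= lo:
            _, neuron, idx = fault_queue.pop(0)
            faulty[neuron, idx] = True
        m = hi - lo
        u_pre = np.stack([g.random((m, n_pre)) for g in streams], axis=1)
        u_trans = np.stack([g.random((m, n_pre)) for g in streams], axis=1)
        if backend == "numba":
            from ._kernels import toy_kernel

            toy_kernel(u_pre, u_trans, pr0, faulty, pr, state.ag, v, refrac,
                       astro, packed, spike_counts, rec_dse, rec_esp, rec_pr,
                       rec_ca, rec_ip3, rec_glu, lo, sample_stride)
            (state.ca, state.ip3, state.h_gate, state.glu, state.esp,
             state.ca_prev) = astro
        else:
            _reference_chunk(u_pre, u_trans, pr0, faulty, pr, state, v,
                             refrac, config, params, lif, spike_counts, rec,
                             lo, sample_stride)
            astro[:] = (state.ca, state.ip3, state.h_gate, state.glu,
                        state.esp, state.ca_prev)
        if not np.all(np.isfinite(astro)) or not np.all(np.isfinite(state.ag)):
            raise IntegrationError("non-finite astrocyte state during simulation")

    window_bins = max(1, int(round(config.rate_window / (sample_stride * dt))))
    kernel = np.ones(window_bins)
    rate = np.empty((n_post, n_samples))
    denom = np.convolve(np.ones(n_samples), kernel)[:n_samples] * sample_stride * dt
    for i in range(n_post):
        rate[i] = np.convolve(spike_counts[i], kernel)[:n_samples] / denom

    return ToyRecord(times=times, rate=rate, dse=rec_dse, esp=rec_esp,
                     pr=rec_pr, ca=rec_ca, ip3=rec_ip3, glu=rec_glu,
                     spike_counts=spike_counts, faulty=faulty, config=config)
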