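"""Stochastic integrate-and-fire population network.

Neurons follow MacGregor-style dynamics, discretised with an exponential
Euler step (default 0.5 ms): the membrane potential (relative to rest)
relaxes under synaptic conductances, a post-spike potassium conductance, a
constant bias, injected afferent bias and additive Gaussian noise; the
threshold adapts toward ``TH0 + C * E``.  A spike is emitted whenever the
potential reaches threshold, incrementing the potassium conductance and
scheduling deliveries at all of the neuron's terminals after their
conduction delays.  Presynaptic-inhibition synapse types do not conduct:
their deliveries charge a saturating gating variable on the target that
scales down transmission of the synapse type they gate.

The I-Driver population additionally carries a slow inward
(persistent-sodium-like) current with population-shared spike-coupled
gates (see :class:`BursterParams`), giving conditional bursting pacemaker
behaviour.  Its constants are a behavioural calibration targeting the
eupneic burst period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .tables import (
    FiberPopulationSpec,
    PopulationSpec,
    ProjectionSpec,
    SynapseSpec,
    default_population_specs,
    default_projection_specs,
    default_synapse_specs,
)

__all__ = [
    "BursterParams",
    "NeuronState",
    "Network",
    "build_network",
    "step_neuron",
    "presynaptic_gate",
    "fiber_events",
    "integrated_rate",
    "expected_divergence",
    "E_K_DEFAULT",
    "DT_MS_DEFAULT",
]

E_K_DEFAULT = -10.0   # potassium reversal potential (mV relative to rest)
DT_MS_DEFAULT = 0.5   # simulation step (ms); part of the frozen configuration
# Optional uniform gain on inhibitory conductance increments; a calibration
# hook (default: published strengths taken at face value).
INHIBITORY_GAIN_DEFAULT = 1.0


@dataclass(frozen=True)
class BursterParams:
    """Slow inward current of the I-Driver conditional burster.

    Conductance ``g_nap * (m_floor + (1 - m_floor) m) * h`` with reversal
    ``E_na``, shared across the population (mean-field slow gates).  The
    activation m charges with population spiking (each population-mean
    spike adds ``a_m (1 - m)``, decay tau_m): an afterdepolarisation that
    regeneratively sustains the burst.  The slow inactivation h is
    hysteretic, standing in for a steep Hodgkin-Huxley-style inactivation
    curve whose constants are not printed in the source network: while
    conducting, population spiking depletes h (``h *= 1 - d_spike`` per
    population-mean spike) until it drops below ``h_off``, which shuts the
    current; h then recovers linearly (tau_h ms to recover the full range)
    until it exceeds ``h_on``, re-arming it.  The floor ``m_floor``
    re-ignites spiking when the gate re-arms.  Defaults are calibrated so
    the isolated, self-excited population bursts near the eupneic period
    with vigorous intraburst rates.
    """
    g_nap: float = 0.9
    m_floor: float = 0.085
    a_m: float = 0.6
    tau_m: float = 100.0
    d_spike: float = 0.0029
    tau_h: float = 5800.0
    h_on: float = 0.95
    h_off: float = 0.35
    offswitch_rate: float = 24.0
    h_reset: float = 0.475
    E_na: float = 115.0


@dataclass
class NeuronState:
    """State of one integrate-and-fire neuron (potentials relative to rest).

    The threshold starts at the population resting threshold (filled in on
    the first :func:`step_neuron` call when left as None).
    """
    E: float = 0.0
    TH: float | None = None
    G_K: float = 0.0
    g: dict = field(default_factory=dict)   # synapse-type conductances
    q: dict = field(default_factory=dict)   # gating levels per gated type


def presynaptic_gate(q: float, gated_strength: float) -> float:
    """Effective strength of a gated synapse at gating level q in [0, 1]."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("gating level must lie in [0, 1]")
    return gated_strength * (1.0 - q)


def step_neuron(state: NeuronState, spec: PopulationSpec,
                synapses: list[SynapseSpec], deliveries: dict | None = None,
                dt_ms: float = DT_MS_DEFAULT, bias: float = 0.0,
                noise: float = 0.0, e_k: float = E_K_DEFAULT,
                ) -> tuple[NeuronState, bool]:
    """Advance a single neuron by one step; returns (new state, spiked).

    `deliveries` maps synapse-type name to the summed strength delivered
    this step (already gated where applicable).  `noise` is the additive
    membrane perturbation for the step (draw it as N(0, noise_amplitude)).
    This scalar path mirrors the vectorised engine exactly and is the
    reference for unit tests.
    """
    if deliveries is None:
        deliveries = {}
    if state.TH is None:
        state.TH = spec.TH0
    syn_by_name = {s.name: s for s in synapses}
    g = dict(state.g)
    q = dict(state.q)
    # Gating deliveries charge q; conducting deliveries add conductance.
    for name, w in deliveries.items():
        s = syn_by_name[name]
        if s.kind == "presynaptic":
            q0 = q.get(s.gates, 0.0)
            q[s.gates] = min(1.0, q0 + w * (1.0 - q0))
        else:
            scale = 1.0
            if any(p.gates == name for p in synapses):
                scale = 1.0 - q.get(name, 0.0)
            g[name] = g.get(name, 0.0) + w * scale
    # Decay conductances and gates.
    for name in list(g):
        g[name] *= math.exp(-dt_ms / syn_by_name[name].tau)
    for pre in synapses:
        if pre.kind == "presynaptic" and pre.gates in q:
            q[pre.gates] *= math.exp(-dt_ms / pre.tau)
    gtot = state.G_K
    ge = state.G_K * e_k
    for name, gs in g.items():
        if syn_by_name[name].kind != "presynaptic":
            gtot += gs
            ge += gs * syn_by_name[name].E_eq
    denom = 1.0 + gtot
    e_inf = (ge + spec.DC + bias) / denom
    e_new = e_inf + (state.E - e_inf) * math.exp(-denom * dt_ms / spec.TMEM)
    e_new += noise
    target = spec.TH0 + spec.C * e_new
    th_new = target + (state.TH - target) * math.exp(-dt_ms / spec.TTH)
    gk_new = state.G_K * math.exp(-dt_ms / spec.TGK)
    spiked = e_new >= th_new
    if spiked:
        gk_new += spec.B * dt_ms / spec.TGK
    if not (math.isfinite(e_new) and math.isfinite(th_new)):
        raise FloatingPointError("non-finite neuron state")
    return NeuronState(E=e_new, TH=th_new, G_K=gk_new, g=g, q=q), spiked


def expected_divergence(n_target: int, terminals: int) -> float:
    """Mean distinct targets per source for uniform draws with replacement."""
    return n_target * (1.0 - (1.0 - 1.0 / n_target) ** terminals)


def integrated_rate(counts: np.ndarray, window_ms: float = 60.0,
                    dt_ms: float = DT_MS_DEFAULT) -> np.ndarray:
    """Population spike counts summed over non-overlapping windows."""
    if window_ms <= 0:
        raise ValueError("window must be positive")
    per = max(1, int(round(window_ms / dt_ms)))
    n = (counts.shape[-1] // per) * per
    return counts[..., :n].reshape(*counts.shape[:-1], -1, per).sum(axis=-1)


def fiber_events(spec: FiberPopulationSpec, n_steps: int, seed: int) -> np.ndarray:
    """Bernoulli spike raster (n_fibers, n_steps) of a stimulus fiber bundle."""
    rng = np.random.default_rng(seed)
    return rng.random((spec.n_fibers, n_steps)) < spec.firing_probability


class Network:
    """A built network: flat state arrays plus the delivery machinery.

    Construction is deterministic in (specs, seed): thresholds are jittered
    uniformly in ``TH0 +/- TH0_variability`` and every projection places its
    terminals on uniformly drawn targets (with replacement) with independent
    uniform conduction delays rounded to the step grid (minimum one step).
    """

    def __init__(self, pops: list[PopulationSpec], syns: list[SynapseSpec],
                 projs: list[ProjectionSpec], seed: int,
                 dt_ms: float = DT_MS_DEFAULT,
                 burster: BursterParams = BursterParams(),
                 e_k: float = E_K_DEFAULT,
                 inhibitory_gain: float = INHIBITORY_GAIN_DEFAULT,
                 synapse_impulse_scaling: bool = False,
                 stimulus: FiberPopulationSpec = FiberPopulationSpec()):
        self.pops = list(pops)
        self.syns = list(syns)
        self.projs = list(projs)
        self.seed = seed
        self.dt_ms = dt_ms
        self.burster = burster
        self.e_k = e_k
        self.inhibitory_gain = inhibitory_gain
        self.synapse_impulse_scaling = synapse_impulse_scaling
        self.stimulus = stimulus
        self.pop_index = {p.name: i for i, p in enumerate(self.pops)}
        self.syn_index = {s.name: i for i, s in enumerate(self.syns)}
        for pr in projs:
            if pr.source not in self.pop_index or pr.target not in self.pop_index:
                raise KeyError(f"projection references unknown population: "
                               f"{pr.source}->{pr.target}")
            if pr.synapse not in self.syn_index:
                raise KeyError(f"unknown synapse type {pr.synapse!r}")
        self._build(seed)
        self.reset_state(seed)

    # -- construction ------------------------------------------------------
    def _build(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        pops, syns = self.pops, self.syns
        self.n_neurons = sum(p.N for p in pops)
        offs = np.cumsum([0] + [p.N for p in pops])
        self.pop_offset = offs
        n = self.n_neurons

        def per_neuron(getter, dtype=np.float64):
            out = np.empty(n, dtype=dtype)
            for i, p in enumerate(pops):
                out[offs[i]:offs[i + 1]] = getter(p)
            return out

        self.TH0 = per_neuron(lambda p: p.TH0)
        jitter = rng.uniform(-1.0, 1.0, n)
        self.TH0 = self.TH0 + jitter * per_neuron(lambda p: p.TH0_variability)
        self.tmem = per_neuron(lambda p: p.TMEM)
        # MacGregor discretisation: the first-order gating equations take
        # spike input as an impulse of area B (resp. strength), so the
        # per-step increment is B*dt/tau.
        self.b_spike = per_neuron(lambda p: p.B * self.dt_ms / p.TGK)
        self.egk = per_neuron(lambda p: math.exp(-self.dt_ms / p.TGK))
        self.c_adapt = per_neuron(lambda p: p.C)
        self.eth = per_neuron(lambda p: math.exp(-self.dt_ms / p.TTH))
        self.noise_sd = per_neuron(lambda p: p.noise_amplitude)
        self.dc = per_neuron(lambda p: p.DC)
        self.pop_of = per_neuron(lambda p: self.pop_index[p.name], dtype=np.int32)
        self.silenced = np.zeros(n, dtype=np.uint8)

        burst_pops = [i for i, p in enumerate(pops) if p.burster]
        if len(burst_pops) > 1:
            raise ValueError("at most one burster population is supported")
        if burst_pops:
            bi = burst_pops[0]
            self.burst_lo, self.burst_hi = int(offs[bi]), int(offs[bi + 1])
        else:
            self.burst_lo = self.burst_hi = 0
        bp = self.burster
        # kernel layout: [g_nap, a_m, m_floor, d_spike, tau_m, E_na, tau_h,
        # h_on, h_off, psr_cutoff, h_reset]
        self.bp_vec = np.array([bp.g_nap, bp.a_m, bp.m_floor, bp.d_spike,
                                bp.tau_m, bp.E_na, bp.tau_h, bp.h_on,
                                bp.h_off, bp.offswitch_rate, bp.h_reset])

        self.syn_eq = np.array([s.E_eq for s in syns])
        self.syn_decay = np.array([math.exp(-self.dt_ms / s.tau) for s in syns])
        self.syn_conducts = np.array([s.kind != "presynaptic" for s in syns],
                                     dtype=np.uint8)
        gated_names = [s.gates for s in syns if s.gates]
        self.gate_slot_of_syn = np.full(len(syns), -1, dtype=np.int64)
        self.pre_slot_of_syn = np.full(len(syns), -1, dtype=np.int64)
        q_decays = []
        for slot, gname in enumerate(gated_names):
            self.gate_slot_of_syn[self.syn_index[gname]] = slot
            pre = next(s for s in syns if s.gates == gname)
            self.pre_slot_of_syn[self.syn_index[pre.name]] = slot
            q_decays.append(math.exp(-self.dt_ms / pre.tau))
        self.q_decay = np.array(q_decays if q_decays else [1.0])
        self.n_gates = max(1, len(gated_names))

        # Terminals, grouped by source neuron (CSR).
        src_list, tgt_list, syn_list, del_list, w_list, pid_list = ([] for _ in range(6))
        for pid, pr in enumerate(self.projs):
            si = self.pop_index[pr.source]
            ti = self.pop_index[pr.target]
            ns, nt = pops[si].N, pops[ti].N
            T = pr.terminals
            tgts = rng.integers(0, nt, size=(ns, T)) + offs[ti]
            delays = rng.uniform(pr.conduction_min, pr.conduction_max, size=(ns, T))
            dsteps = np.maximum(1, np.rint(delays / self.dt_ms).astype(np.int64))
            srcs = np.repeat(np.arange(ns) + offs[si], T)
            src_list.append(srcs)
            tgt_list.append(tgts.ravel())
            syn_list.append(np.full(ns * T, self.syn_index[pr.synapse], dtype=np.int64))
            del_list.append(dsteps.ravel())
            syn = self.syns[self.syn_index[pr.synapse]]
            w = pr.strength
            if self.synapse_impulse_scaling:
                w *= self.dt_ms / syn.tau
            if syn.kind == "inhibitory":
                w *= self.inhibitory_gain
            w_list.append(np.full(ns * T, w))
            pid_list.append(np.full(ns * T, pid, dtype=np.int64))
        src = np.concatenate(src_list)
        # secondary sort by (delay, target) gives the scatter loop better
        # write locality within each source's terminal slice
        order = np.lexsort((np.concatenate(tgt_list),
                            np.concatenate(del_list), src))
        self.t_tgt = np.concatenate(tgt_list)[order].astype(np.int32)
        self.t_syn = np.concatenate(syn_list)[order].astype(np.int16)
        self.t_del = np.concatenate(del_list)[order].astype(np.int16)
        self.t_w = np.concatenate(w_list)[order]
        self.t_pid = np.concatenate(pid_list)[order].astype(np.int32)
        src_sorted = src[order]
        # zero-strength projections are kept in the spec list but place no
        # deliverable terminals
        live = self.t_w != 0.0
        self.t_tgt = self.t_tgt[live]
        self.t_syn = self.t_syn[live]
        self.t_del = self.t_del[live]
        self.t_pid = self.t_pid[live]
        self.t_w = self.t_w[live]
        src_sorted = src_sorted[live]
        self.t_ptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.t_ptr, src_sorted + 1, 1)
        self.t_ptr = np.cumsum(self.t_ptr)
        self.proj_scale = np.ones(len(self.projs))
        self.t_w_eff = self.t_w.copy()

        # Stimulus fiber terminals.
        st = self.stimulus
        ti = self.pop_index[st.target]
        tgts = rng.integers(0, pops[ti].N, size=(st.n_fibers, st.terminals)) + offs[ti]
        self.f_tgt = tgts.ravel().astype(np.int32)
        self.f_syn = np.full(st.n_fibers * st.terminals,
                             self.syn_index[st.synapse], dtype=np.int16)
        self.f_del = np.ones(st.n_fibers * st.terminals, dtype=np.int16)
        st_w = st.strength
        if self.synapse_impulse_scaling:
            st_w *= self.dt_ms / self.syns[self.syn_index[st.synapse]].tau
        self.f_w = np.full(st.n_fibers * st.terminals, st_w)
        self.f_ptr = np.arange(st.n_fibers + 1, dtype=np.int64) * st.terminals

        max_del = int(self.t_del.max()) if self.t_del.size else 1
        self.n_delay_slots = max_del + 2
        self.max_delay_steps = max_del

    # -- runtime state -----------------------------------------------------
    def reset_state(self, seed: int) -> None:
        n = self.n_neurons
        self.E = np.zeros(n)
        self.TH = self.TH0.copy()
        self.GK = np.zeros(n)
        # shared slow gates: h level, availability flag; m level
        self.h_state = np.ones(max(2, self.burst_hi - self.burst_lo))
        self.m_state = np.zeros(max(1, self.burst_hi - self.burst_lo))
        self.g = np.zeros((n, len(self.syns)))
        self.q = np.zeros((n, self.n_gates))
        self.buf = np.zeros((self.n_delay_slots, n, len(self.syns)),
                            dtype=np.float32)
        self.cur_ptr = np.zeros(1, dtype=np.int64)
        _kernels.seed_rng(seed % (2 ** 31 - 1))

    # -- helpers -----------------------------------------------------------
    def slice_of(self, name: str):
        i = self.pop_index[name]
        return int(self.pop_offset[i]), int(self.pop_offset[i + 1])

    def set_silenced(self, names: list[str], silenced: bool = True) -> None:
        for name in names:
            lo, hi = self.slice_of(name)
            self.silenced[lo:hi] = 1 if silenced else 0

    def scale_projections(self, predicate, factor: float) -> None:
        """Multiply the strength scale of every projection matching predicate."""
        hit = False
        for pid, pr in enumerate(self.projs):
            if predicate(pr):
                self.proj_scale[pid] = factor
                hit = True
        if not hit:
            raise KeyError("no projection matched the predicate")
        self._refresh_effective_weights()

    def reset_projection_scales(self) -> None:
        self.proj_scale[:] = 1.0
        self._refresh_effective_weights()

    def _refresh_effective_weights(self) -> None:
        self.t_w_eff = self.t_w * self.proj_scale[self.t_pid]

    def realized_divergence(self, source: str, target: str,
                            synapse: str | None = None) -> float:
        """Mean distinct targets per source neuron over a projection."""
        lo, hi = self.slice_of(source)
        tlo, thi = self.slice_of(target)
        pids = [i for i, pr in enumerate(self.projs)
                if pr.source == source and pr.target == target
                and (synapse is None or pr.synapse == synapse)]
        if not pids:
            raise KeyError("no such projection")
        counts = []
        for i in range(lo, hi):
            sl = slice(self.t_ptr[i], self.t_ptr[i + 1])
            mask = np.isin(self.t_pid[sl], pids)
            tg = self.t_tgt[sl][mask]
            counts.append(len(np.unique(tg)))
        return float(np.mean(counts))

    def realized_convergence(self, source: str, target: str) -> float:
        """Mean distinct sources per target neuron over a projection."""
        lo, hi = self.slice_of(source)
        pids = [i for i, pr in enumerate(self.projs)
                if pr.source == source and pr.target == target]
        pairs = set()
        for i in range(lo, hi):
            sl = slice(self.t_ptr[i], self.t_ptr[i + 1])
            mask = np.isin(self.t_pid[sl], pids)
            for t in np.unique(self.t_tgt[sl][mask]):
                pairs.add((i, int(t)))
        tlo, thi = self.slice_of(target)
        return len(pairs) / (thi - tlo)


def isolated_burster_trial(burster: BursterParams = BursterParams(),
                           bias_mv: float = 39.0, duration_s: float = 30.0,
                           seed: int = 0, dt_ms: float = DT_MS_DEFAULT,
                           pop: PopulationSpec | None = None) -> np.ndarray:
    """Population spike counts per step of the isolated self-excited I-Driver.

    The population keeps only its recurrent excitation; `bias_mv` stands in
    for the tonic pontine drive it receives in the full network.  Used to
    calibrate the conditional-bursting contract (rhythmic population bursts
    near the eupneic period).
    """
    from .tables import default_population_specs, default_projection_specs
    base = pop or next(p for p in default_population_specs() if p.burster)
    pop_ = replace(base, DC=bias_mv)
    projs = [p for p in default_projection_specs()
             if p.source == "I-Driver" and p.target == "I-Driver"]
    syns = default_synapse_specs()
    net = Network([pop_], syns, projs, seed=seed, dt_ms=dt_ms, burster=burster,
                  stimulus=FiberPopulationSpec(n_fibers=1, terminals=1,
                                               firing_probability=0.0,
                                               target="I-Driver"))
    from . import _kernels
    n_steps = int(round(duration_s / (dt_ms * 1e-3)))
    counts = np.zeros((1, n_steps), dtype=np.int32)
    mech_dummy = np.zeros((14, n_steps))
    rates = np.zeros((6, n_steps))
    # mechanics inputs are inert here: zero-size afferent slices, motor maps
    # point at the single population but drive nothing
    from .mechanics import MechanicsModel
    model = _DUMMY_MECH.setdefault("m", MechanicsModel())
    my = np.array([model.derived.V_di_RV - 0.3, model.derived.V_ab_FRC])
    warm = np.zeros(3)
    sm = np.zeros(6)
    motor_lo = np.zeros(6, dtype=np.int64)
    motor_hi = np.full(6, pop_.N, dtype=np.int64)
    _kernels.network_advance(
        n_steps, 0, dt_ms,
        net.E, net.TH, net.GK, net.TH0, net.tmem, net.b_spike, net.egk,
        net.c_adapt, net.eth, net.noise_sd, net.dc, net.silenced, net.pop_of,
        net.burst_lo, net.burst_hi, net.h_state, net.m_state, net.bp_vec,
        net.g, net.syn_eq, net.syn_decay, net.syn_conducts,
        net.gate_slot_of_syn, net.pre_slot_of_syn, net.q, net.q_decay,
        net.e_k,
        net.t_ptr, net.t_tgt, net.t_syn, net.t_del, net.t_w_eff,
        net.buf, net.cur_ptr,
        0, 0, 0, 0, 0, 0, False,
        0, 0,
        *model.kernel_args(), my, warm, 1,
        motor_lo, motor_hi, sm, 0.00833, 100.0, 80.0, 40.0, 40.0, 0.0, 0.0,
        False, 0.0, 0, net.f_ptr, net.f_tgt, net.f_syn, net.f_del, net.f_w,
        np.random.default_rng(seed).standard_normal(
            (n_steps, net.n_neurons), dtype=np.float32),
        counts, mech_dummy, rates)
    return counts[0]


_DUMMY_MECH: dict = {}


def build_network(pop_specs: list[PopulationSpec] | None = None,
                  syn_specs: list[SynapseSpec] | None = None,
                  proj_specs: list[ProjectionSpec] | None = None,
                  seed: int = 0, **kwargs) -> Network:
    """Build a network from the specification tables (defaults: published set)."""
    return Network(pop_specs or default_population_specs(),
                   syn_specs or default_synapse_specs(),
                   proj_specs or default_projection_specs(),
                   seed=seed, **kwargs)
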