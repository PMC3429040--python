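"""Reproducible, seeded experimental protocols over the coupled model.

Every protocol is a pure transformation of a :class:`ProtocolConfig`; a run
is fully determined by (config, seed).  The closed-loop co-simulation
advances the network at its own step (default 0.5 ms) with the mechanics
integrated in lock-step; motor activations are formed from smoothed motor
population rates and lung volume feeds back as afferent bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .coupling import AfferentMap, DriveMap
from .mechanics import MechanicsModel, MuscleActivations
from .network import BursterParams, Network, build_network, DT_MS_DEFAULT
from .tables import FiberPopulationSpec

__all__ = [
    "ProtocolConfig",
    "SimulationResult",
    "run_trial",
    "run_condition",
    "apply_vagotomy",
    "scale_phrenic_gain",
    "perturbation",
    "toggle_speculative_elements",
    "isolated_mech_cough",
    "MECH_ROWS",
]

MECH_ROWS = ["V_L", "flow", "P_alv", "P_pl", "V_di", "V_ab", "Vdot_di",
             "Vdot_ab", "u_di", "u_ab", "u_lm", "sigma_di", "sigma_ab",
             "pct_vc"]
MOTOR_POPS = ["Phrenic", "Phrenic-HT", "Lumbar", "Lumbar-HT", "ILM", "ELM"]
LUNG_AFFERENTS = ["PSR", "Def_1", "Dis_1"]
# Network elements regarded as speculative additions: the deflation- and
# distortion-receptor pathways and the presynaptic gating of the I-Aug ->
# I-Dec_2 excitation by tonic expiratory neurons.
SPECULATIVE_PROJECTIONS = [
    ("Def_1", "Def-2nd"), ("Def-2nd", "E-Dec-Phasic"), ("Pump-", "Def_1"),
    ("Dis_1", "ELM"), ("E-Dec-Tonic", "I-Dec_2"),
]


@dataclass(frozen=True)
class ProtocolConfig:
    """One experimental condition of the closed-loop model."""
    label: str = "baseline"
    duration: float = 60.0           # recorded duration after burn-in (s)
    burn_in: float = 10.0            # discarded settling time (s)
    seeds: tuple = (1, 2, 3, 4)      # one trial per seed
    stim_onset: float | None = None  # cough stimulus onset, s after burn-in
    stim_duration: float = 5.0       # stimulus window length (s)
    stimulus: FiberPopulationSpec = FiberPopulationSpec()
    gain_di: float = 1.0             # phrenic-to-diaphragm activation gain
    gain_ab: float = 1.0
    vagotomy: bool = False           # silence lung afferent populations
    speculative_off: bool = False    # remove speculative network elements
    perturbation: str | None = None  # 'A' | 'B' | 'C' (cough drive changes)
    drive: DriveMap = DriveMap()
    afferent: AfferentMap = AfferentMap()
    burster: BursterParams = BursterParams()
    dt_ms: float = DT_MS_DEFAULT
    mech_substeps: int = 1
    chunk_s: float = 0.5

    def __post_init__(self) -> None:
        if len(self.seeds) < 1:
            raise ValueError("at least one trial seed is required")
        if self.perturbation not in (None, "A", "B", "C"):
            raise ValueError("perturbation must be one of A, B, C")


@dataclass
class SimulationResult:
    """Time-stamped traces of one closed-loop trial (burn-in included)."""
    config: ProtocolConfig
    seed: int
    dt_ms: float
    pop_names: list
    counts: np.ndarray        # (n_pops, n_steps) spikes per step
    mech: np.ndarray          # (len(MECH_ROWS), n_steps)
    motor_rates: np.ndarray   # (6, n_steps) smoothed per-neuron rates
    burn_steps: int
    stim_window: tuple | None  # (start_step, end_step) or None

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.counts.shape[1]) * self.dt_ms * 1e-3

    def trace(self, name: str) -> np.ndarray:
        return self.mech[MECH_ROWS.index(name)]

    def pop_counts(self, name: str) -> np.ndarray:
        return self.counts[self.pop_names.index(name)]

    def flow_pct_vc(self, vc: float) -> np.ndarray:
        """Tracheal flow in %VC/s, expiration positive."""
        return self.trace("flow") * 100.0 / vc

    def to_frame(self, decimate: int = 120) -> pd.DataFrame:
        """Figure-style trace table (default sampling every 60 ms)."""
        sl = slice(None, None, decimate)
        cfg_vc = 100.0 / 5.370
        data = {"t_s": self.t[sl]}
        for name in MECH_ROWS:
            data[name] = self.trace(name)[sl]
        data["transpulmonary"] = (self.trace("P_alv") - self.trace("P_pl"))[sl]
        for i, name in enumerate(MOTOR_POPS):
            data[f"rate_{name}"] = self.motor_rates[i][sl]
        return pd.DataFrame(data)


# -- protocol transformations ---------------------------------------------

def apply_vagotomy(config: ProtocolConfig) -> ProtocolConfig:
    """Silence the lung afferent populations (PSR, Def_1, Dis_1)."""
    return replace(config, vagotomy=True, label=config.label + "+vagotomy")


def scale_phrenic_gain(config: ProtocolConfig, factor: float) -> ProtocolConfig:
    """Scale phrenic-to-diaphragm activation gain (pre-clip), all phases."""
    if factor not in (1, 2, 4):
        raise ValueError("gain factor must be 1, 2 or 4")
    label = config.label if factor == 1 else f"gain{factor}x"
    return replace(config, gain_di=float(factor), label=label)


def perturbation(config: ProtocolConfig, which: str) -> ProtocolConfig:
    """Cough inspiratory-drive perturbations applied during stimulation.

    A doubles the 2nd-order cough excitation of I-Aug and I-Aug-BS; B
    removes it; C additionally blocks I-Dec_2 inhibition of E-Dec-Tonic
    during the cough cycle.
    """
    if which not in ("A", "B", "C"):
        raise ValueError("perturbation must be A, B or C")
    return replace(config, perturbation=which, label=f"perturbation{which}")


def toggle_speculative_elements(config: ProtocolConfig, off: bool = True) -> ProtocolConfig:
    label = config.label + ("-nospec" if off else "")
    return replace(config, speculative_off=off, label=label)


# -- the closed-loop run ----------------------------------------------------

def _perturbation_scales(which: str | None):
    """(projection predicate, factor) pairs active during the cough window."""
    if which is None:
        return []
    cough_exc = lambda pr: (pr.source == "Cough-2nd"
                            and pr.target in ("I-Aug", "I-Aug-BS")
                            and pr.synapse == "ex_1")
    if which == "A":
        return [(cough_exc, 2.0)]
    if which == "B":
        return [(cough_exc, 0.0)]
    disinhib = lambda pr: (pr.source == "I-Dec_2" and pr.target == "E-Dec-Tonic")
    return [(cough_exc, 0.0), (disinhib, 0.0)]


def run_trial(config: ProtocolConfig, seed: int,
              mech_model: MechanicsModel | None = None,
              network: Network | None = None) -> SimulationResult:
    """Run one closed-loop trial; identical (config, seed) gives identical output."""
    model = mech_model or MechanicsModel()
    net = network or build_network(seed=seed, burster=config.burster,
                                   dt_ms=config.dt_ms,
                                   stimulus=config.stimulus)
    net.reset_state(seed)
    net.reset_projection_scales()
    net.silenced[:] = 0
    if config.vagotomy:
        net.set_silenced(LUNG_AFFERENTS)
    if config.speculative_off:
        for src, tgt in SPECULATIVE_PROJECTIONS:
            if (src, tgt) == ("E-Dec-Tonic", "I-Dec_2"):
                net.scale_projections(
                    lambda pr: pr.source == src and pr.target == tgt
                    and pr.synapse == "pre_ex_28", 0.0)
            else:
                net.scale_projections(
                    lambda pr, s=src, t=tgt: pr.source == s and pr.target == t, 0.0)
        net.set_silenced(["Def_1", "Dis_1"])

    dt_ms = config.dt_ms
    n_steps = int(round((config.burn_in + config.duration) / (dt_ms * 1e-3)))
    burn_steps = int(round(config.burn_in / (dt_ms * 1e-3)))
    stim_window = None
    if config.stim_onset is not None:
        s0 = burn_steps + int(round(config.stim_onset / (dt_ms * 1e-3)))
        s1 = s0 + int(round(config.stim_duration / (dt_ms * 1e-3)))
        stim_window = (s0, min(s1, n_steps))

    n_pops = len(net.pops)
    counts = np.zeros((n_pops, n_steps), dtype=np.int32)
    mech = np.zeros((len(MECH_ROWS), n_steps))
    rates = np.zeros((6, n_steps))

    eq = model.passive_equilibrium()
    my = np.array([eq.V_di, eq.V_ab])
    warm = np.zeros(3)
    sm_rates = np.zeros(6)
    motor_lo = np.array([net.pop_index[p] for p in MOTOR_POPS], dtype=np.int64)
    motor_hi = np.array([net.pops[net.pop_index[p]].N for p in MOTOR_POPS],
                        dtype=np.int64)
    psr = net.slice_of("PSR")
    d1 = net.slice_of("Def_1")
    s1_ = net.slice_of("Dis_1")
    off = net.slice_of("VRC-IE")
    dmap = config.drive
    rate_alpha = dt_ms / dmap.smoothing_ms

    chunk = max(1, int(round(config.chunk_s / (dt_ms * 1e-3))))
    pert = _perturbation_scales(config.perturbation)
    pert_active = False
    noise_rng = np.random.default_rng(seed)
    step = 0
    while step < n_steps:
        n = min(chunk, n_steps - step)
        noise = noise_rng.standard_normal((n, net.n_neurons),
                                          dtype=np.float32)
        stim_on = (stim_window is not None
                   and stim_window[0] <= step < stim_window[1])
        if pert and stim_window is not None:
            if stim_on and not pert_active:
                for pred, factor in pert:
                    net.scale_projections(pred, factor)
                pert_active = True
            elif not stim_on and pert_active:
                for pred, _ in pert:
                    net.scale_projections(pred, 1.0)
                pert_active = False
        _kernels.network_advance(
            n, step, dt_ms,
            net.E, net.TH, net.GK, net.TH0, net.tmem, net.b_spike, net.egk,
            net.c_adapt, net.eth, net.noise_sd, net.dc, net.silenced, net.pop_of,
            net.burst_lo, net.burst_hi, net.h_state, net.m_state, net.bp_vec,
            net.g, net.syn_eq, net.syn_decay, net.syn_conducts,
            net.gate_slot_of_syn, net.pre_slot_of_syn, net.q, net.q_decay,
            net.e_k,
            net.t_ptr, net.t_tgt, net.t_syn, net.t_del, net.t_w_eff,
            net.buf, net.cur_ptr,
            psr[0], psr[1], d1[0], d1[1], s1_[0], s1_[1], True,
            off[0], off[1],
            *model.kernel_args(), my, warm, config.mech_substeps,
            motor_lo, motor_hi, sm_rates, rate_alpha,
            dmap.X_phrenic, dmap.X_lumbar, dmap.X_ILM, dmap.X_ELM,
            config.gain_di, config.gain_ab,
            stim_on, config.stimulus.firing_probability,
            config.stimulus.n_fibers, net.f_ptr, net.f_tgt, net.f_syn,
            net.f_del, net.f_w, noise,
            counts[:, step:step + n], mech[:, step:step + n],
            rates[:, step:step + n],
        )
        step += n

    return SimulationResult(
        config=config, seed=seed, dt_ms=dt_ms,
        pop_names=[p.name for p in net.pops], counts=counts, mech=mech,
        motor_rates=rates, burn_steps=burn_steps, stim_window=stim_window)


def run_condition(config: ProtocolConfig,
                  mech_model: MechanicsModel | None = None
                  ) -> list[SimulationResult]:
    """Run all trials of a condition (one per seed)."""
    model = mech_model or MechanicsModel()
    return [run_trial(config, seed, mech_model=model) for seed in config.seeds]


# -- isolated-mechanics cough ----------------------------------------------

def isolated_mech_cough(operating_volumes: list[float],
                        target_p_ab: float = 26.5,
                        model: MechanicsModel | None = None,
                        control_dt: float = 0.005,
                        tol_frac: float = 0.01) -> pd.DataFrame:
    """Simulated coughs with the isolated (deterministic) mechanical model.

    For each requested operating volume (%VC): (i) servo diaphragm
    activation to inflate to the operating volume with the larynx open;
    (ii) close the larynx; (iii) servo abdominal activation until abdominal
    pressure reaches ``target_p_ab`` within ``tol_frac``; (iv) open the
    larynx and record the peak expiratory flow.  Returns one row per cough
    with the realised operating volume, abdominal pressure at opening and
    peak expiratory flow (%VC/s).
    """
    model = model or MechanicsModel()
    vc = model.free.VC
    rows = []
    for target_v in operating_volumes:
        state = model.passive_equilibrium()
        u_di, u_ab = 0.0, 0.0
        # (i) inflate with the larynx open
        ev = model.evaluate(state, MuscleActivations(0.0, 0.0, 0.5))
        for _ in range(int(30.0 / control_dt)):
            pct = model.percent_vc(ev.V_L)
            err = target_v - pct
            if abs(err) < 0.2 and abs(ev.flow) < 0.02:
                break
            u_di = min(1.0, max(0.0, u_di + 0.02 * err * control_dt * 10))
            state, ev = model.step(state, MuscleActivations(u_di, 0.0, 0.5),
                                   control_dt)
        else:
            raise RuntimeError(f"operating volume {target_v} %VC unreachable")
        operating = model.percent_vc(ev.V_L)
        # (ii) close the larynx; inspiratory activity off
        for _ in range(int(0.2 / control_dt)):
            state, ev = model.step(state, MuscleActivations(0.0, u_ab, -1.0),
                                   control_dt)
        # (iii) servo abdominal pressure
        reached = False
        for _ in range(int(20.0 / control_dt)):
            err = target_p_ab - ev.sigma_ab
            u_ab = min(1.0, max(0.0, u_ab + 0.02 * err * control_dt * 10))
            state, ev = model.step(state, MuscleActivations(0.0, u_ab, -1.0),
                                   control_dt)
            if abs(err) < tol_frac * target_p_ab and abs(ev.Vdot_ab) < 0.01:
                reached = True
                break
        if not reached:
            raise RuntimeError(
                f"abdominal pressure {target_p_ab} cmH2O unreachable at "
                f"{target_v} %VC")
        p_ab_close = ev.sigma_ab
        # (iv) open the larynx, record peak expiratory flow
        peak_flow = 0.0
        for _ in range(int(2.0 / control_dt)):
            state, ev = model.step(state, MuscleActivations(0.0, u_ab, 1.0),
                                   control_dt)
            peak_flow = max(peak_flow, ev.flow)
        rows.append({
            "target_volume_pct": target_v,
            "operating_volume_pct": operating,
            "p_ab_at_opening": p_ab_close,
            "peak_flow_pct_vc_s": peak_flow * 100.0 / vc,
        })
    return pd.DataFrame(rows)
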