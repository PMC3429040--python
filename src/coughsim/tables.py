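"""Tabular specification of the brainstem respiratory network.

Three tables define the network: integrate-and-fire population parameters,
synapse types, and the projection (connectivity) list.  The defaults below
are the published parameter set for the raphe-pontomedullary model of
breathing and cough; the I-Driver population additionally carries a slow
inward current giving it conditional bursting pacemaker properties (its
constants live in :class:`coughsim.network.BursterParams`, a behavioural
calibration).

Population naming: Aug/Dec = augmenting/decrementing firing envelope during
the inspiratory (I) or expiratory (E) phase; BS = bulbospinal (premotor);
Tonic = active across phases; HT = high threshold; ILM/ELM = inspiratory
(abductor) / expiratory (adductor) laryngeal motoneurons; PSR = pulmonary
stretch receptors; Def_1/Dis_1 = lung deflation / distortion receptors;
Pump+/- = second-order relay of PSR input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "PopulationSpec",
    "SynapseSpec",
    "ProjectionSpec",
    "FiberPopulationSpec",
    "default_population_specs",
    "default_synapse_specs",
    "default_projection_specs",
    "write_population_table",
    "write_synapse_table",
    "write_projection_table",
    "read_population_table",
    "read_synapse_table",
    "read_projection_table",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one integrate-and-fire population."""
    name: str
    N: int
    TH0: float            # resting threshold (mV above rest)
    TH0_variability: float  # half-width of uniform threshold jitter (mV)
    TMEM: float           # membrane time constant (ms)
    B: float              # post-spike increment of the K+ conductance
    TGK: float            # K+ conductance decay time constant (ms)
    C: float              # threshold-adaptation coupling to membrane potential
    TTH: float            # threshold adaptation time constant (ms)
    noise_amplitude: float  # per-step SD of additive membrane noise (mV)
    DC: float             # constant depolarising bias (mV)
    burster: bool = False  # carries the slow inward pacemaker current

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size must be >= 1")
        if min(self.TMEM, self.TGK, self.TTH) <= 0:
            raise ValueError("time constants must be positive")
        if min(self.B, self.C, self.noise_amplitude) < 0:
            raise ValueError("B, C and noise amplitude must be non-negative")


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse type: reversal potential, kinetics, optional gating role."""
    name: str
    kind: str             # 'excitatory' | 'inhibitory' | 'presynaptic'
    E_eq: float           # equilibrium potential (mV relative to rest)
    tau: float            # conductance decay time constant (ms)
    gates: str | None = None  # for presynaptic types: name of the gated type

    def __post_init__(self) -> None:
        if self.kind == "excitatory" and self.E_eq <= 0:
            raise ValueError("excitatory synapse must have E_eq > 0")
        if self.kind == "inhibitory" and self.E_eq > 0:
            raise ValueError("inhibitory synapse must have E_eq <= 0")


@dataclass(frozen=True)
class ProjectionSpec:
    """One projection: every source neuron places `terminals` terminals on
    uniformly drawn target neurons (with replacement), each with an
    independent uniform conduction delay in [conduction_min, conduction_max] ms."""
    source: str
    target: str
    synapse: str
    conduction_min: float
    conduction_max: float
    terminals: int
    strength: float

    def __post_init__(self) -> None:
        if not 0 <= self.conduction_min <= self.conduction_max:
            raise ValueError("conduction times must satisfy 0 <= min <= max")
        if self.terminals < 1:
            raise ValueError("terminals must be >= 1")


@dataclass(frozen=True)
class FiberPopulationSpec:
    """Afferent fiber bundle firing as independent Bernoulli(p) per step."""
    n_fibers: int = 100
    firing_probability: float = 0.05  # per fiber per simulation step
    terminals: int = 100
    synapse: str = "ex_1"
    strength: float = 0.03
    target: str = "Cough-2nd"

    def __post_init__(self) -> None:
        if not 0.0 <= self.firing_probability <= 1.0:
            raise ValueError("firing probability must lie in [0, 1]")


# --------------------------------------------------------------------------
# Published parameter tables.
# Population columns: name, N, TH0, THO variability, TMEM, B, TGK, C, TTH,
# noise amplitude, DC.
_POPULATIONS = [
    ("I-pons",          100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.03, 2.0),
    ("rostral-IE-pons", 100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.3, 5.0),
    ("caudal-IE-pons",  100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.3, 5.0),
    ("E-pons",          100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.3, 13.0),
    ("EI-pons",         100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.3, 20.0),
    ("NRM-pons",        100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.03, 25.0),
    ("NRM-BotC",        300, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.03, 25.0),
    # I-Driver: threshold/membrane row is a behavioural calibration (the
    # published set defers these to an external appendix); the slow-current
    # constants live in network.BursterParams.
    ("I-Driver",        300, 38.0, 0.5, 25.0, 10.0, 7.0, 0.0, 500.0, 0.1, 0.0),
    ("I-Dec",           300, 10.0, 1.0, 6.0, 75.0, 8.5, 0.9, 1500.0, 0.2, 20.0),
    ("I-Dec_2",         300, 10.0, 1.0, 6.0, 75.0, 8.5, 0.8, 1200.0, 0.2, 5.0),
    ("I-Aug",           300, 12.0, 3.0, 6.0, 75.0, 5.0, 0.0, 5000.0, 0.6, 18.0),
    ("VRC-IE",           99, 18.0, 2.0, 9.0, 50.0, 5.0, 0.0, 1000.0, 0.075, 0.0),
    ("E-Dec-Phasic",    300,  9.0, 1.0, 6.0, 75.0, 8.5, 0.9, 1500.0, 0.1, 4.0),
    ("E-Dec-Tonic",     300,  8.0, 1.0, 9.0, 50.0, 3.8, 0.8, 2000.0, 0.3, 0.0),
    ("E-Aug-early",     300, 10.0, 1.0, 6.0, 27.0, 2.5, 0.0, 500.0, 0.3, 30.0),
    ("E-Aug-late",      300, 10.0, 1.0, 9.0, 27.0, 2.5, 0.0, 500.0, 0.1, 27.0),
    ("E-Aug-Cough",     300, 12.0, 2.0, 9.0, 75.0, 7.5, 0.0, 500.0, 0.2, 0.0),
    ("E-Aug+",          300, 10.0, 2.0, 6.0, 75.0, 7.5, 0.1, 1000.0, 0.5, 20.0),
    ("E-Aug-BS",        300, 12.0, 3.0, 6.0, 100.0, 6.0, 0.1, 1000.0, 0.5, 0.0),
    ("Pump+",           300,  5.0, 0.5, 6.0, 25.0, 3.8, 0.08, 500.0, 0.1, 0.0),
    ("Pump-",           300,  5.0, 0.0, 6.0, 25.0, 3.8, 0.08, 500.0, 0.1, 0.0),
    ("I-Aug-BS",        300, 12.0, 3.0, 6.0, 75.0, 5.0, 0.0, 5000.0, 0.5, 0.0),
    ("Phrenic",         210, 10.0, 2.0, 5.0, 200.0, 6.0, 0.08, 500.0, 0.5, 0.0),
    ("Phrenic-HT",       70, 16.0, 2.0, 60.0, 200.0, 5.0, 0.08, 500.0, 0.5, 0.0),
    ("Lumbar",          210, 15.0, 2.0, 6.0, 75.0, 7.5, 0.08, 500.0, 0.5, 0.0),
    ("Lumbar-HT",        70, 18.0, 2.0, 30.0, 200.0, 7.5, 0.1, 500.0, 0.5, 0.0),
    ("ILM",             300, 20.0, 1.0, 6.0, 25.0, 3.8, 0.08, 500.0, 0.1, 2.0),
    ("E-Dec-pre-ELM",   300, 11.0, 0.0, 6.0, 100.0, 6.0, 0.8, 500.0, 0.5, 1.0),
    ("ELM",             300, 18.0, 2.0, 6.0, 100.0, 6.0, 0.9, 100.0, 0.5, 0.0),
    ("PSR",             300, 11.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.5, 0.0),
    ("Def_1",           300, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.5, 0.0),
    ("Dis_1",           300, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.5, 0.0),
    ("Cough-2nd",       100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.3, 500.0, 0.1, 0.0),
    ("Def-2nd",         300,  8.0, 1.0, 9.0, 27.0, 2.5, 0.5, 1000.0, 0.3, 0.0),
    ("Raphe-8",         100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.01, 0.0),
    ("Raphe-28",        100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.1, 0.0),
    ("Raphe-29",        100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.5, 0.0),
    ("Raphe-30",        100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.5, 0.0),
    ("Raphe-31",        100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.1, 10.0),
    ("Raphe-32",        100, 10.0, 1.0, 9.0, 20.0, 7.0, 0.0, 500.0, 0.1, 10.0),
]

# Synapse columns: name, kind, equilibrium potential, time constant, gates.
_SYNAPSES = [
    ("ex_1",      "excitatory",  115.0, 1.5, None),
    ("inh_4",     "inhibitory",  -25.0, 1.5, None),
    ("inh_7",     "inhibitory",  -25.0, 2.0, None),
    ("inh_10",    "inhibitory",  -25.0, 1.5, None),
    ("ex_13",     "excitatory",  115.0, 1.5, None),
    ("pre_ex_13", "presynaptic",   0.0, 1.5, "ex_13"),
    ("ex_19",     "excitatory",  115.0, 5.0, None),
    ("inh_22",    "inhibitory",  -25.0, 5.0, None),
    ("inh_25",    "inhibitory",  -25.0, 4.5, None),
    ("ex_28",     "excitatory",  115.0, 1.5, None),
    ("pre_ex_28", "presynaptic", -25.0, 3.5, "ex_28"),
]

# Projection columns: source, target, synapse, conduction min/max (ms),
# terminals per source neuron, synaptic strength.
_PROJECTIONS = [
    ("I-Driver", "I-Dec", "ex_1", 2, 6, 100, 0.006),
    ("I-Driver", "I-Aug", "ex_1", 2, 6, 100, 0.01),
    ("I-Driver", "I-Driver", "ex_1", 0, 4, 50, 0.003),
    ("E-Dec-Phasic", "I-Driver", "inh_22", 2, 6, 50, 0.03),
    ("E-Dec-Phasic", "E-Aug-early", "inh_4", 0, 2, 150, 0.012),
    ("E-Dec-Phasic", "E-Aug-late", "inh_4", 2, 4, 150, 0.04),
    ("E-Dec-Phasic", "VRC-IE", "inh_4", 0, 2, 50, 0.1),
    ("E-Dec-Phasic", "I-Dec", "inh_4", 0, 2, 200, 0.2),
    ("E-Dec-Phasic", "I-Aug-BS", "inh_4", 2, 6, 100, 0.15),
    ("E-Dec-Phasic", "I-Aug", "inh_4", 2, 6, 50, 0.1),
    ("E-Dec-Phasic", "rostral-IE-pons", "ex_13", 2, 4, 100, 0.001),
    ("E-Dec-Phasic", "caudal-IE-pons", "ex_13", 2, 4, 100, 0.001),
    ("E-Dec-Phasic", "I-Dec_2", "inh_4", 2, 6, 150, 0.1),
    ("E-Dec-Phasic", "E-Aug+", "inh_4", 2, 6, 100, 0.03),
    ("E-Dec-Phasic", "E-Aug-Cough", "inh_22", 2, 6, 100, 0.025),
    ("I-Dec", "E-Aug-early", "inh_7", 2, 6, 115, 0.5),
    ("I-Dec", "E-Dec-Phasic", "inh_25", 2, 6, 200, 0.2),
    ("I-Dec", "I-Aug", "inh_25", 2, 6, 120, 0.025),
    ("I-Dec", "E-Aug-late", "inh_7", 2, 6, 115, 0.5),
    ("I-Dec", "VRC-IE", "inh_25", 0, 4, 33, 0.025),
    ("I-Dec", "E-Dec-Tonic", "inh_25", 2, 6, 100, 0.001),
    ("I-Dec", "ILM", "ex_1", 0, 3, 50, 0.002),
    ("I-Dec", "E-Aug-BS", "inh_7", 0, 4, 100, 0.05),
    ("I-Dec", "EI-pons", "ex_13", 2, 4, 100, 0.001),
    ("I-Dec", "I-pons", "ex_13", 2, 4, 100, 0.0005),
    ("I-Dec", "I-pons", "inh_7", 2, 4, 100, 0.0005),
    ("I-Dec", "rostral-IE-pons", "inh_4", 2, 4, 100, 0.0001),
    ("I-Dec", "caudal-IE-pons", "inh_7", 2, 4, 100, 0.0001),
    ("I-Dec", "Lumbar", "inh_7", 0, 4, 100, 0.1),
    ("I-Dec", "E-Dec-pre-ELM", "inh_4", 2, 6, 200, 0.06),
    ("I-Dec", "E-Aug+", "inh_4", 0, 2, 130, 1.0),
    ("I-Dec", "ELM", "inh_4", 0, 5, 200, 0.06),
    ("I-Dec", "Lumbar-HT", "inh_7", 2, 6, 100, 0.1),
    ("I-Dec", "I-Dec", "inh_25", 2, 6, 140, 0.0125),
    ("I-Dec", "E-Aug-Cough", "inh_7", 2, 6, 115, 0.16),
    ("I-Aug", "I-Aug", "ex_1", 0, 5, 50, 0.025),
    ("I-Aug", "caudal-IE-pons", "inh_7", 2, 4, 100, 0.0001),
    ("I-Aug", "I-Aug-BS", "ex_1", 2, 6, 100, 0.06),
    ("I-Aug", "ILM", "ex_1", 2, 6, 70, 0.035),
    ("I-Aug", "VRC-IE", "ex_1", 2, 6, 16, 0.0015),
    ("I-Aug", "I-pons", "ex_13", 2, 4, 100, 0.0025),
    ("I-Aug", "rostral-IE-pons", "inh_4", 2, 4, 100, 0.0001),
    ("I-Aug", "I-Dec_2", "ex_28", 2, 6, 200, 0.01),
    ("E-Aug-early", "E-Dec-Phasic", "inh_4", 2, 6, 110, 0.007),
    ("E-Aug-early", "I-Dec", "inh_4", 0, 5, 100, 0.06),
    ("E-Aug-early", "I-Aug", "inh_4", 2, 6, 100, 0.135),
    ("E-Aug-early", "VRC-IE", "inh_4", 0, 2, 24, 0.05),
    ("E-Aug-early", "I-Aug-BS", "inh_4", 0, 2, 150, 0.001),
    ("E-Aug-early", "E-Aug-late", "inh_10", 0, 2, 50, 0.001),
    ("E-Aug-early", "E-pons", "ex_13", 2, 4, 100, 0.002),
    ("E-Aug-early", "I-pons", "inh_7", 2, 4, 100, 0.0005),
    ("E-Aug-early", "I-Dec_2", "inh_4", 2, 6, 150, 0.08),
    ("E-Aug-early", "Phrenic", "inh_4", 0, 2, 150, 0.001),
    ("E-Aug-early", "Phrenic-HT", "inh_4", 0, 2, 150, 0.001),
    ("E-Aug-early", "ELM", "inh_4", 2, 6, 175, 0.007),
    ("E-Aug-late", "E-Aug-early", "inh_10", 0, 2, 200, 0.04),
    ("E-Aug-late", "I-Dec", "inh_4", 2, 6, 55, 0.2),
    ("E-Aug-late", "I-Aug", "inh_4", 2, 6, 100, 0.1),
    ("E-Aug-late", "E-Dec-Phasic", "inh_4", 2, 6, 120, 0.015),
    ("E-Aug-late", "I-Aug-BS", "inh_4", 2, 6, 150, 0.06),
    ("E-Aug-late", "VRC-IE", "inh_4", 0, 2, 24, 0.02),
    ("E-Aug-late", "E-Dec-Tonic", "inh_4", 0, 2, 100, 0.05),
    ("E-Aug-late", "E-Dec-pre-ELM", "inh_22", 2, 6, 115, 0.05),
    ("E-Aug-late", "ELM", "inh_7", 2, 6, 200, 0.1),
    ("E-Aug-late", "I-Dec_2", "inh_4", 2, 6, 150, 0.075),
    ("E-Aug-late", "Phrenic", "inh_4", 4, 8, 150, 0.06),
    ("E-Aug-late", "Phrenic-HT", "inh_4", 0, 2, 150, 0.06),
    ("E-Aug-late", "ILM", "inh_4", 0, 2, 115, 0.04),
    ("VRC-IE", "I-Dec", "inh_7", 0, 4, 200, 0.035),
    ("Raphe-8", "Raphe-29", "ex_1", 0, 3, 50, 0.0125),
    ("Raphe-28", "Raphe-30", "ex_1", 0, 3, 50, 0.0125),
    ("I-Aug-BS", "Phrenic-HT", "ex_1", 3, 6, 18, 0.05),
    ("I-Aug-BS", "Phrenic", "ex_1", 3, 6, 50, 0.05),
    ("NRM-BotC", "rostral-IE-pons", "inh_7", 0, 1, 100, 0.002),
    ("NRM-BotC", "caudal-IE-pons", "inh_7", 0, 1, 100, 0.002),
    ("NRM-BotC", "I-pons", "ex_13", 0, 1, 100, 0.002),
    ("E-Aug-Cough", "E-Aug+", "inh_22", 2, 6, 100, 0.05),
    ("E-Aug-Cough", "E-Aug-BS", "inh_22", 2, 6, 100, 0.5),
    ("E-Aug-Cough", "I-Dec_2", "inh_22", 0, 3, 200, 0.05),
    ("E-Aug-Cough", "E-Dec-pre-ELM", "inh_4", 2, 6, 100, 0.1),
    ("E-Aug-Cough", "I-Aug-BS", "inh_4", 0, 3, 200, 0.025),
    ("E-Aug-Cough", "ILM", "inh_4", 0, 3, 200, 0.025),
    ("PSR", "Pump+", "ex_1", 0, 3, 75, 0.015),
    ("PSR", "Pump-", "ex_1", 0, 3, 50, 0.015),
    ("caudal-IE-pons", "I-Driver", "ex_1", 0, 5, 100, 0.001),
    ("Pump-", "E-pons", "pre_ex_13", 0, 4, 100, 0.99),
    ("Pump-", "I-Dec_2", "inh_4", 0, 2, 25, 0.0035),
    ("Pump-", "I-Dec", "inh_4", 0, 2, 25, 0.0035),
    ("Pump-", "I-pons", "pre_ex_13", 0, 4, 100, 0.99),
    ("Pump-", "EI-pons", "pre_ex_13", 2, 4, 100, 0.99),
    ("Pump-", "Def_1", "inh_4", 0, 4, 100, 0.02),
    ("Pump-", "rostral-IE-pons", "pre_ex_13", 0, 4, 100, 0.99),
    ("Pump-", "caudal-IE-pons", "pre_ex_13", 0, 4, 100, 0.99),
    ("Pump+", "E-Dec-Phasic", "ex_1", 0, 2, 100, 0.01),
    ("Pump+", "VRC-IE", "ex_1", 2, 6, 100, 0.01),
    ("Pump+", "I-Aug", "ex_1", 0, 2, 25, 0.0),
    ("Pump+", "E-Dec-Tonic", "ex_1", 0, 2, 100, 0.002),
    ("Pump+", "I-Dec_2", "ex_1", 2, 6, 100, 0.005),
    ("E-Dec-Tonic", "Raphe-29", "inh_4", 0, 3, 100, 0.001),
    ("E-Dec-Tonic", "I-Aug-BS", "inh_4", 2, 6, 100, 0.03),
    ("E-Dec-Tonic", "rostral-IE-pons", "ex_13", 2, 4, 100, 0.001),
    ("E-Dec-Tonic", "I-pons", "ex_13", 2, 4, 100, 0.0005),
    ("E-Dec-Tonic", "I-pons", "inh_7", 2, 4, 100, 0.0005),
    ("E-Dec-Tonic", "rostral-IE-pons", "inh_4", 2, 4, 100, 0.0005),
    ("E-Dec-Tonic", "caudal-IE-pons", "ex_13", 2, 4, 100, 0.001),
    ("E-Dec-Tonic", "caudal-IE-pons", "inh_7", 2, 4, 100, 0.0005),
    ("E-Dec-Tonic", "ELM", "inh_4", 0, 4, 100, 0.04),
    ("E-Dec-Tonic", "I-Aug", "inh_4", 2, 6, 100, 0.0075),
    ("E-Dec-Tonic", "I-Dec_2", "pre_ex_28", 2, 6, 100, 0.2),
    ("rostral-IE-pons", "EI-pons", "inh_4", 2, 4, 100, 0.03),
    ("rostral-IE-pons", "VRC-IE", "ex_1", 0, 1, 100, 0.001),
    ("rostral-IE-pons", "E-Dec-Phasic", "ex_1", 0, 5, 100, 0.02),
    ("EI-pons", "rostral-IE-pons", "ex_1", 2, 4, 100, 0.002),
    ("EI-pons", "caudal-IE-pons", "ex_1", 2, 4, 100, 0.002),
    ("EI-pons", "VRC-IE", "ex_1", 0, 4, 50, 0.0003),
    ("EI-pons", "E-Dec-Tonic", "ex_1", 0, 4, 100, 0.01),
    ("E-Dec-pre-ELM", "ELM", "ex_19", 2, 6, 250, 0.0125),
    ("Def-2nd", "E-Dec-Phasic", "inh_4", 2, 6, 100, 0.04),
    ("E-Aug+", "E-Aug-BS", "ex_19", 2, 6, 100, 0.02),
    ("Raphe-8", "Raphe-31", "inh_4", 0, 3, 50, 0.005),
    ("Raphe-8", "Raphe-32", "inh_4", 0, 3, 50, 0.005),
    ("Raphe-8", "E-Aug-BS", "inh_22", 0, 3, 400, 0.0),
    ("Raphe-29", "Raphe-30", "ex_1", 0, 3, 50, 0.01),
    ("Raphe-29", "E-Dec-Tonic", "ex_19", 0, 3, 100, 0.15),
    ("Raphe-29", "E-Dec-Phasic", "ex_19", 0, 3, 100, 0.2),
    ("Raphe-30", "Raphe-29", "inh_4", 0, 3, 50, 0.01),
    ("Raphe-32", "Raphe-31", "inh_4", 0, 3, 50, 0.005),
    ("Raphe-32", "E-Dec-Tonic", "inh_22", 0, 3, 100, 0.01),
    ("Raphe-32", "E-Dec-Phasic", "inh_22", 0, 3, 100, 0.01),
    ("Raphe-32", "E-Dec-pre-ELM", "inh_22", 0, 3, 100, 0.01),
    ("Cough-2nd", "I-Aug-BS", "ex_1", 2, 6, 100, 0.02),
    ("Cough-2nd", "I-Aug", "ex_1", 2, 6, 100, 0.0045),
    ("Cough-2nd", "I-Dec", "ex_1", 2, 6, 100, 0.0045),
    ("Cough-2nd", "I-Dec_2", "ex_1", 2, 6, 100, 0.05),
    ("Cough-2nd", "E-Aug-late", "ex_1", 2, 6, 100, 0.005),
    ("Cough-2nd", "E-Aug-early", "ex_1", 0, 3, 100, 0.01),
    ("Cough-2nd", "VRC-IE", "inh_4", 0, 3, 100, 0.2),
    ("Cough-2nd", "caudal-IE-pons", "ex_1", 0, 3, 100, 0.001),
    ("Cough-2nd", "rostral-IE-pons", "ex_1", 0, 3, 100, 0.001),
    ("Cough-2nd", "I-pons", "ex_1", 0, 3, 100, 0.001),
    ("Cough-2nd", "E-pons", "ex_1", 2, 6, 100, 0.001),
    ("Cough-2nd", "EI-pons", "ex_1", 0, 3, 100, 0.001),
    ("Cough-2nd", "E-Dec-pre-ELM", "ex_19", 2, 6, 100, 0.004),
    ("Cough-2nd", "E-Aug+", "ex_1", 2, 6, 100, 0.05),
    ("Cough-2nd", "E-Aug-Cough", "ex_1", 2, 6, 100, 0.04),
    ("Cough-2nd", "ILM", "ex_1", 2, 6, 100, 0.001),
    ("E-pons", "rostral-IE-pons", "inh_4", 2, 4, 100, 0.0001),
    ("E-pons", "caudal-IE-pons", "inh_4", 2, 4, 100, 0.0001),
    ("E-pons", "I-Dec", "inh_4", 0, 1, 100, 0.008),
    ("NRM-pons", "I-pons", "ex_1", 0, 4, 100, 0.015),
    ("NRM-pons", "I-pons", "inh_4", 0, 4, 100, 0.05),
    ("NRM-pons", "I-Driver", "ex_1", 2, 6, 100, 0.11),
    ("NRM-pons", "VRC-IE", "ex_1", 0, 1, 100, 0.01),
    ("NRM-pons", "I-Aug", "ex_1", 0, 1, 100, 0.01),
    ("NRM-pons", "E-Aug-early", "ex_1", 0, 4, 100, 0.025),
    ("NRM-pons", "E-Aug-late", "ex_1", 0, 4, 50, 0.003),
    ("NRM-pons", "E-Dec-Phasic", "ex_1", 0, 1, 100, 0.01),
    ("NRM-pons", "E-Dec-Tonic", "ex_1", 0, 1, 100, 0.1),
    ("NRM-pons", "NRM-BotC", "inh_4", 0, 1, 100, 0.001),
    ("E-Aug-BS", "Lumbar", "ex_1", 6, 10, 25, 0.03),
    ("E-Aug-BS", "Lumbar-HT", "ex_1", 3, 6, 10, 0.05),
    ("I-pons", "rostral-IE-pons", "ex_1", 0, 4, 100, 0.005),
    ("I-pons", "VRC-IE", "ex_1", 0, 5, 100, 0.005),
    ("I-pons", "I-Aug", "ex_1", 0, 4, 50, 0.005),
    ("I-pons", "caudal-IE-pons", "ex_1", 0, 4, 100, 0.005),
    ("I-Dec_2", "E-Dec-Tonic", "inh_4", 2, 6, 125, 0.1),
    ("I-Dec_2", "E-Dec-pre-ELM", "inh_4", 2, 6, 100, 0.01),
    ("I-Dec_2", "E-Aug-BS", "inh_4", 2, 6, 50, 0.00005),
    ("I-Dec_2", "ELM", "inh_4", 2, 6, 100, 0.02),
    ("I-Dec_2", "E-Aug+", "inh_4", 2, 6, 100, 0.02),
    ("Def_1", "Def-2nd", "ex_1", 0, 3, 35, 0.03),
    ("Dis_1", "ELM", "ex_1", 0, 3, 100, 0.09),
]


def default_population_specs() -> list[PopulationSpec]:
    specs = []
    for row in _POPULATIONS:
        specs.append(PopulationSpec(
            name=row[0], N=row[1], TH0=row[2], TH0_variability=row[3],
            TMEM=row[4], B=row[5], TGK=row[6], C=row[7], TTH=row[8],
            noise_amplitude=row[9], DC=row[10], burster=(row[0] == "I-Driver")))
    return specs


def default_synapse_specs() -> list[SynapseSpec]:
    return [SynapseSpec(name=n, kind=k, E_eq=e, tau=t, gates=g)
            for n, k, e, t, g in _SYNAPSES]


def default_projection_specs() -> list[ProjectionSpec]:
    return [ProjectionSpec(source=s, target=t, synapse=y, conduction_min=a,
                           conduction_max=b, terminals=T, strength=w)
            for s, t, y, a, b, T, w in _PROJECTIONS]


# --------------------------------------------------------------------------
# Delimited-text round trip.

_POP_HEADER = ("Population name\tSize\tResting threshold (mV)\t"
               "THO variability (mV)\tMembrane time constant\t"
               "Post-spike increase in G_K+\tPost-spike G_K+ time constant (ms)\t"
               "Adaptation threshold increase\tAdaptation (ms)\tNoise amplitude\tDC (mV)")
_SYN_HEADER = ("Synapse name\tSynapse type\tSynapse equilibrium potential (mV)\t"
               "Synapse time constant (ms)")
_PROJ_HEADER = ("Source population\tTarget population\tSynaptic type\t"
                "Conduction time min\tConduction time max\tNo. of terminals\t"
                "Synaptic strength")


def write_population_table(specs: list[PopulationSpec], path: str | Path) -> None:
    lines = [_POP_HEADER]
    for s in specs:
        lines.append("\t".join(str(v) for v in (
            s.name, s.N, s.TH0, s.TH0_variability, s.TMEM, s.B, s.TGK,
            s.C, s.TTH, s.noise_amplitude, s.DC)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_population_table(path: str | Path) -> list[PopulationSpec]:
    specs = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        specs.append(PopulationSpec(
            name=f[0], N=int(f[1]), TH0=float(f[2]), TH0_variability=float(f[3]),
            TMEM=float(f[4]), B=float(f[5]), TGK=float(f[6]), C=float(f[7]),
            TTH=float(f[8]), noise_amplitude=float(f[9]), DC=float(f[10]),
            burster=(f[0] == "I-Driver")))
    return specs


def write_synapse_table(specs: list[SynapseSpec], path: str | Path) -> None:
    lines = [_SYN_HEADER]
    for s in specs:
        kind = s.kind if s.gates is None else f"{s.kind}:{s.gates}"
        lines.append(f"{s.name}\t{kind}\t{s.E_eq}\t{s.tau}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_synapse_table(path: str | Path) -> list[SynapseSpec]:
    specs = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, kind, eq, tau = line.split("\t")
        gates = None
        if ":" in kind:
            kind, gates = kind.split(":")
        specs.append(SynapseSpec(name=name, kind=kind, E_eq=float(eq),
                                 tau=float(tau), gates=gates))
    return specs


def write_projection_table(specs: list[ProjectionSpec], path: str | Path) -> None:
    lines = [_PROJ_HEADER]
    for s in specs:
        lines.append("\t".join(str(v) for v in (
            s.source, s.target, s.synapse, s.conduction_min, s.conduction_max,
            s.terminals, s.strength)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_projection_table(path: str | Path) -> list[ProjectionSpec]:
    specs = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        specs.append(ProjectionSpec(
            source=f[0], target=f[1], synapse=f[2], conduction_min=float(f[3]),
            conduction_max=float(f[4]), terminals=int(f[5]), strength=float(f[6])))
    return specs
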