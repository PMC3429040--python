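"""Bidirectional coupling between the network and the mechanics.

Motor-population firing rates are smoothed and mapped to the three muscle
activations; lung volume (in %VC relative to residual volume) is mapped to
additive membrane bias currents for the three lung-afferent populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DerivedParameters, FreeParameters

__all__ = [
    "DriveMap",
    "AfferentMap",
    "percent_vc",
    "diaphragm_activation",
    "abdominal_activation",
    "laryngeal_activation",
    "afferent_bias",
    "RateSmoother",
]


@dataclass(frozen=True)
class DriveMap:
    """Firing-rate normalisation for motor outputs.

    ``X_phrenic`` is the per-neuron rate giving full diaphragm activation
    (published admissible range 50-200 spikes/s); ``X_lumbar`` is fixed at
    80 spikes/s.  The low/high-threshold motor pools are combined with
    weights 0.3/0.7.  The laryngeal normalisations are calibrations chosen
    so that eupneic expiratory adduction narrows but never closes the
    airway, while cough-level adductor firing closes it fully.
    """
    X_phrenic: float = 130.0
    X_lumbar: float = 80.0
    w_low: float = 0.3
    w_high: float = 0.7
    X_ILM: float = 40.0
    X_ELM: float = 25.0
    smoothing_ms: float = 60.0

    def __post_init__(self) -> None:
        if min(self.X_phrenic, self.X_lumbar, self.X_ILM, self.X_ELM) <= 0:
            raise ValueError("rate normalisations must be positive")
        if abs(self.w_low + self.w_high - 1.0) > 1e-12:
            raise ValueError("pool weights must sum to 1")


@dataclass(frozen=True)
class AfferentMap:
    """Piecewise-linear lung-volume (%VC) to membrane-bias (mV) maps."""
    psr_gain: float = 0.5          # stretch receptors: 0.5 mV per %VC
    def1_gain: float = -0.225      # deflation receptors, zero at 70 %VC
    def1_offset: float = 70.0
    dis1_gain: float = -1.75       # distortion receptors, active below 10 %VC
    dis1_offset: float = 10.0
    dis1_cutoff: float = 10.0


def percent_vc(V_L: float, free: FreeParameters, p: DerivedParameters) -> float:
    """Lung volume as %VC relative to residual volume."""
    return 100.0 * (V_L - p.V_L_RV) / free.VC


def diaphragm_activation(P: float, P1: float, dmap: DriveMap = DriveMap(),
                         gain: float = 1.0) -> float:
    """Diaphragm activation from phrenic pool rates (spikes/s), clipped to [0,1]."""
    u = gain * (dmap.w_low * P + dmap.w_high * P1) / dmap.X_phrenic
    return min(max(u, 0.0), 1.0)


def abdominal_activation(L: float, L1: float, dmap: DriveMap = DriveMap(),
                         gain: float = 1.0) -> float:
    """Abdominal activation from lumbar pool rates (spikes/s), clipped to [0,1]."""
    u = gain * (dmap.w_low * L + dmap.w_high * L1) / dmap.X_lumbar
    return min(max(u, 0.0), 1.0)


def laryngeal_activation(ilm_rate: float, elm_rate: float,
                         dmap: DriveMap = DriveMap()) -> float:
    """Net laryngeal activation in [-1, +1]; abductors open, adductors close."""
    u = ilm_rate / dmap.X_ILM - elm_rate / dmap.X_ELM
    return min(max(u, -1.0), 1.0)


def afferent_bias(v_pct: float, amap: AfferentMap = AfferentMap()
                  ) -> tuple[float, float, float]:
    """Membrane biases (mV) for the PSR, Def_1 and Dis_1 populations."""
    bias_psr = amap.psr_gain * v_pct
    bias_def1 = amap.def1_gain * (v_pct - amap.def1_offset)
    bias_dis1 = (amap.dis1_gain * (v_pct - amap.dis1_offset)
                 if v_pct < amap.dis1_cutoff else 0.0)
    return bias_psr, bias_def1, bias_dis1


class RateSmoother:
    """First-order exponential smoother of an instantaneous rate signal.

    Unbiased for constant input: a held rate is reproduced exactly once the
    transient (time constant `tau_ms`) has decayed.
    """

    def __init__(self, tau_ms: float = 60.0, dt_ms: float = 0.5):
        self.alpha = dt_ms / tau_ms
        self.value = 0.0

    def update(self, inst_rate: float) -> float:
        self.value += (inst_rate - self.value) * self.alpha
        return self.value
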