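"""Phase segmentation, peak metrics and trial statistics.

The respiratory cycle is segmented from the integrated phrenic trace
(population spike counts in 60 ms bins): inspiration is the set of
contiguous bins above a fraction (default 0.1) of the running cycle peak,
expiration the complement.  Cough phases are segmented from the mechanical
traces: inspiratory (lung filling under stimulation), compressive (glottis
closed, |flow| below a small epsilon) and expulsive (expiration-positive
flow after reopening).

Condition comparisons follow the simulation-study convention: a Welch
(non-pooled SD) two-sided t-test per metric per condition pair, with Holm
step-down adjustment across each metric's family of pairs; significance at
adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import integrated_rate

__all__ = [
    "PhaseSegmentation",
    "segment_phases",
    "segment_cough",
    "eupnea_metrics",
    "cough_peak_metrics",
    "summarize_condition",
    "compare_conditions",
    "holm_adjust",
]

BIN_MS_DEFAULT = 60.0


@dataclass
class PhaseSegmentation:
    """Per-cycle phase durations (s) and inspiration onset bin indices."""
    ti: np.ndarray
    te: np.ndarray
    onsets: np.ndarray
    bin_s: float

    @property
    def n_cycles(self) -> int:
        return len(self.ti)

    @property
    def frequency(self) -> float:
        """Mean cycle frequency, cycles/min."""
        return 60.0 / float(np.mean(self.ti + self.te))


def segment_phases(trace: np.ndarray, bin_s: float = BIN_MS_DEFAULT * 1e-3,
                   threshold_frac: float = 0.1,
                   min_phase_s: float = 0.3) -> PhaseSegmentation:
    """Segment Ti/Te cycles from an integrated (binned) phrenic trace.

    The threshold is `threshold_frac` of the running cycle peak (rolling
    maximum over ~2 cycles); segments shorter than `min_phase_s` are merged
    into their neighbours to reject bin-level chatter.  The threshold is
    relative, so segmentation is invariant to trace scaling.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 4 or np.all(x == x[0]):
        raise ValueError("no cycles detected in trace")
    win = max(3, int(round(12.0 / bin_s)))
    # centered rolling max
    pad = win // 2
    padded = np.pad(x, pad, mode="edge")
    from numpy.lib.stride_tricks import sliding_window_view
    run_peak = sliding_window_view(padded, win).max(axis=-1)[: x.size]
    thr = threshold_frac * run_peak
    above = x > thr
    if not above.any() or above.all():
        raise ValueError("no cycles detected in trace")
    # merge runs shorter than min_phase_s
    min_bins = max(1, int(round(min_phase_s / bin_s)))
    lab = above.copy()
    edges = np.flatnonzero(np.diff(lab.astype(int))) + 1
    bounds = np.concatenate([[0], edges, [lab.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_bins:
            lab[a:b] = not lab[a]
    onsets = np.flatnonzero(np.diff(lab.astype(int)) == 1) + 1
    if len(onsets) < 2:
        raise ValueError("no cycles detected in trace")
    ti, te = [], []
    for a, b in zip(onsets[:-1], onsets[1:]):
        seg = lab[a:b]
        n_insp = int(seg.sum())
        ti.append(n_insp * bin_s)
        te.append((len(seg) - n_insp) * bin_s)
    return PhaseSegmentation(ti=np.array(ti), te=np.array(te),
                             onsets=onsets, bin_s=bin_s)


@dataclass
class CoughPhases:
    """Step-index boundaries of one evoked cough within a trial."""
    insp: tuple
    compress: tuple
    expulse: tuple


def segment_cough(result, flow_eps_pct: float = 0.5,
                  vc: float = 5.370) -> CoughPhases:
    """Locate the canonical cough phases within the stimulus window.

    inspiratory: stimulus onset (restricted to inspiratory flow) up to
    laryngeal closure; compressive: glottis closed with |flow| below
    `flow_eps_pct` %VC/s; expulsive: expiration-positive flow above the
    epsilon after reopening.
    """
    if result.stim_window is None:
        raise ValueError("trial has no cough stimulus")
    s0, s1 = result.stim_window
    dt_s = result.dt_ms * 1e-3
    end = min(result.counts.shape[1], s1 + int(4.0 / dt_s))
    u_lm = result.trace("u_lm")
    flow = result.flow_pct_vc(vc)
    # closure: airway effectively shut (equivalent diameter below the
    # closed-airway threshold); require it to be sustained ~30 ms to reject
    # chatter of the smoothed laryngeal drive around the closing point
    closed = u_lm[s0:end] <= -0.995
    min_run = max(1, int(0.03 / dt_s))
    run = np.convolve(closed.astype(int), np.ones(min_run, int), "valid")
    starts = np.flatnonzero(run == min_run)
    if starts.size == 0:
        raise ValueError("no laryngeal closure: cough not evoked")
    t_close = s0 + int(starts[0])
    # reopening: sustained release of the closure
    opened = u_lm[t_close:end] > -0.9
    run_o = np.convolve(opened.astype(int), np.ones(min_run, int), "valid")
    starts_o = np.flatnonzero(run_o == min_run)
    t_open = t_close + (int(starts_o[0]) if starts_o.size else (end - t_close))
    # expulsive: expiration-positive flow above epsilon after reopening,
    # until it stays below epsilon for ~100 ms
    t_ex_end = end
    rising = np.flatnonzero(flow[t_open:end] > flow_eps_pct)
    if rising.size:
        start = t_open + int(rising[0])
        low = flow[start:end] < flow_eps_pct
        run_l = np.convolve(low.astype(int), np.ones(max(1, int(0.1 / dt_s)),
                                                     int), "valid")
        quiet = np.flatnonzero(run_l >= int(0.1 / dt_s)) if run_l.size else []
        t_ex_end = start + (int(quiet[0]) if len(quiet) else (end - start))
    return CoughPhases(insp=(s0, t_close), compress=(t_close, t_open),
                       expulse=(t_open, t_ex_end))


def eupnea_metrics(result, window: tuple | None = None,
                   bin_ms: float = BIN_MS_DEFAULT) -> dict:
    """Cycle statistics of a (pre-stimulus) eupneic interval of a trial."""
    s0 = result.burn_steps
    s1 = result.stim_window[0] if (window is None and result.stim_window) \
        else (window[1] if window else result.counts.shape[1])
    if window is not None:
        s0, s1 = window
    phr = result.pop_counts("Phrenic")[s0:s1]
    binned = integrated_rate(phr[None, :], bin_ms, result.dt_ms)[0]
    seg = segment_phases(binned, bin_s=bin_ms * 1e-3)
    dt_s = result.dt_ms * 1e-3
    rates = result.motor_rates[0][s0:s1]
    return {
        "frequency_cpm": seg.frequency,
        "ti_s": float(np.mean(seg.ti)),
        "te_s": float(np.mean(seg.te)),
        "peak_phrenic_rate": float(np.max(rates)),
        "n_cycles": seg.n_cycles,
    }


def cough_peak_metrics(result, vc: float = 5.370) -> dict:
    """Peak metrics of the evoked cough.

    Peaks are taken over the stimulation window plus a short tail (the
    stimulus may evoke more than one cough); a detected laryngeal closure
    is required, otherwise no cough was evoked and a ValueError is raised.
    """
    ph = segment_cough(result, vc=vc)  # raises if no cough was evoked
    a = result.stim_window[0]
    b = min(result.counts.shape[1],
            result.stim_window[1] + int(3.0 / (result.dt_ms * 1e-3)))
    pct = result.trace("pct_vc")
    flow = result.flow_pct_vc(vc)
    return {
        "peak_volume_pct": float(pct[a:b].max()),
        "peak_flow_pct_s": float(flow[a:b].max()),
        "peak_alveolar_pressure": float(result.trace("P_alv")[a:b].max()),
        "peak_abdominal_pressure": float(result.trace("sigma_ab")[a:b].max()),
        "peak_abdominal_drive": float(result.trace("u_ab")[a:b].max()),
        "peak_phrenic_rate": float(result.motor_rates[0][a:b].max()),
        "peak_lumbar_rate": float(result.motor_rates[2][a:b].max()),
        "peak_ilm_rate": float(result.motor_rates[4][a:b].max()),
        "peak_elm_rate": float(result.motor_rates[5][a:b].max()),
    }


def summarize_condition(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean, 95% t-based confidence limits and CV of per-trial metric vectors."""
    rows = []
    for metric, v in values.items():
        v = np.asarray(v, dtype=float)
        n = len(v)
        m = v.mean()
        if n > 1 and v.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        rows.append({"metric": metric, "n": n, "mean": m,
                     "ci_lo": m - half, "ci_hi": m + half,
                     "cv": v.std(ddof=1) / m if (n > 1 and m != 0) else 0.0})
    return pd.DataFrame(rows)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; monotone in raw-p order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sided t-test: (t, df, p); p = 1 for two degenerate groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_conditions(groups: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Pairwise Welch tests with Holm adjustment per metric across pairs.

    groups: {condition label: {metric: per-trial values}}.  Returns a tidy
    table (metric, condA, condB, t, df, p_raw, p_holm, significant).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two conditions")
    metrics = sorted(set().union(*(set(g) for g in groups.values())))
    rows = []
    for metric in metrics:
        pair_rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                la, lb = labels[i], labels[j]
                if metric not in groups[la] or metric not in groups[lb]:
                    continue
                a, b = groups[la][metric], groups[lb][metric]
                if len(a) < 2 or len(b) < 2:
                    raise ValueError("need >= 2 trials per group")
                t, df, p = welch_t(a, b)
                pair_rows.append({"metric": metric, "condA": la, "condB": lb,
                                  "t": t, "df": df, "p_raw": p})
        if not pair_rows:
            continue
        p_adj = holm_adjust(np.array([r["p_raw"] for r in pair_rows]))
        for r, pa in zip(pair_rows, p_adj):
            r["p_holm"] = pa
            r["significant"] = pa < 0.05
            rows.append(r)
    return pd.DataFrame(rows)
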