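# coughsim

Closed-loop neuromechanical simulation of human breathing and cough: a
deterministic biomechanical model of the supine respiratory system —
diaphragm, abdominal wall, rib cage, lungs and larynx — driven by a
stochastic integrate-and-fire model of the brainstem respiratory network,
with the lung volume fed back to the network as afferent input.  It is
aimed at researchers studying respiratory pattern generation and airway
defensive behaviours who want to ask how motor patterns interact with the
mechanics they act on: how inspiratory ("operating") volume shapes
expulsive airflow during cough, what simulated vagotomy does to phase
durations, and how selective changes of cough inspiratory drive propagate
to flow and pressure.

## The model

**Mechanics.** Two state volumes — under the diaphragm (V_di) and behind
the abdominal wall (V_ab) — determine lung and rib-cage volumes through
the three-movable-wall constraint V_di + C1·V_rc + V_ab = V_sum.  Two
implicit pressure balances close the system,

    P_pl + f_a σ_di + F_di σ_di + P_ica = σ_rc        (rib cage)
    σ_ab − P_pl = σ_di                                (diaphragm)

with Hill-type active muscle pressures, linear lung recoil, logistic
rib-cage recoil, a circular-segment abdominal-wall geometry, and Rohrer
airway resistance R_rs = (k1 + 0.72) + (k2 + 0.44)|V̇_L| with glottal-
diameter-dependent laryngeal coefficients (k1 = 49.6/d⁴).  The rates
(V̇_di, V̇_ab) are found by Newton iteration each step and integrated with
RK4; a closed glottis switches to the exact constraint V̇_L = 0.

**Network.** Forty populations (8559 MacGregor-style integrate-and-fire
neurons) with tabulated thresholds, adaptation, synapse types and
projection lists; conduction delays per terminal; presynaptic inhibition
as transmission gating; an inspiratory pacemaker population with a slow
inward current giving conditional bursting near the eupneic period.  Motor
pool rates map to the three muscle activations (u_di, u_ab, u_lm); lung
volume biases stretch-, deflation- and distortion-receptor populations.

See `docs/methods.md` for the full account, including engine conventions
and calibrations.

## Worked example

```python
from coughsim.mechanics import MechanicsModel
from coughsim.metrics import cough_peak_metrics, eupnea_metrics
from coughsim.protocols import ProtocolConfig, run_trial

model = MechanicsModel()
cfg = ProtocolConfig(duration=40.0, burn_in=8.0,
                     stim_onset=28.0, stim_duration=5.0)
res = run_trial(cfg, seed=1, mech_model=model)
print(eupnea_metrics(res))
print(cough_peak_metrics(res, vc=model.free.VC))
```

prints, for this seed,

```
{'frequency_cpm': 13.29, 'ti_s': 1.81, 'te_s': 2.70,
 'peak_phrenic_rate': 95.2, 'n_cycles': 4}
{'peak_volume_pct': 39.5, 'peak_flow_pct_s': 54.5,
 'peak_alveolar_pressure': 30.6, 'peak_abdominal_pressure': 18.2,
 'peak_abdominal_drive': 0.28, 'peak_phrenic_rate': 98.2,
 'peak_lumbar_rate': 28.3, 'peak_ilm_rate': 82.6, 'peak_elm_rate': 41.7}
```

i.e. resting breathing at 13.3 cycles/min (inspiration 1.8 s, expiration
2.7 s), and an evoked cough that inflates the lung to ≈40 %VC, closes the
glottis while alveolar pressure builds to ≈31 cmH2O, then expels air at a
peak of ≈55 %VC/s on reopening.  `res.to_frame()` returns the full trace
table (lung volume, flow, pressures, activations, motor rates) for
plotting.

A command-line interface wraps the protocols:

```bash
coughsim simulate --trials 4 --duration 60
coughsim cough --stim-onset 40
coughsim vagotomy
coughsim gain --factor 4
coughsim perturb B
coughsim mech-cough --volumes 25,40,55,70 --pressure 26.5
```

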