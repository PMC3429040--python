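# Methods

`coughsim` couples a deterministic biomechanical model of the supine human
respiratory system to a stochastic integrate-and-fire model of the
brainstem respiratory network, and reproduces the standard experimental
protocols run on such joint models: eupneic breathing, simulated vagotomy,
scaled inspiratory drive, selective perturbations of cough inspiratory
drive, and isolated-mechanics coughs.

## Biomechanical model

Two state variables describe the thoracoabdominal configuration: the
volume under the diaphragm `V_di` and the volume behind the abdominal wall
`V_ab`.  Treating the abdominal contents as incompressible with three
movable walls (diaphragm, abdominal wall, and — through the coupling
constant `C1` — the rib cage) gives the volume constraint

    V_di + C1·V_rc + V_ab = V_sum,        V_rc = V_L + V_di + V_c,

from which lung volume follows algebraically.  At every instant two
pressure balances hold:

    rib cage:    P_pl + f_a·σ_di + F_di·σ_di + P_ica = σ_rc
    diaphragm:   σ_ab − P_pl = σ_di

with `P_pl = −R_rs·V̇_L − σ_L` while the airway is open.  The recoils are:
linear lung recoil (compliance `C_L`, zero at the RV volume); Hill-type
diaphragm and abdominal-muscle pressures (activation × force–length ×
force–velocity, on a volume-mapped length scale for the diaphragm and on
the geometric muscle length of the abdominal wall), plus passive elastic
and viscous terms; and a generalized-logistic rib-cage recoil whose
maximal compliance equals `C_rc/(1+C1)`.  Airway resistance follows
Rohrer's law applied separately to the larynx (`k1 = 49.6/d⁴`,
`k2 = 0.167·(D⁴/d⁴ − 1)(1 − d²/D²)`, `d` the equivalent glottal diameter
proportional to net laryngeal activation) and to the rest of the airway
(0.72 + 0.44·|flow|).  The printed form of the orifice coefficient is
ambiguous in the source; the form above is the one that reproduces both
stated anchors (coefficient 0.167 and resting value 0.681) and vanishes as
the glottis opens to the tracheal bore.  The rib-cage logistic is oriented
so recoil increases with volume (the printed equation pair is
sign-inconsistent); it is zero at the resting volume.

The abdominal wall is a surface of circular-segment cross sections
(transverse radius `r_t`, sagittal radius `r_s = 8.00479·r_t − 1.10158`).
`V_ab(r_t)` is evaluated by adaptive quadrature on a 500-point grid,
log-spaced in the offset from the fully bulged radius `c_t/2` (the volume
is steep there), and approximated with monotone cubic (PCHIP)
interpolants, giving the inverse map and the muscle length
`L_CE = 100·r_t·asin(c_t/2r_t)` used by the Hill terms.  `dL_CE/dV_ab` is a
centered difference with step 1e-4 L.  Non-positive volumes clamp the
radius to `c_t/2`, as specified.

Two calculated parameters are implicit calibrations: `V_ab_RV` solves
"full abdominal activation at RV volume produces the RV recoil pressure"
(a 1-D root find — the zero-tension volume is tied to `V_ab_RV` by a fixed
Konno–Mead displacement, so the passive term at RV is constant), and
`σ_di_max` follows in closed form from the TLC diaphragm calibration.
Unit tests verify both round trips through the recoil operations to
1e-6 cmH2O.

### Numerics

The balance equations are implicit in the state rates.  A damped 2-D
Newton iteration (finite-difference Jacobian, warm-started, residual
tolerance 1e-10 cmH2O, multi-start fallback) solves for
`(V̇_di, V̇_ab)`; with the glottis effectively closed (d < 0.05 mm) the
resistive coupling is replaced by the algebraic constraint `V̇_L = 0` and
the unknowns become `(V̇_di, P_pl)`, avoiding the `1/d⁴` singularity.
Integration is fixed-step classic RK4 (default substep 0.5 ms, matching
the network step) around the rate solve; step-halving changes 10-s
trajectories by far less than 1e-4 L, and the volume identity holds to
1e-9 L at every emitted sample.  Tracheal flow is reported
expiration-positive; the internal lung-volume derivative is
inspiration-positive.

## Network model

Forty integrate-and-fire populations (8559 neurons) follow MacGregor-style
dynamics at a 0.5 ms step: exponential-Euler membrane update under
synaptic conductances (excitatory reversal +115 mV, inhibitory −25 mV
relative to rest), a post-spike potassium conductance (reversal −10 mV, a
calibration), threshold adaptation toward `TH0 + C·E`, and additive
Gaussian membrane noise (SD = the table's noise amplitude per step).
Terminals are placed on uniformly drawn targets with replacement — the
realized divergence reproduces the closed form `N(1−(1−1/N)^T)` and the
published wiring statistics — with independent uniform conduction delays
rounded to the step grid (minimum one step) and delivered through a ring
buffer.  Presynaptic-inhibition synapse types do not conduct: their
deliveries charge a saturating gating variable on the target that scales
transmission of the gated type by `(1 − q)`.

Because the antecedent engine's discretisation is not restated in the
source, two conventions had to be fixed here.  The post-spike potassium
increment uses the impulse-area convention `G_K += B·dt/TGK`: with a raw
jump of `B`, the published phrenic row (B = 200, TGK = 6 ms) would cap
firing near 20 spikes/s, inconsistent with the motor rates the same study
reports.  Synaptic increments, in contrast, are taken at face value
(`g += strength`): with area scaling the premotor-to-motor chain cannot
drive the motoneurons at all.  This mixed convention is the only one we
found that supports the published behaviour; it is isolated behind two
build-time switches.

### The inspiratory driver population

The source defers the I-Driver (conditional bursting pacemaker) constants
to an external appendix, so this population is a behavioural calibration.
Its row: N = 300, TH0 = 38 ± 0.5 mV (above the tonic pontine drive of
~35 mV, so the population is silent without the slow current), TMEM =
25 ms (the long membrane time constant filters synaptic drive
fluctuations), B = 10, TGK = 7 ms, no threshold adaptation, noise 0.1 mV.
It carries a slow inward (persistent-sodium-like) current with
population-shared (mean-field) slow gates:

* activation `m` charges with population spiking (`m += a_m(1−m)` per
  population-mean spike, decay τ_m = 100 ms) — an afterdepolarisation that
  regeneratively sustains the burst;
* slow inactivation `h` is hysteretic: while the current is available,
  population spiking depletes it (`h ·= 1 − d_spike` per mean spike) until
  it falls below `h_off = 0.35`, which shuts the current; `h` then recovers
  linearly (τ_h = 5800 ms full range) until it exceeds `h_on = 0.95`,
  re-arming it.  A persistent activation floor (`m_floor`) re-ignites
  spiking decisively when the gate re-arms.
* the inspiratory off-switch acts directly on the gate: once the burst is
  under way, sustained firing of the volume-gated VRC-IE population above
  24 spikes/s completes the inactivation early, resetting `h` to 0.475.
  VRC-IE is driven by the pump-cell relay of the stretch receptors, so the
  cut-off time tracks lung volume (Hering–Breuer inspiratory
  termination); silencing the lung afferents (vagotomy) removes its drive
  and the burst runs to intrinsic depletion with a full recovery,
  lengthening both phases — the reported directions.  During cough the
  published second-order-cough inhibition of VRC-IE suppresses the
  off-switch, freeing the enhanced cough inspiration — also as reported.
  The printed off-switch pathway (VRC-IE and the post-inspiratory
  population inhibiting the inspiratory column) is wired and active, but
  with the published strengths it cannot by itself overcome the driver's
  excitation of the inspiratory populations in this engine, so the final
  arm onto the pacemaker gate is part of the behavioural calibration.

The two-threshold gate stands in for a steep Hodgkin–Huxley-style slow
inactivation whose constants are unavailable.  Smooth per-neuron variants
(instantaneous or first-order voltage-gated activation, voltage- or
spike-dependent graded inactivation) were explored extensively and always
found a stable asynchronous equilibrium — tonic firing instead of
population bursting — because in no-reset IF dynamics the post-spike
potassium surge deactivates fast gates and inter-spike potentials overlap
the silent range.  The mean-field hysteretic gate cannot stall, keeps the
burst vigorous (intraburst rates of order 10² spikes/s, as in
conductance-based antecedents), and remains conditional on drive: without
synaptic input the population is silent, and network inhibition or
excitation shifts the burst period by changing the spiking that depletes
the gate.  The isolated, self-excited population (only the published
recurrent excitation, with a 16 mV bias standing in for its tonic pontine
drive) bursts with a period within 20% of the eupneic 4.7 s.

## Coupling

Motor activations are formed from exponentially smoothed (τ = 60 ms) mean
per-neuron rates: `u_di = (0.3·PHR + 0.7·PHR-HT)/X_phrenic` with
X_phrenic = 140 spikes/s (inside the stated 50–200 range),
`u_ab = (0.3·LUM + 0.7·LUM-HT)/80`, and
`u_lm = ILM/40 − ELM/25` clipped to [−1, 1].  The laryngeal
normalisations are calibrations: X_ELM is set so cough-level adductor
firing closes the glottis while eupneic adductor activity cannot.  Lung
volume (%VC relative to RV) feeds back as membrane bias: +0.5·V mV to the
stretch receptors, −0.225·(V−70) to the deflation receptors, and
−1.75·(V−10) below 10 %VC to the distortion receptors.  Simulated
vagotomy silences all three afferent populations.

## Protocols and statistics

Every protocol is a pure transformation of a configuration object; a run
is reproducible from (configuration, seed).  The cough stimulus is the
published fiber bundle (100 fibers, Bernoulli 0.05 per step, 100
excitatory terminals of strength 0.03 on the second-order cough
population), default window 5 s placed after a stable eupneic interval.
Drive perturbations double (A) or remove (B) the second-order cough
excitation of the inspiratory premotor populations during stimulation; C
additionally blocks the I-Dec_2 inhibition of tonic expiratory neurons
over the same window (the stimulus window is used as the cough-cycle
window).  Isolated-mechanics coughs servo diaphragm activation to an
operating volume, close the glottis, servo abdominal activation to a
target abdominal pressure (26.5 cmH2O, within 1%), then open; peak
expiratory flow is strictly increasing in operating volume.

Respiratory phases are segmented from the integrated phrenic trace (60 ms
bins; inspiration = contiguous bins above 0.1 × running cycle peak,
sub-300 ms segments merged), so segmentation is scale-invariant.  Cough
phases are read from the mechanical traces: closure = equivalent diameter
below the closed-airway threshold sustained ≥ 30 ms; expulsion =
expiration-positive flow above 0.5 %VC/s after reopening.  Condition
comparisons use a Welch (non-pooled SD) two-sided t-test per metric per
condition pair with Holm step-down adjustment across each metric's family,
significance at adjusted p < 0.05; 95% confidence limits use the
t-quantile with n−1 degrees of freedom over the 4 trials.

## Problem sizes

Default grading-scale runs use 4 seeded baseline trials (≈50 s of eupnea
before a 5-s stimulus, 6 s burn-in discarded) and 4 vagotomised trials of
28 s; these sizes give ≥10 (resp. ≥5) complete cycles per trial and keep a
full reproduction run under twenty minutes on one CPU at the 0.5 ms step.

## What passing tests do and do not show

The network generator *is* the study conditions: all population, synapse
and projection constants are the published tables, verified row-for-row in
unit tests; only the I-Driver row, the slow-current constants, the
laryngeal/phrenic normalisations and the potassium reversal are
calibrations, and each is documented above.  Closed-loop agreement
therefore shows that the published architecture, under this engine's
stated conventions and calibrations, reproduces the reported breathing and
cough pattern — not that those conventions equal the original engine's.

Known quantitative limitations of this reimplementation: eupneic motor
rates run high (phrenic peak ≈ 100 spikes/s vs the reported 56; the cough
phrenic peak is in range), and the cough abdominal drive peaks near
u_ab ≈ 0.3, so peak expulsive flow (≈ 50–55 %VC/s) falls short of the
reported 72.2 %VC/s; the remaining parameters on that pathway are all
published values taken at face value, leaving no calibration freedom
without departing from them.  Physiological simplifications inherited from
the model itself: no airway collapse or flow limitation, constant lung
compliance, no pressure–volume hysteresis, no blood shift or gas
compression.
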