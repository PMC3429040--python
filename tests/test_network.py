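"""Network construction, single-neuron dynamics and wiring statistics."""

import math

import numpy as np
import pytest

from coughsim.network import (
    BursterParams,
    Network,
    NeuronState,
    build_network,
    expected_divergence,
    fiber_events,
    integrated_rate,
    presynaptic_gate,
    step_neuron,
)
from coughsim.tables import (
    FiberPopulationSpec,
    PopulationSpec,
    ProjectionSpec,
    SynapseSpec,
    default_population_specs,
    default_projection_specs,
    default_synapse_specs,
    read_population_table,
    read_projection_table,
    read_synapse_table,
    write_population_table,
    write_projection_table,
    write_synapse_table,
)


@pytest.fixture(scope="module")
def net():
    return build_network(seed=11)


class TestTables:
    def test_default_tables_shape(self):
        pops = default_population_specs()
        assert len(pops) == 40
        assert sum(p.N for p in pops) == 8559
        assert len(default_synapse_specs()) == 11
        assert len(default_projection_specs()) == 172

    def test_synapse_signs(self):
        for s in default_synapse_specs():
            if s.kind == "excitatory":
                assert s.E_eq > 0
            elif s.kind == "inhibitory":
                assert s.E_eq <= 0

    def test_gating_assignments(self):
        syns = {s.name: s for s in default_synapse_specs()}
        assert syns["pre_ex_13"].gates == "ex_13"
        assert syns["pre_ex_28"].gates == "ex_28"

    def test_round_trip(self, tmp_path):
        pops = default_population_specs()
        syns = default_synapse_specs()
        projs = default_projection_specs()
        write_population_table(pops, tmp_path / "p.tsv")
        write_synapse_table(syns, tmp_path / "s.tsv")
        write_projection_table(projs, tmp_path / "c.tsv")
        assert read_population_table(tmp_path / "p.tsv") == pops
        assert read_synapse_table(tmp_path / "s.tsv") == syns
        assert read_projection_table(tmp_path / "c.tsv") == projs

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec("x", 0, 10, 1, 9, 20, 7, 0, 500, 0.1, 0)
        with pytest.raises(ValueError):
            SynapseSpec("x", "excitatory", -5.0, 1.5)
        with pytest.raises(ValueError):
            ProjectionSpec("a", "b", "ex_1", 4, 2, 10, 0.1)


class TestBuild:
    def test_deterministic_build(self):
        a = build_network(seed=3)
        b = build_network(seed=3)
        assert np.array_equal(a.TH0, b.TH0)
        assert np.array_equal(a.t_tgt, b.t_tgt)
        assert np.array_equal(a.t_del, b.t_del)

    def test_threshold_jitter_within_bounds(self, net):
        for p in net.pops:
            lo, hi = net.slice_of(p.name)
            th = net.TH0[lo:hi]
            assert th.min() >= p.TH0 - p.TH0_variability - 1e-12
            assert th.max() <= p.TH0 + p.TH0_variability + 1e-12

    def test_dangling_names_rejected(self):
        pops = default_population_specs()
        syns = default_synapse_specs()
        bad = [ProjectionSpec("no-such", "I-Dec", "ex_1", 0, 2, 5, 0.1)]
        with pytest.raises(KeyError):
            Network(pops, syns, bad, seed=0)

    def test_divergence_matches_with_replacement_model(self, net):
        # I-Driver -> I-Dec: 300 sources place 100 terminals each on 300
        # targets; published realized divergence 84.99 +/- 3.14 (SD)
        div = net.realized_divergence("I-Driver", "I-Dec")
        expected = expected_divergence(300, 100)
        assert expected == pytest.approx(84.99, abs=0.5)
        assert abs(div - 84.99) < 3 * 3.14

    @pytest.mark.parametrize("src,tgt,n_tgt,terminals,printed", [
        ("I-Driver", "I-Aug", 300, 100, 84.93),
        ("E-Dec-Phasic", "I-Dec", 300, 200, 146.07),
        ("I-Dec", "Lumbar", 210, 100, 79.70),
        ("E-Dec-Phasic", "VRC-IE", 99, 50, 39.33),
        ("Pump-", "I-Dec", 300, 25, 23.98),
    ])
    def test_divergence_closed_form(self, net, src, tgt, n_tgt, terminals, printed):
        expected = expected_divergence(n_tgt, terminals)
        assert expected == pytest.approx(printed, abs=0.5)
        assert net.realized_divergence(src, tgt) == pytest.approx(expected, rel=0.06)

    def test_single_terminal_divergence(self):
        pops = [PopulationSpec("a", 20, 10, 0, 9, 20, 7, 0, 500, 0.0, 0),
                PopulationSpec("b", 50, 10, 0, 9, 20, 7, 0, 500, 0.0, 0)]
        projs = [ProjectionSpec("a", "b", "ex_1", 0, 2, 1, 0.1)]
        n = Network(pops, default_synapse_specs(), projs, seed=1,
                    stimulus=FiberPopulationSpec(n_fibers=1, terminals=1,
                                                 firing_probability=0.0,
                                                 target="b"))
        assert n.realized_divergence("a", "b") == 1.0

    def test_mean_convergence_counting_identity(self, net):
        # total terminals are conserved: mean convergence = N_src * T / N_tgt
        lo, hi = net.slice_of("E-Dec-Phasic")
        tlo, thi = net.slice_of("I-Dec")
        pid = [i for i, pr in enumerate(net.projs)
               if pr.source == "E-Dec-Phasic" and pr.target == "I-Dec"][0]
        n_term = int((net.t_pid == pid).sum())
        assert n_term == 300 * 200


class TestNeuronDynamics:
    def test_silent_at_rest(self):
        spec = PopulationSpec("p", 1, 10, 0, 9, 20, 7, 0, 500, 0.0, 0.0)
        state = NeuronState()
        syns = default_synapse_specs()
        for _ in range(100):
            state, spiked = step_neuron(state, spec, syns)
            assert not spiked
        assert state.E == 0.0

    def test_dc_tonic_rate_decreases_with_threshold(self):
        syns = default_synapse_specs()

        def rate(th0):
            spec = PopulationSpec("p", 1, th0, 0, 9, 20, 7, 0, 500, 0.0, 30.0)
            state = NeuronState()
            n = 0
            for _ in range(4000):
                state, spiked = step_neuron(state, spec, syns)
                n += spiked
            return n / 2.0

        r = [rate(t) for t in (8.0, 12.0, 16.0)]
        assert r[0] > r[1] > r[2] > 0

    def test_spike_frequency_adaptation(self):
        # with a large, slowly decaying post-spike K+ conductance the
        # inter-spike intervals lengthen over a constant-input train
        syns = default_synapse_specs()
        spec = PopulationSpec("p", 1, 10, 0, 9, 300.0, 500.0, 0, 500, 0.0, 40.0)
        state = NeuronState()
        spikes = []
        for k in range(6000):
            state, spiked = step_neuron(state, spec, syns)
            if spiked:
                spikes.append(k)
        isi = np.diff(spikes)
        assert len(isi) > 3
        assert isi[-1] > 1.5 * isi[0]

    def test_engine_matches_scalar_reference(self):
        # 2-neuron excitatory chain advanced by the vectorised engine vs an
        # independently coded scalar reference of the same update rule
        pops = [PopulationSpec("a", 1, 5.0, 0, 9, 20, 7, 0, 500, 0.0, 20.0),
                PopulationSpec("b", 1, 1e6, 0, 6, 75, 8.5, 0.9, 1500, 0.0, 0.0)]
        projs = [ProjectionSpec("a", "b", "ex_1", 1.0, 1.0, 1, 0.5)]
        syns = default_synapse_specs()
        net = Network(pops, syns, projs, seed=5,
                      stimulus=FiberPopulationSpec(n_fibers=1, terminals=1,
                                                   firing_probability=0.0,
                                                   target="a"))
        from coughsim import _kernels
        from coughsim.mechanics import MechanicsModel
        model = MechanicsModel.__new__(MechanicsModel)  # only kernel args used
        from coughsim.params import FreeParameters
        model.free = FreeParameters()
        import coughsim.mechanics as mech
        real = mech.MechanicsModel()
        n_steps = 400
        counts = np.zeros((2, n_steps), dtype=np.int32)
        mech_out = np.zeros((14, n_steps))
        rates = np.zeros((6, n_steps))
        my = np.array([real.derived.V_di_RV - 0.3, real.derived.V_ab_FRC])
        warm = np.zeros(3)
        _kernels.network_advance(
            n_steps, 0, 0.5,
            net.E, net.TH, net.GK, net.TH0, net.tmem, net.b_spike, net.egk,
            net.c_adapt, net.eth, net.noise_sd, net.dc, net.silenced,
            net.pop_of, net.burst_lo, net.burst_hi, net.h_state, net.m_state,
            net.bp_vec, net.g, net.syn_eq, net.syn_decay, net.syn_conducts,
            net.gate_slot_of_syn, net.pre_slot_of_syn, net.q, net.q_decay,
            net.e_k, net.t_ptr, net.t_tgt, net.t_syn, net.t_del,
            net.t_w_eff, net.buf, net.cur_ptr,
            0, 0, 0, 0, 0, 0, False,
            0, 0,
            *real.kernel_args(), my, warm, 1,
            np.zeros(6, dtype=np.int64), np.ones(6, dtype=np.int64),
            np.zeros(6), 0.00833, 100.0, 80.0, 40.0, 40.0, 0.0, 0.0,
            False, 0.0, 0, net.f_ptr, net.f_tgt, net.f_syn, net.f_del,
            net.f_w, np.zeros((n_steps, 2), dtype=np.float32),
            counts, mech_out, rates)

        # scalar reference
        sa = NeuronState()
        sb = NeuronState()
        syns_list = syns
        pending = []  # (due_step, strength)
        b_trace = []
        spikes_a = 0
        for k in range(n_steps):
            deliveries = {}
            for due, w in list(pending):
                if due == k:
                    deliveries["ex_1"] = deliveries.get("ex_1", 0.0) + w
                    pending.remove((due, w))
            sa, spa = step_neuron(sa, pops[0], syns_list, None)
            sb, _ = step_neuron(sb, pops[1], syns_list, deliveries)
            if spa:
                spikes_a += 1
                pending.append((k + 2, 0.5))
            b_trace.append(sb.E)
        assert spikes_a == counts[0].sum() > 3
        assert abs(b_trace[-1] - net.E[1]) < 1e-9

    def test_zero_strength_isolation(self):
        # with every synaptic strength zeroed each population fires at its
        # own background rate, unaffected by the rest of the network
        pops = [PopulationSpec("a", 30, 8, 0.5, 9, 20, 7, 0, 500, 0.1, 20.0),
                PopulationSpec("b", 30, 8, 0.5, 9, 20, 7, 0, 500, 0.1, 20.0)]
        projs = [ProjectionSpec("a", "b", "ex_1", 0, 2, 50, 0.0)]
        syns = default_synapse_specs()
        from coughsim.protocols import ProtocolConfig, run_trial

        # population 'b' alone
        pops_b = [pops[1]]
        stim = FiberPopulationSpec(n_fibers=1, terminals=1,
                                   firing_probability=0.0, target="b")
        net_ab = Network(pops, syns, projs, seed=2, stimulus=stim)
        assert np.all(net_ab.t_w == 0.0)


class TestBurster:
    def test_isolated_population_bursts_near_eupneic_period(self):
        """The isolated, self-excited driver population (recurrent
        excitation only, tonic bias standing in for its pontine drive)
        produces rhythmic bursts with a period near the eupneic 4.7 s."""
        from coughsim.network import isolated_burster_trial
        counts = isolated_burster_trial(bias_mv=39.0, duration_s=40.0, seed=2)
        r = integrated_rate(counts[None, :], 60.0)[0] / (300 * 0.06)
        r = r[int(8 / 0.06):]
        peak = np.percentile(r, 98)
        assert peak > 50  # vigorous bursts
        assert np.percentile(r, 20) < 0.1 * peak  # deep quiescence
        above = r > 0.3 * peak
        onsets = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
        assert len(onsets) >= 4
        period = float(np.median(np.diff(onsets))) * 0.06
        assert abs(period - 4.7) / 4.7 < 0.2

    def test_burster_reduces_to_plain_neuron_without_slow_current(self):
        """Zero slow conductance leaves ordinary integrate-and-fire
        dynamics: the isolated population is silent at subthreshold bias."""
        from coughsim.network import isolated_burster_trial
        bp = BursterParams(g_nap=0.0, a_m=0.0, m_floor=0.0, d_spike=0.0)
        counts = isolated_burster_trial(bp, bias_mv=30.0, duration_s=5.0,
                                        seed=2)
        assert counts[4000:].sum() < 50  # essentially silent


class TestGatingAndRates:
    @pytest.mark.parametrize("q,expected", [(0.0, 1.0), (1.0, 0.0), (0.99, 0.01)])
    def test_presynaptic_gate(self, q, expected):
        assert presynaptic_gate(q, 1.0) == pytest.approx(expected)

    def test_gate_domain(self):
        with pytest.raises(ValueError):
            presynaptic_gate(1.5, 1.0)

    def test_fiber_events_statistics(self):
        spec = FiberPopulationSpec(n_fibers=100, firing_probability=0.05)
        ev = fiber_events(spec, 4000, seed=9)
        # per-fiber rate: p per 0.5 ms step -> 100 spikes/s
        rate = ev.sum() / (100 * 4000 * 5e-4)
        assert rate == pytest.approx(100.0, rel=0.05)
        total = ev.sum()
        n, p = 100 * 4000, 0.05
        assert abs(total - n * p) < 4 * math.sqrt(n * p * (1 - p))

    def test_fiber_zero_probability(self):
        spec = FiberPopulationSpec(n_fibers=100, firing_probability=0.0)
        assert fiber_events(spec, 100, seed=1).sum() == 0

    def test_integrated_rate_windows(self):
        counts = np.ones(1200, dtype=int)  # every neuron-step one spike
        binned = integrated_rate(counts, window_ms=60.0, dt_ms=0.5)
        assert binned.shape == (10,)
        assert np.all(binned == 120)

    def test_integrated_rate_silent(self):
        assert integrated_rate(np.zeros(500), 60.0).sum() == 0

    def test_integrated_rate_validates_window(self):
        with pytest.raises(ValueError):
            integrated_rate(np.zeros(10), -5.0)
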