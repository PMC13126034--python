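import numpy as np
import pytest
from scipy.integrate import solve_ivp

from axoaxonic.connectome import (
    ConnectionRecord,
    ConnectomeTable,
    NeuronClass,
    NeuronRecord,
    Transmitter,
)
from axoaxonic.lif import (
    ConductanceEvents,
    LIFParams,
    PoissonDrive,
    PulseTrain,
    SimConfig,
    build_network,
    calibrate_subthreshold_pulse,
    compare_subthreshold,
    delete_neurons,
    run,
    silence_synapses,
    subthreshold_samples,
)
from conftest import make_table


@pytest.fixture
def two_neuron_model():
    """A (cholinergic AN) → B (DN), weight 10."""
    t = make_table(
        [
            (1, "AN", "A", "acetylcholine", "L"),
            (2, "DN", "B", "acetylcholine", "R"),
        ],
        [(1, 2, 10)],
    )
    return build_network(t)


def _quiet(duration, **kw):
    return SimConfig(
        duration=duration, background_rate_hz=0.0, background_conductance_ns=0.0, **kw
    )


class TestBuildNetwork:
    def test_increment_scales_with_weight(self, two_neuron_model):
        m = two_neuron_model
        w = m.weights["ach"][m.index[1], m.index[2]]
        assert w == pytest.approx(0.27 * 10)

    def test_gf_membrane_time_constant(self):
        t = make_table(
            [(1, "DN", "DNp01", "acetylcholine", "L"),
             (2, "DN", "DNx", "acetylcholine", "L")],
            [],
        )
        m = build_network(t)
        tau_gf = m.params.c_m / m.g_l[m.index[1]]
        tau_other = m.params.c_m / m.g_l[m.index[2]]
        assert tau_gf == pytest.approx(1.8)       # 25 MΩ × 72 pF
        assert tau_other == pytest.approx(21.6)   # 300 MΩ × 72 pF

    def test_unknown_transmitter_rejected(self):
        t = make_table(
            [(1, "AN", "A", "unknown", "L"), (2, "DN", "B", "acetylcholine", "R")],
            [(1, 2, 8)],
        )
        with pytest.raises(ValueError, match="unknown transmitter"):
            build_network(t)

    def test_channel_follows_presynaptic_transmitter(self):
        t = make_table(
            [
                (1, "AN", "A", "gaba", "L"),
                (2, "AN", "B", "glutamate", "L"),
                (3, "DN", "C", "acetylcholine", "R"),
            ],
            [(1, 3, 6), (2, 3, 7)],
        )
        m = build_network(t)
        assert m.weights["gaba"][m.index[1], m.index[3]] == pytest.approx(0.8 * 6)
        assert m.weights["glut"][m.index[2], m.index[3]] == pytest.approx(0.8 * 7)
        assert m.weights["ach"].nnz == 0


class TestIntegration:
    def test_quiescent_holds_rest_exactly(self, two_neuron_model):
        res = run(two_neuron_model, _quiet(100.0, record=[1, 2]))
        assert np.all(res.traces[1] == -55.0)
        assert np.all(res.traces[2] == -55.0)
        assert res.spikes == {}

    def test_epsp_matches_dense_ode_oracle(self, two_neuron_model):
        """A single conductance kick reproduces an adaptive high-accuracy
        integration of the membrane + synapse ODEs within 0.01 mV."""
        m = two_neuron_model
        kin, p = m.kinetics, m.params
        amp = 2.7  # nS, J_ach × weight 10
        t0 = 5.0
        res = run(
            m, _quiet(40.0, stimuli=[ConductanceEvents((2,), (t0,), amp)], record=[2])
        )
        gl = m.g_l[m.index[2]]

        def rhs(t, y):
            g = amp * np.exp(-(t - t0) / kin.tau["ach"])
            return [-(gl * (y[0] - p.v_rest) + g * (y[0] - kin.e_rev["ach"])) / p.c_m]

        sol = solve_ivp(
            rhs, (t0, 40.0), [p.v_rest], dense_output=True,
            rtol=1e-11, atol=1e-12, max_step=0.05,
        )
        mask = res.times >= t0
        err = np.abs(res.traces[2][mask] - sol.sol(res.times[mask])[0]).max()
        assert err < 0.01

    def test_inhibitory_input_never_depolarizes(self):
        t = make_table(
            [(1, "IN", "A", "gaba", "L"), (2, "DN", "B", "acetylcholine", "R")],
            [(1, 2, 50)],
        )
        m = build_network(t)
        res = run(
            m,
            _quiet(100.0, stimuli=[ConductanceEvents((2,), (5.0, 20.0), 40.0, "gaba")],
                   record=[2]),
        )
        assert res.traces[2].max() <= -55.0 + 1e-9

    def test_deterministic_given_seed(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        cfg = SimConfig(duration=200.0, stimuli=[PoissonDrive((hub,), 10, 40)],
                        record=[hub], seed=42)
        r1 = run(synth_model, cfg)
        r2 = run(synth_model, cfg)
        assert np.array_equal(r1.traces[hub], r2.traces[hub])
        assert {k: list(v) for k, v in r1.spikes.items()} == {
            k: list(v) for k, v in r2.spikes.items()
        }

    def test_step_halving_stable_spike_count(self, two_neuron_model):
        """Halving dt changes the probe spike count by at most 1 on a driven toy."""
        counts = []
        for dt in (0.1, 0.05):
            cfg = SimConfig(
                dt=dt, duration=500.0, background_rate_hz=0,
                background_conductance_ns=0,
                stimuli=[PulseTrain((2,), 24.0, 60.0)], record=[2],
            )
            counts.append(run(two_neuron_model, cfg).spike_count(2))
        assert counts[0] > 0
        assert abs(counts[0] - counts[1]) <= 1


@pytest.fixture(scope="module")
def bg_result(synth_model, synth_truth):
    probes = synth_truth.hub_ids + synth_truth.octet_ids[:2]
    cfg = SimConfig(duration=2000.0, record=probes, seed=9)
    return run(synth_model, cfg), probes


class TestInvariantsUnderBackground:
    def test_voltage_bounds(self, bg_result):
        res, probes = bg_result
        for p in probes:
            v = res.traces[p]
            assert v.min() >= -60.0 - 1e-9  # min(E_gaba, V_reset)
            assert v.max() <= 0.0 + 1e-9    # E_ach

    def test_refractory_spacing(self, bg_result):
        res, _ = bg_result
        for ts in res.spikes.values():
            if len(ts) > 1:
                assert np.diff(ts).min() > 2.0  # tau_ref

    def test_background_conductance_shot_noise_mean(self):
        """Time-averaged ach conductance under 30 Hz / 5 nS Poisson drive matches
        the shot-noise expectation rate × J × tau within 5% over 2 s."""
        # unconnected population: background drive is the only conductance source
        t = make_table([(i, "DN", f"A{i}", "acetylcholine", "L") for i in range(100)], [])
        m = build_network(t)
        cfg = SimConfig(duration=2000.0, record_conductance=list(range(100)), seed=123)
        res = run(m, cfg)
        mean_g = np.mean([tr.mean() for tr in res.conductances.values()])
        expected = 30e-3 * 5.0 * 1.1  # rate (1/ms) × J (nS) × tau (ms) = 0.165 nS
        assert mean_g == pytest.approx(expected, rel=0.05)


class TestSurgery:
    def test_delete_all_neurons_silences_network(self, two_neuron_model):
        m = delete_neurons(two_neuron_model, [1, 2])
        res = run(m, SimConfig(duration=200.0, record=[2], seed=0))
        assert res.spikes == {}
        assert np.all(res.traces[2] == -55.0)

    def test_deleted_neuron_emits_and_receives_nothing(self, two_neuron_model):
        m = delete_neurons(two_neuron_model, [1])
        assert m.weights["ach"].nnz == 0
        res = run(
            m, _quiet(100.0, stimuli=[ConductanceEvents((1,), (5.0,), 500.0)], record=[1, 2])
        )
        assert res.spike_count(1) == 0
        assert np.all(res.traces[2] == -55.0)

    def test_unknown_id_raises(self, two_neuron_model):
        with pytest.raises(KeyError):
            delete_neurons(two_neuron_model, [99])

    def test_silencing_removes_only_that_pathway(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        octet = synth_truth.octet_ids
        m = silence_synapses(synth_model, octet, [hub])
        for o in octet:
            for ch in ("ach", "gaba", "glut"):
                assert m.weights[ch][m.index[o], m.index[hub]] == 0
        # octet outputs elsewhere survive
        total_out = sum(
            m.weights[ch][m.index[o], :].sum() for ch in ("ach",) for o in octet
        )
        assert total_out > 0

    def test_silenced_octet_still_spikes_hub_loses_drive(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        octet = tuple(synth_truth.octet_ids)
        stims = [PoissonDrive(octet, 10, 40)]
        m_sil = silence_synapses(synth_model, octet, [hub])
        res = run(m_sil, SimConfig(duration=1000.0, stimuli=stims, record=[hub], seed=2))
        assert sum(res.spike_count(o) for o in octet) > 0


class TestCalibration:
    def test_returned_amplitude_is_subthreshold(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        amp = calibrate_subthreshold_pulse(synth_model, hub)
        res = run(
            synth_model,
            _quiet(1000.0, stimuli=[PulseTrain((hub,), 24.0, amp)], record=[hub]),
        )
        assert res.spike_count(hub) == 0

    def test_unscaled_amplitude_spikes(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        amp = calibrate_subthreshold_pulse(synth_model, hub, safety=0.95)
        res = run(
            synth_model,
            _quiet(1000.0, stimuli=[PulseTrain((hub,), 24.0, amp / 0.95 * 1.001)], record=[hub]),
        )
        assert res.spike_count(hub) >= 1

    def test_doubled_amplitude_spikes_on_every_pulse(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        amp = calibrate_subthreshold_pulse(synth_model, hub)
        res = run(
            synth_model,
            _quiet(500.0, stimuli=[PulseTrain((hub,), 24.0, 2 * amp)], record=[hub]),
        )
        n_pulses = len(PulseTrain((hub,), 24.0, 1.0).pulse_times(500.0))
        assert res.spike_count(hub) == n_pulses


class TestSubthreshold:
    def test_identical_conditions_identical_histograms(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        cfg = SimConfig(duration=500.0, stimuli=[PoissonDrive((hub,), 10, 40)],
                        record=[hub], seed=5)
        a = run(synth_model, cfg)
        b = run(synth_model, cfg)
        cmp = compare_subthreshold(a, b, hub)
        assert np.array_equal(cmp["hist_a"], cmp["hist_b"])
        assert cmp["p_value"] == pytest.approx(1.0)

    def test_spike_adjacent_samples_excluded(self, synth_model, synth_truth):
        hub = synth_truth.hub_ids[0]
        cfg = SimConfig(duration=1000.0, stimuli=[PoissonDrive((hub,), 30, 60)],
                        record=[hub], seed=6)
        res = run(synth_model, cfg)
        assert res.spike_count(hub) > 0
        sub = subthreshold_samples(res, hub)
        assert len(sub) < len(res.traces[hub])
        assert sub.max() < -40.0  # never at/above threshold
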