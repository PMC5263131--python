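"""Unit tests for the LIF spiking simulator and its devices."""

import numpy as np
import pytest

from neuroloop.spiking import (
    ConfigurationError,
    DeviceSpec,
    LIFParams,
    Network,
    PoissonGeneratorDevice,
    PopulationRateDevice,
    build_network,
)

P = LIFParams()  # tau_m 20, v_rest -70, v_thresh -55, tau_refrac 2, r_m 10


def single_neuron_net(dt=1.0, params=None):
    net = Network(dt_ms=dt)
    net.add_population("n", 1, params or P)
    return net


class TestMembraneDynamics:
    def test_equilibrium_at_rest_without_input(self):
        net = single_neuron_net()
        spikes = net.run(200.0)
        assert spikes == []
        assert net.populations["n"].v[0] == pytest.approx(P.v_rest)

    def test_constant_current_first_spike_at_tau_ln2(self):
        # r_m * I = 2 * (v_thresh - v_rest) puts the threshold crossing of
        # the membrane ODE solution exactly at t = tau_m * ln 2.
        amp = 2 * (P.v_thresh - P.v_rest) / P.r_m
        net = single_neuron_net()
        net.attach_device("dc", DeviceSpec("dc_generator", target="n",
                                           params={"amplitude": amp}))
        spikes = net.run(50.0)
        assert spikes, "neuron driven at twice threshold current must fire"
        t_expected = P.tau_m * np.log(2.0)
        assert abs(spikes[0].time_ms - t_expected) <= net.dt_ms

    def test_dc_subthreshold_steady_state_is_v_rest_plus_rI(self):
        amp = 1.0  # 10 mV drive < 15 mV threshold gap
        net = single_neuron_net()
        net.attach_device("dc", DeviceSpec("dc_generator", target="n",
                                           params={"amplitude": amp}))
        net.run(500.0)  # 25 membrane time constants
        assert net.populations["n"].v[0] == pytest.approx(
            P.v_rest + P.r_m * amp, abs=1e-6)

    def test_dc_amplitude_change_reaches_new_steady_state(self):
        net = single_neuron_net()
        dc = net.attach_device("dc", DeviceSpec("dc_generator", target="n",
                                                params={"amplitude": 0.5}))
        net.run(500.0)
        dc.amplitude = 1.2
        net.run(500.0)
        assert net.populations["n"].v[0] == pytest.approx(
            P.v_rest + P.r_m * 1.2, abs=1e-6)

    def test_zero_amplitude_device_is_inert(self):
        with_dev = single_neuron_net()
        with_dev.attach_device("dc", DeviceSpec("dc_generator", target="n",
                                                params={"amplitude": 0.0}))
        without = single_neuron_net()
        with_dev.run(100.0)
        without.run(100.0)
        np.testing.assert_array_equal(with_dev.populations["n"].v,
                                      without.populations["n"].v)

    def test_nonfinite_amplitude_rejected(self):
        net = single_neuron_net()
        dc = net.attach_device("dc", DeviceSpec("dc_generator", target="n"))
        with pytest.raises(ConfigurationError):
            dc.amplitude = np.nan

    def test_refractory_period_enforced(self):
        net = single_neuron_net()
        net.attach_device("dc", DeviceSpec("dc_generator", target="n",
                                           params={"amplitude": 20.0}))
        spikes = net.run(500.0)
        times = np.array([s.time_ms for s in spikes])
        assert len(times) > 10
        assert np.all(np.diff(times) >= P.tau_refrac)

    def test_subthreshold_linearity(self):
        """Summed subthreshold inputs produce summed responses."""
        def deflection(amp):
            net = single_neuron_net()
            net.attach_device("dc", DeviceSpec("dc_generator", target="n",
                                               params={"amplitude": amp}))
            net.run(40.0)
            return net.populations["n"].v[0] - P.v_rest

        assert deflection(0.3) + deflection(0.4) == pytest.approx(
            deflection(0.7), abs=1e-9)


class TestDenseTimestepOracle:
    def test_chain_spike_times_converge_to_fine_reference(self):
        """Spike times at dt=1 ms agree with a dt/100 reference integrator
        within one coarse step on a 3-neuron feedforward chain."""
        def run_chain(dt):
            net = Network(dt_ms=dt)
            net.add_population("chain", 3, P)
            net.connect({"population": "chain", "indices": [0]},
                        {"population": "chain", "indices": [1]}, 30.0, delay_ms=1.0)
            net.connect({"population": "chain", "indices": [1]},
                        {"population": "chain", "indices": [2]}, 30.0, delay_ms=1.0)
            net.attach_device("dc", DeviceSpec(
                "dc_generator", target={"population": "chain", "indices": [0]},
                params={"amplitude": 3.0}))
            spikes = net.run(30.0)
            first = {}
            for s in spikes:
                first.setdefault(s.neuron_id, s.time_ms)
            return first

        coarse, fine = run_chain(1.0), run_chain(0.01)
        for neuron in range(3):
            assert neuron in coarse and neuron in fine, \
                f"neuron {neuron} never spiked"
            assert abs(coarse[neuron] - fine[neuron]) <= 1.0


class TestPoissonGenerator:
    def test_zero_rate_never_spikes(self):
        net = single_neuron_net()
        dev = net.attach_device("pg", DeviceSpec(
            "poisson_generator", target="n", params={"rate": 0.0}))
        assert sum(dev.draw(1.0).sum() for _ in range(1000)) == 0

    def test_empirical_rate_within_three_standard_errors(self):
        net = single_neuron_net()
        dev = net.attach_device("pg", DeviceSpec(
            "poisson_generator", target="n", params={"rate": 100.0}))
        dev.seed(12345)
        n_steps = 100_000
        counts = np.array([dev.draw(1.0)[0] for _ in range(n_steps)])
        expected = 0.1  # 100 Hz * 1 ms
        se = np.sqrt(expected / n_steps)
        assert abs(counts.mean() - expected) < 3 * se

    def test_same_seed_reproduces_spike_sequence(self):
        def draw_sequence():
            net = single_neuron_net()
            dev = net.attach_device("pg", DeviceSpec(
                "poisson_generator", target="n", params={"rate": 500.0}))
            dev.seed(7)
            return [int(dev.draw(1.0)[0]) for _ in range(200)]

        assert draw_sequence() == draw_sequence()

    def test_negative_rate_rejected(self):
        net = single_neuron_net()
        dev = net.attach_device("pg", DeviceSpec("poisson_generator", target="n"))
        with pytest.raises(ConfigurationError):
            dev.rate = -1.0


class TestLeakyIntegrator:
    def make_driven_net(self, n_sources=1, li_weight=2.0):
        """Population wired so all sources spike at a known time."""
        net = Network(dt_ms=1.0)
        net.add_population("src", n_sources, P)
        net.attach_device("dc", DeviceSpec("dc_generator", target="src",
                                           params={"amplitude": 3.0}))
        net.attach_device("li", DeviceSpec(
            "leaky_integrator", target="src",
            params={"tau_ms": 10.0, "weight": li_weight, "v_rest": P.v_rest}))
        return net

    def test_no_source_spikes_stays_at_rest(self):
        net = Network(dt_ms=1.0)
        net.add_population("src", 1, P)
        dev = net.attach_device("li", DeviceSpec(
            "leaky_integrator", target="src", params={"tau_ms": 10.0}))
        net.run(100.0)
        assert dev.voltage == pytest.approx(dev.v_rest)

    def test_single_spike_deflection_and_exponential_decay(self):
        net = self.make_driven_net(li_weight=2.0)
        dev = net.devices["li"]
        # run until the first source spike
        while not net.step():
            pass
        peak = dev.voltage - dev.v_rest
        assert peak == pytest.approx(2.0)  # deflection equals the weight
        # remove the drive and watch pure exponential decay
        net.devices["dc"].amplitude = 0.0
        v0 = dev.voltage - dev.v_rest
        net.step()
        assert (dev.voltage - dev.v_rest) == pytest.approx(
            v0 * np.exp(-1.0 / 10.0), rel=1e-9)

    def test_two_simultaneous_spikes_double_the_deflection(self):
        net1 = self.make_driven_net(n_sources=1)
        net2 = self.make_driven_net(n_sources=2)
        for net in (net1, net2):
            while not net.step():
                pass
        d1 = net1.devices["li"].voltage - P.v_rest
        d2 = net2.devices["li"].voltage - P.v_rest
        assert d2 == pytest.approx(2 * d1)

    def test_unattached_device_rejected(self):
        net = Network(dt_ms=1.0)
        net.add_population("src", 3, P)
        with pytest.raises(ConfigurationError):
            net.attach_device("li", DeviceSpec(
                "leaky_integrator",
                target={"population": "src", "indices": []}))


class TestPopulationRate:
    def test_no_spikes_zero_rate(self):
        net = Network(dt_ms=1.0)
        net.add_population("p", 10, P)
        dev = net.attach_device("rate", DeviceSpec(
            "population_rate", target="p", params={"window_ms": 100.0}))
        net.run(150.0)
        assert dev.rate(net.time_ms) == 0.0

    def test_direct_count_arithmetic(self):
        """10 neurons firing 5 spikes each within 100 ms -> 50 Hz."""
        net = Network(dt_ms=1.0)
        net.add_population("p", 10, P)
        dev = net.attach_device("rate", DeviceSpec(
            "population_rate", target="p", params={"window_ms": 100.0}))
        for k in range(5):
            dev.record(20.0 * (k + 1), 10)  # all 10 neurons spike together
        assert dev.rate(100.0) == pytest.approx(50.0)

    def test_spikes_older_than_window_ignored(self):
        net = Network(dt_ms=1.0)
        net.add_population("p", 10, P)
        dev = net.attach_device("rate", DeviceSpec(
            "population_rate", target="p", params={"window_ms": 50.0}))
        dev.record(10.0, 30)
        assert dev.rate(200.0) == 0.0

    def test_window_shorter_than_dt_rejected(self):
        net = Network(dt_ms=1.0)
        net.add_population("p", 10, P)
        with pytest.raises(ConfigurationError):
            net.attach_device("rate", DeviceSpec(
                "population_rate", target="p", params={"window_ms": 0.5}))


class TestNetworkConstruction:
    def test_empty_description_stepping_is_noop(self):
        net = build_network({})
        assert net.n_neurons == 0
        assert net.step() == []

    def test_braitenberg_description_resolves_named_index_sets(self):
        from neuroloop.experiments.braitenberg import braitenberg_brain
        net = build_network(braitenberg_brain())
        assert net.n_neurons == 8
        assert len(net.resolve("sensors")) == 3
        assert len(net.resolve("actors")) == 2
        assert len(net.resolve("relays")) == 3

    def test_overlapping_index_sets_alias_shared_neurons(self):
        net = build_network({
            "populations": [{"name": "p", "size": 4}],
            "index_sets": {"a": {"population": "p", "indices": [0, 1, 2]},
                           "b": {"population": "p", "indices": [2, 3]}},
        })
        assert set(net.resolve("a").indices) & set(net.resolve("b").indices) == {2}

    def test_dangling_population_reference_rejected(self):
        with pytest.raises(ConfigurationError, match="unresolvable|unknown"):
            build_network({
                "populations": [{"name": "p", "size": 2}],
                "projections": [{"pre": "p", "post": "ghost", "weight": 1.0}],
            })

    def test_full_determinism_under_fixed_seed(self):
        def run():
            net = build_network({
                "populations": [{"name": "p", "size": 5}],
                "projections": [{"pre": "p", "post": "p", "weight": 0.5}],
                "devices": {"pg": {"kind": "poisson_generator", "target": "p",
                                   "params": {"rate": 800.0, "weight": 1.0}}},
            })
            net.seed(99)
            return [(s.neuron_id, s.time_ms) for s in net.run(500.0)]

        assert run() == run()


class TestLIFParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"tau_m": 0.0}, {"tau_syn": -1.0},
        {"v_thresh": -70.0},           # not above v_rest
        {"v_thresh": -80.0, "v_reset": -75.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            LIFParams(**kwargs)
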