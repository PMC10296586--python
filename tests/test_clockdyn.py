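import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortexmodes import (
    KClock,
    ClockEdge,
    ClockNetwork,
    StimulusRegime,
    wind,
    next_trigger_time,
    apply_prm,
    build_clock_network,
    simulate_clock_network,
    state_dimension,
    generate_range_dependent_grid,
)

TWO_PI = 2 * np.pi


class TestWinding:
    def test_zero_dt_is_identity(self):
        c = KClock(phases=[0.3, 1.1], rates=[1.0, 2.0])
        assert wind(c, 0.0) == pytest.approx([0.3, 1.1])

    def test_full_revolutions_return_to_start(self):
        c = KClock(phases=[0.5, 1.5], rates=[1.0, 2.0])
        assert wind(c, TWO_PI) == pytest.approx([0.5, 1.5], abs=1e-9)

    def test_direct_arithmetic(self):
        c = KClock(phases=[0.0, np.pi / 2], rates=[1.0, 0.5])
        assert wind(c, 3.0) == pytest.approx([3.0 % TWO_PI, np.pi / 2 + 1.5])

    def test_negative_dt_rejected(self):
        c = KClock(phases=[0.0], rates=[1.0])
        with pytest.raises(ValueError):
            wind(c, -0.1)

    @given(phi=st.floats(0, TWO_PI - 1e-9), omega=st.floats(0.1, 10),
           dt=st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_phases_stay_on_torus(self, phi, omega, dt):
        out = wind(KClock(phases=[phi], rates=[omega]), dt)
        assert 0 <= out[0] < TWO_PI


class TestTriggerTimes:
    def test_phase_exactly_at_trigger_waits_a_full_revolution(self):
        c = KClock(phases=[1.0], rates=[1.0])
        assert next_trigger_time(c, (0, 1.0), 5.0) == pytest.approx(5.0 + TWO_PI)

    def test_crossing_time_closed_form(self):
        c = KClock(phases=[3 * np.pi / 2], rates=[np.pi])
        assert next_trigger_time(c, (0, 0.0), 0.0) == pytest.approx(0.5)

    def test_zero_rate_never_crosses(self):
        # KClock forbids zero rates at construction; the operation guards too
        c = KClock(phases=[0.0], rates=[1.0])
        c.rates = np.array([0.0])
        with pytest.raises(ValueError):
            next_trigger_time(c, (0, 1.0), 0.0)


class TestPhaseResettingMap:
    def test_zero_kick_is_identity(self):
        phi = np.array([0.1, 3.0])
        assert apply_prm(phi, np.zeros(2)) == pytest.approx(phi)

    def test_wraparound(self):
        out = apply_prm(np.array([TWO_PI - 0.1, 0.0]), np.array([0.2, 0.0]))
        assert out == pytest.approx([0.1, 0.0], abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_prm(np.zeros(3), np.zeros(2))

    @given(st.lists(st.floats(0, TWO_PI - 1e-6), min_size=2, max_size=4))
    @settings(max_examples=30, deadline=None)
    def test_kicks_compose_additively(self, kick1):
        k1 = np.array(kick1)
        k2 = k1[::-1].copy()
        phi = np.linspace(0, 3, len(k1))
        seq = apply_prm(apply_prm(phi, k1), k2)
        once = apply_prm(phi, np.mod(k1 + k2, TWO_PI))
        assert seq == pytest.approx(once, abs=1e-9)


class TestClockNetworkSimulation:
    def test_edge_free_network_winds_exactly(self):
        grid = generate_range_dependent_grid(3, 3, beta=0.0, lam=1.0, seed=1)
        net = build_clock_network(grid, k=3, seed=2)
        rec = simulate_clock_network(net, None, t_end=1000.0, sample_dt=7.3)
        for row, cid in enumerate(rec.observed):
            c = net.clocks[cid]
            expected = np.mod(
                c.phases[:, None] + c.rates[:, None] * rec.sample_times[None, :],
                TWO_PI,
            )
            assert np.abs(expected - rec.phases[row, :3, :]).max() <= 1e-9

    def test_single_edge_receiver_matches_event_count_oracle(self):
        # receiver phase = phi0 + omega t + m * kick where m counts sender
        # crossings emitted at times <= t - delay
        om_s, om_r, tau, kick = 1.3, 0.7, 2.0, 0.4
        phi_s, phi_r = 1.0, 0.3
        net = ClockNetwork(
            clocks=[KClock([phi_s], [om_s]), KClock([phi_r], [om_r])],
            edges=[ClockEdge(0, 1, 0, 0.0, tau, np.array([kick]))],
        )
        rec = simulate_clock_network(net, None, t_end=60.0, sample_dt=0.5)
        first = (TWO_PI - phi_s) / om_s
        period = TWO_PI / om_s
        for i, t in enumerate(rec.sample_times):
            m = 0
            while first + m * period <= t - tau + 1e-12:
                m += 1
            expected = (phi_r + om_r * t + m * kick) % TWO_PI
            got = rec.phases[1, 0, i]
            assert abs((got - expected + np.pi) % TWO_PI - np.pi) <= 1e-9

    def test_arrivals_are_emissions_plus_delay(self):
        grid = generate_range_dependent_grid(2, 2, beta=1.0, lam=2.0, seed=3)
        net = build_clock_network(grid, k=2, seed=4)
        rec = simulate_clock_network(net, StimulusRegime(spikes=[(0, 1.0)]),
                                     t_end=30.0, sample_dt=0.5)
        assert rec.events, "expected trigger traffic"
        for ei, emit, arr in rec.events:
            assert arr == pytest.approx(emit + net.edges[ei].delay, abs=1e-12)

    def test_emission_times_increase_per_edge(self):
        grid = generate_range_dependent_grid(2, 2, beta=1.0, lam=2.0, seed=3)
        net = build_clock_network(grid, k=2, seed=4)
        rec = simulate_clock_network(net, None, t_end=40.0, sample_dt=1.0)
        from collections import defaultdict
        per_edge = defaultdict(list)
        for ei, emit, _ in rec.events:
            per_edge[ei].append(emit)
        for times in per_edge.values():
            assert np.all(np.diff(times) > 0)

    def test_replay_determinism_with_stimulus(self):
        grid = generate_range_dependent_grid(2, 2, beta=1.0, lam=2.0, seed=3)
        net = build_clock_network(grid, k=2, seed=4)
        stim = StimulusRegime(spikes=[(0, 1.0), (2, 2.5)])
        a = simulate_clock_network(net, stim, 30.0, sample_dt=0.5, seed=9)
        b = simulate_clock_network(net, stim, 30.0, sample_dt=0.5, seed=9)
        assert np.array_equal(a.phases, b.phases)
        assert a.events == b.events

    def test_sampled_phases_on_torus(self):
        grid = generate_range_dependent_grid(2, 2, beta=1.0, lam=2.0, seed=3)
        net = build_clock_network(grid, k=2, seed=4)
        rec = simulate_clock_network(net, StimulusRegime(spikes=[(1, 0.3)]),
                                     t_end=20.0, sample_dt=0.25)
        assert np.all(rec.phases >= 0) and np.all(rec.phases < TWO_PI)

    def test_unknown_stimulus_clock_rejected(self):
        grid = generate_range_dependent_grid(2, 2, beta=0.0, lam=1.0, seed=0)
        net = build_clock_network(grid, k=2, seed=1)
        with pytest.raises(ValueError):
            simulate_clock_network(net, StimulusRegime(spikes=[(99, 1.0)]),
                                   t_end=5.0)


class TestStateDimension:
    def test_clock_level_cortex_scale(self):
        assert state_dimension({"clocks": 1_000_000, "k": 10}) == 10_000_000

    def test_neuron_level_cortex_scale(self):
        assert state_dimension({"neurons": 10_000_000_000}) == 10_000_000_000

    def test_single_clock(self):
        grid = generate_range_dependent_grid(1, 1, beta=0.0, lam=1.0, seed=0)
        net = build_clock_network(grid, k=3, seed=0)
        assert state_dimension(net) == 3


class TestBuildClockNetwork:
    def test_shared_rates_are_identical_across_clocks(self):
        grid = generate_range_dependent_grid(3, 3, beta=0.5, lam=1.0, seed=2)
        net = build_clock_network(grid, k=4, seed=5, shared_rates=True)
        base = net.clocks[0].rates
        for c in net.clocks[1:]:
            assert np.array_equal(c.rates, base)

    def test_edges_follow_outer_graph(self):
        grid = generate_range_dependent_grid(3, 3, beta=0.7, lam=1.5, seed=2)
        net = build_clock_network(grid, k=2, seed=5)
        outer = set(zip(grid.sources.tolist(), grid.targets.tolist()))
        assert {(e.sender, e.receiver) for e in net.edges} == outer
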