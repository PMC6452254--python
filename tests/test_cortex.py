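"""Spiking sheet: construction, LIF dynamics, STDP, probes."""

import numpy as np
import pytest

from somadev.controllers import ConfigurationError
from somadev.cortex import (CortexState, attach_inputs, build_cortex,
                            lif_fi_rate, lif_step, probe_body_parts,
                            run_resting, stdp_update, stimulate_probe,
                            train_on_stream)
from somadev.fixtures import SyntheticStreamSpec, synth_receptor_stream


@pytest.fixture(scope="module")
def small_net():
    return build_cortex(300, seed=0)


@pytest.fixture(scope="module")
def wired_net():
    net = build_cortex(300, seed=0)
    labels = ["arm_r"] * 10 + ["arm_l"] * 10 + ["leg_l"] * 10 + ["leg_r"] * 10
    return attach_inputs(net, labels, seed=0)


class TestBuildCortex:
    @pytest.mark.parametrize("n, n_exc", [(120, 100), (600, 500), (2004, 1670)])
    def test_exact_five_to_one_ratio(self, n, n_exc):
        net = build_cortex(n, connection_prob=0.05, seed=1)
        assert int(net.is_exc.sum()) == n_exc
        assert net.ei_ratio == 5

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            build_cortex(100)
        with pytest.raises(ConfigurationError):
            build_cortex(601)

    def test_zero_connection_probability_no_synapses(self):
        net = build_cortex(120, connection_prob=0.0, seed=0)
        assert len(net.w) == 0

    def test_same_seed_identical_synapses(self):
        a = build_cortex(300, seed=4)
        b = build_cortex(300, seed=4)
        assert np.array_equal(a.post_idx, b.post_idx)
        assert np.array_equal(a.w, b.w)

    def test_dales_principle_at_build(self, small_net):
        pre = np.searchsorted(small_net.indptr,
                              np.arange(len(small_net.post_idx)),
                              side="right") - 1
        exc = small_net.is_exc[pre]
        assert np.all(small_net.w[exc] >= 0)
        assert np.all(small_net.w[~exc] <= 0)

    def test_stdp_flagged_on_ee_synapses_only(self, small_net):
        pre = np.searchsorted(small_net.indptr,
                              np.arange(len(small_net.post_idx)),
                              side="right") - 1
        plastic = small_net.plastic.astype(bool)
        assert np.all(small_net.is_exc[pre[plastic]])
        assert np.all(small_net.is_exc[small_net.post_idx[plastic]])


class TestLIF:
    def test_rest_is_an_equilibrium(self, small_net):
        state = CortexState.initial(small_net)
        for _ in range(100):
            lif_step(small_net, state, np.zeros(small_net.n_neurons), 1.0)
        assert np.allclose(state.v, small_net.lif_params["v_rest"])

    @pytest.mark.parametrize("I", [1.0, 1.5, 2.5])
    def test_fi_curve_matches_closed_form(self, I):
        net = build_cortex(120, connection_prob=0.0, seed=0)
        state = CortexState.initial(net)
        dt, T = 0.05, 4000.0
        count = 0
        Ivec = np.full(net.n_neurons, I)
        for _ in range(int(T / dt)):
            spikes, state = lif_step(net, state, Ivec, dt)
            count += int(0 in spikes)
        assert count / (T / 1000.0) == pytest.approx(lif_fi_rate(net, I),
                                                     rel=0.02)

    def test_longer_refractory_lowers_rate(self):
        rates = []
        for t_ref in (2.0, 4.0):
            net = build_cortex(120, connection_prob=0.0, seed=0,
                               lif_params={"refractory": t_ref})
            state = CortexState.initial(net)
            count = 0
            I = np.full(net.n_neurons, 2.0)
            for _ in range(20000):
                spikes, state = lif_step(net, state, I, 0.1)
                count += int(0 in spikes)
            rates.append(count)
        assert rates[1] < rates[0]

    def test_subrheobase_never_fires(self):
        net = build_cortex(120, connection_prob=0.0, seed=0)
        assert lif_fi_rate(net, 0.5) == 0.0


class TestSTDP:
    def _two_neuron_net(self):
        net = build_cortex(120, connection_prob=0.0, seed=0)
        # install one plastic E->E synapse 0 -> 1 by hand
        exc = np.nonzero(net.is_exc)[0][:2]
        indptr = np.zeros(net.n_neurons + 1, dtype=np.int64)
        indptr[exc[0] + 1:] = 1
        net.indptr = indptr
        net.post_idx = np.array([exc[1]], dtype=np.int64)
        net.w = np.array([0.5])
        net.plastic = np.ones(1, dtype=np.int8)
        return net, exc

    def test_pre_before_post_potentiates_by_formula(self):
        net, (pre, post) = self._two_neuron_net()
        s = net.stdp_params
        pre_trace = np.zeros(net.n_neurons)
        pre_trace[pre] = np.exp(-5.0 / s["tau_plus"])  # pre spiked 5 ms ago
        spiked = np.zeros(net.n_neurons, dtype=bool)
        spiked[post] = True
        w0 = net.w[0]
        stdp_update(net, pre_trace, np.zeros(net.n_neurons),
                    np.zeros(net.n_neurons, dtype=bool), spiked)
        assert net.w[0] - w0 == pytest.approx(
            s["A_plus"] * np.exp(-5.0 / s["tau_plus"]))

    def test_post_before_pre_depresses_by_formula(self):
        net, (pre, post) = self._two_neuron_net()
        s = net.stdp_params
        post_trace = np.zeros(net.n_neurons)
        post_trace[post] = np.exp(-5.0 / s["tau_minus"])
        spiked = np.zeros(net.n_neurons, dtype=bool)
        spiked[pre] = True
        w0 = net.w[0]
        stdp_update(net, np.zeros(net.n_neurons), post_trace, spiked,
                    np.zeros(net.n_neurons, dtype=bool))
        assert net.w[0] - w0 == pytest.approx(
            -s["A_minus"] * np.exp(-5.0 / s["tau_minus"]))

    def test_no_spikes_no_change(self):
        net, _ = self._two_neuron_net()
        w0 = net.w.copy()
        none = np.zeros(net.n_neurons, dtype=bool)
        stdp_update(net, np.ones(net.n_neurons), np.ones(net.n_neurons),
                    none, none)
        assert np.array_equal(net.w, w0)

    def test_weights_clipped_to_bounds(self):
        net, (pre, post) = self._two_neuron_net()
        net.w[0] = net.stdp_params["w_max"] - 1e-6
        pre_trace = np.full(net.n_neurons, 100.0)
        spiked = np.zeros(net.n_neurons, dtype=bool)
        spiked[post] = True
        stdp_update(net, pre_trace, np.zeros(net.n_neurons),
                    np.zeros(net.n_neurons, dtype=bool), spiked)
        assert net.w[0] <= net.stdp_params["w_max"]


class TestResting:
    def test_silent_network_flagged_degenerate(self, small_net):
        res = run_resting(small_net, 10.0, bg_rate=0.0, seed=0)
        assert res["degenerate"] and res["e_rate"] == 0.0

    def test_active_network_depolarized_above_rest(self, small_net):
        res = run_resting(small_net, 10.0, seed=0)
        assert not res["degenerate"]
        assert res["mean_depolarization"] > 0

    def test_log_rates_closer_to_normal_than_raw(self):
        from scipy import stats
        net = build_cortex(600, seed=0)
        res = run_resting(net, 30.0, seed=0)
        rates = res["rates"]
        pos = rates[rates > 0.05]
        z = (rates - rates.mean()) / rates.std()
        lr = np.log(pos)
        zl = (lr - lr.mean()) / lr.std()
        assert stats.kstest(zl, "norm").statistic < stats.kstest(z, "norm").statistic

    def test_ei_rates_balanced(self):
        net = build_cortex(600, seed=0)
        res = run_resting(net, 20.0, seed=0)
        assert res["i_rate"] == pytest.approx(res["e_rate"],
                                              rel=0.5, abs=1.0)


class TestTraining:
    def _stream(self, rho_in, rho_out, seed=0, duration=20.0):
        labels = ["arm_r"] * 10 + ["arm_l"] * 10 + ["leg_l"] * 10 + ["leg_r"] * 10
        spec = SyntheticStreamSpec(n_channels=40, block_labels=labels,
                                   rho_in=rho_in, rho_out=rho_out,
                                   duration=duration, seed=seed)
        return synth_receptor_stream(spec)

    def test_channel_mismatch_rejected(self, wired_net):
        bad = self._stream(0.5, 0.0)
        bad.values = bad.values[:, :10]
        with pytest.raises(ConfigurationError):
            train_on_stream(wired_net, bad, seed=0)

    def test_zero_amplitude_stream_bounded_drift(self, wired_net):
        stream = self._stream(0.0, 0.0)
        stream.values = np.zeros_like(stream.values)
        trained, log = train_on_stream(wired_net, stream, duration=5.0, seed=0)
        rel = np.abs(trained.w - wired_net.w).sum() / max(np.abs(wired_net.w).sum(), 1)
        assert rel < 0.05  # only background-driven drift

    def test_block_structure_shapes_input_weight_changes(self, wired_net):
        from scipy import stats
        stream = self._stream(0.8, 0.0, seed=3, duration=30.0)
        trained, _ = train_on_stream(wired_net, stream, seed=3)
        dw = trained.in_w - wired_net.in_w
        # correlate per-channel weight-change vectors within vs between blocks
        per_ch = [dw[wired_net.in_indptr[c]:wired_net.in_indptr[c + 1]].mean()
                  for c in range(wired_net.n_channels)]
        per_ch = np.asarray(per_ch)
        labels = np.asarray(wired_net.channel_labels)
        within_spread = np.mean([per_ch[labels == b].std()
                                 for b in np.unique(labels)])
        total_spread = per_ch.std()
        # co-driven channels change coherently: within-block spread smaller
        assert within_spread < total_spread

    def test_more_training_more_cumulative_change(self, wired_net):
        stream = self._stream(0.5, 0.0, seed=2, duration=20.0)
        _, log1 = train_on_stream(wired_net, stream, duration=5.0, seed=2)
        _, log2 = train_on_stream(wired_net, stream, duration=10.0, seed=2)
        assert log2["cumulative_dw"] > log1["cumulative_dw"]

    def test_dale_and_bounds_after_learning(self, wired_net):
        stream = self._stream(0.6, 0.1, seed=5, duration=20.0)
        trained, _ = train_on_stream(wired_net, stream, seed=5)
        pre = np.searchsorted(trained.indptr,
                              np.arange(len(trained.post_idx)),
                              side="right") - 1
        assert np.all(trained.w[~trained.is_exc[pre]] <= 0)
        assert np.all(trained.w[trained.plastic.astype(bool)] <=
                      trained.stdp_params["w_max"] + 1e-12)
        assert np.all(trained.in_w <= trained.in_w_max + 1e-12)
        assert np.all(trained.in_w >= 0)


class TestProbes:
    def test_zero_amplitude_response_small(self, wired_net):
        rm = stimulate_probe(wired_net, np.arange(5), amplitude=0.0,
                             n_trials=5, seed=0)
        assert abs(rm.response.mean()) < 2.0

    def test_all_channels_at_least_single_part_norm(self, wired_net):
        all_ch = np.arange(wired_net.n_channels)
        r_all = stimulate_probe(wired_net, all_ch, n_trials=5, seed=1)
        r_one = stimulate_probe(wired_net, np.arange(10), n_trials=5, seed=1)
        assert np.linalg.norm(np.clip(r_all.response, 0, None)) >= \
            np.linalg.norm(np.clip(r_one.response, 0, None))

    def test_same_seed_identical_maps(self, wired_net):
        a = stimulate_probe(wired_net, np.arange(10), n_trials=5, seed=3)
        b = stimulate_probe(wired_net, np.arange(10), n_trials=5, seed=3)
        assert np.array_equal(a.response, b.response)

    def test_empty_channel_set_rejected(self, wired_net):
        with pytest.raises(ConfigurationError):
            stimulate_probe(wired_net, np.array([], dtype=int))

    def test_probe_does_not_mutate_trained_weights(self, wired_net):
        w0 = wired_net.w.copy()
        stimulate_probe(wired_net, np.arange(10), n_trials=3, seed=0)
        assert np.array_equal(wired_net.w, w0)
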