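import numpy as np
import pytest

from owlsync import circuit as ci
from owlsync import experiments as ex


PAR = ci.AdExParams()


class TestAdEx:
    def test_rest_settles_at_leak_potential(self):
        T = int(5 * PAR.tau_m / ci.DT) + 1000
        tr = ci.simulate_adex(np.zeros(T), PAR)
        assert tr.spike_times.size == 0
        assert abs(tr.v[-1] - PAR.v_leak) < 0.1
        theta_rest = PAR.v1 + PAR.k1 * np.log1p(
            np.exp((PAR.v_leak - PAR.v2) / PAR.k2))
        assert abs(tr.theta[-1] - theta_rest) < 0.1

    def test_refractory_floor_on_isi(self):
        # strong fluctuating drive cannot violate the 1-ms refractory hold
        rng = np.random.default_rng(0)
        g = np.clip(20 + 30 * rng.standard_normal(20000), 0, None)
        tr = ci.simulate_adex(g, PAR)
        assert tr.spike_times.size > 10
        assert np.diff(tr.spike_times).min() >= PAR.refractory - 1e-12

    def test_fi_curve_nondecreasing(self):
        rates = []
        for g in (5.0, 8.0, 12.0, 20.0, 40.0):
            tr = ci.simulate_adex(np.full(20000, g), PAR)
            rates.append((tr.spike_times > 0.1).sum())
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ci.simulate_adex(np.full(100, -1.0), PAR)

    def test_dt_cap(self):
        with pytest.raises(ValueError):
            ci.simulate_adex(np.zeros(100), PAR, dt=1e-3)


class TestWiring:
    def test_frequency_weight_unity_at_own_bf(self):
        w = ci.SpaceMapWiring(n_neurons=5, gain=1.0)
        itds = w.best_itds()
        bfs = ci.spacemap_bf(itds)
        w_exc, w_inh = w.weights(itds, bfs)
        # the diagonal (same best ITD & BF) carries the maximal, excitatory
        # weight of each row
        for i in range(5):
            assert w_exc[i, i] == pytest.approx(1.0, rel=1e-6)
            assert w_inh[i, i] == 0.0

    def test_side_lobe_position_is_inhibitory(self):
        w = ci.SpaceMapWiring(n_neurons=3, itd_span=100e-6, gain=1.0)
        itds = w.best_itds()
        bf = ci.spacemap_bf(itds)
        period = 1.0 / bf[1]
        # an input exactly half a period away from the center neuron's best
        # ITD, same BF: center Gaussian ~0, first side Gaussian = 1/2
        in_itd = np.array([itds[1] + 0.5 * period])
        in_cf = np.array([bf[1]])
        w_exc, w_inh = w.weights(in_itd, in_cf)
        assert w_inh[1, 0] > 0
        assert w_exc[1, 0] == 0.0
        assert w_inh[1, 0] == pytest.approx(0.5, rel=0.05)

    def test_output_weights_peak_at_matched_itd_and_symmetric(self):
        ow = ci.OutputWiring(n_out=9, itd_span=100e-6, gain=1.0)
        W = ow.weights(ow.preferred_itds())
        assert np.allclose(np.diag(W), 1.0)
        assert np.allclose(W, W.T)

    def test_output_sd_outside_robust_range_warns(self):
        with pytest.warns(UserWarning):
            ci.OutputWiring(weight_sd_deg=90.0)


class TestSidePeakMeasure:
    itds = np.linspace(-320e-6, 320e-6, 81)

    def two_gaussian(self, amp_main, amp_side, main=160e-6, side=0.0):
        return (amp_main * np.exp(-0.5 * ((self.itds - main) / 30e-6) ** 2)
                + amp_side * np.exp(-0.5 * ((self.itds - side) / 30e-6) ** 2))

    def test_constructed_two_gaussian_ratio(self):
        curve = self.two_gaussian(100.0, 42.0)
        m = ci.measure_side_peaks(self.itds, curve, 160e-6)
        assert m.percent == pytest.approx(42.0, abs=1.5)

    def test_zero_side_region_scores_zero(self):
        curve = self.two_gaussian(100.0, 0.0)
        regions = ci.find_response_regions(self.itds,
                                           self.two_gaussian(100.0, 42.0),
                                           160e-6)
        m = ci.measure_side_peaks(self.itds, curve, 160e-6, regions=regions)
        assert m.percent == pytest.approx(0.0, abs=1.0)

    def test_flat_curve_is_error(self):
        with pytest.raises(ValueError):
            ci.measure_side_peaks(self.itds, np.ones(81), 160e-6)

    def test_micro_bumps_on_plateau_do_not_split_main(self):
        curve = self.two_gaussian(100.0, 30.0)
        curve[np.abs(self.itds - 160e-6) < 40e-6] += \
            0.2 * np.sin(np.arange((np.abs(self.itds - 160e-6) < 40e-6).sum()))
        reg = ci.find_response_regions(self.itds, curve, 160e-6)
        assert reg.main_peak_itd == pytest.approx(160e-6, abs=20e-6)
        assert all(abs(s - 0.0) < 60e-6 for s in reg.side_peak_itds)


@pytest.fixture(scope="module")
def tiny_run():
    scale = ex.ModelScale(n_cf=5, n_itd=9, n_trials=6, duration=0.25,
                          stim_itds_us=(80,), calib_itds_us=(-80, 0, 80))
    return scale, ex.run_iccl(scale, seed=3)


class TestPopulationPipeline:
    def test_seed_determinism_bit_for_bit(self, tiny_run):
        scale, run = tiny_run
        rerun = ex.run_iccl(scale, seed=3)
        for p1, p2 in zip(run.pops, rerun.pops):
            for n1, n2 in zip(p1.spikes, p2.spikes):
                for t1, t2 in zip(n1, n2):
                    assert np.array_equal(t1, t2)

    def test_iccl_rate_tuned_to_stimulus(self, tiny_run):
        _, run = tiny_run
        pop = run.pops[0]
        rates = pop.rates(analysis_start=0.05)
        # the matched column (best ITD == stimulus ITD) out-fires the
        # anti-phase columns on average
        matched = rates[np.isclose(pop.best_itd, 80e-6)]
        away = rates[np.abs(pop.best_itd * 1e6 - 80) > 100]
        assert matched.mean() > away.mean()

    def test_refractory_respected_in_population(self, tiny_run):
        _, run = tiny_run
        for trains in run.pops[0].spikes:
            for t in trains:
                if t.size > 1:
                    assert np.diff(t).min() >= 1e-3 - 1e-12

    def test_spacemap_and_output_run_and_stay_in_window(self, tiny_run):
        scale, run = tiny_run
        sm = ci.spacemap_layer(run.pops[0], scale.spacemap_wiring(),
                               dt=scale.dt)
        out = ci.output_layer(sm, scale.output_wiring(), dt=scale.dt)
        assert sm.n_neurons == scale.sm_neurons
        assert out.n_neurons == scale.out_neurons
        for pop in (sm, out):
            for trains in pop.spikes:
                for t in trains:
                    assert np.all((t >= 0) & (t <= pop.duration))

    def test_all_silent_input_gives_silent_spacemap(self, tiny_run):
        scale, run = tiny_run
        silent = ci.PopulationResponse(
            spikes=[[np.empty(0)] * 3 for _ in range(run.pops[0].n_neurons)],
            best_itd=run.pops[0].best_itd, best_cf=run.pops[0].best_cf,
            layer="iccl", duration=0.25, stim_itd=0.0)
        sm = ci.spacemap_layer(silent, scale.spacemap_wiring(), dt=scale.dt)
        assert all(t.size == 0 for row in sm.spikes for t in row)
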