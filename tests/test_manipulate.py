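import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from owlsync import manipulate as mp
from owlsync import synthetic
from owlsync.circuit import PopulationResponse, ResponseRegions


def build_population(rng, n_side=4, n_main=4, n_trials=10, duration=0.45,
                     kappa=0.6, side_rate=60.0):
    """Fixture population: main neurons share one envelope, side neurons
    another, so regions have internal synchrony structure."""
    env_main = synthetic.make_envelope(duration, rng)
    env_side = synthetic.make_envelope(duration, rng)
    spikes = []
    for k in range(n_side + n_main):
        env = env_side if k < n_side else env_main
        spec = synthetic.EnvelopeLockedSpec(base_rate=side_rate if k < n_side
                                            else 100.0, kappa=kappa,
                                            envelope=env)
        ts = synthetic.gen_envelope_locked(spec, n_trials, duration, rng)
        spikes.append(ts.spikes)
    n = n_side + n_main
    itds = np.linspace(-100e-6, 100e-6, n)
    side = np.zeros(n, bool)
    side[:n_side] = True
    main = ~side
    pop = PopulationResponse(spikes=spikes, best_itd=itds,
                             best_cf=np.full(n, 5000.0), layer="spacemap",
                             duration=duration, stim_itd=50e-6)
    regions = ResponseRegions(main=main, side=side, main_peak_itd=50e-6,
                              side_peak_itds=[-80e-6])
    return pop, regions


@pytest.fixture
def pop_regions(rng):
    return build_population(rng)


class TestTemplates:
    def test_single_neuron_template_is_own_times(self):
        times = np.array([0.005, 0.030, 0.060])
        pop = PopulationResponse(spikes=[[times]], best_itd=np.zeros(1),
                                 best_cf=np.zeros(1), layer="sm",
                                 duration=0.075, stim_itd=0.0)
        tpl = mp.template_times(pop, np.array([True]))
        assert tpl.shape == (1, 3)
        assert np.allclose(tpl[0], times)

    def test_template_is_mean_across_neurons(self):
        pop = PopulationResponse(
            spikes=[[np.array([0.005])], [np.array([0.015])]],
            best_itd=np.zeros(2), best_cf=np.zeros(2), layer="sm",
            duration=0.025, stim_itd=0.0)
        tpl = mp.template_times(pop, np.array([True, True]))
        assert tpl[0, 0] == pytest.approx(0.010)

    def test_empty_population_no_templates(self):
        pop = PopulationResponse(spikes=[[np.empty(0)]], best_itd=np.zeros(1),
                                 best_cf=np.zeros(1), layer="sm",
                                 duration=0.1, stim_itd=0.0)
        tpl = mp.template_times(pop, np.array([True]))
        assert np.isnan(tpl).all()


class TestShift:
    def test_alpha_zero_is_identity(self, pop_regions):
        pop, regions = pop_regions
        shifted = mp.shift_toward_template(pop, regions, 0.0)
        for a, b in zip(pop.spikes, shifted.spikes):
            for ta, tb in zip(a, b):
                assert np.array_equal(ta, tb)

    def test_alpha_one_lands_on_templates(self, pop_regions):
        pop, regions = pop_regions
        plan = mp.ShiftPlan()
        tpl = mp.template_times(pop, regions.side, plan)
        shifted = mp.shift_toward_template(pop, regions, 1.0, plan, tpl)
        i = int(np.flatnonzero(regions.side)[0])
        for tr, t in enumerate(shifted.spikes[i]):
            if t.size == 0:
                continue
            seg = np.minimum((t / plan.segment_length).astype(int),
                             tpl.shape[1] - 1)
            ok = np.isfinite(tpl[tr, seg])
            assert np.allclose(t[ok], tpl[tr, seg][ok], atol=1e-9)

    @given(alpha=hst.floats(0.0, 1.0))
    @settings(max_examples=12, deadline=None)
    def test_spike_counts_conserved_exactly(self, alpha):
        rng = np.random.default_rng(7)
        pop, regions = build_population(rng, n_trials=4)
        shifted = mp.shift_toward_template(pop, regions, alpha)
        for a, b in zip(pop.spikes, shifted.spikes):
            for ta, tb in zip(a, b):
                assert ta.size == tb.size

    def test_main_peak_untouched(self, pop_regions):
        pop, regions = pop_regions
        shifted = mp.shift_toward_template(pop, regions, 1.0)
        for i in np.flatnonzero(regions.main):
            for ta, tb in zip(pop.spikes[i], shifted.spikes[i]):
                assert np.array_equal(ta, tb)

    def test_spikes_stay_inside_their_segment(self, pop_regions):
        pop, regions = pop_regions
        plan = mp.ShiftPlan()
        shifted = mp.shift_toward_template(pop, regions, 1.0, plan)
        i = int(np.flatnonzero(regions.side)[0])
        for t in shifted.spikes[i]:
            assert np.all(t <= pop.duration)

    def test_invalid_alpha_rejected(self, pop_regions):
        pop, regions = pop_regions
        with pytest.raises(ValueError):
            mp.shift_toward_template(pop, regions, 1.5)


class TestCalibration:
    def test_synchrony_nondecreasing_in_alpha(self, rng):
        pop, regions = build_population(rng, n_trials=12, kappa=0.4)
        vals = []
        for alpha in (0.0, 0.3, 0.6, 1.0):
            s = mp.shift_toward_template(pop, regions, alpha)
            vals.append(mp.synchrony_summary(s, regions).side_standard)
        tol = 0.01 * max(vals)  # binning quantization near full collapse
        assert all(b >= a - tol for a, b in zip(vals, vals[1:]))
        assert vals[-1] > vals[0]

    def test_target_already_met_gives_zero(self, rng):
        pop, regions = build_population(rng, n_trials=8)
        initial = mp.synchrony_summary(pop, regions)
        a, _ = mp.calibrate_alpha(pop, regions,
                                  target=initial.side_standard * 0.5)
        assert a == 0.0

    def test_unreachable_target_saturates_with_warning(self, rng, caplog):
        pop, regions = build_population(rng, n_trials=8)
        with caplog.at_level("WARNING"):
            a, _ = mp.calibrate_alpha(pop, regions, target=1e6)
        assert a == 1.0
        assert any("unreachable" in r.message for r in caplog.records)

    def test_bisection_hits_intermediate_target(self, rng):
        pop, regions = build_population(rng, n_trials=12, kappa=0.4)
        lo = mp.synchrony_summary(pop, regions).side_standard
        hi = mp.synchrony_summary(
            mp.shift_toward_template(pop, regions, 1.0), regions).side_standard
        target = 0.5 * (lo + hi)
        a, _ = mp.calibrate_alpha(pop, regions, target=target)
        got = mp.synchrony_summary(
            mp.shift_toward_template(pop, regions, a), regions).side_standard
        assert got == pytest.approx(target, rel=0.1)
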