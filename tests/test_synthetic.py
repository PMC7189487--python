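import numpy as np
import pytest
from scipy import stats as sps

from owlsync import reproducibility as rp
from owlsync import synchrony as sy
from owlsync import synthetic
from owlsync.trials import Condition, firing_rate


class TestEnvelopeLocked:
    def test_seed_determinism(self):
        spec = synthetic.EnvelopeLockedSpec(base_rate=40, kappa=0.7)
        a = synthetic.gen_envelope_locked(spec, 10, 0.5, seed=42)
        b = synthetic.gen_envelope_locked(spec, 10, 0.5, seed=42)
        for ta, tb in zip(a.spikes, b.spikes):
            assert np.array_equal(ta, tb)

    def test_mean_rate_matches_spec(self, rng):
        spec = synthetic.EnvelopeLockedSpec(base_rate=80, kappa=0.8)
        ts = synthetic.gen_envelope_locked(spec, 200, 0.5, rng,
                                           analysis_start=0.0)
        assert firing_rate(ts) == pytest.approx(80, rel=0.05)

    def test_kappa_bounds_validated(self):
        with pytest.raises(ValueError):
            synthetic.EnvelopeLockedSpec(base_rate=10, kappa=1.5)

    def test_unfrozen_envelope_kills_reproducibility(self, rng):
        spec = synthetic.EnvelopeLockedSpec(base_rate=60, kappa=1.0)
        frozen = synthetic.gen_envelope_locked(spec, 50, 0.5, rng,
                                               frozen_envelope=True,
                                               analysis_start=0.0)
        fresh = synthetic.gen_envelope_locked(spec, 50, 0.5, rng,
                                              frozen_envelope=False,
                                              analysis_start=0.0)
        r_frozen = rp.reproducibility_of(frozen, window=5e-3, bin_size=1e-3)
        r_fresh = rp.reproducibility_of(fresh, window=5e-3, bin_size=1e-3)
        assert r_frozen.value > 5 * max(r_fresh.value, 0.01)

    def test_dead_time_respected(self, rng):
        spec = synthetic.EnvelopeLockedSpec(base_rate=200, kappa=0.5,
                                            dead_time=0.002)
        ts = synthetic.gen_envelope_locked(spec, 5, 0.5, rng)
        for t in ts.spikes:
            if t.size > 1:
                assert np.diff(t).min() >= 0.002 - 1e-12


class TestTunedUnits:
    def test_itd_tuning_quasi_periodic(self):
        spec = synthetic.TunedUnitSpec(kind="itd_quasiperiodic", peak_rate=80,
                                       floor_rate=5, best=0, period_us=200)
        r0 = spec.rate_at(0)
        r_half = spec.rate_at(100)
        r_side = spec.rate_at(200)
        assert r0 == pytest.approx(80)
        assert r_half == pytest.approx(5)  # anti-phase trough at half period
        assert 5 < r_side < 80  # damped side peak

    def test_sigmoid_monotone(self):
        spec = synthetic.TunedUnitSpec(kind="ild_sigmoid", peak_rate=60)
        rates = [spec.rate_at(v) for v in (-20, -10, 0, 10, 20)]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_rate_within_floor_and_peak(self):
        spec = synthetic.TunedUnitSpec(kind="space_gaussian", peak_rate=70,
                                       floor_rate=3)
        for v in np.linspace(-90, 90, 19):
            assert 3 - 1e-9 <= spec.rate_at(v) <= 70 + 1e-9

    def test_kappa_rank_recovery_across_units(self, rng):
        """True locking strength is rank-recoverable from reproducibility."""
        kappas = np.linspace(0.05, 0.95, 12)
        est = []
        for kappa in kappas:
            spec = synthetic.EnvelopeLockedSpec(base_rate=60, kappa=float(kappa))
            ts = synthetic.gen_envelope_locked(spec, 40, 0.5, rng,
                                               analysis_start=0.0)
            est.append(rp.reproducibility_of(ts, window=5e-3,
                                             bin_size=1e-3).value)
        rho = sps.spearmanr(kappas, est)[0]
        assert rho >= 0.8


class TestTetrodeSite:
    conds = [Condition("azimuth_deg", v) for v in (-20.0, 0.0, 20.0)]

    def test_shared_envelope_maximizes_shift_predictor(self, rng):
        site = synthetic.gen_tetrode_site(2, 1.0, self.conds[:1], 30,
                                          seed=rng, couple_kappa=False)
        _, _, pair = site.pairs()[0]
        c = self.conds[0]
        std = sy.pair_synchrony(pair.unit_a[c], pair.unit_b[c], "standard")
        shf = sy.pair_synchrony(pair.unit_a[c], pair.unit_b[c], "shifted")
        cor = sy.pair_synchrony(pair.unit_a[c], pair.unit_b[c], "corrected")
        # shared patterning accounts for nearly all synchrony
        assert shf.value > 0.6 * std.value
        assert abs(cor.value) < 0.4 * std.value

    def test_private_envelopes_give_chance_synchrony(self, rng):
        site = synthetic.gen_tetrode_site(2, 0.0, self.conds[:1], 30,
                                          seed=rng, couple_kappa=False)
        _, _, pair = site.pairs()[0]
        c = self.conds[0]
        cor = sy.pair_synchrony(pair.unit_a[c], pair.unit_b[c], "corrected")
        chance = 0.021 * cor.gm
        assert abs(cor.value) < 0.25 * chance + 0.05

    def test_rho_rank_recovery(self, rng):
        """Shared-envelope fraction is rank-recoverable from the excess
        shift-predictor synchrony, averaged over a site's pairs."""
        rhos = np.linspace(0.05, 0.95, 8)
        est = []
        for rho in rhos:
            site = synthetic.gen_tetrode_site(4, float(rho), self.conds[:2],
                                              30, seed=rng, couple_kappa=False)
            vals = []
            for _, _, pair in site.pairs():
                for c in self.conds[:2]:
                    shf = sy.pair_synchrony(pair.unit_a[c], pair.unit_b[c],
                                            "shifted")
                    vals.append(shf.value - 0.021 * shf.gm)  # excess over chance
            est.append(np.mean(vals))
        assert sps.spearmanr(rhos, est)[0] >= 0.8
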