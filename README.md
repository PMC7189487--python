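# owlsync

Spike-train patterning metrics and a population model of the barn owl's
auditory midbrain, built around one scientific question: **how does
stimulus-dependent spike timing shape the population code for sound
location?**

Neurons in the owl's inferior colliculus (ICcl) lock their spikes to the
envelope of a sound, and they do so more reliably at their preferred
interaural time difference (ITD) — so across-trial reproducibility of spike
trains rises with firing rate. Downstream, in the midbrain map of auditory
space, similarly tuned neurons inherit this stimulus-locked patterning as
pairwise spike synchrony. Because narrowband ITD detection is phase
ambiguous, population responses carry spurious "side peaks" at ITDs offset
by half a period of the best frequency; the model in this package shows
that keeping synchrony *stimulus dependent* (high at the main peak, low in
the side peaks) suppresses those side peaks in a downstream readout, while
artificially equalizing synchrony restores them.

## What is implemented

Analysis (for trial-structured spike data in a plain columnar format):

* **SAC reproducibility** — the shuffled autocorrelogram, a histogram of
  cross-trial spike intervals normalized so independent Poisson trains give
  the squared mean rate m²; reproducibility is
  `R = ∫_{−w}^{w} (SAC(τ) − m²) dτ / m`.
* **Victor–Purpura distance** — minimal edit cost between spike trains
  (insert/delete 1, shift q·|Δt|, q = 100 s⁻¹), averaged pairwise across
  trials and corrected by a Monte-Carlo chance model: a zero-intercept
  quartic in the geometric-mean spike count, with the published
  coefficients for 100/200/400-ms windows built in.
* **CCG synchrony** — 1-ms coincidences, 5-ms smoothing, normalization by
  bin × GM firing rate, ±10-ms integral; standard, shift-predictor
  (trial n vs n+1) and corrected (standard − shifted) variants.
* **Up-state detection** on multiunit activity via a 10-bin median filter.
* **Correlation machinery** — per-unit and pooled metric-vs-rate
  correlations with Fisher-z aggregation, per-unit normalization, slope and
  dynamic-range comparisons, MAD outlier flags.
* **Synthetic generators** — envelope-locked inhomogeneous Poisson units
  with controllable locking strength κ, tuned units (quasi-periodic ITD,
  sigmoidal ILD, Gaussian space), and tetrode-like sites whose only
  pair coupling is a shared envelope fraction ρ.

Model (`owlsync.periphery`, `owlsync.circuit`, `owlsync.experiments`):
a gammatone filterbank (1–9 kHz) and running binaural cross-correlation
with compressive gain control produce ξ(t) per (frequency, lag) channel;
adaptive-exponential integrate-and-fire neurons with a dynamic spiking
threshold form the ICcl sheet (drive `a·[exp(ξ) − b]₊` plus
neuron-specific noise whose level makes SNR grow with response strength),
a Mexican-hat-wired space map, and a Gaussian-pooling output readout.
`owlsync.manipulate` implements the 25-ms-segment spike-shift procedure
that equalizes side-peak with main-peak synchrony while conserving every
neuron's spike count exactly. See `docs/methods.md` for equations,
parameter tables and the reasoning behind every free constant.

## Worked example

Reproducibility and the shift predictor on synthetic units with known
ground truth:

```python
import numpy as np
from owlsync import (EnvelopeLockedSpec, gen_envelope_locked, make_envelope,
                     gen_tetrode_site, pair_synchrony, reproducibility_of,
                     firing_rate, Condition)

env = make_envelope(0.45, np.random.default_rng(0))
for kappa in (0.0, 0.5, 1.0):
    spec = EnvelopeLockedSpec(base_rate=60.0, kappa=kappa, envelope=env)
    ts = gen_envelope_locked(spec, 40, 0.45, seed=1)
    r = reproducibility_of(ts, window=1e-3, bin_size=1e-4)
    print(f"kappa={kappa:.1f}: rate={firing_rate(ts):5.1f} sp/s  "
          f"reproducibility={r.value:6.3f}")
```

    kappa=0.0: rate= 62.6 sp/s  reproducibility= 0.001
    kappa=0.5: rate= 60.2 sp/s  reproducibility= 0.075
    kappa=1.0: rate= 57.3 sp/s  reproducibility= 0.278

Unlocked spiking (κ = 0) sits at chance; reproducibility grows with the
envelope-locking strength at a fixed firing rate.

```python
conds = [Condition("azimuth_deg", 0.0)]
for rho in (0.0, 1.0):
    site = gen_tetrode_site(2, rho, conds, 30, seed=4, couple_kappa=False)
    _, _, pair = site.pairs()[0]
    c = conds[0]
    for kind in ("standard", "shifted", "corrected"):
        res = pair_synchrony(pair.unit_a[c], pair.unit_b[c], kind)
        print(f"rho={rho:.1f} {kind:9s} synchrony = {res.value:+.3f}")
```

    rho=0.0 standard  synchrony = +1.274
    rho=0.0 shifted   synchrony = +1.396
    rho=0.0 corrected synchrony = -0.122
    rho=1.0 standard  synchrony = +1.548
    rho=1.0 shifted   synchrony = +1.537
    rho=1.0 corrected synchrony = +0.010

With no shared envelope (ρ = 0) standard synchrony sits at the chance
level 0.021·GM ≈ 1.35 and the corrected CCG is ≈ 0; with a fully shared
envelope the shift predictor accounts for essentially all of the
(above-chance) synchrony — synchrony from shared patterning, not from
direct coupling.

The model experiments run from one call each, e.g.

```sh
owlsync experiment reproducibility --seed 1 --trials 30 --out rep.csv
owlsync experiment readout --seed 1 --trials 20 --out readout.csv
```

(the readout experiment simulates periphery → ICcl → space map → output
for four stimulus ITDs and takes a few minutes on one CPU).

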