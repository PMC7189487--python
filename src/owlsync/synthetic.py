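"""Synthetic spike-train generators with known ground truth.

These emulate the statistical structure the analyses assume, so every metric
can be validated without recordings: envelope-locked patterned spiking with
a controllable locking strength kappa (0 = homogeneous Poisson, 1 = fully
envelope-modulated), quasi-periodic ITD / sigmoidal ILD / Gaussian spatial
tuning with locking optionally coupled to rate, and tetrode-like sites of
co-tuned units whose only coupling is a shared stimulus envelope (fraction
rho), i.e. synchrony arises from shared patterning, never from direct
spike-level interaction.

Spikes are drawn from an inhomogeneous Poisson process by thinning, which is
exact for the intensity functions used here. An optional dead-time
post-processor enforces a refractory interval when more biological trains
are needed; the metrics themselves do not assume refractoriness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal

from .trials import Condition, TrialSet
from .synchrony import PairResponse

ENVELOPE_FS = 1000.0  # Hz, envelope sample rate
ENVELOPE_CUTOFF = 150.0  # Hz, lowpass corner of the envelope noise


def make_envelope(duration: float, rng: np.random.Generator,
                  cutoff: float = ENVELOPE_CUTOFF, fs: float = ENVELOPE_FS) -> np.ndarray:
    """Half-wave-rectified lowpass Gaussian noise, the default envelope.

    Matches the envelope statistics of a narrowband channel driven by
    broadband noise: positive, irregular, with fluctuations up to ``cutoff``.
    """
    n = int(round(duration * fs))
    x = rng.standard_normal(n + 200)
    sos = signal.butter(4, cutoff, fs=fs, output="sos")
    y = signal.sosfilt(sos, x)[200:]
    env = np.clip(y, 0.0, None)
    if env.max() == 0:
        env[:] = 1.0
    return env


def _thinned_poisson(intensity: np.ndarray, fs: float, duration: float,
                     rng: np.random.Generator) -> np.ndarray:
    lam_max = float(intensity.max())
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0, duration, n))
    grid = np.arange(intensity.size) / fs
    lam_t = np.interp(t, grid, intensity)
    keep = rng.uniform(0, lam_max, n) < lam_t
    return t[keep]


def apply_dead_time(times: np.ndarray, dead: float = 0.001) -> np.ndarray:
    """Remove spikes closer than ``dead`` seconds to the previous kept spike."""
    out = []
    last = -np.inf
    for t in times:
        if t - last >= dead:
            out.append(t)
            last = t
    return np.asarray(out)


@dataclass
class EnvelopeLockedSpec:
    """Envelope-locked inhomogeneous Poisson unit.

    intensity(t) = base_rate * [(1 - kappa) + kappa * env(t)/mean(env)],
    optionally scaled by ``onset_boost`` over the first 50 ms to emulate the
    onset-dominated responses of midbrain neurons.
    """

    base_rate: float
    kappa: float
    envelope: np.ndarray | None = None
    onset_boost: float = 1.0
    dead_time: float | None = None

    def __post_init__(self):
        if not 0 <= self.kappa <= 1:
            raise ValueError("kappa must lie in [0, 1]")
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")


def gen_envelope_locked(
    spec: EnvelopeLockedSpec,
    n_trials: int,
    duration: float,
    seed: int | np.random.Generator = 0,
    frozen_envelope: bool = True,
    unit_id: str = "synth",
    condition: Condition | None = None,
    analysis_start: float = 0.050,
) -> TrialSet:
    """Generate a TrialSet of envelope-locked trials.

    With ``frozen_envelope`` the same envelope is reused across trials (the
    frozen-noise protocol that makes across-trial patterning measurable);
    otherwise each trial gets a fresh envelope and reproducibility collapses
    to chance regardless of kappa.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    env = spec.envelope
    if env is None and frozen_envelope:
        env = make_envelope(duration, rng)
    trials = []
    for _ in range(n_trials):
        e = env if frozen_envelope else make_envelope(duration, rng)
        mean_e = e.mean() if e.mean() > 0 else 1.0
        lam = spec.base_rate * ((1 - spec.kappa) + spec.kappa * e / mean_e)
        if spec.onset_boost != 1.0:
            n_on = int(round(0.050 * ENVELOPE_FS))
            lam = lam.copy()
            lam[:n_on] *= spec.onset_boost
        t = _thinned_poisson(lam, ENVELOPE_FS, duration, rng)
        if spec.dead_time:
            t = apply_dead_time(t, spec.dead_time)
        trials.append(t)
    return TrialSet(unit_id=unit_id, spikes=trials, stim_duration=duration,
                    analysis_start=min(analysis_start, duration / 2),
                    condition=condition)


@dataclass
class TunedUnitSpec:
    """Stimulus-tuned unit: rate from a tuning curve, locking tied to rate.

    kinds: ``itd_quasiperiodic`` (center peak with damped side peaks at
    multiples of ``period_us``), ``ild_sigmoid``, ``space_gaussian``
    (Gaussian over azimuth or elevation in degrees).
    """

    kind: str
    peak_rate: float
    floor_rate: float = 2.0
    best: float = 0.0
    period_us: float = 200.0  # itd_quasiperiodic: side-peak spacing
    sigmoid_slope_db: float = 4.0
    space_sd_deg: float = 20.0
    kappa_max: float = 0.9
    couple_kappa: bool = True  # kappa proportional to normalized rate

    def rate_at(self, value: float) -> float:
        if self.kind == "itd_quasiperiodic":
            x = (value - self.best) / self.period_us
            c = np.cos(2 * np.pi * x) * np.exp(-(x ** 2) / (2 * 1.2 ** 2))
            shape = max(c, 0.0)
        elif self.kind == "ild_sigmoid":
            shape = 1.0 / (1.0 + np.exp(-(value - self.best) / self.sigmoid_slope_db))
        elif self.kind == "space_gaussian":
            shape = np.exp(-((value - self.best) ** 2) / (2 * self.space_sd_deg ** 2))
        else:
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        return self.floor_rate + (self.peak_rate - self.floor_rate) * float(shape)

    def kappa_at(self, value: float) -> float:
        if not self.couple_kappa:
            return self.kappa_max
        span = self.peak_rate - self.floor_rate
        norm = 0.0 if span <= 0 else (self.rate_at(value) - self.floor_rate) / span
        return self.kappa_max * norm


def gen_tuned_unit(
    spec: TunedUnitSpec,
    conditions: list[Condition],
    n_trials: int,
    duration: float = 0.450,
    seed: int | np.random.Generator = 0,
    unit_id: str = "tuned",
    envelope: np.ndarray | None = None,
) -> dict[Condition, TrialSet]:
    """Per-condition TrialSets for a tuned unit (frozen envelope per condition)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for cond in conditions:
        env = envelope if envelope is not None else make_envelope(duration, rng)
        es = EnvelopeLockedSpec(
            base_rate=spec.rate_at(cond.value),
            kappa=spec.kappa_at(cond.value),
            envelope=env,
        )
        out[cond] = gen_envelope_locked(es, n_trials, duration, rng,
                                        unit_id=unit_id, condition=cond)
    return out


@dataclass
class TetrodeSite:
    units: dict[str, dict[Condition, TrialSet]]
    true_rho: float
    true_specs: dict[str, TunedUnitSpec] = field(default_factory=dict)

    def pairs(self) -> list[tuple[str, str, PairResponse]]:
        out = []
        for ua, ub in combinations(self.units, 2):
            out.append((ua, ub, PairResponse(self.units[ua], self.units[ub])))
        return out


def gen_tetrode_site(
    n_units: int,
    shared_envelope_fraction: float,
    conditions: list[Condition],
    n_trials: int,
    duration: float = 0.450,
    peak_rate: float = 60.0,
    seed: int | np.random.Generator = 0,
    couple_kappa: bool = True,
) -> TetrodeSite:
    """Co-tuned units whose intensities mix a shared and a private envelope.

    With rho = 1 all units follow the same envelope, so the shifted CCG
    accounts for essentially all standard-CCG synchrony; with rho = 0 the
    pair's corrected CCG is ~0 and standard ~ shifted ~ chance.
    """
    rho = shared_envelope_fraction
    if not 0 <= rho <= 1:
        raise ValueError("shared_envelope_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shared = {c: make_envelope(duration, rng) for c in conditions}
    units: dict[str, dict[Condition, TrialSet]] = {}
    specs: dict[str, TunedUnitSpec] = {}
    for u in range(n_units):
        uid = f"u{u}"
        spec = TunedUnitSpec(kind="space_gaussian", peak_rate=peak_rate,
                             best=0.0, couple_kappa=couple_kappa)
        specs[uid] = spec
        per_cond = {}
        for cond in conditions:
            private = make_envelope(duration, rng)
            s, p = shared[cond], private
            mix = rho * s / max(s.mean(), 1e-12) + (1 - rho) * p / max(p.mean(), 1e-12)
            es = EnvelopeLockedSpec(base_rate=spec.rate_at(cond.value),
                                    kappa=spec.kappa_at(cond.value), envelope=mix)
            per_cond[cond] = gen_envelope_locked(es, n_trials, duration, rng,
                                                 unit_id=uid, condition=cond)
        units[uid] = per_cond
    return TetrodeSite(units=units, true_rho=rho, true_specs=specs)
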