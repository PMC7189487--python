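"""Trial-structured spike-train containers, readers/writers and rate utilities.

All spike times are in **seconds**, relative to stimulus onset. Every public
interface of the package works in seconds; microsecond or millisecond
quantities (ITDs, coincidence windows) are converted at the boundary. This
single-unit discipline is deliberate: the quantities handled here span five
orders of magnitude (10 us ITD steps to 1 s stimuli) and silent unit mix-ups
are the dominant failure mode of spike-train tooling.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default onset-exclusion window (s): onset-dominated responses are excluded
#: from all patterning analyses by starting 50 ms after stimulus onset.
DEFAULT_ANALYSIS_START = 0.050


@dataclass(frozen=True)
class Condition:
    """A stimulus descriptor: a cue kind and its value.

    kind is one of ``itd_us``, ``ild_db``, ``azimuth_deg``, ``elevation_deg``,
    ``model_itd_us`` (value units follow the kind's suffix).
    """

    kind: str
    value: float

    KINDS = ("itd_us", "ild_db", "azimuth_deg", "elevation_deg", "model_itd_us")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}")


@dataclass
class TrialSet:
    """Spike times of one unit across repeated trials of one condition.

    Parameters
    ----------
    unit_id : str
        Identifier of the unit.
    spikes : list of 1-D arrays
        One sorted array of spike times (s) per trial. Empty trials are kept
        (correlogram estimators need the trial count) but can be dropped where
        a metric requires it (the distance metric omits empty trials).
    stim_duration : float
        Stimulus duration in seconds; all spike times must lie in
        ``[0, stim_duration]``.
    analysis_start : float
        Start of the analysis window (s); defaults to 50 ms onset exclusion.
    condition : Condition or None
        Stimulus descriptor.
    """

    unit_id: str
    spikes: list[np.ndarray]
    stim_duration: float
    analysis_start: float = DEFAULT_ANALYSIS_START
    condition: Condition | None = None

    def __post_init__(self):
        if not self.stim_duration > 0:
            raise ValueError("stim_duration must be positive")
        if not 0 <= self.analysis_start < self.stim_duration:
            raise ValueError("analysis_start must lie in [0, stim_duration)")
        clean = []
        for i, tr in enumerate(self.spikes):
            arr = np.asarray(tr, dtype=float)
            if arr.ndim != 1:
                raise ValueError("each trial must be a 1-D sequence of times")
            if arr.size and (arr.min() < 0 or arr.max() > self.stim_duration):
                raise ValueError(
                    f"trial {i}: spike times outside [0, {self.stim_duration}]"
                )
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                logger.warning("trial %d of unit %s unsorted; sorting", i, self.unit_id)
                arr = np.sort(arr)
            clean.append(arr)
        self.spikes = clean

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def analysis_duration(self) -> float:
        return self.stim_duration - self.analysis_start

    def spike_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spikes])

    def nonempty(self) -> "TrialSet":
        """Copy with empty trials removed (required by the distance metric)."""
        kept = [t for t in self.spikes if t.size]
        return replace(self, spikes=kept)


def windowed(ts: TrialSet, start: float, stop: float) -> TrialSet:
    """Restrict a TrialSet to ``[start, stop)`` and re-reference times to ``start``.

    Re-referencing keeps downstream lag arithmetic independent of where the
    analysis window sits within the stimulus.
    """
    if not (0 <= start < stop <= ts.stim_duration + 1e-12):
        raise ValueError(f"invalid window [{start}, {stop}) for duration {ts.stim_duration}")
    out = []
    for tr in ts.spikes:
        sel = tr[(tr >= start) & (tr < stop)] - start
        out.append(sel)
    return TrialSet(
        unit_id=ts.unit_id,
        spikes=out,
        stim_duration=stop - start,
        analysis_start=0.0,
        condition=ts.condition,
    )


def analysis_window(ts: TrialSet) -> TrialSet:
    """Apply the TrialSet's own onset exclusion (windowed at analysis_start)."""
    if ts.analysis_start == 0.0:
        return ts
    return windowed(ts, ts.analysis_start, ts.stim_duration)


def firing_rate(ts: TrialSet) -> float:
    """Mean firing rate (spikes/s) over the analysis window."""
    w = analysis_window(ts)
    if w.n_trials == 0:
        return 0.0
    return float(w.spike_counts().mean() / w.stim_duration)


def gm_rate(r1: float, r2: float) -> float:
    """Geometric-mean firing rate sqrt(r1*r2); zero if either rate is zero."""
    if r1 < 0 or r2 < 0:
        raise ValueError("rates must be nonnegative")
    return math.sqrt(r1 * r2)


@dataclass
class ConditionGrid:
    """Ordered set of stimulus conditions with a common trial count."""

    conditions: list[Condition]
    trials_per_condition: int

    def __post_init__(self):
        vals = [(c.kind, c.value) for c in self.conditions]
        if len(set(vals)) != len(vals):
            raise ValueError("condition values must be unique")


# ---------------------------------------------------------------------------
# Columnar text I/O
#
# Format: CSV/TSV with header unit_id,trial_id,condition_kind,condition_value,
# spike_time_s. A row per spike. Trials with no spikes are declared in an
# optional manifest CSV (unit_id,trial_id,condition_kind,condition_value) so
# that empty trials survive a round trip.
# ---------------------------------------------------------------------------

HEADER = ["unit_id", "trial_id", "condition_kind", "condition_value", "spike_time_s"]
MANIFEST_HEADER = ["unit_id", "trial_id", "condition_kind", "condition_value"]


def _sniff_delim(path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_spikes(
    path,
    stim_duration: float,
    analysis_start: float = DEFAULT_ANALYSIS_START,
    manifest_path=None,
) -> dict[str, dict[Condition, TrialSet]]:
    """Read a columnar spike file into ``{unit_id: {condition: TrialSet}}``.

    Trials listed in the manifest but absent from the spike file become empty
    trials. Malformed rows and negative times raise with the offending line
    number.
    """
    delim = _sniff_delim(path)
    groups: dict[tuple[str, Condition], dict[int, list[float]]] = {}

    def slot(unit, cond, trial):
        key = (unit, cond)
        trials = groups.setdefault(key, {})
        return trials.setdefault(trial, [])

    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != HEADER:
            raise ValueError(f"{path}: expected header {','.join(HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                unit, trial_s, kind, value_s, time_s = row
                trial = int(trial_s)
                cond = Condition(kind.strip(), float(value_s))
                t = float(time_s)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time {t}")
            slot(unit.strip(), cond, trial).append(t)

    if manifest_path is not None:
        mdelim = _sniff_delim(manifest_path)
        with open(manifest_path, "r", newline="") as fh:
            reader = csv.reader(fh, delimiter=mdelim)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != MANIFEST_HEADER:
                raise ValueError(
                    f"{manifest_path}: expected header {','.join(MANIFEST_HEADER)}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                try:
                    unit, trial_s, kind, value_s = row
                    cond = Condition(kind.strip(), float(value_s))
                    trial = int(trial_s)
                except (ValueError, TypeError) as exc:
                    raise ValueError(
                        f"{manifest_path}:{lineno}: malformed row {row!r}"
                    ) from exc
                slot(unit.strip(), cond, trial)  # ensure trial exists

    out: dict[str, dict[Condition, TrialSet]] = {}
    for (unit, cond), trials in groups.items():
        n = max(trials) + 1
        spikes = [np.sort(np.asarray(trials.get(i, []), dtype=float)) for i in range(n)]
        out.setdefault(unit, {})[cond] = TrialSet(
            unit_id=unit,
            spikes=spikes,
            stim_duration=stim_duration,
            analysis_start=analysis_start,
            condition=cond,
        )
    return out


def write_spikes(path, data: dict[str, dict[Condition, TrialSet]], manifest_path=None):
    """Write ``{unit: {condition: TrialSet}}`` to the columnar format.

    With ``manifest_path`` given, every (unit, trial, condition) triple is
    also listed there so empty trials round-trip.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(HEADER)
        for unit in data:
            for cond, ts in data[unit].items():
                for i, tr in enumerate(ts.spikes):
                    for t in tr:
                        w.writerow([unit, i, cond.kind, _fmt(cond.value), repr(float(t))])
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(MANIFEST_HEADER)
            for unit in data:
                for cond, ts in data[unit].items():
                    for i in range(ts.n_trials):
                        w.writerow([unit, i, cond.kind, _fmt(cond.value)])


def _fmt(x: float) -> str:
    return repr(float(x))
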