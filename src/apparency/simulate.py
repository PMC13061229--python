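"""Synthetic three-day crossover experiments: stimulus schedules, RR-interval
streams with injectable orienting responses, and protocol missingness.

The generator emulates the laboratory protocol end to end so every pipeline
stage is testable without real recordings:

* participants are randomized 1:1 to two groups with permuted blocks of
  sizes four and six;
* each period presents the 16 sounds once per stimulus hour in the two
  segments assigned to the participant's group, with inter-onset gaps of
  225 +- 30 s and no events in the bathing hour (21:00-22:00, segment B);
* RR intervals are baseline + optional sinusoidal diurnal drift + AR(1)
  Gaussian noise (i.i.d. by default, so the closed-form null salience rate
  applies exactly); recordings cover waking windows only (no beats during
  the 23:30-7:30 sleep window);
* each presentation independently elicits acceleration, deceleration or no
  response with probabilities (p_acc, p_dec, 1 - p_acc - p_dec); an
  acceleration subtracts ``response_delta_ms`` from the five post-onset
  intervals, a deceleration adds it — a rectangular shift aligned with the
  OR window, so the injected effect maps analytically to an expected OR of
  about delta / noise SD;
* missingness scenarios reproduce the trial's attrition shape (Period-1
  equipment failures, withdrawals after Period 1, scattered missing
  Period-2 cells for imputation testing).

All randomness flows from one root seed through per-participant spawned
generators, so outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import BeatSeries, StimulusEvent
from .protocol import (
    DAY_MS,
    DEFAULT_LAYOUT,
    ExperimentLayout,
    HOUR_MS,
    Participant,
    SECOND_MS,
    sound_codes,
)

__all__ = [
    "SimulationParams",
    "MissingnessScenario",
    "Experiment",
    "assign_groups",
    "build_schedule",
    "simulate_beats",
    "simulate_experiment",
    "apply_missingness",
    "trial_shaped_scenario",
    "populations",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic experiment.

    Defaults reflect the study conditions: 22 young adult participants,
    resting RR baseline 850 ms with 25 ms beat-to-beat noise (conventional
    healthy-adult values), i.i.d. noise (``ar1_coeff = 0``), and response
    probabilities near the observed per-direction salience rates with a
    100 ms response shift (expected |OR| about 4).
    """

    n_participants: int = 22
    baseline_rri_ms: float = 850.0
    rri_noise_sd_ms: float = 25.0
    ar1_coeff: float = 0.0
    diurnal_drift_ms: float = 0.0
    p_acc: float = 0.12
    p_dec: float = 0.12
    response_delta_ms: float = 100.0
    response_len_beats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coeff < 1:
            raise ValueError("ar1_coeff must be in [0, 1)")
        if self.p_acc < 0 or self.p_dec < 0 or self.p_acc + self.p_dec > 1:
            raise ValueError("need p_acc, p_dec >= 0 and p_acc + p_dec <= 1")
        if min(self.rri_noise_sd_ms, self.diurnal_drift_ms, self.response_delta_ms) < 0:
            raise ValueError("SD / amplitude parameters must be >= 0")
        if self.baseline_rri_ms <= 0:
            raise ValueError("baseline_rri_ms must be positive")


@dataclass(frozen=True)
class MissingnessScenario:
    """Which data vanish: equipment failures, withdrawals, missing cells."""

    machine_failure_period1: tuple[str, ...] = ()
    withdrawals_after_period1: tuple[str, ...] = ()
    missing_period2_cells: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        withdrawn = set(self.withdrawals_after_period1)
        if withdrawn & set(self.missing_period2_cells):
            raise ValueError(
                "withdrawn participants cannot also have missing Period-2 cells"
            )


@dataclass
class Experiment:
    """One complete synthetic experiment (both periods)."""

    participants: list[Participant]
    events: list[StimulusEvent]
    beats: dict[tuple[str, int], BeatSeries]
    truth: pd.DataFrame  # per-event injected outcome
    params: SimulationParams
    layout: ExperimentLayout = field(default_factory=lambda: DEFAULT_LAYOUT)


def assign_groups(n: int, rng: np.random.Generator) -> list[int]:
    """1:1 block randomization with permuted block sizes 4 and 6.

    Block sizes are drawn at random until at least ``n`` slots exist; each
    block holds equal numbers of both groups in random order.
    """
    groups: list[int] = []
    while len(groups) < n:
        size = int(rng.choice([4, 6]))
        block = [1] * (size // 2) + [2] * (size // 2)
        groups.extend(rng.permutation(block).tolist())
    return [int(g) for g in groups[:n]]


def _hour_onsets(
    hour_start_ms: float,
    n_events: int,
    layout: ExperimentLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """Onset times for one stimulus hour.

    Inter-onset gaps are uniform on mean +- halfwidth (225 +- 30 s); gap
    draws are rejected until the event train fits the hour, then the train
    is placed with a uniform lead-in, so every gap honours the stated
    bounds and every onset stays inside the hour.
    """
    lo = (layout.inter_onset_mean_s - layout.inter_onset_halfwidth_s) * SECOND_MS
    hi = (layout.inter_onset_mean_s + layout.inter_onset_halfwidth_s) * SECOND_MS
    if (n_events - 1) * lo >= HOUR_MS:
        raise ValueError(
            f"{n_events} events cannot fit one hour at minimum gap {lo / 1000:.0f} s"
        )
    for _ in range(1000):
        gaps = rng.uniform(lo, hi, size=n_events - 1)
        span = gaps.sum()
        if span < HOUR_MS:
            lead = rng.uniform(0.0, HOUR_MS - span)
            return hour_start_ms + lead + np.concatenate([[0.0], np.cumsum(gaps)])
    raise ValueError("could not place event train inside the hour")  # pragma: no cover


def build_schedule(
    layout: ExperimentLayout,
    participants: list[Participant],
    period: int,
    rng: np.random.Generator,
) -> list[StimulusEvent]:
    """Stimulus events for one period: fresh sound permutation per hour.

    Each participant receives, in each stimulus hour of their group's two
    assigned segments, all 16 sounds once in uniform random order; the
    bathing hour of segment B contains no events.
    """
    codes = sound_codes()
    events: list[StimulusEvent] = []
    for part in participants:
        idx = 0
        for seg in layout.segments_for(part.group, period):
            for hour in layout.stimulus_hours(seg.label):
                start, _ = seg.hour_window_ms(hour)
                onsets = _hour_onsets(start, len(codes), layout, rng)
                order = rng.permutation(len(codes))
                for onset, j in zip(onsets, order):
                    events.append(
                        StimulusEvent(
                            participant_id=part.id,
                            sound_code=codes[j],
                            onset_ms=float(onset),
                            segment=seg.label,
                            period=period,
                            presentation_index=idx,
                        )
                    )
                    idx += 1
    return events


def _waking_windows_ms(layout: ExperimentLayout) -> list[tuple[float, float]]:
    """Recording windows: Day 1 arrival 11:00 to lights-out, then wake to
    lights-out on Day 2, wake to departure 23:00 on Day 3."""
    sleep, wake = layout.sleep_start_hour, layout.wake_hour
    return [
        (11 * HOUR_MS, sleep * HOUR_MS),
        (DAY_MS + wake * HOUR_MS, DAY_MS + sleep * HOUR_MS),
        (2 * DAY_MS + wake * HOUR_MS, 2 * DAY_MS + 23 * HOUR_MS),
    ]


def _window_rri(
    n: int, t0_ms: float, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """n RR intervals starting near time t0: baseline + drift + AR(1) noise."""
    eps_sd = params.rri_noise_sd_ms * np.sqrt(1.0 - params.ar1_coeff**2)
    eps = rng.normal(0.0, eps_sd, size=n)
    if params.ar1_coeff > 0:
        noise = lfilter([1.0], [1.0, -params.ar1_coeff], eps)
    else:
        noise = eps
    rri = params.baseline_rri_ms + noise
    if params.diurnal_drift_ms > 0:
        # drift evaluated at nominal beat times (cheap, adequate for a slow sinusoid)
        t_h = (t0_ms + params.baseline_rri_ms * np.arange(n)) / HOUR_MS
        rri = rri + params.diurnal_drift_ms * np.sin(2 * np.pi * (t_h - 8.0) / 24.0)
    if (rri <= 0).any():
        raise ValueError("simulation parameters produced non-positive RR intervals")
    return rri


def simulate_beats(
    schedule: list[StimulusEvent],
    params: SimulationParams,
    rng: np.random.Generator,
    layout: ExperimentLayout = DEFAULT_LAYOUT,
    period: int = 1,
) -> tuple[dict[tuple[str, int], BeatSeries], pd.DataFrame]:
    """Beat series per participant for one period, with injected responses.

    Returns (beats keyed by (participant_id, period), truth table).  The
    truth table records the outcome drawn for every event: "acceleration",
    "deceleration" or "none".
    """
    by_pid: dict[str, list[StimulusEvent]] = {}
    for e in schedule:
        if e.period != period:
            continue
        by_pid.setdefault(e.participant_id, []).append(e)

    out: dict[tuple[str, int], BeatSeries] = {}
    truth_rows = []
    delta = params.response_delta_ms
    klen = params.response_len_beats
    probs = [params.p_acc, params.p_dec, 1.0 - params.p_acc - params.p_dec]

    for pid in sorted(by_pid):
        events = sorted(by_pid[pid], key=lambda e: e.onset_ms)
        pieces = []
        for w_lo, w_hi in _waking_windows_ms(layout):
            n = int((w_hi - w_lo) / params.baseline_rri_ms * 1.15) + klen + 10
            rri = _window_rri(n, w_lo, params, rng)
            times = w_lo + np.concatenate([[0.0], np.cumsum(rri)])
            w_events = [e for e in events if w_lo <= e.onset_ms < w_hi]
            for e in w_events:
                outcome = ("acceleration", "deceleration", "none")[
                    int(rng.choice(3, p=probs))
                ]
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "period": period,
                        "sound_code": e.sound_code,
                        "segment": e.segment,
                        "onset_ms": e.onset_ms,
                        "outcome": outcome,
                    }
                )
                if outcome == "none" or delta == 0.0:
                    continue
                shift = -delta if outcome == "acceleration" else delta
                b = int(np.searchsorted(times, e.onset_ms, side="left"))
                if b + klen >= times.size:
                    continue  # event too close to window end to carry a response
                rri[b : b + klen] += shift
                if (rri[b : b + klen] <= 0).any():
                    raise ValueError(
                        "response_delta_ms drives RR intervals non-positive"
                    )
                times[b + 1 : b + klen + 1] += shift * np.arange(1, klen + 1)
                times[b + klen + 1 :] += shift * klen
            keep = times <= w_hi
            pieces.append(times[keep])
        out[(pid, period)] = BeatSeries(
            participant_id=pid,
            beat_times_ms=np.concatenate(pieces),
            period=period,
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "period", "sound_code", "segment", "onset_ms", "outcome"],
    )
    return out, truth


def simulate_experiment(
    params: SimulationParams,
    layout: ExperimentLayout = DEFAULT_LAYOUT,
) -> Experiment:
    """Generate a full two-period crossover experiment from one seed."""
    root = np.random.SeedSequence(params.seed)
    ss_groups, ss_sched1, ss_sched2, ss_beats1, ss_beats2 = root.spawn(5)
    rng_groups = np.random.default_rng(ss_groups)
    groups = assign_groups(params.n_participants, rng_groups)
    width = max(2, len(str(params.n_participants)))
    participants = [
        Participant(id=f"p{i + 1:0{width}d}", group=g) for i, g in enumerate(groups)
    ]
    events: list[StimulusEvent] = []
    beats: dict[tuple[str, int], BeatSeries] = {}
    truths = []
    for period, ss_s, ss_b in ((1, ss_sched1, ss_beats1), (2, ss_sched2, ss_beats2)):
        sched = build_schedule(
            layout, participants, period, np.random.default_rng(ss_s)
        )
        b, truth = simulate_beats(
            sched, params, np.random.default_rng(ss_b), layout=layout, period=period
        )
        events.extend(sched)
        beats.update(b)
        truths.append(truth)
    return Experiment(
        participants=participants,
        events=events,
        beats=beats,
        truth=pd.concat(truths, ignore_index=True),
        params=params,
        layout=layout,
    )


def apply_missingness(
    experiment: Experiment, scenario: MissingnessScenario
) -> Experiment:
    """Remove data according to a missingness scenario.

    Period-1 recordings of machine-failure participants are dropped (the
    period stays completed but not valid); withdrawn participants lose all
    Period-2 data; named Period-2 participant x sound cells lose their
    events (for imputation testing).
    """
    known = {p.id for p in experiment.participants}
    named = (
        set(scenario.machine_failure_period1)
        | set(scenario.withdrawals_after_period1)
        | set(scenario.missing_period2_cells)
    )
    unknown = sorted(named - known)
    if unknown:
        raise ValueError(f"scenario names unknown participants: {unknown}")

    failures = set(scenario.machine_failure_period1)
    withdrawn = set(scenario.withdrawals_after_period1)
    cells = {k: set(v) for k, v in scenario.missing_period2_cells.items()}

    participants = []
    for p in experiment.participants:
        q = p
        if p.id in failures:
            q = q.without_period(1, completed=True)
        if p.id in withdrawn:
            q = q.without_period(2, completed=False)
        participants.append(q)

    def _keep_event(e: StimulusEvent) -> bool:
        if e.period == 1 and e.participant_id in failures:
            return False
        if e.period == 2 and e.participant_id in withdrawn:
            return False
        if e.period == 2 and e.sound_code in cells.get(e.participant_id, ()):
            return False
        return True

    events = [e for e in experiment.events if _keep_event(e)]
    beats = {
        (pid, period): s
        for (pid, period), s in experiment.beats.items()
        if not (period == 1 and pid in failures)
        and not (period == 2 and pid in withdrawn)
    }
    t = experiment.truth
    keep = ~(
        ((t["period"] == 1) & t["participant_id"].isin(failures))
        | ((t["period"] == 2) & t["participant_id"].isin(withdrawn))
    )
    return Experiment(
        participants=participants,
        events=events,
        beats=beats,
        truth=t[keep].reset_index(drop=True),
        params=experiment.params,
        layout=experiment.layout,
    )


def trial_shaped_scenario(
    experiment: Experiment,
    rng: np.random.Generator,
    n_failures_per_group: int = 2,
    n_withdrawals_per_group: int = 2,
    n_missing_cell_participants: int = 2,
    n_missing_sounds: int = 6,
) -> MissingnessScenario:
    """A missingness scenario shaped like the trial's attrition.

    Two participants per group lose Period 1 to equipment failure, two per
    group withdraw after Period 1, and two (from Group 2, among those
    remaining) have scattered missing Period-2 sound cells; with 22
    participants this yields an ITT population of 18 and a PPS of 16.
    """
    by_group = {1: [], 2: []}
    for p in experiment.participants:
        by_group[p.group].append(p.id)
    failures, withdrawals = [], []
    for g in (1, 2):
        ids = list(by_group[g])
        fail = rng.choice(ids, size=n_failures_per_group, replace=False).tolist()
        rest = [i for i in ids if i not in fail]
        quit_ = rng.choice(rest, size=n_withdrawals_per_group, replace=False).tolist()
        failures.extend(fail)
        withdrawals.extend(quit_)
    remaining_g2 = [
        i for i in by_group[2] if i not in withdrawals
    ]
    cell_pids = rng.choice(
        remaining_g2, size=n_missing_cell_participants, replace=False
    ).tolist()
    codes = np.array(sound_codes())
    cells = {
        pid: tuple(rng.choice(codes, size=n_missing_sounds, replace=False).tolist())
        for pid in cell_pids
    }
    return MissingnessScenario(
        machine_failure_period1=tuple(failures),
        withdrawals_after_period1=tuple(withdrawals),
        missing_period2_cells=cells,
    )


def populations(experiment: Experiment, scenario: MissingnessScenario) -> dict:
    """Analysis populations implied by a missingness scenario.

    * crossover: both periods valid (completers with usable Period-1 data);
    * ITT: any Period-2 data (withdrawals excluded), missing cells imputed;
    * PPS: ITT minus participants with missing Period-2 cells.
    """
    withdrawn = set(scenario.withdrawals_after_period1)
    failures = set(scenario.machine_failure_period1)
    with_cells = set(scenario.missing_period2_cells)
    ids = [p.id for p in experiment.participants]
    itt = [i for i in ids if i not in withdrawn]
    return {
        "crossover": [i for i in ids if i not in withdrawn and i not in failures],
        "itt": itt,
        "pps": [i for i in itt if i not in with_cells],
    }
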