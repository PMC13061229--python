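"""Shared experiment vocabulary: test sounds, segments, participants, layout.

The protocol presents 16 short chord stimuli — eight "musical" sounds (two
piano notes) M01–M08 and eight "complex" sounds (two pure tones) C09–C16 —
once per hour inside four 7-hour segments (A–D) spread over two full
laboratory days, in two crossover periods.  Everything downstream (window
extraction, apparency aggregation, crossover screening) speaks in terms of
the types defined here.

Time is represented as milliseconds since midnight of Day 1 of the current
period (a non-negative real), which matches RR-interval units and avoids
any timezone arithmetic.  Clock windows are resolved onto this axis via the
day index of each segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SoundDef",
    "Segment",
    "Participant",
    "ExperimentLayout",
    "builtin_sound_table",
    "sound_codes",
    "sound_table_frame",
    "DEFAULT_LAYOUT",
    "HOUR_MS",
    "SECOND_MS",
    "DAY_MS",
]

SECOND_MS = 1_000.0
HOUR_MS = 3_600_000.0
DAY_MS = 24 * HOUR_MS


@dataclass(frozen=True)
class SoundDef:
    """One test sound: a two-note chord at a fixed octave.

    ``timbre`` is "musical" (piano notes, short reverberation) or "complex"
    (pure tones).  Each musical sound has a complex counterpart at identical
    frequencies; ``partner_code`` names it.
    """

    code: str
    timbre: str  # "musical" | "complex"
    freq_low_hz: float
    freq_high_hz: float
    pitch_names: str
    partner_code: str

    def __post_init__(self) -> None:
        if self.timbre not in ("musical", "complex"):
            raise ValueError(f"unknown timbre {self.timbre!r}")
        if not (0 < self.freq_low_hz < self.freq_high_hz):
            raise ValueError("require 0 < freq_low_hz < freq_high_hz")


# The built-in stimulus table: interval families C+E and C+G#, each recorded
# at four octaves from C3 (130.8 Hz) up to G#6 (1661.4 Hz).  Musical codes
# M01–M08 pair one-to-one with complex codes C09–C16 at the same frequencies.
_SOUND_ROWS = [
    # (musical, complex, f_low, f_high, pitch)
    ("M01", "C09", 130.8, 164.8, "C3 + E3"),
    ("M02", "C10", 130.8, 207.7, "C3 + G#3"),
    ("M03", "C11", 261.6, 329.7, "C4 + E4"),
    ("M04", "C12", 261.6, 415.4, "C4 + G#4"),
    ("M05", "C13", 523.3, 659.3, "C5 + E5"),
    ("M06", "C14", 523.3, 830.7, "C5 + G#5"),
    ("M07", "C15", 1046.5, 1318.6, "C6 + E6"),
    ("M08", "C16", 1046.5, 1661.4, "C6 + G#6"),
]


def builtin_sound_table() -> list[SoundDef]:
    """Return the 16 stimulus definitions (8 musical + 8 complex).

    Musical entries come first (M01–M08), then their complex counterparts
    (C09–C16) sharing identical frequencies.
    """
    musical = [
        SoundDef(m, "musical", lo, hi, pitch, c)
        for m, c, lo, hi, pitch in _SOUND_ROWS
    ]
    cmplx = [
        SoundDef(c, "complex", lo, hi, pitch, m)
        for m, c, lo, hi, pitch in _SOUND_ROWS
    ]
    return musical + cmplx


def sound_codes() -> list[str]:
    """The 16 valid sound codes, musical first."""
    return [s.code for s in builtin_sound_table()]


def sound_table_frame():
    """The sound table as a DataFrame (code, timbre, freq_low_hz, freq_high_hz, pitch_names)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "code": s.code,
                "timbre": s.timbre,
                "freq_low_hz": s.freq_low_hz,
                "freq_high_hz": s.freq_high_hz,
                "pitch_names": s.pitch_names,
            }
            for s in builtin_sound_table()
        ]
    )


@dataclass(frozen=True)
class Segment:
    """One 7-hour stimulus window.

    ``day_index`` is 0-based from Day 1 of the period; the default layout
    puts A/B on Day 2 (index 1) and C/D on Day 3 (index 2).  ``clock_window``
    holds (start_hour, end_hour) in local clock hours.
    """

    label: str  # "A" | "B" | "C" | "D"
    daypart: str  # "daytime" | "evening"
    clock_window: tuple[int, int]
    day_index: int

    def __post_init__(self) -> None:
        if self.label not in "ABCD" or len(self.label) != 1:
            raise ValueError(f"unknown segment label {self.label!r}")
        expected = (8, 15) if self.daypart == "daytime" else (16, 23)
        if self.daypart not in ("daytime", "evening"):
            raise ValueError(f"unknown daypart {self.daypart!r}")
        if tuple(self.clock_window) != expected:
            raise ValueError(
                f"segment {self.label}: {self.daypart} clock window must be {expected}"
            )

    @property
    def start_ms(self) -> float:
        return self.day_index * DAY_MS + self.clock_window[0] * HOUR_MS

    @property
    def end_ms(self) -> float:
        return self.day_index * DAY_MS + self.clock_window[1] * HOUR_MS

    @property
    def hours(self) -> int:
        return self.clock_window[1] - self.clock_window[0]

    def hour_window_ms(self, hour: int) -> tuple[float, float]:
        """Absolute [start, end) of the ``hour``-th stimulus hour (0-based)."""
        if not 0 <= hour < self.hours:
            raise ValueError(f"hour {hour} outside segment {self.label}")
        start = self.start_ms + hour * HOUR_MS
        return start, start + HOUR_MS


@dataclass(frozen=True)
class Participant:
    """One randomized participant.

    ``group`` (1 or 2) fixes which segment pair carries stimuli in each
    period.  ``completed_periods`` are periods the participant finished;
    ``valid_periods`` additionally exclude periods lost to equipment failure.
    """

    id: str
    group: int
    completed_periods: frozenset[int] = frozenset({1, 2})
    valid_periods: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise ValueError(f"group must be 1 or 2, got {self.group}")
        if not set(self.valid_periods) <= set(self.completed_periods):
            raise ValueError("valid_periods must be a subset of completed_periods")

    def without_period(self, period: int, completed: bool = True) -> "Participant":
        """Copy with ``period`` removed from the valid (and optionally completed) sets."""
        comp = set(self.completed_periods)
        valid = set(self.valid_periods) - {period}
        if not completed:
            comp -= {period}
        return replace(
            self,
            completed_periods=frozenset(comp),
            valid_periods=frozenset(valid),
        )


def _default_segments() -> dict[str, Segment]:
    return {
        "A": Segment("A", "daytime", (8, 15), 1),
        "B": Segment("B", "evening", (16, 23), 1),
        "C": Segment("C", "daytime", (8, 15), 2),
        "D": Segment("D", "evening", (16, 23), 2),
    }


@dataclass(frozen=True)
class ExperimentLayout:
    """The two-period crossover stimulus layout.

    Group 1 hears stimuli in segments A and D during Period 1 and in B and C
    during Period 2; Group 2 the converse.  Each stimulus hour presents all
    16 sounds once, in random order, with inter-onset gaps of 225 ± 30 s.
    Bathing (21:00–22:00 on the evening day carrying segment B) contains no
    stimuli; its hour is later reconstructed from the 22:00–23:00 hour.
    """

    segments: dict[str, Segment] = field(default_factory=_default_segments)
    group_to_segments: dict[int, dict[int, tuple[str, str]]] = field(
        default_factory=lambda: {
            1: {1: ("A", "D"), 2: ("B", "C")},
            2: {1: ("B", "C"), 2: ("A", "D")},
        }
    )
    presentations_per_hour: int = 16
    hours_per_segment: int = 7
    inter_onset_mean_s: float = 225.0
    inter_onset_halfwidth_s: float = 30.0
    # bathing occupies one clock hour of segment B
    bathing_segment: str = "B"
    bathing_clock_hour: int = 21
    # sleep 23:30–7:30: no ECG recording
    sleep_start_hour: float = 23.5
    wake_hour: float = 7.5

    def __post_init__(self) -> None:
        if set(self.segments) != {"A", "B", "C", "D"}:
            raise ValueError("layout requires exactly segments A, B, C, D")
        for seg in ("A", "C"):
            if self.segments[seg].daypart != "daytime":
                raise ValueError(f"segment {seg} must be daytime")
        for seg in ("B", "D"):
            if self.segments[seg].daypart != "evening":
                raise ValueError(f"segment {seg} must be evening")
        for group, periods in self.group_to_segments.items():
            for period, pair in periods.items():
                if len(set(pair)) != 2:
                    raise ValueError(
                        f"group {group} period {period}: segment pair must be distinct"
                    )

    def segments_for(self, group: int, period: int) -> tuple[Segment, Segment]:
        labels = self.group_to_segments[group][period]
        return tuple(self.segments[lbl] for lbl in labels)

    @property
    def bathing_window_ms(self) -> tuple[float, float]:
        seg = self.segments[self.bathing_segment]
        start = seg.day_index * DAY_MS + self.bathing_clock_hour * HOUR_MS
        return start, start + HOUR_MS

    def is_bathing_hour(self, segment_label: str, onset_ms: float) -> bool:
        if segment_label != self.bathing_segment:
            return False
        lo, hi = self.bathing_window_ms
        return lo <= onset_ms < hi

    def stimulus_hours(self, segment_label: str) -> list[int]:
        """0-based stimulus hours of a segment, omitting the bathing hour."""
        seg = self.segments[segment_label]
        hours = list(range(seg.hours))
        if segment_label == self.bathing_segment:
            bathing_idx = self.bathing_clock_hour - seg.clock_window[0]
            if 0 <= bathing_idx < seg.hours:
                hours.remove(bathing_idx)
        return hours

    def segment_of_onset(self, onset_ms: float) -> str | None:
        for lbl, seg in self.segments.items():
            if seg.start_ms <= onset_ms < seg.end_ms:
                return lbl
        return None


DEFAULT_LAYOUT = ExperimentLayout()
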