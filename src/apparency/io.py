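"""On-disk artifacts: beat series, stimulus event logs, OR tables, apparency
tables and statistics reports.

All tabular artifacts are comma-separated UTF-8 text with a mandatory header
row and "." as the decimal separator.  Beat files carry beat *times*, never
intervals; RR intervals are always derived from successive differences so
there is a single source of truth.  Readers validate strictly and raise on
malformed rows rather than coercing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import sound_codes

__all__ = [
    "BeatSeries",
    "StimulusEvent",
    "read_beats",
    "write_beats",
    "read_events",
    "write_events",
    "write_or_table",
    "read_or_table",
    "write_apparency_table",
    "read_apparency_table",
    "write_report",
    "read_report",
    "read_supplementary_xlsx",
    "RRI_MIN_MS",
    "RRI_MAX_MS",
]

# Physiological plausibility bounds for a single RR interval.  Values outside
# this range (HR > 200 bpm or < 30 bpm) are treated as recording artifacts.
RRI_MIN_MS = 300.0
RRI_MAX_MS = 2000.0


@dataclass
class BeatSeries:
    """Ordered beat timestamps for one participant (one recording period).

    ``rr_intervals_ms[i]`` spans ``beat_times_ms[i]`` to ``beat_times_ms[i+1]``;
    ``beat_valid[i]`` flags whether that interval is physiologically plausible.
    """

    participant_id: str
    beat_times_ms: np.ndarray
    period: int = 1
    rri_min_ms: float = RRI_MIN_MS
    rri_max_ms: float = RRI_MAX_MS
    rr_intervals_ms: np.ndarray = field(init=False)
    beat_valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_ms, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError(
                f"participant {self.participant_id}: beat series must be a "
                "non-empty 1-d sequence"
            )
        diffs = np.diff(t)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"participant {self.participant_id}: non-monotone beat times "
                f"at row {i + 1} (t={t[i]:.1f} followed by t={t[i + 1]:.1f})"
            )
        self.beat_times_ms = t
        self.rr_intervals_ms = diffs
        self.beat_valid = (diffs >= self.rri_min_ms) & (diffs <= self.rri_max_ms)

    def __len__(self) -> int:
        return len(self.beat_times_ms)


@dataclass(frozen=True)
class StimulusEvent:
    """One presentation of one test sound to one participant."""

    participant_id: str
    sound_code: str
    onset_ms: float
    segment: str
    period: int
    presentation_index: int = 0

    def __post_init__(self) -> None:
        if self.segment not in "ABCD" or len(self.segment) != 1:
            raise ValueError(f"unknown segment {self.segment!r}")
        if self.period not in (1, 2):
            raise ValueError(f"period must be 1 or 2, got {self.period}")


_BEAT_COLUMNS = ("participant_id", "t_ms")
_EVENT_COLUMNS = ("participant_id", "sound_code", "onset_ms", "segment", "period")


def _read_csv(path: str | Path, required: tuple[str, ...], label: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{label} file {path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label} file {path} lacks columns {missing}")
    return df


def read_beats(
    path: str | Path,
    rri_min_ms: float = RRI_MIN_MS,
    rri_max_ms: float = RRI_MAX_MS,
) -> dict[tuple[str, int], BeatSeries]:
    """Read a beats.csv (participant_id, t_ms[, period]) into BeatSeries.

    Returns a mapping keyed by (participant_id, period); files without a
    period column are treated as single-period recordings (period 1).
    Timestamps must be non-decreasing *within the file order* per
    participant; rows are grouped by participant but never re-sorted, so a
    non-monotone series is reported as an error rather than silently fixed.
    """
    df = _read_csv(path, _BEAT_COLUMNS, "beats")
    known = set(_BEAT_COLUMNS) | {"period"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"beats file {path}: ignoring unknown columns {extra}")
    if "period" not in df.columns:
        df = df.assign(period=1)
    if df.empty:
        raise ValueError(f"beats file {path} contains no rows")
    out: dict[tuple[str, int], BeatSeries] = {}
    for (pid, period), grp in df.groupby(["participant_id", "period"], sort=True):
        out[(str(pid), int(period))] = BeatSeries(
            participant_id=str(pid),
            beat_times_ms=grp["t_ms"].to_numpy(dtype=float),
            period=int(period),
            rri_min_ms=rri_min_ms,
            rri_max_ms=rri_max_ms,
        )
    return out


def write_beats(series: dict[tuple[str, int], BeatSeries] | list[BeatSeries], path: str | Path) -> None:
    """Write BeatSeries to beats.csv (participant_id, t_ms, period)."""
    if isinstance(series, dict):
        series = list(series.values())
    frames = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "t_ms": s.beat_times_ms,
                "period": s.period,
            }
        )
        for s in series
    ]
    cols = ["participant_id", "t_ms", "period"]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_events(
    path: str | Path, strict_segment: bool = False, layout=None
) -> list[StimulusEvent]:
    """Read events.csv into validated StimulusEvents.

    Sound codes outside the 16-sound table are a hard error.  Onsets lying
    outside their segment's clock window raise a warning (error when
    ``strict_segment``); duplicate (participant, sound, segment, hour) rows
    warn with the offending keys.
    """
    from .protocol import DEFAULT_LAYOUT, HOUR_MS

    layout = layout or DEFAULT_LAYOUT
    df = _read_csv(path, _EVENT_COLUMNS, "events")
    valid_codes = set(sound_codes())
    bad = sorted(set(df["sound_code"]) - valid_codes)
    if bad:
        raise ValueError(f"events file {path}: unknown sound codes {bad}")

    events: list[StimulusEvent] = []
    misplaced = []
    for i, row in enumerate(df.itertuples(index=False)):
        seg = layout.segments[str(row.segment)]
        onset = float(row.onset_ms)
        if not (seg.start_ms <= onset < seg.end_ms):
            misplaced.append((str(row.participant_id), str(row.sound_code), onset))
        idx = int(getattr(row, "presentation_index", i))
        events.append(
            StimulusEvent(
                participant_id=str(row.participant_id),
                sound_code=str(row.sound_code),
                onset_ms=onset,
                segment=str(row.segment),
                period=int(row.period),
                presentation_index=idx,
            )
        )
    if misplaced:
        msg = f"events file {path}: {len(misplaced)} onsets outside their segment window"
        if strict_segment:
            raise ValueError(msg + f": {misplaced[:5]}")
        warnings.warn(msg)

    keys = df.assign(hour=(df["onset_ms"] // HOUR_MS).astype(int))[
        ["participant_id", "sound_code", "segment", "period", "hour"]
    ]
    dup_mask = keys.duplicated(keep=False)
    if dup_mask.any():
        dups = keys[dup_mask].drop_duplicates().to_records(index=False).tolist()
        warnings.warn(
            f"events file {path}: duplicate (participant, sound, segment-hour) rows: {dups}"
        )
    return events


def write_events(events: list[StimulusEvent], path: str | Path) -> None:
    cols = list(_EVENT_COLUMNS) + ["presentation_index"]
    df = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "sound_code": e.sound_code,
                "onset_ms": e.onset_ms,
                "segment": e.segment,
                "period": e.period,
                "presentation_index": e.presentation_index,
            }
            for e in events
        ],
        columns=cols,
    )
    df.to_csv(path, index=False, float_format="%.17g")


_OR_COLUMNS = (
    "participant_id",
    "sound_code",
    "period",
    "segment",
    "onset_ms",
    "m1_ms",
    "m2_ms",
    "sd_ms",
    "or_value",
    "label",
)


def write_or_table(measurements, path: str | Path) -> None:
    """Write scored presentations to or_table.csv in deterministic column order.

    ``measurements`` may be ORMeasurement objects or an equivalent DataFrame.
    Floats round-trip exactly (shortest-repr serialization).
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.loc[:, list(_OR_COLUMNS)]
    else:
        df = pd.DataFrame(
            [
                {
                    "participant_id": m.event.participant_id,
                    "sound_code": m.event.sound_code,
                    "period": m.event.period,
                    "segment": m.event.segment,
                    "onset_ms": m.event.onset_ms,
                    "m1_ms": m.m1_ms,
                    "m2_ms": m.m2_ms,
                    "sd_ms": m.sd_ms,
                    "or_value": m.or_value,
                    "label": m.label,
                }
                for m in measurements
            ],
            columns=list(_OR_COLUMNS),
        )
    bad = set(df["label"]) - {"acceleration", "deceleration", "unnoticed", "invalid"}
    if bad:
        raise ValueError(f"unknown OR labels {sorted(bad)}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_or_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, _OR_COLUMNS, "OR table")
    bad = set(df["label"].dropna()) - {
        "acceleration",
        "deceleration",
        "unnoticed",
        "invalid",
    }
    if bad:
        raise ValueError(f"OR table {path}: unknown labels {sorted(bad)}")
    return df


_APPARENCY_COLUMNS = (
    "participant_id",
    "sound_code",
    "scope",
    "n_valid",
    "n_salient",
    "n_acc",
    "n_dec",
    "apparency_pct",
    "acc_pct",
    "dec_pct",
    "unnoticed_pct",
)


def write_apparency_table(records, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, [c for c in _APPARENCY_COLUMNS if c in records.columns]]
        for col in _APPARENCY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"apparency table lacks column {col}")
    else:
        df = pd.DataFrame(
            [
                {
                    "participant_id": r.participant_id,
                    "sound_code": r.sound_code,
                    "scope": r.scope,
                    "n_valid": r.n_valid,
                    "n_salient": r.n_salient,
                    "n_acc": r.n_acc,
                    "n_dec": r.n_dec,
                    "apparency_pct": r.apparency_pct,
                    "acc_pct": r.acc_pct,
                    "dec_pct": r.dec_pct,
                    "unnoticed_pct": r.unnoticed_pct,
                }
                for r in records
            ],
            columns=list(_APPARENCY_COLUMNS),
        )
    df.to_csv(path, index=False, float_format="%.17g")


def read_apparency_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, _APPARENCY_COLUMNS, "apparency table")


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a statistics report as indented JSON (UTF-8)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(
        json.dumps(report, indent=2, default=_default, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def read_supplementary_xlsx(
    path: str | Path,
    mapping: dict,
) -> pd.DataFrame:
    """Adapter for published supplementary XLSX appendices.

    The sheet schemas of such appendices are not standardized, so the
    mapping is configuration, not code::

        mapping = {
            "sheet": 0,                      # sheet name or index
            "columns": {                     # source column -> internal name
                "ID": "participant_id",
                "Sound": "sound_code",
                "Group": "group",
                "Period": "period",
                "Apparency": "apparency_pct",
            },
        }

    Returns a DataFrame with the mapped internal columns, suitable for the
    crossover and trial analyses (long format, one row per observation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_excel(path, sheet_name=mapping.get("sheet", 0))
    columns = mapping["columns"]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"supplementary file {path}: expected columns {missing} not found "
            f"(present: {list(df.columns)})"
        )
    out = df.loc[:, list(columns)].rename(columns=columns)
    if "sound_code" in out.columns:
        bad = sorted(set(out["sound_code"].astype(str)) - set(sound_codes()))
        if bad:
            raise ValueError(f"supplementary file {path}: unknown sound codes {bad}")
    return out
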