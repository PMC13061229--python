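"""Apparency aggregation: from per-presentation OR labels to salience rates.

The apparency of a sound for a participant is the percentage of *valid*
presentations classified salient (|OR| > 2), with acceleration and
deceleration rates defined analogously.  Invalid presentations are excluded
from both numerator and denominator.  Rates can be aggregated at any scope:
per period (the 14-hour day combining both exposed segments), per daypart
(daytime = segments A and C, evening = B and D), per segment, or overall.

The bathing hour (21:00-22:00 of the evening day carrying segment B) has no
usable recordings; following the protocol's reconstruction rule, its
presentations are replaced by duplicating the same participant's
22:00-23:00 measurements, keeping per-period denominators at 14.  The
duplicates carry a provenance flag and the rule can be disabled.

Internal values are kept unrounded; rounding (1 decimal, half-up) happens
only at the presentation layer to mirror printed tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .protocol import DEFAULT_LAYOUT, HOUR_MS

__all__ = [
    "ApparencyRecord",
    "measurements_frame",
    "interpolate_bathing_hour",
    "compute_apparency",
    "response_ratios",
    "diurnal_split",
    "round_half_up",
]

logger = logging.getLogger("apparency")

_DAYPART = {"A": "daytime", "B": "evening", "C": "daytime", "D": "evening"}


@dataclass(frozen=True)
class ApparencyRecord:
    """Aggregated salience rates for one participant x sound x scope."""

    participant_id: str
    sound_code: str
    scope: str
    n_valid: int
    n_salient: int
    n_acc: int
    n_dec: int
    apparency_pct: float
    acc_pct: float
    dec_pct: float
    unnoticed_pct: float

    @property
    def defined(self) -> bool:
        return self.n_valid > 0


def measurements_frame(measurements) -> pd.DataFrame:
    """Normalize scored measurements to a DataFrame with a daypart column.

    Accepts a list of ORMeasurement or an OR-table DataFrame (as written by
    :func:`apparency.io.write_or_table`).
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
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
        )
    if df.empty:
        df = pd.DataFrame(
            columns=[
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
            ]
        )
    df["daypart"] = df["segment"].map(_DAYPART)
    if "interpolated" not in df.columns:
        df["interpolated"] = False
    return df


def interpolate_bathing_hour(
    measurements, layout=DEFAULT_LAYOUT, enabled: bool = True
) -> pd.DataFrame:
    """Apply the bathing-hour reconstruction rule to scored measurements.

    Measurements with onsets inside the bathing window are dropped; for each
    participant x period with segment-B exposure, measurements from the
    following clock hour (22:00-23:00) are duplicated in their place, with
    onsets shifted back one hour and ``interpolated=True``.  Disabled, the
    function only drops bathing-window measurements.
    """
    df = measurements_frame(measurements)
    lo, hi = layout.bathing_window_ms
    in_bath = (
        (df["segment"] == layout.bathing_segment)
        & (df["onset_ms"] >= lo)
        & (df["onset_ms"] < hi)
    )
    if in_bath.any():
        logger.info("dropping %d bathing-hour measurements", int(in_bath.sum()))
    df = df.loc[~in_bath]
    if not enabled:
        return df.reset_index(drop=True)

    next_hour = (
        (df["segment"] == layout.bathing_segment)
        & (df["onset_ms"] >= hi)
        & (df["onset_ms"] < hi + HOUR_MS)
    )
    dup = df.loc[next_hour].copy()
    dup["onset_ms"] = dup["onset_ms"] - HOUR_MS
    dup["interpolated"] = True
    if len(dup):
        logger.info("duplicating %d measurements into the bathing hour", len(dup))
    return pd.concat([df, dup], ignore_index=True)


def _scope_keys(scope: str) -> list[str]:
    return {
        "period": ["period"],
        "daypart": ["period", "daypart"],
        "segment": ["period", "segment"],
        "all": [],
    }[scope]


def compute_apparency(
    measurements,
    scope: str = "period",
    period: int | None = None,
    segments: list[str] | None = None,
    daypart: str | None = None,
) -> pd.DataFrame:
    """Aggregate OR labels into apparency rates per participant x sound x scope.

    ``scope`` selects the aggregation level ("period", "daypart", "segment"
    or "all"); the keyword filters restrict which measurements enter.
    Returns one row per participant x sound x scope cell with counts and
    percentages; cells whose valid count is zero are flagged
    ``defined=False`` with NaN percentages and a logged count.
    """
    if scope not in ("period", "daypart", "segment", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    df = measurements_frame(measurements)
    if period is not None:
        df = df[df["period"] == period]
    if segments is not None:
        df = df[df["segment"].isin(segments)]
    if daypart is not None:
        df = df[df["daypart"] == daypart]

    keys = ["participant_id", "sound_code"] + _scope_keys(scope)
    lab = df["label"]
    counted = df.assign(
        is_valid=(lab != "invalid"),
        is_acc=(lab == "acceleration"),
        is_dec=(lab == "deceleration"),
    )
    grp = counted.groupby(keys, sort=True)
    out = grp.agg(
        n_valid=("is_valid", "sum"),
        n_acc=("is_acc", "sum"),
        n_dec=("is_dec", "sum"),
    ).reset_index()
    out["n_salient"] = out["n_acc"] + out["n_dec"]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = out["n_valid"].to_numpy(dtype=float)
        out["apparency_pct"] = 100.0 * out["n_salient"] / denom
        out["acc_pct"] = 100.0 * out["n_acc"] / denom
        out["dec_pct"] = 100.0 * out["n_dec"] / denom
        out["unnoticed_pct"] = 100.0 - out["apparency_pct"]
    out["defined"] = out["n_valid"] > 0

    scope_cols = _scope_keys(scope)
    if scope_cols:
        out["scope"] = out[scope_cols].apply(
            lambda r: ",".join(f"{c}={r[c]}" for c in scope_cols), axis=1
        )
    else:
        out["scope"] = "all"
    n_undef = int((~out["defined"]).sum())
    if n_undef:
        logger.info("%d participant x sound cells have no valid presentations", n_undef)
    cols = (
        ["participant_id", "sound_code"]
        + scope_cols
        + [
            "scope",
            "n_valid",
            "n_salient",
            "n_acc",
            "n_dec",
            "apparency_pct",
            "acc_pct",
            "dec_pct",
            "unnoticed_pct",
            "defined",
        ]
    )
    return out[cols]


def response_ratios(
    measurements,
    sounds: list[str] | None = None,
    pooling: str = "counts",
) -> pd.DataFrame:
    """Per-sound acceleration/deceleration/unnoticed percentages over a scope.

    Default pooling sums raw counts across participants (rate = 100 x pooled
    acceleration count / pooled valid count); ``pooling="participants"``
    instead averages per-participant percentages, exposed for sensitivity
    analysis.  Requested sounds absent from the scope are omitted with a
    warning.  Rows sum to exactly 100 before rounding.
    """
    if pooling not in ("counts", "participants"):
        raise ValueError(f"unknown pooling {pooling!r}")
    df = measurements_frame(measurements)
    if sounds is not None:
        present = set(df["sound_code"])
        absent = [s for s in sounds if s not in present]
        if absent:
            warnings.warn(f"sounds absent from scope, omitted: {absent}")
        df = df[df["sound_code"].isin(sounds)]

    if pooling == "counts":
        valid = df[df["label"] != "invalid"]
        grp = valid.groupby("sound_code", sort=True)
        out = grp.agg(
            n_valid=("label", "size"),
            n_acc=("label", lambda s: (s == "acceleration").sum()),
            n_dec=("label", lambda s: (s == "deceleration").sum()),
        ).reset_index()
        out["acc_pct"] = 100.0 * out["n_acc"] / out["n_valid"]
        out["dec_pct"] = 100.0 * out["n_dec"] / out["n_valid"]
    else:
        per = compute_apparency(df, scope="all")
        per = per[per["defined"]]
        grp = per.groupby("sound_code", sort=True)
        out = grp.agg(
            n_valid=("n_valid", "sum"),
            acc_pct=("acc_pct", "mean"),
            dec_pct=("dec_pct", "mean"),
        ).reset_index()
    out["unnoticed_pct"] = 100.0 - out["acc_pct"] - out["dec_pct"]
    if sounds is not None:
        order = [s for s in sounds if s in set(out["sound_code"])]
        out = out.set_index("sound_code").loc[order].reset_index()
    return out[["sound_code", "n_valid", "acc_pct", "dec_pct", "unnoticed_pct"]]


def diurnal_split(measurements) -> pd.DataFrame:
    """Paired per-participant apparency: daytime (A, C) vs evening (B, D).

    Returns one row per participant x sound with ``daytime_pct`` and
    ``evening_pct``; participants missing either side for a sound are
    excluded pairwise with a logged count.
    """
    df = measurements_frame(measurements)
    per = compute_apparency(df, scope="daypart")
    per = per[per["defined"]]
    agg = (
        per.groupby(["participant_id", "sound_code", "daypart"], sort=True)
        .apply(
            lambda g: 100.0 * g["n_salient"].sum() / g["n_valid"].sum(),
            include_groups=False,
        )
        .rename("apparency_pct")
        .reset_index()
    )
    wide = agg.pivot_table(
        index=["participant_id", "sound_code"],
        columns="daypart",
        values="apparency_pct",
        aggfunc="first",
    ).reset_index()
    for col in ("daytime", "evening"):
        if col not in wide.columns:
            wide[col] = np.nan
    incomplete = wide["daytime"].isna() | wide["evening"].isna()
    if incomplete.any():
        logger.info(
            "excluding %d participant x sound pairs missing one daypart",
            int(incomplete.sum()),
        )
    wide = wide[~incomplete]
    return wide.rename(columns={"daytime": "daytime_pct", "evening": "evening_pct"})[
        ["participant_id", "sound_code", "daytime_pct", "evening_pct"]
    ].reset_index(drop=True)


def round_half_up(x, decimals: int = 1):
    """Round half away from zero upward, matching printed-table conventions."""
    q = Decimal(10) ** -decimals
    if np.isscalar(x):
        return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    arr = np.asarray(x, dtype=float)
    return np.array(
        [
            float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))
            for v in arr.ravel()
        ]
    ).reshape(arr.shape)
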