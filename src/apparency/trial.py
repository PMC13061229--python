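"""Randomized-trial analyses on Period-2 apparency data.

After crossover screening, Period-2 apparency values of the retained sounds
are analyzed across participants:

* ITT population (all randomized participants with any Period-2 data):
  missing participant x sound cells are filled with the median of the same
  participant's available Period-2 sound-level apparencies before analysis.
* PPS population (completers without protocol deviations): no imputation.
* One-way fixed-effects ANOVA treats each participant x sound apparency
  value as one observation grouped by sound (df = sounds-1, N - sounds) and
  reports eta-squared = SS_between / SS_total as effect size.
* Per-sound diurnal comparison uses paired t-tests on daytime (A, C) vs
  evening (B, D) apparency with Cohen's d_z = |t| / sqrt(n).
* The pooled per-sound acceleration / deceleration / unnoticed ratio table
  summarizes the response direction over the 14-hour day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import diurnal_split, response_ratios

__all__ = [
    "AnovaResult",
    "PairedTResult",
    "impute_period2_median",
    "anova_oneway",
    "paired_t",
    "diurnal_paired_tests",
    "run_rct",
]

logger = logging.getLogger("apparency")


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA with eta-squared effect size."""

    f: float
    df_between: int
    df_within: int
    p: float
    eta_sq: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairedTResult:
    """Paired t-test (two-tailed) with Cohen's d_z = |t|/sqrt(n)."""

    t: float
    df: int
    p: float
    d: float
    n: int
    degenerate: bool = False


def impute_period2_median(
    apparency: pd.DataFrame,
    sounds: list[str],
    participants: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing participant x sound Period-2 apparency cells.

    Each missing cell gets the median of that participant's *available*
    Period-2 sound-level apparencies (pandas median: midpoint at even
    counts), preserving the participant's own distribution and leaking no
    information across periods or participants.  A participant with zero
    available observations cannot be imputed and raises.

    Returns the completed long-format table and an imputation log with one
    row per filled cell.
    """
    df = apparency[["participant_id", "sound_code", "apparency_pct"]].copy()
    if participants is None:
        participants = sorted(df["participant_id"].unique())
    have = df.set_index(["participant_id", "sound_code"])["apparency_pct"]
    log_rows, new_rows = [], []
    for pid in participants:
        avail = df.loc[df["participant_id"] == pid, "apparency_pct"].dropna()
        missing = [s for s in sounds if (pid, s) not in have.index]
        if missing and avail.empty:
            raise ValueError(
                f"participant {pid}: no available Period-2 observations to impute from"
            )
        med = float(avail.median()) if len(avail) else np.nan
        for s in missing:
            new_rows.append(
                {"participant_id": pid, "sound_code": s, "apparency_pct": med}
            )
            log_rows.append(
                {"participant_id": pid, "sound_code": s, "imputed_value": med}
            )
    log = pd.DataFrame(log_rows, columns=["participant_id", "sound_code", "imputed_value"])
    if new_rows:
        logger.info("imputed %d missing Period-2 cells", len(new_rows))
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return df.sort_values(["participant_id", "sound_code"]).reset_index(drop=True), log


def anova_oneway(observations: dict[str, np.ndarray] | pd.DataFrame) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on values grouped by sound.

    ``observations`` is either a mapping group -> values or a long DataFrame
    with columns sound_code and apparency_pct.  Requires >= 2 groups with
    >= 2 observations each.  All-identical observations (zero total sum of
    squares) are flagged degenerate.
    """
    if isinstance(observations, pd.DataFrame):
        groups = {
            k: g["apparency_pct"].to_numpy(dtype=float)
            for k, g in observations.groupby("sound_code", sort=True)
        }
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in observations.items()}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than two observations")
        if np.isnan(v).any():
            raise ValueError(f"group {k!r} contains NaN")

    values = np.concatenate(list(groups.values()))
    n_total = values.size
    k = len(groups)
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    ss_total = ss_between + ss_within
    df_b, df_w = k - 1, n_total - k
    if ss_total == 0.0:
        return AnovaResult(np.nan, df_b, df_w, np.nan, np.nan, degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    eta_sq = float(ss_between / ss_total)
    return AnovaResult(float(f), df_b, df_w, p, eta_sq)


def paired_t(day, evening) -> PairedTResult:
    """Paired t-test on daytime vs evening apparency (difference = day - evening).

    t = mean(diff) / (sd(diff)/sqrt(n)) with df = n - 1, two-tailed p, and
    Cohen's d_z = |t| / sqrt(n).  Identical vectors (all differences zero)
    give t = 0, p = 1, d = 0; a constant non-zero difference is flagged
    degenerate (p undefined).
    """
    x = np.asarray(day, dtype=float)
    y = np.asarray(evening, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-d arrays")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0, n)
        return PairedTResult(np.nan, n - 1, np.nan, np.nan, n, degenerate=True)
    t = diff.mean() / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    d = abs(t) / np.sqrt(n)
    return PairedTResult(float(t), n - 1, p, float(d), n)


def diurnal_paired_tests(
    measurements, sounds: list[str]
) -> pd.DataFrame:
    """Per-sound paired daytime-vs-evening tests across participants.

    Builds the per-participant (daytime, evening) apparency pairs and runs
    one paired t-test per requested sound; sounds with fewer than two
    complete pairs are reported with NaN statistics.
    """
    pairs = diurnal_split(measurements)
    rows = []
    for sound in sounds:
        sub = pairs[pairs["sound_code"] == sound]
        if len(sub) < 2:
            rows.append(
                {"sound_code": sound, "n": len(sub), "t": np.nan, "df": np.nan,
                 "p": np.nan, "d": np.nan, "degenerate": True}
            )
            continue
        r = paired_t(sub["daytime_pct"].to_numpy(), sub["evening_pct"].to_numpy())
        rows.append(
            {"sound_code": sound, "n": r.n, "t": r.t, "df": r.df, "p": r.p,
             "d": r.d, "degenerate": r.degenerate}
        )
    return pd.DataFrame(rows)


def run_rct(
    period2_measurements,
    retained_sounds: list[str],
    itt_participants: list[str],
    pps_participants: list[str],
    ratio_sounds: list[str] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Run the full randomized-trial analysis bundle on Period-2 data.

    ``period2_measurements`` are scored Period-2 presentations (bathing rule
    already applied); ``retained_sounds`` comes from crossover screening.
    ITT analysis imputes missing participant x sound cells by the
    within-participant Period-2 median; PPS analyzes completers only with no
    imputation.  Returns a report dict with both ANOVAs, the per-sound
    diurnal paired-t table, and the pooled response-ratio table for
    ``ratio_sounds`` (default: the retained set).
    """
    if not retained_sounds:
        raise ValueError("retained sound list is empty; nothing to analyze")
    if not itt_participants:
        raise ValueError("ITT population is empty")
    from .aggregate import compute_apparency, measurements_frame

    df = measurements_frame(period2_measurements)
    df = df[df["sound_code"].isin(retained_sounds)]

    per = compute_apparency(df, scope="period")
    per = per[per["defined"]][["participant_id", "sound_code", "apparency_pct"]]

    itt_base = per[per["participant_id"].isin(itt_participants)]
    itt_full, imputation_log = impute_period2_median(
        itt_base, retained_sounds, participants=list(itt_participants)
    )
    itt_anova = anova_oneway(itt_full)

    pps_base = per[per["participant_id"].isin(pps_participants)]
    pps_anova = anova_oneway(pps_base[["sound_code", "apparency_pct"]])

    diurnal = diurnal_paired_tests(
        df[df["participant_id"].isin(itt_participants)], retained_sounds
    )
    ratios = response_ratios(
        df[df["participant_id"].isin(itt_participants)],
        sounds=ratio_sounds or retained_sounds,
    )

    def _anova_dict(a: AnovaResult) -> dict:
        return {
            "f": a.f, "df_between": a.df_between, "df_within": a.df_within,
            "p": a.p, "eta_sq": a.eta_sq, "degenerate": a.degenerate,
        }

    return {
        "populations": {
            "itt_n": len(set(itt_participants)),
            "pps_n": len(set(pps_participants)),
        },
        "retained_sounds": list(retained_sounds),
        "itt_anova": _anova_dict(itt_anova),
        "pps_anova": _anova_dict(pps_anova),
        "imputation_log": imputation_log,
        "diurnal_paired_tests": diurnal,
        "response_ratios": ratios,
        "conventions": {
            "paired_diff": "daytime - evening",
            "effect_size_paired": "d_z = |t|/sqrt(n)",
            "multiplicity": "no correction across per-sound tests",
        },
    }
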