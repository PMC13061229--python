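"""Two-period crossover reproducibility screening of the 16 test sounds.

For each sound, two per-participant statistics are formed from the 14-hour
apparency values of the two periods:

* carryover statistic: apparency(P1) + apparency(P2)   (range 0-200)
* period statistic:    (apparency(P1) - apparency(P2)) / 2

Each statistic is compared between the two randomization groups with
Welch's unequal-variance t-test (two-tailed, Satterthwaite fractional
degrees of freedom); the difference in means is oriented Group 2 - Group 1.
A sound showing a significant difference on either test (p < alpha) is
excluded as non-reproducible; the remainder is the retained set carried
into the randomized-trial analyses.  No multiplicity correction is applied
across the 16 per-sound tests (per-sound alpha = 0.05 screening); reports
note this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "carryover_values",
    "period_values",
    "welch_t",
    "crossover_table",
    "screen_sounds",
]

logger = logging.getLogger("apparency")


@dataclass(frozen=True)
class WelchResult:
    """Welch's t-test between two independent groups (Group 2 - Group 1)."""

    group1_mean: float
    group2_mean: float
    diff_means: float
    t: float
    df: float
    ci95: tuple[float, float]
    p: float
    n1: int
    n2: int
    degenerate: bool = False


def _per_participant(
    apparency_by_period: pd.DataFrame, statistic
) -> pd.DataFrame:
    """Pivot per-period apparency to wide form and apply a two-period statistic.

    Expects columns participant_id, sound_code, period, apparency_pct.
    Participants missing either period for a sound are excluded with a
    logged count.
    """
    required = {"participant_id", "sound_code", "period", "apparency_pct"}
    missing = required - set(apparency_by_period.columns)
    if missing:
        raise ValueError(f"apparency table lacks columns {sorted(missing)}")
    wide = apparency_by_period.pivot_table(
        index=["participant_id", "sound_code"],
        columns="period",
        values="apparency_pct",
        aggfunc="first",
    )
    for p in (1, 2):
        if p not in wide.columns:
            wide[p] = np.nan
    incomplete = wide[1].isna() | wide[2].isna()
    if incomplete.any():
        logger.info(
            "crossover: excluding %d participant x sound cells missing a period",
            int(incomplete.sum()),
        )
    wide = wide[~incomplete]
    out = wide.reset_index()
    out["value"] = statistic(out[1].to_numpy(), out[2].to_numpy())
    return out[["participant_id", "sound_code", "value"]]


def carryover_values(apparency_by_period: pd.DataFrame) -> pd.DataFrame:
    """Per-participant carryover statistic per sound: apparency P1 + P2."""
    return _per_participant(apparency_by_period, lambda p1, p2: p1 + p2)


def period_values(
    apparency_by_period: pd.DataFrame, orientation: str = "p1_minus_p2"
) -> pd.DataFrame:
    """Per-participant period statistic per sound: half the period difference.

    ``orientation`` selects (P1 - P2)/2 (default) or (P2 - P1)/2; only the
    sign of group means flips, not the test's p-value.
    """
    if orientation == "p1_minus_p2":
        stat = lambda p1, p2: (p1 - p2) / 2.0
    elif orientation == "p2_minus_p1":
        stat = lambda p1, p2: (p2 - p1) / 2.0
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return _per_participant(apparency_by_period, stat)


def welch_t(group1, group2, alpha: float = 0.05) -> WelchResult:
    """Welch's unequal-variance t-test, two-tailed, Group 2 - Group 1.

    t = (m2 - m1) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    fractional df; the 95% CI is diff +- t_{df,1-alpha/2} * SE.  Both groups
    need at least two observations.  Zero variance in both groups with equal
    means gives t = 0, p = 1; zero variance with unequal means is flagged
    degenerate (infinite t, p = 0).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 values (got {n1}, {n2})")
    m1, m2 = g1.mean(), g2.mean()
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    diff = m2 - m1
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if diff == 0.0:
            df = float(n1 + n2 - 2)
            return WelchResult(m1, m2, 0.0, 0.0, df, (0.0, 0.0), 1.0, n1, n2)
        return WelchResult(
            m1, m2, float(diff), np.inf if diff > 0 else -np.inf,
            float(n1 + n2 - 2), (float(diff), float(diff)), 0.0, n1, n2,
            degenerate=True,
        )
    se = np.sqrt(se2)
    t = diff / se
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    ci = (float(diff - tcrit * se), float(diff + tcrit * se))
    return WelchResult(
        float(m1), float(m2), float(diff), float(t), float(df), ci, p, n1, n2
    )


def crossover_table(
    values: pd.DataFrame,
    groups: dict[str, int] | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch comparison of a per-participant statistic between groups, per sound.

    ``values`` has columns participant_id, sound_code, value (as produced by
    :func:`carryover_values` / :func:`period_values`); ``groups`` maps
    participant_id to randomization group (1 or 2).  Output mirrors the
    standard crossover report shape: one row per sound with group means,
    difference (Group 2 - Group 1), t, df, 95% CI and p.
    """
    if isinstance(groups, pd.DataFrame):
        groups = dict(zip(groups["participant_id"], groups["group"]))
    df = values.copy()
    unknown = sorted(set(df["participant_id"]) - set(groups))
    if unknown:
        raise ValueError(f"participants without group assignment: {unknown}")
    df["group"] = df["participant_id"].map(groups)

    rows = []
    for sound, sub in df.groupby("sound_code", sort=True):
        g1 = sub.loc[sub["group"] == 1, "value"].to_numpy()
        g2 = sub.loc[sub["group"] == 2, "value"].to_numpy()
        r = welch_t(g1, g2, alpha=alpha)
        rows.append(
            {
                "sound_code": sound,
                "group1_mean": r.group1_mean,
                "group2_mean": r.group2_mean,
                "diff_means": r.diff_means,
                "t": r.t,
                "df": r.df,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p": r.p,
                "n1": r.n1,
                "n2": r.n2,
            }
        )
    return pd.DataFrame(rows)


def screen_sounds(
    carryover_stats: pd.DataFrame,
    period_stats: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Select sounds with no significant carryover or period effect.

    Both tables must cover the same sound set (one row per sound with a
    ``p`` column).  Returns the retained sound list (p >= alpha on both
    tests) and an exclusion table naming the failing test(s) and p-values.
    """
    c_sounds = set(carryover_stats["sound_code"])
    p_sounds = set(period_stats["sound_code"])
    if c_sounds != p_sounds:
        raise ValueError(
            f"carryover/period tables cover different sounds: "
            f"{sorted(c_sounds ^ p_sounds)}"
        )
    cp = carryover_stats.set_index("sound_code")["p"]
    pp = period_stats.set_index("sound_code")["p"]
    retained, excluded = [], []
    for sound in sorted(c_sounds):
        fails = []
        if cp[sound] < alpha:
            fails.append(("carryover", float(cp[sound])))
        if pp[sound] < alpha:
            fails.append(("period", float(pp[sound])))
        if fails:
            for test, p in fails:
                excluded.append({"sound_code": sound, "failed_test": test, "p": p})
        else:
            retained.append(sound)
    return retained, pd.DataFrame(
        excluded, columns=["sound_code", "failed_test", "p"]
    )
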