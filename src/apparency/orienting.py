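"""Event-locked orienting-response (OR) scoring of RR-interval streams.

For each stimulus onset the five complete RR intervals ending at or before
the onset form the pre-stimulus window and the five complete intervals
beginning at or after the onset form the post-stimulus window; an interval
that straddles the onset belongs to neither, since it mixes pre- and
post-stimulus physiology.  With M1 and SD the mean and sample standard
deviation of the pre window and M2 the mean of the post window, the OR
statistic is

    OR = (M1 - M2) / SD

OR > 2 is classified as heart-rate acceleration (post intervals shorten:
tension / surprise), OR < -2 as deceleration (relaxed attention), and
|OR| <= 2 as unnoticed.  Both thresholds are strict inequalities.

A window pair is invalid — no OR is computed — when either side has fewer
than five intervals within ``max_span_ms`` of the onset, contains an
artifact-flagged interval (outside the plausible RRI range), or when the
pre window has zero variance.

Under independent Gaussian RRIs with no stimulus effect, OR equals
sqrt(2/5) times a Student-t variate with 4 degrees of freedom (the sample
mean and SD of a Gaussian sample are independent), so the null salience
rate is P(|t4| > sqrt(10)) ~= 0.034.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BeatSeries, StimulusEvent

__all__ = [
    "WindowPair",
    "ORMeasurement",
    "extract_window_pair",
    "compute_or",
    "score_events",
    "null_salience_rate",
    "DEFAULT_K",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MAX_SPAN_MS",
]

DEFAULT_K = 5
DEFAULT_THRESHOLD = 2.0
# Five beats at extreme bradycardia (2 s intervals) still fit in 15 s per
# side; anything longer indicates a recording gap the window must not bridge.
DEFAULT_MAX_SPAN_MS = 15_000.0


@dataclass(frozen=True)
class WindowPair:
    """Pre/post RR-interval windows around one stimulus onset."""

    pre_rri_ms: np.ndarray
    post_rri_ms: np.ndarray
    onset_ms: float
    complete: bool


@dataclass(frozen=True)
class ORMeasurement:
    """Scored orienting response for one presentation.

    ``or_value`` is NaN when ``label == "invalid"``.
    """

    event: StimulusEvent
    m1_ms: float
    m2_ms: float
    sd_ms: float
    or_value: float
    label: str  # acceleration | deceleration | unnoticed | invalid

    @property
    def valid(self) -> bool:
        return self.label != "invalid"


def extract_window_pair(
    beats: BeatSeries,
    onset_ms: float,
    k: int = DEFAULT_K,
    max_span_ms: float = DEFAULT_MAX_SPAN_MS,
) -> WindowPair:
    """Extract the k pre- and k post-stimulus RR intervals around an onset.

    The pre window is the last k intervals whose *later* beat is at or
    before the onset; the post window is the first k intervals whose
    *earlier* beat is at or after the onset.  An interval ending exactly at
    the onset is pre; one beginning exactly at the onset is post; an
    interval strictly straddling the onset is dropped.  ``complete`` is
    False (never an exception) when either side has fewer than k intervals
    within ``max_span_ms`` of the onset or contains an artifact interval.
    """
    t = beats.beat_times_ms
    rri = beats.rr_intervals_ms
    valid = beats.beat_valid
    n = rri.size

    # Interval i spans (t[i], t[i+1]).  Pre intervals need t[i+1] <= onset:
    # the last such i is searchsorted(t, onset, 'right') - 2.
    last_pre = int(np.searchsorted(t, onset_ms, side="right")) - 2
    # Post intervals need t[i] >= onset: the first such i.
    first_post = int(np.searchsorted(t, onset_ms, side="left"))

    pre_lo, pre_hi = last_pre - k + 1, last_pre + 1
    post_lo, post_hi = first_post, first_post + k

    complete = pre_lo >= 0 and post_hi <= n
    pre = rri[max(pre_lo, 0) : max(pre_hi, 0)]
    post = rri[min(post_lo, n) : min(post_hi, n)]

    if complete:
        # span guard: window must lie within max_span_ms of the onset
        if onset_ms - t[pre_lo] > max_span_ms or t[post_hi] - onset_ms > max_span_ms:
            complete = False
        elif not (
            valid[pre_lo:pre_hi].all() and valid[post_lo:post_hi].all()
        ):
            complete = False
    else:
        complete = False

    return WindowPair(
        pre_rri_ms=np.asarray(pre, dtype=float),
        post_rri_ms=np.asarray(post, dtype=float),
        onset_ms=float(onset_ms),
        complete=bool(complete and pre.size == k and post.size == k),
    )


def compute_or(
    pair: WindowPair,
    event: StimulusEvent | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ORMeasurement:
    """Compute M1, M2, SD and the OR value for one window pair and classify it.

    SD is the sample standard deviation (divisor k-1) of the pre window.
    A zero-variance pre window yields label "invalid" with undefined OR.
    """
    if event is None:
        event = StimulusEvent("", "M01", pair.onset_ms, "A", 1)
    if not pair.complete:
        return ORMeasurement(event, np.nan, np.nan, np.nan, np.nan, "invalid")

    m1 = float(np.mean(pair.pre_rri_ms))
    m2 = float(np.mean(pair.post_rri_ms))
    sd = float(np.std(pair.pre_rri_ms, ddof=1))
    if sd == 0.0:
        return ORMeasurement(event, m1, m2, sd, np.nan, "invalid")
    or_value = (m1 - m2) / sd
    if or_value > threshold:
        label = "acceleration"
    elif or_value < -threshold:
        label = "deceleration"
    else:
        label = "unnoticed"
    return ORMeasurement(event, m1, m2, sd, float(or_value), label)


def score_events(
    beats: BeatSeries,
    events: list[StimulusEvent],
    k: int = DEFAULT_K,
    max_span_ms: float = DEFAULT_MAX_SPAN_MS,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ORMeasurement]:
    """Score every event of one participant against their beat series.

    Returns one ORMeasurement per event, in event order; deterministic
    given inputs.  Events whose onset falls outside the recording, inside a
    recording gap, or on an artifact interval come back labelled invalid.
    """
    for e in events:
        if e.participant_id != beats.participant_id:
            raise ValueError(
                f"event participant {e.participant_id!r} does not match "
                f"beat series {beats.participant_id!r}"
            )
    out = []
    for e in events:
        pair = extract_window_pair(beats, e.onset_ms, k=k, max_span_ms=max_span_ms)
        out.append(compute_or(pair, event=e, threshold=threshold))
    return out


def null_salience_rate(k: int = DEFAULT_K, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Closed-form P(|OR| > threshold) for i.i.d. Gaussian RRIs, no effect.

    M1 - M2 ~ N(0, 2 sigma^2 / k) independently of the pre-window SD, so
    OR = sqrt(2/k) * t_{k-1} and the salience probability is
    2 * SF_{t(k-1)}(threshold * sqrt(k/2)).
    """
    from scipy import stats

    return float(2.0 * stats.t.sf(threshold * np.sqrt(k / 2.0), df=k - 1))
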