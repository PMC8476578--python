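"""Joint-angle-reproduction (JAR) metrics: active proprioception measures.

A JAR trial asks the participant to align the head or the torso to a
target orientation (0 or +/-15 degrees) with, without, or with degraded
visual feedback. The final orientation is the mean of the tested body
part's steering angle over the last 1.5 s of the 4 s trial; derived
measures quantify proprioceptive accuracy (signed error, overshoot,
settling oscillations) and, for torso trials, head-torso decoupling
(whole-trial head anchoring index, final head-torso difference, and the
head alignment error relative to the target).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import anchoring_index
from .io_model import AngleSeries, JarTrial

FINAL_WINDOW_S = 1.5
SETTLE_BAND_DEG = 1.0

#: weights of the lateral steering combination (roll, yaw) -- the same
#: linear mix that maps lateral flexion and axial rotation onto a turn
LATERAL_WEIGHTS = (0.5, 0.5)


def steering_angle(series: AngleSeries, axis: str = "lateral") -> np.ndarray:
    """The measured control angle of a JAR trial.

    ``'lateral'`` (default) is the steering linear combination
    w_r * roll + w_y * yaw used by the flight game for turns; ``'pitch'``,
    ``'roll'`` and ``'yaw'`` select a single axis.
    """
    if axis == "lateral":
        wr, wy = LATERAL_WEIGHTS
        return wr * series.roll + wy * series.yaw
    return series.axis(axis)


def final_orientation(trial: JarTrial, axis: str = "lateral") -> float:
    """Mean steering angle of the tested body part over the last 1.5 s.

    The window is the set of samples with t >= t_end - 1.5 (closed
    boundary on the sample grid; at the nominal 68 ms step this is the
    last 23 samples of a 4 s trial).
    """
    series = trial.head if trial.body_part == "head" else trial.torso
    if series.duration < FINAL_WINDOW_S:
        raise ValueError("trial shorter than the final 1.5 s window")
    x = steering_angle(series, axis)
    m = series.t >= series.t[-1] - FINAL_WINDOW_S - 1e-9
    return float(x[m].mean())


@dataclass(frozen=True)
class JarMetrics:
    final_angle: float
    signed_error: float               # final - target; + = beyond the target
    overshoot: float                  # max excursion past the target, >= 0
    oscillation_count: int
    head_ai: float | None = None             # torso trials, whole trial
    head_torso_final_diff: float | None = None
    head_alignment_error: float | None = None


def _overshoot(x: np.ndarray, target: float) -> float:
    """Maximum excursion beyond the target in the target's direction."""
    if target > 0:
        over = float(np.max(x) - target)
    elif target < 0:
        over = float(target - np.min(x))
    else:
        over = float(np.max(np.abs(x))) - 0.0  # any excursion past 0 target
    return max(over, 0.0)


def _oscillations(x: np.ndarray, final: float, band: float = SETTLE_BAND_DEG) -> int:
    """Sign changes of (x - final) after first entering +/- band of final."""
    dev = x - final
    inside = np.nonzero(np.abs(dev) <= band)[0]
    if inside.size == 0:
        return 0
    dev = dev[inside[0]:]
    s = np.sign(dev)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def jar_metrics(trial: JarTrial, axis: str = "lateral") -> JarMetrics:
    """All per-trial JAR measures.

    Positive ``signed_error`` means the final position exceeded the target
    angle; ``overshoot`` is measured relative to the target; oscillations
    are counted as sign changes around the final angle after the trace
    first settles within +/-1 degree of it. Head-related fields
    (whole-trial anchoring index, final head-torso difference, head
    alignment error; negative = head angle smaller than torso angle) are
    computed for torso trials only.
    """
    final = final_orientation(trial, axis)
    tested = trial.head if trial.body_part == "head" else trial.torso
    x = steering_angle(tested, axis)
    metrics = dict(
        final_angle=final,
        signed_error=float(final - trial.target_angle),
        overshoot=_overshoot(x, trial.target_angle),
        oscillation_count=_oscillations(x, final),
    )
    if trial.body_part == "torso":
        hx = steering_angle(trial.head, axis)
        tx = steering_angle(trial.torso, axis)
        m = trial.head.t >= trial.head.t[-1] - FINAL_WINDOW_S - 1e-9
        head_final = float(hx[m].mean())
        metrics.update(
            head_ai=anchoring_index(hx, tx),
            head_torso_final_diff=head_final - final,
            head_alignment_error=head_final - trial.target_angle,
        )
    return JarMetrics(**metrics)


def jar_condition_summary(trials: list[JarTrial], axis: str = "lateral"):
    """Per condition x body part summary with mirrored lateral pooling.

    Lateral targets are pooled by mirroring: metrics of -15 degree trials
    are sign-flipped (signed error, final angle, head-torso difference,
    head alignment error) so left and right reproduce the same +15 target.
    Returns a pandas DataFrame with one row per (condition, body_part)
    and the trial counts actually seen per target.
    """
    import pandas as pd

    from .io_model import JAR_CONDITIONS

    rows = []
    for tr in trials:
        if tr.condition not in JAR_CONDITIONS:
            raise ValueError(f"unknown condition {tr.condition!r}")
        m = jar_metrics(tr, axis)
        flip = -1.0 if tr.target_angle < 0 else 1.0
        rows.append(
            dict(
                condition=tr.condition,
                body_part=tr.body_part,
                target=abs(tr.target_angle),
                final_angle=flip * m.final_angle,
                signed_error=flip * m.signed_error,
                overshoot=m.overshoot,
                oscillation_count=m.oscillation_count,
                head_ai=m.head_ai,
                head_torso_final_diff=(
                    None if m.head_torso_final_diff is None
                    else flip * m.head_torso_final_diff
                ),
                head_alignment_error=(
                    None if m.head_alignment_error is None
                    else flip * m.head_alignment_error
                ),
            )
        )
    df = pd.DataFrame(rows)
    agg = df.groupby(["condition", "body_part"], sort=True).agg(
        n_trials=("final_angle", "size"),
        final_angle=("final_angle", "mean"),
        signed_error=("signed_error", "mean"),
        overshoot=("overshoot", "mean"),
        oscillation_count=("oscillation_count", "mean"),
        head_ai=("head_ai", "mean"),
        head_torso_final_diff=("head_torso_final_diff", "mean"),
        head_alignment_error=("head_alignment_error", "mean"),
    )
    return agg.reset_index()
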