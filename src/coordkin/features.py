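"""Segmentation and the 50-variable descriptive battery of a flight sequence.

A flight recording is split into segments at the interpolated coin-plane
crossing times; segments containing IMU discontinuities (any single-sample
angular change above 20 degrees) are rejected; every descriptive variable
is computed per valid segment and arithmetic-mean averaged over the
sequence (the path ratio, and the error summaries, are sequence-level).

Variable groups: steering performance (coin error, path ratio, segment
time), head and torso rotation amplitudes (interquartile ranges), torso
angular-speed statistics, head-torso coupling (absolute correlations,
anchoring indices, cross-correlation peak lags, DTW distances), and
movement smoothness (spectral arc length, time-normalized peak counts,
mean/max speed ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .course import CoinCourse, IdealPath, catmull_rom_path, detect_crossings, path_ratio
from .io_model import AngleSeries, TrialRecording

AXES = ("pitch", "roll", "yaw")
#: axis pairs used for correlations and cross-correlation peak lags
AXIS_PAIRS = (
    ("pitch", "pitch"), ("roll", "roll"), ("yaw", "yaw"),
    ("roll", "yaw"), ("yaw", "roll"),
)

REJECTION_THRESHOLD_DEG = 20.0
DTW_TARGET_LENGTH = 64
PEAK_PROMINENCE_DEG = 1.0
SAL_CUTOFF_HZ = 10.0
SAL_AMP_THRESHOLD = 0.05


class DegenerateSegmentError(ValueError):
    pass


@dataclass
class Segment:
    """Head/torso traces between two consecutive coin-plane crossings."""

    head: AngleSeries
    torso: AngleSeries
    t_start: float
    t_end: float
    coin_index: int            # index of the terminal coin
    error: float               # crossing error at the terminal coin, m
    missed: bool
    bird: AngleSeries | None = None   # flight heading angles on the same grid
    valid: bool = True

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def heading_angles(position: np.ndarray, t: np.ndarray) -> AngleSeries:
    """Flight ('bird') orientation from the trajectory.

    Elevation of the velocity vector maps to pitch, azimuth to yaw; the
    kinematic avatar carries no roll. Finite differences, last sample
    repeated to keep the grid length.
    """
    v = np.gradient(np.asarray(position, dtype=float), t, axis=0)
    horiz = np.hypot(v[:, 0], v[:, 1])
    pitch = np.degrees(np.arctan2(v[:, 2], np.maximum(horiz, 1e-12)))
    yaw = np.degrees(np.unwrap(np.arctan2(v[:, 1], v[:, 0])))
    return AngleSeries(t, pitch, np.zeros_like(pitch), yaw)


def split_segments(
    trial: TrialRecording,
    course: CoinCourse,
    ideal: IdealPath | None = None,
) -> list[Segment]:
    """One segment per consecutive coin pair, cut at plane-crossing times."""
    if trial.position is None:
        raise ValueError("segmentation requires a flight trial with position")
    if ideal is None:
        ideal = catmull_rom_path(course)
    crossings = detect_crossings(trial.position, trial.t, course, ideal)
    if crossings[0].missed and all(c.missed for c in crossings):
        raise ValueError("trajectory never reaches the first coin plane")
    bird = heading_angles(trial.position, trial.t)
    segments = []
    for a, b in zip(crossings[:-1], crossings[1:]):
        t0, t1 = a.time, b.time
        if t1 <= t0:
            t1 = t0 + trial.head.dt
        seg = Segment(
            head=trial.head.slice_time(t0, t1),
            torso=trial.torso.slice_time(t0, t1),
            t_start=t0, t_end=t1,
            coin_index=b.coin_index,
            error=b.error, missed=b.missed,
            bird=bird.slice_time(t0, t1),
        )
        segments.append(seg)
    return segments


def reject_discontinuities(
    segment: Segment, threshold: float = REJECTION_THRESHOLD_DEG
) -> Segment:
    """Invalidate a segment containing IMU-interference jumps.

    A segment is rejected iff any consecutive-sample absolute angular change
    on any axis of either the head or the torso trace strictly exceeds the
    threshold (a change of exactly 20.0 degrees is kept).
    """
    bad = False
    for series in (segment.head, segment.torso):
        for ax in AXES:
            d = np.abs(np.diff(series.axis(ax)))
            if d.size and float(d.max()) > threshold:
                bad = True
    segment.valid = not bad
    return segment


# ---------------------------------------------------------------------------
# per-segment scalar statistics


def iqr_amplitude(x: np.ndarray) -> float:
    """Interquartile range (Q3 - Q1, linear-interpolation quantiles), degrees."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise DegenerateSegmentError("IQR needs at least 4 samples")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return float(q3 - q1)


def angular_speed(x: np.ndarray, dt: float) -> np.ndarray:
    """Per-interval absolute angular rate |delta angle| / dt, deg/s."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateSegmentError("speed needs at least 2 samples")
    return np.abs(np.diff(x)) / dt


def angular_speed_stats(series: AngleSeries) -> dict[str, float]:
    """Mean and max angular speed per axis plus the 3-D rate norm."""
    out: dict[str, float] = {}
    rates = []
    for ax in AXES:
        r = np.diff(series.axis(ax)) / series.dt
        rates.append(r)
        out[f"mean_{ax}"] = float(np.mean(np.abs(r)))
        out[f"max_{ax}"] = float(np.max(np.abs(r)))
    norm = np.linalg.norm(np.vstack(rates), axis=0)
    out["mean_norm"] = float(np.mean(norm))
    out["max_norm"] = float(np.max(norm))
    return out


def head_torso_correlation(head: np.ndarray, torso: np.ndarray) -> float:
    """Absolute Pearson correlation between two angle traces; NaN if flat."""
    head = np.asarray(head, dtype=float)
    torso = np.asarray(torso, dtype=float)
    if head.size != torso.size or head.size < 3:
        raise DegenerateSegmentError("correlation needs equal length >= 3")
    if np.std(head) == 0 or np.std(torso) == 0:
        return float("nan")
    return float(abs(np.corrcoef(head, torso)[0, 1]))


def anchoring_index(head_abs: np.ndarray, torso: np.ndarray) -> float:
    """Anchoring index  (sigma_r - sigma_a) / (sigma_r + sigma_a).

    sigma_a is the SD of the head angles in space, sigma_r the SD of the
    head angles relative to the torso. +1 means the head is stabilized to
    external space, -1 that it rides rigidly on the trunk. NaN when both
    SDs vanish.
    """
    head_abs = np.asarray(head_abs, dtype=float)
    torso = np.asarray(torso, dtype=float)
    sa = float(np.std(head_abs, ddof=1)) if head_abs.size > 1 else 0.0
    rel = head_abs - torso
    sr = float(np.std(rel, ddof=1)) if rel.size > 1 else 0.0
    if sa + sr == 0:
        return float("nan")
    return (sr - sa) / (sr + sa)


def xcorr_peak_time(
    head: np.ndarray, torso: np.ndarray, dt: float, max_lag_fraction: float = 0.5
) -> float:
    """Lag (s) maximizing the per-lag-normalized head-torso cross-correlation.

    The lag search is bounded at +/- ``max_lag_fraction`` of the segment
    duration; each lag's overlap is Pearson-normalized so edge lags are not
    spuriously favoured. Negative lags mean the head leads the torso.
    """
    head = np.asarray(head, dtype=float)
    torso = np.asarray(torso, dtype=float)
    n = head.size
    if torso.size != n:
        raise DegenerateSegmentError("equal lengths required")
    if np.std(head) == 0 or np.std(torso) == 0:
        return float("nan")
    max_lag = max(int(math.floor(max_lag_fraction * (n - 1))), 1)
    best_lag, best_r = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        # at lag L the samples head[i+L] and torso[i] are compared, so the
        # peak sits at L < 0 when the head's signal precedes the torso's
        if lag >= 0:
            a, b = head[lag:], torso[: n - lag]
        else:
            a, b = head[: n + lag], torso[-lag:]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    if not np.isfinite(best_r):
        return float("nan")
    return float(best_lag * dt)


def resample_to_length(x: np.ndarray, target_length: int) -> np.ndarray:
    """Linear interpolation of a trace onto ``target_length`` evenly spaced points."""
    x = np.asarray(x, dtype=float)
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    if x.size == 1:
        return np.full(target_length, x[0])
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, target_length)
    return np.interp(dst, src, x)


def dtw_distance(
    head: np.ndarray, torso: np.ndarray, target_length: int | None = DTW_TARGET_LENGTH
) -> float:
    """Classic DTW distance with absolute-difference cost, unconstrained.

    Both traces are first linearly resampled to ``target_length`` (pass
    None to compare as-is) so distances are comparable across segments of
    different durations; the symmetric-step cumulative path cost is returned.
    """
    a = np.asarray(head, dtype=float)
    b = np.asarray(torso, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty trace")
    if target_length is not None:
        a = resample_to_length(a, target_length)
        b = resample_to_length(b, target_length)
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    # wavefront DP over anti-diagonals: all cells of one diagonal depend only
    # on the two previous diagonals, so each sweep is a vectorized update
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for k in range(2, n + m + 1):
        i = np.arange(max(1, k - m), min(n, k - 1) + 1)
        j = k - i
        D[i, j] = cost[i - 1, j - 1] + np.minimum(
            np.minimum(D[i - 1, j], D[i, j - 1]), D[i - 1, j - 1]
        )
    return float(D[n, m])


def spectral_arc_length(
    speed: np.ndarray,
    dt: float,
    cutoff_hz: float = SAL_CUTOFF_HZ,
    amp_threshold: float = SAL_AMP_THRESHOLD,
    padlevel: int = 4,
) -> float:
    """Spectral arc length of a speed profile (adaptive-cutoff variant).

    The magnitude spectrum of the zero-padded speed profile is normalized
    by its DC value; the arc length of the normalized spectrum is measured
    up to an adaptive cutoff: the last frequency below ``cutoff_hz`` whose
    normalized amplitude still exceeds ``amp_threshold``. Returned negative;
    more negative = jerkier. NaN for an all-zero profile.
    """
    v = np.asarray(speed, dtype=float)
    if v.size < 8:
        raise DegenerateSegmentError("SAL needs at least 8 samples")
    if np.all(v == 0):
        return float("nan")
    nfft = int(2 ** math.ceil(math.log2(v.size) + padlevel))
    f = np.arange(nfft) / (dt * nfft)
    mag = np.abs(np.fft.fft(v, nfft))
    sel = f <= cutoff_hz
    f_sel, mag_sel = f[sel], mag[sel]
    mag_norm = mag_sel / mag_sel[0]
    above = np.nonzero(mag_norm >= amp_threshold)[0]
    inx = np.arange(above[0], above[-1] + 1)
    f_cut, m_cut = f_sel[inx], mag_norm[inx]
    df = np.diff(f_cut / f_cut[-1])
    dm = np.diff(m_cut)
    return float(-np.sum(np.sqrt(df ** 2 + dm ** 2)))


def count_peaks(x: np.ndarray, duration: float, prominence: float = PEAK_PROMINENCE_DEG) -> float:
    """Local maxima above a prominence threshold, per second of segment."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DegenerateSegmentError("peak count needs at least 3 samples")
    if duration <= 0:
        raise DegenerateSegmentError("non-positive duration")
    peaks, _ = _signal.find_peaks(x, prominence=prominence)
    return float(peaks.size / duration)


def speed_ratio(x: np.ndarray, dt: float) -> float:
    """Mean over max absolute angular rate; 1 for perfectly smooth motion."""
    r = angular_speed(x, dt)
    mx = float(r.max())
    if mx == 0:
        return float("nan")
    if mx == float(r.min()):
        return 1.0  # perfectly constant rate, exact by definition
    return float(r.mean() / mx)


# ---------------------------------------------------------------------------
# the assembled battery

#: feature name -> functional-category tag used by the selection clustering
FEATURE_CATEGORIES: dict[str, str] = {}


def _cat(name: str, tag: str) -> str:
    FEATURE_CATEGORIES[name] = tag
    return name

ERROR_FEATURES = [_cat(f"error_{s}", "error") for s in ("mean", "median", "max")]
_cat("path_ratio", "error")
_cat("segment_time", "error")
for _ax in AXES:
    _cat(f"head_amp_{_ax}", "head")
    _cat(f"torso_amp_{_ax}", "torso")
    _cat(f"torso_speed_mean_{_ax}", "torso")
    _cat(f"torso_speed_max_{_ax}", "torso")
    _cat(f"torso_sal_{_ax}", "torso")
    _cat(f"peaks_head_{_ax}", "head")
    _cat(f"peaks_torso_{_ax}", "torso")
    _cat(f"peaks_bird_{_ax}", "error")
    _cat(f"torso_speed_ratio_{_ax}", "torso")
_cat("torso_speed_mean_norm", "torso")
_cat("torso_speed_max_norm", "torso")
for _a, _b in AXIS_PAIRS:
    _cat(f"corr_{_a}_{_b}", "coordination")
    _cat(f"xcorr_peak_{_a}_{_b}", "coordination")
for _ax in AXES:
    _cat(f"ai_{_ax}", "coordination")
    _cat(f"dtw_{_ax}", "coordination")

FEATURE_NAMES = tuple(FEATURE_CATEGORIES)  # 50 variables


@dataclass
class FeatureVector:
    """Sequence-averaged values of the 50 descriptive variables."""

    values: dict[str, float]
    n_segments: int
    n_rejected: int
    meta: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES])


def _segment_features(seg: Segment) -> dict[str, float]:
    dt = seg.head.dt
    out: dict[str, float] = {"segment_time": seg.duration}
    tstats = angular_speed_stats(seg.torso)
    for ax in AXES:
        h, to = seg.head.axis(ax), seg.torso.axis(ax)
        out[f"head_amp_{ax}"] = iqr_amplitude(h)
        out[f"torso_amp_{ax}"] = iqr_amplitude(to)
        out[f"torso_speed_mean_{ax}"] = tstats[f"mean_{ax}"]
        out[f"torso_speed_max_{ax}"] = tstats[f"max_{ax}"]
        out[f"ai_{ax}"] = anchoring_index(h, to)
        out[f"dtw_{ax}"] = dtw_distance(h, to)
        out[f"torso_sal_{ax}"] = spectral_arc_length(
            np.abs(np.diff(to)) / dt, dt
        )
        out[f"peaks_head_{ax}"] = count_peaks(h, seg.duration)
        out[f"peaks_torso_{ax}"] = count_peaks(to, seg.duration)
        bird = seg.bird.axis(ax) if seg.bird is not None else np.zeros_like(h)
        out[f"peaks_bird_{ax}"] = count_peaks(bird, seg.duration)
        out[f"torso_speed_ratio_{ax}"] = speed_ratio(to, dt)
    out["torso_speed_mean_norm"] = tstats["mean_norm"]
    out["torso_speed_max_norm"] = tstats["max_norm"]
    for a, b in AXIS_PAIRS:
        out[f"corr_{a}_{b}"] = head_torso_correlation(seg.head.axis(a), seg.torso.axis(b))
        out[f"xcorr_peak_{a}_{b}"] = xcorr_peak_time(seg.head.axis(a), seg.torso.axis(b), dt)
    return out


def feature_vector(
    trial: TrialRecording,
    course: CoinCourse,
    ideal: IdealPath | None = None,
    rejection_threshold: float = REJECTION_THRESHOLD_DEG,
) -> FeatureVector:
    """Compute every descriptive variable for one flight sequence.

    Variables are computed per valid segment and arithmetic-mean averaged
    (NaN per-segment values, e.g. undefined correlations, are skipped
    rather than zero-filled); the error summaries pool the per-coin
    crossing errors of the valid segments and the path ratio is computed
    once over the whole sequence. Raises ValueError when every segment is
    rejected.
    """
    if ideal is None:
        ideal = catmull_rom_path(course)
    segments = [
        reject_discontinuities(s, rejection_threshold)
        for s in split_segments(trial, course, ideal)
    ]
    valid = [s for s in segments if s.valid]
    if not valid:
        raise ValueError("sequence rejected: no valid segments")
    per_seg = [_segment_features(s) for s in valid]
    values: dict[str, float] = {}
    for name in FEATURE_NAMES:
        if name in ("path_ratio",) or name in ERROR_FEATURES:
            continue
        vals = np.array([f[name] for f in per_seg], dtype=float)
        vals = vals[np.isfinite(vals)]
        values[name] = float(vals.mean()) if vals.size else float("nan")
    errors = np.array([s.error for s in valid], dtype=float)
    errors = errors[np.isfinite(errors)]
    values["error_mean"] = float(errors.mean()) if errors.size else float("nan")
    values["error_median"] = float(np.median(errors)) if errors.size else float("nan")
    values["error_max"] = float(errors.max()) if errors.size else float("nan")
    values["path_ratio"] = path_ratio(trial.position, ideal)
    return FeatureVector(
        values=values,
        n_segments=len(segments),
        n_rejected=len(segments) - len(valid),
        meta=dict(trial.meta),
    )
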