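"""Core data types and plain-text I/O for head-trunk coordination recordings.

A recording pairs two uniformly sampled Euler-angle series -- one for the
head, one for the torso -- optionally with the 3-D flight trajectory of the
steered avatar. Angles are intrinsic Tait-Bryan pitch/roll/yaw in degrees,
zeroed at the participant's self-selected neutral pose. Sign convention:
pitch + = flexion (down-steer), roll + = right lateral flexion,
yaw + = right axial rotation.

The canonical on-disk form is a CSV of the sampled columns plus a JSON
sidecar holding the metadata, so every file stays human-inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Nominal sample period of the acquisition hardware, seconds (68 ms).
SAMPLE_PERIOD = 0.068

AGE_GROUPS = ("6", "8-9", "10", "adult")
CONTROLS = ("head", "torso")
PHASES = ("Before", "Training", "After", "DayAfter")
STUDIES = ("flight", "jar")
JAR_CONDITIONS = ("Feedback", "NoFeedback", "Forward")
JAR_TARGETS = (-15.0, 0.0, 15.0)

_GRID_TOL = 1e-9


class FormatError(ValueError):
    """A file does not follow the canonical schema."""


class DataError(ValueError):
    """A file parses but violates a data invariant."""


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class AngleSeries:
    """One body segment's pitch/roll/yaw trace on a uniform time grid.

    ``t`` is in seconds with a constant step (nominally 0.068 s); angles are
    in degrees relative to the zeroed neutral pose.
    """

    t: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    yaw: np.ndarray

    def __post_init__(self):
        t = _as_1d(self.t, "t")
        if t.size == 0:
            raise DataError("empty angle series")
        for name in ("pitch", "roll", "yaw"):
            a = _as_1d(getattr(self, name), name)
            if a.size != t.size:
                raise DataError(f"{name} length {a.size} != t length {t.size}")
            object.__setattr__(self, name, a)
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise DataError("time stamps must be strictly increasing")
            if np.ptp(dt) > _GRID_TOL:
                raise DataError(
                    "time grid is not uniform; resample before construction"
                )
        object.__setattr__(self, "t", t)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            return SAMPLE_PERIOD
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def axis(self, name: str) -> np.ndarray:
        """Return one axis trace by name ('pitch' | 'roll' | 'yaw')."""
        if name not in ("pitch", "roll", "yaw"):
            raise KeyError(name)
        return getattr(self, name)

    def slice_time(self, t0: float, t1: float) -> "AngleSeries":
        """Sub-series with t0 <= t <= t1 (half-sample tolerance at the ends)."""
        eps = 0.5 * self.dt
        m = (self.t >= t0 - eps) & (self.t <= t1 + eps)
        if not m.any():
            raise DataError(f"empty slice [{t0}, {t1}]")
        return AngleSeries(self.t[m], self.pitch[m], self.roll[m], self.yaw[m])


def resample_series(
    t: np.ndarray, columns: dict[str, np.ndarray], step: float = SAMPLE_PERIOD
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Linearly resample irregular samples onto a uniform grid.

    The grid starts at t[0] and ends at or before t[-1]; endpoints are
    preserved and affine signals are reproduced exactly (linear
    interpolation is exact for degree-1 polynomials).
    """
    t = _as_1d(t, "t")
    if np.any(np.diff(t) <= 0):
        raise DataError("time stamps must be strictly increasing")
    n = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    grid = t[0] + step * np.arange(n)
    out = {k: np.interp(grid, t, _as_1d(v, k)) for k, v in columns.items()}
    return grid, out


@dataclass(frozen=True)
class TrialRecording:
    """Paired head/torso angle series plus (for flight trials) the trajectory.

    ``position`` is the avatar's 3-D position in meters, one row per time
    sample; present exactly when ``meta['study'] == 'flight'``.
    """

    head: AngleSeries
    torso: AngleSeries
    position: np.ndarray | None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.head.n != self.torso.n or not np.allclose(
            self.head.t, self.torso.t, atol=_GRID_TOL
        ):
            raise DataError("head and torso must share one time grid")
        study = self.meta.get("study", "flight")
        if study not in STUDIES:
            raise DataError(f"unknown study {study!r}")
        if study == "flight":
            if self.position is None:
                raise DataError("flight trial requires position data")
            pos = np.asarray(self.position, dtype=float)
            if pos.ndim != 2 or pos.shape != (self.head.n, 3):
                raise DataError(
                    f"position must be (n, 3), got {pos.shape}"
                )
            object.__setattr__(self, "position", pos)
        elif self.position is not None:
            raise DataError("JAR trial must not carry position data")

    @property
    def t(self) -> np.ndarray:
        return self.head.t


@dataclass(frozen=True)
class JarTrial:
    """One joint-angle-reproduction repetition.

    The participant aligns ``body_part`` to ``target_angle`` (degrees,
    one of -15/0/+15) under one of three feedback conditions; traces last
    4 s nominally and must cover at least the final 1.5 s analysis window.
    """

    target_angle: float
    body_part: str
    condition: str
    head: AngleSeries
    torso: AngleSeries
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if float(self.target_angle) not in JAR_TARGETS:
            raise DataError(f"target {self.target_angle} not in {JAR_TARGETS}")
        if self.body_part not in CONTROLS:
            raise DataError(f"body_part must be head or torso")
        if self.condition not in JAR_CONDITIONS:
            raise DataError(f"unknown condition {self.condition!r}")
        if self.head.n != self.torso.n or not np.allclose(
            self.head.t, self.torso.t, atol=_GRID_TOL
        ):
            raise DataError("head and torso must share one time grid")
        if self.head.duration < 1.5 - _GRID_TOL:
            raise DataError("JAR trial shorter than the 1.5 s analysis window")
        object.__setattr__(self, "target_angle", float(self.target_angle))


@dataclass(frozen=True)
class CoinCourse:
    """Ordered coin positions of one flight sequence.

    Consecutive coins are 58 m apart; each span carries a maneuver label.
    Coin diameters start at 1 m and are enlarged to 2 m once a coin has
    been caught. Flight speed is constant at 12 m/s.
    """

    coins: np.ndarray
    maneuvers: tuple[str, ...]
    coin_diameters: np.ndarray | None = None
    speed: float = 12.0

    COIN_SPACING = 58.0
    MANEUVER_SET = ("forward", "right", "left", "ascent", "descent")

    def __post_init__(self):
        coins = np.asarray(self.coins, dtype=float)
        if coins.ndim != 2 or coins.shape[1] != 3:
            raise DataError("coins must be an (n, 3) array")
        object.__setattr__(self, "coins", coins)
        d = np.linalg.norm(np.diff(coins, axis=0), axis=1)
        if np.any(np.abs(d - self.COIN_SPACING) > 1e-6):
            raise DataError("consecutive coins must be 58 m apart")
        if len(self.maneuvers) != self.n_coins - 1:
            raise DataError("need one maneuver label per span")
        for m in self.maneuvers:
            if m not in self.MANEUVER_SET:
                raise DataError(f"unknown maneuver {m!r}")
        if self.coin_diameters is None:
            object.__setattr__(
                self, "coin_diameters",
                np.full(self.n_coins, 1.0),
            )
        else:
            dia = np.asarray(self.coin_diameters, dtype=float)
            if dia.shape != (self.n_coins,):
                raise DataError("one diameter per coin required")
            object.__setattr__(self, "coin_diameters", dia)

    @property
    def n_coins(self) -> int:
        return self.coins.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "coins": self.coins.tolist(),
            "maneuvers": list(self.maneuvers),
            "coin_diameters": self.coin_diameters.tolist(),
            "speed": self.speed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "CoinCourse":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["coins"]), tuple(d["maneuvers"]),
            np.asarray(d["coin_diameters"]), d.get("speed", 12.0),
        )


# ---------------------------------------------------------------------------
# canonical CSV + JSON-sidecar dialect

_ANGLE_COLS = [
    "head_pitch", "head_roll", "head_yaw",
    "torso_pitch", "torso_roll", "torso_yaw",
]
_POS_COLS = ["pos_x", "pos_y", "pos_z"]
_FLOAT_FMT = "%.9g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trial(trial: TrialRecording, path) -> None:
    """Write a trial as canonical CSV plus a ``<path>.json`` metadata sidecar.

    JAR-study trials omit the ``pos_*`` columns. ``read_trial`` is the exact
    inverse on the canonical dialect.
    """
    path = Path(path)
    if trial.head.n == 0:
        raise DataError("refusing to write an empty trial")
    cols: dict[str, np.ndarray] = {"t": trial.t}
    for seg_name, seg in (("head", trial.head), ("torso", trial.torso)):
        for ax in ("pitch", "roll", "yaw"):
            cols[f"{seg_name}_{ax}"] = seg.axis(ax)
    if trial.position is not None:
        for i, c in enumerate(_POS_COLS):
            cols[c] = trial.position[:, i]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(trial.meta, indent=1, sort_keys=True))


def read_trial(path, dialect: str = "canonical") -> TrialRecording:
    """Read one trial from the canonical CSV + JSON-sidecar layout.

    Non-uniform time grids are linearly resampled onto the nominal 68 ms
    step and flagged with ``meta['resampled'] = True``.
    """
    if dialect != "canonical":
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in ["t", *_ANGLE_COLS] if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError("non-monotone time stamps")
    has_pos = all(c in df.columns for c in _POS_COLS)
    names = _ANGLE_COLS + (_POS_COLS if has_pos else [])
    data = {c: df[c].to_numpy(dtype=float) for c in names}
    if t.size > 1 and np.ptp(np.diff(t)) > _GRID_TOL:
        t, data = resample_series(t, data)
        meta = {**meta, "resampled": True}
    head = AngleSeries(t, data["head_pitch"], data["head_roll"], data["head_yaw"])
    torso = AngleSeries(t, data["torso_pitch"], data["torso_roll"], data["torso_yaw"])
    pos = np.column_stack([data[c] for c in _POS_COLS]) if has_pos else None
    meta.setdefault("study", "flight" if has_pos else "jar")
    return TrialRecording(head, torso, pos, meta)
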