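"""Ideal-path geometry and trajectory-level steering performance.

The flight course is a chain of coins 58 m apart. The ideal path is a
centripetal Catmull-Rom spline through the coins (the same smooth guide
line shown to participants). Steering error at a coin is the in-plane
distance from the point where the flown trajectory crosses the coin's
vertical plane -- the plane through the coin center perpendicular to the
ideal-path tangent -- to the coin center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_model import CoinCourse

MISSED = float("nan")


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# centripetal Catmull-Rom spline


def _catmull_rom_span(p0, p1, p2, p3, u: np.ndarray, alpha: float = 0.5):
    """Evaluate one centripetal (alpha=0.5) Catmull-Rom span P1->P2 at u in [0,1]."""
    def tj(ti, pa, pb):
        d = np.linalg.norm(pb - pa)
        return ti + max(d, 1e-12) ** alpha

    t0 = 0.0
    t1 = tj(t0, p0, p1)
    t2 = tj(t1, p1, p2)
    t3 = tj(t2, p2, p3)
    t = t1 + u[:, None] * (t2 - t1)

    def lerp(ta, tb, pa, pb):
        w = ((tb - t) / (tb - ta), (t - ta) / (tb - ta))
        return w[0] * pa + w[1] * pb

    a1 = lerp(t0, t1, p0, p1)
    a2 = lerp(t1, t2, p1, p2)
    a3 = lerp(t2, t3, p2, p3)
    b1 = lerp(t0, t2, a1, a2)
    b2 = lerp(t1, t3, a2, a3)
    return lerp(t1, t2, b1, b2)


@dataclass(frozen=True)
class IdealPath:
    """Dense polyline sampling of the spline through the coins."""

    points: np.ndarray          # (m, 3) meters
    arc_length: np.ndarray      # (m,) cumulative meters, arc_length[0] = 0
    knot_index: np.ndarray      # index into points of each coin
    source_coins: CoinCourse | None = None

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def tangent_at_coin(self, coin_index: int) -> np.ndarray:
        """Unit tangent of the polyline at a coin (central difference)."""
        i = int(self.knot_index[coin_index])
        lo, hi = max(i - 1, 0), min(i + 1, self.points.shape[0] - 1)
        d = self.points[hi] - self.points[lo]
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("degenerate tangent")
        return d / n


def catmull_rom_path(course: CoinCourse, samples_per_span: int = 50) -> IdealPath:
    """Centripetal Catmull-Rom interpolation of the coin chain.

    Endpoints are handled by phantom-point reflection (P_-1 = 2 P_0 - P_1),
    so the spline passes through every coin including the first and last.
    """
    coins = course.coins
    if coins.shape[0] < 4:
        raise GeometryError("need at least 4 coins for a Catmull-Rom path")
    if samples_per_span < 2:
        raise GeometryError("samples_per_span must be >= 2")
    ext = np.vstack([2 * coins[0] - coins[1], coins, 2 * coins[-1] - coins[-2]])
    pts = [coins[0][None, :]]
    knots = [0]
    u = np.linspace(0.0, 1.0, samples_per_span + 1)[1:]
    for i in range(coins.shape[0] - 1):
        seg = _catmull_rom_span(ext[i], ext[i + 1], ext[i + 2], ext[i + 3], u)
        seg[-1] = coins[i + 1]  # pin knot exactly
        pts.append(seg)
        knots.append(knots[-1] + samples_per_span)
    points = np.vstack(pts)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    )
    return IdealPath(points, arc, np.asarray(knots), course)


def polyline_length(xyz: np.ndarray) -> float:
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# coin-plane crossings


def _plane_signed_distance(traj, coin, tangent):
    return (traj - coin) @ tangent


def crossing_point(
    trajectory: np.ndarray,
    t: np.ndarray,
    coin: np.ndarray,
    tangent: np.ndarray,
    start_index: int = 0,
) -> tuple[float, np.ndarray, int] | None:
    """First crossing of the coin plane at/after ``start_index``.

    Returns (crossing time, interpolated crossing point, sample index of the
    sample just before the crossing), or None if the plane is never crossed.
    """
    s = _plane_signed_distance(trajectory[start_index:], coin, tangent)
    neg = s < 0
    idx = np.nonzero(neg[:-1] & ~neg[1:])[0]
    if idx.size == 0:
        if s.size and s[0] >= 0 and start_index == 0:
            # trajectory starts already on/past the plane
            return float(t[0]), trajectory[0].copy(), 0
        return None
    i = int(idx[0]) + start_index
    s0, s1 = s[i - start_index], s[i - start_index + 1]
    w = s0 / (s0 - s1)  # s1 >= 0 > s0 is impossible; s0 < 0 <= s1
    tc = float(t[i] + w * (t[i + 1] - t[i]))
    pc = trajectory[i] + w * (trajectory[i + 1] - trajectory[i])
    return tc, pc, i


def _closest_plane_approach(trajectory, t, coin, tangent):
    s = np.abs(_plane_signed_distance(trajectory, coin, tangent))
    i = int(np.argmin(s))
    return float(t[i]), trajectory[i].copy()


@dataclass(frozen=True)
class CoinCrossing:
    coin_index: int
    time: float
    point: np.ndarray
    error: float        # in-plane distance to coin center, m
    missed: bool        # no plane crossing; error taken at closest approach


def detect_crossings(
    trajectory: np.ndarray,
    t: np.ndarray,
    course: CoinCourse,
    ideal: IdealPath | None = None,
    error_mode: str = "in_plane",
) -> list[CoinCrossing]:
    """Locate every coin-plane crossing along a flown trajectory, in order.

    ``error_mode='in_plane'`` projects out the tangent component before
    measuring the distance to the coin center; ``'3d'`` keeps the full
    Euclidean distance (the crossing point lies on the plane so the two
    agree up to interpolation error, but the option is explicit).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    t = np.asarray(t, dtype=float)
    if ideal is None:
        ideal = catmull_rom_path(course)
    out: list[CoinCrossing] = []
    start = 0
    for k in range(course.n_coins):
        coin = course.coins[k]
        tangent = ideal.tangent_at_coin(k)
        hit = crossing_point(trajectory, t, coin, tangent, start_index=start)
        if hit is None:
            tc, pc = _closest_plane_approach(trajectory[start:], t[start:], coin, tangent)
            missed = True
        else:
            tc, pc, i = hit
            start = max(i, start)
            missed = False
        d = pc - coin
        if error_mode == "in_plane":
            d = d - (d @ tangent) * tangent
        err = float(np.linalg.norm(d))
        out.append(CoinCrossing(k, tc, pc, err, missed))
    return out


def crossing_error(
    trajectory: np.ndarray,
    t: np.ndarray,
    course: CoinCourse,
    coin_index: int,
    ideal: IdealPath | None = None,
) -> float:
    """Unsigned in-plane distance to one coin center at its plane crossing.

    Returns NaN (``MISSED``) if the plane is never crossed; callers decide
    whether to substitute the closest-approach error from
    :func:`detect_crossings`.
    """
    c = detect_crossings(trajectory, t, course, ideal)[coin_index]
    return MISSED if c.missed else c.error


def path_ratio(trajectory: np.ndarray, ideal: IdealPath) -> float:
    """Travelled arc length divided by ideal arc length for the sequence."""
    lt = polyline_length(trajectory)
    li = ideal.total_length
    if li <= 0:
        raise GeometryError("ideal path has zero length")
    if lt <= 0:
        raise GeometryError("degenerate trajectory")
    return lt / li


# ---------------------------------------------------------------------------
# course generation

_TURN_ANGLE = math.radians(45.0)    # heading change of a right/left maneuver
_CLIMB_ANGLE = math.radians(20.0)   # elevation change of ascent/descent
_MAX_ELEVATION = math.radians(35.0)


def generate_course(
    n_coins: int,
    seed: int,
    start: tuple[float, float, float] = (0.0, 0.0, 30.0),
) -> CoinCourse:
    """Random course: 58 m spans alternating forward motion and maneuvers.

    Spans alternate between plain forward motion and a uniformly drawn
    maneuver (right/left turn, ascent/descent); elevation is kept within
    +/-35 degrees so descents never chain into the ground. Deterministic
    for a fixed seed. Coin diameters follow the game rule: 1 m initially,
    2 m for every coin after the first (the preceding coin is assumed
    caught, which is how an ideal run enlarges them).
    """
    if n_coins < 4:
        raise GeometryError("need at least 4 coins")
    rng = np.random.default_rng(seed)
    pos = np.asarray(start, dtype=float)
    az, el = 0.0, 0.0
    coins = [pos.copy()]
    maneuvers: list[str] = []
    for i in range(n_coins - 1):
        if i % 2 == 0:
            m = "forward"
        else:
            m = str(rng.choice(["right", "left", "ascent", "descent"]))
            if m == "right":
                az -= _TURN_ANGLE
            elif m == "left":
                az += _TURN_ANGLE
            elif m == "ascent":
                el = min(el + _CLIMB_ANGLE, _MAX_ELEVATION)
            else:
                el = max(el - _CLIMB_ANGLE, -_MAX_ELEVATION)
        d = np.array(
            [math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)]
        )
        pos = pos + CoinCourse.COIN_SPACING * d
        coins.append(pos.copy())
        maneuvers.append(m)
    diameters = np.full(n_coins, 2.0)
    diameters[0] = 1.0
    return CoinCourse(np.asarray(coins), tuple(maneuvers), diameters)
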