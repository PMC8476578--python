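"""Synthetic recordings with controlled head-trunk coordination structure.

The generator is kinematic, not biomechanical: a pure-pursuit steering
loop flies the avatar through a coin course at 12 m/s, the commanded
controller angle tracks the required heading correction through a
first-order lag, and the head/torso traces are mixed from the controller
signal, an independent smooth gaze process, compensatory opposition and
measurement noise. Four knobs map onto the scientific constructs:

``coupling`` (c)        fraction of head motion rigidly following the
                        torso; c = 1 is the en-bloc strategy.
``overshoot_gain`` (g)  multiplicative bias on the commanded amplitude;
                        g > 1 models proprioceptive overestimation of the
                        produced movement.
``head_comp_gain`` (h)  amplitude of compensatory head movements opposing
                        the torso displacement.
``noise_sd``            measurement/process noise, degrees.

Everything is reproducible: one integer seed fixes a recording bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .course import CoinCourse, catmull_rom_path, generate_course
from .io_model import (
    SAMPLE_PERIOD,
    AngleSeries,
    JarTrial,
    TrialRecording,
)

SPEED = 12.0               # m/s, constant flight speed
DT = SAMPLE_PERIOD

# steering-loop constants (package conventions, not fitted values)
PURSUIT_GAIN = 1.5         # commanded deg per deg of heading error
CMD_LIMIT = 40.0           # deg, maximal commanded controller angle
TURN_RATE_GAIN = 1.0       # deg/s of heading change per deg of lateral angle
CLIMB_RATE_GAIN = 1.0      # deg/s of elevation change per deg of pitch
REPLAN_S = 0.5             # s, interval between steering-command updates
MAX_ANGLE_RATE = 120.0     # deg/s, cap on executed head/torso angular speed
AIM_NOISE_M_PER_DEG = 2.0  # m of aim-point scatter per degree of noise_sd
GAZE_AMP = 5.0             # deg, SD of the independent smooth gaze process
GAZE_SMOOTH_S = 0.5        # s, Gaussian kernel width of smooth processes

# JAR second-order settling dynamics
JAR_DURATION_S = 4.0
JAR_OMEGA = 4.0            # rad/s natural frequency of the reaching response
JAR_ZETA = 0.65            # damping ratio (slightly underdamped -> overshoot)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic participant/trial."""

    seed: int = 0
    coupling: float = 0.8          # c in [0, 1]
    overshoot_gain: float = 1.0    # g > 0
    head_comp_gain: float = 0.0    # h >= 0
    noise_sd: float = 0.5          # degrees
    lag_tau: float = 0.3           # s, first-order tracking lag
    control: str = "torso"

    def __post_init__(self):
        if not (0.0 <= self.coupling <= 1.0):
            raise ParameterError("coupling must lie in [0, 1]")
        if not (self.overshoot_gain > 0 and math.isfinite(self.overshoot_gain)):
            raise ParameterError("overshoot_gain must be positive and finite")
        if self.head_comp_gain < 0:
            raise ParameterError("head_comp_gain must be >= 0")
        if self.lag_tau <= 0:
            raise ParameterError("lag_tau must be positive")
        if self.control not in ("head", "torso"):
            raise ParameterError("control must be 'head' or 'torso'")


def _smooth_noise(rng: np.random.Generator, n: int, amp: float) -> np.ndarray:
    """Zero-mean smooth process: Gaussian-kernel-filtered white noise,
    rescaled to SD ``amp`` (the gaze surrogate)."""
    if amp == 0 or n < 2:
        return np.zeros(n)
    x = gaussian_filter1d(rng.standard_normal(n), sigma=GAZE_SMOOTH_S / DT)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else np.zeros(n)


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def simulate_flight_trial(
    cfg: SynthConfig, course: CoinCourse, meta: dict | None = None
) -> TrialRecording:
    """Closed-loop steering simulation of one flight sequence.

    At every replanning event (every 0.5 s, modelling intermittent human
    steering corrections) the aim point is the next uncrossed coin plus
    visual targeting scatter proportional to ``noise_sd``; the commanded
    controller angle is proportional to the heading error toward the aim
    point and is held until the next replan. The executed angle tracks
    ``overshoot_gain`` times the command through a first-order lag -- the
    amplitude bias survives between corrections, so g > 1 produces
    overshooting turns and larger coin errors. The flight heading
    integrates the lateral steering combination and the pitch channel;
    position advances at 12 m/s. The recorded head/torso series are mixed
    from the controller signal per the coupling/compensation model and
    carry additive measurement noise.
    """
    rng = np.random.default_rng(cfg.seed)
    ideal = catmull_rom_path(course)
    coins = course.coins
    n_coins = coins.shape[0]
    tangents = [ideal.tangent_at_coin(k) for k in range(n_coins)]

    span_s = CoinCourse.COIN_SPACING / SPEED
    max_steps = int((n_coins * span_s / DT) * 3) + 50
    aim_sd = AIM_NOISE_M_PER_DEG * cfg.noise_sd
    replan_every = max(1, int(round(REPLAN_S / DT)))

    x, y, z = coins[0]
    d0 = coins[1] - coins[0]
    az = math.atan2(d0[1], d0[0])
    el = math.asin(d0[2] / np.linalg.norm(d0))
    lat = 0.0     # executed lateral controller angle, deg
    pit = 0.0     # executed pitch controller angle, deg (+ = descend)
    lat_cmd = 0.0
    pit_cmd = 0.0
    g = cfg.overshoot_gain
    alpha = DT / cfg.lag_tau

    pos_list, lat_list, pit_list = [], [], []
    target = 1
    for step in range(max_steps):
        pos_list.append((x, y, z))
        lat_list.append(lat)
        pit_list.append(pit)
        cx, cy, cz = coins[target]
        if step % replan_every == 0:
            ax = cx + rng.normal(0.0, aim_sd) if aim_sd else cx
            ay = cy + rng.normal(0.0, aim_sd) if aim_sd else cy
            azp = cz + rng.normal(0.0, aim_sd) if aim_sd else cz
            dx, dy, dz = ax - x, ay - y, azp - z
            horiz = math.hypot(dx, dy)
            e_az = _wrap_deg(math.degrees(math.atan2(dy, dx) - az))
            e_el = math.degrees(math.atan2(dz, max(horiz, 1e-9))) - math.degrees(el)
            lat_cmd = max(-CMD_LIMIT, min(CMD_LIMIT, PURSUIT_GAIN * e_az))
            pit_cmd = max(-CMD_LIMIT, min(CMD_LIMIT, -PURSUIT_GAIN * e_el))
        max_step = MAX_ANGLE_RATE * DT
        lat += max(-max_step, min(max_step, alpha * (g * lat_cmd - lat)))
        pit += max(-max_step, min(max_step, alpha * (g * pit_cmd - pit)))
        az += math.radians(TURN_RATE_GAIN * lat) * DT
        el += math.radians(-CLIMB_RATE_GAIN * pit) * DT
        el = max(-1.2, min(1.2, el))
        ce = math.cos(el)
        x += SPEED * DT * ce * math.cos(az)
        y += SPEED * DT * ce * math.sin(az)
        z += SPEED * DT * math.sin(el)
        tx, ty, tz = tangents[target]
        if (x - cx) * tx + (y - cy) * ty + (z - cz) * tz >= 0.0:
            target += 1
            if target >= n_coins:
                pos_list.append((x, y, z))
                lat_list.append(lat)
                pit_list.append(pit)
                break

    n = len(pos_list)
    t = DT * np.arange(n)
    position = np.asarray(pos_list)
    lat_arr = np.asarray(lat_list)
    pit_arr = np.asarray(pit_list)

    def noise():
        return rng.normal(0.0, cfg.noise_sd, n)

    # controller segment: true signal driving the flight
    ctl_pitch, ctl_roll, ctl_yaw = pit_arr, lat_arr.copy(), lat_arr.copy()
    c, h = cfg.coupling, cfg.head_comp_gain
    if cfg.control == "torso":
        torso = (ctl_pitch, ctl_roll, ctl_yaw)
        head = tuple(
            (c - h) * ax + (1.0 - c) * _smooth_noise(rng, n, GAZE_AMP) + noise()
            for ax in torso
        )
        torso = tuple(ax + noise() for ax in torso)
    else:
        head = tuple(ax + noise() for ax in (ctl_pitch, ctl_roll, ctl_yaw))
        torso = tuple(
            (1.0 - c) * _smooth_noise(rng, n, GAZE_AMP) + noise()
            for _ in range(3)
        )
    meta = dict(meta or {})
    meta.setdefault("study", "flight")
    meta.setdefault("control", cfg.control)
    return TrialRecording(
        head=AngleSeries(t, *head),
        torso=AngleSeries(t, *torso),
        position=position,
        meta=meta,
    )


def simulate_jar_trial(
    cfg: SynthConfig,
    target: float,
    condition: str,
    body_part: str,
    meta: dict | None = None,
) -> JarTrial:
    """One 4 s joint-angle-reproduction trial.

    The tested body part's lateral angle follows a slightly underdamped
    second-order step response toward g_eff * target, where g_eff is the
    overshoot gain outside the Feedback condition (visual feedback closes
    the loop, so g_eff = 1 with feedback) plus measurement noise. For
    torso trials the head trace mixes coupling, a vertical hold at zero
    and compensatory opposition: head = (c - h) * torso + noise.
    """
    if condition not in ("Feedback", "NoFeedback", "Forward"):
        raise ParameterError(f"unknown condition {condition!r}")
    if float(target) not in (-15.0, 0.0, 15.0):
        raise ParameterError(f"target {target} not in {{-15, 0, 15}}")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(JAR_DURATION_S / DT)) + 1
    t = DT * np.arange(n)
    g_eff = 1.0 if condition == "Feedback" else cfg.overshoot_gain
    amp = g_eff * float(target)
    zw = JAR_ZETA * JAR_OMEGA
    wd = JAR_OMEGA * math.sqrt(1.0 - JAR_ZETA**2)
    phi = math.acos(JAR_ZETA)
    step = 1.0 - np.exp(-zw * t) * np.sin(wd * t + phi) / math.sin(phi)
    angle = amp * step

    def noise(scale=1.0):
        return rng.normal(0.0, scale * cfg.noise_sd, n)

    tested = (noise(0.3), angle + noise(), angle + noise())  # pitch, roll, yaw
    c, h = cfg.coupling, cfg.head_comp_gain
    if body_part == "torso":
        torso = tested
        head = tuple((c - h) * ax + noise() for ax in torso)
    else:
        head = tested
        torso = tuple((1.0 - c) * noise(0.5) for _ in range(3))
    meta = dict(meta or {})
    return JarTrial(
        target_angle=float(target),
        body_part=body_part,
        condition=condition,
        head=AngleSeries(t, *head),
        torso=AngleSeries(t, *torso),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# cohort simulation

#: study-like sequence structure: (phase label, number of coins)
STUDY1_SEQUENCES = (
    ("Before", 26),
    ("Training", 50),
    ("Training", 50),
    ("After", 18),
    ("DayAfter", 26),
)
SHORT_SEQUENCES = (("Before", 8),)

#: JAR repetitions per target angle, by condition
JAR_REPETITIONS = {"Feedback": 5, "NoFeedback": 10, "Forward": 10}

#: default per-group parameter priors: mean values of (c, g, h, noise_sd);
#: young groups couple less, overestimate more and compensate more
DEFAULT_GROUP_PRIORS: dict[str, dict[str, float]] = {
    "6": dict(coupling=0.45, overshoot_gain=1.5, head_comp_gain=0.35, noise_sd=1.0),
    "8-9": dict(coupling=0.60, overshoot_gain=1.30, head_comp_gain=0.25, noise_sd=0.8),
    "10": dict(coupling=0.75, overshoot_gain=1.15, head_comp_gain=0.15, noise_sd=0.6),
    "adult": dict(coupling=0.90, overshoot_gain=1.02, head_comp_gain=0.05, noise_sd=0.5),
}
#: study-1 group sizes (6 y.o., 8-9 y.o., 10 y.o., adults)
STUDY1_GROUP_SIZES = {"6": 9, "8-9": 12, "10": 11, "adult": 13}

_PRIOR_SD = dict(coupling=0.08, overshoot_gain=0.08, head_comp_gain=0.05, noise_sd=0.1)


@dataclass
class CohortDataset:
    flight_trials: list[TrialRecording]
    jar_trials: list[JarTrial]
    courses: dict[tuple[str, int], CoinCourse]
    truth: pd.DataFrame          # participant-level generating parameters


def _draw_participant_params(
    rng: np.random.Generator, prior: dict[str, float]
) -> dict[str, float]:
    out = {}
    for k, mu in prior.items():
        v = rng.normal(mu, _PRIOR_SD[k])
        if k == "coupling":
            v = float(np.clip(v, 0.0, 1.0))
        elif k == "overshoot_gain":
            v = float(np.clip(v, 0.5, 2.5))
        else:
            v = float(np.clip(v, 0.0, None))
        out[k] = v
    return out


def simulate_cohort(
    n_per_group: dict[str, int] | None = None,
    group_params: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    sequences: tuple[tuple[str, int], ...] = STUDY1_SEQUENCES,
    jar_repetitions: dict[str, int] | None = None,
    include_jar: bool = True,
) -> CohortDataset:
    """Full synthetic cohort with the two-control flight protocol plus JAR.

    Per participant and control body part, one flight sequence per entry
    of ``sequences`` (default: the 26/50/50/18/26-coin study-1 structure,
    phases Before/Training/Training/After/DayAfter) and, when
    ``include_jar``, the full JAR protocol (5 repetitions per target with
    feedback, 10 without and 10 in the forward condition). All courses are
    shared across participants, as in a common set of game paths.
    Per-participant parameters are drawn from the group priors; the truth
    table records them for parameter-recovery studies.
    """
    n_per_group = dict(n_per_group or STUDY1_GROUP_SIZES)
    priors = {**DEFAULT_GROUP_PRIORS, **(group_params or {})}
    jar_repetitions = dict(jar_repetitions or JAR_REPETITIONS)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    courses = {
        (phase, i): generate_course(n_coins, seed=int(rng.integers(2**31)))
        for i, (phase, n_coins) in enumerate(sequences)
    }
    flight, jar_trials, truth_rows = [], [], []
    pid = 0
    for group, n_sub in n_per_group.items():
        for _ in range(n_sub):
            pid += 1
            params = _draw_participant_params(rng, priors[group])
            truth_rows.append(dict(participant=pid, age_group=group, **params))
            for control in ("head", "torso"):
                for i, (phase, _) in enumerate(sequences):
                    cfg = SynthConfig(
                        seed=int(rng.integers(2**31)),
                        control=control,
                        lag_tau=0.3,
                        **params,
                    )
                    flight.append(
                        simulate_flight_trial(
                            cfg, courses[(phase, i)],
                            meta=dict(
                                participant=pid, age_group=group,
                                control=control, phase=phase, study="flight",
                                sequence_index=i,
                            ),
                        )
                    )
                if include_jar:
                    for condition, reps in jar_repetitions.items():
                        for target in (-15.0, 0.0, 15.0):
                            for _rep in range(reps):
                                cfg = SynthConfig(
                                    seed=int(rng.integers(2**31)),
                                    control=control,
                                    **params,
                                )
                                jar_trials.append(
                                    simulate_jar_trial(
                                        cfg, target, condition, control,
                                        meta=dict(participant=pid, age_group=group),
                                    )
                                )
    return CohortDataset(
        flight_trials=flight,
        jar_trials=jar_trials,
        courses=courses,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# parameter recovery


def recover_coupling(
    dataset: CohortDataset,
    features: tuple[str, ...] = ("corr_roll_roll", "corr_yaw_yaw"),
) -> pd.DataFrame:
    """Estimate each participant's coupling from torso-trial coordination.

    The estimator is the participant's mean head-torso absolute
    correlation (roll-roll and yaw-yaw pooled by default -- both axes
    carry the lateral steering signal) over torso-controlled flight
    sequences; it is a monotone statistic of c, so recovery is assessed
    by rank correlation, not absolute value.
    """
    from .features import feature_vector

    course_of = {
        k: (c, catmull_rom_path(c)) for k, c in dataset.courses.items()
    }
    rows = []
    for trial in dataset.flight_trials:
        if trial.meta.get("control") != "torso":
            continue
        key = (trial.meta["phase"], trial.meta["sequence_index"])
        course, ideal = course_of[key]
        fv = feature_vector(trial, course, ideal)
        rows.append(
            dict(
                participant=trial.meta["participant"],
                value=float(np.nanmean([fv.values[f] for f in features])),
            )
        )
    est = pd.DataFrame(rows).groupby("participant")["value"].mean()
    out = dataset.truth.set_index("participant")[["coupling"]].copy()
    out["recovered"] = est
    return out.reset_index()


def recover_overshoot_gain(dataset: CohortDataset) -> pd.DataFrame:
    """Estimate g from the no-feedback JAR signed error: g_hat = 1 + err/target."""
    from .jar import jar_metrics

    rows = []
    for tr in dataset.jar_trials:
        if tr.condition == "Feedback" or tr.target_angle == 0:
            continue
        m = jar_metrics(tr)
        rows.append(
            dict(
                participant=tr.meta["participant"],
                g_hat=1.0 + m.signed_error / tr.target_angle,
            )
        )
    est = pd.DataFrame(rows).groupby("participant")["g_hat"].mean()
    out = dataset.truth.set_index("participant")[["overshoot_gain"]].copy()
    out["recovered"] = est
    return out.reset_index()


def parameter_recovery(dataset: CohortDataset) -> pd.DataFrame:
    """True-vs-recovered table with Spearman rank correlations.

    Returns one row per parameter ('coupling', 'overshoot_gain') with the
    rank correlation between the generating value and its feature-based
    estimate across participants.
    """
    from scipy.stats import spearmanr

    rows = []
    for name, table, col in (
        ("coupling", recover_coupling(dataset), "coupling"),
        ("overshoot_gain", recover_overshoot_gain(dataset), "overshoot_gain"),
    ):
        ok = table.dropna()
        rho = spearmanr(ok[col], ok["recovered"]).statistic if len(ok) > 2 else float("nan")
        rows.append(dict(parameter=name, spearman_rho=float(rho), n=len(ok)))
    return pd.DataFrame(rows)
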