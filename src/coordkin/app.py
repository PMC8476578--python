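"""End-to-end study pipelines over a cohort of recordings.

``run_study1`` chains features -> outlier-downweighted PCA variable
selection (all trials on PC1, torso-only on PC1+PC2, head-only on PC1)
-> mixed repeated-measures ANOVAs with TSBKY FDR control, the way the
steering study analyzes its flight recordings. ``run_study2`` computes
per-trial JAR metrics, condition summaries and the per-age-group
regressions of flight steering error on head-torso decoupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pca as _pca
from . import stats as _stats
from .course import catmull_rom_path
from .features import FEATURE_CATEGORIES, FEATURE_NAMES, feature_vector
from .jar import jar_condition_summary, jar_metrics
from .synth import CohortDataset


class ConfigError(ValueError):
    pass


def load_cohort(input_dir, course_map: dict[tuple[str, int], str]) -> CohortDataset:
    """Load a directory of canonical trial CSVs into a cohort.

    ``course_map`` maps (phase, sequence_index) to a course JSON path --
    externally deposited data never ships with a guessable layout, so the
    mapping is explicit. Flight trials must carry participant/age_group/
    control/phase/sequence_index metadata in their JSON sidecars; files
    whose sidecar says ``study: jar`` are loaded as JAR trials using the
    target_angle/condition/body_part metadata fields.
    """
    from pathlib import Path

    from .io_model import CoinCourse, JarTrial, read_trial

    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise ConfigError(f"input directory {input_dir} does not exist")
    courses = {
        key: CoinCourse.from_json(path) for key, path in course_map.items()
    }
    flight, jar = [], []
    for path in sorted(input_dir.glob("*.csv")):
        trial = read_trial(path)
        if trial.meta.get("study") == "jar":
            jar.append(
                JarTrial(
                    target_angle=trial.meta["target_angle"],
                    body_part=trial.meta["body_part"],
                    condition=trial.meta["condition"],
                    head=trial.head, torso=trial.torso,
                    meta=trial.meta,
                )
            )
        else:
            key = (trial.meta["phase"], trial.meta["sequence_index"])
            if key not in courses:
                raise ConfigError(f"no course mapped for sequence {key}")
            flight.append(trial)
    if not flight and not jar:
        raise ConfigError(f"no trial files found in {input_dir}")
    return CohortDataset(
        flight_trials=flight, jar_trials=jar, courses=courses,
        truth=pd.DataFrame(),
    )


@dataclass
class RunConfig:
    """Thresholds and toggles of the analysis chain (defaults: study values)."""

    rejection_threshold: float = 20.0       # deg, segment discontinuity rule
    loading_threshold: float = 0.75         # normalized-loading selection
    outlier_sd: float = 4.0                 # centroid-distance multiplier
    outlier_weight: float = 0.5
    fdr_alpha: float = 0.05
    subsets: tuple[str, ...] = ("all", "torso", "head")
    anova_response: str = "error_mean"

    def __post_init__(self):
        for v in (self.rejection_threshold, self.loading_threshold,
                  self.outlier_sd, self.outlier_weight, self.fdr_alpha):
            if v <= 0:
                raise ConfigError("all thresholds must be positive")


def compute_feature_table(dataset: CohortDataset, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Tidy table: one row per flight sequence, 50 variables + metadata."""
    cfg = cfg or RunConfig()
    cache = {k: (c, catmull_rom_path(c)) for k, c in dataset.courses.items()}
    rows = []
    for trial in dataset.flight_trials:
        key = (trial.meta["phase"], trial.meta["sequence_index"])
        course, ideal = cache[key]
        fv = feature_vector(trial, course, ideal, cfg.rejection_threshold)
        rows.append(
            {
                "participant": trial.meta["participant"],
                "age_group": trial.meta["age_group"],
                "control": trial.meta["control"],
                "phase": trial.meta["phase"],
                "sequence_index": trial.meta["sequence_index"],
                "n_rejected_segments": fv.n_rejected,
                **fv.values,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PcaBundle:
    subset: str
    result: _pca.PcaResult
    n_pcs_examined: int
    separation_p: float | None = None


@dataclass
class Study1Bundle:
    features: pd.DataFrame
    pca: dict[str, PcaBundle]
    anova: pd.DataFrame
    config: RunConfig


def _run_pca_subset(
    feats: pd.DataFrame, subset: str, cfg: RunConfig
) -> PcaBundle:
    if subset == "all":
        sub = feats
        n_pcs = 1
    else:
        sub = feats[feats["control"] == subset]
        n_pcs = 2 if subset == "torso" else 1
    X = sub[list(FEATURE_NAMES)].dropna(axis=1, how="all")
    X = X.loc[:, X.notna().all()]  # PCA needs complete columns
    Z, kept, _dropped = _pca.zscore_matrix(X)
    weights = _pca.detect_outliers(Z, cfg.outlier_sd, cfg.outlier_weight)
    res = _pca.weighted_pca(Z, weights, tuple(kept))
    _pca.select_variables(res, cfg.loading_threshold, n_pcs)
    _pca.cluster_selected(res, FEATURE_CATEGORIES)
    sep = None
    if subset == "all" and sub["control"].nunique() == 2:
        _t, sep = _pca.separation_test(res.scores, sub["control"].to_numpy())
    return PcaBundle(subset, res, n_pcs, sep)


def run_study1(dataset: CohortDataset, cfg: RunConfig | None = None) -> Study1Bundle:
    """The flight-study chain on one cohort.

    Requires at least two participants with both control conditions.
    ANOVAs (Age between, Control and Phase within) are run on the steering
    error and on every variable selected by any subset's PCA, after
    Anderson-Darling screening with Box-Cox fallback, and the Age-effect
    p-value family is TSBKY-corrected.
    """
    cfg = cfg or RunConfig()
    feats = compute_feature_table(dataset, cfg)
    if feats["participant"].nunique() < 2:
        raise ConfigError("need at least 2 participants")
    if set(feats["control"].unique()) != {"head", "torso"}:
        raise ConfigError("both control conditions are required")

    bundles = {s: _run_pca_subset(feats, s, cfg) for s in cfg.subsets}

    selected: list[str] = []
    for b in bundles.values():
        selected.extend(v for v in b.result.selected_variables if v not in selected)
    responses = [cfg.anova_response] + [v for v in selected if v != cfg.anova_response]

    # per-participant x control x phase means feed the rm-ANOVA
    cellmeans = (
        feats.groupby(["participant", "age_group", "control", "phase"], sort=True)
        .mean(numeric_only=True)
        .reset_index()
    )
    anova_rows = []
    for resp in responses:
        sub = cellmeans.dropna(subset=[resp])
        vals = sub[resp].to_numpy(dtype=float)
        if len(sub) < 8 or np.ptp(vals) == 0:
            continue
        tr = _stats.screen_and_transform(vals)
        sub = sub.assign(_resp=tr.x)
        spec = _stats.AnovaSpec(
            response="_resp", subject="participant",
            between="age_group", within=("control", "phase"),
        )
        try:
            results = _stats.mixed_rm_anova(sub, spec)
        except _stats.InferenceError:
            continue
        for r in results:
            anova_rows.append(
                dict(variable=resp, effect=r.effect, F=r.F,
                     df_num=r.df_num, df_den=r.df_den, p=r.p,
                     partial_eta_sq=r.partial_eta_sq,
                     boxcox=tr.rejected_normality)
            )
    anova = pd.DataFrame(anova_rows)
    if len(anova):
        flags = np.zeros(len(anova), dtype=bool)
        age_mask = (anova["effect"] == "age_group").to_numpy()
        if age_mask.any():
            rej, _ = _stats.bky_fdr(anova.loc[age_mask, "p"].to_numpy(), cfg.fdr_alpha)
            flags[np.nonzero(age_mask)[0]] = rej
        anova["fdr_reject_age_family"] = flags
    return Study1Bundle(features=feats, pca=bundles, anova=anova, config=cfg)


@dataclass
class Study2Bundle:
    jar_table: pd.DataFrame
    condition_summary: pd.DataFrame
    regressions: pd.DataFrame
    config: RunConfig


def run_study2(dataset: CohortDataset, cfg: RunConfig | None = None) -> Study2Bundle:
    """The JAR-study chain: per-trial metrics, summaries and regressions.

    The regression relates each participant's mean crossing error in the
    torso-controlled flight sequence to the mean absolute head-torso final
    difference of the no-feedback torso JAR trials, per age group; when no
    flight sequence is available the regressions are skipped (empty table).
    """
    cfg = cfg or RunConfig()
    if not dataset.jar_trials:
        raise ConfigError("no JAR trials in the dataset")
    rows = []
    for tr in dataset.jar_trials:
        m = jar_metrics(tr)
        rows.append(
            dict(
                participant=tr.meta.get("participant"),
                age_group=tr.meta.get("age_group"),
                condition=tr.condition,
                body_part=tr.body_part,
                target=tr.target_angle,
                final_angle=m.final_angle,
                signed_error=m.signed_error,
                overshoot=m.overshoot,
                oscillation_count=m.oscillation_count,
                head_ai=m.head_ai,
                head_torso_final_diff=m.head_torso_final_diff,
                head_alignment_error=m.head_alignment_error,
            )
        )
    jar_table = pd.DataFrame(rows)
    summary = jar_condition_summary(dataset.jar_trials)

    regressions = pd.DataFrame(
        columns=["age_group", "r2", "p", "slope", "n"]
    )
    if dataset.flight_trials:
        feats = compute_feature_table(dataset, cfg)
        flight_err = (
            feats[feats["control"] == "torso"]
            .groupby(["participant", "age_group"])["error_mean"]
            .mean()
            .reset_index()
        )
        decoupling = (
            jar_table[
                (jar_table["body_part"] == "torso")
                & (jar_table["condition"] == "NoFeedback")
            ]
            .assign(absdiff=lambda d: d["head_torso_final_diff"].abs())
            .groupby("participant")["absdiff"]
            .mean()
        )
        merged = flight_err.merge(
            decoupling.rename("decoupling"), on="participant", how="inner"
        ).dropna()
        reg_rows = []
        for grp, sub in merged.groupby("age_group", sort=True):
            if len(sub) < 3 or np.ptp(sub["decoupling"].to_numpy()) == 0:
                continue
            r2, p, slope = _stats.regress_r2(
                sub["decoupling"].to_numpy(), sub["error_mean"].to_numpy()
            )
            reg_rows.append(dict(age_group=grp, r2=r2, p=p, slope=slope, n=len(sub)))
        if reg_rows:
            regressions = pd.DataFrame(reg_rows)
    return Study2Bundle(
        jar_table=jar_table,
        condition_summary=summary,
        regressions=regressions,
        config=cfg,
    )
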