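"""Statistical layer: normality screening, mixed repeated-measures ANOVA,
pairwise contrasts with Cohen's d, two-stage FDR control, and simple OLS.

The analysis chain mirrors classical human-movement group statistics:
each response is screened with the Anderson-Darling test and Box-Cox
transformed on rejection; group effects are tested with a split-plot
(mixed) repeated-measures ANOVA -- one between-subjects factor (age
group) and one or two within-subject factors (control type, phase or
condition) -- reporting F, degrees of freedom, p and partial eta squared;
families of p-values are corrected with the adaptive two-stage
Benjamini-Krieger-Yekutieli (TSBKY) step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normality screening


@dataclass(frozen=True)
class TransformResult:
    x: np.ndarray
    rejected_normality: bool
    lmbda: float | None = None     # Box-Cox exponent when applied
    shift: float = 0.0             # added before Box-Cox to make x > 0


def screen_and_transform(x: np.ndarray, alpha: float = 0.05) -> TransformResult:
    """Anderson-Darling screen with a Box-Cox fallback.

    If the AD test rejects normality at ``alpha``, the sample is shifted
    to be strictly positive (shift recorded) and Box-Cox transformed with
    the maximum-likelihood lambda; otherwise the sample is returned
    unchanged. Constant samples pass through untouched.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise InferenceError("need at least 8 observations to screen")
    if np.ptp(x) == 0:
        return TransformResult(x, rejected_normality=False)
    import warnings

    with warnings.catch_warnings():
        # scipy >= 1.17 deprecates the table-based critical values in favour
        # of a p-value `method`; the fixed 5% critical value is exactly the
        # classical screen used here, so keep it explicitly
        warnings.simplefilter("ignore", FutureWarning)
        res = _stats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float)
    crit = float(res.critical_values[np.argmin(np.abs(levels - 100 * alpha))])
    if res.statistic <= crit:
        return TransformResult(x, rejected_normality=False)
    shift = 0.0
    if x.min() <= 0:
        shift = -float(x.min()) + 1e-6 * max(float(np.ptp(x)), 1.0)
    xt, lam = _stats.boxcox(x + shift)
    return TransformResult(np.asarray(xt), True, float(lam), shift)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA


@dataclass(frozen=True)
class AnovaSpec:
    response: str
    subject: str
    between: str | None = None
    within: tuple[str, ...] = ()

    def __post_init__(self):
        if not (1 <= len(self.within) <= 2):
            raise InferenceError("need one or two within-subject factors")


@dataclass(frozen=True)
class TestResult:
    effect: str
    F: float | None = None
    df_num: float | None = None
    df_den: float | None = None
    p: float | None = None
    partial_eta_sq: float | None = None
    t: float | None = None
    mean_diff: float | None = None
    cohen_d: float | None = None
    fdr_reject: bool | None = None


def _f_test(ss_eff, df_eff, ss_err, df_err, name) -> TestResult:
    if df_eff < 1 or df_err < 1:
        raise InferenceError(f"non-positive degrees of freedom for {name}")
    ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
    if ms_err <= 0:
        raise InferenceError(f"zero error variance for {name}")
    F = ms_eff / ms_err
    p = float(_stats.f.sf(F, df_eff, df_err))
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return TestResult(name, float(F), float(df_eff), float(df_err), p, float(eta))


def _anova_cube(
    Y: np.ndarray, group_idx: np.ndarray, n_groups: int
) -> list[TestResult]:
    """Split-plot sums of squares on a complete (subject, B, C) cube."""
    N, b, c = Y.shape
    a = n_groups
    counts = np.bincount(group_idx, minlength=a).astype(float)
    grand = Y.mean()
    M = Y.mean(axis=(1, 2))                       # subject means
    G = np.array([M[group_idx == g].mean() for g in range(a)])
    Bj = Y.mean(axis=(0, 2))
    Ck = Y.mean(axis=(0, 1))
    Ygj = np.stack([Y[group_idx == g].mean(axis=(0, 2)) for g in range(a)])
    Ygk = np.stack([Y[group_idx == g].mean(axis=(0, 1)) for g in range(a)])
    Ygjk = np.stack([Y[group_idx == g].mean(axis=0) for g in range(a)])
    Yjk = Y.mean(axis=0)
    Yij = Y.mean(axis=2)
    Yik = Y.mean(axis=1)

    out: list[TestResult] = []
    ss_subj = b * c * float(((M - G[group_idx]) ** 2).sum())
    df_subj = N - a
    if a > 1:
        ss_A = b * c * float((counts * (G - grand) ** 2).sum())
        out.append(_f_test(ss_A, a - 1, ss_subj, df_subj, "between"))

    # within factor B
    ss_B = N * c * float(((Bj - grand) ** 2).sum())
    resid_BS = Yij - M[:, None] - Ygj[group_idx] + G[group_idx, None]
    ss_BS = c * float((resid_BS ** 2).sum())
    df_BS = (N - a) * (b - 1)
    out.append(_f_test(ss_B, b - 1, ss_BS, df_BS, "within1"))
    if a > 1:
        resid_AB = Ygj - G[:, None] - Bj[None, :] + grand
        ss_AB = c * float((counts[:, None] * resid_AB ** 2).sum())
        out.append(_f_test(ss_AB, (a - 1) * (b - 1), ss_BS, df_BS, "between x within1"))

    if c > 1:
        ss_C = N * b * float(((Ck - grand) ** 2).sum())
        resid_CS = Yik - M[:, None] - Ygk[group_idx] + G[group_idx, None]
        ss_CS = b * float((resid_CS ** 2).sum())
        df_CS = (N - a) * (c - 1)
        out.append(_f_test(ss_C, c - 1, ss_CS, df_CS, "within2"))
        if a > 1:
            resid_AC = Ygk - G[:, None] - Ck[None, :] + grand
            ss_AC = b * float((counts[:, None] * resid_AC ** 2).sum())
            out.append(_f_test(ss_AC, (a - 1) * (c - 1), ss_CS, df_CS, "between x within2"))
        resid_BC = Yjk - Bj[:, None] - Ck[None, :] + grand
        ss_BC = N * float((resid_BC ** 2).sum())
        resid_ABC = (
            Ygjk - Ygj[:, :, None] - Ygk[:, None, :] - Yjk[None]
            + G[:, None, None] + Bj[None, :, None] + Ck[None, None, :] - grand
        )
        ss_ABC = float((counts[:, None, None] * resid_ABC ** 2).sum())
        resid_BCS = (
            Y - Yij[:, :, None] - Yik[:, None, :] - Ygjk[group_idx]
            + M[:, None, None] + Ygj[group_idx][:, :, None] + Ygk[group_idx][:, None, :]
            - G[group_idx][:, None, None]
        )
        ss_BCS = float((resid_BCS ** 2).sum())
        df_BCS = (N - a) * (b - 1) * (c - 1)
        out.append(_f_test(ss_BC, (b - 1) * (c - 1), ss_BCS, df_BCS, "within1 x within2"))
        if a > 1:
            out.append(
                _f_test(ss_ABC, (a - 1) * (b - 1) * (c - 1), ss_BCS, df_BCS,
                        "between x within1 x within2")
            )
    return out


def mixed_rm_anova(data: pd.DataFrame, spec: AnovaSpec) -> list[TestResult]:
    """Mixed (split-plot) repeated-measures ANOVA from a long table.

    One optional between-subjects factor and one or two within-subject
    factors; each subject must supply exactly one observation per within
    cell (replicates are averaged, subjects with missing cells are dropped
    and the drop is reported via a warning-free return attribute on the
    effect list -- callers can compare len(used) with the input). No
    sphericity correction is applied.
    """
    cols = [spec.subject, spec.response, *spec.within]
    if spec.between:
        cols.append(spec.between)
    for colname in cols:
        if colname not in data.columns:
            raise InferenceError(f"missing column {colname!r}")
    for f in spec.within:
        if data[f].nunique() < 2:
            raise InferenceError(f"within factor {f!r} needs >= 2 levels")
    if spec.between and data[spec.between].nunique() < 2:
        raise InferenceError(f"between factor {spec.between!r} needs >= 2 levels")

    w1 = spec.within[0]
    w2 = spec.within[1] if len(spec.within) == 2 else None
    lev1 = sorted(data[w1].unique())
    lev2 = sorted(data[w2].unique()) if w2 else [None]
    cell = data.groupby(
        [spec.subject, w1] + ([w2] if w2 else []), sort=True
    )[spec.response].mean()

    subjects, rows, groups = [], [], []
    for subj, sub in data.groupby(spec.subject, sort=True):
        try:
            if w2:
                cube = [[cell.loc[(subj, l1, l2)] for l2 in lev2] for l1 in lev1]
            else:
                cube = [[cell.loc[(subj, l1)]] for l1 in lev1]
        except KeyError:
            continue  # incomplete within-design: listwise deletion
        if np.any(~np.isfinite(np.asarray(cube, dtype=float))):
            continue
        subjects.append(subj)
        rows.append(cube)
        groups.append(sub[spec.between].iloc[0] if spec.between else 0)
    if len(subjects) < 2:
        raise InferenceError("fewer than 2 complete subjects")
    Y = np.asarray(rows, dtype=float)
    glevels = sorted(set(groups))
    gidx = np.array([glevels.index(g) for g in groups])
    names = {"within1": w1, "within2": w2, "between": spec.between}
    results = _anova_cube(Y, gidx, len(glevels))
    renamed = []
    for r in results:
        label = r.effect
        for key, val in names.items():
            if val:
                label = label.replace(key, val)
        renamed.append(TestResult(label, r.F, r.df_num, r.df_den, r.p, r.partial_eta_sq))
    return renamed


# ---------------------------------------------------------------------------
# pairwise contrasts


def cohens_d(a: np.ndarray, b: np.ndarray, paired: bool = False) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise InferenceError("paired contrast needs equal sizes")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            raise InferenceError("zero variance of paired differences")
        return float(diff.mean() / sd)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise InferenceError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def pairwise_with_d(
    contrasts: list[tuple[str, np.ndarray, np.ndarray]], paired: bool = False
) -> list[TestResult]:
    """t-tests with Cohen's d for a list of (name, sample_a, sample_b)."""
    out = []
    for name, a, b in contrasts:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise InferenceError(f"contrast {name!r} needs >= 2 per side")
        d = cohens_d(a, b, paired=paired)  # raises first on zero variance
        if paired:
            t, p = _stats.ttest_rel(a, b)
        else:
            t, p = _stats.ttest_ind(a, b)
        out.append(
            TestResult(name, p=float(p), t=float(t),
                       mean_diff=float(a.mean() - b.mean()), cohen_d=d)
        )
    return out


# ---------------------------------------------------------------------------
# two-stage Benjamini-Krieger-Yekutieli FDR


def _bh_rejections(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection flags (input order)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if below.any():
        kmax = int(np.nonzero(below)[0].max())
        flags[order[: kmax + 1]] = True
    return flags


def bky_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Two-stage BKY adaptive step-up FDR control.

    Stage 1 runs a BH step-up at alpha' = alpha / (1 + alpha) to estimate
    the number of true nulls m0 = m - r1; stage 2 reruns the step-up at
    level alpha' * m / m0. Returns (rejection flags in input order, the
    stage-2 per-comparison level used). Degenerate stages follow the
    published rule: r1 = 0 rejects nothing, r1 = m rejects everything.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    m = p.size
    a1 = alpha / (1.0 + alpha)
    stage1 = _bh_rejections(p, a1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool), a1
    if r1 == m:
        return np.ones(m, dtype=bool), a1
    a2 = a1 * m / (m - r1)
    return _bh_rejections(p, a2), a2


# ---------------------------------------------------------------------------
# simple regression


def regress_r2(x, y) -> tuple[float, float, float]:
    """Simple OLS of y on x: returns (R^2, two-sided slope p, slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InferenceError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise InferenceError("constant predictor")
    res = _stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue), float(res.slope)
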