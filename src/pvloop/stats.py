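"""Study statistics: group comparisons, repeated-measures ANOVA, post-tests.

The analysis pipeline of a two-group crossover dose-response experiment:

* baseline contrasts between groups by two-tailed Student's t (pooled
  variance; Welch optional) when both samples pass a normality gate, else
  the Wilcoxon rank-sum (Mann-Whitney) test;
* a paired baseline-shift rule: when the pre-treatment baseline and the
  post-washout baseline differ significantly, dose responses are analysed
  as relative changes from each arm's own baseline;
* repeated-measures two-way ANOVA by the classical sums-of-squares
  decomposition (each within-subject effect tested against its own
  subject-interaction error term, matching the conventions of the usual
  commercial packages), in two layouts: both factors within subject
  (treatment x dose) or group as a between-subject factor (group x dose);
* Bonferroni-adjusted per-dose post-hoc contrasts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RmAnovaResult",
    "BaselineShiftDecision",
    "normality_check",
    "compare_groups",
    "t_from_summary",
    "baseline_shift_rule",
    "relative_change",
    "rm_two_way_anova",
    "bonferroni",
]


@dataclass
class GroupComparison:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    test_used: str          # "student_t", "welch_t" or "wilcoxon"
    statistic: float
    p_value: float
    two_tailed: bool = True


@dataclass
class RmAnovaResult:
    """Factor table plus Bonferroni post-hoc contrasts."""

    table: pd.DataFrame     # index: effect; columns: SS, df, F, p (error rows: SS, df)
    posthoc: pd.DataFrame | None = None
    layout: str = "both_within"

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


@dataclass
class BaselineShiftDecision:
    p_baseline: float
    use_relative: bool
    alpha: float = 0.05


def normality_check(sample, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk gate standing in for a visual Q-Q/histogram check.

    Returns False for degenerate (constant) samples; raises for n < 3.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        return False
    return bool(sps.shapiro(x).pvalue >= alpha)


def compare_groups(x, y, welch: bool = False,
                   alpha_normality: float = 0.05) -> GroupComparison:
    """Two-sample comparison with automatic test selection.

    Student's t (pooled variance; Welch when requested) when both samples
    pass :func:`normality_check`, otherwise the Wilcoxon rank-sum test.
    Two-tailed throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    both_constant = np.ptp(x) == 0 and np.ptp(y) == 0
    try:
        normal = normality_check(x, alpha_normality) and \
            normality_check(y, alpha_normality)
    except ValueError:
        normal = False
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: no evidence of difference, regardless of gate
        normal = True
    if normal or both_constant:
        if np.array_equal(np.sort(x), np.sort(y)) and np.ptp(
                np.concatenate([x, y])) == 0:
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(x, y, equal_var=not welch)
            stat, p = float(res.statistic), float(res.pvalue)
            if np.isnan(stat):  # zero pooled variance, equal means
                stat, p = 0.0, 1.0
        test = "welch_t" if welch else "student_t"
    else:
        res = sps.ranksums(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon"
    return GroupComparison(mean1=float(x.mean()), sd1=float(x.std(ddof=1)),
                           n1=int(x.size), mean2=float(y.mean()),
                           sd2=float(y.std(ddof=1)), n2=int(y.size),
                           test_used=test, statistic=stat, p_value=p)


def t_from_summary(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int,
                   welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t from summary statistics: (t, df, p).

    Pooled variance with df = n1 + n2 − 2 by default;
    Welch–Satterthwaite when ``welch``.  Lets users probe reported
    mean (SD) rows directly.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("sds must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("ns must be >= 2")
    v1, v2 = sd1 ** 2, sd2 ** 2
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            raise ValueError("t undefined: zero variance in both samples")
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = (mean1 - mean2) / np.sqrt(se2)
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            if mean1 == mean2:
                raise ValueError("t undefined: zero pooled variance, equal means")
            return float("inf"), float(df), 0.0
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def baseline_shift_rule(baseline1, baseline2,
                        alpha: float = 0.05) -> BaselineShiftDecision:
    """Paired comparison of the two baselines of a crossover arm.

    ``use_relative`` is set when the paired t rejects at ``alpha``;
    downstream responses should then be expressed as
    100·(value/own-baseline − 1).
    """
    b1 = np.asarray(baseline1, dtype=float)
    b2 = np.asarray(baseline2, dtype=float)
    if b1.shape != b2.shape or b1.ndim != 1:
        raise ValueError("baselines must be paired 1-d samples of equal length")
    if b1.size < 2:
        raise ValueError("need >= 2 paired subjects")
    d = b2 - b1
    if np.ptp(d) == 0 and d[0] == 0:
        p = 1.0
    else:
        p = float(sps.ttest_rel(b2, b1).pvalue)
        if np.isnan(p):  # constant non-zero difference: certain shift
            p = 0.0
    return BaselineShiftDecision(p_baseline=p, use_relative=p < alpha,
                                 alpha=alpha)


def relative_change(values: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """100·(value/own-baseline − 1), broadcasting baseline over trailing axes."""
    baseline = np.asarray(baseline, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(baseline == 0):
        raise ValueError("zero baseline")
    shape = baseline.shape + (1,) * (values.ndim - baseline.ndim)
    return 100.0 * (values / baseline.reshape(shape) - 1.0)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p) elementwise (m defaults to len)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def null_dose_response(rng, n_subjects: int = 5, n_treatments: int = 2,
                       n_doses: int = 4, subject_sd: float = 1.0,
                       noise_sd: float = 1.0,
                       treatment_effect: float = 0.0) -> np.ndarray:
    """Subject-plus-noise response cube for ANOVA calibration studies.

    Responses are independent of treatment and dose (a random subject
    level plus iid noise); ``treatment_effect`` adds a constant shift to
    the second treatment, expressed in units of the noise SD.
    """
    y = rng.normal(0.0, subject_sd, (n_subjects, 1, 1)) + \
        rng.normal(0.0, noise_sd, (n_subjects, n_treatments, n_doses))
    if treatment_effect:
        y[:, 1, :] += treatment_effect * noise_sd
    return y


def crossover_null_run(rng, n_subjects: int = 5, drift_sd: float = 0.02,
                       subject_sd: float = 0.10, noise: float = 0.05,
                       treatment_effect: float = 0.0):
    """One synthetic crossover arm-pair under the null, full pipeline.

    Subject states are multiplicative (lognormal); the second arm's state
    drifts by a lognormal washout factor; measured baselines and dose
    responses follow each arm's own state with relative measurement noise.
    The baseline-shift rule is applied, responses are transformed to
    relative changes when it fires, and the repeated-measures ANOVA with
    Bonferroni post-tests is run.  Returns (RmAnovaResult,
    BaselineShiftDecision).
    """
    s1 = 100.0 * rng.lognormal(0.0, subject_sd, n_subjects)
    s2 = s1 * rng.lognormal(0.0, drift_sd, n_subjects)
    b1 = s1 * (1 + rng.normal(0, noise, n_subjects))
    b2 = s2 * (1 + rng.normal(0, noise, n_subjects))
    states = np.stack([s1, s2], axis=1)
    cube = states[:, :, None] * (1 + rng.normal(0, noise, (n_subjects, 2, 4)))
    if treatment_effect:
        cube[:, 1, :] += treatment_effect * noise * 100.0
    dec = baseline_shift_rule(b1, b2)
    if dec.use_relative:
        arm_base = np.stack([b1, b2], axis=1)
        cube = relative_change(cube, arm_base)
    return rm_two_way_anova(cube, posthoc=True), dec


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _check_complete(a: np.ndarray) -> None:
    if np.isnan(a).any():
        raise ValueError("missing cells are not supported (no silent imputation)")


def rm_two_way_anova(responses, layout: str = "both_within",
                     groups=None, posthoc: bool = True) -> RmAnovaResult:
    """Repeated-measures two-way ANOVA, classical SS decomposition.

    Parameters
    ----------
    responses : ndarray
        ``layout="both_within"``: shape (n_subjects, n_treatments, n_doses),
        every factor within subject, subject as blocking factor.  Each
        within effect is tested against its own subject-by-effect
        interaction.
        ``layout="group_between"``: shape (n_subjects, n_doses) with
        ``groups`` giving each subject's group label; group is tested
        against subjects-within-groups, dose and group x dose against the
        dose x subject-within-group residual.
    posthoc : bool
        Per-dose treatment (or group) contrasts, Bonferroni-adjusted with
        m = number of dose levels: paired t for the within layout,
        two-sample t for the between layout.

    The design must be complete and balanced; missing cells raise.
    """
    y = np.asarray(responses, dtype=float)
    if layout == "both_within":
        return _anova_both_within(y, posthoc)
    if layout == "group_between":
        if groups is None:
            raise ValueError("groups required for layout='group_between'")
        return _anova_group_between(y, np.asarray(groups), posthoc)
    raise ValueError(f"unknown layout {layout!r}")


def _anova_both_within(y: np.ndarray, posthoc: bool) -> RmAnovaResult:
    if y.ndim != 3:
        raise ValueError("both_within layout needs a (subject, treatment, dose) array")
    _check_complete(y)
    n, p, q = y.shape
    if min(n, p, q) < 2:
        raise ValueError("need >= 2 levels of subject, treatment and dose")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_total = ((y - grand) ** 2).sum()
    ss_s = p * q * ((m_s - grand) ** 2).sum()
    ss_a = n * q * ((m_a - grand) ** 2).sum()
    ss_b = n * p * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = q * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = p * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_abs = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs

    rows = []

    def eff(name, ss, df, ss_err, df_err):
        ms, ms_e = ss / df, ss_err / df_err
        F = ms / ms_e if ms_e > 0 else np.inf
        rows.append({"effect": name, "SS": ss, "df": df, "F": F,
                     "p": float(sps.f.sf(F, df, df_err))})

    eff("treatment", ss_a, p - 1, ss_as, (p - 1) * (n - 1))
    eff("dose", ss_b, q - 1, ss_bs, (q - 1) * (n - 1))
    eff("treatment:dose", ss_ab, (p - 1) * (q - 1), ss_abs,
        (p - 1) * (q - 1) * (n - 1))
    rows.append({"effect": "subject", "SS": ss_s, "df": n - 1,
                 "F": np.nan, "p": np.nan})
    for name, ss, df in (("treatment x subject", ss_as, (p - 1) * (n - 1)),
                         ("dose x subject", ss_bs, (q - 1) * (n - 1)),
                         ("residual", ss_abs, (p - 1) * (q - 1) * (n - 1))):
        rows.append({"effect": name, "SS": ss, "df": df, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("effect")

    ph = None
    if posthoc and p == 2:
        recs = []
        for b in range(q):
            res = sps.ttest_rel(y[:, 0, b], y[:, 1, b])
            recs.append({"dose_level": b, "t": float(res.statistic),
                         "p_raw": float(res.pvalue)})
        ph = pd.DataFrame(recs)
        ph["p_adj"] = bonferroni(ph["p_raw"].to_numpy(), q)
    return RmAnovaResult(table=table, posthoc=ph, layout="both_within")


def _anova_group_between(y: np.ndarray, groups: np.ndarray,
                         posthoc: bool) -> RmAnovaResult:
    if y.ndim != 2:
        raise ValueError("group_between layout needs a (subject, dose) array")
    _check_complete(y)
    n, q = y.shape
    if groups.shape != (n,):
        raise ValueError("groups must have one label per subject")
    labels = np.unique(groups)
    g = labels.size
    if g < 2 or q < 2:
        raise ValueError("need >= 2 groups and >= 2 dose levels")
    grand = y.mean()
    counts = np.array([(groups == lab).sum() for lab in labels])
    m_g = np.array([y[groups == lab].mean() for lab in labels])
    m_b = y.mean(axis=0)
    m_s = y.mean(axis=1)
    m_gb = np.array([y[groups == lab].mean(axis=0) for lab in labels])

    ss_total = ((y - grand) ** 2).sum()
    ss_g = q * (counts * (m_g - grand) ** 2).sum()
    ss_subj_within = q * sum(
        ((m_s[groups == lab] - m_g[i]) ** 2).sum() for i, lab in enumerate(labels))
    ss_b = n * ((m_b - grand) ** 2).sum()
    ss_gb = (counts[:, None] * (m_gb - m_g[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_resid = ss_total - ss_g - ss_subj_within - ss_b - ss_gb

    df_g, df_sw = g - 1, n - g
    df_b, df_gb = q - 1, (g - 1) * (q - 1)
    df_res = (n - g) * (q - 1)
    rows = []
    F_g = (ss_g / df_g) / (ss_subj_within / df_sw)
    rows.append({"effect": "group", "SS": ss_g, "df": df_g, "F": F_g,
                 "p": float(sps.f.sf(F_g, df_g, df_sw))})
    F_b = (ss_b / df_b) / (ss_resid / df_res)
    rows.append({"effect": "dose", "SS": ss_b, "df": df_b, "F": F_b,
                 "p": float(sps.f.sf(F_b, df_b, df_res))})
    F_gb = (ss_gb / df_gb) / (ss_resid / df_res)
    rows.append({"effect": "group:dose", "SS": ss_gb, "df": df_gb, "F": F_gb,
                 "p": float(sps.f.sf(F_gb, df_gb, df_res))})
    rows.append({"effect": "subject(group)", "SS": ss_subj_within, "df": df_sw,
                 "F": np.nan, "p": np.nan})
    rows.append({"effect": "residual", "SS": ss_resid, "df": df_res,
                 "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("effect")

    ph = None
    if posthoc and g == 2:
        recs = []
        for b in range(q):
            res = sps.ttest_ind(y[groups == labels[0], b],
                                y[groups == labels[1], b])
            recs.append({"dose_level": b, "t": float(res.statistic),
                         "p_raw": float(res.pvalue)})
        ph = pd.DataFrame(recs)
        ph["p_adj"] = bonferroni(ph["p_raw"].to_numpy(), q)
    return RmAnovaResult(table=table, posthoc=ph, layout="group_between")
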