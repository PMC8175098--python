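import numpy as np
import pytest

from pvloop.stats import (baseline_shift_rule, bonferroni, compare_groups,
                          normality_check, relative_change, rm_two_way_anova,
                          t_from_summary)


# ---------------------------------------------------------------------------
# normality and group comparisons


def test_normality_check_discriminates():
    rng = np.random.default_rng(5)
    assert normality_check(rng.normal(0, 1, 50))
    assert not normality_check(rng.standard_t(1, 50))
    assert not normality_check(np.full(20, 3.0))
    with pytest.raises(ValueError):
        normality_check([1.0, 2.0])


def test_compare_groups_identical_samples():
    x = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
    out = compare_groups(x, x.copy())
    assert out.statistic == pytest.approx(0.0, abs=1e-12)
    assert out.p_value == pytest.approx(1.0)


def test_compare_groups_matches_summary_formula():
    rng = np.random.default_rng(8)
    x = rng.normal(10, 2, 9)
    y = rng.normal(11, 2, 7)
    out = compare_groups(x, y)
    assert out.test_used == "student_t"
    t, df, p = t_from_summary(x.mean(), x.std(ddof=1), x.size,
                              y.mean(), y.std(ddof=1), y.size)
    assert out.statistic == pytest.approx(t, rel=1e-10)
    assert out.p_value == pytest.approx(p, rel=1e-10)
    assert df == x.size + y.size - 2


def test_compare_groups_power_and_symmetry():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 6)
    y = rng.normal(10, 1, 5)  # 10 SD shift
    out = compare_groups(x, y)
    assert out.p_value < 1e-3
    rev = compare_groups(y, x)
    assert rev.statistic == pytest.approx(-out.statistic, rel=1e-12)
    assert rev.p_value == pytest.approx(out.p_value, rel=1e-12)


def test_compare_groups_falls_back_to_ranksum():
    rng = np.random.default_rng(10)
    x = np.exp(rng.standard_t(1, 30))  # wildly non-normal
    y = np.exp(rng.standard_t(1, 30)) + 1
    out = compare_groups(x, y)
    assert out.test_used == "wilcoxon"


def test_t_from_summary_on_reported_style_row():
    # CI row: 5.3 (1.1) n=6 vs 4.1 (0.5) n=5, pooled t
    t, df, p = t_from_summary(5.3, 1.1, 6, 4.1, 0.5, 5)
    # closed-form oracle: sp2 = (5*1.21+4*0.25)/9, t = 1.2/sqrt(sp2*(1/6+1/5))
    sp2 = (5 * 1.1 ** 2 + 4 * 0.5 ** 2) / 9
    t_oracle = 1.2 / np.sqrt(sp2 * (1 / 6 + 1 / 5))
    assert t == pytest.approx(t_oracle, rel=1e-12)
    assert t == pytest.approx(2.2391, abs=1e-4)
    assert df == 9
    assert 0.04 < p < 0.06


def test_t_from_summary_properties():
    t0, _, p0 = t_from_summary(5.0, 1.0, 6, 5.0, 1.0, 6)
    assert t0 == 0.0 and p0 == pytest.approx(1.0)
    t1, _, _ = t_from_summary(5.3, 1.1, 6, 4.1, 0.5, 5)
    t2, _, _ = t_from_summary(5.3, 1.1, 12, 4.1, 0.5, 10)
    assert abs(t2) == pytest.approx(np.sqrt(2) * abs(t1), rel=0.05)
    with pytest.raises(ValueError):
        t_from_summary(5.0, 0.0, 6, 5.0, 0.0, 6)


# ---------------------------------------------------------------------------
# baseline shift rule


def test_baseline_shift_rule():
    b1 = np.array([4.0, 5.0, 6.0, 5.5, 4.5])
    assert not baseline_shift_rule(b1, b1.copy()).use_relative
    dec = baseline_shift_rule(b1, 1.5 * b1)
    assert dec.use_relative and dec.p_baseline < 0.05
    # relative transform maps each subject's own baseline to 0%
    np.testing.assert_allclose(relative_change(b1, b1), 0.0, atol=1e-12)


def test_baseline_shift_requires_pairing():
    with pytest.raises(ValueError):
        baseline_shift_rule([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# bonferroni


def test_bonferroni():
    np.testing.assert_allclose(bonferroni([0.01], 5), [0.05])
    np.testing.assert_allclose(bonferroni([0.5], 4), [1.0])
    np.testing.assert_allclose(bonferroni([0.2, 0.9], 1), [0.2, 0.9])
    with pytest.raises(ValueError):
        bonferroni([1.5], 2)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _projection_ss(y, X_full, X_reduced):
    """SS explained by the columns of X_full beyond X_reduced.

    Projections use the pseudoinverse (the dummy designs are deliberately
    rank-deficient).
    """
    def proj(X):
        return X @ np.linalg.pinv(X) @ y

    return float(np.sum((proj(X_full) - proj(X_reduced)) ** 2))


def test_anova_ss_match_projection_matrix_oracle():
    rng = np.random.default_rng(12)
    n, p, q = 5, 2, 4
    y3 = rng.normal(0, 1, (n, p, q))
    res = rm_two_way_anova(y3, posthoc=False)
    y = y3.ravel()
    subj = np.repeat(np.arange(n), p * q)
    trt = np.tile(np.repeat(np.arange(p), q), n)
    dose = np.tile(np.arange(q), n * p)

    def dummies(codes):
        return (codes[:, None] == np.unique(codes)[None, :]).astype(float)

    one = np.ones((y.size, 1))
    S, A, B = dummies(subj), dummies(trt), dummies(dose)
    AB = np.einsum("ij,ik->ijk", A, B).reshape(y.size, -1)
    AS = np.einsum("ij,ik->ijk", A, S).reshape(y.size, -1)
    BS = np.einsum("ij,ik->ijk", B, S).reshape(y.size, -1)
    base = one
    ss = {
        "subject": _projection_ss(y, np.hstack([base, S]), base),
        "treatment": _projection_ss(y, np.hstack([base, A]), base),
        "dose": _projection_ss(y, np.hstack([base, B]), base),
        "treatment:dose": _projection_ss(
            y, np.hstack([base, A, B, AB]), np.hstack([base, A, B])),
        "treatment x subject": _projection_ss(
            y, np.hstack([base, A, S, AS]), np.hstack([base, A, S])),
        "dose x subject": _projection_ss(
            y, np.hstack([base, B, S, BS]), np.hstack([base, B, S])),
    }
    for effect, expected in ss.items():
        assert res.table.loc[effect, "SS"] == pytest.approx(expected, abs=1e-8), effect


def test_anova_ss_decomposition_conserves_total():
    rng = np.random.default_rng(13)
    y = rng.normal(0, 1, (6, 2, 4))
    res = rm_two_way_anova(y, posthoc=False)
    total = float(((y - y.mean()) ** 2).sum())
    assert res.table["SS"].sum() == pytest.approx(total, rel=1e-10)


def test_anova_detects_additive_treatment_effect():
    rng = np.random.default_rng(14)
    y = rng.normal(0, 1, (5, 2, 4))
    y[:, 1, :] += 3.0
    res = rm_two_way_anova(y)
    assert res.p("treatment") < 0.01
    assert res.posthoc is not None
    assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15).all()


def test_anova_rejects_missing_and_bad_shapes():
    y = np.random.default_rng(0).normal(0, 1, (5, 2, 4))
    y[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        rm_two_way_anova(y)
    with pytest.raises(ValueError):
        rm_two_way_anova(np.zeros((5, 4)), layout="both_within")
    with pytest.raises(ValueError):
        rm_two_way_anova(np.zeros((5, 4)), layout="group_between")


def test_mixed_anova_group_between():
    rng = np.random.default_rng(15)
    n, q = 8, 4
    groups = np.array(["a"] * 4 + ["b"] * 4)
    y = rng.normal(0, 1, (n, q)) + rng.normal(0, 1, (n, 1))
    y[4:] += 2.5
    res = rm_two_way_anova(y, layout="group_between", groups=groups)
    assert res.p("group") < 0.05
    total = float(((y - y.mean()) ** 2).sum())
    assert res.table["SS"].sum() == pytest.approx(total, rel=1e-10)
    assert res.posthoc is not None and len(res.posthoc) == q


def test_anova_matches_pingouin_reference():
    """F and p for every effect agree with an independent RM-ANOVA
    implementation on the same data."""
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(18)
    cube = rng.normal(0, 10, (6, 1, 1)) + rng.normal(0, 5, (6, 2, 4))
    res = rm_two_way_anova(cube, posthoc=False)
    df = pd.DataFrame([{"subject": s, "treatment": a, "dose": b,
                        "y": cube[s, a, b]}
                       for s in range(6) for a in range(2) for b in range(4)])
    ref = pg.rm_anova(dv="y", within=["treatment", "dose"], subject="subject",
                      data=df, detailed=True).set_index("Source")
    for ours, theirs in (("treatment", "treatment"), ("dose", "dose"),
                         ("treatment:dose", "treatment * dose")):
        assert res.table.loc[ours, "SS"] == pytest.approx(
            ref.loc[theirs, "SS"], rel=1e-8)
        assert res.table.loc[ours, "F"] == pytest.approx(
            ref.loc[theirs, "F"], rel=1e-8)
        assert res.table.loc[ours, "p"] == pytest.approx(
            ref.loc[theirs, "p_unc"], rel=1e-8)


def test_full_pipeline_contrasts_within_nominal_alpha():
    """Baseline rule + ANOVA + Bonferroni: per-contrast type-I error stays
    at or below the nominal alpha under the crossover null."""
    from pvloop.stats import crossover_null_run

    rng = np.random.default_rng(17)
    rej = n = 0
    for _ in range(300):
        res, _ = crossover_null_run(rng)
        ph = res.posthoc["p_adj"].to_numpy()
        rej += int((ph < 0.05).sum())
        n += ph.size
    assert rej / n <= 0.05


def test_anova_type_one_error_calibrated():
    """Treatment F-test under a pure subject+noise null rejects at ~alpha."""
    rng = np.random.default_rng(16)
    rejections = 0
    n_sim = 400
    for _ in range(n_sim):
        y = rng.normal(0, 1, (5, 2, 4)) + rng.normal(0, 1, (5, 1, 1))
        res = rm_two_way_anova(y, posthoc=False)
        rejections += res.p("treatment") < 0.05
    rate = rejections / n_sim
    assert 0.025 <= rate <= 0.08  # 400-rep check; the 2000-rep bound is tighter
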