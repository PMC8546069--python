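"""Cross-classified REML: design coding, variance components, tests, R²β."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from grouplink.mixedmodel import (
    EmptyCellError,
    _REMLProblem,
    build_model_frame,
    effect_size_rbeta,
    fit_crossclassified,
    linear_trend_by_condition,
    simple_effects_by_session,
)
from grouplink.mixedmodel import test_effect as wald_test


def _linkage_table(rng, n_cohorts=6, n_people=6, n_sessions=4, effects=None,
                   sds=None):
    """Linkage-style table with known crossed random effects."""
    effects = effects or {}
    sds = sds or dict(cohort=0.3, cell=0.25, dyad=0.35, receiver=0.3,
                      sender=0.2, resid=0.5)
    rows = []
    for c in range(n_cohorts):
        cond = "oxytocin" if c < n_cohorts // 2 else "placebo"
        people = [f"c{c}p{i}" for i in range(n_people)]
        roles = {p: ("facilitator" if i < 2 else "participant")
                 for i, p in enumerate(people)}
        u_c = rng.normal(0, sds["cohort"])
        u_p = {p: (rng.normal(0, sds["receiver"]), rng.normal(0, sds["sender"]))
               for p in people}
        u_d = {}
        for s in range(1, n_sessions + 1):
            u_cs = rng.normal(0, sds["cell"])
            for r in people:
                for snd in people:
                    if r == snd:
                        continue
                    d = "--".join(sorted((r, snd)))
                    u_d.setdefault(d, rng.normal(0, sds["dyad"]))
                    drug = 0.5 if cond == "oxytocin" else -0.5
                    sess = s - (1 + n_sessions) / 2
                    y = (
                        effects.get("intercept", 0.0)
                        + effects.get("drug", 0.0) * drug
                        + effects.get("session", 0.0) * sess
                        + effects.get("drug:session", 0.0) * drug * sess
                        + u_c + u_cs + u_d[d]
                        + u_p[r][0] + u_p[snd][1]
                        + rng.normal(0, sds["resid"])
                    )
                    rows.append(
                        dict(cohort_id=f"C{c}", session=s, receiver_id=r,
                             sender_id=snd, dyad_id=d,
                             receiver_role=roles[r], sender_role=roles[snd],
                             drug_condition=cond, b1=y, included=True,
                             exclusion_reason="none")
                    )
    return pd.DataFrame(rows)


class TestModelFrame:
    def test_session_centering_codes(self, small_study):
        tab = _linkage_table(np.random.default_rng(0), n_sessions=6)
        frame = build_model_frame(tab)
        sess = np.unique(frame.X[:, frame.columns.index("session")])
        np.testing.assert_allclose(
            sess, [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5]
        )

    def test_full_factorial_has_16_columns(self):
        frame = build_model_frame(_linkage_table(np.random.default_rng(0)))
        assert frame.X.shape[1] == 16
        assert len(set(frame.columns)) == 16
        assert "drug:receiver_role:sender_role:session" in frame.columns

    def test_effect_coding_is_plus_minus_half(self):
        frame = build_model_frame(_linkage_table(np.random.default_rng(0)))
        for term in ("drug", "receiver_role", "sender_role"):
            col = frame.X[:, frame.columns.index(term)]
            assert set(np.unique(col)) == {-0.5, 0.5}

    def test_single_role_level_raises_named_error(self):
        tab = _linkage_table(np.random.default_rng(0))
        only_participants = tab[
            (tab["receiver_role"] == "participant")
            & (tab["sender_role"] == "participant")
        ]
        with pytest.raises(EmptyCellError, match="role"):
            build_model_frame(only_participants)

    def test_random_factor_labels_are_global(self):
        tab = _linkage_table(np.random.default_rng(0))
        frame = build_model_frame(tab)
        assert frame.random_levels["cohort"] == 6
        assert frame.random_levels["cohort_session"] == 24


class TestREMLEngine:
    def test_balanced_one_way_matches_anova_estimators(self):
        rng = np.random.default_rng(42)
        a, n = 8, 6
        g = np.repeat(np.arange(a), n)
        y = 2.0 + rng.normal(0, 1.0, a)[g] + rng.normal(0, 0.7, a * n)
        prob = _REMLProblem(y, np.ones((a * n, 1)), {"group": g})
        res = prob.fit()
        gm = np.array([y[g == i].mean() for i in range(a)])
        msb = n * np.sum((gm - y.mean()) ** 2) / (a - 1)
        msw = np.sum((y - gm[g]) ** 2) / (a * n - a)
        assert res.x[0] == pytest.approx(msw, abs=1e-6)
        assert res.x[1] == pytest.approx((msb - msw) / n, abs=1e-6)

    def test_duplicating_rows_leaves_point_estimates_unchanged(self):
        tab = _linkage_table(np.random.default_rng(1), n_cohorts=4)
        f1 = fit_crossclassified(build_model_frame(tab))
        f2 = fit_crossclassified(
            build_model_frame(pd.concat([tab, tab], ignore_index=True))
        )
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-4)

    def test_row_permutation_changes_nothing(self):
        tab = _linkage_table(np.random.default_rng(2), n_cohorts=4)
        f1 = fit_crossclassified(build_model_frame(tab))
        shuffled = tab.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f2 = fit_crossclassified(build_model_frame(shuffled))
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)
        for k in f1.variance_components:
            assert f1.variance_components[k] == pytest.approx(
                f2.variance_components[k], abs=1e-8
            )

    def test_variance_components_are_nonnegative(self):
        fit = fit_crossclassified(
            build_model_frame(_linkage_table(np.random.default_rng(3)))
        )
        assert all(v >= 0 for v in fit.variance_components.values())

    def test_fixed_effects_recovered_without_random_structure(self):
        # all random variances zero, residual 1: estimates within 3 SE
        truth = {"intercept": 0.1, "drug": 0.2, "session": 0.05,
                 "drug:session": -0.08}
        tab = _linkage_table(
            np.random.default_rng(4), n_cohorts=8, n_people=6, n_sessions=5,
            effects=truth,
            sds=dict(cohort=0, cell=0, dyad=0, receiver=0, sender=0, resid=1.0),
        )
        assert len(tab) >= 1200
        fit = fit_crossclassified(build_model_frame(tab))
        fe = fit.fixed_effects.set_index("term")
        for term, val in truth.items():
            est, se = fe.loc[term, "estimate"], fe.loc[term, "se"]
            assert abs(est - val) < 3 * se
        # random variances sit at (or near) the boundary
        assert fit.variance_components["dyad"] < 0.01


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestAgainstLme4:
    def test_variance_components_estimates_and_satterthwaite_df(self, tmp_path):
        rng = np.random.default_rng(3)
        tab = _linkage_table(rng, n_cohorts=6, n_people=6, n_sessions=4,
                             effects={"intercept": 0.1, "drug": 0.2})
        frame = build_model_frame(tab)
        fit = fit_crossclassified(frame)
        ours = {
            t: wald_test(fit, t)
            for t in ("drug", "session", "drug:session")
        }
        csv = tmp_path / "d.csv"
        frame.data.assign(y=frame.y).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$drug <- ifelse(d$drug_condition == "oxytocin", 0.5, -0.5)
            d$rrole <- ifelse(d$receiver_role == "facilitator", 0.5, -0.5)
            d$srole <- ifelse(d$sender_role == "facilitator", 0.5, -0.5)
            d$sess <- d$session - {frame.session_midpoint}
            m <- lmer(y ~ drug*rrole*srole*sess + (1|cohort_id) +
                      (1|cohort_session) + (1|dyad_id) + (1|receiver_id) +
                      (1|sender_id), data=d, REML=TRUE,
                      control=lmerControl(check.conv.singular="ignore"))
            vc <- as.data.frame(VarCorr(m))
            write.csv(vc[, c("grp", "vcov")], "{tmp_path}/vc.csv")
            s <- as.data.frame(summary(m)$coefficients)
            s$term <- rownames(s)
            write.csv(s, "{tmp_path}/fe.csv")
        """))
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True, timeout=300)
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        name_map = {"cohort_id": "cohort", "cohort_session": "cohort_session",
                    "dyad_id": "dyad", "receiver_id": "receiver",
                    "sender_id": "sender", "Residual": "residual"}
        scale = vc["Residual"]
        for rname, pname in name_map.items():
            assert fit.variance_components[pname] == pytest.approx(
                vc[rname], abs=1e-4 * scale
            )
        fe = pd.read_csv(tmp_path / "fe.csv").set_index("term")
        rterm = {"drug": "drug", "session": "sess", "drug:session": "drug:sess"}
        for term, t in ours.items():
            row = fe.loc[rterm[term]]
            assert t.estimate == pytest.approx(row["Estimate"], abs=1e-5)
            assert t.se == pytest.approx(row["Std. Error"], rel=1e-3)
            assert t.df2 == pytest.approx(row["df"], rel=0.02)


class TestEffectSizeRbeta:
    def test_zero_F_gives_zero(self):
        assert effect_size_rbeta(0.0, 1, 50) == 0.0

    def test_monotone_in_F_and_below_one(self):
        fs = np.linspace(0, 100, 25)
        vals = [effect_size_rbeta(f, 1, 73.9) for f in fs]
        assert all(np.diff(vals) > 0)
        assert all(0 <= v < 1 for v in vals)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            effect_size_rbeta(-1.0, 1, 10)
        with pytest.raises(ValueError):
            effect_size_rbeta(1.0, 1, 0)


@pytest.fixture(scope="module")
def fit():
    tab = _linkage_table(
        np.random.default_rng(8), n_sessions=6,
        effects={"intercept": 0.05, "drug": 0.1, "drug:session": -0.03},
    )
    return fit_crossclassified(build_model_frame(tab))


class TestWaldTests:
    def test_one_df_F_is_t_squared(self, fit):
        t = wald_test(fit, "drug")
        assert t.F == pytest.approx(
            (t.estimate / t.se) ** 2, rel=1e-12
        )
        assert t.df1 == 1

    def test_zero_contrast_rejected(self, fit):
        with pytest.raises(ValueError, match="zero contrast"):
            wald_test(fit, np.zeros(16))

    def test_wrong_length_contrast_rejected(self, fit):
        with pytest.raises(ValueError):
            wald_test(fit, np.ones(4))

    def test_recentring_at_midpoint_reproduces_main_effects(self, fit):
        mid = fit.frame.session_midpoint
        eff = simple_effects_by_session(fit, mid)
        diff = eff[2]
        main = wald_test(fit, "drug")
        assert diff.estimate == pytest.approx(main.estimate, abs=1e-12)
        assert diff.se == pytest.approx(main.se, abs=1e-12)

    def test_condition_difference_is_linear_in_session(self, fit):
        mid = fit.frame.session_midpoint
        slope = wald_test(fit, "drug:session").estimate
        d_mid = simple_effects_by_session(fit, mid)[2].estimate
        for s in (1, 2, 6):
            d_s = simple_effects_by_session(fit, s)[2].estimate
            assert d_s == pytest.approx(d_mid + (s - mid) * slope, abs=1e-10)

    def test_condition_slopes_average_to_session_term(self, fit):
        trends = linear_trend_by_condition(fit)
        mean_slope = np.mean([t.estimate for t in trends])
        assert mean_slope == pytest.approx(
            wald_test(fit, "session").estimate, abs=1e-12
        )

    def test_reported_rbeta_matches_formula(self, fit):
        t = wald_test(fit, "drug")
        assert t.rbeta == pytest.approx(
            effect_size_rbeta(t.F, 1, t.df2), abs=1e-15
        )
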