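"""Firth regression oracles and the three PheWAS modes."""

import math

import numpy as np
import pandas as pd
import pytest

import prsphewas as pp
from prsphewas.association import build_design, phewas_table
from prsphewas.errors import EstimationError
from prsphewas.phenome import MatchedStudy


def saturated_2x2(a, b, c, d):
    """Weighted design for a 2x2 table: rows (x=1,y=1),(x=1,y=0),(x=0,y=1),(x=0,y=0)."""
    X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
    y = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.array([a, b, c, d], dtype=float)
    return X, y, w


def half_cell_slope(a, b, c, d):
    return math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))


class TestFirthFit:
    def test_symmetric_table_zero_slope(self):
        X, y, w = saturated_2x2(5, 5, 5, 5)
        fit = pp.firth_fit(X, y, weights=w)
        assert fit.coef[1] == pytest.approx(0.0, abs=1e-10)

    def test_half_cell_closed_form(self):
        X, y, w = saturated_2x2(8, 2, 2, 8)
        fit = pp.firth_fit(X, y, weights=w)
        assert fit.coef[1] == pytest.approx(math.log(11.56), abs=1e-6)

    def test_complete_separation_finite(self):
        X, y, w = saturated_2x2(10, 0, 0, 10)
        fit = pp.firth_fit(X, y, weights=w)
        assert fit.converged
        assert fit.coef[1] == pytest.approx(math.log(441.0), abs=1e-6)

    def test_random_tables_match_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            a, b, c, d = rng.integers(1, 21, size=4)
            X, y, w = saturated_2x2(a, b, c, d)
            fit = pp.firth_fit(X, y, weights=w)
            assert fit.coef[1] == pytest.approx(half_cell_slope(a, b, c, d), abs=1e-6)

    def test_matches_mle_at_large_balanced_n(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 10000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 0.5 * x)))
        y = (rng.random(n) < p).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = pp.firth_fit(X, y)
        mle = sm.Logit(y, X).fit(disp=0)
        assert np.abs(fit.coef - mle.params).max() < 0.01

    def test_rank_deficiency_names_alias(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, 2 * x])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(EstimationError, match="dup"):
            pp.firth_fit(X, y, names=["const", "x", "dup"])

    def test_pl_pvalues_reasonable(self):
        # moderate effect: penalized-LR and Wald p agree to within a decade
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.3 * x))).astype(float)
        X = np.column_stack([np.ones(n), x])
        wald = pp.firth_fit(X, y)
        pl = pp.firth_fit(X, y, pl_pvalues=True)
        assert 0 < pl.p_values[1] <= 1
        assert abs(np.log10(pl.p_values[1]) - np.log10(wald.p_values[1])) < 1.0

    def test_wald_ci_covers_in_simple_simulation(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(40):
            n = 800
            x = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * x)))).astype(float)
            fit = pp.firth_fit(np.column_stack([np.ones(n), x]), y)
            lo, hi = fit.wald_ci(1)
            hits += lo <= 0.3 <= hi
        assert hits >= 33  # ~95% nominal


def make_subjects(n, seed=0, single_sex=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "SUBJECT_ID": [f"s{i}" for i in range(n)],
        "SEX": [single_sex] * n if single_sex else rng.choice(["M", "F"], n),
        "ARRAY": rng.choice(["array_A", "array_B"], n),
        "AGE": rng.integers(30, 80, n).astype(float),
        "PC1": rng.normal(size=n), "PC2": rng.normal(size=n),
        "PC3": rng.normal(size=n), "PC4": rng.normal(size=n),
    })


def null_study(phecode, ids, n_cases, seed):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    cases = [ids[i] for i in perm[:n_cases]]
    controls = [ids[i] for i in perm[n_cases:]]
    return MatchedStudy(phecode=phecode, case_ids=cases, control_ids=controls,
                        matching_mode="unmatched")


class TestRunPhewas:
    def test_direction_rule_and_table(self, cohort, phenome_studies):
        from conftest import true_weight_model

        score = pp.compute_prs(cohort["dosages"], true_weight_model(cohort, "melanoma"))
        results = pp.run_phewas(score, phenome_studies["studies"][:5],
                                cohort["subjects"])
        for r in results:
            assert r.direction == ("up" if r.beta_prs > 0 else "down")
        tab = phewas_table(results, prs_tag="external")
        assert len(tab) == 5 and (tab["N_STUDIES"] == 5).all()

    def test_single_sex_study_drops_sex_column(self):
        subjects = make_subjects(300, seed=5, single_sex="F")
        ids = list(subjects["SUBJECT_ID"])
        study = null_study("x", ids, 60, seed=1)
        prs = pd.Series(np.random.default_rng(2).normal(size=300), index=ids)
        results = pp.run_phewas(prs, [study], subjects)
        assert len(results) == 1 and np.isfinite(results[0].p)

    def test_bonferroni_denominator_is_tested_count(self):
        subjects = make_subjects(400, seed=6)
        ids = list(subjects["SUBJECT_ID"])
        rng = np.random.default_rng(7)
        prs = pd.Series(rng.normal(size=400), index=ids)
        studies = [null_study(f"p{i}", ids, 50, seed=i) for i in range(8)]
        results = pp.run_phewas(prs, studies, subjects, alpha=0.05)
        cut = 0.05 / 8
        for r in results:
            assert r.bonferroni_significant == (r.p < cut)

    def test_true_effect_tops_null_codes(self, cohort, phenome_studies):
        from conftest import true_weight_model
        from prsphewas.synthetic_data import subtype_phecode

        score = pp.compute_prs(cohort["dosages"], true_weight_model(cohort, "scc"))
        results = pp.run_phewas(score, phenome_studies["studies"], cohort["subjects"])
        own = subtype_phecode(cohort["cfg"], "scc")
        p_own = [r.p for r in results if r.phecode == own][0]
        null_ps = [r.p for r in results if r.phecode.startswith("3")]
        assert p_own < min(null_ps)


class TestExclusionPhewas:
    def test_primary_absent_and_empty_set_identity(self, cohort, phenome_studies):
        from conftest import true_weight_model

        score = pp.compute_prs(cohort["dosages"], true_weight_model(cohort, "bcc"))
        studies = phenome_studies["studies"]
        inc = phenome_studies["incidence"]
        skin = ["172", "172.1", "172.2", "172.3"]
        excl = pp.exclusion_phewas(score, studies, skin, inc, cohort["subjects"])
        assert all(r.phecode not in skin for r in excl)
        same = pp.exclusion_phewas(score, studies[:3], [], inc, cohort["subjects"])
        base = pp.run_phewas(score, studies[:3], cohort["subjects"])
        assert [(r.phecode, r.p) for r in same] == [(r.phecode, r.p) for r in base]

    def test_mediated_association_attenuates(self, cohort, phenome_studies):
        # a trait caused only by the primary disease (not genetics) loses its
        # PRS association once primary-disease carriers are excluded
        from conftest import true_weight_model

        cfg, truth = cohort["cfg"], cohort["truth"]
        rng = np.random.default_rng(10)
        primary = truth["melanoma"].to_numpy()
        mediated = (primary & (rng.random(len(primary)) < 0.9)) | (
            rng.random(len(primary)) < 0.05
        )
        ids = list(cohort["subjects"]["SUBJECT_ID"])
        case_ids = [i for i, m in zip(ids, mediated) if m]
        ctl_ids = [i for i, m in zip(ids, mediated) if not m]
        study = MatchedStudy(phecode="999", case_ids=case_ids, control_ids=ctl_ids,
                             matching_mode="unmatched")
        inc = phenome_studies["incidence"]
        score = pp.compute_prs(cohort["dosages"], true_weight_model(cohort, "melanoma"))
        before = pp.run_phewas(score, [study], cohort["subjects"])[0]
        after = pp.exclusion_phewas(score, [study], ["172"], inc, cohort["subjects"],
                                    min_cases=10)[0]
        assert abs(after.beta_prs) < abs(before.beta_prs)
        assert after.p > before.p


class TestSecondaryPredictor:
    def _incidence(self, rows):
        return pd.DataFrame(rows, columns=["SUBJECT_ID", "PHECODE", "FIRST_DATE"])

    def test_lag_rule_classification(self):
        subjects = make_subjects(400, seed=11)
        ids = list(subjects["SUBJECT_ID"])
        d0 = pd.Timestamp("2012-01-01")
        rows = []
        # s0: secondary then primary at +400d -> predictor 1, outcome 1
        rows += [("s0", "sec", d0), ("s0", "pri", d0 + pd.Timedelta(days=400))]
        # s1: secondary then primary at +100d -> excluded
        rows += [("s1", "sec", d0), ("s1", "pri", d0 + pd.Timedelta(days=100))]
        # s2: secondary never primary -> predictor 1, outcome 0
        rows += [("s2", "sec", d0)]
        # s3: primary without secondary -> predictor 0, outcome 1
        rows += [("s3", "pri", d0 + pd.Timedelta(days=50))]
        # background cases so the fit is well posed
        rng = np.random.default_rng(12)
        for i in range(4, 400):
            if rng.random() < 0.25:
                rows.append((f"s{i}", "sec", d0))
            if rng.random() < 0.15:
                rows.append((f"s{i}", "pri", d0 + pd.Timedelta(days=int(rng.integers(400, 900)))))
        inc = self._incidence(rows)
        fit = pp.secondary_predictor_model(inc, "sec", "pri", subjects)
        assert fit.converged
        assert "PREDICTOR" in fit.names

    def test_excluded_subject_does_not_enter_fit(self):
        # a subject whose primary follows the secondary within the lag window
        # is excluded, so adding one leaves the fit unchanged
        subjects = make_subjects(200, seed=13)
        d0 = pd.Timestamp("2012-01-01")
        rng = np.random.default_rng(14)
        rows = []
        for i in range(1, 200):
            if rng.random() < 0.3:
                rows.append((f"s{i}", "sec", d0))
            if rng.random() < 0.2:
                rows.append((f"s{i}", "pri", d0 + pd.Timedelta(days=int(rng.integers(400, 900)))))
        inc = pd.DataFrame(rows, columns=["SUBJECT_ID", "PHECODE", "FIRST_DATE"])
        base = pp.secondary_predictor_model(inc, "sec", "pri", subjects.iloc[1:])
        extra = pd.concat([
            inc,
            pd.DataFrame(
                [("s0", "sec", d0), ("s0", "pri", d0 + pd.Timedelta(days=100))],
                columns=["SUBJECT_ID", "PHECODE", "FIRST_DATE"],
            ),
        ])
        fit = pp.secondary_predictor_model(extra, "sec", "pri", subjects)
        np.testing.assert_allclose(fit.coef, base.coef, atol=1e-10)

    def test_no_qualifying_subjects_errors(self):
        subjects = make_subjects(4, seed=14)
        inc = pd.DataFrame(columns=["SUBJECT_ID", "PHECODE", "FIRST_DATE"])
        with pytest.raises(EstimationError):
            pp.secondary_predictor_model(inc, "sec", "pri", subjects)

    def test_predictive_secondary_gets_positive_coefficient(self, cohort, phenome_studies):
        # the synthetic secondary trait shares genetics with the subtypes, so
        # prior secondary diagnosis predicts later primary status
        inc = phenome_studies["incidence"]
        fit = pp.secondary_predictor_model(inc, "702.1", "172", cohort["subjects"])
        j = fit.names.index("PREDICTOR")
        assert np.isfinite(fit.p_values[j])
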