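"""Tests of the repeated-measures ANOVA, BH-FDR and group pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tcdcm as T
from tcdcm.stats import extract_member, FAMILIES


def brute_force_rm_anova_F(x):
    """Independent sums-of-squares computation with explicit loops."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_cond = 0.0
    for j in range(k):
        mj = sum(x[i, j] for i in range(n)) / n
        ss_cond += n * (mj - grand) ** 2
    ss_subj = 0.0
    for i in range(n):
        mi = sum(x[i, j] for j in range(k)) / k
        ss_subj += k * (mi - grand) ** 2
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    def test_no_condition_effect_gives_zero_F(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(10)
        x = np.tile(col[:, None], (1, 3))
        res = T.rm_anova(x)
        assert res["F"] == 0.0
        assert res["p"] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal((27, 3))
            res = T.rm_anova(x)
            assert res["F"] == pytest.approx(brute_force_rm_anova_F(x),
                                             abs=1e-10, rel=1e-10)
            assert (res["df1"], res["df2"]) == (2, 52)
            assert res["df2_mv"] == 25

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.standard_normal((12, 3))
        long = pd.DataFrame({
            "y": x.ravel(),
            "subject": np.repeat(np.arange(12), 3),
            "cond": np.tile(np.arange(3), 12)})
        out = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        res = T.rm_anova(x)
        assert res["F"] == pytest.approx(float(out["F"][0]), rel=1e-9)
        assert res["p"] == pytest.approx(float(out["p_unc"][0]), rel=1e-9)

    def test_invariant_to_subject_offsets(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((15, 3))
        shifted = x + rng.standard_normal((15, 1)) * 7.0
        assert T.rm_anova(x)["F"] == pytest.approx(
            T.rm_anova(shifted)["F"], rel=1e-9)

    def test_rejects_missing_cells(self):
        x = np.ones((5, 3))
        x[0, 1] = np.nan
        with pytest.raises(ValueError):
            T.rm_anova(x)

    def test_type_one_error_rate_calibrated(self):
        """Null simulation: rejection rate at alpha = .05 within binomial
        tolerance over 200 replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            x = (rng.standard_normal((27, 1))      # subject effects
                 + rng.standard_normal((27, 3)))   # exchangeable error
            rejections += T.rm_anova(x)["p"] < 0.05
        assert 0.02 * 200 <= rejections <= 0.09 * 200


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(T.bh_fdr([0.37]), [0.37])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(T.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(4)
        p = rng.uniform(size=11)
        np.testing.assert_allclose(T.bh_fdr(p),
                                   sm.multipletests(p, method="fdr_bh")[1],
                                   rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            T.bh_fdr([0.1, 1.2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_adjusted_monotone_in_raw_order_and_bounded(self, p):
        adj = T.bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = T.pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 40))
        r, _ = T.pearson_correlation(x, y)
        oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std() * y.std()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_antisymmetric_in_sign(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 25))
        r1, p1 = T.pearson_correlation(x, y)
        r2, p2 = T.pearson_correlation(-x, y)
        assert r2 == pytest.approx(-r1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            T.pearson_correlation(np.ones(10), np.arange(10.0))


def _latent_cohort_frame(params, rng, shifts=None, n=27, sigma=0.08,
                         shared=0.06):
    """Direct latent sampling stand-in for the fitted-parameter pipeline:
    per-condition values = baseline + planted shift + estimation noise with
    a component shared across parameters (mimicking posterior cross-talk)."""
    conds = ("pre", "bolus", "infusion")
    free = [s.name for s in params.specs if s.var > 0]
    rows = []
    for i in range(n):
        base = {k: rng.normal(0, 0.15) for k in free}
        for cond in conds:
            common = rng.normal(0, shared)
            for k in free:
                val = base[k] + common + rng.normal(0, sigma)
                if shifts:
                    val += shifts.get(cond, {}).get(k, 0.0)
                rows.append((f"sub-{i:03d}", cond, k, val))
    return pd.DataFrame(rows, columns=["subject", "condition", "latent",
                                       "value"])


class TestGroupPipeline:
    def test_report_has_eighteen_parameter_rows(self, params):
        rng = np.random.default_rng(11)
        frame = _latent_cohort_frame(params, rng, n=8)
        rep = T.run_group_analysis(frame)
        assert len(rep.anova) == 4 + 8 + 6 == 18
        assert (rep.anova.p_fdr >= rep.anova.p - 1e-15).all()
        assert rep.anova.p.between(0, 1).all()

    def test_extract_member_flips_sign_for_time_constants(self, params):
        rng = np.random.default_rng(12)
        frame = _latent_cohort_frame(params, rng, n=5)
        latent, sign = FAMILIES["time_constants"]["Frontal GABA"]
        mat = extract_member(frame, latent, sign)
        raw = frame[(frame.latent == latent)]
        val = raw[(raw.subject == "sub-000") & (raw.condition == "pre")
                  ]["value"].iloc[0]
        assert mat.loc["sub-000", "pre"] == pytest.approx(-val)

    def test_missing_condition_rejected(self, params):
        rng = np.random.default_rng(13)
        frame = _latent_cohort_frame(params, rng, n=5)
        frame = frame[~((frame.subject == "sub-001")
                        & (frame.condition == "bolus"))]
        with pytest.raises(ValueError):
            T.run_group_analysis(frame)

    def test_zero_effect_cohorts_rarely_significant(self, params):
        """Specificity on null cohorts: BH controls the family-wise
        any-rejection rate at alpha per family (Simes level), so with three
        families the expected fraction of fully clean cohorts is
        (1 - .05)^3 ~ 86%; assert consistency with that calibration."""
        rng = np.random.default_rng(14)
        clean = 0
        for _ in range(50):
            rep = T.run_group_analysis(_latent_cohort_frame(params, rng))
            clean += not (rep.anova.p_fdr < 0.05).any()
        assert clean >= 40

    def test_planted_effect_detected_as_top_extrinsic(self, params):
        """Sensitivity: the forward-AMPA member should carry the smallest
        adjusted p in its family in the majority of replicates."""
        rng = np.random.default_rng(15)
        shifts = {"bolus": {"ext_ampa_fwd": 0.15},
                  "infusion": {"ext_ampa_fwd": 0.30}}
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            frame = _latent_cohort_frame(params, rng, shifts=shifts)
            rep = T.run_group_analysis(frame)
            ext = rep.anova[rep.anova.family == "extrinsics"]
            wins += (ext.loc[ext.p_fdr.idxmin(), "parameter"]
                     == "AMPA forward")
        assert wins > n_rep / 2

    def test_correlations_reported_for_uncorrected_hits(self, params):
        rng = np.random.default_rng(16)
        shifts = {"bolus": {"ext_ampa_fwd": 0.2},
                  "infusion": {"ext_ampa_fwd": 0.4}}
        frame = _latent_cohort_frame(params, rng, shifts=shifts)
        clinical = pd.DataFrame({
            "subject": sorted(frame.subject.unique()),
            "change_24h": rng.normal(-12, 6, 27),
            "change_7d": rng.normal(-10, 6, 27)})
        rep = T.run_group_analysis(frame, clinical)
        hits = rep.anova[rep.anova.p < 0.05].parameter
        assert set(rep.correlations.parameter) == set(hits)
        assert set(rep.correlations.timepoint) == {"24h", "7d"}
        assert (rep.correlations.p_fdr >= rep.correlations.p - 1e-15).all()
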