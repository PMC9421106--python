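"""Survey-reanalysis unit tests: z-scores, exclusions, case definitions,
weighting and design-based prevalence."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from malnowcast import anthro
from malnowcast.anthro import (
    MUAC_DEFINITION,
    WFH_DEFINITION,
    CaseDefinition,
    LmsReferenceTable,
    apply_exclusions,
    classify_child,
    classify_children,
    compute_whz,
    estimate_prevalence,
    rescale_quality,
    sampling_coverage,
)
from malnowcast.exceptions import ConfigError, ReferenceRangeError, UnclassifiableError


class TestWhz:
    def test_weight_at_median_gives_zero(self, lms_table):
        l, m, s = lms_table.params("f", 80.0)
        assert compute_whz(m, 80.0, "f", lms_table) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_at_unit_lambda(self):
        table = LmsReferenceTable(pd.DataFrame({
            "sex": ["f", "f"], "key": [60.0, 100.0],
            "L": [1.0, 1.0], "M": [6.0, 15.0], "S": [0.1, 0.1],
        }))
        # L=1: z = (w/M - 1)/S, so w = M(1+S) gives z = 1
        assert compute_whz(6.0 * 1.1, 60.0, "f", table) == pytest.approx(1.0)

    def test_random_grid_matches_direct_formula(self, rng):
        # brute-force oracle: direct evaluation of ((w/M)^L - 1)/(L S)
        for _ in range(200):
            l = rng.uniform(-2, 2)
            m = rng.uniform(5, 20)
            s = rng.uniform(0.05, 0.2)
            w = rng.uniform(3, 25)
            table = LmsReferenceTable(pd.DataFrame({
                "sex": ["m", "m"], "key": [50.0, 110.0],
                "L": [l, l], "M": [m, m], "S": [s, s],
            }))
            expected = ((w / m) ** l - 1) / (l * s)
            got = compute_whz(w, 70.0, "m", table)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_interpolates_between_rows(self):
        table = LmsReferenceTable(pd.DataFrame({
            "sex": ["f", "f"], "key": [60.0, 62.0],
            "L": [1.0, 1.0], "M": [6.0, 8.0], "S": [0.1, 0.1],
        }))
        # at 61 cm the interpolated median is 7 kg
        assert compute_whz(7.0, 61.0, "f", table) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_reference_raises(self, lms_table):
        with pytest.raises(ReferenceRangeError):
            compute_whz(10.0, 500.0, "f", lms_table)

    def test_add_whz_leaves_precomputed_and_flags_out_of_range(self, lms_table):
        df = pd.DataFrame({
            "sex": ["f", "f", "f"],
            "weight_kg": [10.0, 10.0, 10.0],
            "height_cm": [80.0, 80.0, 500.0],
            "whz": [1.23, np.nan, np.nan],
        })
        out = anthro.add_whz(df, lms_table)
        assert out.loc[0, "whz"] == 1.23
        assert np.isfinite(out.loc[1, "whz"])
        assert np.isnan(out.loc[2, "whz"])


def _random_children(rng, n, survey_ids=("A", "B")):
    return pd.DataFrame({
        "survey_id": rng.choice(survey_ids, n),
        "cluster_id": rng.choice(["c1", "c2", "c3"], n),
        "age_months": np.where(rng.uniform(size=n) < 0.05, np.nan,
                               rng.uniform(0, 80, n)),
        "sex": rng.choice(["f", "m"], n),
        "muac_mm": np.where(rng.uniform(size=n) < 0.1, np.nan,
                            rng.uniform(90, 180, n)),
        "oedema": rng.uniform(size=n) < 0.02,
        "whz": np.where(rng.uniform(size=n) < 0.1, np.nan,
                        rng.normal(-0.5, 2.5, n)),
    })


class TestExclusions:
    def test_age_out_of_range(self):
        df = pd.DataFrame({
            "survey_id": ["A"], "age_months": [61.0], "whz": [0.0],
            "muac_mm": [130.0], "oedema": [False],
        })
        out = apply_exclusions(df)
        assert out.loc[0, "exclusion_reason"] == "age_out_of_range"

    def test_flag_relative_to_survey_mean(self):
        # survey mean ~ -0.5; |-6 - (-0.5)| = 5.5 > 5 flags, |-5.2 - (-0.5)| < 5 does not
        df = pd.DataFrame({
            "survey_id": "A",
            "age_months": 30.0,
            "whz": [-6.0, -5.2] + [-0.5] * 40,
            "muac_mm": 130.0,
            "oedema": False,
        })
        out = apply_exclusions(df, center="survey_mean")
        assert out.loc[0, "exclusion_reason"] == "flagged_outlier"
        assert out.loc[1, "exclusion_reason"] is None

    def test_oedema_never_flagged(self):
        df = pd.DataFrame({
            "survey_id": "A", "age_months": 30.0,
            "whz": [-9.0] + [0.0] * 30, "muac_mm": 130.0,
            "oedema": [True] + [False] * 30,
        })
        out = apply_exclusions(df, center="reference_zero")
        assert out.loc[0, "exclusion_reason"] is None

    @pytest.mark.parametrize("center", ["survey_mean", "reference_zero"])
    def test_matches_brute_force_filter(self, rng, center):
        children = _random_children(rng, 1000)
        out = apply_exclusions(children, center=center)
        # independent three-rule filter, applied record by record
        means = {}
        for sid, grp in children.groupby("survey_id"):
            elig = grp[grp["age_months"].between(6, 59)
                       & ~(grp["whz"].isna() & grp["muac_mm"].isna() & ~grp["oedema"])]
            means[sid] = elig["whz"].mean()
        for i, row in children.iterrows():
            if (np.isnan(row["age_months"])
                    or (np.isnan(row["whz"]) and np.isnan(row["muac_mm"])
                        and not row["oedema"])):
                expected = "missing"
            elif not (6 <= row["age_months"] <= 59):
                expected = "age_out_of_range"
            else:
                c = 0.0 if center == "reference_zero" else means[row["survey_id"]]
                if (not row["oedema"] and np.isfinite(row["whz"])
                        and abs(row["whz"] - c) > 5):
                    expected = "flagged_outlier"
                else:
                    expected = None
            assert out.loc[i, "exclusion_reason"] == expected, i


class TestClassification:
    @pytest.mark.parametrize("whz,expected", [
        (-3.2, "SAM"), (-3.0, "MAM"), (-2.999, "MAM"),
        (-2.0, "none"), (-2.001, "MAM"), (-1.0, "none"), (0.5, "none"),
    ])
    def test_wfh_cutoffs(self, whz, expected):
        rec = {"oedema": False, "whz": whz}
        assert classify_child(rec, WFH_DEFINITION) == expected

    @pytest.mark.parametrize("muac,expected", [
        (114.0, "SAM"), (114.9, "SAM"), (115.0, "MAM"),
        (124.9, "MAM"), (125.0, "none"), (140.0, "none"),
    ])
    def test_muac_cutoffs(self, muac, expected):
        rec = {"oedema": False, "muac_mm": muac}
        assert classify_child(rec, MUAC_DEFINITION) == expected

    def test_oedema_overrides_anthropometry(self):
        assert classify_child({"oedema": True, "whz": -1.0}, WFH_DEFINITION) == "SAM"
        assert classify_child({"oedema": True, "muac_mm": 150.0}, MUAC_DEFINITION) == "SAM"

    def test_missing_basis_without_oedema_unclassifiable(self):
        with pytest.raises(UnclassifiableError):
            classify_child({"oedema": False, "whz": float("nan")}, WFH_DEFINITION)

    def test_sam_cutoff_must_be_stricter(self):
        with pytest.raises(ConfigError):
            CaseDefinition("wfh", -2.0, -3.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_sam_subset_of_gam(self, seed):
        rng = np.random.default_rng(seed)
        children = _random_children(rng, 200)
        for definition in (WFH_DEFINITION, MUAC_DEFINITION):
            cls = classify_children(children, definition)
            n_sam = (cls["status"] == "SAM").sum()
            n_gam = cls["gam"].astype("boolean").fillna(False).sum()
            assert n_sam <= n_gam


class TestWeighting:
    def test_quality_rescale_endpoints_and_midpoint(self):
        assert rescale_quality(0.0) == 1.0
        assert rescale_quality(0.5) == 0.0
        assert rescale_quality(0.125) == pytest.approx(0.75)

    def test_quality_domain_error(self):
        with pytest.raises(ConfigError):
            rescale_quality(0.6)

    def test_sampling_coverage(self):
        assert sampling_coverage(10, 12) == pytest.approx(10 / 12)
        assert sampling_coverage(12, 12) == 1.0
        assert sampling_coverage(1, 4) == 0.25
        with pytest.raises(ConfigError):
            sampling_coverage(1, 0)

    def test_analysis_weight_is_product(self, small_surveys):
        _, meta = small_surveys
        assert np.allclose(meta["analysis_weight"],
                           meta["quality_rescaled"] * meta["sampling_coverage"])
        assert meta["analysis_weight"].between(0, 1).all()


def _survey_frame(y, clusters):
    n = len(y)
    return pd.DataFrame({
        "survey_id": "A", "cluster_id": clusters,
        "age_months": 30.0, "sex": "f",
        "whz": np.where(y, -3.5, 0.0), "muac_mm": 130.0,
        "oedema": False, "exclusion_reason": None,
    })


class TestPrevalence:
    def test_point_is_case_fraction(self):
        y = np.array([1, 1] + [0] * 8, bool)
        est = estimate_prevalence(_survey_frame(y, ["c1"] * 5 + ["c2"] * 5),
                                  WFH_DEFINITION, "sam")
        assert est.point == pytest.approx(0.2)

    def test_singleton_clusters_equal_binomial_variance(self):
        # one record per cluster: the sandwich reduces exactly to the
        # model-based binomial variance (correction factor off)
        rng = np.random.default_rng(5)
        y = rng.uniform(size=40) < 0.3
        clusters = [f"c{i}" for i in range(40)]
        est = estimate_prevalence(_survey_frame(y, clusters), WFH_DEFINITION,
                                  "sam", small_sample=False)
        p = y.mean()
        se = np.sqrt(1 / (40 * p * (1 - p)))
        lo = expit(logit(p) - 1.959963984540054 * se)
        assert est.cis[0.95][0] == pytest.approx(lo, abs=1e-12)

    def test_matches_statsmodels_cluster_glm(self, rng):
        y = rng.uniform(size=120) < 0.25
        clusters = rng.choice([f"c{i}" for i in range(12)], 120)
        est = estimate_prevalence(_survey_frame(y, clusters), WFH_DEFINITION, "sam")
        res = sm.GLM(y.astype(float), np.ones((120, 1)),
                     family=sm.families.Binomial()).fit(
            cov_type="cluster",
            cov_kwds={"groups": pd.Categorical(clusters).codes})
        se = float(np.sqrt(res.cov_params()[0][0]))
        lo = expit(res.params[0] - 1.959963984540054 * se)
        hi = expit(res.params[0] + 1.959963984540054 * se)
        assert est.cis[0.95] == pytest.approx((lo, hi), rel=1e-6)

    def test_invariant_to_cluster_relabelling(self, rng):
        y = rng.uniform(size=60) < 0.3
        clusters = rng.choice(["c1", "c2", "c3", "c4"], 60)
        relabel = {"c1": "z9", "c2": "a0", "c3": "m5", "c4": "k2"}
        est1 = estimate_prevalence(_survey_frame(y, clusters), WFH_DEFINITION, "sam")
        est2 = estimate_prevalence(
            _survey_frame(y, [relabel[c] for c in clusters]), WFH_DEFINITION, "sam")
        assert est1.point == est2.point
        assert est1.cis[0.95] == pytest.approx(est2.cis[0.95], abs=1e-12)

    def test_clustered_ci_covers_naive_undercovers(self):
        # intra-cluster correlated Bernoulli data: the cluster-robust CI
        # keeps ~95% coverage of truth, the iid binomial CI falls short
        truth, sigma = 0.2, 0.8
        a = None
        from malnowcast.simulate import recentre_logit
        a = recentre_logit(truth, sigma)
        n_rep, covered_cl, covered_naive = 250, 0, 0
        master = np.random.default_rng(7)
        for _ in range(n_rep):
            u = master.normal(0, sigma, 20)
            p = expit(a + u)
            y = master.uniform(size=(20, 15)) < p[:, None]
            clusters = np.repeat([f"c{i}" for i in range(20)], 15)
            frame = _survey_frame(y.ravel(), clusters)
            est = estimate_prevalence(frame, WFH_DEFINITION, "sam")
            covered_cl += est.cis[0.95][0] <= truth <= est.cis[0.95][1]
            naive = estimate_prevalence(
                _survey_frame(y.ravel(), [f"i{j}" for j in range(300)]),
                WFH_DEFINITION, "sam")
            covered_naive += naive.cis[0.95][0] <= truth <= naive.cis[0.95][1]
        cov_cl = covered_cl / n_rep
        cov_naive = covered_naive / n_rep
        assert abs(cov_cl - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / n_rep) + 0.01
        assert cov_naive < cov_cl - 0.1
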