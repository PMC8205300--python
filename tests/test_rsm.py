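"""Central composite design construction, ANOVA, diagnostics, optimization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from loinmri import (CCDesign, ResponseSurface, build_ccd, fit_quadratic,
                     load_fresh_loin_ccd, optimize_in_range)
from loinmri.exceptions import ContractError, DegenerateDataError


class TestBuildCCD:
    def test_published_runs_present(self):
        design = build_ccd()
        pts = list(zip(design.runs["te_ms"], design.runs["tr_ms"]))
        for expected in [(26, 910), (18, 630), (22, 630), (26, 770)]:
            assert expected in pts
        assert pts.count((22, 770)) == 5
        assert design.n_runs == 13

    def test_coded_columns_sum_to_zero(self):
        design = build_ccd()
        assert design.runs["te_coded"].sum() == 0
        assert design.runs["tr_coded"].sum() == 0

    def test_nine_distinct_design_points(self):
        design = build_ccd()
        assert len(set(zip(design.runs["te_coded"],
                           design.runs["tr_coded"]))) == 9

    def test_coding_is_consistent(self):
        design = build_ccd()
        a, b = design.code(design.runs["te_ms"], design.runs["tr_ms"])
        np.testing.assert_allclose(a, design.runs["te_coded"])
        np.testing.assert_allclose(b, design.runs["tr_coded"])

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ContractError):
            build_ccd(deltas=(0.0, 140.0))

    def test_non_face_centered_alpha_warns(self):
        with pytest.warns(UserWarning):
            build_ccd(alpha=1.414)


class TestFixture:
    def test_first_run_values(self, ccd):
        design, resp = ccd
        assert tuple(design.runs.loc[1, ["te_coded", "tr_coded"]]) == (1, 1)
        assert tuple(design.runs.loc[1, ["te_ms", "tr_ms"]]) == (26, 910)
        assert resp.loc[1, "moisture"] == 0.881

    def test_run_eight_values(self, ccd):
        design, resp = ccd
        assert tuple(design.runs.loc[8, ["te_ms", "tr_ms"]]) == (26, 630)
        assert resp.loc[8, "ph"] == 0.970

    def test_five_center_replicates(self, ccd):
        design, _ = ccd
        assert design.n_center == 5

    def test_matches_constructed_design_up_to_ordering(self, ccd):
        design, _ = ccd
        built = build_ccd()
        got = sorted(map(tuple, design.coded().tolist()))
        exp = sorted(map(tuple, built.coded().tolist()))
        assert got == exp

    def test_csv_roundtrip_lossless(self, ccd, tmp_path):
        design, resp = ccd
        frame = design.runs.join(resp.add_prefix("r_"))
        path = tmp_path / "ccd.csv"
        frame.to_csv(path)
        back = pd.read_csv(path).set_index("run")
        pd.testing.assert_frame_equal(back, frame, check_dtype=False)


class TestFitQuadratic:
    def test_constant_response(self, ccd):
        design, _ = ccd
        fit = fit_quadratic(design, np.full(13, 0.9))
        assert fit.coef_[0] == pytest.approx(0.9)
        np.testing.assert_allclose(fit.coef_[1:], 0.0, atol=1e-12)

    def test_interaction_coefficient_is_corner_contrast(self, ccd):
        design, resp = ccd
        fit = fit_quadratic(design, resp["moisture"])
        contrast = (0.881 - 0.966 - 0.952 + 0.942) / 4
        assert fit.coef_[3] == pytest.approx(contrast, abs=1e-12)

    def test_exact_recovery_of_noise_free_quadratic(self, rng):
        design = build_ccd()
        beta = rng.normal(size=6)
        coded = design.coded()
        M = np.column_stack([np.ones(13), coded[:, 0], coded[:, 1],
                             coded[:, 0] * coded[:, 1],
                             coded[:, 0] ** 2, coded[:, 1] ** 2])
        fit = fit_quadratic(design, M @ beta)
        np.testing.assert_allclose(fit.coef_, beta, atol=1e-12)

    def test_length_mismatch_rejected(self, ccd):
        design, _ = ccd
        with pytest.raises(ContractError):
            fit_quadratic(design, np.ones(12))


class TestAnova:
    def test_ss_decomposition_on_all_responses(self, ccd):
        design, resp = ccd
        for col in resp.columns:
            a = fit_quadratic(design, resp[col]).anova_
            lhs = a.loc["total", "SS"]
            rhs = (a.loc["model", "SS"] + a.loc["lack of fit", "SS"]
                   + a.loc["pure error", "SS"])
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_contrast_ss_equals_partial_ss_for_linear_terms(self, ccd):
        # the coded design is orthogonal in its linear and interaction
        # columns, so simple contrast SS must equal the partial SS
        design, resp = ccd
        coded = design.coded()
        y = resp["moisture"].to_numpy()
        a = fit_quadratic(design, y).anova_
        for col, term in [(coded[:, 0], "TE"), (coded[:, 1], "TR"),
                          (coded[:, 0] * coded[:, 1], "TE x TR")]:
            ss = (col @ y) ** 2 / (col @ col)
            assert a.loc[term, "SS"] == pytest.approx(ss, abs=1e-12)

    def test_partial_ss_matches_statsmodels_type3(self, ccd):
        design, resp = ccd
        frame = pd.DataFrame(design.coded(), columns=["A", "B"])
        frame["y"] = resp["colorL"].to_numpy()
        ols = smf.ols("y ~ A + B + A:B + I(A**2) + I(B**2)", frame).fit()
        sm_anova = sm.stats.anova_lm(ols, typ=3)
        ours = fit_quadratic(design, resp["colorL"]).anova_
        for sm_term, term in [("A", "TE"), ("B", "TR"), ("A:B", "TE x TR"),
                              ("I(A ** 2)", "TE^2"), ("I(B ** 2)", "TR^2")]:
            assert ours.loc[term, "SS"] == pytest.approx(
                sm_anova.loc[sm_term, "sum_sq"], rel=1e-10)
            assert ours.loc[term, "F"] == pytest.approx(
                sm_anova.loc[sm_term, "F"], rel=1e-10)

    def test_zero_noise_quadratic_with_center_jitter(self, rng):
        design = build_ccd()
        coded = design.coded()
        y = (0.9 + 0.05 * coded[:, 0] - 0.04 * coded[:, 1]
             + 0.03 * coded[:, 0] * coded[:, 1] - 0.06 * coded[:, 0] ** 2
             + 0.02 * coded[:, 1] ** 2)
        center = (coded == 0).all(axis=1)
        jitter = rng.normal(0, 1e-9, center.sum())
        y[center] += jitter - jitter.mean()
        a = fit_quadratic(design, y).anova_
        for term in ["model", "TE", "TR", "TE x TR", "TE^2", "TR^2"]:
            assert a.loc[term, "p"] < 1e-6
        assert a.loc["lack of fit", "F"] < 1e-3

    def test_no_replicates_raises(self):
        design = build_ccd(n_center=1)
        fit = fit_quadratic(design, np.arange(9, dtype=float) ** 1.5)
        with pytest.raises(DegenerateDataError):
            fit.anova_


class TestDiagnostics:
    def test_perfect_fit(self, rng):
        design = build_ccd()
        coded = design.coded()
        y = 1.0 + 0.1 * coded[:, 0] - 0.2 * coded[:, 1] ** 2
        d = fit_quadratic(design, y).diagnostics_
        assert d.r_squared == pytest.approx(1.0)
        assert d.adj_r_squared == pytest.approx(1.0)
        # numerically perfect fits leave at most rounding-level residual
        assert d.adequate_precision > 1e3

    def test_press_exceeds_residual_ss(self, ccd):
        design, resp = ccd
        fit = fit_quadratic(design, resp["moisture"])
        assert fit.diagnostics_.press > float(
            (fit.residuals_ ** 2).sum())

    def test_adjusted_below_plain_r_squared(self, ccd):
        design, resp = ccd
        for col in resp.columns:
            d = fit_quadratic(design, resp[col]).diagnostics_
            assert d.adj_r_squared < d.r_squared


class TestOptimize:
    def test_constructed_corner_maximum(self):
        design = build_ccd()
        coded = design.coded()
        # response increasing in both factors -> optimum at (26, 910)
        y = 0.5 + 0.1 * coded[:, 0] + 0.2 * coded[:, 1]
        fit = fit_quadratic(design, y)
        res = optimize_in_range({"only": fit}, design)
        assert (res.te, res.tr) == (26.0, 910.0)

    def test_aggregation_invariant_to_duplication(self, ccd):
        design, resp = ccd
        fit = fit_quadratic(design, resp["moisture"])
        one = optimize_in_range({"a": fit}, design)
        two = optimize_in_range({"a": fit, "b": fit}, design)
        assert (one.te, one.tr) == (two.te, two.tr)

    def test_fixture_optimum_has_low_tr(self, ccd):
        design, resp = ccd
        fits = {c: fit_quadratic(design, resp[c]) for c in resp.columns}
        res = optimize_in_range(fits, design)
        assert 630.0 <= res.tr <= 630.0 + (910.0 - 630.0) / 3

    def test_empty_fit_collection_rejected(self, ccd):
        design, _ = ccd
        with pytest.raises(ContractError):
            optimize_in_range({}, design)
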