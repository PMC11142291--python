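"""Filter, imputation, and transformation contracts."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_tiny_dataset
from ogttmet.data import ROLE_STUDY
from ogttmet.preprocessing import (
    apply_filters,
    filter_blank,
    filter_qc_rsd,
    impute_missing,
    log10_autoscale,
    timecourse_zscores,
)


class TestQcRsdFilter:
    def test_hand_computed_cases(self):
        # met_a: QC (10,10) -> RSD 0 -> retained
        # met_b: QC (1,3) -> mean 2, SD sqrt(2), RSD ~ 0.707 > 0.5 -> removed
        ds2 = make_tiny_dataset(
            {"met_a": [5.0] * 10, "met_b": [5.0] * 10},
            qc_values={"met_a": [10.0, 10.0], "met_b": [1.0, 3.0]},
        )
        rep = filter_qc_rsd(ds2)
        assert rep.removed == ["met_b"]
        assert rep.retained == ["met_a"]
        val = rep.table.set_index("metabolite").loc["met_b", "value"]
        assert val == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_threshold_monotonicity(self):
        ds = make_tiny_dataset(
            {"m": [5.0] * 10}, qc_values={"m": [1.0, 3.0]}
        )
        assert filter_qc_rsd(ds, threshold=1.0).removed == []
        assert filter_qc_rsd(ds, threshold=0.5).removed == ["m"]

    def test_requires_qc_samples(self):
        ds = make_tiny_dataset({"m": [5.0] * 10})
        with pytest.raises(ValueError, match="skip this filter"):
            filter_qc_rsd(ds)

    def test_partition_invariant(self, qc_cohort):
        _, ds, _ = qc_cohort
        rep = filter_qc_rsd(ds)
        assert sorted(rep.removed + rep.retained) == sorted(ds.metabolites)
        assert not set(rep.removed) & set(rep.retained)


class TestBlankFilter:
    def test_identical_distribution_removed(self):
        vals = list(np.linspace(1, 10, 10))
        ds = make_tiny_dataset(
            {"m": vals}, blank_values={"m": [1.0, 4.0, 7.0, 10.0]}
        )
        rep = filter_blank(ds)
        assert rep.removed == ["m"]  # p >> 0.05: indistinguishable from blanks

    def test_strong_signal_retained(self):
        vals = [float(100 * (k + 1)) for k in range(10)]
        ds = make_tiny_dataset(
            {"m": vals}, blank_values={"m": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        rep = filter_blank(ds)
        assert rep.removed == []

    def test_ratio_rule_fires_alone(self):
        # clearly separable (significant Wilcoxon) but below blanks
        vals = [float(k + 1) for k in range(10)]
        ds = make_tiny_dataset(
            {"m": vals}, blank_values={"m": [100.0, 101.0, 102.0, 103.0, 104.0]}
        )
        rep = filter_blank(ds)
        stats = rep.table.set_index("statistic")
        assert stats.loc["wilcoxon_p", "value"] < 0.05
        assert stats.loc["median_ratio", "value"] < 1
        assert rep.removed == ["m"]

    def test_requires_blanks(self):
        ds = make_tiny_dataset({"m": [5.0] * 10})
        with pytest.raises(ValueError, match="blank"):
            filter_blank(ds)


def test_filters_recover_planted_artifacts_and_commute(qc_cohort):
    _, ds, truth = qc_cohort
    qc_rep = filter_qc_rsd(ds)
    blank_rep = filter_blank(ds)
    assert sorted(qc_rep.removed) == sorted(truth.high_rsd_metabolites)
    assert sorted(blank_rep.removed) == sorted(truth.blank_artifacts)
    ab = apply_filters(ds, [qc_rep, blank_rep]).metabolites
    ba = apply_filters(ds, [blank_rep, qc_rep]).metabolites
    assert ab == ba


class TestImpute:
    def test_identity_when_complete(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3) + 1)
        out = impute_missing(df)
        pd.testing.assert_frame_equal(out, df)

    def test_collinear_regression_prediction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 1, 40)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(0, 1, 40)})
        truth = df.loc[7, "b"]
        df.loc[7, "b"] = np.nan
        out = impute_missing(df, seed=0)
        assert out.loc[7, "b"] == pytest.approx(truth, abs=1e-6)
        # observed entries untouched
        assert ((out == df) | df.isna()).all().all()

    def test_fully_missing_column_errors(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "gone": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="gone"):
            impute_missing(df)

    def test_rmse_below_twice_noise_sd(self, small_cohort):
        cfg, ds, _ = small_cohort
        logged = np.log10(ds.matrix(ROLE_STUDY))
        rng = np.random.default_rng(0)
        mask = rng.random(logged.shape) < 0.1
        holdout = logged.where(~mask)
        filled = impute_missing(holdout, seed=0)
        err = (filled.to_numpy() - logged.to_numpy())[mask]
        assert np.sqrt(np.mean(err**2)) < 2 * cfg.noise_sd


class TestLog10Autoscale:
    def test_hand_computed(self):
        df = pd.DataFrame({"m": [10.0, 100.0, 1000.0]})
        out = log10_autoscale(df)
        assert out["m"].tolist() == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)

    def test_columns_standardized(self, small_cohort):
        _, ds, _ = small_cohort
        out = log10_autoscale(ds.matrix(ROLE_STUDY))
        assert np.allclose(out.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(out.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_constant_column_excluded_with_warning(self):
        df = pd.DataFrame({"flat": [3.0, 3.0, 3.0], "ok": [1.0, 10.0, 100.0]})
        with pytest.warns(UserWarning, match="flat"):
            out = log10_autoscale(df)
        assert list(out.columns) == ["ok"]

    def test_non_positive_errors_with_location(self):
        df = pd.DataFrame({"m": [1.0, 0.0, 3.0]})
        with pytest.raises(ValueError, match="m"):
            log10_autoscale(df)


class TestTimecourseZscores:
    def test_hand_computed_profile(self):
        # one subject => means are the values themselves: profile 1..5
        ds = make_tiny_dataset({"m": [1.0, 2.0, 3.0, 4.0, 5.0]})
        z = timecourse_zscores(ds, log10=False)
        expect = (np.arange(1.0, 6.0) - 3.0) / np.sqrt(2.5)
        assert z.loc["m"].to_numpy() == pytest.approx(expect, abs=1e-9)
        assert expect[0] == pytest.approx(-1.2649, abs=1e-4)

    def test_rows_standardized(self, small_cohort):
        _, ds, _ = small_cohort
        z = timecourse_zscores(ds)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_constant_profile_excluded(self):
        ds = make_tiny_dataset(
            {"flat": [2.0] * 5, "ok": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        with pytest.warns(UserWarning, match="flat"):
            z = timecourse_zscores(ds, log10=False)
        assert list(z.index) == ["ok"]
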