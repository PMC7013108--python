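"""qPCR R0 normalization, replicate QC, outlier screen, boxplot summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from matplotlib import cbook

from greganet.assays import (
    boxplot_stats,
    compute_R0,
    normalize_expression,
    qc_replicates,
    screen_outliers,
)


class TestComputeR0:
    def test_closed_forms(self):
        assert compute_R0(10.0, 1.0) == pytest.approx(2.0**-10, rel=0, abs=0)
        assert compute_R0(0.0, 1.0) == 1.0
        assert compute_R0(20.0, 0.9) == pytest.approx(np.exp(-20 * np.log(1.9)), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="efficiency"):
            compute_R0(10.0, 0.0)
        with pytest.raises(ValueError, match="Ct"):
            compute_R0(-1.0, 0.9)

    def test_percent_efficiency_converted_with_warning(self):
        with pytest.warns(UserWarning, match="percent"):
            assert compute_R0(10.0, 100.0) == pytest.approx(2.0**-10)

    @given(st.floats(0.05, 1.0), st.floats(0.1, 40.0), st.floats(0.1, 5.0))
    def test_strictly_decreasing_in_ct_and_e(self, e, ct, dct):
        assert compute_R0(ct + dct, e) < compute_R0(ct, e)
        if e <= 0.95:
            assert compute_R0(ct, e + 0.05) < compute_R0(ct, e)


class TestNormalizeExpression:
    def _wells(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "region", "gene", "Ct", "E"])

    def test_equal_ct_gives_unit_ratio(self):
        w = self._wells([("s1", "hypothalamus", "TNF-a", 22.0, 0.9),
                         ("s1", "hypothalamus", "Actb", 22.0, 0.9)])
        out = normalize_expression(w)
        assert out.loc[out["gene"] == "TNF-a", "R0_norm"].iloc[0] == pytest.approx(1.0)

    def test_one_extra_cycle_at_perfect_doubling_halves_expression(self):
        w = self._wells([("s1", "cortex", "IFN-g", 23.0, 1.0),
                         ("s1", "cortex", "Actb", 22.0, 1.0)])
        out = normalize_expression(w)
        assert out.loc[out["gene"] == "IFN-g", "R0_norm"].iloc[0] == pytest.approx(0.5)

    def test_duplicate_wells_collapsed_by_mean_ct(self):
        w = self._wells([("s1", "cortex", "IL-1b", 20.0, 1.0),
                         ("s1", "cortex", "IL-1b", 22.0, 1.0),
                         ("s1", "cortex", "Actb", 21.0, 1.0)])
        out = normalize_expression(w)
        row = out[out["gene"] == "IL-1b"].iloc[0]
        assert row["n_wells"] == 2
        assert row["R0_norm"] == pytest.approx(1.0)  # mean Ct 21 vs actin 21

    def test_missing_housekeeping_flagged(self):
        w = self._wells([("s1", "cortex", "TNF-a", 22.0, 0.9)])
        out = normalize_expression(w)
        assert out["flag"].iloc[0] == "missing_housekeeping"
        assert np.isnan(out["R0_norm"].iloc[0])

    def test_scale_invariance_under_input_rna_amount(self):
        # multiplying every concentration by c shifts all Cts equally and
        # leaves the normalized expression unchanged
        for shift in (0.0, 3.3):
            w = self._wells([("s1", "cortex", "TNF-a", 24.0 + shift, 0.9),
                             ("s1", "cortex", "Actb", 21.0 + shift, 0.9)])
            out = normalize_expression(w)
            val = out.loc[out["gene"] == "TNF-a", "R0_norm"].iloc[0]
            assert val == pytest.approx(1.9**-3.0, rel=1e-12)


class TestQcReplicates:
    def _raw(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "analyte", "replicate", "value"])

    def test_identical_replicates_zero_cv(self):
        out = qc_replicates(self._raw([("s1", "TNF-a", 1, 10.0), ("s1", "TNF-a", 2, 10.0)]))
        assert out["mean"].iloc[0] == 10.0
        assert out["cv_pct"].iloc[0] == 0.0

    def test_cv_uses_sample_sd(self):
        out = qc_replicates(self._raw([("s1", "IFN-g", 1, 9.0), ("s1", "IFN-g", 2, 11.0)]))
        assert out["cv_pct"].iloc[0] == pytest.approx(100 * np.sqrt(2.0) / 10.0)

    def test_single_replicate_cv_undefined_not_zero(self):
        out = qc_replicates(self._raw([("s1", "IL-1b", 1, 5.0)]))
        assert out["n_replicates"].iloc[0] == 1
        assert np.isnan(out["cv_pct"].iloc[0])

    def test_below_detection_flag_at_panel_limit(self):
        # TNF-a panel detection limit is 4.02 pg/mL
        out = qc_replicates(self._raw([("s1", "TNF-a", 1, 2.0), ("s1", "TNF-a", 2, 2.0)]))
        assert bool(out["below_detection"].iloc[0])
        out2 = qc_replicates(self._raw([("s1", "TNF-a", 1, 5.0), ("s1", "TNF-a", 2, 5.0)]))
        assert not bool(out2["below_detection"].iloc[0])

    def test_negative_values_rejected_with_reason(self):
        with pytest.warns(UserWarning, match="rejected"):
            out = qc_replicates(self._raw([("s1", "TNF-a", 1, -1.0),
                                           ("s1", "TNF-a", 2, 8.0)]))
        assert out["n_replicates"].iloc[0] == 1
        assert out.attrs["rejected"][0]["reason"] == "negative_concentration"

    def test_cv_invariant_to_unit_rescaling(self, rng):
        vals = rng.uniform(1, 50, 6)
        raw1 = self._raw([("s1", "X", i, v) for i, v in enumerate(vals)])
        raw2 = self._raw([("s1", "X", i, 1000 * v) for i, v in enumerate(vals)])
        cv1 = qc_replicates(raw1, {})["cv_pct"].iloc[0]
        cv2 = qc_replicates(raw2, {})["cv_pct"].iloc[0]
        assert cv1 == pytest.approx(cv2, rel=1e-12)


class TestScreenOutliers:
    def test_seventeen_fold_value_flagged_at_default_threshold(self):
        # one animal at 17.5x the overall mean (the serum cytokine situation);
        # with 28 background values of 1, the extreme solves m = 17.5*(28+m)/29
        m = 17.5 * 28 / (29 - 17.5)
        v = np.r_[np.ones(28), m]
        assert v[-1] / v.mean() == pytest.approx(17.5, rel=1e-12)
        flags = screen_outliers(v)
        assert flags[-1] and flags[:-1].sum() == 0

    def test_all_equal_nothing_flagged(self):
        assert not screen_outliers(np.full(5, 3.3)).any()

    def test_just_below_threshold_not_flagged(self):
        m = 9.9 * 99 / (100 - 9.9)  # max/mean = 9.9 exactly
        v = np.r_[np.ones(99), m]
        assert v[-1] / v.mean() == pytest.approx(9.9, rel=1e-12)
        assert not screen_outliers(v, fold_threshold=10.0).any()

    def test_permutation_invariance(self, rng):
        v = np.r_[rng.uniform(1, 2, 20), [40.0]]
        perm = rng.permutation(v.size)
        f1 = screen_outliers(v)
        f2 = screen_outliers(v[perm])
        assert np.array_equal(f1[perm], f2)

    def test_needs_three_values_and_positive_mean(self):
        with pytest.raises(ValueError, match="at least 3"):
            screen_outliers([1.0, 2.0])
        with pytest.warns(UserWarning, match="skipped"):
            assert not screen_outliers([0.0, 0.0, 0.0]).any()


class TestBoxplotStats:
    def test_one_to_hundred_has_no_outliers(self):
        s = boxplot_stats(np.arange(1.0, 101.0))
        assert s["median"] == 50.5
        assert s["outliers"] == []
        assert s["whisker_low"] == 1.0 and s["whisker_high"] == 100.0

    def test_constant_vector_degenerate_box(self):
        s = boxplot_stats(np.full(7, 4.0))
        assert s["iqr"] == 0.0
        assert s["outliers"] == []

    def test_extreme_point_beyond_upper_whisker(self):
        s = boxplot_stats(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert s["outliers"] == [100.0]
        assert s["whisker_high"] == 4.0
        assert (s["q1"], s["q3"]) == (2.0, 4.0)  # type-7 quartiles

    def test_matches_matplotlib_convention(self, rng):
        for _ in range(5):
            v = rng.standard_normal(rng.integers(8, 60))
            ours = boxplot_stats(v)
            mpl = cbook.boxplot_stats(v, whis=1.5)[0]
            assert ours["median"] == pytest.approx(mpl["med"])
            assert ours["q1"] == pytest.approx(mpl["q1"])
            assert ours["q3"] == pytest.approx(mpl["q3"])
            assert ours["whisker_low"] == pytest.approx(mpl["whislo"])
            assert ours["whisker_high"] == pytest.approx(mpl["whishi"])
            assert sorted(ours["outliers"]) == pytest.approx(sorted(mpl["fliers"]))

    def test_asymmetric_lower_fence_parameter(self):
        v = np.array([-100.0, 1.0, 2.0, 3.0, 4.0])
        tight = boxplot_stats(v, lower_whisker=1.5)
        loose = boxplot_stats(v, lower_whisker=60.0)
        assert -100.0 in tight["outliers"]
        assert loose["outliers"] == []
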