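"""ROC/AUC, DeLong comparisons and Hosmer-Lemeshow calibration."""

import subprocess
import textwrap

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from vvrkit import (
    auc_midrank,
    calibration_bins,
    compare_scores,
    delong_auc_ci,
    delong_paired_test,
    hosmer_lemeshow,
    roc_curve,
)
from vvrkit.discrimination import delong_components


def brute_force_auc(scores, labels):
    """O(mn) pair count: 1 per case>control pair, 0.5 per tie."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    cases, controls = s[y == 1], s[y == 0]
    diff = cases[:, None] - controls[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size


class TestAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([3, 4, 1, 2], [1, 1, 0, 0], 1.0),
            ([5, 5, 5, 5], [1, 1, 0, 0], 0.5),
            # cases [1,3,5] vs controls [2,4]: wins are 3>2, 5>2, 5>4 -> 3/6
            ([1, 3, 5, 2, 4], [1, 1, 1, 0, 0], 3 / 6),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auc_midrank(scores, labels) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 140)
        scores = rng.integers(0, 10, n).astype(float)  # heavy ties
        labels = rng.binomial(1, 0.4, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc_midrank(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_trapezoidal_roc_area(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, 300).astype(float)
        labels = rng.binomial(1, 0.3, 300)
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(auc_midrank(scores, labels), abs=1e-12)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=500)
        labels = rng.binomial(1, 0.3, 500)
        assert auc_midrank(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            auc_midrank([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_structural_component_means_equal_auc(self, rng):
        scores = rng.integers(0, 5, 200).astype(float)
        labels = rng.binomial(1, 0.35, 200)
        auc, v10, v01 = delong_components(scores, labels)
        assert v10.mean() == pytest.approx(auc, abs=1e-12)
        assert v01.mean() == pytest.approx(auc, abs=1e-12)

    def test_perfect_separation_collapses_ci_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            auc, ci, se = delong_auc_ci([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert auc == 1.0
        assert ci == (1.0, 1.0)
        assert se == 0.0

    def test_label_flip_mirrors_auc_same_ci_width(self, rng):
        scores = rng.normal(size=300)
        labels = rng.binomial(1, 0.4, 300)
        auc, ci, se = delong_auc_ci(scores, labels)
        auc_f, ci_f, se_f = delong_auc_ci(scores, 1 - labels)
        assert auc_f == pytest.approx(1 - auc, abs=1e-12)
        assert se_f == pytest.approx(se, abs=1e-12)

    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=100)
        labels = rng.binomial(1, 0.5, 100)
        diff, z, p = delong_paired_test(scores, scores, labels)
        assert diff == 0.0
        assert p == 1.0

    def test_monotone_transform_is_null(self, rng):
        scores = rng.normal(size=100)
        labels = rng.binomial(1, 0.5, 100)
        diff, z, p = delong_paired_test(scores, np.exp(scores), labels)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_antisymmetric_in_score_order(self, rng):
        a = rng.normal(size=250)
        b = 0.5 * a + rng.normal(size=250)
        labels = rng.binomial(1, 0.4, 250)
        d_ab, z_ab, p_ab = delong_paired_test(a, b, labels)
        d_ba, z_ba, p_ba = delong_paired_test(b, a, labels)
        assert d_ab == pytest.approx(-d_ba, abs=1e-12)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_matches_r_proc_reference(self, tmp_path):
        """Single-score CI and paired test agree with the pROC package."""
        rng = np.random.default_rng(99)
        n = 80
        labels = rng.binomial(1, 0.4, n)
        a = labels * 0.9 + rng.normal(size=n)
        b = labels * 0.5 + rng.normal(size=n)
        auc, ci, _ = delong_auc_ci(a, labels)
        diff, z, p = delong_paired_test(a, b, labels)
        csv = tmp_path / "scores.csv"
        np.savetxt(csv, np.column_stack([labels, a, b]),
                   delimiter=",", header="y,a,b", comments="")
        script = textwrap.dedent(f"""
            suppressMessages(library(pROC))
            d <- read.csv("{csv}")
            ra <- roc(d$y, d$a, direction="<", quiet=TRUE)
            rb <- roc(d$y, d$b, direction="<", quiet=TRUE)
            ci <- ci.auc(ra, method="delong")
            tt <- roc.test(ra, rb, method="delong", paired=TRUE)
            cat(sprintf("%.15g", c(ci[1], ci[2], ci[3], tt$p.value)), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        lo_r, auc_r, hi_r, p_r = map(float, out.stdout.split())
        assert auc == pytest.approx(auc_r, abs=1e-10)
        assert ci[0] == pytest.approx(lo_r, abs=1e-6)
        assert ci[1] == pytest.approx(hi_r, abs=1e-6)
        assert p == pytest.approx(p_r, abs=1e-10)

    def test_compare_scores_layout(self, default_cohort):
        frame, _ = default_cohort
        cmp = compare_scores(frame)
        assert set(cmp.auc_per_score) == {"vis", "vvr", "mvvr"}
        assert len(cmp.contrasts) == 3
        for d in cmp.auc_per_score.values():
            assert 0.0 <= d["ci_95"][0] <= d["auc"] <= d["ci_95"][1] <= 1.0


class TestHosmerLemeshow:
    def test_degenerate_single_bin_rejected(self, rng):
        p = np.full(5000, 0.25)
        y = rng.binomial(1, 0.25, 5000)
        with pytest.raises(ValueError, match="bins"):
            hosmer_lemeshow(p, y)

    def test_anticalibrated_probabilities_detected(self, rng):
        true_p = 1 / (1 + np.exp(-rng.normal(-1.0, 1.5, 2000)))
        y = rng.binomial(1, true_p)
        res = hosmer_lemeshow(1 - true_p, y)
        assert res.p_value < 1e-3

    def test_observed_events_partition_the_total(self, rng):
        p = 1 / (1 + np.exp(-rng.normal(-1.0, 1.0, 1000)))
        y = rng.binomial(1, p)
        res = hosmer_lemeshow(p, y)
        assert res.observed_events.sum() == y.sum()
        assert (res.expected_events > 0).all()
        assert (res.expected_events < res.bin_sizes).all()
        assert res.df == res.n_bins - 2

    def test_tied_probabilities_merge_bins_with_warning(self, rng):
        p = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5], 30)
        y = rng.binomial(1, p)
        with pytest.warns(UserWarning, match="merged"):
            res = hosmer_lemeshow(p, y, n_bins=10)
        assert 3 <= res.n_bins <= 5
        assert res.df == res.n_bins - 2

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            hosmer_lemeshow([0.0, 0.5] * 50, [0, 1] * 50)


class TestCalibrationBins:
    def test_well_calibrated_bins_track_the_diagonal(self, rng):
        p = 1 / (1 + np.exp(-rng.normal(-1.0, 1.0, 2000)))
        y = rng.binomial(1, p)
        bins = calibration_bins(p, y, n_bins=10)
        assert (np.abs(bins["observed_rate"] - bins["mean_predicted"]) < 0.05).all()
        assert (bins["ci_low"] <= bins["observed_rate"]).all()
        assert (bins["observed_rate"] <= bins["ci_high"]).all()

    def test_single_bin_is_overall_rate(self, rng):
        p = 1 / (1 + np.exp(-rng.normal(-1.0, 1.0, 400)))
        y = rng.binomial(1, p)
        bins = calibration_bins(p, y, n_bins=1)
        assert len(bins) == 1
        assert bins.loc[0, "observed_rate"] == pytest.approx(y.mean())
        assert bins.loc[0, "mean_predicted"] == pytest.approx(p.mean())

    def test_single_class_rejected(self, rng):
        p = 1 / (1 + np.exp(-rng.normal(0, 1, 100)))
        with pytest.raises(ValueError, match="class"):
            calibration_bins(p, np.zeros(100, dtype=int))
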