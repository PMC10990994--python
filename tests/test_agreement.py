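"""Dwell measures and ICC(A,1) absolute agreement."""

import numpy as np
import pytest

from gazekit import (
    DataError,
    Dwell,
    DwellMeasures,
    compare_measures,
    dwell_measures,
    icc_a1,
    koo_li_label,
)


def brute_force_icc_a1(x, y):
    """ICC(A,1) from first principles: explicit two-way ANOVA sums.

    Deliberately loop-based and definitional, independent of the
    implementation's vectorized decomposition.
    """
    n, k = len(x), 2
    table = [[float(a), float(b)] for a, b in zip(x, y)]
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (table[i][j] - row_means[i] - col_means[j] + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestDwellMeasures:
    def test_full_session_single_dwell(self):
        d = [Dwell("left_lamp", 0.0, 90.0, 2700)]
        m = dwell_measures(d, 90.0)
        assert m.relative_total_dwell_time["left_lamp"] == 1.0
        assert m.relative_total_dwell_time["parent"] == 0.0
        assert m.mean_dwell_duration["left_lamp"] == 90.0

    def test_two_dwell_arithmetic(self):
        d = [Dwell("left_lamp", 0.0, 30.0, 900), Dwell("parent", 30.0, 90.0, 1800)]
        m = dwell_measures(d, 90.0)
        assert m.relative_total_dwell_time["left_lamp"] == pytest.approx(1 / 3)
        assert m.relative_total_dwell_time["parent"] == pytest.approx(2 / 3)
        assert m.mean_dwell_duration["left_lamp"] == 30.0
        assert m.mean_dwell_duration["parent"] == 60.0

    def test_relative_totals_partition_to_one(self):
        rng = np.random.default_rng(0)
        bounds = np.sort(rng.uniform(0, 90, 20))
        bounds = np.concatenate([[0.0], bounds, [90.0]])
        labels = rng.choice(["left_lamp", "parent", "right_lamp", "none"], 21)
        dwells = [
            Dwell(l, a, b, max(1, int((b - a) * 30)))
            for l, a, b in zip(labels, bounds[:-1], bounds[1:])
            if b > a
        ]
        m = dwell_measures(dwells, 90.0)
        assert sum(m.relative_total_dwell_time.values()) == pytest.approx(1.0)

    def test_absent_aoi_mean_is_nan_not_zero(self):
        m = dwell_measures([Dwell("parent", 0.0, 90.0, 2700)], 90.0)
        assert np.isnan(m.mean_dwell_duration["none"])
        assert m.n_dwells["none"] == 0

    def test_out_of_session_dwell_rejected(self):
        with pytest.raises(DataError):
            dwell_measures([Dwell("parent", 80.0, 95.0, 450)], 90.0)


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_a1(x, x.copy())
        assert res.icc == pytest.approx(1.0)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.normal(0, 1, 6)
            y = x + rng.normal(0, 0.5, 6)
            res = icc_a1(x, y)
            assert res.icc == pytest.approx(brute_force_icc_a1(x, y), abs=1e-10)

    def test_matches_pingouin_reference(self):
        # independent cross-check against an established implementation of
        # the two-way random-effects absolute-agreement single-rater ICC
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        x = rng.normal(10, 3, 12)
        y = x + rng.normal(1.0, 1.0, 12)
        df = pd.DataFrame(
            {
                "subject": list(range(12)) * 2,
                "rater": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([x, y]),
            }
        )
        table = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        ref = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
        ci = ref["CI95"] if "CI95" in ref.index else ref["CI95%"]
        res = icc_a1(x, y)
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(ci[0], abs=0.01)
        assert res.ci_high == pytest.approx(ci[1], abs=0.01)

    def test_offset_penalized_below_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = icc_a1(x, x + 10.0)
        assert np.corrcoef(x, x + 10.0)[0, 1] == pytest.approx(1.0)
        assert res.icc < 0.2  # absolute agreement punishes the offset

    def test_symmetric_in_raters(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0, 0.7, 10)
        assert icc_a1(x, y).icc == pytest.approx(icc_a1(y, x).icc)

    def test_joint_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0, 0.5, 10)
        a = icc_a1(x, y).icc
        b = icc_a1(3.0 * x + 7.0, 3.0 * y + 7.0).icc
        assert b == pytest.approx(a)

    def test_variance_ratio_recovery(self):
        # subject effect + independent rater noise: population ICC is
        # sigma_b^2 / (sigma_b^2 + sigma_e^2)
        rng = np.random.default_rng(5)
        sb, se = 2.0, 1.0
        subj = rng.normal(0, sb, 200)
        x = subj + rng.normal(0, se, 200)
        y = subj + rng.normal(0, se, 200)
        expected = sb**2 / (sb**2 + se**2)
        assert icc_a1(x, y).icc == pytest.approx(expected, abs=0.06)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        assert icc_a1(x, y).n == 3

    def test_too_few_subjects(self):
        with pytest.raises(DataError):
            icc_a1([1.0, 2.0], [1.0, 2.0])

    def test_koo_li_labels(self):
        assert koo_li_label(0.3) == "poor"
        assert koo_li_label(0.6) == "moderate"
        assert koo_li_label(0.8) == "good"
        assert koo_li_label(0.95) == "excellent"
        res = icc_a1(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array([1.1, 2.0, 3.2, 3.9, 5.0, 6.1]),
        )
        assert res.ci_low <= res.icc <= res.ci_high
        assert res.interpretation[0] in {"poor", "moderate", "good", "excellent"}
        assert "ICC(A,1)" in res.summary()


def _measures(rel, mean_d):
    return DwellMeasures(
        relative_total_dwell_time=rel,
        mean_dwell_duration=mean_d,
        n_dwells={a: 1 for a in rel},
        session_duration=90.0,
    )


class TestCompareMeasures:
    @staticmethod
    def _cohort(n, rng, noise=0.0):
        est, man = {}, {}
        for i in range(n):
            rel = rng.dirichlet([3, 2, 3, 1.5])
            md = rng.uniform(1, 4, 4)
            labels = ("left_lamp", "parent", "right_lamp", "none")
            man[i] = _measures(dict(zip(labels, rel)), dict(zip(labels, md)))
            est[i] = _measures(
                dict(zip(labels, rel + rng.normal(0, noise, 4))),
                dict(zip(labels, md + rng.normal(0, noise, 4))),
            )
        return est, man

    def test_identical_raters_all_icc_one(self):
        rng = np.random.default_rng(6)
        est, man = self._cohort(10, rng, noise=0.0)
        cmp = compare_measures(est, man)
        for res in cmp.icc.values():
            assert res.icc == pytest.approx(1.0)
        assert (cmp.table.median_estimated == cmp.table.median_manual).all()

    def test_subject_mismatch_listed(self):
        rng = np.random.default_rng(7)
        est, man = self._cohort(5, rng)
        est["extra"] = est[0]
        with pytest.raises(DataError, match="extra"):
            compare_measures(est, man)

    def test_summary_table_shape(self):
        rng = np.random.default_rng(8)
        est, man = self._cohort(8, rng, noise=0.02)
        cmp = compare_measures(est, man)
        assert len(cmp.table) == 8  # 2 measures x 4 AOIs
        assert set(cmp.table.measure) == {
            "relative_total_dwell_time",
            "mean_dwell_duration",
        }
        assert "Agreement" in cmp.summary()
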