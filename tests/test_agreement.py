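"""Agreement statistics: Bland-Altman, heteroscedasticity screen, ICC, tests."""

import numpy as np
import pandas as pd
import pytest

import ichvol as iv
from ichvol.agreement import PairedSample


def make_records(volumes: dict[str, dict[str, float | None]]) -> pd.DataFrame:
    rows = []
    for method, per_case in volumes.items():
        for case, v in per_case.items():
            rows.append(dict(case_id=case, method=method, reader_id=None,
                             volume_mL=v, missed=v is None, partial=False,
                             ivh_included=False, distractor_included=False))
    return pd.DataFrame(rows)


def make_paired(m1, m2):
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    ids = tuple(f"c{i}" for i in range(len(m1)))
    return PairedSample(ids, m1, m2)


class TestPairing:
    def test_missing_cases_excluded(self):
        n = 300
        auto = {f"c{i:03d}": (None if i < 50 else 30.0 + i) for i in range(n)}
        ref = {f"c{i:03d}": 25.0 + i for i in range(n)}
        paired = iv.paired_complete_cases(
            make_records({"auto_sim": auto, "reference_voxel": ref}),
            "auto_sim", "reference_voxel")
        assert paired.n == 250

    def test_no_missing_keeps_all(self):
        rec = make_records({"abc2": {"a": 1.0, "b": 2.0},
                            "reference_voxel": {"a": 1.5, "b": 2.5}})
        assert iv.paired_complete_cases(rec, "abc2", "reference_voxel").n == 2

    def test_disjoint_sets_raise(self):
        rec = make_records({"abc2": {"a": 1.0, "b": 2.0},
                            "auto_sim": {"c": 1.5, "d": 2.5}})
        with pytest.raises(ValueError, match="fewer than 2"):
            iv.paired_complete_cases(rec, "abc2", "auto_sim")

    def test_order_stable_by_case_id(self):
        rec = make_records({"abc2": {"b": 2.0, "a": 1.0},
                            "reference_voxel": {"a": 1.5, "b": 2.5}})
        paired = iv.paired_complete_cases(rec, "abc2", "reference_voxel")
        assert paired.case_ids == ("a", "b")


class TestDifferences:
    def test_absolute_and_percent(self):
        p = make_paired([12.0, 10.0], [10.0, 10.0])
        d_abs, means = iv.differences(p, "absolute")
        assert d_abs[0] == 2.0 and means[0] == 11.0
        d_pct, _ = iv.differences(p, "percent")
        assert d_pct[0] == pytest.approx(100 * 2 / 11)

    def test_identity_gives_zeros(self):
        p = make_paired([5.0, 8.0, 9.0], [5.0, 8.0, 9.0])
        for mode in ("absolute", "percent"):
            d, _ = iv.differences(p, mode)
            assert np.all(d == 0)

    def test_antisymmetry(self):
        m1, m2 = [12.0, 30.0, 7.0], [10.0, 28.0, 9.0]
        d1, _ = iv.differences(make_paired(m1, m2), "absolute")
        d2, _ = iv.differences(make_paired(m2, m1), "absolute")
        assert np.allclose(d1, -d2)

    def test_percent_zero_sum_raises(self):
        p = make_paired([0.0, 1.0], [0.0, 2.0])
        with pytest.raises(ValueError):
            iv.differences(p, "percent")


class TestBlandAltmanLimits:
    def test_small_sample(self):
        mean, sd, lo, hi = iv.bland_altman_limits(np.array([1.0, 2.0, 3.0]))
        assert (mean, sd) == (2.0, 1.0)
        assert lo == pytest.approx(2 - 1.96)
        assert hi == pytest.approx(2 + 1.96)

    def test_constant_differences(self):
        mean, sd, lo, hi = iv.bland_altman_limits(np.array([2.0] * 4))
        assert (mean, sd, lo, hi) == (2.0, 0.0, 2.0, 2.0)

    def test_coverage_95pct(self):
        d = np.random.default_rng(1).normal(5, 10, 10_000)
        _, _, lo, hi = iv.bland_altman_limits(d)
        inside = ((d >= lo) & (d <= hi)).mean()
        assert 0.94 <= inside <= 0.96

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            iv.bland_altman_limits(np.array([1.0]))


class TestKendallTau:
    def test_perfect_proportionality(self):
        x = np.linspace(10, 100, 30)
        assert iv.kendall_tau_het(0.1 * x, x) == pytest.approx(1.0)

    def test_sign_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(10, 100, 50)
        d = rng.normal(0, 1, 50) * x / 50
        assert iv.kendall_tau_het(d, x) == iv.kendall_tau_het(-d, x)

    def test_all_tied_raises(self):
        with pytest.raises(ValueError):
            iv.kendall_tau_het(np.ones(5), np.arange(5.0))

    def test_null_distribution_small(self):
        rng = np.random.default_rng(3)
        small = 0
        for _ in range(200):
            x = rng.uniform(10, 100, 300)
            d = rng.normal(0, 2, 300)
            small += abs(iv.kendall_tau_het(d, x)) <= 0.1
        assert small >= 180


class TestBackTransform:
    def test_zero_log_limit(self):
        assert iv.back_transform_loa(0.0) == 0.0

    def test_ln3_gives_unit_slope(self):
        assert iv.back_transform_loa(np.log(3)) == pytest.approx(1.0)

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0, 2.0, 4.714285714285714])
    def test_round_trip(self, ratio):
        slope = iv.back_transform_loa(np.log(ratio))
        assert iv.slope_to_ratio(slope) == pytest.approx(ratio, abs=1e-9)

    def test_printed_slope_form(self):
        # a slope of 1.30 corresponds to ratio 2(r-1)/(r+1) = 1.30 -> r = 4.714...
        r = iv.slope_to_ratio(1.30)
        assert r == pytest.approx(33 / 7)
        assert iv.back_transform_loa(np.log(r)) == pytest.approx(1.30, abs=1e-9)


class TestAdaptiveLogLoA:
    def test_additive_error_stays_raw(self):
        rng = np.random.default_rng(10)
        entered = 0
        for _ in range(200):
            m1 = rng.uniform(10, 100, 300)
            m2 = m1 + rng.normal(0, 2, 300)
            res = iv.adaptive_log_loa(make_paired(m2, m1))
            entered += res.heteroscedastic
        assert entered <= 20

    def test_multiplicative_error_enters_log_branch(self):
        rng = np.random.default_rng(11)
        entered = reduced = 0
        for _ in range(200):
            m1 = rng.uniform(10, 100, 300)
            m2 = m1 * np.exp(rng.normal(0, 0.4, 300))
            res = iv.adaptive_log_loa(make_paired(m2, m1))
            entered += res.heteroscedastic
            reduced += res.log_branch is not None
            if res.log_branch is not None:
                assert res.log_branch.tau_log < res.tau_raw
        assert entered >= 180
        assert reduced >= 180

    def test_loa_identity_and_slope_order(self):
        rng = np.random.default_rng(12)
        m1 = np.exp(rng.normal(3, 1, 500))
        m2 = m1 * np.exp(rng.normal(0.05, 0.3, 500))
        res = iv.adaptive_log_loa(make_paired(m1, m2))
        assert res.loa_low == pytest.approx(res.mean_diff - 1.96 * res.sd_diff)
        assert res.loa_high == pytest.approx(res.mean_diff + 1.96 * res.sd_diff)
        lb = res.log_branch
        assert lb is not None
        assert lb.ratio_low == pytest.approx(np.exp(lb.loa_log_low))
        assert lb.slope_low < lb.slope_high

    def test_degenerate_identical_methods(self):
        p = make_paired([5.0, 8.0, 9.0, 11.0], [5.0, 8.0, 9.0, 11.0])
        res = iv.adaptive_log_loa(p)
        assert not res.heteroscedastic and res.sd_diff == 0.0

    def test_nonpositive_volume_in_log_branch_raises(self):
        # proportional error guarantees the log branch is triggered, but one
        # nonpositive volume makes the transform impossible
        m1 = np.linspace(10, 100, 40)
        m2 = m1 * 1.5
        m2[0] = -0.5
        with pytest.raises(ValueError, match="positive"):
            iv.adaptive_log_loa(make_paired(m1, m2))

    def test_brute_force_oracle(self):
        """Explicit-sum recomputation matches on random small samples to 1e-10."""
        rng = np.random.default_rng(99)
        for rep in range(50):
            n = int(rng.integers(5, 30))
            m1 = np.exp(rng.normal(3, 1, n))
            m2 = m1 * np.exp(rng.normal(0, rng.uniform(0.05, 0.6), n))
            p = make_paired(m1, m2)
            res = iv.adaptive_log_loa(p)

            # independent recomputation with explicit sums
            d = m1 - m2
            x = (m1 + m2) / 2
            mean = sum(d) / n
            sd = (sum((v - mean) ** 2 for v in d) / (n - 1)) ** 0.5
            assert abs(res.mean_diff - mean) < 1e-10
            assert abs(res.sd_diff - sd) < 1e-10
            assert abs(res.loa_low - (mean - 1.96 * sd)) < 1e-10
            assert abs(res.loa_high - (mean + 1.96 * sd)) < 1e-10

            def tau_bf(a, b):
                conc = disc = ties_a = ties_b = 0
                for i in range(n):
                    for j in range(i + 1, n):
                        da, db = a[i] - a[j], b[i] - b[j]
                        if da == 0 and db == 0:
                            ties_a += 1
                            ties_b += 1
                        elif da == 0:
                            ties_a += 1
                        elif db == 0:
                            ties_b += 1
                        elif da * db > 0:
                            conc += 1
                        else:
                            disc += 1
                n0 = n * (n - 1) / 2
                return (conc - disc) / ((n0 - ties_a) * (n0 - ties_b)) ** 0.5

            tau = tau_bf(np.abs(d), x)
            assert abs(res.tau_raw - tau) < 1e-10
            if tau > 0.1:
                dlog = np.log(m1) - np.log(m2)
                tau_log = tau_bf(np.abs(dlog), x)
                if tau_log < tau:
                    lb = res.log_branch
                    assert lb is not None
                    ml = sum(dlog) / n
                    sl = (sum((v - ml) ** 2 for v in dlog) / (n - 1)) ** 0.5
                    assert abs(lb.mean_log_diff - ml) < 1e-10
                    assert abs(lb.sd_log_diff - sl) < 1e-10
                    for limit, slope in ((ml - 1.96 * sl, lb.slope_low),
                                         (ml + 1.96 * sl, lb.slope_high)):
                        e = np.exp(limit)
                        assert abs(slope - 2 * (e - 1) / (e + 1)) < 1e-10


class TestICC:
    @staticmethod
    def _table(y):
        n, k = y.shape
        return pd.DataFrame({
            "case_id": np.repeat([f"c{i}" for i in range(n)], k),
            "reader_id": np.tile([f"r{j}" for j in range(k)], n),
            "volume": y.ravel(),
        })

    def test_perfect_agreement(self):
        y = np.column_stack([np.arange(10.0)] * 3)
        assert iv.icc_oneway(self._table(y)).icc == pytest.approx(1.0)

    def test_noise_only(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (200, 2))
        assert iv.icc_oneway(self._table(y)).icc <= 0.1

    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        est = []
        for _ in range(500):
            subj = rng.normal(0, np.sqrt(0.97), 30)
            y = subj[:, None] + rng.normal(0, np.sqrt(0.03), (30, 2))
            est.append(iv.icc_oneway(self._table(y)).icc)
        assert np.mean(est) == pytest.approx(0.97, abs=0.02)

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        subj = rng.normal(10, 5, 25)
        y = subj[:, None] + rng.normal(0, 2, (25, 3))
        table = self._table(y)
        ours = iv.icc_oneway(table).icc
        ref = pingouin.intraclass_corr(
            data=table, targets="case_id", raters="reader_id", ratings="volume"
        )
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert ours == pytest.approx(float(icc1), abs=1e-9)

    def test_unbalanced_design(self):
        rows = [("a", "r1", 10.0), ("a", "r2", 10.5), ("a", "r3", 9.5),
                ("b", "r1", 20.0), ("b", "r2", 20.2),
                ("c", "r1", 30.0)]
        df = pd.DataFrame(rows, columns=["case_id", "reader_id", "volume"])
        res = iv.icc_oneway(df)
        assert 0.9 < res.icc <= 1.0
        assert res.n_subjects == 3
        assert res.mean_raters_per_subject < 3

    def test_no_repeats_raises(self):
        df = pd.DataFrame({"case_id": ["a", "b"], "reader_id": ["r1", "r1"],
                           "volume": [1.0, 2.0]})
        with pytest.raises(ValueError):
            iv.icc_oneway(df)


class TestTests:
    def test_paired_t_small_sample(self):
        res = iv.paired_t_test(np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-6)
        assert res.p_value == pytest.approx(0.0742, abs=0.0005)

    def test_symmetric_differences(self):
        res = iv.paired_t_test(np.array([-1.0, 1.0]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_scale_invariance(self):
        d = np.array([0.5, 1.5, -0.2, 2.0])
        a, b = iv.paired_t_test(d), iv.paired_t_test(10 * d)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            iv.paired_t_test(np.array([2.0, 2.0, 2.0]))

    def test_shapiro_type_one_error(self):
        rng = np.random.default_rng(8)
        rej = sum(iv.shapiro_wilk(rng.normal(0, 1, 300)).p_value < 0.05
                  for _ in range(1000))
        assert 30 <= rej <= 70

    def test_shapiro_lognormal_power(self):
        rng = np.random.default_rng(9)
        rej = sum(iv.shapiro_wilk(np.exp(rng.normal(0, 1, 300))).p_value < 0.05
                  for _ in range(100))
        assert rej >= 95

    def test_shapiro_affine_invariance(self):
        x = np.random.default_rng(10).normal(0, 1, 50)
        a = iv.shapiro_wilk(x).statistic
        b = iv.shapiro_wilk(3.0 * x + 7.0).statistic
        assert a == pytest.approx(b, rel=1e-9)

    def test_shapiro_bounds(self):
        with pytest.raises(ValueError):
            iv.shapiro_wilk(np.array([1.0, 2.0]))


class TestSubgroupsAndAcceptance:
    @staticmethod
    def _cohort_records(rng, ivh_bias=10.0):
        truth = pd.DataFrame({
            "case_id": [f"c{i:02d}" for i in range(60)],
            "ivh_present": [i % 2 == 0 for i in range(60)],
            "location": ["lobar" if i % 3 == 0 else "basal_ganglia_thalamus"
                         for i in range(60)],
        })
        ref = rng.uniform(5, 80, 60)
        auto = ref + rng.normal(0, 1, 60)
        auto[truth.ivh_present.to_numpy()] += ivh_bias
        rows = []
        for i in range(60):
            rows.append(dict(case_id=truth.case_id[i], method="reference_voxel",
                             reader_id=None, volume_mL=ref[i], missed=False,
                             partial=False, ivh_included=False,
                             distractor_included=False))
            rows.append(dict(case_id=truth.case_id[i], method="auto_sim",
                             reader_id=None, volume_mL=auto[i], missed=False,
                             partial=False, ivh_included=truth.ivh_present[i],
                             distractor_included=False))
        return pd.DataFrame(rows), truth

    def test_strata_partition_complete_cases(self):
        records, truth = self._cohort_records(np.random.default_rng(20))
        res = iv.subgroup_agreement(records, truth, "ivh",
                                    ("auto_sim", "reference_voxel"))
        assert res["ivh"].n + res["no_ivh"].n == 60

    def test_ivh_inclusion_shows_in_stratum(self):
        records, truth = self._cohort_records(np.random.default_rng(21))
        res = iv.subgroup_agreement(records, truth, "ivh",
                                    ("auto_sim", "reference_voxel"))
        assert res["ivh"].mean_diff > res["no_ivh"].mean_diff

    def test_volume_split_uses_reference(self):
        records, truth = self._cohort_records(np.random.default_rng(22))
        res = iv.subgroup_agreement(records, truth, "volume_40",
                                    ("auto_sim", "reference_voxel"))
        ref = records[records.method == "reference_voxel"]
        n_small = int((ref.volume_mL < 40).sum())
        assert res["lt_40_mL"].n == n_small

    def test_empty_stratum_not_estimable(self):
        records, truth = self._cohort_records(np.random.default_rng(23))
        truth["ivh_present"] = False
        res = iv.subgroup_agreement(records, truth, "ivh",
                                    ("auto_sim", "reference_voxel"))
        assert not res["ivh"].estimable
        assert res["no_ivh"].estimable

    def test_acceptance_rule(self):
        def pct_result(lo, hi):
            return iv.BlandAltmanResult(n=100, mode="percent", mean_diff=0.0,
                                        sd_diff=1.0, loa_low=lo, loa_high=hi,
                                        tau_raw=0.0, heteroscedastic=False)
        # the published three-method comparison failed this check
        assert not iv.acceptance_check(pct_result(-66.7, 121.2))
        assert iv.acceptance_check(pct_result(-9, 9))
        assert iv.acceptance_check(pct_result(-10, 10))  # boundary inclusive
        with pytest.raises(ValueError):
            iv.acceptance_check(
                iv.BlandAltmanResult(n=10, mode="absolute", mean_diff=0.0,
                                     sd_diff=1.0, loa_low=-1, loa_high=1,
                                     tau_raw=0.0, heteroscedastic=False))
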