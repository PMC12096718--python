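"""Cohort statistics: enumeration oracles for the rank-sum test and ROC cutoffs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from firstdose.stats import cda_curves, roc_cutoff, summarize_cohort, wilcoxon_exact
from oracles import wilcoxon_p_enumeration, youden_bruteforce


class TestWilcoxonExact:
    def test_small_worked_example(self):
        # x = {1,2}, y = {3,4}: the observed split is the most extreme of the
        # C(4,2) = 6 equally likely splits; two-sided p = 2/6 = 1/3
        c = wilcoxon_exact([1.0, 2.0], [3.0, 4.0])
        assert c.p_value == pytest.approx(1.0 / 3.0)

    def test_identical_groups_zero_shift(self):
        c = wilcoxon_exact([1.0, 5.0, 9.0], [1.0, 5.0, 9.0])
        assert c.shift_estimate == 0.0

    def test_all_tied_degenerate(self):
        c = wilcoxon_exact([2.0, 2.0], [2.0, 2.0, 2.0])
        assert c.p_value == 1.0
        assert c.ci_low == c.ci_high == 0.0

    def test_matches_enumeration_exhaustively_small_n(self):
        """Exact p equals full enumeration for every group-size split with
        combined n <= 8, on randomly drawn tie-free data."""
        rng = np.random.default_rng(99)
        for total in range(2, 9):
            for m in range(1, total):
                n = total - m
                vals = rng.normal(size=total) * 10
                x, y = vals[:m], vals[m:]
                ours = wilcoxon_exact(x, y).p_value
                oracle = wilcoxon_p_enumeration(x, y)
                assert ours == pytest.approx(oracle, abs=1e-12), (m, n)

    def test_hodges_lehmann_shift_and_ci(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5.0, 1.0, size=10)
        y = rng.normal(0.0, 1.0, size=12)
        c = wilcoxon_exact(x, y)
        diffs = np.sort((x[:, None] - y[None, :]).ravel())
        assert c.shift_estimate == pytest.approx(np.median(diffs))
        assert c.ci_low <= c.shift_estimate <= c.ci_high
        # CI endpoints are order statistics of the pairwise differences
        assert c.ci_low in diffs and c.ci_high in diffs

    def test_ci_covers_true_shift_mostly(self):
        # with a true shift of 3, the 95% interval should usually contain 3
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(40):
            x = rng.normal(3.0, 1.0, size=9)
            y = rng.normal(0.0, 1.0, size=9)
            c = wilcoxon_exact(x, y)
            hits += c.ci_low <= 3.0 <= c.ci_high
        assert hits >= 33  # ~95% nominal coverage, generous slack

    def test_large_sample_normal_approximation_with_ties(self):
        rng = np.random.default_rng(8)
        x = np.round(rng.normal(1.0, 1.0, size=30), 1)
        y = np.round(rng.normal(0.0, 1.0, size=30), 1)
        c = wilcoxon_exact(x, y)
        assert 0 < c.p_value <= 1
        assert c.ci_low <= c.shift_estimate <= c.ci_high

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_exact([], [1.0])


class TestRocCutoff:
    def test_perfect_separation_midpoint(self):
        res = roc_cutoff([0.02, 0.05, 0.2, 0.3], [True, True, False, False])
        assert res.cutoff == pytest.approx(0.125)
        assert res.youden_j == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_matches_bruteforce_on_random_datasets(self):
        rng = np.random.default_rng(314)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            cond = rng.uniform(size=n) < 0.4
            if cond.all() or not cond.any():
                continue
            scores = np.where(cond, rng.lognormal(-3.0, 0.6, n), rng.lognormal(-2.0, 0.6, n))
            res = roc_cutoff(scores, cond)
            j_brute, cut_brute = youden_bruteforce(scores, cond)
            assert res.youden_j == pytest.approx(j_brute[0] if isinstance(j_brute, tuple) else j_brute)
            assert res.cutoff == pytest.approx(cut_brute)

    def test_relabeling_flips_curve(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(size=12)
        cond = rng.uniform(size=12) < 0.5
        if cond.all() or not cond.any():
            cond[0], cond[-1] = True, False
        a = roc_cutoff(scores, cond)
        b = roc_cutoff(scores, ~cond)
        round12 = lambda pts: {(round(u, 12), round(v, 12)) for u, v in pts}
        flipped = round12((tpr, fpr) for fpr, tpr in b.curve)
        assert round12(a.curve) == flipped

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_cutoff([0.1, 0.2], [True, True])

    def test_curve_monotone_in_fpr(self):
        rng = np.random.default_rng(21)
        scores = rng.uniform(size=30)
        cond = np.arange(30) % 3 == 0
        res = roc_cutoff(scores, cond)
        fprs = [p[0] for p in res.curve]
        tprs = [p[1] for p in res.curve]
        assert fprs == sorted(fprs)
        assert all(b >= a for a, b in zip(tprs, tprs[1:]))


class TestCdaCurves:
    def test_ecdf_normalization_and_monotonicity(self):
        rng = np.random.default_rng(17)
        scores = rng.uniform(size=25)
        cond = np.arange(25) % 2 == 0
        df, _ = cda_curves(scores, cond)
        for col in ("ecdf_condition", "ecdf_other"):
            v = df[col].to_numpy()
            assert np.all(np.diff(v) >= -1e-12)
            assert v[-1] == pytest.approx(1.0)

    def test_max_separation_matches_youden_cutoff(self):
        rng = np.random.default_rng(30)
        cond = rng.uniform(size=40) < 0.5
        cond[0], cond[-1] = True, False
        scores = np.where(cond, rng.normal(0.05, 0.02, 40), rng.normal(0.15, 0.04, 40))
        scores = np.abs(scores) + 1e-4
        _, cda_cut = cda_curves(scores, cond)
        roc = roc_cutoff(scores, cond)
        assert cda_cut == pytest.approx(roc.cutoff)


class TestSummarizeCohort:
    @pytest.fixture
    def ten_patient_report(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(10):
            drug = "meropenem" if i < 5 else "piperacillin"
            rows.append(
                dict(
                    patient_id=f"P{i}",
                    drug=drug,
                    age=40.0 + i,
                    weight=70.0 + i,
                    height=170.0 + i,
                    serum_creatinine=60.0 + 2 * i,
                    relative_egfr=80.0 + 5 * i,
                    crcl=90.0 + 10 * i,
                    arc=i % 3 == 0,
                    suspected_arc=i % 3 == 0,
                    egfr_group="above_90" if 80.0 + 5 * i > 90 else "at_or_below_90",
                    regimen="1g+1g q8h" if drug == "meropenem" else "4g+4g q6h",
                    cmin_observed=float(rng.uniform(1, 40)),
                    cmin_predicted=float(rng.uniform(1, 40)),
                    attained_100=i % 2 == 0,
                    ft_above_interval=70.0 + 3 * i,
                    ft_above_24h=65.0 + 3 * i,
                    cmin_cmax_ratio=0.01 * (i + 1),
                    converged=True,
                )
            )
        return pd.DataFrame(rows)

    def test_attainment_proportions_exact(self, ten_patient_report):
        tables = summarize_cohort(ten_patient_report)
        att = tables["attainment"].set_index("drug")
        for drug in ("meropenem", "piperacillin"):
            grp = ten_patient_report[ten_patient_report["drug"] == drug]
            expected = int((~grp["attained_100"]).sum())
            assert att.loc[drug, "n_not_attained"] == expected
            assert att.loc[drug, "pct_not_attained"] == pytest.approx(100 * expected / len(grp))

    def test_hand_computed_medians(self, ten_patient_report):
        tables = summarize_cohort(ten_patient_report)
        chars = tables["characteristics"]
        # meropenem ages are 40..44 -> median 42
        assert chars.loc["age", "meropenem"].startswith("42")
        assert chars.loc["n", "piperacillin"] == "5"

    def test_permutation_invariance(self, ten_patient_report):
        shuffled = ten_patient_report.sample(frac=1.0, random_state=5).reset_index(drop=True)
        t1 = summarize_cohort(ten_patient_report)
        t2 = summarize_cohort(shuffled)
        pd.testing.assert_frame_equal(
            t1["attainment"].sort_values("drug").reset_index(drop=True),
            t2["attainment"].sort_values("drug").reset_index(drop=True),
        )

    def test_single_patient_degenerate(self):
        df = pd.DataFrame(
            [
                dict(
                    patient_id="P0", drug="meropenem", age=50.0, weight=80.0, height=175.0,
                    serum_creatinine=70.0, relative_egfr=95.0, crcl=120.0, arc=False,
                    suspected_arc=False, egfr_group="above_90", regimen="1g+1g q8h",
                    cmin_observed=3.0, cmin_predicted=2.8, attained_100=True,
                    ft_above_interval=100.0, ft_above_24h=100.0, cmin_cmax_ratio=0.06,
                    converged=True,
                )
            ]
        )
        tables = summarize_cohort(df)
        assert tables["attainment"].iloc[0]["n_not_attained"] == 0
        assert tables["characteristics"].loc["age", "meropenem"].startswith("50")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame())
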