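"""Cohort derivations, counting/rounding, and the nonparametric tests."""

import json
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedpkd import cohort as coh
from pedpkd.cohort import (
    DegenerateGroupWarning,
    _ffh_exact,
    build_report,
    compare_categorical,
    compare_continuous,
    derive_all,
    percent,
    stratified_counts,
)
from pedpkd.errors import InvalidInputError
from pedpkd.synthetic import generate_cohort


class TestPercent:
    @pytest.mark.parametrize("count,total,decimals,expected", [
        (67, 75, 1, 89.3),
        (8, 75, 1, 10.7),
        (7, 75, 1, 9.3),
        (0, 75, 1, 0.0),
        (20, 75, 0, 27.0),
        (23, 75, 0, 31.0),
        (1, 8, 0, 13.0),  # 12.5 rounds half away from zero
    ])
    def test_printed_rounding(self, count, total, decimals, expected):
        assert percent(count, total, decimals) == expected

    def test_scale_invariance(self, rng):
        for _ in range(50):
            total = int(rng.integers(1, 200))
            count = int(rng.integers(0, total + 1))
            k = int(rng.integers(1, 10))
            assert percent(count, total, 1) == percent(k * count, k * total, 1)

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            percent(1, 0)
        with pytest.raises(InvalidInputError):
            percent(5, 4)


class TestStratifiedCounts:
    @staticmethod
    def _frame(labels):
        return pd.DataFrame({"merged_class": labels})

    def test_reference_class_counts(self):
        labels = ["A"] * 29 + ["B"] * 21 + ["C"] * 18 + ["D+E"] * 7
        s = stratified_counts(self._frame(labels))
        assert s.counts == {"A": 29, "B": 21, "C": 18, "D+E": 7}
        assert s.percents == {"A": 38.7, "B": 28.0, "C": 24.0, "D+E": 9.3}

    def test_single_class(self):
        s = stratified_counts(self._frame(["B"] * 10))
        assert s.percents == {"A": 0.0, "B": 100.0, "C": 0.0, "D+E": 0.0}

    def test_random_labels_match_tally_oracle(self, rng):
        labels = rng.choice(["A", "B", "C", "D+E"], size=200)
        s = stratified_counts(self._frame(list(labels)))
        for cls in ("A", "B", "C", "D+E"):
            tally = 0
            for v in labels:  # brute-force tally
                if v == cls:
                    tally += 1
            assert s.counts[cls] == tally
        assert sum(s.counts.values()) == s.n_total
        assert sum(s.percents.values()) == pytest.approx(100.0, abs=0.1 * 4)

    def test_crosstab(self):
        df = pd.DataFrame({"merged_class": ["A", "A", "B"], "gene": ["PKD1", "PKD2", "PKD1"]})
        s = stratified_counts(df, cross=("gene",))
        assert s.crosstabs["gene"]["A"]["PKD1"] == (1, 50.0)


def _exact_two_group_p(x, y):
    """Exhaustive-permutation two-sided rank-sum p (oracle)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    us = np.array([u_of(idx) for idx in combinations(range(len(pooled)), n1)])
    u_obs = u_of(range(n1))
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestCompareContinuous:
    def test_separated_groups_exact_p(self):
        res = compare_continuous([[1, 2, 3], [101, 102, 103]])
        assert res.test == "mann-whitney"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_centered_statistic_zero(self):
        res = compare_continuous([[1, 2, 3], [1, 2, 3]])
        assert res.centered_statistic == pytest.approx(0.0)

    def test_matches_permutation_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(0.8, size=5)
            res = compare_continuous([x, y])
            assert res.p_value == pytest.approx(_exact_two_group_p(x, y), rel=1e-9)

    def test_omnibus_and_pairwise(self, rng):
        groups = [rng.normal(loc, 1, size=12) for loc in (0, 0, 2)]
        res = compare_continuous(groups, pairwise=True)
        assert res.test == "kruskal-wallis"
        assert len(res.pairwise) == 3
        for _, _, _, praw, padj in res.pairwise:
            assert praw <= padj <= 1.0
            assert padj == pytest.approx(min(1.0, praw * 3))

    def test_four_groups_give_six_pairs(self, rng):
        groups = [rng.normal(size=8) for _ in range(4)]
        res = compare_continuous(groups, pairwise=True)
        assert len(res.pairwise) == 6
        assert all(padj == pytest.approx(min(1.0, praw * 6))
                   for *_, praw, padj in res.pairwise)

    def test_degenerate_group_warns(self):
        with pytest.warns(DegenerateGroupWarning):
            compare_continuous([[1.0], [2.0, 3.0]])
        with pytest.raises(InvalidInputError):
            compare_continuous([[1.0, 2.0]])


class TestCompareCategorical:
    def test_two_by_two_hypergeometric(self):
        assert compare_categorical([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)
        assert compare_categorical([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_ffh_matches_r_fisher_test(self):
        # reference p-values computed once with R's fisher.test
        assert _ffh_exact(np.array([[3, 1], [1, 3], [0, 4]])) == pytest.approx(
            0.2, rel=1e-9)
        assert _ffh_exact(np.array([[8, 4, 1], [2, 9, 3], [1, 6, 7]])) == pytest.approx(
            0.008008461908, rel=1e-6)

    def test_ffh_agrees_with_scipy_on_2x2(self, rng):
        for _ in range(10):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert _ffh_exact(t) == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9)

    def test_pairwise_bonferroni(self):
        tab = [[10, 2], [8, 4], [3, 9], [1, 11]]
        res = compare_categorical(tab, pairwise=True)
        assert len(res.pairwise) == 6
        for _, _, _, praw, padj in res.pairwise:
            assert padj == pytest.approx(min(1.0, praw * 6))
            assert padj >= praw

    def test_all_zero_table_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_categorical([[0, 0], [0, 0]])
        with pytest.raises(InvalidInputError):
            compare_categorical([[1, -1], [0, 2]])


class TestDeriveAll:
    def test_totality_on_synthetic_cohort(self, derived_cohort):
        derived, truth = derived_cohort
        patients = derived[derived["group"] == "adpkd"]
        for col in ("lic_class", "merged_class", "egfr_combined", "ht_category",
                    "volumes.httkv_ml_per_m", "obesity_flag"):
            assert patients[col].notna().all(), col

    def test_derived_classes_equal_generator_truth(self, derived_cohort):
        derived, truth = derived_cohort
        patients = derived[derived["group"] == "adpkd"].set_index("patient_id")
        t = truth[truth["true_class"].notna()].set_index("patient_id")
        assert (patients.loc[t.index, "lic_class"] == t["true_class"]).all()

    def test_missing_height_partial_derivation(self, synth_cohort):
        cohort, _, _ = synth_cohort
        df = cohort.head(3).copy()
        df.loc[df.index[0], "height_m"] = np.nan
        derived, report = derive_all(df)
        first = derived.iloc[0]
        assert pd.isna(first["volumes.httkv_ml_per_m"])
        assert pd.isna(first["lic_class"])
        assert pd.isna(first["egfr_combined"])  # creatinine arm needs height
        assert first["ht_category"] is not None  # BP phenotype still derived
        assert any(r["patient_id"] == first["patient_id"] for r in report)


class TestBuildReport:
    def test_schema_totality(self, derived_cohort):
        derived, _ = derived_cohort
        report = build_report(derived)
        for key in ("n_patients", "n_controls", "genotype", "lic_classes",
                    "kidney_function", "hypertension", "ht_prevalence_by_class",
                    "continuous_by_class"):
            assert key in report
        json.dumps(report)  # JSON-serializable throughout
        total = sum(report["lic_classes"][c]["n"] for c in report["lic_classes"])
        assert total == report["n_patients"]

    def test_record_order_invariance(self, derived_cohort):
        derived, _ = derived_cohort
        shuffled = derived.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert json.dumps(build_report(derived)) == json.dumps(build_report(shuffled))

    def test_prevalence_plot_smoke(self, derived_cohort):
        import matplotlib

        matplotlib.use("Agg")
        derived, _ = derived_cohort
        ax = coh.plot_ht_prevalence(build_report(derived))
        assert ax.get_ylabel().startswith("hypertension")
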