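import numpy as np
import pandas as pd
import pytest

import corneastain as cs
from corneastain.agreement import GradingMatrix, intrarater_kappas
from corneastain.errors import ValidationError

from conftest import DATA_DIR

FIXTURE = f"{DATA_DIR}/grader_deviation_reference.csv"


def matrix_from(rows):
    df = pd.DataFrame(rows, columns=["grader", "role", "experience_years",
                                     "image_id", "session", "grade"])
    return GradingMatrix(df)


def simple_matrix(grades_by_grader, session="round1"):
    rows = []
    for grader, grades in grades_by_grader.items():
        for i, g in enumerate(grades):
            rows.append((grader, "resident", 3, f"img{i:02d}", session, g))
    return matrix_from(rows)


class TestReadGradingMatrix:
    def write_csv(self, tmp_path, rows):
        path = tmp_path / "grades.csv"
        pd.DataFrame(rows, columns=["grader", "role", "experience_years",
                                    "image_id", "session", "grade"]
                     ).to_csv(path, index=False)
        return path

    def test_well_formed_parse(self, tmp_path):
        rows = [(g, "resident", 2, f"i{i}", "round1", (i + 1) % 6)
                for g in ("a", "b") for i in range(3)]
        m = cs.read_grading_matrix(self.write_csv(tmp_path, rows))
        assert len(m.records) == 6 and m.graders == ["a", "b"]

    def test_out_of_range_grade_names_row(self, tmp_path):
        rows = [("a", "resident", 2, "i0", "round1", 2),
                ("a", "resident", 2, "i1", "round1", 9)]
        with pytest.raises(ValidationError, match="row"):
            cs.read_grading_matrix(self.write_csv(tmp_path, rows))

    def test_duplicate_cell_rejected(self, tmp_path):
        rows = [("a", "resident", 2, "i0", "round1", 2)] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            cs.read_grading_matrix(self.write_csv(tmp_path, rows))

    def test_missing_cells_tolerated(self, tmp_path):
        rows = [("a", "resident", 2, "i0", "round1", 2),
                ("b", "resident", 2, "i1", "round1", 3)]
        m = cs.read_grading_matrix(self.write_csv(tmp_path, rows))
        piv = m.pivot()
        assert piv.isna().sum().sum() == 2  # pairwise-complete downstream


class TestEstimatedTrueGrade:
    def test_plain_mode(self):
        m = simple_matrix({"a": [2], "b": [2], "c": [3]})
        assert cs.estimated_true_grade(m).iloc[0] == 2

    def test_tie_rules(self):
        m = simple_matrix({"a": [1], "b": [1], "c": [2], "d": [2]})
        assert cs.estimated_true_grade(m, tie_rule="lower").iloc[0] == 1
        assert cs.estimated_true_grade(m, tie_rule="higher").iloc[0] == 2
        assert cs.estimated_true_grade(m, tie_rule="mean").iloc[0] == 2

    def test_singleton(self):
        m = simple_matrix({"a": [4]})
        assert cs.estimated_true_grade(m).iloc[0] == 4


class TestDeviationTable:
    def test_perfect_and_off_by_one_rows(self):
        truth_grades = [0, 1, 2, 3, 4, 5, 0, 1, 2]
        m = simple_matrix({
            "exact": truth_grades,
            "offby1": [min(g + 1, 5) if g < 5 else 4 for g in truth_grades]})
        truth = pd.Series(truth_grades,
                          index=[f"img{i:02d}" for i in range(9)])
        table = cs.deviation_table(m, truth)
        assert list(table.loc["exact", "dev0":"dev4"]) == [100.0, 0, 0, 0, 0]
        assert list(table.loc["offby1", "dev0":"dev4"]) == [0, 100.0, 0, 0, 0]

    def test_ninety_grading_percent_granularity(self):
        # 90 gradings, one at deviation 3 -> 1.11% in that column
        grades = [0] * 89 + [3]
        m = simple_matrix({"g": grades})
        truth = pd.Series(0, index=[f"img{i:02d}" for i in range(90)])
        table = cs.deviation_table(m, truth)
        assert table.loc["g", "dev3"] == 1.11
        assert table.loc["g", "dev0"] == 98.89

    def test_generated_rows_sum_to_100(self):
        m = simple_matrix({"a": [0, 1, 2, 3], "b": [3, 2, 1, 0]})
        truth = pd.Series([0, 1, 2, 3], index=[f"img{i:02d}" for i in range(4)])
        table = cs.deviation_table(m, truth)
        sums = table.loc[:, "dev0":"dev4"].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=0.05)


class TestSummarizeDeviations:
    def test_reference_panel_headline_numbers(self):
        """The bundled 22-grader reference panel: 18 graders stray by two or
        more grades somewhere, the worst single deviation is 4 grades, and
        the best grader hits the modal grade in 75.56% of cases."""
        table = cs.read_deviation_table(FIXTURE)
        s = cs.summarize_deviations(table, min_dev=2)
        assert s["n_graders"] == 22
        assert s["n_graders_at_or_above"] == 18
        assert s["max_deviation"] == 4
        assert s["max_exact_pct"] == 75.56

    def test_all_exact_table(self):
        table = pd.DataFrame({"dev0": [100.0, 100.0], "dev1": [0.0, 0.0],
                              "dev2": [0.0, 0.0], "dev3": [0.0, 0.0],
                              "dev4": [0.0, 0.0]}, index=["a", "b"])
        s = cs.summarize_deviations(table, min_dev=2)
        assert s["n_graders_at_or_above"] == 0 and s["max_deviation"] == 0


class TestCohenKappa:
    def test_identical_lists(self):
        rep = cs.cohen_kappa([0, 1, 2, 3], [0, 1, 2, 3])
        assert rep.value == 1.0 and rep.label == "almost perfect"

    def test_hand_computed_half(self):
        # Po = 2/3, Pe = 1/3 -> kappa = 0.5
        rep = cs.cohen_kappa([0, 1, 2], [0, 1, 1])
        assert rep.value == pytest.approx(0.5)

    def test_single_category_degenerate_flagged(self):
        rep = cs.cohen_kappa([2, 2, 2], [2, 2, 2])
        assert rep.value == 1.0 and "convention" in rep.note

    def test_symmetry(self, rng):
        a = rng.integers(0, 6, 50)
        b = rng.integers(0, 6, 50)
        assert cs.cohen_kappa(a, b).value == pytest.approx(
            cs.cohen_kappa(b, a).value)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(25):
            a = rng.integers(0, 6, 40)
            b = rng.integers(0, 6, 40)
            assert cs.cohen_kappa(a, b).value == pytest.approx(
                cohen_kappa_score(a, b))

    def test_missing_pairs_dropped(self):
        a = [0, 1, np.nan, 2]
        b = [0, 1, 3, np.nan]
        assert cs.cohen_kappa(a, b).n == 2


class TestFleissKappa:
    def test_unanimous_with_multiple_categories(self):
        table = np.array([[0, 0, 0], [3, 3, 3], [5, 5, 5]])
        rep = cs.fleiss_kappa(table)
        assert rep.value == pytest.approx(1.0)

    def test_hand_computed_toy_table(self):
        # three images x three graders; kappa = 4/13 from the Fleiss formula
        table = np.array([[0, 0, 1], [1, 1, 1], [2, 2, 0]])
        assert cs.fleiss_kappa(table).value == pytest.approx(4 / 13)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss
        table = rng.integers(0, 6, (40, 5))
        agg, _ = aggregate_raters(table)
        assert cs.fleiss_kappa(table).value == pytest.approx(sm_fleiss(agg))

    def test_missing_values_rejected(self):
        table = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValidationError, match="pairwise-complete"):
            cs.fleiss_kappa(table)


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert cs.spearman_rho([1, 2, 3], [10, 20, 30]).value == 1.0
        assert cs.spearman_rho([1, 2, 3], [-1, -2, -3]).value == -1.0

    def test_hand_computed_minus_half(self):
        # d = (-2, 1, 1): rho = 1 - 6*6/(3*8) = -0.5
        rep = cs.spearman_rho([1, 2, 3], [3, 1, 2])
        assert rep.value == pytest.approx(-0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            cs.spearman_rho([1, 1, 1], [1, 2, 3])

    def test_rank_brute_force_with_ties(self, rng):
        """Pipeline-style check: midrank Pearson equals the reported rho."""
        grades = np.repeat(np.arange(6), 5)
        counts = rng.integers(0, 300, 30).astype(float)
        rep = cs.spearman_rho(counts, grades)

        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v), float)
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks
        ra, rb = midranks(counts), midranks(grades.astype(float))
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rep.value == pytest.approx(expect)


class TestICC:
    def test_identical_columns(self):
        arr = np.tile(np.arange(1, 6, dtype=float)[:, None], (1, 3))
        assert cs.icc(arr).value == pytest.approx(1.0)

    def test_hand_computed_variance_components(self):
        # MSR = 40/3, MSC = 2, MSE = 0 -> ICC(2,1) = 40/43
        arr = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)
        assert cs.icc(arr).value == pytest.approx(40 / 43)

    def test_matches_pingouin_icc2(self, rng):
        import pingouin as pg
        arr = rng.normal(2.5, 1.0, (12, 4))
        long = pd.DataFrame(
            {"subject": np.repeat(np.arange(12), 4),
             "rater": np.tile(np.arange(4), 12),
             "score": arr.ravel()})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[sel, "ICC"].iloc[0]
        assert cs.icc(arr).value == pytest.approx(icc2, abs=1e-9)

    def test_single_rater_rejected(self):
        with pytest.raises(ValidationError):
            cs.icc(np.zeros((5, 1)))


class TestLandisKoch:
    @pytest.mark.parametrize("kappa,label", [
        (0.426, "moderate"), (0.831, "almost perfect"), (0.155, "slight"),
        (1.0, "almost perfect"), (-0.2, "poor"),
        (0.40, "fair"), (0.41, "moderate"),
        (0.20, "slight"), (0.21, "fair"),
        (0.60, "moderate"), (0.61, "substantial"),
        (0.80, "substantial"), (0.81, "almost perfect"),
    ])
    def test_bands(self, kappa, label):
        assert cs.landis_koch_label(kappa) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValidationError):
            cs.landis_koch_label(1.2)


class TestPermutationInvariance:
    def test_statistics_invariant_to_image_reordering(self, rng):
        a = rng.integers(0, 6, 30)
        b = rng.integers(0, 6, 30)
        perm = rng.permutation(30)
        assert cs.cohen_kappa(a, b).value == pytest.approx(
            cs.cohen_kappa(a[perm], b[perm]).value)
        assert cs.spearman_rho(a + 0.0, b + 0.0).value == pytest.approx(
            cs.spearman_rho((a + 0.0)[perm], (b + 0.0)[perm]).value)
        table = rng.integers(0, 6, (30, 4))
        assert cs.fleiss_kappa(table).value == pytest.approx(
            cs.fleiss_kappa(table[perm]).value)
        arr = rng.normal(size=(30, 4))
        assert cs.icc(arr).value == pytest.approx(cs.icc(arr[perm]).value)


class TestCompositeReport:
    def test_intrarater_section_per_session_pair(self):
        rows = []
        for grader in ("a", "b"):
            for s in ("round1", "round2_original", "round2_mirrored"):
                for i in range(6):
                    rows.append((grader, "specialist", 10, f"img{i}", s,
                                 (i + (grader == "b")) % 6))
        m = matrix_from(rows)
        kappas = intrarater_kappas(m)
        pairs = {frozenset(p) for p in zip(kappas["session_a"],
                                           kappas["session_b"])}
        assert pairs == {frozenset(p) for p in [
            ("round1", "round2_original"), ("round1", "round2_mirrored"),
            ("round2_original", "round2_mirrored")]}
        assert (kappas["kappa"] == 1.0).all()  # each grader self-consistent

    def test_full_report_perfect_agreement(self):
        rows = []
        for grader in ("a", "b", "c"):
            for i in range(8):
                rows.append((grader, "resident", 4, f"img{i}", "round1", i % 6))
        m = matrix_from(rows)
        counts = pd.Series(np.arange(8) % 6 * 10 + 1.0,
                           index=[f"img{i}" for i in range(8)])
        report = cs.agreement_report(m, counts_by_image=counts)
        assert report["interrater"]["round1"]["value"] == pytest.approx(1.0)
        assert report["icc"]["value"] == pytest.approx(1.0)
        assert report["count_vs_truth"]["value"] == pytest.approx(1.0)
        assert report["deviation_summary"]["max_deviation"] == 0
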