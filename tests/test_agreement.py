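"""OPA, Fleiss' kappa and ICC(A,1) against oracles and cross-checks.

Kappa is checked against both a naive double-loop evaluation of the
defining formula and statsmodels' implementation; the ICC ANOVA is checked
against explicit summation loops and pingouin's ICC2 row.
"""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats import inter_rater

from rateragree import (
    UndefinedStatisticError,
    agreement_report,
    fleiss_kappa,
    icc_a1,
    opa,
    opa_from_counts,
    render_table1,
    stratified_opa,
    table1_report,
    to_count_table,
)
from rateragree.agreement import round_half_up

from conftest import make_matrix, random_matrix


# ---------------------------------------------------------------- oracles
def fleiss_kappa_naive(counts):
    """Textbook double-loop evaluation of Fleiss' kappa."""
    counts = np.asarray(counts)
    n, c = counts.shape
    r = counts[0].sum()
    p_j = [sum(counts[i][j] for i in range(n)) / (n * r) for j in range(c)]
    p_i = [
        (sum(counts[i][j] ** 2 for j in range(c)) - r) / (r * (r - 1)) for i in range(n)
    ]
    p_bar = sum(p_i) / n
    p_e = sum(p**2 for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


def icc_a1_naive(values):
    """ICC(A,1) from mean squares computed with explicit summation loops."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(values[i]) / k for i in range(n)]
    col = [sum(values[:, j]) / n for j in range(k)]
    ssr = k * sum((x - grand) ** 2 for x in row)
    ssc = n * sum((x - grand) ** 2 for x in col)
    sst = sum((values[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def nondegenerate_matrix(seed, n, r):
    """Random matrix guaranteed to use >= 2 categories with some variance."""
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 4, size=(n, r))
    scores[0, 0], scores[0, 1] = 0, 1  # never single-category
    scores[-1, 0] = 3
    return make_matrix(scores)


# -------------------------------------------------------------------- OPA
class TestOPA:
    def test_printed_worked_ratio(self):
        """63 unanimous of 460 cases gives OPA 0.137, displayed as 0.14."""
        ci = opa_from_counts(63, 460)
        assert ci.estimate == pytest.approx(63 / 460)
        assert round_half_up(ci.estimate, 2) == 0.14

    def test_zero_successes_wilson_upper(self):
        """0 unanimous of 217: lower bound exactly 0, upper displays 0.02."""
        ci = opa_from_counts(0, 217)
        assert ci.estimate == 0.0
        assert ci.lower == 0.0
        z = 1.959963984540054
        assert ci.upper == pytest.approx(z**2 / (217 + z**2), rel=1e-6)
        assert round_half_up(ci.upper, 2) == 0.02

    def test_identical_observers(self):
        assert opa(make_matrix([[1, 1], [3, 3]])).estimate == 1.0

    def test_clopper_pearson_option(self):
        wilson = opa_from_counts(5, 50, method="wilson")
        cp = opa_from_counts(5, 50, method="clopper-pearson")
        assert wilson.estimate == cp.estimate
        assert cp.upper >= wilson.upper  # Clopper-Pearson is conservative

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 40), st.integers(1, 40))
    def test_wilson_contains_point(self, successes, extra):
        n = successes + extra
        ci = opa_from_counts(successes, n)
        assert ci.lower <= ci.estimate <= ci.upper
        if successes == 0:
            assert ci.lower == 0.0


# ----------------------------------------------------------- Fleiss kappa
class TestFleissKappa:
    def test_perfect_agreement(self):
        ci = fleiss_kappa(to_count_table(make_matrix([[0, 0], [3, 3], [1, 1]])))
        assert ci.estimate == pytest.approx(1.0)

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedStatisticError, match="single category"):
            fleiss_kappa(to_count_table(make_matrix([[2, 2], [2, 2]])))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 12), st.integers(2, 6))
    def test_matches_naive_formula_and_statsmodels(self, seed, n, r):
        m = nondegenerate_matrix(seed, max(n, 2), r)
        counts = to_count_table(m).counts
        ours = fleiss_kappa(to_count_table(m)).estimate
        assert ours == pytest.approx(fleiss_kappa_naive(counts))
        assert ours == pytest.approx(inter_rater.fleiss_kappa(counts, method="fleiss"))

    def test_ci_brackets_estimate(self, rng):
        ci = fleiss_kappa(to_count_table(random_matrix(rng, 40, 5)))
        assert ci.lower <= ci.estimate <= ci.upper
        assert ci.upper - ci.lower > 0


# -------------------------------------------------------------------- ICC
class TestICC:
    def test_identical_observers_varying_cases(self):
        ci, _ = icc_a1(make_matrix([[0, 0], [3, 3], [1, 1]]))
        assert ci.estimate == 1.0

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError, match="zero total variance"):
            icc_a1(make_matrix([[2, 2], [2, 2]]))

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**32 - 1), st.integers(3, 10), st.integers(2, 4))
    def test_matches_bruteforce_anova(self, seed, n, r):
        m = nondegenerate_matrix(seed, n, r)
        ours, comp = icc_a1(m)
        assert ours.estimate == pytest.approx(icc_a1_naive(m.scores), abs=1e-10)
        assert comp.ms_rows >= 0 and comp.ms_cols >= 0 and comp.ms_error >= 0

    def test_matches_pingouin_icc2(self, rng):
        m = random_matrix(rng, n=25, r=6)
        ours, _ = icc_a1(m)
        long = pd.DataFrame(
            {
                "case": np.repeat(m.case_ids, m.n_observers),
                "rater": np.tile(m.observer_ids, m.n_cases),
                "score": m.scores.astype(float).ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=long, targets="case", raters="rater", ratings="score"
        ).set_index("Type")
        assert ours.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds the CI to 2 dp
        assert ours.lower == pytest.approx(lo, abs=6e-3)
        assert ours.upper == pytest.approx(hi, abs=6e-3)


# --------------------------------------------------------------- reports
class TestReports:
    def test_report_degrades_gracefully(self):
        rep = agreement_report(make_matrix([[2, 2], [2, 2]]), "degenerate")
        assert rep.opa.estimate == 1.0
        assert rep.fleiss_kappa is None and rep.icc is None
        assert any("kappa undefined" in n for n in rep.notes)

    def test_table1_rows_in_order(self, toy_matrix):
        names = [r.grouping_name for r in table1_report(toy_matrix)]
        assert names == [
            "4-category score (0, 1+, 2+, 3+)",
            "3-category score (0, low, 3+)",
            "0 only",
            "1+ only",
            "2+ only",
            "3+ only",
            "low only",
            "0 vs. not 0",
            "1+ vs. not 1+",
            "2+ vs. not 2+",
            "low vs. not low",
            "3+ vs. not 3+",
            "<2+ vs. >=2+",
        ]

    def test_fully_concordant_matrix_all_opa_one(self):
        m = make_matrix([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])
        for rep in table1_report(m):
            if rep.opa is not None:
                assert rep.opa.estimate == 1.0

    def test_render_uses_display_rounding(self):
        m = make_matrix([[0, 0, 0], [0, 1, 0], [2, 2, 2]])
        text = render_table1(table1_report(m))
        assert text.splitlines()[1].startswith("4-category score (0, 1+, 2+, 3+)\t3\t0.67")


class TestStratifiedOPA:
    def test_noisier_stratum_scores_lower(self):
        rng = np.random.default_rng(7)
        clean = np.repeat(rng.integers(0, 4, size=(60, 1)), 3, axis=1)
        noisy = rng.integers(0, 4, size=(60, 3))
        m = make_matrix(
            np.hstack([clean, noisy]),
            observer_meta={f"o{j}": ("senior" if j < 3 else "junior") for j in range(6)},
        )
        result = stratified_opa(m, "observer_experience")
        assert result.reports["senior"].opa.estimate == 1.0
        assert result.reports["senior"].opa.estimate > result.reports["junior"].opa.estimate
        assert result.difference == pytest.approx(
            1.0 - result.reports["junior"].opa.estimate
        )

    def test_specimen_axis_splits_cases(self):
        m = make_matrix(
            [[0, 0], [1, 2], [3, 3], [2, 2]],
            case_meta={"c0": "biopsy", "c1": "biopsy", "c2": "surgical", "c3": "surgical"},
        )
        result = stratified_opa(m, "specimen_type")
        assert result.reports["biopsy"].opa.estimate == 0.5
        assert result.reports["surgical"].opa.estimate == 1.0
        assert result.difference == pytest.approx(0.5)

    def test_single_stratum_has_no_difference(self):
        m = make_matrix([[0, 1], [2, 2]], case_meta={"c0": "surgical", "c1": "surgical"})
        assert stratified_opa(m, "specimen_type").difference is None

    def test_missing_metadata_is_an_error(self, toy_matrix):
        with pytest.raises(ValueError, match="metadata.*missing"):
            stratified_opa(toy_matrix, "observer_experience")

    def test_tiny_observer_stratum_rejected(self):
        m = make_matrix(
            [[0, 1, 2]], observer_meta={"o0": "senior", "o1": "senior", "o2": "junior"}
        )
        with pytest.raises(ValueError, match="fewer than 2 observers"):
            stratified_opa(m, "observer_experience")
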