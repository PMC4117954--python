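"""Audic-Claverie test, tissue specificity, and fate calling."""

import math
from fractions import Fraction
from math import comb

import pandas as pd
import pytest

from syntepoch.errors import ValidationError
from syntepoch.gene_fate import (
    audic_test,
    call_fate,
    fate_report,
    tissue_specificity,
)
from syntepoch.io_formats import ExpressionTable
from syntepoch.retention import HomoeologGroup


def rational_audic(x: int, y: int) -> Fraction:
    """Exact-rational two-sided p for equal library sizes.

    P(k|x) = C(x+k, k) / 2^(x+k+1); both conditionings are evaluated and
    the smaller doubled tail (capped at 1) is returned, mirroring the
    implementation's symmetric definition.
    """

    def tails(a: int, b: int) -> Fraction:
        P = lambda k: Fraction(comb(a + k, k), 2 ** (a + k + 1))
        lower = sum((P(k) for k in range(0, b + 1)), Fraction(0))
        upper = 1 - sum((P(k) for k in range(0, b)), Fraction(0))
        return min(lower, upper)

    return min(Fraction(1), 2 * min(tails(x, y), tails(y, x)))


class TestAudic:
    def test_worked_example_five_vs_zero(self):
        # P(0|5) = C(5,0)/2^6 = 1/64; doubled -> 2/64
        assert audic_test(5, 0, 1e6, 1e6) == pytest.approx(1 / 32, rel=1e-12)

    def test_equal_counts_cap_at_one(self):
        for x in (0, 3, 17):
            assert audic_test(x, x, 1e6, 1e6) == pytest.approx(1.0, rel=1e-9)

    def test_matches_exact_rational_summation_on_grid(self):
        for x in range(21):
            for y in range(21):
                p = audic_test(x, y, 1e6, 1e6)
                exact = float(rational_audic(x, y))
                assert math.log(p) == pytest.approx(math.log(exact), abs=1e-12)

    def test_symmetry_under_library_swap(self):
        for x, y, n1, n2 in [(0, 1, 1e6, 1e6), (5, 0, 1e6, 1e6), (12, 3, 1e6, 2e6),
                             (7, 7, 5e5, 1e6), (20, 2, 1e6, 4e6)]:
            assert audic_test(x, y, n1, n2) == pytest.approx(
                audic_test(y, x, n2, n1), rel=1e-12)

    def test_large_counts_stay_finite(self):
        p = audic_test(100000, 1000, 1e7, 1e7)
        assert 0 < p < 1e-100 or p == 0.0  # log-space path must not overflow
        assert not math.isnan(p)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            audic_test(-1, 0, 1e6, 1e6)


def table_from(rows: dict[str, list[float]], libraries=None, tissues=None):
    libraries = libraries or ["leaf", "root", "stem", "pool1", "pool2"]
    tissues = tissues or {"leaf": "leaf", "root": "root", "stem": "stem",
                          "pool1": "pool", "pool2": "pool"}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=libraries)
    df.index.name = "gene"
    return ExpressionTable(df.astype(float), tissues)


class TestTissueSpecificity:
    def test_root_specific_gene(self):
        table = table_from({"g1": [0, 120, 0, 15, 15]})
        assert tissue_specificity("g1", table) == {"root"}

    def test_all_zero_gene_has_empty_set(self):
        table = table_from({"g1": [0, 0, 0, 0, 0]})
        assert tissue_specificity("g1", table) == set()

    def test_uniform_expression_has_empty_set(self):
        table = table_from({"g1": [100, 100, 100, 100, 100]})
        assert tissue_specificity("g1", table) == set()

    def test_needs_two_libraries(self):
        table = table_from({"g1": [5]}, libraries=["only"], tissues={"only": "only"})
        with pytest.raises(ValidationError):
            tissue_specificity("g1", table)


def group(subject="sub1", copies=("c1", "c2")):
    return HomoeologGroup(subject_gene=subject, copies=list(copies))


class TestCallFate:
    def test_no_expression_anywhere_is_dead(self):
        table = table_from({"c1": [0] * 5, "c2": [0] * 5})
        call = call_fate(group(), table, {})
        assert call.fate == "dead"
        assert call.expressed_copies == []

    def test_single_expressed_copy_is_nonfunctionalization(self):
        table = table_from({"c1": [50, 60, 40, 50, 55], "c2": [0] * 5})
        call = call_fate(group(), table, {"c1": 0.2, "c2": 0.3})
        assert call.fate == "nonfunctionalization"
        assert call.expressed_copies == ["c1"]

    def test_disjoint_tissue_patterns_are_subfunctionalization(self):
        table = table_from({
            "c1": [120, 1, 0, 20, 20],   # leaf-specific
            "c2": [0, 130, 2, 22, 21],   # root-specific
        })
        call = call_fate(group(), table, {"c1": 0.2, "c2": 0.3})
        assert call.fate == "subfunctionalization"
        assert call.specificity["c1"] == frozenset({"leaf"})
        assert call.specificity["c2"] == frozenset({"root"})

    def test_positive_selection_takes_precedence_over_subfunc(self):
        table = table_from({
            "c1": [120, 1, 0, 20, 20],
            "c2": [0, 130, 2, 22, 21],
        })
        call = call_fate(group(), table, {"c1": 1.4, "c2": 0.3})
        assert call.fate == "neofunctionalization"
        flipped = call_fate(group(), table, {"c1": 1.4, "c2": 0.3},
                            neo_before_subfunc=False)
        assert flipped.fate == "subfunctionalization"

    def test_coexpressed_copies_without_selection_are_unclassified(self):
        table = table_from({"c1": [50] * 5, "c2": [55] * 5})
        call = call_fate(group(), table, {"c1": 0.2, "c2": 0.3})
        assert call.fate == "unclassified"

    def test_boundary_ratio_of_one_is_not_neo(self):
        table = table_from({"c1": [50] * 5, "c2": [55] * 5})
        call = call_fate(group(), table, {"c1": 1.0, "c2": 1.0})
        assert call.fate == "unclassified"

    def test_copy_order_invariance(self):
        table = table_from({
            "c1": [120, 1, 0, 20, 20],
            "c2": [0, 130, 2, 22, 21],
            "c3": [40, 40, 40, 40, 40],
        })
        ratios = {"c1": 0.1, "c2": 0.5, "c3": 0.9}
        fates = {
            call_fate(group(copies=perm), table, ratios).fate
            for perm in (["c1", "c2", "c3"], ["c3", "c1", "c2"], ["c2", "c3", "c1"])
        }
        assert len(fates) == 1

    def test_missing_copy_is_an_error_naming_it(self):
        table = table_from({"c1": [1] * 5})
        with pytest.raises(ValidationError, match="c2"):
            call_fate(group(), table, {})

    def test_fates_are_mutually_exclusive_and_exhaustive(self, small_dataset):
        from syntepoch.divergence import kaks_ratio

        ds = small_dataset
        valid = {"dead", "nonfunctionalization", "subfunctionalization",
                 "neofunctionalization", "unclassified"}
        count = 0
        for s, rec in list(ds.truth.fates.items())[:120]:
            g = HomoeologGroup(subject_gene=s, copies=rec["copies"])
            ratios = {q: kaks_ratio(ds.truth.pair_ka[(q, s)], ds.truth.pair_ks[(q, s)])
                      for q in rec["copies"]}
            assert call_fate(g, ds.expression, ratios).fate in valid
            count += 1
        assert count > 50


class TestFateReport:
    def make_call(self, fate, n):
        from syntepoch.gene_fate import FateCall

        return FateCall("s", n, fate, [], {}, math.nan)

    def test_matrix_counts_by_copy_number(self):
        calls = [self.make_call("nonfunctionalization", 2)] * 2
        calls += [self.make_call("subfunctionalization", 3)] * 3
        rep = fate_report(calls)
        m = rep["matrix"]
        assert m.loc["nonfunctionalization", "two"] == 2
        assert m.loc["subfunctionalization", "three"] == 3
        assert m.loc["total", "two"] == 2
        assert m.loc["total", "three"] == 3

    def test_empty_calls_give_zero_matrix(self):
        rep = fate_report([])
        assert (rep["matrix"].to_numpy() == 0).all()

    def test_dead_and_unclassified_reported_separately(self):
        calls = [self.make_call("dead", 2), self.make_call("unclassified", 3),
                 self.make_call("subfunctionalization", 2)]
        rep = fate_report(calls)
        assert rep["dead"] == 1
        assert rep["unclassified"] == 1
        assert rep["matrix"].loc["total", "two"] == 1
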