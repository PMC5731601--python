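"""Precision/recall/F-measure and abundance-profile correlation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clior.io import UNASSIGNED, AssignmentTable
from clior.metrics import AbundanceProfile, EvalReport, abundance, evaluate, pearson_abundance


def tables_from(pred_labels, truth_labels):
    ids = [f"r{i}" for i in range(len(truth_labels))]
    pred = AssignmentTable("species", dict(zip(ids, pred_labels)))
    truth = AssignmentTable("species", dict(zip(ids, truth_labels)))
    return pred, truth


class TestEvaluate:
    def test_perfect_classifier(self):
        pred, truth = tables_from(["A", "B", "A"], ["A", "B", "A"])
        report = evaluate(pred, truth)
        assert (report.precision, report.recall, report.f_measure) == (1.0, 1.0, 1.0)

    def test_textbook_counts(self):
        # N=100, Y=40, X=30 -> P=0.75, R=0.30, F=2*0.75*0.30/1.05
        truth_labels = ["T"] * 100
        pred_labels = ["T"] * 30 + ["WRONG"] * 10 + [UNASSIGNED] * 60
        report = evaluate(*tables_from(pred_labels, truth_labels))
        assert report.n == 100 and report.assigned == 40 and report.correct == 30
        assert report.precision == pytest.approx(0.75)
        assert report.recall == pytest.approx(0.30)
        assert report.f_measure == pytest.approx(2 * 0.75 * 0.30 / 1.05)

    def test_nothing_assigned_is_all_zero(self):
        report = evaluate(*tables_from([UNASSIGNED] * 5, ["A"] * 5))
        assert (report.precision, report.recall, report.f_measure) == (0.0, 0.0, 0.0)

    def test_read_set_mismatch_raises(self):
        pred = AssignmentTable("species", {"r0": "A"})
        truth = AssignmentTable("species", {"r1": "A"})
        with pytest.raises(ValueError):
            evaluate(pred, truth)

    def test_order_invariance(self):
        labels_t = ["A", "B", "C", "A"]
        labels_p = ["A", UNASSIGNED, "C", "B"]
        fwd = evaluate(*tables_from(labels_p, labels_t))
        ids = [f"r{i}" for i in range(4)][::-1]
        rev = evaluate(
            AssignmentTable("species", dict(zip(ids, labels_p[::-1]))),
            AssignmentTable("species", dict(zip(ids, labels_t[::-1]))),
        )
        assert fwd == rev

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    def test_f_is_harmonic_mean(self, n_extra, y_extra, x):
        x_, y, n = x, x + y_extra, x + y_extra + n_extra
        report = EvalReport(n=n, assigned=y, correct=x_)
        p, r, f = report.precision, report.recall, report.f_measure
        assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12
        if p == r:
            assert f == pytest.approx(p)


class TestAbundance:
    def test_counting(self):
        table = AssignmentTable(
            "species", {"r0": "A", "r1": "A", "r2": "B", "r3": UNASSIGNED}
        )
        profile = abundance(table)
        assert profile.proportions == pytest.approx({"A": 2 / 3, "B": 1 / 3})

    def test_of_all_reads_denominator(self):
        table = AssignmentTable("species", {"r0": "A", "r1": UNASSIGNED})
        assert abundance(table, of_all_reads=True).proportions == {"A": 0.5}

    def test_single_taxon(self):
        assert abundance(AssignmentTable("g", {"r0": "A"})).proportions == {"A": 1.0}

    def test_all_unassigned_warns_empty(self):
        with pytest.warns(UserWarning):
            profile = abundance(AssignmentTable("g", {"r0": UNASSIGNED}))
        assert profile.proportions == {}

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(list("ABCDE"), size=500)
        table = AssignmentTable("species", {f"r{i}": l for i, l in enumerate(labels)})
        assert sum(abundance(table).proportions.values()) == pytest.approx(1.0, abs=1e-12)


class TestPearson:
    def test_identical_profiles(self):
        p = AbundanceProfile("species", {"A": 0.7, "B": 0.2, "C": 0.1})
        assert pearson_abundance(p, p) == pytest.approx(1.0)

    def test_reversed_two_taxon_profile(self):
        a = AbundanceProfile("species", {"A": 0.8, "B": 0.2})
        b = AbundanceProfile("species", {"A": 0.2, "B": 0.8})
        assert pearson_abundance(a, b) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(12)
        x = rng.dirichlet(np.ones(5))
        y = rng.dirichlet(np.ones(5))
        taxa = list("ABCDE")
        r = pearson_abundance(
            AbundanceProfile("species", dict(zip(taxa, x))),
            AbundanceProfile("species", dict(zip(taxa, y))),
        )
        expected = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_union_of_taxa_zero_filled(self):
        a = AbundanceProfile("species", {"A": 1.0})
        b = AbundanceProfile("species", {"B": 1.0})
        assert pearson_abundance(a, b) == pytest.approx(-1.0)

    def test_symmetry(self):
        a = AbundanceProfile("species", {"A": 0.5, "B": 0.3, "C": 0.2})
        b = AbundanceProfile("species", {"A": 0.1, "B": 0.6, "D": 0.3})
        assert pearson_abundance(a, b) == pytest.approx(pearson_abundance(b, a))

    def test_constant_profile_is_nan(self):
        a = AbundanceProfile("species", {"A": 0.5, "B": 0.5})
        b = AbundanceProfile("species", {"A": 0.9, "B": 0.1})
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(pearson_abundance(a, b))

    def test_rank_mismatch_raises(self):
        with pytest.raises(ValueError, match="rank"):
            pearson_abundance(
                AbundanceProfile("species", {"A": 1.0}),
                AbundanceProfile("genus", {"A": 1.0}),
            )
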