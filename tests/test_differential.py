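"""Fold-change classification, direction proportions, reversal, concordance."""

import numpy as np
import pandas as pd
import pytest

from m6array import (
    concordance,
    diff_expression,
    diff_level,
    diff_methylation,
    direction_proportions,
    reversal_intersection,
)
from m6array.differential import read_diff_table, reversal_pct, write_diff_table
from m6array.errors import UniverseMismatchError
from m6array.io import DesignTable
from m6array.quantify import QuantTable

from conftest import make_diff_table


def _quant_from_quantity(quantity: pd.DataFrame, expression: pd.DataFrame | None = None):
    if expression is None:
        expression = quantity * 2.0
    meta = pd.DataFrame(
        {"gene_symbol": [f"g_{t}" for t in quantity.index], "rna_class": "mRNA"},
        index=quantity.index,
    )
    return QuantTable(
        level=quantity / expression, quantity=quantity, expression=expression, meta=meta
    )


def _design(groups_reps):
    rows = {
        f"{g}_{r}": {"group": g, "replicate": r}
        for g, n in groups_reps for r in range(1, n + 1)
    }
    return DesignTable(table=pd.DataFrame.from_dict(rows, orient="index"))


class TestDiffMethylation:
    def test_twofold_change_is_hyper(self):
        quantity = pd.DataFrame(
            {"A_1": [200.0], "A_2": [200.0], "B_1": [100.0], "B_2": [100.0]},
            index=["t1"],
        )
        diff = diff_methylation(
            _quant_from_quantity(quantity), _design([("A", 2), ("B", 2)]), "A", "B"
        )
        assert diff.frame.at["t1", "log2fc"] == pytest.approx(1.0)
        assert diff.frame.at["t1", "class"] == "hyper"

    def test_exact_threshold_fold_change_is_inclusive(self):
        """A fold change of exactly 1.5 meets the >= 1.5 rule."""
        quantity = pd.DataFrame(
            {"A_1": [150.0, 100.0 / 1.5], "A_2": [150.0, 100.0 / 1.5],
             "B_1": [100.0, 100.0], "B_2": [100.0, 100.0]},
            index=["t1", "t2"],
        )
        diff = diff_methylation(
            _quant_from_quantity(quantity), _design([("A", 2), ("B", 2)]), "A", "B"
        )
        assert diff.frame.at["t1", "class"] == "hyper"
        assert diff.frame.at["t2", "class"] == "hypo"

    def test_log2fc_is_mean_difference(self):
        rng = np.random.default_rng(0)
        quantity = pd.DataFrame(
            rng.lognormal(5, 1, (10, 4)),
            index=[f"t{i}" for i in range(10)],
            columns=["A_1", "A_2", "B_1", "B_2"],
        )
        diff = diff_methylation(
            _quant_from_quantity(quantity), _design([("A", 2), ("B", 2)]), "A", "B"
        )
        assert np.allclose(
            diff.frame["log2fc"],
            diff.frame["mean_log2_test"] - diff.frame["mean_log2_ref"],
            atol=1e-9,
        )

    def test_unknown_group_error_lists_available(self):
        quantity = pd.DataFrame(
            {"A_1": [1.0], "A_2": [1.0], "B_1": [1.0], "B_2": [1.0]}, index=["t1"]
        )
        with pytest.raises(KeyError, match="A.*B|available"):
            diff_methylation(
                _quant_from_quantity(quantity), _design([("A", 2), ("B", 2)]), "C", "B"
            )

    def test_swapping_groups_negates_fc_and_swaps_classes(self, noisefree_quant):
        quant, design, _ = noisefree_quant
        fwd = diff_methylation(quant, design, "FS", "Ctrl")
        rev = diff_methylation(quant, design, "Ctrl", "FS")
        assert np.allclose(fwd.frame["log2fc"], -rev.frame["log2fc"], atol=1e-9)
        swapped = rev.frame["class"].map(
            {"hyper": "hypo", "hypo": "hyper", "unchanged": "unchanged"}
        )
        assert (fwd.frame["class"] == swapped).all()

    def test_noisefree_recovery_matches_ground_truth(self, noisefree_quant):
        quant, design, truth = noisefree_quant
        for test, ref in [("FS", "Ctrl"), ("FS-DBS", "Ctrl"), ("FS-DBS", "FS")]:
            diff = diff_methylation(quant, design, test, ref)
            expected = truth.classes[f"{test}_vs_{ref}"].reindex(diff.frame.index)
            assert (diff.frame["class"] == expected).all()

    def test_noisefree_expression_recovery(self, noisefree_quant):
        quant, design, truth = noisefree_quant
        for test, ref in [("FS", "Ctrl"), ("FS-DBS", "FS")]:
            diff = diff_expression(quant, design, test, ref)
            expected = truth.expr_classes[f"{test}_vs_{ref}"].reindex(diff.frame.index)
            assert (diff.frame["class"] == expected).all()


class TestDirectionProportions:
    def test_eighty_twenty(self):
        classes = pd.Series(
            ["hyper"] * 80 + ["hypo"] * 20 + ["unchanged"] * 50,
            index=[f"t{i}" for i in range(150)],
        )
        props = direction_proportions(make_diff_table(classes))
        assert (props.pct_up, props.pct_down) == (80.0, 20.0)

    def test_all_hyper(self):
        classes = pd.Series(["hyper"] * 7, index=[f"t{i}" for i in range(7)])
        props = direction_proportions(make_diff_table(classes))
        assert (props.pct_up, props.pct_down) == (100.0, 0.0)

    def test_no_changed_transcripts_yields_empty_summary(self):
        classes = pd.Series(["unchanged"] * 5, index=[f"t{i}" for i in range(5)])
        props = direction_proportions(make_diff_table(classes))
        assert props.is_empty and props.pct_up is None

    def test_matches_brute_force_count_on_random_fixture(self):
        rng = np.random.default_rng(23)
        classes = pd.Series(
            rng.choice(["hyper", "hypo", "unchanged"], size=50, p=[0.3, 0.2, 0.5]),
            index=[f"t{i}" for i in range(50)],
        )
        props = direction_proportions(make_diff_table(classes))
        n_hyper = sum(c == "hyper" for c in classes)
        n_hypo = sum(c == "hypo" for c in classes)
        assert props.n_changed == n_hyper + n_hypo
        assert props.pct_up == pytest.approx(
            round(100 * n_hyper / (n_hyper + n_hypo), 1), abs=0.051
        )


class TestReversalIntersection:
    @staticmethod
    def _paired_tables(n_a, n_b, n_both, direction, n_total=12000):
        """Two classification tables with |A|=n_a, |B|=n_b, |A∩B|=n_both."""
        ids = [f"t{i:05d}" for i in range(n_total)]
        cls_a_label, cls_b_label = (
            ("hyper", "hypo") if direction == "attenuation" else ("hypo", "hyper")
        )
        cls_a = pd.Series("unchanged", index=ids)
        cls_b = pd.Series("unchanged", index=ids)
        cls_a.iloc[:n_a] = cls_a_label
        cls_b.iloc[n_a - n_both : n_a - n_both + n_b] = cls_b_label
        table_a = make_diff_table(cls_a, test="FS", ref="Ctrl")
        table_b = make_diff_table(cls_b, test="FS-DBS", ref="FS")
        return table_a, table_b

    def test_attenuation_counts_from_reported_set_sizes(self):
        a, b = self._paired_tables(3734, 2605, 613, "attenuation")
        summary = reversal_intersection(a, b, "attenuation")
        assert (summary.size_a, summary.size_b) == (3734, 2605)
        assert summary.intersection == 613
        assert summary.union == 5726
        assert summary.pct_of_union == 10.7

    def test_enhancement_counts_from_reported_set_sizes(self):
        a, b = self._paired_tables(1956, 7714, 1063, "enhancement")
        summary = reversal_intersection(a, b, "enhancement")
        assert summary.union == 8607
        assert summary.pct_of_union == 12.4

    def test_disjoint_sets(self):
        a, b = self._paired_tables(10, 20, 0, "attenuation", n_total=100)
        summary = reversal_intersection(a, b, "attenuation")
        assert summary.intersection == 0
        assert summary.pct_of_union == 0.0

    def test_union_identity_and_bounds(self):
        a, b = self._paired_tables(40, 25, 7, "enhancement", n_total=200)
        s = reversal_intersection(a, b, "enhancement")
        assert s.union == s.size_a + s.size_b - s.intersection
        assert s.intersection <= min(s.size_a, s.size_b)

    def test_mismatched_universes_error(self):
        a, _ = self._paired_tables(5, 5, 2, "attenuation", n_total=50)
        b_small, _ = self._paired_tables(5, 5, 2, "attenuation", n_total=40)
        with pytest.raises(UniverseMismatchError, match="universe"):
            reversal_intersection(a, b_small, "attenuation")

    def test_lncrna_excluded_from_mrna_counts(self):
        ids = [f"t{i}" for i in range(10)]
        cls = pd.Series(["hyper"] * 10, index=ids)
        a = make_diff_table(cls, test="FS", ref="Ctrl")
        b = make_diff_table(
            pd.Series(["hypo"] * 10, index=ids), test="FS-DBS", ref="FS"
        )
        a.frame.loc[ids[:4], "rna_class"] = "lncRNA"
        b.frame.loc[ids[:4], "rna_class"] = "lncRNA"
        summary = reversal_intersection(a, b, "attenuation")
        assert summary.size_a == summary.size_b == summary.intersection == 6

    def test_attenuation_and_enhancement_members_disjoint(self, noisefree_quant):
        quant, design, _ = noisefree_quant
        ab = diff_methylation(quant, design, "FS", "Ctrl")
        cb = diff_methylation(quant, design, "FS-DBS", "FS")
        att = reversal_intersection(ab, cb, "attenuation")
        enh = reversal_intersection(ab, cb, "enhancement")
        assert not set(att.members) & set(enh.members)

    def test_pct_invariant_under_id_relabeling(self):
        a, b = self._paired_tables(30, 20, 5, "attenuation", n_total=100)
        base = reversal_intersection(a, b, "attenuation").pct_of_union
        relabel = {t: f"x{t}" for t in a.frame.index}
        a2 = make_diff_table(
            a.frame["class"].rename(index=relabel), test="FS", ref="Ctrl"
        )
        b2 = make_diff_table(
            b.frame["class"].rename(index=relabel), test="FS-DBS", ref="FS"
        )
        assert reversal_intersection(a2, b2, "attenuation").pct_of_union == base

    def test_rounding_is_half_up(self):
        assert reversal_pct(1235, 10000) == 12.4
        assert reversal_pct(1234, 10000) == 12.3


class TestConcordance:
    def test_identical_vectors_correlate_perfectly(self):
        ids = [f"t{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        fc = pd.Series(rng.normal(size=20), index=ids)
        classes = pd.Series("unchanged", index=ids)
        base = make_diff_table(classes)
        q = base.frame.copy()
        q["log2fc"] = fc
        from m6array.differential import DiffTable

        dq = DiffTable("T", "R", "m6a_quantity", 1.5, q)
        de = DiffTable("T", "R", "expression", 1.5, q.copy())
        dl = DiffTable("T", "R", "m6a_level", 1.5, q.copy())
        out = concordance(dq, de, dl)
        assert out["quantity_vs_expression"]["rho"] == pytest.approx(1.0)

    def test_too_few_transcripts_error(self):
        ids = ["t1", "t2"]
        classes = pd.Series("unchanged", index=ids)
        d = make_diff_table(classes)
        with pytest.raises(UniverseMismatchError, match="3"):
            concordance(d, d, d)


def test_diff_table_roundtrip(tmp_path, noisefree_quant):
    quant, design, _ = noisefree_quant
    diff = diff_methylation(quant, design, "FS", "Ctrl")
    path = tmp_path / "diff.tsv"
    write_diff_table(diff, path)
    back = read_diff_table(path)
    assert back.test == "FS" and back.ref == "Ctrl"
    assert back.fc_threshold == diff.fc_threshold
    assert (back.frame["class"] == diff.frame["class"]).all()
    assert np.allclose(back.frame["log2fc"], diff.frame["log2fc"], atol=1e-12)
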