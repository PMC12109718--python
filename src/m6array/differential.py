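"""Differential methylation/expression classification and reversal analysis.

Transcripts are classified between two groups by the fold change of
group-mean log2 signal (a geometric mean on the linear scale): with
``fc_threshold`` = 1.5, a transcript is hyper-methylated when
log2fc >= log2(1.5), hypo-methylated when log2fc <= -log2(1.5), and
unchanged otherwise.  The boundary is inclusive.  No per-transcript
variance statistic is computed — selection is fold-change-only, which is
why every group needs at least two replicates for the mean to be
meaningful.

The directional reversal analysis intersects two classified comparisons:
"attenuation" collects transcripts pushed up by the insult
(hyper in test-vs-control) and pulled back down by the treatment
(hypo in treatment-vs-test); "enhancement" is the mirror image.  The
summary reports the intersection as a percentage of the union of the two
sets, rounded half-up to one decimal.  These counts are computed on
mRNAs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UniverseMismatchError
from .io import DesignTable
from .quantify import QuantTable

METHYLATION_LABELS = ("hyper", "hypo", "unchanged")
EXPRESSION_LABELS = ("up", "down", "unchanged")

Direction = Literal["attenuation", "enhancement"]


#: slack when comparing a log2 fold change against the threshold, so that
#: a fold change of exactly fc_threshold lands on the inclusive side even
#: when the two log2 computations differ in the last ulp
_BOUNDARY_ATOL = 1e-12


def classify_log2fc(
    log2fc: pd.Series, fc_threshold: float = 1.5, labels: tuple[str, str, str] = METHYLATION_LABELS
) -> pd.Series:
    """Three-way classification of log2 fold changes, boundary inclusive."""
    cut = np.log2(fc_threshold) - _BOUNDARY_ATOL
    up, down, unchanged = labels
    out = pd.Series(unchanged, index=log2fc.index, dtype=object)
    out[log2fc >= cut] = up
    out[log2fc <= -cut] = down
    return out


@dataclass(frozen=True)
class DiffTable:
    """Per-transcript log2 fold change and class for one group comparison."""

    test: str
    ref: str
    variable: str  # m6a_quantity | expression | m6a_level
    fc_threshold: float
    frame: pd.DataFrame  # mean_log2_test, mean_log2_ref, log2fc, class, gene_symbol, rna_class

    @property
    def comparison(self) -> str:
        return f"{self.test}_vs_{self.ref}"

    @property
    def labels(self) -> tuple[str, str, str]:
        return EXPRESSION_LABELS if self.variable == "expression" else METHYLATION_LABELS

    def members(self, cls: str, mrna_only: bool = False) -> pd.Index:
        mask = self.frame["class"] == cls
        if mrna_only:
            mask &= self.frame["rna_class"] == "mRNA"
        return self.frame.index[mask]

    def class_counts(self) -> dict[str, int]:
        counts = self.frame["class"].value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in self.labels}


def _diff(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    design: DesignTable,
    test: str,
    ref: str,
    variable: str,
    fc_threshold: float,
    labels: tuple[str, str, str],
) -> DiffTable:
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    test_samples = design.samples_of(test)
    ref_samples = design.samples_of(ref)
    log2v = np.log2(values)
    mean_test = log2v[test_samples].mean(axis=1)
    mean_ref = log2v[ref_samples].mean(axis=1)
    log2fc = mean_test - mean_ref
    frame = pd.DataFrame(
        {
            "gene_symbol": meta["gene_symbol"],
            "rna_class": meta["rna_class"],
            "mean_log2_test": mean_test,
            "mean_log2_ref": mean_ref,
            "log2fc": log2fc,
            "class": classify_log2fc(log2fc, fc_threshold, labels),
        }
    )
    return DiffTable(test=test, ref=ref, variable=variable, fc_threshold=fc_threshold, frame=frame)


def diff_methylation(
    quant: QuantTable,
    design: DesignTable,
    test: str,
    ref: str,
    fc_threshold: float = 1.5,
) -> DiffTable:
    """Hyper/hypo classification of m6A quantity between two groups."""
    return _diff(
        quant.quantity, quant.meta, design, test, ref,
        "m6a_quantity", fc_threshold, METHYLATION_LABELS,
    )


def diff_expression(
    quant: QuantTable,
    design: DesignTable,
    test: str,
    ref: str,
    fc_threshold: float = 1.5,
) -> DiffTable:
    """Up/down classification of expression level between two groups."""
    return _diff(
        quant.expression, quant.meta, design, test, ref,
        "expression", fc_threshold, EXPRESSION_LABELS,
    )


def diff_level(
    quant: QuantTable,
    design: DesignTable,
    test: str,
    ref: str,
    fc_threshold: float = 1.5,
) -> DiffTable:
    """Fold-change table of the methylated fraction (for concordance checks)."""
    return _diff(
        quant.level, quant.meta, design, test, ref,
        "m6a_level", fc_threshold, METHYLATION_LABELS,
    )


@dataclass(frozen=True)
class DirectionSummary:
    """Proportions of up- vs down-classified transcripts among changed ones."""

    n_changed: int
    pct_up: float | None  # hyper or up
    pct_down: float | None  # hypo or down

    @property
    def is_empty(self) -> bool:
        return self.n_changed == 0


def direction_proportions(diff: DiffTable) -> DirectionSummary:
    """Percent hyper (up) and hypo (down) among changed transcripts.

    Returns an explicit empty summary when nothing changed rather than
    dividing by zero.  Percentages are rounded half-up to one decimal and
    sum to 100 before rounding.
    """
    up_label, down_label, _ = diff.labels
    counts = diff.class_counts()
    n_up, n_down = counts[up_label], counts[down_label]
    n_changed = n_up + n_down
    if n_changed == 0:
        return DirectionSummary(n_changed=0, pct_up=None, pct_down=None)
    return DirectionSummary(
        n_changed=n_changed,
        pct_up=_round1(100 * n_up / n_changed),
        pct_down=_round1(100 * n_down / n_changed),
    )


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReversalSummary:
    """One directional reversal intersection between two comparisons.

    ``pct_of_union`` = 100 * |A ∩ B| / |A ∪ B|, rounded half-up to one
    decimal; A and B are the two directional mRNA sets.
    """

    direction: Direction
    comparison_a: str
    comparison_b: str
    size_a: int
    size_b: int
    intersection: int
    union: int
    pct_of_union: float
    members: tuple[str, ...]
    member_genes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "comparison_a": self.comparison_a,
            "comparison_b": self.comparison_b,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "intersection": self.intersection,
            "union": self.union,
            "pct_of_union": self.pct_of_union,
            "members": list(self.members),
            "member_genes": list(self.member_genes),
        }


def reversal_pct(intersection: int, union: int) -> float:
    """Exact rational percentage of union, rounded half-up to one decimal."""
    if union == 0:
        return 0.0
    pct = Decimal(100 * intersection) / Decimal(union)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def reversal_intersection(
    diff_ab: DiffTable,
    diff_cb: DiffTable,
    direction: Direction,
    mrna_only: bool = True,
) -> ReversalSummary:
    """Intersect directional transcript sets from two comparisons.

    direction="attenuation": A = hyper in ``diff_ab``, B = hypo in
    ``diff_cb`` (insult-induced gains pulled back by treatment);
    direction="enhancement": A = hypo in ``diff_ab``, B = hyper in
    ``diff_cb``.
    """
    if direction not in ("attenuation", "enhancement"):
        raise ValueError(f"direction must be attenuation or enhancement, got {direction!r}")
    if not diff_ab.frame.index.equals(diff_cb.frame.index):
        missing = diff_ab.frame.index.symmetric_difference(diff_cb.frame.index)
        raise UniverseMismatchError(
            f"comparisons cover different transcript universes; "
            f"{len(missing)} mismatched, e.g. {missing.tolist()[:5]}"
        )
    if direction == "attenuation":
        cls_a, cls_b = "hyper", "hypo"
    else:
        cls_a, cls_b = "hypo", "hyper"
    set_a = diff_ab.members(cls_a, mrna_only=mrna_only)
    set_b = diff_cb.members(cls_b, mrna_only=mrna_only)
    inter = set_a.intersection(set_b)
    union = len(set_a) + len(set_b) - len(inter)
    genes = diff_ab.frame.loc[inter, "gene_symbol"]
    return ReversalSummary(
        direction=direction,
        comparison_a=diff_ab.comparison,
        comparison_b=diff_cb.comparison,
        size_a=len(set_a),
        size_b=len(set_b),
        intersection=len(inter),
        union=union,
        pct_of_union=reversal_pct(len(inter), union),
        members=tuple(sorted(inter)),
        member_genes=tuple(sorted(set(genes))),
    )


def concordance(
    diff_quantity: DiffTable,
    diff_expression: DiffTable,
    diff_level: DiffTable,
) -> dict[str, dict[str, float]]:
    """Spearman rank correlation of log2fc vectors between measures.

    Returns ``{"quantity_vs_expression": {"rho", "p"},
    "level_vs_expression": {...}}``.  Fold changes are heavy-tailed, so a
    rank correlation is used.
    """
    out = {}
    for name, diff in (
        ("quantity_vs_expression", diff_quantity),
        ("level_vs_expression", diff_level),
    ):
        if not diff.frame.index.equals(diff_expression.frame.index):
            raise UniverseMismatchError(f"{name}: transcript universes differ")
        if len(diff.frame) < 3:
            raise UniverseMismatchError("need >= 3 shared transcripts for correlation")
        rho, p = stats.spearmanr(
            diff.frame["log2fc"].to_numpy(), diff_expression.frame["log2fc"].to_numpy()
        )
        out[name] = {"rho": float(rho), "p": float(p)}
    return out


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def write_diff_table(diff: DiffTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# test={diff.test}\tref={diff.ref}\tvariable={diff.variable}"
            f"\tfc_threshold={diff.fc_threshold}\n"
        )
        out = diff.frame.copy()
        out.index.name = "transcript_id"
        out.to_csv(fh, sep="\t")


def read_diff_table(path: str | Path) -> DiffTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise UniverseMismatchError(f"{path}: missing '# test=...' metadata line")
        meta = dict(kv.split("=", 1) for kv in header[1:].strip().split("\t"))
        frame = pd.read_csv(fh, sep="\t", index_col=0, keep_default_na=False)
    for col in ("mean_log2_test", "mean_log2_ref", "log2fc"):
        frame[col] = frame[col].astype(float)
    return DiffTable(
        test=meta["test"],
        ref=meta["ref"],
        variable=meta["variable"],
        fc_threshold=float(meta["fc_threshold"]),
        frame=frame,
    )
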