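"""Per-transcript m6A quantification from normalized IP/Sup signals.

For every transcript and sample, with IP and Sup the linear-scale
normalized channel intensities averaged over the transcript's selected
probes:

* ``m6a_quantity`` = IP — the amount of methylated copies,
* ``expression`` = IP + Sup — total abundance (methylated + unmethylated),
* ``m6a_level`` = IP / (IP + Sup) — the methylated fraction, in [0, 1].

These definitions make the conservation identities
``expression = m6a_quantity + unmethylated`` and
``m6a_level = m6a_quantity / expression`` hold exactly, and make the
level invariant to any rescaling applied equally to both channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import UniverseMismatchError
from .io import ProbePanel
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantTable:
    """Per-transcript, per-sample m6A level, quantity and expression.

    The three frames share a transcript index and sample columns; ``meta``
    carries gene_symbol and rna_class per transcript.
    """

    level: pd.DataFrame
    quantity: pd.DataFrame
    expression: pd.DataFrame
    meta: pd.DataFrame

    @property
    def transcripts(self) -> pd.Index:
        return self.quantity.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.quantity.columns


def compute_quant(
    ip: NormalizedMatrix,
    sup: NormalizedMatrix,
    panel: ProbePanel,
    targets: pd.Index,
) -> QuantTable:
    """Collapse selected probes to transcripts and derive the three measures.

    Multi-probe transcripts are collapsed by the mean of linear-scale probe
    intensities per channel (ratio of means, not mean of ratios).
    Transcripts whose probes were all filtered out are omitted and logged.
    """
    if not ip.values.index.equals(sup.values.index):
        raise UniverseMismatchError("IP and Sup matrices must share probe indices")
    if not ip.values.columns.equals(sup.values.columns):
        raise UniverseMismatchError("IP and Sup matrices must share sample columns")
    if len(targets) == 0:
        raise UniverseMismatchError("empty probe target set")

    keep = [p for p in targets if p in ip.values.index]
    tx_of = panel.table.loc[keep, "transcript_id"]

    ip_lin = (2.0 ** ip.values.loc[keep]).groupby(tx_of).mean()
    sup_lin = (2.0 ** sup.values.loc[keep]).groupby(tx_of).mean()

    dropped = panel.table.loc[
        ~panel.table["is_spikein"].astype(bool), "transcript_id"
    ]
    omitted = sorted(set(dropped) - set(ip_lin.index))
    if omitted:
        logger.info(
            "%d transcripts omitted (no selected probes), e.g. %s",
            len(omitted),
            omitted[:5],
        )

    expression = ip_lin + sup_lin
    level = ip_lin / expression

    # one annotation row per transcript (first probe wins; panels map
    # probes of one transcript to one gene)
    meta = (
        panel.table.loc[keep, ["transcript_id", "gene_symbol", "rna_class"]]
        .drop_duplicates("transcript_id")
        .set_index("transcript_id")
        .loc[ip_lin.index]
    )
    return QuantTable(level=level, quantity=ip_lin, expression=expression, meta=meta)


def write_quant_table(quant: QuantTable, path: str | Path) -> None:
    out = quant.meta.copy()
    for sid in quant.sample_ids:
        out[f"{sid}.level"] = quant.level[sid]
        out[f"{sid}.quantity"] = quant.quantity[sid]
        out[f"{sid}.expression"] = quant.expression[sid]
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_quant_table(path: str | Path) -> QuantTable:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    sample_ids = [c[: -len(".level")] for c in df.columns if c.endswith(".level")]
    meta = df[["gene_symbol", "rna_class"]]
    def _grab(suffix: str) -> pd.DataFrame:
        sub = df[[f"{s}.{suffix}" for s in sample_ids]].astype(float)
        sub.columns = sample_ids
        return sub
    return QuantTable(
        level=_grab("level"),
        quantity=_grab("quantity"),
        expression=_grab("expression"),
        meta=meta,
    )
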