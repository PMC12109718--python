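"""Probe selection by detection flags and spike-in normalization.

Selection follows the array vendor's "All Targets" rule: a probe is kept
if it was called present (P), marginal (M) or quality control (QC) in at
least one sample of either fraction.  Spike-in control probes are never
part of the selected biological set but are always retained internally —
they are what normalization is anchored to.

Normalization puts every array of a channel on a common intensity scale:
per sample, the mean log2 intensity of the spike-in controls is shifted
to the grand mean of those per-sample means, and the same shift is
applied to all probes of that sample.  This is a per-sample monotone
transform, so probe ordering within a sample is preserved, and it is
idempotent: a matrix whose spike-in means already coincide gets offset 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NormalizationError, SelectionError
from .io import ChannelMatrix, DesignTable, ProbePanel

SELECTABLE_FLAGS = ("P", "M", "QC")

#: raw fluorescence below this is treated as scanner background before log2
INTENSITY_FLOOR = 1.0


@dataclass(frozen=True)
class NormalizedMatrix:
    """Log2, spike-in-normalized intensities for one fraction.

    ``offsets`` records the per-sample log2 shift that was subtracted;
    after normalization every sample's mean log2 spike-in intensity
    equals the grand mean across samples.
    """

    fraction: str
    values: pd.DataFrame  # probes x samples, log2 units
    offsets: pd.Series  # per sample, log2 units

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def select_targets(
    flags_ip: pd.DataFrame,
    flags_sup: pd.DataFrame,
    panel: ProbePanel,
    design: DesignTable | None = None,
) -> pd.Index:
    """Probes with flag P, M or QC in >= 1 sample of either fraction.

    Spike-in probes are excluded from the returned set (they are controls,
    not biology).  Raises :class:`SelectionError` if nothing passes.
    """
    if not flags_ip.index.equals(flags_sup.index):
        raise SelectionError("IP and Sup flag matrices must share probe indices")
    if design is not None:
        expected = set(design.table.index)
        for name, flags in (("IP", flags_ip), ("Sup", flags_sup)):
            if set(flags.columns) != expected:
                raise SelectionError(
                    f"{name} flag samples {sorted(flags.columns)} do not match "
                    f"design samples {sorted(expected)}"
                )
    detected = (
        flags_ip.isin(SELECTABLE_FLAGS).any(axis=1)
        | flags_sup.isin(SELECTABLE_FLAGS).any(axis=1)
    )
    selected = flags_ip.index[detected]
    selected = selected.difference(panel.spikein_ids, sort=False)
    # preserve original probe order
    selected = flags_ip.index[flags_ip.index.isin(selected) ]
    if len(selected) == 0:
        raise SelectionError("no probes pass selection (flag P/M/QC in >= 1 sample)")
    return selected


def normalize_spikein(raw: ChannelMatrix, panel: ProbePanel) -> NormalizedMatrix:
    """Normalize one channel against its spike-in controls.

    values = log2(max(raw, floor)) - offset[sample], with
    offset[sample] = mean log2 spike-in of that sample - grand mean of
    those per-sample means.
    """
    spikes = panel.spikein_ids.intersection(raw.values.index)
    if len(spikes) < 2:
        raise NormalizationError(
            f"need >= 2 spike-in probes for normalization, found {len(spikes)}"
        )
    spike_flags = raw.flags.loc[spikes]
    absent = spike_flags == "A"
    if absent.to_numpy().any():
        where = [
            (p, s)
            for p in spikes
            for s in raw.flags.columns
            if raw.flags.at[p, s] == "A"
        ]
        raise NormalizationError(
            f"spike-in probe flagged Absent; first offenders: {where[:3]}"
        )
    log2v = np.log2(raw.values.clip(lower=INTENSITY_FLOOR))
    spike_means = log2v.loc[spikes].mean(axis=0)
    offsets = spike_means - spike_means.mean()
    offsets.name = "offset"
    return NormalizedMatrix(
        fraction=raw.fraction, values=log2v.sub(offsets, axis=1), offsets=offsets
    )


def write_normalized_matrix(norm: NormalizedMatrix, path: str | Path, offsets_path: str | Path | None = None) -> None:
    out = norm.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    if offsets_path is not None:
        off = norm.offsets.to_frame()
        off.index.name = "sample_id"
        off.to_csv(offsets_path, sep="\t")


def read_normalized_matrix(path: str | Path, fraction: str, offsets_path: str | Path | None = None) -> NormalizedMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    if offsets_path is not None:
        offsets = pd.read_csv(offsets_path, sep="\t", index_col=0)["offset"].astype(float)
    else:
        offsets = pd.Series(0.0, index=values.columns, name="offset")
    return NormalizedMatrix(fraction=fraction, values=values, offsets=offsets)
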