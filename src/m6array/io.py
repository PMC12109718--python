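"""Readers and writers for all on-disk artifacts.

Every tabular artifact is tab-separated text with a header row.  Channel
matrices store one ``<sample_id>.value`` / ``<sample_id>.flag`` column pair
per sample so that one file fully describes one fraction (IP or Sup).
Gene sets use the standard GMT dialect.  Readers validate and reject
malformed input; they never silently repair it, so every reader/writer
pair is a lossless round trip for valid data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

VALID_FLAGS = ("P", "M", "A", "QC")
FRACTIONS = ("IP", "Sup")
RNA_CLASSES = ("mRNA", "lncRNA")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbePanel:
    """Probe annotations: probe -> transcript/gene, spike-in marker, RNA class.

    ``table`` is indexed by ``probe_id`` with columns ``transcript_id``,
    ``gene_symbol``, ``is_spikein`` (bool) and ``rna_class`` (mRNA/lncRNA for
    biological probes, empty for spike-ins).  Spike-in control probes carry
    no gene annotation: they are exogenous RNAs used only for normalization.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"transcript_id", "gene_symbol", "is_spikein", "rna_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"probe panel missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate probe_id in panel: {dupes[:5]}")
        spike = self.table["is_spikein"].astype(bool)
        bad = self.table.loc[spike & (self.table["gene_symbol"] != ""), :]
        if len(bad):
            raise ParseError(
                f"spike-in probes must have no gene_symbol: {bad.index.tolist()[:5]}"
            )
        bio = self.table.loc[~spike, "rna_class"]
        bad_class = bio[~bio.isin(RNA_CLASSES)]
        if len(bad_class):
            raise ParseError(
                f"unknown rna_class {bad_class.unique().tolist()} "
                f"(expected one of {RNA_CLASSES})"
            )

    @property
    def spikein_ids(self) -> pd.Index:
        return self.table.index[self.table["is_spikein"].astype(bool)]

    @property
    def target_ids(self) -> pd.Index:
        """Biological (non-spike-in) probe ids."""
        return self.table.index[~self.table["is_spikein"].astype(bool)]


@dataclass(frozen=True)
class ChannelMatrix:
    """Raw probe intensities and detection flags for one fraction.

    ``values`` are strictly positive fluorescence intensities
    (probes x samples); ``flags`` is the same-shaped matrix of Agilent-style
    detection calls: P (present), M (marginal), A (absent), QC (control).
    """

    fraction: str
    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ParseError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise ParseError("values and flags must share probe and sample indices")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(vals > 0):
            r, c = np.argwhere(~(vals > 0))[0]
            raise ParseError(
                f"non-positive intensity at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {vals[r, c]}"
            )
        flag_arr = self.flags.to_numpy(dtype=object)
        ok = np.isin(flag_arr, VALID_FLAGS)
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ParseError(
                f"unknown flag {flag_arr[r, c]!r} at probe {self.flags.index[r]!r}, "
                f"sample {self.flags.columns[c]!r} (expected one of {VALID_FLAGS})"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class DesignTable:
    """Sample sheet: sample -> experimental group and replicate number."""

    table: pd.DataFrame  # index sample_id; columns: group, replicate

    def __post_init__(self) -> None:
        required = {"group", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"design table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ParseError("duplicate sample_id in design table")
        pairs = self.table[["group", "replicate"]]
        if pairs.duplicated().any():
            raise ParseError("(group, replicate) pairs must be unique in design table")
        counts = self.table.groupby("group").size()
        small = counts[counts < 2]
        if len(small):
            raise ParseError(
                "every group needs >= 2 samples for differential analysis; "
                f"got {small.to_dict()}"
            )

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: list[str] = []
        for g in self.table["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> pd.Index:
        if group not in set(self.table["group"]):
            raise KeyError(
                f"unknown group {group!r}; available groups: {self.groups}"
            )
        return self.table.index[self.table["group"] == group]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. GO terms) for over-representation analysis."""

    sets: Mapping[str, tuple[str, ...]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ParseError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# channel matrices
# ---------------------------------------------------------------------------

def write_channel_matrix(matrix: ChannelMatrix, path: str | Path) -> None:
    out = pd.DataFrame(index=matrix.values.index)
    out.index.name = "probe_id"
    for sid in matrix.values.columns:
        out[f"{sid}.value"] = matrix.values[sid]
        out[f"{sid}.flag"] = matrix.flags[sid]
    out.to_csv(path, sep="\t")


def read_channel_matrix(path: str | Path, fraction: str) -> ChannelMatrix:
    """Read a probe x sample intensity/flag table for one fraction.

    The first column is ``probe_id``; each sample contributes a
    ``<sample_id>.value`` and ``<sample_id>.flag`` column pair.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    value_cols = [c for c in df.columns if c.endswith(".value")]
    sample_ids = [c[: -len(".value")] for c in value_cols]
    if not sample_ids:
        raise ParseError(f"{path}: no '<sample_id>.value' columns found")
    for sid in sample_ids:
        if f"{sid}.flag" not in df.columns:
            raise ParseError(f"{path}: sample {sid!r} has a value column but no flag column")
    try:
        values = df[[f"{s}.value" for s in sample_ids]].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric intensity value ({exc})") from exc
    values.columns = sample_ids
    flags = df[[f"{s}.flag" for s in sample_ids]].copy()
    flags.columns = sample_ids
    try:
        return ChannelMatrix(fraction=fraction, values=values, flags=flags)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# probe panel / design
# ---------------------------------------------------------------------------

def write_probe_panel(panel: ProbePanel, path: str | Path) -> None:
    out = panel.table.copy()
    out["is_spikein"] = out["is_spikein"].astype(bool).astype(int)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_probe_panel(path: str | Path) -> ProbePanel:
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if "is_spikein" not in df.columns:
        raise ParseError(f"{path}: missing is_spikein column")
    if not df["is_spikein"].isin(["0", "1"]).all():
        raise ParseError(f"{path}: is_spikein must be 0 or 1")
    df["is_spikein"] = df["is_spikein"] == "1"
    try:
        return ProbePanel(table=df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_design_table(design: DesignTable, path: str | Path) -> None:
    out = design.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_design_table(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"group": str, "replicate": int})
    try:
        return DesignTable(table=df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            members = tuple(m for m in fields[2:] if m)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
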