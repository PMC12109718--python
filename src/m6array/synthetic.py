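"""Synthetic two-channel m6A microarray datasets with known ground truth.

The generator emulates a three-group (Ctrl, inescapable foot shock FS, and
FS treated with deep brain stimulation FS-DBS) design with triplicate
arrays per group.  For each transcript it draws a baseline total abundance
and a baseline methylated fraction, plants group-specific shifts of the
methylated amount (the "m6A quantity") for configurable fractions of
genes, and splits the total into an immunoprecipitated (IP, methylated)
and a supernatant (Sup, unmethylated) channel so that IP + Sup equals
total abundance by construction.

All signal construction happens on the log2 scale
(gene baseline + group effect + per-array spike-in drift + replicate
noise) and is exponentiated at the end, which guarantees strictly
positive intensities.  Spike-in control probes receive the per-array
offset and noise but never any group effect, so spike-in normalization
can recover the planted biology exactly in the noise-free limit.

The FS-DBS group inherits the FS effects except for a configurable
fraction of "reversed" genes whose methylation returns to the Ctrl
baseline — the regime the reversal-intersection analysis is designed to
detect — plus optional de-novo effects of its own on genes untouched
by FS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ChannelMatrix, DesignTable, ProbePanel

#: maximum baseline methylated fraction for genes receiving an
#: expression-uncoupled upward quantity shift (keeps level * 2^effect < 1)
_LEVEL_CEILING = 0.95
_LEVEL_FLOOR = 0.05


def comparison_label(test: str, ref: str) -> str:
    return f"{test}_vs_{ref}"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated array experiment.

    ``frac_hyper`` / ``frac_hypo`` give, per non-reference group, the
    fraction of genes planted with an upward / downward m6A-quantity shift
    of ``effect_log2`` relative to the reference (first) group.  For the
    treatment group (third label) these fractions describe de-novo effects
    on genes untouched by the insult group; on top of that the treatment
    group inherits the insult group's effects except for the
    ``frac_reversed`` fraction, which returns to baseline.
    """

    n_genes: int = 2000
    n_spikeins: int = 20
    replicates_per_group: int = 3
    groups: tuple[str, ...] = ("Ctrl", "FS", "FS-DBS")
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.2
    array_offset_sd: float = 0.3
    frac_hyper: Mapping[str, float] = field(
        default_factory=lambda: {"FS": 0.16, "FS-DBS": 0.15}
    )
    frac_hypo: Mapping[str, float] = field(
        default_factory=lambda: {"FS": 0.04, "FS-DBS": 0.05}
    )
    effect_log2: float = 2.0
    frac_reversed: float = 0.2
    expr_coupling: float = 0.7
    dropout_rate: float = 0.02
    frac_lncrna: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_spikeins", "replicates_per_group"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_spikeins < 2:
            raise ConfigError("n_spikeins must be >= 2 for spike-in normalization")
        if len(self.groups) < 2:
            raise ConfigError("groups must list at least two group labels")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("groups must be unique labels")
        for name in ("baseline_log2_sd",):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("noise_log2_sd", "array_offset_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.effect_log2 <= 0:
            raise ConfigError("effect_log2 must be positive")
        if self.effect_log2 > np.log2(_LEVEL_CEILING / _LEVEL_FLOOR):
            raise ConfigError(
                "effect_log2 too large to keep methylated fractions below 1 "
                f"(max {np.log2(_LEVEL_CEILING / _LEVEL_FLOOR):.2f})"
            )
        for name in ("frac_reversed", "expr_coupling", "dropout_rate", "frac_lncrna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        total = 0.0
        for mapping, name in ((self.frac_hyper, "frac_hyper"), (self.frac_hypo, "frac_hypo")):
            for grp, frac in mapping.items():
                if grp not in self.groups[1:]:
                    raise ConfigError(
                        f"{name} keys must be non-reference groups {self.groups[1:]}, "
                        f"got {grp!r}"
                    )
                if not 0.0 <= frac <= 1.0:
                    raise ConfigError(f"{name}[{grp!r}] must lie in [0, 1], got {frac}")
                total += frac
        if total > 1.0 + 1e-12:
            raise ConfigError(
                "frac_hyper + frac_hypo summed over groups must be <= 1 so that "
                f"planted gene sets are disjoint; got {total:.3f}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene truth for every pairwise group comparison.

    ``classes`` / ``expr_classes``: gene x comparison labels in
    {hyper, hypo, unchanged} / {up, down, unchanged}, derived from the
    planted log2 shifts (a gene is hyper in "B_vs_A" iff its planted
    quantity shift is larger in B than in A).  ``reversed_genes`` marks
    insult-group effects that the treatment group returns to baseline.
    ``level`` stores the planted methylated fraction per gene and group;
    ``quantity_delta`` / ``expression_delta`` the planted log2 shifts
    relative to the reference group.
    """

    classes: pd.DataFrame
    expr_classes: pd.DataFrame
    reversed_genes: pd.Series
    expr_shifted: pd.Series
    level: pd.DataFrame
    quantity_delta: pd.DataFrame
    expression_delta: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format table (gene_id, comparison, true_class, reversed)."""
        rows = []
        for comp in self.classes.columns:
            for gene, cls in self.classes[comp].items():
                rows.append(
                    {
                        "gene_id": gene,
                        "comparison": comp,
                        "true_class": cls,
                        "reversed": int(bool(self.reversed_genes.loc[gene])),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _classify_delta(delta: np.ndarray) -> np.ndarray:
    out = np.full(delta.shape, "unchanged", dtype=object)
    out[delta > 0] = "hyper"
    out[delta < 0] = "hypo"
    return out


def _classify_expr_delta(delta: np.ndarray) -> np.ndarray:
    out = np.full(delta.shape, "unchanged", dtype=object)
    out[delta > 0] = "up"
    out[delta < 0] = "down"
    return out


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ChannelMatrix, ChannelMatrix, ProbePanel, DesignTable, GroundTruth]:
    """Simulate one complete two-channel array experiment.

    Returns the IP and Sup channel matrices (probes x samples, raw linear
    intensities with detection flags), the probe panel, the sample design
    table, and the planted ground truth.  The same config and seed always
    produce bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    groups = list(config.groups)
    reps = config.replicates_per_group
    gene_ids = [f"TX{i + 1:06d}" for i in range(n)]
    gene_symbols = [f"Gene{i + 1:06d}" for i in range(n)]
    spike_ids = [f"SPIKE{i + 1:03d}" for i in range(config.n_spikeins)]
    sample_ids = [f"{g}_{r}" for g in groups for r in range(1, reps + 1)]
    sample_group = np.repeat(np.arange(len(groups)), reps)

    # --- probe panel -------------------------------------------------------
    rna_class = np.full(n, "mRNA", dtype=object)
    n_lnc = int(round(config.frac_lncrna * n))
    lnc_idx = rng.permutation(n)[:n_lnc]
    rna_class[lnc_idx] = "lncRNA"
    panel = ProbePanel(
        table=pd.DataFrame(
            {
                "transcript_id": gene_ids + spike_ids,
                "gene_symbol": gene_symbols + [""] * config.n_spikeins,
                "is_spikein": [False] * n + [True] * config.n_spikeins,
                "rna_class": list(rna_class) + [""] * config.n_spikeins,
            },
            index=pd.Index(gene_ids + spike_ids, name="probe_id"),
        )
    )

    design = DesignTable(
        table=pd.DataFrame(
            {
                "group": [g for g in groups for _ in range(reps)],
                "replicate": [r for _ in groups for r in range(1, reps + 1)],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # --- planted effects ---------------------------------------------------
    # one permutation partitions genes into disjoint planted segments
    perm = rng.permutation(n)
    delta_q = pd.DataFrame(0.0, index=gene_ids, columns=groups)
    cursor = 0
    insult = groups[1] if len(groups) > 1 else None
    planted_segments: dict[tuple[str, str], np.ndarray] = {}
    for grp in groups[1:]:
        for sign, mapping in ((+1, config.frac_hyper), (-1, config.frac_hypo)):
            frac = mapping.get(grp, 0.0)
            count = int(round(frac * n))
            idx = perm[cursor : cursor + count]
            cursor += count
            planted_segments[(grp, "hyper" if sign > 0 else "hypo")] = idx
            delta_q.iloc[idx, delta_q.columns.get_loc(grp)] = sign * config.effect_log2

    # treatment groups inherit the insult group's effects unless reversed
    reversed_flag = pd.Series(False, index=gene_ids)
    if len(groups) >= 3 and insult is not None:
        insult_changed = np.concatenate(
            [
                planted_segments.get((insult, "hyper"), np.empty(0, dtype=int)),
                planted_segments.get((insult, "hypo"), np.empty(0, dtype=int)),
            ]
        ).astype(int)
        shuffled = rng.permutation(insult_changed)
        n_rev = int(round(config.frac_reversed * len(insult_changed)))
        rev_idx = shuffled[:n_rev]
        keep_idx = shuffled[n_rev:]
        reversed_flag.iloc[rev_idx] = True
        for grp in groups[2:]:
            col = delta_q.columns.get_loc(grp)
            delta_q.iloc[keep_idx, col] += delta_q.iloc[keep_idx, 1].to_numpy()

    ever_changed = (delta_q.to_numpy() != 0).any(axis=1)
    coupled = np.zeros(n, dtype=bool)
    coupled[ever_changed] = rng.random(ever_changed.sum()) < config.expr_coupling
    delta_t = delta_q.to_numpy() * coupled[:, None]
    delta_t = pd.DataFrame(delta_t, index=gene_ids, columns=groups)

    # --- baselines ---------------------------------------------------------
    baseline_total = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    level0 = rng.uniform(0.2, 0.8, n)
    # genes with an uncoupled upward quantity shift need headroom so that
    # the shifted methylated fraction stays below 1
    up_uncoupled = (~coupled) & (delta_q.to_numpy() > 0).any(axis=1)
    cap = _LEVEL_CEILING / 2.0**config.effect_log2
    level0[up_uncoupled] = rng.uniform(
        _LEVEL_FLOOR, cap, up_uncoupled.sum()
    )

    # planted per-group log2 quantity and total
    q_log2 = baseline_total[:, None] + np.log2(level0)[:, None] + delta_q.to_numpy()
    t_log2 = baseline_total[:, None] + delta_t.to_numpy()
    sup_lin = 2.0**t_log2 - 2.0**q_log2
    if not np.all(sup_lin > 0):
        raise ConfigError(
            "internal invariant violated: planted methylated amount exceeds total"
        )
    level_planted = pd.DataFrame(
        2.0**q_log2 / 2.0**t_log2, index=gene_ids, columns=groups
    )

    # --- per-sample signal -------------------------------------------------
    n_samples = len(sample_ids)

    def _channel_offsets() -> np.ndarray:
        off = rng.normal(0.0, config.array_offset_sd, n_samples)
        return off - off.mean()  # mean-zero drift keeps the grand-mean anchor unbiased

    off_ip = _channel_offsets()
    off_sup = _channel_offsets()
    spike_base = rng.normal(config.baseline_log2_mean, 1.0, config.n_spikeins)

    def _assemble(signal_log2_by_group: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        per_sample = signal_log2_by_group[:, sample_group] + offsets[None, :]
        noise = rng.normal(0.0, config.noise_log2_sd, per_sample.shape)
        return per_sample + noise

    ip_genes = _assemble(q_log2, off_ip)
    sup_genes = _assemble(np.log2(sup_lin), off_sup)
    spike_ip = _assemble(np.broadcast_to(spike_base[:, None], (config.n_spikeins, len(groups))).copy(), off_ip)
    spike_sup = _assemble(np.broadcast_to(spike_base[:, None], (config.n_spikeins, len(groups))).copy(), off_sup)

    def _finish(gene_log2: np.ndarray, spike_log2: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
        flags = np.full((n, n_samples), "P", dtype=object)
        marginal = rng.random((n, n_samples)) < 0.02
        flags[marginal] = "M"
        dropout = rng.random((n, n_samples)) < config.dropout_rate
        flags[dropout] = "A"
        vals = 2.0**gene_log2
        # dropout cells keep a small positive background intensity
        vals[dropout] = 2.0 ** rng.uniform(1.0, 3.0, int(dropout.sum()))
        values = pd.DataFrame(
            np.vstack([vals, 2.0**spike_log2]),
            index=gene_ids + spike_ids,
            columns=sample_ids,
        )
        flag_df = pd.DataFrame(
            np.vstack([flags, np.full((config.n_spikeins, n_samples), "QC", dtype=object)]),
            index=gene_ids + spike_ids,
            columns=sample_ids,
        )
        return values, flag_df

    ip_values, ip_flags = _finish(ip_genes, spike_ip)
    sup_values, sup_flags = _finish(sup_genes, spike_sup)
    ip = ChannelMatrix(fraction="IP", values=ip_values, flags=ip_flags)
    sup = ChannelMatrix(fraction="Sup", values=sup_values, flags=sup_flags)

    # --- ground truth ------------------------------------------------------
    comparisons = [
        (groups[i], groups[j]) for j in range(len(groups)) for i in range(j + 1, len(groups))
    ]
    classes = {}
    expr_classes = {}
    q_delta_cols = {}
    t_delta_cols = {}
    for test, ref in comparisons:
        label = comparison_label(test, ref)
        dq = delta_q[test].to_numpy() - delta_q[ref].to_numpy()
        dt = delta_t[test].to_numpy() - delta_t[ref].to_numpy()
        classes[label] = _classify_delta(dq)
        expr_classes[label] = _classify_expr_delta(dt)
        q_delta_cols[label] = dq
        t_delta_cols[label] = dt

    truth = GroundTruth(
        classes=pd.DataFrame(classes, index=gene_ids),
        expr_classes=pd.DataFrame(expr_classes, index=gene_ids),
        reversed_genes=reversed_flag,
        expr_shifted=pd.Series(coupled & ever_changed, index=gene_ids),
        level=level_planted,
        quantity_delta=pd.DataFrame(q_delta_cols, index=gene_ids),
        expression_delta=pd.DataFrame(t_delta_cols, index=gene_ids),
    )
    return ip, sup, panel, design, truth
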