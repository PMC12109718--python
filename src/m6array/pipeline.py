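"""End-to-end orchestration: simulate/load -> preprocess -> quantify ->
differential -> reversal -> enrichment, with a JSON run manifest.

Every stage writes its outputs under the run's output directory and the
manifest records paths, per-comparison class counts, reversal summaries,
and concordance statistics.  All randomness flows from the single config
seed, so two runs with the same config are identical apart from the
manifest timestamp.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import __version__
from .differential import (
    DiffTable,
    concordance,
    diff_expression,
    diff_level,
    diff_methylation,
    direction_proportions,
    reversal_intersection,
    write_diff_table,
)
from .enrichment import ora, write_enrichment_table
from .errors import ConfigError, PipelineError
from .io import (
    read_channel_matrix,
    read_design_table,
    read_gmt,
    read_probe_panel,
    write_channel_matrix,
    write_design_table,
    write_json,
    write_probe_panel,
)
from .preprocess import normalize_spikein, select_targets, write_normalized_matrix
from .quantify import compute_quant, write_quant_table
from .synthetic import SyntheticConfig, generate_dataset


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``synthetic`` is set (the dataset is simulated) or the four
    input paths point at existing TSVs.  ``comparisons`` are ordered
    (test, ref) group pairs; the default mirrors a three-group
    insult/treatment design.
    """

    out_dir: Path
    synthetic: SyntheticConfig | None = None
    ip_path: Path | None = None
    sup_path: Path | None = None
    panel_path: Path | None = None
    design_path: Path | None = None
    comparisons: tuple[tuple[str, str], ...] = (
        ("FS", "Ctrl"),
        ("FS-DBS", "Ctrl"),
        ("FS-DBS", "FS"),
    )
    fc_threshold: float = 1.5
    gmt_paths: tuple[Path, ...] = ()
    seed: int | None = None

    def validate(self) -> None:
        if not self.comparisons:
            raise ConfigError("comparisons must list at least one (test, ref) pair")
        if self.synthetic is None:
            missing = [
                name
                for name in ("ip_path", "sup_path", "panel_path", "design_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ConfigError(
                    f"without a synthetic config, input paths are required: {missing}"
                )
        if self.fc_threshold <= 0:
            raise ConfigError("fc_threshold must be positive")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "m6array_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "fc_threshold": config.fc_threshold,
        "comparisons": [list(c) for c in config.comparisons],
        "outputs": {},
    }

    # --- inputs ------------------------------------------------------------
    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed is not None:
            syn = replace(syn, seed=config.seed)
        manifest["seed"] = syn.seed
        ip, sup, panel, design, truth = _stage("simulate")(generate_dataset)(syn)
        write_channel_matrix(ip, out / "ip_raw.tsv")
        write_channel_matrix(sup, out / "sup_raw.tsv")
        write_probe_panel(panel, out / "probe_panel.tsv")
        write_design_table(design, out / "design.tsv")
        truth.write(out / "ground_truth.tsv")
        manifest["outputs"]["ground_truth"] = str(out / "ground_truth.tsv")
    else:
        manifest["seed"] = config.seed
        ip = _stage("load")(read_channel_matrix)(config.ip_path, "IP")
        sup = _stage("load")(read_channel_matrix)(config.sup_path, "Sup")
        panel = _stage("load")(read_probe_panel)(config.panel_path)
        design = _stage("load")(read_design_table)(config.design_path)
        truth = None

    known_groups = set(design.groups)
    for test, ref in config.comparisons:
        for g in (test, ref):
            if g not in known_groups:
                raise ConfigError(
                    f"comparison group {g!r} not in design groups {sorted(known_groups)}"
                )

    # --- preprocess --------------------------------------------------------
    ip_norm = _stage("normalize")(normalize_spikein)(ip, panel)
    sup_norm = _stage("normalize")(normalize_spikein)(sup, panel)
    targets = _stage("select")(select_targets)(ip.flags, sup.flags, panel, design)
    write_normalized_matrix(ip_norm, out / "ip_norm.tsv", out / "ip_offsets.tsv")
    write_normalized_matrix(sup_norm, out / "sup_norm.tsv", out / "sup_offsets.tsv")
    manifest["n_selected_probes"] = int(len(targets))

    # --- quantify ----------------------------------------------------------
    quant = _stage("quantify")(compute_quant)(ip_norm, sup_norm, panel, targets)
    write_quant_table(quant, out / "quant.tsv")
    manifest["outputs"]["quant"] = str(out / "quant.tsv")
    manifest["n_transcripts"] = int(len(quant.transcripts))

    # --- differential ------------------------------------------------------
    meth_tables: dict[str, DiffTable] = {}
    manifest["differential"] = {}
    for test, ref in config.comparisons:
        meth = _stage("diff")(diff_methylation)(quant, design, test, ref, config.fc_threshold)
        expr = _stage("diff")(diff_expression)(quant, design, test, ref, config.fc_threshold)
        level = _stage("diff")(diff_level)(quant, design, test, ref, config.fc_threshold)
        label = meth.comparison
        meth_tables[label] = meth
        write_diff_table(meth, out / f"diff_m6a_{label}.tsv")
        write_diff_table(expr, out / f"diff_expr_{label}.tsv")
        props = direction_proportions(meth)
        expr_props = direction_proportions(expr)
        manifest["differential"][label] = {
            "methylation": meth.class_counts(),
            "expression": expr.class_counts(),
            "pct_hyper": props.pct_up,
            "pct_hypo": props.pct_down,
            "pct_up": expr_props.pct_up,
            "pct_down": expr_props.pct_down,
            "concordance": concordance(meth, expr, level),
        }

    # --- reversal ----------------------------------------------------------
    manifest["reversal"] = {}
    chain = _find_chain(config.comparisons)
    enrichment_queries: dict[str, tuple[str, ...]] = {}
    if chain is not None:
        (b, a), (c, _) = chain
        diff_ab = meth_tables[f"{b}_vs_{a}"]
        diff_cb = meth_tables[f"{c}_vs_{b}"]
        for direction in ("attenuation", "enhancement"):
            summary = _stage("reverse")(reversal_intersection)(diff_ab, diff_cb, direction)
            write_json(summary.to_dict(), out / f"reversal_{direction}.json")
            manifest["reversal"][direction] = {
                k: v for k, v in summary.to_dict().items() if k not in ("members", "member_genes")
            }
            enrichment_queries[direction] = summary.member_genes

    # --- enrichment --------------------------------------------------------
    if config.gmt_paths and enrichment_queries:
        mrna = quant.meta["rna_class"] == "mRNA"
        universe = sorted(set(quant.meta.loc[mrna, "gene_symbol"]))
        manifest["enrichment"] = {}
        for gmt_path in config.gmt_paths:
            sets = _stage("enrich")(read_gmt)(gmt_path)
            for direction, genes in enrichment_queries.items():
                query = sorted(set(genes) & set(universe))
                if not query:
                    continue
                table = _stage("enrich")(ora)(query, universe, sets)
                dest = out / f"enrichment_{Path(gmt_path).stem}_{direction}.tsv"
                write_enrichment_table(table, dest)
                manifest["enrichment"][f"{Path(gmt_path).stem}:{direction}"] = {
                    "n_sets_tested": int(len(table)),
                    "n_significant_q05": int((table["q_value"] < 0.05).sum()) if len(table) else 0,
                    "path": str(dest),
                }

    write_json(manifest, out / "manifest.json")
    return manifest


def _find_chain(
    comparisons: tuple[tuple[str, str], ...]
) -> tuple[tuple[str, str], tuple[str, str]] | None:
    """Find a pair of comparisons (B vs A, C vs B) suitable for reversal."""
    for b, a in comparisons:
        for c, b2 in comparisons:
            if b2 == b and c != a:
                return (b, a), (c, b)
    return None
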