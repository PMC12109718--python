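import numpy as np
import pandas as pd
import pytest

from m6array import (
    SyntheticConfig,
    compute_quant,
    generate_dataset,
    normalize_spikein,
    select_targets,
)
from m6array.differential import DiffTable, classify_log2fc


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Small noise-free dataset where every class is exactly recoverable."""
    cfg = SyntheticConfig(
        n_genes=400, noise_log2_sd=0.0, dropout_rate=0.0, seed=42
    )
    ip, sup, panel, design, truth = generate_dataset(cfg)
    return cfg, ip, sup, panel, design, truth


@pytest.fixture(scope="session")
def noisefree_quant(noisefree_dataset):
    cfg, ip, sup, panel, design, truth = noisefree_dataset
    ip_norm = normalize_spikein(ip, panel)
    sup_norm = normalize_spikein(sup, panel)
    targets = select_targets(ip.flags, sup.flags, panel, design)
    quant = compute_quant(ip_norm, sup_norm, panel, targets)
    return quant, design, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    """Defaults-like dataset with replicate noise and dropout."""
    cfg = SyntheticConfig(n_genes=300, seed=3)
    return cfg, *generate_dataset(cfg)


def make_diff_table(
    classes: pd.Series,
    test: str = "T",
    ref: str = "R",
    variable: str = "m6a_quantity",
    rna_class: str = "mRNA",
) -> DiffTable:
    """Build a consistent DiffTable from a desired class assignment.

    log2fc is set to +1 / -1 / 0 so the stored class always agrees with
    the classifier at the default 1.5-fold threshold.
    """
    fc = pd.Series(0.0, index=classes.index)
    fc[classes.isin(["hyper", "up"])] = 1.0
    fc[classes.isin(["hypo", "down"])] = -1.0
    labels = (
        ("up", "down", "unchanged")
        if set(classes.unique()) <= {"up", "down", "unchanged"}
        else ("hyper", "hypo", "unchanged")
    )
    frame = pd.DataFrame(
        {
            "gene_symbol": classes.index,
            "rna_class": rna_class,
            "mean_log2_test": fc,
            "mean_log2_ref": 0.0,
            "log2fc": fc,
            "class": classify_log2fc(fc, 1.5, labels),
        },
        index=classes.index,
    )
    assert (frame["class"] == classes).all()
    return DiffTable(
        test=test, ref=ref, variable="expression" if labels[0] == "up" else variable,
        fc_threshold=1.5, frame=frame,
    )
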