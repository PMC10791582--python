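"""Shared fixtures: all data is generated programmatically and heavy
artefacts (the 600-gene study, one trained flank classifier) are built
once per session."""

from __future__ import annotations

import numpy as np
import pytest

from trnareg.presets import desk_spec, desk_train_config
from trnareg.simulate import (
    SimulationConfig,
    generate_chip_counts,
    generate_gene_set,
    generate_trna_counts,
)
from trnareg.trnet import CLASS_NAMES, build_model, one_hot, train

CLS_TO_INT = {c: i for i, c in enumerate(CLASS_NAMES)}


@pytest.fixture(scope="session")
def sim_small():
    """90-gene study with balanced classes."""
    cfg = SimulationConfig(n_genes=90, seed=7)
    genes, truth = generate_gene_set(cfg)
    return cfg, genes, truth


@pytest.fixture(scope="session")
def counts_small(sim_small):
    cfg, genes, truth = sim_small
    return generate_trna_counts(genes, truth, cfg)


@pytest.fixture(scope="session")
def study600():
    """The full desk-scale study: 600 genes, 4 cell types x 2 replicates,
    cleanly planted motifs and strong ChIP enrichment."""
    cfg = SimulationConfig(n_genes=600, n_anticodon_families=40, seed=0, motif_effect=1.0)
    genes, truth = generate_gene_set(cfg)
    ip, inp, mm = generate_chip_counts(genes, truth, cfg)
    return cfg, genes, truth, ip, inp, mm


@pytest.fixture(scope="session")
def flanks600(study600):
    _, genes, truth, *_ = study600
    x = np.stack([one_hot(g.flank5_seq) for g in genes])
    y = np.array([CLS_TO_INT[truth.labels[g.name]] for g in genes])
    return x, y


@pytest.fixture(scope="session")
def trained_binary():
    """Desk-scale binary (housekeeping vs inactive) flank model, trained
    on a 360-gene study; used by the attribution tests."""
    cfg = SimulationConfig(n_genes=360, n_anticodon_families=30, seed=1, motif_effect=1.0)
    genes, truth = generate_gene_set(cfg)
    lab = truth.labels
    sel = [g for g in genes if lab[g.name] in ("housekeeping", "inactive")]
    x = np.stack([one_hot(g.flank5_seq) for g in sel])
    y = np.array([1 if lab[g.name] == "housekeeping" else 0 for g in sel])
    model = build_model(desk_spec(), "binary", seed=0)
    train(model, x, y, desk_train_config(seed=0, max_epochs=30), early_stopping=False)
    housekeeping = [g for g in sel if lab[g.name] == "housekeeping"]
    return model, housekeeping, truth
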