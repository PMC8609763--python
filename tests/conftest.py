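"""Shared fixtures: toy genes, a small synthetic genome, and desk-scale
trained models (session-scoped; training is the expensive part)."""

from __future__ import annotations

import numpy as np
import pytest

import splicevision as sv


@pytest.fixture(scope="session")
def default_params() -> sv.GeneratorParams:
    return sv.GeneratorParams(seed=42)


@pytest.fixture(scope="session")
def small_genes(default_params):
    """60 synthetic genes, enough for window extraction and sampling tests."""
    return sv.generate_genome_set(60, default_params, seed=42)


@pytest.fixture()
def toy_gene() -> sv.GeneRecord:
    """Two exons around a 10-nt intron GTAAGT...CTAG; hand-enumerable."""
    return sv.GeneRecord(
        gene_id="toy",
        sequence="ACGACGACGA" + "GTAAGTCTAG" + "CCTACGTACG",
        exons=[(1, 10), (21, 30)],
    )


def build_desk_dataset(site_type: str, seed: int = 11, n_genes: int = 850,
                       max_positives: int = 2600, window: int = 200):
    """A GS_1-style dataset (1:1, heterogeneous negatives) at desk scale."""
    params = sv.GeneratorParams(seed=seed)
    genes = sv.generate_genome_set(n_genes, params, seed=seed)
    pos600 = sv.extract_positive_windows(genes, site_type, flank=300)
    positives = [sv.trim_window(e, window) for e in pos600][:max_positives]
    spec = sv.DatasetSpec.from_strategy("GS_1", window_length=window,
                                        replicate=1, seed=seed)
    dataset = sv.assemble_dataset(spec, positives, genes, flank=window // 2)
    return sv.split_train_test(dataset, 0.8, seed=seed)


def train_desk_model(site_type: str, seed: int = 11, epochs: int = 40):
    """Train one desk-scale model; returns (results, train_batch, test_frame)."""
    train_ds, test_ds = build_desk_dataset(site_type, seed=seed)
    tr = train_ds.to_frame()
    batch = sv.encode_batch(tr.window.tolist(), tr.label.tolist())
    model = sv.SpliceCNN(batch, site_type=site_type,
                         config=sv.ModelConfig(seed=seed))
    results = model.fit(sv.TrainConfig(epochs=epochs, learning_rate=1e-3,
                                       seed=seed))
    return results, batch, test_ds.to_frame()


@pytest.fixture(scope="session")
def desk_donor_model():
    return train_desk_model("donor")


@pytest.fixture(scope="session")
def desk_acceptor_model():
    return train_desk_model("acceptor")
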