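"""Shared fixtures: small synthetic corpora and (for the end-to-end checks) a
single trained model reused across tests, since training dominates runtime."""

from __future__ import annotations

import numpy as np
import pytest

import puritynet as pn


@pytest.fixture(scope="session")
def fixture_cfg() -> pn.FixtureConfig:
    """Default synthetic-study configuration: 200 genes, 8 patients."""
    return pn.FixtureConfig()


@pytest.fixture(scope="session")
def corpus(fixture_cfg) -> pn.SingleCellCorpus:
    return pn.generate_corpus(fixture_cfg)


@pytest.fixture(scope="session")
def gene_lengths(fixture_cfg) -> pn.GeneLengths:
    return pn.generate_gene_lengths(fixture_cfg)


@pytest.fixture(scope="session")
def tiny_corpus() -> pn.SingleCellCorpus:
    """3 genes x 6 cells, 2 samples, hand-checkable."""
    counts = pn.CountMatrix(
        ["gA", "gB", "gC"],
        [f"c{i}" for i in range(6)],
        np.array(
            [
                [1, 2, 0, 4, 1, 3],
                [0, 3, 1, 0, 2, 2],
                [5, 0, 2, 1, 0, 1],
            ],
            dtype=float,
        ),
    )
    return pn.SingleCellCorpus(
        counts=counts,
        cell_samples=np.array(["s1", "s1", "s1", "s2", "s2", "s2"], dtype=object),
        malignant=np.array([True, False, True, True, True, False]),
    )


@pytest.fixture(scope="session")
def selected_features(fixture_cfg, corpus):
    pb, _ = pn.pseudobulk_per_sample(corpus)
    bulk, _ = pn.generate_bulk_cohort(fixture_cfg, 50)
    fs, _ = pn.select_features(bulk, pb)
    return fs


@pytest.fixture(scope="session")
def heldout_pseudobulks(fixture_cfg):
    """200 simulated pseudobulks from 2 synthetic patients unseen in training."""
    hold_cfg = pn.FixtureConfig(
        **{**fixture_cfg.__dict__, "n_samples": 2}
    )
    rng = np.random.default_rng(999)
    hold = pn.generate_corpus(hold_cfg, rng=rng, sample_prefix="H")
    cols, labels, ids = [], [], []
    for j in range(200):
        sid = hold.sample_ids[j % 2]
        p = float(rng.uniform(0, 1))
        n = int(rng.integers(200, 4001))
        pb = pn.simulate_pseudobulk(hold, sid, p, n, rng)
        cols.append(pb.counts)
        labels.append(pb.purity)
        ids.append(f"h{j:03d}")
    cm = pn.CountMatrix(hold_cfg.gene_ids, ids, np.array(cols).T)
    return cm, np.array(labels)


@pytest.fixture(scope="session")
def trained_model(corpus, selected_features, gene_lengths):
    """Model trained on the default synthetic corpus with the published
    hyperparameters; shared because training takes minutes."""
    model, _log = pn.train(
        corpus,
        selected_features,
        gene_lengths,
        pn.SimulationConfig(seed=1),
        pn.ModelConfig(seed=2),
    )
    return model
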