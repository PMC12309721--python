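"""On-the-fly simulation of labeled pseudobulk tumors.

Training data is produced ad hoc: pick an eligible sample, draw a target purity
``p ~ Uniform(purity_min, purity_max)`` and a cell number
``N ~ DiscreteUniform{cells_min..cells_max}``, split ``N`` into
``N_m = round(p*N)`` malignant and ``N_n = N - N_m`` nonmalignant draws, sample
cells with replacement from that sample only, and sum their count vectors. The
label is the realized malignant fraction ``N_m / N`` (not the target ``p``).
Sampling never crosses samples, which preserves inter-patient heterogeneity.

RNG draw order per simulated tumor (replayable with a same-seeded generator):
``rng.integers`` over malignant cell indices (size ``N_m``), then over
nonmalignant indices (size ``N_n``). Per batch entry the order is sample index,
purity, cell number, then the two index draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .corpus import SingleCellCorpus, eligible_samples
from .matrix import CountMatrix, GeneLengths, ValidationError
from .normalize import model_input_transform

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureSet


@dataclass
class SimulationConfig:
    """Simulation ranges: purity in [0,1], cell count 200-4000 by default."""

    purity_min: float = 0.0
    purity_max: float = 1.0
    cells_min: int = 200
    cells_max: int = 4000
    min_cells_per_class: int = 5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.purity_min <= self.purity_max <= 1):
            raise ValidationError("need 0 <= purity_min <= purity_max <= 1")
        if self.cells_min < 1 or self.cells_max < self.cells_min:
            raise ValidationError("need 1 <= cells_min <= cells_max")
        if self.min_cells_per_class < 1:
            raise ValidationError("min_cells_per_class must be >= 1")


@dataclass
class LabeledPseudobulk:
    """One simulated tumor: summed counts, exact purity label, provenance."""

    counts: np.ndarray
    purity: float
    sample_id: str
    n_cells: int

    def __post_init__(self) -> None:
        if not (0 <= self.purity <= 1):
            raise ValidationError(f"purity {self.purity} outside [0, 1]")
        if (self.counts < 0).any():
            raise ValidationError("negative simulated counts")


def _round_half_up(x: float) -> int:
    # round-half-away-from-zero; x >= 0 here
    return int(np.floor(x + 0.5))


def simulate_pseudobulk(
    corpus: SingleCellCorpus,
    sample_id: str,
    p: float,
    n_cells: int,
    rng: np.random.Generator,
    min_cells_per_class: int = 5,
) -> LabeledPseudobulk:
    """Simulate one pseudobulk tumor of target purity ``p`` from one sample.

    ``N_m = round(p * N)`` malignant and ``N_n = N - N_m`` nonmalignant cells
    are drawn uniformly WITH replacement from ``sample_id`` only; the label is
    the realized fraction ``N_m / N``.
    """
    if not (0 <= p <= 1):
        raise ValidationError(f"target purity {p} outside [0, 1]")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    n_mal_avail, n_non_avail = corpus.class_counts(sample_id)
    if n_mal_avail < min_cells_per_class or n_non_avail < min_cells_per_class:
        raise ValidationError(
            f"sample {sample_id!r} ineligible: {n_mal_avail} malignant / "
            f"{n_non_avail} nonmalignant cells (need >= {min_cells_per_class} of each)"
        )
    n_m = _round_half_up(p * n_cells)
    n_n = n_cells - n_m
    mal_cols = corpus.cells_of(sample_id, malignant=True)
    non_cols = corpus.cells_of(sample_id, malignant=False)
    counts = np.zeros(corpus.counts.n_genes)
    for cols, n_draw in ((mal_cols, n_m), (non_cols, n_n)):
        if n_draw == 0:
            continue
        draws = rng.integers(0, len(cols), size=n_draw)
        per_cell = np.bincount(draws, minlength=len(cols)).astype(np.float64)
        counts += corpus.counts.values[:, cols] @ per_cell
    return LabeledPseudobulk(
        counts=counts, purity=n_m / n_cells, sample_id=sample_id, n_cells=n_cells
    )


def simulate_batch(
    corpus: SingleCellCorpus,
    features: "FeatureSet",
    lengths: GeneLengths,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    eligible: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one training batch of model inputs and exact purity labels.

    Returns ``(X, y)`` where ``X`` is ``batch_size x |features|`` of
    MODEL_INPUT values (TPM computed over all corpus genes before subsetting)
    and ``y`` the realized purity labels. ``eligible`` may be precomputed to
    avoid rescanning the corpus every batch.
    """
    if eligible is None:
        eligible = eligible_samples(corpus, cfg.min_cells_per_class)
    raw = np.zeros((corpus.counts.n_genes, cfg.batch_size))
    y = np.zeros(cfg.batch_size)
    ids = []
    for b in range(cfg.batch_size):
        s = eligible[int(rng.integers(0, len(eligible)))]
        p = float(rng.uniform(cfg.purity_min, cfg.purity_max))
        n = int(rng.integers(cfg.cells_min, cfg.cells_max + 1))
        pb = simulate_pseudobulk(corpus, s, p, n, rng, cfg.min_cells_per_class)
        raw[:, b] = pb.counts
        y[b] = pb.purity
        ids.append(f"sim{b}")
    cm = CountMatrix(list(corpus.counts.gene_ids), ids, raw)
    transformed, _ = model_input_transform(cm, features, lengths)
    return transformed.values.T.copy(), y
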