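"""Synthetic labeled single-cell corpora and paired bulk-like cohorts.

Stands in for a real annotated tumor atlas so every pipeline stage is testable
without downloads. Each synthetic patient carries a log-normal per-gene effect
(inter-patient heterogeneity); each cell draws a malignant / nonmalignant label
from the patient's malignant fraction and negative-binomial counts whose means
follow a shared base expression program, with malignant marker genes
up-regulated by a fold-change in malignant cells and nonmalignant markers
up-regulated symmetrically in nonmalignant cells. Library sizes vary per cell.

What this emulates: distinct malignant/nonmalignant programs, inter-patient
heterogeneity, overdispersed counts, library-size variation, and a bulk-like
cohort with sequencing-depth resampling noise. What it does not: realistic
cell-state substructure, doublets, or ambient RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import SingleCellCorpus
from .matrix import CountMatrix, GeneLengths, ValidationError
from .simulate import simulate_pseudobulk


@dataclass
class FixtureConfig:
    """Generator parameters; defaults are small enough for minute-scale tests."""

    n_samples: int = 8
    cells_per_sample: tuple[int, int] = (200, 400)
    n_genes: int = 200
    n_malignant_markers: int = 20
    n_nonmalignant_markers: int = 20
    base_expression_sd: float = 1.0  # log-scale spread of the shared program
    fold_change: float = 4.0
    patient_effect_sd: float = 0.15  # log-scale
    library_size: tuple[int, int] = (1000, 3000)
    dispersion: float = 10.0  # NB size parameter; larger -> closer to Poisson
    malignant_fraction: tuple[float, float] = (0.2, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_malignant_markers + self.n_nonmalignant_markers:
            raise ValidationError("more marker genes than genes")
        if min(self.n_samples, self.n_genes, self.cells_per_sample[0],
               self.library_size[0]) < 1:
            raise ValidationError("counts must be positive")
        if self.fold_change <= 1:
            raise ValidationError("fold_change must exceed 1")
        lo, hi = self.malignant_fraction
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("malignant_fraction range must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    @property
    def malignant_marker_ids(self) -> list[str]:
        return self.gene_ids[: self.n_malignant_markers]

    @property
    def nonmalignant_marker_ids(self) -> list[str]:
        n = self.n_malignant_markers
        return self.gene_ids[n : n + self.n_nonmalignant_markers]


def _base_rates(cfg: FixtureConfig) -> np.ndarray:
    # The shared expression program is a property of the simulated "biology",
    # keyed to the config seed alone so that corpora and bulk cohorts generated
    # from the same config measure the same transcriptome.
    rng = np.random.default_rng(cfg.seed + 424_243)
    return rng.lognormal(mean=0.0, sigma=cfg.base_expression_sd, size=cfg.n_genes)


def _class_rates(cfg: FixtureConfig, base: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene relative expression for (malignant, nonmalignant) cells."""
    mal = base.copy()
    non = base.copy()
    mal[: cfg.n_malignant_markers] *= cfg.fold_change
    non[cfg.n_malignant_markers : cfg.n_malignant_markers + cfg.n_nonmalignant_markers] *= cfg.fold_change
    return mal, non


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    # gamma-poisson mixture: var = mu + mu^2/dispersion
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam).astype(np.float64)


def generate_corpus(
    cfg: FixtureConfig,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "S",
) -> SingleCellCorpus:
    """Generate a labeled synthetic single-cell corpus.

    Deterministic for a fixed config seed (or caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base = _base_rates(cfg)
    mal_rate, non_rate = _class_rates(cfg, base)
    all_counts: list[np.ndarray] = []
    cell_ids: list[str] = []
    cell_samples: list[str] = []
    labels: list[bool] = []
    for s in range(cfg.n_samples):
        sid = f"{sample_prefix}{s:02d}"
        patient = rng.lognormal(0.0, cfg.patient_effect_sd, size=cfg.n_genes)
        frac = rng.uniform(*cfg.malignant_fraction)
        n_cells = int(rng.integers(cfg.cells_per_sample[0], cfg.cells_per_sample[1] + 1))
        is_mal = rng.random(n_cells) < frac
        libs = rng.integers(cfg.library_size[0], cfg.library_size[1] + 1, size=n_cells)
        rates = np.where(is_mal[:, None], mal_rate, non_rate) * patient  # cells x genes
        probs = rates / rates.sum(axis=1, keepdims=True)
        means = probs * libs[:, None]
        counts = _nb_counts(means, cfg.dispersion, rng)  # cells x genes
        all_counts.append(counts.T)
        cell_ids.extend(f"{sid}_c{i:04d}" for i in range(n_cells))
        cell_samples.extend([sid] * n_cells)
        labels.extend(bool(b) for b in is_mal)
    values = np.concatenate(all_counts, axis=1)
    counts_m = CountMatrix(cfg.gene_ids, cell_ids, values)
    return SingleCellCorpus(
        counts=counts_m,
        cell_samples=np.array(cell_samples, dtype=object),
        malignant=np.array(labels, dtype=bool),
    )


def generate_gene_lengths(
    cfg: FixtureConfig,
    rng: np.random.Generator | None = None,
    uniform: bool = False,
) -> GeneLengths:
    """Gene-length table for the fixture genes.

    With ``uniform=True`` all lengths are 1000 bases, making TPM coincide with
    CPM — useful for cross-checks.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1_000_003)
    if uniform:
        lengths = {g: 1000.0 for g in cfg.gene_ids}
    else:
        draws = rng.integers(300, 10_000, size=cfg.n_genes)
        lengths = {g: float(l) for g, l in zip(cfg.gene_ids, draws)}
    return GeneLengths(lengths)


def generate_bulk_cohort(
    cfg: FixtureConfig,
    n_bulk: int,
    purity_range: tuple[float, float] = (0.05, 0.95),
    rng: np.random.Generator | None = None,
    n_holdout_patients: int = 4,
    cells_per_mixture: tuple[int, int] = (300, 1500),
    bulk_library_size: int = 2_000_000,
) -> tuple[CountMatrix, np.ndarray]:
    """A bulk-like cohort from held-out synthetic patients, with ground truth.

    Each column is a fresh cell mixture at a drawn purity from a patient NOT in
    the training corpus (own generator stream), resampled to a bulk library
    size with a multinomial to add sequencing-depth noise. Returns the matrix
    and the true purities.
    """
    if n_bulk < 1:
        raise ValidationError("n_bulk must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 7_777_777)
    holdout_cfg = FixtureConfig(**{**cfg.__dict__, "n_samples": n_holdout_patients})
    holdout = generate_corpus(holdout_cfg, rng=rng, sample_prefix="B")
    samples = holdout.sample_ids
    cols = np.zeros((cfg.n_genes, n_bulk))
    purities = np.zeros(n_bulk)
    for j in range(n_bulk):
        sid = samples[int(rng.integers(0, len(samples)))]
        p = float(rng.uniform(*purity_range))
        n = int(rng.integers(cells_per_mixture[0], cells_per_mixture[1] + 1))
        pb = simulate_pseudobulk(holdout, sid, p, n, rng, min_cells_per_class=1)
        total = pb.counts.sum()
        cols[:, j] = rng.multinomial(bulk_library_size, pb.counts / total)
        purities[j] = pb.purity
    ids = [f"bulk{j:03d}" for j in range(n_bulk)]
    return CountMatrix(cfg.gene_ids, ids, cols), purities


def inject_modality_shift(
    bulk: CountMatrix,
    shifted_gene_fraction: float,
    shift_factor: float,
    rng: np.random.Generator,
) -> tuple[CountMatrix, list[str]]:
    """Multiply a random gene subset's counts by a factor, recording which.

    Creates genes whose bulk distribution departs from the single-cell one, so
    the KS screen's sensitivity can be measured against known ground truth.
    """
    if not (0 <= shifted_gene_fraction <= 1):
        raise ValidationError("shifted_gene_fraction must be in [0, 1]")
    n_shift = int(round(shifted_gene_fraction * bulk.n_genes))
    idx = rng.choice(bulk.n_genes, size=n_shift, replace=False)
    vals = bulk.values.copy()
    vals[idx] *= shift_factor
    shifted = sorted(bulk.gene_ids[i] for i in idx)
    return CountMatrix(list(bulk.gene_ids), list(bulk.column_ids), vals), shifted
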