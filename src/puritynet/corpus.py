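"""Labeled single-cell corpora and per-sample pseudobulking.

A :class:`SingleCellCorpus` is a genes x cells count matrix where every cell
carries a sample (patient) id and a malignant / nonmalignant label. Summing all
cells of one sample yields that sample's pseudobulk, whose ground-truth purity
is simply the malignant fraction among its cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ValidationError

MALIGNANT = "malignant"
NONMALIGNANT = "nonmalignant"


@dataclass
class SingleCellCorpus:
    """Counts (genes x cells) plus per-cell sample id and malignancy flag.

    ``cell_samples`` and ``malignant`` are aligned to ``counts.column_ids``.
    """

    counts: CountMatrix
    cell_samples: np.ndarray  # str per cell
    malignant: np.ndarray  # bool per cell

    def __post_init__(self) -> None:
        self.cell_samples = np.asarray(self.cell_samples, dtype=object)
        self.malignant = np.asarray(self.malignant, dtype=bool)
        n = self.counts.n_columns
        if len(self.cell_samples) != n or len(self.malignant) != n:
            raise ValidationError(
                f"annotation length ({len(self.cell_samples)}/{len(self.malignant)}) "
                f"does not match {n} cells"
            )
        if len(self.sample_ids) == 0:
            raise ValidationError("corpus has no samples")

    @property
    def n_cells(self) -> int:
        return self.counts.n_columns

    @property
    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        known: set[str] = set()
        for s in self.cell_samples:
            if s not in known:
                known.add(s)
                seen.append(s)
        return seen

    def cells_of(self, sample_id: str, malignant: bool | None = None) -> np.ndarray:
        """Column indices of cells of one sample, optionally restricted by label."""
        mask = self.cell_samples == sample_id
        if malignant is not None:
            mask &= self.malignant == malignant
        return np.nonzero(mask)[0]

    def class_counts(self, sample_id: str) -> tuple[int, int]:
        """(n_malignant, n_nonmalignant) for one sample."""
        mask = self.cell_samples == sample_id
        n_mal = int((mask & self.malignant).sum())
        return n_mal, int(mask.sum()) - n_mal


def read_cell_annotations(path: str | Path) -> pd.DataFrame:
    """Read a cell annotation TSV with columns cell_id, sample_id, label.

    Labels must be ``malignant`` or ``nonmalignant``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "sample_id", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: annotation TSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = set(df["label"]) - {MALIGNANT, NONMALIGNANT}
    if bad:
        raise ValidationError(f"{path}: unknown labels {sorted(bad)}")
    return df


def corpus_from_annotations(counts: CountMatrix, annotations: pd.DataFrame) -> SingleCellCorpus:
    """Align an annotation table (cell_id, sample_id, label) to a count matrix."""
    ann = annotations.set_index("cell_id")
    missing = [c for c in counts.column_ids if c not in ann.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells lack annotations, e.g. {missing[:5]}"
        )
    ann = ann.loc[counts.column_ids]
    return SingleCellCorpus(
        counts=counts,
        cell_samples=ann["sample_id"].to_numpy(dtype=object),
        malignant=(ann["label"] == MALIGNANT).to_numpy(),
    )


def write_cell_annotations(corpus: SingleCellCorpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tsample_id\tlabel\n")
        for cell, samp, mal in zip(
            corpus.counts.column_ids, corpus.cell_samples, corpus.malignant
        ):
            fh.write(f"{cell}\t{samp}\t{MALIGNANT if mal else NONMALIGNANT}\n")


def pseudobulk_per_sample(corpus: SingleCellCorpus) -> tuple[CountMatrix, dict[str, float]]:
    """Sum each sample's cells into one pseudobulk column.

    Returns the samples-as-columns matrix and each sample's ground-truth purity
    (malignant cell fraction).
    """
    samples = corpus.sample_ids
    vals = np.zeros((corpus.counts.n_genes, len(samples)))
    purity: dict[str, float] = {}
    for j, s in enumerate(samples):
        cols = corpus.cells_of(s)
        vals[:, j] = corpus.counts.values[:, cols].sum(axis=1)
        purity[s] = float(corpus.malignant[cols].mean())
    return CountMatrix(list(corpus.counts.gene_ids), samples, vals), purity


def eligible_samples(corpus: SingleCellCorpus, min_cells_per_class: int = 5) -> list[str]:
    """Samples with at least ``min_cells_per_class`` cells of BOTH classes.

    Simulation across the full purity spectrum needs enough cells of each class
    to draw from, so thinly represented samples are excluded.
    """
    out = []
    for s in corpus.sample_ids:
        n_mal, n_non = corpus.class_counts(s)
        if n_mal >= min_cells_per_class and n_non >= min_cells_per_class:
            out.append(s)
    if not out:
        raise ValidationError("no sample eligible for simulation")
    return out
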