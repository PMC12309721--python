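"""Cross-modality feature selection.

Bulk RNA-seq and pseudobulked single-cell data measure the same transcriptome
through different protocols, so many genes have systematically different
abundance distributions across the two modalities. The model should only see
genes it can trust in either modality, selected in two passes:

1. **Prevalence filter** — drop genes absent or lowly expressed (CPM below a
   threshold in at least a given fraction of samples) in *either* modality.
2. **KS screen** — for each surviving gene, compute the exact two-sample
   Kolmogorov–Smirnov statistic D between its CPM values across bulk samples
   and across per-sample pseudobulks; drop genes with D above a threshold
   (default 0.4).

The surviving genes, in the single-cell matrix's gene order, form the ordered
:class:`FeatureSet` that fixes the model's input dimension.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .matrix import CountMatrix, NormalizedMatrix, ValidationError
from .normalize import cpm_normalize

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """Ordered gene panel fixed at training time, with selection provenance."""

    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError("FeatureSet must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("FeatureSet gene ids must be unique")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"gene_ids": self.gene_ids, "provenance": self.provenance},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(gene_ids=obj["gene_ids"], provenance=obj.get("provenance", {}))


def ks_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sample Kolmogorov–Smirnov statistic.

    ``D = sup_x |F_a(x) - F_b(x)|`` over the empirical CDFs, evaluated at every
    observed breakpoint. Symmetric in its arguments; always in [0, 1].
    """
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValidationError("ks_statistic requires non-empty samples")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def _require_cpm(m: NormalizedMatrix, name: str) -> None:
    if getattr(m, "scheme", None) != "CPM":
        raise ValidationError(f"{name} must be CPM-normalized (scheme={getattr(m, 'scheme', None)!r})")


def prevalence_filter(
    bulk_cpm: NormalizedMatrix,
    pseudo_cpm: NormalizedMatrix,
    cpm_threshold: float = 1.0,
    fraction: float = 0.5,
) -> list[str]:
    """Genes retained after the low-expression screen, in bulk gene order.

    A gene is EXCLUDED when, in either modality, the proportion of samples with
    CPM < ``cpm_threshold`` is >= ``fraction``. Gene universes are intersected
    first; an empty intersection is an error.
    """
    _require_cpm(bulk_cpm, "bulk_cpm")
    _require_cpm(pseudo_cpm, "pseudo_cpm")
    common = [g for g in bulk_cpm.gene_ids if g in set(pseudo_cpm.gene_ids)]
    if not common:
        raise ValidationError("no genes shared between the two modalities")
    bidx, pidx = bulk_cpm.gene_index(), pseudo_cpm.gene_index()
    retained = []
    for g in common:
        low_bulk = np.mean(bulk_cpm.values[bidx[g]] < cpm_threshold)
        low_pseudo = np.mean(pseudo_cpm.values[pidx[g]] < cpm_threshold)
        if low_bulk >= fraction or low_pseudo >= fraction:
            continue
        retained.append(g)
    return retained


def select_features(
    bulk: CountMatrix,
    sc_pseudobulks: CountMatrix,
    cpm_threshold: float = 1.0,
    fraction: float = 0.5,
    ks_threshold: float = 0.4,
) -> tuple[FeatureSet, dict[str, float]]:
    """Run the full two-pass selection on raw count matrices.

    ``sc_pseudobulks`` is the per-sample pseudobulk matrix of the training
    corpus (one column per sample). Returns the ordered FeatureSet (single-cell
    gene order restricted to survivors) and a per-gene KS report for every gene
    that reached the KS screen.
    """
    bulk_cpm = cpm_normalize(bulk)
    pseudo_cpm = cpm_normalize(sc_pseudobulks)
    n_common = len(set(bulk.gene_ids) & set(sc_pseudobulks.gene_ids))
    prevalent = prevalence_filter(bulk_cpm, pseudo_cpm, cpm_threshold, fraction)
    bidx, pidx = bulk_cpm.gene_index(), pseudo_cpm.gene_index()
    ks_report: dict[str, float] = {}
    keep: set[str] = set()
    for g in prevalent:
        d = ks_statistic(bulk_cpm.values[bidx[g]], pseudo_cpm.values[pidx[g]])
        ks_report[g] = d
        if d <= ks_threshold:
            keep.add(g)
    ordered = [g for g in sc_pseudobulks.gene_ids if g in keep]
    logger.info(
        "feature selection: %d shared genes -> %d after prevalence -> %d after KS",
        n_common, len(prevalent), len(ordered),
    )
    if not ordered:
        raise ValidationError(
            f"no genes survived selection ({n_common} shared, "
            f"{len(prevalent)} after prevalence filter, 0 after KS screen)"
        )
    fs = FeatureSet(
        gene_ids=ordered,
        provenance={
            "cpm_threshold": cpm_threshold,
            "prevalence_fraction": fraction,
            "ks_threshold": ks_threshold,
            "n_bulk_samples": bulk.n_columns,
            "n_pseudobulk_samples": sc_pseudobulks.n_columns,
            "n_shared_genes": n_common,
            "n_after_prevalence": len(prevalent),
            "n_after_ks": len(ordered),
        },
    )
    return fs, ks_report
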