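"""Library-size normalizations and the model-input transform.

CPM divides each column by its total count; TPM first divides each gene by its
length in bases so that the result approximates transcript proportions. Both
rescale columns to sum to one million. Model inputs are ``log2(TPM/100 + 1)``
over a fixed, ordered feature-gene panel, with genes absent from the input
zero-filled and reported as a missing fraction.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

from .matrix import CountMatrix, GeneLengths, NormalizedMatrix, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureSet

MILLION = 1.0e6
#: TPM values are divided by this before the log2(1+x) transform.
TPM_RESCALE = 100.0


def cpm_normalize(m: CountMatrix) -> NormalizedMatrix:
    """Counts per million: ``CPM_ij = x_ij / sum_k x_kj * 1e6``.

    Every column must have a positive total count.
    """
    totals = m.values.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValidationError(
            f"zero total count in column(s): {[m.column_ids[j] for j in zero[:10]]}"
        )
    vals = m.values / totals * MILLION
    return NormalizedMatrix(list(m.gene_ids), list(m.column_ids), vals, scheme="CPM")


def tpm_normalize(m: CountMatrix, lengths: GeneLengths) -> NormalizedMatrix:
    """Transcripts per million: ``TPM_ij = (x_ij/l_i) / sum_k (x_kj/l_k) * 1e6``.

    ``l_i`` is the length of gene *i* in bases; every gene in ``m`` must have a
    length and every column a positive length-normalized total.
    """
    lvec = lengths.vector_for(m.gene_ids)
    rates = m.values / lvec[:, None]
    totals = rates.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValidationError(
            f"zero length-normalized total in column(s): "
            f"{[m.column_ids[j] for j in zero[:10]]}"
        )
    vals = rates / totals * MILLION
    return NormalizedMatrix(list(m.gene_ids), list(m.column_ids), vals, scheme="TPM")


def model_input_transform(
    m: CountMatrix, features: "FeatureSet", lengths: GeneLengths
) -> tuple[NormalizedMatrix, float]:
    """Prepare network inputs: TPM on the full matrix, subset/reorder to the
    feature panel, then ``log2(TPM/100 + 1)``.

    TPM denominators use ALL genes present in ``m`` (computed before subsetting),
    so genes outside the panel still contribute to library size. Panel genes
    absent from ``m`` become all-zero rows and are counted in the returned
    ``missing_fraction`` = |absent| / |panel|. The missing-gene policy (warn /
    refuse) is enforced by ``predict``, not here.
    """
    tpm = tpm_normalize(m, lengths)
    gidx = tpm.gene_index()
    panel = features.gene_ids
    out = np.zeros((len(panel), tpm.n_columns), dtype=np.float64)
    n_missing = 0
    for i, g in enumerate(panel):
        j = gidx.get(g)
        if j is None:
            n_missing += 1
        else:
            out[i] = tpm.values[j]
    vals = np.log2(out / TPM_RESCALE + 1.0)
    nm = NormalizedMatrix(list(panel), list(m.column_ids), vals, scheme="MODEL_INPUT")
    return nm, n_missing / len(panel)
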