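"""Generate a synthetic labeled single-cell corpus and pseudobulk it.

Builds a small corpus of 8 synthetic patients whose cells carry
malignant/nonmalignant labels, sums each patient's cells into a pseudobulk
profile, and prints each pseudobulk's ground-truth purity — the malignant
cell fraction, which is exactly what the purity model is trained to recover.
"""

import puritynet as pn

cfg = pn.FixtureConfig()  # 200 genes, 8 patients, ~300 cells each
corpus = pn.generate_corpus(cfg)
print(f"corpus: {corpus.counts.n_genes} genes x {corpus.n_cells} cells, "
      f"{len(corpus.sample_ids)} patients")

pseudobulks, purity = pn.pseudobulk_per_sample(corpus)
print("\nper-patient pseudobulk purity (malignant cell fraction):")
for s in pseudobulks.column_ids:
    n_mal, n_non = corpus.class_counts(s)
    print(f"  {s}: purity {purity[s]:.3f}  ({n_mal} malignant / {n_non} nonmalignant cells)")

eligible = pn.eligible_samples(corpus)
print(f"\n{len(eligible)} of {len(corpus.sample_ids)} patients have >= 5 cells of both "
      "classes and are eligible for purity-spectrum simulation")
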