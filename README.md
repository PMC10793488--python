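# neumo

Analysis toolkit for quantifying a **neutrophil-like monocyte (NeuMo)
transcriptional state** in monocytic myeloid-derived suppressor cells
(M-MDSCs) and monocytes, and for measuring how glucocorticoid
(dexamethasone, DEX) exposure reshapes their differential expression.

It is aimed at computational biologists analyzing paired bulk RNA-seq of
isolated myeloid populations (with or without drug exposure), or validating
monocyte-state signatures in external cohorts and single-cell data.

## What it computes

- **DEX attenuation.** For a gene differentially expressed between M-MDSC
  and monocyte in both exposure groups with the same sign, the statistic is
  the ratio of log2 fold changes, `fc_yes / fc_no`. A ratio in (0, 1) means
  the drug attenuated the difference; above 1, potentiated it. Whether the
  observed number of attenuated genes among the shared DEGs is surprising
  is judged against a resampling null: repeatedly draw the same number of
  genes from all same-direction analyzed genes and count ratios in (0, 1)
  (`neumo.attenuation`). The equivalent change index,
  `sign(a·b)·min(|a|,|b|)/max(|a|,|b|)`, compares fold changes across
  studies on a [-1, 1] scale.
- **Preranked GSEA and the consensus metagene.** A weighted
  Kolmogorov-Smirnov enrichment score over a log2FC-ranked gene list, with
  a gene-label permutation null, per-sign normalized enrichment scores
  (NES), pooled-NES FDR and leading-edge extraction (`neumo.enrichment`).
  The NeuMo signature is the intersection, across exposure groups, of
  genes in ≥ 50% of the enriched sets' leading edges; a sample's score is
  its mean log2CPM over the signature genes (`neumo.metagene`), with
  rank-based group comparisons and inverse-variance (DerSimonian-Laird)
  meta-analytic pooling across cohorts.
- **Guided NMF deconvolution.** A binary gene-by-state guide matrix
  (markers thresholded at log2 fold-enrichment ≥ 0.58) constrains a
  nonnegative factorization `X ≈ S·F`; masked multiplicative updates keep
  non-marker signature entries at exactly zero, and per-sample Neu-like /
  DC-like fractions are reported on the unit simplex
  (`neumo.deconvolution`).
- **Clustering stability and set overlap.** Adjusted-Rand-index stability
  sweeps over a clustering-resolution grid (choose the resolution just
  before the mean reseeded ARI first drops), and overlap-coefficient
  matrices over gene-set collections (`neumo.cluster_eval`).
- **Synthetic data.** Generators for paired negative-binomial counts with
  planted, attenuated fold changes; guide-respecting mixtures with known
  fractions; and toy single-cell populations with discrete states
  (`neumo.simulate`) — every downstream stage is testable with known truth.

## Worked example

```python
import pandas as pd
from neumo.simulate import simulate_paired_counts
from neumo.expression import filter_low_expression, log2cpm, paired_de
from neumo.attenuation import (classify_attenuation, class_counts,
                               attenuation_null, attenuation_test)

study = simulate_paired_counts(n_genes=2000, n_pairs_yes=6, n_pairs_no=12,
                               de_fraction=0.2, attenuation_factor=0.5, seed=1)
cm = filter_low_expression(study.count_matrix())
em = log2cpm(cm)
de_yes = paired_de(em, study.pairing("Yes"))
de_no = paired_de(em, study.pairing("No"))

merged = pd.DataFrame({"fc_yes": de_yes.log2fc, "fc_no": de_no.log2fc})
same_dir = merged.fc_yes * merged.fc_no > 0
shared_degs = merged.index[(de_yes.fdr <= 0.05) & (de_no.fdr <= 0.05) & same_dir]
records = classify_attenuation(merged, restrict_to=shared_degs)
counts = class_counts(records)

null = attenuation_null(merged[same_dir], n_draw=len(shared_degs),
                        n_iter=10_000, seed=2)
p, outside = attenuation_test(counts["attenuated"], null)
print(f"shared same-direction DEGs: {len(shared_degs)}")
print(f"attenuated: {counts['attenuated']}  potentiated: {counts['potentiated']}")
print(f"null range: [{null.min}, {null.max}]  empirical p = {p:.2e}  outside: {outside}")
```

which prints

```
shared same-direction DEGs: 70
attenuated: 68  potentiated: 2
null range: [26, 57]  empirical p = 1.00e-04  outside: True
```

The simulation planted an attenuation factor of 0.5 on every
differentially expressed gene, so nearly all shared DEGs (68 of 70) have a
fold-change ratio in (0, 1) — far above the null's [26, 57] range of
attenuated counts among random same-direction genes, hence the smallest
attainable empirical p at 10,000 resampling iterations.

The same chain is available from the shell:

```sh
neumo run --config config.yaml --stages simulate,de,attenuation
neumo attenuate --de-yes de_Yes.tsv --de-no de_No.tsv --n-iter 100000 --seed 1
```

Every pipeline run writes a `manifest.json` with parameters, derived seeds
and input/output checksums, and reruns are byte-identical.

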