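# repde

Reproducibility-based detection of differentially expressed (DE) genes in
small cancer cell-line experiments that have only **technical replicates**.

Typical drug-resistance experiments profile a resistant and a sensitive
clonal cell line with two or three technical replicates each. With no
biological variance to model, the common practice is a fold-change (FC)
cut-off, which lacks statistical control and is biased toward genes that
are lowly expressed in both lines (where measurement noise inflates
ratios), while missing highly expressed genes whose absolute differences
are large but whose ratios are modest. `repde` implements an alternative:
treat every resistant–sensitive replicate pair as one *experiment*, rank
genes within each experiment, and call a gene DE only when its
dysregulation direction **reproduces across independent experiments**
(pairs sharing no sample).

## The method

For a pair *j* with linear-scale expression values *E\_R* and *E\_S* of
gene *i*:

* **PD** (pairwise difference): `PD_ij = E_R − E_S`; up-regulated iff
  PD > 0. Sensitive to high-expression genes with large absolute shifts.
* **PFC** (pairwise fold change): `PFC_ij = E_R / E_S`; up-regulated iff
  PFC > 1; ranked by the symmetric magnitude `max(PFC, 1/PFC)`.
  Sensitive to low-expression genes with large ratios.

Two gene lists sharing *k* genes of which *s* agree in direction get the
consistency score *s/k*, tested against the upper binomial tail

    P(X ≥ s) = Σ_{i=s}^{k} C(k, i) p_e^i (1 − p_e)^{k−i},   p_e = 0.5,

and are *significantly reproducible* when p < 0.01. This test drives two
stages:

1. **Pair selection** — among all r×s sample pairs, seed with the
   independent duo whose top-300 consistency is most significant, then
   admit pairs one by one while they are independent of every selected
   pair and consistent (p < 0.01) with at least one. Pairs left out flag
   unreliable replicates.
2. **Block-wise DE search** — for each duo of selected pairs, walk list A
   in blocks of 300 genes, accepting a block when the genes it shares
   with the cumulative top prefix of list B agree in direction at ≥ CT
   (default 90%); on failure, look one block ahead, then halve the step
   and re-partition the tail to recover the top of the failed block. Run
   both directions (degAB, degBA), merge, and across duos delete genes
   with conflicting directions.

Optionally, the final DE list is tested for gene-set over-representation
with the hypergeometric upper tail and Benjamini–Hochberg FDR control at
5%.

## Worked example

Simulate a 3-vs-3 technical-replicate design (2000 genes, 100 planted
high-expression/large-difference genes, 100 planted low-expression/
large-fold genes) and run both pipelines:

```sh
repde simulate --outdir demo/sim --seed 5
repde run --matrix demo/sim/matrix.tsv --annotation demo/sim/annotation.tsv \
          --outdir demo/run --score pd --score pfc
```

prints

```json
{
  "conflicts_PD": 0,
  "conflicts_PFC": 0,
  "conflicts_combined": 0,
  "de_genes_PD": 152,
  "de_genes_PFC": 147,
  "de_genes_combined": 253,
  "selected_pairs_PD": 3,
  "selected_pairs_PFC": 3
}
```

All three mutually independent pairs are selected (no replicate is
corrupt here), PD finds 152 reproducible DE genes and PFC 147; their
union after conflict removal has 253 — the two score rules capture
largely complementary gene sets, which is the point of combining them.
`demo/run/pair_report_PD.tsv` holds every independent pair-duo
comparison, e.g.

```text
pair_a    pair_b    K    S   S/K(%)  p
R1 VS S1  R2 VS S2  206  166 80.58%  <2.2E-16
R1 VS S1  R2 VS S3  208  165 79.33%  <2.2E-16
```

i.e. the top-300 PD lists of two independent experiments shared K = 206
genes, S = 166 of them with the same direction — far beyond the 50%
chance level. `demo/run/de_genes_PD.tsv` lists each DE gene with its
direction and the number of supporting pair-duo comparisons.

The same stages are available as library functions
(`repde.select_reproducible_pairs`, `repde.multi_pair_de`,
`repde.consistency`, `repde.enrich`, ...) on pandas-backed
`ExpressionMatrix` objects.

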