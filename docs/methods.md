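# Methods

## Model and assumptions

`repde` targets two-group designs with *clonal* cell lines: every
replicate of a phenotype (drug-resistant R, drug-sensitive S) measures
the same underlying expression profile plus technical noise. Under that
assumption any resistant–sensitive replicate pair is an experiment
estimating the same set of expression differences, and two pairs sharing
no sample are independent experiments. A real DE gene should then show
the same dysregulation direction in independent pairs; a noise-driven
gene agrees only by coin flip. The package never models biological
variance — it is explicitly unsuitable for tissue samples or other
designs with biological replication, where variance-based tests
(e.g. limma/SAM-style moderated statistics) are the right tool.

All scoring operates on linear-scale intensities: the pairwise
difference `PD = E_R − E_S` and pairwise fold change `PFC = E_R / E_S`
are defined on non-log values. Preprocessing helpers (quantile
normalisation, probe collapsing) therefore work on log2 internally and
return linear matrices.

## Statistical core

Direction concordance of two lists sharing *k* genes with *s* agreements
is scored *s/k* and tested against the Binomial(k, 0.5) upper tail;
"reproducible" means p < 0.01. Tail probabilities are computed in log
space (log-sum-exp over binomial log-pmf terms), so the deep tails that
arise at k ≈ 3000 (p ~ 1e-900) remain exactly representable as `log_p`
while `p_value` reports 0.0 and the display string `<2.2E-16`.
A comparison with k = 0 is flagged *not evaluable* — never scored 0 —
and downstream stages treat it as a failure (pair selection) or block
rejection (DE search).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `top_n` | 300 | genes per list compared during pair selection |
| `ct` | 0.90 | minimum block consistency score in the DE search |
| `init_step` | 300 | initial block size of the DE search |
| `min_step` | 1 | halving stops when the step would drop below max(min_step, 2) |
| `p_e` | 0.5 | null probability of direction agreement |
| `alpha` | 0.01 | significance rule for reproducibility |
| `floor` | 1.0 | intensity floor applied before fold changes |
| `fdr_level` | 0.05 | BH threshold for enrichment |

A large initial step lets weakly consistent genes at the bottom of a
block ride in on the strong top; a small one makes block scores unstable
(few shared genes) and terminates the search early. 300 with CT = 90% is
the recommended operating point; raising CT to 95% shrinks the DE list,
lowering it to 85% grows it (monotonicity is checked in the test suite).

## The block search, precisely

Lists A and B (each ranked by descending score magnitude) are divided
into consecutive blocks of `k` genes; the trailing remainder forms a
final short block rather than being dropped, since it is reached only
after every earlier block passed. Walking A's blocks in order, block
A(i) is evaluated against the *cumulative prefix* B(1..i) — under
synchronous partitioning the prefix always ends where the current A
block ends, also after re-partitioning. A block passes when its shared
genes agree at ≥ CT; its shared, direction-concordant genes are
admitted. On the first failure at block m:

1. *Lookahead*: block m+1 is evaluated against B(1..m+1); if it passes,
   the walk resumes after it. Block m itself is **not** admitted — its
   genes can only return through step-halving. This is the stricter of
   the two readings of the lookahead rule and is recorded in the audit
   log.
2. *Halving*: otherwise the step becomes `k // 2` and both tails are
   re-partitioned from the start of block m. The recursion exits when
   the failed block shares no genes with the prefix or the halved step
   would fall below max(min_step, 2) — the guard prevents k = 1 churn,
   where a "block" cannot produce a meaningful proportion.

Both directions are searched (degAB and degBA) and merged; a
within-duo direction conflict is impossible by construction (agreement
is the membership criterion) and asserted. Across duos, genes whose
directions conflict between any two duo results are deleted and
reported. Equivalence with a literal block-list transcription of the
procedure is verified on 500 random instances in the test suite.

Ties in ranking magnitude are broken by lexicographic gene ID; the seed
duo of pair selection breaks p-value ties by higher score then
lexicographic pair IDs; greedy admission takes the most significant
qualifying candidate first. These choices make every stage deterministic
and invariant to input column order.

## Synthetic data

The generator emulates the structure the algorithm assumes, not any real
dataset: gene baselines log2 ~ N(7, 2); technical noise on the log2
scale with sd(µ) = 0.1 + 2/√µ, so fold changes of dim genes are unstable
while bright genes measure precisely; 3 vs 3 replicates by default. The
sensitive parental line is the unperturbed reference profile and
dysregulation is modelled in the resistant derivative only, matching how
resistant lines are produced (stepwise drug exposure of the parental
line). Two planted regimes of 100 genes each mirror the two score rules'
sweet spots:

* *high*: baseline log2 ~ N(11, 0.5), additive shift of 1000 intensity
  units (large |PD|, fold ≈ 1.5) — found by PD, largely missed by PFC;
* *low*: baseline log2 ~ N(4.5, 0.5), 8-fold shift (large PFC, |PD| of a
  few dozen units) — found by PFC, largely missed by PD.

A sample listed in `corrupt_samples` is re-drawn as an independent
random profile (fresh baselines, no planted signal), emulating a failed
array; pair selection should exclude every pair containing it, which the
suite checks across 100 seeds (the ~2–3 % residual admissions are the
one-sided α = 0.01 rule firing by chance, not a signal leak).

What passing these simulations does **not** show: robustness to probe
cross-hybridisation, batch effects, normalisation artefacts, or any
violation of the clonality assumption — none of these are generated.

## Numerical choices and degenerate inputs

* Quantile normalisation uses average ranks for ties and interpolates
  fractional ranks between adjacent rank means; it matches limma's
  `normalizeQuantiles` to ~1e-14 on dense random matrices and is
  idempotent to 1e-9 on the log2 scale.
* Probe collapsing preserves single-probe genes bit-exactly (no log
  round trip for them).
* Zero intensities are not defined for PFC; `floor_values` (default
  floor 1.0) is applied before fold-change scoring, and
  quantile normalisation refuses zeros with a pointer to it.
* Genes with PD = 0 or PFC = 1 carry no direction and are excluded from
  ranked lists rather than ranked last.
* A 1×1 design enumerates one pair and fails pair selection with
  "insufficient replicates"; empty ranked lists make consistency
  not-evaluable rather than raising.

## Problem sizes in the test suite

The bundled simulations use 2000 genes, 3 vs 3 replicates and 200
planted DE genes — large enough that top-300 comparisons and 300-gene
blocks behave as in full-scale transcriptomes (the block mechanics
depend on block size, not genome size), small enough that the whole
suite runs in well under a minute. Oracle equivalence uses instances of
up to 60 genes with steps up to 10, where the literal transcription is
tractable.

## Known limitations

* The method does not control the FDR of the DE list; reproducibility
  filtering lowers, but does not bound, false discoveries. Enrichment
  analysis of the resulting list is the recommended plausibility check.
* With more than three replicates per phenotype, greedy admission of
  independent pairs is not guaranteed to find the maximum set of
  mutually independent reproducible pairs; the greedy rule is
  implemented as specified.
* RMA summarisation of raw Affymetrix data is out of scope; matrices are
  expected already summarised (the Illumina-style log2 + quantile path
  is provided).
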