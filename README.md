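# ssmutpa

Single-sample, mutation-induced pathway activity from network propagation of
somatic mutations, with downstream survival-based subtype discovery.

Somatic mutation profiles are extremely sparse: two patients with the same
disease may share almost no mutated genes, even when their mutations hit the
same biological processes. `ssmutpa` addresses this for anyone stratifying
cancer cohorts from mutation calls alone (no expression data needed). It maps
each sample's nonsilent mutations onto a protein–protein interaction (PPI)
network and converts them into a per-sample **pathway activity profile**, the
ssMutPES (single-sample mutation-based pathway enrichment score), which is
smooth, comparable across samples, and usable for survival analysis and
clustering.

## Method

For a sample with K mutated genes mapped into a connected PPI network of
N genes:

1. **Local seed weighting.** Each mutated seed gene G_i with M_i neighbors
   and X_i mutated neighbors is weighted by its neighborhood mutation excess.
   Under a hypergeometric model the expected count is E(X_i) = M_i·K/N, and
   with w_i = X_i − E(X_i):

       W_i = log_α( w_i · I(w_i > 0) + α ),   α = 2 by default,

   so W_i ≥ 1 with equality when the excess is non-positive — seeds sitting
   in mutated neighborhoods are up-weighted, isolated seeds are not punished.

2. **Global propagation.** The weights are normalized into a restart
   distribution p₀ and propagated with a seed-weighted random walk with
   restart on the column-stochastic adjacency A:

       p_{t+1} = (1 − c) A p_t + c p₀,   c = 0.7,

   iterated until the L1 change falls below 1e-10. The steady state p is the
   sample's global gene-weight vector.

3. **Pathway scoring.** Genes are ranked by p (descending) and each pathway P
   is scored with a weighted Kolmogorov–Smirnov running sum: walking down the
   ranked list, hits accumulate |r_j|^p′/N_R (N_R the pathway's total weight
   mass, p′ = 1 by default) and misses accumulate 1/N_NotP. The ssMutPES is
   the maximum of the running difference, floored at zero, hence in [0, 1].

4. **Subtyping.** Pathways prognostic for overall survival are screened with
   univariate Cox models (Wald p < 0.05); a Gaussian-kernel similarity over
   Euclidean score distances is spectrally clustered, with the number of
   clusters chosen by the mean silhouette over k = 2..6; subtypes are compared
   with the multi-group log-rank test.

A synthetic-fixture module generates networks, pathways, mutation cohorts
with planted pathway programs, and survival times, so the entire pipeline is
testable end to end without downloading anything.

## Worked example

Simulate a 200-gene network with two 30-sample subgroups, each enriched 10×
for mutations in its own network-localized pathway program (PW01 carries a
3× event hazard relative to PW02), then score and cluster:

```bash
ssmutpa simulate --spec spec.json --out-dir data
# wrote network (200 nodes, 1351 edges), 10 pathways, 60 samples to data

ssmutpa score --table data/mutations.tsv --network data/network.tsv \
              --gmt data/pathways.gmt --out scores.tsv
# wrote scores.tsv and scores.meta.json

ssmutpa cluster --scores scores.tsv --survival data/survival.tsv --out subtypes
# k=2, 2 screened pathways, log-rank p=5.07e-05
```

The score matrix holds one ssMutPES column per sample:

```
pathway   S0001   S0002   S0003
PW01     0.9238  0.9092  0.9568
PW02     0.4204  0.5414  0.4592
PW03     0.5785  0.4496  0.6619
```

S0001–S0003 belong to the PW01 subgroup, and PW01 is their top-scoring
pathway. The Cox screen recovers exactly the two planted programs with
opposite hazard directions — PW01 is the risk program (HR = 36.2,
p = 8.8e-04) and PW02 the protective one (HR = 0.059, p = 8.1e-05) — and
spectral clustering selects k = 2 subtypes whose survival separates at
log-rank p = 5.1e-05.

The same stages are available as library calls (`score_cohort`, `cox_screen`,
`similarity_matrix`, `choose_k_and_cluster`, `logrank_compare`) for use from
Python.

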