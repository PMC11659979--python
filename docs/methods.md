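# Methods

## Model

The package treats a tumor's somatic mutations as noisy observations of a
small number of perturbed processes, and uses network propagation to denoise
them. The assumptions are:

- the PPI network is undirected, simple and connected; analysis is restricted
  to its largest connected component, and gene symbols are matched
  case-sensitively without alias resolution;
- only nonsilent (protein-affecting) variants matter; a gene mutated more
  than once in a sample counts once (set semantics);
- mutations whose network neighborhoods are also mutated are more likely to
  be drivers of a perturbed module, which motivates the hypergeometric
  local weight;
- the influence of a mutation decays with network distance in the way a
  restarting random walk does; the restart probability c controls the decay;
- a pathway is "mutation-induced" in a sample exactly when its member genes
  concentrate at the top of the propagation-ranked gene list, measured by the
  weighted Kolmogorov–Smirnov running sum.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 2 | log base of the local weight; sets the floor W = 1 and the scale of up-weighting. Must be > 1. |
| `restart` (c) | 0.7 | probability of restarting at the seeds each step; higher c keeps mass near the seeds. Results are known to be insensitive over 0.1–0.9. |
| `tol` | 1e-10 | L1 convergence threshold for the walk; with c = 0.7 the iteration contracts by 0.3 per step and converges in ~20–60 iterations. |
| `p_exp` | 1 | exponent on gene weights in the running sum; 0 recovers the classical unweighted KS statistic. |
| `min_sources` | 2 | edge filter for multi-source PPI edge lists: keep edges supported by strictly more than this many sources. |
| `alpha_level` | 0.05 | Cox screen significance level, uncorrected Wald p by default; a Benjamini–Hochberg flag is available. |
| k range | 2–6 | candidate cluster numbers for the silhouette selection. |

Numerical conventions: the convergence metric is the L1 norm (natural for
probability vectors); rank ties are broken by gene symbol ascending, making
every score deterministic; the running-sum maximum is taken over all N
positions *before* the zero floor is applied; pathway genes absent from the
network are dropped per pathway; the complement count N_NotP is taken within
the network gene list, not within any larger gene universe. Degenerate cells
(no pathway gene in the network, pathway covering the whole network, zero
weight mass) are skipped with a reason code and stored as 0. A sample with no
mutation mapping into the network yields an all-zero column and a warning.
The largest-component tie, which cannot occur on real PPI data with one
dominant component, is broken toward the component containing the
lexicographically smallest symbol.

In the local weighting, the expectation E(X_i) = M_i·K/N deliberately counts
the seed itself in K even though a gene cannot neighbor itself; using K − 1
would change scores and is not done. The indicator uses strict inequality
w_i > 0.

## Similarity and clustering choices

The distance-to-similarity conversion for spectral clustering is a Gaussian
kernel s = exp(−d²/2σ²) on Euclidean distances between screened score
vectors, with σ the median nonzero pairwise distance (the standard
median-heuristic bandwidth); the silhouette used for selecting k is computed
on the distances themselves. k-means label assignment runs with a fixed,
exposed random seed. These choices were genuinely open; the kernel-on-median
bandwidth was picked because it is the common default for spectral clustering
on distance data and has no free scale parameter.

## What the synthetic generator emulates

`simulate.FixtureSpec` defaults define the study conditions used throughout
the tests and the acceptance script:

- **Network:** Barabási–Albert preferential attachment, 500 nodes, m = 7
  (mean degree ≈ 14, matching the edge density of curated human PPI
  networks, which run around 7 edges per node). A planted-community model is
  also available.
- **Pathways:** 20 gene sets of 20–40 genes. Planted pathways are grown by
  short restarting random walks from a well-connected start node, so their
  members are topologically coherent — propagation can only concentrate
  signal on a network-localized program, which is the mechanism under test.
  Background sets are sampled uniformly from the genes outside every planted
  program: if background sets shared planted genes they would inherit the
  planted program's top-ranked members and the recovery readout would measure
  set overlap rather than the method.
- **Cohorts:** each gene mutates independently at a background rate of 0.04
  per sample (a few dozen mutated genes per sample, consistent with typical
  nonsilent per-tumor counts on a network of this size), multiplied by 10 for
  the subgroup's planted pathway.
- **Survival:** exponential event times with baseline rate ln 2/500 per day
  (median survival 500 days) and a 3× rate ratio between the two planted
  subgroups in the two-program design; exponential censoring at 3e-4 per day
  (~18% censoring in the slower group). Exponential forms keep the log-rank
  power analysis tractable.

What the generator does **not** emulate: mutational signatures and
hypermutators, copy-number events, gene-length effects on mutation
probability, pathway overlap (real KEGG pathways share genes), and the
10–100× larger scale of real networks and cohorts. Passing tests therefore
demonstrate the machinery is correct and the pipeline recovers planted
signal under clean conditions; they do not certify performance on real
tumor cohorts.

## Experiment sizes

The validation experiments (tests and `scripts/acceptance.py`) use: 50
random networks of up to 200 nodes for the propagation-vs-direct-solve
check; 200 random instances of up to 50 genes for the running-sum oracle
check; one 100-sample single-program cohort for planted recovery; one
100-sample two-program cohort for subtype recovery; 10 independent null
cohorts × 20 pathways (200 Cox fits) plus 200 log-rank replicates for
calibration; and 2 removal replicates per fraction (5/10/15/20%) for the
edge-removal robustness experiment, summarized by the median per-sample
Spearman correlation against the intact-network scores. These sizes keep the
full suite in well under a minute of compute while leaving the statistical
checks adequately powered.

## Known limitations

- The weighted KS statistic saturates on small gene sets: a lean set whose
  only in-network weight mass sits on one highly ranked gene can score close
  to a genuinely enriched program. At desk scale this is mitigated by the
  fixture design above; on real data it argues for interpreting single very
  high scores of small pathways with care.
- Silhouette-based k selection is the least stable stage: on stochastic
  two-program cohorts the silhouette profile over k is sometimes nearly flat
  and a larger k (splitting a true group) can win on particular
  realizations, which lowers the adjusted Rand index against truth even
  while the log-rank separation stays strong. The fixed-seed acceptance
  checks pass; across arbitrary seeds, expect occasional k > 2 selections.
- The Cox screen uses uncorrected p-values by design (matching common
  practice for pathway screens feeding a clustering stage); with many
  pathways and no true signal it passes ~5% of them, and the clustering then
  falls back on whatever structure those noise pathways carry.
- Scores are floored at zero: the method is one-sided by construction and
  cannot represent pathways *depleted* at the top of the ranking.
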