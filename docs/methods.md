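# Methods notes

## Model and assumptions

The pipeline treats pleiotropy as a transitive signal: if a locus carries
positively correlated SNP effects for a predisposing disease and breast
cancer, genes in that locus that are independently associated with the
predisposing disease and dysregulated in the same direction in both
diseases are taken as drivers of the shared etiology. Connectivity in a
protein–protein interaction network then stands in for functional
relatedness: a canonical pathway is "connected" to a gene when a restart
random walk started at the gene deposits unusually much stationary mass on
the pathway's members, relative to walks started at random genes of
comparable degree.

Assumptions worth keeping in mind:

- Propagation uses the *unweighted* adjacency of the confidence-filtered
  graph. STRING confidence scores gate which edges exist (≥ 700 on the
  0–1000 scale) but do not weight the walk; the filter threshold is the
  conventional "high confidence" 0.7.
- Only pathway *membership* matters; pathway topology is ignored.
- Degree is the only topological covariate matched in the null. Quartile
  bins are coarse: within the top bin, hubs of degree 20 and 200 are
  treated as exchangeable.
- Direction concordance uses one signed statistic per gene per disease;
  z = 0 carries no direction and is treated as discordant.

## Parameters

| parameter | default | notes |
|---|---|---|
| `restart` | 0.8 | probability of returning to the seed after each step; high restart keeps mass local (1–2 steps from the seed), which is what makes pathway-level means discriminative |
| `n_perm` | 1000 | permuted seeds per (seed, pathway) pair, drawn with replacement from the seed's degree bin |
| `tol` | 1e-10 | L1 stopping tolerance of power iteration; contraction factor is (1 − restart), so ~15 iterations at the default restart |
| `alpha` | 0.05 | threshold on Bonferroni-adjusted permutation p |
| `window_bp` | 10,000 | positional mapping window, inclusive at the boundary (a gap of exactly 10 kb maps; 10,001 bp does not) |
| `min_score` | 700 | STRING combined-score cut (integer 0–1000 scale) |
| `include_seed` | true | the seed's own score is included in the pathway mean when the seed is a member — the natural reading of "average score of genes within the pathway" |

Coordinates are 1-based with inclusive interval ends throughout; overlap
means at least one shared base.

## The permutation p-value and Bonferroni

The permutation p-value is the empirical frequency
`#{permuted mean ≥ observed} / n_perm`, which is exactly 0 when the
observed score beats every permuted draw. This choice is deliberate and
load-bearing: significance requires `p_perm × m < 0.05` with
`m = #seeds × #pathways` (gene stage) or `m = #targets` (drug stage), and
m is typically in the hundreds to hundreds of thousands. Only exact zeros
— seeds that beat the entire degree-matched null — can survive that
adjustment; with an add-one estimator (floor `1/(n_perm+1)`) *no* pair
could ever reach adjusted significance once `m > 0.05·(n_perm+1)`, and the
method would return no results at any realistic scale. The add-one
estimator remains available (`PPRParams.add_one_p`) for calibration work
where a strictly positive p is wanted.

Per-(seed, pathway) RNG substreams are derived by hashing
`(rng_seed, seed gene, pathway name)`, so results are identical regardless
of evaluation order or caching.

Degenerate cases: a degree bin with fewer than two other members falls
back to the nearest non-empty bin (warning logged); fewer than four
distinct degrees yields degenerate bins (warning); equal degrees always
share a bin, so on a regular graph all nodes land in one bin.

## Multiple-testing families

- Gene-based association p-values are BH-adjusted genome-wide over the
  whole association file, not just locus genes, before the 0.05 filter.
- The gene stage Bonferroni family is (#shared genes in network) ×
  (#pathways). The drug stage family is the number of distinct
  network-mapped targets across all drugs of the predisposing disease;
  the shared-pathway set is fixed by the gene stage and is not counted
  again. A target shared by several drugs is tested once and attributed
  to each.

## Synthetic data: what it does and does not emulate

The generator emits every input format the pipeline reads — STRING-style
links and alias files (including sub-threshold edges, duplicate records, a
self-loop and alias-less proteins, to exercise the loader), a GMT pathway
file, 1-based gene annotations, a signed correlated-loci table, a
gene-association table with genome-wide p-values, a signed-z table, and
drug/indication tables — with a known planted chain:

- Each planted pathway is a dense module (within-module edge probability
  0.35) whose *anchor* gene is adjacent to every other member and has no
  edges outside the module. Because every degree-bin mate of the anchor
  either leaks walk mass outside the pathway (fellow members have
  background edges) or deposits almost none on it (non-members), the
  anchor's pathway mean exceeds every permuted draw by a structural
  margin — the planted signal is recoverable by design, not by tuning.
- Anchors sit inside positively correlated loci with planted-significant
  association p-values and concordant z; decoy locus genes get null
  p-values or discordant signs. Two genes are placed exactly 10,000 and
  10,001 bp outside loci to pin the mapping boundary.
- True-positive drugs target anchors; decoy drugs target random
  non-module genes; one decoy's only target is absent from the network.
  The breast-cancer list overlaps the true positives so the evaluation
  has signal.
- Defaults: 2,000 genes on 22 autosomes, scale-free background
  (Barabási–Albert, m = 3, plus uniform noise edges at density 5e-4), 100
  pathways of 10–50 genes (4 planted modules drawn from the small end of
  that range to keep the signal local), 18 loci of 150 kb (12 positive),
  7 shared genes of which ~60 % are wired into modules, 60 drugs
  (12 true positives). One disease pair is generated per run.

Not emulated: linkage disequilibrium and SNP-level signal (locus tables
are generated directly), correlated pathway overlap, realistic degree
assortativity of drug targets, multiple disease pairs with shared drugs,
and any pharmacology. Passing tests therefore show that the pipeline's
*inference machinery* behaves correctly under its own null and recovers a
plantable signal; they say nothing about the biological validity of any
specific real-data finding.

## Problem sizes in the test and acceptance runs

Unit tests run on 300–400-gene bundles; the calibration check uses the
2,000-gene default network with 500 replicate seed/pathway pairs at
n_perm = 200; recovery checks run the full pipeline at default settings
(n_perm = 1000) over 20 seeds in the test suite and 10 seeds in
`scripts/acceptance.py`. Propagation vectors and per-bin pathway scores
are cached per network, which is what keeps 10⁶-scale permutation draws
cheap; a cache hit is contractually identical to recomputation.

## Known limitations

- Region-based positional mapping uses locus bounds ±10 kb directly
  rather than per-SNP windows; the two coincide up to SNP density.
- The conditional-MLE odds ratio and one-sided p come from
  `scipy.stats`; with a zero cell in the denominator the sample odds
  ratio is reported as infinity.
- The leave-one-pair-out re-analysis is available by listing a pair in
  `exclude_pairs`; the evaluation universe then shrinks to the remaining
  indications.
- Redundant (near-duplicate) pathways are retained as-is; they inflate
  the Bonferroni family and can mask borderline signal.
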