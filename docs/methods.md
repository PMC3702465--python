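# Methods

## Model and assumptions

`netprio` ranks the genes of an undirected PPI network by similarity to a
seed set of known disease genes, under the working assumptions that disease
genes (i) are topologically prominent — hubs and bottlenecks — and close to
other disease genes in the network, and (ii) co-express with one another, so
expression clusters that overlap a disease-gene-like pool are informative.
Because the two evidence channels fail differently — topology is
seed-independent except through proximity, expression overlap depends on a
GO-derived gene pool that is noisy by construction — their rank-level fusion
degrades gracefully when the seed set is contaminated, which pure diffusion
methods do not.

### Network score S_N

Three per-gene attributes: degree `c_d`; betweenness `c_b`, summed over
unordered source–target pairs with endpoints excluded and no normalization
(any affine normalization is rank-neutral, which the tests assert
implicitly by checking ranks against a literal path-enumeration oracle);
and `c_spl`, the mean shortest-path distance to the reachable seed genes.
Directions are configurable flags with defaults: degree high-is-good,
betweenness high-is-good (disease genes as hubs/bottlenecks), seed distance
low-is-good. A seed's own zero distance is included by default
(`exclude_self` flips this). Genes reaching no seed carry no proximity
evidence and share the worst ranks.

Raw attributes are converted to fractional (tie-averaged) ranks. Because
rank positions live on different effective scales across evidence sources,
every rank vector is rescaled to [0, 1] via `(rank − 1)/(N − 1)` before
averaging; S_N is the mean of the three rescaled ranks. This keeps S_N and
S_E commensurable while preserving every ordering.

### GOSet derivation

Terms are tested one-sided hypergeometrically (study hits k of n seeds
against K of N universe genes; universe defaults to the network's genes,
overridable). Only the biological-process aspect is tested by default; no
multiple-testing correction is applied for term *selection* because the
selection is a fixed-size top-K (default K = 50), optionally unioned with an
editable hallmark-term list; boundary ties are all included. Evidence-code
filtering exists but is off by default — uncurated (IEA) annotations are
deliberately part of the signal model, since the GOSet is *meant* to be an
enriched-but-noisy pool. Annotation propagation up the GO graph is not
performed. The selected terms map back to all annotated genes intersected
with the network.

### Expression score S_E

Preprocessing drops rows with missing values, genes outside the network,
and resolves duplicate gene rows to the largest-mean profile (first
occurrence on ties); datasets with fewer than five samples are deleted.
Clustering is affinity propagation on the pairwise Pearson correlation
matrix — damping 0.9, preference = median off-diagonal similarity, max 1000
iterations, convergence window 50 (the algorithm's customary defaults);
zero-variance rows are dropped (Pearson undefined) and non-convergence
falls back to singleton clusters with a warning rather than failing a whole
run.

Cluster/GOSet overlap significance: the observed overlap is compared with
1000 same-size draws from the dataset's genes without replacement; the
p-value is the upper normal tail of the standardized observed count. A
continuity correction (observed − 0.5) is applied by default: without it
the normal tail misses the matching discrete tail by about half the
probability mass at the observed count, which at typical cluster sizes
exceeds the agreement the test suite demands against the exact
hypergeometric tail; an uncorrected flag and an empirical-quantile mode are
provided. A degenerate null (sd = 0) yields p = 1 unless the observed count
exceeds the null mean, in which case the smallest positive float is
reported. Within a dataset clusters are ranked ascending by p (ties
averaged) and rescaled to [0, 1] (a lone cluster maps to 0.5). A gene's S_E
averages over the datasets containing it; genes in no dataset get a neutral
0.5 — absence of evidence is not negative evidence, and it keeps the fused
ranking defined over the whole network.

### Fusion, P-score, RWR

`S = (1 − λ) S_N + λ S_E` with λ ∈ [0, 1], default 0.2; final positions are
tie-averaged ranks of S. The P-score is the mean final position of seed
genes at or above the top-10% cutoff `floor(0.1 N)`; it is undefined
(reported absent) when no seed qualifies. Note the criterion is not
monotone in ranking quality — a seed dropping *out* of the top decile can
lower the mean — so λ-tuning reports the full curve, not just the argmin
(ties go to the smallest λ).

The RWR baseline iterates `p ← (1 − r) W p + r p0` with W the
column-normalized adjacency (without normalization the iteration diverges;
zero columns of isolated genes are left as-is and their mass re-enters
through the restart term), r = 0.7, L1 convergence tolerance 1e−10,
max 10,000 iterations. p0 is uniform over the seeds present in the network.

### Noise protocols

GOSet noise: `ratio × |known|` genes sampled from GOSet∖Known; known and
noise genes are independently split into five near-equal folds; each fold
trains on 4/5 of both. The method ranks **all** network genes from the
noisy training seeds; Precision/Recall/F at threshold k are computed on the
held-out pool (fold's known + noise genes), with B = pool genes whose
*global* position ≤ k and A = the fold's known genes; a `global_topk`
option evaluates against the genome-wide top k instead. Held-out noise
genes count as negatives. During cross-validation the proposed method's
GOSet is rebuilt from the training seeds only (no leakage of held-out genes
into the expression reference); a flag disables the rebuild. F = 0 whenever
precision + recall = 0. RNG discipline: one master seed; substreams keyed
by (experiment, method, ratio, fold), so the whole benchmark is
bit-reproducible and independent of evaluation order.

Random noise: random non-seed network genes are added to the seeds at a
given ratio and the proportion of them each method places in its top 10% is
reported (absent at ratio 0).

## Synthetic data

The generator plants exactly the structure the method exploits and nothing
else. Background network: Barabási–Albert preferential attachment
(2 edges/node) — real PPI degree distributions are heavy-tailed and the
degree component of S_N is meaningless on Erdős–Rényi graphs; node labels
are shuffled so module membership is independent of attachment age. Module:
a random gene subset densified to internal edge probability 0.3. KnownSet:
a random module subset. GOSet: a purity-weighted module/background mixture
— better than random, worse than the known set, mimicking a GO-derived
pool. Annotations: planted terms hit module genes at rate 0.8 versus 0.05
in the background; non-planted terms annotate uniformly at the background
rate. Expression: module genes share a latent factor per dataset (loading
√ρ, residual √(1−ρ)·noise_sd, so pairwise Pearson = ρ/(ρ + (1−ρ)·noise_sd²)
— the configured ρ at noise_sd = 1, vanishing as noise_sd → ∞); background
genes are white noise; duplicate rows (lower-mean decoys), `null` cells and
off-network rows exercise preprocessing.

Reference scenarios, chosen once as desk-scale analogues of a genome-scale
study:

* **recovery scenario** (the default constructor): 500 genes, 30-gene module,
  20 seeds, GOSet 40 @ purity 0.6, 4 datasets × 20 samples × 250 genes,
  ρ = 0.8.
* **noise benchmark** (`SyntheticScenario.noise_benchmark`): 800 genes,
  40-gene module, 10 seeds, GOSet 280 containing 30 module genes (~2.9×
  chance — "enriched but imperfect"), 3 datasets × 300 genes; ratios 0–25
  in steps of 5 (the largest range the GOSet can supply at 10 seeds);
  k ∈ {16, 20}, the same fractions of the 800-gene universe as thresholds
  300 and 400 are of a 15,494-gene genome. Enrichment top-K is set to the
  number of planted terms (5) because the synthetic term space has 30
  terms, not a genome's thousands; the genome-scale default stays 50.

What the generator does **not** emulate: literature/ascertainment bias in
PPI edges, batch effects and platform differences across expression
datasets, the GO DAG's hierarchical dependence between terms, or
evidence-code structure. Passing tests therefore demonstrate that the
implementation realizes the intended statistical behaviour under the
planted model — not that the method will rank real disease genes with any
particular accuracy on a given real dataset.

## Numerical choices and degenerate inputs

Fractional ranking throughout (unbiased under ties); unreachable genes and
NaN attributes share the worst positions so rank sums are always
N(N+1)/2. Rescaling a length-1 rank vector yields 0.5. Self-loops are
dropped at network construction; rows with unmappable identifiers are
counted and discarded; an empty network is an error. Empty study sets,
universes, term sets, GOSets and over-large clusters raise immediately
rather than propagating NaNs. RWR probability conservation (sum = 1 within
1e−12) holds on graphs without isolated nodes.

## Experiment sizes

The reference experiments use 10 generator seeds for module recovery and 5
for the noise benchmark, sizes at which the recovery median and the slope
ordering are stable in replicate runs while a full benchmark remains a
few-minute, single-CPU computation.

## Known limitations

* Betweenness is exact (Brandes) and cubic-ish in practice; networks beyond
  ~10⁴–10⁵ nodes will want approximate betweenness, which is not included.
* The per-dataset [0, 1] rescaling of cluster ranks discards cluster-count
  information (a 2-cluster and a 40-cluster dataset weigh equally).
* The P-score's dropout non-monotonicity (above) makes λ-tuning on small
  seed sets noisy; inspect the curve.
* The GOSet inherits every bias of its annotation source; the package
  treats that as a feature to be benchmarked, not corrected.
* PSI-MITAB and SOFT readers are minimal convenience parsers (gene-name
  aliases and the `IDENTIFIER` table respectively), not full-format
  implementations.
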