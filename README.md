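# netprio

Noise-tolerant disease-gene prioritization by fusing protein–protein
interaction (PPI) network topology with expression-cluster / Gene Ontology
evidence.

## The problem

Candidate-gene prioritization ranks the genes of a genome by their likely
involvement in a disease, starting from a small set of curated disease genes
("seeds"). Diffusion methods such as the random walk with restart (RWR) are
accurate when the seed set is clean, but real seed sets are contaminated —
e.g. by genes inferred from uncurated GO annotations — and diffusion methods
promote whatever they are fed. `netprio` implements a rank-fusion method
built for that regime, together with the RWR baseline and a benchmarking
harness that quantifies exactly how fast each method decays as seed noise
grows. It is aimed at computational biologists studying polygenic diseases
(the motivating application is breast-cancer gene mining) who need rankings
that survive dirty inputs.

## The method

For each gene *v* of the PPI network three topological attributes are
computed: degree *c_d(v)*, unnormalized betweenness
*c_b(v) = Σ_{j<k} σ_jk(v)/σ_jk*, and the mean shortest-path distance to the
seed genes *c_spl(v) = Σ_{t∈seeds} d(v,t)/n*. Each attribute is converted to
a tie-averaged rank rescaled to [0, 1] and the three are averaged into the
network score **S_N(v)** (0 = best).

Expression datasets are clustered by affinity propagation on pairwise
Pearson correlation; each cluster's overlap with the **GOSet** — the genes
carrying GO terms enriched among the seeds plus user-supplied hallmark terms
— is tested against 1000 same-size random draws and summarized as an
upper-tail normal p-value. Clusters are ranked by p, genes inherit their
cluster's rescaled rank, and averaging over datasets gives the expression
score **S_E(v)** (genes with no expression evidence get a neutral 0.5).

The final score is the convex fusion

    S(v) = (1 − λ) S_N(v) + λ S_E(v),   λ ∈ [0, 1] (default 0.2),

with genes sorted ascending by *S*. λ is tuned by the **P-score**: the mean
final position of seed genes landing in the top 10% of the list. The RWR
comparator iterates *p^{t+1} = (1 − r) W p^t + r p^0* (column-normalized
adjacency *W*, restart *r* = 0.7, seeds uniform in *p^0*) and ranks genes by
steady-state probability.

Noise robustness is measured by mixing noise genes drawn from the GOSet into
the seeds in multiples of the known-set size, running stratified five-fold
cross-validation, and tracking Precision(k)/Recall(k)/F-score(k) on held-out
genes as the noise ratio grows — plus a completely-random-noise variant that
reports how much injected junk each method pulls into its top 10%.

## Worked example

Every capability has a narrative script under `examples/`. The end-to-end
run (`python examples/01_simulate_and_rank.py`) generates a 500-gene
scale-free network with a planted 30-gene disease module, uses 20 module
genes as seeds and asks where the ten *held-out* module genes land:

```
network: 500 genes, 1128 interactions
seeds: 20 known genes; held-out module genes: 10
...
held-out module gene positions: [1, 2, 6, 7, 10, 11, 15, 29, 37, 38]
median position = 10 of 500 (top 2.1% of the list)
```

The method places unseen disease genes at a median position of 10 out of
500 — deep inside the top 5%. The noise benchmark
(`python examples/05_noise_benchmark.py`) shows the headline property: as
the seed set is contaminated at up to 25× its size, the fused ranking's
cross-validated F-score falls gently (0.40 → 0.24) while the random-walk
baseline collapses (0.27 → 0.00).

A thin CLI mirrors the pipeline for shell use: `netprio simulate`,
`netprio rank`, `netprio rwr`, `netprio evaluate` (see `--help`).

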