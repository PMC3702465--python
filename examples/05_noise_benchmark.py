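"""Noise tolerance: fused ranking vs random walk under seed contamination.

Noise genes drawn from the GOSet are mixed into the training seeds in
multiples of the known-set size; five-fold cross-validation measures the
F-score at a top-k threshold as the noise ratio grows. A method whose
F-score slope is flatter tolerates dirty input better.

(One generator seed, a short ratio range and reduced permutations keep this
demo around a minute; the acceptance script runs the full protocol.)
"""

from netprio import SyntheticScenario, run_noise_benchmark
from netprio.benchmarks import build_prioritizer

data = SyntheticScenario.noise_benchmark(seed=0).generate()
prio = build_prioritizer(data, n_perm=200)
results = run_noise_benchmark(
    prio, data.known, data.goset, ratios=(0, 10, 25), k_values=(16,), seed=0
)

mean_f = results.groupby(["method", "ratio"])["f_score"].mean().unstack("method")
print("mean F-score (5-fold CV, k=16) by noise ratio:")
print(mean_f.round(3))
drop = mean_f.iloc[0] - mean_f.iloc[-1]
print(f"\nF-score drop from ratio 0 to 25:  proposed {drop['proposed']:.3f}, "
      f"rwr {drop['rwr']:.3f}")
print("the fusion leans on seed-independent evidence (degree, betweenness,"
      " co-expression), so contaminated seeds hurt it far less than the"
      " pure-diffusion baseline")
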