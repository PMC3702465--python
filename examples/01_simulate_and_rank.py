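"""Generate a synthetic study and rank its genes end to end.

A 500-gene scale-free network carries a planted 30-gene disease module; 20
module genes act as the known seed set. The pipeline scores every network
gene by topology (S_N) and expression-cluster/GO overlap (S_E), fuses them
with lambda = 0.2, and we check where the *held-out* module genes — disease
genes the method has never seen — land in the final list.
"""

from netprio import SyntheticScenario
from netprio.benchmarks import build_prioritizer

data = SyntheticScenario(seed=7).generate()
prio = build_prioritizer(data)
ranking = prio.rank(data.known)

print(f"network: {data.net.n_nodes} genes, {data.net.n_edges} interactions")
print(f"seeds: {len(data.known)} known genes; held-out module genes: "
      f"{len(data.heldout_module_genes)}")
print("\ntop 10 of the fused ranking:")
print(ranking.table.head(10).round(3))

pos = ranking.positions.loc[data.heldout_module_genes].sort_values()
pct = pos.median() / data.net.n_nodes * 100
print(f"\nheld-out module gene positions: {[int(p) for p in pos]}")
print(f"median position = {pos.median():.0f} of {data.net.n_nodes} "
      f"(top {pct:.1f}% of the list)")
print("a median inside the top 5% means the fusion recovers unseen module genes")
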