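"""Pick hyperparameters by maximizing biological separation.

The model needs sparsity/concentration values up front. The selection
procedure refits over a grid and scores each partition by how strongly it
separates external covariates — an ANOVA F-test per continuous index, a
chi-square test per binary pathway indicator — combining p-values with
Fisher's method. The best setting is the one explaining maximal differences.
"""

from graphdpm import FitConfig, GridSpec, grid_search, rand_index
from graphdpm.simulate import SimulationDesign, simulate, simulate_covariates

data, truth = simulate(SimulationDesign(n=300, p=200, seed=7))
# covariates linked to the planted groups (stand-ins for e.g. an immune
# index and a pathway alteration call)
index, pathway = simulate_covariates(truth, snr=10.0, seed=7)

grid = GridSpec(
    alpha0_values=(1.0, 10.0, 100.0),
    eta_values=((75.0, 4.0), (150.0, 8.0), (300.0, 16.0)),  # (continuous, binary) sparsity
    nu_values=(0.0,),
)
ranked, best = grid_search(
    data, None, grid,
    continuous={"index": index}, binary={"pathway": pathway},
    config=FitConfig(seed=7), H=10,
)

print("rank  alpha0  eta          fisher_p      occupied")
for i, s in enumerate(ranked[:5], 1):
    print(f"{i:>4}  {s.hyper.alpha0:>6.0f}  {str(s.hyper.ising.eta):<12} "
          f"{s.fisher_p:<12.3e} {s.occupied}")
ri, _ = rand_index(best.labels, truth.labels)
print(f"\ntop-ranked setting recovers the planted partition at Rand {ri:.3f}")
# A tiny combined p-value means the partition separates the covariates far
# beyond chance; settings that over- or under-penalize selection rank lower.
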