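"""Cluster a planted two-modality dataset and recover its signal features.

Generates the standard study conditions — 300 subjects, 200 features across a
continuous (Normal) and a binary (Bernoulli) modality, three planted groups
defined by 10% signal features — fits the graph-guided DPM by variational
Bayes, and compares the result against the planted truth.
"""

import numpy as np

import graphdpm
from graphdpm import FitConfig, Hyperparameters, IsingHyper, rand_index
from graphdpm.simulate import SimulationDesign, simulate

data, truth = simulate(SimulationDesign(n=300, p=200, seed=0))
hyper = Hyperparameters(alpha0=10.0, H=10, ising=IsingHyper(eta=(150.0, 8.0), nu=(0.0, 0.0)))
result = graphdpm.fit(data, None, hyper, FitConfig(seed=0))

ri, ari = rand_index(result.labels, truth.labels)
is_sig = np.array([k in truth.signal_registry_keys() for k in data.registry_keys()])
best_sel = np.vstack(result.selection_prob)[:, : result.occupied].max(axis=1)

print(f"occupied clusters: {result.occupied}   (3 groups were planted)")
print(f"Rand index vs planted labels: {ri:.3f}  adjusted: {ari:.3f}")
print(f"signal features selected somewhere: {(best_sel[is_sig] > 0.5).mean():.1%}")
print(f"noise features rejected everywhere: {(best_sel[~is_sig] <= 0.5).mean():.1%}")
print(f"final ELBO: {result.elbo_trace[-1]:.1f} after {len(result.elbo_trace)} sweeps")
# Rand 1.0 means every pair of subjects is grouped exactly as planted; the
# selection rates show the sparsity prior keeps cluster definitions to the
# features that actually differ between groups.
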