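# graphdpm

Network-guided Bayesian nonparametric clustering with feature selection for
high-dimensional multi-modal molecular data.

## The problem

Multi-modal profiling studies — bulk tumor cohorts with expression and DNA
alteration matrices, or multi-modal single-cell assays — need clustering that
(i) integrates data types with different likelihoods, (ii) says *which*
features define each cluster, and (iii) uses known biology (pathway
membership, regulatory links) to steer that selection. Conventional
clustering on most-variable features is dominated by cell-of-origin or
histology; a sparse, network-aware model can instead surface groups driven by
shared pathway activity.

## The model

Subjects `x_i` are draws from a Dirichlet process mixture with concentration
`α₀`, truncated at `H` components for inference (stick-breaking weights
`w'_h = w_h ∏_{l<h}(1−w_l)`, `w_l ~ Beta(1, α₀)`). Each cluster `h` carries a
binary selection indicator `γ_jh` per feature. Observations follow a
two-component mixture per feature:

    x_ij | z_i=h  ~  γ_jh · f_active(θ_jh)  +  (1−γ_jh) · f_null

where `f_active` is `N(μ_jh, σ²_jh)` (continuous modality) or `Bern(p_jh)`
(binary modality) with conjugate base measures `N-IG(0, λ, α_σ, β_σ)` and
`Beta(α_p, β_p)`, and `f_null` is a fixed cluster-unrelated diffuse null:
`N(0, 20)` or `Bern(0.5)`. Selection indicators get a multi-modal Ising prior
over user-supplied graphs,

    π(γ) ∝ exp( −Σ_m η_m Σ_j γ_j^(m)
                + Σ_m Σ_{j~k in G^(m)} ν_m · I[γ_j^(m) = γ_k^(m)]
                + Σ_{j~k in G^(1,2)} ν' · I[γ_j^(1) = γ_k^(2)] )

so sparsity (`η`) competes with concordance rewards (`ν`, `ν'`) along
within- and cross-modality edges.

Inference is blockwise coordinate-ascent variational Bayes (mean field over
`z`, `w`, `γ`, `(μ,σ²)`, `p`), maximizing the ELBO at `O(npH + eH)` per
sweep (`e` = total edges). A blocked Gibbs sampler for the same truncated
posterior serves as a small-scale reference, and a grid-search procedure
picks hyperparameters by Fisher-combining ANOVA/χ² p-values of external
covariates across candidate partitions.

## Worked example

```bash
python examples/simulate_and_fit.py
```

generates the standard validation conditions (n=300 subjects, p=200 features
across a Normal and a Bernoulli modality, three planted groups defined by
10% signal features: means −2/2/6 sd 0.1, probabilities 0.2/0.5/0.8,
standard-Normal noise) and prints:

```
occupied clusters: 3   (3 groups were planted)
Rand index vs planted labels: 1.000  adjusted: 1.000
signal features selected somewhere: 100.0%
noise features rejected everywhere: 100.0%
final ELBO: -90408.4 after 5 sweeps
```

Rand 1.0 means every subject pair is grouped exactly as planted; the
selection rates show the sparsity prior confines each cluster's definition
to the features that genuinely differ between groups. The other examples
show the network prior rescuing a weak connected biomarker
(`network_prior_effect.py`), the Gibbs cross-check (`gibbs_cross_check.py`),
and covariate-scored hyperparameter selection (`grid_selection.py`).

A thin CLI covers the same pipeline from the shell:

```bash
graphdpm simulate --n 300 --p 200 --seed 0 --out sim/
graphdpm fit --modality expr:normal:sim/expr.tsv --modality alt:bernoulli:sim/alt.tsv \
             --graphs sim/graphs.tsv --seed 0 --out fit/
graphdpm evaluate --labels-a fit/fit_labels.tsv --labels-b sim/truth_labels.tsv --out eval/
```

## Layout

- `src/graphdpm/data.py` — multi-modal containers, two-component likelihood
- `src/graphdpm/graphs.py` — feature graphs, Ising prior, mean-field fields
- `src/graphdpm/vb.py` — variational engine (the core)
- `src/graphdpm/gibbs.py` — blocked Gibbs reference sampler
- `src/graphdpm/evaluate.py` — ANOVA/χ²/Fisher scoring, Rand indices, grid search
- `src/graphdpm/simulate.py` — planted-cluster generator and graph simulator
- `src/graphdpm/io.py`, `src/graphdpm/cli.py` — file formats and the CLI

See `docs/methods.md` for modeling assumptions, numerical choices and
limitations.
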