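# Methods

## Model

`graphdpm` clusters `n` subjects observed across `M` data modalities, each
modality `m` an `n × p_m` matrix of one likelihood family — Normal for
continuous values (log expression, indices), Bernoulli for binary values
(alteration calls). The generative model is a Dirichlet process mixture:
subject-level parameters are drawn from a random discrete distribution
`G ~ DP(G₀, α₀)`, whose atoms are shared, so subjects with the same atom form
a cluster. For inference the stick-breaking representation is truncated at
`H` components (`w_H = 1`); the model itself is unbounded, and `H` is chosen
comfortably above any plausible cluster count.

Each atom carries, per feature `j`, a selection indicator `γ_jh` and active
parameters. Given `z_i = h`, feature `j` of subject `i` follows the
cluster-specific active density when `γ_jh = 1` and a fixed diffuse null
otherwise — `N(0, 20)` for continuous features, `Bern(0.5)` for binary ones.
The null is cluster-unrelated and never updated; it represents "this feature
does not help define this cluster". Because the indicator lives in the atom,
all subjects of a cluster share one selection pattern; the package exposes
per-cluster (not per-subject) selection probabilities throughout.

The indicators get an unnormalized multi-modal Ising prior over user-supplied
undirected graphs: a per-modality sparsity field `η_m` penalizing each
selected feature, concordance rewards `ν_m` along within-modality edges and
`ν'` along cross-modality edges. Each cross edge is counted once, stored as
an ordered (modality-a feature, modality-b feature) pair. The prior is
applied independently to every cluster's selection vector — the variational
family factorizes `γ_jh` over `h`, and nothing couples selection across
clusters. The partition function of the Ising prior is intractable but
depends only on `(η, ν)`, not on the variational distribution, so it is
dropped; reported ELBO values are therefore comparable within one
hyperparameter setting, not across settings (grid selection uses the
covariate statistics below instead).

Base measures are conjugate: `(μ_jh, σ²_jh) ~ N-IG(0, λ, α_σ, β_σ)` and
`p_jh ~ Beta(α_p, β_p)`.

## Variational inference

The mean field factorizes over `z`, `w`, `γ`, `(μ, σ²)`, `p`:
categorical responsibilities `softmax(b_i·)`, Beta sticks `(f_h, g_h)`,
Bernoulli selection `expit(c_jh)`, Normal-Inverse-Gamma `(m, v, d/2, r/2)`
and Beta `(s, t)` blocks. One sweep applies the exact coordinate maximizer
of each block in the fixed order `z → w → γ → (μ,σ²) → p`:

- responsibilities: `b_ih = E[ln w'_h] + Σ_j [q_jh·E(log f_active) +
  (1−q_jh)·log f_null]`, normalized by log-sum-exp;
- sticks: `f_h = 1 + Σ_i r_ih`, `g_h = α₀ + Σ_i Σ_{l>h} r_il`;
- selection: `c_jh = L_jh − η_m + Σ_{k~j} ν·(2 q_kh − 1)`, where `L_jh` is
  the responsibility-weighted expected active-vs-null log-likelihood
  difference. Under this parameterization the atom-parameter priors are
  selection-independent, so no further prior term enters the logit.
  Features untouched by any edge are decoupled and updated in one vectorized
  pass; edge-touching features are updated sequentially (exact coordinate
  ascent on the mean-field Ising system), iterated up to 3 inner passes or
  max-change < 1e-6. Logits are clamped at ±30 (`expit` is saturated there
  far below double precision, so the clamp cannot affect any reported
  probability while preventing overflow);
- conjugate blocks: responsibility-and-selection-weighted sufficient
  statistics (`ω_ijh = r_ih·q_jh`), standard N-IG and Beta posteriors; a
  floating-point-cancellation floor `r ≥ 2β_σ·1e−8` guards the NIG scale.

Every block update is an exact coordinate maximizer, so the ELBO is
non-decreasing across sweeps; the trace is asserted monotone (1e−8 relative)
in the test suite. Convergence: relative ELBO change below `rel_tol`
(default 1e−6) or `max_iters` (default 500). All operations are
matmul-based; per-sweep cost is `O(npH + eH)`, verified by an instrumented
operation counter that the suite checks for linear scaling in `n`, `p` and
`H` separately.

### Initialization and warm start

Responsibilities are initialized from k-means at `K = H` on per-feature
standardized concatenated data, converted to soft responsibilities by a
distance softmax whose temperature is the mean margin between each subject's
two nearest centers. The softness matters: k-means at `K = H` necessarily
tiles true groups with several centers, and hard one-hot initialization lets
those duplicate components fit slightly different parameters and lock into a
split — soft assignments keep same-group components near-identical so the
redundant ones drain under the stick-breaking preference.

Selection has two self-consistent mean-field fixed points per feature
(selected with fitted parameters, unselected with prior-valued parameters).
With a fixed sparsity penalty, k-means-split clusters at initialization
carry too little evidence to ignite true signals, while full-size clusters
later carry enough evidence to ignite noise. `fit()` therefore runs a few
initialization-refinement sweeps (default 8) with `η` annealed linearly from
zero — a deterministic-annealing warm start. Features ignite while clusters
form; once clusters reach full size the full penalty prunes the noise
features, whose evidence (≈1 nat per subject against the `N(0,20)` null for
standard-Normal noise) falls well below a suitably chosen `η`, while signal
features (≈3–4 nats per subject at the planted effect sizes) stay selected.
The reported ELBO trace begins after the warm start, at the full
hyperparameters, so the monotone-ascent guarantee applies to every recorded
value.

### Defaults and units

| parameter | default | meaning |
|---|---|---|
| `α₀` | 10 | DP concentration; larger favors more clusters |
| `H` | 30 | truncation; choose well above the expected cluster count (study-scale runs here use 10) |
| `λ` | 0.1 | prior precision scale of active means; weak so fitted means are data-driven |
| `α_σ, β_σ` | 0.25 | weak Inverse-Gamma on active variances; a strong prior here inflates fitted signal variances and erodes their evidence |
| `α_p, β_p` | 1 | flat Beta on active Bernoulli probabilities |
| `η_m` | data-scale | per-feature sparsity cost in nats; must sit between the per-cluster evidence mass of noise (≈ cluster size × 1 nat for continuous) and signal features. The n=300 study conditions use (150, 8) |
| `ν_m, ν'` | 0 | concordance reward per satisfied graph edge, in nats |
| `rel_tol` | 1e−6 | relative ELBO convergence threshold |

`η` trades off against cluster size (evidence is a sum over subjects), which
is why the selection grid in the model-selection procedure spans an order of
magnitude. Continuous data are assumed roughly standardized so the fixed
`N(0, 20)` null is diffuse relative to the data; the CLI standardizes
continuous modalities by default (flag to disable), the library operates on
data as given.

Cluster labels are `argmax` responsibilities (ties to the lowest index),
re-indexed by decreasing expected cluster size for reproducible reporting
under label switching; `occupied` counts clusters with expected size ≥ 1.
`classify()` scores new subjects by `E[ln w'_h]` plus selection-weighted
active/null log-likelihood at posterior-mean parameters.

## Gibbs reference sampler

A blocked Gibbs sampler targets the same truncated posterior and acts as a
small-scale correctness oracle (guard: `n·p·H ≤ 1e7`). Full conditionals:
categorical `z` given sampled `(w, γ, θ)`; Beta sticks from cluster counts;
`(γ_j·, θ_j·)` as one block — `γ` is sampled against the *marginalized*
active likelihood (conjugate closed forms) plus the Ising conditional from
current neighbor indicators in a systematic feature scan, then `θ | γ` from
the N-IG/Beta posteriors. Marginalizing `θ` out of the `γ` draw is essential:
against a freshly sampled `θ` the active likelihood essentially never matches
the data and indicators freeze at zero. The suite verifies the sampler
against brute-force numerical integration of the exact posterior on a
two-subject instance, against prior moments on an empty dataset, and checks
VB/Gibbs point-partition agreement (Rand ≥ 0.9) on planted tiny instances.
The point partition from draws maximizes the Rand index against the
thresholded (>0.5) co-clustering graph's connected components.

## Model selection and evaluation

Candidate hyperparameter settings are refit with identical seeds and scored
against external covariates: one-way ANOVA F per continuous covariate,
Pearson χ² (no continuity correction) per binary covariate, all p-values
combined by Fisher's method (`−2Σln p ~ χ²_{2k}`) into a single score;
settings rank by ascending combined p (ties: fewer occupied clusters, then
grid order). Degenerate tests use fixed conventions, recorded on the result:
single group or empty margin → p = 1; zero within-group variance with
distinct means → p = 0. A pluggable hook accepts additional label-scoring
callables (e.g. a survival log-rank statistic); none is built in. Both the
classic and adjusted Rand index are reported wherever partitions are
compared.

## Synthetic data generator

`simulate()` reproduces the validation conditions: uniform group assignment
over `K = 3` groups; 10% of features signal (per modality, feature budget
split equally between a Normal and a Bernoulli modality); continuous signals
`N(μ_g, 0.1²)` with `μ = (−2, 2, 6)`, binary signals `Bern(p_g)` with
`p = (0.2, 0.5, 0.8)`; continuous noise `N(0, 1)`, binary noise
`Bern(0.5)`. `simulate_graph()` plants within-modality edges among signal
features at a chosen density (decoy edges only among noise features) and
random signal–signal cross edges; `simulate_covariates()` produces
truth-linked continuous/binary scoring covariates for the grid search. All
draws are reproducible from seeds.

What the generator does *not* emulate: feature–feature correlation within a
group, heavy tails, batch structure, missingness, count distributions, or
realistic pathway topology. Passing tests on this generator demonstrate the
inference machinery recovers planted structure under the model's own
assumptions; they do not certify behavior on real cohorts, where
standardization choices, the diffuse-null scale and `η` calibration matter.

## Problem sizes used in validation

Study-condition runs use `n = 300`, `p = 200`, `H = 10`; tiny oracle
instances for the VB-vs-Gibbs comparison use `n = 60`, `p = 20`, `K = 2`,
`H = 5` with a denser signal fraction (0.3) so the handful of features still
carries the group structure. The grid-selection demonstration uses a 3×3
grid (three `α₀` values × three `(η₁, η₂)` pairs). These sizes keep the full
suite and the reproduction script fast while preserving every qualitative
regime of the method (ignition, pruning, coupling, truncation pruning).

## Known limitations

- Mean-field VB underestimates posterior uncertainty and can lock into
  local optima; the warm start removes the systematic failure modes we
  identified, but pathological seeds may still converge to split or merged
  partitions — the Gibbs reference exists to audit small cases.
- The two selection fixed points imply hysteresis: a feature driven to
  `q ≈ 0` cannot re-ignite at fixed `η`. Run-to-run differences therefore
  come almost entirely from initialization.
- Only Normal and Bernoulli modalities are implemented; the modality enum is
  extensible but counts (Poisson) carry no prior here.
- Missing values are rejected, not imputed.
- Graphs are unweighted and undirected; edge weights would require an
  obvious but unimplemented generalization of the concordance terms.
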