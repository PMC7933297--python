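"""Synthetic multi-modal datasets with planted clusters, signals and graphs.

The generator reproduces the study conditions used to validate the method:
subjects fall into K = 3 groups; 10% of features are signal; continuous
signal features follow group Normal distributions with means -2, 2 and 6 and
standard deviation 0.1; binary signal features follow group Bernoulli
distributions with probabilities 0.2, 0.5 and 0.8; continuous noise features
are standard Normal, binary noise features Bernoulli(0.5).  Two modalities
split the feature budget equally by default.  Everything is reproducible
from a seed, and the planted truth (labels, signal sets, parameters) is
returned for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ModalityKind, ModalitySpec, MultiModalDataset
from .graphs import GraphSet, build_graphset

__all__ = ["SimulationDesign", "SimulatedTruth", "simulate", "simulate_graph", "simulate_covariates"]


@dataclass(frozen=True)
class SimulationDesign:
    n: int = 300
    p: int = 200  # total features across modalities
    modality_split: tuple[float, ...] = (0.5, 0.5)  # (normal, bernoulli)
    signal_frac: float = 0.10
    K: int = 3
    normal_means: tuple[float, ...] = (-2.0, 2.0, 6.0)
    normal_sd: float = 0.1
    bern_probs: tuple[float, ...] = (0.2, 0.5, 0.8)
    bern_noise_prob: float = 0.5
    pair_signals: bool = False  # same signal columns in both modalities
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.signal_frac <= 1.0:
            raise ValueError("signal_frac must lie in (0, 1]")
        if self.K < 1:
            raise ValueError("need at least one group")
        if len(self.normal_means) != self.K or len(self.bern_probs) != self.K:
            raise ValueError("normal_means and bern_probs must have one entry per group")
        if any(not 0 < q < 1 for q in self.bern_probs) or not 0 < self.bern_noise_prob < 1:
            raise ValueError("Bernoulli probabilities must lie in (0, 1)")
        if abs(sum(self.modality_split) - 1.0) > 1e-9 or any(
            s <= 0 for s in self.modality_split
        ):
            raise ValueError("modality_split must be positive and sum to 1")
        if round(self.p * min(self.modality_split)) < 1:
            raise ValueError("empty modality: p too small for the requested split")


@dataclass
class SimulatedTruth:
    labels: np.ndarray  # (n,) planted groups, 1..K
    signal_features: dict[str, list[str]]  # modality name -> signal feature ids
    design: SimulationDesign = field(repr=False, default=None)

    def signal_registry_keys(self) -> set[str]:
        return {f"{m}:{f}" for m, feats in self.signal_features.items() for f in feats}


def simulate(design: SimulationDesign) -> tuple[MultiModalDataset, SimulatedTruth]:
    """Draw one dataset and its planted truth.

    Group labels are uniform over 1..K; per modality, round(signal_frac*p_m)
    signal columns are drawn (shared column indices across modalities when
    ``pair_signals``), the rest are noise.
    """
    rng = np.random.default_rng(design.seed)
    n, K = design.n, design.K
    p1 = round(design.p * design.modality_split[0])
    p2 = design.p - p1
    labels = rng.integers(1, K + 1, size=n)

    n_sig1 = round(design.signal_frac * p1)
    n_sig2 = round(design.signal_frac * p2)
    sig1 = np.sort(rng.choice(p1, size=n_sig1, replace=False))
    if design.pair_signals:
        sig2 = sig1[sig1 < p2]
        if len(sig2) < n_sig2:
            extra = np.setdiff1d(np.arange(p2), sig2)
            sig2 = np.sort(
                np.concatenate([sig2, rng.choice(extra, size=n_sig2 - len(sig2), replace=False)])
            )
    else:
        sig2 = np.sort(rng.choice(p2, size=n_sig2, replace=False))

    X1 = rng.standard_normal((n, p1))
    means = np.asarray(design.normal_means)[labels - 1]  # (n,)
    X1[:, sig1] = means[:, None] + design.normal_sd * rng.standard_normal((n, n_sig1))

    X2 = (rng.random((n, p2)) < design.bern_noise_prob).astype(float)
    probs = np.asarray(design.bern_probs)[labels - 1]
    X2[:, sig2] = (rng.random((n, n_sig2)) < probs[:, None]).astype(float)

    spec1 = ModalitySpec("expr", ModalityKind.NORMAL, tuple(f"g{j}" for j in range(p1)))
    spec2 = ModalitySpec("alt", ModalityKind.BERNOULLI, tuple(f"a{j}" for j in range(p2)))
    data = MultiModalDataset(
        sample_ids=tuple(f"s{i}" for i in range(n)),
        modalities=[(spec1, X1), (spec2, X2)],
    )
    truth = SimulatedTruth(
        labels=labels,
        signal_features={
            "expr": [spec1.feature_ids[j] for j in sig1],
            "alt": [spec2.feature_ids[j] for j in sig2],
        },
        design=design,
    )
    return data, truth


def simulate_graph(
    truth: SimulatedTruth,
    data: MultiModalDataset,
    within_density: float = 0.3,
    cross_pairs: int = 0,
    decoy_density: float = 0.0,
    seed: int = 0,
) -> GraphSet:
    """Random graphs consistent with the planted truth.

    Within each modality, edges are drawn independently among signal features
    at ``within_density`` and among noise features at ``decoy_density``
    (decoys never touch signal features).  ``cross_pairs`` random
    signal-signal edges connect the first two modalities.
    """
    for dens in (within_density, decoy_density):
        if not 0.0 <= dens <= 1.0:
            raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edge_lists: dict[str, list[tuple[str, str]]] = {}
    for spec, _ in data.modalities:
        sig = list(truth.signal_features.get(spec.name, []))
        noise = [f for f in spec.feature_ids if f not in set(sig)]
        edges: list[tuple[str, str]] = []
        for group, dens in ((sig, within_density), (noise, decoy_density)):
            if dens > 0:
                for a_i in range(len(group)):
                    for b_i in range(a_i + 1, len(group)):
                        if rng.random() < dens:
                            edges.append((group[a_i], group[b_i]))
        if edges:
            edge_lists[f"within:{spec.name}"] = edges
    if cross_pairs > 0 and len(data.modalities) >= 2:
        m1, m2 = data.modalities[0][0].name, data.modalities[1][0].name
        s1 = truth.signal_features.get(m1, [])
        s2 = truth.signal_features.get(m2, [])
        if s1 and s2:
            pairs = [
                (s1[rng.integers(len(s1))], s2[rng.integers(len(s2))])
                for _ in range(cross_pairs)
            ]
            edge_lists[f"cross:{m1}:{m2}"] = pairs
    return build_graphset(edge_lists, data.specs)


def simulate_covariates(
    truth: SimulatedTruth, snr: float = 10.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Truth-linked scoring covariates for exercising the grid search.

    Continuous: group index plus Normal(0, 1/snr) noise.  Binary: Bernoulli
    with group-dependent probability (cycled over 0.2/0.5/0.8).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    labels = truth.labels
    cont = labels.astype(float) + rng.standard_normal(labels.size) / np.sqrt(snr)
    probs = np.array([0.2, 0.5, 0.8])[(labels - 1) % 3]
    binary = (rng.random(labels.size) < probs).astype(int)
    return cont, binary
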