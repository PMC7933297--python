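"""Multi-modal data containers and the two-component (null/active) likelihood.

Each modality is a samples x features block of one distributional family:
continuous values modeled Normal (e.g. log expression) or binary values
modeled Bernoulli (e.g. gene alteration status).  Per cluster, every feature
is either *active* — following a cluster-specific distribution — or
*inactive*, following a shared diffuse null that does not depend on the
cluster.  The null is fixed at N(0, 20) for continuous features and
Bernoulli(0.5) for binary features and is never updated during inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ModalityKind",
    "ModalitySpec",
    "MultiModalDataset",
    "NullParams",
    "ClusterParams",
    "ValidationReport",
    "log_density_active",
    "log_density_null",
    "subject_cluster_loglik",
    "validate_dataset",
    "DEFAULT_NULL_MEAN",
    "DEFAULT_NULL_VAR",
    "DEFAULT_NULL_PROB",
]

DEFAULT_NULL_MEAN = 0.0
DEFAULT_NULL_VAR = 20.0
DEFAULT_NULL_PROB = 0.5

#: fitted Bernoulli probabilities are clamped inside this open interval
PROB_EPS = 1e-6

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


class ModalityKind(str, Enum):
    """Likelihood family of a modality.  Extensible; only these two carry priors."""

    NORMAL = "normal"
    BERNOULLI = "bernoulli"


@dataclass(frozen=True)
class ModalitySpec:
    """Name, family and ordered feature identifiers of one modality."""

    name: str
    kind: ModalityKind
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ModalityKind(self.kind))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if len(set(self.feature_ids)) != len(self.feature_ids):
            seen: set[str] = set()
            dup = next(f for f in self.feature_ids if f in seen or seen.add(f))
            raise ValueError(f"duplicate feature id {dup!r} in modality {self.name!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def registry_keys(self) -> list[str]:
        """Global feature addresses, ``modality_name:feature_id``."""
        return [f"{self.name}:{f}" for f in self.feature_ids]


@dataclass
class MultiModalDataset:
    """Aligned samples x per-modality feature matrices.

    All modalities share the same samples in the same order.  Matrices are
    dense float arrays of shape ``(n, p_m)``; Bernoulli entries must be 0/1.
    """

    sample_ids: tuple[str, ...]
    modalities: list[tuple[ModalitySpec, np.ndarray]]

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        coerced = []
        for spec, mat in self.modalities:
            arr = np.asarray(mat, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"modality {spec.name!r}: matrix must be 2-D")
            if arr.shape != (self.n_samples, spec.n_features):
                raise ValueError(
                    f"modality {spec.name!r}: matrix shape {arr.shape} does not match "
                    f"(n={self.n_samples}, p_m={spec.n_features})"
                )
            coerced.append((spec, arr))
        self.modalities = coerced

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return sum(spec.n_features for spec, _ in self.modalities)

    @property
    def specs(self) -> list[ModalitySpec]:
        return [spec for spec, _ in self.modalities]

    def registry_keys(self) -> list[str]:
        keys: list[str] = []
        for spec, _ in self.modalities:
            keys.extend(spec.registry_keys())
        return keys

    def feature_index(self) -> dict[str, tuple[int, int]]:
        """Map registry key -> (modality index, column index)."""
        out: dict[str, tuple[int, int]] = {}
        for mi, (spec, _) in enumerate(self.modalities):
            for j, f in enumerate(spec.feature_ids):
                out[f"{spec.name}:{f}"] = (mi, j)
        return out


@dataclass(frozen=True)
class NullParams:
    """Fixed null-distribution constants (never updated during inference)."""

    mu0: float = DEFAULT_NULL_MEAN
    sigma0_sq: float = DEFAULT_NULL_VAR
    p0: float = DEFAULT_NULL_PROB

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly inside (0, 1)")


@dataclass
class ClusterParams:
    """Per-cluster active-distribution parameters for each modality.

    ``normal_mean``/``normal_var`` have shape (p_m, H) for each Normal
    modality; ``bern_prob`` has shape (p_m, H) for each Bernoulli modality.
    Keyed by modality name.
    """

    normal_mean: dict[str, np.ndarray] = field(default_factory=dict)
    normal_var: dict[str, np.ndarray] = field(default_factory=dict)
    bern_prob: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for name, v in self.normal_var.items():
            if np.any(v <= 0):
                raise ValueError(f"non-positive variance in modality {name!r}")
        for name, pr in self.bern_prob.items():
            if np.any((pr <= 0) | (pr >= 1)):
                raise ValueError(f"Bernoulli probability outside (0,1) in modality {name!r}")


def log_density_active(x, kind: ModalityKind | str, params) -> np.ndarray | float:
    """Log-density of the cluster-active component.

    ``params`` is ``(mean, var)`` for Normal, or ``prob`` for Bernoulli.
    Vectorized: ``x`` and parameters broadcast.
    """
    kind = ModalityKind(kind)
    x = np.asarray(x, dtype=float)
    if kind is ModalityKind.NORMAL:
        mean, var = params
        mean = np.asarray(mean, dtype=float)
        var = np.asarray(var, dtype=float)
        if np.any(var <= 0):
            raise ValueError("variance must be positive")
        out = -_HALF_LOG_2PI - 0.5 * np.log(var) - 0.5 * (x - mean) ** 2 / var
    else:
        prob = np.asarray(params, dtype=float)
        if np.any((prob <= 0) | (prob >= 1)):
            raise ValueError("Bernoulli probability must lie strictly inside (0,1)")
        if np.any((x != 0) & (x != 1)):
            raise ValueError("Bernoulli observations must be 0 or 1")
        out = x * np.log(prob) + (1.0 - x) * np.log1p(-prob)
    return float(out) if out.ndim == 0 else out


def log_density_null(x, kind: ModalityKind | str, null: NullParams = NullParams()):
    """Log-density of the shared cluster-unrelated null component."""
    kind = ModalityKind(kind)
    if kind is ModalityKind.NORMAL:
        return log_density_active(x, kind, (null.mu0, null.sigma0_sq))
    return log_density_active(x, kind, null.p0)


def subject_cluster_loglik(
    x_i: Sequence[np.ndarray],
    gamma_h: Sequence[np.ndarray],
    specs: Sequence[ModalitySpec],
    params_h: Sequence,
    null: NullParams = NullParams(),
) -> float:
    """Log-likelihood of one subject's row under cluster h's selection pattern.

    Per feature, the binary indicator gamma picks the active density
    (cluster-specific parameters) or the null; contributions add in log over
    features and modalities.  ``x_i``, ``gamma_h`` and ``params_h`` are
    per-modality sequences aligned with ``specs``; ``params_h[m]`` is
    ``(means, vars)`` or ``probs`` arrays of length p_m.
    """
    if not (len(x_i) == len(gamma_h) == len(specs) == len(params_h)):
        raise ValueError("per-modality sequences must have equal length")
    total = 0.0
    for xm, gm, spec, pm in zip(x_i, gamma_h, specs, params_h):
        xm = np.asarray(xm, dtype=float)
        gm = np.asarray(gm, dtype=float)
        if xm.shape != gm.shape or xm.shape[0] != spec.n_features:
            raise ValueError(
                f"modality {spec.name!r}: row/indicator length mismatch with feature registry"
            )
        la = log_density_active(xm, spec.kind, pm)
        ln = log_density_null(xm, spec.kind, null)
        total += float(np.sum(gm * la + (1.0 - gm) * ln))
    return total


@dataclass
class ValidationReport:
    n_samples: int
    modality_sizes: dict[str, int]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dataset(dataset: MultiModalDataset, *, strict: bool = True) -> ValidationReport:
    """Structural and value checks; raises on fatal violations when strict.

    Fatal: NaN anywhere (no imputation supported), non-binary entries in a
    Bernoulli modality.  Sample alignment is enforced by construction.
    """
    report = ValidationReport(
        n_samples=dataset.n_samples,
        modality_sizes={spec.name: spec.n_features for spec, _ in dataset.modalities},
    )
    if len(set(dataset.sample_ids)) != len(dataset.sample_ids):
        report.violations.append("duplicate sample ids")
    for spec, mat in dataset.modalities:
        bad = np.argwhere(np.isnan(mat))
        for i, j in bad[:10]:
            report.violations.append(
                f"NaN in modality {spec.name!r} at sample {dataset.sample_ids[i]!r}, "
                f"feature {spec.feature_ids[j]!r}"
            )
        if spec.kind is ModalityKind.BERNOULLI:
            nb = np.argwhere(~np.isnan(mat) & (mat != 0) & (mat != 1))
            for i, j in nb[:10]:
                report.violations.append(
                    f"non-binary value {mat[i, j]!r} in bernoulli modality {spec.name!r} "
                    f"at sample {dataset.sample_ids[i]!r}, feature {spec.feature_ids[j]!r}"
                )
        else:
            inf = np.argwhere(np.isinf(mat))
            for i, j in inf[:10]:
                report.violations.append(
                    f"non-finite value in modality {spec.name!r} at sample "
                    f"{dataset.sample_ids[i]!r}, feature {spec.feature_ids[j]!r}"
                )
    if strict and report.violations:
        raise ValueError("dataset validation failed:\n" + "\n".join(report.violations))
    return report
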