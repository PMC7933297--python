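"""Biological networks over features and the multi-modal Ising selection prior.

Features are graph nodes addressed as ``modality:feature_id``.  Within each
modality an undirected graph encodes e.g. shared pathway membership; across a
pair of modalities a bipartite graph encodes e.g. regulation between a gene's
expression and its DNA alteration.  The Ising prior on the binary selection
indicators rewards concordant selection of connected features (smoothness
``nu`` within a modality, ``nu_cross`` across) and penalizes the number of
selected features (sparsity ``eta`` per modality).  The prior is unnormalized;
its partition function is never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import ModalitySpec

__all__ = [
    "GraphSet",
    "IsingHyper",
    "build_graphset",
    "ising_log_potential",
    "mean_field_edge_concordance",
    "neighbor_field",
    "read_edge_list",
    "write_edge_list",
]


@dataclass
class GraphSet:
    """Deduplicated, self-loop-free edges over registered features.

    ``within[m]`` holds unordered column-index pairs inside modality index m;
    ``cross[(m, g)]`` (m < g) holds ordered pairs (column in m, column in g).
    """

    n_modalities: int
    within: dict[int, set[tuple[int, int]]] = field(default_factory=dict)
    cross: dict[tuple[int, int], set[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.within.values()) + sum(
            len(e) for e in self.cross.values()
        )

    def within_edges(self, m: int) -> list[tuple[int, int]]:
        return sorted(self.within.get(m, ()))

    def cross_edges(self, m: int, g: int) -> list[tuple[int, int]]:
        if m > g:
            return [(b, a) for a, b in sorted(self.cross.get((g, m), ()))]
        return sorted(self.cross.get((m, g), ()))

    def adjacency(self) -> dict[tuple[int, int], list[tuple[int, int, str]]]:
        """Neighbor lists: (modality, column) -> [(nbr modality, nbr column, tag)].

        tag is ``"within"`` or ``"cross"`` and selects the coupling strength.
        """
        adj: dict[tuple[int, int], list[tuple[int, int, str]]] = {}
        for m, edges in self.within.items():
            for a, b in edges:
                adj.setdefault((m, a), []).append((m, b, "within"))
                adj.setdefault((m, b), []).append((m, a, "within"))
        for (m, g), edges in self.cross.items():
            for a, b in edges:
                adj.setdefault((m, a), []).append((g, b, "cross"))
                adj.setdefault((g, b), []).append((m, a, "cross"))
        return adj


@dataclass(frozen=True)
class IsingHyper:
    """Sparsity and smoothness strengths of the Ising selection prior.

    ``eta[m]`` penalizes each selected feature of modality m; ``nu[m]``
    rewards concordant selection along within-modality edges; ``nu_cross``
    rewards concordance along cross-modality edges.  All nonnegative.
    """

    eta: tuple[float, ...]
    nu: tuple[float, ...]
    nu_cross: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "eta", tuple(float(e) for e in self.eta))
        object.__setattr__(self, "nu", tuple(float(v) for v in self.nu))
        if len(self.eta) != len(self.nu):
            raise ValueError("eta and nu must have one value per modality")
        if any(e < 0 for e in self.eta) or any(v < 0 for v in self.nu) or self.nu_cross < 0:
            raise ValueError("Ising hyperparameters must be nonnegative")


def build_graphset(
    edge_lists: Mapping[str, Iterable[tuple[str, str]]],
    specs: Sequence[ModalitySpec],
) -> GraphSet:
    """Assemble a GraphSet from per-graph feature-id edge lists.

    Keys of ``edge_lists`` are graph tags: ``within:<modality>`` or
    ``cross:<modality1>:<modality2>``.  Within-modality edges are symmetric
    and deduplicated; self-loops are dropped.  Unknown feature ids raise,
    listing the offenders; a same-modality pair under a cross tag raises.
    """
    name_to_idx = {spec.name: mi for mi, spec in enumerate(specs)}
    col_of = [
        {f: j for j, f in enumerate(spec.feature_ids)} for spec in specs
    ]
    gs = GraphSet(n_modalities=len(specs))

    def resolve(modality: str, fid: str, tag: str) -> tuple[int, int]:
        if modality not in name_to_idx:
            raise KeyError(f"graph {tag!r}: unknown modality {modality!r}")
        mi = name_to_idx[modality]
        if fid not in col_of[mi]:
            raise KeyError(f"graph {tag!r}: unknown feature {modality}:{fid}")
        return mi, col_of[mi][fid]

    for tag, pairs in edge_lists.items():
        parts = tag.split(":")
        if parts[0] == "within" and len(parts) == 2:
            mi = name_to_idx.get(parts[1])
            if mi is None:
                raise KeyError(f"graph {tag!r}: unknown modality {parts[1]!r}")
            unknown = [
                f for pair in pairs for f in pair if f not in col_of[mi]
            ]
            if unknown:
                raise KeyError(f"graph {tag!r}: unknown features {sorted(set(unknown))}")
            edges = gs.within.setdefault(mi, set())
            for a, b in pairs:
                ia, ib = col_of[mi][a], col_of[mi][b]
                if ia == ib:
                    continue  # self-loop
                edges.add((min(ia, ib), max(ia, ib)))
        elif parts[0] == "cross" and len(parts) == 3:
            m1, m2 = parts[1], parts[2]
            if m1 == m2:
                raise ValueError(
                    f"graph {tag!r}: cross-modality graph cannot pair a modality with itself"
                )
            for a, b in pairs:
                (ma, ca) = resolve(m1, a, tag)
                (mb, cb) = resolve(m2, b, tag)
                if ma > mb:
                    (ma, ca), (mb, cb) = (mb, cb), (ma, ca)
                gs.cross.setdefault((ma, mb), set()).add((ca, cb))
        else:
            raise ValueError(
                f"unrecognized graph tag {tag!r}; expected 'within:<modality>' or "
                "'cross:<modality1>:<modality2>'"
            )
    return gs


def ising_log_potential(
    gamma: Sequence[np.ndarray], graphs: GraphSet, hyper: IsingHyper
) -> float:
    """Unnormalized log prior of one binary selection configuration.

    ``gamma[m]`` is the 0/1 vector over modality m's features.  Returns
    ``-sum_m eta_m * #selected_m + sum_m nu_m * #concordant within edges
    + nu_cross * #concordant cross edges``.
    """
    if len(gamma) != graphs.n_modalities or len(gamma) != len(hyper.eta):
        raise ValueError("gamma must supply one vector per modality")
    gamma = [np.asarray(g) for g in gamma]
    total = 0.0
    for m, g in enumerate(gamma):
        total -= hyper.eta[m] * float(np.sum(g))
        edges = graphs.within.get(m)
        if edges:
            idx = np.array(sorted(edges))
            total += hyper.nu[m] * float(np.sum(g[idx[:, 0]] == g[idx[:, 1]]))
    for (m, gmod), edges in graphs.cross.items():
        if edges:
            idx = np.array(sorted(edges))
            total += hyper.nu_cross * float(
                np.sum(gamma[m][idx[:, 0]] == gamma[gmod][idx[:, 1]])
            )
    return total


def mean_field_edge_concordance(q_j: float, q_k: float):
    """Probability that two independently selected features agree.

    Expectation of the Ising concordance indicator under independent
    Bernoulli(q_j), Bernoulli(q_k): ``q_j q_k + (1-q_j)(1-q_k)``.
    """
    q_j = np.asarray(q_j, dtype=float)
    q_k = np.asarray(q_k, dtype=float)
    if np.any((q_j < 0) | (q_j > 1) | (q_k < 0) | (q_k > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = q_j * q_k + (1.0 - q_j) * (1.0 - q_k)
    return float(out) if out.ndim == 0 else out


def neighbor_field(
    j: int,
    m: int,
    sel_prob: Sequence[np.ndarray],
    h: int,
    graphs: GraphSet,
    hyper: IsingHyper,
) -> float:
    """Local mean-field log-odds contribution of the Ising prior.

    The difference in expected Ising potential between selecting and not
    selecting feature ``(m, j)`` in cluster ``h``, holding neighbors at their
    current selection probabilities ``sel_prob[m][j, h]``:
    ``-eta_m + sum_within nu_m (2 q_kh - 1) + sum_cross nu_cross (2 q_kh - 1)``.
    """
    val = -hyper.eta[m]
    for gm, k, tag in graphs.adjacency().get((m, j), ()):  # noqa: B007
        q = float(np.asarray(sel_prob[gm])[k, h])
        strength = hyper.nu[m] if tag == "within" else hyper.nu_cross
        val += strength * (2.0 * q - 1.0)
    return val


def read_edge_list(path) -> dict[str, list[tuple[str, str]]]:
    """Parse a tab-separated edge-list file: columns [graph_tag, feature_a, feature_b].

    Feature columns carry bare feature ids (the tag names the modality).
    Lines starting with ``#`` and blank lines are skipped.
    """
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            tag, a, b = parts
            out.setdefault(tag, []).append((a, b))
    return out


def write_edge_list(path, edge_lists: Mapping[str, Iterable[tuple[str, str]]]) -> None:
    with open(path, "w") as fh:
        fh.write("# graph_tag\tfeature_a\tfeature_b\n")
        for tag in sorted(edge_lists):
            for a, b in edge_lists[tag]:
                fh.write(f"{tag}\t{a}\t{b}\n")
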