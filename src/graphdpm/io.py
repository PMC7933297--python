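"""Readers, writers and dataset assembly.

Matrices travel as delimited text (TSV default, header row + id column) or
Matrix Market sparse files with ``.rownames``/``.colnames`` sidecar files.
The conventional on-disk orientation is features-in-rows (gene-by-sample
matrices); in memory everything is samples x features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ModalityKind, ModalitySpec, MultiModalDataset

__all__ = [
    "LabeledMatrix",
    "read_matrix",
    "write_matrix",
    "align_modalities",
    "write_fit_outputs",
    "write_manifest",
    "read_config",
]

log = logging.getLogger("graphdpm")


@dataclass
class LabeledMatrix:
    """Samples x features matrix with unique id labels on both axes."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (n, p)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("matrix shape does not match id labels")


def _check_unique(ids, what: str, path) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"{path}: duplicate {what} id {x!r}")
        seen.add(x)


def read_matrix(
    path,
    orientation: str = "features_in_rows",
    delimiter: str = "\t",
) -> LabeledMatrix:
    """Read a delimited or Matrix Market matrix into samples x features form.

    A ``.mtx`` path must have companion ``<path>.rownames`` and
    ``<path>.colnames`` files (one id per line).
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError("orientation must be 'samples_in_rows' or 'features_in_rows'")
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(path)
        values = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        rownames = Path(str(path) + ".rownames").read_text().split()
        colnames = Path(str(path) + ".colnames").read_text().split()
        if values.shape != (len(rownames), len(colnames)):
            raise ValueError(f"{path}: sidecar name files do not match matrix shape")
        df = pd.DataFrame(values, index=rownames, columns=colnames)
    else:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "features_in_rows":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    _check_unique(sample_ids, "sample", path)
    _check_unique(feature_ids, "feature", path)
    return LabeledMatrix(sample_ids, feature_ids, df.to_numpy(dtype=float))


def write_matrix(
    path,
    matrix: LabeledMatrix,
    orientation: str = "features_in_rows",
    delimiter: str = "\t",
) -> None:
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids)
    if orientation == "features_in_rows":
        df = df.T
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(df.to_numpy()))
        Path(str(path) + ".rownames").write_text("\n".join(map(str, df.index)) + "\n")
        Path(str(path) + ".colnames").write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        df.to_csv(path, sep=delimiter, index_label="id")


def align_modalities(
    matrices: list[tuple[str, str, LabeledMatrix]],
    policy: str = "strict",
) -> MultiModalDataset:
    """Assemble a MultiModalDataset from (name, kind, matrix) triples.

    ``strict`` requires identical sample ids in identical order across all
    modalities; ``intersect`` inner-joins on sample ids (output order taken
    from the first matrix), logging the drop count.
    """
    if not matrices:
        raise ValueError("need at least one modality")
    if policy not in ("strict", "intersect"):
        raise ValueError("policy must be 'strict' or 'intersect'")
    first = matrices[0][2]
    common = set(first.sample_ids)
    for _, _, mat in matrices[1:]:
        ids = set(mat.sample_ids)
        if policy == "strict":
            if ids != common:
                missing = sorted(common.symmetric_difference(ids))[:10]
                raise ValueError(
                    f"strict alignment failed; first mismatched sample ids: {missing}"
                )
            if list(mat.sample_ids) != list(first.sample_ids):
                offenders = [
                    a for a, b in zip(first.sample_ids, mat.sample_ids) if a != b
                ][:10]
                raise ValueError(
                    "strict alignment failed: sample order differs across "
                    f"modalities (first offenders: {offenders}); use policy="
                    "'intersect' to re-align by id"
                )
        common &= ids
    if not common:
        raise ValueError("empty sample intersection across modalities")
    order = [s for s in first.sample_ids if s in common]
    dropped = len(first.sample_ids) - len(order)
    if dropped:
        log.warning("align_modalities dropped %d samples not shared by all modalities", dropped)
    mods = []
    for name, kind, mat in matrices:
        pos = {s: i for i, s in enumerate(mat.sample_ids)}
        rows = [pos[s] for s in order]
        spec = ModalitySpec(name, ModalityKind(kind), tuple(mat.feature_ids))
        mods.append((spec, mat.values[rows]))
    return MultiModalDataset(sample_ids=tuple(order), modalities=mods)


def write_fit_outputs(outdir, result, prefix: str = "fit") -> dict[str, str]:
    """Write labels, selection probabilities and the ELBO trace as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    labels_path = outdir / f"{prefix}_labels.tsv"
    pd.DataFrame(
        {"sample_id": result.dataset.sample_ids, "cluster": result.labels}
    ).to_csv(labels_path, sep="\t", index=False)
    paths["labels"] = str(labels_path)

    sel = result.selection_frame().iloc[:, : max(result.occupied, 1)]
    sel_path = outdir / f"{prefix}_selection.tsv"
    sel.to_csv(sel_path, sep="\t", index_label="feature")
    paths["selection"] = str(sel_path)

    trace_path = outdir / f"{prefix}_elbo.txt"
    trace_path.write_text("\n".join(f"{v:.10g}" for v in result.elbo_trace) + "\n")
    paths["elbo"] = str(trace_path)
    return paths


def write_manifest(outdir, prefix: str = "run", **fields) -> str:
    """Reproducibility record (seed, config echo, version) as JSON."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{prefix}_manifest.json"
    payload = {"version": __version__, **fields}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return str(path)


def read_config(path) -> dict:
    """Load a YAML (nested) or flat ``key=value`` configuration file."""
    text = Path(path).read_text()
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")]
    if all("=" in ln and ":" not in ln.split("=")[0] for ln in stripped):
        out = {}
        for ln in stripped:
            k, v = ln.split("=", 1)
            out[k.strip()] = v.strip()
        return out
    import yaml

    return yaml.safe_load(text) or {}
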