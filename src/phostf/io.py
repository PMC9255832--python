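"""Tab-separated readers/writers for expression matrices and manifests.

All writers prepend ``#``-prefixed provenance comment lines (tool version
and a short configuration hash) which every reader skips.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "read_logfc_matrix",
    "write_logfc_matrix",
    "read_experiment_manifest",
    "write_experiment_manifest",
]


def _provenance(config: dict | None) -> str:
    blob = repr(sorted((config or {}).items())).encode()
    h = hashlib.sha1(blob).hexdigest()[:12]
    return f"# phostf {__version__} config={h}\n"


def write_logfc_matrix(X: np.ndarray, genes, experiments, path,
                       config: dict | None = None) -> None:
    df = pd.DataFrame(X, index=list(genes), columns=list(experiments))
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index_label="gene")


def read_logfc_matrix(path) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Returns (matrix, gene ids, experiment ids, missing mask).

    Empty cells are allowed and reported in the boolean missing mask (True =
    unmeasured); they are NaN in the matrix and should be excluded from any
    loss through the passive-observation mechanism.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    X = df.to_numpy(dtype=float)
    missing = np.isnan(X)
    return X, [str(g) for g in df.index], [str(c) for c in df.columns], missing


def write_experiment_manifest(rows, path, config: dict | None = None) -> None:
    """rows: iterable of (experiment, gene, kind) with kind in {KO, OE}."""
    df = pd.DataFrame(list(rows), columns=["experiment", "gene", "kind"])
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False)


def read_experiment_manifest(path, known_genes=None
                             ) -> dict[str, list[tuple[str, str]]]:
    """Manifest TSV -> ordered map experiment -> [(gene, kind), ...].

    Multi-gene experiments are supported (several rows per experiment id);
    a duplicated (experiment, gene) pair or unknown kind is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    bad = ~df["kind"].isin(["KO", "OE"])
    if bad.any():
        raise ValueError(f"unknown perturbation kind(s): "
                         f"{sorted(df.loc[bad, 'kind'].unique())}")
    if df.duplicated(["experiment", "gene"]).any():
        raise ValueError("duplicate (experiment, gene) rows in manifest")
    if known_genes is not None:
        known = set(known_genes)
        missing = sorted(set(df["gene"]) - known)
        if missing:
            raise ValueError(f"manifest references unknown genes: {missing}")
    out: dict[str, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["experiment"], []).append((row["gene"], row["kind"]))
    return out
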