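"""Exploratory ordination, abundance ranking and report assembly.

PCA on non-scaled log2 CPM separates samples by fiber-type
predominance; gene matrices are pre-filtered by dropping the 10% of
features with the lowest variance.  Abundance ranking compares datasets
by per-dataset ranks of mean CPM.  ``make_report`` writes the
pipeline's tabular outputs plus a run-metadata file, deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_matrix import InputError


@dataclass
class PcaResult:
    """Principal components of a centered (optionally scaled) matrix.

    ``scores``: samples x components; ``loadings``: features x
    components (orthonormal columns); ``variance_explained``:
    non-increasing fractions summing to at most one.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def variance_filter(matrix: pd.DataFrame, drop_frac: float = 0.10) -> pd.DataFrame:
    """Drop the lowest-variance features (rows).

    Removes ``floor(drop_frac * n_features)`` rows with the smallest
    variance across samples; ties are broken by feature name so the
    result is deterministic.
    """
    if not 0.0 <= drop_frac < 1.0:
        raise InputError("drop_frac must lie in [0, 1)")
    n_drop = int(np.floor(drop_frac * matrix.shape[0]))
    if n_drop == 0:
        return matrix.copy()
    order = (
        pd.DataFrame(
            {"var": matrix.var(axis=1, ddof=1), "name": matrix.index.astype(str)}
        )
        .sort_values(["var", "name"])
        .index
    )
    return matrix.drop(index=order[:n_drop])


def run_pca(
    matrix: pd.DataFrame, center: bool = True, scale: bool = False
) -> PcaResult:
    """PCA of a features x samples matrix via SVD of the centered data.

    Samples are observations.  Components are sign-fixed by making each
    component's largest-|loading| entry positive, so results are fully
    deterministic.
    """
    if matrix.size == 0:
        raise InputError("empty matrix")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(s.size):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s[None, :]
    total = float((x**2).sum())
    var_exp = (s**2) / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{k + 1}" for k in range(s.size)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comp),
        variance_explained=var_exp,
    )


def rank_by_abundance(cpm_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Rank features by mean CPM within each dataset (rank 1 = highest).

    The joined table covers the union of features; a feature absent from
    a dataset gets rank ``n_features + 1`` there.  Ties are broken by
    feature name.
    """
    if not cpm_tables:
        raise InputError("no datasets supplied")
    union: list[str] = []
    for df in cpm_tables.values():
        union.extend(str(i) for i in df.index if str(i) not in set(union))
    out = pd.DataFrame(index=sorted(union))
    for name, df in cpm_tables.items():
        means = df.mean(axis=1)
        order = (
            pd.DataFrame({"mean": means, "name": df.index.astype(str)})
            .sort_values(["mean", "name"], ascending=[False, True])
            .index
        )
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
        out[name] = ranks.reindex(out.index).fillna(len(df.index) + 1).astype(int)
    return out


def make_report(
    de_tables: dict[str, pd.DataFrame],
    correlation_tables: dict[str, pd.DataFrame],
    isomir_summary: pd.DataFrame | None,
    out_dir,
    metadata: dict | None = None,
) -> list[Path]:
    """Write the pipeline's tabular outputs and run metadata.

    Each table lands as a TSV (header always written, so empty tables
    produce header-only files); metadata goes to ``run_metadata.json``
    with sorted keys.  Re-running with identical inputs reproduces the
    files byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in {**de_tables, **correlation_tables}.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=bool(df.index.name))
        written.append(path)
    if isomir_summary is not None:
        path = out / "isomir_class_fractions.tsv"
        isomir_summary.rename_axis("sample").to_csv(path, sep="\t")
        written.append(path)
    meta_path = out / "run_metadata.json"
    meta_path.write_text(
        json.dumps(metadata or {}, sort_keys=True, indent=2, default=str) + "\n"
    )
    written.append(meta_path)
    return written
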