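"""miRNome-transcriptome correlation integration.

Links miRNA expression to gene expression two ways: miRtronic miRNAs
against their host genes (positive coupling expected, since the miRNA
precursor is spliced from the host gene's intron) and miRNAs against
their experimentally validated targets (negative coupling expected for
repressive regulation).  For every pair the module reports Spearman's
rho, a two-sided p from the t approximation with n-2 degrees of
freedom, and an empirical permutation p from seeded resampling of the
gene vector.  Strong pairs are those with |rho| strictly above 0.8.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_matrix import InputError

#: evidence methods required of a validated miRNA-target interaction
REQUIRED_METHODS = frozenset({"reporter assay", "western blot", "qpcr"})


class DegenerateCorrelation(ValueError):
    """Raised when a vector has zero rank variance (rho undefined)."""


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------


def spearman(x, y) -> float:
    """Spearman's rho: Pearson correlation of average-tie ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("x and y must be equal-length 1-D vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("inputs must be finite")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateCorrelation("zero rank variance; rho undefined")
    rho = stats.spearmanr(x, y).statistic
    # snap floating-point residue so perfectly monotone data give |rho| = 1
    return float(np.clip(round(rho, 12), -1.0, 1.0))


def t_approx_p(rho: float, n: int) -> float:
    """Two-sided p for Spearman's rho via the t approximation.

    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` referred to Student's t
    with n-2 degrees of freedom.  |rho| = 1 returns the limit p = 0.
    """
    if n < 3:
        raise InputError("n must be >= 3")
    if not -1.0 <= rho <= 1.0:
        raise InputError("rho must lie in [-1, 1]")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def nearest_attainable_rho(rho: float, n: int) -> float:
    """Nearest Spearman rho attainable from untied ranks of length n.

    Without ties, rho = 1 - 6*S/(n*(n^2-1)) for integer S (the sum of
    squared rank differences), so published coefficients rounded to a
    few decimals can be de-rounded to the exact attainable value before
    recomputing their p-values.
    """
    denom = n * (n * n - 1)
    s = round((1.0 - rho) * denom / 6.0)
    return 1.0 - 6.0 * s / denom


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def permutation_p(
    x,
    y,
    B: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    add_one: bool = True,
) -> float:
    """Permutation p-value for |Spearman rho|.

    The gene vector ``y`` is permuted ``B`` times (seeded) and the
    fraction of permutations with |rho| at least as extreme as observed
    is reported with the add-one estimator ``(b + 1) / (B + 1)``
    (``add_one=False`` gives the plain fraction ``b / B``).  In
    ``exhaustive`` mode all n! permutations are enumerated and the exact
    fraction over them is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs = abs(spearman(x, y))
    rx, ry = _rank(x), _rank(y)
    rxc = rx - rx.mean()
    tol = 1e-12

    def rho_of(perm_ry: np.ndarray) -> float:
        ryc = perm_ry - perm_ry.mean()
        return float(rxc @ ryc / math.sqrt((rxc @ rxc) * (ryc @ ryc)))

    if exhaustive:
        n = x.size
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(rho_of(ry[list(perm)])) >= rho_obs - tol:
                hits += 1
        return hits / total

    if B < 1:
        raise InputError("B must be >= 1")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (B, 1)), axis=1)
    # permutation leaves the rank mean and sum of squares unchanged
    ryc_ss = float(((ry - ry.mean()) ** 2).sum())
    rho_b = (perms - ry.mean()) @ rxc / math.sqrt((rxc @ rxc) * ryc_ss)
    hits = int(np.sum(np.abs(rho_b) >= rho_obs - tol))
    if add_one:
        return (hits + 1) / (B + 1)
    return hits / B


# ---------------------------------------------------------------------------
# Pair tables
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    feature_a: str  # miRNA
    feature_b: str  # gene
    rho: float
    p_t: float
    p_perm: float
    n: int
    B: int
    kind: str  # host_gene | target


def _correlate_pairs(
    mirna_cpm: pd.DataFrame,
    gene_cpm: pd.DataFrame,
    pairs: list[tuple[str, str]],
    kind: str,
    B: int,
    seed: int,
) -> pd.DataFrame:
    shared = [s for s in mirna_cpm.columns if s in set(gene_cpm.columns)]
    if len(shared) < 3:
        raise InputError("need at least three shared samples")
    rows = []
    for i, (m, g) in enumerate(pairs):
        if m not in mirna_cpm.index or g not in gene_cpm.index:
            warnings.warn(f"pair ({m}, {g}) absent from matrices; skipped")
            continue
        x = mirna_cpm.loc[m, shared].to_numpy(dtype=float)
        y = gene_cpm.loc[g, shared].to_numpy(dtype=float)
        try:
            rho = spearman(x, y)
        except DegenerateCorrelation:
            warnings.warn(f"pair ({m}, {g}) has zero rank variance; skipped")
            continue
        # per-pair independent, reproducible permutation substream
        p_perm = permutation_p(x, y, B=B, seed=np.random.SeedSequence([seed, i]))
        rows.append(
            dict(
                feature_a=m,
                feature_b=g,
                rho=rho,
                p_t=t_approx_p(rho, len(shared)),
                p_perm=p_perm,
                n=len(shared),
                B=B,
                kind=kind,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["feature_a", "feature_b", "rho", "p_t", "p_perm", "n", "B", "kind"],
    )


def host_gene_correlations(
    mirna_cpm: pd.DataFrame,
    gene_cpm: pd.DataFrame,
    host_annotation: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate miRtronic miRNAs with their host genes.

    ``host_annotation`` needs columns ``mirna`` and ``host_gene``; pairs
    missing from either matrix are skipped with a warning.
    """
    pairs = [
        (r.mirna, r.host_gene)
        for r in host_annotation.itertuples()
        if isinstance(r.host_gene, str) and r.host_gene
    ]
    return _correlate_pairs(mirna_cpm, gene_cpm, pairs, "host_gene", B, seed)


# ---------------------------------------------------------------------------
# Validated-target interactions
# ---------------------------------------------------------------------------


def _normalize_token(tok: str) -> str:
    return re.sub(r"[^a-z0-9]", "", tok.lower())


def _matches_method(token_norm: str, method: str) -> bool:
    if method == "qpcr":
        return "qpcr" in token_norm or "qrtpcr" in token_norm
    return _normalize_token(method) in token_norm or any(
        w in token_norm for w in method.split()
    )


def _evidence_tokens(evidence) -> list[str]:
    if isinstance(evidence, str):
        return [t for t in re.split(r"[;/|]+", evidence) if t.strip()]
    return list(evidence)


def filter_interactions(
    interactions: pd.DataFrame,
    required_methods: frozenset[str] = REQUIRED_METHODS,
    mode: str = "required",
    min_methods: int = 3,
) -> pd.DataFrame:
    """Keep interactions with strong experimental validation.

    Default mode keeps records whose evidence covers every required
    method (reporter assay, Western blot, qPCR); ``mode='any'`` keeps
    records with at least ``min_methods`` distinct evidence methods of
    any kind.  Evidence strings are matched case-insensitively and
    punctuation-insensitively (so "qRT-PCR" satisfies qPCR).
    """
    if mode not in ("required", "any"):
        raise InputError("mode must be 'required' or 'any'")

    def keep(evidence) -> bool:
        tokens = _evidence_tokens(evidence)
        norm = [_normalize_token(t) for t in tokens]
        if mode == "any":
            return len(set(norm)) >= min_methods
        return all(any(_matches_method(t, m) for t in norm) for m in required_methods)

    if not len(interactions):
        return interactions.copy()
    mask = interactions["evidence_methods"].apply(keep)
    return interactions[mask].reset_index(drop=True)


def target_correlations(
    mirna_cpm: pd.DataFrame,
    gene_cpm: pd.DataFrame,
    interactions: pd.DataFrame,
    strong_abs_rho: float = 0.8,
    B: int = 1000,
    seed: int = 0,
):
    """Correlate miRNAs with their validated target genes.

    Returns ``(full, strong, n_negative, n_positive)``: the full pair
    table, the strong subset with |rho| strictly above
    ``strong_abs_rho``, and the strong-negative / strong-positive
    counts.
    """
    pairs = list(
        dict.fromkeys(
            (r.mirna, r.target_gene) for r in interactions.itertuples()
        )
    )
    full = _correlate_pairs(mirna_cpm, gene_cpm, pairs, "target", B, seed)
    strong = full[full["rho"].abs() > strong_abs_rho].copy()
    n_neg = int((strong["rho"] < 0).sum())
    n_pos = int((strong["rho"] > 0).sum())
    return full, strong, n_neg, n_pos


def strong_pairs(rhos: pd.Series | np.ndarray, strong_abs_rho: float = 0.8):
    """Split correlation coefficients into strong negative/positive sets.

    Strictly-greater comparison on |rho|; returns ``(negative, positive)``
    boolean masks.
    """
    r = np.asarray(rhos, dtype=float)
    strong = np.abs(r) > strong_abs_rho
    return strong & (r < 0), strong & (r > 0)


def shared_target_network(
    de_mirnas: list[str], interactions: pd.DataFrame, min_shared: int = 2
) -> pd.DataFrame:
    """miRNA-target edges for targets shared by several DE miRNAs.

    Keeps target genes connected to at least ``min_shared`` of the
    supplied miRNAs and returns the surviving edges.
    """
    sub = interactions[interactions["mirna"].isin(set(de_mirnas))]
    edges = sub[["mirna", "target_gene"]].drop_duplicates()
    deg = edges.groupby("target_gene")["mirna"].nunique()
    keep = set(deg[deg >= min_shared].index)
    return (
        edges[edges["target_gene"].isin(keep)]
        .sort_values(["target_gene", "mirna"])
        .reset_index(drop=True)
    )


def read_interactions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_host_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
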