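"""Count-matrix hygiene and between-sample normalization.

Implements the standard small-RNA / RNA-seq count workflow: a noise
filter removing features that are both low-abundance and mostly absent,
trimmed-mean-of-M-values (TMM) normalization factors, counts-per-million
(CPM) on effective library sizes, group-wise mean-CPM expression filters
and the log2 transform used for ordination.

TMM follows the published method: a reference sample is chosen by the
75th-percentile criterion; per sample, gene-wise log ratios M and
average log abundances A against the reference are doubly trimmed (30%
of each M tail, 5% of each A tail) and the normalization factor is two
to the precision-weighted mean of the surviving M values, with factors
rescaled to geometric mean one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with normalization state.

    ``library_sizes`` default to column sums; ``norm_factors`` default to
    one and after :func:`tmm_factors` have geometric mean one.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = None
    norm_factors: pd.Series = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise InputError("feature and sample ids must be unique")
        if (c.to_numpy() < 0).any():
            raise InputError("counts must be nonnegative")
        if self.library_sizes is None:
            self.library_sizes = c.sum(axis=0)
        else:
            self.library_sizes = pd.Series(self.library_sizes, index=c.columns).astype(
                float
            )
            if (self.library_sizes < 0).any():
                raise InputError("library sizes must be nonnegative")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=c.columns)
        else:
            self.norm_factors = pd.Series(self.norm_factors, index=c.columns).astype(
                float
            )

    @property
    def feature_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    def subset(self, features) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[features],
            library_sizes=self.library_sizes,
            norm_factors=self.norm_factors,
        )

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.norm_factors


@dataclass
class GroupDesign:
    """Sample-to-group assignment for the two fiber-type groups.

    type1 = slow-fiber-predominant, type2 = fast-fiber-predominant.
    """

    groups: pd.Series  # index: sample ids, values: group labels

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)

    @classmethod
    def from_metadata(cls, meta: pd.DataFrame, sample_col="sample", group_col="group"):
        return cls(pd.Series(meta[group_col].values, index=meta[sample_col].values))

    def labels_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups.index]
        if missing:
            raise InputError(f"samples without group assignment: {missing}")
        return self.groups.loc[sample_ids].to_numpy()

    def group_names(self) -> list[str]:
        return sorted(pd.unique(self.groups))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def noise_filter(
    cm: CountMatrix,
    max_mean: float = 2.0,
    min_missing_frac: float = 0.90,
    combine: str = "and",
) -> CountMatrix:
    """Remove likely-noise features.

    A feature is dropped when its mean count per sample is <= ``max_mean``
    AND it is absent (zero) in at least ``min_missing_frac`` of samples.
    ``combine='or'`` switches to the disjunctive form.  Library sizes are
    kept as-is so CPM scaling is unaffected by the removal.
    """
    if combine not in ("and", "or"):
        raise InputError("combine must be 'and' or 'or'")
    c = cm.counts
    low_mean = c.mean(axis=1) <= max_mean
    missing = (c == 0).mean(axis=1) >= min_missing_frac
    drop = (low_mean & missing) if combine == "and" else (low_mean | missing)
    return CountMatrix(
        c.loc[~drop], library_sizes=cm.library_sizes, norm_factors=cm.norm_factors
    )


def group_expression_filter(
    cpm: pd.DataFrame, design: GroupDesign, threshold: float, inclusive: bool = False
) -> list[str]:
    """Keep features whose maximal group-mean CPM exceeds ``threshold``.

    The comparison is strict by default (``> threshold``); ``inclusive``
    switches to ``>=``.
    """
    labels = design.labels_for(cpm.columns)
    maxima = pd.concat(
        [cpm.loc[:, labels == gname].mean(axis=1) for gname in np.unique(labels)],
        axis=1,
    ).max(axis=1)
    keep = maxima >= threshold if inclusive else maxima > threshold
    return list(cpm.index[keep])


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, q: float = 0.75) -> np.ndarray:
    return np.quantile(counts / lib, q, axis=0)


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: the one whose 75th-percentile count fraction is
    closest to the mean across samples (unless ``ref_sample`` is given).
    ``logratio_trim`` / ``sum_trim`` are trimmed from each tail of M and
    A respectively.  Weights are the inverse asymptotic variances of M.
    Factors are rescaled so their geometric mean is one.
    """
    y = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes.to_numpy(dtype=float)
    n_samples = y.shape[1]
    if n_samples < 2:
        raise InputError("TMM needs at least two samples")
    if (y.sum(axis=0) == 0).any():
        raise InputError("every sample needs at least one nonzero count")

    f75 = _quantile_factor(y, lib)
    if ref_sample is None:
        r = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        r = list(cm.sample_ids).index(ref_sample)

    factors = np.ones(n_samples)
    yr, nr = y[:, r], lib[r]
    for s in range(n_samples):
        if s == r:
            continue
        factors[s] = _tmm_pair(
            y[:, s], lib[s], yr, nr, logratio_trim, sum_trim, weighted
        )
    # rescale to geometric mean 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="norm_factor")


def _tmm_pair(ys, ns, yr, nr, logratio_trim, sum_trim, weighted) -> float:
    both = (ys > 0) & (yr > 0)
    if not both.any():
        warnings.warn("sample shares no nonzero features with reference; factor = 1")
        return 1.0
    ys, yr = ys[both], yr[both]
    ps, pr = ys / ns, yr / nr
    m = np.log2(ps / pr)
    a = 0.5 * np.log2(ps * pr)
    v = (ns - ys) / (ns * ys) + (nr - yr) / (nr * yr)

    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0

    # double trim, edgeR-style rank cut on each tail
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.nansum(m[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    else:
        f = np.nanmean(m[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def apply_tmm(cm: CountMatrix, **kwargs) -> CountMatrix:
    """Return a copy of ``cm`` with TMM norm_factors set."""
    return CountMatrix(
        cm.counts, library_sizes=cm.library_sizes, norm_factors=tmm_factors(cm, **kwargs)
    )


# ---------------------------------------------------------------------------
# CPM and log transform
# ---------------------------------------------------------------------------


def compute_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million on effective (factor-adjusted) library sizes."""
    eff = cm.effective_library_sizes
    if (eff <= 0).any():
        raise InputError("zero or negative effective library size")
    return cm.counts / eff * 1e6


def log_transform(cpm: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    """log2(CPM + prior); the prior keeps zeros finite and order-preserved."""
    if prior < 0:
        raise InputError("prior must be nonnegative")
    if (cpm.to_numpy() < 0).any():
        raise InputError("CPM values must be nonnegative")
    return np.log2(cpm + prior)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.astype(np.int64))


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
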