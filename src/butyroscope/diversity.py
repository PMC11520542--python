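"""Alpha diversity, Bray-Curtis dissimilarity and PERMANOVA.

PERMANOVA partitions the total sum of squared dissimilarities into
between- and within-group components and assesses the pseudo-F ratio
against a permutation distribution of group labels.  For ``a`` groups and
``n`` samples:

    SS_total   = sum_{i<j} d_ij^2 / n
    SS_within  = sum_g sum_{i<j in g} d_ij^2 / n_g
    SS_between = SS_total - SS_within
    F          = (SS_between / (a - 1)) / (SS_within / (n - a))
    R^2        = SS_between / SS_total

The permutation p uses the add-one convention
p = (1 + #{F_perm >= F_obs}) / (1 + B); when the number of distinct label
assignments is small they are enumerated exhaustively instead and
p = #{F >= F_obs} / #assignments.  A two-way variant with interaction is
provided via sequential sums of squares on the Gower-centered matrix.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import CommunityProfile, FormatError


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    ids: Sequence

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def simpson_index(counts_row) -> float:
    """Simpson diversity 1 - sum(p_i^2) of one sample's counts.

    Ranges from 0 (one taxon) to 1 - 1/k (k equally abundant taxa).
    """
    x = np.asarray(counts_row, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Simpson index undefined for an all-zero sample")
    p = x / total
    return float(1.0 - np.sum(p * p))


def alpha_diversity(profile: CommunityProfile) -> pd.Series:
    """Per-sample Simpson index."""
    return pd.Series(
        {s: simpson_index(profile.counts.loc[s]) for s in profile.sample_ids},
        name="simpson",
    )


def bray_curtis_matrix(
    profile: CommunityProfile, normalize: bool = False
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    Computed on raw counts, or on per-sample proportions when
    ``normalize`` is set (making it depth-invariant).
    """
    counts = profile.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(profile.sample_ids, totals) if t == 0]
        raise FormatError(f"zero-total samples: {bad}")
    if normalize:
        counts = counts / totals[:, None]
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    diff = np.abs(counts[:, None, :] - counts[None, :, :]).sum(axis=2)
    summ = (counts[:, None, :] + counts[None, :, :]).sum(axis=2)
    d = diff / summ
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, ids=list(profile.sample_ids))


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "exhaustive" | "permutation"
    seed: Optional[int] = None
    terms: Optional[pd.DataFrame] = None  # per-term records for multi-factor fits


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> tuple:
    """(SS_total, SS_within) from squared distances and integer labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(ss_between: float, ss_within: float, a: int, n: int) -> float:
    if ss_within <= 0:
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _distinct_assignments(counts: Sequence[int]):
    """Yield all distinct assignments of group sizes ``counts`` to n slots.

    Each assignment is an integer label array; positions for group 0 are
    chosen first, then group 1 among the rest, and so on, so every
    multiset permutation appears exactly once.
    """
    n = sum(counts)

    def rec(slots, sizes, gi, labels):
        if gi == len(sizes) - 1:
            out = labels.copy()
            out[list(slots)] = gi
            yield out
            return
        for chosen in itertools.combinations(slots, sizes[gi]):
            out = labels.copy()
            out[list(chosen)] = gi
            remaining = tuple(s for s in slots if s not in set(chosen))
            yield from rec(remaining, sizes, gi + 1, out)

    yield from rec(tuple(range(n)), list(counts), 0, np.full(n, -1, dtype=int))


def n_distinct_assignments(counts: Sequence[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(
    dist: DistanceMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: Optional[int] = None,
    exhaustive_if_small: bool = True,
    exhaustive_max: int = 10_000,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    When the number of distinct label assignments is at most
    ``exhaustive_max`` (and ``exhaustive_if_small``), the permutation
    distribution is enumerated exhaustively; otherwise ``n_permutations``
    random shuffles are drawn.  Perfect separation (SS_within = 0) gives
    F = +inf, compared with >=.
    """
    n = dist.n
    if n < 3:
        raise ValueError("PERMANOVA needs at least 3 samples")
    groups = np.asarray(pd.Categorical(list(groups)).codes)
    if len(groups) != n:
        raise ValueError("groups must cover all samples")
    uniq, sizes = np.unique(groups, return_counts=True)
    a = uniq.size
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if a == 2 and (sizes == 1).any():
        warnings.warn(
            "group of size 1 contributes zero within-group degrees of freedom",
            stacklevel=2,
        )

    d2 = dist.values**2
    ss_total, ss_within = _group_ss(d2, groups)
    ss_between = ss_total - ss_within
    f_obs = _pseudo_f(ss_between, ss_within, a, n)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    n_assign = n_distinct_assignments(sizes)
    if exhaustive_if_small and n_assign <= exhaustive_max:
        count = 0
        for labels in _distinct_assignments(sizes):
            sst, ssw = _group_ss(d2, labels)
            f = _pseudo_f(sst - ssw, ssw, a, n)
            if f >= f_obs:
                count += 1
        return PermanovaResult(
            r_squared=r2, pseudo_f=f_obs, p_value=count / n_assign,
            n_permutations=n_assign, method="exhaustive", seed=seed,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        sst, ssw = _group_ss(d2, perm)
        f = _pseudo_f(sst - ssw, ssw, a, n)
        if f >= f_obs:
            count += 1
    return PermanovaResult(
        r_squared=r2, pseudo_f=f_obs, p_value=(1 + count) / (1 + n_permutations),
        n_permutations=n_permutations, method="permutation", seed=seed,
    )


# --------------------------------------------------------------------------
# Two-factor PERMANOVA (sequential sums of squares on the Gower matrix)
# --------------------------------------------------------------------------


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _design(codes: np.ndarray) -> np.ndarray:
    return pd.get_dummies(pd.Categorical(codes)).to_numpy(dtype=float)


def permanova_two_way(
    dist: DistanceMatrix,
    factor_a: Sequence,
    factor_b: Sequence,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """Two-factor PERMANOVA with interaction (sequential SS, A then B).

    Terms A, B and A:B are fitted sequentially on the Gower-centered
    squared-distance matrix; each term's p comes from free permutation of
    raw sample labels with the sequential SS recomputed per shuffle.
    The returned ``terms`` frame has one row per term (df, SS, R^2, F, p).
    """
    n = dist.n
    fa = np.asarray(pd.Categorical(list(factor_a)).codes)
    fb = np.asarray(pd.Categorical(list(factor_b)).codes)
    if len(fa) != n or len(fb) != n:
        raise ValueError("factors must cover all samples")
    g = _gower_center(dist.values**2)
    ss_total = np.trace(g)

    def seq_ss(fa, fb):
        ones = np.ones((n, 1))
        xa = np.hstack([ones, _design(fa)])
        xab = np.hstack([xa, _design(fb)])
        inter = fa.astype(np.int64) * (fb.max() + 1) + fb
        xfull = np.hstack([xab, _design(inter)])
        tr = [float(np.trace(_hat(x) @ g)) for x in (xa, xab, xfull)]
        df_a = np.unique(fa).size - 1
        df_b = np.unique(fb).size - 1
        df_full = np.linalg.matrix_rank(xfull) - 1
        df_ab = df_full - df_a - df_b
        ss = np.array([tr[0], tr[1] - tr[0], tr[2] - tr[1]])
        df = np.array([df_a, df_b, max(df_ab, 0)])
        ss_res = ss_total - tr[2]
        df_res = n - 1 - df.sum()
        return ss, df, ss_res, df_res

    ss, df, ss_res, df_res = seq_ss(fa, fb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss / np.maximum(df, 1)) / (ss_res / max(df_res, 1))
    f_obs = np.where(df > 0, f_obs, np.nan)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(3)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ssp, dfp, ssrp, dfrp = seq_ss(fa[perm], fb[perm])
        with np.errstate(divide="ignore", invalid="ignore"):
            fp = (ssp / np.maximum(dfp, 1)) / (ssrp / max(dfrp, 1))
        exceed += (fp >= f_obs) & (df > 0)
    p = (1 + exceed) / (1 + n_permutations)

    terms = pd.DataFrame(
        {
            "term": ["A", "B", "A:B"],
            "df": df,
            "ss": ss,
            "r_squared": ss / ss_total,
            "pseudo_f": f_obs,
            "p_value": np.where(df > 0, p, np.nan),
        }
    )
    inter_row = terms.iloc[2]
    return PermanovaResult(
        r_squared=float(inter_row["r_squared"]),
        pseudo_f=float(inter_row["pseudo_f"]),
        p_value=float(inter_row["p_value"]),
        n_permutations=n_permutations,
        method="permutation",
        seed=seed,
        terms=terms,
    )
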