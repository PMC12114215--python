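"""Beta diversity: dissimilarity matrices, PERMANOVA, and Baselga
turnover/nestedness partitioning of Jaccard (or Sørensen) dissimilarity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .table import CommunityTable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities keyed by sample id."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class BetaTriplet:
    """Baselga decomposition of a pair: similarity + turnover + nestedness = 1."""

    similarity: float
    turnover: float
    nestedness: float


def dissimilarity(table: CommunityTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray–Curtis (abundance) or Jaccard (presence/absence)
    dissimilarity.  BC(x, y) = Σ|x−y| / Σ(x+y)."""
    mat = table.matrix()
    if mat.shape[0] < 2:
        raise ValueError("need at least two samples")
    if np.any(mat.sum(axis=1) == 0):
        raise ValueError("all-zero samples cannot be compared")
    if metric == "bray_curtis":
        d = pdist(mat, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(mat > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(table.sample_ids, squareform(d), metric=metric)


def partition_beta(x, y, family: str = "jaccard") -> BetaTriplet:
    """Partition one pair's presence/absence dissimilarity into turnover and
    nestedness (Baselga family).

    Jaccard family: β_jac = (b+c)/(a+b+c); β_jtu = 2·min(b,c)/(a+2·min(b,c));
    β_jne = β_jac − β_jtu.  Sørensen family uses (b+c)/(2a+b+c) and
    min(b,c)/(a+min(b,c)).
    """
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    if a + b + c == 0:
        raise ValueError("both samples are empty")
    mn = min(b, c)
    if family == "jaccard":
        total = (b + c) / (a + b + c)
        turnover = 2 * mn / (a + 2 * mn) if (a + 2 * mn) > 0 else 0.0
    elif family == "sorensen":
        total = (b + c) / (2 * a + b + c)
        turnover = mn / (a + mn) if (a + mn) > 0 else 0.0
    else:
        raise ValueError(f"unknown family {family!r}")
    nestedness = total - turnover
    return BetaTriplet(
        similarity=1.0 - total, turnover=turnover, nestedness=nestedness
    )


def partition_beta_pairs(table: CommunityTable, family: str = "jaccard") -> pd.DataFrame:
    """All-pairs Baselga triplets plus the triangular-summary means."""
    mat = table.matrix() > 0
    n = mat.shape[0]
    rows = []
    ids = table.sample_ids
    for i in range(n):
        for j in range(i + 1, n):
            t = partition_beta(mat[i], mat[j], family=family)
            rows.append((ids[i], ids[j], t.similarity, t.turnover, t.nestedness))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "similarity", "turnover", "nestedness"]
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squares for a batch of group-indicator masks.

    ``masks`` has shape (batch, n_groups, n); returns SS_within per batch
    member using SS_g = (1/n_g) Σ_{i<j∈g} d²_ij.
    """
    ssw = np.einsum("bgi,ij,bgj->bg", masks, d2, masks) / 2.0
    return (ssw / sizes[None, :]).sum(axis=1)


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """One-way PERMANOVA (Adonis) on a distance matrix.

    R² = SS_between / SS_total from squared distances; pseudo-F with
    (a−1, n−a) degrees of freedom; p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1)
    under free permutation of sample labels.
    """
    groups = np.asarray(groups)
    if len(groups) != len(dist.sample_ids):
        raise ValueError("group labels must match distance matrix samples")
    labels, inverse = np.unique(groups, return_inverse=True)
    a = len(labels)
    n = len(groups)
    if a < 2:
        raise ValueError("need at least two groups")
    d2 = dist.values**2
    sizes = np.bincount(inverse).astype(float)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def one_hot(inv: np.ndarray) -> np.ndarray:
        m = np.zeros((a, n))
        m[inv, np.arange(n)] = 1.0
        return m

    ss_within = _permanova_ss(d2, one_hot(inverse)[None], sizes)[0]
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    if df_w <= 0 or ss_within <= 0:
        f_obs = np.inf
    else:
        f_obs = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    batch = np.empty((n_perm, a, n))
    for b in range(n_perm):
        batch[b] = one_hot(rng.permutation(inverse))
    ssw_perm = _permanova_ss(d2, batch, sizes)
    ssb_perm = ss_total - ssw_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb_perm / df_b) / (ssw_perm / df_w)
    f_perm = np.where(ssw_perm <= 0, np.inf, f_perm)
    p = (np.sum(f_perm >= f_obs) + 1) / (n_perm + 1)
    return {
        "R2": float(r2),
        "F": float(f_obs),
        "p": float(p),
        "n_perm": int(n_perm),
        "df": (df_b, df_w),
    }
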