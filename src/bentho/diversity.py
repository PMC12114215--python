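"""Alpha diversity, seasonal group testing, and shared/unique taxon counts."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .table import CommunityTable


def alpha_diversity(table: CommunityTable, base: float | None = None) -> pd.DataFrame:
    """Shannon diversity (natural log by default) and observed taxa per sample.

    Returns a tidy DataFrame with columns ``sample_id, shannon, observed,
    season`` (season NaN if the table carries no season information).
    """
    mat = table.matrix()
    totals = mat.sum(axis=1)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"empty sample(s): {bad}")
    p = mat / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    if base is not None:
        shannon = shannon / np.log(base)
    observed = (mat > 0).sum(axis=1)
    try:
        seasons = table.seasons()
    except Exception:
        seasons = pd.Series(np.nan, index=table.counts.index)
    return pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "shannon": shannon,
            "observed": observed,
            "season": seasons.to_numpy(),
        }
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across groups.

    Degenerate input where every observation is identical returns
    ``(0.0, 1.0)`` instead of an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    split = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in split):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*split)
    return float(h), float(p)


def posthoc_letters(values, groups, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from uncorrected pairwise Kruskal–Wallis tests.

    Groups that do not differ at ``alpha`` share a letter.  Uses the simple
    insert-and-absorb algorithm over groups ordered by mean value.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups), key=lambda g: -np.mean(values[groups == g]))
    differ = {}
    for a, b in itertools.combinations(labels, 2):
        sel = (groups == a) | (groups == b)
        _, p = kruskal_wallis(values[sel], groups[sel])
        differ[(a, b)] = differ[(b, a)] = p < alpha
    # greedy letter assignment
    letter_sets: list[set] = []
    for g in labels:
        placed = False
        for s in letter_sets:
            if not any(differ[(g, other)] for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def venn_counts(table: CommunityTable, group_key: str = "season") -> dict[tuple, int]:
    """Exact counts of the presence/absence partition among groups.

    Keys are sorted tuples of group labels (the Venn region: taxa present in
    exactly those groups); values are taxon counts.  Regions sum to the
    number of taxa observed in at least one group.
    """
    labels = table.groups(group_key)
    if labels.isna().any():
        warnings.warn("samples with missing group labels are ignored")
    mat = table.matrix() > 0
    group_names = sorted(pd.unique(labels.dropna()))
    presence = {}
    for g in group_names:
        rows = (labels == g).to_numpy()
        presence[g] = mat[rows].any(axis=0)
    out: dict[tuple, int] = {}
    stacked = np.array([presence[g] for g in group_names])  # groups x taxa
    observed = stacked.any(axis=0)
    for size in range(1, len(group_names) + 1):
        for combo in itertools.combinations(group_names, size):
            in_combo = np.array([g in combo for g in group_names])
            region = stacked[in_combo].all(axis=0) & ~stacked[~in_combo].any(axis=0)
            out[tuple(combo)] = int(region.sum())
    assert sum(out.values()) == int(observed.sum())
    return out
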