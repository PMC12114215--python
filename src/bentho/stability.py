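"""Community stability via the average variation degree (AVD).

For sample j in group g, AVD_j is the mean over taxa of the absolute
deviation of the taxon's relative abundance from its within-group mean,
standardized by its within-group standard deviation:

    AVD_j = (1/n_g) Σ_i |a_ij − ā_ig| / δ_ig

Lower AVD means a more stable community.  Taxa with zero within-group
variance carry no information about dispersion and are excluded from that
group's computation (logged), rather than contributing zero deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import kruskal_wallis, posthoc_letters
from .table import CommunityTable

logger = logging.getLogger(__name__)


@dataclass
class AVDResult:
    per_sample: pd.DataFrame  # sample_id, group, avd, n_taxa_included, all_excluded
    group_means: dict
    H: float
    p: float
    letters: dict = field(default_factory=dict)


def avd(
    table: CommunityTable,
    groups=None,
    ddof: int = 1,
) -> AVDResult:
    """Per-sample AVD on a relative-abundance table, grouped (e.g. by season).

    ``ddof=1`` (sample standard deviation) by default; ``ddof=0`` for the
    population convention.  Groups need at least two samples.  Group
    differences are tested by Kruskal–Wallis with compact letters when there
    are two or more groups.
    """
    mat = table.matrix()
    n = mat.shape[0]
    if groups is None:
        groups = table.seasons().to_numpy()
    elif isinstance(groups, str):
        groups = table.groups(groups).to_numpy()
    else:
        groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        sel = np.flatnonzero(groups == g)
        if sel.size < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
        sub = mat[sel]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=ddof)
        # treat rounding-level spread as zero variance
        include = sd > 1e-12 * np.maximum(np.abs(mean), 1.0)
        n_inc = int(include.sum())
        if n_inc == 0:
            logger.warning("group %r: every taxon has zero variance", g)
            for i in sel:
                rows.append((table.sample_ids[i], g, 0.0, 0, True))
            continue
        if n_inc < include.size:
            logger.info(
                "group %r: excluded %d zero-variance taxa", g, include.size - n_inc
            )
        dev = np.abs(sub[:, include] - mean[include]) / sd[include]
        vals = dev.mean(axis=1)
        for i, v in zip(sel, vals):
            rows.append((table.sample_ids[i], g, float(v), n_inc, False))
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "group", "avd", "n_taxa_included", "all_excluded"]
    )
    group_means = per_sample.groupby("group")["avd"].mean().to_dict()
    if per_sample["group"].nunique() >= 2:
        h, p = kruskal_wallis(per_sample["avd"], per_sample["group"])
        letters = posthoc_letters(
            per_sample["avd"].to_numpy(), per_sample["group"].to_numpy()
        )
    else:
        h, p, letters = float("nan"), float("nan"), {}
    return AVDResult(per_sample=per_sample, group_means=group_means, H=h, p=p, letters=letters)
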