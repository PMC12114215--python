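"""Stochastic vs deterministic community assembly.

Two complementary statistics:

* The Sloan neutral community model (NCM): a taxon's occurrence frequency
  across samples is predicted from its mean relative abundance ``p`` by the
  survival function of the stationary Beta(N·m·p, N·m·(1−p)) distribution at
  the detection limit 1/N, where ``N`` is the per-sample community size
  (reads after rarefaction) and ``m`` the migration rate, fitted by least
  squares.  R² near 1 indicates assembly consistent with neutral dispersal;
  R² near or below 0 indicates departure from neutrality.

* The modified stochasticity ratio (MST): for each within-group sample pair,
  the observed Bray–Curtis dissimilarity D is compared with its expectation
  E under a constrained null model (per-sample richness and totals kept;
  occurrences drawn proportional to regional occurrence frequency;
  abundances proportional to regional mean relative abundance).
  MST = min(D, E)/max(D, E) ∈ [0, 1]; values above 0.5 are read as
  predominantly stochastic assembly, below 0.5 as deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.proportion import proportion_confint

from .table import CommunityTable


@dataclass
class NCMFit:
    """Fitted neutral community model."""

    m: float
    N: int
    d: float
    R2: float
    informative: bool
    taxa: pd.DataFrame  # per-taxon: p, observed_freq, predicted_freq, lower, upper, envelope

    @property
    def envelope_counts(self) -> dict[str, int]:
        return self.taxa["envelope"].value_counts().to_dict()


@dataclass
class MSTResult:
    """Pairwise modified stochasticity ratios and their group means."""

    pairs: pd.DataFrame  # sample_a, sample_b, group, D_obs, E_null, mst
    group_means: dict
    overall: float
    settings: dict = field(default_factory=dict)


def ncm_predict(p, N: int, m: float):
    """Predicted occurrence frequency: probability that a stationary
    Beta(N·m·p, N·m·(1−p)) relative abundance exceeds the detection limit
    d = 1/N."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("mean relative abundance must lie strictly in (0, 1)")
    if N * m <= 0:
        raise ValueError("N*m must be positive")
    d = 1.0 / N
    return stats.beta.sf(d, N * m * p, N * m * (1.0 - p))


def _predicted_frequency(p: np.ndarray, N: int, m: float, detection: str) -> np.ndarray:
    if detection == "threshold":
        return stats.beta.sf(1.0 / N, N * m * p, N * m * (1.0 - p))
    if detection == "exact":
        # P(count > 0) when the count is Binomial(N, x) with x ~ Beta(a, b):
        # 1 - E[(1-x)^N] = 1 - B(a, b+N)/B(a, b)
        from scipy.special import gammaln

        a = N * m * p
        b = N * m * (1.0 - p)
        return 1.0 - np.exp(
            gammaln(a + b) + gammaln(b + N) - gammaln(b) - gammaln(a + b + N)
        )
    raise ValueError(f"unknown detection model {detection!r}")


def fit_ncm(
    table: CommunityTable, loss: str = "frequency", detection: str = "exact"
) -> NCMFit:
    """Fit the neutral model's migration rate to occurrence-frequency data.

    ``p_i`` is each taxon's mean relative abundance across samples, observed
    frequency its occupancy / n_samples.  ``m`` minimizes the sum of squared
    frequency residuals (or logit-scale residuals with ``loss="logit"``).
    The 95% envelope uses Wilson binomial intervals around the predicted
    frequency at n_samples trials.

    ``detection`` selects the predicted-frequency formula: ``"exact"``
    (default) uses the beta-binomial probability of observing at least one
    read out of N, which is unbiased when communities are read-sampled;
    ``"threshold"`` uses the classic sharp detection limit
    P(x > 1/N) of :func:`ncm_predict`, which overestimates the migration
    rate slightly because reads can detect taxa below 1/N.
    """
    mat = table.matrix()
    n_samples = mat.shape[0]
    totals = mat.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("empty samples cannot be fitted")
    N = int(round(totals.mean()))
    if not np.allclose(totals, totals[0]):
        warnings.warn(
            "sample totals are unequal; using their mean as community size N "
            "(rarefy first for a cleaner fit)"
        )
    rel = mat / totals[:, None]
    p = rel.mean(axis=0)
    freq = (mat > 0).mean(axis=0)
    present = (p > 0) & (freq > 0)
    p, freq = p[present], freq[present]
    taxa_ids = [t for t, keep in zip(table.taxon_ids, present) if keep]
    if p.size < 5:
        raise ValueError("need at least five taxa to fit the neutral model")
    d = 1.0 / N

    if loss == "frequency":
        def sse(m: float) -> float:
            pred = _predicted_frequency(p, N, m, detection)
            return float(np.sum((freq - pred) ** 2))
    elif loss == "logit":
        eps = 0.5 / n_samples
        f_adj = np.clip(freq, eps, 1 - eps)

        def sse(m: float) -> float:
            pred = np.clip(_predicted_frequency(p, N, m, detection), eps, 1 - eps)
            return float(np.sum((np.log(f_adj / (1 - f_adj)) - np.log(pred / (1 - pred))) ** 2))
    else:
        raise ValueError(f"unknown loss {loss!r}")

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    if not res.success:
        raise RuntimeError(f"neutral-model fit did not converge: {res}")
    m_hat = float(res.x)
    pred = _predicted_frequency(p, N, m_hat, detection)
    sse_val = float(np.sum((freq - pred) ** 2))
    sst = float(np.sum((freq - freq.mean()) ** 2))
    informative = sst > 0
    r2 = 1.0 - sse_val / sst if informative else float("nan")
    if not informative:
        warnings.warn(
            "observed occurrence frequencies are constant; R2 is non-informative"
        )
    lower, upper = proportion_confint(pred * n_samples, n_samples, alpha=0.05, method="wilson")
    envelope = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))
    taxa = pd.DataFrame(
        {
            "taxon_id": taxa_ids,
            "p": p,
            "observed_freq": freq,
            "predicted_freq": pred,
            "lower": lower,
            "upper": upper,
            "envelope": envelope,
        }
    )
    return NCMFit(m=m_hat, N=N, d=d, R2=r2, informative=informative, taxa=taxa)


# ---------------------------------------------------------------------------
# null model + MST
# ---------------------------------------------------------------------------

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if total == 0:
        return np.zeros(weights.size, dtype=np.int64)
    q = weights / weights.sum() * total
    base = np.floor(q).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        frac = q - base
        top = np.argsort(-frac, kind="stable")[:short]
        base[top] += 1
    return base


def null_model_randomize(
    table: CommunityTable,
    algorithm: str = "taxa_shuffle_proportional",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CommunityTable:
    """Constrained randomization of a count table.

    Each null sample keeps its observed richness and total count; its taxa
    are drawn without replacement with probability proportional to regional
    occurrence frequency; abundances are re-assigned proportional to
    regional mean relative abundance among the drawn taxa (every drawn taxon
    gets at least one read so richness is conserved exactly).
    """
    if algorithm != "taxa_shuffle_proportional":
        raise ValueError(f"unknown null algorithm {algorithm!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = np.round(table.matrix()).astype(np.int64)
    n, s = mat.shape
    occ = (mat > 0).mean(axis=0)
    rel = mat / mat.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    candidates = np.flatnonzero(occ > 0)
    w = occ[candidates]
    out = np.zeros_like(mat)
    # weighted sampling without replacement: smallest Exp(1)/w keys win
    keys = rng.exponential(1.0, size=(n, candidates.size)) / w[None, :]
    order = np.argsort(keys, axis=1)
    for j in range(n):
        richness = int((mat[j] > 0).sum())
        total = int(mat[j].sum())
        drawn = candidates[order[j, :richness]]
        v = mean_rel[drawn]
        v = np.where(v > 0, v, v.min() if v.min() > 0 else 1.0)
        out[j, drawn] = 1 + _largest_remainder(v, total - richness)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return table.copy_with(counts, null_model=algorithm)


def mst(
    table: CommunityTable,
    groups=None,
    n_null: int = 1000,
    seed: int | None = None,
    algorithm: str = "taxa_shuffle_proportional",
) -> MSTResult:
    """Modified stochasticity ratio per within-group sample pair.

    MST_ij = min(D_ij, E_ij)/max(D_ij, E_ij) where D is the observed
    Bray–Curtis dissimilarity and E its mean over ``n_null`` null-model
    randomizations.  Group values are arithmetic means over the group's
    pairs; the overall value pools within-group pairs across groups.
    """
    mat = table.matrix()
    n = mat.shape[0]
    if groups is None:
        groups = np.array(["all"] * n)
    elif isinstance(groups, str):
        groups = table.groups(groups).to_numpy()
    else:
        groups = np.asarray(groups)
    counts_per_group = pd.Series(groups).value_counts()
    small = counts_per_group[counts_per_group < 2]
    if len(small):
        raise ValueError(f"groups with fewer than two samples: {list(small.index)}")

    d_obs = pdist(mat, metric="braycurtis")
    rng = np.random.default_rng(seed)
    e_sum = np.zeros_like(d_obs)
    for _ in range(n_null):
        null = null_model_randomize(table, algorithm=algorithm, rng=rng)
        e_sum += pdist(null.matrix(), metric="braycurtis")
    e_null = e_sum / n_null

    hi = np.maximum(d_obs, e_null)
    lo = np.minimum(d_obs, e_null)
    with np.errstate(divide="ignore", invalid="ignore"):
        mst_pairs = np.where(hi > 0, lo / hi, 1.0)

    ids = table.sample_ids
    iu = np.triu_indices(n, 1)
    same = groups[iu[0]] == groups[iu[1]]
    pairs = pd.DataFrame(
        {
            "sample_a": np.asarray(ids)[iu[0]],
            "sample_b": np.asarray(ids)[iu[1]],
            "group": np.where(same, groups[iu[0]], "between"),
            "D_obs": d_obs,
            "E_null": e_null,
            "mst": mst_pairs,
        }
    )
    within = pairs[same]
    group_means = within.groupby("group")["mst"].mean().to_dict()
    overall = float(within["mst"].mean())
    return MSTResult(
        pairs=pairs,
        group_means=group_means,
        overall=overall,
        settings={"algorithm": algorithm, "n_null": int(n_null), "seed": seed,
                  "metric": "bray_curtis"},
    )
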