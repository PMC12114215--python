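"""Environmental-driver screening: canonical correspondence analysis (CCA),
envfit-style permutation tests on ordination axes, and Pearson correlation
screens between community summaries and environmental variables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .table import CommunityTable, EnvTable


@dataclass
class CCAResult:
    """Constrained ordination result.

    ``proportion_total`` is each constrained axis's share of total inertia;
    ``proportion_constrained`` its share of constrained inertia (both are
    reported because published axis percentages are stated either way).
    """

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    proportion_total: np.ndarray
    proportion_constrained: np.ndarray
    sample_scores: pd.DataFrame       # linear-combination (LC) site scores
    sample_scores_wa: pd.DataFrame    # weighted-average site scores
    taxon_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    env_variables: list[str] = field(default_factory=list)


def _chi_square_standardize(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    total = y.sum()
    if total <= 0:
        raise ValueError("community matrix has zero total")
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r <= 0):
        raise ValueError("zero-sum sample rows are not allowed in CCA")
    if np.any(c <= 0):
        raise ValueError("zero-sum taxon columns are not allowed in CCA")
    qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return qbar, r, c


def total_inertia(table: CommunityTable) -> float:
    """Total inertia: the chi-square statistic of the table divided by the
    grand total (sum of squared chi-square standardized deviations)."""
    qbar, _, _ = _chi_square_standardize(table.matrix())
    return float((qbar**2).sum())


def cca(community: CommunityTable, env: EnvTable, n_axes: int | None = None) -> CCAResult:
    """Canonical correspondence analysis of a (transformed) abundance table
    constrained by environmental variables.

    The chi-square standardized community matrix is regressed (row-weighted)
    on the environmental variables; the fitted matrix is decomposed by SVD.
    Env columns are dropped with a warning if there are too few samples for
    a full fit; collinear columns raise an error naming them.
    """
    y = community.matrix()
    empty = y.sum(axis=0) <= 0
    if empty.any():  # taxa absent from every sample carry no inertia
        warnings.warn(f"dropping {int(empty.sum())} all-zero taxa from the CCA")
        keep = ~empty
        y = y[:, keep]
        taxon_ids = [t for t, k in zip(community.taxon_ids, keep) if k]
    else:
        taxon_ids = community.taxon_ids
    x_df = env.values.loc[community.sample_ids]
    if x_df.isna().any().any():
        raise ValueError("environment table has missing values for fitted samples")
    n = y.shape[0]
    if x_df.shape[1] >= n:
        keep = list(x_df.columns[: n - 1])
        warnings.warn(
            f"more env variables than samples allow; keeping {keep}"
        )
        x_df = x_df[keep]
    x = x_df.to_numpy(dtype=float)

    qbar, r, c = _chi_square_standardize(y)
    sqrt_r = np.sqrt(r)
    # weighted centering and standardization of env variables
    xbar = np.average(x, axis=0, weights=r)
    xc = x - xbar
    xw = sqrt_r[:, None] * xc
    cond = np.linalg.cond(xw)
    if cond > 1e10:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"collinear environmental columns (condition number {cond:.3g}); "
            f"worst pair: {x_df.columns[i]!r}, {x_df.columns[j]!r}"
        )
    # projection of Qbar onto the column space of the weighted env matrix
    q_x, _ = np.linalg.qr(xw)
    fitted = q_x @ (q_x.T @ qbar)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * (s[0] if s.size else 1.0)))
    if n_axes is not None:
        rank = min(rank, n_axes)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    eig = s**2
    tot = float((qbar**2).sum())
    con = float((fitted**2).sum())
    axes = [f"CCA{k + 1}" for k in range(rank)]

    lc = (u * s) / sqrt_r[:, None]
    wa = (qbar @ vt.T) / sqrt_r[:, None]
    taxon = vt.T / np.sqrt(c)[:, None]
    # biplot scores: weighted correlation of env variables with LC axes
    xw_norm = xw / np.linalg.norm(xw, axis=0, keepdims=True)
    biplot = xw_norm.T @ u

    return CCAResult(
        eigenvalues=eig,
        total_inertia=tot,
        constrained_inertia=con,
        proportion_total=eig / tot,
        proportion_constrained=eig / con if con > 0 else eig * 0,
        sample_scores=pd.DataFrame(lc, index=community.sample_ids, columns=axes),
        sample_scores_wa=pd.DataFrame(wa, index=community.sample_ids, columns=axes),
        taxon_scores=pd.DataFrame(taxon, index=taxon_ids, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=list(x_df.columns), columns=axes),
        env_variables=list(x_df.columns),
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def envfit(
    scores,
    env: EnvTable,
    n_perm: int = 999,
    seed: int | None = None,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Per-variable fit of environmental vectors to ordination axes.

    R² is the squared multiple correlation of the variable regressed on the
    first ``n_axes`` axis scores; p-values come from permuting the variable
    across samples.  Returns a DataFrame with columns ``variable, R2, p,
    stars``.
    """
    if isinstance(scores, CCAResult):
        score_df = scores.sample_scores
    elif isinstance(scores, pd.DataFrame):
        score_df = scores
    else:
        score_df = pd.DataFrame(np.asarray(scores))
        score_df.index = env.values.index[: len(score_df)]
    s = score_df.to_numpy(dtype=float)[:, :n_axes]
    n = s.shape[0]
    if n < 3:
        raise ValueError("need scores for at least three samples")
    sc = s - s.mean(axis=0)
    q, _ = np.linalg.qr(sc)
    rng = np.random.default_rng(seed)
    records = []
    x = env.values.loc[score_df.index]
    for var in x.columns:
        y = x[var].to_numpy(dtype=float)
        yc = y - y.mean()
        sst = float(yc @ yc)
        if sst <= 0:
            warnings.warn(f"constant environmental variable {var!r}")
            records.append((var, 0.0, 1.0, ""))
            continue
        r2 = float(np.sum((q.T @ yc) ** 2) / sst)
        perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)  # (n_perm, n)
        proj = perms @ q  # (n_perm, k)
        r2_perm = np.sum(proj**2, axis=1) / sst
        p = float((np.sum(r2_perm >= r2 - 1e-12) + 1) / (n_perm + 1))
        records.append((var, r2, p, _stars(p)))
    return pd.DataFrame(records, columns=["variable", "R2", "p", "stars"])


def correlation_screen(
    x: pd.DataFrame,
    env: EnvTable,
    method: str = "pearson",
    adjust: bool = False,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between the columns of ``x`` (taxa at a
    rank, alpha indices, ...) and environmental variables.

    Two-sided p from the t distribution with n−2 df.  Zero-variance series
    yield missing r with an ``undefined`` flag.  Benjamini–Hochberg adjusted
    p-values are appended when ``adjust`` is true.
    """
    if method != "pearson":
        raise ValueError("only Pearson screening is implemented")
    e = env.values
    common = x.index.intersection(e.index)
    if len(common) < 3:
        raise ValueError("need at least three aligned observations")
    xs = x.loc[common].to_numpy(dtype=float)
    es = e.loc[common].to_numpy(dtype=float)
    n = len(common)
    xs_c = xs - xs.mean(axis=0)
    es_c = es - es.mean(axis=0)
    x_sd = xs_c.std(axis=0, ddof=1)
    e_sd = es_c.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xs_c.T @ es_c) / ((n - 1) * np.outer(x_sd, e_sd))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    rows = []
    for i, xi in enumerate(x.columns):
        for j, ej in enumerate(e.columns):
            undefined = x_sd[i] == 0 or e_sd[j] == 0
            rows.append(
                (
                    xi, ej,
                    np.nan if undefined else float(r[i, j]),
                    np.nan if undefined else float(p[i, j]),
                    bool(undefined),
                )
            )
    out = pd.DataFrame(rows, columns=["x", "env", "r", "p", "undefined"])
    if adjust:
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p"], method="fdr_bh"
            )[1]
        out["p_adj"] = adj
    return out


def top_taxa(table: CommunityTable, n: int = 15) -> pd.DataFrame:
    """Relative abundances of the top ``n`` taxa (or collapsed ranks) by mean
    relative abundance across samples."""
    mat = table.matrix()
    rel = mat / mat.sum(axis=1, keepdims=True)
    order = np.argsort(rel.mean(axis=0))[::-1][:n]
    cols = [table.taxon_ids[i] for i in order]
    return pd.DataFrame(rel[:, order], index=table.counts.index, columns=cols)
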