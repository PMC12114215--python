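"""End-to-end study workflow: load → rarefy → diversity → beta → env →
assembly → network → stability, from a single config, with per-stage
artifacts and a deterministic JSON summary."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import fit_ncm, mst
from .beta import dissimilarity, partition_beta_pairs, permanova
from .diversity import alpha_diversity, kruskal_wallis, posthoc_letters, venn_counts
from .envdrivers import cca, correlation_screen, envfit, top_taxa
from .network import build_network, detect_modules, major_modules, topology_with_null, zi_pi
from .stability import avd
from .table import (
    CommunityTable,
    EnvTable,
    collapse_taxonomy,
    load_env,
    load_metadata,
    load_table,
    prevalence_filter,
    rarefy,
    transform,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on; echoed into its provenance."""

    community: str = ""
    metadata: str | None = None
    environment: str | None = None
    output_dir: str = "bentho_out"
    rarefaction_depth: int | None = None  # None: minimum sample total
    group_key: str = "season"
    seed: int = 0
    prevalence_threshold: float = 0.25
    r_threshold: float = 0.7
    p_threshold: float = 0.05
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    mst_boundary: float = 0.5
    n_permutations: int = 999   # PERMANOVA and envfit
    n_null: int = 1000          # MST null randomizations
    n_random_graphs: int = 1000  # Erdős–Rényi ensemble
    cca_transform: str = "hellinger"
    top_taxa: int = 15

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        return cls(**doc)

    def validate(self) -> None:
        for name, value in [
            ("prevalence_threshold", self.prevalence_threshold),
            ("r_threshold", self.r_threshold),
            ("p_threshold", self.p_threshold),
            ("pi_threshold", self.pi_threshold),
            ("mst_boundary", self.mst_boundary),
        ]:
            if not 0 < value < 1:
                raise ValueError(f"{name} out of range: {value}")
        if self.zi_threshold <= 0:
            raise ValueError("zi_threshold must be positive")
        if self.n_permutations < 1 or self.n_null < 1 or self.n_random_graphs < 1:
            raise ValueError("permutation/null counts must be positive")


# fixed offsets give every stage its own named, reproducible stream
_STAGE_SEEDS = {
    "rarefy": 11,
    "permanova": 23,
    "envfit": 31,
    "mst": 47,
    "network_null": 59,
    "louvain": 67,
}


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (int(config.seed) * 1009 + _STAGE_SEEDS[stage]) % (2**31 - 1)


def run_pipeline(
    config: PipelineConfig,
    table: CommunityTable | None = None,
    env: EnvTable | None = None,
) -> dict:
    """Execute all stages and write artifacts under ``config.output_dir``.

    ``table``/``env`` may be passed in memory (e.g. from the synthetic
    generators); otherwise they are loaded from the configured paths.
    Re-running with identical config and inputs is bit-identical.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"bentho {__version__}", f"config: {json.dumps(asdict(config), sort_keys=True)}"]
    summary: dict = {"config": asdict(config)}
    stage = "load"
    try:
        if table is None:
            metadata = load_metadata(config.metadata) if config.metadata else None
            table = load_table(config.community, metadata=metadata)
        if env is None and config.environment:
            env = load_env(config.environment)
        log_lines.append(f"loaded {table.n_samples} samples x {table.n_taxa} taxa")

        stage = "rarefy"
        depth = config.rarefaction_depth or int(table.matrix().sum(axis=1).min())
        seed = _stage_seed(config, "rarefy")
        rare = rarefy(table, depth, seed=seed)
        log_lines.append(f"rarefied to {depth} reads/sample (seed {seed})")
        summary["rarefaction"] = {"depth": depth, "n_samples": rare.n_samples}
        groups = rare.groups(config.group_key).to_numpy()

        stage = "diversity"
        alpha = alpha_diversity(rare)
        alpha.to_csv(out / "alpha.csv", index=False)
        h, p = kruskal_wallis(alpha["shannon"], groups)
        letters = posthoc_letters(alpha["shannon"].to_numpy(), groups)
        venn = venn_counts(rare, config.group_key)
        summary["alpha"] = {
            "shannon_mean": float(alpha["shannon"].mean()),
            "shannon_sd": float(alpha["shannon"].std(ddof=1)),
            "observed_mean": float(alpha["observed"].mean()),
            "observed_sd": float(alpha["observed"].std(ddof=1)),
            "kruskal_H": h,
            "kruskal_p": p,
            "letters": letters,
            "group_means": alpha.groupby(pd.Series(groups, index=alpha.index))["shannon"]
            .mean().to_dict(),
        }
        summary["venn"] = {" & ".join(k): v for k, v in venn.items()}

        stage = "beta"
        dist = dissimilarity(rare, "bray_curtis")
        dist.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
        perma = permanova(dist, groups, n_perm=config.n_permutations,
                          seed=_stage_seed(config, "permanova"))
        with open(out / "permanova.json", "w") as fh:
            json.dump(perma, fh, sort_keys=True)
        parts = partition_beta_pairs(rare)
        parts.to_csv(out / "beta_partition.csv", index=False)
        summary["beta"] = {
            "permanova_R2": perma["R2"],
            "permanova_F": perma["F"],
            "permanova_p": perma["p"],
            "mean_similarity": float(parts["similarity"].mean()),
            "mean_turnover": float(parts["turnover"].mean()),
            "mean_nestedness": float(parts["nestedness"].mean()),
        }

        if env is not None:
            stage = "env_drivers"
            com_aligned, env_aligned = env.align_to(rare)
            ord_res = cca(transform(com_aligned, config.cca_transform), env_aligned)
            ord_res.sample_scores.to_csv(out / "cca_scores.csv")
            fit = envfit(ord_res, env_aligned, n_perm=config.n_permutations,
                         seed=_stage_seed(config, "envfit"))
            fit.to_csv(out / "envfit.csv", index=False)
            try:
                taxa_block = top_taxa(collapse_taxonomy(com_aligned, "phylum"),
                                      config.top_taxa)
            except Exception:
                taxa_block = top_taxa(com_aligned, config.top_taxa)
            alpha_block = alpha_diversity(com_aligned).set_index("sample_id")[
                ["shannon", "observed"]
            ]
            corr = pd.concat(
                [
                    correlation_screen(taxa_block, env_aligned),
                    correlation_screen(alpha_block, env_aligned),
                ],
                ignore_index=True,
            )
            corr.to_csv(out / "correlations.csv", index=False)
            k = min(2, len(ord_res.eigenvalues))
            summary["cca"] = {
                "axis_proportion_total": ord_res.proportion_total[:k].tolist(),
                "axis_proportion_constrained": ord_res.proportion_constrained[:k].tolist(),
                "total_inertia": ord_res.total_inertia,
                "constrained_inertia": ord_res.constrained_inertia,
                "significant_envfit": fit.loc[fit["p"] < 0.05, "variable"].tolist(),
            }

        stage = "assembly"
        ncm = fit_ncm(rare)
        ncm.taxa.to_csv(out / "ncm_taxa.csv", index=False)
        mst_res = mst(rare, groups, n_null=config.n_null,
                      seed=_stage_seed(config, "mst"))
        mst_res.pairs.to_csv(out / "mst.tsv", sep="\t", index=False)
        summary["assembly"] = {
            "ncm_m": ncm.m,
            "ncm_R2": ncm.R2,
            "ncm_N": ncm.N,
            "mst_overall": mst_res.overall,
            "mst_by_group": mst_res.group_means,
            "mst_boundary": config.mst_boundary,
            "stochastic_dominated": mst_res.overall > config.mst_boundary,
        }

        stage = "network"
        net = build_network(
            rare,
            min_prevalence=config.prevalence_threshold,
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
        )
        net.edges.to_csv(out / "network_edges.csv", index=False)
        if net.n_edges == 0:
            # a legitimate outcome for weakly correlated communities
            log_lines.append("no edges pass the correlation thresholds")
            pd.DataFrame(columns=["node", "module", "Zi", "Pi", "category",
                                  "keystone", "sd_zero"]).to_csv(
                out / "node_roles.csv", index=False)
            summary["network"] = {"n_nodes": 0, "n_edges": 0}
        else:
            topo = topology_with_null(net, n_random=config.n_random_graphs,
                                      seed=_stage_seed(config, "network_null"))
            modules, modularity = detect_modules(net, seed=_stage_seed(config, "louvain"))
            roles = zi_pi(net, modules, config.zi_threshold, config.pi_threshold)
            roles.to_csv(out / "node_roles.csv", index=False)
            summary["network"] = {
                **topo["observed"],
                "MD": modularity,
                "null_means": topo["null_means"],
                "small_world_r": topo["small_world_r"],
                "positive_fraction": net.positive_fraction,
                "negative_fraction": net.negative_fraction,
                "major_modules": major_modules(modules).head(8).to_dict("records"),
                "keystone_taxa": roles.loc[roles["keystone"], "node"].tolist(),
                "role_counts": roles["category"].value_counts().to_dict(),
            }

        stage = "stability"
        avd_res = avd(transform(rare, "relative"), groups)
        avd_res.per_sample.to_csv(out / "avd.csv", index=False)
        summary["avd"] = {
            "group_means": avd_res.group_means,
            "kruskal_H": avd_res.H,
            "kruskal_p": avd_res.p,
            "letters": avd_res.letters,
        }
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, sort_keys=True, indent=1)
    log_lines.append("pipeline complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
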