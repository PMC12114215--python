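"""Sample-by-taxon count tables: data model, I/O, and deterministic transforms.

The central container is :class:`CommunityTable`, a validated wrapper around a
samples × taxa ``pandas.DataFrame`` of non-negative counts (or transformed
real abundances) plus per-sample metadata (date, season, group) and optional
per-taxon taxonomy.  Environmental measurements live in :class:`EnvTable`.

Supported on-disk formats: TSV/CSV count tables (taxa-as-rows or
samples-as-rows, auto-detected by header keyword) and BIOM 1.0 (JSON).
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("Spr", "Sum", "Aut", "Win")

#: month -> meteorological season label
_MONTH_SEASON = {
    3: "Spr", 4: "Spr", 5: "Spr",
    6: "Sum", 7: "Sum", 8: "Sum",
    9: "Aut", 10: "Aut", 11: "Aut",
    12: "Win", 1: "Win", 2: "Win",
}

# header keywords used to auto-detect TSV/CSV orientation
_TAXON_KEYWORDS = {
    "#otu id", "otu id", "otu", "otu_id", "taxon", "taxon_id", "taxa",
    "asv", "asv_id", "feature id", "featureid", "feature_id", "#asv id",
}
_SAMPLE_KEYWORDS = {"sample", "sample id", "sample_id", "sample-id", "samples"}

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TableError(ValueError):
    """Raised for invalid community/environment table content."""


@dataclass
class CommunityTable:
    """Samples × taxa abundance table with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with taxon ids as columns.  Values
        must be non-negative; integer counts for raw tables, reals after
        :func:`transform`.
    sample_metadata
        DataFrame indexed by sample id.  Recognized columns: ``date``
        (ISO-8601 string), ``season`` (one of Spr/Sum/Aut/Win), ``group``.
    taxonomy
        Optional DataFrame indexed by taxon id with rank columns
        (domain..genus).
    provenance
        Free-form record of how the table was produced (seeds, depths,
        ground truth for synthetic tables).
    """

    counts: pd.DataFrame
    sample_metadata: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise TableError(f"duplicate sample identifiers: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise TableError(f"duplicate taxon identifiers: {dupes}")
        values = self.counts.to_numpy()
        if values.size and np.nanmin(values) < 0:
            raise TableError("negative abundances are not allowed")
        if self.sample_metadata is None:
            self.sample_metadata = pd.DataFrame(index=self.counts.index.copy())
        else:
            self.sample_metadata.index = self.sample_metadata.index.astype(str)
            missing = self.sample_metadata.index.difference(self.counts.index)
            if len(missing):
                raise TableError(
                    f"metadata references unknown samples: {missing.tolist()}"
                )
            self.sample_metadata = self.sample_metadata.reindex(self.counts.index)
        if self.taxonomy is not None:
            self.taxonomy.index = self.taxonomy.index.astype(str)
            self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def seasons(self) -> pd.Series:
        """Per-sample season labels; derived from dates if absent."""
        md = self.sample_metadata
        if "season" in md.columns and md["season"].notna().all():
            return md["season"]
        if "date" in md.columns:
            return pd.Series(
                assign_seasons(md["date"].tolist()), index=md.index, name="season"
            )
        raise TableError("no season labels or dates in sample metadata")

    def groups(self, key: str = "season") -> pd.Series:
        if key == "season":
            return self.seasons()
        md = self.sample_metadata
        if key not in md.columns:
            raise TableError(f"metadata column {key!r} not found")
        return md[key]

    def copy_with(self, counts: pd.DataFrame, **prov) -> "CommunityTable":
        meta = self.sample_metadata.reindex(counts.index)
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.reindex(counts.columns)
        return CommunityTable(
            counts=counts,
            sample_metadata=meta,
            taxonomy=tax,
            provenance={**self.provenance, **prov},
        )

    def __eq__(self, other: object) -> bool:  # identity on counts + ids
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and list(self.counts.index) == list(other.counts.index)
            and list(self.counts.columns) == list(other.counts.columns)
            and np.allclose(self.matrix(), other.matrix())
        )


@dataclass
class EnvTable:
    """Samples × environmental variables (reals), with per-variable units.

    Missing values stay as NaN and are flagged by :meth:`missing_mask`;
    nothing is imputed.
    """

    values: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        if self.values.index.duplicated().any():
            raise TableError("duplicate sample identifiers in environment table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def align_to(self, table: CommunityTable) -> tuple[CommunityTable, "EnvTable"]:
        """Inner-join on sample ids; returns the aligned pair."""
        common = [s for s in table.sample_ids if s in self.values.index]
        if not common:
            raise TableError("no shared samples between community and environment")
        sub = table.copy_with(table.counts.loc[common])
        env = EnvTable(self.values.loc[common].copy(), units=dict(self.units))
        return sub, env


# ---------------------------------------------------------------------------
# season assignment
# ---------------------------------------------------------------------------

def assign_seasons(dates: list) -> list[str | None]:
    """Map dates to meteorological seasons (Mar–May Spr, Jun–Aug Sum,
    Sep–Nov Aut, Dec–Feb Win).  Unparseable dates yield ``None`` with a
    warning."""
    labels: list[str | None] = []
    for d in dates:
        month = None
        if isinstance(d, (_dt.date, _dt.datetime, pd.Timestamp)):
            month = d.month
        else:
            try:
                month = _dt.date.fromisoformat(str(d)[:10]).month
            except (ValueError, TypeError):
                warnings.warn(f"unparseable date {d!r}; season left unset")
        labels.append(_MONTH_SEASON[month] if month else None)
    return labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".biom":
        return "biom"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def load_table(
    path,
    format: str | None = None,
    orientation: str | None = None,
    metadata: pd.DataFrame | None = None,
) -> CommunityTable:
    """Load a community table from TSV, CSV, or BIOM 1.0 (JSON).

    ``orientation`` forces ``"taxa_rows"`` or ``"samples_rows"`` for
    delimited files; by default the header keyword decides, falling back to
    taxa-as-rows (the common ASV-table layout).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "biom":
        table = _read_biom_json(path)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        header = str(df.index.name or "").strip().lower()
        if orientation is None:
            if header in _SAMPLE_KEYWORDS:
                orientation = "samples_rows"
            elif header in _TAXON_KEYWORDS:
                orientation = "taxa_rows"
            else:
                orientation = "taxa_rows"
        if orientation == "taxa_rows":
            df = df.T
        table = CommunityTable(counts=df)
    else:
        raise TableError(f"unknown format {fmt!r}")
    table.provenance.setdefault("source", str(path))
    if metadata is not None:
        table = CommunityTable(
            counts=table.counts, sample_metadata=metadata,
            taxonomy=table.taxonomy, provenance=table.provenance,
        )
    return table


def write_table(table: CommunityTable, path, format: str | None = None) -> None:
    """Write a community table as TSV/CSV (taxa-as-rows) or BIOM 1.0 JSON."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "biom":
        _write_biom_json(table, path)
        return
    sep = "\t" if fmt == "tsv" else ","
    out = table.counts.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep=sep)


def _read_biom_json(path: Path) -> CommunityTable:
    """Minimal BIOM 1.0 (JSON) reader: rows are observations (taxa),
    columns are samples."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    n_taxa, n_samples = doc["shape"]
    mat = np.zeros((n_taxa, n_samples))
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    counts = pd.DataFrame(mat.T, index=samples, columns=taxa)
    taxonomy = None
    row_md = [r.get("metadata") or {} for r in doc["rows"]]
    if any("taxonomy" in md for md in row_md):
        tax_rows = {}
        for taxon, md in zip(taxa, row_md):
            ranks = md.get("taxonomy") or []
            tax_rows[taxon] = dict(zip(TAXONOMY_RANKS, ranks))
        taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")
    return CommunityTable(counts=counts, taxonomy=taxonomy)


def _write_biom_json(table: CommunityTable, path: Path) -> None:
    mat = table.counts.T.to_numpy()  # taxa x samples
    integral = np.allclose(mat, np.round(mat))
    data = []
    for i, j in zip(*np.nonzero(mat)):
        v = mat[i, j]
        data.append([int(i), int(j), int(v) if integral else float(v)])
    rows = []
    for taxon in table.taxon_ids:
        md = None
        if table.taxonomy is not None and taxon in table.taxonomy.index:
            ranks = table.taxonomy.loc[taxon].dropna().tolist()
            if ranks:
                md = {"taxonomy": [str(r) for r in ranks]}
        rows.append({"id": taxon, "metadata": md})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "bentho",
        "date": _dt.datetime.now().isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int" if integral else "float",
        "shape": [table.n_taxa, table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_env(path, units: dict | None = None) -> EnvTable:
    """Load a samples × variables environment table from CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return EnvTable(values=df, units=units or {})


def load_metadata(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    md = pd.read_csv(path, sep=sep, index_col=0)
    md.index = md.index.astype(str)
    if "date" in md.columns and "season" not in md.columns:
        md["season"] = assign_seasons(md["date"].tolist())
    return md


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Rarefy every sample to ``depth`` reads by a single random subsample
    without replacement (multivariate hypergeometric draw).

    Samples whose total is below ``depth`` are dropped with a warning; a
    sample whose total equals ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise TableError("rarefaction depth must be positive")
    mat = table.counts.to_numpy()
    if not np.allclose(mat, np.round(mat)):
        raise TableError("rarefaction requires integer counts")
    mat = np.round(mat).astype(np.int64)
    totals = mat.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise TableError(f"all samples are below rarefaction depth {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), mat.shape[1]), dtype=np.int64)
    row = 0
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            out[row] = mat[i]
        else:
            out[row] = rng.multivariate_hypergeometric(mat[i], depth)
        row += 1
    counts = pd.DataFrame(
        out, index=table.counts.index[keep], columns=table.counts.columns
    )
    return table.copy_with(counts, rarefaction={"depth": int(depth), "seed": int(seed)})


def transform(table: CommunityTable, method: str = "relative") -> CommunityTable:
    """Row-wise transform: ``relative`` (proportions) or ``hellinger``
    (square root of proportions; unit Euclidean norm per sample)."""
    mat = table.matrix()
    totals = mat.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise TableError(f"zero-sum sample row(s): {bad}")
    rel = mat / totals[:, None]
    if method == "relative":
        res = rel
    elif method == "hellinger":
        res = np.sqrt(rel)
    else:
        raise TableError(f"unknown transform {method!r}")
    counts = pd.DataFrame(res, index=table.counts.index, columns=table.counts.columns)
    return table.copy_with(counts, transform=method)


def prevalence_filter(table: CommunityTable, min_fraction: float) -> CommunityTable:
    """Keep taxa whose occupancy is strictly greater than
    ``min_fraction × n_samples`` (e.g. present in more than 25% of samples)."""
    if not 0 < min_fraction < 1:
        raise TableError("min_fraction must be in (0, 1)")
    occupancy = (table.matrix() > 0).sum(axis=0)
    keep = occupancy > min_fraction * table.n_samples
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon")
    counts = table.counts.loc[:, table.counts.columns[keep]]
    return table.copy_with(counts, prevalence_filter=float(min_fraction))


def collapse_taxonomy(table: CommunityTable, rank: str = "phylum") -> CommunityTable:
    """Sum abundances of taxa sharing the same label at ``rank``."""
    if table.taxonomy is None or rank not in table.taxonomy.columns:
        raise TableError(f"taxonomy rank {rank!r} not available")
    labels = table.taxonomy[rank].fillna("unclassified")
    collapsed = table.counts.T.groupby(labels).sum().T
    return CommunityTable(
        counts=collapsed,
        sample_metadata=table.sample_metadata.copy(),
        provenance={**table.provenance, "collapsed_rank": rank},
    )
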