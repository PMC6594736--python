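"""Reading, writing, validation and transformation of OTU count tables.

The central container is :class:`OTUTable`: an integer count matrix with one
row per OTU and one column per sample (the classic QIIME orientation),
optionally carrying semicolon-delimited taxonomy lineages per OTU and
key/value metadata per sample.  All downstream statistics operate on this
container or on the real-valued :class:`AbundanceMatrix` produced by
:func:`hellinger` / :func:`relative_abundance`.

Read-depth normalization is rarefaction: a seeded multivariate-hypergeometric
subsample of each sample's reads to a common depth, without replacement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("asgroups")

#: float formatting used by every TSV writer in the package
FLOAT_FORMAT = "%.6g"


class TableValidationError(ValueError):
    """Raised when an OTU table violates a structural invariant."""


@dataclass
class OTUTable:
    """Integer OTU-by-sample count matrix with optional annotations.

    Parameters
    ----------
    otu_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of int, shape (n_otus, n_samples)
        Non-negative read counts.
    taxonomy : dict, optional
        Map ``otu_id -> list of lineage strings`` (domain ... genus).
    metadata : dict, optional
        Map ``sample_id -> {covariate: value}``.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, list[str]] | None = None
    metadata: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        self.otu_ids = [str(i) for i in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.size == 0 or len(self.otu_ids) == 0 or len(self.sample_ids) == 0:
            raise TableValidationError("empty OTU table")
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise TableValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.otu_ids)}, {len(self.sample_ids)}) ids"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise TableValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise TableValidationError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        for name, ids in (("otu", self.otu_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise TableValidationError(f"duplicate {name} id {dup!r}")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise TableValidationError(f"taxonomy for unknown OTU ids: {sorted(unknown)}")
        if self.metadata is not None:
            unknown = set(self.metadata) - set(self.sample_ids)
            if unknown:
                raise TableValidationError(f"metadata for unknown sample ids: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def otu_index(self, otu_id: str) -> int:
        return self.otu_ids.index(otu_id)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def occupancy(self) -> np.ndarray:
        """Number of samples in which each OTU is detected (count > 0)."""
        return (self.counts > 0).sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and self.taxonomy == other.taxonomy
        )


@dataclass
class AbundanceMatrix:
    """Real-valued transform of an :class:`OTUTable` (same ids, same shape)."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transform_tag: str = "none"  # one of {relative, hellinger, none}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise TableValidationError("values shape does not match ids")
        if (self.values < 0).any():
            raise TableValidationError("abundance values must be non-negative")
        if self.transform_tag not in {"relative", "hellinger", "none"}:
            raise TableValidationError(f"unknown transform_tag {self.transform_tag!r}")


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OTUTable:
    """Read an OTU table from classic TSV or dense BIOM-style JSON.

    The TSV layout is a header row of sample ids (first cell is the OTU id
    column, conventionally ``#OTU ID``), one row per OTU, and an optional
    trailing ``taxonomy`` column of semicolon-delimited lineages.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom-json'")


def _read_tsv(path) -> OTUTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise TableValidationError(f"empty or header-only OTU table: {path}")
    otu_ids = df.iloc[:, 0].tolist()
    cols = list(df.columns[1:])
    taxonomy = None
    if cols and cols[-1].strip().lower() == "taxonomy":
        tax_col = df.iloc[:, -1]
        taxonomy = {
            otu: [t.strip() for t in lineage.split(";") if t.strip()]
            for otu, lineage in zip(otu_ids, tax_col)
            if lineage.strip()
        }
        df = df.iloc[:, :-1]
        cols = cols[:-1]
    counts = np.empty((len(otu_ids), len(cols)), dtype=np.int64)
    for j, c in enumerate(cols):
        for i, raw in enumerate(df[c]):
            try:
                val = float(raw)
            except ValueError:
                raise TableValidationError(
                    f"non-numeric count {raw!r} at row {otu_ids[i]!r}, column {c!r}"
                ) from None
            if val < 0 or val != int(val):
                raise TableValidationError(
                    f"non-integer or negative count {raw!r} at row {otu_ids[i]!r}, column {c!r}"
                )
            counts[i, j] = int(val)
    return OTUTable(otu_ids, cols, counts, taxonomy=taxonomy)


def _read_biom_json(path) -> OTUTable:
    # Dense BIOM 1.0-style JSON, read-only.  Sparse variants and HDF5 BIOM
    # are out of scope; convert upstream.
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise TableValidationError("only dense BIOM-style JSON is supported")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = np.asarray(doc["data"])
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax:
            taxonomy[r["id"]] = list(tax)
    return OTUTable(otu_ids, sample_ids, counts, taxonomy=taxonomy or None)


def write_otu_table(table: OTUTable, path) -> None:
    """Write a classic TSV OTU table (taxonomy appended when present)."""
    df = table.to_dataframe()
    df.index.name = "#OTU ID"
    if table.taxonomy is not None:
        df["taxonomy"] = [
            "; ".join(table.taxonomy.get(o, [])) for o in table.otu_ids
        ]
    df.to_csv(path, sep="\t")


def read_sample_metadata(path) -> dict[str, dict]:
    """Read a sample metadata TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    key = df.columns[0]
    dup = _first_duplicate(df[key].tolist())
    if dup is not None:
        raise TableValidationError(f"duplicate sample id {dup!r} in metadata")
    return {
        row[key]: {c: row[c] for c in df.columns[1:]}
        for _, row in df.iterrows()
    }


def write_sample_metadata(metadata: dict[str, dict], path) -> None:
    df = pd.DataFrame.from_dict(metadata, orient="index")
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def rarefy(
    table: OTUTable,
    depth: int,
    seed: int,
    drop_empty: bool = False,
    n_draws: int = 1,
) -> OTUTable:
    """Rarefy each sample to ``depth`` reads without replacement.

    Each retained sample's column is replaced by one multivariate-
    hypergeometric draw of ``depth`` reads; samples whose total is below
    ``depth`` are dropped with a warning (subsampling cannot create reads).
    OTU rows that become all-zero are kept unless ``drop_empty``.  With
    ``n_draws > 1`` the column is the rounded mean of independent draws
    (an averaged-rarefaction option; the default is a single draw).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError("no samples at requested depth")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, ", ".join(dropped))
    rng = np.random.default_rng(seed)
    kept_idx = np.flatnonzero(keep)
    out = np.zeros((table.counts.shape[0], kept_idx.size), dtype=np.int64)
    for jj, j in enumerate(kept_idx):
        col = table.counts[:, j]
        if totals[j] == depth:
            out[:, jj] = col
            continue
        draws = np.stack([
            rng.multivariate_hypergeometric(col, depth, method="marginals")
            for _ in range(n_draws)
        ])
        out[:, jj] = draws[0] if n_draws == 1 else np.round(draws.mean(axis=0)).astype(np.int64)
    sample_ids = [table.sample_ids[j] for j in kept_idx]
    otu_ids = list(table.otu_ids)
    taxonomy = dict(table.taxonomy) if table.taxonomy else None
    if drop_empty:
        nonzero = out.sum(axis=1) > 0
        otu_ids = [o for o, nz in zip(otu_ids, nonzero) if nz]
        out = out[nonzero]
        if taxonomy:
            taxonomy = {o: t for o, t in taxonomy.items() if o in set(otu_ids)}
    metadata = None
    if table.metadata is not None:
        metadata = {s: table.metadata[s] for s in sample_ids if s in table.metadata}
    return OTUTable(otu_ids, sample_ids, out, taxonomy=taxonomy, metadata=metadata)


def relative_abundance(table: OTUTable) -> AbundanceMatrix:
    """Per-sample relative abundances; all-zero samples map to zeros."""
    totals = table.sample_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(totals > 0, table.counts / totals, 0.0)
    return AbundanceMatrix(list(table.otu_ids), list(table.sample_ids), vals, "relative")


def hellinger(table: OTUTable) -> AbundanceMatrix:
    """Hellinger transform: sqrt of per-sample relative abundances.

    Makes Euclidean-geometry methods (PCoA on Euclidean distances, RDA)
    appropriate for count data; each non-empty sample column has squared
    entries summing to 1.
    """
    rel = relative_abundance(table)
    return AbundanceMatrix(rel.otu_ids, rel.sample_ids, np.sqrt(rel.values), "hellinger")


def subset_table(table: OTUTable, otu_subset) -> OTUTable:
    """Restrict rows to ``otu_subset``, preserving the table's row order."""
    subset = set(map(str, otu_subset))
    unknown = subset - set(table.otu_ids)
    if unknown:
        raise KeyError(f"unknown OTU id(s): {sorted(unknown)}")
    mask = [o in subset for o in table.otu_ids]
    otu_ids = [o for o, m in zip(table.otu_ids, mask) if m]
    counts = table.counts[np.asarray(mask)]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {o: t for o, t in table.taxonomy.items() if o in subset} or None
    return OTUTable(otu_ids, list(table.sample_ids), counts,
                    taxonomy=taxonomy, metadata=table.metadata)
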