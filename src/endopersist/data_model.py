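"""Count-table container, I/O and preprocessing.

The analysis consumes a taxa x samples integer count table (amplicon
sequence variants or OTUs agglomerated at genus/species level) together
with per-sample metadata describing the study design: site (control vs
radiation-stressed), tissue (aerial vs root), season and replicate.

Preprocessing mirrors the standard amplicon workflow: drop singleton and
doubleton taxa, drop taxa below a dataset-wide relative-abundance floor,
then rarefy every sample to a common read depth so that occupancy and
diversity are comparable across samples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("endopersist")

SITES = ("control", "radiation")
TISSUES = ("aerial", "root")
SEASONS = ("spring", "summer", "autumn", "winter")

METADATA_COLUMNS = ("site", "tissue", "season", "replicate")


class TableFormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid count table."""


class TableValidationError(ValueError):
    """Raised when table content violates a contract (ids, counts, metadata)."""


@dataclass
class AbundanceTable:
    """Integer count matrix (taxa x samples) plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample id;
        entries are non-negative integers (read counts).
    metadata
        DataFrame indexed by sample id with columns
        ``site``, ``tissue``, ``season``, ``replicate``. May be ``None``
        for tables that only feed metadata-free operations.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            raise TableValidationError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise TableValidationError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableFormatError("non-numeric counts")
        if np.any(values < 0):
            raise TableValidationError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise TableValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.metadata is not None:
            self.metadata = pd.DataFrame(self.metadata)
            missing = set(self.sample_ids) - set(self.metadata.index.astype(str))
            if missing:
                raise TableValidationError(
                    f"metadata missing for samples: {sorted(missing)}"
                )
            self.metadata = self.metadata.loc[list(self.sample_ids)]

    # -- basic accessors -------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        meta = self.metadata.loc[sample_ids] if self.metadata is not None else None
        return AbundanceTable(self.counts[sample_ids].copy(), meta)

    def select(self, **criteria: object) -> "AbundanceTable":
        """Subset samples by metadata equality, e.g. ``select(season="spring")``."""
        if self.metadata is None:
            raise TableValidationError("table has no metadata to select on")
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in criteria.items():
            if col not in self.metadata.columns:
                raise TableValidationError(f"unknown metadata column: {col}")
            mask &= self.metadata[col] == val
        return self.subset_samples(list(self.metadata.index[mask]))

    def drop_empty_taxa(self) -> "AbundanceTable":
        keep = self.counts.sum(axis=1) > 0
        return AbundanceTable(self.counts.loc[keep].copy(), self.metadata)


@dataclass
class TaxonStats:
    """Per-taxon mean relative abundance and occupancy.

    ``p`` is the mean over samples of within-sample relative abundance
    (sums to 1 across taxa); ``freq`` is the fraction of samples in which
    the taxon was detected (count > 0). These are the x and y axes of the
    Sloan neutral-model fit.
    """

    taxon_ids: list[str]
    p: np.ndarray
    freq: np.ndarray
    n_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.p, "freq": self.freq}, index=self.taxon_ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: str, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise TableFormatError(f"duplicate taxon ids in {path}")
    if df.columns.has_duplicates:
        raise TableFormatError(f"duplicate sample ids in {path}")
    return df


def _read_biom_json(path: str) -> pd.DataFrame:
    """Read a BIOM v1.0 (JSON flavor) table into taxa x samples counts."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        data = doc["data"]
        mtype = doc.get("matrix_type", "sparse")
    except (KeyError, TypeError) as exc:
        raise TableFormatError(f"not a BIOM-JSON table: {path}") from exc
    mat = np.zeros(shape)
    if mtype == "dense":
        mat[:] = np.asarray(data)
    else:
        for i, j, v in data:
            mat[int(i), int(j)] = v
    return pd.DataFrame(mat, index=rows, columns=cols)


def load_metadata(path: str, sep: str | None = None) -> pd.DataFrame:
    """Load the sample metadata TSV/CSV (sample_id, site, tissue, season, replicate)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise TableFormatError("metadata file must have a sample_id column")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TableFormatError(f"metadata file missing columns: {missing}")
    return meta.set_index("sample_id")


def load_table(
    path: str,
    format: str | None = None,
    metadata_path: str | None = None,
) -> AbundanceTable:
    """Load a taxa x samples count table.

    Parameters
    ----------
    path
        Count-table file; first column taxon ids, header sample ids for
        tsv/csv; BIOM v1.0 JSON also accepted.
    format
        One of ``tsv``, ``csv``, ``biom-json``; inferred from the file
        extension when omitted.
    metadata_path
        Optional sample-metadata table joined onto the counts.
    """
    if format is None:
        s = str(path)
        if s.endswith(".csv"):
            format = "csv"
        elif s.endswith((".biom", ".json")):
            format = "biom-json"
        else:
            format = "tsv"
    if format == "tsv":
        df = _read_delimited(path, "\t")
    elif format == "csv":
        df = _read_delimited(path, ",")
    elif format == "biom-json":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format: {format}")
    meta = load_metadata(metadata_path) if metadata_path else None
    return AbundanceTable(df, meta)


def save_table(table: AbundanceTable, path: str, sep: str = "\t") -> None:
    table.counts.to_csv(path, sep=sep, index_label="taxon_id")


def save_metadata(table: AbundanceTable, path: str, sep: str = "\t") -> None:
    if table.metadata is None:
        raise TableValidationError("table has no metadata")
    table.metadata.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_taxa(
    table: AbundanceTable,
    min_total_count: int = 3,
    min_rel_abund: float = 0.001,
) -> AbundanceTable:
    """Drop low-abundance taxa.

    Taxa whose dataset-wide total count is below ``min_total_count``
    (default 3, i.e. singletons and doubletons) are removed, as are taxa
    whose dataset-wide relative abundance (taxon total over grand total)
    is below ``min_rel_abund``. The sample set is unchanged.
    """
    if min_total_count < 0:
        raise ValueError("min_total_count must be >= 0")
    if not 0 <= min_rel_abund < 1:
        raise ValueError("min_rel_abund must be in [0, 1)")
    totals = table.counts.sum(axis=1)
    grand = totals.sum()
    keep = totals >= min_total_count
    if min_rel_abund > 0 and grand > 0:
        keep &= (totals / grand) >= min_rel_abund
    if not keep.any():
        raise TableValidationError("all taxa filtered out")
    return AbundanceTable(table.counts.loc[keep].copy(), table.metadata)


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a
    logged warning. Each retained column sums exactly to ``depth``.
    A single draw per sample; reproducible given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = sorted(set(table.sample_ids) - set(keep))
    if not keep:
        raise TableValidationError(f"all samples below rarefaction depth {depth}")
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        total = int(col.sum())
        if total == depth:
            out[s] = col.copy()
        else:
            # multivariate hypergeometric draw == subsampling reads
            # without replacement
            out[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index)
    meta = table.metadata.loc[keep] if table.metadata is not None else None
    return AbundanceTable(counts, meta)


def taxon_stats(table: AbundanceTable) -> TaxonStats:
    """Mean relative abundance and occupancy per taxon.

    Requires every sample to have positive total (rarefy/validate first).
    """
    if table.shape[1] < 1:
        raise TableValidationError("need at least one sample")
    counts = table.counts.to_numpy(dtype=float)
    sums = counts.sum(axis=0)
    if np.any(sums <= 0):
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise TableValidationError(f"samples with zero total: {bad}")
    rel = counts / sums
    p = rel.mean(axis=1)
    freq = (counts > 0).mean(axis=1)
    return TaxonStats(table.taxon_ids, p, freq, n_samples=table.shape[1])
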