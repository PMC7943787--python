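"""Count-table container, tabular I/O, rarefaction and depth filtering.

The central exchange object of the pipeline is :class:`CountTable`, a thin
validated wrapper around a pandas DataFrame of non-negative integer read
counts oriented samples x taxa.  Taxonomy and per-sample metadata travel as
plain DataFrames with documented column conventions (see
:func:`read_taxonomy` and :func:`read_metadata`).

On disk, count tables are tab-separated with taxa as rows and samples as
columns, the header sentinel ``#taxon_id`` marking the taxon column.  A
minimal BIOM 2.1 (HDF5) reader/writer is provided for interchange with
QIIME-style tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAXON_SENTINEL = "#taxon_id"

#: Columns required of a metadata table.
METADATA_COLUMNS = ("mouse_id", "day", "group", "antibiotic_window", "diet")

#: SILVA-style ranks used by taxonomy tables.
RANKS = ("Domain", "Phylum", "Class", "Order", "Family", "Genus", "Species")


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected format."""


@dataclass
class CountTable:
    """Integer ASV counts, samples x taxa.

    Parameters
    ----------
    data:
        DataFrame with unique sample identifiers as the index and unique
        taxon identifiers as columns.  Cells must be non-negative integers
        (read counts).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon identifiers: {dupes}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                r, c = bad[0]
                raise FormatError(
                    f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
                )
            df = df.astype(np.int64)
        if values.size and (df.to_numpy() < 0).any():
            raise FormatError("negative counts are not valid read counts")
        object.__setattr__(self, "data", df.astype(np.int64))

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as a (n_samples, n_taxa) int array."""
        return self.data.to_numpy()

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.data.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)])

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions; zero-depth rows become NaN."""
        depths = self.depths().to_numpy()[:, None].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.data / depths

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


# -- readers / writers -----------------------------------------------------

def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a count table from ``tsv`` (taxa rows x sample columns) or BIOM 2.1.

    The TSV dialect requires the header sentinel ``#taxon_id`` in the first
    column; files without it are rejected rather than orientation-guessed.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown count table format: {format!r}")


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        out = table.data.T
        out.index.name = TAXON_SENTINEL
        out.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown count table format: {format!r}")


def _read_tsv(path) -> CountTable:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty count table file") from exc
    if df.columns.size == 0 or df.columns[0] != TAXON_SENTINEL:
        raise FormatError(
            f"{path}: first header field must be {TAXON_SENTINEL!r} "
            "(taxa as rows, samples as columns)"
        )
    df = df.set_index(TAXON_SENTINEL)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        taxon, sample = bad[bad].index[0]
        raise FormatError(f"{path}: non-numeric count at taxon {taxon!r}, sample {sample!r}")
    frac = numeric - numeric.round()
    if (frac.abs() > 0).any().any():
        bad = (frac.abs() > 0).stack()
        taxon, sample = bad[bad].index[0]
        raise FormatError(f"{path}: non-integer count at taxon {taxon!r}, sample {sample!r}")
    return CountTable(numeric.round().astype(np.int64).T)


# BIOM 2.1 stores the matrix in CSR layout under 'observation/' (taxa rows).
def _write_biom(table: CountTable, path) -> None:
    from scipy import sparse

    mat = sparse.csr_matrix(table.data.T.to_numpy())  # taxa x samples
    with h5py.File(path, "w") as fh:
        fh.attrs["id"] = "No Table ID"
        fh.attrs["type"] = "OTU table"
        fh.attrs["format-url"] = "http://biom-format.org"
        fh.attrs["format-version"] = (2, 1)
        fh.attrs["generated-by"] = "abxtol"
        fh.attrs["creation-date"] = ""
        fh.attrs["shape"] = mat.shape
        fh.attrs["nnz"] = mat.nnz
        obs = fh.create_group("observation")
        obs.create_dataset("ids", data=[str(t).encode() for t in table.taxon_ids])
        om = obs.create_group("matrix")
        om.create_dataset("data", data=mat.data.astype(np.float64))
        om.create_dataset("indices", data=mat.indices.astype(np.int32))
        om.create_dataset("indptr", data=mat.indptr.astype(np.int32))
        obs.create_group("metadata")
        smp = fh.create_group("sample")
        smp.create_dataset("ids", data=[str(s).encode() for s in table.sample_ids])
        smp.create_group("metadata")


def _read_biom(path) -> CountTable:
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        taxa = [t.decode() for t in fh["observation/ids"][:]]
        samples = [s.decode() for s in fh["sample/ids"][:]]
        mat = sparse.csr_matrix(
            (
                fh["observation/matrix/data"][:],
                fh["observation/matrix/indices"][:],
                fh["observation/matrix/indptr"][:],
            ),
            shape=(len(taxa), len(samples)),
        )
    dense = mat.toarray()
    if np.any(dense != np.floor(dense)):
        raise FormatError(f"{path}: BIOM matrix holds non-integer counts")
    return CountTable(pd.DataFrame(dense.T.astype(np.int64), index=samples, columns=taxa))


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV: taxon_id column plus the seven SILVA-style ranks.

    Missing ranks are filled with ``"Unassigned"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("taxon_id")
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = "Unassigned"
    return df[list(RANKS)].fillna("Unassigned")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, mouse_id, day, group, antibiotic_window, diet)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    df["day"] = df["day"].astype(int)
    if (df["day"] < 0).any():
        raise FormatError(f"{path}: negative study day")
    df["antibiotic_window"] = df["antibiotic_window"].map(
        {"True": True, "False": False, "1": True, "0": False, True: True, False: False}
    )
    if df["antibiotic_window"].isna().any():
        raise FormatError(f"{path}: antibiotic_window must be boolean")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# -- depth normalization ---------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples shallower than ``depth`` are dropped (logged), mirroring the
    common "rarefy to 10,000, drop the rest" workflow.  Each sample draws
    from its own random substream derived from ``(seed, position)`` so the
    draw for one sample is unaffected by which other samples are present.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    totals = table.depths()
    kept_rows = []
    kept_ids = []
    dropped = []
    for i, sid in enumerate(table.sample_ids):
        total = int(totals.iloc[i])
        if total < depth:
            dropped.append(sid)
            continue
        row = table.counts[i]
        if total == depth:
            kept_rows.append(row.copy())
        else:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
            kept_rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    data = (
        pd.DataFrame(np.asarray(kept_rows, dtype=np.int64), index=kept_ids, columns=table.taxon_ids)
        if kept_rows
        else pd.DataFrame(np.empty((0, len(table.taxon_ids)), dtype=np.int64), columns=table.taxon_ids)
    )
    return CountTable(data)


def filter_low_depth(table: CountTable, min_depth: int) -> CountTable:
    """Retain exactly the samples with depth >= ``min_depth`` (inclusive)."""
    if min_depth < 0:
        raise ValueError(f"min_depth must be >= 0, got {min_depth}")
    keep = table.depths() >= min_depth
    return CountTable(table.data.loc[keep])
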