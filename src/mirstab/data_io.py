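"""Count matrices, CPM, expression filtering and percentile windows.

Containers are thin frozen wrappers around pandas objects: a gene x sample
integer count matrix with per-sample library sizes, and its CPM (counts per
million) transform.  The percentile-window primitive implemented here is
the value-trimming operation every scoring component is built on: keep the
entries of a vector lying between its lo-th and hi-th percentile
(linear-interpolation percentiles, inclusive bounds).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TISSUES = ("tumor", "normal")
CLINICAL_FEATURES = ("T", "N", "M", "stage", "neoplasm_status")

META_COLUMNS = ("sample_id", "patient_id", "tissue", "subtype") + CLINICAL_FEATURES


class DataError(ValueError):
    """Invalid input data (duplicate ids, negative counts, empty matrix...)."""


@dataclass(frozen=True)
class PercentileWindow:
    """Percentile window (lo, hi), in percent, 0 <= lo < hi <= 100."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 100):
            raise ValueError(f"invalid percentile window ({self.lo}, {self.hi})")


# windows used by the scoring system
W_MID = PercentileWindow(10, 90)
W_HIGH = PercentileWindow(90, 100)
W_LOW = PercentileWindow(0, 10)
W_FULL = PercentileWindow(0, 100)


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample raw read counts with per-sample library sizes."""

    counts: pd.DataFrame  # genes in rows, samples in columns, integers
    library_size: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise DataError("empty count matrix")
        if c.index.has_duplicates:
            raise DataError(f"duplicate gene ids: {sorted(c.index[c.index.duplicated()])}")
        if c.columns.has_duplicates:
            raise DataError(
                f"duplicate sample ids: {sorted(c.columns[c.columns.duplicated()])}"
            )
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("non-numeric counts")
        if np.isnan(arr.astype(float)).any():
            raise DataError("missing values in count matrix")
        if (arr < 0).any():
            raise DataError("negative counts")
        if self.library_size is None:
            object.__setattr__(self, "library_size", c.sum(axis=0))
        lib = self.library_size
        if not lib.index.equals(c.columns):
            raise DataError("library_size index does not match sample ids")
        if (lib <= 0).any():
            bad = list(lib.index[lib <= 0])
            raise DataError(f"non-positive library size for samples {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class CpmMatrix:
    """Gene x sample CPM values (reads per million mapped reads)."""

    cpm: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cpm.shape[0] == 0 or self.cpm.shape[1] == 0:
            raise DataError("empty CPM matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)

    def gene(self, gene_id: str, samples: Sequence[str] | None = None) -> np.ndarray:
        row = self.cpm.loc[gene_id]
        if samples is not None:
            row = row.loc[list(samples)]
        return row.to_numpy(dtype=float)


def read_counts(
    path: str | os.PathLike,
    layout: str = "matrix",
    manifest: str | os.PathLike | None = None,
    annotation_column: str = "miRNA_region",
) -> CountMatrix:
    """Read a count matrix.

    ``layout="matrix"``: TSV with first column ``gene_id``, one column per
    sample, integer counts.

    ``layout="tcga_isoform"``: *path* is a directory of per-sample isoform
    quantification TSVs; *manifest* is a TSV with columns ``file`` and
    ``sample_id``.  Each isoform file carries ``miRNA_ID``, ``read_count``
    and an annotation column naming the mature form (``mature,MIMAT...``
    in the GDC dialect); read counts of rows annotated to the same mature
    name are summed, unannotated rows (``precursor``, ``unannotated``...)
    are dropped.
    """
    if layout == "matrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dup = sorted({h for h in header if header.count(h) > 1})
            raise DataError(f"duplicate sample ids: {dup}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        try:
            df = df.astype(float)
        except ValueError as e:
            raise DataError(f"non-numeric counts in {path}: {e}") from e
        if not np.allclose(df.to_numpy(), np.round(df.to_numpy())):
            raise DataError("counts must be integers")
        return CountMatrix(df.astype(np.int64))
    if layout == "tcga_isoform":
        if manifest is None:
            raise DataError("tcga_isoform layout requires a manifest")
        man = pd.read_csv(manifest, sep="\t")
        if not {"file", "sample_id"} <= set(man.columns):
            raise DataError("manifest needs columns 'file' and 'sample_id'")
        if man["sample_id"].duplicated().any():
            raise DataError("duplicate sample id in manifest")
        cols = {}
        for _, rec in man.iterrows():
            fp = os.path.join(os.fspath(path), rec["file"])
            iso = pd.read_csv(fp, sep="\t")
            for need in ("read_count", annotation_column):
                if need not in iso.columns:
                    raise DataError(f"{fp}: missing column {need!r}")
            ann = iso[annotation_column].astype(str)
            mature = ann.where(ann.str.contains(","), other=pd.NA)
            mature = mature.str.split(",").str[-1]
            keep = iso.loc[mature.notna()].assign(mature=mature.dropna())
            cols[str(rec["sample_id"])] = keep.groupby("mature")["read_count"].sum()
        df = pd.DataFrame(cols).fillna(0)
        if df.empty:
            raise DataError("no mature-annotated isoform rows found")
        return CountMatrix(df.astype(np.int64))
    raise ValueError(f"unknown layout {layout!r}")


def to_cpm(m: CountMatrix) -> CpmMatrix:
    """Counts per million: cpm[g, s] = counts[g, s] / library_size[s] * 1e6."""
    cpm = m.counts.div(m.library_size, axis=1) * 1e6
    return CpmMatrix(cpm)


def filter_expressed(
    cpm: CpmMatrix, threshold: float = 5.9, max_low_fraction: float = 0.05
) -> list[str]:
    """Gene ids expressed above *threshold* CPM in enough samples.

    A gene is retained iff the fraction of samples with CPM < threshold is
    at most *max_low_fraction* (strictly more fails; exactly the boundary
    passes).  Defaults: 5.9 CPM in at most 5% of samples.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if not 0 <= max_low_fraction < 1:
        raise ValueError("max_low_fraction must be in [0, 1)")
    frac_low = (cpm.cpm < threshold).mean(axis=1)
    return list(cpm.cpm.index[frac_low <= max_low_fraction])


def percentile_window_values(
    x: np.ndarray | Sequence[float], w: PercentileWindow
) -> np.ndarray:
    """Entries of *x* between its lo-th and hi-th percentile, inclusive.

    Percentiles use linear interpolation on the sorted values (the
    numpy/R-type-7 default); this single convention is used by every
    component of the scoring system.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise DataError("empty vector for percentile window")
    plo, phi = np.percentile(arr, [w.lo, w.hi])
    return arr[(arr >= plo) & (arr <= phi)]


def write_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV with header, deterministic row order."""
    if rows.shape[0] == 0:
        raise DataError("refusing to write an empty table")
    rows.to_csv(path, sep="\t", index=rows.index.name is not None)


def read_meta(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample metadata TSV (empty cells = missing) and validate it."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise DataError(f"metadata missing columns {sorted(missing)}")
    return validate_meta(meta)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in metadata")
    bad = set(meta["tissue"]) - set(TISSUES)
    if bad:
        raise DataError(f"unknown tissue labels {sorted(bad)}")
    for tissue in TISSUES:
        sub = meta[meta["tissue"] == tissue]
        if sub["patient_id"].duplicated().any():
            raise DataError(f"patient with more than one {tissue} sample")
    return meta


def complete_pairs(meta: pd.DataFrame) -> list[tuple[str, str]]:
    """(tumor sample, normal sample) pairs sharing a patient, sorted by patient."""
    t = meta[meta["tissue"] == "tumor"].set_index("patient_id")["sample_id"]
    n = meta[meta["tissue"] == "normal"].set_index("patient_id")["sample_id"]
    shared = sorted(set(t.index) & set(n.index))
    return [(t[p], n[p]) for p in shared]


def tissue_samples(meta: pd.DataFrame, tissue: str) -> list[str]:
    return list(meta.loc[meta["tissue"] == tissue, "sample_id"])


def subtype_groups(
    meta: pd.DataFrame, subtypes: Iterable[str] | None = None
) -> dict[str, list[str]]:
    """Tumor samples grouped by subtype value (missing/'unknown' excluded)."""
    tum = meta[meta["tissue"] == "tumor"]
    sub = tum["subtype"].astype("string")
    present = [s for s in sub.dropna().unique() if s != "unknown"]
    wanted = list(subtypes) if subtypes is not None else sorted(present)
    groups = {}
    for name in wanted:
        members = list(tum.loc[sub == name, "sample_id"])
        if not members:
            raise DataError(f"subgroup {name!r} has no samples")
        groups[name] = members
    if len(groups) < 2:
        raise DataError("multigroup mode needs at least 2 subgroups")
    return groups
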