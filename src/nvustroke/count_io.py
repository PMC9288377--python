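"""Reading, validating and joining count matrices with the sample design.

The pipeline starts from gene x sample integer read-count matrices — one per
sorted cell type, or a single joint matrix covering every sample — together
with a design table assigning each sample to a cell type (endothelial EC,
pericyte PC, astrocyte AC, microglia MG by default), a hemisphere
(contralateral = control, ipsilateral = ischemic) and a replicate index.
Counts must be raw (un-normalized) integers because the downstream expression
threshold is phrased in reads.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

DEFAULT_CELL_TYPES = ("EC", "PC", "AC", "MG")
DEFAULT_HEMISPHERES = ("contralateral", "ipsilateral")

#: tolerance for rounding float exporter artifacts to integers
FLOAT_ROUND_TOL = 1e-6


class CountDataError(ValueError):
    """Invalid count matrix or design table."""


@dataclass
class CountMatrix:
    """Gene x sample table of raw read counts.

    ``counts`` is a pandas DataFrame with gene identifiers on the index and
    sample identifiers on the columns; entries are non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CountDataError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountDataError(f"duplicate sample identifiers: {dups[:5]}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if np.nanmax(np.abs(arr - rounded)) > FLOAT_ROUND_TOL:
                g, s = np.unravel_index(
                    int(np.nanargmax(np.abs(arr - rounded))), arr.shape
                )
                raise CountDataError(
                    f"non-integer count {arr[g, s]!r} for gene "
                    f"{df.index[g]!r}, sample {df.columns[s]!r}"
                )
            df = pd.DataFrame(
                rounded.astype(np.int64), index=df.index, columns=df.columns
            )
            self.counts = df
            arr = df.to_numpy()
        if arr.size and arr.min() < 0:
            g, s = np.unravel_index(int(arr.argmin()), arr.shape)
            raise CountDataError(
                f"negative count {arr[g, s]} for gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        if df.isna().any().any():
            raise CountDataError("missing values are illegal in count matrices")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleDesign:
    """Sample annotation: cell type, hemisphere and replicate per sample.

    Extra columns beyond the required four are preserved in ``metadata``.
    """

    table: pd.DataFrame
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    hemispheres: tuple[str, ...] = DEFAULT_HEMISPHERES
    metadata: pd.DataFrame | None = None

    REQUIRED = ("sample_id", "cell_type", "hemisphere", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise CountDataError(f"design is missing required columns: {missing}")
        extra = [c for c in t.columns if c not in self.REQUIRED]
        if extra:
            self.metadata = t[["sample_id", *extra]].copy()
            t = t[list(self.REQUIRED)]
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise CountDataError(f"duplicate sample_id in design: {dups}")
        hemis = sorted(t["hemisphere"].unique())
        bad_h = [h for h in hemis if h not in self.hemispheres]
        if bad_h or len(hemis) > 2:
            raise CountDataError(
                f"hemisphere labels {bad_h or hemis} not allowed; "
                f"allowed: {list(self.hemispheres)}"
            )
        bad_ct = sorted(set(t["cell_type"]) - set(self.cell_types))
        if bad_ct:
            raise CountDataError(
                f"cell_type labels {bad_ct} not in {list(self.cell_types)}"
            )
        rep = pd.to_numeric(t["replicate"], errors="raise")
        if (rep < 1).any():
            raise CountDataError("replicate indices must be positive integers")
        small = (
            t.groupby(["cell_type", "hemisphere"], observed=True)
            .size()
            .loc[lambda n: n < 2]
        )
        if len(small):
            raise CountDataError(
                "groups with fewer than 2 replicates: "
                + ", ".join(f"{ct}/{h} (n={n})" for (ct, h), n in small.items())
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, cell_type: str, hemisphere: str | None = None) -> list[str]:
        t = self.table
        m = t["cell_type"] == cell_type
        if hemisphere is not None:
            m &= t["hemisphere"] == hemisphere
        return list(t.loc[m, "sample_id"])

    def groups(self) -> list[tuple[str, str]]:
        """(cell_type, hemisphere) pairs present, in cell-type order."""
        present = set(
            map(tuple, self.table[["cell_type", "hemisphere"]].drop_duplicates().values)
        )
        return [
            (ct, h)
            for ct in self.cell_types
            for h in self.hemispheres
            if (ct, h) in present
        ]


@dataclass
class Dataset:
    """Validated counts-plus-design bundle driving the pipeline.

    ``matrices`` maps each cell type to the CountMatrix restricted to that
    cell type's samples; a gene absent from a cell type's matrix is treated
    downstream as unexpressed there.
    """

    matrices: dict[str, CountMatrix]
    design: SampleDesign
    provenance: dict = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return [ct for ct in self.design.cell_types if ct in self.matrices]

    @property
    def all_genes(self) -> list[str]:
        """Union of gene identifiers across cell types, first-seen order."""
        seen: dict[str, None] = {}
        for ct in self.cell_types:
            for g in self.matrices[ct].gene_ids:
                seen.setdefault(g)
        return list(seen)

    def counts_for(self, cell_type: str, hemisphere: str | None = None) -> pd.DataFrame:
        cols = self.design.samples(cell_type, hemisphere)
        return self.matrices[cell_type].counts[cols]


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV, CSV or MatrixMarket triplet.

    For ``mtx`` the sidecar files ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` must sit next to the matrix, one identifier per
    line (genes = rows, samples = columns).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        genes_f = path.with_suffix(".genes.txt")
        samples_f = path.with_suffix(".samples.txt")
        for f in (genes_f, samples_f):
            if not f.exists():
                raise FileNotFoundError(f"missing mtx sidecar {f}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_f.read_text().split()
        samples = samples_f.read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    elif format in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",", index_col=0)
        df.index = df.index.astype(str)
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(cm.counts.to_numpy()))
        path.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        path.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        cm.counts.to_csv(path, sep="\t" if format == "tsv" else ",", index_label="gene")


def read_design(
    path: str | Path,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    hemispheres: Sequence[str] = DEFAULT_HEMISPHERES,
) -> SampleDesign:
    """Read the sample design table (TSV or CSV, sniffed from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    t = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return SampleDesign(t, tuple(cell_types), tuple(hemispheres))


def write_design(design: SampleDesign, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    design.table.to_csv(path, sep=sep, index=False)


def validate_dataset(
    counts: CountMatrix | Mapping[str, CountMatrix],
    design: SampleDesign,
    source: str | None = None,
    logger=None,
) -> Dataset:
    """Join counts with the design, checking every design sample resolves.

    ``counts`` may be a single joint matrix (columns spanning all cell
    types) or a mapping cell type -> matrix. Count columns absent from the
    design are dropped with a warning; design samples absent from the counts
    are an error.
    """
    import logging

    log = logger or logging.getLogger(__name__)
    if isinstance(counts, CountMatrix):
        matrices: dict[str, CountMatrix] = {}
        have = set(counts.sample_ids)
        missing = [s for s in design.sample_ids if s not in have]
        if missing:
            raise CountDataError(f"design samples absent from counts: {missing[:10]}")
        extra = [s for s in counts.sample_ids if s not in set(design.sample_ids)]
        if extra:
            log.warning("dropping %d count columns absent from design: %s",
                        len(extra), extra[:10])
        for ct in design.cell_types:
            cols = design.samples(ct)
            if cols:
                matrices[ct] = CountMatrix(counts.counts[cols])
    else:
        matrices = {}
        for ct, cm in counts.items():
            have = set(cm.sample_ids)
            want = design.samples(ct)
            missing = [s for s in want if s not in have]
            if missing:
                raise CountDataError(
                    f"design samples for {ct} absent from counts: {missing[:10]}"
                )
            extra = [s for s in cm.sample_ids if s not in set(want)]
            if extra:
                log.warning("%s: dropping %d columns absent from design", ct, len(extra))
            matrices[ct] = CountMatrix(cm.counts[want])
    for ct in {c for c, _ in design.groups()}:
        hemis = {h for c, h in design.groups() if c == ct}
        if len(hemis) < 2 and ct in matrices:
            raise CountDataError(f"cell type {ct} lacks one hemisphere")
    for ct, h in design.groups():
        if ct not in matrices:
            continue
        sub = matrices[ct].counts[design.samples(ct, h)]
        log.info("group %s/%s: n=%d samples, %d total reads",
                 ct, h, sub.shape[1], int(sub.to_numpy().sum()))
    prov = {
        "source": source or "in-memory",
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksum": _dataset_checksum(matrices),
    }
    return Dataset(matrices, design, prov)


def _dataset_checksum(matrices: Mapping[str, CountMatrix]) -> str:
    h = hashlib.sha256()
    for ct in sorted(matrices):
        h.update(ct.encode())
        h.update(matrices[ct].counts.to_csv().encode())
    return h.hexdigest()[:16]
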