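"""Binary expression/regulation transformation and per-cell-type status.

Each gene is reduced, per cell type, to three bits:

* ``<ct>_contra_expr`` — 1 iff the raw reads exceed the threshold
  (strictly > 10 by default) in *every* contralateral replicate;
* ``<ct>_ipsi_expr``  — the same rule on the ipsilateral replicates;
* ``<ct>_reg``        — 1 iff the gene is DE-significant in that cell type
  AND expressed (by the rule above) in at least one hemisphere.

Four cell types give the 12 binary sets driving the intersection stage.
Expression calls use raw reads, not normalized counts — the threshold is
phrased in reads; a switch allows normalized counts for sensitivity
analysis. Genes absent from a cell type's matrix get all three bits 0 there.

The per-cell-type status partitions each cell type's regulated genes into
shut down (expressed contralateral only, down), induced (ipsilateral only,
up), downregulated and upregulated (expressed in both hemispheres).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .count_io import Dataset
from .diffexp import ThresholdConfig, size_factors

log = logging.getLogger(__name__)

STATUSES = ("shutdown", "downregulated", "upregulated", "induced", "not_regulated")

#: per-cell-type column suffixes, bit columns then carried-through metadata
BIT_SUFFIXES = ("contra_expr", "ipsi_expr", "reg")
META_SUFFIXES = ("meanReads_contra", "meanReads_ipsi", "log2FC")


def expression_call(replicate_counts: Sequence[float], min_reads: int = 10) -> int:
    """1 iff every replicate's reads are strictly greater than ``min_reads``."""
    counts = np.asarray(replicate_counts)
    if counts.size == 0:
        raise ValueError("expression_call needs at least one replicate")
    return int((counts > min_reads).all())


def binary_columns(cell_types: Sequence[str]) -> list[str]:
    """The 12 bit-column names in cell-type-major order."""
    return [f"{ct}_{sfx}" for ct in cell_types for sfx in BIT_SUFFIXES]


def table_columns(cell_types: Sequence[str]) -> list[str]:
    """Full export schema: per cell type, bits then mean reads and log2FC."""
    return [
        f"{ct}_{sfx}" for ct in cell_types for sfx in (*BIT_SUFFIXES, *META_SUFFIXES)
    ]


def build_binary_table(
    dataset: Dataset,
    de: Mapping[str, pd.DataFrame],
    config: ThresholdConfig | None = None,
    use_normalized: bool = False,
) -> pd.DataFrame:
    """The 12-column binary table plus carried-through means and log2FC.

    Index: the union of gene identifiers across cell types. The regulation
    bit is significant AND (expressed_contra OR expressed_ipsi); this is
    what demotes a gene that passes the fold-change and p-value criteria in
    a cell type but dips below the read threshold in a single replicate of
    both hemispheres (the Mmp12 case).
    """
    config = config or ThresholdConfig()
    genes = dataset.all_genes
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for ct in dataset.cell_types:
        known = set(dataset.matrices[ct].gene_ids)
        de_ct = de[ct]
        unknown = set(de_ct["gene"]) - set(genes)
        if unknown:
            raise ValueError(
                f"DE table for {ct} references unknown genes: {sorted(unknown)[:5]}"
            )
        contra = dataset.counts_for(ct, "contralateral")
        ipsi = dataset.counts_for(ct, "ipsilateral")
        if use_normalized:
            joint = pd.concat([contra, ipsi], axis=1)
            sf = size_factors(joint)
            contra = contra / sf[contra.columns]
            ipsi = ipsi / sf[ipsi.columns]
        expr_c = (contra.to_numpy() > config.min_reads).all(axis=1)
        expr_i = (ipsi.to_numpy() > config.min_reads).all(axis=1)
        expr_c = pd.Series(expr_c.astype(np.int8), index=contra.index)
        expr_i = pd.Series(expr_i.astype(np.int8), index=ipsi.index)

        de_idx = de_ct.set_index("gene")
        sig = de_idx["significant"].reindex(expr_c.index).fillna(False).astype(bool)
        reg = (sig & ((expr_c == 1) | (expr_i == 1))).astype(np.int8)
        demoted = sig & (reg == 0)
        if demoted.any():
            log.debug("%s: %d significant genes demoted by the read filter: %s",
                      ct, int(demoted.sum()), list(expr_c.index[demoted])[:10])

        out[f"{ct}_contra_expr"] = expr_c.reindex(out.index).fillna(0).astype(np.int8)
        out[f"{ct}_ipsi_expr"] = expr_i.reindex(out.index).fillna(0).astype(np.int8)
        out[f"{ct}_reg"] = reg.reindex(out.index).fillna(0).astype(np.int8)
        out[f"{ct}_meanReads_contra"] = contra.mean(axis=1).reindex(out.index)
        out[f"{ct}_meanReads_ipsi"] = ipsi.mean(axis=1).reindex(out.index)
        out[f"{ct}_log2FC"] = de_idx["log2fc"].reindex(out.index)
        # genes absent from this cell type's matrix keep NaN metadata
        absent = [g for g in genes if g not in known]
        if absent:
            out.loc[absent, [f"{ct}_{s}" for s in BIT_SUFFIXES]] = 0
    return out[table_columns(dataset.cell_types)]


def per_celltype_status(
    binary: pd.DataFrame, cell_types: Sequence[str]
) -> pd.DataFrame:
    """Classify every (gene, cell type) into the regulation status classes.

    Long-format DataFrame with columns gene, cell_type, status. A gene is
    classed only through its regulation bit (which already encodes
    significance and the expression filter); a regulated gene expressed in
    neither hemisphere cannot occur by construction, and a log2FC of
    exactly 0 (possible only via external ingest) falls to not_regulated
    because its direction is undefined.
    """
    frames = []
    for ct in cell_types:
        reg = binary[f"{ct}_reg"].to_numpy().astype(bool)
        ec = binary[f"{ct}_contra_expr"].to_numpy().astype(bool)
        ei = binary[f"{ct}_ipsi_expr"].to_numpy().astype(bool)
        lfc = binary[f"{ct}_log2FC"].to_numpy(dtype=float)
        up = reg & (lfc > 0)
        down = reg & (lfc < 0)
        status = np.full(len(binary), "not_regulated", dtype=object)
        status[ec & ~ei & down] = "shutdown"
        status[~ec & ei & up] = "induced"
        status[ec & ei & down] = "downregulated"
        status[ec & ei & up] = "upregulated"
        odd = reg & (status == "not_regulated")
        if odd.any():
            log.debug("%s: %d regulated genes with contradictory bits or zero "
                      "log2FC left not_regulated", ct, int(odd.sum()))
        frames.append(
            pd.DataFrame(
                {"gene": binary.index, "cell_type": ct, "status": status}
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_binary_csv(binary: pd.DataFrame, path: str | Path) -> None:
    """Export the binary table: gene, then per cell type bits + metadata."""
    binary.to_csv(path, index_label="gene")


def read_binary_csv(path: str | Path, cell_types: Sequence[str] | None = None) -> pd.DataFrame:
    """Re-import an exported binary table (inverse of write_binary_csv)."""
    t = pd.read_csv(path, index_col="gene")
    if cell_types is not None:
        t = t[table_columns(cell_types)]
    for c in t.columns:
        if c.endswith(BIT_SUFFIXES):
            t[c] = t[c].astype(np.int8)
    return t
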