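"""Exclusive intersections of the 12 binary sets and the category taxonomy.

With three binary sets per cell type (contralateral expression, ipsilateral
expression, regulation) and four cell types, every gene carries a 12-bit
membership pattern; there are 2**12 = 4096 possible exclusive intersections.
Genes are grouped by exact pattern (UpSet's exclusive-intersection
semantics), empty patterns are omitted, and the named categories are applied
strictly — a name matches its pattern and no other bits:

* ``Ed Pd Ad Md`` — shut down in one cell type only (contralateral
  expression + regulation there, nothing else);
* ``Ei Pi Ai Mi`` — induced in one cell type only (ipsilateral expression +
  regulation);
* ``E P A M``     — expressed in both hemispheres and regulated, one cell
  type only;
* ``Epam ePam epAm epaM`` — expressed in both hemispheres of all four cell
  types, regulated in the uppercase one only;
* ``EPAM``        — all 12 bits set: expressed and regulated everywhere.

Strict semantics is what demotes a gene regulated in all four cell types by
fold change and p-value, but failing the read filter in three of them, into
the single-cell-type induced category (the Mmp12 case). A "definitional"
mode constraining only the sets a name mentions is available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .binarize import BIT_SUFFIXES, META_SUFFIXES, binary_columns
from .count_io import DEFAULT_CELL_TYPES

N_SETS = 12
PATTERN_SPACE = 2 ** N_SETS  # 4096


@dataclass
class IntersectionRecord:
    """One exclusive membership pattern with its gene list."""

    pattern: str  # bit string, cell-type-major: (contra, ipsi, reg) per type
    gene_ids: list[str]
    label: str

    @property
    def count(self) -> int:
        return len(self.gene_ids)


def pattern_string(bits: Sequence[int]) -> str:
    return "".join("1" if b else "0" for b in bits)


def canonical_pattern_label(pattern: str, cell_types: Sequence[str]) -> str:
    """Human-readable pattern string, e.g. ``"EC:ce,r|MG:ie"``."""
    if not any(c == "1" for c in pattern):
        return "none"
    codes = {"contra_expr": "ce", "ipsi_expr": "ie", "reg": "r"}
    parts = []
    for i, ct in enumerate(cell_types):
        on = [
            codes[sfx]
            for j, sfx in enumerate(BIT_SUFFIXES)
            if pattern[3 * i + j] == "1"
        ]
        if on:
            parts.append(f"{ct}:{','.join(on)}")
    return "|".join(parts)


def build_taxonomy(cell_types: Sequence[str] = DEFAULT_CELL_TYPES) -> dict[str, str]:
    """Mapping from the 17 category names to their exact 12-bit patterns.

    Single-letter codes come from the first letter of each cell-type label
    (E, P, A, M for the default EC, PC, AC, MG order).
    """
    letters = [ct[0].upper() for ct in cell_types]
    if len(set(letters)) != len(letters):
        raise ValueError("cell-type labels must start with distinct letters")
    n = len(cell_types)

    def pat(bits_by_ct: Mapping[int, tuple[int, int, int]]) -> str:
        bits = []
        for i in range(n):
            bits.extend(bits_by_ct.get(i, (0, 0, 0)))
        return pattern_string(bits)

    tax: dict[str, str] = {}
    for i, up in enumerate(letters):
        tax[f"{up}d"] = pat({i: (1, 0, 1)})  # shutdown: contra expr + reg only
        tax[f"{up}i"] = pat({i: (0, 1, 1)})  # induced: ipsi expr + reg only
        tax[up] = pat({i: (1, 1, 1)})        # expressed both + reg, one type
        # expressed everywhere, regulated in this cell type only (e.g. Epam)
        name = "".join(
            letters[j] if j == i else letters[j].lower() for j in range(n)
        )
        tax[name] = pat({j: (1, 1, int(j == i)) for j in range(n)})
    tax["".join(letters)] = pat({j: (1, 1, 1) for j in range(n)})  # EPAM
    if len(set(tax.values())) != len(tax):
        raise ValueError("taxonomy patterns are not injective")
    return tax


def classify_gene(
    pattern: str,
    taxonomy: Mapping[str, str],
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    mode: str = "strict",
) -> str:
    """Name a 12-bit pattern; unnamed patterns get the canonical string.

    ``strict`` (default): the pattern must equal the taxonomy pattern
    exactly. ``definitional``: a name matches when every bit its pattern
    sets is set (other bits unconstrained); the most specific (largest)
    matching name wins.
    """
    if mode == "strict":
        for name, pat in taxonomy.items():
            if pattern == pat:
                return name
    elif mode == "definitional":
        best, best_bits = None, -1
        for name, pat in taxonomy.items():
            need = int(pat, 2)
            if int(pattern, 2) & need == need and bin(need).count("1") > best_bits:
                best, best_bits = name, bin(need).count("1")
        if best is not None:
            return best
    else:
        raise ValueError("mode must be 'strict' or 'definitional'")
    return canonical_pattern_label(pattern, cell_types)


def exclusive_intersections(
    binary: pd.DataFrame,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    taxonomy: Mapping[str, str] | None = None,
    mode: str = "strict",
) -> list[IntersectionRecord]:
    """Group genes by exact 12-bit pattern (exclusive intersections).

    Records are sorted by count descending, ties broken by pattern key.
    The all-zero pattern is kept (labelled "none") so the records partition
    the gene universe; exports drop it, as empty memberships carry no
    intersection.
    """
    taxonomy = taxonomy or build_taxonomy(cell_types)
    cols = binary_columns(cell_types)
    bits = binary[cols].astype(int).astype(str)
    keys = bits.iloc[:, 0].str.cat([bits.iloc[:, j] for j in range(1, len(cols))])
    records = [
        IntersectionRecord(
            pattern=pat,
            gene_ids=list(group.index),
            label=classify_gene(pat, taxonomy, cell_types, mode),
        )
        for pat, group in binary.groupby(keys, sort=False)
    ]
    records.sort(key=lambda r: (-r.count, r.pattern))
    return records


def regulated_only_intersections(
    binary: pd.DataFrame,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
) -> list[IntersectionRecord]:
    """Intersections over the 4 regulation bits only (<= 16 patterns).

    Ignores the hemisphere expression sets: a gene counts as regulated in a
    cell type iff its regulation bit is set there. The all-four pattern is
    labelled "EPAM-regulated"; the all-zero pattern "none"; other patterns
    get the uppercase letters of the regulated cell types (e.g. "EM").
    """
    cols = [f"{ct}_reg" for ct in cell_types]
    letters = [ct[0].upper() for ct in cell_types]
    bits = binary[cols].astype(int).astype(str)
    keys = bits.iloc[:, 0].str.cat([bits.iloc[:, j] for j in range(1, len(cols))])

    def label(pat: str) -> str:
        if pat == "1" * len(cell_types):
            return "".join(letters) + "-regulated"
        if pat == "0" * len(cell_types):
            return "none"
        return "".join(l for l, b in zip(letters, pat) if b == "1")

    records = [
        IntersectionRecord(pattern=pat, gene_ids=list(g.index), label=label(pat))
        for pat, g in binary.groupby(keys, sort=False)
    ]
    records.sort(key=lambda r: (-r.count, r.pattern))
    return records


def records_frame(records: Sequence[IntersectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": [r.pattern for r in records],
            "label": [r.label for r in records],
            "count": [r.count for r in records],
            "genes": [";".join(r.gene_ids) for r in records],
        }
    )


def write_long_table(
    records: Sequence[IntersectionRecord], path: str | Path
) -> None:
    """Long-format TSV (gene, label, pattern) for downstream tools."""
    rows = [
        (g, r.label, r.pattern) for r in records for g in r.gene_ids
    ]
    pd.DataFrame(rows, columns=["gene", "label", "pattern"]).to_csv(
        path, sep="\t", index=False
    )


def export_upset(
    binary: pd.DataFrame,
    csv_path: str | Path,
    json_path: str | Path,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    dataset_name: str = "NVU stroke binary sets",
) -> None:
    """Write the UpSet-tool-compatible CSV and JSON descriptor.

    The CSV puts the gene id first, then the 12 binary set columns as one
    contiguous block, then the mean-read and log2FC meta columns, so the
    descriptor can declare the set block by column range (the public UpSet
    web tool's binary data-descriptor convention).
    """
    bit_cols = binary_columns(cell_types)
    meta_cols = [f"{ct}_{s}" for ct in cell_types for s in META_SUFFIXES]
    ordered = binary[bit_cols + meta_cols]
    ordered.to_csv(csv_path, index_label="gene")
    descriptor = {
        "file": Path(csv_path).name,
        "name": dataset_name,
        "header": 0,
        "separator": ",",
        "skip": 0,
        "meta": [{"type": "id", "index": 0, "name": "gene"}]
        + [
            {"type": "float", "index": 1 + len(bit_cols) + i, "name": c}
            for i, c in enumerate(meta_cols)
        ],
        "sets": [{"format": "binary", "start": 1, "end": len(bit_cols)}],
    }
    with open(json_path, "w") as fh:
        json.dump(descriptor, fh, indent=2)


def read_upset_csv(
    path: str | Path, cell_types: Sequence[str] = DEFAULT_CELL_TYPES
) -> pd.DataFrame:
    """Re-import an export_upset CSV; bit columns come back as integers."""
    t = pd.read_csv(path, index_col="gene")
    for c in binary_columns(cell_types):
        t[c] = t[c].astype("int8")
    return t


def plot_upset(
    records: Sequence[IntersectionRecord],
    path: str | Path,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    top: int = 20,
) -> None:
    """UpSet-style bar + membership-matrix figure (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = [r for r in records if any(c == "1" for c in r.pattern)][:top]
    set_names = binary_columns(cell_types)
    n_sets = len(set_names)
    fig, (ax_bar, ax_mat) = plt.subplots(
        2, 1, figsize=(max(6, 0.5 * len(recs) + 2), 7),
        gridspec_kw={"height_ratios": [2, 3]}, sharex=True,
    )
    xs = range(len(recs))
    ax_bar.bar(xs, [r.count for r in recs], color="0.2")
    for x, r in zip(xs, recs):
        ax_bar.text(x, r.count, str(r.count), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("genes in intersection")
    for x, r in zip(xs, recs):
        on = [i for i, b in enumerate(r.pattern) if b == "1"]
        ax_mat.scatter([x] * n_sets, range(n_sets), s=18, color="0.85")
        ax_mat.scatter([x] * len(on), on, s=22, color="0.1")
        if len(on) > 1:
            ax_mat.plot([x, x], [min(on), max(on)], color="0.1", lw=1.5)
    ax_mat.set_yticks(range(n_sets))
    ax_mat.set_yticklabels(set_names, fontsize=7)
    ax_mat.set_xticks(list(xs))
    ax_mat.set_xticklabels([r.label for r in recs], rotation=90, fontsize=7)
    ax_mat.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
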