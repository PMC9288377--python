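import itertools
import json

import numpy as np
import pandas as pd
import pytest

import nvustroke as nv
from nvustroke.binarize import binary_columns, table_columns
from nvustroke.intersect import (
    PATTERN_SPACE,
    canonical_pattern_label,
    read_upset_csv,
    records_frame,
    write_long_table,
)

CTS = ("EC", "PC", "AC", "MG")


def random_binary_table(n_genes, seed, with_meta=True):
    rng = np.random.default_rng(seed)
    cols = binary_columns(CTS)
    df = pd.DataFrame(
        rng.integers(0, 2, size=(n_genes, len(cols))).astype(np.int8),
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
        columns=cols,
    )
    if with_meta:
        for ct in CTS:
            df[f"{ct}_meanReads_contra"] = rng.uniform(0, 500, n_genes).round(2)
            df[f"{ct}_meanReads_ipsi"] = rng.uniform(0, 500, n_genes).round(2)
            df[f"{ct}_log2FC"] = rng.normal(0, 2, n_genes).round(3)
        df = df[table_columns(CTS)]
    return df


class TestTaxonomy:
    def test_intersection_space_is_4096(self):
        assert PATTERN_SPACE == 2 ** 12 == 4096

    def test_seventeen_names_with_expected_patterns(self):
        tax = nv.build_taxonomy(CTS)
        assert len(tax) == 17
        assert tax["EPAM"] == "1" * 12
        # induced microglia: ipsilateral expression + regulation there only
        assert tax["Mi"] == "000" * 3 + "011"
        # endothelial shutdown: contralateral expression + regulation only
        assert tax["Ed"] == "101" + "000" * 3
        # expressed everywhere, regulated in pericytes only
        assert tax["ePam"] == "110" + "111" + "110" + "110"

    def test_classify_round_trips_every_name(self):
        tax = nv.build_taxonomy(CTS)
        for name, pattern in tax.items():
            assert nv.classify_gene(pattern, tax, CTS) == name

    def test_unnamed_pattern_gets_canonical_string(self):
        tax = nv.build_taxonomy(CTS)
        pattern = "101" + "000" + "000" + "011"  # Ed-like EC + Mi-like MG
        assert nv.classify_gene(pattern, tax, CTS) == "EC:ce,r|MG:ie,r"

    def test_definitional_mode_relaxes_matching(self):
        tax = nv.build_taxonomy(CTS)
        # EPAM pattern with one extra gene-level context is impossible (all
        # bits set); instead: an "E"-super pattern also expressed in PC
        pattern = "111" + "110" + "000" + "000"
        assert nv.classify_gene(pattern, tax, CTS, mode="strict") == "EC:ce,ie,r|PC:ce,ie"
        assert nv.classify_gene(pattern, tax, CTS, mode="definitional") == "E"


class TestExclusiveIntersections:
    def test_matches_brute_force_grouping(self):
        """Oracle: naive per-gene dict grouping over random bit tables."""
        table = random_binary_table(500, seed=123)
        records = nv.exclusive_intersections(table, CTS)
        oracle: dict[str, list[str]] = {}
        for gene, row in table.iterrows():
            key = "".join(str(int(row[c])) for c in binary_columns(CTS))
            oracle.setdefault(key, []).append(gene)
        assert len(records) == len(oracle)
        for rec in records:
            assert rec.gene_ids == oracle[rec.pattern]

    def test_partition_and_sorting(self):
        table = random_binary_table(200, seed=5)
        records = nv.exclusive_intersections(table, CTS)
        assert sum(r.count for r in records) == len(table)
        counts = [r.count for r in records]
        assert counts == sorted(counts, reverse=True)
        all_genes = [g for r in records for g in r.gene_ids]
        assert sorted(all_genes) == sorted(table.index)

    def test_mmp12_like_pattern_labelled_mi(self):
        table = random_binary_table(5, seed=2)
        table.loc[:, binary_columns(CTS)] = 0
        table.loc["g0", ["MG_ipsi_expr", "MG_reg"]] = 1
        records = nv.exclusive_intersections(table, CTS)
        by_gene = {g: r.label for r in records for g in r.gene_ids}
        assert by_gene["g0"] == "Mi"
        assert by_gene["g1"] == "none"


class TestRegulatedOnly:
    def test_all_four_is_epam_regulated(self):
        table = random_binary_table(6, seed=3)
        table.loc[:, binary_columns(CTS)] = 0
        table.loc["g0", [f"{ct}_reg" for ct in CTS]] = 1
        table.loc["g1", ["EC_reg", "MG_reg"]] = 1
        records = nv.regulated_only_intersections(table, CTS)
        by_gene = {g: r.label for r in records for g in r.gene_ids}
        assert by_gene["g0"] == "EPAM-regulated"
        assert by_gene["g1"] == "EM"
        assert by_gene["g2"] == "none"

    def test_coarsening_of_full_patterns(self):
        """Summing 12-bit record counts within each 4-bit regulation
        pattern reproduces the regulated-only record counts."""
        table = random_binary_table(400, seed=9)
        full = nv.exclusive_intersections(table, CTS)
        reg = nv.regulated_only_intersections(table, CTS)
        reg_counts = {r.pattern: r.count for r in reg}
        coarse: dict[str, int] = {}
        for r in full:
            key = "".join(r.pattern[3 * i + 2] for i in range(4))
            coarse[key] = coarse.get(key, 0) + r.count
        assert coarse == reg_counts

    def test_distinct_patterns_give_singletons(self):
        table = random_binary_table(5, seed=1)
        table.loc[:, binary_columns(CTS)] = 0
        for i, ct in enumerate(CTS):
            table.loc[f"g{i}", f"{ct}_reg"] = 1
        table.loc["g4", ["EC_reg", "PC_reg"]] = 1
        records = nv.regulated_only_intersections(table, CTS)
        assert all(r.count == 1 for r in records if r.label != "none")


class TestExport:
    def test_csv_and_descriptor(self, tmp_path):
        table = random_binary_table(10, seed=4)
        csv_p, json_p = tmp_path / "u.csv", tmp_path / "u.json"
        nv.export_upset(table, csv_p, json_p, CTS)
        lines = csv_p.read_text().strip().splitlines()
        assert len(lines) == 11  # header + 10 genes
        desc = json.loads(json_p.read_text())
        assert desc["separator"] == ","
        assert desc["header"] == 0
        sets = desc["sets"][0]
        assert sets["format"] == "binary"
        assert sets["end"] - sets["start"] + 1 == 12
        header = lines[0].split(",")
        assert header[sets["start"]:sets["end"] + 1] == binary_columns(CTS)
        for meta in desc["meta"]:
            assert header[meta["index"]] == meta["name"]

    def test_reimport_reproduces_bits_exactly(self, tmp_path):
        table = random_binary_table(25, seed=8)
        nv.export_upset(table, tmp_path / "u.csv", tmp_path / "u.json", CTS)
        back = read_upset_csv(tmp_path / "u.csv", CTS)
        bits = binary_columns(CTS)
        pd.testing.assert_frame_equal(
            back[bits].astype(int), table[bits].astype(int)
        )

    def test_long_table_and_records_frame(self, tmp_path):
        table = random_binary_table(30, seed=6)
        records = nv.exclusive_intersections(table, CTS)
        p = tmp_path / "long.tsv"
        write_long_table(records, p)
        long = pd.read_csv(p, sep="\t")
        assert len(long) == len(table)
        rf = records_frame(records)
        assert rf["count"].sum() == len(table)

    def test_plot_writes_figure(self, tmp_path):
        pytest.importorskip("matplotlib")
        table = random_binary_table(40, seed=11)
        records = nv.exclusive_intersections(table, CTS)
        out = tmp_path / "upset.svg"
        nv.intersect.plot_upset(records, out, CTS)
        assert out.stat().st_size > 0


def test_canonical_label_of_empty_pattern():
    assert canonical_pattern_label("0" * 12, CTS) == "none"
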