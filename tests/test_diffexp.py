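import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nvustroke as nv
from nvustroke.diffexp import ALPHA_FLOOR, moderate_dispersion
from nvustroke.synthetic_data import SimulationConfig, generate_dataset


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]}, index=list("xyz"))
        np.testing.assert_allclose(nv.size_factors(df), 1.0)

    def test_fourfold_sample_hand_computed(self):
        # sample2 = 4 x sample1, no zeros: geometric mean 2c per gene,
        # ratios c/2c = 0.5 and 4c/2c = 2 for every gene
        df = pd.DataFrame({"s1": [3, 10, 50], "s2": [12, 40, 200]}, index=list("xyz"))
        np.testing.assert_allclose(nv.size_factors(df), [0.5, 2.0])

    def test_all_zero_rows_error_without_fallback(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]}, index=list("xy"))
        with pytest.raises(ValueError, match="fallback"):
            nv.size_factors(df)
        fb = nv.size_factors(df, allow_fallback=True)
        np.testing.assert_allclose(fb, [5 / 4, 3 / 4])  # library sizes 5, 3


class TestDispersion:
    def test_poisson_like_clips_to_floor(self):
        # variance equal to mean => (s2 - m)/m^2 = 0 -> floor
        vals = np.array([9, 11, 10, 10, 9, 11])
        m, s2 = vals.mean(), vals.var(ddof=1)
        assert s2 <= m
        assert nv.estimate_dispersion(vals) == ALPHA_FLOOR

    def test_hand_computed_moments(self):
        # mean 10, sample variance 30 -> alpha = (30-10)/100 = 0.2
        vals = np.array([10 - np.sqrt(30), 10, 10 + np.sqrt(30)])
        assert np.isclose(vals.mean(), 10) and np.isclose(vals.var(ddof=1), 30)
        assert np.isclose(nv.estimate_dispersion(vals), 0.2)
        # integer case: mean 10, s2 = 25 -> 0.15
        assert np.isclose(nv.estimate_dispersion(np.array([5, 10, 15])), 0.15)

    def test_zero_mean_untestable(self):
        assert np.isnan(nv.estimate_dispersion(np.zeros(4)))

    def test_moderation_pulls_toward_median(self):
        a = np.array([0.01, 0.1, 1.0, np.nan])
        out = moderate_dispersion(a, residual_df=10, prior_df=10)
        assert np.isnan(out[3])
        assert out[0] > 0.01 and out[2] < 1.0
        np.testing.assert_allclose(out[1], 0.1)


def _two_group_dataset(contra, ipsi, gene_names=None):
    from conftest import make_celltype_dataset

    genes = gene_names or [f"g{i}" for i in range(len(contra))]
    return make_celltype_dataset({
        ("EC", "contralateral"): {g: contra[i] for i, g in enumerate(genes)},
        ("EC", "ipsilateral"): {g: ipsi[i] for i, g in enumerate(genes)},
    })


class TestNbWaldTest:
    def test_identical_groups_give_null_result(self):
        row = [100, 110, 90, 105, 95, 100]
        ds = _two_group_dataset([row, [50] * 6], [row, [50] * 6])
        de = nv.nb_wald_test(ds, "EC").set_index("gene")
        assert de.loc["g0", "log2fc"] == 0
        assert de.loc["g0", "p_value"] == 1

    def test_label_swap_antisymmetry(self, tiny_run):
        """Swapping hemisphere labels negates log2fc, p unchanged."""
        ds = tiny_run["dataset"]
        de = nv.nb_wald_test(ds, "EC")
        swapped_design = ds.design.table.copy()
        swapped_design["hemisphere"] = swapped_design["hemisphere"].map(
            {"contralateral": "ipsilateral", "ipsilateral": "contralateral"}
        )
        joint = nv.CountMatrix(
            ds.matrices[ds.cell_types[0]].counts.join(
                [ds.matrices[ct].counts for ct in ds.cell_types[1:]]
            )
        )
        ds_sw = nv.validate_dataset(joint, nv.SampleDesign(swapped_design))
        de_sw = nv.nb_wald_test(ds_sw, "EC")
        np.testing.assert_allclose(de["log2fc"], -de_sw["log2fc"], atol=1e-12)
        np.testing.assert_allclose(de["p_value"], de_sw["p_value"], atol=1e-12)

    def test_invariant_to_per_sample_rescaling(self, tiny_run):
        """Per-sample depth rescalings with unit geometric mean are
        absorbed exactly by the median-of-ratios size factors."""
        ds = tiny_run["dataset"]
        base = nv.CountMatrix(ds.matrices["PC"].counts * 2)  # even counts
        ds1 = nv.Dataset({"PC": base}, ds.design)
        de = nv.nb_wald_test(ds1, "PC")
        scaled = base.counts.copy()
        for i, c in enumerate(scaled.columns):
            scaled[c] = scaled[c] * 2 if i % 2 == 0 else scaled[c] // 2
        ds2 = nv.Dataset({"PC": nv.CountMatrix(scaled)}, ds.design)
        de2 = nv.nb_wald_test(ds2, "PC")
        np.testing.assert_allclose(de["log2fc"], de2["log2fc"], atol=1e-9)
        np.testing.assert_allclose(de["p_value"], de2["p_value"], atol=1e-9)

    def test_all_zero_gene_untestable_not_significant(self):
        rows_c = [[0] * 6, [100, 90, 110, 95, 105, 100]]
        rows_i = [[0] * 6, [210, 180, 190, 220, 200, 205]]
        ds = _two_group_dataset(rows_c, rows_i)
        de = nv.nb_wald_test(ds, "EC").set_index("gene")
        assert de.loc["g0", "p_value"] == 1
        assert de.loc["g0", "log2fc"] == 0
        assert not de.loc["g0", "significant"]

    def test_planted_effect_power(self):
        """Planted log2fc = 2 at mean 200, alpha 0.1: >= 90% flagged."""
        cfg = SimulationConfig(
            seed=42, n_background=2000, n_up=50, n_epam=0, n_induced=0,
            n_shutdown=0, n_down=0, n_opposite=0, n_markers=0,
        )
        ds, truth = generate_dataset(cfg)
        de = nv.nb_wald_test(ds, "EC").set_index("gene")
        planted = truth.index[truth["category"] == "up:EC"]
        assert de.loc[planted, "significant"].mean() >= 0.9


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            nv.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(nv.bh_adjust([0.37]), [0.37])
        np.testing.assert_allclose(nv.bh_adjust([0.05, 1.0]), [0.10, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            nv.bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_properties_and_statsmodels_agreement(self, p):
        """>= input pointwise, <= 1, isotonic; equals statsmodels fdr_bh."""
        from statsmodels.stats.multitest import multipletests

        q = nv.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestCallSignificantAndIngest:
    def test_inclusive_boundaries(self):
        from conftest import make_de_table

        de = make_de_table("EC", [
            ("a", 0.585, 0.05, False),   # both exactly at cutoff -> significant
            ("b", 3.0, 0.051, False),    # padj just over -> not
            ("c", -0.600, 0.001, False), # downregulated -> significant
        ])
        out = nv.call_significant(de).set_index("gene")["significant"]
        assert out["a"] and not out["b"] and out["c"]

    def test_ingest_round_trip(self, tmp_path):
        p = tmp_path / "ext.tsv"
        pd.DataFrame({
            "gene": ["a", "b", "c"],
            "log2fc": [2.0, 0.1, -1.0],
            "padj": [0.001, 0.9, 0.04],
        }).to_csv(p, sep="\t", index=False)
        de = nv.ingest_external_de(p, "EC").set_index("gene")
        assert list(de["significant"]) == [True, False, True]
        assert de["dispersion"].isna().all()

    def test_ingest_recomputes_padj_from_p(self, tmp_path, caplog):
        p = tmp_path / "ext.tsv"
        pd.DataFrame({
            "gene": ["a", "b"], "log2fc": [1, 1], "p_value": [0.05, 1.0],
        }).to_csv(p, sep="\t", index=False)
        with caplog.at_level("WARNING"):
            de = nv.ingest_external_de(p, "EC")
        np.testing.assert_allclose(de["padj"], [0.10, 1.0])

    def test_ingest_rejects_bad_padj(self, tmp_path):
        p = tmp_path / "ext.csv"
        p.write_text("gene,log2fc,padj\na,1.0,1.2\n")
        with pytest.raises(ValueError, match="padj"):
            nv.ingest_external_de(p, "EC")


@pytest.mark.parametrize("n_genes", [80])
def test_agrees_with_deseq2_oracle(tmp_path, n_genes):
    """Independent oracle: DESeq2 on a tiny fixture gives the same fold
    changes (r > 0.98) and significance direction for strong effects."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    cfg = SimulationConfig(
        seed=5, n_background=n_genes - 20, n_epam=4, n_induced=2,
        n_shutdown=2, n_up=3, n_down=3, n_opposite=0, n_markers=0,
    )
    ds, _ = generate_dataset(cfg)
    ds.counts_for("EC").to_csv(tmp_path / "counts.tsv", sep="\t")
    ds.design.table[ds.design.table.cell_type == "EC"].to_csv(
        tmp_path / "design.tsv", sep="\t", index=False
    )
    rscript = tmp_path / "de.R"
    rscript.write_text(
        'suppressMessages(library(DESeq2))\n'
        'a <- commandArgs(trailingOnly=TRUE)\n'
        'counts <- as.matrix(read.table(a[1], header=TRUE, row.names=1, sep="\\t"))\n'
        'design <- read.table(a[2], header=TRUE, sep="\\t")\n'
        'design$hemisphere <- relevel(factor(design$hemisphere), "contralateral")\n'
        'dds <- DESeq(DESeqDataSetFromMatrix(counts, design, ~ hemisphere), quiet=TRUE)\n'
        'res <- results(dds)\n'
        'write.table(data.frame(gene=rownames(res), log2fc=res$log2FoldChange,'
        ' padj=res$padj), a[3], sep="\\t", row.names=FALSE, quote=FALSE)\n'
    )
    subprocess.run(
        ["Rscript", str(rscript), str(tmp_path / "counts.tsv"),
         str(tmp_path / "design.tsv"), str(tmp_path / "deseq2.tsv")],
        check=True, capture_output=True, timeout=300,
    )
    mine = nv.nb_wald_test(ds, "EC").set_index("gene")
    ref = pd.read_csv(tmp_path / "deseq2.tsv", sep="\t").set_index("gene")
    j = mine.join(ref, rsuffix="_ref").dropna(subset=["log2fc_ref", "padj_ref"])
    assert len(j) >= n_genes * 0.8
    assert np.corrcoef(j["log2fc"], j["log2fc_ref"])[0, 1] > 0.98
    strong = j[j["log2fc"].abs() > 1]
    assert (np.sign(strong["log2fc"]) == np.sign(strong["log2fc_ref"])).all()
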