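import numpy as np
import pandas as pd
import pytest

import nvustroke as nv


@pytest.fixture(scope="session")
def tiny_run():
    """Full pipeline outputs on the 200-gene fixture dataset (seed 1)."""
    cfg = nv.tiny_fixture_config(seed=1)
    dataset, truth = nv.generate_dataset(cfg)
    de = nv.run_de_all(dataset)
    binary = nv.build_binary_table(dataset, de)
    statuses = nv.per_celltype_status(binary, dataset.cell_types)
    records = nv.exclusive_intersections(binary)
    return {
        "config": cfg,
        "dataset": dataset,
        "truth": truth,
        "de": de,
        "binary": binary,
        "statuses": statuses,
        "records": records,
    }


@pytest.fixture()
def small_counts():
    """3-gene x 4-sample integer matrix with a 2 v 2 design, no zeros."""
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.integers(5, 200, size=(3, 4)),
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return nv.CountMatrix(df)


@pytest.fixture()
def small_design():
    return nv.SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "cell_type": ["EC"] * 4,
                "hemisphere": ["contralateral", "contralateral",
                               "ipsilateral", "ipsilateral"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


def make_celltype_dataset(counts_by_group, n_rep=6):
    """Build a Dataset from {(cell_type, hemisphere): {gene: [reads]*n_rep}}.

    Helper for hand-constructed binary-transformation fixtures.
    """
    genes = sorted({g for grp in counts_by_group.values() for g in grp})
    cols, rows = {}, []
    for (ct, h), gene_counts in counts_by_group.items():
        for r in range(1, n_rep + 1):
            sid = f"{ct}_{h[:6]}_{r}"
            cols[sid] = [gene_counts[g][r - 1] for g in genes]
            rows.append({"sample_id": sid, "cell_type": ct,
                         "hemisphere": h, "replicate": r})
    cm = nv.CountMatrix(pd.DataFrame(cols, index=genes))
    design = nv.SampleDesign(pd.DataFrame(rows))
    return nv.validate_dataset(cm, design)


def make_de_table(cell_type, rows):
    """DE table from (gene, log2fc, padj, significant) tuples."""
    return pd.DataFrame(
        {
            "gene": [r[0] for r in rows],
            "cell_type": cell_type,
            "mean_contra": np.nan,
            "mean_ipsi": np.nan,
            "dispersion": np.nan,
            "log2fc": [r[1] for r in rows],
            "p_value": np.nan,
            "padj": [r[2] for r in rows],
            "significant": [r[3] for r in rows],
        }
    )
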