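"""Negative-binomial count simulator with planted gene categories.

Emulates the study design the pipeline assumes: 4 sorted neurovascular-unit
cell types (EC, PC, AC, MG) x 2 hemispheres (contralateral control,
ipsilateral ischemic) x 6 biological replicates, with counts drawn from a
negative binomial parameterized by (mean m, dispersion alpha) so that
variance = m + alpha * m^2 — the same model the DE stage assumes. Planted
structure provides ground truth for recovery testing:

* ``background``    — log-uniform baseline means, no regulation anywhere;
* ``marker:<ct>``   — expressed in one cell type only, unregulated
  (exercises cross-cell-type expression asymmetry);
* ``epam``          — expressed in both hemispheres of all four cell types
  and upregulated (+planted log2FC) in all of them;
* ``up:<ct>`` / ``down:<ct>`` — expressed in both hemispheres of one cell
  type, regulated there (+/- planted log2FC);
* ``induced:<ct>``  — essentially absent contralaterally (mean 0.5, below
  the read-threshold regime), well expressed ipsilaterally;
* ``shutdown:<ct>`` — the mirror image;
* ``opposite:<ct+;ct->`` — expressed everywhere, up in one cell type and
  down in another (an unnamed multi-cell-type pattern).

Library-size factors are log-normal per sample. The generator is fully
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .count_io import (
    DEFAULT_CELL_TYPES,
    DEFAULT_HEMISPHERES,
    CountMatrix,
    Dataset,
    SampleDesign,
    validate_dataset,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and planted-structure parameters for the simulator.

    Defaults reproduce the assumed design: n = 6 replicates per
    (cell type, hemisphere), 10000 background genes, NB dispersion 0.1,
    log-normal library sizes (sd 0.2 on the log scale), planted |log2FC| = 2
    (well above the 0.585 regulation cutoff), and per-cell-type planted
    category sizes of 5 with 10 commonly-upregulated (epam) genes.
    ``expressed_mean`` (200 reads) keeps planted expressed genes safely
    above the >10-reads-in-all-replicates expression call;
    ``low_mean`` (0.5) keeps the silent side of induced/shutdown genes
    safely below it.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_replicates: int = 6
    n_background: int = 10000
    baseline_range: tuple[float, float] = (1.0, 5000.0)
    dispersion: float = 0.1
    dispersion_jitter: float = 0.0  # sd of log-normal per-gene jitter
    libsize_sd: float = 0.2
    n_epam: int = 10
    n_induced: int = 5
    n_shutdown: int = 5
    n_up: int = 5
    n_down: int = 5
    n_opposite: int = 3
    n_markers: int = 20
    planted_log2fc: float = 2.0
    expressed_mean: float = 200.0
    low_mean: float = 0.5
    induced_mean: float = 100.0
    marker_mean: float = 300.0
    off_target_mean: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_replicates", "n_background", "n_epam", "n_induced",
                     "n_shutdown", "n_up", "n_down", "n_opposite", "n_markers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 for DE testing")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.planted_log2fc <= 0:
            raise ValueError("planted_log2fc must be > 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) draws via the gamma-Poisson mixture.

    variance = mean + alpha * mean^2; alpha -> 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        shape = 1.0 / alpha[pos]
        lam = rng.gamma(shape, mean[pos] * alpha[pos])
        out[pos] = rng.poisson(lam)
    return out


def _truth_rows(config: SimulationConfig, rng: np.random.Generator):
    """Per-gene category and true means per (cell type, hemisphere)."""
    cts = config.cell_types
    fc = 2.0 ** config.planted_log2fc
    rows: list[dict] = []

    def add(category: str, means: dict[tuple[str, str], float]) -> None:
        row = {"category": category}
        for ct in cts:
            for h in DEFAULT_HEMISPHERES:
                row[f"true_mean_{ct}_{h}"] = means.get((ct, h), 0.0)
        rows.append(row)

    flat = {
        (ct, h): config.expressed_mean for ct in cts for h in DEFAULT_HEMISPHERES
    }
    for _ in range(config.n_epam):
        m = dict(flat)
        for ct in cts:
            m[(ct, "ipsilateral")] = config.expressed_mean * fc
        add("epam", m)
    for ct in cts:
        for _ in range(config.n_up):
            add("up:%s" % ct, {
                (ct, "contralateral"): config.expressed_mean,
                (ct, "ipsilateral"): config.expressed_mean * fc,
            })
        for _ in range(config.n_down):
            add("down:%s" % ct, {
                (ct, "contralateral"): config.expressed_mean,
                (ct, "ipsilateral"): config.expressed_mean / fc,
            })
        for _ in range(config.n_induced):
            add("induced:%s" % ct, {
                (ct, "contralateral"): config.low_mean,
                (ct, "ipsilateral"): config.induced_mean,
            })
        for _ in range(config.n_shutdown):
            add("shutdown:%s" % ct, {
                (ct, "contralateral"): config.induced_mean,
                (ct, "ipsilateral"): config.low_mean,
            })
        for _ in range(config.n_markers):
            add("marker:%s" % ct, {
                (ct, "contralateral"): config.marker_mean,
                (ct, "ipsilateral"): config.marker_mean,
            })
    for k in range(config.n_opposite):
        up_ct = cts[k % len(cts)]
        down_ct = cts[(k + 1) % len(cts)]
        m = dict(flat)
        m[(up_ct, "ipsilateral")] = config.expressed_mean * fc
        m[(down_ct, "ipsilateral")] = config.expressed_mean / fc
        add(f"opposite:{up_ct};{down_ct}", m)
    lo, hi = config.baseline_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_background))
    for b in base:
        add("background", {
            (ct, h): float(b) for ct in cts for h in DEFAULT_HEMISPHERES
        })
    return rows


def generate_dataset(config: SimulationConfig) -> tuple[Dataset, pd.DataFrame]:
    """Simulate counts and the ground-truth table.

    Returns a validated :class:`~nvustroke.count_io.Dataset` holding one
    joint count matrix split per cell type, and the SyntheticTruth
    DataFrame (index gene; columns category, per-(cell type, hemisphere)
    true means, per-cell-type true log2FC, dispersion). Genes whose true
    mean is zero in a cell type stand in for genes absent from that cell
    type's matrix; off-target leakage (``off_target_mean``) keeps marker
    genes detectably asymmetric rather than strictly absent.
    """
    rng = np.random.default_rng(config.seed)
    rows = _truth_rows(config, rng)
    n_genes = len(rows)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    truth = pd.DataFrame(rows, index=pd.Index(genes, name="gene"))

    if config.dispersion_jitter > 0:
        alpha = config.dispersion * rng.lognormal(
            0.0, config.dispersion_jitter, size=n_genes
        )
    else:
        alpha = np.full(n_genes, config.dispersion)
    truth["dispersion"] = alpha

    eps = 1e-9
    for ct in config.cell_types:
        mc = truth[f"true_mean_{ct}_contralateral"].to_numpy()
        mi = truth[f"true_mean_{ct}_ipsilateral"].to_numpy()
        lfc = np.where(
            (mc == 0) & (mi == 0), 0.0, np.log2((mi + eps) / (mc + eps))
        )
        truth[f"true_log2fc_{ct}"] = lfc

    design_rows = []
    cols: dict[str, np.ndarray] = {}
    for ct in config.cell_types:
        for h in DEFAULT_HEMISPHERES:
            mean = truth[f"true_mean_{ct}_{h}"].to_numpy().copy()
            # off-target leakage for marker genes of other cell types
            for other in config.cell_types:
                if other != ct:
                    mask = truth["category"] == f"marker:{other}"
                    mean[mask.to_numpy()] = config.off_target_mean
            for r in range(1, config.n_replicates + 1):
                sid = f"{ct}_{h[:6]}_{r}"
                sf = rng.lognormal(0.0, config.libsize_sd)
                cols[sid] = _nb_draw(rng, mean * sf, alpha)
                design_rows.append(
                    {"sample_id": sid, "cell_type": ct, "hemisphere": h,
                     "replicate": r}
                )
    counts = CountMatrix(pd.DataFrame(cols, index=pd.Index(genes, name="gene")))
    design = SampleDesign(pd.DataFrame(design_rows), config.cell_types)
    dataset = validate_dataset(counts, design, source=f"simulated(seed={config.seed})")
    return dataset, truth


# ---------------------------------------------------------------------------
# recovery evaluation


def predicted_categories(
    binary: pd.DataFrame,
    statuses: pd.DataFrame,
    labels: dict[str, str],
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
) -> pd.Series:
    """Map pipeline outputs back onto the planted category vocabulary.

    A gene is predicted ``epam`` when its exclusive-intersection label is
    the all-12-bits name; ``induced/shutdown/up/down:<ct>`` when exactly one
    cell type is regulated, from its status; ``opposite:<up;down>`` when
    exactly two are regulated in opposite directions; ``marker:<ct>`` when
    unregulated but expressed in exactly one cell type; ``background``
    otherwise; any other multi-cell-type pattern maps to ``other``.
    """
    epam_name = "".join(ct[0].upper() for ct in cell_types)
    st = statuses.pivot(index="gene", columns="cell_type", values="status")
    st = st.reindex(binary.index)
    out = []
    status_map = {"induced": "induced", "shutdown": "shutdown",
                  "upregulated": "up", "downregulated": "down"}
    for gene in binary.index:
        if labels.get(gene) == epam_name:
            out.append("epam")
            continue
        row = st.loc[gene]
        reg = [ct for ct in cell_types if row[ct] != "not_regulated"]
        if len(reg) == 1:
            out.append(f"{status_map[row[reg[0]]]}:{reg[0]}")
        elif len(reg) == 2:
            s0, s1 = row[reg[0]], row[reg[1]]
            ups = {"induced", "upregulated"}
            if (s0 in ups) != (s1 in ups):
                up_ct, down_ct = (reg[0], reg[1]) if s0 in ups else (reg[1], reg[0])
                out.append(f"opposite:{up_ct};{down_ct}")
            else:
                out.append("other")
        elif len(reg) == 0:
            expressed = [
                ct for ct in cell_types
                if binary.at[gene, f"{ct}_contra_expr"]
                or binary.at[gene, f"{ct}_ipsi_expr"]
            ]
            out.append(f"marker:{expressed[0]}" if len(expressed) == 1 else "background")
        else:
            out.append("other")
    return pd.Series(out, index=binary.index, name="predicted")


@dataclass
class RecoveryReport:
    per_category: pd.DataFrame  # index category; sensitivity, precision, n
    confusion: pd.DataFrame     # truth x predicted counts


def evaluate_recovery(
    truth: pd.DataFrame, predicted: pd.Series
) -> RecoveryReport:
    """Per-category sensitivity and precision plus the confusion table.

    sensitivity(cat) = planted genes recovered as cat / planted;
    precision(cat) = correct predictions of cat / all predictions of cat.
    """
    if set(truth.index) != set(predicted.index):
        raise ValueError("truth and predictions cover different gene universes")
    predicted = predicted.reindex(truth.index)
    t = truth["category"]
    confusion = pd.crosstab(t, predicted, rownames=["truth"], colnames=["predicted"])
    cats = sorted(t.unique())
    rows = []
    for cat in cats:
        planted = int((t == cat).sum())
        tp = int(((t == cat) & (predicted == cat)).sum())
        pred = int((predicted == cat).sum())
        rows.append({
            "category": cat,
            "n_planted": planted,
            "sensitivity": tp / planted if planted else np.nan,
            "precision": tp / pred if pred else np.nan,
        })
    per_cat = pd.DataFrame(rows).set_index("category")
    return RecoveryReport(per_cat, confusion)


def tiny_fixture_config(seed: int = 0) -> SimulationConfig:
    """A 200-gene configuration for fast tests and the bundled fixture."""
    return SimulationConfig(
        n_background=149,
        n_epam=5,
        n_induced=2,
        n_shutdown=2,
        n_up=2,
        n_down=2,
        n_opposite=2,
        n_markers=3,
        seed=seed,
    )
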