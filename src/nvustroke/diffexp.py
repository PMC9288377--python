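"""Per-cell-type differential expression, ipsilateral vs contralateral.

A transparent negative-binomial moments Wald test stands in for a full
DESeq2-style fit: counts are normalized with median-of-ratios size factors,
the NB dispersion alpha (variance = m + alpha * m^2) is estimated per gene by
the method of moments and pooled across the two hemisphere groups, and the
log2 fold change is tested against a t reference with n1 + n2 - 2 degrees of
freedom. Shrunken fold changes, independent filtering and outlier refitting
are deliberately out of scope; externally computed DE tables (e.g. from
DESeq2) can be ingested instead, since the downstream binary transformation
needs only (log2FC, adjusted p).

Significance uses the study thresholds: |log2FC| >= 0.585 (fold change 1.5)
and Benjamini-Hochberg adjusted p <= 0.05, both inclusive. BH adjustment is
applied within each cell type separately, mirroring per-cell-type contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .count_io import Dataset

log = logging.getLogger(__name__)

#: minimum dispersion retained after method-of-moments estimation
ALPHA_FLOOR = 1e-8

DE_COLUMNS = [
    "gene", "cell_type", "mean_contra", "mean_ipsi", "dispersion",
    "log2fc", "p_value", "padj", "significant",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Expression and regulation thresholds.

    min_reads
        Read threshold for the binary expression call; a gene is expressed
        in a group only when every replicate has strictly more reads.
    min_abs_log2fc
        Minimum |log2 fold change| for regulation (0.585 = log2 of 1.5).
    max_padj
        Maximum BH-adjusted p for regulation. Both cutoffs are inclusive.
    pseudocount
        Added to each group's normalized mean before the fold-change ratio,
        so induced and shut-down genes get finite log2FC.
    test_reference
        "normal" (default) refers the Wald statistic to the standard
        normal, the convention of count-based Wald tests in this field;
        "t" (df = n1 + n2 - 2) is a more conservative small-n alternative.
    dispersion_prior_df
        Weight (in pseudo-degrees-of-freedom) of the empirical-Bayes prior
        pulling each gene's method-of-moments dispersion toward the
        across-gene central value. The raw moments estimator is far too
        noisy at n = 6 and its errors propagate into the Wald SE;
        moderation is the standard stabilization (cf. edgeR / DESeq2
        dispersion shrinkage). 0 disables moderation.
    """

    min_reads: int = 10
    min_abs_log2fc: float = 0.585
    max_padj: float = 0.05
    pseudocount: float = 0.5
    test_reference: str = "normal"
    dispersion_prior_df: float = 10.0

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not (0 < self.max_padj <= 1):
            raise ValueError("max_padj must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.test_reference not in ("t", "normal"):
            raise ValueError("test_reference must be 't' or 'normal'")
        if self.dispersion_prior_df < 0:
            raise ValueError("dispersion_prior_df must be >= 0")


def size_factors(counts: pd.DataFrame, allow_fallback: bool = False) -> pd.Series:
    """Median-of-ratios size factors for one cell type's samples.

    The reference is the per-gene geometric mean across samples, computed on
    genes with no zero count; each sample's factor is the median over those
    genes of count / geometric mean. When every gene has a zero, the
    library-size fallback (library size / mean library size) is applied only
    if ``allow_fallback`` is set.
    """
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        if not allow_fallback:
            raise ValueError(
                "no gene is free of zeros; enable the library-size fallback "
                "(allow_fallback=True) to normalize this matrix"
            )
        lib = arr.sum(axis=0)
        return pd.Series(lib / lib.mean(), index=counts.columns)
    ref = arr[nonzero]
    log_geo = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def estimate_dispersion(values: np.ndarray) -> float:
    """Method-of-moments NB dispersion for one gene's normalized counts.

    alpha = max(ALPHA_FLOOR, (s^2 - m) / m^2); returns NaN when the mean is
    zero (the gene is untestable in that group).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("dispersion estimation needs >= 2 replicates")
    m = values.mean()
    if m == 0:
        return float("nan")
    s2 = values.var(ddof=1)
    return max(ALPHA_FLOOR, (s2 - m) / m**2)


def moderate_dispersion(
    alpha: np.ndarray, residual_df: float, prior_df: float
) -> np.ndarray:
    """Shrink per-gene dispersions toward the across-gene central value.

    alpha_mod = (residual_df * alpha + prior_df * alpha0) /
    (residual_df + prior_df), with alpha0 the median of the finite
    per-gene estimates. Untestable genes (NaN) stay NaN. prior_df = 0
    returns the input unchanged.
    """
    if prior_df <= 0:
        return alpha
    finite = np.isfinite(alpha)
    if not finite.any():
        return alpha
    alpha0 = float(np.median(alpha[finite]))
    out = alpha.copy()
    out[finite] = (residual_df * alpha[finite] + prior_df * alpha0) / (
        residual_df + prior_df
    )
    return out


def _group_moments(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and ddof-1 variance over the sample axis."""
    m = arr.mean(axis=1)
    s2 = arr.var(axis=1, ddof=1)
    return m, s2


def nb_wald_test(
    dataset: Dataset,
    cell_type: str,
    config: ThresholdConfig | None = None,
    allow_fallback: bool = False,
) -> pd.DataFrame:
    """NB Wald test of ipsilateral vs contralateral for one cell type.

    Returns a DataFrame with columns ``DE_COLUMNS``. The per-group standard
    error of the log mean is sqrt(1/(n*m) + alpha/n) on the natural-log
    scale (delta method for an NB mean); the two groups combine in
    quadrature and convert to log2. Genes with zero mean in both groups are
    untestable: log2fc = 0, p = 1, never significant.
    """
    config = config or ThresholdConfig()
    contra = dataset.counts_for(cell_type, "contralateral")
    ipsi = dataset.counts_for(cell_type, "ipsilateral")
    if contra.shape[1] < 2 or ipsi.shape[1] < 2:
        raise ValueError(f"{cell_type}: both hemispheres need >= 2 replicates")
    joint = pd.concat([contra, ipsi], axis=1)
    sf = size_factors(joint, allow_fallback=allow_fallback)
    norm = joint.to_numpy(dtype=float) / sf.to_numpy()
    n_c, n_i = contra.shape[1], ipsi.shape[1]
    arr_c, arr_i = norm[:, :n_c], norm[:, n_c:]

    m_c, s2_c = _group_moments(arr_c)
    m_i, s2_i = _group_moments(arr_i)

    with np.errstate(divide="ignore", invalid="ignore"):
        a_c = np.where(m_c > 0, np.maximum(ALPHA_FLOOR, (s2_c - m_c) / m_c**2), np.nan)
        a_i = np.where(m_i > 0, np.maximum(ALPHA_FLOOR, (s2_i - m_i) / m_i**2), np.nan)
    # count-weighted pooling over the groups where the estimate exists
    w_c = np.where(np.isnan(a_c), 0.0, n_c)
    w_i = np.where(np.isnan(a_i), 0.0, n_i)
    wsum = w_c + w_i
    alpha = np.where(
        wsum > 0,
        (np.nan_to_num(a_c) * w_c + np.nan_to_num(a_i) * w_i) / np.maximum(wsum, 1),
        np.nan,
    )

    alpha = moderate_dispersion(alpha, n_c + n_i - 2, config.dispersion_prior_df)

    pc = config.pseudocount
    log2fc = np.log2((m_i + pc) / (m_c + pc))

    alpha_se = np.nan_to_num(alpha)  # untestable genes overridden below
    se_ln = np.sqrt(
        1.0 / (n_i * (m_i + pc)) + alpha_se / n_i
        + 1.0 / (n_c * (m_c + pc)) + alpha_se / n_c
    )
    se_log2 = se_ln / np.log(2)
    stat = np.divide(log2fc, se_log2, out=np.zeros_like(log2fc), where=se_log2 > 0)
    if config.test_reference == "t":
        p = 2 * stats.t.sf(np.abs(stat), df=n_c + n_i - 2)
    else:
        p = 2 * stats.norm.sf(np.abs(stat))

    untestable = (m_c == 0) & (m_i == 0)
    if untestable.any():
        log.debug("%s: %d untestable all-zero genes", cell_type, untestable.sum())
    log2fc = np.where(untestable, 0.0, log2fc)
    p = np.where(untestable, 1.0, p)
    alpha = np.where(untestable, np.nan, alpha)

    de = pd.DataFrame(
        {
            "gene": joint.index,
            "cell_type": cell_type,
            "mean_contra": m_c,
            "mean_ipsi": m_i,
            "dispersion": alpha,
            "log2fc": log2fc,
            "p_value": p,
            "padj": bh_adjust(p),
        }
    )
    return call_significant(de, config)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)]
        raise ValueError(f"p-values outside [0, 1]: {bad[:5]}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(m)
    out[order] = q
    return out


def call_significant(de: pd.DataFrame, config: ThresholdConfig | None = None) -> pd.DataFrame:
    """Set the ``significant`` flag from the inclusive study thresholds."""
    config = config or ThresholdConfig()
    de = de.copy()
    de["significant"] = (de["padj"] <= config.max_padj) & (
        de["log2fc"].abs() >= config.min_abs_log2fc
    )
    return de


def ingest_external_de(
    path: str | Path,
    cell_type: str,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Load an externally computed DE table (e.g. a DESeq2 export).

    Requires columns ``gene`` and ``log2fc`` plus ``padj`` and/or
    ``p_value``; when only raw p-values are present, padj is recomputed by
    BH with a warning. Optional ``mean_contra`` / ``mean_ipsi`` columns are
    carried through; the dispersion is marked unavailable (NaN).
    Significance flags are recomputed from the thresholds.
    """
    config = config or ThresholdConfig()
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    t = pd.read_csv(path, sep=sep)
    missing = [c for c in ("gene", "log2fc") if c not in t.columns]
    if missing:
        raise ValueError(f"external DE table missing columns: {missing}")
    if "padj" not in t.columns:
        if "p_value" not in t.columns:
            raise ValueError("external DE table needs padj or p_value")
        log.warning("external DE table lacks padj; recomputing by BH from p_value")
        t["padj"] = bh_adjust(t["p_value"].to_numpy())
    for col in ("log2fc", "padj"):
        vals = pd.to_numeric(t[col], errors="raise")
        t[col] = vals
    if ((t["padj"] < 0) | (t["padj"] > 1)).any():
        bad = t.loc[(t["padj"] < 0) | (t["padj"] > 1), "padj"].tolist()
        raise ValueError(f"padj outside [0, 1]: {bad[:5]}")
    de = pd.DataFrame(
        {
            "gene": t["gene"].astype(str),
            "cell_type": cell_type,
            "mean_contra": pd.to_numeric(t.get("mean_contra", np.nan), errors="coerce"),
            "mean_ipsi": pd.to_numeric(t.get("mean_ipsi", np.nan), errors="coerce"),
            "dispersion": np.nan,
            "log2fc": t["log2fc"],
            "p_value": pd.to_numeric(t.get("p_value", np.nan), errors="coerce"),
            "padj": t["padj"],
        }
    )
    return call_significant(de, config)


def run_de_all(
    dataset: Dataset,
    config: ThresholdConfig | None = None,
    allow_fallback: bool = False,
) -> dict[str, pd.DataFrame]:
    """NB Wald test for every cell type in the dataset."""
    return {
        ct: nb_wald_test(dataset, ct, config, allow_fallback=allow_fallback)
        for ct in dataset.cell_types
    }


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, columns=DE_COLUMNS)
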