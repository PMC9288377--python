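"""End-to-end orchestration: configuration, logging, reports and manifest.

``run_pipeline`` chains the stages in analysis order — counts (read or
simulated) -> per-cell-type differential expression -> binary
transformation -> exclusive intersections and the category report — and
writes every artifact with a checksum manifest, so reruns with the same
seed and inputs are verifiably identical. When the input is simulated, the
planted truth is evaluated and a recovery report is added.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import binarize, count_io, diffexp, intersect, synthetic_data

log = logging.getLogger("nvustroke")


def setup_logging(verbosity: int = 0, logfile: str | Path | None = None) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    """One run's inputs, thresholds and output location.

    Exactly one of ``counts_path`` (+ ``design_path``) or ``simulation``
    must be supplied.
    """

    outdir: Path
    counts_path: Path | None = None
    design_path: Path | None = None
    simulation: synthetic_data.SimulationConfig | None = None
    thresholds: diffexp.ThresholdConfig = field(default_factory=diffexp.ThresholdConfig)
    cell_types: tuple[str, ...] = count_io.DEFAULT_CELL_TYPES
    seed: int = 0
    verbosity: int = 0
    allow_sf_fallback: bool = False

    def __post_init__(self) -> None:
        has_files = self.counts_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError(
                "exactly one of counts_path/design_path or a simulation "
                "block must be configured"
            )
        if has_files and self.design_path is None:
            raise ValueError("counts_path requires design_path")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulation", None)
        thresholds = raw.pop("thresholds", None)
        kwargs = dict(raw)
        if sim is not None:
            if "seed" not in sim and "seed" in raw:
                sim["seed"] = raw["seed"]
            kwargs["simulation"] = synthetic_data.SimulationConfig(**sim)
        if thresholds is not None:
            kwargs["thresholds"] = diffexp.ThresholdConfig(**thresholds)
        for key in ("counts_path", "design_path"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "cell_types" in kwargs:
            kwargs["cell_types"] = tuple(kwargs["cell_types"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summarize_categories(
    records: list[intersect.IntersectionRecord],
    reg_records: list[intersect.IntersectionRecord],
    statuses: pd.DataFrame,
    cell_types,
) -> dict:
    """Category report: per-cell-type status counts, named-category gene
    lists and the regulated-only pattern counts.

    Per cell type, shutdown + downregulated + upregulated + induced equals
    the regulated-gene total (the four classes partition regulated genes).
    """
    per_ct = {}
    for ct in cell_types:
        sub = statuses[statuses["cell_type"] == ct]
        counts = sub["status"].value_counts().to_dict()
        regulated = sum(counts.get(s, 0) for s in
                        ("shutdown", "downregulated", "upregulated", "induced"))
        per_ct[ct] = {
            "shutdown": counts.get("shutdown", 0),
            "downregulated": counts.get("downregulated", 0),
            "upregulated": counts.get("upregulated", 0),
            "induced": counts.get("induced", 0),
            "regulated_total": regulated,
        }
    named = {
        r.label: {"count": r.count, "genes": r.gene_ids}
        for r in records
        if not set("|:") & set(r.label) and r.label != "none"
    }
    reg_patterns = {
        r.label: {"count": r.count, "genes": r.gene_ids} for r in reg_records
    }
    return {
        "per_cell_type": per_ct,
        "named_categories": named,
        "regulated_only": reg_patterns,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary.

    Artifacts (all under ``config.outdir``): per-cell-type DE tables,
    the binary table CSV, the UpSet CSV + JSON descriptor, exclusive and
    regulated-only intersection tables, the long gene/label table, the
    category report, and — for simulated input — the truth table and the
    recovery report. ``manifest.json`` lists every file with its sha256.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(config.verbosity, out / "run.log")
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        log.info("simulating dataset (seed=%d)", sim.seed)
        dataset, truth = synthetic_data.generate_dataset(sim)
        cell_types = sim.cell_types
    else:
        counts = count_io.read_counts(config.counts_path)
        design = count_io.read_design(config.design_path, config.cell_types)
        dataset = count_io.validate_dataset(counts, design,
                                            source=str(config.counts_path))
        cell_types = tuple(dataset.cell_types)

    files: list[Path] = []
    de = {}
    for ct in dataset.cell_types:
        de[ct] = diffexp.nb_wald_test(dataset, ct, config.thresholds,
                                      allow_fallback=config.allow_sf_fallback)
        n_sig = int(de[ct]["significant"].sum())
        log.info("%s: %d genes tested, %d significant", ct, len(de[ct]), n_sig)
        p = out / f"de_{ct}.tsv"
        diffexp.write_de_table(de[ct], p)
        files.append(p)

    binary = binarize.build_binary_table(dataset, de, config.thresholds)
    p = out / "binary_table.csv"
    binarize.write_binary_csv(binary, p)
    files.append(p)

    csv_p, json_p = out / "upset_data.csv", out / "upset_descriptor.json"
    intersect.export_upset(binary, csv_p, json_p, cell_types)
    files.extend([csv_p, json_p])

    records = intersect.exclusive_intersections(binary, cell_types)
    reg_records = intersect.regulated_only_intersections(binary, cell_types)
    p = out / "intersections.tsv"
    intersect.records_frame(records).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "intersections_regulated_only.tsv"
    intersect.records_frame(reg_records).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "gene_labels.tsv"
    intersect.write_long_table(records, p)
    files.append(p)

    statuses = binarize.per_celltype_status(binary, cell_types)
    p = out / "celltype_status.tsv"
    statuses.to_csv(p, sep="\t", index=False)
    files.append(p)

    report = summarize_categories(records, reg_records, statuses, cell_types)
    p = out / "category_report.json"
    p.write_text(json.dumps(report, indent=2))
    files.append(p)

    if truth is not None:
        p = out / "truth.tsv"
        truth.to_csv(p, sep="\t")
        files.append(p)
        labels = {g: r.label for r in records for g in r.gene_ids}
        predicted = synthetic_data.predicted_categories(
            binary, statuses, labels, cell_types
        )
        recovery = synthetic_data.evaluate_recovery(truth, predicted)
        p = out / "recovery_per_category.tsv"
        recovery.per_category.to_csv(p, sep="\t")
        files.append(p)
        p = out / "recovery_confusion.tsv"
        recovery.confusion.to_csv(p, sep="\t")
        files.append(p)

    manifest = {
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "cell_types": list(cell_types),
        # creation timestamp excluded: same seed + inputs => identical manifest
        "provenance": {k: v for k, v in dataset.provenance.items() if k != "created"},
        "artifacts": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %d artifacts to %s", len(files), out)
    return manifest
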