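"""End-to-end orchestration: screen -> intersect -> consensus, and
quantify -> cohort statistics, with per-stage logging and a reproducibility
manifest.

Each stage writes its table under the output directory and logs record
counts in/out, so the screening funnel (all genes -> TPM floor -> fold
screen -> cross-database consensus -> consensus fold filter) is auditable
from the log alone.  The manifest records the configuration hash, seed and
package version; every output is a pure function of those.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSample,
    read_metadata_tsv,
    results_to_frame,
    run_cohort_analysis,
)
from .crossdb import (
    build_consensus_records,
    build_summary_table,
    consensus_fold_filter,
    intersect_gene_sets,
    write_venn_tsv,
)
from .expression_io import (
    ExpressionPanel,
    read_family_list,
    read_gct,
    read_tsv_matrix,
    summarize_panel,
    subset_to_family,
)
from .qpcr import (
    CqMeasurement,
    levels_to_frame,
    quantify_plate,
    read_cq_table,
)
from .specificity import (
    ScreenConfig,
    screen_panel,
    specific_gene_set,
    write_screen_tsv,
)

logger = logging.getLogger("tissuescreen")


def setup_logging(level: int = logging.INFO) -> None:
    """Stage-granularity logging to stderr (idempotent)."""
    root = logging.getLogger("tissuescreen")
    if not root.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(h)
    root.setLevel(level)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    panel_paths: list[str] = field(default_factory=list)
    family_path: str | None = None
    cq_path: str | None = None
    metadata_path: str | None = None
    target_tissue: str = "testis"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    consensus_min_fold: float = 1.5
    reference_genes: list[str] = field(default_factory=lambda: ["18S", "GAPDH"])
    alpha: float = 0.05
    linkage: str = "complete"
    k_range: list[int] = field(default_factory=lambda: list(range(2, 11)))
    out_dir: str = "tissuescreen_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        screen_raw = raw.pop("screen", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.screen = ScreenConfig(**screen_raw)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: Path, stages: list[str]) -> Path:
    manifest = {
        "package": "tissuescreen",
        "version": __version__,
        "python": sys.version.split()[0],
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": stages,
    }
    path = out_dir / "manifest.json"
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def load_panel(path: str | Path, na_action: str = "drop") -> ExpressionPanel:
    """Dispatch on extension: .gct(.gz) -> GCT reader, else TSV matrix."""
    name = str(path)
    if name.endswith(".gct") or name.endswith(".gct.gz"):
        return read_gct(path, na_action=na_action)
    return read_tsv_matrix(path, na_action=na_action)


# ---------------------------------------------------------------------------
# Screening pipeline
# ---------------------------------------------------------------------------


def run_screen_pipeline(
    config: RunConfig,
    panels: Sequence[ExpressionPanel] | None = None,
) -> set[str]:
    """Screen every panel, intersect across databases, apply the consensus
    fold filter, and write all intermediate tables.

    Returns the final consensus gene set.  ``panels`` may be passed directly
    (e.g. synthetic ones); otherwise they are read from ``panel_paths``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    if panels is None:
        if not config.panel_paths:
            raise ValueError("no panels given and no panel_paths configured")
        panels = [load_panel(p) for p in config.panel_paths]
    if config.family_path:
        family = read_family_list(config.family_path)
        restricted = []
        for p in panels:
            sub, unmatched = subset_to_family(p, family)
            logger.info(
                "stage family-subset %s: %d -> %d genes (%d family members absent)",
                p.database_name, p.n_genes, sub.n_genes, len(unmatched),
            )
            restricted.append(sub)
        panels = restricted
        stages.append("family-subset")

    per_db_sets: dict[str, set[str]] = {}
    per_db_summaries: dict[str, dict] = {}
    for p in panels:
        records = screen_panel(p, config.screen, config.target_tissue)
        write_screen_tsv(records, out_dir / f"screen_{p.database_name}.tsv")
        flagged = specific_gene_set(records)
        per_db_sets[p.database_name] = flagged
        per_db_summaries[p.database_name] = {
            r.gene: r.summary for r in records if r.specific
        }
        logger.info(
            "stage screen %s: %d genes in, %d candidates >= %g TPM, %d specific",
            p.database_name, p.n_genes, len(records), config.screen.tpm_min, len(flagged),
        )
    stages.append("screen")

    if len(panels) == 1:
        core = set(per_db_sets[panels[0].database_name])
        logger.info("stage intersect: single panel, consensus = its specific set (%d)", len(core))
    else:
        partition = intersect_gene_sets(per_db_sets)
        write_venn_tsv(partition, out_dir / "venn_regions.tsv")
        core = partition.core
        logger.info(
            "stage intersect: %d databases -> core of %d genes", len(panels), len(core)
        )
    stages.append("intersect")

    records = build_consensus_records(
        {db: {g: s[g] for g in core if g in s} for db, s in per_db_summaries.items()},
        core=core,
    )
    consensus = consensus_fold_filter(records, min_fold=config.consensus_min_fold)
    kept = [r for r in records if r.gene in consensus]
    table = build_summary_table(kept)
    table.to_csv(out_dir / "consensus_table.tsv", sep="\t")
    with open(out_dir / "consensus_genes.txt", "wt", encoding="utf-8") as fh:
        fh.writelines(g + "\n" for g in sorted(consensus))
    logger.info(
        "stage consensus-fold: %d core genes -> %d at min fold > %g in all databases",
        len(core), len(consensus), config.consensus_min_fold,
    )
    stages.append("consensus-fold")

    write_manifest(config, out_dir, stages)
    return consensus


# ---------------------------------------------------------------------------
# Validation (qPCR + cohort) pipeline
# ---------------------------------------------------------------------------


def run_validation_pipeline(
    config: RunConfig,
    measurements: Sequence[CqMeasurement] | None = None,
    metadata: Sequence[CohortSample] | None = None,
) -> pd.DataFrame:
    """Quantify a Cq table against the reference panel and run the cohort
    comparisons; returns the per-gene comparison report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    if measurements is None:
        if not config.cq_path:
            raise ValueError("no measurements given and no cq_path configured")
        measurements = read_cq_table(config.cq_path)
    if metadata is None:
        if not config.metadata_path:
            raise ValueError("no metadata given and no metadata_path configured")
        metadata = read_metadata_tsv(config.metadata_path)

    levels = quantify_plate(measurements, reference_genes=config.reference_genes)
    frame = levels_to_frame(levels)
    frame.to_csv(out_dir / "relative_levels.tsv", sep="\t", index=False)
    logger.info(
        "stage quantify: %d measurements -> %d relative levels (%d samples)",
        len(measurements), len(frame), frame["sample_id"].nunique(),
    )
    stages.append("quantify")

    results = run_cohort_analysis(frame, list(metadata))
    report = results_to_frame(results)
    report["significant"] = report["p_value"] < config.alpha
    report.to_csv(out_dir / "cohort_report.tsv", sep="\t", index=False)
    logger.info(
        "stage cohort: %d comparisons, %d significant at alpha=%g",
        len(report), int(report["significant"].sum()), config.alpha,
    )
    stages.append("cohort")

    write_manifest(config, out_dir, stages)
    return report
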