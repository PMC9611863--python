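"""Cross-database integration of per-database specificity screens.

Databases disagree — tissue coverage, sample counts and processing all
differ — so a single-database call is weak evidence.  This module combines
per-database screens three ways: a full Venn partition of the specific gene
sets, a consensus fold filter keeping genes whose target/other fold exceeds
a threshold (default 1.5, strict) in *every* database, and a report table
formatting each gene x database cell as ``target (max/median)`` TPM.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .expression_io import GeneTissueSummary

logger = logging.getLogger("tissuescreen")


@dataclass
class VennPartition:
    """Disjoint partition of genes by the exact subset of databases calling them.

    ``region_sets`` maps each non-empty frozenset of database names to the
    genes specific in exactly those databases (all 2^D - 1 regions present,
    possibly empty).
    """

    database_names: list[str]
    region_sets: dict[frozenset[str], set[str]]

    @property
    def core(self) -> set[str]:
        """Genes specific in all databases (the consensus region)."""
        return set(self.region_sets[frozenset(self.database_names)])

    def region(self, *names: str) -> set[str]:
        return set(self.region_sets[frozenset(names)])


@dataclass
class ConsensusRecord:
    """One gene's per-database summaries plus its weakest cross-database fold."""

    gene: str
    summaries: dict[str, GeneTissueSummary]  # database name -> summary
    min_fold_across_dbs: float
    in_core: bool


def intersect_gene_sets(per_db_sets: Mapping[str, set[str]]) -> VennPartition:
    """Partition genes by exactly which databases call them specific."""
    names = list(per_db_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 databases to intersect")
    regions: dict[frozenset[str], set[str]] = {
        frozenset(combo): set()
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    all_genes = set().union(*per_db_sets.values())
    for gene in all_genes:
        membership = frozenset(n for n in names if gene in per_db_sets[n])
        regions[membership].add(gene)
    return VennPartition(names, regions)


def _fold(summary: GeneTissueSummary) -> float:
    """Target/max-other fold; +inf when no other tissue is transcribed."""
    if summary.max_other == 0:
        return math.inf
    return summary.target_tpm / summary.max_other


def build_consensus_records(
    per_db_summaries: Mapping[str, Mapping[str, GeneTissueSummary]],
    core: set[str] | None = None,
) -> list[ConsensusRecord]:
    """Assemble per-gene consensus records from per-database summary maps.

    Genes missing from any database are excluded (they cannot satisfy an
    "in all databases" condition) and logged.
    """
    db_names = list(per_db_summaries)
    genes = set().union(*(set(s) for s in per_db_summaries.values()))
    records: list[ConsensusRecord] = []
    for gene in sorted(genes):
        missing = [db for db in db_names if gene not in per_db_summaries[db]]
        if missing:
            logger.info("consensus: %s excluded, missing_in:%s", gene, ",".join(missing))
            continue
        summaries = {db: per_db_summaries[db][gene] for db in db_names}
        min_fold = min(_fold(s) for s in summaries.values())
        records.append(
            ConsensusRecord(
                gene=gene,
                summaries=summaries,
                min_fold_across_dbs=min_fold,
                in_core=(core is None or gene in core),
            )
        )
    return records


def consensus_fold_filter(
    records: Sequence[ConsensusRecord],
    min_fold: float = 1.5,
    strict: bool = True,
) -> set[str]:
    """Genes whose fold exceeds ``min_fold`` in every database.

    Strict (>) by default: the consensus condition is "exceeded ... by more
    than 1.5-fold", unlike the inclusive (>=) 3-fold screen.
    """
    keep: set[str] = set()
    for rec in records:
        if not rec.in_core:
            continue
        ok = rec.min_fold_across_dbs > min_fold if strict else rec.min_fold_across_dbs >= min_fold
        if ok:
            keep.add(rec.gene)
    return keep


# ---------------------------------------------------------------------------
# Report table: "target (max/median)" cells per gene x database
# ---------------------------------------------------------------------------


def _fmt(v: float) -> str:
    v = float(v)
    if v == int(v):
        return str(int(v))
    s = f"{v:.10f}".rstrip("0")
    return s if float(s) == v else repr(v)


def format_summary_cell(summary: GeneTissueSummary) -> str:
    """Format as ``T (M/m)``, e.g. ``109.3 (6.5/0.3)``; zeros print as ``0``."""
    return (
        f"{_fmt(summary.target_tpm)} "
        f"({_fmt(summary.max_other)}/{_fmt(summary.median_other)})"
    )


def parse_summary_cell(cell: str, gene: str = "", tissue: str = "") -> GeneTissueSummary:
    """Inverse of :func:`format_summary_cell`."""
    target_s, rest = cell.split(" (", 1)
    max_s, med_s = rest.rstrip(")").split("/")
    return GeneTissueSummary(
        gene=gene,
        target_tissue=tissue,
        target_tpm=float(target_s),
        max_other=float(max_s),
        median_other=float(med_s),
    )


def build_summary_table(records: Sequence[ConsensusRecord]) -> pd.DataFrame:
    """One row per gene, one ``T (M/m)`` cell per database."""
    if not records:
        return pd.DataFrame()
    db_names = list(records[0].summaries)
    rows = {
        rec.gene: {db: format_summary_cell(rec.summaries[db]) for db in db_names}
        for rec in records
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=db_names)
    df.index.name = "gene"
    return df


def write_venn_tsv(partition: VennPartition, path: str | Path) -> None:
    """Venn regions as TSV: region label (db names joined by '&'), gene list."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("region\tn_genes\tgenes\n")
        for r in range(len(partition.database_names), 0, -1):
            for combo in itertools.combinations(partition.database_names, r):
                genes = sorted(partition.region_sets[frozenset(combo)])
                fh.write("&".join(combo) + f"\t{len(genes)}\t" + ",".join(genes) + "\n")
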