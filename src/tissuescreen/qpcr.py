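"""qPCR relative quantification against multi-reference geometric-mean
normalization.

Replicate Cq values (typically technical triplicates) are aggregated on the
Cq scale; a target's relative level is its abundance ``E^-Cq`` divided by the
geometric mean of the reference genes' abundances — on the Cq scale, with
efficiency E = 2, simply ``2^(mean(reference Cq) - target Cq)``.  The default
reference pair is 18S rRNA + GAPDH.  Because the normalization subtracts the
mean reference Cq, any sample-wide Cq shift (loading, global efficiency)
cancels exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("tissuescreen")

DEFAULT_REFERENCE_GENES = ("18S", "GAPDH")


@dataclass
class CqMeasurement:
    """Replicate quantification-cycle values for one (sample, gene)."""

    sample_id: str
    gene: str
    replicate_cqs: list[float]

    def __post_init__(self) -> None:
        if not self.replicate_cqs:
            raise ValueError(f"{self.sample_id}/{self.gene}: no replicates")
        for cq in self.replicate_cqs:
            if not (math.isfinite(cq) and 0 < cq < 45):
                raise ValueError(
                    f"{self.sample_id}/{self.gene}: Cq {cq} outside (0, 45)"
                )


@dataclass(frozen=True)
class RelativeLevel:
    """Reference-normalized relative abundance of a target gene in a sample."""

    sample_id: str
    gene: str
    level: float
    reference_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.level > 0:
            raise ValueError(f"{self.sample_id}/{self.gene}: level must be > 0")


def aggregate_replicates(
    measurement: CqMeasurement, max_spread: float = 0.5
) -> tuple[float, float, bool]:
    """Arithmetic mean Cq, replicate spread (max - min), and a spread flag.

    A spread above ``max_spread`` cycles (default 0.5) marks a noisy
    triplicate; flagged, not fatal.
    """
    cqs = measurement.replicate_cqs
    mean = sum(cqs) / len(cqs)
    spread = max(cqs) - min(cqs)
    flagged = spread > max_spread
    if flagged:
        logger.warning(
            "%s/%s: replicate spread %.3g cycles exceeds %.3g",
            measurement.sample_id, measurement.gene, spread, max_spread,
        )
    return mean, spread, flagged


def relative_level(
    target_cq: float,
    reference_cqs: Sequence[float],
    efficiency: float = 2.0,
) -> float:
    """``E^(mean(reference Cq) - target Cq)`` with E = 2 by default.

    Algebraically identical to dividing the target abundance ``E^-Cq`` by the
    geometric mean of the reference abundances: the geometric mean on the
    abundance scale is the arithmetic mean on the Cq scale.
    """
    if not reference_cqs:
        raise ValueError("at least one reference Cq is required")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must be > 1")
    mean_ref = sum(reference_cqs) / len(reference_cqs)
    return float(efficiency ** (mean_ref - target_cq))


def quantify_plate(
    measurements: Sequence[CqMeasurement],
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    max_spread: float = 0.5,
    efficiency: float | Mapping[str, float] = 2.0,
) -> list[RelativeLevel]:
    """Normalize every (sample, non-reference gene) to the reference panel.

    Reference replicate Cqs are aggregated per gene first, then averaged
    across reference genes.  Samples missing any reference gene are skipped
    with a log entry.  ``efficiency`` may be a single value or a per-gene
    mapping (reference genes use the mapping too, falling back to 2).
    """
    refs = tuple(reference_genes)
    if not refs:
        raise ValueError("reference gene list is empty")

    def eff(gene: str) -> float:
        if isinstance(efficiency, Mapping):
            return float(efficiency.get(gene, 2.0))
        return float(efficiency)

    by_sample: dict[str, dict[str, CqMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, {})[m.gene] = m

    levels: list[RelativeLevel] = []
    for sample_id, genes in by_sample.items():
        missing = [r for r in refs if r not in genes]
        if missing:
            logger.warning(
                "sample %s skipped: missing reference gene(s) %s",
                sample_id, ",".join(missing),
            )
            continue
        ref_means = [aggregate_replicates(genes[r], max_spread)[0] for r in refs]
        mean_ref = sum(ref_means) / len(ref_means)
        for gene, m in genes.items():
            if gene in refs:
                continue
            mean_cq, _, _ = aggregate_replicates(m, max_spread)
            levels.append(
                RelativeLevel(
                    sample_id=sample_id,
                    gene=gene,
                    level=float(eff(gene) ** (mean_ref - mean_cq)),
                    reference_genes=refs,
                )
            )
    return levels


# ---------------------------------------------------------------------------
# I/O: long-format Cq tables and level tables
# ---------------------------------------------------------------------------


def read_cq_table(path: str | Path) -> list[CqMeasurement]:
    """Long-format TSV (sample_id, gene, cq); repeated rows are replicates."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    for col in ("sample_id", "gene", "cq"):
        if col not in df.columns:
            raise ValueError(f"Cq table missing column {col!r}")
    out: list[CqMeasurement] = []
    for (sample_id, gene), grp in df.groupby(["sample_id", "gene"], sort=False):
        out.append(CqMeasurement(str(sample_id), str(gene), grp["cq"].astype(float).tolist()))
    return out


def write_cq_table(measurements: Sequence[CqMeasurement], path: str | Path) -> None:
    rows = [
        {"sample_id": m.sample_id, "gene": m.gene, "cq": cq}
        for m in measurements
        for cq in m.replicate_cqs
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene", "cq"]).to_csv(
        path, sep="\t", index=False
    )


def levels_to_frame(levels: Sequence[RelativeLevel]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": lv.sample_id,
            "gene": lv.gene,
            "level": lv.level,
            "reference_genes": ",".join(lv.reference_genes),
        }
        for lv in levels
    ]
    return pd.DataFrame(rows, columns=["sample_id", "gene", "level", "reference_genes"])


def write_levels_tsv(levels: Sequence[RelativeLevel], path: str | Path) -> None:
    levels_to_frame(levels).to_csv(path, sep="\t", index=False)


def read_levels_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
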