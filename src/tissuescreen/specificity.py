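"""Tissue-specificity screen over an expression panel.

A gene is called tissue-specific in a target tissue when its TPM there is at
least ``tpm_min`` (default 5) and at least ``fold_min`` (default 3) times its
level in every other tissue.  The fold condition is evaluated through the
*inverted* ratio — the maximum over other tissues of (other TPM / target
TPM) — which stays defined when other tissues are silent: a gene expressed
only in the target tissue gets ratio 0 and passes, instead of tripping a
division by zero in the direct target/other formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionPanel, GeneTissueSummary, summarize_gene


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the specificity screen.

    ``tpm_min``: TPM floor for candidacy in the scanned tissue (default 5).
    ``fold_min``: minimum target/other fold (default 3).
    ``inv_ratio_max``: cap on the inverted ratio; defaults to ``1/fold_min``
    so that the inverted and direct formulations agree exactly.  A stricter
    cap (e.g. 0.3) may be set explicitly.
    ``active_tpm``: floor for counting a gene as transcribed (default 3).
    """

    tpm_min: float = 5.0
    fold_min: float = 3.0
    inv_ratio_max: float | None = None
    active_tpm: float = 3.0

    def __post_init__(self) -> None:
        if self.tpm_min <= 0:
            raise ValueError("tpm_min must be > 0")
        if self.fold_min <= 1:
            raise ValueError("fold_min must be > 1")
        if self.active_tpm < 0:
            raise ValueError("active_tpm must be >= 0")
        if self.inv_ratio_max is None:
            object.__setattr__(self, "inv_ratio_max", 1.0 / self.fold_min)
        elif self.inv_ratio_max <= 0:
            raise ValueError("inv_ratio_max must be > 0")


@dataclass(frozen=True)
class SpecificityRecord:
    """Screen outcome for one (gene, tissue) pair."""

    gene: str
    tissue: str
    summary: GeneTissueSummary
    inv_ratio: float
    specific: bool


def inverse_specificity_ratio(values: Sequence[float], target_index: int) -> float:
    """Max over non-target tissues of values[i] / values[target_index].

    0 when every other tissue is silent.  The target value must be positive
    (a zero-target gene cannot clear the TPM floor anyway, so the screen
    never evaluates the ratio there).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 tissues")
    target = values[target_index]
    if target <= 0:
        raise ValueError(
            f"ratio undefined for target TPM {target}; target must be > 0"
        )
    others = np.delete(values, target_index)
    return float(others.max() / target)


def is_tissue_specific(summary: GeneTissueSummary, config: ScreenConfig) -> bool:
    """True iff target TPM >= tpm_min and inverted ratio <= inv_ratio_max.

    Both boundaries are inclusive ("at least 5 TPM", "at least 3"-fold).
    """
    if summary.target_tpm < config.tpm_min:
        return False
    inv = summary.max_other / summary.target_tpm
    return inv <= config.inv_ratio_max


def screen_panel(
    panel: ExpressionPanel,
    config: ScreenConfig = ScreenConfig(),
    target_tissue: str | None = None,
) -> list[SpecificityRecord]:
    """Screen a panel for tissue-specific genes.

    With ``target_tissue`` given, returns one record per gene clearing the
    TPM floor in that tissue.  Without it, every (gene, tissue) pair clearing
    the floor is scanned, i.e. each tissue is screened in turn.
    """
    if panel.n_tissues < 2:
        raise ValueError("screen requires at least 2 tissues")
    if target_tissue is not None:
        tissues = [target_tissue]
        panel.tissue_index(target_tissue)  # raises on unknown tissue
    else:
        tissues = list(panel.tissue_labels)
    records: list[SpecificityRecord] = []
    for tissue in tissues:
        t = panel.tissue_index(tissue)
        for i, gene in enumerate(panel.gene_ids):
            target = panel.values[i, t]
            if target < config.tpm_min:
                continue
            summary = summarize_gene(panel, gene, tissue)
            inv = inverse_specificity_ratio(panel.values[i], t)
            records.append(
                SpecificityRecord(
                    gene=gene,
                    tissue=tissue,
                    summary=summary,
                    inv_ratio=inv,
                    specific=is_tissue_specific(summary, config),
                )
            )
    return records


def specific_gene_set(records: Sequence[SpecificityRecord]) -> set[str]:
    """Genes flagged specific in a screen result."""
    return {r.gene for r in records if r.specific}


def count_active(
    panel: ExpressionPanel, config: ScreenConfig = ScreenConfig()
) -> dict[str, int]:
    """Per-tissue count of genes transcribed at >= active_tpm (inclusive)."""
    counts = (panel.values >= config.active_tpm).sum(axis=0)
    return {t: int(c) for t, c in zip(panel.tissue_labels, counts)}


def records_to_frame(records: Sequence[SpecificityRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "tissue": r.tissue,
            "target_tpm": r.summary.target_tpm,
            "max_other": r.summary.max_other,
            "median_other": r.summary.median_other,
            "inv_ratio": r.inv_ratio,
            "specific": r.specific,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "tissue", "target_tpm", "max_other",
            "median_other", "inv_ratio", "specific",
        ],
    )


def write_screen_tsv(records: Sequence[SpecificityRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_screen_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["specific"] = df["specific"].astype(bool)
    return df
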