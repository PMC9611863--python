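"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators mirror the statistical structure the analysis assumes:

* :func:`generate_panels` — several correlated pseudo-database TPM panels
  over the same genes.  Background expression is log-normal per tissue
  (heavy right tail, like real TPM); a chosen subset of genes is planted as
  target-tissue-specific at a configurable fold, enforced post-jitter so
  recovery tests are sharp rather than probabilistic.
* :func:`generate_qpcr_cohort` — replicate Cq tables plus sample metadata
  emulating a tumor/normal testis cohort, with planted tumor suppression of
  chosen genes expressed as a Cq shift of log2(fold) cycles.
* :func:`generate_correlated_blocks` — a genes x samples matrix whose gene
  blocks share a latent per-sample factor, giving tunable within-block
  Spearman correlation for clustering tests.

All generators are pure functions of (config, seed): a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import CohortSample
from .expression_io import ExpressionPanel
from .qpcr import CqMeasurement

_MAX_REJECTION_ROUNDS = 1000


# ---------------------------------------------------------------------------
# Expression panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthExpressionConfig:
    """Shape and signal of the synthetic multi-database expression panels.

    Background TPM is log-normal with natural-log mean ``background_log_mean``
    and sd ``background_log_sd`` (defaults 0.5 / 1.0: median ~1.6 TPM with a
    heavy right tail).  ``n_specific`` genes are planted with target-tissue
    TPM at least ``specific_fold`` times every other tissue and at least 5
    TPM, in every database.  ``cross_db_noise_sd`` is log-scale jitter
    applied independently per database, emulating databases that measure the
    same biology with different pipelines.

    ``background_max_fold`` keeps recovery sharp: background genes whose
    target-tissue TPM happens to reach ``min_target_tpm`` at that fold over
    every other tissue are redrawn, so planted and background genes are
    separated by construction rather than with high probability.  Set it to
    None for a free background (e.g. to measure false-positive rates).
    """

    n_genes: int = 100
    n_tissues: int = 20
    n_databases: int = 4
    n_specific: int = 9
    background_log_mean: float = 0.5
    background_log_sd: float = 1.0
    specific_fold: float = 10.0
    cross_db_noise_sd: float = 0.25
    target_tissue_label: str = "testis"
    seed: int = 0
    min_target_tpm: float = 5.0
    background_max_fold: float | None = 3.0

    def __post_init__(self) -> None:
        if self.n_specific > self.n_genes:
            raise ValueError("n_specific cannot exceed n_genes")
        if self.specific_fold <= 1:
            raise ValueError("specific_fold must be > 1")
        if self.background_log_sd < 0 or self.cross_db_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")


def generate_panels(
    config: SynthExpressionConfig,
) -> tuple[list[ExpressionPanel], set[str]]:
    """Generate one panel per pseudo-database plus the planted gene set.

    Planted genes satisfy, in every database after jitter: target-tissue TPM
    >= 5 and >= ``specific_fold`` x every other tissue; background genes
    (unless ``background_max_fold`` is None) never reach 5 TPM at
    ``background_max_fold``-fold in the target tissue.  Both constraints are
    enforced by redrawing a violating gene's jitter (bounded retries), so an
    infeasible configuration raises rather than silently degrading.
    """
    rng = np.random.default_rng(config.seed)
    g, t, d = config.n_genes, config.n_tissues, config.n_databases
    gene_ids = [f"GENE{i:04d}" for i in range(g)]
    tissues = [config.target_tissue_label] + [f"tissue{j:02d}" for j in range(1, t)]
    planted_idx = np.arange(config.n_specific)
    planted = {gene_ids[i] for i in planted_idx}

    def background_looks_specific(row: np.ndarray) -> bool:
        if config.background_max_fold is None:
            return False
        return bool(
            row[0] >= config.min_target_tpm
            and row[0] >= config.background_max_fold * row[1:].max()
        )

    # shared biology: one base matrix, jittered per database
    base = rng.lognormal(config.background_log_mean, config.background_log_sd, size=(g, t))
    for i in range(config.n_specific, g):
        tries = 0
        while background_looks_specific(base[i]):
            tries += 1
            if tries > _MAX_REJECTION_ROUNDS:
                raise RuntimeError(f"could not draw a non-specific background row for {gene_ids[i]}")
            base[i] = rng.lognormal(
                config.background_log_mean, config.background_log_sd, size=t
            )
    # plant target-tissue elevation in the base matrix
    for i in planted_idx:
        other_max = base[i, 1:].max()
        base[i, 0] = max(config.min_target_tpm, config.specific_fold * other_max)

    panels: list[ExpressionPanel] = []
    for db in range(d):
        jitter = np.exp(rng.normal(0.0, config.cross_db_noise_sd, size=(g, t)))
        values = base * jitter
        for i in range(g):
            planted_gene = i < config.n_specific
            tries = 0
            while True:
                other_max = values[i, 1:].max()
                target = values[i, 0]
                if planted_gene:
                    ok = (
                        target >= config.min_target_tpm
                        and target >= config.specific_fold * other_max
                    )
                else:
                    ok = not background_looks_specific(values[i])
                if ok:
                    break
                tries += 1
                if tries > _MAX_REJECTION_ROUNDS:
                    raise RuntimeError(
                        f"could not satisfy the planted/background constraint for "
                        f"{gene_ids[i]} in database {db}: fold thresholds too tight "
                        "for the jitter level"
                    )
                values[i] = base[i] * np.exp(
                    rng.normal(0.0, config.cross_db_noise_sd, size=t)
                )
        panels.append(
            ExpressionPanel(
                database_name=f"synthdb{db}",
                gene_ids=list(gene_ids),
                gene_symbols=list(gene_ids),
                tissue_labels=list(tissues),
                values=values,
            )
        )
    return panels, planted


# ---------------------------------------------------------------------------
# qPCR cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthCohortConfig:
    """Shape of the synthetic qPCR tumor/normal cohort.

    Sample counts default to the studied cohort shape: 2 healthy controls,
    7 germ / 4 non-germ adjacent normals, 27 germ / 4 non-germ tumors, with
    6 germ and 3 non-germ adjacent-normal/tumor pairs sharing a patient id.  ``suppression_fold``
    maps each planted gene to its tumor-suppression factor (germ-histology
    tumors only, matching the biology being emulated); other genes are null.
    ``cq_noise_sd`` is Gaussian replicate noise in cycles (default 0.1,
    typical technical-replicate scatter).
    """

    n_control: int = 2
    n_adjacent_germ: int = 7
    n_adjacent_nongerm: int = 4
    n_tumor_germ: int = 27
    n_tumor_nongerm: int = 4
    n_paired_germ: int = 6
    n_paired_nongerm: int = 3
    genes: tuple[str, ...] = ("TSG1", "TSG2", "NULLG")
    suppression_fold: dict[str, float] = field(
        default_factory=lambda: {"TSG1": 100.0, "TSG2": 10.0}
    )
    normal_level: float = 1.0
    reference_cq_base: float = 17.0
    cq_noise_sd: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.suppression_fold.values()):
            raise ValueError("suppression_fold values must be >= 1")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        if set(self.suppression_fold) - set(self.genes):
            raise ValueError("suppression_fold keys must be listed in genes")


def generate_qpcr_cohort(
    config: SynthCohortConfig,
    reference_genes: Sequence[str] = ("18S", "GAPDH"),
) -> tuple[list[CqMeasurement], list[CohortSample], dict[str, dict[str, float]]]:
    """Generate Cq measurements, sample metadata, and true relative levels.

    Reference genes sit at ``reference_cq_base`` plus a per-sample loading
    shift shared by all genes in the sample (it cancels in normalization).
    A target with true level L is placed at ``mean reference Cq - log2(L)``;
    germ-tumor samples of planted genes are shifted up by
    ``log2(suppression_fold)`` cycles.  Returns (measurements, metadata,
    truth) with truth[sample_id][gene] = true relative level.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[CohortSample] = []
    for i in range(config.n_control):
        samples.append(CohortSample(f"K{i + 1}", "control", "germ", None))
    pair = 0
    for histology, n_adj, n_tum, n_paired in (
        ("germ", config.n_adjacent_germ, config.n_tumor_germ, config.n_paired_germ),
        ("non_germ", config.n_adjacent_nongerm, config.n_tumor_nongerm,
         config.n_paired_nongerm),
    ):
        tag = "G" if histology == "germ" else "NG"
        n_paired = min(n_paired, n_adj, n_tum)
        for j in range(n_adj):
            pid = f"P{pair + j + 1}" if j < n_paired else None
            samples.append(CohortSample(f"{tag}{j + 1}N", "adjacent_normal", histology, pid))
        for j in range(n_tum):
            pid = f"P{pair + j + 1}" if j < n_paired else None
            samples.append(CohortSample(f"{tag}{j + 1}T", "tumor", histology, pid))
        pair += n_paired

    measurements: list[CqMeasurement] = []
    truth: dict[str, dict[str, float]] = {}
    for s in samples:
        loading = rng.normal(0.0, 1.0)  # sample-wide Cq shift, cancels out
        ref_cqs = {}
        for ref in reference_genes:
            cqs = config.reference_cq_base + loading + rng.normal(
                0.0, config.cq_noise_sd, size=config.n_replicates
            )
            ref_cqs[ref] = cqs
            measurements.append(CqMeasurement(s.sample_id, ref, cqs.tolist()))
        truth[s.sample_id] = {}
        for gene in config.genes:
            level = config.normal_level
            suppressed = (
                s.state == "tumor"
                and s.histology == "germ"
                and gene in config.suppression_fold
            )
            if suppressed:
                level = level / config.suppression_fold[gene]
            truth[s.sample_id][gene] = level
            cq_center = config.reference_cq_base + loading - math.log2(level)
            cqs = cq_center + rng.normal(0.0, config.cq_noise_sd, size=config.n_replicates)
            measurements.append(CqMeasurement(s.sample_id, gene, cqs.tolist()))
    return measurements, samples, truth


# ---------------------------------------------------------------------------
# Correlated blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthBlockConfig:
    """Block-correlated genes x samples matrix for clustering tests.

    Each block shares a latent standard-normal factor per sample; gene g in
    block b is ``within_block_rho * z_b + noise_sd * sqrt(1 - rho^2) * eps``,
    so realized within-block correlation rises with ``within_block_rho`` and
    reaches exactly 1 when ``noise_sd`` is 0.  ``sign_flip_fraction`` of the
    genes in each block are negated, planting anti-correlated members that a
    sign-blind distance must still place inside the block.
    """

    block_sizes: tuple[int, ...] = (10, 10)
    n_samples: int = 50
    within_block_rho: float = 0.9
    noise_sd: float = 1.0
    sign_flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.within_block_rho <= 1:
            raise ValueError("within_block_rho must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.sign_flip_fraction <= 1:
            raise ValueError("sign_flip_fraction must be in [0, 1]")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")


def generate_correlated_blocks(
    config: SynthBlockConfig,
) -> tuple[np.ndarray, list[str], list[int]]:
    """Returns (genes x samples matrix, gene labels, true block labels)."""
    rng = np.random.default_rng(config.seed)
    n_genes = sum(config.block_sizes)
    x = np.zeros((n_genes, config.n_samples))
    labels: list[str] = []
    blocks: list[int] = []
    row = 0
    rho = config.within_block_rho
    for b, size in enumerate(config.block_sizes):
        z = rng.standard_normal(config.n_samples)
        n_flip = int(round(config.sign_flip_fraction * size))
        for j in range(size):
            eps = rng.standard_normal(config.n_samples)
            signal = rho * z + config.noise_sd * math.sqrt(1 - rho**2) * eps
            if j < n_flip:
                signal = -signal
            x[row] = signal
            labels.append(f"B{b}_{j}")
            blocks.append(b)
            row += 1
    return x, labels, blocks


# ---------------------------------------------------------------------------
# Truth serialization (self-verifying downstream tests)
# ---------------------------------------------------------------------------


def write_truth_json(truth: object, path: str | Path) -> None:
    """Write planted ground truth alongside generated data."""

    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=default)
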