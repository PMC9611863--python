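"""Tumor-vs-normal cohort comparisons of relative expression levels.

Groups are compared with rank tests: Mann-Whitney U for independent groups
and the Wilcoxon signed-rank test for patient-paired samples, both
two-sided.  Exact p-values are used where they are cheap (small groups, no
ties); otherwise the normal approximation with midrank tie correction and
continuity correction.  Effect sizes are reported as the ratio of group
medians, the "normal/tumor ratio" convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tissuescreen")

STATES = ("control", "adjacent_normal", "tumor")
HISTOLOGIES = ("germ", "non_germ")

# combined sample size at or below which exact enumeration is used
EXACT_N_MAX = 12


@dataclass(frozen=True)
class CohortSample:
    """Sample metadata driving group comparisons."""

    sample_id: str
    state: str
    histology: str
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(
                f"histology must be one of {HISTOLOGIES}, got {self.histology!r}"
            )


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group comparison for one gene."""

    gene: str
    stratum: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str  # "mann-whitney" or "wilcoxon-paired"
    statistic: float
    p_value: float
    median_fold: float
    exact: bool
    degenerate: bool = False


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U test; returns (U_a, p, exact_used).

    The exact null distribution is used when the combined sample size is at
    most 12 and there are no ties; otherwise the normal approximation with
    midrank tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = a.size + b.size <= EXACT_N_MAX and not _has_ties(np.concatenate([a, b]))
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0)), exact


def wilcoxon_paired(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, bool, bool]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Returns ``(W, p, exact_used, degenerate)`` where W is the smaller of the
    two signed-rank sums (so all-positive differences give W = 0).  Zero
    differences are discarded before ranking; if every difference is zero
    the comparison is degenerate and reported as p = 1 with a flag.  Exact
    enumeration of sign patterns (midranks on tied absolute differences) is
    used for at most 12 informative pairs; otherwise the normal approximation
    with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired groups must be non-empty and equal-length")
    d = a - b
    informative = d[d != 0]
    if informative.size == 0:
        return 0.0, 1.0, False, True
    exact = informative.size <= EXACT_N_MAX
    if exact:
        ranks = stats.rankdata(np.abs(informative))
        w_plus = float(ranks[informative > 0].sum())
        w = min(w_plus, float(ranks.sum()) - w_plus)
        # conditional null distribution of W+ given the observed |d| ranks:
        # every sign pattern equally likely
        dist = np.zeros(1)
        for r in ranks:
            dist = np.concatenate([dist, dist + r])
        p = 2 * min((dist <= w_plus).mean(), (dist >= w_plus).mean())
        return w, float(min(p, 1.0)), True, False
    res = stats.wilcoxon(
        informative,
        zero_method="wilcox",
        alternative="two-sided",
        method="approx",
        correction=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0)), False, False


def median_fold_change(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, bool]:
    """median(a) / median(b); (+inf, flagged) when the denominator median is 0."""
    med_a = float(np.median(np.asarray(group_a, dtype=float)))
    med_b = float(np.median(np.asarray(group_b, dtype=float)))
    if med_b == 0:
        logger.warning("median fold change: zero denominator median")
        return math.inf, True
    return med_a / med_b, False


def round_sig(x: float, digits: int = 3) -> float:
    """Round to significant digits, the precision fold tables are printed at."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------


def run_cohort_analysis(
    levels: pd.DataFrame,
    metadata: Sequence[CohortSample],
    genes: Sequence[str] | None = None,
    normal_states: Sequence[str] = ("control", "adjacent_normal"),
    min_group: int = 2,
) -> list[ComparisonResult]:
    """Per-gene tumor-vs-normal comparisons, overall and per histology stratum.

    ``levels`` is a long-format frame with columns sample_id / gene / level.
    "Normal" pools the states in ``normal_states`` (controls plus adjacent
    normal tissue by default; pass ``("control",)`` for controls only).
    Strata with fewer than ``min_group`` samples on either side are skipped
    with a log entry.  Patients contributing both a tumor and a normal sample
    additionally enter a paired Wilcoxon comparison.
    """
    meta = {s.sample_id: s for s in metadata}
    unknown = set(levels["sample_id"].astype(str)) - set(meta)
    if unknown:
        raise ValueError(f"levels contain samples without metadata: {sorted(unknown)[:5]}")
    if genes is None:
        genes = sorted(levels["gene"].unique())

    results: list[ComparisonResult] = []
    strata: dict[str, set[str]] = {
        "all": set(HISTOLOGIES),
        "germ": {"germ"},
        "non_germ": {"non_germ"},
    }
    for gene in genes:
        sub = levels[levels["gene"] == gene]
        value = {str(r.sample_id): float(r.level) for r in sub.itertuples()}
        for stratum, histos in strata.items():
            normal = [
                v for sid, v in value.items()
                if meta[sid].state in normal_states and meta[sid].histology in histos
            ]
            tumor = [
                v for sid, v in value.items()
                if meta[sid].state == "tumor" and meta[sid].histology in histos
            ]
            if len(normal) < min_group or len(tumor) < min_group:
                logger.info(
                    "%s/%s: skipped (normal n=%d, tumor n=%d)",
                    gene, stratum, len(normal), len(tumor),
                )
                continue
            u, p, exact = mann_whitney(normal, tumor)
            fold, flagged = median_fold_change(normal, tumor)
            results.append(
                ComparisonResult(
                    gene=gene, stratum=stratum,
                    group_a="normal", group_b="tumor",
                    n_a=len(normal), n_b=len(tumor),
                    test="mann-whitney", statistic=u, p_value=p,
                    median_fold=fold, exact=exact, degenerate=flagged,
                )
            )
        # paired comparison over patients with both states
        pairs: list[tuple[float, float]] = []
        by_patient: dict[str, dict[str, float]] = {}
        for sid, v in value.items():
            s = meta[sid]
            if s.patient_id is None:
                continue
            slot = "tumor" if s.state == "tumor" else "normal"
            by_patient.setdefault(s.patient_id, {})[slot] = v
        for pat, slots in by_patient.items():
            if "tumor" in slots and "normal" in slots:
                pairs.append((slots["normal"], slots["tumor"]))
        if len(pairs) >= min_group:
            normals, tumors = zip(*pairs)
            w, p, exact, degenerate = wilcoxon_paired(normals, tumors)
            fold, flagged = median_fold_change(normals, tumors)
            results.append(
                ComparisonResult(
                    gene=gene, stratum="paired",
                    group_a="normal", group_b="tumor",
                    n_a=len(pairs), n_b=len(pairs),
                    test="wilcoxon-paired", statistic=w, p_value=p,
                    median_fold=fold, exact=exact,
                    degenerate=degenerate or flagged,
                )
            )
        elif pairs:
            logger.info("%s/paired: skipped (%d pair)", gene, len(pairs))
    return results


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene, "stratum": r.stratum, "test": r.test,
            "n_a": r.n_a, "n_b": r.n_b, "statistic": r.statistic,
            "p_value": r.p_value, "median_fold": r.median_fold,
            "exact": r.exact, "degenerate": r.degenerate,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "stratum", "test", "n_a", "n_b", "statistic",
                 "p_value", "median_fold", "exact", "degenerate"],
    )


def write_results_tsv(results: Sequence[ComparisonResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> list[CohortSample]:
    """Sample metadata TSV: sample_id, state, histology[, patient_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = []
    for r in df.itertuples():
        pid = getattr(r, "patient_id", None)
        if pid is not None and (pd.isna(pid) or pid == ""):
            pid = None
        samples.append(CohortSample(str(r.sample_id), str(r.state), str(r.histology), pid))
    return samples


def write_metadata_tsv(samples: Sequence[CohortSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id, "state": s.state,
            "histology": s.histology, "patient_id": s.patient_id or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "state", "histology", "patient_id"]).to_csv(
        path, sep="\t", index=False
    )
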