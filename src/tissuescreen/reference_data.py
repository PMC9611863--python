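"""Published reference values for the testis-specific C2H2 gene screen.

Two small tables of printed values, embedded so they can be re-screened and
re-compared without access to the original database exports:

* ``TESTIS_SUMMARIES_BY_DB`` — for each of the four public expression
  databases (HPA, ENCODE, GTEx, Illumina Body Map), the reported testis TPM
  together with the maximum and median TPM over all non-testis tissues, for
  the nine C2H2 genes called testis-specific in all four databases.
* ``TUMOR_NORMAL_MEDIANS`` — reported median TPM of testis-specific C2H2
  genes in normal testis (GTEx) versus testicular germ-cell tumor (TCGA)
  cohorts, the basis of the printed normal/tumor fold ratios.
"""

from __future__ import annotations

from .expression_io import ExpressionPanel, GeneTissueSummary

DATABASES = ("HPA", "ENCODE", "GTEx", "Illumina")

CONSENSUS_GENES = (
    "ZNF473", "ZBTB32", "ZNF541", "ZSCAN5A", "ZNF487",
    "PRDM9", "ZNF560", "CTCFL", "ZNF165",
)

# gene -> per-database (testis TPM, max other-tissue TPM, median other-tissue TPM)
TESTIS_SUMMARIES_BY_DB: dict[str, dict[str, tuple[float, float, float]]] = {
    "HPA": {
        "ZNF473": (76.4, 11.1, 4.25),
        "ZBTB32": (43.3, 7.5, 0.15),
        "ZNF541": (19.2, 1.7, 0.1),
        "ZSCAN5A": (34.6, 11.3, 3.4),
        "ZNF487": (51.4, 9.9, 2.95),
        "PRDM9": (7.0, 1.7, 0.0),
        "ZNF560": (11.9, 1.2, 0.0),
        "CTCFL": (20.4, 0.8, 0.3),
        "ZNF165": (35.8, 7.4, 1.55),
    },
    "ENCODE": {
        "ZNF473": (79.0, 8.0, 2.5),
        "ZBTB32": (84.0, 4.0, 0.0),
        "ZNF541": (40.0, 1.0, 0.3),
        "ZSCAN5A": (12.0, 2.0, 0.95),
        "ZNF487": (28.0, 7.0, 2.0),
        "PRDM9": (9.0, 0.0, 0.0),
        "ZNF560": (15.0, 0.2, 0.0),
        "CTCFL": (14.0, 0.2, 0.0),
        "ZNF165": (46.0, 15.0, 2.0),
    },
    "GTEx": {
        "ZNF473": (49.1, 8.3, 3.25),
        "ZBTB32": (109.3, 6.5, 0.3),
        "ZNF541": (45.7, 2.7, 0.3),
        "ZSCAN5A": (14.4, 2.3, 1.2),
        "ZNF487": (23.2, 4.4, 2.1),
        "PRDM9": (6.9, 0.0, 0.0),
        "ZNF560": (15.5, 0.6, 0.0),
        "CTCFL": (7.5, 0.1, 0.0),
        "ZNF165": (45.6, 7.6, 1.35),
    },
    "Illumina": {
        "ZNF473": (46.0, 8.0, 4.0),
        "ZBTB32": (32.0, 5.0, 0.4),
        "ZNF541": (18.0, 2.0, 0.3),
        "ZSCAN5A": (12.0, 3.0, 1.0),
        "ZNF487": (21.0, 5.0, 2.0),
        "PRDM9": (6.0, 0.0, 0.0),
        "ZNF560": (12.0, 0.3, 0.0),
        "CTCFL": (17.0, 0.5, 0.2),
        "ZNF165": (49.0, 9.0, 2.0),
    },
}

# gene -> (median TPM in normal testis, median TPM in germ-cell tumor)
TUMOR_NORMAL_MEDIANS: dict[str, tuple[float, float]] = {
    "ZBTB32": (93.0, 0.93),
    "PRDM9": (4.52, 0.05),
    "ZNF541": (27.4, 0.36),
    "KLF17": (15.8, 0.31),
    "CTCFL": (9.11, 0.20),
    "ZNF479": (3.34, 0.13),
    "ZFHX2": (17.7, 1.09),
    "ZNF487": (33.0, 2.48),
    "ZNF433": (32.9, 2.61),
    "ZSCAN5B": (2.25, 0.18),
    "ZNF165": (21.3, 2.20),
    "ZNF563": (15.3, 1.98),
    "ZNF473": (39.1, 6.37),
    "ZSCAN5A": (34.6, 5.94),
    "ZNF628": (31.7, 5.45),
    "ZNF233": (9.55, 1.68),
    "ZNF829": (12.6, 3.28),
    "ZNF646": (32.7, 8.83),
    "ZNF689": (22.4, 6.40),
    "ZNF318": (46.8, 14.3),
    "BNC1": (19.6, 6.45),
    "ZNF574": (37.0, 15.7),
    "ZNF728": (5.86, 3.44),
    "ZNF560": (8.89, 7.53),
    "ZFP42": (2.54, 43.0),
}


def reference_panels(target_tissue: str = "testis") -> list[ExpressionPanel]:
    """Per-database mini-panels built from the published summaries.

    Each panel has three columns — the testis TPM plus two pseudo-tissues
    holding the reported max and median of the other tissues — so the
    screen's per-gene summary over non-target columns reproduces the printed
    (max/median) pair exactly.
    """
    panels = []
    for db in DATABASES:
        table = TESTIS_SUMMARIES_BY_DB[db]
        genes = list(table)
        values = [[table[g][0], table[g][1], table[g][2]] for g in genes]
        panels.append(
            ExpressionPanel(
                database_name=db,
                gene_ids=genes,
                gene_symbols=genes,
                tissue_labels=[target_tissue, "other_max", "other_median"],
                values=values,
            )
        )
    return panels


def reference_summaries(
    target_tissue: str = "testis",
) -> dict[str, dict[str, GeneTissueSummary]]:
    """The published per-database summaries as GeneTissueSummary maps."""
    out: dict[str, dict[str, GeneTissueSummary]] = {}
    for db in DATABASES:
        out[db] = {
            g: GeneTissueSummary(g, target_tissue, *vals)
            for g, vals in TESTIS_SUMMARIES_BY_DB[db].items()
        }
    return out
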