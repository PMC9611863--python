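"""Expression-matrix I/O and per-gene tissue summaries.

A database export is modelled as an :class:`ExpressionPanel`: a genes x
tissues matrix of median TPM values with Ensembl-style gene IDs as the
primary identity and display symbols carried alongside.  Panels are read
from GCT 1.2 (the format GTEx distributes median-TPM matrices in) or from
plain TSV matrices, restricted to a gene family of interest, and reduced
per gene to the three numbers the screen works with: the target-tissue TPM
and the maximum and median TPM over all other tissues.
"""

from __future__ import annotations

import gzip
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tissuescreen")


class PanelFormatError(ValueError):
    """A panel file violates its format contract (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionPanel:
    """One database's genes x tissues non-negative TPM matrix.

    Parameters
    ----------
    database_name
        Label for the source database (e.g. ``"GTEx"``).
    gene_ids
        Ordered, unique primary identifiers (Ensembl-style IDs).
    gene_symbols
        Display symbols parallel to ``gene_ids``; may repeat or be empty.
    tissue_labels
        Ordered, unique tissue/column labels.
    values
        ``(n_genes, n_tissues)`` array of TPM, all finite and >= 0.
    """

    database_name: str
    gene_ids: list[str]
    gene_symbols: list[str]
    tissue_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_genes, n_tissues = len(self.gene_ids), len(self.tissue_labels)
        if self.values.shape != (n_genes, n_tissues):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n_genes} genes x {n_tissues} tissues"
            )
        if len(self.gene_symbols) != n_genes:
            raise ValueError("gene_symbols must parallel gene_ids")
        if len(set(self.gene_ids)) != n_genes:
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene id: {dup!r}")
        if len(set(self.tissue_labels)) != n_tissues:
            dup = _first_duplicate(self.tissue_labels)
            raise ValueError(f"duplicate tissue label: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains non-finite TPM values")
        if np.any(self.values < 0):
            raise ValueError("panel contains negative TPM values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_labels)

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame indexed by gene id, columns = tissues."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.tissue_labels)

    def gene_vector(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r} in panel {self.database_name!r}") from None
        return self.values[i]

    def tissue_index(self, tissue: str) -> int:
        try:
            return self.tissue_labels.index(tissue)
        except ValueError:
            raise KeyError(
                f"unknown tissue {tissue!r} in panel {self.database_name!r}"
            ) from None


@dataclass
class GeneFamilyList:
    """Membership list for a gene family (e.g. the C2H2 zinc-finger family)."""

    member_ids: set[str]
    id_to_symbol: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("gene family is empty")
        extra = set(self.id_to_symbol) - self.member_ids
        if extra:
            raise ValueError(f"id_to_symbol keys not in member_ids: {sorted(extra)[:5]}")


@dataclass(frozen=True)
class GeneTissueSummary:
    """Per (gene, target tissue) reduction: target TPM, max/median of the rest."""

    gene: str
    target_tissue: str
    target_tpm: float
    max_other: float
    median_other: float

    def __post_init__(self) -> None:
        vals = (self.target_tpm, self.max_other, self.median_other)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite summary for {self.gene}: {vals}")
        if self.median_other < 0 or self.max_other < self.median_other:
            raise ValueError(
                f"require max_other >= median_other >= 0, got "
                f"{self.max_other}/{self.median_other} for {self.gene}"
            )


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_gct(
    path: str | Path,
    database_name: str | None = None,
    na_action: str = "drop",
) -> ExpressionPanel:
    """Read a GCT 1.2 expression matrix.

    The format: a ``#1.2`` version line, a ``<rows>\\t<cols>`` count line, a
    header ``Name\\tDescription\\t<tissue...>`` and one row per gene.  The
    Description column is stored as the gene symbol.

    ``na_action`` controls missing cells: ``"drop"`` removes the gene with a
    warning (default), ``"zero"`` imputes 0, ``"error"`` rejects the file.
    """
    path = Path(path)
    name = database_name or path.stem.removesuffix(".gct")
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise PanelFormatError(f"expected GCT version line '#1.2', got {lines[0]!r}" if lines else "empty file", line=1)
    try:
        n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise PanelFormatError(f"malformed count line {lines[1]!r}", line=2) from None
    header = lines[2].split("\t")
    if len(header) < 3 or header[0] != "Name" or header[1] != "Description":
        raise PanelFormatError("header must start with Name\\tDescription", line=3)
    tissues = header[2:]
    if len(tissues) != n_cols:
        raise PanelFormatError(
            f"declared {n_cols} data columns but header has {len(tissues)}", line=3
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise PanelFormatError(
            f"declared {n_rows} rows but found {len(body)}", line=4 + len(body)
        )
    return _assemble_panel(name, body, tissues, path, first_line=4,
                           has_description=True, na_action=na_action)


def read_tsv_matrix(
    path: str | Path,
    database_name: str | None = None,
    na_action: str = "drop",
) -> ExpressionPanel:
    """Read a plain TSV matrix: first column gene IDs, header row tissue labels.

    Gene symbols default to the gene IDs.
    """
    path = Path(path)
    name = database_name or path.stem
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise PanelFormatError("empty file", line=1)
    header = lines[0].split("\t")
    tissues = header[1:]
    if not tissues:
        raise PanelFormatError("no tissue columns in header", line=1)
    body = [ln for ln in lines[1:] if ln.strip()]
    return _assemble_panel(name, body, tissues, path, first_line=2,
                           has_description=False, na_action=na_action)


_NA_TOKENS = {"", "na", "nan", "null", "none"}


def _assemble_panel(
    name: str,
    body: list[str],
    tissues: list[str],
    path: Path,
    first_line: int,
    has_description: bool,
    na_action: str,
) -> ExpressionPanel:
    if na_action not in {"drop", "zero", "error"}:
        raise ValueError(f"na_action must be drop/zero/error, got {na_action!r}")
    skip = 2 if has_description else 1
    gene_ids: list[str] = []
    symbols: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    dropped: list[str] = []
    for offset, ln in enumerate(body):
        lineno = first_line + offset
        parts = ln.split("\t")
        if len(parts) != skip + len(tissues):
            raise PanelFormatError(
                f"expected {skip + len(tissues)} fields, got {len(parts)}", line=lineno
            )
        gid = parts[0]
        if gid in seen:
            raise PanelFormatError(f"duplicate gene id {gid!r}", line=lineno)
        row: list[float] = []
        has_na = False
        for j, cell in enumerate(parts[skip:]):
            if cell.strip().lower() in _NA_TOKENS:
                if na_action == "error":
                    raise PanelFormatError(
                        f"missing value at row {gid!r}, column {tissues[j]!r}",
                        line=lineno,
                    )
                has_na = True
                row.append(0.0)
                continue
            try:
                v = float(cell)
            except ValueError:
                raise PanelFormatError(
                    f"non-numeric cell {cell!r} at row {gid!r}, column {tissues[j]!r}",
                    line=lineno,
                ) from None
            if not np.isfinite(v) or v < 0:
                raise PanelFormatError(
                    f"invalid TPM {cell!r} at row {gid!r}, column {tissues[j]!r}",
                    line=lineno,
                )
            row.append(v)
        if has_na and na_action == "drop":
            dropped.append(gid)
            continue
        seen.add(gid)
        gene_ids.append(gid)
        symbols.append(parts[1] if has_description else gid)
        rows.append(row)
    if dropped:
        logger.warning(
            "%s: dropped %d gene(s) with missing values (first: %s)",
            path, len(dropped), dropped[0],
        )
    values = np.array(rows, dtype=float).reshape(len(gene_ids), len(tissues))
    return ExpressionPanel(name, gene_ids, symbols, list(tissues), values)


def _fmt(v: float) -> str:
    """Decimal formatting that preserves short inputs ('0', '4.25', '109.3')."""
    v = float(v)
    if v == int(v):
        return str(int(v))
    s = f"{v:.10f}".rstrip("0")
    # fall back to repr for values that need more than 10 decimals
    return s if float(s) == v else repr(v)


def write_gct(panel: ExpressionPanel, path: str | Path) -> None:
    """Write a panel as GCT 1.2 (UTF-8, tab-separated)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{panel.n_genes}\t{panel.n_tissues}\n")
        fh.write("Name\tDescription\t" + "\t".join(panel.tissue_labels) + "\n")
        for gid, sym, row in zip(panel.gene_ids, panel.gene_symbols, panel.values):
            fh.write(gid + "\t" + sym + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_tsv(panel: ExpressionPanel, path: str | Path) -> None:
    """Write a panel as a plain TSV matrix (gene column + tissue columns)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(panel.tissue_labels) + "\n")
        for gid, row in zip(panel.gene_ids, panel.values):
            fh.write(gid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_family_list(path: str | Path) -> GeneFamilyList:
    """Read a gene-family list: one ID per line, or two-column TSV (id, symbol)."""
    members: set[str] = set()
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            members.add(parts[0])
            if len(parts) > 1 and parts[1]:
                mapping[parts[0]] = parts[1]
    return GeneFamilyList(members, mapping)


def write_family_list(family: GeneFamilyList, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gid in sorted(family.member_ids):
            sym = family.id_to_symbol.get(gid, "")
            fh.write(f"{gid}\t{sym}\n" if sym else f"{gid}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def subset_to_family(
    panel: ExpressionPanel, family: GeneFamilyList
) -> tuple[ExpressionPanel, list[str]]:
    """Restrict a panel to family members, preserving panel order.

    Returns the restricted panel and the family members not found in the
    panel (the databases carry 709-718 of ~700+ family genes each, so some
    members are routinely absent).  Raises if the intersection is empty.
    """
    keep = [i for i, g in enumerate(panel.gene_ids) if g in family.member_ids]
    if not keep:
        raise ValueError(
            f"no family members found in panel {panel.database_name!r}; "
            "the screen would be vacuous"
        )
    present = {panel.gene_ids[i] for i in keep}
    unmatched = sorted(family.member_ids - present)
    sub = ExpressionPanel(
        panel.database_name,
        [panel.gene_ids[i] for i in keep],
        [panel.gene_symbols[i] for i in keep],
        list(panel.tissue_labels),
        panel.values[keep],
    )
    return sub, unmatched


def summarize_gene(
    panel: ExpressionPanel, gene: str, target_tissue: str
) -> GeneTissueSummary:
    """Reduce one gene to (target TPM, max over others, median over others).

    The median of an even count of tissues is the mean of the two central
    values — the convention behind printed half-values like 4.25.
    """
    if panel.n_tissues < 2:
        raise ValueError("summary requires at least 2 tissues")
    vec = panel.gene_vector(gene)
    t = panel.tissue_index(target_tissue)
    others = np.delete(vec, t)
    return GeneTissueSummary(
        gene=gene,
        target_tissue=target_tissue,
        target_tpm=float(vec[t]),
        max_other=float(others.max()),
        median_other=float(statistics.median(others.tolist())),
    )


def summarize_panel(
    panel: ExpressionPanel, target_tissue: str, genes: Sequence[str] | None = None
) -> dict[str, GeneTissueSummary]:
    """summarize_gene for every gene (or a subset), keyed by gene id."""
    genes = list(genes) if genes is not None else panel.gene_ids
    return {g: summarize_gene(panel, g, target_tissue) for g in genes}
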