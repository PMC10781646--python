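"""Quality control, library-size normalization and gene exclusion lists.

QC keeps cells with more than ``min_genes`` detected genes, more than
``min_umi`` total counts and less than ``max_mito_frac`` mitochondrial
content (all strict).  Normalization scales each cell to a total of 10,000
counts and applies ln(x+1).  Exclusion policies remove gene categories
(ribosomal, mitochondrial, unlabelled, dissociation-induced, cell-cycle,
globally overabundant, rarely detected) before signature or programme
analysis.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io import Compendium, NORMALIZED_TOTAL, packaged_gene_list

log = logging.getLogger("immunedict")


@dataclass(frozen=True)
class QcThresholds:
    """Cell-level QC cut-offs; all comparisons are strict inequalities."""

    min_genes: int = 500
    min_umi: int = 1000
    max_mito_frac: float = 0.10

    def __post_init__(self):
        if self.min_genes <= 0 or self.min_umi <= 0:
            raise ValueError("min_genes and min_umi must be positive")
        if not (0 < self.max_mito_frac <= 1):
            raise ValueError("max_mito_frac must be in (0, 1]")


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which gene categories to drop, and how each category is recognized.

    Ribosomal genes match the Rps*/Rpl* prefixes, mitochondrial genes the
    ``mt-`` prefix (mouse dialect), and "unlabelled" genes are predicted
    models / *Rik clones matched by configurable regular expressions.
    Dissociation-induced and cell-cycle genes come from packaged lists.
    Globally overabundant genes (top ``overabundant_q`` fraction of total
    counts) are off by default.  ``min_cells_expressed=0`` disables the
    rare-gene filter.
    """

    ribosomal: bool = True
    mitochondrial: bool = True
    unlabelled: bool = True
    dissociation: bool = False
    cell_cycle: bool = False
    overabundant: bool = False
    min_cells_expressed: int = 0
    mito_prefix: str = "mt-"
    unlabelled_patterns: tuple[str, ...] = (r"^Gm\d+$", r"Rik$")
    overabundant_q: float = 0.001
    dissociation_genes: tuple[str, ...] = field(default=None)
    cell_cycle_genes: tuple[str, ...] = field(default=None)

    def __post_init__(self):
        if self.dissociation_genes is None:
            object.__setattr__(self, "dissociation_genes",
                               tuple(packaged_gene_list("dissociation_genes.txt")))
        if self.cell_cycle_genes is None:
            object.__setattr__(self, "cell_cycle_genes",
                               tuple(packaged_gene_list("cell_cycle_genes.txt")))

    @classmethod
    def for_signatures(cls) -> "ExclusionPolicy":
        """Categories excluded from DEG signatures: ribosomal,
        mitochondrial and unlabelled genes."""
        return cls(ribosomal=True, mitochondrial=True, unlabelled=True)

    @classmethod
    def for_programs(cls) -> "ExclusionPolicy":
        """Stricter set used before NMF: additionally drops
        dissociation-induced, cell-cycle, overabundant and <10-cell genes."""
        return cls(ribosomal=True, mitochondrial=True, unlabelled=True,
                   dissociation=True, cell_cycle=True, overabundant=True,
                   min_cells_expressed=10)

    @classmethod
    def for_polarization(cls) -> "ExclusionPolicy":
        """Discriminating-gene selection drops dissociation, cell-cycle,
        mitochondrial and ribosomal genes."""
        return cls(ribosomal=True, mitochondrial=True, unlabelled=True,
                   dissociation=True, cell_cycle=True)


def _is_mito(genes, prefix: str) -> np.ndarray:
    return np.array([g.startswith(prefix) for g in genes])


def qc_filter(raw: Compendium, thresholds: QcThresholds | None = None,
              mito_prefix: str = "mt-") -> Compendium:
    """Drop cells failing the QC thresholds (strict inequalities).

    Raises if no cell survives, reporting per-criterion attrition.
    """
    t = thresholds or QcThresholds()
    if raw.normalized:
        raise ValueError("qc_filter expects raw counts")
    X = sp.csr_matrix(raw.X)
    genes_per_cell = X.getnnz(axis=1)
    umi = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = _is_mito(raw.genes, mito_prefix)
    mito_counts = (np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
                   if mito_mask.any() else np.zeros(raw.n_cells))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito_counts / np.maximum(umi, 1), 1.0)

    pass_genes = genes_per_cell > t.min_genes
    pass_umi = umi > t.min_umi
    pass_mito = mito_frac < t.max_mito_frac
    keep = pass_genes & pass_umi & pass_mito
    if not keep.any():
        raise ValueError(
            "no cells pass QC: "
            f"{int((~pass_genes).sum())} fail genes>{t.min_genes}, "
            f"{int((~pass_umi).sum())} fail UMI>{t.min_umi}, "
            f"{int((~pass_mito).sum())} fail mito<{t.max_mito_frac}"
        )
    log.info("qc_filter: kept %d/%d cells", int(keep.sum()), raw.n_cells)
    return raw.subset_cells(keep)


def normalize_log(raw: Compendium, total: float = NORMALIZED_TOTAL) -> Compendium:
    """Scale each cell to ``total`` counts and apply the natural log1p."""
    if raw.normalized:
        return raw
    X = sp.csr_matrix(raw.X, dtype=float)
    sums = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize all-zero cells: {list(raw.cells[zero[:5]])}"
        )
    scale = sp.diags(total / sums)
    X = scale @ X
    X.data = np.log1p(X.data)
    return replace(raw, X=sp.csr_matrix(X), normalized=True)


def apply_exclusions(genes, policy: ExclusionPolicy,
                     expr=None) -> list[str]:
    """Return the genes retained under ``policy``; removals are logged per
    category.  ``expr`` (cells x genes, aligned with ``genes``) is required
    when ``min_cells_expressed`` or ``overabundant`` is active."""
    genes = list(genes)
    if not genes:
        return []
    removed: dict[str, int] = {}
    drop = np.zeros(len(genes), dtype=bool)

    def flag(mask, label):
        mask = np.asarray(mask, dtype=bool)
        removed[label] = int((mask & ~drop).sum())
        return mask

    if policy.ribosomal:
        drop |= flag([g.startswith(("Rps", "Rpl")) for g in genes], "ribosomal")
    if policy.mitochondrial:
        drop |= flag([g.startswith(policy.mito_prefix) for g in genes],
                     "mitochondrial")
    if policy.unlabelled:
        pats = [re.compile(p) for p in policy.unlabelled_patterns]
        drop |= flag([any(p.search(g) for p in pats) for g in genes],
                     "unlabelled")
    if policy.dissociation:
        dis = set(policy.dissociation_genes)
        drop |= flag([g in dis for g in genes], "dissociation")
    if policy.cell_cycle:
        cc = set(policy.cell_cycle_genes)
        drop |= flag([g in cc for g in genes], "cell_cycle")
    if policy.overabundant or policy.min_cells_expressed > 0:
        if expr is None:
            raise ValueError("expression matrix required for expression-based "
                             "exclusion criteria")
        M = expr.tocsc() if sp.issparse(expr) else sp.csc_matrix(np.asarray(expr))
        if M.shape[1] != len(genes):
            raise ValueError("expr column count does not match gene list")
        if policy.min_cells_expressed > 0:
            n_cells_expr = M.getnnz(axis=0)
            drop |= flag(n_cells_expr < policy.min_cells_expressed, "rare")
        if policy.overabundant:
            totals = np.asarray(M.sum(axis=0)).ravel()
            k = max(1, int(np.ceil(policy.overabundant_q * len(genes))))
            cut = np.sort(totals)[-k]
            drop |= flag(totals >= cut, "overabundant")

    kept = [g for g, d in zip(genes, drop) if not d]
    log.info("apply_exclusions: removed %s of %d genes",
             {k: v for k, v in removed.items() if v}, len(genes))
    if not kept:
        warnings.warn("exclusion policy removed every gene")
    return kept
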