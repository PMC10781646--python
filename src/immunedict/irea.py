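"""Immune Response Enrichment Analysis (IREA).

Scores user expression data against a reference perturbational compendium.
For a gene-set query, per-cell set scores in the reference are compared
between each cytokine's cells and PBS controls (rank-sum), or the set's
overlap with each cytokine's significant DEGs is tested hypergeometrically.
For an expression-matrix query, the user's differential vector (condition
mean minus control mean, on the log-normalized scale) is projected onto
every reference cell's PBS-centred profile by cosine similarity; the
projection scores of cytokine-treated versus PBS-treated reference cells
are compared by rank-sum test, with the mean difference as effect size and
BH FDR across the cytokine panel.  The same machinery scores polarization
states and assembles cell-cell communication networks from per-cell-type
results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import Compendium, CytokineCatalog
from .polarization import PolarizationState
from .signatures import differential_expression, gene_set_score
from .stats import bh_fdr, hypergeom_sf, rank_sum_p

log = logging.getLogger("immunedict")

MIN_REFERENCE_EXPR = 0.25
MIN_SHARED_GENES = 10
NETWORK_FDR = 0.01
RECEPTOR_THRESHOLD = 0.05
PRODUCTION_THRESHOLD = 0.1


@dataclass
class IreaResult:
    """Per-cytokine enrichment of a user query in one cell type."""

    cell_type: str
    table: pd.DataFrame  # cytokine, effect_size, p, fdr, direction, ...
    contributions: dict[str, pd.Series] = field(default_factory=dict)

    def top_cytokine(self) -> str:
        return self.table.sort_values("effect_size", ascending=False
                                      ).iloc[0]["cytokine"]


def _per_cell_scores_test(comp: Compendium, cell_type: str,
                          scores: pd.Series) -> pd.DataFrame:
    pbs = scores[comp.mask(cell_type=cell_type, condition=comp.control)]
    rows = []
    for ck in comp.cytokines:
        treated = scores[comp.mask(cell_type=cell_type, condition=ck)]
        if treated.size < 2 or pbs.size < 2:
            continue
        effect = float(treated.mean() - pbs.mean())
        rows.append(dict(cytokine=ck, effect_size=effect,
                         p=rank_sum_p(treated.to_numpy(), pbs.to_numpy()),
                         direction="condition" if effect >= 0 else "control"))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def irea_geneset(gene_set, reference: Compendium, cell_type: str,
                 mode: str = "score", deg_fdr: float = 0.01) -> IreaResult:
    """Enrichment of a gene set across the reference cytokine panel.

    ``mode="score"``: rank-sum test of per-cell summed set expression,
    cytokine-treated vs PBS-treated reference cells.
    ``mode="hypergeometric"``: upper-tail overlap of the set with each
    cytokine's significant DEGs (FDR < ``deg_fdr``), universe = all
    reference genes.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    if cell_type not in reference.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if mode == "score":
        scores = gene_set_score(reference, genes)
        table = _per_cell_scores_test(reference, cell_type, scores)
        return IreaResult(cell_type=cell_type, table=table)
    if mode != "hypergeometric":
        raise ValueError(f"unknown mode {mode!r}")
    universe = set(reference.genes)
    query = set(genes) & universe
    rows = []
    for ck in reference.cytokines:
        stats = differential_expression(reference, cell_type, ck)
        degs = {s.gene for s in stats if s.fdr < deg_fdr}
        k = len(query & degs)
        rows.append(dict(cytokine=ck, overlap=k, n_degs=len(degs),
                         effect_size=float(k),
                         p=hypergeom_sf(k, len(universe), len(degs),
                                        len(query)),
                         direction="condition"))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return IreaResult(cell_type=cell_type, table=table)


def _as_matrix(data, genes=None) -> pd.DataFrame:
    """Coerce user input (DataFrame cells x genes, or Series) to a frame."""
    if isinstance(data, pd.Series):
        return data.to_frame().T
    if isinstance(data, pd.DataFrame):
        return data
    if genes is None:
        raise ValueError("gene names required for array input")
    return pd.DataFrame(np.atleast_2d(np.asarray(data)), columns=list(genes))


def _cosine_rows(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1) * np.linalg.norm(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (M @ v) / norms
    return np.where(norms > 0, sims, 0.0)


def irea_transcriptome(user_condition, user_control, reference: Compendium,
                       cell_type: str, min_expr: float = MIN_REFERENCE_EXPR,
                       center: bool = True,
                       n_contributions: int = 20) -> IreaResult:
    """Expression-matrix IREA via cosine projection scores.

    ``user_condition`` / ``user_control`` are cells x genes frames on the
    same log-normalized scale as the reference (totals 10,000, then log1p);
    they are averaged to a single differential vector.  Genes must be shared
    with the reference and exceed ``min_expr`` average reference expression;
    fewer than 10 surviving genes is an error.  Each reference cell of the
    chosen cell type is centred by the PBS mean of that cell type (so both
    vectors are differentials), the cosine of the user differential with
    each cell is taken as the projection score, and cytokine-treated scores
    are compared with PBS-treated scores by rank-sum test, with the mean
    difference as the (signed) effect size and BH FDR across cytokines.
    Per-gene contribution weights (product of user and reference mean
    differential components) accompany each cytokine.
    """
    cond = _as_matrix(user_condition)
    ctrl = _as_matrix(user_control)
    if cell_type not in reference.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}")
    shared = reference.genes.intersection(cond.columns).intersection(ctrl.columns)
    ct_mask = reference.mask(cell_type=cell_type)
    ref_mean = pd.Series(
        np.asarray(reference.X[ct_mask].mean(axis=0)).ravel(),
        index=reference.genes,
    )
    shared = pd.Index([g for g in shared if ref_mean[g] > min_expr])
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} shared genes above the expression filter; "
            f"need at least {MIN_SHARED_GENES}"
        )
    user_diff = (cond[shared].mean(axis=0) - ctrl[shared].mean(axis=0)).to_numpy()
    if not np.any(user_diff):
        warnings.warn("user condition equals control; all scores are zero")

    R = reference.subset_cells(ct_mask).subset_genes(shared)
    M = R.dense()
    if center:
        pbs_mean = M[R.mask(condition=R.control)].mean(axis=0)
        M = M - pbs_mean
    scores = pd.Series(_cosine_rows(M, user_diff), index=R.cells)
    table = _per_cell_scores_test(R, cell_type, scores)

    contributions = {}
    for ck in table["cytokine"]:
        ref_diff = (M[R.mask(condition=ck)].mean(axis=0)
                    - M[R.mask(condition=R.control)].mean(axis=0))
        w = pd.Series(user_diff * ref_diff, index=shared)
        contributions[ck] = w.reindex(w.abs().sort_values(ascending=False)
                                      .index[:n_contributions])
    return IreaResult(cell_type=cell_type, table=table,
                      contributions=contributions)


@dataclass
class PolarizationEnrichment:
    cell_type: str
    table: pd.DataFrame  # state, effect_size, p, fdr, normalized_es
    polarized: bool      # False when no state is significant


def irea_polarization(user_condition, user_control,
                      reference: Compendium,
                      states: list[PolarizationState], cell_type: str,
                      min_expr: float = MIN_REFERENCE_EXPR,
                      alpha: float = 0.05) -> PolarizationEnrichment:
    """Polarization-state enrichment with the projection-score machinery.

    Each state's member cells play the treated group and the remaining
    cells of the cell type the control group.  When at least one state is
    significant (FDR < ``alpha``) the enrichment scores are clipped at zero
    and divided by their maximum so they lie in [0, 1]; otherwise every
    normalized score is zero (an unpolarized radar).
    """
    states = [s for s in states if s.cell_type == cell_type]
    if not states:
        return PolarizationEnrichment(cell_type=cell_type,
                                      table=pd.DataFrame(), polarized=False)
    cond = _as_matrix(user_condition)
    ctrl = _as_matrix(user_control)
    ct_mask = reference.mask(cell_type=cell_type)
    ref_mean = pd.Series(
        np.asarray(reference.X[ct_mask].mean(axis=0)).ravel(),
        index=reference.genes,
    )
    shared = reference.genes.intersection(cond.columns).intersection(ctrl.columns)
    shared = pd.Index([g for g in shared if ref_mean[g] > min_expr])
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError("too few shared genes above the expression filter")
    user_diff = (cond[shared].mean(axis=0) - ctrl[shared].mean(axis=0)).to_numpy()

    R = reference.subset_cells(ct_mask).subset_genes(shared)
    M = R.dense()
    pbs_mean = M[R.mask(condition=R.control)].mean(axis=0)
    M = M - pbs_mean
    scores = pd.Series(_cosine_rows(M, user_diff), index=R.cells)

    rows = []
    for s in states:
        member = np.isin(R.cells, s.cells)
        inside, outside = scores[member], scores[~member]
        if inside.size < 2 or outside.size < 2:
            continue
        rows.append(dict(state=s.id,
                         effect_size=float(inside.mean() - outside.mean()),
                         p=rank_sum_p(inside.to_numpy(), outside.to_numpy())))
    table = pd.DataFrame(rows)
    if table.empty:
        return PolarizationEnrichment(cell_type=cell_type, table=table,
                                      polarized=False)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    polarized = bool((table["fdr"] < alpha).any())
    if polarized:
        clipped = table["effect_size"].clip(lower=0.0)
        top = clipped.max()
        table["normalized_es"] = clipped / top if top > 0 else 0.0
    else:
        table["normalized_es"] = 0.0
    return PolarizationEnrichment(cell_type=cell_type, table=table,
                                  polarized=polarized)


@dataclass
class CommunicationNetwork:
    producer_edges: pd.DataFrame  # source cell type -> cytokine
    responder_edges: pd.DataFrame  # cytokine -> target cell type
    receptor_flags: pd.DataFrame   # per (cell type, cytokine) bool


def build_communication_network(results: dict[str, IreaResult],
                                user_expression: pd.DataFrame,
                                catalog: CytokineCatalog,
                                production_threshold: float = PRODUCTION_THRESHOLD,
                                receptor_threshold: float = RECEPTOR_THRESHOLD,
                                fdr_max: float = NETWORK_FDR,
                                ) -> CommunicationNetwork:
    """Cell-cell communication network from per-cell-type IREA results.

    ``user_expression`` is a cell type x gene table of mean log-normalized
    expression in the user data.  Producer edges need any ligand subunit
    above ``production_threshold`` (heteromers asterisked); responder edges
    need IREA FDR < ``fdr_max`` with positive effect size; receptor flags
    use the dedicated ``receptor_threshold``.
    """
    producers, receptor_rows = [], []
    for ct in user_expression.index:
        expr = user_expression.loc[ct]
        for ck in catalog:
            present = [g for g in ck.ligand_genes if g in expr.index]
            if present and max(expr[g] for g in present) > production_threshold:
                producers.append(dict(source=ct, cytokine=ck.name,
                                      asterisk=ck.multimeric))
            receptor_ok = any(
                all(g in expr.index and expr[g] > receptor_threshold
                    for g in option)
                for option in ck.receptor_options
            )
            receptor_rows.append(dict(cell_type=ct, cytokine=ck.name,
                                      receptor_expressed=receptor_ok))
    responders = []
    for ct, res in results.items():
        if res.table.empty:
            continue
        hits = res.table[(res.table["fdr"] < fdr_max)
                         & (res.table["effect_size"] > 0)]
        for _, row in hits.iterrows():
            star = (row["cytokine"] in catalog
                    and catalog[row["cytokine"]].multimeric)
            responders.append(dict(cytokine=row["cytokine"], target=ct,
                                   fdr=row["fdr"],
                                   effect_size=row["effect_size"],
                                   asterisk=star))
    return CommunicationNetwork(
        producer_edges=pd.DataFrame(producers),
        responder_edges=pd.DataFrame(responders),
        receptor_flags=pd.DataFrame(receptor_rows),
    )


def load_homolog_table() -> pd.DataFrame:
    """The packaged synthetic mouse<->human homolog subset."""
    with resources.as_file(
        resources.files("immunedict.data") / "homolog_map_subset.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def map_homologs(genes, from_species: str, to_species: str,
                 table: pd.DataFrame | None = None):
    """Map symbols between species using a two-column homolog table.

    Only one-to-one mappings are applied; one-to-many pairs are dropped
    with a warning.  Returns ``(mapped, unmapped)`` where ``mapped`` is a
    dict from input symbol to target symbol.
    """
    species = {"mouse", "human"}
    if from_species not in species or to_species not in species:
        raise ValueError(f"species must be one of {sorted(species)}")
    genes = list(genes)
    if from_species == to_species:
        return {g: g for g in genes}, []
    table = load_homolog_table() if table is None else table
    src, dst = from_species, to_species
    tab = table[[src, dst]].dropna()
    ambiguous = set(tab[src][tab[src].duplicated(keep=False)])
    ambiguous |= set(tab[src][tab[dst].isin(
        tab[dst][tab[dst].duplicated(keep=False)])])
    if ambiguous & set(genes):
        warnings.warn(f"dropping one-to-many mappings: "
                      f"{sorted(ambiguous & set(genes))[:5]}")
    lookup = {r[src]: r[dst] for _, r in tab.iterrows()
              if r[src] not in ambiguous}
    mapped = {g: lookup[g] for g in genes if g in lookup}
    unmapped = [g for g in genes if g not in lookup]
    return mapped, unmapped
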