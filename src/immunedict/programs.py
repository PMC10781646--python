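"""Gene programmes by non-negative matrix factorization.

Cytokine-centric programmes (default k=40) factorize cells from one
cytokine treatment plus PBS controls across all cell types; cell-type-
centric programmes (default k=10) factorize one cell type across all
conditions.  A programme's per-cell weights are tested between treated and
control cells with the rank-sum kernel, and its top-weighted genes feed a
generic hypergeometric over-representation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .io import Compendium, GeneSetCollection
from .preprocess import ExclusionPolicy, apply_exclusions
from .stats import bh_fdr, hypergeom_sf, rank_sum_p

log = logging.getLogger("immunedict")

CYTOKINE_CENTRIC_K = 40
CELLTYPE_CENTRIC_K = 10
EFFECT_SIZE_CAP = 10.0
TOP_GENES_DEFAULT = 30


@dataclass
class GeneProgram:
    """One NMF factor: non-negative gene loadings plus per-cell weights."""

    id: str
    loadings: pd.Series   # gene -> weight
    cell_weights: pd.Series  # cell -> weight
    stats: pd.DataFrame | None = None  # per-cell-type significance


def _sample_groups(comp: Compendium, max_per_group: int, seed: int):
    """Indices of at most ``max_per_group`` cells per (cell type, condition)."""
    rng = np.random.default_rng(seed)
    picked = []
    grouped = comp.meta.groupby(["cell_type", "condition"], sort=True,
                                observed=True)
    for _, grp in grouped:
        idx = comp.cells.get_indexer(grp.index)
        if idx.size > max_per_group:
            idx = rng.choice(idx, size=max_per_group, replace=False)
        picked.append(np.sort(idx))
    return np.concatenate(picked) if picked else np.array([], dtype=int)


def fit_programs(comp: Compendium, k: int, seed: int = 0,
                 policy: ExclusionPolicy | None = None,
                 max_cells_per_group: int = 100,
                 max_iter: int = 500) -> tuple[list[GeneProgram], float]:
    """Fit ``k`` programmes on the (sampled, gene-filtered) compendium.

    Deterministic for a fixed seed (NNDSVD-ar initialization).  Returns the
    programmes and the relative Frobenius reconstruction error.
    """
    if not comp.normalized:
        raise ValueError("fit_programs expects normalized data")
    policy = policy or ExclusionPolicy.for_programs()
    idx = _sample_groups(comp, max_cells_per_group, seed)
    sub = comp.subset_cells(np.isin(np.arange(comp.n_cells), idx))
    keep_genes = apply_exclusions(list(sub.genes), policy, expr=sub.X)
    sub = sub.subset_genes(keep_genes)
    if k >= min(sub.n_cells, sub.n_genes):
        raise ValueError(
            f"k={k} must be below min(cells, genes) = "
            f"{min(sub.n_cells, sub.n_genes)}"
        )
    X = sub.dense()
    model = NMF(n_components=k, init="nndsvda", solver="cd",
                max_iter=max_iter, random_state=seed, tol=1e-5)
    W = model.fit_transform(X)  # cells x k
    H = model.components_       # k x genes
    # fix the scale indeterminacy: unit-norm loadings, weights carry scale
    norms = np.linalg.norm(H, axis=1)
    nz = norms > 0
    H[nz] /= norms[nz, None]
    W[:, nz] *= norms[nz]
    denom = np.linalg.norm(X)
    rel_err = float(model.reconstruction_err_ / denom) if denom > 0 else 0.0
    programs = [
        GeneProgram(
            id=f"GP{j + 1}",
            loadings=pd.Series(H[j], index=sub.genes),
            cell_weights=pd.Series(W[:, j], index=sub.cells),
        )
        for j in range(k)
    ]
    log.info("fit_programs: k=%d on %d cells x %d genes, rel err %.4f",
             k, sub.n_cells, sub.n_genes, rel_err)
    return programs, rel_err


def fit_cytokine_programs(comp: Compendium, cytokine, k: int = CYTOKINE_CENTRIC_K,
                          **kwargs):
    """Cytokine-centric programmes: the treatment (or a group of treatments
    processed jointly, e.g. the two type I interferons) plus PBS controls,
    across all cell types."""
    conds = [cytokine] if isinstance(cytokine, str) else list(cytokine)
    mask = comp.meta["condition"].isin(conds + [comp.control]).to_numpy()
    return fit_programs(comp.subset_cells(mask), k=k, **kwargs)


def fit_celltype_programs(comp: Compendium, cell_type: str,
                          k: int = CELLTYPE_CENTRIC_K, **kwargs):
    """Cell-type-centric programmes: one cell type across all conditions."""
    mask = comp.mask(cell_type=cell_type)
    return fit_programs(comp.subset_cells(mask), k=k, **kwargs)


def program_significance(programs: list[GeneProgram], meta: pd.DataFrame,
                         control: str = "PBS",
                         effect_cap: float = EFFECT_SIZE_CAP) -> pd.DataFrame:
    """Rank-sum test of programme weights, treated vs control, per cell type.

    Effect size is the difference in mean weight (display value capped at
    ``effect_cap``, raw value retained); FDR is Benjamini-Hochberg across
    all (programme, cell type) pairs.  Cell types with fewer than two cells
    in either group get NA.  The result is also attached to each
    programme's ``stats``.
    """
    rows = []
    for gp in programs:
        m = meta.loc[gp.cell_weights.index]
        for ct in sorted(m["cell_type"].unique()):
            sel = m["cell_type"] == ct
            w = gp.cell_weights[sel.to_numpy()]
            is_ctrl = (m.loc[sel, "condition"] == control).to_numpy()
            treated, ctrl = w[~is_ctrl], w[is_ctrl]
            if len(treated) < 2 or len(ctrl) < 2:
                rows.append(dict(program=gp.id, cell_type=ct,
                                 effect_size=np.nan, p=np.nan))
                continue
            rows.append(dict(
                program=gp.id, cell_type=ct,
                effect_size=float(treated.mean() - ctrl.mean()),
                p=rank_sum_p(treated.to_numpy(), ctrl.to_numpy()),
            ))
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["effect_size_display"] = df["effect_size"].clip(upper=effect_cap)
    for gp in programs:
        gp.stats = df[df["program"] == gp.id].set_index("cell_type")
    return df


def upregulated_programs(significance: pd.DataFrame,
                         effect_min: float = 1.0,
                         fdr_max: float = 0.01) -> list[str]:
    """Programmes counted as cytokine-response programmes: effect size above
    ``effect_min`` at FDR below ``fdr_max`` in at least one cell type."""
    hits = significance[(significance["effect_size"] > effect_min)
                        & (significance["fdr"] < fdr_max)]
    return sorted(hits["program"].unique(),
                  key=lambda s: int(s.lstrip("GP")))


def top_program_genes(gp: GeneProgram, n: int = TOP_GENES_DEFAULT) -> list[str]:
    """The ``n`` highest-loading genes, ties broken lexicographically."""
    order = sorted(gp.loadings.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:n]]


def over_representation(query_genes, collection: GeneSetCollection,
                        universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of the query in each
    set of the collection, with BH FDR across sets."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe is empty")
    uni = set(universe)
    query = set(query_genes) & uni
    dropped = set(query_genes) - uni
    if dropped:
        log.warning("over_representation: %d query genes outside universe",
                    len(dropped))
    N, n = len(uni), len(query)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & uni
        k = len(query & members)
        rows.append(dict(set=name, overlap=k, set_size=len(members),
                         p=hypergeom_sf(k, N, len(members), n)))
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df
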