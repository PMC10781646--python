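"""Cytokine-driven polarization states.

Cells of one cell type are subclustered on discriminating genes (large fold
change versus PBS under any treatment) via PCA, a k-nearest-neighbour graph
and Leiden community detection.  Clusters holding significantly more cells
of a cytokine than expected (upper-tail hypergeometric, BH FDR < 0.01
across all cluster x cytokine pairs) become polarization states; each state
gets rank-sum markers against the rest of its cell type, a PBS-subtracted
differential profile, cross-state similarity (Pearson / up- and down-set
Jaccard / uniqueness / average-linkage dendrogram) and a canonical
"<cell-type>-<letter>" name, with letters a-d reserved for type I
interferon, type II interferon, IL-1 and TNF drivers.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import Compendium
from .preprocess import ExclusionPolicy, apply_exclusions
from .signatures import DeStat, differential_expression
from .stats import bh_fdr, hypergeom_sf, log2_fold_change

log = logging.getLogger("immunedict")

#: reserved letters for the driver classes that polarize many cell types
RESERVED_LETTERS = ("a", "b", "c", "d")
TYPE_I_IFN = frozenset({"IFNα1", "IFNβ", "IFNε", "IFNκ"})
TYPE_II_IFN = frozenset({"IFNγ"})
IL1_CLASS = frozenset({"IL-1α", "IL-1β"})
TNF_CLASS = frozenset({"TNF"})
DRIVER_CLASSES = (TYPE_I_IFN, TYPE_II_IFN, IL1_CLASS, TNF_CLASS)


@dataclass
class PolarizationState:
    """A subcluster enriched for cytokine-treated cells."""

    id: str
    cell_type: str
    cells: pd.Index
    drivers: pd.DataFrame          # cytokine, fdr, p, n_in_cluster
    markers: list[DeStat] = field(default_factory=list)
    differential_profile: pd.Series | None = None  # state mean - PBS mean

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def top_driver(self) -> str:
        return self.drivers.iloc[0]["cytokine"]


def discriminating_genes(comp: Compendium, cell_type: str,
                         fc_threshold: float = 0.75,
                         policy: ExclusionPolicy | None = None) -> list[str]:
    """Genes with |log2FC| above ``fc_threshold`` versus PBS in at least one
    cytokine, after category exclusions.  Raises when the result is empty."""
    policy = policy or ExclusionPolicy.for_polarization()
    cmask = comp.mask(cell_type=cell_type, condition=comp.control)
    if not cmask.any():
        raise ValueError(f"no PBS cells for cell type {cell_type!r}")
    C = comp.dense(cmask)
    max_abs = np.zeros(comp.n_genes)
    for ck in comp.cytokines:
        tmask = comp.mask(cell_type=cell_type, condition=ck)
        if not tmask.any():
            continue
        lfc = log2_fold_change(comp.dense(tmask), C)
        max_abs = np.maximum(max_abs, np.abs(lfc))
    candidates = [g for g, m in zip(comp.genes, max_abs) if m > fc_threshold]
    kept = apply_exclusions(candidates, policy)
    if not kept:
        raise ValueError(
            f"no discriminating genes at |log2FC| > {fc_threshold}; "
            "try a lower threshold"
        )
    return kept


def subcluster(comp_subset: Compendium, n_pcs: int = 20,
               resolution: float = 0.5, n_neighbors: int = 20,
               seed: int = 0) -> np.ndarray:
    """Leiden clustering of cells on a kNN graph of principal components.

    Deterministic for a fixed seed; singleton clusters are merged into the
    cluster with the nearest centroid.
    """
    n = comp_subset.n_cells
    if n <= n_pcs:
        raise ValueError(f"need more cells ({n}) than principal components "
                         f"({n_pcs})")
    X = comp_subset.dense()
    X = X - X.mean(axis=0)
    n_comp = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full",
              random_state=seed).fit_transform(X)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, nbrs = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(nbrs)
             for j in row if i != j}
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    return _merge_singletons(labels, pcs)


def _merge_singletons(labels: np.ndarray, coords: np.ndarray) -> np.ndarray:
    labels = labels.copy()
    sizes = pd.Series(labels).value_counts()
    big = sizes[sizes > 1].index.to_numpy()
    if big.size == 0 or big.size == sizes.size:
        return _relabel(labels)
    centroids = np.vstack([coords[labels == c].mean(axis=0) for c in big])
    for c in sizes[sizes == 1].index:
        i = int(np.flatnonzero(labels == c)[0])
        labels[i] = big[np.argmin(np.linalg.norm(centroids - coords[i], axis=1))]
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 0..K-1 in decreasing size order (ties by first
    appearance), so labels are stable across runs."""
    order = pd.Series(labels).value_counts(sort=True).index
    mapping = {old: new for new, old in enumerate(order)}
    return np.asarray([mapping[l] for l in labels])


def call_states(labels, condition_labels, cell_type: str = "",
                control: str = "PBS", alpha: float = 0.01,
                cells: pd.Index | None = None) -> list[PolarizationState]:
    """Hypergeometric enrichment of cytokine-treated cells in each cluster.

    For every (cluster, cytokine) pair: population = all cells of the type,
    marked = that cytokine's cells, draws = the cluster.  BH correction runs
    across all pairs within the cell type; clusters with any driver below
    ``alpha`` become states (ids assigned later by :func:`name_states`).
    """
    labels = np.asarray(labels)
    conditions = np.asarray(condition_labels)
    if cells is None:
        cells = pd.Index([f"cell{i}" for i in range(len(labels))])
    N = len(labels)
    cytokines = sorted(set(conditions) - {control})
    rows = []
    for cl in np.unique(labels):
        in_cl = labels == cl
        for ck in cytokines:
            is_ck = conditions == ck
            k = int((in_cl & is_ck).sum())
            rows.append(dict(cluster=int(cl), cytokine=ck, n_in_cluster=k,
                             p=hypergeom_sf(k, N, int(is_ck.sum()),
                                            int(in_cl.sum()))))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())

    states = []
    for cl, grp in table.groupby("cluster"):
        drivers = grp[grp["fdr"] < alpha].sort_values(["fdr", "p"])
        if drivers.empty:
            continue
        states.append(PolarizationState(
            id=f"{cell_type}-cluster{cl}",
            cell_type=cell_type,
            cells=cells[labels == cl],
            drivers=drivers[["cytokine", "p", "fdr", "n_in_cluster"]]
            .reset_index(drop=True),
        ))
    return states


def state_markers(state: PolarizationState, comp: Compendium,
                  cell_type: str, fdr_max: float = 0.05) -> list[DeStat]:
    """Rank-sum DE of the state's cells against all other cells of the cell
    type, significant genes sorted by descending log2FC."""
    ct_mask = comp.mask(cell_type=cell_type)
    in_state = np.isin(comp.cells, state.cells) & ct_mask
    rest = ct_mask & ~in_state
    if not rest.any():
        raise ValueError("state contains every cell of the cell type")
    if in_state.sum() < 2 or rest.sum() < 2:
        raise ValueError("need >=2 cells in the state and in the rest")
    sub = comp.subset_cells(ct_mask)
    meta = sub.meta.copy()
    meta["condition"] = np.where(np.isin(sub.cells, state.cells),
                                 "state", comp.control)
    labelled = Compendium(X=sub.X, genes=sub.genes, cells=sub.cells,
                          meta=meta, normalized=sub.normalized)
    stats = differential_expression(labelled, cell_type, "state")
    sig = [s for s in stats if s.fdr < fdr_max and s.log2fc > 0]
    markers = sorted(sig, key=lambda s: -s.log2fc)
    state.markers = markers
    return markers


def state_profile(state: PolarizationState, comp: Compendium) -> pd.Series:
    """Differential profile: state mean minus PBS mean (same cell type)."""
    in_state = np.isin(comp.cells, state.cells)
    pbs = comp.mask(cell_type=state.cell_type, condition=comp.control)
    profile = pd.Series(
        comp.dense(in_state).mean(axis=0) - comp.dense(pbs).mean(axis=0),
        index=comp.genes,
    )
    state.differential_profile = profile
    return profile


@dataclass
class StateSimilarity:
    pearson: pd.DataFrame
    jaccard_up: pd.DataFrame
    jaccard_down: pd.DataFrame
    uniqueness: pd.Series
    linkage: np.ndarray

    def to_newick(self) -> str:
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage,
                                            list(self.pearson.index))
        return str(tree)


def jaccard(a, b) -> float:
    """Jaccard index of two sets; two empty sets count as identical."""
    a, b = set(a), set(b)
    union = a | b
    return 1.0 if not union else len(a & b) / len(union)


def state_similarity(states: list[PolarizationState], comp: Compendium,
                     fc_cut: float = 0.5) -> StateSimilarity:
    """Cross-state similarity on PBS-subtracted profiles.

    Pearson correlation of the differential profiles; Jaccard of up- and
    down-regulated gene sets (|log2FC| > ``fc_cut`` versus PBS of the same
    cell type), computed separately; uniqueness = inverse of the mean
    off-diagonal Jaccard (up/down pooled where defined); average-linkage
    dendrogram on Euclidean distances between similarity rows.
    """
    if len(states) < 2:
        raise ValueError("need at least two states")
    ids = [s.id for s in states]
    profiles, ups, downs = [], [], []
    for s in states:
        if s.differential_profile is None:
            state_profile(s, comp)
        profiles.append(s.differential_profile.to_numpy())
        pbs = comp.mask(cell_type=s.cell_type, condition=comp.control)
        lfc = log2_fold_change(comp.dense(np.isin(comp.cells, s.cells)),
                               comp.dense(pbs))
        ups.append({g for g, v in zip(comp.genes, lfc) if v > fc_cut})
        downs.append({g for g, v in zip(comp.genes, lfc) if v < -fc_cut})

    P = np.vstack(profiles)
    with np.errstate(invalid="ignore"):
        pearson = np.corrcoef(P)
    if np.isnan(pearson).any():
        warnings.warn("zero-variance differential profile; Pearson NA")
    n = len(states)
    jup = np.array([[jaccard(ups[i], ups[j]) for j in range(n)]
                    for i in range(n)])
    jdn = np.array([[jaccard(downs[i], downs[j]) for j in range(n)]
                    for i in range(n)])

    uniq = []
    for i in range(n):
        vals = []
        for j in range(n):
            if j == i:
                continue
            if ups[i] or ups[j]:
                vals.append(jup[i, j])
            if downs[i] or downs[j]:
                vals.append(jdn[i, j])
        mean = np.mean(vals) if vals else 0.0
        uniq.append(np.inf if mean == 0 else 1.0 / mean)

    rows = np.nan_to_num(pearson, nan=0.0)
    Z = linkage(pdist(rows, metric="euclidean"), method="average")
    return StateSimilarity(
        pearson=pd.DataFrame(pearson, index=ids, columns=ids),
        jaccard_up=pd.DataFrame(jup, index=ids, columns=ids),
        jaccard_down=pd.DataFrame(jdn, index=ids, columns=ids),
        uniqueness=pd.Series(uniq, index=ids),
        linkage=Z,
    )


def _letters():
    for ch in string.ascii_lowercase:
        yield ch
    for a in string.ascii_lowercase:
        for b in string.ascii_lowercase:
            yield a + b


def name_states(states: list[PolarizationState], cell_type_abbrev: str,
                driver_classes=DRIVER_CLASSES) -> list[PolarizationState]:
    """Assign canonical ids "<abbrev>-<letter>".

    Letters a-d go to the state whose top driver belongs to the respective
    reserved class (type I IFN, type II IFN, IL-1, TNF); when several states
    share a class, the largest takes the letter.  Remaining states get e,
    f, ... in decreasing size order (two-letter suffixes past z).
    """
    assigned: dict[int, str] = {}
    for letter, cls in zip(RESERVED_LETTERS, driver_classes):
        candidates = [i for i, s in enumerate(states)
                      if i not in assigned and s.top_driver in cls]
        if candidates:
            best = max(candidates, key=lambda i: states[i].size)
            assigned[best] = letter
    rest = sorted((i for i in range(len(states)) if i not in assigned),
                  key=lambda i: -states[i].size)
    free = (l for l in _letters() if l not in RESERVED_LETTERS)
    for i in rest:
        assigned[i] = next(free)
    for i, s in enumerate(states):
        s.id = f"{cell_type_abbrev}-{assigned[i]}"
    return states


def find_polarization_states(comp: Compendium, cell_type: str,
                             fc_threshold: float = 0.75,
                             n_pcs: int = 20, resolution: float = 0.5,
                             alpha: float = 0.01, seed: int = 0,
                             abbrev: str | None = None,
                             ) -> list[PolarizationState]:
    """End-to-end state calling for one cell type: discriminating genes ->
    subclustering -> hypergeometric driver calling -> markers, profiles and
    canonical names."""
    genes = discriminating_genes(comp, cell_type, fc_threshold)
    ct_mask = comp.mask(cell_type=cell_type)
    sub = comp.subset_cells(ct_mask).subset_genes(genes)
    labels = subcluster(sub, n_pcs=min(n_pcs, sub.n_cells - 1, len(genes)),
                        resolution=resolution, seed=seed)
    states = call_states(labels, sub.meta["condition"].to_numpy(),
                         cell_type=cell_type, control=comp.control,
                         alpha=alpha, cells=sub.cells)
    for s in states:
        state_markers(s, comp, cell_type)
        state_profile(s, comp)
    return name_states(states, abbrev or cell_type)
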