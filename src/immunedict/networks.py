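"""Cytokine production and receptor maps, and the two cell-cell interactomes.

The production map averages each cytokine's encoding gene(s) per cell type
over all conditions (to capture induced expression), caps means at 1
expression unit, normalizes each cytokine row to its maximum cell type and
flags expression above 0.1 normalized units; cytokines detected in fewer
than 50 cells are dropped.  The ligand-response interactome connects a
producing cell type through a cytokine to every cell type with more than
ten DEGs in the corresponding signature; the ligand-receptor interactome
instead requires the target to express a cognate receptor complex (every
component above threshold, any receptor option sufficing).  Heteromeric
cytokines count as expressed when at least one subunit is, and carry an
asterisk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Compendium, CytokineCatalog

log = logging.getLogger("immunedict")

MIN_CELLS_DETECTED = 50
EXPRESSION_THRESHOLD = 0.1
MIN_DEGS = 10

# strict > comparisons on derived ratios need a guard against float noise
# (e.g. 0.05/0.5 evaluates just above 0.1)
_EPS = 1e-9


def _above(values, threshold):
    return np.asarray(values) > threshold + _EPS


@dataclass
class ProductionMap:
    """Per (cytokine, cell type) production of cytokine transcripts."""

    raw: pd.DataFrame         # cytokine x cell type, mean normalized expr
    normalized: pd.DataFrame  # capped then row-normalized to [0, 1]
    expressed: pd.DataFrame   # normalized > threshold
    n_cells_detected: pd.Series  # per cytokine, cells expressing any subunit
    asterisk: pd.Series       # per cytokine, heteromer flag
    skipped: list[str]        # catalog entries absent from the matrix


def _celltype_means(comp: Compendium) -> pd.DataFrame:
    """Mean expression per cell type (rows) over all conditions."""
    rows = {}
    for ct in comp.cell_types:
        mask = comp.mask(cell_type=ct)
        rows[ct] = np.asarray(comp.X[mask].mean(axis=0)).ravel()
    return pd.DataFrame(rows, index=comp.genes).T  # cell types x genes


def production_map(comp: Compendium, catalog: CytokineCatalog,
                   min_cells: int = MIN_CELLS_DETECTED, cap: float = 1.0,
                   expr_threshold: float = EXPRESSION_THRESHOLD,
                   ) -> ProductionMap:
    """Build the cytokine production map from a normalized compendium."""
    if not comp.normalized:
        raise ValueError("production_map expects normalized data")
    means = _celltype_means(comp)
    raw_rows, n_detected, asterisk, skipped = {}, {}, {}, []
    for ck in catalog:
        present = [g for g in ck.ligand_genes if g in comp.genes]
        if not present:
            skipped.append(ck.name)
            warnings.warn(f"cytokine {ck.name}: no ligand gene in matrix")
            continue
        idx = comp.genes.get_indexer(present)
        detected_cells = int((comp.X[:, idx] > 0).max(axis=1).sum())
        if detected_cells < min_cells:
            continue
        # a heteromer counts via its most-expressed subunit
        raw_rows[ck.name] = means[present].max(axis=1)
        n_detected[ck.name] = detected_cells
        asterisk[ck.name] = ck.multimeric
    raw = pd.DataFrame(raw_rows).T  # cytokine x cell type
    if raw.empty:
        raw = pd.DataFrame(columns=comp.cell_types)
    capped = raw.clip(upper=cap)
    maxes = capped.max(axis=1).replace(0, np.nan)
    normalized = capped.div(maxes, axis=0).fillna(0.0)
    return ProductionMap(
        raw=raw, normalized=normalized,
        expressed=normalized.gt(expr_threshold + _EPS),
        n_cells_detected=pd.Series(n_detected, dtype=int),
        asterisk=pd.Series(asterisk, dtype=bool),
        skipped=skipped,
    )


def receptor_map(comp: Compendium, catalog: CytokineCatalog,
                 threshold: float = EXPRESSION_THRESHOLD) -> pd.DataFrame:
    """Boolean cytokine x cell type table of receptor expression.

    A receptor complex is expressed when every component gene's mean
    normalized expression exceeds ``threshold``; a cytokine is
    receptor-positive when any of its receptor options is expressed.
    Components missing from the matrix count as unexpressed.
    """
    if not comp.normalized:
        raise ValueError("receptor_map expects normalized data")
    means = _celltype_means(comp)
    out = {}
    for ck in catalog:
        flags = {}
        for ct in comp.cell_types:
            expressed = False
            for option in ck.receptor_options:
                if all(g in comp.genes and means.at[ct, g] > threshold + _EPS
                       for g in option):
                    expressed = True
                    break
            flags[ct] = expressed
        out[ck.name] = flags
    return pd.DataFrame(out).T.astype(bool)


@dataclass(frozen=True)
class InteractomeEdge:
    source: str
    cytokine: str
    target: str
    evidence: str          # "response" or "receptor"
    asterisk: bool = False
    n_degs: int | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.cytokine, self.target)


def _deg_count(entry) -> int:
    return entry if isinstance(entry, (int, np.integer)) else entry.n_degs


def response_interactome(production: ProductionMap, signatures,
                         min_degs: int = MIN_DEGS) -> list[InteractomeEdge]:
    """Ligand-response edges: source expresses the cytokine and the target's
    signature has strictly more than ``min_degs`` DEGs.

    ``signatures`` maps (cell_type, cytokine) to a signature object or a
    plain DEG count.
    """
    edges = []
    for ck in production.expressed.index:
        sources = production.expressed.columns[production.expressed.loc[ck]]
        star = bool(production.asterisk.get(ck, False))
        for (ct, sig_ck), sig in signatures.items():
            if sig_ck != ck:
                continue
            n = _deg_count(sig)
            if n > min_degs:
                edges.extend(
                    InteractomeEdge(source=src, cytokine=ck, target=ct,
                                    evidence="response", asterisk=star,
                                    n_degs=n)
                    for src in sources
                )
    return sorted(edges, key=lambda e: e.key)


def receptor_interactome(production: ProductionMap,
                         receptors: pd.DataFrame) -> list[InteractomeEdge]:
    """Ligand-receptor edges: source expresses the cytokine and the target
    expresses a cognate receptor complex.  The production side is identical
    to the ligand-response interactome."""
    edges = []
    common = production.expressed.index.intersection(receptors.index)
    for ck in common:
        sources = production.expressed.columns[production.expressed.loc[ck]]
        star = bool(production.asterisk.get(ck, False))
        targets = receptors.columns[receptors.loc[ck]]
        edges.extend(
            InteractomeEdge(source=src, cytokine=ck, target=tgt,
                            evidence="receptor", asterisk=star)
            for src in sources for tgt in targets
        )
    return sorted(edges, key=lambda e: e.key)


def compare_interactomes(a: list[InteractomeEdge], b: list[InteractomeEdge]):
    """Partition edges (keyed by source, cytokine, target) into those common
    to both networks and those private to each."""
    ka = {e.key for e in a}
    kb = {e.key for e in b}
    return sorted(ka & kb), sorted(ka - kb), sorted(kb - ka)


def edges_to_frame(edges: list[InteractomeEdge]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(source=e.source, cytokine=e.cytokine, asterisk=e.asterisk,
             target=e.target, evidence=e.evidence, n_degs=e.n_degs)
        for e in edges
    ])


def abundance_production_correlation(comp: Compendium,
                                     catalog: CytokineCatalog,
                                     n_cells_per_type: int = 100,
                                     detection_threshold: float = 0.1,
                                     seed: int = 0):
    """Pearson correlation between cell-type abundance and the number of
    cytokine genes the type expresses.

    Abundance is the log10 count of PBS cells per type; detection counts a
    cytokine when any of its ligand genes averages above
    ``detection_threshold`` on an equal-size sample of cells per type.
    Returns ``(r, p)``; p is NaN below three cell types and both are NaN
    when the detection counts are constant.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for ct in comp.cell_types:
        n_pbs = int(comp.mask(cell_type=ct, condition=comp.control).sum())
        if n_pbs == 0:
            continue
        idx = np.flatnonzero(comp.mask(cell_type=ct))
        take = min(n_cells_per_type, idx.size)
        idx = rng.choice(idx, size=take, replace=False)
        means = np.asarray(comp.X[idx].mean(axis=0)).ravel()
        mseries = pd.Series(means, index=comp.genes)
        detected = sum(
            any(g in comp.genes and mseries[g] > detection_threshold
                for g in ck.ligand_genes)
            for ck in catalog
        )
        xs.append(np.log10(n_pbs))
        ys.append(detected)
    xs, ys = np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
    if len(xs) < 2 or np.std(ys) == 0 or np.std(xs) == 0:
        warnings.warn("correlation undefined (constant or too few points)")
        return (np.nan, np.nan)
    r, p = sps.pearsonr(xs, ys)
    if len(xs) < 3:
        p = np.nan
    return (float(r), float(p) if np.isfinite(p) else np.nan)
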