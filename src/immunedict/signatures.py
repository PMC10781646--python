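"""Per-cell-type cytokine response signatures and derived summaries.

A cytokine signature for a (cell type, cytokine) pair is the list of genes
passing, in order: FDR < 0.05 (Benjamini-Hochberg over tested genes),
|log2FC| > 0.25 against PBS controls, expression in >10% of the
direction-appropriate group, fold-change consistency in at least two of the
three replicate animals, and category exclusions (ribosomal, mitochondrial,
unlabelled genes).  On top of the signatures this module computes the 0-100
response-magnitude map (winsorized centroid distances), replicate
concordance, per-cell gene-set scores with ROC-AUC separation, and the
secondary-response analysis that scores every treatment against a donor
cytokine's strict signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Compendium, GeneSetCollection
from .preprocess import ExclusionPolicy, apply_exclusions
from .stats import (bh_fdr, log2_fold_change, pairwise_auc, rank_sum_matrix,
                    rank_sum_p)

log = logging.getLogger("immunedict")

FDR_MAX = 0.05
LOG2FC_MIN = 0.25
PCT_MIN = 0.10
MIN_REPLICATES_PASSING = 2


@dataclass
class DeStat:
    """Differential expression statistics for one gene (cytokine vs PBS)."""

    gene: str
    log2fc: float
    p: float
    fdr: float
    pct_treated: float
    pct_control: float
    n_replicates_passing: int = 0

    @property
    def direction(self) -> str:
        return "up" if self.log2fc >= 0 else "down"


@dataclass
class CytokineSignature:
    """The dictionary's atomic entry: surviving DEGs for one pair."""

    cell_type: str
    cytokine: str
    entries: list[DeStat] = field(default_factory=list)

    @property
    def n_degs(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    @property
    def up_genes(self) -> list[str]:
        return [e.gene for e in self.entries if e.direction == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [e.gene for e in self.entries if e.direction == "down"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(gene=e.gene, log2fc=e.log2fc, p=e.p, fdr=e.fdr,
                 pct_treated=e.pct_treated, pct_control=e.pct_control,
                 n_replicates_passing=e.n_replicates_passing,
                 direction=e.direction, cell_type=self.cell_type,
                 cytokine=self.cytokine)
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def _groups(comp: Compendium, cell_type: str, cytokine: str):
    tmask = comp.mask(cell_type=cell_type, condition=cytokine)
    cmask = comp.mask(cell_type=cell_type, condition=comp.control)
    return tmask, cmask


def differential_expression(comp: Compendium, cell_type: str, cytokine: str,
                            log2fc_threshold: float = LOG2FC_MIN,
                            ) -> list[DeStat]:
    """Two-sided Wilcoxon rank-sum DE of a cytokine against PBS controls.

    Requires a normalized compendium and at least two cells in each group.
    P-values are exact by enumeration when both groups have at most eight
    cells and tie-corrected normal approximations otherwise; FDR is
    Benjamini-Hochberg over all tested genes.  ``n_replicates_passing``
    counts the replicates whose within-replicate fold change exceeds
    ``log2fc_threshold`` in the gene's overall direction.
    """
    if not comp.normalized:
        raise ValueError("differential_expression expects normalized data")
    tmask, cmask = _groups(comp, cell_type, cytokine)
    nt, nc = int(tmask.sum()), int(cmask.sum())
    if nt < 2 or nc < 2:
        raise ValueError(
            f"need >=2 cells per group for {cell_type}/{cytokine}: "
            f"{nt} treated, {nc} control"
        )
    T = comp.dense(tmask)
    C = comp.dense(cmask)
    p = rank_sum_matrix(T, C)
    lfc = log2_fold_change(T, C)
    pct_t = (T > 0).mean(axis=0)
    pct_c = (C > 0).mean(axis=0)
    fdr = bh_fdr(p)

    # replicate-wise fold changes, each mouse's treated cells vs its own PBS
    reps = comp.meta.loc[tmask, "replicate"].unique()
    n_pass = np.zeros(comp.n_genes, dtype=int)
    for r in reps:
        rt = comp.mask(cell_type=cell_type, condition=cytokine, replicate=r)
        rc = comp.mask(cell_type=cell_type, condition=comp.control, replicate=r)
        if not rc.any():
            rc = cmask  # no replicate-matched controls; fall back to all PBS
        if not rt.any():
            continue
        rep_lfc = log2_fold_change(comp.dense(rt), comp.dense(rc))
        n_pass += np.where(lfc >= 0, rep_lfc > log2fc_threshold,
                           rep_lfc < -log2fc_threshold)

    return [
        DeStat(gene=g, log2fc=float(lfc[i]), p=float(p[i]), fdr=float(fdr[i]),
               pct_treated=float(pct_t[i]), pct_control=float(pct_c[i]),
               n_replicates_passing=int(n_pass[i]))
        for i, g in enumerate(comp.genes)
    ]


def build_signature(stats: list[DeStat], cell_type: str, cytokine: str,
                    policy: ExclusionPolicy | None = None,
                    fdr_max: float = FDR_MAX,
                    log2fc_min: float = LOG2FC_MIN,
                    pct_min: float = PCT_MIN,
                    min_replicates: int = MIN_REPLICATES_PASSING,
                    ) -> CytokineSignature:
    """Apply the signature filter cascade, logging per-filter attrition.

    Order: FDR, |log2FC|, expression fraction in the direction-appropriate
    group (treated for up, control for down), replicate consistency, then
    gene-category exclusions.
    """
    policy = policy or ExclusionPolicy.for_signatures()
    counts = {"input": len(stats)}
    kept = [s for s in stats if s.fdr < fdr_max]
    counts["fdr"] = len(kept)
    kept = [s for s in kept if abs(s.log2fc) > log2fc_min]
    counts["log2fc"] = len(kept)
    kept = [s for s in kept
            if (s.pct_treated if s.direction == "up" else s.pct_control) > pct_min]
    counts["pct"] = len(kept)
    kept = [s for s in kept if s.n_replicates_passing >= min_replicates]
    counts["replicates"] = len(kept)
    allowed = set(apply_exclusions([s.gene for s in kept], policy))
    kept = [s for s in kept if s.gene in allowed]
    counts["exclusions"] = len(kept)
    log.info("build_signature %s/%s attrition: %s", cell_type, cytokine, counts)
    return CytokineSignature(cell_type=cell_type, cytokine=cytokine,
                             entries=kept)


def cytokine_signature(comp: Compendium, cell_type: str, cytokine: str,
                       **kwargs) -> CytokineSignature:
    """DE followed by the filter cascade, in one call."""
    stats = differential_expression(comp, cell_type, cytokine)
    return build_signature(stats, cell_type, cytokine, **kwargs)


def build_dictionary(comp: Compendium, cell_types=None, cytokines=None,
                     min_cells: int = 2, **kwargs
                     ) -> dict[tuple[str, str], CytokineSignature]:
    """Signatures for every (cell type, cytokine) pair with enough cells."""
    out = {}
    for ct in (cell_types or comp.cell_types):
        for ck in (cytokines or comp.cytokines):
            tmask, cmask = _groups(comp, ct, ck)
            if tmask.sum() < max(2, min_cells) or cmask.sum() < 2:
                continue
            out[(ct, ck)] = cytokine_signature(comp, ct, ck, **kwargs)
    return out


# ---------------------------------------------------------------------------
# Response magnitude
# ---------------------------------------------------------------------------

def response_magnitude(comp: Compendium, cell_type: str,
                       max_cells: int = 100, min_cells: int = 5,
                       winsor_pct: float = 95.0,
                       seed: int = 0) -> pd.DataFrame:
    """0-100 magnitude of each cytokine's response within one cell type.

    Samples at most ``max_cells`` cells per condition (seeded), measures the
    Euclidean distance between the treated and PBS centroids over all genes,
    winsorizes distances at the ``winsor_pct`` percentile across cytokines
    and linearly rescales so the maximum is 100.  Pairs with fewer than
    ``min_cells`` treated cells are omitted.
    """
    if not comp.normalized:
        raise ValueError("response_magnitude expects normalized data")
    if cell_type not in comp.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}")
    rng = np.random.default_rng(seed)

    def sampled_centroid(mask):
        idx = np.flatnonzero(mask)
        if idx.size > max_cells:
            idx = rng.choice(idx, size=max_cells, replace=False)
        return comp.X[idx].mean(axis=0).A1 if idx.size else None, idx.size

    pbs_centroid, _ = sampled_centroid(comp.mask(cell_type=cell_type,
                                                 condition=comp.control))
    if pbs_centroid is None:
        raise ValueError(f"no PBS cells for cell type {cell_type!r}")

    rows = []
    for ck in comp.cytokines:
        mask = comp.mask(cell_type=cell_type, condition=ck)
        if mask.sum() < min_cells:
            continue
        centroid, n = sampled_centroid(mask)
        rows.append(dict(cytokine=ck, n_cells_sampled=n,
                         distance=float(np.linalg.norm(centroid - pbs_centroid))))
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(magnitude=pd.Series(dtype=float))
    df["magnitude"] = winsorized_scale(df["distance"].to_numpy(), winsor_pct)
    return df


def winsorized_scale(values, winsor_pct: float = 95.0) -> np.ndarray:
    """Cap values above the given percentile (linear interpolation) at that
    percentile, then rescale linearly so the maximum equals 100."""
    values = np.asarray(values, dtype=float)
    cap = np.percentile(values, winsor_pct)
    w = np.minimum(values, cap)
    top = w.max()
    return w / top * 100.0 if top > 0 else np.zeros_like(w)


def magnitude_map(comp: Compendium, signatures=None, seed: int = 0,
                  **kwargs) -> pd.DataFrame:
    """Magnitudes for all cell types; joins DEG counts when a signature
    dictionary is supplied."""
    frames = []
    for ct in comp.cell_types:
        df = response_magnitude(comp, ct, seed=seed, **kwargs)
        df.insert(0, "cell_type", ct)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if signatures is not None and not out.empty:
        out["n_degs"] = [
            signatures[(ct, ck)].n_degs if (ct, ck) in signatures else np.nan
            for ct, ck in zip(out["cell_type"], out["cytokine"])
        ]
    return out


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

def replicate_concordance(comp: Compendium, cell_type: str, cytokine: str,
                          signature: CytokineSignature) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-replicate differential vectors
    (mean treated minus mean PBS on signature genes)."""
    tmask, cmask = _groups(comp, cell_type, cytokine)
    reps = sorted(comp.meta.loc[tmask, "replicate"].unique())
    if len(reps) < 2:
        warnings.warn("fewer than 2 replicates; concordance undefined")
        return pd.DataFrame()
    genes = signature.genes
    if len(genes) < 2:
        warnings.warn("fewer than 2 signature genes; returning NA matrix")
        return pd.DataFrame(np.nan, index=reps, columns=reps)
    vectors = []
    for r in reps:
        rt = comp.mask(cell_type=cell_type, condition=cytokine, replicate=r)
        rc = comp.mask(cell_type=cell_type, condition=comp.control, replicate=r)
        if not rc.any():
            rc = cmask
        vectors.append(comp.dense(rt, genes).mean(axis=0)
                       - comp.dense(rc, genes).mean(axis=0))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(np.vstack(vectors))
    return pd.DataFrame(corr, index=reps, columns=reps)


# ---------------------------------------------------------------------------
# Gene-set scoring and cytokine-access ROC
# ---------------------------------------------------------------------------

def gene_set_score(comp: Compendium, gene_set) -> pd.Series:
    """Per-cell score: sum of normalized expression over the set's genes.
    Genes absent from the matrix contribute zero (with a warning)."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    present = [g for g in genes if g in comp.genes]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} set genes absent from matrix: "
                      f"{missing[:5]}")
    if not present:
        return pd.Series(0.0, index=comp.cells)
    idx = comp.genes.get_indexer(present)
    scores = np.asarray(comp.X[:, idx].sum(axis=1)).ravel()
    return pd.Series(scores, index=comp.cells)


def access_auc(scores_treated, scores_control) -> float:
    """ROC AUC separating treated from control cells by gene-set score,
    computed by pair counting (ties count half)."""
    return pairwise_auc(scores_treated, scores_control)


def cytokine_access(comp: Compendium, gene_set, treated_condition: str,
                    max_cells: int = 100, seed: int = 0) -> pd.DataFrame:
    """Per cell type, the AUC with which the summed gene-set score predicts
    treatment with ``treated_condition`` versus PBS (at most ``max_cells``
    sampled per condition)."""
    rng = np.random.default_rng(seed)
    scores = gene_set_score(comp, gene_set)
    rows = []
    for ct in comp.cell_types:
        t_idx = np.flatnonzero(comp.mask(cell_type=ct,
                                         condition=treated_condition))
        c_idx = np.flatnonzero(comp.mask(cell_type=ct,
                                         condition=comp.control))
        if t_idx.size == 0 or c_idx.size == 0:
            continue
        if t_idx.size > max_cells:
            t_idx = rng.choice(t_idx, size=max_cells, replace=False)
        if c_idx.size > max_cells:
            c_idx = rng.choice(c_idx, size=max_cells, replace=False)
        rows.append(dict(cell_type=ct,
                         auc=access_auc(scores.iloc[t_idx], scores.iloc[c_idx]),
                         n_treated=t_idx.size, n_control=c_idx.size))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Secondary responses to an induced donor cytokine
# ---------------------------------------------------------------------------

def secondary_response_score(comp: Compendium, donor_cytokine: str,
                             fdr_max: float = 1e-3,
                             log2fc_min: float = 1.0) -> pd.DataFrame:
    """Score every treatment for activity of a donor cytokine's strict
    signature (upregulated genes at FDR < ``fdr_max`` and
    log2FC > ``log2fc_min``).

    Returns one row per (cell type, cytokine) with the log2 fold change of
    the mean signature score versus PBS and a rank-sum FDR (BH across
    cytokines within each cell type).  Cell types whose strict signature is
    empty yield NA rows.
    """
    rows = []
    for ct in comp.cell_types:
        tmask, cmask = _groups(comp, ct, donor_cytokine)
        if tmask.sum() < 2 or cmask.sum() < 2:
            continue
        stats = differential_expression(comp, ct, donor_cytokine)
        strict = [s.gene for s in stats
                  if s.fdr < fdr_max and s.log2fc > log2fc_min]
        if not strict:
            rows.extend(dict(cell_type=ct, cytokine=ck, score_log2fc=np.nan,
                             p=np.nan) for ck in comp.cytokines)
            continue
        scores = gene_set_score(comp, strict)
        pbs = scores[comp.mask(cell_type=ct, condition=comp.control)]
        for ck in comp.cytokines:
            treated = scores[comp.mask(cell_type=ct, condition=ck)]
            if treated.empty or pbs.empty:
                continue
            mt, mc = treated.mean(), pbs.mean()
            lfc = np.log2((mt + 1e-9) / (mc + 1e-9)) if mc > 0 or mt > 0 else 0.0
            rows.append(dict(cell_type=ct, cytokine=ck,
                             score_log2fc=float(lfc),
                             p=rank_sum_p(treated.to_numpy(), pbs.to_numpy())))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = np.nan
    for ct, grp in df.groupby("cell_type"):
        df.loc[grp.index, "fdr"] = bh_fdr(grp["p"].to_numpy())
    return df
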