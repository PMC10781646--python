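"""Data model and file I/O.

The central container is the :class:`Compendium`: a sparse cell x gene
expression matrix with per-cell metadata (``cell_type``, ``condition``,
``replicate``) where the condition vocabulary contains a reserved control
token (``"PBS"`` by default).  A :class:`CytokineCatalog` maps each cytokine
to the gene(s) encoding it and to its receptor complex options, and a
:class:`GeneSetCollection` holds named gene sets read from GMT files.

On-disk layout for a compendium is a Matrix Market bundle: ``matrix.mtx``
(cells x genes), ``genes.tsv``, ``barcodes.tsv`` and ``metadata.tsv``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger("immunedict")

#: reserved condition label for vehicle-injected control cells
CONTROL_LABEL = "PBS"

REQUIRED_META = ("cell_type", "condition", "replicate")

NORMALIZED_TOTAL = 10_000.0


# ---------------------------------------------------------------------------
# Compendium
# ---------------------------------------------------------------------------

@dataclass
class Compendium:
    """Cell x gene expression with aligned per-cell metadata.

    ``X`` holds raw counts when ``normalized`` is False, and
    log1p-transformed values on the 10,000-total scale when True.
    """

    X: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index
    meta: pd.DataFrame
    normalized: bool = False
    control: str = CONTROL_LABEL

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        if self.X.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if self.genes.has_duplicates:
            dups = self.genes[self.genes.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        missing_cols = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing_cols:
            raise ValueError(f"metadata missing required columns: {missing_cols}")
        if not self.meta.index.equals(self.cells):
            missing = self.cells.difference(self.meta.index).tolist()
            if missing:
                raise ValueError(f"metadata missing cells: {missing[:5]}")
            self.meta = self.meta.loc[self.cells]
        for col in REQUIRED_META:
            if self.meta[col].isna().any():
                bad = self.meta.index[self.meta[col].isna()].tolist()
                raise ValueError(f"metadata column {col!r} missing for cells {bad[:5]}")
        if self.control not in set(self.meta["condition"]):
            warnings.warn(
                f"control condition {self.control!r} absent from metadata",
                stacklevel=2,
            )
    def check_normalized_totals(self) -> None:
        """Verify the pre-log totals invariant (10,000 per cell) on a full
        normalized compendium.  Not part of ``validate`` because gene
        subsets of a normalized compendium legitimately break it."""
        if not self.normalized or not self.n_cells:
            return
        totals = np.expm1(self.X.toarray()).sum(axis=1)
        if not np.allclose(totals, NORMALIZED_TOTAL, rtol=1e-6):
            raise ValueError("normalized flag set but per-cell pre-log "
                             "totals are not 10,000")

    # -- convenience -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.meta["cell_type"]))

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.meta["condition"]))

    @property
    def cytokines(self) -> list[str]:
        return [c for c in self.conditions if c != self.control]

    def mask(self, cell_type=None, condition=None, replicate=None) -> np.ndarray:
        m = np.ones(self.n_cells, dtype=bool)
        if cell_type is not None:
            m &= (self.meta["cell_type"] == cell_type).to_numpy()
        if condition is not None:
            m &= (self.meta["condition"] == condition).to_numpy()
        if replicate is not None:
            m &= (self.meta["replicate"] == replicate).to_numpy()
        return m

    def dense(self, cell_mask=None, genes=None) -> np.ndarray:
        """Dense view of a (subset of the) matrix, cells x genes."""
        X = self.X
        if cell_mask is not None:
            X = X[cell_mask]
        if genes is not None:
            idx = self.genes.get_indexer(pd.Index(genes))
            if (idx < 0).any():
                missing = [g for g, i in zip(genes, idx) if i < 0]
                raise KeyError(f"genes absent from compendium: {missing[:5]}")
            X = X[:, idx]
        return np.asarray(X.todense())

    def subset_cells(self, mask) -> "Compendium":
        mask = np.asarray(mask)
        return replace(
            self,
            X=self.X[mask],
            cells=self.cells[mask],
            meta=self.meta.loc[self.cells[mask]],
        )

    def subset_genes(self, genes) -> "Compendium":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            raise KeyError("requested genes absent from compendium")
        return replace(self, X=self.X[:, idx], genes=self.genes[idx])

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.X.copy(),
            obs=self.meta.copy(),
            var=pd.DataFrame(index=self.genes),
        )


def read_compendium(matrix_path, genes_path, cells_path, meta_path,
                    normalized: bool = False,
                    known_conditions=None) -> Compendium:
    """Read a Matrix Market compendium bundle.

    The matrix is stored cells x genes; ``genes_path`` and ``cells_path``
    are one-symbol-per-line TSVs and ``meta_path`` is a TSV keyed by cell
    ID with at least cell_type, condition and replicate columns.  A cell
    without metadata is an error; condition labels outside
    ``known_conditions`` (if given) only trigger a warning.
    """
    X = sp.csr_matrix(mmread(str(matrix_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0]
    if X.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix dimensions {X.shape} do not match gene/cell files "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = pd.Index(cells).difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing cells: {missing.tolist()[:5]}")
    meta = meta.loc[cells]
    if known_conditions is not None:
        unknown = set(meta["condition"]) - set(known_conditions) - {CONTROL_LABEL}
        if unknown:
            warnings.warn(f"conditions outside catalog vocabulary: {sorted(unknown)[:5]}")
    comp = Compendium(X=X, genes=pd.Index(genes), cells=pd.Index(cells),
                      meta=meta, normalized=normalized)
    if normalized:
        comp.check_normalized_totals()
    return comp


def write_compendium(comp: Compendium, out_dir) -> Path:
    """Write the Matrix Market bundle; float values keep full precision so
    read-back is bit-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(comp.X), precision=17)
    pd.Series(comp.genes).to_csv(out / "genes.tsv", sep="\t",
                                 index=False, header=False)
    pd.Series(comp.cells).to_csv(out / "barcodes.tsv", sep="\t",
                                 index=False, header=False)
    comp.meta.to_csv(out / "metadata.tsv", sep="\t")
    return out


# ---------------------------------------------------------------------------
# Cytokine catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cytokine:
    """One catalog entry: the genes encoding the ligand and the receptor
    complex options (each a tuple of component gene symbols)."""

    name: str
    family: str
    ligand_genes: tuple[str, ...]
    receptor_options: tuple[tuple[str, ...], ...] = ()

    @property
    def multimeric(self) -> bool:
        return len(self.ligand_genes) > 1

    def __post_init__(self):
        if not self.ligand_genes:
            raise ValueError(f"{self.name}: at least one ligand gene required")
        for complex_ in self.receptor_options:
            if not complex_:
                raise ValueError(
                    f"{self.name}: receptor complex referencing no genes"
                )


class CytokineCatalog:
    """Ordered, name-unique collection of :class:`Cytokine` entries."""

    def __init__(self, cytokines):
        self._entries: dict[str, Cytokine] = {}
        for c in cytokines:
            if c.name in self._entries:
                raise ValueError(f"duplicate cytokine name: {c.name}")
            self._entries[c.name] = c

    def __len__(self):
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, name):
        return name in self._entries

    def __getitem__(self, name) -> Cytokine:
        return self._entries[name]

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def subset(self, names) -> "CytokineCatalog":
        return CytokineCatalog([self._entries[n] for n in names])


def _parse_receptor_options(text: str) -> tuple[tuple[str, ...], ...]:
    text = (text or "").strip()
    if not text:
        return ()
    options = []
    for part in text.split("|"):
        components = tuple(g.strip() for g in part.split("+"))
        if any(not g for g in components):
            raise ValueError(f"receptor complex referencing no genes: {text!r}")
        options.append(components)
    return tuple(options)


def load_catalog(path) -> CytokineCatalog:
    """Load a cytokine catalog from TSV (columns name, family, ligand_genes,
    receptor_options) or JSON.  In the TSV, ligand genes are comma-separated
    and receptor options are ``|``-separated complexes of ``+``-joined
    component genes."""
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
        entries = [
            Cytokine(
                name=r["name"], family=r.get("family", ""),
                ligand_genes=tuple(r["ligand_genes"]),
                receptor_options=tuple(tuple(o) for o in r.get("receptor_options", [])),
            )
            for r in records
        ]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.empty:
            warnings.warn(f"catalog {path} is empty")
            return CytokineCatalog([])
        entries = [
            Cytokine(
                name=row["name"], family=row.get("family", ""),
                ligand_genes=tuple(g.strip() for g in row["ligand_genes"].split(",")),
                receptor_options=_parse_receptor_options(row.get("receptor_options", "")),
            )
            for _, row in df.iterrows()
        ]
    return CytokineCatalog(entries)


def default_catalog() -> CytokineCatalog:
    """The packaged 86-cytokine catalog (mouse gene symbols)."""
    with resources.as_file(
        resources.files("immunedict.data") / "cytokine_catalog.tsv"
    ) as p:
        return load_catalog(p)


def packaged_gene_list(name: str) -> list[str]:
    """Read a packaged one-symbol-per-line gene list fixture."""
    text = (resources.files("immunedict.data") / name).read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

class GeneSetCollection:
    """Named gene sets with an optional universe; preserves insertion order."""

    def __init__(self, sets: dict[str, tuple[str, ...]],
                 descriptions: dict[str, str] | None = None,
                 universe=None):
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {k: tuple(v) for k, v in sets.items()}
        self.descriptions = descriptions or {k: "" for k in sets}
        self.universe = None if universe is None else tuple(universe)

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line has fewer than 3 fields")
        name, desc, *genes = fields
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate gene set name {name!r}")
        sets[name] = tuple(g for g in genes if g)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> Path:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + list(genes))
        for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
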