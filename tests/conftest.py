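import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import immunedict as idt
from immunedict.io import Compendium


def make_compendium(values, genes, conditions, cell_types=None,
                    replicates=None, normalized=True):
    """Build a small Compendium directly from a dense value matrix."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    cells = pd.Index([f"c{i}" for i in range(n)])
    meta = pd.DataFrame(
        {
            "cell_type": cell_types if cell_types is not None else ["T"] * n,
            "condition": conditions,
            "replicate": replicates if replicates is not None
            else [f"rep{(i % 3) + 1}" for i in range(n)],
        },
        index=cells,
    )
    return Compendium(X=sp.csr_matrix(values), genes=pd.Index(genes),
                      cells=cells, meta=meta, normalized=normalized)


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark, generated once per session:
    raw compendium + truth, the QC'd/normalized compendium, and the full
    signature dictionary."""
    spec = idt.default_benchmark_spec(seed=1)
    comp, truth = idt.generate_compendium(spec)
    norm = idt.normalize_log(idt.qc_filter(comp))
    signatures = idt.build_dictionary(norm)
    return dict(spec=spec, raw=comp, truth=truth, norm=norm,
                signatures=signatures)


@pytest.fixture()
def toy_compendium():
    """3 cells x 5 genes of raw counts with full metadata."""
    counts = [[2, 3, 5, 0, 1],
              [1, 0, 4, 2, 0],
              [0, 6, 1, 1, 3]]
    return make_compendium(counts, genes=[f"g{i}" for i in range(5)],
                           conditions=["PBS", "IL-6", "IL-6"],
                           replicates=["rep1", "rep1", "rep2"],
                           normalized=False)
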