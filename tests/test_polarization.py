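"""Polarization-state calling, similarity and naming tests."""

import numpy as np
import pandas as pd
import pytest

import immunedict as idt
from immunedict.polarization import (PolarizationState, call_states,
                                     discriminating_genes,
                                     find_polarization_states, jaccard,
                                     name_states, state_markers,
                                     state_similarity, subcluster)
from immunedict.stats import hypergeom_sf

from conftest import make_compendium


def _state(id_, driver, size, cell_type="NK"):
    return PolarizationState(
        id=id_, cell_type=cell_type,
        cells=pd.Index([f"{id_}_{i}" for i in range(size)]),
        drivers=pd.DataFrame([dict(cytokine=driver, p=1e-5, fdr=1e-4,
                                   n_in_cluster=size)]),
    )


class TestDiscriminatingGenes:
    def test_threshold_inclusion(self):
        # gene a: 4-fold induction (|log2FC| ~ 2 > 0.75); gene b flat
        vals = np.zeros((8, 2))
        vals[:4, 0] = np.log1p(3.0)
        vals[:, 1] = np.log1p(1.0)
        comp = make_compendium(vals, genes=["a", "b"],
                               conditions=["IL-6"] * 4 + ["PBS"] * 4)
        assert discriminating_genes(comp, "T", 0.75) == ["a"]

    def test_dissociation_gene_excluded(self):
        vals = np.zeros((8, 2))
        vals[:4] = np.log1p(5.0)
        comp = make_compendium(vals, genes=["Fos", "Stat1"],
                               conditions=["IL-6"] * 4 + ["PBS"] * 4)
        assert discriminating_genes(comp, "T", 0.75) == ["Stat1"]

    def test_empty_result_advises_lower_threshold(self):
        comp = make_compendium(np.ones((8, 2)), genes=["a", "b"],
                               conditions=["IL-6"] * 4 + ["PBS"] * 4)
        with pytest.raises(ValueError, match="lower threshold"):
            discriminating_genes(comp, "T", 1.5)


class TestSubcluster:
    def _blobs(self, seed=0, n=60, sep=20.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 0.5, size=(n, 8))
        b = rng.normal(sep, 0.5, size=(n, 8))
        X = np.abs(np.vstack([a, b]))
        return make_compendium(X, genes=[f"g{i}" for i in range(8)],
                               conditions=["IL-6"] * n + ["PBS"] * n)

    def test_two_separated_blobs_two_clusters(self):
        comp = self._blobs()
        labels = subcluster(comp, n_pcs=5, seed=0)
        assert len(set(labels)) == 2
        # each blob lands in one cluster
        assert len(set(labels[:60])) == 1
        assert len(set(labels[60:])) == 1

    def test_deterministic_for_seed(self):
        comp = self._blobs(seed=3)
        l1 = subcluster(comp, n_pcs=5, seed=42)
        l2 = subcluster(comp, n_pcs=5, seed=42)
        assert np.array_equal(l1, l2)

    def test_too_few_cells_errors(self):
        comp = self._blobs(n=3)
        with pytest.raises(ValueError, match="cells"):
            subcluster(comp, n_pcs=10)


class TestCallStates:
    def test_hypergeometric_matches_oracle(self):
        # cluster of 10 holding 8 cells of a cytokine with 20 of 100 cells
        labels = np.zeros(100, dtype=int)
        labels[:10] = 1
        conditions = np.array(["PBS"] * 100, dtype=object)
        conditions[:8] = "IL-6"              # 8 in the cluster
        conditions[10:22] = "IL-6"           # 12 outside -> K = 20
        states = call_states(labels, conditions, cell_type="T")
        assert len(states) == 1
        p = states[0].drivers.iloc[0]["p"]
        assert p == pytest.approx(hypergeom_sf(8, 100, 20, 10), abs=1e-15)

    def test_background_composition_no_state(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=120)
        conditions = np.where(rng.random(120) < 0.5, "IL-6", "PBS")
        assert call_states(labels, conditions, cell_type="T") == []

    def test_fdr_above_alpha_not_called(self):
        labels = np.zeros(40, dtype=int)
        labels[:6] = 1
        conditions = np.array(["PBS"] * 40, dtype=object)
        conditions[:3] = "IL-6"
        conditions[10:17] = "IL-6"
        states = call_states(labels, conditions, cell_type="T", alpha=0.01)
        # mild enrichment only; nothing passes FDR < 0.01
        assert states == []


class TestMarkers:
    def test_planted_marker_recovery(self):
        rng = np.random.default_rng(1)
        vals = np.log1p(rng.random((40, 6)))
        vals[:12, :2] += np.log(4.0)  # state overexpresses m1, m2
        comp = make_compendium(
            vals, genes=["m1", "m2", "x1", "x2", "x3", "x4"],
            conditions=["IL-6"] * 20 + ["PBS"] * 20)
        state = PolarizationState(
            id="T-a", cell_type="T", cells=comp.cells[:12],
            drivers=pd.DataFrame([dict(cytokine="IL-6", p=0, fdr=0,
                                       n_in_cluster=12)]))
        markers = state_markers(state, comp, "T")
        assert {m.gene for m in markers[:2]} == {"m1", "m2"}

    def test_state_equal_to_rest_no_markers(self):
        vals = np.ones((20, 3))
        comp = make_compendium(vals, genes=list("abc"),
                               conditions=["IL-6"] * 10 + ["PBS"] * 10)
        state = PolarizationState(
            id="T-a", cell_type="T", cells=comp.cells[:8],
            drivers=pd.DataFrame([dict(cytokine="IL-6", p=0, fdr=0,
                                       n_in_cluster=8)]))
        assert state_markers(state, comp, "T") == []

    def test_state_covering_all_cells_errors(self):
        comp = make_compendium(np.ones((6, 2)), genes=["a", "b"],
                               conditions=["IL-6"] * 3 + ["PBS"] * 3)
        state = PolarizationState(
            id="T-a", cell_type="T", cells=comp.cells,
            drivers=pd.DataFrame([dict(cytokine="IL-6", p=0, fdr=0,
                                       n_in_cluster=6)]))
        with pytest.raises(ValueError, match="every cell"):
            state_markers(state, comp, "T")


class TestSimilarity:
    def test_jaccard_set_arithmetic(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard(set(), set()) == 1.0
        assert jaccard({"a"}, set()) == 0.0

    def _two_state_comp(self):
        # genes: s1 up in state1, s2 up in state2, shared up in both
        rng = np.random.default_rng(2)
        vals = np.log1p(rng.random((30, 4)) * 0.1)
        vals[:10, 0] += 2.0   # state1: g0, g2 up
        vals[:10, 2] += 2.0
        vals[10:20, 1] += 2.0  # state2: g1, g2 up
        vals[10:20, 2] += 2.0
        comp = make_compendium(vals, genes=["g0", "g1", "g2", "g3"],
                               conditions=["IL-6"] * 10 + ["TNF"] * 10
                               + ["PBS"] * 10)
        mk = lambda i, cells: PolarizationState(
            id=f"T-{i}", cell_type="T", cells=cells,
            drivers=pd.DataFrame([dict(cytokine="IL-6", p=0, fdr=0,
                                       n_in_cluster=10)]))
        return comp, [mk("a", comp.cells[:10]), mk("b", comp.cells[10:20])]

    def test_similarity_structure(self):
        comp, states = self._two_state_comp()
        sim = state_similarity(states, comp)
        assert np.allclose(np.diag(sim.jaccard_up), 1.0)
        assert np.allclose(sim.jaccard_up, sim.jaccard_up.T)
        # up sets {g0,g2} and {g1,g2} -> Jaccard 1/3
        assert sim.jaccard_up.iloc[0, 1] == pytest.approx(1 / 3)
        assert ((sim.pearson >= -1 - 1e-12) & (sim.pearson <= 1 + 1e-12)
                ).all().all()

    def test_uniqueness_inverse_mean_jaccard(self):
        comp, states = self._two_state_comp()
        sim = state_similarity(states, comp)
        # only up sets are non-empty; mutual Jaccard 1/3 -> uniqueness 3
        assert sim.uniqueness.iloc[0] == pytest.approx(3.0)

    def test_identical_states_pearson_and_jaccard_one(self):
        comp, states = self._two_state_comp()
        twin = PolarizationState(id="T-c", cell_type="T",
                                 cells=states[0].cells,
                                 drivers=states[0].drivers)
        sim = state_similarity([states[0], twin], comp)
        assert sim.pearson.iloc[0, 1] == pytest.approx(1.0)
        assert sim.jaccard_up.iloc[0, 1] == 1.0

    def test_newick_export(self):
        comp, states = self._two_state_comp()
        twin = PolarizationState(id="T-c", cell_type="T",
                                 cells=states[0].cells,
                                 drivers=states[0].drivers)
        sim = state_similarity(states + [twin], comp)
        nwk = sim.to_newick()
        assert nwk.startswith("(") and "T-a" in nwk

    def test_fewer_than_two_states_errors(self):
        comp, states = self._two_state_comp()
        with pytest.raises(ValueError):
            state_similarity(states[:1], comp)


class TestNaming:
    def test_reserved_letters(self):
        states = [_state("s1", "IFNβ", 50), _state("s2", "IFNγ", 40),
                  _state("s3", "IL-1α", 30), _state("s4", "TNF", 20),
                  _state("s5", "IL-18", 60)]
        named = name_states(states, "NK")
        assert [s.id for s in named] == ["NK-a", "NK-b", "NK-c", "NK-d",
                                         "NK-e"]

    def test_fallback_by_size(self):
        states = [_state("s1", "IL-18", 10), _state("s2", "IL-6", 99),
                  _state("s3", "TNF", 5)]
        named = name_states(states, "NK")
        assert [s.id for s in named] == ["NK-f", "NK-e", "NK-d"]

    def test_many_states_two_letter_suffixes(self):
        states = [_state(f"s{i}", "IL-6", 100 - i) for i in range(30)]
        named = name_states(states, "B")
        ids = [s.id for s in named]
        assert ids[0] == "B-e"
        assert any(len(i.split("-")[1]) == 2 for i in ids)
        assert len(set(ids)) == 30


def test_benchmark_planted_states_recovered(benchmark):
    """Each planted cytokine module yields a called state whose top driver
    is that cytokine at hypergeometric FDR < 0.01."""
    states = idt.find_polarization_states(benchmark["norm"], "NK", seed=0,
                                          abbrev="NK")
    drivers = {s.top_driver for s in states}
    assert drivers == set(benchmark["spec"].cytokines)
    for s in states:
        assert (s.drivers["fdr"] < 0.01).all()
    # reserved letters went to the reserved driver classes
    by_id = {s.id: s.top_driver for s in states}
    assert by_id["NK-a"] == "IFNβ"
    assert by_id["NK-b"] == "IFNγ"
    assert by_id["NK-c"] == "IL-1β"
    assert by_id["NK-d"] == "TNF"


def test_all_null_data_yields_no_states():
    spec = idt.SyntheticSpec(cell_types=("NK",),
                             cytokines=("IL-6", "TNF"),
                             n_genes=100, cells_per_condition=60, seed=5)
    comp, _ = idt.generate_compendium(spec)
    norm = idt.normalize_log(comp)
    sub = norm.subset_cells(norm.mask(cell_type="NK"))
    labels = subcluster(sub, n_pcs=10, seed=0)
    states = call_states(labels, sub.meta["condition"].to_numpy(),
                         cell_type="NK", cells=sub.cells)
    assert states == []
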