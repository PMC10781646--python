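"""IREA enrichment tests: planted recovery, symmetry and calibration."""

import numpy as np
import pandas as pd
import pytest

import immunedict as idt
from immunedict.irea import (build_communication_network, irea_geneset,
                             irea_polarization, irea_transcriptome,
                             map_homologs)

from conftest import make_compendium


class TestGeneSetMode:
    def test_planted_signature_ranks_first(self, benchmark):
        truth, norm = benchmark["truth"], benchmark["norm"]
        query = list(truth.deg_sets[("IL-18", "NK")])
        res = irea_geneset(query, norm, "NK")
        assert res.top_cytokine() == "IL-18"
        top = res.table.set_index("cytokine").loc["IL-18"]
        assert top["fdr"] < 0.05

    def test_hypergeometric_mode_closed_form(self):
        # reference with 10 genes where IL-6's DEGs are exactly 5 genes and
        # the query is those same 5 -> p = 1/252
        rng = np.random.default_rng(0)
        vals = np.log1p(rng.random((40, 10)) * 0.01)
        vals[:20, :5] += 2.0
        comp = make_compendium(vals, genes=[f"g{i}" for i in range(10)],
                               conditions=["IL-6"] * 20 + ["PBS"] * 20)
        res = irea_geneset([f"g{i}" for i in range(5)], comp, "T",
                           mode="hypergeometric")
        row = res.table.set_index("cytokine").loc["IL-6"]
        assert row["n_degs"] == 5
        assert row["p"] == pytest.approx(1 / 252, abs=1e-12)

    def test_empty_set_and_unknown_cell_type(self, benchmark):
        with pytest.raises(ValueError, match="empty"):
            irea_geneset([], benchmark["norm"], "NK")
        with pytest.raises(ValueError, match="cell type"):
            irea_geneset(["Gene0001"], benchmark["norm"], "Hepatocyte")

    def test_null_reference_type_i_error_controlled(self):
        """Against a reference with no planted signal, random gene sets
        produce significant calls at no more than the nominal rate."""
        spec = idt.SyntheticSpec(cell_types=("T",),
                                 cytokines=("A", "B", "C", "D", "E", "F"),
                                 n_genes=100, cells_per_condition=30, seed=9)
        comp, _ = idt.generate_compendium(spec)
        norm = idt.normalize_log(comp)
        rng = np.random.default_rng(1)
        calls = total = 0
        for _ in range(40):
            query = list(rng.choice(norm.genes, size=10, replace=False))
            res = irea_geneset(query, norm, "T")
            calls += int((res.table["fdr"] < 0.05).sum())
            total += len(res.table)
        rate = calls / total
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


class TestTranscriptomeMode:
    def test_end_to_end_recovery_with_noise(self, benchmark):
        """Queries generated from each planted (cytokine, cell type) truth
        with 20% gene-level noise rank the true cytokine first by effect
        size in at least 90% of runs."""
        spec, truth, norm = (benchmark["spec"], benchmark["truth"],
                             benchmark["norm"])
        hits = total = 0
        for i, ck in enumerate(spec.cytokines):
            for j, ct in enumerate(spec.cell_types):
                cond, ctrl = idt.generate_query(truth, ck, ct, noise_sd=0.2,
                                                seed=100 + 10 * i + j)
                res = irea_transcriptome(cond, ctrl, norm, ct)
                hits += res.top_cytokine() == ck
                total += 1
        assert hits / total >= 0.9

    def test_negated_query_flips_sign_exactly(self, benchmark):
        truth, norm = benchmark["truth"], benchmark["norm"]
        cond, ctrl = idt.generate_query(truth, "TNF", "NK", noise_sd=0.2,
                                        seed=7)
        fwd = irea_transcriptome(cond, ctrl, norm, "NK")
        rev = irea_transcriptome(ctrl, cond, norm, "NK")
        e1 = fwd.table.set_index("cytokine")["effect_size"]
        e2 = rev.table.set_index("cytokine")["effect_size"]
        assert np.allclose(e1.to_numpy(), -e2.loc[e1.index].to_numpy())
        # directions follow the sign
        t = fwd.table
        up = t[t["effect_size"] > 0]["direction"]
        assert (up == "condition").all()

    def test_identical_condition_and_control(self, benchmark):
        norm, truth = benchmark["norm"], benchmark["truth"]
        cond, _ = idt.generate_query(truth, "TNF", "NK", noise_sd=0.0, seed=0)
        with pytest.warns(UserWarning, match="equals control"):
            res = irea_transcriptome(cond, cond, norm, "NK")
        assert np.allclose(res.table["effect_size"], 0.0)

    def test_scale_invariance_of_projection(self, benchmark):
        """Cosine projection is invariant to positive rescaling of the user
        differential vector."""
        truth, norm = benchmark["truth"], benchmark["norm"]
        cond, ctrl = idt.generate_query(truth, "IL-6", "Bcell", noise_sd=0.1,
                                        seed=3)
        base = irea_transcriptome(cond, ctrl, norm, "Bcell")
        scaled = irea_transcriptome(ctrl + 3.0 * (cond - ctrl), ctrl, norm,
                                    "Bcell")
        assert np.allclose(base.table["effect_size"],
                           scaled.table["effect_size"], atol=1e-9)

    def test_too_few_shared_genes_errors(self, benchmark):
        norm = benchmark["norm"]
        cond = pd.DataFrame(np.ones((3, 2)), columns=["Gene0000", "Gene0001"])
        with pytest.raises(ValueError, match="shared genes"):
            irea_transcriptome(cond, cond * 0.5, norm, "NK")

    def test_contribution_weights_highlight_module_genes(self, benchmark):
        spec, truth, norm = (benchmark["spec"], benchmark["truth"],
                             benchmark["norm"])
        cond, ctrl = idt.generate_query(truth, "IFNγ", "Tcell", noise_sd=0.1,
                                        seed=11)
        res = irea_transcriptome(cond, ctrl, norm, "Tcell")
        top = res.contributions["IFNγ"].index[:10]
        module = set(truth.deg_sets[("IFNγ", "Tcell")])
        assert len(set(top) & module) >= 8


@pytest.fixture(scope="module")
def nk_states(benchmark):
    return idt.find_polarization_states(benchmark["norm"], "NK", seed=0,
                                        abbrev="NK")


class TestPolarizationMode:
    def test_planted_state_gets_max_normalized_es(self, benchmark, nk_states):
        truth, norm = benchmark["truth"], benchmark["norm"]
        cond, ctrl = idt.generate_query(truth, "IL-18", "NK", noise_sd=0.1,
                                        seed=2)
        enr = irea_polarization(cond, ctrl, norm, nk_states, "NK")
        assert enr.polarized
        best = enr.table.sort_values("normalized_es", ascending=False).iloc[0]
        il18_state = next(s.id for s in nk_states if s.top_driver == "IL-18")
        assert best["state"] == il18_state
        assert best["normalized_es"] == pytest.approx(1.0)
        assert ((enr.table["normalized_es"] >= 0)
                & (enr.table["normalized_es"] <= 1)).all()

    def test_null_query_unpolarized_radar(self, benchmark, nk_states):
        norm = benchmark["norm"]
        rng = np.random.default_rng(0)
        genes = norm.genes
        noise = pd.DataFrame(rng.random((20, len(genes))) * 2,
                             columns=genes)
        noise2 = pd.DataFrame(rng.random((20, len(genes))) * 2,
                              columns=genes)
        enr = irea_polarization(noise, noise2, norm, nk_states, "NK")
        if not enr.polarized:
            assert (enr.table["normalized_es"] == 0).all()

    def test_no_states_for_cell_type(self, benchmark, nk_states):
        cond = pd.DataFrame(np.ones((2, 12)),
                            columns=benchmark["norm"].genes[:12])
        enr = irea_polarization(cond, cond, benchmark["norm"], nk_states,
                                "Bcell")
        assert not enr.polarized and enr.table.empty


class TestCommunicationNetwork:
    def _user_expression(self, benchmark):
        norm = benchmark["norm"]
        rows = {ct: np.asarray(norm.X[norm.mask(cell_type=ct)].mean(axis=0)
                               ).ravel()
                for ct in norm.cell_types}
        return pd.DataFrame(rows, index=norm.genes).T

    def test_responder_edges_require_strict_fdr(self, benchmark):
        spec, norm, truth = (benchmark["spec"], benchmark["norm"],
                             benchmark["truth"])
        results = {}
        for ct in ("NK",):
            cond, ctrl = idt.generate_query(truth, "IL-18", ct, noise_sd=0.2,
                                            seed=5)
            results[ct] = irea_transcriptome(cond, ctrl, norm, ct)
        net = build_communication_network(results,
                                          self._user_expression(benchmark),
                                          spec.catalog)
        resp = net.responder_edges
        assert (resp["fdr"] < 0.01).all()
        assert "IL-18" in set(resp[resp["target"] == "NK"]["cytokine"])

    def test_producer_edges_follow_transcripts(self, benchmark):
        spec = benchmark["spec"]
        net = build_communication_network({},
                                          self._user_expression(benchmark),
                                          spec.catalog)
        prod = net.producer_edges
        # cDC was simulated to produce IFNβ; Bcell was not
        assert dict(source="cDC", cytokine="IFNβ", asterisk=False) in \
            prod.to_dict("records")
        assert not ((prod["source"] == "Bcell")
                    & (prod["cytokine"] == "IFNβ")).any()

    def test_receptor_flag_threshold(self):
        from immunedict.io import Cytokine, CytokineCatalog
        catalog = CytokineCatalog([
            Cytokine("X", "fam", ("Xl",), (("R1", "R2"),)),
        ])
        expr = pd.DataFrame(
            {"Xl": [0.2], "R1": [0.2], "R2": [0.04]}, index=["A"])
        net = build_communication_network({}, expr, catalog)
        flags = net.receptor_flags.set_index(["cell_type", "cytokine"])
        # component at 0.04 < 0.05 threshold -> receptor not expressed
        assert not flags.loc[("A", "X"), "receptor_expressed"]
        expr2 = expr.assign(R2=[0.06])
        net2 = build_communication_network({}, expr2, catalog)
        flags2 = net2.receptor_flags.set_index(["cell_type", "cytokine"])
        assert flags2.loc[("A", "X"), "receptor_expressed"].item()


class TestHomologs:
    def test_fixture_lookup(self):
        mapped, unmapped = map_homologs(["Il6", "Ifng"], "mouse", "human")
        assert mapped == {"Il6": "IL6", "Ifng": "IFNG"}
        assert unmapped == []

    def test_same_species_identity(self):
        mapped, unmapped = map_homologs(["Foo"], "human", "human")
        assert mapped == {"Foo": "Foo"}

    def test_unmapped_listed(self):
        mapped, unmapped = map_homologs(["NotAGene"], "mouse", "human")
        assert unmapped == ["NotAGene"]

    def test_one_to_many_dropped_with_warning(self):
        table = pd.DataFrame({"mouse": ["A", "A", "B"],
                              "human": ["A1", "A2", "B1"]})
        with pytest.warns(UserWarning, match="one-to-many"):
            mapped, unmapped = map_homologs(["A", "B"], "mouse", "human",
                                            table=table)
        assert mapped == {"B": "B1"}
        assert unmapped == ["A"]

    def test_unknown_species(self):
        with pytest.raises(ValueError, match="species"):
            map_homologs(["Il6"], "mouse", "zebrafish")
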