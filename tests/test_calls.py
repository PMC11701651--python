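"""Present/absent calls: reference selection, empirical p-values,
pseudo-bulking, p-value combination and graph-integrated calls."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from ontoexpr import (
    Annotation,
    Condition,
    Sample,
    build_condition_graph,
    call_expression,
    combine_pvalues,
    generate_calls,
    present_pvalue,
    pseudobulk,
    select_reference_intergenic,
    simulate_bundle,
    SynthConfig,
)
from ontoexpr.calls import sample_pvalues
from ontoexpr.errors import (
    AllRegionsDubious,
    EmptyCluster,
    EmptyList,
    GeneNotDetectable,
    NoData,
    OutOfRange,
    TooFewRegions,
    UnknownBarcode,
)

HUMAN = 9606


def _bulk_sample(abund, sample_id="S1", retina_ctx=None, anat="UBERON:0000966"):
    ann = Annotation(
        library_id=sample_id, experiment_id="E1",
        condition=Condition(anat, "CL:0000000", "UBERON:0000113",
                            "any sex", "wild type", HUMAN),
    )
    genes = frozenset(g for g in abund if not g.startswith("IG"))
    return Sample(sample_id=sample_id, annotation=ann, abundance=dict(abund),
                  detectable_genes=genes, origin="bulk")


class TestReferenceSelection:
    def test_silent_regions_all_retained(self):
        regions = pd.DataFrame(0.0, index=[f"IG{i}" for i in range(20)],
                               columns=["s1", "s2"])
        genes = pd.DataFrame(
            np.random.default_rng(0).uniform(1, 50, (100, 2)),
            index=[f"G{i}" for i in range(100)], columns=["s1", "s2"],
        )
        assert select_reference_intergenic(regions, genes) == \
            frozenset(regions.index)

    def test_region_above_every_gene_discarded(self):
        rng = np.random.default_rng(1)
        genes = pd.DataFrame(rng.uniform(1, 50, (100, 2)),
                             index=[f"G{i}" for i in range(100)],
                             columns=["s1", "s2"])
        regions = pd.DataFrame(0.5, index=[f"IG{i}" for i in range(20)],
                               columns=["s1", "s2"])
        regions.loc["IG0"] = 1000.0
        kept = select_reference_intergenic(regions, genes)
        assert "IG0" not in kept
        assert len(kept) == 19

    def test_planted_dubious_regions_mostly_discarded(self):
        """1000 regions, 100 resampled from the genic distribution: at least
        90 of the planted dubious regions are discarded at the default q."""
        bundle, truth = simulate_bundle(SynthConfig(seed=2))
        kept = select_reference_intergenic(bundle.intergenic, bundle.bulk)
        discarded_dubious = truth.dubious_regions - kept
        assert len(discarded_dubious) >= 90

    def test_too_few_regions(self):
        df = pd.DataFrame(0.0, index=["IG0"], columns=["s1"])
        with pytest.raises(TooFewRegions):
            select_reference_intergenic(df, df)

    def test_all_dubious_raises(self):
        regions = pd.DataFrame(100.0, index=[f"IG{i}" for i in range(20)],
                               columns=["s1"])
        genes = pd.DataFrame(1.0, index=[f"G{i}" for i in range(50)],
                             columns=["s1"])
        with pytest.raises(AllRegionsDubious):
            select_reference_intergenic(regions, genes)


class TestPresentPvalue:
    def test_gene_above_all_99_regions(self):
        abund = {f"IG{i}": float(i) / 100 for i in range(99)}
        abund["g1"] = 10.0
        s = _bulk_sample(abund)
        assert present_pvalue(s, "g1", abund.keys() - {"g1"}).p == \
            pytest.approx(1 / 100)

    def test_all_zero_ties_give_p_one(self):
        abund = {f"IG{i}": 0.0 for i in range(50)}
        abund["g1"] = 0.0
        s = _bulk_sample(abund)
        assert present_pvalue(s, "g1", abund.keys() - {"g1"}).p == 1.0

    def test_gene_at_median_of_199(self):
        vals = np.linspace(1, 199, 199)
        abund = {f"IG{i}": float(v) for i, v in enumerate(vals)}
        abund["g1"] = float(np.median(vals))
        s = _bulk_sample(abund)
        p = present_pvalue(s, "g1", abund.keys() - {"g1"}).p
        assert abs(p - 0.5) <= 0.01

    def test_not_detectable(self):
        s = _bulk_sample({"g1": 1.0, "IG0": 0.0})
        with pytest.raises(GeneNotDetectable):
            present_pvalue(s, "IG0", ["IG0"])

    @given(st.lists(st.floats(0, 1e4), min_size=12, max_size=60),
           st.floats(0, 1e4), st.floats(0, 1e4))
    def test_monotone_in_abundance(self, ref_vals, a, b):
        abund = {f"IG{i}": v for i, v in enumerate(ref_vals)}
        lo, hi = min(a, b), max(a, b)
        abund["lo"], abund["hi"] = lo, hi
        s = _bulk_sample(abund)
        ref = [r for r in abund if r.startswith("IG")]
        assert present_pvalue(s, "hi", ref).p <= present_pvalue(s, "lo", ref).p

    def test_null_pvalues_super_uniform(self):
        """Genes drawn i.i.d. from the reference law: P(p <= a) <= a + 2/(n+1)."""
        rng = np.random.default_rng(3)
        n = 499
        ref_vals = rng.lognormal(0, 1, n)
        abund = {f"IG{i}": v for i, v in enumerate(ref_vals)}
        genes = {f"g{i}": v for i, v in enumerate(rng.lognormal(0, 1, 4000))}
        abund.update(genes)
        s = _bulk_sample(abund)
        ps = sample_pvalues(s, sorted(genes), [r for r in abund if r.startswith("IG")])
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            rate = float((ps <= alpha).mean())
            assert rate <= alpha + 2 / (n + 1) + 3 * math.sqrt(alpha / 4000)


class TestPseudobulk:
    def _annotation(self, cluster):
        return Annotation(
            library_id=cluster, experiment_id="E1",
            condition=Condition("UBERON:0000966", "CL:0000561",
                                "UBERON:0000113", "any sex", "wild type", HUMAN),
            data_type="sc_droplet",
        )

    def test_counts_add_up(self):
        counts = sp.csc_matrix(np.array([[3, 2], [0, 5]]))
        samples = pseudobulk(
            counts, ["g1", "g2"], ["bc1", "bc2"],
            {"bc1": "c0", "bc2": "c0"}, {"c0": self._annotation("c0")},
            normalize="none",
        )
        assert samples[0].abundance == {"g1": 5.0, "g2": 5.0}

    def test_singleton_clusters_reproduce_cells(self):
        mat = np.array([[3, 2], [0, 5], [1, 1]])
        samples = pseudobulk(
            sp.csc_matrix(mat), ["g1", "g2", "g3"], ["bc1", "bc2"],
            {"bc1": "c0", "bc2": "c1"},
            {c: self._annotation(c) for c in ("c0", "c1")},
            normalize="none",
        )
        by_id = {s.sample_id: s for s in samples}
        assert [by_id["c0"].abundance[g] for g in ("g1", "g2", "g3")] == [3, 0, 1]
        assert [by_id["c1"].abundance[g] for g in ("g1", "g2", "g3")] == [2, 5, 1]

    def test_per_gene_counts_conserved_on_random_matrix(self):
        rng = np.random.default_rng(4)
        mat = rng.poisson(2.0, size=(30, 50))
        barcodes = [f"bc{i}" for i in range(50)]
        assignment = {b: f"c{rng.integers(4)}" for b in barcodes[:45]}  # 5 unassigned
        anns = {f"c{i}": self._annotation(f"c{i}") for i in range(4)}
        samples = pseudobulk(sp.csc_matrix(mat), [f"g{i}" for i in range(30)],
                             barcodes, assignment, anns, normalize="none")
        assigned_cols = [i for i, b in enumerate(barcodes) if b in assignment]
        expected = mat[:, assigned_cols].sum(axis=1)
        total = np.zeros(30)
        for s in samples:
            total += np.array([s.abundance[f"g{i}"] for i in range(30)])
        np.testing.assert_array_equal(total.astype(int), expected)

    def test_cpm_normalization_sums_to_million(self):
        mat = np.array([[3, 2], [0, 5]])
        samples = pseudobulk(
            sp.csc_matrix(mat), ["g1", "g2"], ["bc1", "bc2"],
            {"bc1": "c0", "bc2": "c0"}, {"c0": self._annotation("c0")},
        )
        assert sum(samples[0].abundance.values()) == pytest.approx(1e6)

    def test_unknown_barcode_strict(self):
        with pytest.raises(UnknownBarcode):
            pseudobulk(sp.csc_matrix(np.eye(2)), ["g1", "g2"], ["bc1", "bc2"],
                       {"ghost": "c0"}, {"c0": self._annotation("c0")})

    def test_empty_cluster(self):
        with pytest.raises(EmptyCluster):
            pseudobulk(sp.csc_matrix(np.eye(2)), ["g1", "g2"], ["bc1", "bc2"],
                       {"bc1": "c0"}, {"c0": self._annotation("c0"),
                                       "c1": self._annotation("c1")})


class TestCombinePvalues:
    @pytest.mark.parametrize("method", ["fisher", "stouffer", "bh_best"])
    def test_singleton_identity(self, method):
        assert combine_pvalues([0.03], method=method) == pytest.approx(0.03)

    def test_fisher_against_chi2_closed_form(self):
        # df=4: survival = exp(-x/2) * (1 + x/2), with x = -2*sum(log p)
        p = combine_pvalues([0.5, 0.5], method="fisher")
        x = -2 * (math.log(0.5) + math.log(0.5))
        assert p == pytest.approx(math.exp(-x / 2) * (1 + x / 2), abs=1e-12)
        assert p == pytest.approx(0.5966, abs=5e-4)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_fisher_matches_closed_form_chain(self, ps):
        # chi2 survival with 2k df via the Erlang/Poisson closed form
        x = -2 * sum(math.log(p) for p in ps)
        k = len(ps)
        sf = math.exp(-x / 2) * sum((x / 2) ** i / math.factorial(i)
                                    for i in range(k))
        assert combine_pvalues(ps, method="fisher") == pytest.approx(
            min(1.0, sf), rel=1e-9, abs=1e-12)

    def test_bh_best_hand_computed(self):
        assert combine_pvalues([0.01, 0.04], method="bh_best") == \
            pytest.approx(0.02)
        assert combine_pvalues([0.5, 0.9, 1.0], method="bh_best") == 1.0

    def test_empty_and_out_of_range(self):
        with pytest.raises(EmptyList):
            combine_pvalues([])
        for bad in ([0.0, 0.5], [0.5, 1.2], [float("nan")]):
            with pytest.raises(OutOfRange):
                combine_pvalues(bad)


class TestCallExpression:
    @pytest.fixture
    def setting(self, retina_ctx):
        """Two samples: one in the retina (child), one in the eye (parent)."""
        ref_ids = [f"IG{i}" for i in range(99)]
        ref = {r: 0.01 * (i + 1) for i, r in enumerate(ref_ids)}
        child = _bulk_sample({**ref, "g_on": 50.0, "g_off": 0.0}, "S_child")
        parent = _bulk_sample({**ref, "g_on": 60.0, "g_off": 0.0}, "S_parent",
                              anat="UBERON:0000970")
        graph = build_condition_graph(
            [child.annotation, parent.annotation], retina_ctx
        )
        return graph, [child, parent], frozenset(ref_ids)

    def test_present_when_above_all_regions(self, setting):
        graph, samples, ref = setting
        call = call_expression("g_on", samples[0].condition, graph, samples, ref)
        assert call.state == "present"
        assert call.p_integrated <= 0.05
        assert call.quality == "silver"  # one contributing sample only

    def test_gold_quality_needs_two_significant_samples(self, setting):
        # the eye condition pools its own sample and the retina one
        graph, samples, ref = setting
        call = call_expression("g_on", samples[1].condition, graph, samples, ref)
        assert (call.state, call.quality) == ("present", "gold")
        assert (call.n_samples_self, call.n_samples_descendant) == (1, 1)

    def test_zero_abundance_gene_absent(self, setting):
        graph, samples, ref = setting
        call = call_expression("g_off", samples[0].condition, graph, samples, ref)
        assert call.state == "absent"
        assert call.p_integrated == 1.0

    def test_parent_condition_inherits_child_data(self, setting, retina_ctx):
        """A condition with no direct sample still gets a call from the data
        annotated to its descendant conditions."""
        graph, samples, ref = setting
        child_only = [samples[0]]
        grandparent = retina_ctx.root_condition(HUMAN)
        call = call_expression("g_on", grandparent, graph, child_only, ref)
        assert call.state == "present"
        assert call.n_samples_self == 0
        assert call.n_samples_descendant >= 1
        assert call.sample_ids == ("S_child",)

    def test_no_data_raises(self, setting, retina_ctx):
        graph, samples, ref = setting
        lone = Condition("UBERON:0000966", "CL:0000066", "UBERON:0000113",
                         "any sex", "wild type", HUMAN)
        with pytest.raises(NoData):
            call_expression("g_on", lone, graph, samples, ref)

    def test_generate_calls_matches_single_calls(self, setting):
        graph, samples, ref = setting
        calls = generate_calls(graph, samples, ref)
        for call in calls:
            single = call_expression(call.gene, call.condition, graph,
                                     samples, ref)
            assert call.p_integrated == pytest.approx(single.p_integrated)
            assert (call.state, call.quality) == (single.state, single.quality)
            assert call.sample_ids == single.sample_ids

    def test_propagation_conserves_contributors(self, setting):
        """Samples contributing to a condition are a superset of the union of
        contributors of each of its children."""
        graph, samples, ref = setting
        calls = {(c.gene, c.condition): c for c in
                 generate_calls(graph, samples, ref)}
        for (gene, cond), call in calls.items():
            for child in graph.children_of(cond):
                child_call = calls.get((gene, child))
                if child_call:
                    assert set(child_call.sample_ids) <= set(call.sample_ids)

    def test_null_call_rate_tracks_alpha(self):
        """2000 genes resampled from the reference distribution: the fraction
        significant at alpha=0.05 stays within [0.03, 0.07], averaged over
        replicate samples (a single reference draw leaves ~0.7% noise on the
        conditional rate, so replication mirrors the integration setting)."""
        rng = np.random.default_rng(6)
        ref_ids = [f"IG{i}" for i in range(999)]
        rates = []
        for rep in range(8):
            abund = dict(zip(ref_ids, rng.lognormal(0, 1, 999)))
            genes = {f"g{i}": v for i, v in enumerate(rng.lognormal(0, 1, 2000))}
            abund.update(genes)
            s = _bulk_sample(abund, sample_id=f"S{rep}")
            ps = sample_pvalues(s, sorted(genes), ref_ids)
            rates.append(float((ps <= 0.05).mean()))
        assert 0.03 <= np.mean(rates) <= 0.07
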