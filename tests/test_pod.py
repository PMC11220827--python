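"""PoD derivation: pathway aggregation, selection rules, safety-factor chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ngra.pod import (
    AssayPanel,
    AssayResult,
    GeneBMD,
    SelectionRules,
    bmd_fold_ratio,
    derive_pod,
    lowest_median_bmd,
    pathway_median_bmd,
    select_pod,
)


def _genes(values, prefix="g", passes=True):
    return [
        GeneBMD(gene_id=f"{prefix}{i}", bmd=v, passes_filters=passes)
        for i, v in enumerate(values)
    ]


class TestPathwayMedian:
    def test_simple_median(self):
        genes = _genes([1.0, 2.0, 3.0])
        pmap = {g.gene_id: ["pw"] for g in genes}
        out = pathway_median_bmd(genes, pmap, min_genes=3)
        assert len(out) == 1 and out[0].median_bmd == 2.0

    def test_min_genes_excludes(self):
        genes = _genes([1.0, 2.0, 3.0, 4.0])
        pmap = {g.gene_id: ["pw"] for g in genes}
        assert pathway_median_bmd(genes, pmap, min_genes=5) == []
        assert len(pathway_median_bmd(genes, pmap, min_genes=3)) == 1

    def test_failing_genes_ignored(self):
        genes = _genes([1.0, 2.0, 3.0]) + _genes([1e-6], prefix="bad", passes=False)
        pmap = {g.gene_id: ["pw"] for g in genes}
        out = pathway_median_bmd(genes, pmap, min_genes=3)
        assert out[0].median_bmd == 2.0 and out[0].n_genes_passing == 3

    def test_empty_input_empty_output(self):
        assert pathway_median_bmd([], {}, min_genes=3) == []

    def test_unmapped_gene_rejected(self):
        with pytest.raises(ValueError, match="without pathway"):
            pathway_median_bmd(_genes([1.0]), {}, min_genes=1)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1e-3, max_value=1e3),
                st.integers(min_value=0, max_value=4),
                st.booleans(),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_agrees_with_bruteforce(self, rows):
        """Property: per-pathway medians match an independent brute force."""
        genes = [
            GeneBMD(gene_id=f"g{i}", bmd=v, passes_filters=p)
            for i, (v, _, p) in enumerate(rows)
        ]
        pmap = {f"g{i}": [f"pw{pw}"] for i, (_, pw, _) in enumerate(rows)}
        out = {s.pathway_id: s for s in pathway_median_bmd(genes, pmap, min_genes=1)}
        # brute force: collect and sort, take middle
        brute: dict[str, list[float]] = {}
        for g in genes:
            if g.passes_filters:
                brute.setdefault(pmap[g.gene_id][0], []).append(g.bmd)
        assert set(out) == set(brute)
        for pw, vals in brute.items():
            vals = sorted(vals)
            n = len(vals)
            med = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert out[pw].median_bmd == pytest.approx(med, rel=1e-12)

    def test_five_gene_output_subset_of_three(self):
        rng = np.random.default_rng(5)
        genes = _genes(rng.lognormal(0, 1, size=60))
        pmap = {g.gene_id: [f"pw{i % 12}"] for i, g in enumerate(genes)}
        three = {s.pathway_id for s in pathway_median_bmd(genes, pmap, 3)}
        five = {s.pathway_id for s in pathway_median_bmd(genes, pmap, 5)}
        assert five <= three
        if five:
            lo3 = lowest_median_bmd(pathway_median_bmd(genes, pmap, 3)).median_bmd
            lo5 = lowest_median_bmd(pathway_median_bmd(genes, pmap, 5)).median_bmd
            assert lo5 >= lo3


class TestLowestMedian:
    def test_single_summary(self):
        out = pathway_median_bmd(_genes([2.0]), {"g0": ["only"]}, min_genes=1)
        assert lowest_median_bmd(out).pathway_id == "only"

    def test_tie_breaks_lexicographically(self):
        genes = _genes([1.0, 1.0])
        pmap = {"g0": ["b_path"], "g1": ["a_path"]}
        best = lowest_median_bmd(pathway_median_bmd(genes, pmap, min_genes=1))
        assert best.pathway_id == "a_path"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lowest_median_bmd([])


class TestFoldRatio:
    @pytest.mark.parametrize("a,b,expected", [
        (33.1, 0.040, 828.0),   # hepatic cell line, 3-gene filter
        (0.038, 0.0065, 6.0),   # mammary cell line, 3-gene filter
        (30.0, 15.7, 2.0),      # hepatoma cell line, 5-gene filter
        (16.2, 15.7, pytest.approx(1.0318, rel=1e-3)),  # below 2: exact ratio
    ])
    def test_reported_fold_ratios(self, a, b, expected):
        assert bmd_fold_ratio(a, b) == expected

    def test_identity(self):
        assert bmd_fold_ratio(3.3, 3.3) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bmd_fold_ratio(0.0, 1.0)


class TestSelectPod:
    def test_daidzein_functional_over_binding(self, assay_table):
        """The ERα transactivation LOEC (100 nM) governs even though ERβ
        binding is 30-fold more potent: binding never sets the PoD."""
        panel = AssayPanel.from_dataframe(assay_table, "daidzein")
        selected = select_pod(panel)
        assert selected.assay_id == "calux_er_alpha"
        assert selected.value == 100.0 and selected.s9 == "plus"
        log = select_pod.last_selection_log
        assert any(e["rule"] == "supporting_evidence_only" and
                   e["assay_id"] == "pharmacology_er_beta" for e in log)

    def test_genistein_s9_minimum_rule(self, assay_table):
        panel = AssayPanel.from_dataframe(assay_table, "genistein")
        selected = select_pod(panel)
        assert selected.value == 5.2 and selected.s9 == "plus"
        pair = [e for e in select_pod.last_selection_log if e["rule"] == "s9_pair_minimum"]
        assert pair and pair[0]["difference_within_sd"] is True

    def test_single_functional_entry(self):
        r = AssayResult(
            chemical_id="x", assay_id="a", endpoint_class="cell_stress",
            measure="LOEC", value=50.0,
        )
        panel = AssayPanel(chemical_id="x", results=[r])
        assert select_pod(panel) is r

    def test_row_order_invariance(self, assay_table):
        panel = AssayPanel.from_dataframe(assay_table, "daidzein")
        reversed_panel = AssayPanel(
            chemical_id="daidzein", results=list(reversed(panel.results))
        )
        assert select_pod(panel).model_dump() == select_pod(reversed_panel).model_dump()

    def test_no_functional_result_errors(self):
        r = AssayResult(
            chemical_id="x", assay_id="bind", endpoint_class="receptor_binding",
            measure="Ki", value=1.0,
        )
        with pytest.raises(ValueError, match="broaden the panel"):
            select_pod(AssayPanel(chemical_id="x", results=[r]))


class TestDerivePod:
    def test_safety_factor_chain(self, assay_table):
        panel = AssayPanel.from_dataframe(assay_table, "daidzein")
        d = derive_pod(select_pod(panel), sf1=3.0, sf2=3.3)
        assert d.loec == 100.0
        assert d.noec == pytest.approx(100.0 / 3.0, rel=1e-12)
        assert d.safe_internal_concentration == pytest.approx(100.0 / 3.0 / 3.3, rel=1e-12)
        disp = d.display()
        assert disp == {
            "loec_nM": 100.0, "noec_nM": 33.0, "safe_internal_concentration_nM": 10.0
        }

    def test_intraindividual_factor_skipped(self, assay_table):
        panel = AssayPanel.from_dataframe(assay_table, "genistein")
        d = derive_pod(select_pod(panel), sf1=3.0, sf2=1.0)
        assert d.noec == pytest.approx(5.2 / 3.0, rel=1e-12)  # 1.73 nM
        assert d.safe_internal_concentration == d.noec

    def test_unit_factors_identity(self, assay_table):
        panel = AssayPanel.from_dataframe(assay_table, "daidzein")
        d = derive_pod(select_pod(panel), sf1=1.0, sf2=1.0)
        assert d.loec == d.noec == d.safe_internal_concentration

    def test_ordering_for_factors_above_one(self, assay_table):
        panel = AssayPanel.from_dataframe(assay_table, "daidzein")
        d = derive_pod(select_pod(panel))
        assert d.safe_internal_concentration < d.noec < d.loec

    def test_requires_loec(self):
        r = AssayResult(
            chemical_id="x", assay_id="a", endpoint_class="transcriptomic_pathway",
            measure="BMD_median", value=38.0,
        )
        with pytest.raises(ValueError, match="LOEC"):
            derive_pod(r)
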