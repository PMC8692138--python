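"""Cross-species gene sets, Welch comparison, over-representation."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tumorcross import (
    AlterationSet,
    OrthologMap,
    common_genes,
    compare_event_rates,
    frequency_table,
    human_included_genes,
    mouse_alteration_set,
    overrepresentation,
)


def cohort_frame(rows):
    return pd.DataFrame(
        rows, columns=["tumor_id", "gene", "cn_state", "protein_change",
                       "variant_class", "deleterious_flag"]
    )


class TestHumanIncludedGenes:
    def test_two_tumor_boundary_inclusive(self):
        frame = cohort_frame(
            [("H1", "GENE1", "amp", "", "", False),
             ("H2", "GENE1", "amp", "", "", False),
             ("H1", "GENE2", "amp", "", "", False)]
        )
        out = human_included_genes(frame, "CNA", min_tumors=2)
        assert out.gene_names == {"GENE1"}

    def test_short_gene_excluded_from_cnd(self):
        frame = cohort_frame([(f"H{i}", "SHORT", "homdel", "", "", False) for i in range(5)]
                             + [(f"H{i}", "LONG", "homdel", "", "", False) for i in range(5)])
        out = human_included_genes(frame, "CND", min_tumors=2,
                                   gene_lengths={"SHORT": 900, "LONG": 5000})
        assert out.gene_names == {"LONG"}
        # exactly 1000 bp is not "longer than 1000"
        out = human_included_genes(frame, "CND", min_tumors=2,
                                   gene_lengths={"SHORT": 1000, "LONG": 1001})
        assert out.gene_names == {"LONG"}

    def test_partial_gene_amplification_excluded(self):
        frame = cohort_frame(
            [("H1", "GENE1", "amp", "", "", False), ("H2", "GENE1", "amp", "", "", False)]
        )
        frame["whole_gene"] = [True, False]
        out = human_included_genes(frame, "CNA", min_tumors=2)
        assert out.gene_names == set()

    def test_deleterious_flag_drives_nspm(self):
        frame = cohort_frame(
            [("H1", "GENE1", "", "R10H", "missense", True),
             ("H2", "GENE1", "", "R12H", "missense", False)]
        )
        out = human_included_genes(frame, "NSPM_InDel", min_tumors=1)
        assert out.genes == {"GENE1": frozenset({"H1"})}

    def test_min_tumors_monotonicity(self):
        rng = np.random.default_rng(3)
        rows = [(f"H{t}", f"GENE{g}", "amp", "", "", False)
                for g in range(10) for t in rng.choice(20, rng.integers(0, 6), replace=False)]
        frame = cohort_frame(rows)
        sizes = [len(human_included_genes(frame, "CNA", min_tumors=k).genes)
                 for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)


class TestCommonGenes:
    def test_disjoint_sets_zero_percent(self):
        mouse = AlterationSet("mouse", "CNA", {"Abc": frozenset({"M1"})})
        human = AlterationSet("human", "CNA", {"XYZ": frozenset({"H1"})})
        rep = common_genes(mouse, human, OrthologMap([("Abc", "ABC")]))
        assert rep.common_genes == () and rep.percentage == 0.0

    def test_unmapped_mouse_genes_stay_in_denominator(self):
        mouse = AlterationSet("mouse", "CNA",
                              {"Abc": frozenset({"M1"}), "Nomap": frozenset({"M2"})})
        human = AlterationSet("human", "CNA", {"ABC": frozenset({"H1"})})
        rep = common_genes(mouse, human, OrthologMap([("Abc", "ABC")]))
        assert rep.common_genes == ("Abc",)
        assert rep.mouse_total == 2
        assert rep.percentage == 50.0

    def test_empty_ortholog_map_means_no_common_genes(self):
        mouse = AlterationSet("mouse", "CND", {"Abc": frozenset({"M1"})})
        human = AlterationSet("human", "CND", {"ABC": frozenset({"H1"})})
        rep = common_genes(mouse, human, OrthologMap([]))
        assert rep.percentage == 0.0

    def test_class_mismatch_rejected(self):
        mouse = AlterationSet("mouse", "CNA", {})
        human = AlterationSet("human", "CND", {})
        with pytest.raises(ValueError, match="classes differ"):
            common_genes(mouse, human, OrthologMap([]))


class TestOrthologMap:
    def test_case_canonicalization(self):
        m = OrthologMap([("TRP53", "tp53")])
        assert m.to_human("trp53") == "TP53"
        assert m.to_human("Trp53") == "TP53"

    def test_conflicting_pairs_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            OrthologMap([("Abc", "ABC"), ("abc", "XYZ")])

    def test_identity_map(self):
        m = OrthologMap.identity_for(["Gene1", "Gene2"])
        assert m.to_human("Gene1") == "GENE1"


class TestFrequencyTable:
    def test_percentages(self):
        aset = AlterationSet(
            "mouse", "CNA",
            {"A": frozenset({f"M{i}" for i in range(8)}),
             "B": frozenset({"M1", "M2"}),
             "C": frozenset()},
        )
        out = frequency_table(aset, n_tumors=8).set_index("gene")
        assert out.loc["A", "percent"] == 100.0
        assert out.loc["B", "percent"] == 25.0
        assert "C" not in out.index


class TestCompareEventRates:
    def test_matches_hand_computed_welch(self):
        # {1,2,3} vs {11,12,13}: s^2 = 1 each, se = sqrt(2/3),
        # t = -10 / sqrt(2/3), Welch df = 4
        out = compare_event_rates([1, 2, 3], [11, 12, 13])
        t_hand = -10.0 / np.sqrt(2.0 / 3.0)
        p_hand = 2.0 * stats.t.sf(abs(t_hand), df=4)
        assert out["t"] == pytest.approx(t_hand)
        assert out["p"] == pytest.approx(p_hand)
        assert out["mouse_sem"] == pytest.approx(1.0 / np.sqrt(3))

    def test_zero_variance_shortcut(self):
        same = compare_event_rates([5, 5, 5], [5, 5])
        assert same["p"] == 1.0 and same["t"] == 0.0
        diff = compare_event_rates([5, 5, 5], [7, 7])
        assert diff["p"] == 0.0 and np.isinf(diff["t"])

    def test_detects_mouse_excess(self):
        rng = np.random.default_rng(21)
        mouse = rng.poisson(900, size=8)
        human = rng.poisson(300, size=100)
        out = compare_event_rates(mouse, human)
        assert out["mouse_mean"] > out["human_mean"]
        assert out["p"] < 0.01

    def test_small_cohorts_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_event_rates([1], [1, 2])


def brute_force_hypergeom_p(n_universe, set_size, list_size, overlap):
    """P(X >= overlap) by summing the exact counting formula."""
    total = comb(n_universe, list_size)
    hits = sum(
        comb(set_size, k) * comb(n_universe - set_size, list_size - k)
        for k in range(overlap, min(set_size, list_size) + 1)
    )
    return hits / total


class TestOverrepresentation:
    def test_matches_enumeration_on_20_gene_universe(self):
        universe = [f"G{i}" for i in range(20)]
        gene_set = universe[:5]
        gene_list = universe[1:5] + [universe[10]]  # overlap 4
        out = overrepresentation(gene_list, {"S": gene_set}, universe)
        expected = brute_force_hypergeom_p(20, 5, 5, 4)
        assert out.loc[0, "p"] == pytest.approx(expected)
        # and against literal enumeration of all C(20,5) draws
        count = sum(
            1 for draw in itertools.combinations(universe, 5)
            if len(set(draw) & set(gene_set)) >= 4
        )
        assert out.loc[0, "p"] == pytest.approx(count / comb(20, 5))

    def test_full_set_as_list_degenerate(self):
        universe = [f"G{i}" for i in range(5)]
        out = overrepresentation(universe, {"S": universe}, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_small_overlap_skipped(self):
        universe = [f"G{i}" for i in range(20)]
        sets = {"S0": universe[10:15], "S1": [universe[0]] + universe[15:19]}
        out = overrepresentation(universe[:5], sets, universe)  # overlaps 0 and 1
        assert len(out) == 0

    def test_bh_qvalues_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        universe = [f"G{i}" for i in range(40)]
        gene_list = list(rng.choice(universe, size=12, replace=False))
        sets = {f"S{k}": list(rng.choice(universe, size=10, replace=False)) for k in range(8)}
        out = overrepresentation(gene_list, sets, universe, min_overlap=1)
        if len(out):
            assert (out["q"].to_numpy() >= out["p"].to_numpy() - 1e-12).all()
            assert (np.diff(out["q"].to_numpy()) >= -1e-12).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="universe"):
            overrepresentation(["A"], {"S": ["A"]}, [])
        with pytest.raises(ValueError, match="outside universe"):
            overrepresentation(["A"], {"S": ["B"]}, ["B"])


class TestMouseAlterationSet:
    def test_from_gene_cnvs_and_mutations(self):
        cnvs = pd.DataFrame(
            {"gene": ["Abc", "Abc", "Def"], "tumor_id": ["M1", "M2", "M1"],
             "cnv_class": ["CNA", "CNA", "CND"]}
        )
        assert mouse_alteration_set(cnvs, "CNA").genes == {"Abc": frozenset({"M1", "M2"})}
        assert mouse_alteration_set(cnvs, "CND").genes == {"Def": frozenset({"M1"})}
        muts = pd.DataFrame(
            {"gene": ["Ghi"], "tumor_id": ["M3"], "deleterious": [True]}
        )
        assert mouse_alteration_set(muts, "NSPM_InDel").genes == {"Ghi": frozenset({"M3"})}
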