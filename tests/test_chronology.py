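"""Interval-comparison complement inference, bracketing and chromacy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palaeopsin.chronology import (
    PrecedenceVerdict,
    bracket_extant,
    chromacy,
    infer_all,
    infer_complement,
    precedes,
)
from palaeopsin.dated_trees import CredibleInterval
from palaeopsin.errors import ChronologyError
from palaeopsin.nomenclature import split_name
from palaeopsin.synthetic import simulate_duplications, simulate_species_tree, SimulationConfig

from _oracles import frontier_by_time_cut
from conftest import bare

CI = CredibleInterval


def interval(rng, lo=400.0, hi=700.0):
    a, b = sorted(rng.uniform(lo, hi, size=2))
    return CI(a, b)


class TestPrecedes:
    def test_divergence_entirely_younger_means_precedes(self):
        # first opsin duplication versus the Opabinia divergence
        assert precedes(CI(587, 615), CI(562, 585)) is PrecedenceVerdict.PRECEDES

    def test_any_overlap_is_ambiguous(self):
        # MWS/LWS duplication versus the Anomalocaris divergence: 580 > 577
        assert precedes(CI(577, 605), CI(558, 580)) is PrecedenceVerdict.AMBIGUOUS

    def test_boundary_equality_counts_as_overlap(self):
        assert precedes(CI(600, 600), CI(600, 600)) is PrecedenceVerdict.AMBIGUOUS
        assert precedes(CI(600, 610), CI(590, 600)) is PrecedenceVerdict.AMBIGUOUS

    def test_widening_never_creates_precedence(self):
        """Widening the divergence upward or the duplication downward can
        only move verdicts toward ambiguity (seeded randomised sweep)."""
        rng = np.random.default_rng(99)
        for _ in range(2000):
            dup, div = interval(rng), interval(rng)
            v0 = precedes(dup, div)
            wider_div = CI(div.young, div.old + rng.uniform(0, 50))
            lower_dup = CI(max(0.0, dup.young - rng.uniform(0, 50)), dup.old)
            for v in (precedes(dup, wider_div), precedes(lower_dup, div)):
                if v0 is PrecedenceVerdict.AMBIGUOUS:
                    assert v is PrecedenceVerdict.AMBIGUOUS


@pytest.fixture(scope="module")
def table(opsin_chain, divergences):
    return infer_all(None, opsin_chain, list(divergences.items()))


class TestInferComplement:
    @pytest.mark.parametrize(
        "focus,size,genes",
        [
            # NB: the narrative for this first split says the duplication
            # "postdates" it, yet the two intervals (587–615 and 572–595)
            # overlap; the CI rule therefore returns ambiguous — which gives
            # the same single-gene complement either way.
            ("Pambdelurion_split", 1, {"Rh7/UV/SWS/MWS/LWS"}),
            ("Opabinia_split", 2, {"Rh7/UV/SWS", "MWS/LWS"}),
            ("Anomalocaris_split", 2, {"Rh7/UV/SWS", "MWS/LWS"}),
            ("Fuxianhuia_split", 3, {"Rh7/UV/SWS", "MWS", "LWS"}),
            ("crown_Arthropoda", 4, {"Rh7", "UV/SWS", "MWS", "LWS"}),
        ],
    )
    def test_golden_stem_lineage_complements(self, opsin_chain, divergences, focus, size, genes):
        got = infer_complement(opsin_chain, divergences[focus])
        assert got == genes
        assert len(got) == size

    def test_complement_size_monotone_in_divergence_age(self, opsin_chain):
        """Older divergences can only inherit fewer (more ancestral) genes."""
        rng = np.random.default_rng(5)
        for _ in range(500):
            div = interval(rng, 450, 650)
            wider = CI(div.young, div.old + rng.uniform(0, 40))
            assert len(infer_complement(opsin_chain, wider)) <= len(
                infer_complement(opsin_chain, div)
            )

    def test_nesting_refinement_between_disjoint_divergences(self, opsin_chain):
        """If div1 is entirely younger than div2, complement(div1) refines
        complement(div2): every gene of the older complement is either kept
        or replaced by its own descendants."""
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(800):
            d1, d2 = interval(rng, 430, 680), interval(rng, 430, 680)
            if not d1.old < d2.young:  # need div1 strictly younger
                continue
            young_set = {split_name(g) for g in infer_complement(opsin_chain, d1)}
            old_set = {split_name(g) for g in infer_complement(opsin_chain, d2)}
            for g_old in old_set:
                assert g_old in young_set or any(g < g_old for g in young_set)
            checked += 1
        assert checked > 50

    def test_degenerate_intervals_equal_exact_time_cut(self):
        """With zero-width CIs the frontier equals the brute-force cut of
        true duplication times at the true divergence time."""
        rng = np.random.default_rng(8)
        cfg = SimulationConfig(seed=1)
        tree = simulate_species_tree(cfg, np.random.default_rng(1))
        span = tree.root.age
        for _ in range(60):
            k = int(rng.integers(1, 6))
            times = sorted(rng.uniform(5, span - 1, size=k), reverse=True)
            history = simulate_duplications(tree, times=list(times))
            for a in rng.uniform(0, span, size=10):
                got = infer_complement(history.glt, CI(a, a))
                assert got == frontier_by_time_cut(history.glt, a)

    def test_duplication_exactly_at_divergence_keeps_ancestral_gene(self):
        # one duplication at 600 Ma, divergence exactly at 600 Ma
        from palaeopsin.nomenclature import build_gene_lineage_tree, NamePrecedence

        glt = build_gene_lineage_tree(
            [({"a"}, {"b"}, CI(600, 600))], NamePrecedence(["a", "b"])
        )
        assert infer_complement(glt, CI(600, 600)) == {"a/b"}


class TestInferAll:
    def test_five_published_foci_sizes(self, table):
        assert [row.size for row in table] == [1, 2, 2, 3, 4]

    def test_empty_foci_yield_empty_table(self, opsin_chain):
        assert len(infer_all(None, opsin_chain, [])) == 0

    def test_row_order_follows_input(self, opsin_chain, divergences):
        rev = list(divergences.items())[::-1]
        t = infer_all(None, opsin_chain, rev)
        assert [r.label for r in t] == [lab for lab, _ in rev]

    def test_focus_without_ci_recorded_as_error_and_run_continues(self, species_tree, opsin_chain):
        t = infer_all(species_tree, opsin_chain, ["Mandibulata", "crown_Arthropoda"])
        assert t.rows[0].error is not None and "interval" in t.rows[0].error
        assert t.rows[1].size == 4

    def test_audit_trail_reproduces_each_verdict(self, table):
        for row in table:
            for v in row.audit:
                assert precedes(v.dup_ci, v.div_ci) is v.verdict

    def test_foci_resolved_through_species_tree_nodes(self, species_tree, opsin_chain, divergences):
        t = infer_all(species_tree, opsin_chain, [("Opabinia", "Pancrustacea")])
        assert t.rows[0].label == "Opabinia_split"
        assert t.rows[0].div == divergences["Opabinia_split"]
        assert t.rows[0].size == 2


class TestChromacy:
    @pytest.mark.parametrize(
        "genes,count,cls",
        [
            ({"Rh7/UV/SWS/MWS/LWS"}, 1, "monochromat"),
            ({"Rh7/UV/SWS", "MWS/LWS"}, 2, "dichromat"),
            ({"Rh7", "UV/SWS", "MWS", "LWS"}, 3, "trichromat"),
            ({"Rh7", "UV", "SWS", "MWS", "LWS"}, 4, "polychromat"),
            (set(), 0, "none"),
        ],
    )
    def test_classes(self, genes, count, cls):
        assert chromacy(genes) == (count, cls)

    def test_rh7_flag_can_count_rh7_as_visual(self):
        assert chromacy({"Rh7", "UV/SWS", "MWS", "LWS"}, rh7_nonvisual=False) == (
            4,
            "polychromat",
        )

    def test_visual_count_never_exceeds_complement_size(self, opsin_chain):
        rng = np.random.default_rng(17)
        for _ in range(300):
            comp = infer_complement(opsin_chain, interval(rng, 430, 680))
            n, _ = chromacy(comp)
            assert 0 <= n <= len(comp)


class TestBracketExtant:
    def test_presence_in_two_child_subtrees_forces_presence(self):
        tree = bare("((A,B),(C,D));")
        pres = {"A": {"X"}, "C": {"X"}, "B": set(), "D": set()}
        assert bracket_extant(tree, pres, tree.root) == {"X"}

    def test_gene_in_single_tip_absent_from_strict_ancestors(self):
        tree = bare("((A,B),(C,D));")
        pres = {"A": {"X"}, "B": set(), "C": set(), "D": set()}
        assert bracket_extant(tree, pres, tree.root) == set()
        assert bracket_extant(tree, pres, ("A", "B")) == set()
        assert bracket_extant(tree, pres, "A") == {"X"}

    def test_uniform_single_gene_clade_brackets_exactly_that_gene(self):
        # velvet-worm-style clade: every member carries only the root gene
        tree = bare("((O1,O2),O3);")
        pres = {t: {"Rh7/UV/SWS/MWS/LWS"} for t in ("O1", "O2", "O3")}
        assert bracket_extant(tree, pres, tree.root) == {"Rh7/UV/SWS/MWS/LWS"}

    def test_mandibulate_ancestor_brackets_crown_genes(self, species_tree, presence):
        got = bracket_extant(species_tree, presence, "Mandibulata")
        assert {split_name(g) for g in got} == {
            split_name(g) for g in ("Rh7", "UV/SWS", "MWS", "LWS")
        }

    def test_fossil_descendants_rejected_with_guidance(self, species_tree, presence):
        with pytest.raises(ChronologyError, match="infer_complement"):
            bracket_extant(species_tree, presence, "crown_Arthropoda")

    def test_unknown_gene_names_rejected(self):
        tree = bare("(A,B);")
        with pytest.raises(ChronologyError, match="unknown gene"):
            bracket_extant(tree, {"A": {"Zeta"}}, tree.root, known_genes=["X"])
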