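"""Gene-gene similarity measures: the generalized cosine and the four
reference measures, their worked examples and contracts."""

import math

import pytest

from intelligo import (
    AnnotationRecord,
    CorpusSpec,
    GeneVector,
    ICTable,
    MISSING,
    UndefinedICError,
    UndefinedSimilarityError,
    almubaid_sim,
    build_vectors,
    compute_iaf,
    curate,
    extend_with_ancestors,
    generate_corpus,
    get_weight_list,
    intelligo_sim,
    is_missing,
    lord_normalize,
    lord_sim,
    resnik_term_sim,
    simgic_sim,
    term_ic,
    weighted_cosine_sim,
)


def ann(gene, term, evidence="IDA"):
    return AnnotationRecord(gene=gene, term=term, evidence=evidence,
                            aspect="BP", taxon=1)


@pytest.fixture(scope="module")
def fix_ic(fixa):
    """IC table where half of a 10-gene corpus sits at or below term B."""
    recs = [ann(f"G{i}", t) for i, t in enumerate(
        ["B", "D", "E", "F", "G",      # 5 genes under B (ancestor closure hits B)
         "C", "C", "I", "I", "I"])]    # 5 genes elsewhere
    return term_ic(recs, fixa)


class TestInformationContent:
    def test_descendant_inclusive_probability(self, fixa, fix_ic):
        # 5 of 10 genes annotated at or below B -> p = 0.5, IC = -log10(0.5)
        assert fix_ic.probability("B") == pytest.approx(0.5)
        assert fix_ic["B"] == pytest.approx(math.log10(2), abs=1e-12)

    def test_root_and_saturated_terms(self, fixa, fix_ic):
        assert fix_ic["Root"] == 0.0  # every gene is under the global root
        assert fix_ic.probability("E") == pytest.approx(0.1)
        assert fix_ic["E"] == pytest.approx(1.0)

    def test_unseen_term_raises(self, fixa):
        ic = term_ic([ann("G1", "B")], fixa)
        with pytest.raises(UndefinedICError):
            ic["I"]

    def test_resnik(self, fixa, fix_ic):
        assert resnik_term_sim("D", "D", fix_ic, fixa) == fix_ic["D"]
        assert resnik_term_sim("B", "I", fix_ic, fixa) == 0.0  # LCA is Root
        assert resnik_term_sim("B", "C", fix_ic, fixa) == fix_ic["A"]

    def test_resnik_multiple_lcas_takes_max_ic(self, fixa, fix_ic):
        # LCAset(F, G) = {B, C}; the most informative common ancestor wins
        assert resnik_term_sim("F", "G", fix_ic, fixa) == max(
            fix_ic["B"], fix_ic["C"]
        )


class TestIntelligo:
    def test_self_similarity_is_one(self, fixa):
        g = GeneVector("g", {"B": 1.2})
        assert intelligo_sim(g, g, fixa) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("alpha, beta", [(1.0, 1.0), (0.3, 2.5), (7.0, 0.1)])
    def test_single_term_coefficients_cancel(self, fixa, alpha, beta):
        g = GeneVector("g", {"B": alpha})
        h = GeneVector("h", {"C": beta})
        assert intelligo_sim(g, h, fixa) == pytest.approx(0.5)

    def test_two_term_worked_example(self, fixa):
        g = GeneVector("g", {"B": 1.0, "C": 1.0})
        h = GeneVector("h", {"B": 1.0})
        # numerator 1 + 0.5; g.g = 1 + 1 + 2*0.5 = 3
        assert intelligo_sim(g, h, fixa) == pytest.approx(1.5 / math.sqrt(3.0))

    def test_missing_on_empty_vector(self, fixa):
        g = GeneVector("g", {"B": 1.0})
        assert is_missing(intelligo_sim(g, GeneVector("h", {}), fixa))
        assert is_missing(intelligo_sim(GeneVector("h", {}), g, fixa))

    def test_cross_aspect_orthogonal_vectors(self, fixa):
        g = GeneVector("g", {"B": 2.0})
        h = GeneVector("h", {"I": 3.0})
        assert intelligo_sim(g, h, fixa) == 0.0


class TestLord:
    def test_single_pair_is_resnik(self, fixa, fix_ic):
        assert lord_sim({"D"}, {"D"}, fix_ic, fixa) == fix_ic["D"]

    def test_root_only_pairs_average_zero(self, fixa, fix_ic):
        assert lord_sim({"B"}, {"I"}, fix_ic, fixa) == 0.0

    def test_cross_pair_average(self, fixa):
        ic = ICTable({"Root": 1.0, "A": 10 ** -0.2, "B": 0.1, "C": 0.1,
                      "F": 0.01})
        # brute-force mean of resnik over {B, C} x {F}
        expected = (resnik_term_sim("B", "F", ic, fixa)
                    + resnik_term_sim("C", "F", ic, fixa)) / 2.0
        assert lord_sim({"B", "C"}, {"F"}, ic, fixa) == pytest.approx(expected)
        assert expected == pytest.approx((1.0 + 1.0) / 2.0)  # both LCAs have IC 1

    def test_missing_on_empty_set(self, fixa, fix_ic):
        assert is_missing(lord_sim(set(), {"B"}, fix_ic, fixa))

    def test_normalize(self):
        assert lord_normalize([0.5, 1.0, 2.0]) == [0.25, 0.5, 1.0]
        assert lord_normalize([0.7]) == [1.0]
        assert lord_normalize([0.0, 0.0, 0.0]) == [0.0, 0.0, 0.0]
        out = lord_normalize([1.0, MISSING, 4.0])
        assert out[0] == 0.25 and is_missing(out[1]) and out[2] == 1.0
        with pytest.raises(UndefinedSimilarityError):
            lord_normalize([MISSING, MISSING])


class TestAlMubaid:
    def test_identical_single_terms(self, fixa):
        assert almubaid_sim({"D"}, {"D"}, fixa) == 1.0

    def test_transfer_function(self, fixa):
        # min_spl(B, C) = 2 -> exp(-0.2 * 2)
        assert almubaid_sim({"B"}, {"C"}, fixa) == pytest.approx(math.exp(-0.4))

    def test_custom_decay(self, fixa):
        assert almubaid_sim({"B"}, {"C"}, fixa, f=0.5) == pytest.approx(
            math.exp(-1.0))

    def test_strictly_decreasing_in_mean_pl(self, fixa):
        # mean PLs 0 < 1 < 2 < 4 give strictly decreasing similarities
        sims = [
            almubaid_sim({"D"}, {"D"}, fixa),
            almubaid_sim({"E"}, {"D"}, fixa),
            almubaid_sim({"B"}, {"C"}, fixa),
            almubaid_sim({"B"}, {"I"}, fixa),  # meets only at the root: PL 4
        ]
        assert all(1.0 >= a > b > 0.0 for a, b in zip(sims, sims[1:]))

    def test_missing_on_empty_set(self, fixa):
        assert is_missing(almubaid_sim(set(), {"B"}, fixa))


class TestWeightedCosine:
    def test_identical_vectors(self):
        g = GeneVector("g", {"B": 1.3, "C": 0.4})
        assert weighted_cosine_sim(g, g) == pytest.approx(1.0)

    def test_disjoint_terms_score_zero(self):
        g = GeneVector("g", {"B": 1.0})
        h = GeneVector("h", {"C": 1.0})
        assert weighted_cosine_sim(g, h) == 0.0

    def test_partial_overlap(self):
        g = GeneVector("g", {"B": 1.0, "C": 1.0})
        h = GeneVector("h", {"B": 1.0})
        assert weighted_cosine_sim(g, h) == pytest.approx(1.0 / math.sqrt(2.0))

    def test_missing_on_empty(self):
        assert is_missing(weighted_cosine_sim(GeneVector("g", {}),
                                              GeneVector("h", {"B": 1.0})))


class TestSimGIC:
    def test_extend_with_ancestors(self, fixa):
        assert extend_with_ancestors({"E"}, fixa) == {"E", "D", "B", "C", "A"}
        assert extend_with_ancestors({"A"}, fixa) == {"A"}
        assert extend_with_ancestors(set(), fixa) == set()

    def test_identical_sets(self, fixa, fix_ic):
        assert simgic_sim({"D", "F"}, {"D", "F"}, fix_ic, fixa) == 1.0

    def test_weighted_jaccard_arithmetic(self, fixa):
        # extended sets {A, B} and {A, C} with IC(A)=1, IC(B)=IC(C)=2
        ic = ICTable({"A": 0.1, "B": 0.01, "C": 0.01})
        assert simgic_sim({"B"}, {"C"}, ic, fixa) == pytest.approx(0.2)

    def test_cross_aspect_sets_score_zero(self, fixa, fix_ic):
        # extended sets {A, B} vs {H, I} are disjoint with positive ICs
        assert simgic_sim({"B"}, {"I"}, fix_ic, fixa) == 0.0

    def test_zero_ic_union_is_missing(self, fixa):
        ic = ICTable({"A": 1.0, "B": 1.0, "C": 1.0})  # p=1 everywhere -> IC 0
        assert is_missing(simgic_sim({"B"}, {"C"}, ic, fixa))

    def test_nested_sets_ratio(self, fixa, fix_ic):
        # extended({E}) strictly contains extended({D}); ratio of IC sums
        inner = extend_with_ancestors({"D"}, fixa)
        outer = extend_with_ancestors({"E"}, fixa)
        expected = (sum(fix_ic[t] for t in inner)
                    / sum(fix_ic[t] for t in outer))
        assert simgic_sim({"D"}, {"E"}, fix_ic, fixa) == pytest.approx(expected)

    def test_missing_on_empty_set(self, fixa, fix_ic):
        assert is_missing(simgic_sim(set(), {"B"}, fix_ic, fixa))


class TestSymmetryOnRandomCorpora:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_measures_symmetric(self, fixa, seed):
        recs = generate_corpus(CorpusSpec(n_genes=8, seed=seed), fixa)
        wl = get_weight_list("list2")
        curated = curate(recs, wl)
        iaf = compute_iaf(recs)
        vectors = build_vectors(curated, iaf)
        ic = term_ic(recs, fixa)
        genes = sorted(curated)
        for i, a in enumerate(genes):
            for b in genes[i:]:
                va, vb = vectors[a], vectors[b]
                ta, tb = set(curated[a]), set(curated[b])
                pairs = [
                    (intelligo_sim(va, vb, fixa), intelligo_sim(vb, va, fixa)),
                    (lord_sim(ta, tb, ic, fixa), lord_sim(tb, ta, ic, fixa)),
                    (almubaid_sim(ta, tb, fixa), almubaid_sim(tb, ta, fixa)),
                    (weighted_cosine_sim(va, vb), weighted_cosine_sim(vb, va)),
                    (simgic_sim(ta, tb, ic, fixa), simgic_sim(tb, ta, ic, fixa)),
                ]
                for x, y in pairs:
                    if is_missing(x) or is_missing(y):
                        assert is_missing(x) and is_missing(y)
                    else:
                        assert x == pytest.approx(y, abs=1e-12)
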