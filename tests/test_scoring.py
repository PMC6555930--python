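"""Interaction-scoring schemes and matrix construction."""

import numpy as np
import pytest

from drugsig.chem import Fingerprint
from drugsig.scoring import (
    SCHEMES,
    BindingSite,
    InteractionMatrix,
    Protein,
    build_interaction_matrix,
    count_all_zero_signatures,
    normalize_bsscores,
    score_best_bs,
    score_best_ob,
    score_best_ob_plus_bs,
    score_best_ob_times_bs,
    score_pair,
)

from conftest import compound, fp, protein

# compound {1,2,3,4}; ligand_a {1,2} -> ob 0.5 ; ligand_b {1,2,3,4} -> ob 1.0
C = compound("c", 1, 2, 3, 4)
LIG_HALF = fp(1, 2)          # obscore 0.5
LIG_FULL = fp(1, 2, 3, 4)    # obscore 1.0
LIG_FIFTH = fp(1, 5, 6, 7)   # obscore 1/7


class TestPerPairSchemes:
    def test_best_ob_takes_max_over_sites(self):
        p = protein("p", (0.9, LIG_HALF), (0.1, LIG_FULL))
        assert score_best_ob(C, p) == 1.0

    def test_best_bs_follows_top_confidence_site(self):
        # best site has the weaker ligand: Best BS < Best OB
        p = protein("p", (0.9, LIG_HALF), (0.4, LIG_FULL))
        assert score_best_bs(C, p) == 0.5

    def test_best_bs_tie_broken_by_input_order(self):
        p = protein("p", (0.5, LIG_HALF), (0.5, LIG_FULL))
        assert score_best_bs(C, p) == 0.5

    def test_best_ob_plus_bs(self):
        p = protein("p", (0.8, LIG_HALF), (0.4, LIG_FULL))
        assert score_best_ob_plus_bs(C, p) == pytest.approx(1.4)

    def test_best_ob_times_bs(self):
        p = protein("p", (0.8, LIG_HALF), (0.4, LIG_FULL))
        assert score_best_ob_times_bs(C, p) == pytest.approx(0.4)

    def test_product_picks_different_site_than_sum(self):
        # sum favours (0.4 ob + 0.8 bs)=1.2 over (0.7+0.4)=1.1;
        # product favours 0.7*0.4=0.28 over 0.4*0.8=0.32 -> actually 0.32 wins
        p = protein("p", (0.8, fp(1, 2, 3, 4, 5, 10, 20, 30, 40, 50)), (0.4, fp(2, 3, 4)))
        ob1 = score_best_ob(C, protein("q", (0.8, fp(1, 2, 3, 4, 5, 10, 20, 30, 40, 50))))
        ob2 = score_best_ob(C, protein("q", (0.4, fp(2, 3, 4))))
        assert score_best_ob_plus_bs(C, p) == pytest.approx(max(ob1 + 0.8, ob2 + 0.4))
        assert score_best_ob_times_bs(C, p) == pytest.approx(max(ob1 * 0.8, ob2 * 0.4))

    @pytest.mark.parametrize(
        "scorer",
        [score_best_ob, score_best_bs, score_best_ob_plus_bs, score_best_ob_times_bs],
    )
    def test_no_sites_scores_zero(self, scorer):
        assert scorer(C, Protein(id="empty")) == 0.0

    def test_single_site_degeneracy(self):
        # all schemes reduce to the formula applied to the lone site
        p = protein("p", (0.5, LIG_HALF))
        assert score_best_ob(C, p) == 0.5
        assert score_best_bs(C, p) == 0.5
        assert score_best_ob_plus_bs(C, p) == 1.0
        assert score_best_ob_times_bs(C, p) == 0.25

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="rocs"):
            score_pair(C, protein("p", (0.5, LIG_HALF)), "rocs")


def _random_instance(rng, n_compounds, n_proteins):
    compounds = [
        compound(f"c{i:02d}", *rng.choice(32, size=rng.integers(0, 9), replace=False))
        for i in range(n_compounds)
    ]
    proteins = []
    for j in range(n_proteins):
        sites = [
            BindingSite(
                site_id=f"s{s}",
                bsscore=float(rng.uniform()),
                ligand=Fingerprint(
                    frozenset(rng.choice(32, size=rng.integers(0, 9), replace=False).tolist())
                ),
            )
            for s in range(rng.integers(0, 4))
        ]
        proteins.append(Protein(id=f"p{j:02d}", sites=sites))
    return compounds, proteins


class TestBuildMatrix:
    def test_shape_and_per_pair_definition(self, toy_library):
        proteins = [
            protein("p0", (0.2, LIG_HALF), (0.7, LIG_FULL)),
            protein("p1", (0.5, LIG_FIFTH)),
            Protein(id="p2"),
        ]
        m = build_interaction_matrix(toy_library, proteins, "best_ob",
                                     normalize_bsscore=False)
        assert m.scores.shape == (3, 3)
        for i, c in enumerate(toy_library):
            for j, p in enumerate(proteins):
                assert m.scores[i, j] == score_best_ob(c, p)

    def test_identical_fingerprints_identical_rows(self):
        compounds = [compound("a", 1, 2), compound("b", 1, 2)]
        proteins = [protein("p", (0.3, LIG_HALF), (0.9, LIG_FULL))]
        m = build_interaction_matrix(compounds, proteins, "best_ob_times_bs")
        assert np.array_equal(m.scores[0], m.scores[1])

    def test_zero_bsscores_collapse_sum_to_ob(self, toy_library):
        proteins = [protein("p0", (0.0, LIG_HALF), (0.0, LIG_FULL)),
                    protein("p1", (0.0, LIG_FIFTH))]
        ob = build_interaction_matrix(toy_library, proteins, "best_ob",
                                      normalize_bsscore=False)
        both = build_interaction_matrix(toy_library, proteins, "best_ob_plus_bs",
                                        normalize_bsscore=False)
        assert np.allclose(ob.scores, both.scores)

    def test_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            compounds, proteins = _random_instance(rng, 10, 8)
            for scheme in SCHEMES:
                m = build_interaction_matrix(compounds, proteins, scheme,
                                             normalize_bsscore=False)
                for i, c in enumerate(compounds):
                    for j, p in enumerate(proteins):
                        assert m.scores[i, j] == score_pair(c, p, scheme)

    def test_best_ob_invariant_to_bsscore_permutation(self):
        rng = np.random.default_rng(3)
        compounds, proteins = _random_instance(rng, 6, 5)
        shuffled = []
        for p in proteins:
            scores = [s.bsscore for s in p.sites]
            rng.shuffle(scores)
            shuffled.append(Protein(id=p.id, sites=[
                BindingSite(site_id=s.site_id, bsscore=v, ligand=s.ligand)
                for s, v in zip(p.sites, scores)
            ]))
        a = build_interaction_matrix(compounds, proteins, "best_ob")
        b = build_interaction_matrix(compounds, shuffled, "best_ob")
        assert np.array_equal(a.scores, b.scores)

    def test_empty_library_rejected(self, toy_library):
        with pytest.raises(ValueError):
            build_interaction_matrix([], [protein("p", (0.1, LIG_HALF))], "best_ob")
        with pytest.raises(ValueError):
            build_interaction_matrix(toy_library, [], "best_ob")

    def test_unknown_scheme_rejected(self, toy_library):
        with pytest.raises(ValueError, match="unknown"):
            build_interaction_matrix(toy_library, [protein("p", (0.1, LIG_HALF))], "v1")


class TestNormalization:
    def test_minmax_to_unit_interval(self):
        proteins = [protein("p", (2.0, LIG_HALF), (6.0, LIG_FULL)),
                    protein("q", (4.0, LIG_FIFTH))]
        normed = normalize_bsscores(proteins)
        values = [s.bsscore for p in normed for s in p.sites]
        assert values == [0.0, 1.0, 0.5]

    def test_constant_positive_scores_map_to_one(self):
        normed = normalize_bsscores([protein("p", (3.0, LIG_HALF), (3.0, LIG_FULL))])
        assert [s.bsscore for s in normed[0].sites] == [1.0, 1.0]

    def test_input_not_mutated(self):
        proteins = [protein("p", (2.0, LIG_HALF), (6.0, LIG_FULL))]
        normalize_bsscores(proteins)
        assert [s.bsscore for s in proteins[0].sites] == [2.0, 6.0]


class TestZeroSignatureDiagnostics:
    def test_counts_and_ids(self):
        m = InteractionMatrix(
            compound_ids=["a", "b", "c"],
            protein_ids=["p", "q"],
            scores=np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.0]]),
        )
        n, ids = count_all_zero_signatures(m)
        assert (n, ids) == (2, ["a", "c"])

    def test_all_positive(self):
        m = InteractionMatrix(["a", "b"], ["p"], np.array([[0.1], [0.2]]))
        assert count_all_zero_signatures(m) == (0, [])

    def test_empty_fingerprints_give_zero_rows_under_best_ob(self):
        compounds = [compound("a", 1), compound("b"), compound("c", 2), compound("d"),
                     compound("e", 1, 2)]
        proteins = [protein("p", (0.5, fp(1, 2)))]
        m = build_interaction_matrix(compounds, proteins, "best_ob")
        n, ids = count_all_zero_signatures(m)
        assert (n, ids) == (2, ["b", "d"])
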