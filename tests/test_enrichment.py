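import itertools

import numpy as np
import pandas as pd
import pytest

from scstate.enrichment import (
    RankedList,
    assign_superclusters,
    enrichment_score,
    nes_and_p,
    nes_matrix,
    run_enrichment,
    supercluster_signatures,
    top_genesets,
)
from scstate.io_core import GeneSetCollection


def brute_es(genes, scores, members, weight_exp=1.0):
    """Independent running-sum walk used as the ES oracle."""
    hits = [g in set(members) for g in genes]
    nh = sum(hits)
    n = len(genes)
    hit_total = sum(abs(s) ** weight_exp for g, s, h in zip(genes, scores, hits) if h)
    running, cur = [], 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            cur += (abs(s) ** weight_exp / hit_total) if hit_total else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
    return max(running, key=abs)


def _ranked(n=20, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    return RankedList([f"g{i}" for i in range(n)], scores)


class TestEnrichmentScore:
    def test_six_gene_walk(self):
        ranked = RankedList([f"g{i}" for i in range(1, 7)],
                            np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]))
        expected = brute_es(ranked.genes, ranked.scores, {"g1", "g6"})
        es, _ = enrichment_score(ranked, {"g1", "g6"})
        assert es == pytest.approx(expected)
        assert es == pytest.approx(0.5)  # frozen from the 6-step enumeration

    def test_top_block_positive_closed_form(self):
        ranked = _ranked(12, seed=1)
        members = ranked.genes[:4]
        es, running = enrichment_score(ranked, members)
        # contiguous prefix: running sum peaks right after the block
        w = np.abs(ranked.scores[:4])
        assert es == pytest.approx(1.0)  # all hit weight accumulated before any miss
        assert np.argmax(running) == 3

    def test_geneset_is_everything(self):
        ranked = _ranked(8, seed=2)
        es, _ = enrichment_score(ranked, ranked.genes)
        assert es == 1.0

    def test_geneset_outside_errors(self):
        with pytest.raises(ValueError, match="no gene"):
            enrichment_score(_ranked(), {"nope"})

    def test_matches_brute_force_exhaustively(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 51)
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedList([f"g{i}" for i in range(n)], scores)
            k = rng.integers(1, n)
            members = list(rng.choice(ranked.genes, size=k, replace=False))
            es, _ = enrichment_score(ranked, members)
            assert es == pytest.approx(brute_es(ranked.genes, scores, members))

    def test_weight_zero_invariant_to_monotone_rescale(self):
        # classic KS case: only ranks matter
        ranked = _ranked(15, seed=4)
        rescaled = RankedList(ranked.genes, np.exp(ranked.scores / 2.0))
        members = ranked.genes[3:8]
        es1, _ = enrichment_score(ranked, members, weight_exp=0.0)
        es2, _ = enrichment_score(rescaled, members, weight_exp=0.0)
        assert es1 == pytest.approx(es2)


class TestNesAndP:
    def test_determinism(self):
        ranked = _ranked(50, seed=5)
        members = ranked.genes[:6]
        r1 = nes_and_p(ranked, members, n_perm=200, seed=9)
        r2 = nes_and_p(ranked, members, n_perm=200, seed=9)
        assert r1 == r2

    def test_top_block_attains_minimal_p(self):
        # the smallest attainable p: no null geneset is as extreme
        ranked = _ranked(60, seed=6)
        res = nes_and_p(ranked, ranked.genes[:6], n_perm=200, seed=0)
        assert res["n_more_extreme"] == 0
        assert res["p"] <= 0.02
        assert res["nes"] > 1.0

    def test_null_geneset_large_p(self):
        # distributional check over seeds: random sets on a random ranking
        ps, ness = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            ranked = _ranked(80, seed=seed + 100)
            members = list(rng.choice(ranked.genes, size=8, replace=False))
            res = nes_and_p(ranked, members, n_perm=200, seed=seed)
            ps.append(res["p"])
            ness.append(abs(res["nes"]))
        assert np.median(ps) > 0.2
        assert np.median(ness) < 1.5

    def test_permutation_p_matches_exact_enumeration(self):
        # exchangeable null oracle: enumerate all C(8,2)=28 same-size genesets
        ranked = _ranked(8, seed=7)
        members = [ranked.genes[1], ranked.genes[4]]
        es, _ = enrichment_score(ranked, members)
        null = [brute_es(ranked.genes, ranked.scores, list(c))
                for c in itertools.combinations(ranked.genes, 2)]
        same = [e for e in null if e * np.sign(es) > 0]
        exact_p = sum(abs(e) >= abs(es) - 1e-12 for e in same) / len(same)
        res = nes_and_p(ranked, members, n_perm=4000, seed=1)
        # MC standard error uses the matching-sign permutation count
        n_same = round((1 + res["n_more_extreme"]) / res["p"] - 1)
        mc_se = np.sqrt(exact_p * (1 - exact_p) / n_same)
        assert abs(res["p"] - exact_p) <= 3 * mc_se + 2 / n_same

    def test_nperm_floor(self):
        with pytest.raises(ValueError, match="n_perm"):
            nes_and_p(_ranked(), ["g0"], n_perm=10)


class TestTopGenesets:
    def _results(self):
        return pd.DataFrame({
            "cluster": [0, 0, 1, 1],
            "geneset": ["A", "B", "A", "C"],
            "nes": [1.0, -3.0, 2.5, 2.0],
        })

    def test_single_best(self):
        assert top_genesets(self._results(), 1) == ["B"]

    def test_order_and_truncation(self):
        assert top_genesets(self._results(), 2) == ["B", "A"]
        assert top_genesets(self._results(), 99) == ["B", "A", "C"]

    def test_lexicographic_ties(self):
        df = pd.DataFrame({"cluster": [0, 0], "geneset": ["Z", "A"], "nes": [2.0, -2.0]})
        assert top_genesets(df, 2) == ["A", "Z"]


class TestSuperclusters:
    def test_orthogonal_rows_are_singletons(self):
        nes = pd.DataFrame(np.eye(3) * 5, index=[0, 1, 2], columns=["a", "b", "c"])
        labels, _ = assign_superclusters(nes, 3)
        assert labels.nunique() == 3

    def test_duplicate_rows_co_assigned(self):
        nes = pd.DataFrame([[5.0, 0.0], [5.0, 0.0], [0.0, 5.0], [0.1, 4.9]],
                           index=[0, 1, 2, 3], columns=["a", "b"])
        labels, _ = assign_superclusters(nes, 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        block_means = np.repeat(np.eye(3, 4) * 4, 2, axis=0)
        nes = pd.DataFrame(rng.normal(size=(6, 4)) + block_means,
                           index=list(range(6)), columns=list("abcd"))
        l1, _ = assign_superclusters(nes, 3)
        shuffled = nes.sample(frac=1, random_state=0)
        l2, _ = assign_superclusters(shuffled, 3)
        grouping1 = {i: {j for j in nes.index if l1[j] == l1[i]} for i in nes.index}
        grouping2 = {i: {j for j in nes.index if l2[j] == l2[i]} for i in nes.index}
        assert grouping1 == grouping2

    def test_too_many_superclusters(self):
        nes = pd.DataFrame(np.eye(2), index=[0, 1], columns=["a", "b"])
        with pytest.raises(ValueError, match="n_super"):
            assign_superclusters(nes, 3)

    def test_proliferation_ordering(self):
        nes = pd.DataFrame([[3.0], [-3.0], [0.0]], index=[0, 1, 2], columns=["prolif"])
        labels, _ = assign_superclusters(nes, 3, proliferation_sets=["prolif"])
        assert labels[1] == "A" and labels[2] == "B" and labels[0] == "C"


class TestSignatures:
    def test_definition(self):
        ups = {
            ("A", "B"): ["g1", "g2"],
            ("A", "C"): ["g1", "g3"],
            ("B", "A"): ["g4"],
            ("B", "C"): ["g4", "g5"],
            ("C", "A"): ["g6"],
            ("C", "B"): ["g6"],
        }
        sig = supercluster_signatures(ups)
        assert sig["A"] == ["g1"]
        assert sig["B"] == ["g4"]
        assert sig["C"] == ["g6"]

    def test_gene_up_elsewhere_excluded(self):
        ups = {("A", "B"): ["g1"], ("B", "A"): ["g1"]}
        sig = supercluster_signatures(ups)
        assert sig["A"] == [] and sig["B"] == []

    def test_pairwise_disjoint(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        ups = {}
        for x, y in itertools.permutations("ABC", 2):
            ups[(x, y)] = list(rng.choice(genes, size=15, replace=False))
        sig = supercluster_signatures(ups)
        for a, b in itertools.combinations(sig, 2):
            assert not set(sig[a]) & set(sig[b])


class TestRunEnrichment:
    def test_frame_and_determinism(self):
        rankings = {0: _ranked(40, seed=1), 1: _ranked(40, seed=2)}
        sets = GeneSetCollection({"TOP": [f"g{i}" for i in range(5)],
                                 "RAND": ["g7", "g13", "g21"]})
        r1 = run_enrichment(rankings, sets, n_perm=150, seed=3)
        r2 = run_enrichment(rankings, sets, n_perm=150, seed=3)
        pd.testing.assert_frame_equal(r1, r2)
        assert set(r1["cluster"]) == {0, 1}
        assert ((r1["es"] >= -1) & (r1["es"] <= 1)).all()
        assert ((r1["p"] > 0) & (r1["p"] <= 1)).all()
        assert (np.sign(r1["nes"]) == np.sign(r1["es"])).all()

    def test_nes_matrix_shape(self):
        rankings = {0: _ranked(30, seed=4), 1: _ranked(30, seed=5)}
        sets = GeneSetCollection({"S1": ["g0", "g1"], "S2": ["g5", "g9"]})
        res = run_enrichment(rankings, sets, n_perm=120, seed=0)
        wide = nes_matrix(res, ["S1", "S2"])
        assert wide.shape == (2, 2)
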