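import numpy as np
import pandas as pd
import pytest

from nddmeta.core_io import GeneSetCollection
from nddmeta.enrichment import (
    RankedList,
    cluster_terms,
    gsea_es,
    gsea_preranked,
    rank_genes,
    resnik_matrix,
    resnik_similarity,
    signed_log10_p,
)
from nddmeta.synthetic_data import SimulationConfig, simulate_collection

from .conftest import make_dataset


def ranked(scores, ids=None, seed=0):
    ids = ids if ids is not None else [f"g{i}" for i in range(len(scores))]
    order = np.argsort(-np.asarray(scores, dtype=float), kind="mergesort")
    return RankedList(
        np.asarray(ids, dtype=object)[order],
        np.asarray(scores, dtype=float)[order], seed,
    )


def brute_force_es(gene_ids, scores, members, q=1.0):
    """Straightforward running-sum loop, independent of the implementation."""
    members = set(members)
    hits = [g in members for g in gene_ids]
    n_hits = sum(hits)
    N = len(gene_ids)
    n_r = sum(abs(s) ** q for s, h in zip(scores, hits) if h)
    running, best = 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            running += (abs(s) ** q / n_r) if n_r > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / (N - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def es_oracle_diff(impl, brute):
    """Discrepancy vs the oracle, treating equal-magnitude extrema on
    opposite sides of zero as a tie (either sign is then valid)."""
    if abs(abs(impl) - abs(brute)) < 1e-9 and np.sign(impl) != np.sign(brute):
        return abs(abs(impl) - abs(brute))
    return abs(impl - brute)


class TestRankGenes:
    def test_orders_by_log2fc_descending(self):
        ds = make_dataset("d", ["A", "B", "C"], log2fc=[2.0, -1.0, 0.5])
        rl = rank_genes(ds)
        assert list(rl.gene_ids) == ["A", "C", "B"]

    def test_tie_break_deterministic(self):
        ds = make_dataset("d", list("ABCDE"), log2fc=[1.0, 1.0, 1.0, 1.0, 0.0])
        a = rank_genes(ds, seed=42)
        b = rank_genes(ds, seed=42)
        assert list(a.gene_ids) == list(b.gene_ids)
        assert a.tie_break_seed == 42

    def test_all_missing_rejected(self):
        ds = make_dataset("d", ["A", "B"], log2fc=[np.nan, np.nan])
        with pytest.raises(ValueError):
            rank_genes(ds)


class TestEnrichmentScore:
    def test_top_gene_set_reaches_plus_one(self):
        assert gsea_es(ranked([4, 3, 2, 1]), {"g0"}) == pytest.approx(1.0)

    def test_bottom_gene_set_reaches_minus_one(self):
        assert gsea_es(ranked([4, 3, 2, 1]), {"g3"}) == pytest.approx(-1.0)

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(ranked([4, 3, 2, 1]), {"nope"})

    def test_full_cover_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(ranked([4, 3, 2, 1]), {"g0", "g1", "g2", "g3"})

    def test_matches_bruteforce_on_random_instances(self, rng):
        """200 random instances (N <= 50) against the independent loop."""
        for _ in range(200):
            N = int(rng.integers(5, 51))
            scores = np.round(rng.normal(size=N) * 3, 3)
            scores += rng.random(N) * 1e-6  # avoid exact ties
            rl = ranked(scores)
            m = int(rng.integers(1, N))
            members = set(rng.choice(rl.gene_ids, size=m, replace=False))
            q = float(rng.choice([0.0, 1.0, 2.0]))
            expected = brute_force_es(rl.gene_ids, rl.scores, members, q)
            got = gsea_es(rl, members, weight_exponent=q)
            assert es_oracle_diff(got, expected) < 1e-12

    def test_scale_invariance_and_bounds(self, rng):
        for _ in range(20):
            scores = rng.normal(size=30)
            rl = ranked(scores)
            members = set(rng.choice(rl.gene_ids, 6, replace=False))
            es = gsea_es(rl, members)
            assert -1.0 <= es <= 1.0
            scaled = RankedList(rl.gene_ids, rl.scores * 7.3, 0)
            assert gsea_es(scaled, members) == pytest.approx(es, abs=1e-12)


class TestSignedLog10P:
    @pytest.mark.parametrize(
        "p, es, expected",
        [(0.01, 0.4, 2.0), (1.0, -0.3, 0.0), (0.001, -0.9, -3.0)],
    )
    def test_worked_examples(self, p, es, expected):
        assert signed_log10_p(p, es) == pytest.approx(expected)

    def test_zero_p_instructs_permutation_floor(self):
        with pytest.raises(ValueError, match="floor"):
            signed_log10_p(0.0, 0.5)

    def test_zero_es_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert signed_log10_p(0.5, 0.0) == 0.0


class TestGseaPreranked:
    def test_small_n_perm_rejected(self):
        rl = ranked(np.arange(10.0))
        sets = GeneSetCollection({"S": {"g0", "g1"}})
        with pytest.raises(ValueError):
            gsea_preranked(rl, sets, n_perm=50)

    def test_determinism_and_floor(self, rng):
        scores = rng.normal(size=60)
        rl = ranked(scores)
        sets = GeneSetCollection(
            {f"S{i}": set(rng.choice(rl.gene_ids, 8, replace=False))
             for i in range(5)}
        )
        a = gsea_preranked(rl, sets, n_perm=100, seed=9)
        b = gsea_preranked(rl, sets, n_perm=100, seed=9)
        assert [(r.set_id, r.es, r.p) for r in a] == [
            (r.set_id, r.es, r.p) for r in b
        ]
        assert all(r.p >= 1 / 101 for r in a)
        for r in a:
            if r.p < 1:
                assert np.sign(r.signed_logp) == np.sign(r.es)
            assert abs(r.signed_logp) == pytest.approx(-np.log10(r.p))

    def test_universe_covering_set_skipped(self, rng):
        rl = ranked(rng.normal(size=20))
        sets = GeneSetCollection({"ALL": set(rl.gene_ids), "OK": {"g0", "g1"}})
        res = gsea_preranked(rl, sets, n_perm=100, seed=1)
        assert "ALL" in res.skipped
        assert [r.set_id for r in res] == ["OK"]

    def test_null_rejection_rate_calibrated(self):
        """Random sets under a null ranking reject at ~alpha (module-scale
        version of the Monte-Carlo calibration; the full 500-set version runs
        in the acceptance suite)."""
        coll = simulate_collection(
            SimulationConfig(n_genes=800, n_datasets=1, disorder_labels=["other"],
                             frac_true_effects=0.0, tau=0.0, seed=21)
        )
        rl = rank_genes(coll.datasets[0], seed=0)
        rng = np.random.default_rng(5)
        sets = GeneSetCollection(
            {f"S{i}": set(rng.choice(coll.gene_universe, 30, replace=False))
             for i in range(200)}
        )
        res = gsea_preranked(rl, sets, n_perm=199, seed=3)
        rate = np.mean([r.p <= 0.05 for r in res])
        assert 0.01 <= rate <= 0.09


class TestResnik:
    def test_hand_computed_similarity(self, tiny_ontology):
        # IC(A)=ln2, max IC = IC(C) = ln4 -> sim(A,C) = ln2/ln4 = 0.5
        assert resnik_similarity(tiny_ontology, "A", "C") == pytest.approx(0.5)

    def test_root_only_common_ancestor_is_zero(self, tiny_ontology):
        assert resnik_similarity(tiny_ontology, "A", "B") == 0.0

    def test_max_ic_self_similarity_is_one(self, tiny_ontology):
        assert resnik_similarity(tiny_ontology, "C", "C") == pytest.approx(1.0)

    def test_symmetry_and_self_bound(self, tiny_ontology):
        terms = ["root", "A", "B", "C"]
        M = resnik_matrix(tiny_ontology, terms).to_numpy()
        assert np.allclose(M, M.T)
        for i in range(len(terms)):
            for j in range(len(terms)):
                assert M[i, j] <= min(M[i, i], M[j, j]) + 1e-12

    def test_unknown_term_rejected(self, tiny_ontology):
        with pytest.raises(KeyError):
            resnik_similarity(tiny_ontology, "A", "missing")


class TestClusterTerms:
    def test_pair_above_threshold_merges(self):
        sim = pd.DataFrame(
            [[1.0, 0.9], [0.9, 1.0]], index=["t1", "t2"], columns=["t1", "t2"]
        )
        clusters = cluster_terms(sim, threshold=0.85)
        assert len(clusters) == 1
        assert clusters[0].members == ["t1", "t2"]

    def test_representative_has_max_significance_count(self):
        sim = pd.DataFrame(
            [[1.0, 0.9], [0.9, 1.0]], index=["t1", "t2"], columns=["t1", "t2"]
        )
        clusters = cluster_terms(
            sim, significance_counts={"t1": 10, "t2": 7}
        )
        assert clusters[0].representative == "t1"
        # tie resolves lexicographically
        clusters = cluster_terms(sim, significance_counts={"t1": 7, "t2": 7})
        assert clusters[0].representative == "t1"

    def test_zero_similarity_yields_singletons(self):
        ids = ["a", "b", "c"]
        sim = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        clusters = cluster_terms(sim)
        assert sorted(c.members[0] for c in clusters) == ids
        assert all(len(c.members) == 1 for c in clusters)
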