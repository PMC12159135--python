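import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nddmeta.cross_dataset import (
    cluster_term_profiles,
    consistent_direction_rank,
    count_significant,
    gene_de_frequency,
    mwu_association,
    phenotype_gene_fisher,
    term_profile_matrix,
)
from nddmeta.synthetic_data import SimulationConfig, simulate_collection

from .conftest import make_collection, make_dataset


def gsea_frame(rows):
    """rows: (set_id, es, p, p_adj, signed_logp)"""
    return pd.DataFrame(
        rows, columns=["set_id", "es", "p", "p_adj", "signed_logp"]
    ).assign(n_hits=5)


class TestCountSignificant:
    def test_counts_significant_datasets(self):
        results = {
            f"d{i}": gsea_frame([("T", 0.5, 0.001, 0.01 if i < 3 else 0.5, 3.0)])
            for i in range(5)
        }
        profiles = count_significant(results)
        assert profiles[0].significant_count == 3

    def test_tiebreak_by_mean_abs_signed_logp(self):
        results = {
            "d1": gsea_frame([("A", 0.5, 0.01, 0.01, 2.0),
                              ("B", 0.5, 0.01, 0.01, 1.0)]),
        }
        profiles = count_significant(results)
        assert [p.set_id for p in profiles] == ["A", "B"]


class TestClusterTermProfiles:
    def test_identical_profiles_merge_at_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0]], index=["a", "b"], columns=["d1", "d2"]
        )
        order, Z = cluster_term_profiles(mat)
        assert sorted(order) == ["a", "b"]
        assert Z[0, 2] == pytest.approx(0.0)

    def test_identical_pair_merges_before_distant_profile(self):
        mat = pd.DataFrame(
            [[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]],
            index=["a", "far", "b"], columns=["d1", "d2"],
        )
        order, Z = cluster_term_profiles(mat)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        labels = sorted(mat.sort_index().index[i] for i in first)
        assert labels == ["a", "b"]

    def test_scalar_profiles_ward_heights(self):
        """One-column profiles: first Ward merge height equals the smallest
        pairwise gap."""
        mat = pd.DataFrame(
            {"d1": [0.0, 1.0, 10.0]}, index=["a", "b", "c"]
        )
        _, Z = cluster_term_profiles(mat)
        assert Z[0, 2] == pytest.approx(1.0)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_term_profiles(pd.DataFrame({"d1": [1.0]}, index=["a"]))


def exact_mwu_p(a, b):
    """Two-sided P by enumerating every label assignment."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)

    def u_stat(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        return min(
            sum((xi > yj) for xi in x for yj in y),
            sum((yj > xi) for xi in x for yj in y),
        )
    observed = u_stat(range(na))
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        total += 1
        if u_stat(idx) <= observed:
            count += 1
    return count / total


class TestMannWhitney:
    def test_worked_example(self):
        r = mwu_association([1, 2, 3, 4], [True, True, False, False])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(1 / 3)
        assert r.method == "exact"

    def test_identical_groups_p_one(self):
        r = mwu_association([5, 5, 5, 5], [True, True, False, False])
        assert r.p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_association([1.0, 2.0], [True, True])

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 3), (2, 4), (4, 4), (3, 5)])
    def test_exact_branch_matches_enumeration(self, na, nb, rng):
        """Exhaustive oracle over label assignments for tie-free n <= 8."""
        for _ in range(10):
            vals = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = vals[:na], vals[na:]
            r = mwu_association(
                vals, np.array([True] * na + [False] * nb)
            )
            assert r.method == "exact"
            assert r.p == pytest.approx(exact_mwu_p(a, b), abs=1e-12)

    def test_large_or_tied_inputs_use_corrected_normal(self, rng):
        vals = rng.normal(size=20)
        r = mwu_association(vals, np.arange(20) < 10)
        assert r.method == "normal-approx"
        ref = stats.mannwhitneyu(
            vals[:10], vals[10:], alternative="two-sided", method="asymptotic"
        )
        assert r.p == pytest.approx(ref.pvalue)


class TestGeneDEFrequency:
    def test_fraction_counts_only_measuring_datasets(self):
        datasets = []
        for i in range(10):
            p = [0.01 if i < 3 else 0.5, 0.5]
            datasets.append(make_dataset(f"d{i}", ["A", "B"], p=p))
        coll = make_collection(datasets)
        freq = gene_de_frequency(coll)
        assert freq.loc["A", "n_de"] == 3
        assert freq.loc["A", "fraction"] == pytest.approx(0.3)

    def test_unmeasured_gene_absent(self):
        d0 = make_dataset("d0", ["A", "B"], p=[0.5, np.nan])
        d1 = make_dataset("d1", ["A", "B"], p=[0.5, np.nan])
        freq = gene_de_frequency(make_collection([d0, d1]))
        assert "B" not in freq.index

    def test_null_corpus_max_fraction_within_order_statistic_bound(self):
        """On a null corpus the most frequently DE gene stays below the 99%
        bound for the maximum of m Binomial(n, 0.05) fractions."""
        coll = simulate_collection(
            SimulationConfig(n_genes=2000, n_datasets=20,
                             frac_true_effects=0.0, tau=0.0, seed=31)
        )
        freq = gene_de_frequency(coll)
        m, n = 2000, 20
        bound = stats.binom.ppf(0.99 ** (1 / m), n, 0.05) / n
        assert freq["fraction"].iloc[0] <= bound


class TestConsistentDirection:
    def test_majority_direction_scores(self):
        results = {}
        for i in range(5):
            es = 0.5 if i < 4 else -0.5
            results[f"d{i}"] = gsea_frame([("T", es, 0.01, 0.05, 2.0 * np.sign(es))])
        tab = consistent_direction_rank(results)
        assert tab.loc["T", "score"] == 4
        assert tab.loc["T", "direction"] == "up"

    def test_never_significant_scores_zero(self):
        results = {"d0": gsea_frame([("T", 0.5, 0.5, 0.9, 0.3)])}
        tab = consistent_direction_rank(results)
        assert tab.loc["T", "score"] == 0
        assert tab.loc["T", "direction"] == "none"

    def test_exact_tie_reported_ambiguous(self):
        results = {}
        for i in range(4):
            es = 0.5 if i < 2 else -0.5
            results[f"d{i}"] = gsea_frame([("T", es, 0.01, 0.05, 2.0 * np.sign(es))])
        tab = consistent_direction_rank(results)
        assert tab.loc["T", "score"] == 2
        assert tab.loc["T", "direction"] == "ambiguous"


class TestPhenotypeGeneFisher:
    def _coll(self, de_pattern):
        """12 datasets, first 6 carry seizure; de_pattern maps gene ->
        list of 12 booleans (DE flags)."""
        genes = sorted(de_pattern)
        datasets = [
            make_dataset(
                f"d{i}", genes,
                p=[0.01 if de_pattern[g][i] else 0.5 for g in genes],
            )
            for i in range(12)
        ]
        phen = [frozenset({"seizure"})] * 6 + [frozenset()] * 6
        return make_collection(datasets, phenotypes=phen)

    def test_fully_separated_gene_worked_p(self):
        coll = self._coll({"G": [True] * 6 + [False] * 6,
                           "H": [False] * 12})
        tab = phenotype_gene_fisher(coll, "seizure")
        assert tuple(tab.loc["G", ["de_ph", "notde_ph", "de_noph",
                                   "notde_noph"]]) == (6, 0, 0, 6)
        assert tab.loc["G", "p"] == pytest.approx(2 / 924)

    def test_balanced_gene_null(self):
        coll = self._coll({"G": [True, True, True, False, False, False] * 2,
                           "H": [False] * 12})
        tab = phenotype_gene_fisher(coll, "seizure")
        assert tab.loc["G", "log2_or"] == pytest.approx(0.0)
        assert tab.loc["G", "p"] == pytest.approx(1.0)

    def test_unknown_phenotype_rejected(self):
        coll = self._coll({"G": [False] * 12, "H": [True] * 12})
        with pytest.raises(ValueError, match="tremor"):
            phenotype_gene_fisher(coll, "tremor")

    def test_recovers_planted_phenotype_genes(self):
        """Planted phenotype-linked genes are recovered at FDR < 0.05 with
        high sensitivity and few false calls (module-scale version; the
        20-seed version runs in the acceptance suite)."""
        genes = [f"G{i:06d}" for i in range(1000)]
        planted = set(genes[:60])
        sens, fdp = [], []
        for seed in range(5):
            coll = simulate_collection(
                SimulationConfig(
                    n_genes=1000, n_datasets=16,
                    disorder_labels=["A"] * 8 + ["B"] * 8,
                    phenotype_map={"A": frozenset({"seizure"}),
                                   "B": frozenset()},
                    frac_true_effects=0.0, tau=0.0,
                    phenotype_gene_sets={"seizure": sorted(planted)},
                    phenotype_shift=5.0, seed=seed,
                )
            )
            tab = phenotype_gene_fisher(coll, "seizure")
            padj_col = [c for c in tab.columns if c.startswith("p_adj")][0]
            called = set(tab.index[tab[padj_col] < 0.05])
            sens.append(len(called & planted) / len(planted))
            fdp.append(len(called - planted) / max(1, len(called)))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdp) <= 0.1

    def test_planted_genes_take_top_odds_ratio_ranks(self):
        """The planted phenotype set dominates the top of the log2 OR
        ranking among measured genes."""
        genes = [f"G{i:06d}" for i in range(500)]
        planted = set(genes[:30])
        coll = simulate_collection(
            SimulationConfig(
                n_genes=500, n_datasets=16,
                disorder_labels=["A"] * 8 + ["B"] * 8,
                phenotype_map={"A": frozenset({"seizure"}), "B": frozenset()},
                frac_true_effects=0.0, tau=0.0,
                phenotype_gene_sets={"seizure": sorted(planted)},
                phenotype_shift=5.0, seed=17,
            )
        )
        tab = phenotype_gene_fisher(coll, "seizure")
        top = set(tab.sort_values("log2_or", ascending=False).index[:30])
        assert len(top & planted) >= 24


def test_term_profile_matrix_imputes_missing_as_zero():
    results = {
        "d1": gsea_frame([("A", 0.5, 0.01, 0.01, 2.0)]),
        "d2": gsea_frame([("A", 0.5, 0.01, 0.01, 1.5),
                          ("B", -0.5, 0.01, 0.01, -1.0)]),
    }
    profiles = count_significant(results)
    mat = term_profile_matrix(profiles, ["d1", "d2"])
    assert mat.loc["B", "d1"] == 0.0
    assert mat.loc["A", "d2"] == 1.5
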