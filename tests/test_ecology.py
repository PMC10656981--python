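"""Alpha/beta diversity, PERMANOVA, rank tests, Venn, correlation networks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from twobradm import (AbundanceStudy, alpha_diversity_table, beta_distance,
                      chao1, correlation_network, permanova, rank_sum_test,
                      shannon, simpson, venn_counts)
from twobradm.simulate import default_design, make_case_control


def make_study(matrix: pd.DataFrame, groups: dict, counts=None, **kw):
    counts = matrix.round().astype(int) if counts is None else counts
    return AbundanceStudy(matrix=matrix, counts=counts,
                          groups=pd.Series(groups), **kw)


class TestAlphaDiversity:
    def test_chao1_bias_corrected(self):
        assert chao1([4, 3, 2, 1, 1]) == 5.5  # S_obs=5, F1=2, F2=1

    def test_chao1_no_singletons(self):
        assert chao1([4, 3, 2]) == 3.0

    def test_chao1_all_zero(self):
        assert chao1([0, 0, 0]) == 0.0

    def test_chao1_rejects_proportions(self):
        with pytest.raises(ValueError):
            chao1([0.5, 0.3, 0.2])

    def test_shannon_uniform(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4))

    def test_shannon_single_species(self):
        assert shannon([1.0]) == 0.0
        assert simpson([1.0]) == 0.0

    def test_simpson_even_pair(self):
        assert simpson([0.5, 0.5]) == pytest.approx(0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon([-0.1, 1.1])

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            assert shannon(p) <= np.log(6) + 1e-12
            assert 0 <= simpson(p) < 1

    def test_cross_check_against_skbio(self):
        from skbio.diversity import alpha as sk
        rng = np.random.default_rng(5)
        for _ in range(10):
            counts = rng.integers(0, 20, size=12)
            if counts.sum() == 0:
                continue
            assert chao1(counts) == pytest.approx(
                sk.chao1(counts, bias_corrected=True))
            assert shannon(counts) == pytest.approx(
                sk.shannon(counts, base=np.e))
            assert simpson(counts) == pytest.approx(sk.simpson(counts))

    def test_table_uses_counts(self, default_study):
        tab = alpha_diversity_table(default_study)
        assert list(tab.columns) == ["chao1", "shannon", "simpson"]
        assert len(tab) == 44
        assert (tab["shannon"] >= 0).all()


class TestBetaDistance:
    def test_identical_samples_zero(self):
        m = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]},
                         index=["a", "b"])
        for metric in ("bray_curtis", "jaccard_binary", "euclidean"):
            dm = beta_distance(m, metric)
            assert dm[0, 1] == 0.0

    def test_disjoint_species_sets(self):
        m = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]},
                         index=["a", "b"])
        assert beta_distance(m, "bray_curtis")[0, 1] == pytest.approx(1.0)
        assert beta_distance(m, "jaccard_binary")[0, 1] == pytest.approx(1.0)

    def test_jaccard_partial_overlap(self):
        m = pd.DataFrame({"s1": [0.5, 0.5, 0.0], "s2": [0.0, 0.5, 0.5]},
                         index=["a", "b", "c"])
        # presence sets {a,b} vs {b,c}: 1 - 1/3
        assert beta_distance(m, "jaccard_binary")[0, 1] == pytest.approx(2 / 3)

    def test_unknown_metric(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            beta_distance(m, "manhattan")

    def test_valid_distance_matrices_on_random_studies(self, default_study):
        for metric in ("bray_curtis", "jaccard_binary", "euclidean"):
            dm = beta_distance(default_study, metric)
            data = dm.data  # skbio validates symmetry + zero diagonal
            assert (data >= 0).all()
            assert np.allclose(data, data.T)
            assert np.allclose(np.diag(data), 0)


class TestPermanova:
    def _separated(self, n=8):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2 * n, 5))
        X[:n] += 10.0
        ids = [f"s{i}" for i in range(2 * n)]
        dm = DistanceMatrix(squareform(pdist(X)), ids=ids)
        groups = pd.Series(["a"] * n + ["b"] * n, index=ids)
        return dm, groups

    def test_minimal_p_with_999_perms(self):
        # 12 per group so random permutations are unlikely to reproduce
        # the true split (or its complement) and tie the observed F
        dm, groups = self._separated(n=12)
        res = permanova(dm, groups, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(0.001)  # 1/(1+999)

    def test_matches_skbio_statistic(self):
        dm, groups = self._separated()
        res = permanova(dm, groups, n_perm=99, seed=3)
        sk = skbio_permanova(dm, list(groups), permutations=99, seed=3)
        assert res.pseudo_f == pytest.approx(float(sk["test statistic"]))

    def test_invariance_to_sample_relabeling(self):
        dm, groups = self._separated()
        order = list(dm.ids)[::-1]
        dm2 = dm.filter(order)
        res1 = permanova(dm, groups, n_perm=99, seed=7)
        res2 = permanova(dm2, groups.loc[order], n_perm=99, seed=7)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f)

    def test_type_i_error_calibration(self):
        root = np.random.SeedSequence(77)
        rej = 0
        n_rep = 100
        for child in root.spawn(n_rep):
            rng = np.random.default_rng(child)
            X = rng.random((16, 10))
            ids = [f"s{i}" for i in range(16)]
            dm = DistanceMatrix(squareform(pdist(X)), ids=ids)
            labels = np.array(["a"] * 8 + ["b"] * 8)
            rng.shuffle(labels)
            res = permanova(dm, pd.Series(labels, index=ids), n_perm=99,
                            seed=int(rng.integers(2**31)))
            rej += res.p_value <= 0.05
        assert 0.01 <= rej / n_rep <= 0.10

    def test_small_group_error(self):
        dm, groups = self._separated(n=4)
        groups.iloc[:] = ["a"] * 7 + ["b"]
        with pytest.raises(ValueError):
            permanova(dm, groups)


class TestRankSum:
    def test_exact_enumeration_small_n(self):
        stat, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 * (1/20)

    def test_paired_identical_vectors(self):
        stat, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert p == 1.0

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            rank_sum_test([1, 2], [1, 2, 3], paired=True)

    def test_empty_vector(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])

    def test_power_under_shift(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.normal(0, 1, 20)
            y = rng.normal(1, 1, 20)  # 1 SD shift
            _, p = rank_sum_test(x, y)
            hits += p < 0.05
        assert hits / n_rep > 0.5


class TestVenn:
    def test_partition_by_construction(self):
        m = pd.DataFrame(
            {"c1": [0.5, 0.5, 0.0, 0.0], "c2": [0.4, 0.6, 0.0, 0.0],
             "k1": [0.3, 0.0, 0.7, 0.0], "k2": [0.5, 0.0, 0.5, 0.0]},
            index=["shared_sp", "case_only", "ctrl_only", "nowhere"])
        study = make_study(m, {"c1": "case", "c2": "case",
                               "k1": "control", "k2": "control"})
        vc = venn_counts(study)
        assert (vc.shared, vc.unique_a, vc.unique_b) == (1, 1, 1)
        assert vc.percentages()["shared"] == pytest.approx(100 / 3)

    def test_species_in_single_sample_counts(self):
        m = pd.DataFrame({"c1": [1.0, 0.0], "c2": [0.5, 0.5],
                          "k1": [1.0, 0.0], "k2": [1.0, 0.0]},
                         index=["everywhere", "one_case_sample"])
        study = make_study(m, {"c1": "case", "c2": "case",
                               "k1": "control", "k2": "control"})
        vc = venn_counts(study)
        assert vc.unique_a == 1  # detected in >=1 case sample only


class TestCorrelationNetwork:
    def _study(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(12)]
        u = rng.random(12)
        # four compositions, each a monotone function of u, summing to 1
        m = pd.DataFrame(
            {s: [u[i] / 4, (1 - u[i]) / 4, (u[i] + 0.1) / 2.2,
                 0.75 - (u[i] + 0.1) / 2.2]
             for i, s in enumerate(samples)},
            index=["Bacteroides_a", "Prevotella_b", "Malassezia_c", "Saccharo_d"])
        kingdom = pd.Series({"Bacteroides_a": "bacteria", "Prevotella_b": "bacteria",
                             "Malassezia_c": "fungi", "Saccharo_d": "fungi"})
        lineage = pd.DataFrame(
            {"phylum": ["Bacteroidota", "Bacteroidota2", "Basidiomycota",
                        "Ascomycota"]},
            index=kingdom.index)
        groups = {s: ("case" if i < 6 else "control")
                  for i, s in enumerate(samples)}
        return make_study(m, groups, kingdom=kingdom, lineage=lineage)

    def test_monotone_pairs(self):
        study = self._study()
        edges = correlation_network(study, level="phylum")
        case = edges[edges.group == "case"].set_index(["taxon1", "taxon2"])
        assert case.loc[("Bacteroidota", "Basidiomycota"), "rho"] == pytest.approx(1.0)
        assert case.loc[("Bacteroidota2", "Basidiomycota"), "rho"] == pytest.approx(-1.0)

    def test_missing_rank_error(self):
        study = self._study()
        with pytest.raises(ValueError, match="genus"):
            correlation_network(study, level="genus")

    def test_null_pairs_have_small_mean_rho(self):
        rng = np.random.default_rng(8)
        rhos = []
        for _ in range(300):
            x = rng.random(20)
            y = rng.random(20)
            from scipy.stats import spearmanr
            rhos.append(spearmanr(x, y).statistic)
        assert abs(np.mean(rhos)) < 0.05


class TestAbundanceStudyValidation:
    def test_columns_must_sum_to_one(self):
        m = pd.DataFrame({"s1": [0.5, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="sum to 1"):
            make_study(m, {"s1": "case"})

    def test_missing_group_label(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="without group"):
            AbundanceStudy(matrix=m, counts=m.astype(int),
                           groups=pd.Series({"s1": "case"}))

    def test_default_study_shape(self, default_study):
        assert default_study.matrix.shape == (18, 44)
        assert default_study.group_labels() == ["case", "control"]
        assert np.allclose(default_study.matrix.sum(axis=0), 1.0)
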