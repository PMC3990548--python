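"""Clustering, dynamic tree cut, eigengenes, kME and reassignment."""

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.exceptions import InputError
from coexnet.modules import UNASSIGNED


def diss_frame(d, labels=None):
    d = np.asarray(d, dtype=float)
    labels = labels or [f"g{i}" for i in range(d.shape[0])]
    return pd.DataFrame(d, index=labels, columns=labels)


class TestHierarchicalCluster:
    def test_two_perfect_blocks(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        z = cx.hierarchical_cluster(diss_frame(d))
        heights = z[:, 2]
        assert heights[-1] == pytest.approx(1.0)  # final merge joins the blocks
        assert np.all(heights[:-1] == 0.0)

    def test_hand_worked_upgma_merge_heights(self):
        # d(1,2)=2 d(1,3)=6 d(1,4)=10 d(2,3)=5 d(2,4)=9 d(3,4)=4
        # UPGMA: {1,2}@2; {3,4}@4; final @ (6+10+5+9)/4 = 7.5
        d = np.array(
            [
                [0, 2, 6, 10],
                [2, 0, 5, 9],
                [6, 5, 0, 4],
                [10, 9, 4, 0],
            ],
            dtype=float,
        )
        z = cx.hierarchical_cluster(diss_frame(d))
        np.testing.assert_allclose(sorted(z[:, 2]), [2.0, 4.0, 7.5])

    def test_single_gene_yields_empty_dendrogram(self):
        z = cx.hierarchical_cluster(diss_frame([[0.0]]))
        assert z.shape == (0, 4)

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(InputError):
            cx.hierarchical_cluster(diss_frame(d))


class TestDynamicTreeCut:
    def two_block_dissimilarity(self, n1=8, n2=8):
        n = n1 + n2
        d = np.ones((n, n))
        d[:n1, :n1] = 0.1
        d[n1:, n1:] = 0.1
        np.fill_diagonal(d, 0.0)
        return diss_frame(d)

    def test_two_clean_blocks_found(self):
        d = self.two_block_dissimilarity()
        z = cx.hierarchical_cluster(d)
        part = cx.dynamic_tree_cut(z, d.index, min_module_size=5)
        sizes = part.sizes()
        assert len(sizes) == 2
        assert sorted(sizes) == [8, 8]
        assert (part.labels != UNASSIGNED).all()

    def test_cut_below_every_merge_leaves_all_unassigned(self):
        d = self.two_block_dissimilarity()
        z = cx.hierarchical_cluster(d)
        part = cx.dynamic_tree_cut(z, d.index, cut_height=0.05, min_module_size=5)
        assert (part.labels == UNASSIGNED).all()

    def test_labels_follow_size_rank(self):
        d = self.two_block_dissimilarity(n1=12, n2=6)
        z = cx.hierarchical_cluster(d)
        part = cx.dynamic_tree_cut(z, d.index, min_module_size=5)
        sizes = part.sizes()
        assert sizes["turquoise"] == 12 and sizes["blue"] == 6

    def test_planted_recovery_with_reassignment(self):
        # 5 planted modules + background: median ARI over seeds >= 0.90
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            mods = tuple(
                cx.ModuleSpec(f"m{i}", s, 0.6, 0.95, "preserved", 50 + i)
                for i, s in enumerate([30, 38, 45, 52, 60])
            )
            cfg = cx.SimulationConfig(
                modules=mods, n_background_genes=200, noise_sd=0.4, rng_seed=seed
            )
            st = cx.simulate_two_condition_dataset(cfg)
            net = cx.build_network(st.test, power=6)
            det = cx.detect_modules(st.test, net.tom)
            mask = st.truth_labels != "background"
            aris.append(
                adjusted_rand_score(
                    st.truth_labels[mask], det.partition.labels[mask]
                )
            )
        assert np.median(aris) >= 0.90

    def test_partition_is_complete_and_respects_min_size(self, standard_study):
        net = cx.build_network(standard_study.test, power=6)
        d = 1.0 - net.tom.to_numpy()
        np.fill_diagonal(d, 0.0)
        z = cx.hierarchical_cluster(pd.DataFrame(d, index=net.tom.index, columns=net.tom.index))
        part = cx.dynamic_tree_cut(z, net.tom.index)
        assert set(part.labels.index) == set(standard_study.gene_ids)
        assert (part.sizes() >= 30).all()


class TestModuleEigengene:
    def test_rank_one_block_fully_explained(self):
        profile = np.sin(np.linspace(0, 6, 12))
        block = pd.DataFrame(
            np.tile(profile, (4, 1)) * np.array([1.0, 2.0, 3.0, 4.0])[:, None],
            index=list("abcd"),
        )
        me, ve = cx.module_eigengene(block)
        assert ve == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(me, z)[0, 1] > 0  # oriented with the block average

    def test_sign_orientation_balanced_block(self):
        profile = np.cos(np.linspace(0, 4, 10))
        block = pd.DataFrame(
            np.vstack([profile, -profile, profile, -profile]), index=list("abcd")
        )
        me, _ = cx.module_eigengene(block)
        # average standardized expression is ~0; tie broken toward the first gene
        assert np.corrcoef(me, profile)[0, 1] > 0

    def test_unit_norm(self):
        rng = np.random.default_rng(0)
        me, _ = cx.module_eigengene(pd.DataFrame(rng.normal(size=(5, 9))))
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_variance_explained_matches_decomposition_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=(10, 8))
            block = pd.DataFrame(x)
            _, ve = cx.module_eigengene(block)
            xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
            eig = np.linalg.eigvalsh(xs @ xs.T)  # independent route: Gram spectrum
            assert ve == pytest.approx(eig[-1] / eig.sum(), abs=1e-10)

    def test_me_is_variance_optimal(self):
        # no random unit-norm profile explains more variance than the ME
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 10))
        block = pd.DataFrame(x)
        me, ve = cx.module_eigengene(block)
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        total = (xs**2).sum()
        for _ in range(200):
            v = rng.normal(size=10)
            v /= np.linalg.norm(v)
            assert ((xs @ v) ** 2).sum() / total <= ve + 1e-12

    def test_constant_gene_rejected(self):
        block = pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]], index=["flat", "ok"])
        with pytest.raises(InputError):
            cx.module_eigengene(block)


class TestModuleMembership:
    def test_gene_equal_to_eigengene_scores_one(self):
        rng = np.random.default_rng(3)
        me = rng.normal(size=12)
        expr = pd.DataFrame([me, -me, rng.normal(size=12)], index=["same", "neg", "noise"])
        mes = pd.DataFrame([me], index=["mod"], columns=expr.columns)
        kme = cx.module_membership(expr, mes)
        assert kme.loc["same", "mod"] == pytest.approx(1.0)
        assert kme.loc["neg", "mod"] == pytest.approx(-1.0)

    def test_noise_genes_have_small_membership(self):
        rng = np.random.default_rng(4)
        me = rng.normal(size=24)
        noise = rng.normal(size=(1000, 24))
        expr = pd.DataFrame(noise, index=[f"n{i}" for i in range(1000)])
        mes = pd.DataFrame([me], index=["mod"], columns=expr.columns)
        kme = cx.module_membership(expr, mes)
        assert kme["mod"].abs().mean() < 0.25


@pytest.fixture(scope="module")
def clean_study():
    # planted modules only, no noise pool: every gene clearly belongs
    cfg = cx.SimulationConfig(
        modules=(
            cx.ModuleSpec("a", 30, 0.7, 0.95, "preserved", 61),
            cx.ModuleSpec("b", 30, 0.7, 0.95, "preserved", 62),
            cx.ModuleSpec("c", 30, 0.7, 0.95, "preserved", 63),
        ),
        n_background_genes=0,
        noise_sd=0.25,
        rng_seed=17,
    )
    study = cx.simulate_two_condition_dataset(cfg)
    partition = cx.ModulePartition(labels=study.truth_labels.copy())
    return study, partition


class TestReassignByKme:
    def test_low_membership_genes_become_unassigned(self, standard_study, truth_partition):
        result = cx.reassign_by_kme(standard_study.test, truth_partition, kme_min=0.3)
        labels = result.partition.labels
        kme = result.eigengenes.kme
        unassigned = labels.index[labels == UNASSIGNED]
        assert (kme.loc[unassigned].abs().max(axis=1) < 0.3).all()

    def test_argmax_rule_moves_misassigned_gene(self, standard_study, truth_partition):
        # swap one alpha gene into beta; reassignment must move it back
        labels = truth_partition.labels.copy()
        alpha_gene = labels.index[labels == "alpha"][0]
        labels[alpha_gene] = "beta"
        moved = cx.reassign_by_kme(
            standard_study.test, cx.ModulePartition(labels=labels), kme_min=0.3
        )
        assert moved.partition.labels[alpha_gene] == "alpha"

    def test_fixed_point_on_clean_data(self, clean_study):
        study, partition = clean_study
        result = cx.reassign_by_kme(study.test, partition)
        assert result.n_iterations <= 3
        again = cx.reassign_by_kme(study.test, result.partition)
        pd.testing.assert_series_equal(
            again.partition.labels, result.partition.labels, check_names=False
        )

    def test_objective_never_decreases(self, clean_study):
        study, partition = clean_study
        result = cx.reassign_by_kme(study.test, partition)
        path = result.objective_path
        assert all(b >= a - 1e-9 for a, b in zip(path, path[1:]))
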