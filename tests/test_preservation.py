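"""Preservation statistics, permutation nulls, Z composites and stage tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.exceptions import InputError
from coexnet.preservation import density_statistic, connectivity_statistic, permutation_null

from conftest import random_symmetric_adjacency


def adj_frame(a, labels=None):
    a = np.asarray(a, dtype=float)
    labels = labels or [f"g{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=labels, columns=labels)


class TestDensityStatistic:
    def test_clique_and_empty_extremes(self):
        n = 6
        clique = adj_frame(np.ones((n, n)) - np.eye(n))
        empty = adj_frame(np.zeros((n, n)))
        genes = list(clique.index[:4])
        assert density_statistic(clique, genes) == pytest.approx(1.0)
        assert density_statistic(empty, genes) == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = adj_frame(random_symmetric_adjacency(15, rng))
        genes = [f"g{i}" for i in (1, 3, 4, 7, 9, 10, 11, 12, 13, 14)]
        got = density_statistic(a, genes)
        total, count = 0.0, 0
        for gi in genes:
            for gj in genes:
                if gi != gj:
                    total += a.loc[gi, gj]
                    count += 1
        assert got == pytest.approx(total / count, abs=1e-12)

    def test_small_module_rejected(self):
        a = adj_frame(np.zeros((5, 5)))
        with pytest.raises(InputError):
            density_statistic(a, ["g0", "g1"])


class TestConnectivityStatistic:
    def test_identical_networks_score_one(self):
        rng = np.random.default_rng(1)
        a = adj_frame(random_symmetric_adjacency(10, rng))
        genes = [f"g{i}" for i in range(6)]
        assert connectivity_statistic(a, a.copy(), genes) == pytest.approx(1.0)

    def test_hand_computed_four_gene_module(self):
        ref = adj_frame(
            [
                [0.0, 0.9, 0.1, 0.2],
                [0.9, 0.0, 0.3, 0.4],
                [0.1, 0.3, 0.0, 0.5],
                [0.2, 0.4, 0.5, 0.0],
            ]
        )
        test = adj_frame(
            [
                [0.0, 0.8, 0.2, 0.1],
                [0.8, 0.0, 0.4, 0.3],
                [0.2, 0.4, 0.0, 0.6],
                [0.1, 0.3, 0.6, 0.0],
            ]
        )
        # kIM_ref = (1.2, 1.6, 0.9, 1.1), kIM_test = (1.1, 1.5, 1.2, 1.0)
        # Pearson r = 0.14 / sqrt(0.26 * 0.14) = 0.7337993857
        got = connectivity_statistic(ref, test, list(ref.index))
        assert got == pytest.approx(0.7337993857, abs=1e-9)

    def test_label_shuffle_destroys_pattern(self):
        rng = np.random.default_rng(2)
        a = random_symmetric_adjacency(12, rng)
        ref = adj_frame(a)
        stats = []
        for _ in range(100):
            perm = rng.permutation(12)
            shuffled = adj_frame(a[np.ix_(perm, perm)], labels=list(ref.index))
            stats.append(connectivity_statistic(ref, shuffled, list(ref.index)))
        assert abs(np.mean(stats)) < 0.2

    def test_zero_variance_reported_as_zero_with_warning(self):
        n = 5
        clique = adj_frame(np.ones((n, n)) - np.eye(n))
        rng = np.random.default_rng(3)
        other = adj_frame(random_symmetric_adjacency(n, rng))
        with pytest.warns(UserWarning):
            got = connectivity_statistic(clique, other, list(clique.index)[:4])
        assert got == 0.0


class TestPermutationNull:
    def test_deterministic_given_seed(self, standard_networks):
        _, net = standard_networks
        genes = list(net.adjacency.index[:20])
        _, _, d1 = permutation_null(net.adjacency, genes, 60, seed=5)
        _, _, d2 = permutation_null(net.adjacency, genes, 60, seed=5)
        np.testing.assert_array_equal(d1, d2)

    def test_two_seeds_agree_within_sampling_error(self, standard_networks):
        _, net = standard_networks
        genes = list(net.adjacency.index[:20])
        m1, s1, _ = permutation_null(net.adjacency, genes, 200, seed=1)
        m2, s2, _ = permutation_null(net.adjacency, genes, 200, seed=2)
        se = np.hypot(s1, s2) / np.sqrt(200)
        assert m1 != m2
        assert abs(m1 - m2) < 3 * se

    def test_constant_adjacency_degenerate_null(self):
        n = 30
        const = adj_frame(np.full((n, n), 0.4) - np.diag(np.full(n, 0.4)))
        genes = list(const.index[:5])
        mu, sd, draws = permutation_null(const, genes, 50, seed=0)
        assert mu == pytest.approx(0.4)
        assert sd == 0.0
        with pytest.warns(UserWarning):
            from coexnet.preservation import _z_score

            assert _z_score(0.9, mu, sd) == np.inf

    def test_minimum_permutations_enforced(self, standard_networks):
        _, net = standard_networks
        with pytest.raises(InputError):
            permutation_null(net.adjacency, list(net.adjacency.index[:10]), 10, seed=0)


class TestZComposite:
    @pytest.mark.parametrize("zd,zc,expected", [(19, 19, 19), (0, 0, 0), (4, 10, 7)])
    def test_zsummary_is_the_mean(self, zd, zc, expected):
        assert cx.z_summary(zd, zc) == expected

    @pytest.mark.parametrize(
        "z,cls",
        [
            # characteristic stage-wise values of a proliferation-driven module:
            # priming -0.65 (none), proliferation 19 (strong), termination 8.6 (weak)
            (-0.65, "none"),
            (19.0, "strong"),
            (8.6, "weak"),
            (2.0, "weak"),
            (10.0, "weak"),
            (1.999, "none"),
            (10.001, "strong"),
        ],
    )
    def test_evidence_thresholds(self, z, cls):
        assert cx.classify_preservation(z) == cls


class TestModulePreservation:
    def test_identical_networks_all_strong(self, standard_networks, truth_partition):
        _, net = standard_networks
        results = cx.module_preservation(net, net, truth_partition, n_perm=100, seed=0)
        assert len(results) == 4
        for r in results:
            assert r.observed_connectivity == pytest.approx(1.0)
            assert r.evidence_class == "strong"
            assert not r.specific

    def test_preserved_strong_specific_none(self, standard_networks, truth_partition):
        ref_net, test_net = standard_networks
        results = {
            r.module_id: r
            for r in cx.module_preservation(
                test_net, ref_net, truth_partition, n_perm=200, seed=0
            )
        }
        assert results["alpha"].z_summary > 10
        assert results["beta"].z_summary > 10
        assert results["delta"].z_summary < 2
        assert results["delta"].specific
        assert not results["alpha"].specific

    def test_reproducible_given_seed(self, standard_networks, truth_partition):
        ref_net, test_net = standard_networks
        r1 = cx.module_preservation(test_net, ref_net, truth_partition, n_perm=60, seed=9)
        r2 = cx.module_preservation(test_net, ref_net, truth_partition, n_perm=60, seed=9)
        assert [(a.z_density, a.z_connectivity) for a in r1] == [
            (b.z_density, b.z_connectivity) for b in r2
        ]

    def test_z_calibration_on_random_gene_sets(self, standard_networks):
        # pseudo-modules drawn at random should give ~standard-normal Z
        ref_net, test_net = standard_networks
        rng = np.random.default_rng(10)
        genes = np.array(ref_net.gene_ids)
        zd, zc = [], []
        for b in range(60):
            pick = list(genes[rng.choice(len(genes), size=25, replace=False)])
            od = density_statistic(ref_net.adjacency, pick)
            oc = connectivity_statistic(test_net.adjacency, ref_net.adjacency, pick)
            mu_d, sd_d, _ = permutation_null(ref_net.adjacency, pick, 100, seed=300 + b)
            mu_c, sd_c, _ = permutation_null(
                ref_net.adjacency, pick, 100, seed=900 + b,
                statistic_kind="connectivity", ref_adjacency=test_net.adjacency,
            )
            zd.append((od - mu_d) / sd_d)
            zc.append((oc - mu_c) / sd_c)
        for z in (np.array(zd), np.array(zc)):
            assert -0.4 < z.mean() < 0.4
            assert 0.6 < z.std(ddof=1) < 1.4

    def test_stronger_loadings_never_lower_median_zsummary(self):
        medians = []
        for low, high in [(0.4, 0.6), (0.6, 0.8), (0.8, 0.95)]:
            zs = []
            for seed in range(5):
                cfg = cx.SimulationConfig(
                    modules=(cx.ModuleSpec("m", 30, low, high, "preserved", 8),),
                    n_background_genes=90,
                    noise_sd=0.3,
                    rng_seed=seed,
                )
                st = cx.simulate_two_condition_dataset(cfg)
                tn = cx.build_network(st.test, power=6)
                rn = cx.build_network(st.reference, power=6)
                part = cx.ModulePartition(
                    labels=st.truth_labels.where(st.truth_labels != "background", cx.UNASSIGNED)
                )
                zs.append(
                    cx.module_preservation(tn, rn, part, n_perm=100, seed=seed)[0].z_summary
                )
            medians.append(np.median(zs))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9


class TestStagewisePreservation:
    def test_stage_restricted_module_pattern(self):
        cfg = cx.SimulationConfig(
            modules=(cx.ModuleSpec("prolif", 40, 0.7, 0.95, "preserved", 32),),
            n_background_genes=160,
            noise_sd=0.3,
            rng_seed=4,
        )
        st = cx.simulate_two_condition_dataset(cfg)
        cx.restrict_module_to_stages(st, "prolif", ["proliferative"], seed=40)
        part = cx.ModulePartition(
            labels=st.truth_labels.where(st.truth_labels != "background", cx.UNASSIGNED)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = cx.stagewise_preservation(st, part, n_perm=100, seed=4)
        assert cx.classify_preservation(table.loc["prolif", "priming"]) == "none"
        assert cx.classify_preservation(table.loc["prolif", "proliferative"]) == "strong"

    def test_short_stage_skipped_with_warning(self, standard_study, truth_partition):
        # termination holds a single time point x 3 replicates < 4 samples
        with pytest.warns(UserWarning, match="termination"):
            table = cx.stagewise_preservation(
                standard_study, truth_partition, n_perm=60, seed=0
            )
        assert table["termination"].isna().all()
        assert set(table.columns) == {"priming", "proliferative", "termination"}

    def test_missing_stage_annotation_names_sample(self, standard_study, truth_partition):
        broken = cx.ExpressionStudy(
            reference=standard_study.reference,
            test=standard_study.test,
            samples=standard_study.samples.copy(),
            truth_labels=standard_study.truth_labels,
        )
        victim = broken.samples.index[broken.samples["condition"] == "test"][0]
        broken.samples.loc[victim, "stage"] = "nonsense"
        with pytest.raises(InputError, match=victim):
            cx.stagewise_preservation(broken, truth_partition, n_perm=60, seed=0)
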