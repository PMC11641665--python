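import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import subnetmark as sm
from subnetmark.discovery import score_subnetwork, gene_statistics

from conftest import make_dataset

finite_floats = st.floats(-50, 50, allow_nan=False)


class TestIqrWelchT:
    def test_identical_groups_zero(self):
        assert sm.iqr_welch_t([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 0.0

    def test_shifted_group_closed_form(self):
        # a = (0,1,2,3), b = a + 10: each IQR = 1.5, so
        # t = -10 / ((1.5/1.349) / sqrt(2)) = -10 * 1.349 * sqrt(2) / 1.5
        t = sm.iqr_welch_t([0, 1, 2, 3], [10, 11, 12, 13])
        assert t == pytest.approx(-10 * 1.349 * math.sqrt(2) / 1.5, abs=1e-12)

    def test_monotone_in_shift(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        ts = [sm.iqr_welch_t(base, base + c) for c in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_degenerate_scales_nan(self):
        assert math.isnan(sm.iqr_welch_t([2, 2, 2], [5, 5, 5]))

    def test_short_vector_rejected(self):
        with pytest.raises(sm.SubnetmarkError):
            sm.iqr_welch_t([1.0], [1, 2, 3])

    @given(
        st.lists(finite_floats, min_size=4, max_size=12),
        st.lists(finite_floats, min_size=4, max_size=12),
    )
    def test_antisymmetric(self, a, b):
        t_ab = sm.iqr_welch_t(a, b)
        t_ba = sm.iqr_welch_t(b, a)
        if math.isnan(t_ab):
            assert math.isnan(t_ba)
        else:
            assert t_ab == pytest.approx(-t_ba, abs=1e-9)

    @given(
        st.lists(finite_floats, min_size=4, max_size=10),
        st.lists(finite_floats, min_size=4, max_size=10),
        st.floats(-100, 100),
        st.floats(0.01, 50),
    )
    def test_shift_and_scale_invariance(self, a, b, c, scale):
        a, b = np.array(a), np.array(b)
        t0 = sm.iqr_welch_t(a, b)
        if not math.isfinite(t0):
            return
        assert sm.iqr_welch_t(a + c, b + c) == pytest.approx(t0, abs=1e-6)
        assert sm.iqr_welch_t(a * scale, b * scale) == pytest.approx(
            t0, rel=1e-9, abs=1e-9
        )


class TestSelectRepresentatives:
    def test_all_returned_when_fewer_than_five(self, two_class_dataset):
        reps = sm.select_representatives(
            frozenset(["g0", "g1", "g2"]), two_class_dataset
        )
        assert {r.gene_id for r in reps} == {"g0", "g1", "g2"}
        mags = [abs(r.t_iqr) for r in reps]
        assert mags == sorted(mags, reverse=True)

    def test_tie_broken_by_gene_id(self):
        # two identical genes compete: the lexicographically smaller wins rank
        values = np.vstack([[0, 1, 2, 10, 11, 12]] * 2 + [[5, 5, 5, 5, 5, 6]])
        ds = make_dataset(values, gene_ids=["gB", "gA", "gC"],
                          labels=["tumor"] * 3 + ["normal"] * 3)
        reps = sm.select_representatives(frozenset(["gA", "gB", "gC"]), ds)
        assert [r.gene_id for r in reps[:2]] == ["gA", "gB"]

    def test_direction_matches_sign(self, two_class_dataset):
        reps = sm.select_representatives(
            frozenset(two_class_dataset.gene_ids), two_class_dataset
        )
        for r in reps:
            assert (r.direction == "up") == (r.t_iqr > 0)

    def test_planted_genes_dominate(self):
        hits = 0
        for seed in range(10):
            cfg = sm.SimulationConfig(
                n_genes=200, n_planted_modules=1, module_size=10,
                effect_size_delta=3.0, noise_sd=1.0, seed=seed,
            )
            net, truth = sm.simulate_network(cfg)
            ds = sm.simulate_expression(net, truth, cfg)
            module = truth.planted_gene_sets[0]
            # candidate = module plus background genes
            extra = [g for g in ds.gene_ids if g not in module][:20]
            reps = sm.select_representatives(frozenset(module | set(extra)), ds)
            hits += all(r.gene_id in module for r in reps)
        assert hits >= 9


class TestClusterSamples:
    def test_two_blobs_match_brute_force(self):
        rng = np.random.default_rng(0)
        n = 10
        x = np.vstack([rng.normal(0, 0.3, (5, 3)), rng.normal(5, 0.3, (5, 3))])
        ds = make_dataset(x.T, labels=["tumor"] * 5 + ["normal"] * 5)
        reps = [sm.GeneStatistic(g, 1.0, "up") for g in ds.gene_ids]
        labels, degenerate = sm.cluster_samples(reps, ds)
        assert not degenerate

        # brute-force best 2-partition by within-cluster sum of squares on the
        # same standardized coordinates the implementation clusters
        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        best, best_w = None, np.inf
        for mask_bits in range(1, 2 ** (n - 1)):
            mask = np.array([(mask_bits >> i) & 1 for i in range(n)], bool)
            if mask.all() or (~mask).all():
                continue
            w = sum(
                ((xs[m] - xs[m].mean(axis=0)) ** 2).sum()
                for m in (mask, ~mask)
            )
            if w < best_w:
                best, best_w = mask, w
        same = labels == labels[0]
        assert np.array_equal(same, best) or np.array_equal(same, ~best)

    def test_identical_samples_degenerate(self):
        ds = make_dataset(np.ones((3, 6)), labels=["tumor"] * 3 + ["normal"] * 3)
        reps = [sm.GeneStatistic(g, 1.0, "up") for g in ds.gene_ids]
        labels, degenerate = sm.cluster_samples(reps, ds)
        assert degenerate
        assert set(labels) == {0}

    def test_duplicate_samples_co_cluster(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 7))
        x[:, 6] = x[:, 0]  # duplicate sample 0
        ds = make_dataset(x, labels=["tumor"] * 4 + ["normal"] * 3)
        reps = [sm.GeneStatistic(g, 1.0, "up") for g in ds.gene_ids]
        labels, _ = sm.cluster_samples(reps, ds)
        assert labels[0] == labels[6]

    def test_fewer_samples_than_clusters_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(2, 3)),
                          labels=["tumor", "tumor", "normal"])
        reps = [sm.GeneStatistic("g0", 1.0, "up")]
        with pytest.raises(sm.SubnetmarkError):
            sm.cluster_samples(reps, ds, n_clusters=4)


class TestEntropyScore:
    def test_pure_clusters_zero(self):
        assert sm.entropy_score([0, 0, 1, 1], ["tumor", "tumor", "normal", "normal"]) == 0.0

    def test_single_mixed_cluster_one_bit(self):
        assert sm.entropy_score([0, 0, 0, 0], ["tumor", "normal"] * 2) == pytest.approx(1.0)

    def test_three_one_split_frozen_value(self):
        # clusters of 4 with class counts (3,1) and (1,3):
        # H = -(0.75 log2 0.75 + 0.25 log2 0.25) = 0.8112781244591328
        labels = ["t", "t", "t", "n", "t", "n", "n", "n"]
        assignments = [0, 0, 0, 0, 1, 1, 1, 1]
        assert sm.entropy_score(assignments, labels) == pytest.approx(
            0.8112781244591328, abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(sm.SubnetmarkError):
            sm.entropy_score([0, 1], ["tumor"])

    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=24),
        st.data(),
    )
    def test_relabeling_invariance(self, assignments, data):
        labels = data.draw(
            st.lists(st.sampled_from(["tumor", "normal"]),
                     min_size=len(assignments), max_size=len(assignments))
        )
        h = sm.entropy_score(assignments, labels)
        perm = {c: (c + 1) % 4 for c in range(4)}
        swapped = {"tumor": "normal", "normal": "tumor"}
        assert sm.entropy_score([perm[a] for a in assignments], labels) == pytest.approx(h)
        assert sm.entropy_score(assignments, [swapped[c] for c in labels]) == pytest.approx(h)
        # zero iff every cluster is pure
        pure = all(
            len({c for a2, c in zip(assignments, labels) if a2 == a}) == 1
            for a in set(assignments)
        )
        assert (h == 0.0) == pure


class TestMergeAndRank:
    def _scored(self, sid, genes, entropy, cond=0.1):
        return sm.ScoredSubnetwork(sid, frozenset(genes), [], entropy, cond)

    def test_identical_sets_merge(self, two_class_dataset, small_network):
        a = self._scored("A", ["g0", "g1", "g2"], 0.5)
        b = self._scored("B", ["g0", "g1", "g2"], 0.7)
        out = sm.merge_overlapping([a, b], two_class_dataset, small_network)
        assert len(out) == 1
        assert out[0].gene_set == frozenset(["g0", "g1", "g2"])

    def test_disjoint_unchanged(self, two_class_dataset, small_network):
        a = self._scored("A", ["g0", "g1"], 0.5)
        b = self._scored("B", ["g2", "g3"], 0.2)
        out = sm.merge_overlapping([a, b], two_class_dataset, small_network)
        assert {s.id for s in out} == {"A", "B"}

    def test_third_overlap_below_default_threshold(self, small_network):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(9)]
        ds = make_dataset(rng.normal(size=(9, 6)), gene_ids=genes,
                          labels=["tumor"] * 3 + ["normal"] * 3)
        net = sm.InteractionNetwork.from_edges(
            [(genes[i], genes[i + 1], 900.0) for i in range(8)]
        )
        a = self._scored("A", genes[:6], 0.5)
        b = self._scored("B", genes[3:9], 0.6)
        assert len(frozenset(genes[:6]) & frozenset(genes[3:9])) / 9 == pytest.approx(1 / 3)
        out = sm.merge_overlapping([a, b], ds, net, jaccard_threshold=0.5)
        assert {s.id for s in out} == {"A", "B"}

    def test_merge_idempotent_at_fixpoint(self, two_class_dataset, small_network):
        a = self._scored("A", ["g0", "g1", "g2"], 0.5)
        b = self._scored("B", ["g1", "g2", "g3"], 0.7)
        once = sm.merge_overlapping([a, b], two_class_dataset, small_network, 0.4)
        twice = sm.merge_overlapping(once, two_class_dataset, small_network, 0.4)
        assert [s.gene_set for s in once] == [s.gene_set for s in twice]

    def test_rank_orders_by_entropy_then_conductance(self):
        subs = [
            self._scored("A", ["a"], 0.9, 0.1),
            self._scored("B", ["b"], 0.1, 0.5),
            self._scored("C", ["c"], 0.5, 0.3),
            self._scored("D", ["d"], 0.1, 0.2),
        ]
        ranked = sm.rank_subnetworks(subs)
        assert [s.id for s in ranked] == ["D", "B", "C", "A"]
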