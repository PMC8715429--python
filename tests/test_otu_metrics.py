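import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from near16s.otu_metrics import (
    Clustering,
    cluster_otus,
    msa_distances,
    optimal_threshold_sweep,
    pair_confusion_metrics,
    richness_ratio,
)


def _seq_at_distance(rng, base, n_diff):
    chars = list(base)
    for pos in rng.choice(len(base), size=n_diff, replace=False):
        chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
    return "".join(chars)


class TestClusterOtus:
    def test_identical_sequences_one_cluster(self):
        c = cluster_otus(["ACGT" * 30] * 5, threshold=0.99)
        assert c.n_clusters == 1

    @pytest.mark.parametrize("n_diff, expected", [(10, 2), (2, 1)])
    def test_threshold_cut(self, n_diff, expected):
        # 100-column alignment: 10 % distance > 3 % cut -> split;
        # 2 % distance <= 3 % cut -> merged
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 100))
        other = _seq_at_distance(rng, base, n_diff)
        c = cluster_otus([base, other], threshold=0.97, aligned=True)
        assert c.n_clusters == expected

    def test_empty_input(self):
        assert cluster_otus([], 0.97).assignments == {}

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), 120))
        seqs = [_seq_at_distance(rng, base, int(d)) for d in rng.integers(0, 30, size=12)]
        dist = msa_distances(seqs)
        counts = [
            cluster_otus(seqs, t, distances=dist).n_clusters
            for t in [0.90, 0.93, 0.96, 0.99]
        ]
        assert counts == sorted(counts)


class TestRichnessRatio:
    @pytest.mark.parametrize("S, O, expected", [(8, 8, 1.0), (10, 5, 0.5), (5, 10, 0.5)])
    def test_formula_and_symmetry(self, S, O, expected):
        assert richness_ratio(S, O) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            richness_ratio(0, 5)


def _pair_oracle(true, pred):
    """Exhaustive pair enumeration: TP/FP/FN/TN over all unordered pairs."""
    tp = fp = fn = tn = 0
    for i, j in combinations(range(len(true)), 2):
        same_true = true[i] == true[j]
        same_pred = pred[i] == pred[j]
        if same_true and same_pred:
            tp += 1
        elif not same_true and same_pred:
            fp += 1
        elif same_true and not same_pred:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestPairConfusionMetrics:
    def test_perfect_clustering(self):
        ids = [f"s{i}" for i in range(6)]
        labels = dict(zip(ids, ["a", "a", "b", "b", "c", "c"]))
        clustering = Clustering(dict(zip(ids, [1, 1, 2, 2, 3, 3])), 0.97)
        mcc, nmi, bij = pair_confusion_metrics(clustering, labels)
        assert (mcc, nmi, bij) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_interleaved_bijection_zero(self):
        ids = ["s1a", "s1b", "s2a", "s2b"]
        labels = dict(zip(ids, ["s1", "s1", "s2", "s2"]))
        clustering = Clustering(dict(zip(ids, [1, 2, 1, 2])), 0.97)
        _, _, bij = pair_confusion_metrics(clustering, labels)
        assert bij == 0.0

    def test_split_species_bijection(self):
        # one species split into two pure clusters, two species perfect
        ids = [f"s{i}" for i in range(6)]
        labels = dict(zip(ids, ["a", "a", "b", "b", "c", "c"]))
        clustering = Clustering(dict(zip(ids, [1, 4, 2, 2, 3, 3])), 0.97)
        mcc, _, bij = pair_confusion_metrics(clustering, labels)
        assert bij == pytest.approx(2 / 3)
        tp, fp, fn, tn = _pair_oracle(list(labels.values()), [1, 4, 2, 2, 3, 3])
        expected_mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc == pytest.approx(expected_mcc)

    def test_mcc_undefined_single_cluster_single_species(self):
        ids = ["a", "b"]
        labels = dict(zip(ids, ["s", "s"]))
        clustering = Clustering(dict(zip(ids, [1, 1])), 0.9)
        mcc, _, _ = pair_confusion_metrics(clustering, labels)
        assert np.isnan(mcc)

    def test_agrees_with_pair_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 30
            true = [f"sp{v}" for v in rng.integers(0, 5, size=n)]
            pred = [int(v) for v in rng.integers(0, 6, size=n)]
            ids = [f"q{i}" for i in range(n)]
            mcc, nmi, _ = pair_confusion_metrics(
                Clustering(dict(zip(ids, pred)), 0.9), dict(zip(ids, true))
            )
            tp, fp, fn, tn = _pair_oracle(true, pred)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom == 0:
                assert np.isnan(mcc)
            else:
                assert mcc == pytest.approx((tp * tn - fp * fn) / np.sqrt(denom))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        n = 25
        true = [f"sp{v}" for v in rng.integers(0, 4, size=n)]
        pred = [int(v) for v in rng.integers(0, 4, size=n)]
        ids = [f"q{i}" for i in range(n)]
        base = pair_confusion_metrics(
            Clustering(dict(zip(ids, pred)), 0.9), dict(zip(ids, true))
        )
        relabel = {0: 7, 1: 5, 2: 9, 3: 2}
        permuted = pair_confusion_metrics(
            Clustering(dict(zip(ids, [relabel[p] for p in pred])), 0.9),
            dict(zip(ids, true)),
        )
        for a, b in zip(base, permuted):
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b)


class TestThresholdSweep:
    def _clean_fixture(self, seed=0):
        # three species at exactly 4 % pairwise divergence (disjoint mutated
        # position blocks), strains within a species identical
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), 200))
        rows = []
        for si in range(3):
            chars = list(base)
            for pos in range(si * 4, si * 4 + 4):
                chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
            variant = "".join(chars)
            for ti in range(3):
                rows.append((f"sp{si}", f"st{si}{ti}", variant))
        return pd.DataFrame(rows, columns=["species", "strain", "sequence"])

    def test_clean_divergence_optimum_near_97(self):
        # at a 5 % cut the species merge, at a 2.5 % cut they separate
        # exactly, so every metric's argmax lands on 0.975 (ties -> lowest)
        table = self._clean_fixture()
        thresholds = [0.90, 0.925, 0.95, 0.975, 0.99]
        argmax, frame = optimal_threshold_sweep(table, thresholds)
        for metric, best in argmax.items():
            assert best == pytest.approx(0.975), metric

    def test_single_species_richness(self):
        rows = [("sp0", f"st{i}", "ACGT" * 50) for i in range(4)]
        table = pd.DataFrame(rows, columns=["species", "strain", "sequence"])
        _, frame = optimal_threshold_sweep(table, [0.95])
        assert frame.loc[0, "O"] == 1
        assert frame.loc[0, "richness_ratio"] == 1.0

    def test_representative_mode_reproducible(self):
        table = self._clean_fixture()
        a1, f1 = optimal_threshold_sweep(table, [0.95, 0.97], representative=True, seed=11)
        a2, f2 = optimal_threshold_sweep(table, [0.95, 0.97], representative=True, seed=11)
        pd.testing.assert_frame_equal(f1, f2)
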