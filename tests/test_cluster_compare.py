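import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from nanomir import (
    LodThresholds,
    SampleMeta,
    call_detection,
    method_concordance,
    ward_cluster,
)
from nanomir.cluster_compare import age_correlation, zscore_rows

from conftest import build_matrix


def ward_heights_oracle(points: np.ndarray) -> list[float]:
    """Brute-force Ward (ward.D2) agglomeration via the Lance-Williams update.

    Starts from Euclidean distances; merges the closest pair (lowest indices
    on ties) and updates d(k, i+j)^2 = ((n_i+n_k) d_ki^2 + (n_j+n_k) d_kj^2
    - n_k d_ij^2) / (n_i+n_j+n_k). Returns the sorted merge heights.
    """
    d2 = squareform(pdist(points)) ** 2
    active = list(range(len(points)))
    sizes = {i: 1 for i in active}
    d2 = {(i, j): d2[i, j] for i in active for j in active if i < j}
    heights = []
    next_id = len(points)
    while len(active) > 1:
        (i, j), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(best))
        ni, nj = sizes[i], sizes[j]
        merged = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dki = d2[tuple(sorted((k, i)))]
            dkj = d2[tuple(sorted((k, j)))]
            merged[k] = ((ni + nk) * dki + (nj + nk) * dkj - nk * best) / (ni + nj + nk)
        active = [k for k in active if k not in (i, j)] + [next_id]
        sizes[next_id] = ni + nj
        d2 = {
            (a, b): v
            for (a, b), v in d2.items()
            if a not in (i, j) and b not in (i, j)
        }
        for k, v in merged.items():
            d2[tuple(sorted((k, next_id)))] = v
        next_id += 1
    return sorted(heights)


class TestWardCluster:
    def make(self, counts, stage="normalized"):
        return build_matrix(
            {f"miR-{i:02d}": counts[i] for i in range(counts.shape[0])}, stage=stage
        )

    def test_linkage_heights_match_lance_williams_oracle(self, rng):
        counts = np.round(2 ** rng.uniform(3, 10, size=(6, 7))).astype(float)
        m = self.make(counts)
        res = ward_cluster(m, list(m.counts.index))
        Z, _ = zscore_rows(np.log2(m.counts + 1))
        np.testing.assert_allclose(
            sorted(res.sample_linkage[:, 2]), ward_heights_oracle(Z.to_numpy().T),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            sorted(res.probe_linkage[:, 2]), ward_heights_oracle(Z.to_numpy()),
            atol=1e-9,
        )

    def test_duplicated_sample_merges_first_at_height_zero(self, rng):
        counts = np.round(2 ** rng.uniform(3, 10, size=(5, 4))).astype(float)
        counts = np.hstack([counts, counts[:, [0]]])  # S05 duplicates S01
        m = self.make(counts)
        res = ward_cluster(m, list(m.counts.index))
        first = res.sample_linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first[0]), int(first[1])} == {0, 4}

    def test_two_planted_blobs_recovered_at_top_split(self, rng):
        n_probes, per_group = 12, 5
        base = 2 ** rng.uniform(5, 9, n_probes)
        shift = np.where(rng.random(n_probes) < 0.5, 4.0, 0.25)
        cols = []
        for g, mult in enumerate([np.ones(n_probes), shift]):
            for _ in range(per_group):
                cols.append(base * mult * 2 ** rng.normal(0, 0.1, n_probes))
        counts = np.column_stack(cols)
        m = self.make(np.round(counts))
        res = ward_cluster(m, list(m.counts.index))
        from nanomir.cluster_compare import cut_clusters

        labels = cut_clusters(res.sample_linkage, 2)
        assert len(set(labels[:per_group])) == 1
        assert len(set(labels[per_group:])) == 1
        assert labels[0] != labels[-1]

    def test_constant_probe_zeroed_and_flagged(self):
        counts = np.array([[5.0, 5.0, 5.0], [1.0, 8.0, 64.0]])
        m = self.make(counts)
        res = ward_cluster(m, list(m.counts.index))
        assert res.constant_probes == ["miR-00"]
        assert (res.scaled_matrix.loc["miR-00"] == 0).all()

    def test_row_zscores_have_zero_mean_unit_sd(self, rng):
        counts = np.round(2 ** rng.uniform(2, 12, size=(10, 8))).astype(float)
        m = self.make(counts)
        res = ward_cluster(m, list(m.counts.index))
        np.testing.assert_allclose(res.scaled_matrix.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(res.scaled_matrix.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_sample_order_invariance_of_merge_heights(self, rng):
        counts = np.round(2 ** rng.uniform(3, 10, size=(8, 6))).astype(float)
        m1 = self.make(counts)
        perm = rng.permutation(6)
        m2 = self.make(counts[:, perm])
        r1 = ward_cluster(m1, list(m1.counts.index))
        r2 = ward_cluster(m2, list(m2.counts.index))
        np.testing.assert_allclose(
            sorted(r1.sample_linkage[:, 2]), sorted(r2.sample_linkage[:, 2]), atol=1e-9
        )

    def test_row_scaling_invariance_of_zscores(self, rng):
        """Positive scaling (and shifts) of a row cancel exactly in z-scores,
        so clustering the z-scored matrix is row-scale invariant."""
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(5, 6)))
        Z1, _ = zscore_rows(X)
        X2 = X.copy()
        X2.iloc[2] = X2.iloc[2] * 5.0 + 7.0
        Z2, _ = zscore_rows(X2)
        np.testing.assert_allclose(Z1.to_numpy(), Z2.to_numpy(), atol=1e-12)

    def test_too_few_items_rejected(self):
        m = self.make(np.ones((1, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            ward_cluster(m, list(m.counts.index))


class TestMethodConcordance:
    LOD = LodThresholds.from_low_medium(20, 20)

    def calls_for(self, counts, ids):
        m = build_matrix(
            {f"miR-{i:02d}": counts[i] for i in range(counts.shape[0])},
            sample_ids=ids,
        )
        return call_detection(m, self.LOD)

    def test_identical_calls_have_no_exclusives(self, rng):
        counts = rng.integers(0, 100, size=(30, 4))
        cm = self.calls_for(counts, ["M1", "M2", "M3", "M4"])
        ca = self.calls_for(counts, ["A1", "A2", "A3", "A4"])
        pairs = [("M1", "A1"), ("M2", "A2"), ("M3", "A3"), ("M4", "A4")]
        res = method_concordance(cm, ca, pairs)
        assert (res.per_pair["manual_only"] == 0).all()
        assert (res.per_pair["auto_only"] == 0).all()
        expected_common = (counts > 20).sum(axis=0)
        np.testing.assert_array_equal(res.per_pair["common"].to_numpy(), expected_common)

    def test_planted_manual_only_probes_count_exactly(self, rng):
        counts = rng.integers(30, 100, size=(30, 4))  # everything detected
        auto = counts.copy()
        auto[:10] = 0  # 10 probes lost in the automated lanes
        cm = self.calls_for(counts, ["M1", "M2", "M3", "M4"])
        ca = self.calls_for(auto, ["A1", "A2", "A3", "A4"])
        pairs = [("M1", "A1"), ("M2", "A2"), ("M3", "A3"), ("M4", "A4")]
        res = method_concordance(cm, ca, pairs)
        assert (res.per_pair["manual_only"] == 10).all()
        assert res.summary.loc["manual_only", "mean"] == 10.0
        assert res.summary.loc["manual_only", "sd"] == 0.0

    def test_count_identity_common_plus_exclusive(self, rng):
        counts_m = rng.integers(0, 100, size=(25, 3))
        counts_a = rng.integers(0, 100, size=(25, 3))
        cm = self.calls_for(counts_m, ["M1", "M2", "M3"])
        ca = self.calls_for(counts_a, ["A1", "A2", "A3"])
        res = method_concordance(cm, ca, [("M1", "A1"), ("M2", "A2"), ("M3", "A3")])
        manual_totals = (counts_m > 20).sum(axis=0)
        got = (res.per_pair["common"] + res.per_pair["manual_only"]).to_numpy()
        np.testing.assert_array_equal(got, manual_totals)

    def test_single_pair_has_no_sd(self, rng):
        counts = rng.integers(0, 100, size=(10, 1))
        cm = self.calls_for(counts, ["M1"])
        ca = self.calls_for(counts, ["A1"])
        res = method_concordance(cm, ca, [("M1", "A1")])
        assert res.summary["sd"].isna().all()

    def test_higher_in_labels_from_normalized_means(self, rng):
        counts = (rng.integers(15, 50, size=(5, 2)) * 2).astype(float)
        mm = build_matrix({f"miR-{i:02d}": counts[i] for i in range(5)},
                          sample_ids=["M1", "M2"], stage="normalized")
        auto_counts = counts / 2
        auto_counts[0] = counts[0] * 4
        ma = build_matrix({f"miR-{i:02d}": auto_counts[i] for i in range(5)},
                          sample_ids=["A1", "A2"], stage="normalized")
        cm = call_detection(build_matrix({f"miR-{i:02d}": counts[i] for i in range(5)},
                                         sample_ids=["M1", "M2"]), self.LOD)
        ca = call_detection(build_matrix({f"miR-{i:02d}": auto_counts[i] for i in range(5)},
                                         sample_ids=["A1", "A2"]), self.LOD)
        res = method_concordance(cm, ca, [("M1", "A1"), ("M2", "A2")], mm, ma)
        assert res.higher_in.iloc[0] == "automated"
        assert (res.higher_in.iloc[1:] == "manual").all()

    def test_empty_pairing_rejected(self, rng):
        counts = rng.integers(0, 100, size=(5, 1))
        cm = self.calls_for(counts, ["M1"])
        ca = self.calls_for(counts, ["A1"])
        with pytest.raises(ValueError, match="pairs"):
            method_concordance(cm, ca, [])


class TestAgeCorrelation:
    @staticmethod
    def meta_for(ages, samples):
        return [
            SampleMeta(s, "healthy", "F", a, False, "manual", 5.0, 25.0)
            for s, a in zip(samples, ages)
        ]

    def test_expression_linear_in_age_gives_r2_one(self):
        ages = [30.0, 40.0, 50.0, 60.0]
        counts = [2 ** (0.1 * a) for a in ages]
        m = build_matrix({"miR-a": counts}, stage="normalized")
        res = age_correlation(m, self.meta_for(ages, m.samples), ["miR-a"])
        assert res.loc["miR-a", "r2"] > 0.999

    def test_random_expression_matches_pearson_oracle(self, rng):
        ages = list(rng.uniform(25, 70, 12))
        counts = list(rng.integers(50, 5000, 12).astype(float))
        m = build_matrix({"miR-a": counts}, stage="normalized")
        res = age_correlation(m, self.meta_for(ages, m.samples), ["miR-a"])
        r, p = stats.pearsonr(np.array(ages), np.log2(np.array(counts) + 1))
        assert res.loc["miR-a", "r2"] == pytest.approx(r * r, abs=1e-12)
        assert res.loc["miR-a", "p"] == pytest.approx(p, abs=1e-12)

    def test_constant_probe_flagged(self):
        m = build_matrix({"miR-a": [5.0, 5.0, 5.0]}, stage="normalized")
        res = age_correlation(m, self.meta_for([30, 40, 50], m.samples), ["miR-a"])
        assert bool(res.loc["miR-a", "constant"])
        assert np.isnan(res.loc["miR-a", "r2"])

    def test_two_samples_rejected(self):
        m = build_matrix({"miR-a": [5.0, 6.0]}, stage="normalized")
        with pytest.raises(ValueError, match="3"):
            age_correlation(m, self.meta_for([30, 40], m.samples), ["miR-a"])
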