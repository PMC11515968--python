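import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from nanomir import (
    NormalizationFactors,
    background_subtract,
    content_factors,
    fold_change,
    normalize_pipeline,
    positive_control_factors,
)
from nanomir.normalize import apply_normalization

from conftest import build_matrix


class TestBackgroundSubtract:
    def test_floor_at_zero(self):
        m = build_matrix(
            {"miR-a": [100], "miR-b": [5]},
            negatives={"NEG_A": [10], "NEG_B": [10]},
        )
        out = background_subtract(m)
        assert out.counts.loc["miR-a", "S01"] == 90.0
        assert out.counts.loc["miR-b", "S01"] == 0.0
        assert out.stage == "background_subtracted"

    def test_all_negatives_one_subtracts_one(self):
        m = build_matrix(
            {"miR-a": [100, 7]},
            negatives={"NEG_A": [1, 1], "NEG_B": [1, 1]},
        )
        out = background_subtract(m)
        assert list(out.counts.loc["miR-a"]) == [99.0, 6.0]

    def test_negative_rows_kept_unmodified(self):
        m = build_matrix({"miR-a": [100]}, negatives={"NEG_A": [10]})
        out = background_subtract(m)
        assert out.counts.loc["NEG_A", "S01"] == 10.0

    def test_random_matrix_matches_elementwise_oracle(self, rng):
        counts = rng.integers(0, 500, size=(20, 6)).astype(float)
        negs = rng.poisson(16, size=(4, 6)).astype(float)
        m = build_matrix(
            {f"miR-{i}": counts[i] for i in range(20)},
            negatives={f"NEG_{i}": negs[i] for i in range(4)},
        )
        out = background_subtract(m)
        for j in range(6):
            col = np.where(negs[:, j] == 0, 1, negs[:, j])
            bg = np.exp(np.mean(np.log(col)))
            expected = np.clip(counts[:, j] - bg, 0, None)
            np.testing.assert_allclose(
                out.endogenous().iloc[:, j].to_numpy(), expected, atol=1e-9
            )

    def test_requires_negatives(self):
        with pytest.raises(ValueError, match="Negative"):
            background_subtract(build_matrix({"miR-a": [1]}))


class TestPositiveFactors:
    def pos_matrix(self, cols):
        positives = {
            f"POS_{chr(65 + i)}": (c, list(rows))
            for i, (c, rows) in enumerate(zip((128, 32, 8, 2, 0.5, 0.125), cols))
        }
        n = len(cols[0])
        return build_matrix({"miR-a": [10.0] * n}, positives=positives,
                            stage="background_subtracted")

    def test_identical_samples_give_unit_factors(self):
        m = self.pos_matrix([[100, 100]] * 6)
        np.testing.assert_allclose(positive_control_factors(m), 1.0)

    def test_uniformly_doubled_sample(self):
        m = self.pos_matrix([[100, 200]] * 6)
        f = positive_control_factors(m)
        assert f["S01"] == pytest.approx(1.5)
        assert f["S02"] == pytest.approx(0.75)

    def test_zero_geomean_names_sample(self):
        m = self.pos_matrix([[100, 0]] * 6)
        with pytest.raises(ValueError, match="S02"):
            positive_control_factors(m)


class TestContentFactors:
    def big_matrix(self, n_probes, cols_scale, rng):
        base = rng.uniform(10, 1000, n_probes)
        endo = {
            f"miR-{i:03d}": [base[i] * s for s in cols_scale] for i in range(n_probes)
        }
        return build_matrix(endo, stage="background_subtracted")

    def test_identical_samples_unit_factors(self, rng):
        m = self.big_matrix(120, [1.0, 1.0, 1.0], rng)
        top, f = content_factors(m)
        assert len(top) == 100
        np.testing.assert_allclose(f, 1.0)

    def test_scaled_sample_matches_brute_force_oracle(self, rng):
        m = self.big_matrix(150, [1.0, 4.0, 1.0], rng)
        top, f = content_factors(m)
        # oracle: recompute from the definition with an independent gmean
        endo = m.endogenous()
        top_oracle = list(endo.mean(axis=1).sort_values(ascending=False).index[:100])
        assert set(top) == set(top_oracle)
        h = np.array([gmean(endo.loc[top, s]) for s in m.samples])
        np.testing.assert_allclose(f.to_numpy(), h.mean() / h, rtol=1e-12)

    def test_fewer_than_100_probes_warns_and_uses_all(self, rng):
        m = self.big_matrix(99, [1.0, 1.0], rng)
        with pytest.warns(UserWarning, match="99"):
            top, _ = content_factors(m)
        assert len(top) == 99

    def test_tie_break_by_name_ascending(self):
        m = build_matrix(
            {"miR-b": [10.0], "miR-a": [10.0], "miR-c": [20.0]},
            stage="background_subtracted",
        )
        top, _ = content_factors(m, n_top=2)
        assert top == ["miR-c", "miR-a"]


class TestApplyAndPipeline:
    def test_unit_factors_are_identity(self):
        m = build_matrix({"miR-a": [10, 20], "miR-b": [5, 5]},
                         stage="background_subtracted")
        f = NormalizationFactors(
            pos_factor=pd.Series(1.0, index=m.samples),
            content_factor=pd.Series(1.0, index=m.samples),
        )
        out = apply_normalization(m, f)
        pd.testing.assert_frame_equal(out.counts, m.counts.astype(float))
        assert out.stage == "normalized"

    def test_single_sample_doubling(self):
        m = build_matrix({"miR-a": [10, 10]}, stage="background_subtracted")
        f = NormalizationFactors(
            pos_factor=pd.Series({"S01": 2.0, "S02": 1.0}),
            content_factor=pd.Series(1.0, index=m.samples),
        )
        out = apply_normalization(m, f)
        assert list(out.counts.loc["miR-a"]) == [20.0, 10.0]

    def test_missing_factor_rejected(self):
        m = build_matrix({"miR-a": [10, 10]}, stage="background_subtracted")
        f = NormalizationFactors(
            pos_factor=pd.Series({"S01": 2.0}),
            content_factor=pd.Series({"S01": 1.0}),
        )
        with pytest.raises(ValueError, match="S02"):
            apply_normalization(m, f)

    def test_pipeline_equals_composed_oracle(self, rng):
        """background -> positive -> content equals a single-shot recomputation."""
        n = 150
        base = rng.integers(5, 2000, n).astype(float)
        cols = {s: np.round(base * f) for s, f in zip("ABCD", [1.0, 1.3, 0.8, 1.1])}
        endo = {f"miR-{i:03d}": [cols[s][i] for s in "ABCD"] for i in range(n)}
        pos = {
            f"POS_{c}": (conc, list(rng.integers(50, 5000, 4).astype(float)))
            for c, conc in zip("ABCDEF", (128, 32, 8, 2, 0.5, 0.125))
        }
        negs = {f"NEG_{i}": list(rng.poisson(16, 4).astype(float)) for i in range(8)}
        m = build_matrix(endo, negatives=negs, positives=pos)
        result, factors = normalize_pipeline(m)

        # oracle: plain numpy recomputation of the same composition
        raw = m.counts.to_numpy()
        neg_rows = [i for i, p in enumerate(m.codeset.probes) if p.code_class.value == "Negative"]
        bg = np.array([gmean(np.where(raw[neg_rows, j] == 0, 1, raw[neg_rows, j]))
                       for j in range(4)])
        sub = raw.copy().astype(float)
        mask = np.ones(len(m.codeset), bool)
        mask[neg_rows] = False
        sub[mask] = np.clip(sub[mask] - bg, 0, None)
        pos_rows = [i for i, p in enumerate(m.codeset.probes) if p.code_class.value == "Positive"]
        g = np.array([gmean(sub[pos_rows, j]) for j in range(4)])
        pf = g.mean() / g
        after_pos = sub * pf
        endo_rows = [i for i, p in enumerate(m.codeset.probes) if p.code_class.value == "Endogenous"]
        means = after_pos[endo_rows].mean(axis=1)
        top_idx = np.array(endo_rows)[np.argsort(-means)[:100]]
        h = np.array([gmean(np.where(after_pos[top_idx, j] == 0, 1, after_pos[top_idx, j]))
                      for j in range(4)])
        cf = h.mean() / h
        np.testing.assert_allclose(factors.pos_factor.to_numpy(), pf, rtol=1e-12)
        np.testing.assert_allclose(factors.content_factor.to_numpy(), cf, rtol=1e-12)
        np.testing.assert_allclose(result.counts.to_numpy(), sub * pf * cf, rtol=1e-9)

    def test_out_of_range_factor_flagged(self, rng):
        n = 120
        base = rng.integers(100, 2000, n).astype(float)
        endo = {f"miR-{i:03d}": [base[i], np.round(base[i] * 20)] for i in range(n)}
        pos = {
            f"POS_{c}": (conc, [1000.0, 20000.0])
            for c, conc in zip("ABCDEF", (128, 32, 8, 2, 0.5, 0.125))
        }
        negs = {f"NEG_{i}": [16.0, 16.0] for i in range(8)}
        m = build_matrix(endo, negatives=negs, positives=pos)
        _, factors = normalize_pipeline(m)
        assert bool(factors.out_of_range.any())

    def test_no_negative_counts_after_normalization(self, tiny_config):
        from nanomir import simulate_counts

        matrix, _, _ = simulate_counts(tiny_config)
        result, _ = normalize_pipeline(matrix)
        assert (result.counts.to_numpy() >= 0).all()

    def test_positive_scale_invariance_without_content(self, rng):
        """Scaling one whole lane by c cancels exactly when content is off."""
        n = 30
        base = rng.integers(50, 1000, n).astype(float)
        c = 3.0
        endo = {f"miR-{i:02d}": [base[i], base[i] * c] for i in range(n)}
        pos = {
            f"POS_{ch}": (conc, [500.0, 500.0 * c])
            for ch, conc in zip("ABCDEF", (128, 32, 8, 2, 0.5, 0.125))
        }
        negs = {f"NEG_{i}": [16.0, 16.0 * c] for i in range(8)}
        m = build_matrix(endo, negatives=negs, positives=pos)
        result, _ = normalize_pipeline(m, skip_content=True)
        endo_out = result.endogenous()
        np.testing.assert_allclose(
            endo_out["S01"].to_numpy(), endo_out["S02"].to_numpy(), rtol=1e-9
        )


class TestFoldChange:
    def test_identical_groups_zero(self):
        m = build_matrix({"miR-a": [10, 10, 10, 10]}, stage="normalized")
        fc = fold_change(m, ["S01", "S02"], ["S03", "S04"])
        assert fc["miR-a"] == 0.0

    def test_three_fold_ratio_with_large_counts(self, rng):
        base = rng.integers(5000, 20000, 10).astype(float)
        endo = {f"miR-{i}": list(np.concatenate([base[i] * 3 * np.ones(3), base[i] * np.ones(3)]))
                for i in range(10)}
        m = build_matrix(endo, stage="normalized")
        fc = fold_change(m, ["S01", "S02", "S03"], ["S04", "S05", "S06"])
        np.testing.assert_allclose(fc.to_numpy(), np.log2(3), atol=0.01)

    def test_single_probe_pseudocount_exact(self):
        m = build_matrix({"miR-a": [7, 3]}, stage="normalized")
        fc = fold_change(m, ["S01"], ["S02"])
        assert fc["miR-a"] == pytest.approx(np.log2(8) - np.log2(4))

    def test_antisymmetry_exact(self, rng):
        counts = rng.integers(0, 1000, size=(15, 8)).astype(float)
        m = build_matrix({f"miR-{i}": counts[i] for i in range(15)}, stage="normalized")
        a, b = m.samples[:4], m.samples[4:]
        np.testing.assert_array_equal(
            fold_change(m, a, b).to_numpy(), -fold_change(m, b, a).to_numpy()
        )

    def test_empty_group_rejected(self):
        m = build_matrix({"miR-a": [1, 2]}, stage="normalized")
        with pytest.raises(ValueError, match="nonempty"):
            fold_change(m, [], ["S01"])
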