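"""Feature stacking, ARI scoring, synthetic twins, prototypes, comorbidity
maps."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from neurotwin.models import ModelSpec, ContrastiveVAE
from neurotwin.subtyping import (
    ensemble_feature_matrix, cluster_and_score, synthetic_twin, cvae_prototypes,
    vae_prototypes, comorbid_maps, oracle_subtype_ari, DifferenceMap,
    _match_and_correlate,
)


def pair_counting_ari(a, b):
    """ARI from the contingency-table closed form (independent oracle)."""
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    n = len(a)
    nij = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua])
    sum_ij = comb(nij, 2).sum()
    sum_a = comb(nij.sum(axis=1), 2).sum()
    sum_b = comb(nij.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return (sum_ij - expected) / (max_index - expected)


def set_partitions(n):
    """All set partitions of range(n) as label vectors (restricted growth)."""
    def rec(prefix, m):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(m + 1):
            yield from rec(prefix + [lab], max(m, lab + 1))
    yield from rec([0], 1)


class TestAri:
    def test_known_values(self):
        res = cluster_and_score(np.array([[0.0], [0.1], [5.0], [5.1]]), 2,
                                [0, 0, 1, 1], seed=0)
        assert res.ari == pytest.approx(1.0)
        assert pair_counting_ari([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)
        assert pair_counting_ari([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(-0.5)

    def test_matches_pair_counting_on_all_small_partitions(self):
        from sklearn.metrics import adjusted_rand_score
        for n in (3, 4, 5):
            parts = list(set_partitions(n))
            for pa, pb in itertools.product(parts, parts):
                assert adjusted_rand_score(pa, pb) == pytest.approx(
                    pair_counting_ari(pa, pb), abs=1e-12)

    def test_matches_pair_counting_on_random_partitions_up_to_8(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(0)
        for n in (6, 7, 8):
            for _ in range(300):
                pa = rng.integers(0, 4, n)
                pb = rng.integers(0, 4, n)
                assert adjusted_rand_score(pa, pb) == pytest.approx(
                    pair_counting_ari(pa, pb), abs=1e-12)

    def test_k_bounds(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            cluster_and_score(X, 1, [0, 0, 0])
        with pytest.raises(ValueError):
            cluster_and_score(X, 5, [0, 0, 0])

    def test_oracle_subtyping_ceiling(self):
        # per-locus true magnitudes separate subtypes perfectly
        rng = np.random.default_rng(0)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        feats = np.zeros((n, 2))
        feats[labels == 0, 0] = rng.uniform(0.2, 2.0, n // 2)
        feats[labels == 1, 1] = rng.uniform(0.2, 2.0, n // 2)
        assert oracle_subtype_ari(feats, labels, 2) == pytest.approx(1.0)


class TestFeatureMatrix:
    def test_column_count(self, tiny_spec, rng):
        x = rng.uniform(0, 1, (5, 16, 16, 16)).astype(np.float32)
        models = [ContrastiveVAE(tiny_spec, seed=s) for s in range(4)]
        mat = ensemble_feature_matrix(models, x, "specific")
        assert mat.shape == (5, 4 * 2)

    def test_single_model_equals_latents(self, tiny_cvae, rng):
        from neurotwin.rsa import encode_mu
        x = rng.uniform(0, 1, (5, 16, 16, 16)).astype(np.float32)
        mat = ensemble_feature_matrix([tiny_cvae], x, "shared")
        assert np.array_equal(mat, encode_mu(tiny_cvae, x, "shared"))

    def test_block_permutation_preserves_kmeans_objective(self, tiny_spec, rng):
        x = rng.uniform(0, 1, (12, 16, 16, 16)).astype(np.float32)
        models = [ContrastiveVAE(tiny_spec, seed=s) for s in range(3)]
        a = ensemble_feature_matrix(models, x, "specific")
        b = ensemble_feature_matrix(models[::-1], x, "specific")
        ra = cluster_and_score(a, 2, [0] * 6 + [1] * 6, seed=0)
        rb = cluster_and_score(b, 2, [0] * 6 + [1] * 6, seed=0)
        assert ra.inertia == pytest.approx(rb.inertia, rel=1e-9)

    def test_empty_ensemble_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            ensemble_feature_matrix([], np.zeros((2, 16, 16, 16)), "shared")


class TestSyntheticTwin:
    def test_control_map_is_zero(self, tiny_cvae, rng):
        x = rng.uniform(0, 1, (16, 16, 16)).astype(np.float32)
        dm = synthetic_twin(tiny_cvae, x, "control")
        assert not np.any(dm.grid)

    def test_patient_map_nonzero_and_deterministic(self, tiny_cvae, rng):
        x = rng.uniform(0, 1, (16, 16, 16)).astype(np.float32)
        a = synthetic_twin(tiny_cvae, x, "patient")
        b = synthetic_twin(tiny_cvae, x, "patient")
        assert np.array_equal(a.grid, b.grid)
        assert a.grid.shape == (16, 16, 16)

    def test_vae_rejected(self, rng):
        vae = ContrastiveVAE(ModelSpec(kind="vae", input_shape=(16, 16, 16),
                                       conv_filters=(4, 6)), seed=0)
        with pytest.raises(ValueError, match="contrastive"):
            synthetic_twin(vae, np.zeros((16, 16, 16), np.float32), "patient")


class TestPrototypes:
    def test_perfect_prototypes_correlate_one(self):
        rng = np.random.default_rng(0)
        truth = {1: rng.uniform(0, 1, (8, 8, 8)), 2: rng.uniform(0, 1, (8, 8, 8))}
        protos = {0: DifferenceMap(grid=truth[2], map_kind="prototype"),
                  1: DifferenceMap(grid=truth[1], map_kind="prototype")}
        matched, mean_r = _match_and_correlate(protos, truth, np.ones((8, 8, 8), bool))
        assert mean_r == pytest.approx(1.0)
        assert set(matched) == {1, 2}

    def test_cluster_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        truth = {1: rng.uniform(0, 1, (8, 8, 8)), 2: rng.uniform(0, 1, (8, 8, 8))}
        p1 = DifferenceMap(grid=truth[1] + rng.normal(0, 0.1, (8, 8, 8)), map_kind="prototype")
        p2 = DifferenceMap(grid=truth[2] + rng.normal(0, 0.1, (8, 8, 8)), map_kind="prototype")
        mask = np.ones((8, 8, 8), bool)
        _, r_a = _match_and_correlate({0: p1, 1: p2}, truth, mask)
        _, r_b = _match_and_correlate({0: p2, 1: p1}, truth, mask)
        assert r_a == pytest.approx(r_b)

    def test_vae_prototype_trivial_cases(self, rng):
        x = rng.uniform(0, 1, (8, 8, 8, 8))
        groups = ["control"] * 4 + ["patient"] * 4
        truth = {1: rng.uniform(0, 1, (8, 8, 8))}
        # patients identical to controls -> zero prototypes
        x[4:] = x[:4]
        protos, _, _ = vae_prototypes(x, groups, [0, 0, 0, 0], truth,
                                      np.ones((8, 8, 8), bool))
        assert np.allclose(protos[0].grid, 0)

    def test_single_cluster_is_patient_minus_control_mean(self, rng):
        x = rng.uniform(0, 1, (6, 8, 8, 8))
        groups = ["control"] * 3 + ["patient"] * 3
        truth = {1: rng.uniform(0, 1, (8, 8, 8))}
        protos, _, _ = vae_prototypes(x, groups, [0, 0, 0], truth,
                                      np.ones((8, 8, 8), bool))
        assert np.allclose(protos[0].grid, x[3:].mean(0) - x[:3].mean(0))

    def test_no_controls_rejected(self, rng):
        with pytest.raises(ValueError, match="control"):
            vae_prototypes(np.zeros((2, 8, 8, 8)), ["patient", "patient"], [0, 0],
                           {1: np.zeros((8, 8, 8))}, np.ones((8, 8, 8), bool))


class TestComorbidMaps:
    def test_selective_zeroing_invariances(self, tiny_comorbid, rng):
        x = rng.uniform(0, 1, (16, 16, 16)).astype(np.float32)
        d1 = comorbid_maps(tiny_comorbid, x, "d1")
        # the d1 map only decodes {shared, d1} and {shared}: perturbing the
        # d2 and patient_shared encoders must leave it bit-identical
        for space in ("d2", "patient_shared"):
            tiny_comorbid.encoders[space].dense_mu.params["W"] += 3.0
        d1_again = comorbid_maps(tiny_comorbid, x, "d1")
        assert np.array_equal(d1.grid, d1_again.grid)
        assert d1.map_kind == "comorbid_d1"

    def test_all_three_kinds_produced(self, tiny_comorbid, rng):
        x = rng.uniform(0, 1, (16, 16, 16)).astype(np.float32)
        kinds = {comorbid_maps(tiny_comorbid, x, w).map_kind
                 for w in ("d1", "d2", "comorbid")}
        assert kinds == {"comorbid_d1", "comorbid_d2", "comorbid_comorbid"}

    def test_wrong_model_rejected(self, tiny_cvae):
        with pytest.raises(ValueError, match="comorbidity model"):
            comorbid_maps(tiny_cvae, np.zeros((16, 16, 16), np.float32), "d1")

    def test_unknown_which_rejected(self, tiny_comorbid):
        with pytest.raises(ValueError, match="which"):
            comorbid_maps(tiny_comorbid, np.zeros((16, 16, 16), np.float32), "d3")
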