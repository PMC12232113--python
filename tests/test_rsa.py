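"""RDM construction, Kendall-tau RSA, Fisher-z tests, PCA baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurotwin.models import ModelSpec, ContrastiveVAE
from neurotwin.rsa import (
    RDM, latent_rdm, magnitude_rdm, rsa_correlation, ensemble_rsa, encode_mu,
    fisher_z_ttest, variance_explained, pca_baseline,
)


def brute_force_tau(a, b):
    """O(m^2) tau-b by explicit concordant/discordant/tie counting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    m = len(a)
    conc = disc = ties_a = ties_b = 0
    for i in range(m):
        for j in range(i + 1, m):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                continue
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = m * (m - 1) / 2
    denom = np.sqrt((n0 - _tie_term(a)) * (n0 - _tie_term(b)))
    return (conc - disc) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


class TestRdms:
    def test_latent_rdm_examples(self):
        r = latent_rdm(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert r.matrix[0, 1] == pytest.approx(5.0)
        r2 = latent_rdm(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert r2.matrix[0, 1] == 0.0

    def test_magnitude_rdm_examples(self):
        assert magnitude_rdm([1.0, 4.0]).matrix[0, 1] == 3.0
        assert not np.any(magnitude_rdm([2.0, 2.0, 2.0]).matrix)

    def test_affine_shift_invariance(self):
        m = np.array([0.3, 1.1, 2.9, 0.4])
        assert np.allclose(magnitude_rdm(m).matrix, magnitude_rdm(m + 10).matrix)

    def test_permutation_equivariance(self):
        mu = np.random.default_rng(0).normal(size=(6, 2))
        perm = [3, 1, 5, 0, 2, 4]
        a = latent_rdm(mu).matrix
        b = latent_rdm(mu[perm]).matrix
        assert np.allclose(b, a[np.ix_(perm, perm)])

    def test_invalid_rdm_rejected(self):
        with pytest.raises(ValueError):
            RDM(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            RDM(np.array([[1.0]]))


class TestRsaCorrelation:
    def _rdm_from_upper(self, upper, n):
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = upper
        return RDM(m + m.T)

    def test_self_correlation_is_one(self):
        r = self._rdm_from_upper([1.0, 2.0, 3.0], 3)
        assert rsa_correlation(r, r) == pytest.approx(1.0)

    def test_full_reversal(self):
        a = self._rdm_from_upper([1.0, 2.0, 3.0], 3)
        b = self._rdm_from_upper([3.0, 2.0, 1.0], 3)
        assert rsa_correlation(a, b) == pytest.approx(-1.0)

    def test_known_partial_agreement(self):
        # [1,2,3,4] vs [1,3,2,4]: exhaustive count over the 6 pairs gives
        # 5 concordant and 1 discordant (the 2-3 swap) -> tau = 4/6 = 2/3
        from scipy.stats import kendalltau
        assert brute_force_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)
        assert kendalltau([1, 2, 3, 4], [1, 3, 2, 4]).statistic == pytest.approx(2 / 3)
        a = self._rdm_from_upper([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 4)
        b = self._rdm_from_upper([1.0, 3.0, 2.0, 4.0, 5.0, 6.0], 4)
        assert rsa_correlation(a, b) == pytest.approx(
            brute_force_tau(a.upper(), b.upper()))

    def test_constant_rdm_flagged(self):
        a = self._rdm_from_upper([1.0, 1.0, 1.0], 3)
        b = self._rdm_from_upper([1.0, 2.0, 3.0], 3)
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(rsa_correlation(a, b))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_bruteforce_pair_counts(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 15))
        n = m * (m + 1) // 2  # enough upper-triangle slots
        a = rng.integers(0, 6, m * (m - 1) // 2).astype(float)  # with ties
        b = rng.normal(size=m * (m - 1) // 2)
        ra, rb = self._rdm_from_upper(a, m), self._rdm_from_upper(b, m)
        if np.ptp(a) == 0:
            return
        assert rsa_correlation(ra, rb) == pytest.approx(brute_force_tau(a, b), abs=1e-12)


class TestFisherZ:
    def test_identical_groups_t_zero(self):
        t, df, p = fisher_z_ttest([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_atanh_value(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert np.arctanh(0.5) == pytest.approx(0.5 * np.log(3))

    def test_two_groups_of_five_df8(self):
        rng = np.random.default_rng(0)
        t, df, p = fisher_z_ttest(rng.uniform(0.1, 0.3, 5), rng.uniform(0.4, 0.6, 5))
        assert df == 8

    def test_paired_df(self):
        t, df, p = fisher_z_ttest([0.1, 0.2, 0.3], [0.15, 0.22, 0.35], paired=True)
        assert df == 2

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            fisher_z_ttest([1.0, 0.5], [0.2, 0.3])


class TestEnsembleRsa:
    def test_identical_models_mean_equals_single(self, tiny_cvae, rng):
        x = rng.uniform(0, 1, (6, 16, 16, 16)).astype(np.float32)
        mags = rng.uniform(0, 2, 6)
        single = ensemble_rsa([tiny_cvae], x, mags, "shared").tau
        triple = ensemble_rsa([tiny_cvae] * 3, x, mags, "shared")
        assert triple.tau == pytest.approx(single)
        assert len(triple.per_model_taus) == 3

    def test_untrained_models_near_zero(self, tiny_spec, rng):
        x = rng.uniform(0, 1, (20, 16, 16, 16)).astype(np.float32)
        mags = rng.uniform(0, 2, 20)
        taus = [abs(ensemble_rsa([ContrastiveVAE(tiny_spec, seed=s)], x, mags,
                                 "shared").tau) for s in range(10)]
        assert np.mean(taus) < 0.1

    def test_model_order_invariance(self, tiny_spec, rng):
        x = rng.uniform(0, 1, (6, 16, 16, 16)).astype(np.float32)
        mags = rng.uniform(0, 2, 6)
        models = [ContrastiveVAE(tiny_spec, seed=s) for s in range(3)]
        a = ensemble_rsa(models, x, mags, "shared").tau
        b = ensemble_rsa(models[::-1], x, mags, "shared").tau
        assert a == pytest.approx(b)

    def test_groundtruth_latents_give_tau_one(self):
        # pipeline oracle: latents replaced by the true magnitude
        mags = np.array([0.3, 1.2, 0.8, 2.0, 0.1])
        lat = latent_rdm(mags[:, None])
        truth = magnitude_rdm(mags)
        assert rsa_correlation(lat, truth) == pytest.approx(1.0)


class TestVarianceExplained:
    class _Perfect:
        spec = type("S", (), {"spaces": ("shared",)})

        def reconstruct(self, x, group):
            return np.asarray(x, dtype=np.float32)

    class _MeanPredictor:
        def __init__(self, xbar):
            self.xbar = xbar

        def reconstruct(self, x, group):
            return np.repeat(self.xbar, np.asarray(x).shape[0], axis=0)

    def test_perfect_reconstruction(self, rng):
        x = rng.uniform(0, 1, (4, 8, 8, 8)).astype(np.float32)
        assert variance_explained(self._Perfect(), x, ["control"] * 4) == pytest.approx(1.0)

    def test_mean_predictor_is_zero(self, rng):
        x = rng.uniform(0, 1, (4, 8, 8, 8)).astype(np.float32)
        m = self._MeanPredictor(x.mean(axis=0, keepdims=True))
        assert variance_explained(m, x, ["control"] * 4) == pytest.approx(0.0, abs=1e-6)

    def test_constant_inputs_rejected(self):
        x = np.full((3, 8, 8, 8), 0.5, dtype=np.float32)
        with pytest.raises(ValueError, match="constant"):
            variance_explained(self._Perfect(), x, ["control"] * 3)


class TestPcaBaseline:
    def _data(self, rng, n=40):
        # low-rank images: a few spatial modes scaled by subject loadings
        modes = rng.normal(size=(6, 8 * 8 * 8))
        load = rng.normal(size=(n, 6)) * np.array([5, 4, 3, 2, 1, 0.5])
        x = (load @ modes).reshape(n, 8, 8, 8)
        mags = load[:, 0]  # ground truth aligned with the top mode
        return x, np.abs(mags)

    def test_heldout_equal_train_gives_equal_tau(self, rng):
        x, mags = self._data(rng)
        mask = np.ones((8, 8, 8), bool)
        res = pca_baseline(x, x, mags, mags, mask, variance_floor=0.85)
        assert res.transfer.tau == pytest.approx(res.train.tau)
        assert res.variance_explained >= 0.85

    def test_invalid_floor_rejected(self, rng):
        x, mags = self._data(rng, n=5)
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError, match="variance_floor"):
            pca_baseline(x, x, mags, mags, mask, variance_floor=1.5)

    def test_transfer_weaker_than_train_on_fresh_sample(self, rng):
        xa, ma = self._data(rng)
        xb, mb = self._data(rng)
        noise_a = rng.normal(0, 2.0, xa.shape)
        res = pca_baseline(xa + noise_a, xb, ma, mb,
                           np.ones((8, 8, 8), bool), variance_floor=0.6)
        assert res.transfer.tau < res.train.tau + 0.05
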