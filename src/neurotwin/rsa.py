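"""Representational similarity analysis between latent spaces and the
generator's ground-truth effect magnitudes, plus the statistical helpers
used to compare model families.

An RDM (representational dissimilarity matrix) holds pairwise subject
distances — Euclidean distance between posterior-mean latents, or absolute
difference between scalar ground-truth magnitudes.  Two RDMs are compared
by Kendall's tau-b over their strictly-upper triangles.  Posterior means
(μ), never samples, feed every analysis here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA


@dataclass
class RDM:
    matrix: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
            raise ValueError("RDM must be square with n >= 2")
        if np.abs(np.diag(m)).max() > 1e-10 or np.abs(m - m.T).max() > 1e-10:
            raise ValueError("RDM must be symmetric with zero diagonal")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper(self) -> np.ndarray:
        return self.matrix[np.triu_indices(self.n, 1)]


@dataclass
class RsaResult:
    tau: float
    n_pairs: int
    feature_space: str = ""
    ground_truth: str = ""
    per_model_taus: list = field(default_factory=list)


def latent_rdm(mu: np.ndarray, labels=None) -> RDM:
    """Pairwise Euclidean distances between per-subject μ vectors."""
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    if mu.shape[0] < 2:
        raise ValueError("need at least two subjects")
    return RDM(squareform(pdist(mu)), labels=list(labels or range(mu.shape[0])))


def magnitude_rdm(magnitudes, labels=None) -> RDM:
    """Pairwise absolute differences between scalar magnitudes."""
    m = np.asarray(magnitudes, dtype=np.float64).ravel()
    if m.size < 2:
        raise ValueError("need at least two subjects")
    return RDM(np.abs(m[:, None] - m[None, :]), labels=list(labels or range(m.size)))


def rsa_correlation(rdm_a: RDM, rdm_b: RDM) -> float:
    """Kendall tau-b between the strictly-upper triangles of two RDMs."""
    if rdm_a.n != rdm_b.n:
        raise ValueError("RDMs must have the same size")
    ua, ub = rdm_a.upper(), rdm_b.upper()
    if np.ptp(ua) == 0 or np.ptp(ub) == 0:
        warnings.warn("constant RDM: Kendall tau undefined, returning NaN")
        return float("nan")
    return float(stats.kendalltau(ua, ub).statistic)


def ensemble_rsa(models, volumes, truth_magnitudes, space: str,
                 ground_truth_name: str = "", subject_mask=None,
                 batch_size: int = 64) -> RsaResult:
    """Per-model tau between a latent-space RDM and a ground-truth RDM,
    averaged arithmetically across the ensemble.

    ``subject_mask`` restricts the comparison (disorder-specific RSA uses
    patients only: controls' specific magnitude is identically zero and
    would inject ties).
    """
    mags = np.asarray(truth_magnitudes, dtype=np.float64)
    if subject_mask is not None:
        sel = np.asarray(subject_mask, dtype=bool)
        mags = mags[sel]
    truth = magnitude_rdm(mags)
    taus = []
    for model in models:
        mu = encode_mu(model, volumes, space, batch_size=batch_size)
        if subject_mask is not None:
            mu = mu[sel]
        taus.append(rsa_correlation(latent_rdm(mu), truth))
    return RsaResult(tau=float(np.mean(taus)), n_pairs=truth.n * (truth.n - 1) // 2,
                     feature_space=space, ground_truth=ground_truth_name,
                     per_model_taus=[float(t) for t in taus])


def encode_mu(model, volumes, space: str | None = None, batch_size: int = 64) -> np.ndarray:
    """Posterior-mean latents for a volume stack, batched for memory.

    ``space=None`` concatenates all of the model's spaces (the baseline
    VAE convention of "all features").
    """
    x = np.asarray(volumes, dtype=np.float32)
    spaces = model.spec.spaces if space is None else (space,)
    chunks = []
    for start in range(0, x.shape[0], batch_size):
        code = model.encode(x[start:start + batch_size])
        chunks.append(np.concatenate([code.mu[s] for s in spaces], axis=1))
    return np.concatenate(chunks, axis=0)


def fisher_z_ttest(taus_a, taus_b, paired: bool = False):
    """Student's t-test on Fisher z-transformed correlations.

    Returns ``(t, df, p)``; two-sample df = n_a + n_b - 2 (two groups of
    five give df = 8), paired df = n - 1.
    """
    a = np.asarray(taus_a, dtype=np.float64)
    b = np.asarray(taus_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two correlations per group")
    if np.any(np.abs(a) >= 1) or np.any(np.abs(b) >= 1):
        raise ValueError("|correlation| = 1: Fisher z-transform is infinite")
    za, zb = np.arctanh(a), np.arctanh(b)
    if paired:
        res = stats.ttest_rel(za, zb)
        df = a.size - 1
    else:
        res = stats.ttest_ind(za, zb)
        df = a.size + b.size - 2
    return float(res.statistic), int(df), float(res.pvalue)


def variance_explained(models, volumes, groups, batch_size: int = 64) -> float:
    """R² of μ-based reconstructions: 1 - SSE/SST, SST about the voxelwise
    dataset mean.  For an ensemble, the mean of per-model values."""
    if not isinstance(models, (list, tuple)):
        models = [models]
    x = np.asarray(volumes, dtype=np.float32)
    xbar = x.mean(axis=0, keepdims=True)
    sst = float(((x - xbar) ** 2).sum())
    if sst == 0:
        raise ValueError("constant input set: variance undefined")
    by_group: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        by_group.setdefault(g, []).append(i)
    r2s = []
    for model in models:
        sse = 0.0
        for g, idx in by_group.items():
            for start in range(0, len(idx), batch_size):
                sel = idx[start:start + batch_size]
                recon = model.reconstruct(x[sel], g)
                sse += float(((recon - x[sel]) ** 2).sum())
        r2s.append(1.0 - sse / sst)
    return float(np.mean(r2s))


@dataclass
class PcaBaselineResult:
    train: RsaResult
    transfer: RsaResult
    n_components: int
    variance_explained: float


def pca_baseline(train_volumes, heldout_volumes, train_magnitudes, heldout_magnitudes,
                 mask, variance_floor: float = 0.85,
                 train_subject_mask=None, heldout_subject_mask=None) -> PcaBaselineResult:
    """PCA generalization probe.

    Fits components on masked, flattened training voxels (smallest count
    whose cumulative explained variance reaches ``variance_floor``), scores
    both sets with the SAME loadings, and correlates each score-space RDM
    with the corresponding ground-truth magnitude RDM.
    """
    if not 0 < variance_floor < 1:
        raise ValueError("variance_floor must be in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    Xtr = np.asarray(train_volumes, dtype=np.float64).reshape(len(train_volumes), -1)[:, mask.ravel()]
    Xte = np.asarray(heldout_volumes, dtype=np.float64).reshape(len(heldout_volumes), -1)[:, mask.ravel()]
    full = PCA(n_components=min(Xtr.shape[0] - 1, Xtr.shape[1]), svd_solver="randomized",
               random_state=0)
    scores_tr = full.fit_transform(Xtr)
    cum = np.cumsum(full.explained_variance_ratio_)
    if cum[-1] < variance_floor:
        raise ValueError(f"variance floor {variance_floor} unreachable "
                         f"(max {cum[-1]:.3f} with n-1 components)")
    k = int(np.searchsorted(cum, variance_floor) + 1)
    scores_tr = scores_tr[:, :k]
    scores_te = full.transform(Xte)[:, :k]

    def _res(scores, mags, sel, which):
        mags = np.asarray(mags, dtype=np.float64)
        if sel is not None:
            s = np.asarray(sel, dtype=bool)
            scores, mags = scores[s], mags[s]
        truth = magnitude_rdm(mags)
        tau = rsa_correlation(latent_rdm(scores), truth)
        return RsaResult(tau=tau, n_pairs=truth.n * (truth.n - 1) // 2,
                         feature_space=f"pca{k}", ground_truth=which)

    return PcaBaselineResult(
        train=_res(scores_tr, train_magnitudes, train_subject_mask, "train"),
        transfer=_res(scores_te, heldout_magnitudes, heldout_subject_mask, "transfer"),
        n_components=k, variance_explained=float(cum[k - 1]))
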