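"""VAE, contrastive VAE, and the four-encoder comorbidity CVAE.

All three share one body plan: per latent space an encoder of two
stride-2 3-D conv layers followed by dense heads for the posterior mean
and log-variance, and a single decoder (dense -> two transposed-conv
layers -> sigmoid) that consumes the concatenation of every space's
latent vector.  Disentanglement is purely architectural: before decoding,
spaces that are *inactive* for a subject's group are replaced by zeros,
so e.g. control reconstructions can never use disorder-specific latents
and those encoders receive no gradient from controls.

Active spaces by group:

==================  =====================================================
vae                 ``all`` for every group (non-contrastive baseline,
                    single encoder with doubled filters)
cvae                control: ``shared``; patients: ``shared, specific``
comorbid_cvae       control: ``shared``; disorder1: ``shared,
                    patient_shared, d1``; disorder2: likewise with ``d2``;
                    disorder1+2: all four
==================  =====================================================

Loss = per-batch mean of (voxel-summed squared reconstruction error)
+ kl_weight * per-batch mean of (coordinate-summed Gaussian KL over the
subject's active spaces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import DTYPE

SPACES = {
    "vae": ("all",),
    "cvae": ("shared", "specific"),
    "comorbid_cvae": ("shared", "patient_shared", "d1", "d2"),
}

_ACTIVE = {
    "cvae": {"control": ("shared",)},
    "comorbid_cvae": {
        "control": ("shared",),
        "disorder1": ("shared", "patient_shared", "d1"),
        "disorder2": ("shared", "patient_shared", "d2"),
        "disorder1+2": ("shared", "patient_shared", "d1", "d2"),
    },
}


def active_spaces(kind: str, group: str) -> tuple[str, ...]:
    """Latent spaces used to reconstruct a subject of ``group``."""
    if kind == "vae":
        return ("all",)
    if kind == "cvae":
        if group == "control":
            return ("shared",)
        return ("shared", "specific")
    if kind == "comorbid_cvae":
        try:
            return _ACTIVE["comorbid_cvae"][group]
        except KeyError:
            raise ValueError(f"unknown group {group!r} for comorbid_cvae") from None
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class ModelSpec:
    kind: str = "cvae"
    input_shape: tuple[int, int, int] = (64, 64, 64)
    latent_dim_per_space: int = 2
    conv_filters: tuple[int, int] = (32, 64)
    hidden_dim: int = 128         # dense layer between conv stack and heads
    learning_rate: float = 1e-3
    kl_weight: float = 1.0
    kl_all_spaces: bool = False   # include KL for inactive spaces as well
    batch_size: int = 32

    def __post_init__(self):
        if self.kind not in SPACES:
            raise ValueError(f"kind must be one of {sorted(SPACES)}")
        if self.latent_dim_per_space < 1:
            raise ValueError("latent_dim_per_space must be >= 1")
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.conv_filters = tuple(int(c) for c in self.conv_filters)
        if any(s % 4 for s in self.input_shape):
            raise ValueError("input_shape axes must be divisible by 4")

    @property
    def spaces(self) -> tuple[str, ...]:
        return SPACES[self.kind]

    def encoder_filters(self) -> tuple[int, int]:
        """The non-contrastive baseline doubles the conv filters."""
        c1, c2 = self.conv_filters
        return (2 * c1, 2 * c2) if self.kind == "vae" else (c1, c2)

    @property
    def total_latent(self) -> int:
        return self.latent_dim_per_space * len(self.spaces)


@dataclass
class LatentCode:
    """Per-space posterior parameters (and optional sample) for a batch."""

    mu: dict
    logvar: dict
    z: dict = field(default_factory=dict)

    def concat_mu(self, spaces) -> np.ndarray:
        return np.concatenate([self.mu[s] for s in spaces], axis=1)


@dataclass
class LossBreakdown:
    total: float
    mse: float
    kl: float


class Encoder:
    """Two stride-2 conv layers, a dense hidden layer, and μ / log σ² heads."""

    def __init__(self, spec: ModelSpec, rng):
        c1, c2 = spec.encoder_filters()
        d = spec.input_shape
        self.conv1 = nn.Conv2x2(1, c1, rng)
        self.conv2 = nn.Conv2x2(c1, c2, rng)
        flat = (d[0] // 4) * (d[1] // 4) * (d[2] // 4) * c2
        self.hidden = nn.Dense(flat, spec.hidden_dim, rng)
        self.dense_mu = nn.Dense(spec.hidden_dim, spec.latent_dim_per_space, rng)
        self.dense_lv = nn.Dense(spec.hidden_dim, spec.latent_dim_per_space, rng)

    @property
    def layers(self):
        return [self.conv1, self.conv2, self.hidden, self.dense_mu, self.dense_lv]

    def forward(self, x):
        h1, cache1 = self.conv1.forward(x)
        a1 = nn.relu(h1)
        h2, cache2 = self.conv2.forward(a1)
        a2 = nn.relu(h2)
        flat = a2.reshape(a2.shape[0], -1)
        hh, ch = self.hidden.forward(flat)
        ah = nn.relu(hh)
        mu, cm = self.dense_mu.forward(ah)
        lv, cl = self.dense_lv.forward(ah)
        lv = np.clip(lv, -15.0, 15.0)
        cache = (cache1, h1, cache2, h2, a2.shape, ch, hh, cm, cl)
        return mu, lv, cache

    def backward(self, gmu, glv, cache):
        cache1, h1, cache2, h2, a2shape, ch, hh, cm, cl = cache
        gah = self.dense_mu.backward(gmu, cm)
        gah += self.dense_lv.backward(glv, cl)
        ghh = nn.relu_grad(gah, hh)
        gflat = self.hidden.backward(ghh, ch)
        ga2 = gflat.reshape(a2shape)
        gh2 = nn.relu_grad(ga2, h2)
        ga1 = self.conv2.backward(gh2, cache2)
        gh1 = nn.relu_grad(ga1, h1)
        return self.conv1.backward(gh1, cache1)


class Decoder:
    def __init__(self, spec: ModelSpec, rng):
        c1, c2 = spec.encoder_filters()
        d = spec.input_shape
        self.low = (d[0] // 4, d[1] // 4, d[2] // 4, c2)
        flat = self.low[0] * self.low[1] * self.low[2] * c2
        self.hidden = nn.Dense(spec.total_latent, spec.hidden_dim, rng)
        self.dense = nn.Dense(spec.hidden_dim, flat, rng)
        self.deconv1 = nn.Deconv2x2(c2, c1, rng)
        self.deconv2 = nn.Deconv2x2(c1, 1, rng)

    @property
    def layers(self):
        return [self.hidden, self.dense, self.deconv1, self.deconv2]

    def forward(self, z):
        hh, chh = self.hidden.forward(z)
        ah = nn.relu(hh)
        h0, c0 = self.dense.forward(ah)
        a0 = nn.relu(h0)
        a0v = a0.reshape((z.shape[0],) + self.low)
        h1, c1 = self.deconv1.forward(a0v)
        a1 = nn.relu(h1)
        h2, c2 = self.deconv2.forward(a1)
        y = nn.sigmoid(h2)
        return y, (chh, hh, c0, h0, c1, h1, c2, y)

    def backward(self, gy, cache):
        chh, hh, c0, h0, c1, h1, c2, y = cache
        gh2 = gy * y * (1.0 - y)
        ga1 = self.deconv2.backward(gh2, c2)
        gh1 = nn.relu_grad(ga1, h1)
        ga0 = self.deconv1.backward(gh1, c1)
        ga0 = ga0.reshape(ga0.shape[0], -1)
        gh0 = nn.relu_grad(ga0, h0)
        gah = self.dense.backward(gh0, c0)
        ghh = nn.relu_grad(gah, hh)
        return self.hidden.backward(ghh, chh)


class ContrastiveVAE:
    """One trainable model (any of the three kinds)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7**5]))
        self.encoders = {s: Encoder(spec, rng) for s in spec.spaces}
        self.decoder = Decoder(spec, rng)
        self.optimizer = nn.Adam(self.layers, lr=spec.learning_rate)
        self.flagged = False

    @property
    def layers(self):
        out = []
        for s in self.spec.spaces:
            out.extend(self.encoders[s].layers)
        out.extend(self.decoder.layers)
        return out

    def parameter_count(self, part: str = "all") -> int:
        layers = []
        if part in ("all", "encoder"):
            for s in self.spec.spaces:
                layers.extend(self.encoders[s].layers)
        if part in ("all", "decoder"):
            layers.extend(self.decoder.layers)
        return int(sum(p.size for ly in layers for p in ly.params.values()))

    # -- inference -------------------------------------------------------
    def _as_batch(self, volumes) -> np.ndarray:
        x = np.asarray(volumes, dtype=DTYPE)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(f"volume shape {x.shape[1:]} != input {self.spec.input_shape}")
        return x[..., None]

    def encode(self, volumes, rng=None) -> LatentCode:
        """Posterior means/log-variances per space; a reparameterized
        sample is included when ``rng`` is given."""
        x = self._as_batch(volumes)
        mu, lv, z = {}, {}, {}
        for s in self.spec.spaces:
            m, l, _ = self.encoders[s].forward(x)
            mu[s], lv[s] = m, l
            if rng is not None:
                z[s] = reparameterize(m, l, rng)
        return LatentCode(mu=mu, logvar=lv, z=z)

    def decode(self, latents: LatentCode, group: str, use: str = "mu") -> np.ndarray:
        """Reconstruction from latents; spaces inactive for ``group`` are
        zeroed in the decoder input."""
        act = active_spaces(self.spec.kind, group)
        src = latents.z if (use == "z" and latents.z) else latents.mu
        ref = next(iter(src.values()))
        parts = []
        for s in self.spec.spaces:
            v = src[s] if s in act else np.zeros_like(ref)
            parts.append(np.asarray(v, dtype=DTYPE))
        z = np.concatenate(parts, axis=1)
        y, _ = self.decoder.forward(z)
        return y[..., 0]

    def reconstruct(self, volumes, group: str, spaces=None) -> np.ndarray:
        """Encode then decode using the μ latents; ``spaces`` overrides the
        group's active set (for counterfactual reconstructions)."""
        lat = self.encode(volumes)
        if spaces is None:
            return self.decode(lat, group)
        ref = next(iter(lat.mu.values()))
        parts = [np.asarray(lat.mu[s] if s in spaces else np.zeros_like(ref), dtype=DTYPE)
                 for s in self.spec.spaces]
        y, _ = self.decoder.forward(np.concatenate(parts, axis=1))
        return y[..., 0]

    # -- training --------------------------------------------------------
    def _active_mask(self, groups) -> np.ndarray:
        L = self.spec.latent_dim_per_space
        mask = np.zeros((len(groups), self.spec.total_latent), dtype=DTYPE)
        for i, g in enumerate(groups):
            act = active_spaces(self.spec.kind, g)
            for j, s in enumerate(self.spec.spaces):
                if s in act:
                    mask[i, j * L:(j + 1) * L] = 1.0
        return mask

    def _forward_backward(self, x, groups, rng, update: bool) -> LossBreakdown:
        B = x.shape[0]
        mask = self._active_mask(groups)
        L = self.spec.latent_dim_per_space
        mus, lvs, caches, zs, eps = [], [], [], [], []
        for s in self.spec.spaces:
            m, l, c = self.encoders[s].forward(x)
            e = rng.standard_normal(m.shape).astype(DTYPE) if rng is not None \
                else np.zeros_like(m)
            mus.append(m); lvs.append(l); caches.append(c); eps.append(e)
            zs.append(m + np.exp(0.5 * l) * e)
        mu = np.concatenate(mus, axis=1)
        lv = np.concatenate(lvs, axis=1)
        z = np.concatenate(zs, axis=1) * mask
        ep = np.concatenate(eps, axis=1)

        y, dcache = self.decoder.forward(z)
        err = y - x
        mse = float((err ** 2).sum() / B)
        klmask = np.ones_like(mask) if self.spec.kl_all_spaces else mask
        kl_terms = -0.5 * (1.0 + lv - mu ** 2 - np.exp(lv)) * klmask
        kl = float(kl_terms.sum() / B)
        total = mse + self.spec.kl_weight * kl

        if update:
            self.optimizer.zero_grad()
            gy = (2.0 / B) * err
            gz = self.decoder.backward(gy, dcache) * mask
            w = self.spec.kl_weight / B
            gmu = gz + w * mu * klmask
            glv = gz * ep * 0.5 * np.exp(0.5 * lv) + w * 0.5 * (np.exp(lv) - 1.0) * klmask
            for j, s in enumerate(self.spec.spaces):
                sl = slice(j * L, (j + 1) * L)
                self.encoders[s].backward(gmu[:, sl].astype(DTYPE),
                                          glv[:, sl].astype(DTYPE), caches[j])
            self.optimizer.step()
        return LossBreakdown(total=total, mse=mse, kl=kl)

    def train_epoch(self, volumes, groups, rng) -> LossBreakdown:
        """One pass over the data in shuffled minibatches; returns the
        epoch-mean loss breakdown (weighted by batch size)."""
        x = self._as_batch(volumes)
        n = x.shape[0]
        order = rng.permutation(n)
        bs = self.spec.batch_size
        tot = np.zeros(3)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            lb = self._forward_backward(x[idx], [groups[i] for i in idx], rng, update=True)
            tot += np.array([lb.total, lb.mse, lb.kl]) * len(idx)
        tot /= n
        return LossBreakdown(*map(float, tot))

    def evaluate(self, volumes, groups) -> LossBreakdown:
        """Loss on a dataset without updating weights (μ-based, no sampling)."""
        x = self._as_batch(volumes)
        bs = self.spec.batch_size
        tot = np.zeros(3)
        for start in range(0, x.shape[0], bs):
            sl = slice(start, start + bs)
            lb = self._forward_backward(x[sl], groups[sl.start:sl.stop], None, update=False)
            tot += np.array([lb.total, lb.mse, lb.kl]) * (min(sl.stop, x.shape[0]) - sl.start)
        tot /= x.shape[0]
        return LossBreakdown(*map(float, tot))

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {}
        for name, enc in self.encoders.items():
            for lname, ly in zip(("conv1", "conv2", "hidden", "dense_mu", "dense_lv"), enc.layers):
                for k, v in ly.params.items():
                    arrays[f"enc:{name}:{lname}:{k}"] = v
        for lname, ly in zip(("hidden", "dense", "deconv1", "deconv2"), self.decoder.layers):
            for k, v in ly.params.items():
                arrays[f"dec:{lname}:{k}"] = v
        np.savez_compressed(path, **arrays)
        meta = asdict(self.spec) | {"seed": self.seed, "flagged": self.flagged}
        Path(str(path) + ".spec.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "ContrastiveVAE":
        meta = json.loads(Path(str(path) + ".spec.json").read_text())
        seed = meta.pop("seed")
        flagged = meta.pop("flagged", False)
        for key in ("input_shape", "conv_filters"):
            meta[key] = tuple(meta[key])
        model = cls(ModelSpec(**meta), seed=seed)
        model.flagged = flagged
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        with np.load(path) as data:
            for name, enc in model.encoders.items():
                for lname, ly in zip(("conv1", "conv2", "hidden", "dense_mu", "dense_lv"), enc.layers):
                    for k in ly.params:
                        ly.params[k][...] = data[f"enc:{name}:{lname}:{k}"]
            for lname, ly in zip(("hidden", "dense", "deconv1", "deconv2"), model.decoder.layers):
                for k in ly.params:
                    ly.params[k][...] = data[f"dec:{lname}:{k}"]
        return model


def reparameterize(mu, logvar, rng) -> np.ndarray:
    """z = mu + exp(logvar/2) * eps with eps ~ N(0, I) drawn from ``rng``."""
    mu = np.asarray(mu)
    logvar = np.asarray(logvar)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar must have matching shapes")
    eps = rng.standard_normal(mu.shape)
    return mu + np.exp(0.5 * logvar) * eps


def gaussian_kl(mu, logvar) -> float:
    """Closed-form KL(N(mu, sigma^2) || N(0, 1)), summed over coordinates."""
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    return float((-0.5 * (1.0 + logvar - mu ** 2 - np.exp(logvar))).sum())


def loss(model: ContrastiveVAE, volumes, groups) -> LossBreakdown:
    """Dataset loss with the package's reduction convention (see module
    docstring); does not update weights."""
    if len(groups) == 0:
        raise ValueError("batch must be non-empty")
    return model.evaluate(volumes, list(groups))
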