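"""Two-stage hierarchical ensemble training.

VAEs are sensitive to weight initialization: individual fits can diverge
or collapse their posterior, making single-model results unreliable.
The procedure here trains a pool of independently seeded candidates for a
short first stage, keeps the k candidates with the lowest reconstruction
(MSE) loss, and continues training only those to the full epoch budget.
Downstream analyses always consume the whole surviving ensemble and
average across it.

Scale profiles (paper-scale mirrors the published experiment: pool of 50
for 10 epochs, keep 20, train to 100 epochs on 64³ volumes; the desk
profile is sized for a single CPU).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .models import ContrastiveVAE, ModelSpec

PROFILES = {
    "paper": dict(pool_size=50, keep=20, stage1_epochs=10, total_epochs=100,
                  shape=(64, 64, 64), n_subjects=1000),
    "desk": dict(pool_size=10, keep=5, stage1_epochs=5, total_epochs=30,
                 shape=(32, 32, 32), n_subjects=500),
}


@dataclass
class Ensemble:
    models: list
    seeds: list
    selection_losses: list          # stage-1 MSE for every candidate
    stage1_pool_size: int
    stage1_epochs: int
    total_epochs: int
    flagged: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.models) > self.stage1_pool_size:
            raise ValueError("more selected models than the stage-1 pool")

    def __len__(self):
        return len(self.models)

    def unflagged(self) -> list:
        return [m for m in self.models if not m.flagged]

    def reference_model(self, volumes, groups) -> ContrastiveVAE:
        """Ensemble member with the lowest final total loss."""
        losses = [m.evaluate(volumes, groups).total for m in self.unflagged()]
        return self.unflagged()[int(np.argmin(losses))]

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.models):
            m.save(out / f"model-{i:03d}.npz")
        manifest = {
            "seeds": [int(s) for s in self.seeds],
            "selection_losses": [float(x) for x in self.selection_losses],
            "stage1_pool_size": self.stage1_pool_size,
            "stage1_epochs": self.stage1_epochs,
            "total_epochs": self.total_epochs,
            "flagged": list(self.flagged),
            "n_models": len(self.models),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, indir) -> "Ensemble":
        src = Path(indir)
        manifest = json.loads((src / "manifest.json").read_text())
        models = [ContrastiveVAE.load(src / f"model-{i:03d}.npz")
                  for i in range(manifest["n_models"])]
        return cls(models=models, seeds=manifest["seeds"],
                   selection_losses=manifest["selection_losses"],
                   stage1_pool_size=manifest["stage1_pool_size"],
                   stage1_epochs=manifest["stage1_epochs"],
                   total_epochs=manifest["total_epochs"],
                   flagged=manifest["flagged"])


@dataclass
class Candidate:
    model: ContrastiveVAE
    seed: int
    stage1_mse: float
    flagged: bool = False


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def train_stage1(spec: ModelSpec, volumes, groups, pool_size: int,
                 epochs: int, master_seed: int = 0, verbose: bool = False) -> list[Candidate]:
    """Train ``pool_size`` independently seeded candidates for a short
    stage and tag each with its end-of-stage training-set MSE.  Candidates
    with non-finite losses are flagged and excluded from selection."""
    if len(groups) == 0:
        raise ValueError("dataset is empty")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    x = np.asarray(volumes, dtype=np.float32)
    seeds = _derive_seeds(master_seed, pool_size)
    pool = []
    for seed in seeds:
        model = ContrastiveVAE(spec, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        mse = np.inf
        for _ in range(epochs):
            lb = model.train_epoch(x, groups, rng)
            if not np.isfinite(lb.total):
                break
        else:
            mse = model.evaluate(x, groups).mse
        flagged = not np.isfinite(mse)
        model.flagged = flagged
        pool.append(Candidate(model=model, seed=seed, stage1_mse=float(mse),
                              flagged=flagged))
        if verbose:
            print(f"  stage1 seed={seed} mse={mse:.4g}{' FLAGGED' if flagged else ''}")
    return pool


def select_top(pool: list[Candidate], k: int) -> list[Candidate]:
    """The k unflagged candidates with the smallest stage-1 reconstruction
    loss; ties broken by position in the pool (seed order)."""
    survivors = [c for c in pool if not c.flagged]
    if len(survivors) < k:
        raise ValueError(f"only {len(survivors)} unflagged candidates, need {k}")
    order = sorted(range(len(survivors)), key=lambda i: (survivors[i].stage1_mse, i))
    return [survivors[i] for i in order[:k]]


def train_stage2(selected: list[Candidate], volumes, groups, stage1_epochs: int,
                 total_epochs: int, pool_size: int, selection_losses=None,
                 restart: bool = False, verbose: bool = False) -> Ensemble:
    """Continue the selected candidates to ``total_epochs``.

    Training is warm-started from the stage-1 weights (and a fresh
    optimizer); ``restart=True`` instead re-initializes and trains the
    full duration from scratch.  A model whose loss turns non-finite is
    retained but flagged.
    """
    if not selected:
        raise ValueError("no selected candidates")
    x = np.asarray(volumes, dtype=np.float32)
    flagged = []
    for cand in selected:
        if restart:
            cand.model = ContrastiveVAE(cand.model.spec, seed=cand.seed)
            done = 0
        else:
            cand.model.optimizer = type(cand.model.optimizer)(
                cand.model.layers, lr=cand.model.spec.learning_rate)
            done = stage1_epochs
        rng = np.random.default_rng(np.random.SeedSequence([cand.seed, 13]))
        for _ in range(total_epochs - done):
            lb = cand.model.train_epoch(x, groups, rng)
            if not np.isfinite(lb.total):
                cand.model.flagged = True
                break
        if cand.model.flagged:
            flagged.append(cand.seed)
        if verbose:
            print(f"  stage2 seed={cand.seed} mse={cand.model.evaluate(x, groups).mse:.4g}")
    return Ensemble(models=[c.model for c in selected],
                    seeds=[c.seed for c in selected],
                    selection_losses=list(selection_losses or
                                          [c.stage1_mse for c in selected]),
                    stage1_pool_size=pool_size,
                    stage1_epochs=stage1_epochs, total_epochs=total_epochs,
                    flagged=flagged)


def train_ensemble(spec: ModelSpec, volumes, groups, pool_size: int = 10,
                   keep: int = 5, stage1_epochs: int = 5, total_epochs: int = 30,
                   master_seed: int = 0, restart: bool = False,
                   verbose: bool = False) -> Ensemble:
    """The full two-stage procedure: pool -> select k lowest-MSE -> continue."""
    pool = train_stage1(spec, volumes, groups, pool_size, stage1_epochs,
                        master_seed=master_seed, verbose=verbose)
    selected = select_top(pool, keep)
    return train_stage2(selected, volumes, groups, stage1_epochs, total_epochs,
                        pool_size, selection_losses=[c.stage1_mse for c in pool],
                        restart=restart, verbose=verbose)


def reliability_protocol(spec: ModelSpec, volumes, groups, truth_shared,
                         truth_specific, patient_mask, n_repeats: int = 5,
                         master_seed: int = 0, **ensemble_kw) -> dict:
    """Across-seed stability of the evaluation metrics.

    Repeats the full two-stage procedure ``n_repeats`` times with distinct
    master seeds; for each repeat computes variance explained, shared-RSA
    tau and specific-RSA tau, both per model and ensemble-averaged.
    Reports the across-repeat SD of individual-model metrics, of
    ensemble-averaged metrics, and their ratio (SD reduction factor).
    """
    from .rsa import ensemble_rsa, variance_explained
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    seeds = _derive_seeds(np.random.SeedSequence([master_seed, 99]).generate_state(1)[0] % 2**31,
                          n_repeats)
    rows = {"var_explained": ([], []), "shared_tau": ([], []), "specific_tau": ([], [])}
    for seed in seeds:
        ens = train_ensemble(spec, volumes, groups, master_seed=seed, **ensemble_kw)
        models = ens.unflagged()
        shared_space = "all" if spec.kind == "vae" else "shared"
        specific_space = None if spec.kind == "vae" else "specific"
        sh = ensemble_rsa(models, volumes, truth_shared, shared_space, "shared")
        sp = ensemble_rsa(models, volumes, truth_specific, specific_space,
                          "specific", subject_mask=patient_mask)
        ve = [variance_explained(m, volumes, groups) for m in models]
        rows["var_explained"][0].append(ve)
        rows["var_explained"][1].append(float(np.mean(ve)))
        rows["shared_tau"][0].append(sh.per_model_taus)
        rows["shared_tau"][1].append(sh.tau)
        rows["specific_tau"][0].append(sp.per_model_taus)
        rows["specific_tau"][1].append(sp.tau)
    report = {}
    for metric, (per_model, per_ensemble) in rows.items():
        pm = np.asarray(per_model)                 # (repeats, models)
        individual_sd = float(np.mean(pm.std(axis=0, ddof=1)))
        ensemble_sd = float(np.std(per_ensemble, ddof=1))
        report[metric] = {
            "individual_sd": individual_sd,
            "ensemble_sd": ensemble_sd,
            "sd_reduction": individual_sd / ensemble_sd if ensemble_sd > 0 else np.inf,
            "ensemble_values": [float(v) for v in per_ensemble],
        }
    return report
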