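"""End-to-end experiment orchestration: configuration, the benchmark
runner, and the small fixture dataset used throughout the test suite.

Every random draw in a run derives from one master seed, so a benchmark
re-run with the same config is bit-for-bit reproducible (under fixed
threading).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .datasets import GenerationConfig, SyntheticDataset, generate_dataset, calibrate_ratio, \
    ground_truth_subtype_map
from .models import ModelSpec
from .training import PROFILES, train_ensemble
from .rsa import ensemble_rsa, pca_baseline, variance_explained
from .subtyping import ensemble_feature_matrix, cluster_and_score, cvae_prototypes, \
    vae_prototypes

REPORT_SCHEMA = {
    "required": {"profile": str, "master_seed": int, "timing": dict, "results": dict},
}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA) -> None:
    for key, typ in schema["required"].items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}, "
                             f"expected {typ.__name__}")


@dataclass
class ExperimentConfig:
    """One benchmark run: dataset design, model family, training scale."""

    profile: str = "desk"
    master_seed: int = 0
    dataset_ids: tuple = (1, 2)
    n_subjects: int | None = None          # default from profile
    model: dict = field(default_factory=dict)        # ModelSpec overrides
    training: dict = field(default_factory=dict)     # train_ensemble overrides
    generation: dict = field(default_factory=dict)   # GenerationConfig overrides
    analysis: dict = field(default_factory=dict)     # e.g. n_restarts, z_score

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {sorted(PROFILES)}")
        self.dataset_ids = tuple(int(d) for d in self.dataset_ids)

    def resolved(self) -> dict:
        prof = PROFILES[self.profile]
        n = self.n_subjects or prof["n_subjects"]
        spec_kw = dict(input_shape=prof["shape"]) | dict(self.model)
        train_kw = dict(pool_size=prof["pool_size"], keep=prof["keep"],
                        stage1_epochs=prof["stage1_epochs"],
                        total_epochs=prof["total_epochs"]) | dict(self.training)
        return {"n": n, "spec_kw": spec_kw, "train_kw": train_kw}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["dataset_ids"] = tuple(payload.get("dataset_ids", (1, 2)))
        return cls(**payload)


def fixture_dataset(seed: int = 0, n: int = 16, shape=(32, 32, 32),
                    dataset_id: int = 1) -> SyntheticDataset:
    """Tiny deterministic cohort with exaggerated effects for unit tests."""
    cfg = GenerationConfig(dataset_id=dataset_id, shape=shape,
                           shared_radius_frac=(0.24, 0.36),
                           specific_radius_frac=(0.10, 0.26))
    return generate_dataset(dataset_id, n, cfg, seed=seed)


def _truth_arrays(ds: SyntheticDataset):
    shared = np.array([t.shared_mag for t in ds.truth])
    specific = np.array([t.specific_mag for t in ds.truth])
    patients = np.array([t.group != "control" for t in ds.truth])
    subtypes = np.array([-1 if t.subtype is None else t.subtype for t in ds.truth])
    return shared, specific, patients, subtypes


def run_benchmark(config: ExperimentConfig, outdir=None, verbose: bool = False) -> dict:
    """Generate -> train -> analyze for each requested dataset design.

    Produces a machine-readable report holding RSA taus (cvae and vae),
    clustering ARIs and prototype correlations where the design has
    subtypes, with per-stage timing and all seeds."""
    res = config.resolved()
    report = {"profile": config.profile, "master_seed": int(config.master_seed),
              "timing": {}, "results": {}}
    for did in config.dataset_ids:
        t0 = time.time()
        gen_kw = dict(config.generation) | {"dataset_id": did,
                                            "shape": tuple(res["spec_kw"]["input_shape"])}
        gcfg = GenerationConfig(**gen_kw)
        ds = generate_dataset(did, res["n"], gcfg, seed=config.master_seed)
        shared, specific, patients, subtypes = _truth_arrays(ds)
        x = ds.stack()
        groups = ds.groups
        entry: dict = {"n": len(ds), "displacement_ratio": None}
        t_gen = time.time() - t0

        kind = "comorbid_cvae" if did == 5 else "cvae"
        spec = ModelSpec(kind=kind, **res["spec_kw"])
        ens = train_ensemble(spec, x, groups, master_seed=config.master_seed,
                             verbose=verbose, **res["train_kw"])
        vspec = ModelSpec(kind="vae", **res["spec_kw"])
        vens = train_ensemble(vspec, x, groups, master_seed=config.master_seed + 1,
                              verbose=verbose, **res["train_kw"])
        t_train = time.time() - t0 - t_gen

        entry["shared_tau"] = ensemble_rsa(ens.unflagged(), x, shared, "shared").tau
        if kind == "cvae":
            entry["specific_tau"] = ensemble_rsa(ens.unflagged(), x, specific,
                                                 "specific", subject_mask=patients).tau
        entry["vae_shared_tau"] = ensemble_rsa(vens.unflagged(), x, shared, None).tau
        entry["vae_specific_tau"] = ensemble_rsa(vens.unflagged(), x, specific, None,
                                                 subject_mask=patients).tau
        entry["variance_explained"] = variance_explained(ens.unflagged(), x, groups)

        if did in (2, 3, 4):
            k = {2: 2, 3: 3, 4: 5}[did]
            pidx = np.where(patients)[0]
            feats = ensemble_feature_matrix(ens.unflagged(), x[pidx], "specific")
            cres = cluster_and_score(feats, k, subtypes[pidx],
                                     seed=config.master_seed)
            vfeats = ensemble_feature_matrix(vens.unflagged(), x[pidx], None)
            vres = cluster_and_score(vfeats, k, subtypes[pidx],
                                     seed=config.master_seed)
            entry["ari_cvae"] = cres.ari
            entry["ari_vae"] = vres.ari
            truth_maps = {st: ground_truth_subtype_map(gcfg, st)
                          for st in sorted(gcfg.subtype_loci)}
            ref = ens.reference_model(x, groups)
            _, _, entry["prototype_r_cvae"] = cvae_prototypes(
                ref, x[pidx], [groups[i] for i in pidx], cres.labels,
                truth_maps, ds.template.brain_mask)
            _, _, entry["prototype_r_vae"] = vae_prototypes(
                x, groups, vres.labels, truth_maps, ds.template.brain_mask)
        entry["seeds"] = {"cvae": ens.seeds, "vae": vens.seeds}
        report["timing"][f"dataset{did}"] = {"generate_s": round(t_gen, 2),
                                             "train_s": round(t_train, 2),
                                             "analyze_s": round(time.time() - t0 - t_gen - t_train, 2)}
        report["results"][f"dataset{did}"] = entry
    validate_report(report)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
        (out / "report.schema.json").write_text(json.dumps(REPORT_SCHEMA, default=str))
    return report
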