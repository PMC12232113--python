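"""Synthetic cohorts with known shared / disorder-specific / comorbid effects.

Every subject is the template warped by a composed deformation field:

* a whole-brain "shared" sphere pair at the brain centroid (global
  expansion or contraction, present in controls and patients alike — the
  stand-in for age/sex/site variation), and
* for patients, one focal sphere pair per applicable disorder locus.

Reference and target radii of each pair are drawn independently from a
uniform range, so the signed radius change is symmetric around zero
(expansion and compression equally likely, small effects most common).
The ground-truth "magnitude" bookkeeping follows the absolute difference
in sphere *diameters*, which is what latent spaces are later scored
against.  Default radius ranges are calibrated so that shared fields are
on average 2.4x larger in mean voxelwise displacement than
disorder-specific fields, mirroring the relative effect sizes of
demographic versus disorder-related neuroanatomical variation.

Five designs are supported:

=========  =================================================================
Dataset 1  patients share a single disorder locus (graded severity only)
Dataset 2  two subtypes at distinct loci
Dataset 3  three subtypes
Dataset 4  five subtypes
Dataset 5  comorbidity: disorder 1, disorder 2 and disorder 1+2 groups; each
           disorder has a unique locus and all patient groups additionally
           carry a common ("comorbid") locus
=========  =================================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .phantom import (
    TemplateVolume, SphereDeformation, DeformationField,
    make_template, build_field, warp, mean_displacement, field_magnitude_map,
    save_nifti,
)

CONTROL = "control"
PATIENT_GROUPS_BY_DATASET = {
    1: ["patient"],
    2: ["patient"],
    3: ["patient"],
    4: ["patient"],
    5: ["disorder1", "disorder2", "disorder1+2"],
}
N_SUBTYPES = {1: 1, 2: 2, 3: 3, 4: 4 + 1}

# Interior locus positions (fractions of the grid), ordered so that the
# first k are maximally spread for a k-subtype design.
_LOCUS_FRACTIONS = [
    (0.35, 0.35, 0.50),
    (0.65, 0.65, 0.50),
    (0.35, 0.65, 0.50),
    (0.65, 0.35, 0.50),
    (0.50, 0.50, 0.72),
]
_COMORBID_FRACTION = (0.50, 0.50, 0.30)


@dataclass
class GenerationConfig:
    """Geometry and sampling ranges for one synthetic cohort.

    Radius ranges are fractions of the smallest grid axis so one config is
    valid at any resolution.  ``specific_radius_frac`` defaults are the
    result of the 2.4x shared/specific displacement calibration.
    """

    dataset_id: int = 1
    shape: tuple[int, int, int] = (64, 64, 64)
    template_seed: int = 0
    shared_radius_frac: tuple[float, float] = (0.26, 0.34)
    shared_support_frac: float = 0.48          # of max(shape); covers the mask
    specific_radius_frac: tuple[float, float] = (0.10, 0.224)
    specific_support_factor: float = 2.5       # of r_ref
    subtype_loci: dict | None = None           # subtype -> (x, y, z) voxels
    comorbid_loci: list | None = None          # dataset 5 only

    def __post_init__(self):
        if self.dataset_id not in PATIENT_GROUPS_BY_DATASET:
            raise ValueError(f"dataset_id must be 1-5, got {self.dataset_id}")
        for lo, hi in (self.shared_radius_frac, self.specific_radius_frac):
            if not (0 < lo < hi):
                raise ValueError("radius ranges must be positive and increasing")
        self.shape = tuple(int(s) for s in self.shape)
        if self.subtype_loci is None:
            s = np.asarray(self.shape, dtype=float)
            k = N_SUBTYPES.get(self.dataset_id, 2)
            self.subtype_loci = {
                i + 1: tuple(np.asarray(_LOCUS_FRACTIONS[i]) * s)
                for i in range(k if self.dataset_id != 5 else 2)
            }
        if self.dataset_id == 5 and self.comorbid_loci is None:
            s = np.asarray(self.shape, dtype=float)
            self.comorbid_loci = [tuple(np.asarray(_COMORBID_FRACTION) * s)]

    # -- derived voxel-scale geometry ------------------------------------
    @property
    def _scale(self) -> float:
        return float(min(self.shape))

    def shared_center(self) -> tuple[float, float, float]:
        return tuple((s - 1) / 2 for s in self.shape)

    def shared_support(self) -> float:
        return self.shared_support_frac * max(self.shape)

    def draw_shared_sphere(self, rng) -> SphereDeformation:
        lo, hi = self.shared_radius_frac
        r_ref, r_tar = rng.uniform(lo * self._scale, hi * self._scale, size=2)
        return SphereDeformation(self.shared_center(), r_ref, r_tar, self.shared_support())

    def draw_specific_sphere(self, center, rng, direction: int = 1) -> SphereDeformation:
        """Focal sphere pair with per-locus fixed direction.

        Two radii are drawn independently; the smaller maps to the larger
        for an expansion locus (``direction=+1``) and vice versa for a
        compression locus, so only the magnitude |r1 - r2| varies across
        subjects of one locus.  (A subtype is a *directional* alteration
        at its locus; per-subject sign flips would make subtypes
        unrecoverable by clustering even from perfect latents.)
        """
        lo, hi = self.specific_radius_frac
        a, b = np.sort(rng.uniform(lo * self._scale, hi * self._scale, size=2))
        r_ref, r_tar = (a, b) if direction >= 0 else (b, a)
        support = max(self.specific_support_factor * r_ref, 1.05 * r_tar)
        return SphereDeformation(tuple(center), r_ref, r_tar, support)

    def nominal_specific_sphere(self, center) -> SphereDeformation:
        """Midpoint-radius sphere with the mean absolute radius change."""
        lo, hi = self.specific_radius_frac
        r_ref = 0.5 * (lo + hi) * self._scale
        delta = (hi - lo) * self._scale / 3.0     # E|U1 - U2| for U ~ U(lo, hi)
        return SphereDeformation(tuple(center), r_ref, r_ref + delta,
                                 self.specific_support_factor * r_ref)

    def loci_for(self, group: str, subtype) -> list:
        """(center, direction) of every focal locus a subject receives.

        Direction alternates by locus index (odd: expansion, even:
        compression); comorbid loci expand.
        """
        if group == CONTROL:
            return []
        if self.dataset_id != 5:
            k = int(subtype)
            return [(self.subtype_loci[k], 1 if k % 2 else -1)]
        uniq = {"disorder1": [1], "disorder2": [2], "disorder1+2": [1, 2]}
        if group not in uniq:
            raise ValueError(f"unknown group {group!r} for dataset 5")
        out = [(self.subtype_loci[i], 1 if i % 2 else -1) for i in uniq[group]]
        return out + [(c, 1) for c in self.comorbid_loci]


@dataclass
class SubjectGroundTruth:
    subject_id: str
    group: str
    subtype: int | None
    shared_sphere: SphereDeformation
    specific_spheres: list[SphereDeformation] = field(default_factory=list)

    @property
    def shared_mag(self) -> float:
        """Absolute diameter difference of the shared sphere pair (voxels)."""
        return abs(2 * self.shared_sphere.r_tar - 2 * self.shared_sphere.r_ref)

    @property
    def specific_mag(self) -> float:
        return float(sum(abs(2 * s.r_tar - 2 * s.r_ref) for s in self.specific_spheres))


@dataclass
class SyntheticDataset:
    volumes: list
    truth: list
    config: GenerationConfig
    seed: int
    template: TemplateVolume

    def __len__(self):
        return len(self.volumes)

    @property
    def groups(self) -> list[str]:
        return [t.group for t in self.truth]

    def frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append({
                "subject_id": t.subject_id, "group": t.group,
                "subtype": -1 if t.subtype is None else t.subtype,
                "shared_mag": t.shared_mag, "specific_mag": t.specific_mag,
                "shared_sphere": _sphere_json(t.shared_sphere),
                "specific_spheres": json.dumps([json.loads(_sphere_json(s))
                                                for s in t.specific_spheres]),
            })
        return pd.DataFrame(rows)

    def stack(self) -> np.ndarray:
        """(n, D, H, W) float32 intensity stack for model input."""
        return np.stack([v.grid for v in self.volumes]).astype(np.float32)

    def subset(self, idx) -> "SyntheticDataset":
        idx = list(idx)
        return SyntheticDataset([self.volumes[i] for i in idx],
                                [self.truth[i] for i in idx],
                                self.config, self.seed, self.template)


def _sphere_json(s: SphereDeformation) -> str:
    return json.dumps({"center": [round(float(c), 4) for c in s.center],
                       "r_ref": round(float(s.r_ref), 6),
                       "r_tar": round(float(s.r_tar), 6),
                       "r_support": round(float(s.r_support), 6)})


def _sphere_from_dict(d) -> SphereDeformation:
    return SphereDeformation(tuple(d["center"]), d["r_ref"], d["r_tar"], d["r_support"])


# ---------------------------------------------------------------------------
# Sampling

def sample_subject(group, subtype, config: GenerationConfig, rng,
                   template: TemplateVolume, subject_id="s"):
    """One subject volume plus its ground-truth record."""
    shared = config.draw_shared_sphere(rng)
    loci = config.loci_for(group, subtype)
    specific = [config.draw_specific_sphere(c, rng, direction=d) for c, d in loci]
    defield = build_field([shared] + specific, config.shape)
    vol = warp(template, defield)
    truth = SubjectGroundTruth(subject_id, group, subtype, shared, specific)
    return vol, truth


def generate_dataset(dataset_id: int, n: int, config: GenerationConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Generate a full cohort: controls:patients = 1:1, patients split
    equally over the design's subtypes (or disorder groups for Dataset 5)."""
    if config is None:
        config = GenerationConfig(dataset_id=dataset_id)
    elif config.dataset_id != dataset_id:
        raise ValueError("config.dataset_id does not match dataset_id")
    if n % 2:
        raise ValueError(f"n must be even, got {n}")
    n_patients = n // 2

    if dataset_id == 5:
        cells = [(g, None) for g in PATIENT_GROUPS_BY_DATASET[5]]
    else:
        cells = [("patient", st) for st in sorted(config.subtype_loci)]
    if n_patients % len(cells):
        raise ValueError(f"{n_patients} patients not divisible into {len(cells)} groups")
    per_cell = n_patients // len(cells)

    template = make_template(config.shape, seed=config.template_seed)
    ss = np.random.SeedSequence([seed, dataset_id])
    plan = [(CONTROL, None)] * (n - n_patients)
    for cell in cells:
        plan += [cell] * per_cell
    volumes, truth = [], []
    for i, ((group, subtype), child) in enumerate(zip(plan, ss.spawn(len(plan)))):
        rng = np.random.default_rng(child)
        vol, t = sample_subject(group, subtype, config, rng, template,
                                subject_id=f"sub-{i:05d}")
        volumes.append(vol)
        truth.append(t)
    return SyntheticDataset(volumes, truth, config, seed, template)


def calibrate_ratio(config: GenerationConfig, n_probe: int = 200, seed: int = 0) -> float:
    """Shared-to-specific displacement ratio over probe patients.

    Reported as the ratio of the probe-average shared-field mean
    displacement to the probe-average specific-field mean displacement
    (both over the brain mask).  A mean of per-subject ratios is not used:
    the specific radius change has positive density at zero, so that
    estimator has infinite expectation and never converges.
    """
    if n_probe < 50:
        raise ValueError("n_probe must be >= 50")
    template = make_template(config.shape, seed=config.template_seed)
    mask = template.brain_mask
    group = "patient" if config.dataset_id != 5 else "disorder1"
    subtype = None if config.dataset_id == 5 else sorted(config.subtype_loci)[0]
    ss = np.random.SeedSequence([seed, 424242])
    shared_disp, specific_disp = [], []
    for child in ss.spawn(n_probe):
        rng = np.random.default_rng(child)
        shared = config.draw_shared_sphere(rng)
        specific = [config.draw_specific_sphere(c, rng, direction=d)
                    for c, d in config.loci_for(group, subtype)]
        shared_disp.append(mean_displacement(build_field([shared], config.shape), mask))
        specific_disp.append(mean_displacement(build_field(specific, config.shape), mask))
    denom = float(np.mean(specific_disp))
    if denom == 0:
        raise ValueError("probe patients have zero specific displacement")
    return float(np.mean(shared_disp)) / denom


def ground_truth_subtype_map(config: GenerationConfig, subtype,
                             template: TemplateVolume | None = None) -> np.ndarray:
    """Voxelwise displacement-norm map of one subtype's focal effect at the
    nominal (expected-magnitude) sphere — the reference image prototype
    correlations are scored against."""
    if config.dataset_id != 5:
        centers = [config.subtype_loci[int(subtype)]]
    else:
        key = {"d1": [1], "d2": [2], "comorbid": None}[subtype]
        centers = list(config.comorbid_loci) if key is None \
            else [config.subtype_loci[i] for i in key]
    spheres = [config.nominal_specific_sphere(c) for c in centers]
    return field_magnitude_map(build_field(spheres, config.shape))


# ---------------------------------------------------------------------------
# Directory round-trip

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for vol, t in zip(dataset.volumes, dataset.truth):
        save_nifti(out / f"{t.subject_id}.nii.gz", vol)
    dataset.frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    cfg = asdict(dataset.config)
    cfg["subtype_loci"] = {int(k): [float(x) for x in v]
                           for k, v in dataset.config.subtype_loci.items()}
    if dataset.config.comorbid_loci is not None:
        cfg["comorbid_loci"] = [[float(x) for x in c] for c in dataset.config.comorbid_loci]
    cfg["shape"] = list(dataset.config.shape)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": cfg, "seed": dataset.seed}, fh)


def read_dataset(indir) -> SyntheticDataset:
    from pathlib import Path
    import nibabel as nib
    src = Path(indir)
    with open(src / "config.yaml") as fh:
        payload = yaml.safe_load(fh)
    cfg_d = payload["config"]
    cfg_d["shape"] = tuple(cfg_d["shape"])
    cfg_d["subtype_loci"] = {int(k): tuple(v) for k, v in cfg_d["subtype_loci"].items()}
    if cfg_d.get("comorbid_loci"):
        cfg_d["comorbid_loci"] = [tuple(c) for c in cfg_d["comorbid_loci"]]
    for key in ("shared_radius_frac", "specific_radius_frac"):
        cfg_d[key] = tuple(cfg_d[key])
    config = GenerationConfig(**cfg_d)
    template = make_template(config.shape, seed=config.template_seed)
    frame = pd.read_csv(src / "ground_truth.tsv", sep="\t")
    volumes, truth = [], []
    for _, row in frame.iterrows():
        img = nib.load(str(src / f"{row.subject_id}.nii.gz"))
        grid = np.asarray(img.get_fdata(), dtype=np.float32)
        volumes.append(TemplateVolume(grid=grid, brain_mask=grid > 0))
        truth.append(SubjectGroundTruth(
            row.subject_id, row.group, None if row.subtype == -1 else int(row.subtype),
            _sphere_from_dict(json.loads(row.shared_sphere)),
            [_sphere_from_dict(d) for d in json.loads(row.specific_spheres)]))
    return SyntheticDataset(volumes, truth, config, payload["seed"], template)
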