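# neurotwin

A self-contained benchmark for **contrastive variational autoencoders
(CVAEs)** in psychiatric neuroimaging.  Most psychiatric disorders are
heterogeneous: patients differ from each other in the magnitude *and
kind* of their neural alterations, those alterations are superimposed on
much larger disorder-unrelated variation shared with healthy controls,
and disorders co-occur.  `neurotwin` builds synthetic 3-D
neuroanatomy with known ground truth for all three ingredients and asks
whether contrastive latent-variable models can pull them apart — the
controlled experiment that real MRI datasets, which lack ground truth,
cannot provide.

The package is aimed at methods researchers in computational psychiatry
and neuroimaging who want a reproducible test bed for
contrastive/disentangling models before touching real data.

## What is inside

* **Synthetic neuroanatomy** (`neurotwin.phantom`, `neurotwin.datasets`)
  — a procedural template brain; deformation effects parameterized by
  reference/target sphere pairs (radial displacement `m(ρ)` rising to
  `r_tar − r_ref` at the reference surface, decaying to zero at a
  support radius); cohorts with a whole-brain *shared* effect (signed:
  global expansion or contraction) and focal *disorder-specific*
  effects at subtype-dependent loci, calibrated so shared displacements
  are on average **2.4×** larger than specific ones.  Five designs:
  graded severity, 2/3/5 subtypes, and a comorbidity design (disorder 1,
  disorder 2, disorder 1+2, with unique plus comorbid loci).
* **Models** (`neurotwin.models`) — a baseline VAE, the two-encoder
  CVAE (shared + disorder-specific latent spaces, controls decoded with
  specific latents zeroed), and a four-encoder comorbidity CVAE
  (shared / patient-shared / disorder-1 / disorder-2), implemented in
  NumPy with exact hand-derived gradients and Adam.
* **Two-stage ensemble training** (`neurotwin.training`) — train a pool
  of seeded candidates briefly, keep the k with the lowest
  reconstruction loss, continue those to the full budget; reliability
  protocol comparing across-seed SDs of single models vs ensembles.
* **Evaluation** (`neurotwin.rsa`, `neurotwin.subtyping`) —
  representational similarity analysis (Euclidean latent RDMs vs
  ground-truth magnitude RDMs, Kendall tau-b, Fisher-z t-tests), PCA
  generalization baseline, K-means subtyping scored by adjusted Rand
  index, synthetic-twin counterfactual maps, cluster prototypes, and
  comorbidity difference maps.
* **CLI** (`neurotwin` command) — `generate`, `train`, `rsa`,
  `subtype`, `twin`, `comorbid`, `benchmark`, `report` subcommands over
  NIfTI/TSV/YAML files.

## Worked example

Train a small CVAE ensemble on a severity cohort and measure how well
each latent space tracks its ground truth:

```python
import numpy as np
from neurotwin import (GenerationConfig, generate_dataset, ModelSpec,
                       train_ensemble, ensemble_rsa)

cfg = GenerationConfig(dataset_id=1, shape=(32, 32, 32))
ds = generate_dataset(1, n=300, config=cfg, seed=1)      # 150 controls, 150 patients
shared = np.array([t.shared_mag for t in ds.truth])      # |diameter difference|
specific = np.array([t.specific_mag for t in ds.truth])
patients = np.array([g != "control" for g in ds.groups])

spec = ModelSpec(kind="cvae", input_shape=(32, 32, 32),
                 conv_filters=(16, 32), learning_rate=2e-3)
ens = train_ensemble(spec, ds.stack(), ds.groups,
                     pool_size=4, keep=2, stage1_epochs=5,
                     total_epochs=90, master_seed=1)

print("shared tau  ", round(ensemble_rsa(ens.unflagged(), ds.stack(),
                                         shared, "shared").tau, 3))
print("specific tau", round(ensemble_rsa(ens.unflagged(), ds.stack(),
                                         specific, "specific",
                                         subject_mask=patients).tau, 3))
```

Output from this exact run (about eight minutes on one CPU):

```
shared tau   0.383
specific tau 0.124
```

Reading the numbers: the shared latent space ranks subjects by their
global expansion/contraction severity with Kendall tau 0.383 — close to
the ≈0.48 ceiling imposed by comparing a *signed* latent code against an
*absolute* severity (see `docs/methods.md`) — while the
disorder-specific space tracks focal-effect severity (tau 0.12; the
focal signal is 2.4× weaker by construction).  The same trained
ensemble, asked to rank patients by the *wrong* ground truth, returns
taus near zero, which is the disentanglement claim in one line.

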