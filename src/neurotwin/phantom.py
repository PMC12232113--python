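"""Procedural brain phantom and sphere-pair deformation fields.

A deformation effect is parameterized by a pair of concentric spheres: a
*reference* sphere of radius ``r_ref`` is mapped onto a *target* sphere of
radius ``r_tar``, displacing tissue radially.  ``r_tar > r_ref`` expands the
region, ``r_tar < r_ref`` compresses it, and the displacement decays
linearly to zero at an outer support radius so each effect is strictly
local.  Summing one whole-brain sphere pair (the "shared" effect standing in
for age/sex/site variation) with focal sphere pairs at disorder loci gives a
subject's total warp.

The built-in phantom is a smoothed ellipsoidal head with several interior
structures of distinct intensity plus a low-frequency texture, so that
warps anywhere inside the mask produce visible intensity change.  A real
template volume can be loaded from NIfTI instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage

log = logging.getLogger(__name__)


@dataclass
class TemplateVolume:
    """3-D intensity grid in [0, 1] with a brain mask."""

    grid: np.ndarray
    brain_mask: np.ndarray
    spacing: float = 1.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("template intensities must be finite")
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("template intensities must lie in [0, 1]")
        frac = self.brain_mask.mean()
        if not 0.05 < frac < 0.80:
            raise ValueError(f"brain mask covers {frac:.1%} of voxels, expected 5-80%")
        if np.any(self.grid[~self.brain_mask] != 0):
            raise ValueError("intensity outside the brain mask must be 0")


@dataclass(frozen=True)
class SphereDeformation:
    """One radial expansion/compression effect (reference -> target sphere)."""

    center: tuple[float, float, float]
    r_ref: float
    r_tar: float
    r_support: float

    def __post_init__(self):
        if not (0 < self.r_ref and 0 < self.r_tar):
            raise ValueError("sphere radii must be positive")
        if self.r_support <= max(self.r_ref, self.r_tar):
            raise ValueError("r_support must exceed both sphere radii")

    @property
    def delta(self) -> float:
        """Signed radius change (voxels); 0 encodes the identity."""
        return self.r_tar - self.r_ref


@dataclass
class DeformationField:
    """Per-voxel displacement vectors, shape (D, H, W, 3), in voxel units."""

    displacements: np.ndarray
    spheres: list[SphereDeformation] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.displacements.shape[:3])


# ---------------------------------------------------------------------------
# Phantom construction

def _ellipsoid(coords, center, semiaxes):
    u = [(c - mu) / a for c, mu, a in zip(coords, center, semiaxes)]
    return u[0] ** 2 + u[1] ** 2 + u[2] ** 2 <= 1.0


def make_template(shape=(64, 64, 64), seed: int = 0, spacing: float = 1.0) -> TemplateVolume:
    """Deterministic brain-like phantom.

    Outer smoothed ellipsoid "cortex" (bright rim, dimmer interior), a dark
    central "ventricle", several randomly placed interior nuclei of distinct
    intensity, and a smooth random texture.  Deterministic for a fixed
    ``(shape, seed)``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError(f"shape {shape} too small: each axis must be >= 16")
    rng = np.random.default_rng(seed)
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    semi = [0.42 * s for s in shape]

    mask = _ellipsoid(coords, center, semi)
    # Radial profile: bright cortex rim, mid-intensity interior.
    rho2 = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semi))
    rho = np.sqrt(np.clip(rho2, 0, None))
    vol = np.where(mask, 0.45 + 0.40 * np.clip((rho - 0.55) / 0.45, 0, 1), 0.0)

    # Central ventricle (dark).
    vent = _ellipsoid(coords, center, [0.12 * s for s in shape])
    vol[vent] = 0.08

    # Interior nuclei at jittered canonical positions, distinct intensities.
    canonical = np.array([
        [0.32, 0.38, 0.40], [0.68, 0.38, 0.40], [0.32, 0.66, 0.45],
        [0.68, 0.66, 0.45], [0.50, 0.30, 0.62], [0.50, 0.70, 0.62],
    ])
    intensities = [0.85, 0.20, 0.70, 0.30, 0.95, 0.55]
    for pos, inten in zip(canonical, intensities):
        jitter = rng.uniform(-0.02, 0.02, size=3)
        c = [(p + j) * s for p, j, s in zip(pos, jitter, shape)]
        r = [rng.uniform(0.055, 0.075) * s for s in shape]
        nucleus = _ellipsoid(coords, c, r) & mask & ~vent
        vol[nucleus] = inten

    # Smooth low-frequency texture so every interior locus has gradient.
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma=[0.06 * s for s in shape])
    noise /= max(np.abs(noise).max(), 1e-12)
    vol = np.where(mask, vol + 0.10 * noise, 0.0)

    vol = ndimage.gaussian_filter(vol, sigma=1.0)
    vol = np.where(mask, np.clip(vol, 0.02, 1.0), 0.0)

    out = TemplateVolume(grid=vol.astype(np.float32), brain_mask=mask, spacing=spacing)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Radial fields

def radial_magnitude(rho: np.ndarray, sphere: SphereDeformation) -> np.ndarray:
    """Displacement magnitude profile m(rho).

    m rises linearly from 0 at the center to ``r_tar - r_ref`` on the
    reference-sphere surface, then decays linearly to 0 at ``r_support``.
    """
    delta = sphere.delta
    rho = np.asarray(rho, dtype=np.float64)
    inner = rho / sphere.r_ref
    outer = (sphere.r_support - rho) / (sphere.r_support - sphere.r_ref)
    m = np.where(rho <= sphere.r_ref, delta * inner, delta * np.clip(outer, 0.0, None))
    return np.where(rho >= sphere.r_support, 0.0, m)


def radial_displacement(point, sphere: SphereDeformation) -> np.ndarray:
    """Displacement 3-vector of one sphere effect at a single point."""
    p = np.asarray(point, dtype=np.float64)
    d = p - np.asarray(sphere.center, dtype=np.float64)
    rho = float(np.linalg.norm(d))
    if rho == 0.0 or rho >= sphere.r_support:
        return np.zeros(3)
    return (radial_magnitude(rho, sphere) / rho) * d


def build_field(spheres, shape) -> DeformationField:
    """Voxelwise superposition of sphere effects over a grid.

    Each sphere only touches voxels inside its support ball; support
    extending past the grid is clipped with a logged warning.
    """
    shape = tuple(int(s) for s in shape)
    disp = np.zeros(shape + (3,), dtype=np.float64)
    for sph in spheres:
        if sph.delta == 0.0:
            continue
        lo = [int(np.floor(c - sph.r_support)) for c in sph.center]
        hi = [int(np.ceil(c + sph.r_support)) + 1 for c in sph.center]
        if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, shape)):
            warnings.warn(f"sphere support extends outside grid {shape}; field clipped "
                          "at the boundary", stacklevel=2)
            log.debug("clipped sphere: center=%s support=%.1f grid=%s",
                      sph.center, sph.r_support, shape)
        lo = [max(l, 0) for l in lo]
        hi = [min(h, s) for h, s in zip(hi, shape)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        axes = [np.arange(l, h, dtype=np.float64) for l, h in zip(lo, hi)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        dx = gx - sph.center[0]
        dy = gy - sph.center[1]
        dz = gz - sph.center[2]
        rho = np.sqrt(dx * dx + dy * dy + dz * dz)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rho > 0, radial_magnitude(rho, sphere=sph) / np.where(rho > 0, rho, 1.0), 0.0)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        disp[sl + (0,)] += scale * dx
        disp[sl + (1,)] += scale * dy
        disp[sl + (2,)] += scale * dz
    return DeformationField(displacements=disp, spheres=list(spheres))


def warp(volume: TemplateVolume, defield: DeformationField) -> TemplateVolume:
    """Pull-back warp: output voxel v samples the input at v - displacement(v).

    Trilinear interpolation, zero fill outside the grid, output clipped to
    [0, 1].  A zero field returns the input bit-for-bit.
    """
    if tuple(volume.shape) != tuple(defield.shape):
        raise ValueError(f"volume shape {volume.shape} != field shape {defield.shape}")
    disp = defield.displacements
    if not np.any(disp):
        return TemplateVolume(grid=volume.grid.copy(), brain_mask=volume.brain_mask.copy(),
                              spacing=volume.spacing)
    idx = np.indices(volume.shape, dtype=np.float64)
    sample = idx - np.moveaxis(disp, -1, 0)
    grid = ndimage.map_coordinates(volume.grid.astype(np.float64), sample,
                                   order=1, mode="constant", cval=0.0)
    mask = ndimage.map_coordinates(volume.brain_mask.astype(np.float64), sample,
                                   order=1, mode="constant", cval=0.0) > 0.5
    return TemplateVolume(grid=np.clip(grid, 0.0, 1.0).astype(np.float32),
                          brain_mask=mask, spacing=volume.spacing)


def mean_displacement(defield: DeformationField, mask: np.ndarray) -> float:
    """Mean Euclidean displacement norm over ``mask`` voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    norms = np.linalg.norm(defield.displacements[mask], axis=-1)
    return float(norms.mean())


def field_magnitude_map(defield: DeformationField) -> np.ndarray:
    """Voxelwise Euclidean norm of the displacement field."""
    return np.linalg.norm(defield.displacements, axis=-1)


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_nifti(path, volume: TemplateVolume) -> None:
    affine = np.diag([volume.spacing] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.grid, dtype=np.float32), affine), str(path))


def load_nifti(path, mask_threshold: float = 0.0) -> TemplateVolume:
    """Load a user template; the mask is intensity > ``mask_threshold``."""
    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata(), dtype=np.float32)
    if grid.ndim != 3:
        raise ValueError("expected a 3-D volume")
    lo, hi = float(grid.min()), float(grid.max())
    if hi > 1.0 or lo < 0.0:  # rescale arbitrary-intensity templates
        grid = (grid - lo) / max(hi - lo, 1e-12)
    mask = grid > mask_threshold
    grid = np.where(mask, grid, 0.0).astype(np.float32)
    spacing = float(np.abs(img.affine[0, 0])) or 1.0
    vol = TemplateVolume(grid=grid, brain_mask=mask, spacing=spacing)
    vol.validate()
    return vol


def save_field(path, defield: DeformationField, spacing: float = 1.0) -> None:
    """Store displacement vectors as 4-D NIfTI (last axis = xyz)."""
    affine = np.diag([spacing] * 3 + [1.0])
    nib.save(nib.Nifti1Image(defield.displacements.astype(np.float32), affine), str(path))
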