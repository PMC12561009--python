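"""Synthetic ultra-high-field brain phantoms.

Generates NIfTI image/mask pairs with the statistical structure the
segmentation pipeline assumes: an ellipsoidal two-compartment "brain"
(gray shell around a white core, so a learned model has to use spatial
context rather than a single intensity threshold), a CSF-filled
ventricle that is excluded from the tissue mask, anisotropic
submillimeter voxel spacing in the 0.6-0.8 mm range, a smooth
multiplicative bias field standing in for B1 inhomogeneity, and additive
Gaussian noise.  It deliberately does not attempt physical MR simulation
(no Bloch equations, no MP2RAGE contrast model, no partial-volume
mixing); what it provides is a fully controlled ground truth at zero
download cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ImageVolume, MaskVolume, write_nifti

_SEED_MOD = 2**31


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the phantom generator.

    Intensities loosely follow T1-weighted contrast (white > gray >> CSF
    ~ background); noise sigma of 0.04 on a unit-intensity scale is an
    SNR of ~25, typical of high-field structural imaging; the bias field
    is an exponentiated low-order polynomial with ~+-20% amplitude.
    """

    dims: tuple[int, int, int] = (64, 64, 32)
    spacing_range: tuple[float, float] = (0.6, 0.8)
    white_intensity: float = 1.0
    gray_intensity: float = 0.7
    csf_intensity: float = 0.15
    background_intensity: float = 0.02
    noise_sigma: float = 0.04
    bias_amplitude: float = 0.2
    brain_axes_frac: tuple[float, float] = (0.30, 0.42)
    ventricle_axes_frac: tuple[float, float] = (0.08, 0.15)
    gray_white_radius: float = 0.70

    def __post_init__(self):
        if min(self.dims) < 16:
            raise ValueError("phantom dims must be >= 16 in every axis")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        vals = {self.white_intensity, self.gray_intensity, self.csf_intensity,
                self.background_intensity}
        if len(vals) != 4:
            raise ValueError("tissue intensities must be distinct")


def _ellipsoid_radius(shape, center, axes):
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    rho2 = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, axes):
        rho2 += ((g - c) / a) ** 2
    return np.sqrt(rho2)


def generate_phantom(config: PhantomConfig, seed: int) -> tuple[ImageVolume, MaskVolume]:
    """One phantom subject; byte-identical for a fixed (config, seed).

    The tissue mask is brain minus ventricle; the ventricle is resampled
    until fully contained in the brain (error after 100 attempts).
    """
    rng = np.random.default_rng(seed % _SEED_MOD)
    dims = np.array(config.dims, dtype=np.float64)

    spacing = tuple(float(rng.uniform(*config.spacing_range)) for _ in range(3))
    center = dims / 2.0 + rng.uniform(-0.03, 0.03, size=3) * dims
    lo, hi = config.brain_axes_frac
    brain_axes = rng.uniform(lo, hi, size=3) * dims
    rho = _ellipsoid_radius(config.dims, center, brain_axes)
    brain = rho <= 1.0

    vlo, vhi = config.ventricle_axes_frac
    ventricle = None
    for _ in range(100):
        v_center = center + rng.uniform(-0.08, 0.08, size=3) * dims
        v_axes = rng.uniform(vlo, vhi, size=3) * dims
        cand = _ellipsoid_radius(config.dims, v_center, v_axes) <= 1.0
        if cand.any() and not (cand & ~brain).any():
            ventricle = cand
            break
    if ventricle is None:
        raise RuntimeError("could not place a ventricle inside the brain in 100 attempts")

    white = brain & (rho <= config.gray_white_radius)
    gray = brain & ~white

    image = np.full(config.dims, config.background_intensity, dtype=np.float64)
    image[gray] = config.gray_intensity
    image[white] = config.white_intensity
    image[ventricle] = config.csf_intensity

    # smooth multiplicative bias: exp of a zero-mean 2nd-order polynomial
    if config.bias_amplitude > 0:
        coords = [np.linspace(-1.0, 1.0, n) for n in config.dims]
        xx, yy, zz = np.meshgrid(*coords, indexing="ij")
        basis = [xx, yy, zz, xx * yy, xx * zz, yy * zz, xx**2, yy**2, zz**2]
        coeffs = rng.uniform(-1.0, 1.0, size=len(basis))
        poly = sum(c * b for c, b in zip(coeffs, basis))
        peak = np.abs(poly).max()
        if peak > 0:
            poly = poly / peak * np.log1p(config.bias_amplitude)
        image = image * np.exp(poly)

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=config.dims)

    affine = np.diag(list(spacing) + [1.0])
    sid = f"phantom-{seed % _SEED_MOD:06d}"
    mask = (brain & ~ventricle).astype(np.uint8)
    return (
        ImageVolume(image, spacing, affine, sid),
        MaskVolume(mask, spacing, affine, sid),
    )


def generate_cohort(n_subjects: int, out_dir: str | Path, seed: int,
                    config: PhantomConfig | None = None) -> pd.DataFrame:
    """Write n phantom NIfTI pairs plus a manifest CSV.

    Per-subject seeds are derived deterministically from the master seed,
    so identical (n, seed, config) always reproduce identical cohorts.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    config = config or PhantomConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed % _SEED_MOD).generate_state(n_subjects) % _SEED_MOD
    rows = []
    for i, s in enumerate(child_seeds):
        image, mask = generate_phantom(config, int(s))
        sid = f"sub-{i:03d}"
        image.subject_id = mask.subject_id = sid
        image_path = out_dir / f"{sid}_T1w.nii.gz"
        mask_path = out_dir / f"{sid}_mask.nii.gz"
        write_nifti(image, image_path)
        write_nifti(mask, mask_path)
        rows.append({"subject_id": sid, "image_path": str(image_path),
                     "mask_path": str(mask_path), "split": ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
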