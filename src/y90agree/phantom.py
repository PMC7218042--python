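"""Digital phantoms and local-deposition voxel dosimetry for Y-90.

A phantom is an ellipsoidal "liver" containing one or more ellipsoidal or
spherical "tumors" on a regular voxel grid (axis order (z, y, x), 0-based,
default 4 mm isotropic voxels).  The injected activity is partitioned between
tumor and non-tumor liver voxels proportionally to a tumor-to-liver uptake
ratio, optionally followed by an isotropic Gaussian blur that emulates PET
resolution.

Absorbed dose uses the local-deposition method: every decay deposits its
energy in the voxel containing it, so

    dose_voxel [Gy] = K * activity_voxel [GBq] / mass_voxel [kg]

with K the total energy released per GBq of Y-90 carried to complete decay,
K = E_mean * T_half / ln 2 per unit activity.  With E_mean = 0.9267 MeV per
decay and T_half = 64.05 h this gives K = 49.38 J/GBq (pinned below).

Observer-specific segmentations are emulated by morphological perturbation of
the true masks (signed dilation/erosion margin plus random boundary-voxel
flips), and the four dosimetric quantities (TV, TLV, THLV = TLV - TV, TD,
THLD) are extracted by voxel counting and mask-restricted dose means.  The
lung shunt fraction is fixed at 0, so the full injected activity stays in
the liver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Y90_MEAN_ENERGY_MEV",
    "Y90_HALF_LIFE_H",
    "J_PER_GBQ",
    "LUNG_SHUNT_FRACTION",
    "DEFAULT_DENSITY_KG_PER_L",
    "Ellipsoid",
    "PhantomGeometry",
    "PerturbationSpec",
    "DigitalPhantom",
    "DosimetryMeasurement",
    "build_phantom",
    "local_deposition_dose",
    "perturb_mask",
    "extract_measurements",
    "save_volume",
    "load_volume",
]

MEV_TO_J = 1.602176634e-13
#: Mean beta energy per Y-90 decay (MeV).
Y90_MEAN_ENERGY_MEV = 0.9267
#: Y-90 physical half-life (hours).
Y90_HALF_LIFE_H = 64.05
#: Total energy released to complete decay per GBq present at t=0:
#: K = E_mean * tau with tau = T_half/ln2, i.e. the decay integral
#: of A0 * exp(-lambda t) * E_mean over t in [0, inf).
J_PER_GBQ = Y90_MEAN_ENERGY_MEV * MEV_TO_J * (Y90_HALF_LIFE_H * 3600.0 / math.log(2)) * 1e9

#: Fraction of microspheres shunting to the lungs; fixed at zero (it shifts
#: every observer's dose identically and has no effect on variability).
LUNG_SHUNT_FRACTION = 0.0

#: Soft-tissue density, kg per litre.
DEFAULT_DENSITY_KG_PER_L = 1.05


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm, grid coordinates
    (z, y, x)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def mask(self, shape, voxel_size_mm) -> np.ndarray:
        zz, yy, xx = np.indices(shape, dtype=float)
        coords = (zz, yy, xx)
        r2 = np.zeros(shape, dtype=float)
        for c, vs, center, ax in zip(
            coords, voxel_size_mm, self.center_mm, self.semi_axes_mm
        ):
            r2 += ((c * vs + vs / 2.0 - center) / ax) ** 2
        return r2 <= 1.0


@dataclass(frozen=True)
class PhantomGeometry:
    shape: tuple[int, int, int]
    liver: Ellipsoid
    tumors: tuple[Ellipsoid, ...]
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)


@dataclass(frozen=True)
class PerturbationSpec:
    """Observer-segmentation perturbation: signed morphological margin in
    voxels (dilate if > 0, erode if < 0) then random flips of boundary
    voxels with the given probability.

    A non-integer margin applies the integer part morphologically and the
    fractional part as a seeded random subset of the next boundary shell,
    emulating sub-voxel systematic over-/under-contouring."""

    margin_voxels: float = 0
    boundary_flip_prob: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.boundary_flip_prob <= 1.0:
            raise ValueError("boundary_flip_prob must be in [0, 1]")


@dataclass
class DigitalPhantom:
    activity: np.ndarray  # GBq per voxel, axis order (z, y, x)
    liver_mask: np.ndarray
    tumor_masks: list[np.ndarray]
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    density_kg_per_l: float = DEFAULT_DENSITY_KG_PER_L
    blurred: bool = False

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0  # mm^3 -> ml

    @property
    def voxel_mass_kg(self) -> float:
        return self.density_kg_per_l * self.voxel_volume_ml / 1000.0  # ml -> L

    def validate(self) -> None:
        if self.activity.shape != self.liver_mask.shape:
            raise ValueError("activity and liver_mask shapes differ")
        if np.any(self.activity < 0):
            raise ValueError("negative activity")
        for tm in self.tumor_masks:
            if np.any(tm & ~self.liver_mask):
                raise ValueError("tumor mask extends outside the liver")
        if not self.blurred and np.any(self.activity[~self.liver_mask] > 0):
            raise ValueError("activity outside the liver in an unblurred phantom")


@dataclass(frozen=True)
class DosimetryMeasurement:
    """One observer's reading of one treatment."""

    observer_id: str
    TV: float  # ml
    TLV: float  # ml
    THLV: float  # ml, always TLV - TV
    TD: float  # Gy (nan when the tumor region is empty)
    THLD: float  # Gy
    td_defined: bool = True


def build_phantom(
    geometry: PhantomGeometry,
    total_activity_gbq: float = 1.98,
    tumor_to_liver_uptake_ratio: float = 4.0,
    seed: int | None = None,
    blur_fwhm_mm: float | None = None,
    heterogeneity_sigma: float = 0.0,
    density_kg_per_l: float = DEFAULT_DENSITY_KG_PER_L,
) -> DigitalPhantom:
    """Construct a phantom with activity partitioned by uptake ratio.

    Each tumor voxel receives ``ratio`` times the activity concentration of a
    non-tumor liver voxel; the grid then sums exactly to the injected
    activity.  ``heterogeneity_sigma`` > 0 adds seeded log-normal voxel
    texture (renormalized, so conservation still holds); ``blur_fwhm_mm``
    applies an isotropic Gaussian emulating PET resolution after
    partitioning.
    """
    if total_activity_gbq < 0:
        raise ValueError("negative activity")
    if tumor_to_liver_uptake_ratio <= 0:
        raise ValueError("uptake ratio must be > 0")
    liver = geometry.liver.mask(geometry.shape, geometry.voxel_size_mm)
    if not liver.any():
        raise ValueError("liver mask is empty for this geometry")
    tumor_masks = []
    for t in geometry.tumors:
        tm = t.mask(geometry.shape, geometry.voxel_size_mm)
        if np.any(tm & ~liver):
            raise ValueError("tumor not fully inside the liver")
        tumor_masks.append(tm)
    tumor_union = np.zeros(geometry.shape, dtype=bool)
    for tm in tumor_masks:
        tumor_union |= tm

    weights = np.zeros(geometry.shape, dtype=float)
    weights[liver] = 1.0
    weights[tumor_union] = tumor_to_liver_uptake_ratio
    if heterogeneity_sigma > 0.0:
        rng = np.random.default_rng(seed)
        texture = np.exp(
            rng.normal(0.0, heterogeneity_sigma, size=int(liver.sum()))
        )
        weights[liver] *= texture
    activity = weights * (total_activity_gbq / weights.sum())

    blurred = False
    if blur_fwhm_mm is not None and blur_fwhm_mm > 0:
        sigma_vox = [
            blur_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / vs
            for vs in geometry.voxel_size_mm
        ]
        activity = ndimage.gaussian_filter(activity, sigma=sigma_vox, mode="constant")
        blurred = True

    phantom = DigitalPhantom(
        activity=activity,
        liver_mask=liver,
        tumor_masks=tumor_masks,
        voxel_size_mm=geometry.voxel_size_mm,
        density_kg_per_l=density_kg_per_l,
        blurred=blurred,
    )
    phantom.validate()
    return phantom


def local_deposition_dose(phantom: DigitalPhantom) -> np.ndarray:
    """Absorbed dose grid (Gy) under the local-deposition assumption."""
    if phantom.voxel_volume_ml <= 0:
        raise ValueError("zero voxel volume")
    if phantom.density_kg_per_l <= 0:
        raise ValueError("zero or negative density")
    return J_PER_GBQ * phantom.activity / phantom.voxel_mass_kg


def perturb_mask(
    mask: np.ndarray,
    spec: PerturbationSpec,
    seed: int | None = None,
    clip_to: np.ndarray | None = None,
) -> np.ndarray:
    """Emulate one observer's delineation of a structure.

    Deterministic dilation (margin > 0) or erosion (margin < 0) with a
    6-connected structuring element, then seeded random flips of boundary
    voxels, then optional re-clipping to a containing mask (tumors stay
    inside the observer's liver).  Raises if the result empties.
    """
    spec.validate()
    if not mask.any():
        raise ValueError("input mask is empty")
    out = mask.copy()
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    rng = np.random.default_rng(seed)
    margin = float(spec.margin_voxels)
    whole = int(math.floor(abs(margin)))
    frac = abs(margin) - whole
    if margin > 0:
        if whole:
            out = ndimage.binary_dilation(out, structure, iterations=whole)
        if frac > 0.0:
            shell = ndimage.binary_dilation(out, structure) & ~out
            out |= shell & (rng.random(mask.shape) < frac)
    elif margin < 0:
        if whole:
            out = ndimage.binary_erosion(out, structure, iterations=whole)
        if frac > 0.0 and out.any():
            shell = out & ~ndimage.binary_erosion(out, structure)
            out &= ~(shell & (rng.random(mask.shape) < frac))
        if not out.any():
            raise ValueError("erosion emptied the mask: perturbation too aggressive")
    if spec.boundary_flip_prob > 0.0:
        outer = ndimage.binary_dilation(out, structure) & ~out
        inner = out & ~ndimage.binary_erosion(out, structure)
        boundary = outer | inner
        flips = boundary & (
            rng.random(mask.shape) < spec.boundary_flip_prob
        )
        out = out ^ flips
    if clip_to is not None:
        out &= clip_to
    if not out.any():
        raise ValueError("perturbation emptied the mask")
    return out


def extract_measurements(
    phantom: DigitalPhantom,
    dose_grid: np.ndarray,
    liver_mask_obs: np.ndarray,
    tumor_masks_obs: list[np.ndarray],
    observer_id: str,
) -> DosimetryMeasurement:
    """Extract TV, TLV, THLV, TD, THLD from one observer's segmentation.

    Volumes are voxel count times voxel volume (no partial-volume
    weighting, matching slice-wise manual contouring granularity); the total
    tumor region is the union of the per-lesion masks; TD is the mean dose
    over that union and THLD the mean dose over liver minus tumor.
    """
    if dose_grid.shape != phantom.activity.shape:
        raise ValueError("dose grid shape does not match phantom grid")
    tumor_union = np.zeros(phantom.activity.shape, dtype=bool)
    for tm in tumor_masks_obs:
        tumor_union |= tm
    if np.any(tumor_union & ~liver_mask_obs):
        raise ValueError("observer tumor voxels outside the observer liver mask")
    vol = phantom.voxel_volume_ml
    tv = float(tumor_union.sum()) * vol
    tlv = float(liver_mask_obs.sum()) * vol
    healthy = liver_mask_obs & ~tumor_union
    if tumor_union.any():
        td = float(dose_grid[tumor_union].mean())
        td_defined = True
    else:
        td = float("nan")
        td_defined = False
    thld = float(dose_grid[healthy].mean()) if healthy.any() else float("nan")
    return DosimetryMeasurement(
        observer_id=observer_id,
        TV=tv,
        TLV=tlv,
        THLV=tlv - tv,
        TD=td,
        THLD=thld,
        td_defined=td_defined,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def save_volume(grid: np.ndarray, voxel_size_mm, path) -> None:
    """Save a grid (axis order (z, y, x)) as NIfTI with the voxel spacing in
    the affine."""
    import nibabel as nib

    dz, dy, dx = voxel_size_mm
    affine = np.diag([dx, dy, dz, 1.0])
    data = np.asarray(grid)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    # NIfTI stores x fastest: transpose (z, y, x) -> (x, y, z)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data.T), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume back into (z, y, x) axis order; returns the grid
    and the (dz, dy, dx) spacing."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).T
    dx, dy, dz = img.header.get_zooms()[:3]
    return np.asarray(data), (float(dz), float(dy), float(dx))
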