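"""Synthetic serial-image phantoms with known volume change.

A phantom is a 3-D intensity grid containing a "brain" (large sphere)
and a "hippocampus" (small ellipsoid inside it), each with its own
tissue intensity so that both structure boundaries carry contrast.
A follow-up phantom is produced by eroding a structure's boundary by a
Euclidean-distance threshold chosen so the removed tissue volume is as
close as possible to a requested amount; the achieved ground truth is
recorded exactly as (voxel-count difference) x (voxel volume).  The
pair is generated aligned, so no registration is required downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

BACKGROUND_INTENSITY = 0.0
BRAIN_INTENSITY = 0.4
HIPPO_INTENSITY = 2.0


@dataclass
class ShapeSpec:
    """Geometry of the phantom (sizes in voxels / mm)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radius_mm: float = 24.0
    hippo_semiaxes_mm: tuple[float, float, float] = (8.0, 5.0, 5.0)
    hippo_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: sub-voxel displacement of the structure centers; breaks lattice
    #: symmetry so erosion shells have near-voxel volume granularity
    center_offset_mm: tuple[float, float, float] = (0.1234, 0.2468, 0.3702)
    #: Gaussian partial-volume blur applied to the ideal piecewise-
    #: constant image, in voxels (0 = sharp edges)
    smooth_sigma_vox: float = 0.5


@dataclass
class Phantom:
    """One synthetic scan: intensities plus structure masks."""

    image: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    brain_mask: np.ndarray
    hippo_mask: np.ndarray
    true_volume_change_ml: dict[str, float] = field(default_factory=dict)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_dims_mm)) / 1000.0

    def structure_volume_ml(self, structure: str) -> float:
        mask = self.brain_mask if structure == "brain" else self.hippo_mask
        return float(mask.sum()) * self.voxel_volume_ml


def _distance_fields(spec: ShapeSpec):
    """Approximate signed distances to the structure surfaces (mm).

    Negative inside the structure.  The brain field is exact (sphere);
    the hippocampal field is the scaled ellipsoidal level function,
    which is monotone in the true distance and adequate for shell
    erosion.
    """
    shape = spec.shape
    center = (np.asarray(shape) - 1) / 2.0
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    mm = [(c - mu) * d - off for c, mu, d, off in
          zip(coords, center, spec.voxel_dims_mm, spec.center_offset_mm)]
    brain_field = np.sqrt(sum(x**2 for x in mm)) - spec.brain_radius_mm
    level = np.sqrt(sum(((x - o) / a) ** 2 for x, o, a in
                        zip(mm, spec.hippo_offset_mm, spec.hippo_semiaxes_mm)))
    hippo_field = (level - 1.0) * min(spec.hippo_semiaxes_mm)
    return brain_field, hippo_field


def _erode_to_volume(field: np.ndarray, target_voxels: int) -> np.ndarray:
    """Erode the structure ``field <= 0`` by the surface offset whose
    removed-voxel count is closest to ``target_voxels``.

    The offset is found by bisection on the sorted interior field
    values, so the removal is always a geometric shell; the achieved
    count can differ from the target only by field-value ties
    (typically a handful of voxels).
    """
    mask = field <= 0.0
    if target_voxels <= 0:
        return mask
    inside = np.sort(field[mask])[::-1]          # closest-to-surface first
    if target_voxels >= inside.size:
        raise ValueError("requested shrink exceeds the structure volume")
    threshold = inside[target_voxels - 1]        # remove field > -delta
    return field < threshold


def _render(spec: ShapeSpec, brain: np.ndarray, hippo: np.ndarray,
            noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    img = np.full(spec.shape, BACKGROUND_INTENSITY, dtype=float)
    img[brain] = BRAIN_INTENSITY
    img[hippo] = HIPPO_INTENSITY
    if spec.smooth_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, spec.smooth_sigma_vox)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def generate_phantom_pair(spec: ShapeSpec | None = None, shrink_ml: float = 1.0,
                          noise_sd: float = 0.0, seed: int = 0,
                          structure: str = "brain") -> tuple[Phantom, Phantom]:
    """Generate an aligned baseline/follow-up phantom pair.

    ``shrink_ml`` of the named structure (``"brain"`` or ``"hippo"``)
    is removed from its outer boundary in the follow-up image.  Both
    phantoms record the achieved ground-truth volume change in
    ``true_volume_change_ml`` (positive = loss); noise is additive
    Gaussian on the intensities, independent between the two scans but
    reproducible from ``seed``.
    """
    if spec is None:
        spec = ShapeSpec()
    if shrink_ml < 0:
        raise ValueError("shrink_ml must be >= 0")
    if structure not in ("brain", "hippo"):
        raise ValueError("structure must be 'brain' or 'hippo'")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    brain_field, hippo_field = _distance_fields(spec)
    brain1 = brain_field <= 0.0
    hippo1 = (hippo_field <= 0.0) & brain1
    voxvol_ml = float(np.prod(spec.voxel_dims_mm)) / 1000.0
    target_vox = int(round(shrink_ml / voxvol_ml))

    brain2, hippo2 = brain1.copy(), hippo1.copy()
    if structure == "brain":
        brain2 = _erode_to_volume(brain_field, target_vox)
        hippo2 = hippo1 & brain2
    else:
        hippo2 = _erode_to_volume(hippo_field, target_vox) & brain1

    truth = {
        "brain": (int(brain1.sum()) - int(brain2.sum())) * voxvol_ml,
        "hippo": (int(hippo1.sum()) - int(hippo2.sum())) * voxvol_ml,
    }

    img1 = _render(spec, brain1, hippo1, noise_sd, rng)
    img2 = _render(spec, brain2, hippo2, noise_sd, rng)
    p1 = Phantom(img1, spec.voxel_dims_mm, brain1, hippo1, dict(truth))
    p2 = Phantom(img2, spec.voxel_dims_mm, brain2, hippo2, dict(truth))
    return p1, p2


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def save_phantom(phantom: Phantom, prefix: str) -> list[str]:
    """Write image + masks as NIfTI-1 (.nii.gz); returns the paths."""
    import nibabel as nib

    affine = np.diag(list(phantom.voxel_dims_mm) + [1.0])
    paths = []
    for suffix, arr in (("", phantom.image),
                        ("_brain_mask", phantom.brain_mask.astype(np.uint8)),
                        ("_hippo_mask", phantom.hippo_mask.astype(np.uint8))):
        path = f"{prefix}{suffix}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), path)
        paths.append(path)
    return paths


def load_image(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI image; returns (data, voxel dims in mm)."""
    import nibabel as nib

    img = nib.load(path)
    return np.asarray(img.get_fdata()), tuple(float(z) for z in img.header.get_zooms()[:3])
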