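"""SUV-threshold mask rules on small 3-D voxel phantoms.

Two segmentation rules used to define regions of interest on
PSMA-PET-derived voxel grids:

* bone marrow: the whole-body bone mask minus voxels whose SUV exceeds
  50% of the whole-body maximum (tumor-infiltrated bone is excluded;
  voxels exactly at the threshold stay in marrow);
* tumor: iso-contour of voxels strictly above a patient-specific
  fraction of the global SUV maximum.

Arrays are indexed 0-based in (z, y, x) order; no world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fraction of the whole-body SUV maximum above which bone voxels are
#: considered tumor-infiltrated and excluded from marrow.
MARROW_SUV_FRACTION = 0.5


@dataclass(frozen=True)
class VoxelPhantom:
    """A label/SUV voxel grid standing in for a registered PET volume."""

    bone_mask: np.ndarray
    suv: np.ndarray
    voxel_volume_ml: float = 1.0

    def __post_init__(self) -> None:
        bone = np.asarray(self.bone_mask)
        suv = np.asarray(self.suv, dtype=float)
        if bone.shape != suv.shape or bone.ndim != 3:
            raise ValueError("bone_mask and suv must share a 3-D shape")
        if not np.isin(bone, (0, 1)).all():
            raise ValueError("bone_mask values must be 0 or 1")
        if not (np.isfinite(suv).all() and (suv >= 0).all()):
            raise ValueError("suv must be finite and >= 0")
        if not self.voxel_volume_ml > 0:
            raise ValueError("voxel_volume_ml must be > 0")
        object.__setattr__(self, "bone_mask", bone.astype(bool))
        object.__setattr__(self, "suv", suv)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.suv.shape


def marrow_mask(phantom: VoxelPhantom) -> np.ndarray:
    """Non-tumor-infiltrated bone marrow mask.

    bone AND (SUV <= 0.5 × global SUV max); the threshold is relative to
    the whole-body maximum, and boundary voxels are retained in marrow.
    """
    suv_max = float(phantom.suv.max())
    if suv_max <= 0:
        raise ValueError("undefined threshold")
    return phantom.bone_mask & (phantom.suv <= MARROW_SUV_FRACTION * suv_max)


def tumor_mask(suv: np.ndarray, threshold_fraction: float) -> np.ndarray:
    """Iso-contour mask: voxels strictly above fraction × global max."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("invalid threshold")
    suv = np.asarray(suv, dtype=float)
    suv_max = float(suv.max())
    if suv_max <= 0:
        raise ValueError("undefined threshold")
    return suv > threshold_fraction * suv_max


def random_phantom(
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (8, 8, 8),
    bone_fraction: float = 0.4,
    n_lesions: int = 3,
) -> VoxelPhantom:
    """A random phantom: diffuse background SUV, a few hot lesions, and
    a random bone compartment.  Used for property tests and cohort
    generation."""
    bone = rng.random(shape) < bone_fraction
    suv = rng.gamma(2.0, 0.5, size=shape)
    for _ in range(n_lesions):
        idx = tuple(rng.integers(0, s) for s in shape)
        suv[idx] += rng.uniform(5.0, 15.0)
    return VoxelPhantom(bone.astype(int), suv)


# --- plain-text fixture format (shape header + flattened values) -----------

def save_phantom_txt(phantom: VoxelPhantom, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(map(str, phantom.shape)) + "\n")
        fh.write(f"{phantom.voxel_volume_ml}\n")
        fh.write(" ".join(map(str, phantom.bone_mask.astype(int).ravel())) + "\n")
        fh.write(" ".join(f"{v:.6g}" for v in phantom.suv.ravel()) + "\n")


def load_phantom_txt(path) -> VoxelPhantom:
    with open(path, encoding="utf-8") as fh:
        shape = tuple(int(x) for x in fh.readline().split())
        voxel_volume = float(fh.readline())
        bone = np.array(fh.readline().split(), dtype=int).reshape(shape)
        suv = np.array(fh.readline().split(), dtype=float).reshape(shape)
    return VoxelPhantom(bone, suv, voxel_volume)
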