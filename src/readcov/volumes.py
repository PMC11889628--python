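"""Volumetric handling of grey-matter-volume (GMV) maps.

This module covers everything between "a stack of spatially normalized GMV
images" and "a subjects x regions table of mean GMV": Gaussian smoothing,
spherical ROI construction in MNI millimetre space, parcellation label
images, and mean-GMV extraction.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are obtained through the
  image affine and assumed RAS+ (MNI).
* All maps entering a joint analysis must already share one grid and
  affine; no resampling is performed.
* Sphere membership is decided by the voxel-centre rule: a voxel belongs
  to the sphere iff the MNI position of its centre lies within ``radius``
  millimetres of the sphere centre (ties included). Centres are never
  snapped to the lattice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import FormatError, GeometryError

logger = logging.getLogger(__name__)

# FWHM -> Gaussian sigma conversion factor: fwhm = sigma * sqrt(8 ln 2)
_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class GMVMap:
    """A 3-D grey-matter-volume image with a voxel-to-MNI affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3-D map, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("map contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length in mm along each voxel axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "GMVMap", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @classmethod
    def load(cls, path: str | Path) -> "GMVMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine)

    def save(self, path: str | Path) -> None:
        nib.Nifti1Image(self.data.astype(np.float32), self.affine).to_filename(
            str(path)
        )


@dataclass(frozen=True)
class ROISpec:
    """A named sphere in MNI space: centre in mm and radius in mm."""

    name: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"ROI {self.name!r}: radius must be >= 0")


@dataclass
class ROIMask:
    """A region realized as voxel indices on a reference grid."""

    name: str
    indices: np.ndarray  # (k, 3) integer voxel indices
    shape: tuple[int, int, int]
    source: str = "sphere"  # {"sphere", "parcel"}

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("indices must be (k, 3)")
        if self.indices.shape[0] == 0:
            raise ValueError(f"ROI {self.name!r}: empty mask")
        if np.any(self.indices < 0) or np.any(
            self.indices >= np.asarray(self.shape)
        ):
            raise ValueError(f"ROI {self.name!r}: indices outside grid {self.shape}")

    @property
    def size(self) -> int:
        return int(self.indices.shape[0])

    def as_boolean(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(self.indices.T)] = True
        return out


# ---------------------------------------------------------------------------
# operations


def smooth_map(gmv: GMVMap, fwhm: float) -> GMVMap:
    """Gaussian-smooth a map with an isotropic kernel of ``fwhm`` mm.

    The kernel width is specified as full width at half maximum in
    millimetres and converted per axis to voxel units through the voxel
    size. ``fwhm=0`` returns the map unchanged. Boundary handling is
    "reflect", which keeps constant maps exactly constant.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return GMVMap(gmv.data.copy(), gmv.affine.copy())
    rot = gmv.affine[:3, :3]
    # shear/oblique grids would make a per-axis voxel sigma wrong
    gram = rot.T @ rot
    if not np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-6):
        raise GeometryError("smoothing requires an orthogonal (shear-free) affine")
    sigma_vox = (fwhm * _FWHM_TO_SIGMA) / gmv.voxel_size
    smoothed = ndimage.gaussian_filter(gmv.data, sigma=sigma_vox, mode="reflect")
    return GMVMap(smoothed, gmv.affine.copy())


def make_sphere_roi(spec: ROISpec, grid: GMVMap) -> ROIMask:
    """Realize a spherical ROI on the grid of ``grid``.

    Every voxel whose centre's world position lies within ``spec.radius``
    mm (Euclidean, boundary included) of ``spec.center`` is part of the
    mask.
    """
    inv = np.linalg.inv(grid.affine)
    center = np.asarray(spec.center, dtype=float)
    center_vox = (inv @ np.append(center, 1.0))[:3]
    # bounding box in voxel units, padded by one voxel
    halfwidth = spec.radius / grid.voxel_size + 1.0
    lo = np.maximum(np.floor(center_vox - halfwidth).astype(int), 0)
    hi = np.minimum(
        np.ceil(center_vox + halfwidth).astype(int) + 1, np.asarray(grid.shape)
    )
    if np.any(lo >= hi):
        raise ValueError(f"ROI {spec.name!r}: centre {spec.center} outside the grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = vox @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    d2 = np.sum((world - center) ** 2, axis=1)
    # small tolerance so exact-radius lattice points are not lost to rounding
    inside = d2 <= spec.radius**2 + 1e-9
    if not np.any(inside):
        raise ValueError(
            f"ROI {spec.name!r}: no voxel centre within {spec.radius} mm of "
            f"{spec.center} on this grid"
        )
    return ROIMask(spec.name, vox[inside], grid.shape, source="sphere")


def load_parcellation(
    label_map: GMVMap, names: dict[int, str] | None = None
) -> list[ROIMask]:
    """Split an integer-labeled parcellation image into one mask per label.

    Label 0 is background. ``names`` optionally maps label values to
    region names; unnamed labels are called ``"label_<value>"``.
    """
    data = label_map.data
    if not np.allclose(data, np.round(data), atol=1e-9):
        raise FormatError("parcellation image must contain integer labels")
    labels = np.unique(np.round(data).astype(int))
    labels = labels[labels != 0]
    if labels.size == 0:
        warnings.warn("parcellation image contains no nonzero labels", stacklevel=2)
        return []
    intdata = np.round(data).astype(int)
    masks = []
    for lab in labels:
        idx = np.argwhere(intdata == lab)
        name = names.get(int(lab), f"label_{lab}") if names else f"label_{lab}"
        masks.append(ROIMask(name, idx, label_map.shape, source="parcel"))
    return masks


def extract_mean_gmv(
    maps: dict[str, GMVMap], rois: list[ROIMask]
) -> pd.DataFrame:
    """Mean GMV per subject and region.

    ``maps`` maps subject id to a GMVMap; all maps must share one grid and
    affine. Returns a DataFrame indexed by subject id with one column per
    ROI, each cell the arithmetic mean of the map over the ROI's voxels.
    """
    if not maps:
        raise ValueError("no maps supplied")
    ids = list(maps)
    ref = maps[ids[0]]
    offenders = [sid for sid in ids if not maps[sid].same_grid(ref)]
    if offenders:
        raise GeometryError(
            "maps do not share the reference grid/affine; offending subjects: "
            + ", ".join(offenders)
        )
    flat_idx = [np.ravel_multi_index(tuple(r.indices.T), ref.shape) for r in rois]
    values = np.empty((len(ids), len(rois)))
    for i, sid in enumerate(ids):
        flat = maps[sid].data.ravel()
        for j, idx in enumerate(flat_idx):
            values[i, j] = flat[idx].mean()
    return pd.DataFrame(values, index=pd.Index(ids, name="id"),
                        columns=[r.name for r in rois])


# ---------------------------------------------------------------------------
# ROI spec I/O and the packaged reading-network ROIs


def read_roi_specs(path: str | Path) -> list[ROISpec]:
    """Read ROI specs from a CSV with columns name, x, y, z, radius."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z", "radius"}
    if not required.issubset(df.columns):
        raise FormatError(f"ROI spec CSV must have columns {sorted(required)}")
    return [
        ROISpec(str(r["name"]), (float(r["x"]), float(r["y"]), float(r["z"])),
                float(r["radius"]))
        for _, r in df.iterrows()
    ]


def write_roi_specs(specs: list[ROISpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": s.name, "x": s.center[0], "y": s.center[1],
             "z": s.center[2], "radius": s.radius}
            for s in specs
        ]
    ).to_csv(path, index=False)


def reading_network_rois() -> list[ROISpec]:
    """The six left-hemisphere reading-network spheres shipped with the package.

    4 mm-radius spheres centred on literature MNI coordinates for the
    lexical and perceptual subdivisions of the visual word form area
    (VWFA_lex, VWFA_per), the superior temporal gyrus (STG), precentral
    gyrus (PCG), inferior frontal gyrus (IFG) and inferior parietal
    lobule (IPL).
    """
    ref = resources.files("readcov").joinpath("data/reading_rois.csv")
    with resources.as_file(ref) as path:
        return read_roi_specs(path)
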