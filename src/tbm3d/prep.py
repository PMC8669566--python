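"""Pre-processing for segmented tissue-density images.

The morphometry pipeline expects, for every subject, a nonnegative 3D
tissue-density volume (grey or white matter, or a phantom stand-in) that is
already segmented and affinely co-registered to a common grid.  This module
supplies the steps between those inputs and the transport solver: NIfTI I/O,
Gaussian smoothing, normalization of every image to unit total mass (so all
images are comparable probability densities), construction of the population
reference as the Euclidean (voxelwise) mean, and covariate residualization
used to remove confounds before the transport-domain regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "TissueImage",
    "read_image",
    "write_image",
    "smooth_gaussian",
    "normalize_mass",
    "euclidean_mean_reference",
    "residualize",
    "support_mask",
]

#: FWHM (in voxels) of the isotropic Gaussian applied to segmented images.
DEFAULT_FWHM = 2.35

#: Relative floor added before mass normalization so densities are strictly
#: positive, as the transport solver requires.
DEFAULT_EPSILON = 1e-6

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TissueImage:
    """A nonnegative tissue-density volume on a fixed grid.

    Parameters
    ----------
    data : 3D float array, values >= 0 and finite.
    voxel_size_mm : physical edge lengths of a voxel, one per axis.
    tissue_class : "GM", "WM" or "phantom".
    subject_id : identifier used in error messages and file names.
    meta : free-form provenance (mass errors, solver notes, ...).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_class: str = "phantom"
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"TissueImage expects a 3D array, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("TissueImage contains non-finite values")
        if self.data.min() < 0:
            raise ValueError("TissueImage contains negative intensities")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        else:
            self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def mass(self) -> float:
        return float(self.data.sum())

    def copy_with(self, data: np.ndarray, **meta) -> "TissueImage":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, data=data, meta=new_meta)


def read_image(path, tissue_class: str = "phantom", subject_id: str = "") -> TissueImage:
    """Load a 3D NIfTI-1 volume as a :class:`TissueImage`.

    The voxel size is taken from the header zooms; a 4D file (e.g. a time
    series) is rejected because the pipeline operates on single volumes.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"image file not found: {path}") from None
    except Exception as exc:  # nibabel raises its own family of errors
        raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D data {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return TissueImage(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_mm=tuple(float(z) for z in zooms),
        tissue_class=tissue_class,
        subject_id=subject_id or str(path),
    )


def write_image(img: TissueImage, path) -> None:
    """Write a :class:`TissueImage` as float32 NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(img.voxel_size_mm) + [1.0])
    nii = nib.Nifti1Image(img.data.astype(np.float32), affine)
    nii.header.set_zooms(img.voxel_size_mm)
    nib.save(nii, str(path))


def smooth_gaussian(img: TissueImage, fwhm_voxels: float = DEFAULT_FWHM) -> TissueImage:
    """Isotropic Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)).

    The reflective boundary keeps the total mass unchanged.
    """
    if fwhm_voxels <= 0:
        raise ValueError(f"fwhm_voxels must be positive, got {fwhm_voxels}")
    sigma = fwhm_voxels * _FWHM_TO_SIGMA
    out = ndimage.gaussian_filter(img.data, sigma, mode="reflect")
    return img.copy_with(out, fwhm_voxels=fwhm_voxels)


def normalize_mass(img: TissueImage, epsilon: float = DEFAULT_EPSILON) -> TissueImage:
    """Rescale to unit total mass after flooring by ``epsilon * mean``.

    The floor makes the density strictly positive everywhere, which the
    transport solver (and the Knothe-type initialization in particular)
    requires; ``epsilon`` is expressed relative to the mean intensity so the
    floor is scale-free.
    """
    total = img.data.sum()
    if total <= 0:
        raise ValueError(f"cannot normalize all-zero image {img.subject_id!r}")
    data = img.data + epsilon * img.data.mean()
    data = data / data.sum()
    if epsilon > 0 and data.min() <= 0:
        raise ValueError("epsilon floor failed to produce a positive density")
    return img.copy_with(data, normalize_epsilon=epsilon)


def euclidean_mean_reference(imgs: list[TissueImage], epsilon: float = DEFAULT_EPSILON) -> TissueImage:
    """Population reference: voxelwise mean of the images, mass-normalized."""
    if not imgs:
        raise ValueError("need at least one image to build a reference")
    shape = imgs[0].shape
    acc = np.zeros(shape, dtype=np.float64)
    for im in imgs:
        if im.shape != shape:
            raise ValueError(
                f"grid mismatch for subject {im.subject_id!r}: "
                f"{im.shape} vs {shape}"
            )
        acc += im.data
    ref = TissueImage(
        data=acc / len(imgs),
        voxel_size_mm=imgs[0].voxel_size_mm,
        tissue_class=imgs[0].tissue_class,
        subject_id="reference",
    )
    return normalize_mass(ref, epsilon=epsilon)


def residualize(y: np.ndarray, Z: np.ndarray | None, add_intercept: bool = True) -> np.ndarray:
    """Remove the linear span of confounds from a covariate.

    Computes ``v = y - Z (Z^T Z)^{-1} Z^T y``, the component of ``y``
    orthogonal to the columns of ``Z``.  An all-ones intercept column is
    appended by default so that "centered" quantities are well defined.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    cols = []
    if Z is not None:
        Z = np.asarray(Z, dtype=np.float64)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError(f"length mismatch: y has {n} rows, Z has {Z.shape[0]}")
        cols.append(Z)
    if add_intercept:
        cols.append(np.ones((n, 1)))
    if not cols:
        return y.copy()
    Zfull = np.hstack(cols)
    rank = np.linalg.matrix_rank(Zfull)
    if rank < Zfull.shape[1]:
        raise ValueError(
            "confound matrix is rank-deficient (collinear columns); "
            "remove redundant confounds"
        )
    beta, *_ = np.linalg.lstsq(Zfull, y, rcond=None)
    return y - Zfull @ beta


def support_mask(img: TissueImage, rel_threshold: float = 0.1) -> np.ndarray:
    """Voxels carrying appreciable mass: density above ``rel_threshold * mean``."""
    return img.data > rel_threshold * img.data.mean()
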