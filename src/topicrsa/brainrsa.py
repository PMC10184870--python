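"""Searchlight and ROI representational similarity analysis.

For each subject, sentence × voxel pattern matrices are compared with a model
RDM: at every in-mask center voxel a sphere of given millimetre radius is
gathered, the sphere's pattern RDM (1 - Pearson r, after per-voxel demeaning)
is correlated with the model RDM over the vectorised upper triangles, the
correlation is Fisher-z transformed and stored at the center, and the
resulting map is smoothed with a mask-normalised Gaussian kernel.  ROI RSA is
the same statistic computed once over all voxels of a region.

Internal math is grid-based (voxel indices, millimetre distances from the
per-axis voxel size); NIfTI affines are respected only at I/O time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import RDM, build_rdm, compare_rdms, vectorize_rdm
from .synthetic import BrainGeometry

logger = logging.getLogger("topicrsa")

SENTINEL = np.nan  # value of undefined (out-of-mask / failed) map voxels
FISHER_CLIP = 1 - 1e-7

__all__ = [
    "RsaConfig",
    "SearchlightMap",
    "sphere_offsets",
    "demean_patterns",
    "fisher_z",
    "smooth_map",
    "searchlight_rsa",
    "roi_rsa",
    "save_map_nifti",
    "load_map_nifti",
]


@dataclass
class RsaConfig:
    """Searchlight/ROI RSA parameters (radius and smoothing in millimetres).

    Defaults are the study values: 8 mm spheres, 12 mm FWHM smoothing,
    per-voxel demeaning on.
    """

    radius_mm: float = 8.0
    smooth_fwhm_mm: float = 12.0
    min_sphere_voxels: int = 10
    demean: bool = True

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")
        if self.min_sphere_voxels < 3:
            raise ValueError("min_sphere_voxels must be >= 3")


@dataclass
class SearchlightMap:
    """3-D map of Fisher-z model correlations; NaN outside the mask."""

    data: np.ndarray
    geometry: BrainGeometry
    model_name: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError("map shape does not match geometry")


def sphere_offsets(
    radius_mm: float, voxel_size_mm: float | tuple[float, float, float]
) -> np.ndarray:
    """All integer voxel offsets within a millimetre radius (incl. origin)."""
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (voxel_size_mm,) * 3
    vs = np.asarray(voxel_size_mm, dtype=float)
    lim = np.floor(radius_mm / vs).astype(int)
    grids = np.meshgrid(*[np.arange(-l, l + 1) for l in lim], indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    d2 = ((offs * vs) ** 2).sum(axis=1)
    return offs[d2 <= radius_mm**2 + 1e-9]


def demean_patterns(patterns: np.ndarray) -> np.ndarray:
    """Subtract each voxel's mean across sentences (removes the grand spatial
    pattern before correlation); output column means are 0."""
    X = np.asarray(patterns, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 sentences")
    return X - X.mean(axis=0, keepdims=True)


def fisher_z(r) -> np.ndarray | float:
    """atanh(r) with |r| clipped to 1 - 1e-7 to keep maps finite."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-9):
        raise ValueError("|r| > 1")
    out = np.arctanh(np.clip(r_arr, -FISHER_CLIP, FISHER_CLIP))
    return float(out) if np.isscalar(r) else out


def smooth_map(smap: SearchlightMap, fwhm_mm: float) -> SearchlightMap:
    """Mask-normalised Gaussian smoothing: NaNs are treated as missing and
    the result divided by the smoothed mask, so constant maps stay constant
    inside the mask.  ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return SearchlightMap(smap.data.copy(), smap.geometry, smap.model_name, smap.subject_id)
    sigma_vox = [
        fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / v
        for v in smap.geometry.voxel_size_mm
    ]
    valid = np.isfinite(smap.data)
    filled = np.where(valid, smap.data, 0.0)
    num = gaussian_filter(filled, sigma_vox)
    den = gaussian_filter(valid.astype(float), sigma_vox)
    out = np.full(smap.data.shape, SENTINEL)
    ok = valid & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return SearchlightMap(out, smap.geometry, smap.model_name, smap.subject_id)


def _model_vec_standardized(model_rdm: RDM | np.ndarray) -> np.ndarray:
    v = vectorize_rdm(model_rdm)
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("constant model RDM: correlation undefined")
    return v / n


def _pattern_rdm_vec(sub: np.ndarray) -> np.ndarray | None:
    """Vectorised 1 - Pearson RDM of a (sentences × voxels) block; None when
    any sentence pattern has zero variance."""
    sd = sub.std(axis=1)
    if np.any(sd == 0):
        return None
    r = np.corrcoef(sub)
    return vectorize_rdm(1.0 - np.clip((r + r.T) / 2, -1.0, 1.0))


def searchlight_rsa(
    patterns: np.ndarray,
    geometry: BrainGeometry,
    model_rdm: RDM | np.ndarray,
    config: RsaConfig,
    model_name: str = "",
    subject_id: str = "",
) -> SearchlightMap:
    """Whole-brain searchlight RSA for one subject.

    ``patterns`` is (n_sentences × n_brain_voxels) in the geometry's canonical
    voxel order.  Centers whose in-mask sphere has fewer than
    ``min_sphere_voxels`` voxels (or a zero-variance pattern) are set to the
    NaN sentinel.  The Fisher-z map is smoothed with ``smooth_fwhm_mm``.
    """
    X = np.asarray(patterns, dtype=float)
    m = model_rdm.matrix if isinstance(model_rdm, RDM) else np.asarray(model_rdm)
    if X.shape[0] != m.shape[0]:
        raise ValueError("model RDM items do not align with pattern rows")
    if X.shape[1] != geometry.n_voxels:
        raise ValueError("pattern columns do not match geometry voxels")
    if config.demean:
        X = demean_patterns(X)
    mv = _model_vec_standardized(model_rdm)

    offs = sphere_offsets(config.radius_mm, geometry.voxel_size_mm)
    idx_vol = geometry.flat_index_volume()
    coords = geometry.voxel_coords()
    shape = np.asarray(geometry.shape)

    zmap = np.full(geometry.shape, SENTINEL)
    n_small = 0
    for c in coords:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        cols = idx_vol[pts[ok, 0], pts[ok, 1], pts[ok, 2]]
        cols = cols[cols >= 0]
        if cols.size < config.min_sphere_voxels:
            n_small += 1
            continue
        pv = _pattern_rdm_vec(X[:, cols])
        if pv is None:
            n_small += 1
            continue
        pv = pv - pv.mean()
        nrm = np.linalg.norm(pv)
        if nrm == 0:
            n_small += 1
            continue
        r = float(pv @ mv) / nrm
        zmap[c[0], c[1], c[2]] = fisher_z(min(max(r, -1.0), 1.0))
    if n_small:
        logger.info("searchlight: %d centers below threshold or degenerate", n_small)
    smap = SearchlightMap(zmap, geometry, model_name, subject_id)
    return smooth_map(smap, config.smooth_fwhm_mm)


def roi_rsa(
    patterns: np.ndarray,
    roi_columns: np.ndarray,
    model_rdm: RDM | np.ndarray,
    config: RsaConfig,
) -> float:
    """RSA over all voxels of one ROI; returns the raw Pearson r between the
    ROI pattern RDM and the model RDM (Fisher z is left to the caller)."""
    roi_columns = np.asarray(roi_columns, dtype=int)
    if roi_columns.size == 0:
        raise ValueError("empty ROI")
    X = np.asarray(patterns, dtype=float)[:, roi_columns]
    if config.demean:
        X = demean_patterns(X)
    pv = _pattern_rdm_vec(X)
    if pv is None:
        raise ValueError("zero-variance sentence pattern in ROI")
    mv = _model_vec_standardized(model_rdm)
    pv = pv - pv.mean()
    nrm = np.linalg.norm(pv)
    if nrm == 0:
        raise ValueError("constant ROI pattern RDM")
    return float(pv @ mv / nrm)


def save_map_nifti(smap: SearchlightMap, path) -> None:
    nib.save(
        nib.Nifti1Image(smap.data.astype(np.float32), smap.geometry.affine()), str(path)
    )


def load_map_nifti(path, geometry: BrainGeometry, model_name="", subject_id="") -> SearchlightMap:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return SearchlightMap(data, geometry, model_name, subject_id)
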