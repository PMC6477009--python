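"""ROI-based voxel morphometry on tissue-probability maps.

Consumes already-segmented gray-matter probability volumes (values in
[0, 1]): Gaussian smoothing at a given FWHM, mean density inside
box-shaped regions of interest, a voxel-wise pooled-variance two-sample
t map thresholded at an uncorrected alpha with 26-connectivity cluster
labeling, and a paired left-vs-right density contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage
from scipy import stats as sstats

from .config import DEFAULTS


@dataclass
class VolumeImage:
    """3D volume with voxel size (mm) and a voxel->mm affine."""

    data: np.ndarray
    voxel_size: Tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("expected a 3D volume")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.affine = np.asarray(self.affine, dtype=float)

    @classmethod
    def from_nifti(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(data=np.asarray(img.dataobj, dtype=np.float32),
                   voxel_size=tuple(float(z) for z in zooms),
                   affine=np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))


@dataclass(frozen=True)
class ROISpec:
    """Box region of interest, addressed in voxel indices.

    The box spans ``[c - e//2, c - e//2 + e)`` per axis, so the default
    4×4×2-voxel box is 6×6×3 mm at 1.5 mm voxels.
    """

    name: str
    center_voxel: Tuple[int, int, int]
    extents: Tuple[int, int, int] = DEFAULTS.roi_extents_vox

    def slices(self, shape: Tuple[int, int, int]) -> Tuple[slice, slice, slice]:
        sl = []
        for c, e, n in zip(self.center_voxel, self.extents, shape):
            start = int(c) - int(e) // 2
            stop = start + int(e)
            if start < 0 or stop > n:
                raise ValueError(f"ROI {self.name!r} exceeds volume bounds "
                                 f"(axis span [{start}, {stop}) vs size {n})")
            sl.append(slice(start, stop))
        return tuple(sl)


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(vol: VolumeImage, fwhm: float = DEFAULTS.smoothing_fwhm_mm,
                    clip: bool = True) -> VolumeImage:
    """Separable Gaussian smoothing with a FWHM given in millimetres
    (sigma scaled per axis by voxel size); reflect boundary handling.
    Probability maps are re-clipped to [0, 1]."""
    if fwhm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm == 0:
        return VolumeImage(vol.data.copy(), vol.voxel_size, vol.affine.copy())
    sigma_vox = [fwhm_to_sigma(fwhm) / v for v in vol.voxel_size]
    sm = ndimage.gaussian_filter(vol.data.astype(float), sigma=sigma_vox,
                                 mode="reflect")
    if clip:
        sm = np.clip(sm, 0.0, 1.0)
    return VolumeImage(sm, vol.voxel_size, vol.affine.copy())


def roi_density(vol: VolumeImage, roi: ROISpec) -> float:
    """Mean value inside the ROI box; rejects out-of-bounds boxes rather
    than silently cropping."""
    sl = roi.slices(vol.data.shape)
    return float(np.asarray(vol.data[sl], dtype=float).mean())


@dataclass
class TMapResult:
    t_map: np.ndarray              # NaN where variance is zero
    mask: np.ndarray               # suprathreshold (two-tailed) boolean
    labels: np.ndarray             # 26-connectivity cluster labels
    clusters: pd.DataFrame         # label, size_voxels, peak_t, peak_voxel
    t_critical: float
    df: int


def voxelwise_two_sample_t(group_a: Sequence[VolumeImage],
                           group_b: Sequence[VolumeImage],
                           alpha: float = DEFAULTS.vbm_alpha) -> TMapResult:
    """Per-voxel pooled-variance two-sample t statistic with an
    uncorrected two-tailed threshold and 26-connectivity cluster table."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 volumes per group")
    shapes = {v.data.shape for v in list(group_a) + list(group_b)}
    if len(shapes) != 1:
        raise ValueError("volume grids do not match")
    a = np.stack([v.data.astype(float) for v in group_a])
    b = np.stack([v.data.astype(float) for v in group_b])
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    t[denom == 0] = np.nan

    t_crit = float(sstats.t.isf(alpha / 2.0, df))
    mask = np.isfinite(t) & (np.abs(t) >= t_crit)
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    rows = []
    for lab in range(1, n_lab + 1):
        idx = labels == lab
        tv = t[idx]
        peak_flat = np.nanargmax(np.abs(np.where(idx, t, 0.0)))
        rows.append({"label": lab, "size_voxels": int(idx.sum()),
                     "peak_t": float(tv[np.argmax(np.abs(tv))]),
                     "peak_voxel": tuple(int(i) for i in
                                         np.unravel_index(peak_flat, t.shape))})
    clusters = pd.DataFrame(rows, columns=["label", "size_voxels",
                                           "peak_t", "peak_voxel"])
    return TMapResult(t_map=t, mask=mask, labels=labels, clusters=clusters,
                      t_critical=t_crit, df=df)


def laterality_contrast(left: Sequence[float], right: Sequence[float],
                        subject_ids: Optional[Sequence[str]] = None):
    """Per-subject left-minus-right density differences plus the paired
    Wilcoxon signed-rank test (test omitted when n < 2, differences still
    reported)."""
    from .stats import wilcoxon_signed_rank

    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size != right.size:
        raise ValueError("left/right lengths differ")
    keep = np.isfinite(left) & np.isfinite(right)
    dropped = int((~keep).sum())
    diffs = left[keep] - right[keep]
    test = wilcoxon_signed_rank(diffs) if diffs.size >= 2 else None
    return {"differences": diffs, "n_dropped": dropped, "test": test}
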