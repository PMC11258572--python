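"""Global GM/WM aTSC by PSF-aware partial-volume linear regression.

Each sodium voxel mixes grey matter, white matter and CSF.  With the tissue
fractions re-gridded to the sodium resolution and convolved with the same
PSF that blurred the acquisition, the calibrated concentration at voxel v
obeys (up to noise)

    c_v - f_csf,v * c_CSF = f_gm,v * aTSC_GM + f_wm,v * aTSC_WM

and the two global unknowns are solved by ordinary least squares over all
brain voxels.  CSF enters as a fixed 140 mM term subtracted from the
observations by default; a three-unknown variant leaves it free.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from nibabel.processing import resample_from_to
from scipy.signal import fftconvolve

from .calibration import SodiumImage
from .phantom import TissueFractionMaps, block_average, lores_affine

__all__ = [
    "GlobalATSC",
    "regrid_fractions",
    "smooth_fractions",
    "solve_global_atsc",
    "normalized_ventricular_volume",
]

MAX_CONDITION = 1e8


@dataclass(frozen=True)
class GlobalATSC:
    """Two-unknown regression estimate with fit diagnostics."""

    atsc_gm: float
    atsc_wm: float
    n_voxels_used: int
    residual_rms: float
    design_condition_number: float
    atsc_csf: float | None = None  # only set by the three-unknown variant

    def __post_init__(self) -> None:
        if not (np.isfinite(self.atsc_gm) and np.isfinite(self.atsc_wm)):
            raise ValueError("aTSC estimates must be finite")
        if self.n_voxels_used < 2:
            raise ValueError("need at least 2 voxels")
        if self.design_condition_number <= 0:
            raise ValueError("condition number must be positive")


# --------------------------------------------------------------------------
# re-gridding
# --------------------------------------------------------------------------

def _nested_factors(src_affine, dst_affine, src_shape, dst_shape):
    """Integer block factors if dst grid exactly block-averages src, else None."""
    A, B = np.asarray(src_affine), np.asarray(dst_affine)
    f = []
    for i in range(3):
        if dst_shape[i] == 0 or src_shape[i] % dst_shape[i]:
            return None
        f.append(src_shape[i] // dst_shape[i])
    expect = lores_affine(A, tuple(f))
    if np.allclose(expect, B, atol=1e-6):
        return tuple(f)
    return None


def _bbox_world(shape, affine):
    corners = np.array(
        [[i, j, k, 1] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
    ).T
    w = (np.asarray(affine) @ corners)[:3]
    return w.min(axis=1), w.max(axis=1)


def regrid_fractions(
    fractions: TissueFractionMaps,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
) -> TissueFractionMaps:
    """Volume-weighted re-gridding of fraction maps onto a target grid.

    Exactly nested grids use block averaging (conserves total tissue volume
    to floating point); otherwise trilinear resampling in world space.
    Rejects grids with disjoint fields of view.
    """
    lo1, hi1 = _bbox_world(fractions.grid_shape, fractions.affine)
    lo2, hi2 = _bbox_world(target_shape, target_affine)
    if np.any(hi1 < lo2) or np.any(hi2 < lo1):
        raise ValueError("source and target fields of view are disjoint")

    factors = _nested_factors(
        fractions.affine, target_affine, fractions.grid_shape, target_shape
    )
    if factors is not None:
        out = TissueFractionMaps(
            f_gm=block_average(fractions.f_gm, factors),
            f_wm=block_average(fractions.f_wm, factors),
            f_csf=block_average(fractions.f_csf, factors),
            affine=np.asarray(target_affine, dtype=float),
        )
    else:
        fields = []
        target = nib.Nifti1Image(np.zeros(target_shape), np.asarray(target_affine, dtype=float))
        for f in (fractions.f_gm, fractions.f_wm, fractions.f_csf):
            img = nib.Nifti1Image(f.astype(np.float64), fractions.affine)
            res = resample_from_to(img, target, order=1, mode="nearest")
            fields.append(np.clip(np.asarray(res.dataobj, dtype=float), 0.0, 1.0))
        out = TissueFractionMaps(*fields, affine=np.asarray(target_affine, dtype=float))
    out.validate(atol=1e-7)
    return out


def smooth_fractions(
    fractions: TissueFractionMaps, kernel: np.ndarray
) -> TissueFractionMaps:
    """Convolve each fraction field with a normalized PSF kernel.

    Edge-padded convolution with a unit-sum kernel is a convex combination
    of in-field values, so the fraction invariants are preserved.
    """
    if abs(kernel.sum() - 1.0) > 1e-9:
        raise ValueError("kernel must be normalized to unit sum")
    pads = tuple((s // 2, s // 2) for s in kernel.shape)

    def conv(f):
        return fftconvolve(np.pad(f, pads, mode="edge"), kernel, mode="valid")

    out = TissueFractionMaps(
        f_gm=conv(fractions.f_gm),
        f_wm=conv(fractions.f_wm),
        f_csf=conv(fractions.f_csf),
        affine=fractions.affine.copy(),
    )
    out.validate(atol=1e-7)
    return out


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------

def solve_global_atsc(
    image: SodiumImage,
    fractions: TissueFractionMaps,
    csf_mM: float = 140.0,
    mask_threshold: float = 0.5,
    mask: np.ndarray | None = None,
    csf_free: bool = False,
) -> GlobalATSC:
    """Least-squares solve for global GM and WM aTSC.

    ``mask`` overrides the default inclusion rule f_gm+f_wm+f_csf >=
    ``mask_threshold`` (which excludes background and eyes).  ``csf_free``
    switches to the three-unknown variant in which the CSF concentration is
    estimated instead of fixed.
    """
    if image.data.shape != fractions.grid_shape:
        raise ValueError("image and fractions must share a grid")
    if mask is None:
        mask = fractions.total >= mask_threshold
    mask = mask & np.isfinite(image.data)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no voxels pass the inclusion mask")

    cols = [fractions.f_gm[mask], fractions.f_wm[mask]]
    if csf_free:
        cols.append(fractions.f_csf[mask])
        y = image.data[mask]
    else:
        y = image.data[mask] - csf_mM * fractions.f_csf[mask]
    design = np.stack(cols, axis=1)

    sv = np.linalg.svd(design, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ValueError(
            f"rank-deficient partial-volume design (condition number {cond:.3g}); "
            "GM and WM fractions do not separate the two unknowns"
        )

    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return GlobalATSC(
        atsc_gm=float(coef[0]),
        atsc_wm=float(coef[1]),
        n_voxels_used=n,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        design_condition_number=cond,
        atsc_csf=float(coef[2]) if csf_free else None,
    )


def normalized_ventricular_volume(
    left_mm3: float, right_mm3: float, etiv_mm3: float
) -> float:
    """Bilateral ventricular volume normalized to total intracranial volume."""
    if etiv_mm3 <= 0:
        raise ValueError("eTIV must be positive")
    if left_mm3 < 0 or right_mm3 < 0:
        raise ValueError("ventricular volumes must be non-negative")
    return (left_mm3 + right_mm3) / etiv_mm3
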