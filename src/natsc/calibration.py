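"""Signal-to-concentration calibration via two internal anchors.

The sodium image is calibrated with a straight line through two anchor
points: the standard deviation of the background noise maps to 0 mM, and
the vitreous-humour reference signal maps to 140 mM.  The module offers two
ways to obtain the eye reference signal:

* a plain ROI statistic (mean or median) over the declared eye voxels --
  the conventional scheme for real acquisitions, where the eyes sit in
  signal-bearing orbital tissue; and
* a partial-volume-corrected reference that regresses the measured signal
  on the PSF-blurred eye occupancy (plus a pooled brain-spill regressor),
  recovering the signal a *pure* vitreous voxel would have.  With a
  heavy-tailed readout PSF and an isolated synthetic eye the plain ROI mean
  is substantially depressed, so quantitative phantom work should use the
  corrected reference.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .phantom import RawSodiumVolume

__all__ = [
    "CalibrationModel",
    "estimate_noise_sd",
    "eye_reference_signal",
    "fit_calibration",
    "apply_calibration",
    "SodiumImage",
]

REFERENCE_MM = 140.0  # vitreous humour sodium concentration


@dataclass
class SodiumImage:
    """Calibrated concentration volume (mM) with provenance metadata."""

    data: np.ndarray
    affine: np.ndarray
    meta: dict


@dataclass(frozen=True)
class CalibrationModel:
    """Line through (noise_sd, 0 mM) and (eye_mean, 140 mM)."""

    slope: float       # mM per signal unit
    intercept: float   # mM
    noise_sd: float    # signal units
    eye_mean: float    # signal units

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if abs(self.slope * self.eye_mean + self.intercept - REFERENCE_MM) > 1e-9 * REFERENCE_MM:
            raise ValueError("model does not map the eye anchor to 140 mM")
        if abs(self.slope * self.noise_sd + self.intercept) > 1e-9 * REFERENCE_MM:
            raise ValueError("model does not map the noise anchor to 0 mM")

    def __call__(self, signal: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(signal, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_noise_sd(volume: RawSodiumVolume) -> float:
    """Sample SD (n-1 denominator) of the signal over the background region."""
    vals = volume.signal[volume.background_region]
    if vals.size < 2:
        raise ValueError("background region must contain at least 2 voxels")
    return float(np.std(vals, ddof=1))


def eye_reference_signal(
    volume: RawSodiumVolume,
    statistic: str = "mean",
    eye_weights: np.ndarray | None = None,
    spill_weights: np.ndarray | None = None,
) -> float:
    """Eye reference signal in raw units.

    Without weights: the ROI ``statistic`` (mean/median) over the declared
    eye voxels.  With ``eye_weights`` (PSF-blurred eye occupancy at image
    resolution): the least-squares signal per unit occupancy, optionally
    with a pooled brain-spill column (PSF-blurred total brain occupancy),
    which removes both the partial-volume depression of the eye and
    contamination from nearby brain signal.
    """
    mask = volume.eye_mask
    if not mask.any():
        raise ValueError("no eye voxels declared")
    if eye_weights is None:
        vals = volume.signal[mask]
        if statistic == "mean":
            return float(vals.mean())
        if statistic == "median":
            return float(np.median(vals))
        raise ValueError(f"unknown statistic {statistic!r}")

    w = eye_weights.sum(axis=0) if eye_weights.ndim == 4 else eye_weights
    cols = [w[mask]]
    if spill_weights is not None:
        cols.append(spill_weights[mask])
    design = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(design, volume.signal[mask], rcond=None)
    if coef[0] <= 0:
        raise ValueError("eye reference regression produced a non-positive signal")
    return float(coef[0])


def fit_calibration(noise_sd: float, eye_mean: float) -> CalibrationModel:
    """Unique line through the two anchors (noise_sd -> 0, eye_mean -> 140)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if eye_mean <= noise_sd:
        raise ValueError(
            "eye reference signal must exceed the background noise SD; "
            "the internal reference is unusable"
        )
    slope = REFERENCE_MM / (eye_mean - noise_sd)
    return CalibrationModel(
        slope=slope, intercept=-slope * noise_sd, noise_sd=noise_sd, eye_mean=eye_mean
    )


def apply_calibration(
    volume: RawSodiumVolume, model: CalibrationModel, clamp_negative: bool = True
) -> SodiumImage:
    """Voxelwise affine mapping of signal to mM."""
    data = model(volume.signal)
    if clamp_negative:
        data = np.maximum(data, 0.0)
    return SodiumImage(
        data=data,
        affine=volume.affine.copy(),
        meta={"calibration": model.to_dict(), "clamp_negative": clamp_negative},
    )
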