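"""Synthetic sodium-MRI phantom: tissue-fraction maps, PSF model, acquisition.

The phantom is a nested-ellipsoid head: a white-matter core containing two
ellipsoidal ventricles (CSF), wrapped in a cortical grey-matter shell and a
thin subarachnoid CSF rim, plus two spherical eyes (vitreous humour, 140 mM)
placed outside the brain.  Geometry is deliberately non-anatomical: the
downstream estimator only ever sees per-voxel tissue fractions and voxel
intensities, so nested ellipsoids exercise exactly the same partial-volume
structure as a segmented head would.

The acquisition model is image-level: the ground-truth concentration volume
is convolved with the point-spread function implied by mono-exponential T2
signal decay during the readout, block-averaged down to the nominal sodium
resolution (6 mm), scaled to arbitrary signal units, and corrupted with
Rician (magnitude) noise.  No k-space trajectory is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.fft import fftfreq, fftshift, ifftn
from scipy.signal import fftconvolve

__all__ = [
    "PhantomTruth",
    "TissueFractionMaps",
    "RawSodiumVolume",
    "PhantomGeometry",
    "Ellipsoid",
    "build_psf_kernel",
    "kernel_fwhm_mm",
    "generate_phantom",
    "eye_occupancy",
    "simulate_acquisition",
    "simulate_study",
    "StudyImages",
    "block_average",
    "lores_affine",
    "default_affine",
    "parenchymal_noise_sigma",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth tissue concentrations and acquisition parameters.

    Concentrations are in mM.  CSF and vitreous humour default to 140 mM,
    the standard internal-reference value.  ``t2_ms`` is the mono-exponential
    transverse relaxation time shaping the PSF; ``readout_ms`` the effective
    readout duration over which the decay acts (a typical 3-hub FLORET
    readout is ~36 ms).  ``gain`` converts mM to raw signal units so that
    calibration has real work to do.
    """

    c_gm: float = 35.0
    c_wm: float = 30.0
    c_csf: float = 140.0
    c_eye: float = 140.0
    hi_res_voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lo_res_voxel_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    t2_ms: float = 56.0
    readout_ms: float = 36.3
    noise_sigma: float = 0.0
    noise_model: str = "rician"  # rician | gaussian | none
    gain: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c_gm", "c_wm", "c_csf", "c_eye"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.t2_ms <= 0:
            raise ValueError("t2_ms must be positive")
        if any(v <= 0 for v in self.hi_res_voxel_mm + self.lo_res_voxel_mm):
            raise ValueError("voxel sizes must be positive")
        if any(lo < hi for hi, lo in zip(self.hi_res_voxel_mm, self.lo_res_voxel_mm)):
            raise ValueError("lo-res voxel must be >= hi-res voxel componentwise")
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class TissueFractionMaps:
    """Per-voxel GM/WM/CSF volume fractions on a shared grid with an affine."""

    f_gm: np.ndarray
    f_wm: np.ndarray
    f_csf: np.ndarray
    affine: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.f_gm.shape)

    def validate(self, atol: float = 1e-9) -> None:
        if not (self.f_gm.shape == self.f_wm.shape == self.f_csf.shape):
            raise ValueError("fraction fields must share a grid shape")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        for name, f in (("f_gm", self.f_gm), ("f_wm", self.f_wm), ("f_csf", self.f_csf)):
            if f.min() < -atol or f.max() > 1 + atol:
                raise ValueError(f"{name} outside [0, 1]")
        total = self.f_gm + self.f_wm + self.f_csf
        if total.max() > 1 + 1e-9 + atol:
            raise ValueError("fraction triple-sum exceeds 1")

    @property
    def total(self) -> np.ndarray:
        return self.f_gm + self.f_wm + self.f_csf


@dataclass
class RawSodiumVolume:
    """Uncalibrated sodium magnitude image with declared reference regions.

    ``background_region`` and ``eye_regions`` are boolean masks on the image
    grid; the background defaults to a 560-voxel corner box, the eyes to the
    voxels dominated by each vitreous sphere.
    """

    signal: np.ndarray
    affine: np.ndarray
    background_region: np.ndarray
    eye_regions: tuple[np.ndarray, np.ndarray]

    def validate(self) -> None:
        if self.signal.min() < 0:
            raise ValueError("magnitude signal must be non-negative")
        masks = [self.background_region, *self.eye_regions]
        for m in masks:
            if m.shape != self.signal.shape or m.dtype != bool:
                raise ValueError("region masks must be boolean on the image grid")
        if np.any(self.background_region & (self.eye_regions[0] | self.eye_regions[1])):
            raise ValueError("background and eye regions must be disjoint")
        if np.any(self.eye_regions[0] & self.eye_regions[1]):
            raise ValueError("eye regions must be disjoint")

    @property
    def eye_mask(self) -> np.ndarray:
        return self.eye_regions[0] | self.eye_regions[1]


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PhantomGeometry:
    """Nested-ellipsoid head geometry in world millimetres.

    The brain is the ordered nest outer-CSF > GM shell > WM core, with
    ventricles inside the WM core; eyes must not intersect the outer CSF
    envelope.  ``transition_mm`` is the width of the soft partial-volume
    boundary between compartments.
    """

    fov_mm: tuple[float, float, float] = (192.0, 192.0, 192.0)
    outer_csf: Ellipsoid = Ellipsoid((0.0, -6.0, 0.0), (62.0, 72.0, 56.0))
    gm_shell: Ellipsoid = Ellipsoid((0.0, -6.0, 0.0), (57.0, 67.0, 51.0))
    wm_core: Ellipsoid = Ellipsoid((0.0, -6.0, 0.0), (42.0, 50.0, 38.0))
    ventricles: tuple[Ellipsoid, ...] = (
        Ellipsoid((-11.0, 4.0, 2.0), (7.0, 16.0, 9.0)),
        Ellipsoid((11.0, 4.0, 2.0), (7.0, 16.0, 9.0)),
    )
    eyes: tuple[Ellipsoid, Ellipsoid] = (
        Ellipsoid((-30.0, 84.0, -8.0), (11.0, 11.0, 11.0)),
        Ellipsoid((30.0, 84.0, -8.0), (11.0, 11.0, 11.0)),
    )
    transition_mm: float = 2.0
    background_box: tuple[int, int, int] = (10, 8, 7)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.fov_mm):
            raise ValueError("field of view must be positive")
        if self.transition_mm <= 0:
            raise ValueError("transition width must be positive")
        nb = self.background_box
        if len(nb) != 3 or any(n <= 0 for n in nb):
            raise ValueError("background box must be a positive integer triple")

    def scaled_ventricles(self, factor: float) -> "PhantomGeometry":
        """Return a geometry with ventricle semi-axes scaled by ``factor``."""
        vents = tuple(
            Ellipsoid(v.center_mm, tuple(a * factor ** (1 / 3) for a in v.semiaxes_mm))
            for v in self.ventricles
        )
        return replace(self, ventricles=vents)


def default_affine(shape: tuple[int, ...], voxel_mm: tuple[float, ...]) -> np.ndarray:
    """World-centred RAS affine: voxel (0,0,0) sits at -(n-1)/2 * voxel."""
    aff = np.eye(4)
    for i in range(3):
        aff[i, i] = voxel_mm[i]
        aff[i, 3] = -(shape[i] - 1) / 2 * voxel_mm[i]
    return aff


def lores_affine(hi_affine: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Affine of the block-averaged grid given the hi-res affine."""
    lo = hi_affine.copy()
    f = np.asarray(factors, dtype=float)
    lo[:3, :3] = hi_affine[:3, :3] * f
    lo[:3, 3] = hi_affine[:3, 3] + hi_affine[:3, :3] @ ((f - 1) / 2)
    return lo


def _world_coords(shape: tuple[int, ...], affine: np.ndarray) -> tuple[np.ndarray, ...]:
    axes = [np.arange(n) for n in shape]
    I, J, K = np.meshgrid(*axes, indexing="ij")
    M, t = affine[:3, :3], affine[:3, 3]
    X = M[0, 0] * I + M[0, 1] * J + M[0, 2] * K + t[0]
    Y = M[1, 0] * I + M[1, 1] * J + M[1, 2] * K + t[1]
    Z = M[2, 0] * I + M[2, 1] * J + M[2, 2] * K + t[2]
    return X, Y, Z


def _occupancy(ell: Ellipsoid, coords, transition_mm: float) -> np.ndarray:
    """Soft [0,1] occupancy of an ellipsoid with a linear boundary ramp."""
    X, Y, Z = coords
    cx, cy, cz = ell.center_mm
    ax, ay, az = ell.semiaxes_mm
    r = np.sqrt(((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2)
    # approximate signed distance to the surface in mm
    d = (r - 1.0) * min(ell.semiaxes_mm)
    return np.clip(0.5 - d / transition_mm, 0.0, 1.0)


# --------------------------------------------------------------------------
# PSF
# --------------------------------------------------------------------------

def build_psf_kernel(
    t2_ms: float,
    readout_ms: float,
    voxel_mm: tuple[float, float, float],
    kernel_mode: str = "exponential_kspace",
    kernel_shape: tuple[int, int, int] = (31, 31, 31),
    kmax_cycles_per_mm: float | None = None,
) -> np.ndarray:
    """PSF kernel from mono-exponential T2 decay during the readout.

    In ``exponential_kspace`` mode the kernel is the inverse transform of a
    radially symmetric k-space weighting ``exp(-t(k)/T2)`` with the sampling
    time ``t(k)`` linear from 0 at the k-space centre to ``readout_ms`` at
    ``kmax`` (by default the Nyquist radius of the target resolution along
    the coarsest axis).  ``gaussian`` mode returns an isotropic Gaussian
    whose FWHM matches the exponential kernel's main lobe.  Either way the
    kernel is normalized to unit sum and symmetric under axis reflection.
    """
    if t2_ms <= 0:
        raise ValueError("t2_ms must be positive")
    if readout_ms < 0:
        raise ValueError("readout_ms must be non-negative")
    if any(n % 2 == 0 or n < 3 for n in kernel_shape):
        raise ValueError("kernel_shape entries must be odd and >= 3")
    if kernel_mode not in ("exponential_kspace", "gaussian"):
        raise ValueError(f"unknown kernel_mode {kernel_mode!r}")

    if kmax_cycles_per_mm is None:
        kmax_cycles_per_mm = 1.0 / (2.0 * max(voxel_mm))

    if kernel_mode == "gaussian":
        fwhm = kernel_fwhm_mm(t2_ms, readout_ms, voxel_mm, kmax_cycles_per_mm)
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        parts = []
        for n, v in zip(kernel_shape, voxel_mm):
            x = (np.arange(n) - n // 2) * v
            parts.append(np.exp(-0.5 * (x / sigma) ** 2))
        ker = parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]
        return ker / ker.sum()

    ks = [fftfreq(n, d=v) for n, v in zip(kernel_shape, voxel_mm)]
    KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
    kr = np.sqrt(KX**2 + KY**2 + KZ**2)
    t_of_k = readout_ms * kr / kmax_cycles_per_mm
    weights = np.exp(-t_of_k / t2_ms)
    ker = np.real(fftshift(ifftn(weights)))
    ker /= ker.sum()
    return ker


def kernel_fwhm_mm(
    t2_ms: float,
    readout_ms: float,
    voxel_mm: tuple[float, float, float],
    kmax_cycles_per_mm: float | None = None,
    oversample: int = 5,
) -> float:
    """Main-lobe FWHM (mm) of the exponential-decay PSF along the first axis.

    Measured on an oversampled rendering of the same k-space weighting so
    sub-voxel widths are resolved.
    """
    if kmax_cycles_per_mm is None:
        kmax_cycles_per_mm = 1.0 / (2.0 * max(voxel_mm))
    fine_vox = tuple(v / oversample for v in voxel_mm)
    n = 31 * oversample
    n += 1 - n % 2  # odd
    ker = build_psf_kernel(
        t2_ms, readout_ms, fine_vox, "exponential_kspace", (n, n, n), kmax_cycles_per_mm
    )
    c = n // 2
    profile = ker[c:, c, c]
    half = profile[0] / 2.0
    below = np.nonzero(profile < half)[0]
    if below.size == 0:
        raise ValueError("kernel support too small to measure FWHM")
    i = below[0]
    # linear interpolation between samples i-1 and i
    p0, p1 = profile[i - 1], profile[i]
    frac = (p0 - half) / (p0 - p1)
    return 2.0 * (i - 1 + frac) * fine_vox[0]


# --------------------------------------------------------------------------
# phantom generation
# --------------------------------------------------------------------------

def _grid_from(geometry: PhantomGeometry, truth: PhantomTruth):
    shape = []
    for fov, v in zip(geometry.fov_mm, truth.hi_res_voxel_mm):
        n = fov / v
        if abs(n - round(n)) > 1e-6:
            raise ValueError("field of view must be an integer number of hi-res voxels")
        shape.append(int(round(n)))
    shape = tuple(shape)
    return shape, default_affine(shape, truth.hi_res_voxel_mm)


def generate_phantom(
    geometry: PhantomGeometry, truth: PhantomTruth
) -> tuple[TissueFractionMaps, np.ndarray]:
    """Build fraction maps and the ground-truth concentration volume.

    The concentration at each voxel is the fraction-weighted sum of tissue
    concentrations, with eye voxels at ``c_eye`` and background at zero.
    Deterministic given its arguments.
    """
    shape, affine = _grid_from(geometry, truth)
    coords = _world_coords(shape, affine)
    w = geometry.transition_mm

    o_out = _occupancy(geometry.outer_csf, coords, w)
    o_gm = np.minimum(_occupancy(geometry.gm_shell, coords, w), o_out)
    o_wm = np.minimum(_occupancy(geometry.wm_core, coords, w), o_gm)
    o_vent = np.zeros(shape)
    for v in geometry.ventricles:
        o_vent = np.maximum(o_vent, _occupancy(v, coords, w))
    o_vent = np.minimum(o_vent, o_wm)

    fractions = TissueFractionMaps(
        f_gm=o_gm - o_wm,
        f_wm=o_wm - o_vent,
        f_csf=o_vent + (o_out - o_gm),
        affine=affine,
    )
    fractions.validate()

    eye = eye_occupancy(geometry, truth)
    if np.max(eye.sum(axis=0) + o_out) > 1.0 + 1e-6:
        raise ValueError("eye geometry overlaps the brain envelope")

    conc = (
        fractions.f_gm * truth.c_gm
        + fractions.f_wm * truth.c_wm
        + fractions.f_csf * truth.c_csf
        + eye.sum(axis=0) * truth.c_eye
    )
    return fractions, conc


def eye_occupancy(geometry: PhantomGeometry, truth: PhantomTruth) -> np.ndarray:
    """Per-eye soft occupancy fields on the hi-res grid, stacked (2, ...)."""
    shape, affine = _grid_from(geometry, truth)
    coords = _world_coords(shape, affine)
    return np.stack(
        [_occupancy(e, coords, geometry.transition_mm) for e in geometry.eyes]
    )


# --------------------------------------------------------------------------
# acquisition
# --------------------------------------------------------------------------

def block_average(field: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Exact block-average downsampling by integer factors per axis."""
    for n, f in zip(field.shape, factors):
        if f < 1 or n % f:
            raise ValueError(
                f"grid shape {field.shape} is not an integer multiple of factors {factors}; "
                "choose a lo-res voxel that is an integer multiple of the hi-res voxel"
            )
    n0, n1, n2 = (n // f for n, f in zip(field.shape, factors))
    f0, f1, f2 = factors
    return field.reshape(n0, f0, n1, f1, n2, f2).mean(axis=(1, 3, 5))


def _blur(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Edge-padded convolution: preserves constants exactly (up to fp)."""
    pads = tuple((s // 2, s // 2) for s in kernel.shape)
    return fftconvolve(np.pad(field, pads, mode="edge"), kernel, mode="valid")


def _downsample_factors(truth: PhantomTruth) -> tuple[int, int, int]:
    factors = []
    for hi, lo in zip(truth.hi_res_voxel_mm, truth.lo_res_voxel_mm):
        f = lo / hi
        if abs(f - round(f)) > 1e-9:
            raise ValueError(
                f"lo-res voxel {lo} mm is not an integer multiple of hi-res {hi} mm; "
                "block-averaging requires nested grids"
            )
        factors.append(int(round(f)))
    return tuple(factors)


def background_corner_mask(
    shape: tuple[int, int, int], box: tuple[int, int, int]
) -> np.ndarray:
    """Corner box of exactly prod(box) voxels, anchored at index (0, 0, 0)."""
    if any(b > n for b, n in zip(box, shape)):
        raise ValueError(f"background box {box} does not fit in grid {shape}")
    m = np.zeros(shape, dtype=bool)
    m[: box[0], : box[1], : box[2]] = True
    return m


def simulate_acquisition(
    concentration_field: np.ndarray,
    truth: PhantomTruth,
    *,
    eye_regions: tuple[np.ndarray, np.ndarray],
    background_region: np.ndarray | None = None,
    background_box: tuple[int, int, int] = (10, 8, 7),
    hi_affine: np.ndarray | None = None,
    kernel_mode: str = "exponential_kspace",
    kernel_shape: tuple[int, int, int] = (31, 31, 31),
) -> RawSodiumVolume:
    """Forward model: PSF blur, block-average, gain, magnitude noise.

    The PSF is built on the hi-res grid with ``kmax`` at the nominal (lo-res)
    Nyquist radius, so the decay weighting matches the kernel a downstream
    consumer would build at the sodium resolution.
    """
    factors = _downsample_factors(truth)
    kmax = 1.0 / (2.0 * max(truth.lo_res_voxel_mm))
    kernel = build_psf_kernel(
        truth.t2_ms, truth.readout_ms, truth.hi_res_voxel_mm,
        kernel_mode, kernel_shape, kmax,
    )
    blurred = _blur(concentration_field, kernel)
    lo = block_average(blurred, factors)
    signal = truth.gain * lo

    rng = np.random.default_rng(truth.seed)
    if truth.noise_sigma > 0 and truth.noise_model == "rician":
        n_re = rng.normal(0.0, truth.noise_sigma, signal.shape)
        n_im = rng.normal(0.0, truth.noise_sigma, signal.shape)
        signal = np.sqrt((signal + n_re) ** 2 + n_im**2)
    elif truth.noise_sigma > 0 and truth.noise_model == "gaussian":
        signal = signal + rng.normal(0.0, truth.noise_sigma, signal.shape)

    if hi_affine is None:
        hi_affine = default_affine(concentration_field.shape, truth.hi_res_voxel_mm)
    affine = lores_affine(hi_affine, factors)

    if background_region is None:
        background_region = background_corner_mask(signal.shape, background_box)
    vol = RawSodiumVolume(
        signal=np.abs(signal),
        affine=affine,
        background_region=background_region,
        eye_regions=eye_regions,
    )
    vol.validate()
    return vol


@dataclass
class StudyImages:
    """Bundle of everything a single simulated imaging session produces."""

    fractions: TissueFractionMaps          # hi-res
    concentration: np.ndarray              # hi-res ground truth, mM
    raw: RawSodiumVolume                   # lo-res magnitude image
    eye_weights: np.ndarray                # (2, lo-res): PSF-blurred eye occupancy
    truth: PhantomTruth
    geometry: PhantomGeometry


def simulate_study(
    geometry: PhantomGeometry,
    truth: PhantomTruth,
    kernel_mode: str = "exponential_kspace",
    kernel_shape: tuple[int, int, int] = (31, 31, 31),
) -> StudyImages:
    """Phantom + acquisition with all reference regions wired up."""
    fractions, conc = generate_phantom(geometry, truth)
    eyes_hi = eye_occupancy(geometry, truth)
    factors = _downsample_factors(truth)
    kmax = 1.0 / (2.0 * max(truth.lo_res_voxel_mm))
    kernel = build_psf_kernel(
        truth.t2_ms, truth.readout_ms, truth.hi_res_voxel_mm,
        kernel_mode, kernel_shape, kmax,
    )
    eye_weights = np.stack(
        [block_average(_blur(e, kernel), factors) for e in eyes_hi]
    )
    eye_masks = tuple(w > 0.3 for w in eye_weights)
    raw = simulate_acquisition(
        conc, truth,
        eye_regions=eye_masks,
        background_box=geometry.background_box,
        hi_affine=fractions.affine,
        kernel_mode=kernel_mode,
        kernel_shape=kernel_shape,
    )
    return StudyImages(fractions, conc, raw, eye_weights, truth, geometry)


def parenchymal_noise_sigma(
    fractions: TissueFractionMaps, truth: PhantomTruth, level: float = 0.05
) -> float:
    """Noise SD as a fraction of the mean parenchymal (GM+WM) signal.

    Uses the volume-weighted mean tissue concentration times the gain, a
    closed-form quantity independent of any simulated image.
    """
    v_gm = float(fractions.f_gm.sum())
    v_wm = float(fractions.f_wm.sum())
    mean_c = (v_gm * truth.c_gm + v_wm * truth.c_wm) / (v_gm + v_wm)
    return level * truth.gain * mean_c
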