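"""Full-field screening for magnetically modulated objects.

A time-resolved hologram sequence is drift-corrected, reconstructed over a
depth grid, and scanned for periodic motion with the computational motion
analysis (CMA) contrast

    C(z_j) = 1/(N_F - N) * sum_i ( 1/2 |B_i - B_{i+N/2}|
                                 + 1/2 |B_{i+N/2} - B_{i+N}|
                                 -     |B_i - B_{i+N}| )

where N is the number of frames per modulation period.  Objects that
oscillate at the drive frequency make large half-period differences and a
small whole-period difference, so C is large and positive at their
locations; static content cancels exactly, and monotonically moving content
(drift, Brownian walkers on average) gives C <= 0 by the triangle
inequality.  A maximum intensity projection D(x, y) = max_z C(x, y; z)
flattens the volume for threshold-based 2D candidate detection.

Coordinates are 0-based with x = column, y = row, origin at the top left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation

from .optics import ComplexField, DepthGrid, FilterSpec, filtered_backpropagate

__all__ = [
    "HologramVideo",
    "MotionContrastVolume",
    "ProjectionMap",
    "Candidate",
    "estimate_drift",
    "correct_drift",
    "reconstruct_video",
    "cma_contrast",
    "motion_contrast_volume",
    "project_max_intensity",
    "detect_candidates",
]


@dataclass
class HologramVideo:
    """An ordered stack of raw (or drift-corrected) hologram frames A_i."""

    frames: np.ndarray  # (N_F, H, W) real
    frame_rate: float = 26.7  # fps
    pixel_pitch: float = 1.67  # um
    wavelength: float = 0.65  # um
    modulation_period: float = 1.0  # s
    drift_corrected: bool = False

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError(f"frames must be (N_F, H, W), got {f.shape}")
        self.frames = f
        if self.frames_per_period % 2 or not (0 < self.frames_per_period < len(f)):
            raise ValueError(
                f"frames per period N={self.frames_per_period} must be even and < N_F={len(f)}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frames_per_period(self) -> int:
        """Nearest even integer to frame_rate * modulation_period.

        26.7 fps at a 1 s drive period gives 26.7 frames; the CMA sum needs
        an even integer, so N = 26 (a <=1.3% period mismatch).
        """
        n = self.frame_rate * self.modulation_period
        return int(2 * round(n / 2.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_field(self, i: int) -> ComplexField:
        return ComplexField(self.frames[i], self.pixel_pitch, self.wavelength)


@dataclass
class MotionContrastVolume:
    """3D CMA contrast map C(x, y; z), stored as (N_H, H, W)."""

    values: np.ndarray
    grid: DepthGrid

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[0] != len(self.grid):
            raise ValueError("values must be (N_H, H, W) matching the depth grid")
        self.values = v


@dataclass
class ProjectionMap:
    """Axial maximum intensity projection D(x, y) of a contrast volume."""

    values: np.ndarray


@dataclass
class Candidate:
    """A detected periodic-motion candidate (lateral position in pixels)."""

    x: float
    y: float
    area: int
    peak_score: float
    border_flag: bool = False
    z_coarse: float | None = None  # um, filled by focusing
    z_refined: float | None = None  # um

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


# ---------------------------------------------------------------------------
# drift correction


def estimate_drift(
    video: HologramVideo, reference_index: int | None = None, upsample_factor: int = 20
) -> np.ndarray:
    """Per-frame translation (dx, dy) of each frame relative to a reference.

    Uses phase correlation with correlation-peak upsampling (subpixel
    resolution 1/upsample_factor pixels).  The reference defaults to the
    middle frame; its own shift is exactly (0, 0).  Returned shifts are the
    displacement of each frame's content relative to the reference, i.e. a
    frame whose content sits 3 px to the right of the reference reports
    dx = +3.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate drift")
    if reference_index is None:
        reference_index = video.n_frames // 2
    ref = video.frames[reference_index].astype(np.float64)
    if np.ptp(ref) == 0:
        warnings.warn("reference frame is constant; drift estimation is degenerate",
                      RuntimeWarning, stacklevel=2)
        return np.zeros((video.n_frames, 2))
    shifts = np.zeros((video.n_frames, 2))
    for i, frame in enumerate(video.frames):
        if i == reference_index:
            continue
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {i} is constant; zero shift assumed",
                          RuntimeWarning, stacklevel=2)
            continue
        # phase_cross_correlation returns the (dy, dx) to APPLY to the moving
        # frame to align it with the reference; content displacement is the
        # negative of that.
        (dy, dx), _, _ = phase_cross_correlation(
            ref, frame.astype(np.float64), upsample_factor=upsample_factor,
        )
        shifts[i] = (-dx, -dy)
    return shifts


def correct_drift(
    video: HologramVideo, shifts: np.ndarray, axes: frozenset | set | tuple = ("x",)
) -> HologramVideo:
    """Resample each frame to undo the estimated drift along ``axes``.

    The default corrects the horizontal axis only (the tube axis along which
    the fluid drifts), leaving the vertical, magnetically driven motion
    untouched; pass ``axes={'x','y'}`` for full 2D correction.  Bilinear
    interpolation; samples falling outside the frame are filled with the
    frame mean.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (video.n_frames, 2):
        raise ValueError(f"expected {video.n_frames} (dx, dy) shifts, got {shifts.shape}")
    axes = set(axes)
    if not axes <= {"x", "y"}:
        raise ValueError("axes must be a subset of {'x', 'y'}")
    out = np.empty_like(video.frames)
    for i, frame in enumerate(video.frames):
        dx = shifts[i, 0] if "x" in axes else 0.0
        dy = shifts[i, 1] if "y" in axes else 0.0
        if dx == 0.0 and dy == 0.0:
            out[i] = frame
            continue
        # content displaced by (+dx, +dy) is moved back by (-dx, -dy)
        out[i] = ndimage.shift(
            frame, (-dy, -dx), order=1,
            mode="constant", cval=float(frame.mean()), prefilter=False,
        )
    corrected = replace(video, frames=out)
    corrected.drift_corrected = True
    return corrected


# ---------------------------------------------------------------------------
# CMA contrast


def reconstruct_video(
    video: HologramVideo,
    grid: DepthGrid,
    spec: FilterSpec | None = None,
    pad_factor: int = 2,
    sqrt_intensity: bool = False,
) -> np.ndarray:
    """Filtered back-propagation B_i(z_j) of every frame: (N_F, N_H, H, W)."""
    spec = spec or FilterSpec()
    h, w = video.shape
    out = np.empty((video.n_frames, len(grid), h, w), dtype=np.complex64)
    for i in range(video.n_frames):
        frame = ComplexField(video.frames[i].astype(np.float32), video.pixel_pitch, video.wavelength)
        out[i] = filtered_backpropagate(frame, grid, spec, pad_factor=pad_factor,
                                        sqrt_intensity=sqrt_intensity)
    return out


def _cma_plane(planes: np.ndarray, N: int) -> np.ndarray:
    """CMA average for one depth plane; ``planes`` is (N_F, H, W)."""
    half = N // 2
    m = planes.shape[0] - N
    a = planes[:m]
    b = planes[half : half + m]
    c = planes[N : N + m]
    acc = np.abs(a - b)
    acc += np.abs(b - c)
    acc *= 0.5
    acc -= np.abs(a - c)
    return acc.mean(axis=0, dtype=np.float64).astype(np.float32)


def cma_contrast(stacks: np.ndarray, N: int, grid: DepthGrid | None = None) -> MotionContrastVolume | np.ndarray:
    """Periodic-motion contrast of a reconstructed sequence.

    ``stacks`` holds the complex planes B_i(z_j) with frame index first,
    shape (N_F, N_H, H, W) (a (N_F, H, W) array is treated as a single
    plane).  ``N`` is the (even) number of frames per modulation period.
    Negative values are retained; they are meaningful (monotonic motion
    gives C <= 0) and are ignored naturally by the projection/threshold.

    Returns a MotionContrastVolume when ``grid`` is given, else the raw
    (N_H, H, W) array.
    """
    B = np.asarray(stacks)
    squeeze = B.ndim == 3
    if squeeze:
        B = B[:, None]
    if B.ndim != 4:
        raise ValueError("stacks must be (N_F, N_H, H, W)")
    n_f = B.shape[0]
    if N % 2 or not (0 < N < n_f):
        raise ValueError(f"N={N} must be even and satisfy 0 < N < N_F={n_f}")
    C = np.empty(B.shape[1:], dtype=np.float32)
    for j in range(B.shape[1]):  # per-plane to bound transient memory
        C[j] = _cma_plane(B[:, j], N)
    if squeeze:
        C = C[0] if grid is None else C
    if grid is not None:
        return MotionContrastVolume(values=C, grid=grid)
    return C


def motion_contrast_volume(
    video: HologramVideo,
    grid: DepthGrid,
    spec: FilterSpec | None = None,
    pad_factor: int = 2,
    sqrt_intensity: bool = False,
) -> MotionContrastVolume:
    """Fused reconstruction + CMA, one depth plane at a time.

    Numerically identical to ``cma_contrast(reconstruct_video(...), N)``
    (the per-frame forward FFT is shared, so each reconstructed plane is
    bit-for-bit the filtered back-propagation of that frame) but holds only
    one depth's worth of planes in memory, which keeps large fields of view
    within a few hundred MB instead of several GB.
    """
    from .optics import _as_transfer, _pad, high_pass_filter

    spec = spec or FilterSpec()
    N = video.frames_per_period
    h, w = video.shape
    # cache the forward FFT of every mean-subtracted, padded frame
    ffts = []
    window = None
    for i in range(video.n_frames):
        v = video.frames[i].astype(np.float32)
        if sqrt_intensity:
            v = np.sqrt(np.clip(v, 0, None))
        v = v.astype(np.complex64) - v.mean()
        padded, window = _pad(v, pad_factor)
        ffts.append(sfft.fft2(padded))

    C = np.empty((len(grid), h, w), dtype=np.float32)
    planes = np.empty((video.n_frames, h, w), dtype=np.complex64)
    for j, z in enumerate(grid.z_values):
        H = _as_transfer(ffts[0].shape, video.pixel_pitch, video.wavelength,
                         -float(z), np.complex64)
        for i in range(video.n_frames):
            plane = sfft.ifft2(ffts[i] * H)[window]
            planes[i] = high_pass_filter(
                ComplexField(plane, video.pixel_pitch, video.wavelength),
                spec, pad_factor=pad_factor,
            ).values
        C[j] = _cma_plane(planes, N)
    return MotionContrastVolume(values=C, grid=grid)


def project_max_intensity(volume: MotionContrastVolume) -> ProjectionMap:
    """Pointwise maximum of C over the axial direction."""
    return ProjectionMap(values=volume.values.max(axis=0))


# ---------------------------------------------------------------------------
# candidate detection


def detect_candidates(
    projection: ProjectionMap,
    threshold: float | None = None,
    kappa: float = 6.0,
    min_area: int = 4,
    border_margin: int = 32,
    closing_radius: int = 3,
) -> list[Candidate]:
    """Threshold-based segmentation of the projection map.

    The map is binarized at ``threshold`` if given, else adaptively at
    mean + kappa * std (default kappa = 6).  The binary mask is closed with
    a small disk (``closing_radius``; 0 disables) so that the lobed
    motion-contrast response of a single oscillating object — difference
    maps of a displaced pattern are dipole-like — segments as one component
    whose intensity-weighted centroid sits on the object.  8-connected
    components with at least ``min_area`` pixels become candidates;
    components whose bounding box comes within ``border_margin`` pixels of
    the frame edge are flagged (default 32 px, half the crop used
    downstream).
    """
    from skimage.morphology import closing as morph_closing, disk

    D = np.asarray(projection.values)
    if not np.all(np.isfinite(D)):
        raise ValueError("projection map must be finite")
    if threshold is None:
        threshold = float(D.mean() + kappa * D.std())
    mask = D > threshold
    if closing_radius > 0 and mask.any():
        mask = morph_closing(mask, disk(closing_radius))
    if not mask.any():
        return []
    labels = cc_label(mask, connectivity=2)
    h, w = D.shape
    out: list[Candidate] = []
    for region in regionprops(labels, intensity_image=D):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        r0, c0, r1, c1 = region.bbox
        near_border = (
            r0 < border_margin or c0 < border_margin
            or r1 > h - border_margin or c1 > w - border_margin
        )
        out.append(
            Candidate(
                x=float(cx), y=float(cy), area=int(region.area),
                peak_score=float(region.intensity_max), border_flag=bool(near_border),
            )
        )
    out.sort(key=lambda cand: -cand.peak_score)
    return out
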