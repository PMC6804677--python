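"""Synthetic magnetically modulated holographic speckle videos.

The generator renders time-resolved in-line holograms of a sparse scene of
scatterers suspended above the sensor, under a square-wave magnetic drive:

* ``oscillating_cell`` -- a bead-labelled cell: a weakly absorbing disk
  containing an asymmetric pattern of strongly scattering magnetic beads.
  The bead pattern rotates ("rolls") between two extremes following the
  square-wave drive with a first-order exponential relaxation, so the
  appearance as well as the position oscillates at the drive frequency.
* ``bead_chain`` -- a chain of unbound magnetic beads swinging between two
  angular extremes at the drive period, with a shorter relaxation time
  (less drag than a labelled cell): the dominant source of false positives.
* ``random_walker`` -- a Brownian background particle (seeded random walk,
  per-axis mean-squared displacement 2*D*t).
* ``static_particle`` -- immobile debris contributing static speckle.

Each object is a weak-scattering complex transmittance patch at its own
depth whose perturbation field is forward-propagated (angular spectrum) to
the sensor and superposed on a unit reference wave; the recorded frame is
the quantized, noisy intensity of the total field.  The magnetic physics is
deliberately phenomenological (square wave + relaxation); no force-field
model is simulated.

All randomness derives from the scene seed: rendering is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .motion import HologramVideo
from .optics import ComplexField, DepthGrid, angular_spectrum_propagate

__all__ = [
    "SimObject",
    "SceneSpec",
    "Pose",
    "object_trajectory",
    "render_hologram_video",
    "RenderedScene",
    "generate_labelled_dataset",
    "benchmark_scene",
    "desk_scene_template",
]

KINDS = ("oscillating_cell", "bead_chain", "random_walker", "static_particle")


@dataclass
class SimObject:
    """One scatterer with a motion class and its kinematic parameters."""

    kind: str
    x: float  # px
    y: float  # px
    z: float  # um above the sensor
    radius: float = 8.0  # cell body radius, um
    amplitude_contrast: float = 0.25  # cell-body absorption
    phase_contrast: float = 0.8  # cell-body phase delay, rad
    bead_contrast: float = 0.7  # bead absorption (beads dominate scattering)
    bead_radius: float = 1.4  # um (magnetic capture beads)
    n_beads: int = 8  # beads bound to a cell
    chain_length: int = 4  # beads in an unbound chain
    osc_amplitude_px: float = 0.8  # driven lateral (vertical) swing, px
    osc_amplitude_rad: float = 0.9  # driven rolling amplitude, rad
    relaxation_time: float = 0.15  # s; cells respond slowly (drag + inertia)
    phase_offset: float = 0.0  # s, drive phase offset
    swing_angle: float = 0.7  # rad, chain swing half-angle
    diffusion: float = 0.5  # px^2/frame per axis (random_walker)
    obj_id: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown object kind {self.kind!r}")


@dataclass
class SceneSpec:
    """Scene geometry, acquisition parameters and noise model.

    Defaults mirror the acquisition geometry of the instrument being
    emulated: 1.67 um pixel pitch, 650 nm illumination, 120 frames at
    26.7 fps under a 1 s square-wave magnetic drive.
    """

    fov: tuple[int, int] = (256, 256)  # (rows, cols)
    pixel_pitch: float = 1.67  # um
    wavelength: float = 0.65  # um
    frame_rate: float = 26.7  # fps
    n_frames: int = 120
    modulation_period: float = 1.0  # s
    objects: list = field(default_factory=list)
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # (vx, vy) px/frame
    speckle_density: float = 0.0  # static background particles per px^2
    speckle_amplitude: float = 0.25
    speckle_z_range: tuple[float, float] = (900.0, 3500.0)  # um
    # Brownian debris: the dense dynamic background (cell fragments, unbound
    # beads) whose decorrelating speckle partially obscures the targets
    debris_density: float = 0.0  # particles per px^2
    debris_amplitude: float = 0.5
    debris_diffusion: float = 0.3  # px^2/frame per axis
    debris_z_range: tuple[float, float] = (900.0, 3000.0)  # um
    debris_slabs: int = 4
    background_level: float = 110.0  # DN of unit (reference) intensity
    gaussian_noise: float = 2.0  # DN
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("pixel_pitch", "wavelength", "frame_rate", "n_frames",
                     "modulation_period", "background_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class Pose:
    """Pose of an object at one frame: lateral offset (px) + orientation."""

    dx: float
    dy: float
    angle: float


def square_wave_response(times: np.ndarray, period: float, tau: float,
                         phase_offset: float = 0.0) -> np.ndarray:
    """First-order relaxation response in [-1, 1] to a square-wave drive.

    The drive targets +1 during the first half of each period and -1 during
    the second; the response starts at -1 (extreme A) at t = 0 and relaxes
    exponentially toward the current target with time constant ``tau``.
    With tau << period/2 the response sits at extreme A at integer periods
    and at extreme B at half periods.
    """
    t = np.asarray(times, dtype=float) - phase_offset
    r = np.full_like(t, -1.0)
    if t.size == 0:
        return r
    half = period / 2.0
    n_half = max(0, int(math.floor(np.max(t) / half))) + 1
    r_start, t0 = -1.0, 0.0
    for m in range(n_half + 1):
        target = 1.0 if m % 2 == 0 else -1.0
        t1 = t0 + half
        sel = (t >= t0) & (t < t1)
        if tau <= 0:
            r[sel] = target
            r_start = target
        else:
            r[sel] = target + (r_start - target) * np.exp(-(t[sel] - t0) / tau)
            r_start = target + (r_start - target) * math.exp(-half / tau)
        t0 = t1
    return r


def _walker_steps(obj: SimObject, scene: SceneSpec) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed & 0x7FFFFFFF, 7901, obj.obj_id]))
    steps = rng.normal(0.0, math.sqrt(2.0 * obj.diffusion), size=(scene.n_frames, 2))
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def object_trajectories(obj: SimObject, scene: SceneSpec) -> list[Pose]:
    """Pose at every frame (lateral offsets relative to the rest position)."""
    t = scene.times
    vx, vy = scene.drift_velocity
    drift_x = vx * np.arange(scene.n_frames)
    drift_y = vy * np.arange(scene.n_frames)
    if obj.kind == "oscillating_cell":
        r = square_wave_response(t, scene.modulation_period, obj.relaxation_time,
                                 obj.phase_offset)
        dx, dy = drift_x, drift_y + obj.osc_amplitude_px * r
        angle = obj.osc_amplitude_rad * r
    elif obj.kind == "bead_chain":
        # chains respond faster than bead-laden cells
        r = square_wave_response(t, scene.modulation_period,
                                 obj.relaxation_time / 3.0, obj.phase_offset)
        dx, dy = drift_x, drift_y
        angle = obj.swing_angle * r
    elif obj.kind == "random_walker":
        walk = _walker_steps(obj, scene)
        dx, dy = drift_x + walk[:, 0], drift_y + walk[:, 1]
        angle = np.zeros(scene.n_frames)
    else:  # static_particle
        dx, dy = drift_x, drift_y
        angle = np.zeros(scene.n_frames)
    return [Pose(float(dx[i]), float(dy[i]), float(angle[i]))
            for i in range(scene.n_frames)]


def object_trajectory(obj: SimObject, frame_index: int, scene: SceneSpec) -> Pose:
    """Pose of ``obj`` at one frame (see :func:`object_trajectories`)."""
    if not (0 <= frame_index < scene.n_frames):
        raise ValueError("frame_index out of range")
    return object_trajectories(obj, scene)[frame_index]


# ---------------------------------------------------------------------------
# rendering


def _bead_layout(obj: SimObject) -> np.ndarray:
    """Fixed per-object bead positions (px, relative to centre, unrotated)."""
    rng = np.random.default_rng(np.random.SeedSequence([9173, obj.obj_id]))
    if obj.kind == "bead_chain":
        spacing = 2.0 * obj.bead_radius / 1.67  # touching beads, px
        idx = np.arange(obj.chain_length) - (obj.chain_length - 1) / 2.0
        return np.stack([idx * spacing, np.zeros_like(idx)], axis=1)
    # beads scattered over the cell disk; heavily labelled cells carry many
    # beads, so the layout is recentred on the cell (its centroid is what
    # the motion-contrast detection localizes)
    r_max = 0.75 * obj.radius / 1.67
    rho = r_max * np.sqrt(rng.uniform(0.15, 1.0, obj.n_beads))
    theta = rng.uniform(0, 2 * np.pi, obj.n_beads)
    pts = np.stack([rho * np.cos(theta), rho * np.sin(theta)], axis=1)
    return pts - pts.mean(axis=0)


def _rot(p: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return p @ np.array([[c, s], [-s, c]])


def _transmittance_patch(obj: SimObject, pose: Pose, frac: tuple[float, float],
                         pitch: float, size: int, layout: np.ndarray) -> np.ndarray:
    """Weak-scattering perturbation delta = t - 1 on a patch grid.

    ``frac`` is the sub-pixel part of the object centre so motion is
    rendered continuously.
    """
    half = size // 2
    xx = (np.arange(size) - half - frac[0])[None, :]
    yy = (np.arange(size) - half - frac[1])[:, None]
    delta = np.zeros((size, size), dtype=np.complex64)
    sig_b = max(obj.bead_radius / pitch, 0.6) / 1.5  # Gaussian bead spot, px
    if obj.kind == "oscillating_cell":
        r_px = obj.radius / pitch
        rho = np.hypot(xx, yy)
        disk = 1.0 / (1.0 + np.exp((rho - r_px) / 0.7))
        delta -= (obj.amplitude_contrast - 1j * obj.phase_contrast) * disk
        beads = np.zeros((size, size))
        for bx, by in _rot(layout, pose.angle):
            beads += np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig_b**2))
        delta -= obj.bead_contrast * np.clip(beads, 0, 1.2)
    elif obj.kind == "bead_chain":
        beads = np.zeros((size, size))
        for bx, by in _rot(layout, pose.angle):
            beads += np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig_b**2))
        delta -= obj.bead_contrast * np.clip(beads, 0, 1.2)
    else:  # walker / static: a single particle
        spot = np.exp(-(xx**2 + yy**2) / (2 * sig_b**2))
        delta -= (obj.bead_contrast - 0.3j * obj.bead_contrast) * spot
    return delta


def _add_patch(canvas: np.ndarray, patch: np.ndarray, cx: int, cy: int) -> bool:
    """Add a patch centred at integer (cx, cy); returns True if clipped."""
    h, w = canvas.shape
    size = patch.shape[0]
    half = size // 2
    y0, x0 = cy - half, cx - half
    sy0, sy1 = max(0, y0), min(h, y0 + size)
    sx0, sx1 = max(0, x0), min(w, x0 + size)
    if sy1 <= sy0 or sx1 <= sx0:
        return True
    canvas[sy0:sy1, sx0:sx1] += patch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0]
    return (sy1 - sy0 != size) or (sx1 - sx0 != size)


def _propagate_patch(delta: np.ndarray, pitch: float, wavelength: float,
                     z: float) -> np.ndarray:
    f = ComplexField(delta.astype(np.complex64), pitch, wavelength)
    return angular_spectrum_propagate(f, float(z), pad_factor=2).values


@dataclass
class RenderedScene:
    """A rendered hologram video with its ground truth."""

    video: HologramVideo
    truth: pd.DataFrame  # one row per object
    trajectories: dict  # obj_id -> (n_frames, 2) array of (x, y) positions


def _stamp_spots(plane: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                 amps: np.ndarray, sigma: float = 0.7) -> None:
    """Accumulate Gaussian spots at sub-pixel positions (vectorized)."""
    h, w = plane.shape
    off = np.arange(-3, 4)
    cx = np.rint(xs).astype(int)
    cy = np.rint(ys).astype(int)
    gx = cx[:, None] + off[None, :]  # (K, 7)
    gy = cy[:, None] + off[None, :]
    wx = np.exp(-((gx - xs[:, None]) ** 2) / (2 * sigma**2))
    wy = np.exp(-((gy - ys[:, None]) ** 2) / (2 * sigma**2))
    vals = amps[:, None, None] * wy[:, :, None] * wx[:, None, :]  # (K, 7, 7)
    iy = np.broadcast_to(gy[:, :, None], vals.shape)
    ix = np.broadcast_to(gx[:, None, :], vals.shape)
    ok = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
    np.add.at(plane, (iy[ok], ix[ok]), vals[ok])


def render_hologram_video(scene: SceneSpec, patch_size: int = 96) -> RenderedScene:
    """Render the time-resolved hologram sequence of a scene.

    Per frame, every object's transmittance perturbation is placed at its
    posed position, forward-propagated to the sensor plane, and superposed
    on a unit reference wave (weak-scattering, single pass); the intensity
    is scaled to ``background_level``, Gaussian read noise is added and the
    result quantized to the sensor bit depth.  Static content (speckle
    background and static particles) is rendered once and translated per
    frame by the global drift.
    """
    h, w = scene.fov
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed & 0x7FFFFFFF, 11]))
    dynamic = [o for o in scene.objects if o.kind in ("oscillating_cell", "bead_chain", "random_walker")]
    static_objs = [o for o in scene.objects if o.kind == "static_particle"]

    # --- static scattered field at the sensor (before drift) ---
    static_field = np.zeros((h, w), dtype=np.complex64)
    n_speckle = int(round(scene.speckle_density * h * w))
    if n_speckle > 0:
        sx = rng.uniform(0, w, n_speckle)
        sy = rng.uniform(0, h, n_speckle)
        sz = rng.uniform(*scene.speckle_z_range, n_speckle)
        n_slabs = min(6, n_speckle)
        edges = np.quantile(sz, np.linspace(0, 1, n_slabs + 1))
        for s in range(n_slabs):
            sel = (sz >= edges[s]) & (sz <= edges[s + 1] if s == n_slabs - 1 else sz < edges[s + 1])
            if not sel.any():
                continue
            plane = np.zeros((h, w), dtype=np.complex64)
            xx = np.arange(w)[None, :]
            yy = np.arange(h)[:, None]
            for px, py in zip(sx[sel], sy[sel]):
                x0, x1 = max(0, int(px) - 4), min(w, int(px) + 5)
                y0, y1 = max(0, int(py) - 4), min(h, int(py) + 5)
                plane[y0:y1, x0:x1] -= scene.speckle_amplitude * np.exp(
                    -((xx[:, x0:x1] - px) ** 2 + (yy[y0:y1] - py) ** 2) / (2 * 0.7**2)
                ).astype(np.complex64)
            zc = float(np.mean(sz[sel]))
            f = ComplexField(plane, scene.pixel_pitch, scene.wavelength)
            static_field += angular_spectrum_propagate(f, zc, pad_factor=2).values
    layouts = {o.obj_id: _bead_layout(o) for o in scene.objects}
    for o in static_objs:
        delta = _transmittance_patch(o, Pose(0, 0, 0), (o.x % 1.0, o.y % 1.0),
                                     scene.pixel_pitch, patch_size, layouts[o.obj_id])
        scattered = _propagate_patch(delta, scene.pixel_pitch, scene.wavelength, o.z)
        _add_patch(static_field, scattered, int(round(o.x)), int(round(o.y)))

    # --- Brownian debris slabs (positions per frame via seeded random walk) ---
    n_debris = int(round(scene.debris_density * h * w))
    debris = None
    if n_debris > 0:
        drng = np.random.default_rng(np.random.SeedSequence([scene.seed & 0x7FFFFFFF, 13]))
        dx0 = drng.uniform(0, w, n_debris)
        dy0 = drng.uniform(0, h, n_debris)
        dz = drng.uniform(*scene.debris_z_range, n_debris)
        damp = scene.debris_amplitude * drng.uniform(0.4, 1.0, n_debris)
        steps = drng.normal(0.0, math.sqrt(2.0 * scene.debris_diffusion),
                            size=(scene.n_frames, n_debris, 2))
        steps[0] = 0.0
        dwalk = np.cumsum(steps, axis=0)  # (T, K, 2)
        slab_idx = np.minimum(
            (np.argsort(np.argsort(dz)) * scene.debris_slabs) // n_debris,
            scene.debris_slabs - 1,
        )
        slab_z = np.array([dz[slab_idx == s].mean() for s in range(scene.debris_slabs)])
        debris = (dx0, dy0, damp, dwalk, slab_idx, slab_z)

    # precompute Fourier grid for per-frame drift shifts of the static field
    vx, vy = scene.drift_velocity
    drifting = (vx != 0.0 or vy != 0.0) and (np.abs(static_field).max() > 0)
    if drifting:
        Fstat = np.fft.fft2(static_field)
        fyy = np.fft.fftfreq(h)[:, None]
        fxx = np.fft.fftfreq(w)[None, :]

    traj = {o.obj_id: object_trajectories(o, scene) for o in dynamic}
    positions = {o.obj_id: np.zeros((scene.n_frames, 2)) for o in scene.objects}
    clipped = {o.obj_id: False for o in scene.objects}

    frames = np.empty((scene.n_frames, h, w), dtype=np.float32)
    for i in range(scene.n_frames):
        if drifting:
            shift = np.exp(-2j * np.pi * (fxx * vx * i + fyy * vy * i))
            field_i = np.fft.ifft2(Fstat * shift).astype(np.complex64)
        else:
            field_i = static_field.copy()
        if debris is not None:
            dx0, dy0, damp, dwalk, slab_idx, slab_z = debris
            px = dx0 + dwalk[i, :, 0] + vx * i
            py = dy0 + dwalk[i, :, 1] + vy * i
            for s in range(scene.debris_slabs):
                sel = slab_idx == s
                if not sel.any():
                    continue
                plane = np.zeros((h, w), dtype=np.float64)
                _stamp_spots(plane, px[sel], py[sel], -damp[sel])
                f = ComplexField(plane.astype(np.complex64),
                                 scene.pixel_pitch, scene.wavelength)
                field_i += angular_spectrum_propagate(f, float(slab_z[s]),
                                                      pad_factor=2).values
        for o in static_objs:
            positions[o.obj_id][i] = (o.x + vx * i, o.y + vy * i)
            if not (0 <= o.x + vx * i < w and 0 <= o.y + vy * i < h):
                clipped[o.obj_id] = True
        for o in dynamic:
            pose = traj[o.obj_id][i]
            px, py = o.x + pose.dx, o.y + pose.dy
            positions[o.obj_id][i] = (px, py)
            if not (0 <= px < w and 0 <= py < h):
                clipped[o.obj_id] = True
            cx, cy = int(round(px)), int(round(py))
            # single small particles need no wide fringe support
            psize = patch_size if o.kind in ("oscillating_cell", "bead_chain") \
                else min(patch_size, 48)
            delta = _transmittance_patch(o, pose, (px - cx, py - cy),
                                         scene.pixel_pitch, psize,
                                         layouts[o.obj_id])
            scattered = _propagate_patch(delta, scene.pixel_pitch,
                                         scene.wavelength, o.z)
            _add_patch(field_i, scattered, cx, cy)
        intensity = np.abs(1.0 + field_i) ** 2
        dn = intensity * scene.background_level
        if scene.gaussian_noise > 0:
            dn = dn + rng.normal(0.0, scene.gaussian_noise, dn.shape)
        full = 2**scene.bit_depth - 1
        frames[i] = np.clip(np.rint(dn), 0, full)

    video = HologramVideo(frames, frame_rate=scene.frame_rate,
                          pixel_pitch=scene.pixel_pitch,
                          wavelength=scene.wavelength,
                          modulation_period=scene.modulation_period)
    rows = []
    for o in scene.objects:
        p = positions[o.obj_id]
        rows.append(dict(obj_id=o.obj_id, kind=o.kind, x0=o.x, y0=o.y, z_um=o.z,
                         x_mean=float(p[:, 0].mean()), y_mean=float(p[:, 1].mean()),
                         clipped=bool(clipped[o.obj_id])))
    truth = pd.DataFrame(rows)
    return RenderedScene(video=video, truth=truth, trajectories=positions)


# ---------------------------------------------------------------------------
# canned scenes and dataset generation


def benchmark_scene(seed: int = 0, n_cells: int = 10, n_walkers: int = 20,
                    n_static: int = 6, fov: tuple[int, int] = (320, 320),
                    z_range: tuple[float, float] = (900.0, 1200.0)) -> SceneSpec:
    """The fixed screening benchmark: oscillating cells among Brownian
    walkers, static speckle and dense Brownian debris, with a slow
    horizontal fluid drift.

    Target cells sit 0.9--1.2 mm above the sensor so the field of view
    captures their full high-NA fringe systems (needed for the 10 um
    autofocus refinement); the margin keeps the fringes inside the frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 21]))
    h, w = fov
    margin = 64
    n_total = n_cells + n_walkers + n_static
    # rejection-sample positions: target cells mutually well separated (their
    # focus windows must not overlap), background objects merely non-touching
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n_total:
        attempts += 1
        if attempts > 500:
            pts, attempts = [], 0
        sep = 48 if len(pts) < n_cells else 20
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - qx) ** 2 + (y - qy) ** 2 > sep**2
               for j, (qx, qy) in enumerate(pts)
               if j < n_cells or len(pts) >= n_cells):
            pts.append((x, y))
    objects = []
    for i in range(n_total):
        kind = ("oscillating_cell" if i < n_cells
                else "random_walker" if i < n_cells + n_walkers
                else "static_particle")
        x, y = pts[i]
        objects.append(SimObject(kind=kind, x=x, y=y,
                                 z=float(rng.uniform(*z_range)), obj_id=i))
    return SceneSpec(fov=fov, objects=objects, drift_velocity=(0.15, 0.0),
                     speckle_density=0.002, debris_density=0.004,
                     debris_z_range=(900.0, 2500.0), seed=seed)


def desk_scene_template(seed: int = 0) -> SceneSpec:
    """Reduced-scale scene profile for classifier dataset generation:
    small field of view, 24 frames at 8 fps (3 drive periods, N = 8)."""
    return SceneSpec(fov=(96, 96), frame_rate=8.0, n_frames=24,
                     modulation_period=1.0, drift_velocity=(0.0, 0.0),
                     speckle_density=0.0008, seed=seed)


def desk_depth_grid() -> DepthGrid:
    return DepthGrid.regular(400.0, 1000.0, 150.0)


def generate_labelled_dataset(
    n_per_class: int,
    kinds: tuple[str, ...] = ("bead_chain", "oscillating_cell"),
    template: SceneSpec | None = None,
    seed: int = 0,
    grid: DepthGrid | None = None,
    objects_per_scene: int = 3,
    crop: int = 16,
    kappa: float = 6.0,
    match_radius: float = 3.0,
    refine_step: float = 25.0,
    refine_halfspan: float = 75.0,
    z_range: tuple[float, float] = (500.0, 900.0),
    max_scene_factor: int = 6,
):
    """Balanced labelled candidate videos produced by the full pipeline.

    Scenes each containing ``objects_per_scene`` same-class objects are
    rendered and pushed through screening (reconstruction, CMA, projection,
    detection) and focusing (coarse + refined autofocus, crop extraction);
    only detections that match exactly one ground-truth object within
    ``match_radius`` px are kept, so every label is unambiguous.  Returns
    ``(videos, labels, manifest)`` with videos stacked as
    (n, 2, T, crop, crop) and ``labels[i]`` the index into ``kinds``.
    """
    from .focusing import autofocus_coarse, autofocus_refine, extract_candidate_video
    from .motion import cma_contrast, detect_candidates, project_max_intensity, reconstruct_video

    template = template or desk_scene_template()
    grid = grid or desk_depth_grid()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 33]))
    h, w = template.fov
    margin = max(crop, 20)
    videos: dict[int, list] = {k: [] for k in range(len(kinds))}
    n_scenes = 0
    max_scenes = max_scene_factor * math.ceil(n_per_class / objects_per_scene) * len(kinds)
    while any(len(videos[k]) < n_per_class for k in range(len(kinds))) and n_scenes < max_scenes:
        k = min(range(len(kinds)), key=lambda q: len(videos[q]))
        kind = kinds[k]
        pts: list[tuple[float, float]] = []
        attempts = 0
        while len(pts) < objects_per_scene:
            attempts += 1
            if attempts > 200:  # restart: the partial set may admit no extension
                pts, attempts = [], 0
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            if all((x - qx) ** 2 + (y - qy) ** 2 > (2.0 * crop) ** 2 for qx, qy in pts):
                pts.append((x, y))
        objects = [
            SimObject(kind=kind, x=x, y=y, z=float(rng.uniform(*z_range)),
                      obj_id=j, phase_offset=float(rng.uniform(0, 0.12)))
            for j, (x, y) in enumerate(pts)
        ]
        scene = replace(template, objects=objects,
                        seed=int(rng.integers(0, 2**31 - 1)))
        rendered = render_hologram_video(scene)
        video = rendered.video
        stacks = reconstruct_video(video, grid)
        volume = cma_contrast(stacks, video.frames_per_period, grid=grid)
        proj = project_max_intensity(volume)
        cands = detect_candidates(proj, kappa=kappa, min_area=3,
                                  border_margin=crop // 2)
        for cand in cands:
            d = [(math.hypot(cand.x - o.x, cand.y - o.y), o) for o in objects]
            near = [o for dist, o in d if dist <= match_radius]
            if len(near) != 1 or len(videos[k]) >= n_per_class:
                continue
            z_c = autofocus_coarse(volume, cand, criterion="peak")
            z_r = autofocus_refine(video, cand, z_c, grid,
                                   fine_step=refine_step,
                                   fine_halfspan=refine_halfspan,
                                   patch_size=64)
            cv = extract_candidate_video(video, cand, z_r, crop=crop,
                                         candidate_id=len(videos[k]),
                                         patch_size=64)
            videos[k].append(cv.values)
        n_scenes += 1
    for k, kind in enumerate(kinds):
        if not videos[k]:
            raise RuntimeError(f"pipeline recovered zero objects of class {kind!r}")
    n_keep = min(min(len(v) for v in videos.values()), n_per_class)
    data = np.stack([v for k in range(len(kinds)) for v in videos[k][:n_keep]])
    labels = np.repeat(np.arange(len(kinds)), n_keep)
    manifest = dict(seed=seed, kinds=list(kinds),
                    counts={kinds[k]: int(n_keep) for k in range(len(kinds))},
                    n_scenes=n_scenes, crop=crop, n_frames=template.n_frames,
                    frame_rate=template.frame_rate, fov=list(template.fov))
    return data, labels, manifest
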