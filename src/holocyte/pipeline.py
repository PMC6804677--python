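"""End-to-end screening: hologram videos in, cell concentration out.

Per field of view (FOV) the pipeline runs drift correction, filtered
back-propagation over the depth grid, CMA motion contrast, maximum
intensity projection, threshold detection, coarse + refined autofocusing,
in-focus video extraction and (when a trained classifier is supplied)
video classification at the configured decision threshold.  Counts are
aggregated over FOVs and converted to a whole-blood concentration:

    V_equiv = V_screened * V_blood / V_final          [mL]
    concentration = positives / V_equiv               [cells/mL]

where V_screened is the optically screened sample volume (FOV area x tube
inner depth x number of FOVs) and the blood/final volumes describe the
enrichment step (e.g. 4 mL blood concentrated into a 3.2 mL prepared
sample: screening 0.942 mL of sample interrogates 1.1775 mL of blood).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .focusing import autofocus_coarse, autofocus_refine, extract_candidate_video
from .motion import (
    HologramVideo,
    correct_drift,
    detect_candidates,
    estimate_drift,
    motion_contrast_volume,
    project_max_intensity,
)
from .optics import DepthGrid, FilterSpec

logger = logging.getLogger("holocyte")

__all__ = [
    "ScreeningConfig",
    "ScreeningResult",
    "screen_sample",
    "estimate_concentration",
    "report",
]


@dataclass
class ScreeningConfig:
    """Tunable parameters of the screening pipeline."""

    grid: DepthGrid = field(default_factory=DepthGrid.regular)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    drift_axes: tuple = ("x",)
    kappa: float = 6.0  # adaptive detection threshold: mean + kappa * std
    min_area: int = 4
    border_margin: int = 32
    coarse_criterion: str = "peak"
    refine_step: float = 10.0
    refine_halfspan: float = 150.0
    refine_patch: int = 256
    crop: int = 64
    tube_depth_mm: float = 2.0  # capillary inner depth along the optical axis
    blood_volume_ml: float = 4.0
    final_sample_volume_ml: float = 3.2
    pad_factor: int = 2

    @classmethod
    def desk_scale(cls) -> "ScreeningConfig":
        """Reduced-scale profile matching the desk-scale simulator scenes."""
        return cls(
            grid=DepthGrid.regular(400.0, 1000.0, 150.0),
            refine_step=25.0, refine_halfspan=150.0, refine_patch=64,
            crop=16, border_margin=8, min_area=3,
        )


@dataclass
class CandidateRecord:
    """One candidate as reported in a ScreeningResult."""

    fov: int
    x: float
    y: float
    area: int
    peak_score: float
    border_flag: bool
    z_coarse: float | None = None
    z_refined: float | None = None
    probability: float | None = None
    label: bool | None = None


@dataclass
class ScreeningResult:
    """Aggregated outcome of screening one sample."""

    candidates: list
    positive_count: int
    n_fov: int
    n_fov_failed: int
    screened_volume_ml: float
    whole_blood_equivalent_ml: float
    concentration_per_ml: float
    complete: bool
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningResult":
        d = dict(d)
        d["candidates"] = [CandidateRecord(**c) for c in d["candidates"]]
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ScreeningResult":
        return cls.from_dict(json.loads(s))


def estimate_concentration(count: int, screened_volume_ml: float,
                           blood_volume_ml: float = 4.0,
                           final_sample_volume_ml: float = 3.2) -> float:
    """Cells per mL of whole blood from a positive count.

    The screened sample volume is scaled by blood/final to the whole-blood
    volume it represents before enrichment.
    """
    if screened_volume_ml <= 0 or blood_volume_ml <= 0 or final_sample_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    equivalent = screened_volume_ml * blood_volume_ml / final_sample_volume_ml
    return count / equivalent


def whole_blood_equivalent(screened_volume_ml: float, blood_volume_ml: float,
                           final_sample_volume_ml: float) -> float:
    if screened_volume_ml <= 0 or blood_volume_ml <= 0 or final_sample_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    return screened_volume_ml * blood_volume_ml / final_sample_volume_ml


def _screen_fov(video: HologramVideo, config: ScreeningConfig) -> tuple[list, list]:
    """Candidates and their in-focus videos for one FOV."""
    shifts = estimate_drift(video)
    corrected = correct_drift(video, shifts, axes=config.drift_axes)
    volume = motion_contrast_volume(corrected, config.grid, config.filter_spec,
                                    pad_factor=config.pad_factor)
    projection = project_max_intensity(volume)
    cands = detect_candidates(projection, kappa=config.kappa,
                              min_area=config.min_area,
                              border_margin=config.border_margin)
    videos = []
    for k, cand in enumerate(cands):
        z_c = autofocus_coarse(volume, cand, criterion=config.coarse_criterion)
        z_r = autofocus_refine(corrected, cand, z_c, config.grid,
                               spec=config.filter_spec,
                               fine_step=config.refine_step,
                               fine_halfspan=config.refine_halfspan,
                               patch_size=config.refine_patch)
        videos.append(extract_candidate_video(corrected, cand, z_r,
                                              crop=config.crop,
                                              spec=config.filter_spec,
                                              candidate_id=k,
                                              patch_size=config.refine_patch))
    return cands, videos


def screen_sample(videos: list[HologramVideo], model=None, threshold=None,
                  config: ScreeningConfig | None = None,
                  metadata: dict | None = None) -> ScreeningResult:
    """Screen a set of FOV videos and estimate the cell concentration.

    ``model``/``threshold`` are the trained video classifier and its
    decision threshold; without them every focused candidate is counted as
    a (tentative) positive.  A FOV that fails any stage is logged and
    skipped; the run fails only if every FOV fails.
    """
    from .nn import classify  # local import: the classifier is optional

    config = config or ScreeningConfig()
    records: list[CandidateRecord] = []
    n_failed = 0
    positive = 0
    fov_area_mm2 = None
    for f, video in enumerate(videos):
        t0 = time.time()
        try:
            cands, cand_videos = _screen_fov(video, config)
        except Exception:
            logger.exception("FOV %d failed; skipping", f)
            n_failed += 1
            continue
        h, w = video.shape
        fov_area_mm2 = (h * video.pixel_pitch * 1e-3) * (w * video.pixel_pitch * 1e-3)
        probs = labels = None
        if model is not None and cand_videos:
            data = np.stack([cv.values for cv in cand_videos])
            labels, probs = classify(model, data, threshold)
        for k, cand in enumerate(cands):
            rec = CandidateRecord(
                fov=f, x=cand.x, y=cand.y, area=cand.area,
                peak_score=cand.peak_score, border_flag=cand.border_flag,
                z_coarse=cand.z_coarse, z_refined=cand.z_refined,
            )
            if probs is not None:
                rec.probability = float(probs[k])
                rec.label = bool(labels[k])
            else:
                rec.label = True  # no classifier: every candidate counts
            positive += bool(rec.label)
            records.append(rec)
        logger.info("FOV %d: %d candidates (%.1f s)", f, len(cands),
                    time.time() - t0)
    if videos and n_failed == len(videos):
        raise RuntimeError("all FOVs failed during screening")
    n_ok = len(videos) - n_failed
    screened = (fov_area_mm2 or 0.0) * config.tube_depth_mm * n_ok * 1e-3  # mL
    equivalent = (whole_blood_equivalent(screened, config.blood_volume_ml,
                                         config.final_sample_volume_ml)
                  if screened > 0 else 0.0)
    concentration = positive / equivalent if equivalent > 0 else 0.0
    return ScreeningResult(
        candidates=records, positive_count=positive, n_fov=len(videos),
        n_fov_failed=n_failed, screened_volume_ml=screened,
        whole_blood_equivalent_ml=equivalent,
        concentration_per_ml=concentration,
        complete=(n_failed == 0), metadata=metadata or {},
    )


def report(result: ScreeningResult, fmt: str = "text") -> str:
    """Human-readable summary (``text``) or machine record (``json``)."""
    if fmt == "json":
        return result.to_json(indent=2)
    lines = [
        "screening summary",
        "-----------------",
        f"FOVs screened            : {result.n_fov - result.n_fov_failed}/{result.n_fov}"
        + ("" if result.complete else "  (INCOMPLETE)"),
        f"candidates detected      : {len(result.candidates)}",
        f"classified positives     : {result.positive_count}",
        f"screened volume          : {result.screened_volume_ml:.4f} mL",
        f"whole-blood equivalent   : {result.whole_blood_equivalent_ml:.4f} mL",
        f"concentration            : {result.concentration_per_ml:.3f} cells/mL",
    ]
    return "\n".join(lines)
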