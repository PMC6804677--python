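"""File formats: TIFF stacks, HDF5 candidate videos, YAML scenes, CSV tables.

Hologram videos travel as multi-page TIFF plus a YAML metadata block
(pixel pitch, wavelength, frame rate, modulation period).  Complex fields
are stored as paired float32 TIFF planes (real/imaginary).  Candidate
videos (2 x T x H x W amplitude/phase crops) and labelled datasets use
HDF5.  Model checkpoints are .npz archives holding the architecture
config, every parameter tensor and the training seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .focusing import CandidateVideo
from .motion import Candidate, HologramVideo
from .nn.network import Network, NetworkConfig, build_network
from .optics import ComplexField

__all__ = [
    "save_video", "load_video", "save_field", "load_field",
    "candidates_to_csv", "candidates_from_csv",
    "save_candidate_videos", "load_candidate_videos",
    "save_model", "load_model", "scene_to_yaml", "scene_from_yaml",
]


def save_video(path, video: HologramVideo) -> None:
    """Write frames as multi-page TIFF with a YAML metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(video.frames, dtype=np.float32))
    meta = dict(frame_rate=video.frame_rate, pixel_pitch=video.pixel_pitch,
                wavelength=video.wavelength,
                modulation_period=video.modulation_period,
                drift_corrected=bool(video.drift_corrected))
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_video(path, metadata_path=None) -> HologramVideo:
    path = Path(path)
    frames = tifffile.imread(path)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    return HologramVideo(frames=np.asarray(frames), **meta)


def save_field(path, field: ComplexField) -> None:
    """Complex field as a 2-page float32 TIFF (real, imaginary)."""
    planes = np.stack([field.values.real, field.values.imag]).astype(np.float32)
    tifffile.imwrite(Path(path), planes,
                     metadata={"pixel_pitch": field.pixel_pitch,
                               "wavelength": field.wavelength})


def load_field(path, pixel_pitch: float | None = None,
               wavelength: float | None = None) -> ComplexField:
    with tifffile.TiffFile(Path(path)) as tf:
        planes = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return ComplexField(planes[0] + 1j * planes[1],
                        pixel_pitch=pixel_pitch or float(meta["pixel_pitch"]),
                        wavelength=wavelength or float(meta["wavelength"]))


def candidates_to_csv(path, candidates: list[Candidate]) -> None:
    rows = [dict(x=c.x, y=c.y, area=c.area, peak_score=c.peak_score,
                 border_flag=c.border_flag, z_coarse=c.z_coarse,
                 z_refined=c.z_refined) for c in candidates]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def candidates_from_csv(path) -> list[Candidate]:
    df = pd.read_csv(Path(path))
    out = []
    for row in df.itertuples(index=False):
        c = Candidate(x=row.x, y=row.y, area=int(row.area),
                      peak_score=row.peak_score, border_flag=bool(row.border_flag))
        c.z_coarse = None if pd.isna(row.z_coarse) else float(row.z_coarse)
        c.z_refined = None if pd.isna(row.z_refined) else float(row.z_refined)
        out.append(c)
    return out


def save_candidate_videos(path, videos: list[CandidateVideo] | np.ndarray,
                          labels=None, manifest: dict | None = None) -> None:
    with h5py.File(Path(path), "w") as f:
        if isinstance(videos, np.ndarray):
            f.create_dataset("videos", data=videos.astype(np.float32),
                             compression="gzip")
        else:
            f.create_dataset("videos",
                             data=np.stack([v.values for v in videos]),
                             compression="gzip")
            f.create_dataset("z_refined", data=[v.z_refined for v in videos])
            f.create_dataset("centroid_x", data=[v.centroid[0] for v in videos])
            f.create_dataset("centroid_y", data=[v.centroid[1] for v in videos])
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        if manifest:
            f.attrs["manifest"] = json.dumps(manifest)


def load_candidate_videos(path):
    with h5py.File(Path(path), "r") as f:
        videos = f["videos"][...]
        labels = f["labels"][...] if "labels" in f else None
        manifest = json.loads(f.attrs["manifest"]) if "manifest" in f.attrs else {}
    return videos, labels, manifest


def save_model(path, model: Network, seed: int | None = None,
               extra: dict | None = None) -> None:
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    # running batch-norm statistics are state, not Params
    from .nn.layers import BatchNorm3d
    from .nn.network import DenseP3DBlock, _ConvStage

    bns = _collect_batchnorms(model)
    for i, bn in enumerate(bns):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    meta = dict(config=dataclasses.asdict(model.config), seed=seed,
                extra=extra or {})
    np.savez_compressed(Path(path), meta=json.dumps(meta), **arrays)


def _collect_batchnorms(model: Network):
    from .nn.layers import BatchNorm3d
    from .nn.network import DenseP3DBlock, _ConvStage

    out = []
    for layer in model.layers:
        if isinstance(layer, BatchNorm3d):
            out.append(layer)
        elif isinstance(layer, DenseP3DBlock):
            out.extend([layer.conv_s.bn, layer.conv_t.bn])
    return out


def load_model(path) -> tuple[Network, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta["config"].items()})
        model = build_network(cfg)
        for i, p in enumerate(model.params()):
            p.value = data[f"param_{i}"].astype(np.float32)
            p.grad = np.zeros_like(p.value)
        for i, bn in enumerate(_collect_batchnorms(model)):
            bn.running_mean = data[f"bn_{i}_mean"]
            bn.running_var = data[f"bn_{i}_var"]
    return model, meta


def scene_to_yaml(path, scene) -> None:
    d = dataclasses.asdict(scene)
    Path(path).write_text(yaml.safe_dump(d))


def scene_from_yaml(path):
    from .simulate import SceneSpec, SimObject

    d = yaml.safe_load(Path(path).read_text())
    d["objects"] = [SimObject(**o) for o in d.get("objects", [])]
    for key in ("fov", "drift_velocity", "speckle_z_range", "debris_z_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SceneSpec(**d)
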