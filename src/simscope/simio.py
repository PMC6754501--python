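"""File I/O: multipage TIFF raw stacks, float32 reconstructions and
structured-text parameter files.

Raw stacks are 16-bit multipage TIFFs, angle-major page order, with a JSON
page description carrying channel/angle/phase/timestamp; reconstructions are
32-bit float TIFFs with the parameters used recorded in the description.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile

from simscope.model import FRAMES_PER_SET, N_PHASES, IlluminationParams, RawSimSet

__all__ = [
    "load_params",
    "read_raw_stack",
    "save_params",
    "write_raw_stack",
    "write_reconstruction",
    "read_reconstruction",
]


def write_raw_stack(path: str | Path, sets: Sequence[RawSimSet],
                    sidecar_meta: dict[str, Any] | None = None) -> Path:
    """Write raw sets to one multipage 16-bit TIFF (9 pages per set).

    An optional sidecar ``<path>.json`` records optics/illumination truth for
    test harnesses.
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for s in sets:
            frames = np.asarray(s.frames)
            if not np.issubdtype(frames.dtype, np.integer):
                if frames.max(initial=0) > 0xFFFF or frames.min(initial=0) < 0:
                    raise ValueError("raw frames not 16-bit representable")
                frames = np.round(frames).astype(np.uint16)
            for i in range(FRAMES_PER_SET):
                desc = json.dumps({
                    "channel": s.channel_id, "angle": i // N_PHASES,
                    "phase": i % N_PHASES, "timestamp_ns": int(s.timestamps_ns[i]),
                    "exposure_ms": s.exposure_ms,
                })
                tif.write(frames[i].astype(np.uint16), description=desc,
                          contiguous=False)
    if sidecar_meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar_meta, indent=2))
    return path


def read_raw_stack(path: str | Path, *, channel_override: int | None = None
                   ) -> list[RawSimSet]:
    """Read a multipage raw TIFF back into 9-frame sets (lossless round trip).

    The page count must be divisible by 9; page metadata must be present
    unless ``channel_override`` supplies the channel id.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if n_pages == 0 or n_pages % FRAMES_PER_SET:
            raise ValueError(
                f"{path}: page count {n_pages} is not a positive multiple of "
                f"{FRAMES_PER_SET}")
        sets = []
        for s0 in range(0, n_pages, FRAMES_PER_SET):
            frames, ts, channel, exposure = [], [], None, 1.0
            for i in range(FRAMES_PER_SET):
                page = tif.pages[s0 + i]
                frames.append(page.asarray())
                meta = None
                if page.description:
                    try:
                        meta = json.loads(page.description)
                    except (json.JSONDecodeError, TypeError):
                        meta = None
                if meta is not None and "timestamp_ns" not in meta:
                    meta = None  # foreign description (e.g. plain tifffile shape tag)
                if meta is None:
                    if channel_override is None:
                        raise ValueError(
                            f"{path}: page {s0 + i} has no metadata; pass "
                            "channel_override to read untagged stacks")
                    ts.append(s0 + i)
                    channel = channel_override
                else:
                    ts.append(int(meta["timestamp_ns"]))
                    channel = meta["channel"] if channel_override is None else channel_override
                    exposure = float(meta.get("exposure_ms", 1.0))
            sets.append(RawSimSet(frames=np.stack(frames), channel_id=int(channel),
                                  exposure_ms=exposure,
                                  timestamps_ns=np.asarray(ts, dtype=np.int64)))
    return sets


def write_reconstruction(path: str | Path, image: np.ndarray,
                         meta: dict[str, Any] | None = None) -> Path:
    """Write a reconstruction (or wide-field view) as 32-bit float TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32),
                     description=json.dumps(meta or {}))
    return path


def read_reconstruction(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except json.JSONDecodeError:
                meta = {}
        return page.asarray(), meta


def save_params(path: str | Path, params_by_channel: dict[int, IlluminationParams],
                *, pixel_size: float | None = None,
                grid_shape: tuple[int, int] | None = None,
                extra: dict[str, Any] | None = None) -> Path:
    """Serialize per-channel illumination parameters to a JSON text file."""
    payload: dict[str, Any] = {"format": "simscope-params", "version": 1}
    if pixel_size is not None:
        payload["pixel_size_um"] = pixel_size
    if grid_shape is not None:
        payload["grid_shape"] = list(grid_shape)
    channels = {}
    for ch, p in params_by_channel.items():
        entry = {
            "wave_vectors_cyc_per_um": p.wave_vectors.tolist(),
            "start_phases_rad": p.start_phases.tolist(),
            "modulation": p.modulation,
            "phase_step_rad": p.phase_step,
        }
        if p.scores is not None:
            entry["scores"] = np.asarray(p.scores).tolist()
        if pixel_size is not None and grid_shape is not None:
            entry["wave_vectors_bins"] = (
                p.wave_vectors * np.asarray(grid_shape) * pixel_size).tolist()
        channels[str(ch)] = entry
    payload["channels"] = channels
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_params(path: str | Path) -> dict[int, IlluminationParams]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "simscope-params":
        raise ValueError(f"{path}: not a simscope parameter file")
    out = {}
    for ch, entry in payload["channels"].items():
        out[int(ch)] = IlluminationParams(
            wave_vectors=np.asarray(entry["wave_vectors_cyc_per_um"]),
            start_phases=np.asarray(entry["start_phases_rad"]),
            modulation=float(entry["modulation"]),
            phase_step=float(entry.get("phase_step_rad", 2 * np.pi / 3)),
            scores=np.asarray(entry["scores"]) if "scores" in entry else None)
    return out
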