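"""Sequence, ground-truth, result and config file I/O.

Internal convention everywhere in the package: 0-based pixel coordinates and
half-open boxes.  External files follow the OTB dialect (1-based inclusive
``x,y,w,h`` rows), and conversion happens only here, at the file boundary.
Result files are written 0-based with an explicit header line declaring the
convention to avoid silent off-by-one mismatches.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import yaml

from .boxes import Box
from .config import TrackerConfig

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
RESULTS_HEADER = "# pawss results: 0-based half-open boxes; columns frame,x,y,w,h,score"


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", name)]


def list_sequence_files(path: Path) -> List[Path]:
    files = [
        p
        for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    ]
    return sorted(files, key=lambda p: _natural_key(p.name))


def _to_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[..., :3]
    return img


def read_sequence(path: str | Path) -> List[np.ndarray]:
    """Read an image-directory sequence (or video file) as RGB frames.

    Directory frames are ordered by natural filename sort (``img2`` before
    ``img10``).  Video files are delegated to imageio and require a video
    backend plugin.
    """
    path = Path(path)
    if path.is_dir():
        files = list_sequence_files(path)
        if not files:
            raise ValueError(f"no image files found in directory {path}")
        frames = []
        for f in files:
            try:
                frames.append(_to_rgb(iio.imread(f)))
            except Exception as exc:  # noqa: BLE001 - name the offending file
                raise ValueError(f"unreadable frame {f}: {exc}") from exc
        return frames
    if path.is_file():
        try:
            return [_to_rgb(frame) for frame in iio.imiter(path)]
        except Exception as exc:  # noqa: BLE001
            raise ValueError(
                f"could not read video file {path} (a video backend plugin "
                f"such as ffmpeg may be missing): {exc}"
            ) from exc
    raise ValueError(f"sequence path {path} does not exist")


def read_groundtruth(path: str | Path, indexing: str = "one") -> List[Optional[Box]]:
    """Parse an OTB-dialect ground-truth rectangle file.

    One ``x,y,w,h`` row per frame; the delimiter (comma, tab or space) is
    auto-detected.  Under the 1-based inclusive convention (``indexing='one'``)
    rows convert to internal 0-based boxes ``(x-1, y-1, w, h)``.  NaN or
    non-positive-size rows mark invalid (out-of-view) frames and parse to
    ``None``.
    """
    if indexing not in ("one", "zero"):
        raise ValueError("indexing must be 'one' or 'zero'")
    shift = 1.0 if indexing == "one" else 0.0
    boxes: List[Optional[Box]] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in re.split(r"[,\t ]+", line) if p]
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                x, y, w, h = (float(p) for p in parts[:4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if any(math.isnan(v) for v in (x, y, w, h)) or w <= 0 or h <= 0:
                boxes.append(None)
            else:
                boxes.append(Box(x - shift, y - shift, w, h))
    if not boxes:
        raise ValueError(f"{path}: no parsable rows")
    return boxes


def write_groundtruth(path: str | Path, boxes: Sequence[Optional[Box]]) -> None:
    """Write boxes in the 1-based OTB dialect (inverse of ``read_groundtruth``)."""
    with open(path, "w") as fh:
        for box in boxes:
            if box is None:
                fh.write("NaN,NaN,NaN,NaN\n")
            else:
                fh.write(
                    f"{box.x + 1:.2f},{box.y + 1:.2f},{box.w:.2f},{box.h:.2f}\n"
                )


def write_results(
    path: str | Path, boxes: Sequence[Box], scores: Sequence[float]
) -> None:
    """Write per-frame results CSV: ``frame,x,y,w,h,score`` (0-based, header)."""
    with open(path, "w") as fh:
        fh.write(RESULTS_HEADER + "\n")
        for i, (box, score) in enumerate(zip(boxes, scores)):
            fh.write(
                f"{i},{box.x:.3f},{box.y:.3f},{box.w:.3f},{box.h:.3f},{score:.6f}\n"
            )


def read_results(path: str | Path) -> Tuple[List[Box], List[float]]:
    boxes: List[Box] = []
    scores: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: malformed results row {line!r}")
            _, x, y, w, h, score = parts
            boxes.append(Box(float(x), float(y), float(w), float(h)))
            scores.append(float(score))
    return boxes, scores


def write_frames(path: str | Path, frames: Sequence[np.ndarray]) -> List[Path]:
    """Write frames as zero-padded PNGs into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for i, frame in enumerate(frames):
        p = path / f"{i + 1:04d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        out.append(p)
    return out


def load_config(path: str | Path) -> TrackerConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return TrackerConfig.from_dict(data)


def save_config(path: str | Path, config: TrackerConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
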