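"""Frame-stream I/O: numbered PNG image sequences (and single-file reads).

Recordings are exchanged as directories of numbered grayscale PNGs
(``frame_000000.png`` …), one image per 0.1-s analysis step.  Standard
video containers can be read when an imageio plugin for them is available;
the PNG sequence is the canonical interchange format.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def write_frames(frames: np.ndarray, directory) -> Path:
    """Write a (T, H, W) uint8 stack as a numbered PNG sequence."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame)
    return directory


def read_frames(path) -> np.ndarray:
    """Read a recording from a PNG-sequence directory or a video file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    if path.is_dir():
        files = sorted(path.glob("*.png")) + sorted(path.glob("*.tif")) + sorted(
            path.glob("*.tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    else:
        frames = np.asarray(iio.imread(path))
    if frames.ndim == 4:  # RGB(A) -> luma
        frames = frames[..., :3].mean(axis=-1)
    if frames.ndim != 3:
        raise ValueError(f"expected a (T, H, W) stream, got shape {frames.shape}")
    return frames.astype(np.uint8)
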