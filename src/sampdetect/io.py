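"""Reading and writing frame stacks.

The first-class input format is a lexicographically ordered directory of
PNG/TIFF frames (what the simulator writes and what acquisition software
can export losslessly); common video containers are read through imageio
when a suitable plugin is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .measure import DEFAULT_PIXEL_SCALE_UM

__all__ = ["FrameStack", "read_frames", "write_frames"]

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class FrameStack:
    """Ordered fluorescence frames with acquisition metadata."""

    frames: np.ndarray                 # (T, H, W) or (T, H, W, C)
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    frame_rate_fps: float = 10.0

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


def read_frames(path: str | Path,
                pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
                frame_rate_fps: float = 10.0) -> FrameStack:
    """Load a frame directory (PNG/TIFF, lexicographic order) or a video file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = []
        for f in files:
            try:
                frames.append(iio.imread(f))
            except Exception as exc:
                raise OSError(f"could not read frame {f}: {exc}") from exc
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {shapes}")
        stack = np.stack(frames)
    elif path.is_file():
        try:
            stack = np.asarray(iio.imread(path))
        except Exception as exc:
            raise OSError(f"could not read video {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
    else:
        raise FileNotFoundError(str(path))
    return FrameStack(frames=stack, pixel_scale_um=pixel_scale_um,
                      frame_rate_fps=frame_rate_fps)


def write_frames(frames: np.ndarray, outdir: str | Path,
                 prefix: str = "frame") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ndigits = max(4, len(str(len(frames))))
    paths = []
    for t, frame in enumerate(frames):
        p = outdir / f"{prefix}_{t:0{ndigits}d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths
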