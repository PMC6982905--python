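"""Frame streams: numbered image sequences and video containers."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def iter_frames(source):
    """Yield frames from a directory of numbered images or a video file.

    Directory entries are sorted by name, so zero-padded frame numbering
    preserves temporal order.  Color frames come back as the file stores
    them; the pipeline treats 3-channel input as BGR-ordered for the
    grayscale conversion.
    """
    path = Path(source)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        for f in files:
            yield iio.imread(f)
    elif path.is_file():
        for frame in iio.imiter(path):
            yield np.asarray(frame)
    else:
        raise FileNotFoundError(f"no such file or directory: {path}")


def write_frames(frames, out_dir, prefix: str = "frame", start: int = 0) -> list:
    """Write frames as zero-padded PNGs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames, start=start):
        p = out_dir / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths
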