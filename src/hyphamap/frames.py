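"""Panorama frame container and on-disk frame series I/O.

A *panorama* is a single assembled grayscale image of the whole thallus at a
known time after germination.  Frames carry the pixel-size calibration
(default 1.63 um/px) and the pixel coordinates of the germination center,
which downstream stages use to select the thallus polygon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

#: acquisition-time uncertainty, hours (time to scan all tiles of a panorama)
TIME_UNCERTAINTY_H = 1.0 / 60.0

#: default pixel size of the imaging rig, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 1.63


@dataclass
class PanoramaFrame:
    """One grayscale image of the thallus at a known time.

    Parameters
    ----------
    image
        2-D ``uint8`` (or float) grayscale array, indexed ``(row, col)``.
    time
        Hours since germination.  The acquisition uncertainty is
        ``TIME_UNCERTAINTY_H`` (1 min).
    pixel_size
        Micrometres per pixel.
    center
        ``(row, col)`` pixel coordinates of the germination point.
    """

    image: np.ndarray
    time: float
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    center: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.center is None:
            self.center = (self.image.shape[0] // 2, self.image.shape[1] // 2)
        r, c = self.center
        if not (0 <= r < self.image.shape[0] and 0 <= c < self.image.shape[1]):
            raise ValueError(f"center {self.center} outside image {self.image.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


def save_frames(frames: list[PanoramaFrame], out_dir: str | Path) -> Path:
    """Write frames as PNG plus a ``frames.csv`` manifest; return manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "frames.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "time_h", "pixel_size_um", "center_row", "center_col"])
        for i, fr in enumerate(frames):
            name = f"frame_{i:04d}.png"
            Image.fromarray(np.asarray(fr.image, dtype=np.uint8)).save(out / name)
            w.writerow([name, f"{fr.time:.6f}", f"{fr.pixel_size:.6f}",
                        fr.center[0], fr.center[1]])
    return manifest


def load_frames(manifest: str | Path) -> list[PanoramaFrame]:
    """Read a frame series back from a ``frames.csv`` manifest."""
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "frames.csv"
    frames: list[PanoramaFrame] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(Image.open(manifest.parent / row["filename"]).convert("L"))
            frames.append(PanoramaFrame(
                image=img,
                time=float(row["time_h"]),
                pixel_size=float(row["pixel_size_um"]),
                center=(int(row["center_row"]), int(row["center_col"])),
            ))
    frames.sort(key=lambda fr: fr.time)
    return frames
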