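"""Composite summary images: where the mosquitoes went, in one picture.

Mosquitoes are dark against the bright cone scene, so the pixel-wise minimum
across all 0.1-s samples of a test accumulates every position each mosquito
visited into a single image — a crawl along the net surface shows up as a
dark band at the bottom, dispersed flight as speckle throughout the cone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .video import VideoAsset, sample_frames


@dataclass(frozen=True)
class CompositeImage:
    """Pixel-wise minimum over the sampled frames of one assay."""

    pixels: np.ndarray
    n_samples_merged: int


def composite_summary(
    asset: VideoAsset | str | Path, *, interval: float = 0.1
) -> CompositeImage:
    """Merge the darkest components of each sampled frame (pixel-wise min)."""
    acc: np.ndarray | None = None
    n = 0
    for frame in sample_frames(asset, interval):
        if not frame.valid:
            continue
        if acc is None:
            acc = frame.pixels.copy()
        else:
            np.minimum(acc, frame.pixels, out=acc)
        n += 1
    if acc is None:
        raise ValueError("no decodable samples to composite")
    return CompositeImage(acc, n)


def merge(a: CompositeImage, b: CompositeImage) -> CompositeImage:
    """Combine two composites (order-invariant, idempotent)."""
    return CompositeImage(np.minimum(a.pixels, b.pixels),
                          a.n_samples_merged + b.n_samples_merged)


def save_png(composite: CompositeImage, path: str | Path) -> None:
    iio.imwrite(Path(path), composite.pixels)
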