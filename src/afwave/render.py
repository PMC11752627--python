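"""Rendering time-frequency magnitude matrices as fixed-size RGB images.

The classifier consumes square RGB images (224 x 224 x 3 by default).
Magnitudes are log-compressed, min-max normalized per image, and mapped
through a perceptual colormap whose high end is yellow (viridis), so
regions of high energy concentration appear yellow on a dark background.
Rows are ordered high-frequency at the top. Because CWT center
frequencies are geometrically spaced, plain row-wise resampling of the
coefficient matrix yields a log-scaled frequency axis for scalograms and
a linear axis for STFT spectrograms, with no chart furniture (axes,
ticks, colorbars) in the exported image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from matplotlib import colormaps
from PIL import Image

from afwave.errors import InputError, ParameterError

DEFAULT_SIZE = (224, 224)
LOG_EPS = 1e-8
_CMAP = colormaps["viridis"]
#: 256-entry uint8 lookup table; monotone in lightness, yellow at the top.
_LUT = (np.asarray(_CMAP(np.linspace(0.0, 1.0, 256)))[:, :3] * 255).round().astype(np.uint8)


@dataclass
class ScalogramImage:
    """A rendered RGB time-frequency image plus provenance."""

    pixels: np.ndarray  # height x width x 3, uint8
    source_id: str
    label: str

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def render_tf_image(
    matrix: np.ndarray,
    source_id: str = "",
    label: str = "unknown",
    size: tuple[int, int] = DEFAULT_SIZE,
) -> ScalogramImage:
    """Render a nonnegative magnitude matrix to a fixed-size RGB image.

    Pipeline: log(1 + m/eps) compression -> bilinear resize to the target
    size -> per-image min-max normalization -> viridis lookup. Rendering
    is invariant to positive rescaling of the input, and an all-zero (or
    constant) matrix maps to a uniform image at the colormap's low end.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise InputError(f"expected a 2-D magnitude matrix, got shape {m.shape}")
    if m.size == 0:
        raise InputError("empty matrix")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise InputError("matrix must be nonnegative and finite")
    if size[0] < 1 or size[1] < 1:
        raise ParameterError(f"size must be positive, got {size}")
    # scale invariance: normalize before log compression
    peak = m.max()
    if peak > 0:
        m = m / peak
    compressed = np.log1p(m / LOG_EPS)
    img = Image.fromarray(compressed.astype(np.float32), mode="F")
    resized = np.asarray(img.resize((size[1], size[0]), Image.BILINEAR), dtype=float)
    lo, hi = resized.min(), resized.max()
    if hi > lo:
        norm = (resized - lo) / (hi - lo)
    else:
        norm = np.zeros_like(resized)
    idx = np.clip((norm * 255).round().astype(int), 0, 255)
    return ScalogramImage(pixels=_LUT[idx], source_id=source_id, label=label)


def colormap_position(magnitudes: np.ndarray) -> np.ndarray:
    """Normalized colormap positions in [0, 1] for a magnitude vector.

    Exposes the monotone value -> colormap mapping used by
    :func:`render_tf_image` for property checks and colorbar rendering.
    """
    m = np.asarray(magnitudes, dtype=float)
    peak = m.max()
    c = np.log1p((m / peak if peak > 0 else m) / LOG_EPS)
    lo, hi = c.min(), c.max()
    return (c - lo) / (hi - lo) if hi > lo else np.zeros_like(c)


def save_image(image: ScalogramImage, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path, format=fmt)
    return path


def batch_render(
    matrices: Iterable[tuple[str, str, np.ndarray]],
    out_dir: str | Path,
    size: tuple[int, int] = DEFAULT_SIZE,
    image_format: str = "png",
) -> "pd.DataFrame":
    """Render and save one image per (record_id, label, matrix) triple.

    Files are named ``<label>_<record_id>.<ext>`` (AF segment 3111
    becomes ``A_3111.png``); the returned manifest has columns
    ``path, label, record_id`` and is also written to
    ``out_dir/manifest.csv``. Rendering is deterministic, so a rerun
    over the same inputs reproduces byte-identical files.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory not writable: {out_dir} ({exc})") from exc
    ext = image_format.lower().lstrip(".")
    rows = []
    for record_id, label, matrix in matrices:
        image = render_tf_image(matrix, source_id=record_id, label=label, size=size)
        fname = f"{label}_{record_id}.{ext}"
        save_image(image, out_dir / fname)
        rows.append({"path": str(out_dir / fname), "label": label, "record_id": record_id})
    manifest = pd.DataFrame(rows, columns=["path", "label", "record_id"])
    manifest.to_csv(out_dir / "manifest.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    return manifest
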