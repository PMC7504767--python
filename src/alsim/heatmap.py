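"""Potency color gradient, heatmap rendering, and RG intensity extraction.

Potency is encoded on a red-yellow-green gradient anchored at pKi 3.72
(pure green), 5.75 (yellow) and 8.75 (pure red); values outside the
range clamp to the end colors and the blue channel is unused.  Because
only R and G carry signal, a heatmap collapses losslessly to a single
per-pixel intensity (R - G)/255 in [-1, 1]: -1 deepest valley (lowest
potency), 0 intermediate (yellow; white regions also map here since
R = G), +1 highest peak.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .config import GRADIENT_ANCHORS, IMAGE_WIDTH, IMAGE_HEIGHT
from .datatypes import PotencyRaster

PKI_GREEN, PKI_YELLOW, PKI_RED = GRADIENT_ANCHORS


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _gradient_channels(pki: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized R and G channels (floats 0-255) for pKi values."""
    pki = np.asarray(pki, dtype=float)
    # fraction of the way from green (0) through yellow (1) to red (2)
    low = np.clip((pki - PKI_GREEN) / (PKI_YELLOW - PKI_GREEN), 0.0, 1.0)
    high = np.clip((pki - PKI_YELLOW) / (PKI_RED - PKI_YELLOW), 0.0, 1.0)
    r = 255.0 * low        # green -> yellow ramps red up
    g = 255.0 * (1 - high)  # yellow -> red ramps green down
    return r, g


def potency_to_rgb(pki: float) -> tuple[int, int, int]:
    """Map a pKi value to its gradient color as an (R, G, B) triple.

    pKi <= 3.72 gives (0, 255, 0); 8.75 and above give (255, 0, 0);
    between the anchors the color interpolates linearly in RGB through
    yellow (255, 255, 0).  Channels round half-up; blue is always 0.
    """
    if not np.isfinite(pki):
        raise ValueError(f"potency must be finite, got {pki!r}")
    r, g = _gradient_channels(np.asarray([pki]))
    return int(_round_half_up(r[0])), int(_round_half_up(g[0])), 0


def render_heatmap(raster: PotencyRaster) -> np.ndarray:
    """Render a potency raster as an 8-bit RGB heatmap array.

    Returns an array of shape (height, width, 3), dtype uint8, produced
    by applying :func:`potency_to_rgb` per pixel.
    """
    if raster.height != IMAGE_HEIGHT or raster.width != IMAGE_WIDTH:
        raise ValueError(
            f"expected a {IMAGE_WIDTH}x{IMAGE_HEIGHT} raster, got "
            f"{raster.width}x{raster.height}")
    r, g = _gradient_channels(raster.values)
    img = np.zeros((raster.height, raster.width, 3), dtype=np.uint8)
    img[..., 0] = _round_half_up(r).astype(np.uint8)
    img[..., 1] = _round_half_up(g).astype(np.uint8)
    return img


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.shape[0] != IMAGE_HEIGHT or img.shape[1] != IMAGE_WIDTH:
        raise ValueError(
            f"expected a {IMAGE_WIDTH}x{IMAGE_HEIGHT} image, got "
            f"{img.shape[1]}x{img.shape[0]}")
    return img


def rg_intensity(img: np.ndarray) -> np.ndarray:
    """Combined, normalized red-green intensity of a heatmap.

    Per pixel: (R - G) / 255, in [-1, 1].  The blue channel is ignored.
    White and near-white pixels (R close to G) land near 0, the same as
    yellow, so uncolored surface regions read as intermediate potency.
    """
    img = _validate_image(img)
    return (img[..., 0].astype(float) - img[..., 1].astype(float)) / 255.0


def write_png(img: np.ndarray, path) -> None:
    """Write an RGB heatmap array as an 8-bit PNG (no alpha)."""
    arr = np.asarray(img, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


def read_png(path, resize: bool = False) -> np.ndarray:
    """Read a heatmap PNG as an (H, W, 3) uint8 array.

    With ``resize=True``, images of other sizes are area-averaged down
    (or box-resampled up) to 280x300; otherwise a size mismatch is an
    error naming the expected dimensions.
    """
    with Image.open(path) as im:
        im = im.convert("RGB")
        if (im.width, im.height) != (IMAGE_WIDTH, IMAGE_HEIGHT):
            if not resize:
                raise ValueError(
                    f"{path}: image is {im.width}x{im.height}, expected "
                    f"{IMAGE_WIDTH}x{IMAGE_HEIGHT} (pass resize to rescale)")
            im = im.resize((IMAGE_WIDTH, IMAGE_HEIGHT), Image.BOX)
        return np.asarray(im, dtype=np.uint8)
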