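"""Diverging color palettes and perceptual interpolation.

A palette is an odd-length ordered list of hex colors: the negative endpoint
first, a neutral middle, the positive endpoint last.  The built-ins are
colorblind-friendly diverging schemes with Color Brewer anchor colors; their
exact hexes are a repository convention, documented here.

Interpolation runs in CIELAB: the a*/b* (chroma) channels are interpolated
piecewise-linearly through the anchors of the relevant half, while L*
(lightness) is replaced by a linear ramp from the neutral middle's lightness
down to the endpoint's — the "lightness correction" that makes perceived
intensity increase monotonically with attribution magnitude.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage import color as _skcolor

__all__ = ["BUILTIN_PALETTES", "get_palette", "score_to_color", "lightness"]

# Color Brewer 5-class diverging anchors (negative -> neutral -> positive).
BUILTIN_PALETTES: dict[str, tuple[str, ...]] = {
    # RdBu reversed: negative = blue, positive = red
    "red_blue": ("#0571b0", "#92c5de", "#f7f7f7", "#f4a582", "#ca0020"),
    # PiYG reversed: negative = green, positive = magenta
    "pink_green": ("#4dac26", "#b8e186", "#f7f7f7", "#f1b6da", "#d01c8b"),
    # PuOr: negative = orange, positive = purple
    "purple_orange": ("#e66101", "#fdb863", "#f7f7f7", "#b2abd2", "#5e3c99"),
}


class PaletteError(ValueError):
    """Palette is not a valid odd-length diverging color list."""


def _hex_to_rgb(h: str) -> np.ndarray:
    h = h.lstrip("#")
    if len(h) != 6:
        raise PaletteError(f"bad hex color {h!r}")
    return np.array([int(h[i : i + 2], 16) for i in (0, 2, 4)], dtype=float) / 255.0


def _rgb_to_hex(rgb: np.ndarray) -> str:
    r, g, b = (int(round(c * 255)) for c in np.clip(rgb, 0.0, 1.0))
    return f"#{r:02x}{g:02x}{b:02x}"


def _to_lab(rgb: np.ndarray) -> np.ndarray:
    return _skcolor.rgb2lab(rgb.reshape(1, 1, 3)).reshape(3)


def _to_rgb(lab: np.ndarray) -> np.ndarray:
    return _skcolor.lab2rgb(lab.reshape(1, 1, 3)).reshape(3)


def get_palette(palette: str | Sequence[str]) -> tuple[str, ...]:
    """Resolve a palette name or validate a custom color list.

    Custom palettes must be odd-length (>= 3) so they have a neutral middle;
    even-length lists are rejected as non-diverging.
    """
    if isinstance(palette, str):
        try:
            return BUILTIN_PALETTES[palette]
        except KeyError:
            raise PaletteError(
                f"unknown palette {palette!r}; built-ins: "
                f"{sorted(BUILTIN_PALETTES)}"
            ) from None
    colors = tuple(palette)
    if len(colors) < 3 or len(colors) % 2 == 0:
        raise PaletteError(
            "custom palette must be an odd-length diverging list "
            f"(neutral middle); got {len(colors)} colors"
        )
    for c in colors:
        _hex_to_rgb(c)
    return colors


def score_to_color(t: float, palette: str | Sequence[str]) -> str:
    """Color for a normalized score t in [-1, 1] (values clamp).

    t = 0 returns the neutral middle exactly; |t| = 1 returns the endpoint
    exactly.  In between, chroma follows the anchors of the matching half
    and lightness ramps linearly from neutral to endpoint.
    """
    colors = get_palette(palette)
    t = float(np.clip(t, -1.0, 1.0))
    mid = len(colors) // 2
    if t == 0.0:
        return colors[mid]
    if t > 0:
        half = colors[mid:]  # neutral .. positive endpoint
        u = t
    else:
        half = colors[mid::-1]  # neutral .. negative endpoint
        u = -t
    if u == 1.0:
        return half[-1]
    labs = np.array([_to_lab(_hex_to_rgb(c)) for c in half])
    # piecewise-linear position along the half's anchors
    pos = u * (len(half) - 1)
    k = min(int(pos), len(half) - 2)
    frac = pos - k
    lab = (1 - frac) * labs[k] + frac * labs[k + 1]
    # lightness correction: monotone ramp neutral -> endpoint
    lab[0] = (1 - u) * labs[0, 0] + u * labs[-1, 0]
    return _rgb_to_hex(_to_rgb(lab))


def lightness(hex_color: str) -> float:
    """CIELAB L* of a hex color (0 = black, 100 = white)."""
    return float(_to_lab(_hex_to_rgb(hex_color))[0])
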