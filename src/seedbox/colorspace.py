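"""Colour-space conversions for per-patch channel means.

All derived quantities are computed on channel *proportions* (value / 255);
the raw 0-255 histogram means are kept unchanged on :class:`ChannelMeans`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateInputError

__all__ = ["ChannelMeans", "NormalizedRGB", "HSB", "to_normalized", "to_hsb", "luminosity"]

#: Nominal band centres reported for the source camera, metadata only —
#: never used in any computation.
WAVELENGTH_NM = {"red": 580, "green": 540, "blue": 550}

_LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # Rec.601


@dataclass(frozen=True)
class ChannelMeans:
    """Mean red/green/blue intensity of the foreground pixels of one patch,
    on the 0-255 histogram scale."""

    mean_r: float
    mean_g: float
    mean_b: float
    n_pixels: int = 1

    def __post_init__(self) -> None:
        for name in ("mean_r", "mean_g", "mean_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v!r} outside [0, 255]")
        if self.n_pixels < 1:
            raise ValueError(f"n_pixels={self.n_pixels} must be >= 1")

    def proportions(self) -> tuple[float, float, float]:
        """Channels rescaled to [0, 1] by dividing by 255."""
        return (self.mean_r / 255.0, self.mean_g / 255.0, self.mean_b / 255.0)


@dataclass(frozen=True)
class NormalizedRGB:
    """Brightness ratios r, g, b — each channel over the channel sum."""

    r: float
    g: float
    b: float


@dataclass(frozen=True)
class HSB:
    """Hue (degrees), saturation, brightness and chroma on proportions.

    ``achromatic`` marks inputs with zero chroma, for which hue and
    saturation carry no information (hue is reported as 0 by convention).
    """

    hue: float
    saturation: float
    brightness: float
    chroma: float
    achromatic: bool


def to_normalized(c: ChannelMeans, label: str | None = None) -> NormalizedRGB:
    """Each channel divided by the channel sum; scale-invariant.

    Raises
    ------
    DegenerateInputError
        If all three channels are zero (pure black patch).
    """
    total = c.mean_r + c.mean_g + c.mean_b
    if total <= 0.0:
        who = f" (patch {label})" if label else ""
        raise DegenerateInputError(f"all-zero channel means{who}: normalized RGB undefined")
    return NormalizedRGB(c.mean_r / total, c.mean_g / total, c.mean_b / total)


def to_hsb(c: ChannelMeans) -> HSB:
    """Piecewise hue / saturation / brightness conversion on proportions.

    Negative piecewise hue values are wrapped into [0, 360) by adding 360.
    All-black input yields brightness 0, saturation 0 and the achromatic flag.
    """
    r, g, b = c.proportions()
    mx = max(r, g, b)
    mn = min(r, g, b)
    chroma = mx - mn
    if chroma == 0.0:
        return HSB(hue=0.0, saturation=0.0, brightness=mx, chroma=0.0, achromatic=True)
    if mx == r:
        hue = 60.0 * ((g - b) / chroma)
    elif mx == g:
        hue = 60.0 * (2.0 + (b - r) / chroma)
    else:
        hue = 60.0 * (4.0 + (r - g) / chroma)
    if hue < 0.0:
        hue += 360.0
    saturation = chroma / mx
    return HSB(hue=hue, saturation=saturation, brightness=mx, chroma=chroma, achromatic=False)


def luminosity(c: ChannelMeans) -> float:
    """Weighted luma 0.299 R + 0.587 G + 0.114 B on the 0-255 scale.

    Carried as metadata only; no vegetation index consumes it.
    """
    wr, wg, wb = _LUMA_WEIGHTS
    return wr * c.mean_r + wg * c.mean_g + wb * c.mean_b
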