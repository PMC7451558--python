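"""Vegetation / colour indices computed from per-patch channel means.

Indices follow the means-first convention: they are evaluated on the
per-patch channel *means* (as proportions of 255), mirroring a
histogram-mean workflow, not averaged over per-pixel index values.
A per-pixel mode exists for sensitivity checks; outputs are labelled with
the mode that produced them.

Two formula sets are available:

* canonical (default) — the forms as published by the indices' original
  authors;
* literal — the forms exactly as printed in the source screening protocol
  table, which contains typographic defects (selected with
  ``literal=True`` / the ``--table1-literal`` CLI flag). Where a printed
  string cannot be parsed at all (DGCI) the canonical form is used in both
  modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .colorspace import HSB, ChannelMeans, luminosity, to_hsb, to_normalized
from .errors import ConfigurationError

__all__ = ["INDEX_NAMES", "IndexVector", "compute_index", "compute_all", "compute_all_per_pixel"]

logger = logging.getLogger(__name__)

INDEX_NAMES = ("gmr", "gdr", "ngrdi", "vari", "gli", "tgi", "dgci")


@dataclass(frozen=True)
class IndexVector:
    """All derived colour quantities for one patch observation.

    ``None`` marks a value whose denominator was degenerate, or DGCI on an
    achromatic patch.
    """

    gmr: float
    gdr: float | None
    ngrdi: float | None
    vari: float | None
    gli: float | None
    tgi: float
    dgci: float | None
    r: float
    g: float
    b: float
    hue: float
    saturation: float
    brightness: float
    chroma: float
    luminosity: float
    achromatic: bool
    mode: str = "means-first"

    def get(self, name: str) -> float | None:
        name = name.lower()
        if name not in INDEX_NAMES:
            raise ConfigurationError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
        return getattr(self, name)


def _warn_degenerate(name: str, reason: str) -> None:
    logger.warning("index %s undefined: %s; emitting missing value", name, reason)


def _gmr(r: float, g: float, b: float) -> float:
    return g - r


def _gdr(r: float, g: float, b: float) -> float | None:
    if r == 0.0:
        _warn_degenerate("gdr", "red channel is zero")
        return None
    return g / r


def _ngrdi(r: float, g: float, b: float) -> float | None:
    if g + r == 0.0:
        _warn_degenerate("ngrdi", "green + red is zero")
        return None
    return (g - r) / (g + r)


def _vari(r: float, g: float, b: float) -> float | None:
    den = g + r - b
    if den == 0.0:
        _warn_degenerate("vari", "green + red - blue is zero")
        return None
    return (g - r) / den


def _gli(r: float, g: float, b: float) -> float | None:
    den = 2.0 * g + r + b
    if den == 0.0:
        _warn_degenerate("gli", "2*green + red + blue is zero")
        return None
    return (2.0 * g - r - b) / den


def _gli_literal(r: float, g: float, b: float) -> float | None:
    # as printed: 2*(G - R - B) / (2*G + R + B)
    den = 2.0 * g + r + b
    if den == 0.0:
        _warn_degenerate("gli", "2*green + red + blue is zero")
        return None
    return 2.0 * (g - r - b) / den


def _tgi(r: float, g: float, b: float) -> float:
    return -0.5 * (190.0 * (r - g) - 120.0 * (r - b))


def _tgi_literal(r: float, g: float, b: float) -> float:
    # as printed: -0.5*190*(R-G) - 120*(R-B)
    return -0.5 * 190.0 * (r - g) - 120.0 * (r - b)


def _dgci(hsb: HSB) -> float | None:
    if hsb.achromatic:
        _warn_degenerate("dgci", "achromatic input, hue undefined")
        return None
    return ((hsb.hue - 60.0) / 60.0 + (1.0 - hsb.saturation) + (1.0 - hsb.brightness)) / 3.0


def compute_index(name: str, c: ChannelMeans, literal: bool = False) -> float | None:
    """Evaluate one named index on proportions of ``c``.

    Degenerate denominators yield ``None`` (plus a logged warning), never an
    exception; an unknown ``name`` raises :class:`ConfigurationError`.
    """
    name = name.lower()
    if name not in INDEX_NAMES:
        raise ConfigurationError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
    r, g, b = c.proportions()
    if name == "gmr":
        return _gmr(r, g, b)
    if name == "gdr":
        return _gdr(r, g, b)
    if name == "ngrdi":
        return _ngrdi(r, g, b)
    if name == "vari":
        return _vari(r, g, b)
    if name == "gli":
        return (_gli_literal if literal else _gli)(r, g, b)
    if name == "tgi":
        return (_tgi_literal if literal else _tgi)(r, g, b)
    # dgci
    return _dgci(to_hsb(c))


def compute_all(c: ChannelMeans, literal: bool = False) -> IndexVector:
    """All indices plus carried colour-space quantities, from one HSB pass."""
    r, g, b = c.proportions()
    hsb = to_hsb(c)
    try:
        norm = to_normalized(c)
        nr, ng, nb = norm.r, norm.g, norm.b
    except Exception:
        # all-black patch: normalized fractions undefined, report equal thirds
        # is wrong — carry NaN instead so the degeneracy stays visible.
        nr = ng = nb = float("nan")
    return IndexVector(
        gmr=_gmr(r, g, b),
        gdr=_gdr(r, g, b),
        ngrdi=_ngrdi(r, g, b),
        vari=_vari(r, g, b),
        gli=(_gli_literal if literal else _gli)(r, g, b),
        tgi=(_tgi_literal if literal else _tgi)(r, g, b),
        dgci=_dgci(hsb),
        r=nr,
        g=ng,
        b=nb,
        hue=hsb.hue,
        saturation=hsb.saturation,
        brightness=hsb.brightness,
        chroma=hsb.chroma,
        luminosity=luminosity(c),
        achromatic=hsb.achromatic,
        mode="means-first",
    )


def compute_all_per_pixel(pixels: np.ndarray, mask: np.ndarray, literal: bool = False) -> IndexVector:
    """Sensitivity-check mode: average per-pixel index values over a mask.

    ``pixels`` is an H x W x 3 uint8 array; ``mask`` a congruent boolean
    array with at least one pixel set. Per-pixel degenerate values are
    dropped from each average. The result is labelled ``mode='per-pixel'``.
    """
    sel = np.asarray(pixels, dtype=np.float64)[np.asarray(mask, dtype=bool)] / 255.0
    if sel.size == 0:
        raise ConfigurationError("per-pixel mode requires a non-empty mask")
    r, g, b = sel[:, 0], sel[:, 1], sel[:, 2]

    def _safe_mean(num: np.ndarray, den: np.ndarray) -> float | None:
        ok = den != 0.0
        if not ok.any():
            return None
        return float((num[ok] / den[ok]).mean())

    mx = sel.max(axis=1)
    mn = sel.min(axis=1)
    chroma = mx - mn
    chromatic = chroma > 0.0
    hue = np.zeros(len(sel))
    if chromatic.any():
        rc, gc, bc = r[chromatic], g[chromatic], b[chromatic]
        mxc, chc = mx[chromatic], chroma[chromatic]
        h = np.where(
            mxc == rc,
            60.0 * (gc - bc) / chc,
            np.where(mxc == gc, 60.0 * (2.0 + (bc - rc) / chc), 60.0 * (4.0 + (rc - gc) / chc)),
        )
        hue[chromatic] = np.where(h < 0.0, h + 360.0, h)
    sat = np.where(mx > 0.0, chroma / np.where(mx > 0.0, mx, 1.0), 0.0)
    dgci_px = ((hue - 60.0) / 60.0 + (1.0 - sat) + (1.0 - mx)) / 3.0
    gli_num = 2.0 * (g - r - b) if literal else (2.0 * g - r - b)
    tgi_fn = _tgi_literal if literal else _tgi
    total = r + g + b
    ok_total = total > 0.0
    return IndexVector(
        gmr=float((g - r).mean()),
        gdr=_safe_mean(g, r),
        ngrdi=_safe_mean(g - r, g + r),
        vari=_safe_mean(g - r, g + r - b),
        gli=_safe_mean(gli_num, 2.0 * g + r + b),
        tgi=float(tgi_fn(r, g, b).mean()),
        dgci=float(dgci_px[chromatic].mean()) if chromatic.any() else None,
        r=float((r[ok_total] / total[ok_total]).mean()) if ok_total.any() else float("nan"),
        g=float((g[ok_total] / total[ok_total]).mean()) if ok_total.any() else float("nan"),
        b=float((b[ok_total] / total[ok_total]).mean()) if ok_total.any() else float("nan"),
        hue=float(hue[chromatic].mean()) if chromatic.any() else 0.0,
        saturation=float(sat.mean()),
        brightness=float(mx.mean()),
        chroma=float(chroma.mean()),
        luminosity=float((255.0 * (0.299 * r + 0.587 * g + 0.114 * b)).mean()),
        achromatic=not bool(chromatic.any()),
        mode="per-pixel",
    )
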