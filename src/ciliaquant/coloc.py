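"""Mander's co-localization coefficients with a pixel-shift null control.

M1 is the fraction of the red channel's above-threshold intensity that
co-occurs with green signal; M2 the symmetric quantity for green.  Both use
the thresholded-Mander's convention: each coefficient's denominator sums only
the own channel's above-own-threshold pixels (a flag restores unthresholded
denominators).

As a null control for chance overlap, the green channel is displaced along
the x-axis (five pixels by default) and the coefficients recomputed on the
overlapping region; real co-occupancy drops under displacement, chance
overlap does not.  Across a set of image pairs, a paired two-tailed t-test of
M versus its shifted counterpart quantifies that drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import InputError
from .movieio import ChannelImage


@dataclass
class ColocResult:
    """Original and shift-null Mander's coefficients for one image pair."""

    image_id: str
    M1: float
    M2: float
    M1_shift: float
    M2_shift: float
    shift_pixels: int
    threshold_red: float
    threshold_green: float


def resolve_threshold(image: ChannelImage, threshold: str | float) -> float:
    """Resolve ``'otsu'`` or a fixed value to a numeric threshold."""
    if threshold == "otsu":
        if np.ptp(image.pixels) == 0:
            return float(image.pixels.flat[0])
        return float(threshold_otsu(image.pixels))
    t = float(threshold)
    if t < 0:
        raise InputError("threshold must be >= 0")
    return t


def _manders_arrays(
    red: np.ndarray,
    green: np.ndarray,
    t_red: float,
    t_green: float,
    thresholded_denominator: bool,
) -> tuple[float, float]:
    red_sel = red > t_red
    green_sel = green > t_green
    denom1 = red[red_sel].sum() if thresholded_denominator else red.sum()
    denom2 = green[green_sel].sum() if thresholded_denominator else green.sum()
    m1 = red[red_sel & green_sel].sum() / denom1 if denom1 > 0 else math.nan
    m2 = green[red_sel & green_sel].sum() / denom2 if denom2 > 0 else math.nan
    return float(m1), float(m2)


def manders(
    red: ChannelImage,
    green: ChannelImage,
    t_red: float,
    t_green: float,
    thresholded_denominator: bool = True,
) -> tuple[float, float]:
    """Mander's M1 (red over green) and M2 (green over red).

    ``M1 = sum(red_i for red_i > t_red and green_i > t_green) /
    sum(red_i for red_i > t_red)`` and symmetrically for M2.  A channel with
    no above-threshold signal yields NaN for its coefficient rather than an
    exception.
    """
    if red.shape != green.shape:
        raise InputError(f"channel shapes differ: {red.shape} vs {green.shape}")
    if t_red < 0 or t_green < 0:
        raise InputError("thresholds must be >= 0")
    return _manders_arrays(
        red.pixels, green.pixels, t_red, t_green, thresholded_denominator
    )


def shift_null(
    red: ChannelImage,
    green: ChannelImage,
    shift_pixels: int = 5,
    t_red: float = 0.0,
    t_green: float = 0.0,
    thresholded_denominator: bool = True,
) -> tuple[float, float]:
    """Mander's coefficients after displacing green by ``shift_pixels`` in x.

    The strip without data after translation is excluded: both channels are
    cropped to the overlap region (no wrap-around, which would fabricate
    overlap at the seam).  ``shift_pixels = 0`` is allowed and reduces to
    ``manders``.
    """
    if red.shape != green.shape:
        raise InputError(f"channel shapes differ: {red.shape} vs {green.shape}")
    width = red.shape[1]
    if shift_pixels < 0:
        raise InputError("shift_pixels must be >= 0")
    if shift_pixels >= width:
        raise InputError(f"shift of {shift_pixels} px >= image width {width}")
    if shift_pixels == 0:
        return _manders_arrays(
            red.pixels, green.pixels, t_red, t_green, thresholded_denominator
        )
    red_crop = red.pixels[:, shift_pixels:]
    green_crop = green.pixels[:, : width - shift_pixels]
    return _manders_arrays(red_crop, green_crop, t_red, t_green, thresholded_denominator)


def coloc_pair(
    red: ChannelImage,
    green: ChannelImage,
    image_id: str = "",
    t_red: str | float = "otsu",
    t_green: str | float = "otsu",
    shift_pixels: int = 5,
    thresholded_denominator: bool = True,
) -> ColocResult:
    """Compute original and shift-null coefficients for one image pair."""
    tr = resolve_threshold(red, t_red)
    tg = resolve_threshold(green, t_green)
    m1, m2 = manders(red, green, tr, tg, thresholded_denominator)
    m1s, m2s = shift_null(red, green, shift_pixels, tr, tg, thresholded_denominator)
    return ColocResult(
        image_id=image_id,
        M1=m1,
        M2=m2,
        M1_shift=m1s,
        M2_shift=m2s,
        shift_pixels=shift_pixels,
        threshold_red=tr,
        threshold_green=tg,
    )


def paired_shift_test(results: list[ColocResult]) -> dict:
    """Paired two-tailed t-test of M versus M_shift across image pairs.

    Requires at least three images with defined coefficients.  If the
    differences have exactly zero variance the p-value is undefined and the
    result carries an ``exact_tie`` marker instead.
    """
    if len(results) < 3:
        raise InputError(f"need >= 3 image pairs, got {len(results)}")
    out: dict[str, dict] = {}
    for name, orig_attr, shift_attr in (
        ("M1", "M1", "M1_shift"),
        ("M2", "M2", "M2_shift"),
    ):
        orig = np.array([getattr(r, orig_attr) for r in results])
        shifted = np.array([getattr(r, shift_attr) for r in results])
        ok = np.isfinite(orig) & np.isfinite(shifted)
        if ok.sum() < 3:
            raise InputError(f"fewer than 3 image pairs with defined {name}")
        deltas = orig[ok] - shifted[ok]
        entry = {
            "mean_delta": float(deltas.mean()),
            "n": int(ok.sum()),
            "exact_tie": bool(np.ptp(deltas) == 0),
        }
        if entry["exact_tie"]:
            entry["p_value"] = math.nan
            entry["t_statistic"] = math.nan
        else:
            t, p = stats.ttest_rel(orig[ok], shifted[ok])
            entry["p_value"] = float(p)
            entry["t_statistic"] = float(t)
        out[name] = entry
    return out
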