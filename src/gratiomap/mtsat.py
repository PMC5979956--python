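"""Magnetization-transfer saturation (MTsat) mapping and MVF calibration.

From three differently weighted spoiled gradient-echo (FLASH) volumes —
PD-, T1- and MT-weighted — the apparent longitudinal relaxation rate
``R1app``, apparent signal amplitude ``Aapp`` and apparent MT saturation
``delta_app`` are computed by exact inversion of the rational
small-angle FLASH signal model.  ``delta_app`` is corrected for B1
transmit inhomogeneity (double-angle B1 map, empirical dilution
correction) and linearly calibrated to a myelin volume fraction by
anchoring the mean aggregate g-ratio of a designated calibration region.

Flip angles are accepted in degrees at every interface and converted to
radians internally.  Invalid voxels (non-positive signals, degenerate
denominators) propagate as NaN and are excluded downstream; they are
never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .gratio import compute_avf, compute_gratio

__all__ = [
    "FlashTriplet",
    "MtsatMaps",
    "compute_r1app",
    "compute_aapp",
    "compute_delta_app",
    "compute_mtsat_maps",
    "estimate_b1",
    "correct_delta_b1",
    "calibrate_mvf",
]

_DEG = np.pi / 180.0

B1_CORRECTION_C = 0.4  # empirical dilution constant of the MTsat B1 fix


@dataclass
class FlashTriplet:
    """Three co-registered FLASH volumes plus their protocol.

    Flip angles in degrees, repetition times in seconds.
    """

    s_pd: np.ndarray
    s_t1: np.ndarray
    s_mt: np.ndarray
    alpha_pd_deg: float = 5.0
    alpha_t1_deg: float = 13.0
    alpha_mt_deg: float = 5.0
    tr_pd_s: float = 0.024
    tr_t1_s: float = 0.010
    tr_mt_s: float = 0.024

    def __post_init__(self) -> None:
        self.s_pd = np.asarray(self.s_pd, dtype=float)
        self.s_t1 = np.asarray(self.s_t1, dtype=float)
        self.s_mt = np.asarray(self.s_mt, dtype=float)
        if not (self.s_pd.shape == self.s_t1.shape == self.s_mt.shape):
            raise ValueError("FLASH volumes must share one grid")
        for a in (self.alpha_pd_deg, self.alpha_t1_deg, self.alpha_mt_deg):
            if not 0 < a < 90:
                raise ValueError("flip angles must lie in (0, 90) degrees")
        for tr in (self.tr_pd_s, self.tr_t1_s, self.tr_mt_s):
            if tr <= 0:
                raise ValueError("repetition times must be positive")


@dataclass
class MtsatMaps:
    r1app: np.ndarray  # 1/s
    a_app: np.ndarray  # a.u.
    delta_app: np.ndarray  # saturation fraction (B1-corrected if map given)
    mvf: np.ndarray | None = None
    calibration_factor: float | None = None


def _invalid_to_nan(arr: np.ndarray, bad: np.ndarray) -> np.ndarray:
    out = np.array(arr, dtype=float)
    out[bad] = np.nan
    return out


def compute_r1app(triplet: FlashTriplet) -> np.ndarray:
    """Apparent longitudinal relaxation rate (1/s) from the PD/T1 pair.

    ``R1app = 1/2 * (S_T1 a_T1 / TR_T1 - S_PD a_PD / TR_PD)
    / (S_PD / a_PD - S_T1 / a_T1)``.  Voxels with a non-positive
    denominator are flagged NaN.
    """
    a_pd = triplet.alpha_pd_deg * _DEG
    a_t1 = triplet.alpha_t1_deg * _DEG
    num = (
        triplet.s_t1 * a_t1 / triplet.tr_t1_s
        - triplet.s_pd * a_pd / triplet.tr_pd_s
    )
    den = triplet.s_pd / a_pd - triplet.s_t1 / a_t1
    bad = ~(den > 0) | ~np.isfinite(num)
    # identical-protocol degenerate inputs: zero numerator with zero
    # denominator reduces to R1app = 0 rather than NaN
    zero_over_zero = np.isclose(num, 0.0) & np.isclose(den, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = 0.5 * num / den
    r1 = np.where(zero_over_zero, 0.0, r1)
    return _invalid_to_nan(r1, bad & ~zero_over_zero)


def compute_aapp(triplet: FlashTriplet) -> np.ndarray:
    """Apparent signal amplitude (a.u.), linear in the global signal scale.

    ``Aapp = S_PD S_T1 (TR_PD a_T1/a_PD - TR_T1 a_PD/a_T1)
    / (S_T1 TR_PD a_T1 - S_PD TR_T1 a_PD)``.
    """
    a_pd = triplet.alpha_pd_deg * _DEG
    a_t1 = triplet.alpha_t1_deg * _DEG
    num = triplet.s_pd * triplet.s_t1 * (
        triplet.tr_pd_s * a_t1 / a_pd - triplet.tr_t1_s * a_pd / a_t1
    )
    den = triplet.s_t1 * triplet.tr_pd_s * a_t1 - triplet.s_pd * triplet.tr_t1_s * a_pd
    bad = np.isclose(den, 0.0) | ~np.isfinite(num)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_app = num / den
    return _invalid_to_nan(a_app, bad)


def compute_delta_app(
    s_mt: np.ndarray,
    alpha_mt_deg: float,
    tr_mt_s: float,
    a_app: np.ndarray,
    r1app: np.ndarray,
) -> np.ndarray:
    """Apparent MT saturation (dimensionless fraction).

    ``delta_app = (Aapp a_MT / S_MT - 1) R1app TR_MT - a_MT^2 / 2``.
    Voxels with non-positive MT signal are flagged NaN.
    """
    if tr_mt_s <= 0:
        raise ValueError("repetition time must be positive")
    a_mt = alpha_mt_deg * _DEG
    s_mt = np.asarray(s_mt, dtype=float)
    bad = ~(s_mt > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a_app * a_mt / s_mt - 1.0) * r1app * tr_mt_s - a_mt**2 / 2.0
    return _invalid_to_nan(delta, bad)


def estimate_b1(
    s_low: np.ndarray,
    s_high: np.ndarray,
    alpha_low_deg: float = 10.0,
    median_filter: int = 0,
) -> np.ndarray:
    """Double-angle B1 mapping from acquisitions at alpha and 2*alpha.

    Actual flip = arccos(S_2a / (2 S_a)); returns b1_scale =
    actual / nominal.  Voxels whose ratio leaves (0, 1] are degenerate;
    they fall back to b1 = 1 with a warning.  ``median_filter`` > 0
    applies a median smoothing of that kernel size.
    """
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    if s_low.shape != s_high.shape:
        raise ValueError("B1 pair volumes must share one grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s_high / (2.0 * s_low)
    bad = ~(s_low > 0) | ~(ratio > 0) | (ratio > 1) | ~np.isfinite(ratio)
    # ratio == 1 -> arccos(1) = 0: zero actual flip is equally degenerate
    bad |= np.isclose(ratio, 1.0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} voxel(s) outside the double-angle domain; "
            "falling back to b1 = 1 there",
            stacklevel=2,
        )
    actual = np.arccos(np.clip(ratio, -1.0, 1.0))
    b1 = actual / (alpha_low_deg * _DEG)
    b1 = np.where(bad, 1.0, b1)
    if median_filter > 0:
        from scipy import ndimage

        b1 = ndimage.median_filter(b1, size=median_filter)
    return b1


def correct_delta_b1(
    delta_app: np.ndarray, b1_scale: np.ndarray, c: float = B1_CORRECTION_C
) -> np.ndarray:
    """Empirical B1 dilution correction of the MT saturation map.

    ``delta_corr = delta_app * (1 - c) / (1 - c * b1_scale)``; identity
    at b1 = 1.  Voxels with b1 >= 1/c are flagged NaN.
    """
    b1 = np.asarray(b1_scale, dtype=float)
    if np.any(b1 <= 0):
        raise ValueError("b1_scale must be positive")
    bad = b1 >= 1.0 / c
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.asarray(delta_app, dtype=float) * (1.0 - c) / (1.0 - c * b1)
    return _invalid_to_nan(corr, bad)


def compute_mtsat_maps(
    triplet: FlashTriplet, b1_scale: np.ndarray | None = None
) -> MtsatMaps:
    """R1app, Aapp and (B1-corrected) delta_app from a FLASH triplet."""
    r1app = compute_r1app(triplet)
    a_app = compute_aapp(triplet)
    delta = compute_delta_app(
        triplet.s_mt, triplet.alpha_mt_deg, triplet.tr_mt_s, a_app, r1app
    )
    if b1_scale is not None:
        delta = correct_delta_b1(delta, b1_scale)
    return MtsatMaps(r1app=r1app, a_app=a_app, delta_app=delta)


def calibrate_mvf(
    delta: np.ndarray,
    vic: np.ndarray,
    viso: np.ndarray,
    calib_mask: np.ndarray,
    g_target: float = 0.70,
    bracket: tuple[float, float] = (1e-3, 100.0),
    xtol: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Linear delta-to-MVF calibration anchored on a g-ratio target.

    Finds the scalar ``c > 0`` such that the mean aggregate g-ratio over
    ``calib_mask`` — computed with ``MVF = clip(c * delta, 0, 1)`` and
    ``AVF = (1 - MVF)(1 - Viso) Vic`` — equals ``g_target``; bracketed
    1-D root finding (the ROI-mean g is strictly decreasing in ``c``
    wherever delta and Vic are positive).  Returns ``(c, mvf_volume)``
    with the calibration applied to the whole volume.
    """
    mask = np.asarray(calib_mask, dtype=bool)
    if not mask.any():
        raise ValueError("calibration mask is empty")
    d = np.asarray(delta, dtype=float)[mask]
    v = np.asarray(vic, dtype=float)[mask]
    f = np.asarray(viso, dtype=float)[mask]
    ok = np.isfinite(d) & np.isfinite(v) & np.isfinite(f)
    if not ok.any():
        raise ValueError("calibration mask contains no valid voxels")
    d, v, f = d[ok], v[ok], f[ok]

    def mean_g(c: float) -> float:
        mvf = np.clip(c * d, 0.0, 1.0)
        avf = compute_avf(mvf, f, v)
        g = compute_gratio(avf, mvf)
        return float(np.nanmean(g))

    lo, hi = bracket
    g_lo, g_hi = mean_g(lo), mean_g(hi)
    attainable = sorted((g_hi, g_lo))
    if not attainable[0] - 1e-12 <= g_target <= attainable[1] + 1e-12:
        raise ValueError(
            f"g_target {g_target} unreachable by calibration: attainable "
            f"ROI-mean g range is [{attainable[0]:.4f}, {attainable[1]:.4f}]"
        )
    c = brentq(lambda x: mean_g(x) - g_target, lo, hi, xtol=xtol, rtol=1e-12)
    mvf_volume = np.clip(c * np.asarray(delta, dtype=float), 0.0, 1.0)
    return float(c), mvf_volume
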