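"""Fluorescence and absorbance indices characterizing FDOM source and quality.

Fluorescence indices (FI, BIX, HIX) are ratios of Raman-normalized intensities
at fixed excitation/emission coordinates and are therefore invariant to global
intensity scaling. Absorbance-derived quantities (SUVA254, spectral slopes and
their ratio SR) come from the decadic absorbance spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eem import EEM, AbsorbanceSpectrum, WL_TOL
from .errors import DomainError, UndefinedIndexError

__all__ = [
    "OpticalIndices",
    "fluorescence_index",
    "biological_index",
    "humification_index",
    "suva254",
    "spectral_slope",
    "slope_ratio",
    "compute_indices",
]


@dataclass(frozen=True)
class OpticalIndices:
    sample_id: str
    fi: float
    bix: float
    hix: float
    suva254: float | None = None
    s275_295: float | None = None
    s350_400: float | None = None
    sr: float | None = None


def _ratio(eem: EEM, ex: float, em_num: float, em_den: float) -> float:
    try:
        num = eem.value_at(ex, em_num)
        den = eem.value_at(ex, em_den)
    except DomainError as exc:
        raise UndefinedIndexError(f"index wavelengths unavailable: {exc}") from exc
    if den == 0:
        raise UndefinedIndexError(
            f"zero denominator intensity at (ex={ex}, em={em_den}) for {eem.sample_id!r}"
        )
    return num / den


def fluorescence_index(eem: EEM, emission_pair: tuple[float, float] = (470.0, 520.0),
                       ex: float = 370.0) -> float:
    """FI: intensity(ex 370, em 470) / intensity(ex 370, em 520).

    Values below ~1.4 indicate predominantly terrestrial FDOM, above ~1.9
    predominantly microbial/endogenous. The legacy 450/500 nm emission pair is
    available via ``emission_pair``.
    """
    return _ratio(eem, ex, emission_pair[0], emission_pair[1])


def biological_index(eem: EEM, ex: float = 310.0,
                     emission_pair: tuple[float, float] = (380.0, 430.0)) -> float:
    """BIX: intensity(ex 310, em 380) / intensity(ex 310, em 430)."""
    return _ratio(eem, ex, emission_pair[0], emission_pair[1])


def _band_sum(eem: EEM, ex: float, band: tuple[float, float]) -> float:
    # closed band resampled to a 1 nm comb so the sum is grid-independent
    lo, hi = band
    if eem.em_nm[0] > lo + WL_TOL or eem.em_nm[-1] < hi - WL_TOL or \
            not (eem.ex_nm[0] - WL_TOL <= ex <= eem.ex_nm[-1] + WL_TOL):
        raise UndefinedIndexError(
            f"band {band} at ex {ex} nm not covered by EEM grid for {eem.sample_id!r}"
        )
    scan = eem.emission_scan(ex)
    comb = np.arange(lo, hi + 0.5)
    return float(np.interp(comb, eem.em_nm, scan).sum())


def humification_index(eem: EEM, variant: str = "zsolnay", ex: float = 254.0,
                       humic_band: tuple[float, float] = (435.0, 480.0),
                       protein_band: tuple[float, float] = (300.0, 345.0)) -> float:
    """HIX at excitation 254 nm.

    ``zsolnay`` (default) returns H/L; ``ohno`` returns H/(H+L), where H and L
    are the emission band sums over 435–480 nm and 300–345 nm.
    """
    if variant not in {"zsolnay", "ohno"}:
        raise UndefinedIndexError(f"unknown HIX variant {variant!r}")
    h = _band_sum(eem, ex, humic_band)
    l = _band_sum(eem, ex, protein_band)
    if variant == "zsolnay":
        if l == 0:
            raise UndefinedIndexError(f"HIX undefined: zero 300–345 nm band for {eem.sample_id!r}")
        return h / l
    if h + l == 0:
        raise UndefinedIndexError(f"HIX undefined: zero total band for {eem.sample_id!r}")
    return h / (h + l)


def suva254(absorbance: AbsorbanceSpectrum, doc_mg_per_l: float) -> float:
    """SUVA254 in L·mg⁻¹·m⁻¹: 1 cm-path absorbance at 254 nm × 100 / DOC."""
    if doc_mg_per_l <= 0:
        raise UndefinedIndexError("DOC concentration must be positive")
    try:
        a254 = absorbance.at(254.0)
    except DomainError as exc:
        raise UndefinedIndexError(str(exc)) from exc
    return a254 * 100.0 / doc_mg_per_l


def spectral_slope(absorbance: AbsorbanceSpectrum, band: tuple[float, float]) -> float:
    """Exponential spectral slope S (nm⁻¹) over ``band``.

    Fits ``ln a`` against wavelength by least squares, where
    ``a = 2.303 * A / pathlength_m`` is the Napierian absorption coefficient;
    returns the negated regression slope.
    """
    lo, hi = band
    sel = (absorbance.wl_nm >= lo - WL_TOL) & (absorbance.wl_nm <= hi + WL_TOL)
    if sel.sum() < 5:
        raise UndefinedIndexError(f"fewer than 5 wavelengths in band {band}")
    wl = absorbance.wl_nm[sel]
    path_m = absorbance.pathlength_cm / 100.0
    a = 2.303 * absorbance.absorbance[sel] / path_m
    if np.any(a <= 0):
        bad = wl[a <= 0]
        raise UndefinedIndexError(
            f"non-positive absorbance in band {band} at wavelengths {bad.tolist()}"
        )
    slope = np.polyfit(wl, np.log(a), 1)[0]
    return float(-slope)


def slope_ratio(absorbance: AbsorbanceSpectrum,
                uv_band: tuple[float, float] = (275.0, 295.0),
                vis_band: tuple[float, float] = (350.0, 400.0)) -> float:
    """SR = S(275–295) / S(350–400); inversely related to DOM molecular weight."""
    s_uv = spectral_slope(absorbance, uv_band)
    s_vis = spectral_slope(absorbance, vis_band)
    if s_vis == 0:
        raise UndefinedIndexError("SR undefined: zero long-wavelength slope")
    return s_uv / s_vis


def compute_indices(eem: EEM, absorbance: AbsorbanceSpectrum | None = None,
                    doc_mg_per_l: float | None = None,
                    hix_variant: str = "zsolnay") -> OpticalIndices:
    """All indices for one sample; absorbance-based ones are None without a spectrum."""
    suva = s_uv = s_vis = sr = None
    if absorbance is not None:
        s_uv = spectral_slope(absorbance, (275.0, 295.0))
        s_vis = spectral_slope(absorbance, (350.0, 400.0))
        sr = s_uv / s_vis if s_vis != 0 else None
        if doc_mg_per_l is not None:
            suva = suva254(absorbance, doc_mg_per_l)
    return OpticalIndices(
        sample_id=eem.sample_id,
        fi=fluorescence_index(eem),
        bix=biological_index(eem),
        hix=humification_index(eem, variant=hix_variant),
        suva254=suva,
        s275_295=s_uv,
        s350_400=s_vis,
        sr=sr,
    )
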