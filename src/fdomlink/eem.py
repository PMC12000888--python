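"""Excitation–emission matrix (EEM) data model, I/O and spectral preprocessing.

An :class:`EEM` stores one sample's fluorescence intensity surface on an
(emission × excitation) wavelength grid together with the ordered set of
corrections already applied to it. Preprocessing operations are pure: each
returns a new :class:`EEM` with the corresponding flag appended, and raises
:class:`~fdomlink.errors.CorrectionError` if asked to apply the same
correction twice.

The supported corrections, in their conventional order:

1. :func:`subtract_blank` — Milli-Q blank subtraction.
2. :func:`inner_filter_correct` — absorbance-based inner-filter correction,
   ``F_corr = F_obs * 10**((A_ex + A_em) / 2)``.
3. :func:`raman_normalize` — division by the integrated Raman scatter peak of
   the blank, putting intensities in Raman units (RU).
4. :func:`excise_and_interpolate_scatter` — removal and interpolation of
   first/second-order Rayleigh and Raman ridges.
5. :func:`trim_wavelengths` — exclusion of signal-free wavelength ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    CorrectionError,
    DomainError,
    FormatError,
    GridError,
    NormalizationError,
    ScatterError,
    TrimError,
)

WL_TOL = 1e-6  # wavelength comparison tolerance, nm

CORRECTION_FLAGS = (
    "blank_subtracted",
    "ife_corrected",
    "raman_normalized",
    "scatter_excised",
    "trimmed",
)


class InnerFilterWarning(UserWarning):
    """Absorbance too high for a reliable inner-filter correction."""


@dataclass(frozen=True)
class EEM:
    """One sample's excitation–emission intensity surface.

    ``intensity`` has shape ``(len(em_nm), len(ex_nm))`` — emission in rows,
    excitation in columns. Missing cells are NaN.
    """

    sample_id: str
    ex_nm: np.ndarray
    em_nm: np.ndarray
    intensity: np.ndarray
    corrections: tuple[str, ...] = ()
    units: str = "arbitrary"

    def __post_init__(self):
        ex = np.asarray(self.ex_nm, dtype=float)
        em = np.asarray(self.em_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ex_nm", ex)
        object.__setattr__(self, "em_nm", em)
        object.__setattr__(self, "intensity", inten)
        if inten.shape != (em.size, ex.size):
            raise GridError(
                f"intensity shape {inten.shape} does not match "
                f"(n_em={em.size}, n_ex={ex.size}) for sample {self.sample_id!r}"
            )
        for wl, name in ((ex, "excitation"), (em, "emission")):
            if wl.size == 0:
                raise GridError(f"empty {name} axis for sample {self.sample_id!r}")
            if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
                raise GridError(f"{name} wavelengths must be finite and positive")
            if np.any(np.diff(wl) <= WL_TOL):
                raise GridError(f"{name} wavelengths must be strictly ascending")
        if len(set(self.corrections)) != len(self.corrections):
            raise CorrectionError("duplicate correction flag")
        for flag in self.corrections:
            if flag not in CORRECTION_FLAGS:
                raise CorrectionError(f"unknown correction flag {flag!r}")
        expected_units = "RU" if "raman_normalized" in self.corrections else "arbitrary"
        if self.units != expected_units:
            raise CorrectionError(
                f"units {self.units!r} inconsistent with corrections {self.corrections}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def has(self, flag: str) -> bool:
        return flag in self.corrections

    def _with_flag(self, flag: str, intensity: np.ndarray, **kw) -> "EEM":
        if self.has(flag):
            raise CorrectionError(f"{flag} already applied to sample {self.sample_id!r}")
        units = "RU" if (flag == "raman_normalized" or self.units == "RU") else "arbitrary"
        return replace(
            self,
            intensity=intensity,
            corrections=self.corrections + (flag,),
            units=units,
            **kw,
        )

    def value_at(self, ex: float, em: float) -> float:
        """Bilinearly interpolated intensity at exact (ex, em) wavelengths."""
        if not (self.ex_nm[0] - WL_TOL <= ex <= self.ex_nm[-1] + WL_TOL):
            raise DomainError(f"excitation {ex} nm outside grid for {self.sample_id!r}")
        if not (self.em_nm[0] - WL_TOL <= em <= self.em_nm[-1] + WL_TOL):
            raise DomainError(f"emission {em} nm outside grid for {self.sample_id!r}")
        interp = RegularGridInterpolator(
            (self.em_nm, self.ex_nm), self.intensity, method="linear"
        )
        return float(interp([[np.clip(em, self.em_nm[0], self.em_nm[-1]),
                              np.clip(ex, self.ex_nm[0], self.ex_nm[-1])]])[0])

    def emission_scan(self, ex: float) -> np.ndarray:
        """Emission scan at excitation ``ex``, linearly interpolated between columns."""
        if not (self.ex_nm[0] - WL_TOL <= ex <= self.ex_nm[-1] + WL_TOL):
            raise DomainError(f"excitation {ex} nm outside grid for {self.sample_id!r}")
        ex = float(np.clip(ex, self.ex_nm[0], self.ex_nm[-1]))
        j = int(np.searchsorted(self.ex_nm, ex + WL_TOL)) - 1
        j = max(0, min(j, self.ex_nm.size - 2))
        x0, x1 = self.ex_nm[j], self.ex_nm[j + 1]
        t = 0.0 if x1 == x0 else (ex - x0) / (x1 - x0)
        return (1 - t) * self.intensity[:, j] + t * self.intensity[:, j + 1]


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Decadic absorbance spectrum for a known cuvette path length."""

    sample_id: str
    wl_nm: np.ndarray
    absorbance: np.ndarray
    pathlength_cm: float = 1.0

    def __post_init__(self):
        wl = np.asarray(self.wl_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wl_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.size != ab.size:
            raise GridError("wavelength and absorbance vectors differ in length")
        if np.any(np.diff(wl) <= 0):
            raise GridError("absorbance wavelengths must be strictly ascending")
        if not np.all(np.isfinite(ab)):
            raise FormatError("non-finite absorbance values")
        if self.pathlength_cm <= 0:
            raise GridError("pathlength must be positive")

    def at(self, wl: float) -> float:
        """Absorbance at ``wl`` (nm), linearly interpolated, scaled to 1 cm path."""
        if wl < self.wl_nm[0] - WL_TOL or wl > self.wl_nm[-1] + WL_TOL:
            raise DomainError(
                f"wavelength {wl} nm outside absorbance coverage "
                f"[{self.wl_nm[0]}, {self.wl_nm[-1]}] for {self.sample_id!r}"
            )
        return float(np.interp(wl, self.wl_nm, self.absorbance)) / self.pathlength_cm


@dataclass
class EEMDataset:
    """A stack of EEMs on one shared grid plus per-sample metadata."""

    eems: list[EEM]
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.eems:
            raise GridError("dataset requires at least one EEM")
        ref = self.eems[0]
        for e in self.eems[1:]:
            if e.ex_nm.size != ref.ex_nm.size or e.em_nm.size != ref.em_nm.size or \
                    np.max(np.abs(e.ex_nm - ref.ex_nm)) > WL_TOL or \
                    np.max(np.abs(e.em_nm - ref.em_nm)) > WL_TOL:
                raise GridError(
                    f"EEM {e.sample_id!r} is not on the shared grid; run harmonize_grid first"
                )
        if self.meta is not None:
            missing = [e.sample_id for e in self.eems if e.sample_id not in self.meta.index]
            if missing:
                raise GridError(f"samples missing from metadata: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.eems]

    @property
    def ex_nm(self) -> np.ndarray:
        return self.eems[0].ex_nm

    @property
    def em_nm(self) -> np.ndarray:
        return self.eems[0].em_nm

    def tensor(self) -> np.ndarray:
        """Stack to (n_samples, n_em, n_ex)."""
        return np.stack([e.intensity for e in self.eems])


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def load_eem_csv(path, dialect: str = "wide_matrix", sample_id: str | None = None) -> EEM:
    """Read a wide-matrix EEM file: emission in the first column, excitation in the header.

    A non-numeric corner cell (e.g. ``Sample``) is ignored. Axes stored in
    descending order are flipped so that the ascending invariant holds.
    """
    if dialect != "wide_matrix":
        raise FormatError(f"unknown EEM dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty EEM file {path}") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed EEM file {path}: {exc}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty EEM grid in {path}")
    try:
        ex = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"non-numeric excitation header in {path}: {exc}") from None
    try:
        em = np.array([float(r) for r in df.index])
    except ValueError as exc:
        raise FormatError(f"non-numeric emission column in {path}: {exc}") from None
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at emission row {df.index[r]!r}, "
            f"excitation column {df.columns[c]!r} in {path}"
        )
    values = values.astype(float)
    if em.size > 1 and np.all(np.diff(em) < 0):
        em, values = em[::-1], values[::-1]
    if ex.size > 1 and np.all(np.diff(ex) < 0):
        ex, values = ex[::-1], values[:, ::-1]
    if np.any(np.diff(em) <= 0):
        raise FormatError(f"non-monotone emission wavelengths in {path}")
    if np.any(np.diff(ex) <= 0):
        raise FormatError(f"non-monotone excitation wavelengths in {path}")
    return EEM(
        sample_id=sample_id or path.stem,
        ex_nm=ex,
        em_nm=em,
        intensity=values,
    )


def write_eem_csv(eem: EEM, path) -> None:
    """Write an EEM as a wide matrix (round-trips with :func:`load_eem_csv`)."""
    path = Path(path)
    df = pd.DataFrame(eem.intensity, index=eem.em_nm, columns=eem.ex_nm)
    df.index.name = "em_nm"
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def load_absorbance_csv(path, sample_id: str | None = None,
                        pathlength_cm: float = 1.0) -> AbsorbanceSpectrum:
    """Read a two-column (wavelength, absorbance) CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty absorbance file {path}") from None
    if df.shape[1] < 2:
        raise FormatError(f"absorbance file {path} needs two columns (wl_nm, A)")
    return AbsorbanceSpectrum(
        sample_id=sample_id or path.stem,
        wl_nm=df.iloc[:, 0].to_numpy(dtype=float),
        absorbance=df.iloc[:, 1].to_numpy(dtype=float),
        pathlength_cm=pathlength_cm,
    )


def load_metadata_tsv(path) -> pd.DataFrame:
    """Read the sample metadata table (TSV, indexed by sample_id)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "matrix_type", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns {sorted(missing)}")
    bad_matrix = set(df["matrix_type"]) - {"water", "sediment"}
    if bad_matrix:
        raise FormatError(f"unknown matrix_type values {sorted(bad_matrix)}")
    bad_group = set(df["group"]) - {"HH", "LH", "R"}
    if bad_group:
        raise FormatError(f"unknown group values {sorted(bad_group)}")
    if "doc_mg_per_L" in df.columns and (df["doc_mg_per_L"].dropna() <= 0).any():
        raise FormatError("doc_mg_per_L must be positive where present")
    return df.set_index("sample_id")


def _check_same_grid(a: EEM, b: EEM) -> None:
    if a.ex_nm.size != b.ex_nm.size or a.em_nm.size != b.em_nm.size or \
            np.max(np.abs(a.ex_nm - b.ex_nm)) > WL_TOL or \
            np.max(np.abs(a.em_nm - b.em_nm)) > WL_TOL:
        raise GridError(
            f"grid mismatch between {a.sample_id!r} {a.shape} and {b.sample_id!r} {b.shape}"
        )


def subtract_blank(eem: EEM, blank: EEM) -> EEM:
    """Subtract a Milli-Q blank scan elementwise. Negative results are kept."""
    _check_same_grid(eem, blank)
    if blank.has("blank_subtracted"):
        raise CorrectionError("blank EEM is itself blank-subtracted")
    return eem._with_flag("blank_subtracted", eem.intensity - blank.intensity)


def inner_filter_correct(eem: EEM, absorbance: AbsorbanceSpectrum,
                         max_reliable_a: float = 1.5) -> EEM:
    """Absorbance-based inner-filter correction.

    ``F_corr(em, ex) = F_obs(em, ex) * 10**((A(ex) + A(em)) / 2)`` with A
    interpolated linearly to the EEM wavelengths and scaled to a 1 cm path.
    Emits :class:`InnerFilterWarning` when any used absorbance exceeds
    ``max_reliable_a``.
    """
    if eem.has("ife_corrected"):
        raise CorrectionError(f"ife_corrected already applied to {eem.sample_id!r}")
    lo = min(eem.ex_nm[0], eem.em_nm[0])
    hi = max(eem.ex_nm[-1], eem.em_nm[-1])
    if absorbance.wl_nm[0] > lo + WL_TOL or absorbance.wl_nm[-1] < hi - WL_TOL:
        raise DomainError(
            f"absorbance coverage [{absorbance.wl_nm[0]}, {absorbance.wl_nm[-1]}] nm "
            f"does not span the EEM range [{lo}, {hi}] nm"
        )
    a_ex = np.interp(eem.ex_nm, absorbance.wl_nm, absorbance.absorbance) / absorbance.pathlength_cm
    a_em = np.interp(eem.em_nm, absorbance.wl_nm, absorbance.absorbance) / absorbance.pathlength_cm
    if max(a_ex.max(), a_em.max()) > max_reliable_a:
        warnings.warn(
            f"absorbance exceeds {max_reliable_a} within the EEM range for "
            f"{eem.sample_id!r}; inner-filter correction is unreliable",
            InnerFilterWarning,
            stacklevel=2,
        )
    factor = 10.0 ** ((a_ex[None, :] + a_em[:, None]) / 2.0)
    return eem._with_flag("ife_corrected", eem.intensity * factor)


def raman_area(blank: EEM, ex_ref: float = 350.0,
               em_band: tuple[float, float] = (371.0, 428.0)) -> float:
    """Trapezoidal integral of the blank's emission scan at ``ex_ref`` over ``em_band``."""
    lo, hi = em_band
    if lo >= hi:
        raise NormalizationError(f"invalid Raman band {em_band}")
    if blank.em_nm[0] > lo + WL_TOL or blank.em_nm[-1] < hi - WL_TOL:
        raise NormalizationError(
            f"blank emission range [{blank.em_nm[0]}, {blank.em_nm[-1]}] does not "
            f"cover the Raman band {em_band}"
        )
    scan = blank.emission_scan(ex_ref)
    inside = (blank.em_nm > lo + WL_TOL) & (blank.em_nm < hi - WL_TOL)
    em_pts = np.concatenate(([lo], blank.em_nm[inside], [hi]))
    vals = np.interp(em_pts, blank.em_nm, scan)
    return float(np.trapezoid(vals, em_pts))


def raman_normalize(eem: EEM, blank: EEM, ex_ref: float = 350.0,
                    em_band: tuple[float, float] = (371.0, 428.0)) -> tuple[EEM, float]:
    """Divide all intensities by the blank's Raman peak area; units become RU."""
    if eem.has("raman_normalized"):
        raise CorrectionError(f"raman_normalized already applied to {eem.sample_id!r}")
    area = raman_area(blank, ex_ref=ex_ref, em_band=em_band)
    if area <= 0:
        raise NormalizationError(f"non-positive Raman area {area}")
    return eem._with_flag("raman_normalized", eem.intensity / area), area


def raman_emission_nm(ex_nm) -> np.ndarray:
    """Emission wavelength of the water Raman scatter line for excitation ``ex_nm``."""
    ex = np.asarray(ex_nm, dtype=float)
    return 1.0 / (1.0 / ex - 0.00036)


@dataclass(frozen=True)
class ScatterWidths:
    """Half-widths (nm) of the scatter ridges; a ridge with width <= 0 is skipped."""

    rayleigh1: float = 10.0
    raman1: float = 5.0
    rayleigh2: float = 10.0


def excise_and_interpolate_scatter(eem: EEM, widths: ScatterWidths | None = None) -> EEM:
    """Excise Rayleigh/Raman scatter ridges and refill along emission.

    Ridge cells are removed and refilled by 1-D linear interpolation along the
    emission axis within each excitation column. The physically signal-free
    region below the first-order Rayleigh line (``em < ex - w``) is zeroed
    rather than interpolated. Cells outside the declared ridges are untouched.
    """
    if eem.has("scatter_excised"):
        raise CorrectionError(f"scatter_excised already applied to {eem.sample_id!r}")
    w = widths or ScatterWidths()
    em = eem.em_nm[:, None]
    ex = eem.ex_nm[None, :]
    mask = np.zeros(eem.shape, dtype=bool)
    if w.rayleigh1 > 0:
        mask |= np.abs(em - ex) <= w.rayleigh1
    if w.raman1 > 0:
        mask |= np.abs(em - raman_emission_nm(eem.ex_nm)[None, :]) <= w.raman1
    if w.rayleigh2 > 0:
        mask |= np.abs(em - 2.0 * ex) <= w.rayleigh2
    out = eem.intensity.copy()
    for j in range(eem.ex_nm.size):
        col_mask = mask[:, j]
        if not col_mask.any():
            continue
        keep = ~col_mask
        if keep.sum() < 2:
            raise ScatterError(
                f"emission scan at excitation {eem.ex_nm[j]} nm fully excised; "
                "cannot interpolate"
            )
        out[col_mask, j] = np.interp(eem.em_nm[col_mask], eem.em_nm[keep],
                                     eem.intensity[keep, j])
    if w.rayleigh1 > 0:
        out[em < ex - w.rayleigh1] = 0.0
    return eem._with_flag("scatter_excised", out)


def trim_wavelengths(eem: EEM, em_max: float = 600.0, ex_min: float = 250.0) -> EEM:
    """Retain emission <= ``em_max`` and excitation >= ``ex_min``."""
    if eem.has("trimmed"):
        raise CorrectionError(f"trimmed already applied to {eem.sample_id!r}")
    keep_em = eem.em_nm <= em_max + WL_TOL
    keep_ex = eem.ex_nm >= ex_min - WL_TOL
    if keep_em.sum() < 2 or keep_ex.sum() < 2:
        raise TrimError(
            f"trim (em_max={em_max}, ex_min={ex_min}) leaves fewer than 2 "
            f"wavelengths on an axis for {eem.sample_id!r}"
        )
    return eem._with_flag(
        "trimmed",
        eem.intensity[np.ix_(keep_em, keep_ex)],
        em_nm=eem.em_nm[keep_em],
        ex_nm=eem.ex_nm[keep_ex],
    )


def harmonize_grid(eems: list[EEM], meta: pd.DataFrame | None = None) -> EEMDataset:
    """Interpolate every EEM onto the shared intersection grid.

    The intersection grid consists of the wavelengths present (within
    tolerance) in every input, restricted to the overlapping range; values are
    obtained by bilinear interpolation (identity for points already on an
    EEM's grid).
    """
    if not eems:
        raise GridError("no EEMs to harmonize")

    def _common(axes: list[np.ndarray]) -> np.ndarray:
        lo = max(a[0] for a in axes)
        hi = min(a[-1] for a in axes)
        base = axes[0][(axes[0] >= lo - WL_TOL) & (axes[0] <= hi + WL_TOL)]
        keep = np.ones(base.size, dtype=bool)
        for a in axes[1:]:
            keep &= np.array([np.min(np.abs(a - v)) <= WL_TOL for v in base],
                             dtype=bool)
        return base[keep]

    ex = _common([e.ex_nm for e in eems])
    em = _common([e.em_nm for e in eems])
    if ex.size < 2 or em.size < 2:
        raise GridError("wavelength grids have an empty (or degenerate) intersection")
    out = []
    for e in eems:
        if e.ex_nm.size == ex.size and e.em_nm.size == em.size and \
                np.max(np.abs(e.ex_nm - ex)) <= WL_TOL and np.max(np.abs(e.em_nm - em)) <= WL_TOL:
            out.append(e)
            continue
        interp = RegularGridInterpolator((e.em_nm, e.ex_nm), e.intensity, method="linear")
        mesh_em, mesh_ex = np.meshgrid(em, ex, indexing="ij")
        vals = interp(np.column_stack([mesh_em.ravel(), mesh_ex.ravel()])).reshape(em.size, ex.size)
        out.append(replace(e, ex_nm=ex, em_nm=em, intensity=vals))
    return EEMDataset(eems=out, meta=meta)


def preprocess(eem: EEM, blank: EEM, absorbance: AbsorbanceSpectrum, *,
               em_max: float = 600.0, ex_min: float = 250.0,
               widths: ScatterWidths | None = None,
               ex_ref: float = 350.0,
               em_band: tuple[float, float] = (371.0, 428.0)) -> tuple[EEM, float]:
    """Full preprocessing chain: blank, inner-filter, Raman, scatter, trim."""
    e = subtract_blank(eem, blank)
    e = inner_filter_correct(e, absorbance)
    e, area = raman_normalize(e, blank, ex_ref=ex_ref, em_band=em_band)
    e = excise_and_interpolate_scatter(e, widths)
    e = trim_wavelengths(e, em_max=em_max, ex_min=ex_min)
    return e, area
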