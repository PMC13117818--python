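"""Spectral data structures and colorimetric projection.

The pipeline models the light radiating from a fluorescent-tracer-covered
surface as a linear mixture of source spectra.  Each source is represented by
its *spectral power density function* (SPDF): the spectrum renormalized to
integrate to 1 over the visible range, so that it carries only chromaticity
(shape) and no radiant power (scale).  Projecting an SPDF through the XYZ
color-matching functions yields a tristimulus 3-vector; stacking the white,
skin, and fluorophore columns gives the 3x3 design matrix used by both the
matched filter and the non-negative least-squares decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VISIBLE_NM",
    "DEFAULT_GRID_NM",
    "DEFAULT_BASIS",
    "Spectrum",
    "SPDF",
    "CMFSet",
    "ProjectionBasis",
    "resample",
    "normalize_to_spdf",
    "skin_radiance",
    "mean_skin_spdf",
    "project_to_xyz",
    "build_design_matrix",
    "default_cmfs",
    "analytic_cmfs",
    "read_spectrum_csv",
    "read_spectrum_xlsx",
]

#: Visible domain V used for every quadrature, in nanometers.
VISIBLE_NM = (390.0, 830.0)

#: Default working grid: 1 nm steps over V (441 samples).
DEFAULT_GRID_NM = np.arange(VISIBLE_NM[0], VISIBLE_NM[1] + 1.0, 1.0)

_VALID_LABELS = frozenset({"illuminant", "reflectance", "emission", "radiance"})


def _check_grid(wavelengths_nm: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least 2 samples")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if wl[0] < 200.0 or wl[-1] > 1000.0:
        raise ValueError("wavelengths must lie within [200, 1000] nm")
    return wl


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing grid in nanometers, within [200, 1000].
    values
        Non-negative spectral magnitudes (arbitrary radiometric units per nm).
        Reflectance-labelled spectra must additionally lie in [0, 1].
    label
        Role tag: ``illuminant``, ``reflectance``, ``emission`` or ``radiance``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str = "radiance"

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths_nm)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != wl.shape:
            raise ValueError("values and wavelengths must have the same shape")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectral values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectral values must be non-negative")
        if self.label not in _VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "reflectance" and np.any(vals > 1.0):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SPDF:
    """A spectrum normalized to unit integral over the visible range.

    The density is defined on a grid restricted to V = [390, 830] nm and
    integrates to 1 (trapezoidal quadrature) within 1e-9.  SPDFs can be read
    as conditional probability densities over photon wavelength given the
    source, so mixtures of sources are convex/conic combinations of SPDFs.
    """

    wavelengths_nm: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths_nm)
        if wl[0] < VISIBLE_NM[0] - 1e-9 or wl[-1] > VISIBLE_NM[1] + 1e-9:
            raise ValueError("SPDF grid must lie within the visible range")
        dens = np.asarray(self.density, dtype=float)
        if dens.shape != wl.shape:
            raise ValueError("density and wavelengths must have the same shape")
        if np.any(dens < 0):
            raise ValueError("SPDF density must be non-negative")
        integral = np.trapezoid(dens, wl)
        if abs(integral - 1.0) > 1e-9:
            raise ValueError(f"SPDF must integrate to 1 over V (got {integral!r})")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "density", dens)


@dataclass(frozen=True)
class CMFSet:
    """XYZ color-matching functions tabulated on a common grid."""

    wavelengths_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths_nm)
        for name in ("xbar", "ybar", "zbar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelengths_nm", wl)


@dataclass(frozen=True)
class ProjectionBasis:
    """The 3x3 design matrix of tristimulus columns [L(w), L(s), L(f)].

    ``white_col`` is exactly (1, 1, 1) by definition; ``skin_col`` and
    ``fluor_col`` are the XYZ projections of the skin and fluorophore SPDFs.
    """

    skin_col: np.ndarray
    fluor_col: np.ndarray
    white_col: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        for name in ("white_col", "skin_col", "fluor_col"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        if not np.array_equal(self.white_col, np.ones(3)):
            raise ValueError("white_col must be exactly (1, 1, 1)")
        if np.any(self.skin_col < 0) or np.any(self.fluor_col < 0):
            raise ValueError("skin_col and fluor_col must be entrywise >= 0")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("basis columns are collinear (singular design matrix)")

    @property
    def matrix(self) -> np.ndarray:
        """Stacked 3x3 design matrix with columns (white, skin, fluor)."""
        return np.column_stack([self.white_col, self.skin_col, self.fluor_col])


#: Default projection basis for the UV-illuminated skin + blue fluorophore
#: setup, computed from measured spectra under the CIE 2-degree XYZ CMFs.
DEFAULT_BASIS = ProjectionBasis(
    skin_col=np.array([0.0914, 0.0702, 0.3381]),
    fluor_col=np.array([0.2149, 0.1614, 1.1198]),
)


# ---------------------------------------------------------------------------
# Operations


def resample(spec: Spectrum, grid, *, extrapolate: bool = False) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    Values outside the source support are set to 0, which is only permitted
    when ``extrapolate=True``; otherwise the target grid must lie inside the
    convex hull of the source grid.
    """
    grid = _check_grid(np.asarray(grid, dtype=float))
    src = spec.wavelengths_nm
    if not extrapolate and (grid[0] < src[0] - 1e-12 or grid[-1] > src[-1] + 1e-12):
        raise ValueError(
            "target grid extends beyond the source support; "
            "pass extrapolate=True to zero-fill outside it"
        )
    vals = np.interp(grid, src, spec.values, left=0.0, right=0.0)
    return Spectrum(grid, vals, spec.label)


def _restrict_to_visible(spec: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """Resample onto the default 1 nm visible grid, zero outside support."""
    vals = np.interp(
        DEFAULT_GRID_NM, spec.wavelengths_nm, spec.values, left=0.0, right=0.0
    )
    return DEFAULT_GRID_NM, vals


def normalize_to_spdf(spec: Spectrum) -> SPDF:
    """Normalize a spectrum to unit integral over the visible range.

    The spectrum is first restricted (resampled, zero-filled) to the default
    1 nm grid on V = [390, 830] nm, then divided by its trapezoidal integral.
    Raises ``ValueError`` if the visible integral is not strictly positive.
    """
    grid, vals = _restrict_to_visible(spec)
    integral = np.trapezoid(vals, grid)
    if integral <= 0:
        raise ValueError("spectrum has non-positive integral over the visible range")
    return SPDF(grid, vals / integral)


def skin_radiance(reflectance: Spectrum, illuminant: Spectrum) -> Spectrum:
    """Radiance of skin under an illuminant: pointwise product R(l) * P(l)."""
    if reflectance.wavelengths_nm.shape != illuminant.wavelengths_nm.shape or not np.allclose(
        reflectance.wavelengths_nm, illuminant.wavelengths_nm
    ):
        raise ValueError("reflectance and illuminant must share a wavelength grid")
    return Spectrum(
        reflectance.wavelengths_nm,
        reflectance.values * illuminant.values,
        "radiance",
    )


def mean_skin_spdf(reflectances: list[Spectrum], illuminant: Spectrum) -> SPDF:
    """Population skin chromaticity: mean of per-subject radiance SPDFs.

    Each subject's radiance R_k(l) * P(l) is normalized to an SPDF before
    averaging, so per-subject radiant power (overall skin brightness) cancels
    and only chromatic shape differences survive.  Under a narrowband
    illuminant those shape differences are tiny, which is what makes a single
    mean skin column adequate for the whole population.
    """
    if len(reflectances) == 0:
        raise ValueError("need at least one reflectance curve")
    densities = []
    for refl in reflectances:
        common = illuminant
        if refl.wavelengths_nm.shape != illuminant.wavelengths_nm.shape or not np.allclose(
            refl.wavelengths_nm, illuminant.wavelengths_nm
        ):
            common = resample(illuminant, refl.wavelengths_nm, extrapolate=True)
        spdf = normalize_to_spdf(skin_radiance(refl, common))
        densities.append(spdf.density)
    mean_density = np.mean(densities, axis=0)
    # Mean of unit-integral densities integrates to 1 up to roundoff;
    # renormalize so the SPDF invariant holds exactly.
    mean_density = mean_density / np.trapezoid(mean_density, DEFAULT_GRID_NM)
    return SPDF(DEFAULT_GRID_NM, mean_density)


def project_to_xyz(spdf: SPDF, cmfs: CMFSet) -> np.ndarray:
    """Tristimulus coordinates of a density: L(t) = integral of CMFs * t.

    The CMFs are resampled onto the density's grid (zero outside their
    tabulated support) and integrated by the trapezoid rule.
    """
    wl = spdf.wavelengths_nm
    out = np.empty(3)
    for i, bar in enumerate((cmfs.xbar, cmfs.ybar, cmfs.zbar)):
        bar_on_grid = np.interp(wl, cmfs.wavelengths_nm, bar, left=0.0, right=0.0)
        out[i] = np.trapezoid(bar_on_grid * spdf.density, wl)
    return out


def build_design_matrix(
    skin: SPDF | None = None,
    fluor: SPDF | None = None,
    cmfs: CMFSet | None = None,
) -> ProjectionBasis:
    """Assemble the projection basis [L(w), L(s), L(f)].

    With no arguments, returns the shipped default basis.  Otherwise the skin
    and fluorophore columns are the XYZ projections of the given SPDFs and
    the white column is (1, 1, 1) by definition.
    """
    if skin is None and fluor is None:
        return DEFAULT_BASIS
    if skin is None or fluor is None:
        raise ValueError("provide both skin and fluor SPDFs, or neither")
    if cmfs is None:
        cmfs = default_cmfs()
    return ProjectionBasis(
        skin_col=project_to_xyz(skin, cmfs),
        fluor_col=project_to_xyz(fluor, cmfs),
    )


# ---------------------------------------------------------------------------
# Color-matching functions


def _piecewise_gaussian(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def analytic_cmfs(grid=None) -> CMFSet:
    """Multi-lobe Gaussian analytic model of the CIE 2-degree XYZ CMFs.

    Evaluates the piecewise-Gaussian fits of Wyman, Sloan & Shirley (J.
    Comput. Graph. Tech. 2013) on the requested grid.  Small negative values
    from the fit's correction lobe are clipped to zero so the result
    satisfies the CMF non-negativity invariant.
    """
    wl = DEFAULT_GRID_NM if grid is None else _check_grid(np.asarray(grid, float))
    x = (
        1.056 * _piecewise_gaussian(wl, 599.8, 37.9, 31.0)
        + 0.362 * _piecewise_gaussian(wl, 442.0, 16.0, 26.7)
        - 0.065 * _piecewise_gaussian(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _piecewise_gaussian(wl, 568.8, 46.9, 40.5) + 0.286 * _piecewise_gaussian(
        wl, 530.9, 16.3, 31.1
    )
    z = 1.217 * _piecewise_gaussian(wl, 437.0, 11.8, 36.0) + 0.681 * _piecewise_gaussian(
        wl, 459.0, 26.0, 13.8
    )
    return CMFSet(wl, np.clip(x, 0.0, None), np.clip(y, 0.0, None), np.clip(z, 0.0, None))


def default_cmfs() -> CMFSet:
    """Load the shipped 1 nm CMF table (analytic 2-degree XYZ model)."""
    with resources.files("glowsplit.data").joinpath("cmf_xyz_2deg_1nm.csv").open() as fh:
        df = pd.read_csv(fh)
    return CMFSet(
        df["wavelength_nm"].to_numpy(float),
        df["xbar"].to_numpy(float),
        df["ybar"].to_numpy(float),
        df["zbar"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Spectral table readers


def _frame_to_spectrum(df: pd.DataFrame, label: str) -> Spectrum:
    if df.shape[1] < 2:
        raise ValueError("spectral table needs at least two columns")
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(float)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(float)
    keep = np.isfinite(wl) & np.isfinite(vals)
    order = np.argsort(wl[keep])
    return Spectrum(wl[keep][order], vals[keep][order], label)


def read_spectrum_csv(path: str | Path, label: str = "radiance") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV with a one-line header.

    Extra columns are ignored.
    """
    return _frame_to_spectrum(pd.read_csv(path), label)


def read_spectrum_xlsx(path: str | Path, label: str = "radiance") -> Spectrum:
    """Read the first sheet of an .xlsx workbook as a two-column spectrum."""
    return _frame_to_spectrum(pd.read_excel(path, sheet_name=0), label)
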