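"""Optical-property primitives: spectra, Beer–Lambert extraction, media tables.

Units are fixed throughout the package: wavelengths in nm, lengths in mm,
absorption and scattering coefficients in mm^-1.  Anisotropy ``g`` and
refractive index ``n`` are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "OpticalProperties",
    "Medium",
    "MediumTable",
    "AMBIENT_ID",
    "beer_lambert_mua",
    "scale_concentration",
    "mus_from_reduced",
    "read_spectrum",
    "write_spectrum",
]

AMBIENT_ID = 0

_WL_MIN, _WL_MAX = 400.0, 1000.0


@dataclass(frozen=True)
class Spectrum:
    """A sampled per-wavelength scalar (coefficient in mm^-1 or dimensionless).

    ``wavelengths`` must be strictly increasing and lie within
    [400, 1000] nm; values must be finite.  Evaluation off the grid uses
    linear interpolation and refuses to extrapolate.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size or wl.size == 0:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < _WL_MIN or wl[-1] > _WL_MAX:
            raise ValueError(f"wavelengths must lie within [{_WL_MIN}, {_WL_MAX}] nm")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def __call__(self, wavelength):
        """Interpolate linearly at ``wavelength`` (nm); error on extrapolation."""
        wl = np.asarray(wavelength, dtype=float)
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength outside tabulated range "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        out = np.interp(wl, self.wavelengths, self.values)
        return float(out) if np.isscalar(wavelength) else out

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * float(factor))


@dataclass(frozen=True)
class OpticalProperties:
    """(mua, mus, g, n) of one medium at one wavelength."""

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mus_prime(self) -> float:
        """Reduced scattering coefficient mus * (1 - g), mm^-1."""
        return self.mus * (1.0 - self.g)


@dataclass
class Medium:
    """A named medium whose mua/mus may be spectra or constants.

    ``g`` and ``n`` are wavelength-independent here; tissue dispersion of
    both is weak over 450-900 nm compared with the mua/mus spectra that
    drive every trend this package studies.
    """

    name: str
    mua: "Spectrum | float" = 0.0
    mus: "Spectrum | float" = 0.0
    g: float = 0.9
    n: float = 1.4

    def at(self, wavelength: float) -> OpticalProperties:
        mua = self.mua(wavelength) if isinstance(self.mua, Spectrum) else float(self.mua)
        mus = self.mus(wavelength) if isinstance(self.mus, Spectrum) else float(self.mus)
        return OpticalProperties(mua=mua, mus=mus, g=self.g, n=self.n)


@dataclass
class MediumTable:
    """Integer-labelled media; id 0 is reserved for the ambient medium."""

    media: dict[int, Medium] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if AMBIENT_ID not in self.media:
            self.media = {AMBIENT_ID: Medium("ambient", 0.0, 0.0, 0.0, 1.0), **self.media}
        for mid in self.media:
            if not (0 <= int(mid) == mid):
                raise ValueError("medium ids must be small non-negative integers")

    def __getitem__(self, mid: int) -> Medium:
        return self.media[mid]

    def __contains__(self, mid: int) -> bool:
        return mid in self.media

    @property
    def n_media(self) -> int:
        return max(self.media) + 1

    def ids(self):
        return sorted(self.media)

    def arrays(self, wavelength: float):
        """Dense (mua, mus, g, n) arrays indexed by medium id, for the kernel."""
        n = self.n_media
        mua = np.zeros(n)
        mus = np.zeros(n)
        g = np.zeros(n)
        nn = np.ones(n)
        for mid, med in self.media.items():
            op = med.at(wavelength)
            mua[mid], mus[mid], g[mid], nn[mid] = op.mua, op.mus, op.g, op.n
        if not (np.all(np.isfinite(mua)) and np.all(np.isfinite(mus))):
            raise ValueError("non-finite optical properties")
        return mua, mus, g, nn


def beer_lambert_mua(transmission: float, pathlength: float) -> float:
    """Absorption coefficient from a collimated transmission measurement.

    mua = -ln(T) / L, the Beer-Lambert inversion used to characterise
    chromophore stock solutions in a cuvette of pathlength ``L`` (mm).
    """
    if not 0.0 < transmission <= 1.0:
        raise ValueError("transmission must lie in (0, 1]")
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    return -np.log(transmission) / pathlength


def scale_concentration(base: Spectrum, base_conc: float, target_conc: float) -> Spectrum:
    """Rescale an absorption spectrum linearly with chromophore concentration.

    Beer-Lambert absorption is linear in concentration, so the spectrum
    measured at ``base_conc`` (mg/mL) maps to ``target_conc`` by a single
    multiplicative factor.
    """
    if base_conc <= 0:
        raise ValueError("base concentration must be positive")
    if target_conc < 0:
        raise ValueError("target concentration must be non-negative")
    return base.scaled(target_conc / base_conc)


def mus_from_reduced(mus_prime: float, g: float) -> float:
    """Scattering coefficient from the reduced coefficient: mus = mus' / (1 - g)."""
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    if mus_prime < 0:
        raise ValueError("mus_prime must be non-negative")
    return mus_prime / (1.0 - g)


def read_spectrum(path: "str | Path") -> Spectrum:
    """Read a two-column (wavelength_nm, value) delimited text file.

    Lines starting with '#' are comments; whitespace or commas delimit.
    """
    data = np.loadtxt(path, comments="#", delimiter=None if _sniff_ws(path) else ",")
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    return Spectrum(data[:, 0], data[:, 1])


def _sniff_ws(path) -> bool:
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                return "," not in s
    return True


def write_spectrum(path: "str | Path", spectrum: Spectrum, header: str = "") -> None:
    """Write the two-column dialect that :func:`read_spectrum` reads."""
    lines = []
    if header:
        lines.extend(f"# {ln}" for ln in header.splitlines())
    lines.append("# wavelength_nm value")
    for wl, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{wl:.6g} {v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
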