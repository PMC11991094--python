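"""Default chromophore spectra and ready-made media tables.

These are parameterized, literature-shaped *defaults*, not measured ground
truth: an oxyhemoglobin-shaped absorption spectrum with the characteristic
540/577 nm double peak, a melanin-like power-law decay shared by India ink
and epidermal melanin, a power-law Intralipid reduced-scattering spectrum,
and weak water/baseline terms for bloodless dermis.  Every helper accepts
user-supplied spectra in their place; the package's conclusions are about
orderings driven by these spectral *shapes*, which are robust to the exact
amplitudes chosen here.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .optics import Medium, MediumTable, Spectrum, mus_from_reduced

__all__ = [
    "DEFAULT_GRID",
    "SKIN_GRID",
    "hb_mua",
    "ink_mua",
    "intralipid_mus_prime",
    "epidermis_mua",
    "dermis_baseline_mua",
    "water_mua",
    "phantom_media",
    "skin_media",
    "PHANTOM_TOP_ID",
    "PHANTOM_BOTTOM_ID",
    "EPIDERMIS_ID",
    "DERMIS_ID",
    "BLOOD_ID",
]

#: Instrument band of the phantom pipeline: 450-900 nm at 2 nm.
DEFAULT_GRID = np.arange(450.0, 900.0 + 1e-9, 2.0)
#: Extended grid for skin simulations that include the 945 nm NIR line.
SKIN_GRID = np.arange(450.0, 1000.0 + 1e-9, 2.0)

# Approximate oxyhemoglobin absorption per unit concentration,
# mm^-1 per (mg/mL), sampled at control points and interpolated
# monotonically in log space.  Shape features that matter downstream:
# the 540 and 577 nm peaks, the deep red-NIR window, and the mild NIR
# rise toward 900-1000 nm.
_HB_TABLE_NM = np.array(
    [400.0, 430.0, 450.0, 480.0, 500.0, 520.0, 530.0, 540.0, 548.0, 555.0,
     560.0, 568.0, 577.0, 585.0, 590.0, 600.0, 620.0, 650.0, 700.0, 750.0,
     800.0, 850.0, 900.0, 945.0, 1000.0]
)
_HB_TABLE_MM1_PER_MGML = np.array(
    [0.83, 1.90, 0.225, 0.095, 0.072, 0.090, 0.140, 0.190, 0.160, 0.115,
     0.100, 0.140, 0.215, 0.130, 0.090, 0.0115, 0.0030, 0.0013, 0.0010,
     0.0019, 0.0029, 0.0038, 0.0043, 0.0046, 0.0048]
)
_HB_INTERP = PchipInterpolator(_HB_TABLE_NM, np.log(_HB_TABLE_MM1_PER_MGML))


def hb_mua(concentration_mg_ml: float, wavelengths: np.ndarray = DEFAULT_GRID) -> Spectrum:
    """Hemoglobin absorption spectrum (mm^-1) at the given concentration."""
    if concentration_mg_ml < 0:
        raise ValueError("concentration must be non-negative")
    wl = np.asarray(wavelengths, dtype=float)
    return Spectrum(wl, concentration_mg_ml * np.exp(_HB_INTERP(wl)))


def ink_mua(fraction_v_v_pct: float = 1.0, wavelengths: np.ndarray = DEFAULT_GRID,
            mua_500: float = 2.0, exponent: float = 3.0) -> Spectrum:
    """Melanin-like monotone power-law absorber (India ink surrogate).

    mua(lambda) = mua_500 * (500/lambda)^exponent per 1% v/v, scaled
    linearly with the volume fraction.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return Spectrum(wl, fraction_v_v_pct * mua_500 * (500.0 / wl) ** exponent)


def intralipid_mus_prime(fraction_w_v_pct: float = 1.0,
                         wavelengths: np.ndarray = DEFAULT_GRID,
                         mus_prime_500: float = 1.7, exponent: float = 2.4) -> Spectrum:
    """Reduced scattering of an Intralipid suspension, mm^-1 (power law)."""
    wl = np.asarray(wavelengths, dtype=float)
    return Spectrum(wl, fraction_w_v_pct * mus_prime_500 * (500.0 / wl) ** exponent)


def epidermis_mua(melanin_fraction: float = 0.30,
                  wavelengths: np.ndarray = SKIN_GRID) -> Spectrum:
    """Epidermal absorption from a melanosome volume fraction.

    Uses the standard melanosome power law mua = 6.6e10 * lambda^-3.33 mm^-1
    (lambda in nm); 0.30 corresponds to a heavily pigmented epidermis.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return Spectrum(wl, melanin_fraction * 6.6e10 * wl ** -3.33)


_WATER_NM = np.array([400.0, 500.0, 550.0, 600.0, 650.0, 700.0, 750.0,
                      800.0, 850.0, 900.0, 950.0, 1000.0])
_WATER_MM1 = np.array([6.6e-6, 2.5e-6, 4.5e-6, 2.2e-5, 3.2e-5, 6.0e-5,
                       2.6e-4, 2.0e-4, 4.3e-4, 6.8e-4, 3.9e-3, 3.6e-3])
_WATER_INTERP = PchipInterpolator(_WATER_NM, np.log(_WATER_MM1))


def water_mua(wavelengths: np.ndarray = SKIN_GRID) -> Spectrum:
    """Pure-water absorption, mm^-1 (log-interpolated sparse table)."""
    wl = np.asarray(wavelengths, dtype=float)
    return Spectrum(wl, np.exp(_WATER_INTERP(wl)))


def dermis_baseline_mua(water_fraction: float = 0.65,
                        wavelengths: np.ndarray = SKIN_GRID) -> Spectrum:
    """Bloodless dermis absorption: weak tissue baseline plus water."""
    wl = np.asarray(wavelengths, dtype=float)
    baseline = 0.00244 + 0.853 * np.exp(-(wl - 154.0) / 66.2)
    return Spectrum(wl, baseline + water_fraction * np.exp(_WATER_INTERP(wl)))


# -- medium tables ----------------------------------------------------------

PHANTOM_TOP_ID, PHANTOM_BOTTOM_ID = 1, 2
EPIDERMIS_ID, DERMIS_ID, BLOOD_ID = 1, 2, 3

#: defaults: g/n for soft-gel phantoms and for skin layers
PHANTOM_G, PHANTOM_N = 0.75, 1.33
SKIN_G, SKIN_N = 0.9, 1.40


def phantom_media(hb_conc_mg_ml: float, ink_pct: float = 1.0, lipid_pct: float = 1.0,
                  wavelengths: np.ndarray = DEFAULT_GRID,
                  g: float = PHANTOM_G, n: float = PHANTOM_N) -> MediumTable:
    """Two-layer gel phantom: ink+lipid top (id 1) over Hb+lipid bottom (id 2)."""
    musp = intralipid_mus_prime(lipid_pct, wavelengths)
    mus = Spectrum(musp.wavelengths, musp.values / (1.0 - g))
    return MediumTable({
        PHANTOM_TOP_ID: Medium("ink+lipid gel", ink_mua(ink_pct, wavelengths), mus, g, n),
        PHANTOM_BOTTOM_ID: Medium("Hb+lipid gel", hb_mua(hb_conc_mg_ml, wavelengths), mus, g, n),
    })


def skin_media(melanin_fraction: float = 0.30, blood_hb_mg_ml: float = 150.0,
               wavelengths: np.ndarray = SKIN_GRID,
               g: float = SKIN_G, n: float = SKIN_N) -> MediumTable:
    """Heavily pigmented skin: epidermis (1), bloodless dermis (2), whole blood (3).

    Scattering follows tissue power laws (dermis/epidermis mus' = 4.6*(500/wl)^1.42,
    blood mus' = 2.2*(500/wl)^0.66); absorption combines melanin, dermis
    baseline + water, and whole-blood hemoglobin at ~150 mg/mL.
    """
    wl = np.asarray(wavelengths, dtype=float)
    musp_tissue = 4.6 * (500.0 / wl) ** 1.42
    musp_blood = 2.2 * (500.0 / wl) ** 0.66
    mus_t = Spectrum(wl, musp_tissue / (1.0 - g))
    mus_b = Spectrum(wl, musp_blood / (1.0 - g))
    return MediumTable({
        EPIDERMIS_ID: Medium("epidermis", epidermis_mua(melanin_fraction, wl), mus_t, g, n),
        DERMIS_ID: Medium("dermis", dermis_baseline_mua(wavelengths=wl), mus_t, g, n),
        BLOOD_ID: Medium("blood", hb_mua(blood_hb_mg_ml, wl), mus_b, g, n),
    })
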