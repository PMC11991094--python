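"""Synthetic phantom measurements: the seven-phantom PPG pulse, with noise.

A cardiac pulse is emulated by a series of gel phantoms whose bottom-layer
hemoglobin concentration traces a rise-and-fall arc (default
2.0 -> 3.1 -> 2.0 mg/mL over seven phantoms); each phantom is one phase
point of the pulse.  The forward model produces their DRS spectra either
with the fast diffusion engine or with the Monte Carlo engine at the
instrument's 0.5 mm source-detector distance, and the noise model overlays
multiplicative, wavelength-correlated measurement noise over configurable
replicate sets.  ``emulate_measurement_set`` writes the whole thing to disk
in the measured-spectra format, so the phantom analysis pipeline can be
exercised end to end with no instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .chromophores import (DEFAULT_GRID, PHANTOM_G, PHANTOM_N, hb_mua, ink_mua,
                           intralipid_mus_prime, phantom_media)
from .diffusion import two_layer_neg_log_drs
from .geometry import PhantomSpec, build_phantom_volume
from .optics import Spectrum, write_spectrum

__all__ = [
    "PhantomSeries",
    "NoiseModel",
    "DEFAULT_ARC",
    "forward_drs",
    "add_noise",
    "emulate_measurement_set",
]

#: seven-phantom concentration arc spanning 2.0-3.1 mg/mL (one pulse)
DEFAULT_ARC = (2.0, 2.4, 2.8, 3.1, 2.8, 2.4, 2.0)


@dataclass(frozen=True)
class PhantomSeries:
    """The phantom set emulating one PPG pulse."""

    hb_concentrations: tuple = DEFAULT_ARC
    d_mm: float = 0.0
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    replicates: int = 3
    ink_pct: float = 1.0
    lipid_pct: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.hb_concentrations, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        k = int(np.argmax(c))
        if not (np.all(np.diff(c[:k + 1]) >= 0) and np.all(np.diff(c[k:]) <= 0)
                and c.size >= 2 and k not in (0,)):
            raise ValueError("the concentration arc must rise to a peak and fall")
        if self.d_mm < 0:
            raise ValueError("top layer thickness must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise, correlated along wavelength."""

    rel_sd: float = 0.01
    corr_length_nm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_sd < 0:
            raise ValueError("noise sd must be non-negative")


def forward_drs(series: PhantomSeries, engine: str = "diffusion",
                sdd: float = 0.5, detector_radius: float = 0.2,
                dpf_top: float = 2.0, n_photons: int = 300_000,
                seed: int = 0) -> xr.DataArray:
    """DRS grid (phantom x wavelength) from the forward model.

    engine 'diffusion' evaluates the dipole closed form (with the modified
    Beer-Lambert top-layer correction when D > 0 — an approximation, flagged
    in the result's provenance); engine 'mc' runs the voxel Monte Carlo on
    the two-layer phantom geometry at the same SDD.
    """
    wl = series.wavelengths
    concs = np.asarray(series.hb_concentrations, dtype=float)
    if engine == "diffusion":
        musp = intralipid_mus_prime(series.lipid_pct, wl).values
        mua_top = (ink_mua(series.ink_pct, wl).values
                   if series.d_mm > 0 else np.zeros_like(wl))
        out = np.empty((concs.size, wl.size))
        n_rel = PHANTOM_N
        for i, c in enumerate(concs):
            p = two_layer_neg_log_drs(sdd, mua_top, series.d_mm,
                                      hb_mua(c, wl).values, musp,
                                      n_rel=n_rel, detector_radius=detector_radius,
                                      dpf_top=dpf_top)
            out[i] = np.exp(-p)
        provenance = "diffusion-approx" if series.d_mm > 0 else "diffusion"
    elif engine == "mc":
        from .transport import DetectorSpec, SourceSpec, simulate

        out = np.empty((concs.size, wl.size))
        extent = (4.0, 4.0, 3.0)
        vol = build_phantom_volume(PhantomSpec(series.d_mm), extent=extent,
                                   voxel_size=0.02)
        src = SourceSpec(beam_diameter=0.2, center=(extent[0] / 2, extent[1] / 2))
        det = DetectorSpec(sdd=sdd, radius=detector_radius)
        for i, c in enumerate(concs):
            media = phantom_media(c, series.ink_pct, series.lipid_pct, wl)
            for j, w in enumerate(wl):
                res = simulate(vol, media, src, [det], n_photons,
                               rng=seed, wavelength=float(w))
                out[i, j] = res.detected_weight / res.launched
        provenance = "mc"
    else:
        raise ValueError("engine must be 'diffusion' or 'mc'")
    return xr.DataArray(
        out, dims=("phantom", "wavelength"),
        coords={"phantom": np.arange(concs.size), "wavelength": wl,
                "hb_mg_ml": ("phantom", concs)},
        attrs={"provenance": provenance, "d_mm": series.d_mm, "sdd_mm": sdd})


def _correlated_unit_noise(rng, n_wl: int, wl: np.ndarray, corr_length: float,
                           shape: tuple) -> np.ndarray:
    """Unit-variance Gaussian field, correlated along the last (wavelength) axis."""
    if corr_length <= 0:
        return rng.standard_normal(shape + (n_wl,))
    d = wl[:, None] - wl[None, :]
    cov = np.exp(-0.5 * (d / corr_length) ** 2) + 1e-10 * np.eye(n_wl)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal(shape + (n_wl,))
    return z @ L.T


def add_noise(drs_grid: xr.DataArray, noise: NoiseModel) -> xr.DataArray:
    """Noisy replicate sets of a DRS grid (new leading 'replicate' dim).

    Multiplicative log-normal with mean exactly preserved
    (factor exp(sd*z - sd^2/2)), so replicate means converge to the
    noiseless grid.  Deterministic for a fixed noise seed.
    """
    rng = np.random.default_rng(noise.seed)
    wl = drs_grid.coords["wavelength"].values
    n_rep = int(drs_grid.attrs.get("replicates", 3))
    shape = (n_rep,) + drs_grid.shape[:-1]
    sd = noise.rel_sd
    z = _correlated_unit_noise(rng, wl.size, wl, noise.corr_length_nm, shape)
    factor = np.exp(sd * z - 0.5 * sd * sd) if sd > 0 else np.ones_like(z)
    out = drs_grid.expand_dims(replicate=np.arange(n_rep)).copy()
    out.values = drs_grid.values[None, ...] * factor
    out.attrs = dict(drs_grid.attrs, noise_rel_sd=sd,
                     noise_corr_length_nm=noise.corr_length_nm,
                     noise_seed=noise.seed)
    return out


def emulate_measurement_set(series: PhantomSeries, noise: NoiseModel,
                            out_dir: "str | Path",
                            reference_reflectance: float = 0.99,
                            engine: str = "diffusion") -> Path:
    """Write a synthetic measurement campaign to disk; returns the manifest path.

    One two-column spectrum file (wavelength_nm, intensity_counts) per
    phantom per replicate, plus one reference file from a 99%-reflectance
    Spectralon-like target, plus a JSON manifest mapping files to roles.
    The counts are DRS / reference_reflectance x a smooth lamp-detector
    response, so running the phantom pipeline on a noiseless set recovers
    the forward-model DRS exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wl = series.wavelengths
    truth = forward_drs(series, engine=engine)
    grid = add_noise(truth.assign_attrs(replicates=series.replicates), noise)
    # smooth halogen-lamp-times-detector response, counts
    ref_counts = 4.0e4 * np.exp(-0.5 * ((wl - 700.0) / 260.0) ** 2)
    ref_file = "reference.txt"
    write_spectrum(out_dir / ref_file, Spectrum(wl, ref_counts),
                   header=f"synthetic Spectralon-like reference, "
                          f"reflectance factor {reference_reflectance}")
    samples = []
    for r in range(series.replicates):
        for p in range(len(series.hb_concentrations)):
            counts = grid.values[r, p] / reference_reflectance * ref_counts
            fname = f"phantom{p}_rep{r}.txt"
            write_spectrum(out_dir / fname, Spectrum(wl, counts),
                           header=f"synthetic phantom spectrum, "
                                  f"Hb {series.hb_concentrations[p]} mg/mL, "
                                  f"D {series.d_mm} mm, replicate {r}")
            samples.append({"file": fname, "phantom_index": p, "replicate": r,
                            "hb_mg_ml": series.hb_concentrations[p]})
    manifest = {
        "reference": {"file": ref_file, "reflectance": reference_reflectance},
        "samples": samples,
        "d_mm": series.d_mm,
        "sdd_mm": float(truth.attrs["sdd_mm"]),
        "provenance": "synthetic",
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
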