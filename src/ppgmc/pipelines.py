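"""Configuration-driven experiments: skin sweeps, phantom analysis, oracles.

These functions tie geometry -> transport -> PPG analysis together with
seeds and provenance.  They are the package's entry points; each is a plain
Python callable driven by a :class:`RunConfig` that round-trips through
YAML, so sweeps are declarative and diffable.  Every written output embeds
the config hash, the seed and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .chromophores import skin_media
from .geometry import (DEFAULT_SKIN_EXTENT, PhantomSpec, SkinSpec,
                       build_phantom_volume, build_skin_volume, dilate_vessels,
                       resolve_centers)
from .optics import Medium, MediumTable, Spectrum, read_spectrum
from .ppg import DRSValue, PulseMetrics, ac_dc, mop, pulse_metrics, waveform_from_series
from .transport import (DetectionRecords, DetectorSpec, RngPolicy, SourceSpec,
                        fresnel_reflectance, simulate)
from . import _kernel

log = logging.getLogger("ppgmc")

__all__ = [
    "RunConfig",
    "run_skin_sweep",
    "run_phantom_pipeline",
    "run_oracle_suite",
    "run_pulse_trend_study",
    "run_phantom_trend_study",
    "run_diffusion_check",
    "simulate_pulse_pair",
    "medium_table_to_dict",
    "medium_table_from_dict",
]


@dataclass
class RunConfig:
    """Declarative description of one experiment run."""

    experiment: str = "skin_sweep"  # skin_sweep | phantom_pipeline | oracle_suite
    wavelengths: tuple = (523.0, 945.0)
    sdds: tuple = (1.0, 2.0)
    epidermal_thicknesses_um: tuple = (50.0, 100.0, 150.0)
    systole_diameter_um: float = 75.0
    diastole_diameter_um: float = 117.0
    vessel_density_per_mm2: float = 33.75
    melanin_fraction: float = 0.30
    n_photons: int = 1_000_000
    seed: int = 0
    voxel_size_mm: float = 0.010
    detector_radius_mm: float = 0.5
    detector_count_per_sdd: int = 1
    extent_mm: tuple = DEFAULT_SKIN_EXTENT
    out_dir: "str | None" = None
    # phantom pipeline inputs
    manifest: "str | None" = None
    waveform_wavelengths: tuple = (450.0, 540.0, 580.0, 900.0)

    def validate(self) -> None:
        if self.experiment not in ("skin_sweep", "phantom_pipeline", "oracle_suite"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_photons < 1:
            raise ValueError("photon budget must be >= 1")
        if self.experiment == "phantom_pipeline":
            if not self.manifest:
                raise ValueError("phantom_pipeline needs a manifest path")
            if not Path(self.manifest).exists():
                raise ValueError(f"manifest not found: {self.manifest}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed,
                "package_version": __version__}

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)

    def to_yaml(self, path: "str | Path") -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def medium_table_to_dict(table: MediumTable) -> dict:
    """JSON/YAML-serializable form of a media table (spectra as column lists)."""
    out = {}
    for mid, med in table.media.items():
        entry = {"name": med.name, "g": med.g, "n": med.n}
        for key, val in (("mua", med.mua), ("mus", med.mus)):
            if isinstance(val, Spectrum):
                entry[key] = {"wavelengths_nm": val.wavelengths.tolist(),
                              "values_per_mm": val.values.tolist()}
            else:
                entry[key] = float(val)
        out[str(mid)] = entry
    return out


def medium_table_from_dict(d: dict) -> MediumTable:
    media = {}
    for mid, entry in d.items():
        kw = {}
        for key in ("mua", "mus"):
            val = entry[key]
            kw[key] = (Spectrum(np.asarray(val["wavelengths_nm"]),
                                np.asarray(val["values_per_mm"]))
                       if isinstance(val, dict) else float(val))
        media[int(mid)] = Medium(entry["name"], g=entry["g"], n=entry["n"], **kw)
    return MediumTable(media)


def simulate_pulse_pair(d_um: float, wavelength: float, sdds,
                        n_photons: int, seed: int,
                        media: "MediumTable | None" = None,
                        systole_diameter_um: float = 75.0,
                        diastole_diameter_um: float = 117.0,
                        vessel_density_per_mm2: float = 33.75,
                        voxel_size_mm: float = 0.010,
                        detector_radius_mm: float = 0.5,
                        detector_count_per_sdd: int = 1,
                        extent_mm=DEFAULT_SKIN_EXTENT,
                        melanin_fraction: float = 0.30) -> "list[PulseMetrics]":
    """Coupled-seed systole/diastole pair at one (D, wavelength); one row per SDD.

    Both phase runs share the photon launch streams (identical RngPolicy),
    the variance-reduction that makes the small systole-diastole reflectance
    difference resolvable at desk-scale budgets.  Vessel centers are sampled
    once for the larger (diastolic) diameter and preserved under dilation to
    systole.
    """
    media = media or skin_media(melanin_fraction=melanin_fraction)
    dia_spec = resolve_centers(
        SkinSpec(epidermal_thickness_um=d_um,
                 vessel_diameter_um=diastole_diameter_um,
                 vessel_density_per_mm2=vessel_density_per_mm2,
                 placement_seed=seed),
        extent_mm)
    sys_spec = dilate_vessels(dia_spec, systole_diameter_um, extent_mm)
    vol_d = build_skin_volume(dia_spec, extent_mm, voxel_size_mm)
    vol_s = build_skin_volume(sys_spec, extent_mm, voxel_size_mm)
    dets = [DetectorSpec(sdd=s, radius=detector_radius_mm,
                         count_per_sdd=detector_count_per_sdd) for s in sdds]
    src = SourceSpec()
    rng = RngPolicy(seed=seed)
    res_s = simulate(vol_s, media, src, dets, n_photons, rng=rng, wavelength=wavelength)
    res_d = simulate(vol_d, media, src, dets, n_photons, rng=rng, wavelength=wavelength)
    rows = []
    for k in range(len(dets)):
        pm = pulse_metrics(res_s, res_d, k, boot_seed=seed)
        rows.append(dataclasses.replace(pm, epidermal_thickness_um=d_um))
    return rows


_SWEEP_COLUMNS = ["wavelength_nm", "sdd_mm", "D_um", "ac_dc_percent", "ac_dc_se",
                  "mop_mm", "n_detected", "seed"]


def run_skin_sweep(config: RunConfig) -> pd.DataFrame:
    """AC/DC and MOP over (D, SDD, wavelength): the simulated PPG trend table.

    Each (D, wavelength) cell runs a coupled systole/diastole pair; a failed
    cell is logged and marked with NaNs, and the sweep continues.
    """
    config.validate()
    rows = []
    for d_um in config.epidermal_thicknesses_um:
        for wl in config.wavelengths:
            try:
                metrics = simulate_pulse_pair(
                    d_um, wl, config.sdds, config.n_photons, config.seed,
                    systole_diameter_um=config.systole_diameter_um,
                    diastole_diameter_um=config.diastole_diameter_um,
                    vessel_density_per_mm2=config.vessel_density_per_mm2,
                    voxel_size_mm=config.voxel_size_mm,
                    detector_radius_mm=config.detector_radius_mm,
                    detector_count_per_sdd=config.detector_count_per_sdd,
                    extent_mm=config.extent_mm,
                    melanin_fraction=config.melanin_fraction)
            except Exception:
                log.exception("sweep cell failed: D=%s um, wavelength=%s nm", d_um, wl)
                for s in config.sdds:
                    rows.append([wl, s, d_um] + [np.nan] * 4 + [config.seed])
                continue
            for pm in metrics:
                rows.append([pm.wavelength, pm.sdd, pm.epidermal_thickness_um,
                             pm.ac_dc, pm.ac_dc_se, pm.mop, pm.n_detected,
                             config.seed])
    table = pd.DataFrame(rows, columns=_SWEEP_COLUMNS)
    if config.out_dir:
        _write_table(Path(config.out_dir), "skin_sweep", table, config)
    return table


def _write_table(out_dir: Path, stem: str, table: pd.DataFrame,
                 config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    header = "".join(f"# {k}: {v}\n" for k, v in prov.items())
    with open(out_dir / f"{stem}.csv", "w") as fh:
        fh.write(header)
        table.to_csv(fh, index=False)
    payload = {"provenance": prov, "rows": table.to_dict(orient="records")}
    (out_dir / f"{stem}.json").write_text(json.dumps(payload, indent=2))


def run_phantom_pipeline(config: RunConfig) -> dict:
    """The phantom analysis: spectra files -> DRS -> waveforms -> AC/DC spectrum.

    Reads a manifest of measured (or emulated) sample spectra plus one
    reference spectrum from a known-reflectance standard, normalizes to DRS,
    builds the -log(DRS) pulse waveform across the phantom series at the
    selected wavelengths, and the AC/DC ratio against wavelength with
    replicate spread.
    """
    config.validate()
    manifest = json.loads(Path(config.manifest).read_text())
    base = Path(config.manifest).parent
    if "reference" not in manifest or not manifest["reference"].get("file"):
        raise ValueError("manifest has no reference spectrum")
    if not manifest.get("samples"):
        raise ValueError("manifest lists no sample spectra")
    ref_path = base / manifest["reference"]["file"]
    if not ref_path.exists():
        raise FileNotFoundError(f"reference spectrum missing: {ref_path}")
    ref_refl = float(manifest["reference"].get("reflectance", 0.99))
    ref = read_spectrum(ref_path)
    wl = ref.wavelengths
    sdd = float(manifest.get("sdd_mm", 0.5))

    phantoms = sorted({s["phantom_index"] for s in manifest["samples"]})
    reps = sorted({s["replicate"] for s in manifest["samples"]})
    drs = np.full((len(reps), len(phantoms), wl.size), np.nan)
    conc = np.full(len(phantoms), np.nan)
    for s in manifest["samples"]:
        spec = read_spectrum(base / s["file"])
        if not np.array_equal(spec.wavelengths, wl):
            raise ValueError(f"{s['file']}: wavelength grid differs from the reference")
        drs[reps.index(s["replicate"]), phantoms.index(s["phantom_index"])] = (
            spec.values / ref.values * ref_refl)
        conc[phantoms.index(s["phantom_index"])] = s.get("hb_mg_ml", np.nan)
    if np.any(np.isnan(drs)):
        raise ValueError("manifest is missing phantom/replicate combinations")

    drs_da = xr.DataArray(
        drs, dims=("replicate", "phantom", "wavelength"),
        coords={"replicate": reps, "phantom": phantoms, "wavelength": wl,
                "hb_mg_ml": ("phantom", conc)},
        attrs={"provenance": manifest.get("provenance", "measured"),
               "d_mm": manifest.get("d_mm"), "sdd_mm": sdd})

    mean_drs = drs_da.mean("replicate")
    waveforms = {}
    for wsel in config.waveform_wavelengths:
        j = int(np.argmin(np.abs(wl - wsel)))
        series = [DRSValue(float(v), float(wl[j]), sdd, "measured")
                  for v in mean_drs.values[:, j]]
        waveforms[float(wl[j])] = waveform_from_series(series)

    p = -np.log(drs_da.values)  # (rep, phantom, wl)
    acdc_rep = 100.0 * (p.max(axis=1) - p.min(axis=1)) / p.min(axis=1)
    acdc = pd.DataFrame({
        "wavelength_nm": wl,
        "ac_dc_percent": acdc_rep.mean(axis=0),
        "ac_dc_sd": acdc_rep.std(axis=0, ddof=1) if len(reps) > 1 else 0.0,
    })
    out = {"drs": drs_da, "waveforms": waveforms, "ac_dc": acdc}
    if config.out_dir:
        _write_table(Path(config.out_dir), "phantom_ac_dc", acdc, config)
        wf = pd.DataFrame({f"neg_log_drs_{w:g}nm": v.neg_log_drs
                           for w, v in waveforms.items()})
        wf.insert(0, "phantom", phantoms)
        _write_table(Path(config.out_dir), "phantom_waveforms", wf, config)
    return out


def run_pulse_trend_study(seed: int = 0,
                          green_budget: int = 4_000_000,
                          nir_budget: int = 1_200_000,
                          thick_budget: int = 1_500_000) -> pd.DataFrame:
    """Scaled-down AC/DC-vs-MOP trend study at 523 and 945 nm.

    Desk-scale rendition of the wearable-PPG simulation design: SDDs of
    1 and 2 mm, enlarged 0.5 mm detector discs, 10 um voxels and per-cell
    photon budgets sized so the bootstrap uncertainties resolve the
    orderings of interest (green AC/DC rising with SDD and exceeding NIR
    AC/DC, MOP rising with SDD, green AC/DC collapsing as the epidermis
    thickens from 50 to 150 um).  Budgets are per cardiac phase.
    """
    cells = [
        (523.0, 50.0, (1.0, 2.0), green_budget),
        (945.0, 50.0, (1.0, 2.0), nir_budget),
        (523.0, 150.0, (1.0,), thick_budget),
    ]
    media = skin_media()
    rows = []
    for wl, d_um, sdds, budget in cells:
        for pm in simulate_pulse_pair(d_um, wl, sdds, budget, seed, media=media):
            rows.append([pm.wavelength, pm.sdd, pm.epidermal_thickness_um,
                         pm.ac_dc, pm.ac_dc_se, pm.mop, pm.n_detected, seed])
    return pd.DataFrame(rows, columns=_SWEEP_COLUMNS)


def run_phantom_trend_study(seed: int = 0, work_dir: "str | Path | None" = None) -> dict:
    """Noiseless seven-phantom pulse at D = 0 and D = 0.20 mm, end to end.

    Emulates the measurement sets with the diffusion forward engine, runs
    the phantom pipeline on the written files, and summarizes the spectral
    orderings: AC/DC at 540 vs 900 nm, and the fractional AC/DC drop from
    D = 0 to D = 0.20 mm at 450 vs 900 nm.
    """
    import tempfile

    from .synth import NoiseModel, PhantomSeries, emulate_measurement_set

    work_dir = Path(work_dir) if work_dir else Path(tempfile.mkdtemp(prefix="ppgmc_"))
    out = {}
    acdc_by_d = {}
    for d in (0.0, 0.20):
        series = PhantomSeries(d_mm=d, replicates=1)
        man = emulate_measurement_set(series, NoiseModel(rel_sd=0.0, seed=seed),
                                      work_dir / f"D{d:g}")
        res = run_phantom_pipeline(RunConfig(experiment="phantom_pipeline",
                                             manifest=str(man), seed=seed))
        acdc = res["ac_dc"].set_index("wavelength_nm")["ac_dc_percent"]
        acdc_by_d[d] = acdc
        out[f"drs_540_by_phantom_D{d:g}"] = (
            res["drs"].mean("replicate").sel(wavelength=540.0).values)
        out[f"acdc_540_D{d:g}"] = float(acdc.loc[540.0])
        out[f"acdc_900_D{d:g}"] = float(acdc.loc[900.0])
        out[f"waveform_540_D{d:g}"] = res["waveforms"][540.0].neg_log_drs
    for wl in (450.0, 900.0):
        out[f"drop_{wl:g}"] = float(
            (acdc_by_d[0.0].loc[wl] - acdc_by_d[0.20].loc[wl]) / acdc_by_d[0.0].loc[wl])
    return out


def run_diffusion_check(seed: int = 0, n_photons: int = 10_000_000,
                        rho_range: tuple = (2.0, 4.0)) -> dict:
    """Monte Carlo vs diffusion-theory spatially resolved reflectance.

    Semi-infinite homogeneous medium (mua = 0.01 mm^-1, mus' = 1.0 mm^-1,
    index-matched boundary): compares the simulated R(rho) against the
    dipole closed form over ``rho_range`` mm and reports the worst relative
    deviation.  The 16 x 16 x 10 mm volume keeps boundary truncation small
    against the ~5.7 mm penetration depth of these properties.
    """
    from .diffusion import diffusion_reflectance

    mt = MediumTable({1: Medium("turbid", 0.01, 10.0, 0.9, 1.0)})
    vol = build_phantom_volume(PhantomSpec(0.0, bottom_medium=1),
                               extent=(16.0, 16.0, 10.0), voxel_size=0.1)
    res = simulate(vol, mt, SourceSpec(beam_diameter=1e-3, center=(8.0, 8.0)),
                   [], n_photons, rng=seed, wavelength=523.0,
                   radial_bins=(0.2, 30))
    edges, hist = res.radial_hist
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    r_mc = hist / res.launched / area
    r_th = diffusion_reflectance(r_mid, 0.01, 1.0)
    sel = (r_mid >= rho_range[0]) & (r_mid <= rho_range[1])
    dev = np.abs(r_mc[sel] / r_th[sel] - 1.0)
    return {"rho_mm": r_mid[sel], "R_mc": r_mc[sel], "R_diffusion": r_th[sel],
            "max_abs_rel_dev": float(dev.max()), "n_photons": res.launched,
            "ledger_closure_residual": res.ledger_closure()}


def run_oracle_suite(seed: int = 0, n_hg: int = 1_000_000) -> dict:
    """Closed-form sanity oracles for the transport engine and the PPG math.

    Returns measured-vs-expected pairs for: weight-ledger closure on a
    mismatched-boundary heterogeneous run, ballistic Beer-Lambert
    transmission through a scattering-free slab, normal-incidence Fresnel
    reflectance, the Henyey-Greenstein mean cosine, and the hand-worked
    MOP / AC/DC examples.
    """
    out = {}
    # ledger closure on a small skin run with mismatched surface
    media = skin_media()
    spec = resolve_centers(SkinSpec(epidermal_thickness_um=100.0, placement_seed=seed))
    vol = build_skin_volume(spec)
    res = simulate(vol, media, SourceSpec(), [DetectorSpec(sdd=1.0, radius=0.5)],
                   50_000, rng=seed, wavelength=523.0)
    out["ledger_closure_residual"] = res.ledger_closure()

    # ballistic transmission through a purely absorbing slab, mua*L = 1
    slab = MediumTable({1: Medium("absorber", 1.0, 0.0, 0.0, 1.0)})
    vol_b = build_phantom_volume(PhantomSpec(0.0, bottom_medium=1),
                                 extent=(2.0, 2.0, 1.0), voxel_size=0.05)
    res_b = simulate(vol_b, slab, SourceSpec(beam_diameter=1e-3, center=(1.0, 1.0)),
                     [], 10_000, rng=seed, wavelength=523.0)
    out["ballistic_transmission"] = res_b.ledger["escaped_sides_bottom"] / res_b.launched
    out["ballistic_expected"] = float(np.exp(-1.0))

    out["fresnel_normal_R"] = fresnel_reflectance(1.0, 1.4, 1.0)
    out["fresnel_expected"] = ((1.4 - 1.0) / (1.4 + 1.0)) ** 2

    out["hg_mean_cos_g0.9"] = float(_kernel.hg_mean(0.9, n_hg, seed + 1))
    out["hg_mean_cos_g0"] = float(_kernel.hg_mean(0.0, n_hg, seed + 2))
    out["hg_n_draws"] = n_hg

    recs = DetectionRecords(np.array([1.0, 3.0]), np.array([[2.0], [4.0]]),
                            np.array([2.0, 4.0]), np.zeros((2, 2)),
                            np.zeros(2, dtype=np.int32))
    out["mop_example_mm"] = mop(recs)
    out["ac_dc_example_percent"] = ac_dc(
        DRSValue(float(np.exp(-0.5)), 540.0, 0.5),
        DRSValue(float(np.exp(-0.4)), 540.0, 0.5))
    return out
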