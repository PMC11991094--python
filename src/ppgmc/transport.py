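"""Voxel Monte Carlo photon transport: launch, scatter, absorb, detect.

The engine traces weighted photon packets through a labelled voxel grid,
sampling scattering lengths from the local scattering coefficient,
deflections from the Henyey-Greenstein phase function, and applying
continuous Beer-Lambert weight attenuation for absorption (see
:mod:`ppgmc._kernel` for the exact stepping semantics).  Every detected
photon carries its per-medium partial pathlengths, which is what the PPG
analysis layer consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .geometry import TissueVolume
from .optics import MediumTable

__all__ = [
    "SourceSpec",
    "DetectorSpec",
    "DetectionRecords",
    "SimulationResult",
    "RngPolicy",
    "simulate",
    "sample_hg",
    "fresnel_reflectance",
    "fresnel_interaction",
    "roulette",
]


def sample_hg(g: float, u: float) -> float:
    """Henyey-Greenstein deflection cosine by inverse-CDF sampling.

    For g = 0 the distribution is isotropic and the sample is 2u - 1;
    the mean cosine over many draws equals g.
    """
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    return float(_kernel.hg_cos(g, u))


def fresnel_reflectance(cos_i: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel reflectance at a planar index step."""
    if not 0.0 < cos_i <= 1.0:
        raise ValueError("incidence cosine must lie in (0, 1]")
    return float(_kernel.fresnel_R(cos_i, n_in, n_out))


def fresnel_interaction(cos_i: float, n_in: float, n_out: float, u: float):
    """Stochastic boundary interaction: ('reflect', cos_i) or ('transmit', cos_t).

    The photon reflects with probability equal to the unpolarized Fresnel
    reflectance (always, beyond the critical angle); on transmission the
    refracted cosine from Snell's law is returned.
    """
    R = fresnel_reflectance(cos_i, n_in, n_out)
    if u < R:
        return "reflect", cos_i
    sin_t2 = (n_in / n_out) ** 2 * (1.0 - cos_i * cos_i)
    return "transmit", math.sqrt(1.0 - sin_t2)


def roulette(w: float, threshold: float, survival_p: float, u: float) -> float:
    """Russian roulette: unbiased termination of low-weight packets."""
    if not 0.0 < survival_p <= 1.0:
        raise ValueError("survival probability must lie in (0, 1]")
    if w >= threshold:
        return w
    return w / survival_p if u < survival_p else 0.0


@dataclass(frozen=True)
class SourceSpec:
    """Gaussian surface source.  ``beam_diameter`` = 2 sigma (mm).

    ``center`` is an (x, y) mm pair on the surface; None centers the beam
    laterally and places it so the detector row fits in +y.  ``direction``
    must point into the tissue (positive z component).
    """

    beam_diameter: float = 0.4
    center: "tuple | None" = None
    direction: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.beam_diameter <= 0:
            raise ValueError("beam diameter must be positive")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,) or d[2] <= 0:
            raise ValueError("direction must be a 3-vector pointing into the tissue")
        object.__setattr__(self, "direction", tuple(d / np.linalg.norm(d)))

    @property
    def sigma(self) -> float:
        return self.beam_diameter / 2.0


@dataclass(frozen=True)
class DetectorSpec:
    """Detector discs at one source-detector distance (center-to-center).

    ``count_per_sdd`` azimuthal copies are fanned around the +y direction
    from the source (evenly spaced within ±``fan_deg``) and pooled into a
    single effective detector, matching the practice of reporting one
    reflectance per SDD.  ``acceptance_cos`` is the cosine of the maximum
    exit angle accepted (0 = full hemisphere).
    """

    sdd: float
    radius: float = 0.3
    count_per_sdd: int = 1
    acceptance_cos: float = 0.0
    fan_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("detector radius must be positive")
        if self.sdd < 0:
            raise ValueError("sdd must be non-negative")
        if self.count_per_sdd < 1:
            raise ValueError("count_per_sdd must be >= 1")

    def disc_centers(self, src_x: float, src_y: float) -> np.ndarray:
        m = self.count_per_sdd
        if m == 1:
            ang = np.array([0.0])
        else:
            ang = np.deg2rad(np.linspace(-self.fan_deg, self.fan_deg, m))
        return np.stack([src_x + self.sdd * np.sin(ang),
                         src_y + self.sdd * np.cos(ang)], axis=1)


class DetectionRecords:
    """Columnar store of detected photons (weights, per-medium pathlengths)."""

    def __init__(self, weights, pathlengths, totals, exit_xy, detector_ids):
        self.weights = np.asarray(weights, dtype=float)
        self.pathlengths = np.asarray(pathlengths, dtype=float)
        self.totals = np.asarray(totals, dtype=float)
        self.exit_xy = np.asarray(exit_xy, dtype=float)
        self.detector_ids = np.asarray(detector_ids, dtype=np.int32)

    def __len__(self) -> int:
        return self.weights.size

    @classmethod
    def empty(cls, n_media: int) -> "DetectionRecords":
        return cls(np.empty(0), np.empty((0, n_media)), np.empty(0),
                   np.empty((0, 2)), np.empty(0, dtype=np.int32))

    def for_detector(self, detector_id: int) -> "DetectionRecords":
        m = self.detector_ids == detector_id
        return DetectionRecords(self.weights[m], self.pathlengths[m],
                                self.totals[m], self.exit_xy[m],
                                self.detector_ids[m])

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def concat(self, other: "DetectionRecords") -> "DetectionRecords":
        return DetectionRecords(
            np.concatenate([self.weights, other.weights]),
            np.concatenate([self.pathlengths, other.pathlengths]),
            np.concatenate([self.totals, other.totals]),
            np.concatenate([self.exit_xy, other.exit_xy]),
            np.concatenate([self.detector_ids, other.detector_ids]),
        )

    def to_table(self, media_names: "dict | None" = None):
        """Delimited-text-friendly table: one row per detected photon."""
        import pandas as pd

        n_media = self.pathlengths.shape[1]
        cols = {"detector_id": self.detector_ids, "weight": self.weights}
        for m in range(n_media):
            name = media_names.get(m, f"medium{m}") if media_names else f"medium{m}"
            cols[f"l_{name}_mm"] = self.pathlengths[:, m]
        cols["l_total_mm"] = self.totals
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class RngPolicy:
    """Seeded, batched RNG discipline: one independent stream per photon batch."""

    seed: int = 0
    batch_size: int = 1_000_000

    def batch_seeds(self, n_batches: int) -> np.ndarray:
        return np.random.SeedSequence(self.seed).generate_state(n_batches).astype(np.int64)


@dataclass
class SimulationResult:
    """Outcome of one transport run at one wavelength."""

    launched: int
    records: DetectionRecords
    ledger: dict
    seed: int
    wavelength: float
    fluence: "np.ndarray | None" = None
    radial_hist: "tuple | None" = None  # (bin_edges_mm, weights)
    detector_specs: list = field(default_factory=list)

    @property
    def detected_weight(self) -> float:
        return self.ledger["detected"]

    def ledger_closure(self) -> float:
        """Relative residual of the weight ledger against the launched weight."""
        total = sum(self.ledger.values())
        return abs(total - self.launched) / self.launched


def _resolve_source(source: SourceSpec, extent) -> tuple:
    if source.center is not None:
        return float(source.center[0]), float(source.center[1])
    # centered in x; in y, leave room for the detector row toward +y
    return extent[0] / 2.0, min(0.35, extent[1] / 2.0)


def simulate(volume: TissueVolume, media: MediumTable, source: SourceSpec,
             detectors: "list[DetectorSpec]", n_photons: int,
             rng: "RngPolicy | int" = 0, wavelength: float = 523.0,
             n_ambient: float = 1.0,
             roulette_threshold: float = 1e-4, roulette_survival: float = 0.1,
             fluence: bool = False, radial_bins: "tuple | None" = None,
             n_detected_target: "int | None" = None,
             max_photons: "int | None" = None) -> SimulationResult:
    """Run the Monte Carlo transport and collect detection records.

    Parameters
    ----------
    n_photons:
        Photons to launch.  If ``n_detected_target`` is given, batches keep
        launching (up to ``max_photons``, default 50x ``n_photons``) until
        every detector has at least that many detected photons — the budget
        rule of aiming for a detected-photon count rather than a launched
        count.
    radial_bins:
        Optional ``(dr_mm, n_bins)``: histogram all top-escaping photons by
        exit radius from the source (for spatially resolved reflectance).
    """
    if isinstance(rng, (int, np.integer)):
        rng = RngPolicy(seed=int(rng))
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mua, mus, g, n_arr = media.arrays(wavelength)
    labels = np.ascontiguousarray(volume.labels)
    if labels.max() >= mua.shape[0]:
        raise ValueError("volume references medium ids missing from the table")
    h = volume.voxel_size
    extent = volume.extent
    src_x, src_y = _resolve_source(source, extent)
    ux0, uy0, uz0 = source.direction

    det_cx, det_cy, det_r2, det_pool, det_accept = [], [], [], [], []
    for i, spec in enumerate(detectors):
        for cx, cy in spec.disc_centers(src_x, src_y):
            if not (spec.radius <= cx <= extent[0] - spec.radius
                    and spec.radius <= cy <= extent[1] - spec.radius):
                raise ValueError(
                    f"detector at SDD {spec.sdd} mm lies outside the surface")
            det_cx.append(cx)
            det_cy.append(cy)
            det_r2.append(spec.radius ** 2)
            det_pool.append(i)
            det_accept.append(spec.acceptance_cos)
    det_cx = np.asarray(det_cx, dtype=float)
    det_cy = np.asarray(det_cy, dtype=float)
    det_r2 = np.asarray(det_r2, dtype=float)
    det_pool = np.asarray(det_pool, dtype=np.int32)
    det_accept = np.asarray(det_accept, dtype=float)

    if radial_bins is not None:
        hist_dr, n_hist = float(radial_bins[0]), int(radial_bins[1])
        hist = np.zeros(n_hist)
    else:
        hist_dr, hist = 1.0, np.zeros(0)
    flu = np.zeros(labels.shape) if fluence else np.zeros((1, 1, 1))

    n_media = mua.shape[0]
    cap = min(n_photons, rng.batch_size)
    rec_w = np.empty(cap)
    rec_path = np.empty((cap, n_media))
    rec_total = np.empty(cap)
    rec_x = np.empty(cap)
    rec_y = np.empty(cap)
    rec_det = np.empty(cap, dtype=np.int32)

    budget = n_photons if n_detected_target is None else (max_photons or 50 * n_photons)
    max_batches = int(np.ceil(budget / cap))
    seeds = rng.batch_seeds(max_batches)
    ledger = np.zeros(_kernel.N_LEDGER)
    chunks = []
    launched = 0
    for b in range(max_batches):
        nb = min(cap, budget - launched)
        if nb <= 0:
            break
        n_rec, led = _kernel.run_batch(
            labels, h, mua, mus, g, n_arr, n_ambient,
            src_x, src_y, source.sigma, ux0, uy0, uz0,
            nb, seeds[b],
            det_cx, det_cy, det_r2, det_pool, det_accept,
            roulette_threshold, roulette_survival,
            rec_w, rec_path, rec_total, rec_x, rec_y, rec_det,
            hist, hist_dr, flu, fluence)
        ledger += led
        launched += nb
        chunks.append(DetectionRecords(
            rec_w[:n_rec].copy(), rec_path[:n_rec].copy(), rec_total[:n_rec].copy(),
            np.stack([rec_x[:n_rec], rec_y[:n_rec]], axis=1),
            rec_det[:n_rec].copy()))
        if launched >= n_photons and n_detected_target is not None:
            counts = np.bincount(
                np.concatenate([c.detector_ids for c in chunks]),
                minlength=len(detectors))
            if counts.min() >= n_detected_target:
                break
        if n_detected_target is None and launched >= n_photons:
            break

    records = DetectionRecords.empty(n_media)
    for c in chunks:
        records = records.concat(c)
    ledger_d = {
        "detected": ledger[_kernel.DETECTED],
        "absorbed": ledger[_kernel.ABSORBED],
        "escaped_top": ledger[_kernel.ESC_TOP],
        "escaped_sides_bottom": ledger[_kernel.ESC_SIDE],
        "specular": ledger[_kernel.SPECULAR],
        "roulette_net": ledger[_kernel.ROULETTE],
    }
    edges = np.arange(hist.size + 1) * hist_dr if radial_bins is not None else None
    return SimulationResult(
        launched=launched, records=records, ledger=ledger_d,
        seed=rng.seed, wavelength=wavelength,
        fluence=flu if fluence else None,
        radial_hist=(edges, hist) if radial_bins is not None else None,
        detector_specs=list(detectors))
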