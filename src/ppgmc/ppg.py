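"""PPG analysis layer: diffuse reflectance, -log transform, AC/DC, pathlengths.

The PPG pulse in reflection mode is the change of the diffuse reflectance
signal (DRS) over a cardiac cycle.  Its quality metric is the AC/DC ratio

    AC/DC = 100% x (max(-log DRS) - min(-log DRS)) / min(-log DRS),

taken over the two cardiac phases, and the depth-sensitivity proxy is the
mean optical pathlength (MOP)

    MOP = sum_ij l_ij w_ij / sum_ij w_ij,

the detected-weight-averaged photon pathlength summed over tissue layers i
and detected photons j.  The logarithm is natural; the base cancels in the
AC/DC ratio.  Note AC/DC is *not* invariant to a common multiplicative
error in both DRS values (a miscalibrated reference changes it), which is
why reference normalization matters for measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import DetectionRecords, SimulationResult

__all__ = [
    "DRSValue",
    "PPGWaveform",
    "PulseMetrics",
    "compute_drs",
    "measured_drs",
    "ac_dc",
    "mop",
    "pulse_metrics",
    "waveform_from_series",
]


@dataclass(frozen=True)
class DRSValue:
    """A diffuse reflectance value with its acquisition context."""

    value: float
    wavelength: float
    sdd: float
    provenance: str = "simulated"  # simulated | measured | synthetic

    @property
    def empty(self) -> bool:
        return not np.isfinite(self.value)


@dataclass(frozen=True)
class PPGWaveform:
    """-log(DRS) over the ordered phase points of one cardiac pulse."""

    neg_log_drs: np.ndarray
    wavelength: float

    def ac_dc(self) -> float:
        """AC/DC ratio of the waveform extrema, percent."""
        p = self.neg_log_drs
        return 100.0 * (p.max() - p.min()) / p.min()


@dataclass(frozen=True)
class PulseMetrics:
    """AC/DC (%) and MOP (mm) for one (wavelength, SDD, geometry) condition."""

    ac_dc: float
    mop: float
    wavelength: float
    sdd: float
    epidermal_thickness_um: float
    ac_dc_se: float
    n_detected: int


def compute_drs(result: SimulationResult, detector_id: int) -> DRSValue:
    """Simulated DRS: detected weight fraction at one (pooled) detector.

    With unit launch weight this is the absolute diffuse reflectance into
    the detector; a measured DRS normalized to a 99%-reflectance standard
    estimates the same quantity up to the reference factor.  A run with no
    detected photons yields a flagged empty (NaN) value rather than zero.
    """
    if not 0 <= detector_id < len(result.detector_specs):
        raise ValueError(f"result has no detector {detector_id}")
    w = result.records.for_detector(detector_id).total_weight()
    value = w / result.launched if w > 0 else float("nan")
    return DRSValue(value=value, wavelength=result.wavelength,
                    sdd=result.detector_specs[detector_id].sdd)


def measured_drs(sample_counts: float, reference_counts: float,
                 reference_reflectance: float = 0.99,
                 wavelength: float = float("nan"), sdd: float = 0.5) -> DRSValue:
    """DRS from spectrometer counts: (sample / reference) x reference factor."""
    if reference_counts <= 0:
        raise ValueError("reference counts must be positive")
    if sample_counts < 0:
        raise ValueError("sample counts must be non-negative")
    return DRSValue(value=sample_counts / reference_counts * reference_reflectance,
                    wavelength=wavelength, sdd=sdd, provenance="measured")


def _neg_log(drs: DRSValue) -> float:
    if drs.empty:
        raise ValueError("cannot take -log of an empty DRS value")
    if drs.value <= 0 or drs.value > 1:
        raise ValueError("DRS must lie in (0, 1]")
    return -np.log(drs.value)


def ac_dc(drs_a: DRSValue, drs_b: DRSValue) -> float:
    """AC/DC ratio (percent) of a two-phase DRS pair.

    Symmetric in its arguments; the phase producing the larger -log DRS
    contributes the max.  Raises if the smaller -log DRS is zero (DRS = 1,
    no baseline attenuation to normalize by).
    """
    p_a, p_b = _neg_log(drs_a), _neg_log(drs_b)
    lo, hi = min(p_a, p_b), max(p_a, p_b)
    if lo == 0.0:
        raise ValueError("baseline -log DRS is zero; AC/DC undefined")
    return 100.0 * (hi - lo) / lo


def mop(records: DetectionRecords, media_subset: "set | None" = None) -> float:
    """Mean optical pathlength (mm) over the detected photons.

    ``media_subset`` restricts the summed pathlength to those medium ids
    (e.g. blood only, for a partial pathlength); None uses the total path
    through all media.
    """
    if len(records) == 0:
        raise ValueError("no detection records")
    w = records.weights
    if w.sum() <= 0:
        raise ValueError("all detected weights are zero")
    if media_subset is None:
        l = records.pathlengths.sum(axis=1)
    else:
        ids = sorted(media_subset)
        l = records.pathlengths[:, ids].sum(axis=1)
    return float(np.sum(l * w) / np.sum(w))


def _bootstrap_acdc(rec_a: DetectionRecords, rec_b: DetectionRecords,
                    launched_a: float, launched_b: float,
                    wavelength: float, sdd: float,
                    n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    na, nb = len(rec_a), len(rec_b)
    for i in range(n_boot):
        wa = rec_a.weights[rng.integers(0, na, na)].sum() / launched_a
        wb = rec_b.weights[rng.integers(0, nb, nb)].sum() / launched_b
        pa, pb = -np.log(wa), -np.log(wb)
        lo, hi = min(pa, pb), max(pa, pb)
        vals[i] = 100.0 * (hi - lo) / lo
    return float(vals.std(ddof=1))


def pulse_metrics(systole: SimulationResult, diastole: SimulationResult,
                  detector_id: int, mop_phase: str = "diastole",
                  n_boot: int = 200, boot_seed: int = 0) -> PulseMetrics:
    """AC/DC and MOP for a systole/diastole simulation pair at one detector.

    The metric is symmetric in the two phases.  MOP is reported for the
    ``mop_phase`` run ('diastole' default, 'systole', or 'pooled'); the
    AC/DC standard error is a nonparametric bootstrap over the detection
    records of both runs.
    """
    if systole.wavelength != diastole.wavelength:
        raise ValueError("phase runs must share the wavelength")
    drs_s = compute_drs(systole, detector_id)
    drs_d = compute_drs(diastole, detector_id)
    value = ac_dc(drs_s, drs_d)
    rec_s = systole.records.for_detector(detector_id)
    rec_d = diastole.records.for_detector(detector_id)
    if mop_phase == "diastole":
        mop_rec = rec_d
    elif mop_phase == "systole":
        mop_rec = rec_s
    elif mop_phase == "pooled":
        mop_rec = rec_s.concat(rec_d)
    else:
        raise ValueError("mop_phase must be 'systole', 'diastole' or 'pooled'")
    se = _bootstrap_acdc(rec_s, rec_d, systole.launched, diastole.launched,
                         systole.wavelength, drs_s.sdd, n_boot, boot_seed)
    spec = systole.detector_specs[detector_id]
    return PulseMetrics(
        ac_dc=value, mop=mop(mop_rec), wavelength=systole.wavelength,
        sdd=spec.sdd, epidermal_thickness_um=float("nan"),
        ac_dc_se=se, n_detected=len(rec_s) + len(rec_d))


def waveform_from_series(drs_series: "list[DRSValue]") -> PPGWaveform:
    """-log(DRS) waveform over an ordered series of phase points."""
    if len(drs_series) < 2:
        raise ValueError("a waveform needs at least two phase points")
    wl = drs_series[0].wavelength
    if any(d.wavelength != wl for d in drs_series):
        raise ValueError("all phase points must share the wavelength")
    p = np.array([_neg_log(d) for d in drs_series])
    return PPGWaveform(neg_log_drs=p, wavelength=wl)
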