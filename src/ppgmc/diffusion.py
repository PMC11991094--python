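"""Steady-state diffusion-theory reflectance: the analytic cross-check.

The dipole (extrapolated-boundary) solution for a semi-infinite homogeneous
medium gives the spatially resolved diffuse reflectance R(rho) used to
validate the Monte Carlo engine in its diffusive regime, and doubles as the
fast forward engine for the phantom pipeline.  The two-layer phantom case
uses a documented modified Beer-Lambert approximation: a thin top absorber
adds 2 * DPF * mua_top * D to -log(DRS), with a differential-pathlength
factor for the doubly traversed layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "boundary_mismatch_A",
    "diffusion_reflectance",
    "two_layer_neg_log_drs",
]


def boundary_mismatch_A(n_rel: float = 1.0) -> float:
    """Internal-reflection parameter A of the extrapolated boundary.

    Groenhuis' polynomial fit in the relative refractive index
    n_rel = n_tissue / n_ambient; A = 1 for an index-matched boundary.
    """
    if n_rel == 1.0:
        return 1.0
    r_i = -1.440 / n_rel ** 2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_i) / (1.0 - r_i)


def diffusion_reflectance(rho, mua: float, mus_prime: float,
                          n_rel: float = 1.0):
    """Spatially resolved diffuse reflectance R(rho), mm^-2.

    Dipole solution: an isotropic point source at depth z0 = 1/mus' and its
    image above the extrapolated boundary zb = 2AD, using the
    absorption-independent diffusion coefficient D = 1/(3 mus') and
    mu_eff = sqrt(3 mua mus').  With absorption entering only through
    mu_eff, R is strictly decreasing in mua at every rho (the physically
    required Beer-Lambert limit, which the mut'-based variant violates
    at rho comparable to z0).  Valid for mus' >> mua and rho beyond a
    transport mean free path or two.
    """
    mua = np.asarray(mua, dtype=float)
    mus_prime = np.asarray(mus_prime, dtype=float)
    if np.any(mua < 0) or np.any(mus_prime <= 0):
        raise ValueError("need mua >= 0 and mus_prime > 0")
    rho = np.asarray(rho, dtype=float)
    z0 = 1.0 / mus_prime
    D = 1.0 / (3.0 * mus_prime)
    mu_eff = np.sqrt(3.0 * mua * mus_prime)
    zb = 2.0 * boundary_mismatch_A(n_rel) * D
    r1 = np.sqrt(rho ** 2 + z0 ** 2)
    r2 = np.sqrt(rho ** 2 + (z0 + 2.0 * zb) ** 2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1 ** 2
    term2 = (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2 ** 2
    return (term1 + term2) / (4.0 * np.pi)


def two_layer_neg_log_drs(rho, mua_top, d_top: float, mua_bottom, mus_prime,
                          n_rel: float = 1.0, detector_radius: float = 0.2,
                          dpf_top: float = 2.0):
    """-log DRS of a thin-top-layer medium (modified Beer-Lambert form).

    The bottom layer is treated as semi-infinite with the dipole solution
    integrated over a detector disc of ``detector_radius`` (DRS is then the
    dimensionless detected fraction); the top layer of thickness ``d_top``
    (mm) adds 2 * dpf_top * mua_top * d_top of attenuation for the double
    (diffuse) traversal.  An approximation: it holds for d_top small against
    the transport mean free path and ignores top-layer scattering contrast.
    """
    r_bottom = diffusion_reflectance(rho, mua_bottom, mus_prime, n_rel)
    drs = r_bottom * np.pi * detector_radius ** 2
    return -np.log(drs) + 2.0 * dpf_top * np.asarray(mua_top, dtype=float) * d_top
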