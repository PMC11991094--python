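"""Closed-form sanity checks on the Monte Carlo engine and the PPG math.

Runs the oracle suite: weight-ledger closure on a full skin simulation,
ballistic Beer-Lambert transmission through a scattering-free slab,
normal-incidence Fresnel reflectance, the Henyey-Greenstein mean cosine,
and the hand-workable mean-optical-pathlength / AC/DC examples.
"""

import numpy as np

from ppgmc import run_oracle_suite

out = run_oracle_suite(seed=0, n_hg=1_000_000)

print("weight-ledger closure residual : "
      f"{out['ledger_closure_residual']:.2e}  (should be < 1e-9)")
print("ballistic transmission         : "
      f"{out['ballistic_transmission']:.6f}  (exp(-mua*L) = {np.exp(-1.0):.6f})")
print("Fresnel normal-incidence R     : "
      f"{out['fresnel_normal_R']:.6f}  (((n-1)/(n+1))^2 = {out['fresnel_expected']:.6f})")
print("HG mean cos, g=0.9             : "
      f"{out['hg_mean_cos_g0.9']:.5f}  (<cos> = g = 0.9)")
print("MOP of records (w,l)=(1,2),(3,4): "
      f"{out['mop_example_mm']:.2f} mm  (hand value 3.50 mm)")
print("AC/DC of -log DRS 0.5 vs 0.4   : "
      f"{out['ac_dc_example_percent']:.2f} %  (hand value 25.00 %)")
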