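"""The seven-phantom PPG pulse: spectra, waveform, and AC/DC orderings.

A cardiac pulse is emulated by seven gel phantoms whose bottom-layer
hemoglobin concentration rises from 2.0 to 3.1 mg/mL and falls back.
This script runs the diffusion forward model at source-detector distance
0.5 mm, prints the -log(DRS) waveform at 540 nm, and compares AC/DC at
green vs NIR wavelengths and with/without the 0.20 mm melanin-like ink
top layer.
"""

import numpy as np

from ppgmc import PhantomSeries, forward_drs

for d_mm in (0.0, 0.20):
    series = PhantomSeries(d_mm=d_mm)
    drs = forward_drs(series)  # (phantom, wavelength)
    wl = drs.wavelength.values
    p = -np.log(drs.values)
    acdc = 100.0 * (p.max(axis=0) - p.min(axis=0)) / p.min(axis=0)

    print(f"\n== top layer D = {d_mm:.2f} mm ==")
    print("Hb arc (mg/mL):", series.hb_concentrations)
    w540 = p[:, wl == 540.0].ravel()
    print("-log DRS waveform @540 nm:", np.array2string(w540, precision=4))
    print("  (rises with Hb to the 3.1 mg/mL apex and falls back: the pulse)")
    for w in (450.0, 540.0, 580.0, 900.0):
        print(f"AC/DC @{w:.0f} nm: {acdc[wl == w][0]:6.2f} %")

print("\nShort and green wavelengths give a far stronger pulse than NIR, "
      "and the ink layer\nsuppresses the short-wavelength pulse much more "
      "than the NIR one.")
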