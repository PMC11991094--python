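"""Round trip: emulate a noisy phantom measurement campaign, then analyze it.

Writes 7 phantoms x 3 replicates of synthetic spectrometer files plus a
99%-reflectance reference to a temporary directory, then runs the phantom
pipeline on the files: DRS normalization, pulse waveforms, and the AC/DC
spectrum with replicate error bars.
"""

import tempfile

from ppgmc import (NoiseModel, PhantomSeries, RunConfig,
                   emulate_measurement_set, run_phantom_pipeline)

with tempfile.TemporaryDirectory() as tmp:
    series = PhantomSeries(d_mm=0.0, replicates=3)
    manifest = emulate_measurement_set(series, NoiseModel(rel_sd=0.01, seed=0), tmp)
    print(f"wrote {7 * 3} sample spectra + 1 reference under {tmp}")

    res = run_phantom_pipeline(RunConfig(experiment="phantom_pipeline",
                                         manifest=str(manifest)))
    acdc = res["ac_dc"].set_index("wavelength_nm")
    print("\nAC/DC spectrum (mean over 3 replicates +/- sd):")
    for wl in (450.0, 540.0, 580.0, 700.0, 900.0):
        row = acdc.loc[wl]
        print(f"  {wl:5.0f} nm: {row['ac_dc_percent']:6.2f} +/- "
              f"{row['ac_dc_sd']:5.2f} %")
    print("\nStrong hemoglobin absorption below ~600 nm carries the pulse; "
          "the NIR AC/DC sits at the noise floor.")
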