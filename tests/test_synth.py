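import json

import numpy as np
import pytest

from ppgmc.diffusion import diffusion_reflectance
from ppgmc.pipelines import RunConfig, run_phantom_pipeline
from ppgmc.synth import (DEFAULT_ARC, NoiseModel, PhantomSeries, add_noise,
                         emulate_measurement_set, forward_drs)


class TestPhantomSeries:
    def test_default_arc_is_pulse_shaped(self):
        s = PhantomSeries()
        assert s.hb_concentrations == DEFAULT_ARC
        assert max(s.hb_concentrations) == 3.1 and min(s.hb_concentrations) == 2.0

    def test_rejects_non_arc(self):
        with pytest.raises(ValueError):
            PhantomSeries(hb_concentrations=(2.0, 3.0, 2.5, 3.1))
        with pytest.raises(ValueError):
            PhantomSeries(hb_concentrations=(3.0, 2.0, 2.5))

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            PhantomSeries(hb_concentrations=(2.0, 0.0, 2.0))


class TestForwardModel:
    def test_drs_decreases_with_hb_everywhere_hb_absorbs(self):
        g = forward_drs(PhantomSeries())
        wl = g.wavelength.values
        rising = g.values[:4]  # concentrations 2.0 -> 3.1
        sel = wl <= 600.0  # strong Hb absorption band
        assert np.all(np.diff(rising[:, sel], axis=0) < 0)
        assert np.all(np.diff(rising, axis=0) <= 1e-12)  # never increases anywhere

    def test_neg_log_waveform_is_pulse_shaped_at_540(self):
        g = forward_drs(PhantomSeries())
        p = -np.log(g.sel(wavelength=540.0).values)
        apex = int(np.argmax(p))
        assert apex == 3  # the 3.1 mg/mL phantom
        assert np.all(np.diff(p[:4]) > 0) and np.all(np.diff(p[3:]) < 0)

    def test_green_beats_nir_acdc(self):
        g = forward_drs(PhantomSeries())
        p = -np.log(g.values)
        acdc = 100 * (p.max(axis=0) - p.min(axis=0)) / p.min(axis=0)
        wl = g.wavelength.values
        assert acdc[wl == 540.0] > acdc[wl == 900.0]

    def test_ink_layer_hits_short_wavelengths_harder(self):
        bare = forward_drs(PhantomSeries(d_mm=0.0))
        inked = forward_drs(PhantomSeries(d_mm=0.20))
        ratio = inked.values[0] / bare.values[0]
        wl = bare.wavelength.values
        assert ratio[wl == 450.0] < ratio[wl == 900.0]

    def test_doubling_absorber_never_raises_reflectance(self):
        rho = 0.5
        musp = 1.7
        r = [float(diffusion_reflectance(rho, mua, musp)) for mua in
             (0.0, 0.1, 0.2, 0.4, 0.8, 1.6)]
        assert np.all(np.diff(r) < 0)

    def test_mc_engine_agrees_on_orderings(self):
        """Dual route: the Monte Carlo engine reproduces the diffusion-model
        orderings (darker with Hb; green AC/DC above NIR) at SDD 0.5 mm."""
        s = PhantomSeries(hb_concentrations=(2.0, 3.1, 2.0),
                          wavelengths=np.array([540.0, 900.0]))
        mc = forward_drs(s, engine="mc", n_photons=100_000, seed=3)
        assert mc.values[1, 0] < mc.values[0, 0]  # more Hb -> darker at 540
        p = -np.log(mc.values)
        acdc = 100 * (p.max(axis=0) - p.min(axis=0)) / p.min(axis=0)
        assert acdc[0] > acdc[1]

    def test_unknown_engine_errors(self):
        with pytest.raises(ValueError):
            forward_drs(PhantomSeries(), engine="magic")


class TestNoise:
    def test_zero_sd_is_identity(self):
        g = forward_drs(PhantomSeries())
        noisy = add_noise(g.assign_attrs(replicates=2), NoiseModel(rel_sd=0.0))
        assert noisy.shape == (2,) + g.shape
        np.testing.assert_array_equal(noisy.values[0], g.values)
        np.testing.assert_array_equal(noisy.values[1], g.values)

    def test_same_seed_same_noise(self):
        g = forward_drs(PhantomSeries())
        a = add_noise(g.assign_attrs(replicates=2), NoiseModel(seed=4))
        b = add_noise(g.assign_attrs(replicates=2), NoiseModel(seed=4))
        np.testing.assert_array_equal(a.values, b.values)
        c = add_noise(g.assign_attrs(replicates=2), NoiseModel(seed=5))
        assert not np.array_equal(a.values, c.values)

    def test_replicate_mean_converges_to_truth(self):
        """Law of large numbers: 1e4 replicates recover the grid to 1%."""
        small = PhantomSeries(hb_concentrations=(2.0, 3.1, 2.0),
                              wavelengths=np.arange(500.0, 600.0, 25.0))
        g = forward_drs(small)
        noisy = add_noise(g.assign_attrs(replicates=10_000),
                          NoiseModel(rel_sd=0.05, seed=1))
        rel = np.abs(noisy.values.mean(axis=0) / g.values - 1.0)
        assert rel.max() < 0.01


class TestEmulatedMeasurementSet:
    def test_file_count_and_manifest(self, tmp_path):
        man = emulate_measurement_set(PhantomSeries(), NoiseModel(), tmp_path)
        d = json.loads(man.read_text())
        assert len(d["samples"]) == 7 * 3
        assert (tmp_path / d["reference"]["file"]).exists()
        for s in d["samples"]:
            assert (tmp_path / s["file"]).exists()

    def test_noiseless_round_trip_through_pipeline(self, tmp_path):
        series = PhantomSeries(replicates=1)
        man = emulate_measurement_set(series, NoiseModel(rel_sd=0.0), tmp_path)
        res = run_phantom_pipeline(RunConfig(experiment="phantom_pipeline",
                                             manifest=str(man)))
        truth = forward_drs(series)
        rec = res["drs"].mean("replicate").values
        np.testing.assert_allclose(rec, truth.values, rtol=1e-8)

    def test_noisy_acdc_within_replicate_spread(self, tmp_path):
        """Noise propagation: AC/DC from a noisy set stays within a few
        replicate SDs of the noiseless value at 540 nm."""
        series = PhantomSeries(replicates=3)
        man = emulate_measurement_set(series, NoiseModel(rel_sd=0.01, seed=2),
                                      tmp_path / "noisy")
        res = run_phantom_pipeline(RunConfig(experiment="phantom_pipeline",
                                             manifest=str(man)))
        truth = forward_drs(series)
        p = -np.log(truth.sel(wavelength=540.0).values)
        acdc_true = 100 * (p.max() - p.min()) / p.min()
        row = res["ac_dc"].set_index("wavelength_nm").loc[540.0]
        # noise inflates the extrema spread, so allow the bias plus 3 SD
        assert abs(row["ac_dc_percent"] - acdc_true) < 3 * max(row["ac_dc_sd"], 0.2)
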