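import pytest

from ppgmc.chromophores import skin_media
from ppgmc.geometry import SkinSpec, build_skin_volume, dilate_vessels, resolve_centers
from ppgmc.transport import DetectorSpec, RngPolicy, SourceSpec, simulate


@pytest.fixture(scope="session")
def skin_pair():
    """Small coupled-seed systole/diastole pair at 523 nm, SDD 1 mm.

    Shared across transport/ppg tests to amortize the Monte Carlo cost.
    """
    media = skin_media()
    dia = resolve_centers(SkinSpec(epidermal_thickness_um=50.0,
                                   vessel_diameter_um=117.0, placement_seed=3))
    sys_ = dilate_vessels(dia, 75.0)
    dets = [DetectorSpec(sdd=1.0, radius=0.5)]
    src = SourceSpec()
    rng = RngPolicy(seed=9)
    res_s = simulate(build_skin_volume(sys_), media, src, dets, 150_000,
                     rng=rng, wavelength=523.0)
    res_d = simulate(build_skin_volume(dia), media, src, dets, 150_000,
                     rng=rng, wavelength=523.0)
    return res_s, res_d
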