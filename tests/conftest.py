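import numpy as np
import pytest

from olfnet import epithelium as epi
from olfnet import odor_space as osp
from olfnet.pipeline import PipelineConfig, train


@pytest.fixture(scope="session")
def default_dist():
    return osp.default_distance_distribution()


@pytest.fixture(scope="session")
def panel50(default_dist):
    """The reference training panel: 50 patterns over 40 ORs."""
    return osp.generate_pattern_set(50, 40, default_dist, seed=1)


@pytest.fixture(scope="session")
def family():
    return epi.make_family(0, n_orn=800, n_groups=8,
                           rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def trained_model(panel50):
    """Full-scale model trained once and shared across read-only tests."""
    return train(panel50, config=PipelineConfig(), seed=1)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down pipeline for fast functional tests."""
    return PipelineConfig(n_patterns=10, n_or=12, n_orn=80, n_groups=4,
                          n_hc=4, n_mc=8, m=2)


@pytest.fixture(scope="session")
def spiking_run():
    """Reduced-scale end-to-end spiking run: train, wire, simulate pattern 0.

    10 glomeruli, 6 HC x 10 MC with 10 PYR per MC — small enough to
    integrate in seconds while keeping the modular architecture intact.
    """
    import pandas as pd

    from olfnet import bulb as bulb_mod
    from olfnet import spiking_backend as spk
    from olfnet import wiring

    cfg = PipelineConfig(n_patterns=20, n_or=10, n_orn=200, n_groups=4,
                         n_hc=6, n_mc=10, m=3)
    panel = osp.generate_pattern_set(20, 10, seed=2)
    model = train(panel, config=cfg, seed=2)
    arch = wiring.Architecture(n_glom=10, mt_per_glom=4, n_hc=6, n_mc=10,
                               pyr_per_mc=10, rsnp_per_mc=4, basket_per_mc=4,
                               n_readout=20)
    ff = wiring.realize_feedforward(
        wiring.map_weights_to_conductances(model.ff_net.w, "mt_to_cortex"),
        arch, seed=2)
    rec_t = wiring.realize_recurrent(
        wiring.map_weights_to_conductances(model.rec_net.w, "pyr_origin",
                                           pos_cap=1.0), arch, seed=2)
    static = wiring.build_static_circuit(arch, seed=2)
    ro = wiring.connect_readout(
        arch, wiring.map_weights_to_conductances(model.ro_net.w, "pyr_origin",
                                                 pos_cap=0.5))
    table = wiring.jitter_weights(
        pd.concat([static, ff, rec_t, ro], ignore_index=True), 0.10, seed=2)
    one = osp.AffinityMatrix(panel.values[:1], panel.active[:1])
    resp = bulb_mod.bulb_response(one, model.families, poisson_noise=False)
    rates = resp.f[:, 0] / (resp.window_ms / 1000.0)
    scfg = spk.SpikingConfig(duration_ms=800.0, dt_ms=0.2, seed=5,
                             background_hz=5.0)
    record = spk.build_and_simulate(table, rates, scfg, arch,
                                    mc_bias=model.ff_net.beta)
    return record, arch, model
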