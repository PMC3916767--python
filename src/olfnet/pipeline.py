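"""End-to-end training and classification with the abstract backend.

``train`` runs panel → bulb → normalizations → MI/MDS/VQ → BCPNN and
returns a :class:`TrainedModel`; ``classify`` presents new panels to a
trained model.  Test responses are normalized with the *training* per-cell
spike totals, so a weaker (incomplete, low-concentration) stimulus yields
proportionally weaker ξ rather than being renormalized away.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import bulb as bulb_mod
from . import cortex_abstract as cortex
from . import epithelium as epi
from . import odor_space
from . import selforg
from .odor_space import AffinityMatrix
from .selforg import BCPNNNet, ProjectionMap


@dataclass
class PipelineConfig:
    """Default geometry and front-end parameters of the reference system.

    40 ORs/glomeruli with 8 MT cells each (320 MT), 800 ORNs per family,
    cortex of 12 hypercolumns × 30 minicolumns, m = 4 HC assignments per
    MT cell, 50 training patterns activating 30–50% of the ORs.
    """

    n_patterns: int = 50
    n_or: int = 40
    activation_range: tuple = (0.3, 0.5)
    sharpness: float = odor_space.DEFAULT_SHARPNESS
    # epithelium
    n_orn: int = 800
    n_groups: int = 8
    sensitivity_range: tuple = epi.DEFAULT_SENSITIVITY_RANGE
    rate_range: tuple = epi.DEFAULT_RATE_RANGE
    hill: float = epi.DEFAULT_HILL
    # bulb
    window_ms: float = bulb_mod.DEFAULT_WINDOW_MS
    alpha: float = bulb_mod.DEFAULT_ALPHA
    inhibition_weight: float = bulb_mod.DEFAULT_INHIBITION_WEIGHT
    target_rate: float = bulb_mod.DEFAULT_TARGET_RATE
    poisson_noise: bool = False
    # cortex
    n_hc: int = 12
    n_mc: int = 30
    m: int = 4
    n_iter: int = cortex.DEFAULT_N_ITER
    rec_gain: float = cortex.DEFAULT_REC_GAIN
    onset: float = epi.DEFAULT_ONSET

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedModel:
    """Everything needed to classify new stimuli."""

    config: PipelineConfig
    seed: int
    families: list
    row_totals: np.ndarray  # per-MT summed training counts (Eq.-3 normalizer)
    xi_train: np.ndarray
    projection: ProjectionMap
    ff_net: BCPNNNet
    rec_net: BCPNNNet
    ro_net: BCPNNNet
    labels: np.ndarray  # training label per pattern

    @property
    def hc_of_mc(self) -> np.ndarray:
        return self.projection.hc_of_mc


def _stimulus_to_xi(
    panel: AffinityMatrix, model_families, cfg: PipelineConfig,
    row_totals: np.ndarray, seed: int,
) -> np.ndarray:
    resp = bulb_mod.bulb_response(
        panel, model_families, seed=seed, window_ms=cfg.window_ms,
        poisson_noise=cfg.poisson_noise, alpha=cfg.alpha,
        inhibition_weight=cfg.inhibition_weight, target_rate=cfg.target_rate)
    f_prime = np.divide(resp.f, row_totals[:, None],
                        out=np.zeros_like(resp.f), where=row_totals[:, None] > 0)
    return selforg.half_normalize(f_prime, resp.glomerulus_index)


def train(
    panel: AffinityMatrix,
    config: PipelineConfig | None = None,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> TrainedModel:
    """Self-organize the full bulb→cortex→readout system on a panel."""
    cfg = config or PipelineConfig()
    if panel.n_or != cfg.n_or:
        cfg = PipelineConfig(**{**cfg.to_dict(), "n_or": panel.n_or})
    n_p = panel.n_patterns
    labels = np.arange(n_p) if labels is None else np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    families = epi.make_families(
        cfg.n_or, seed=int(rng.integers(2**31 - 1)), n_orn=cfg.n_orn,
        n_groups=cfg.n_groups, sensitivity_range=cfg.sensitivity_range,
        rate_range=cfg.rate_range, hill=cfg.hill, onset=cfg.onset)
    resp = bulb_mod.bulb_response(
        panel, families, seed=int(rng.integers(2**31 - 1)),
        window_ms=cfg.window_ms, poisson_noise=cfg.poisson_noise,
        alpha=cfg.alpha, inhibition_weight=cfg.inhibition_weight,
        target_rate=cfg.target_rate)
    row_totals = resp.f.sum(axis=1)
    f_prime = selforg.normalize_responses(resp.f)
    xi = selforg.half_normalize(f_prime, resp.glomerulus_index)

    p_mt, p_joint_mt = selforg.activation_probabilities(xi)
    stats = selforg.mi_distance(p_mt, p_joint_mt)
    coords = selforg.embed_mds(stats.distance, dims=3,
                               seed=int(rng.integers(2**31 - 1)))
    silent = row_totals == 0
    hc_of_mt, mt_of_hc, _ = selforg.vq_mt_to_hc(
        coords, cfg.n_hc, m=cfg.m, silent_mask=silent,
        seed=int(rng.integers(2**31 - 1)))
    zeta = selforg.vq_patterns_to_mc(
        xi, mt_of_hc, cfg.n_mc, seed=int(rng.integers(2**31 - 1)))
    projection = ProjectionMap(coords, hc_of_mt, mt_of_hc, zeta,
                               cfg.n_hc, cfg.n_mc, cfg.m)

    # feedforward BCPNN: MT (pre, graded xi) -> MC (post, binary zeta);
    # connections exist only between an MT cell and MCs of its assigned HCs
    p_mc = zeta.mean(axis=0)
    p_joint_ff = selforg.joint_probabilities(xi, zeta.T)
    w_ff = selforg.bcpnn_weights(p_mt, p_mc, p_joint_ff, n_p)
    hc_of_mc = projection.hc_of_mc
    allowed = np.zeros_like(w_ff, dtype=bool)
    for i, hcs in enumerate(hc_of_mt):
        if hcs.size:
            allowed[i] = np.isin(hc_of_mc, hcs)
    w_ff[~allowed] = 0.0
    ff_net = BCPNNNet(w_ff, selforg.bcpnn_bias(p_mc, n_p), n_p)

    s = cortex.feedforward_support(ff_net.w, xi)
    o_prime = cortex._activate_and_normalize(s, ff_net.beta, hc_of_mc)
    rec_net = cortex.learn_recurrent(o_prime, hc_of_mc, n_p)
    ro_net = cortex.learn_readout(o_prime, labels)
    return TrainedModel(cfg, seed, families, row_totals, xi, projection,
                        ff_net, rec_net, ro_net, labels)


def classify(
    model: TrainedModel,
    panel: AffinityMatrix,
    with_recurrence: bool = True,
    n_iter: int | None = None,
    seed: int = 0,
) -> cortex.RecallResult:
    """Present a panel to a trained model and classify every pattern."""
    xi_test = _stimulus_to_xi(panel, model.families, model.config,
                              model.row_totals, seed)
    rec = model.rec_net if with_recurrence else None
    n_iter = model.config.n_iter if n_iter is None else n_iter
    return cortex.recall(xi_test, model.ff_net, rec, model.ro_net,
                         model.hc_of_mc, n_iter=n_iter,
                         rec_gain=model.config.rec_gain)
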