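"""Olfactory bulb front end: the mitral/tufted concentration-interval code.

Each glomerulus hosts one MT cell per ORN group (default 8).  MT cell *g*
receives the excitation of ORN group *g* minus the (periglomerular-relayed)
inhibition driven by the next less sensitive group *g+1*, rectified — the
difference of two adjacent saturating response curves, which is a bump
tuned to one concentration interval.  The least sensitive MT keeps its own
group's drive and covers the top of the range.  Intra-glomerular inhibition
is summarized by a divisive normalization toward a target summed output
rate, so total glomerular output is approximately concentration-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .epithelium import ORNFamily, group_rates
from .odor_space import AffinityMatrix

DEFAULT_WINDOW_MS = 1600.0
DEFAULT_TARGET_RATE = 40.0  # spikes/s summed per glomerulus
DEFAULT_ALPHA = 1.0
DEFAULT_INHIBITION_WEIGHT = 1.0


@dataclass
class ResponseMatrix:
    """MT spike counts over the stimulation window: cells × patterns."""

    f: np.ndarray  # (n_mt, n_patterns), non-negative counts
    n_glomeruli: int
    n_groups: int
    window_ms: float = DEFAULT_WINDOW_MS

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.min(initial=0.0) < 0:
            raise ValueError("spike counts must be non-negative")
        if self.f.shape[0] != self.n_glomeruli * self.n_groups:
            raise ValueError("row count must equal n_glomeruli * n_groups")

    @property
    def n_mt(self) -> int:
        return self.f.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.f.shape[1]

    @property
    def glomerulus_index(self) -> np.ndarray:
        """Glomerulus id of each MT row (rows are glomerulus-major)."""
        return np.repeat(np.arange(self.n_glomeruli), self.n_groups)

    def save(self, path, seed=None) -> None:
        path = Path(path)
        pd.DataFrame(self.f).to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(
            {"n_glomeruli": self.n_glomeruli, "n_groups": self.n_groups,
             "window_ms": self.window_ms, "seed": seed}))

    @classmethod
    def load(cls, path) -> "ResponseMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        f = pd.read_csv(path).to_numpy(dtype=float)
        return cls(f, meta["n_glomeruli"], meta["n_groups"], meta["window_ms"])


def mt_interval_response(
    family: ORNFamily,
    oav,
    alpha: float = DEFAULT_ALPHA,
    inhibition_weight: float = DEFAULT_INHIBITION_WEIGHT,
    target_rate: float | None = DEFAULT_TARGET_RATE,
) -> np.ndarray:
    """MT rates (spikes/s) of one glomerulus at the given OAV(s).

    ``MT_g = max(0, alpha * (G_g - inhibition_weight * G_{g+1}))`` for all
    but the last group; the last MT carries ``alpha * G_last``.  When the
    summed MT rate exceeds ``target_rate`` the vector is divisively scaled
    to it (set ``target_rate=None`` to disable the normalization).
    """
    g = group_rates(family, np.atleast_1d(oav))  # (n_groups, P)
    mt = np.empty_like(g)
    if family.n_groups > 1:
        mt[:-1] = np.maximum(0.0, alpha * (g[:-1] - inhibition_weight * g[1:]))
        mt[-1] = alpha * g[-1]
    else:
        mt[0] = alpha * g[0]
    if target_rate is not None:
        tot = mt.sum(axis=0)
        scale = np.where(tot > target_rate, np.divide(
            target_rate, tot, out=np.ones_like(tot), where=tot > 0), 1.0)
        mt = mt * scale[None, :]
    return mt[:, 0] if np.isscalar(oav) or np.ndim(oav) == 0 else mt


def bulb_response(
    panel: AffinityMatrix,
    families: list[ORNFamily],
    seed: int = 0,
    window_ms: float = DEFAULT_WINDOW_MS,
    poisson_noise: bool = False,
    alpha: float = DEFAULT_ALPHA,
    inhibition_weight: float = DEFAULT_INHIBITION_WEIGHT,
    target_rate: float | None = DEFAULT_TARGET_RATE,
) -> ResponseMatrix:
    """Simulate MT spike counts of the whole bulb for every panel pattern.

    Rows are glomerulus-major (glomerulus 0 groups 0..n_groups-1, then
    glomerulus 1, ...).  Counts are expected counts over the window;
    ``poisson_noise=True`` draws Poisson counts around them (seeded).
    """
    if panel.n_or != len(families):
        raise ValueError(
            f"panel has {panel.n_or} ORs but {len(families)} families given")
    n_groups = families[0].n_groups
    rng = np.random.default_rng(seed)
    blocks = []
    for j, fam in enumerate(families):
        rates = mt_interval_response(
            fam, panel.values[:, j], alpha=alpha,
            inhibition_weight=inhibition_weight, target_rate=target_rate)
        blocks.append(rates * (window_ms / 1000.0))
    f = np.vstack(blocks)
    if poisson_noise:
        f = rng.poisson(f).astype(float)
    return ResponseMatrix(f, len(families), n_groups, window_ms)
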