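"""Translate abstract BCPNN weights into a cell-level synapse table.

Abstract weights live between populations (MT cell → minicolumn,
minicolumn → minicolumn, minicolumn → readout).  Here they are linearly
mapped to conductances (nS) and expanded into individual cell pairs:

* excitatory MT→MC weights target half of the MC's pyramidal (PYR) cells;
* inhibitory MT→MC weights excite 3 of the MC's 4 RSNP interneurons,
  which inhibit the PYR cells (the most negative weight maps to 3 nS);
* positive MC→MC weights become 45 distinct long-range PYR→PYR pairs
  (5% of the 30 × 30 possible pairs); negative ones 10 source PYR × 3
  target RSNP (PYR-origin negative cap 1.5 nS);
* every PYR of an MC contacts every readout unit;
* the static intra-cortical circuit (PYR→PYR within MC 25%, PYR→basket
  70%, basket→PYR 70% within HC, RSNP→PYR 70% within MC) is a Bernoulli
  realization.

Conductances mapping below 5 pS are discarded.  Cell ids are global
0-based integers, population-major: MT, PYR, RSNP, basket, readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDUCTANCE_FLOOR_NS = 0.005  # 5 pS
NEG_CAP_MT_NS = 3.0  # most negative MT→cortex weight
NEG_CAP_PYR_NS = 1.5  # most negative PYR-origin weight
POS_CAP_NS = 2.0  # positive-route cap (free scaling, "a few nS")

#: Static-circuit conductances (nS); functional placeholders on the same
#: "few nS" scale as the learned routes.
STATIC_G = {"PYR→PYR(MC)": 0.5, "PYR→basket": 1.0, "basket→PYR": 2.0,
            "RSNP→PYR": 2.0}


@dataclass(frozen=True)
class Architecture:
    """Cell counts and static connection probabilities of the full system."""

    n_glom: int = 40
    mt_per_glom: int = 8
    orn_per_mt: int = 100
    pg_per_mt: int = 20
    gc_per_mt: int = 200
    n_hc: int = 12
    n_mc: int = 30
    pyr_per_mc: int = 30
    rsnp_per_mc: int = 4
    basket_per_mc: int = 6
    n_readout: int = 50
    p_pyr_pyr: float = 0.25  # within MC
    p_pyr_basket: float = 0.7  # within HC
    p_basket_pyr: float = 0.7  # within HC
    p_rsnp_pyr: float = 0.7  # within MC
    # fan-outs of realized learned connections; derived from the population
    # fractions (50% of PYR, 75% of RSNP, 5% of PYR pairs, 1/3 of PYR) when
    # left unset — 15 / 3 / 45 / 10 / 3 at the reference scale
    mt_exc_targets: int | None = None
    mt_inh_targets: int | None = None
    rec_exc_pairs: int | None = None
    rec_inh_src_pyr: int | None = None
    rec_inh_tgt_rsnp: int | None = None

    def __post_init__(self):
        for name in ("p_pyr_pyr", "p_pyr_basket", "p_basket_pyr", "p_rsnp_pyr"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        derived = {
            "mt_exc_targets": max(1, round(0.5 * self.pyr_per_mc)),
            "mt_inh_targets": max(1, round(0.75 * self.rsnp_per_mc)),
            "rec_exc_pairs": max(1, round(0.05 * self.pyr_per_mc**2)),
            "rec_inh_src_pyr": max(1, round(self.pyr_per_mc / 3)),
            "rec_inh_tgt_rsnp": max(1, round(0.75 * self.rsnp_per_mc)),
        }
        for name, value in derived.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)

    # population sizes -----------------------------------------------------
    @property
    def n_mt(self) -> int:
        return self.n_glom * self.mt_per_glom

    @property
    def n_orn(self) -> int:
        return self.n_mt * self.orn_per_mt

    @property
    def n_pg(self) -> int:
        return self.n_mt * self.pg_per_mt

    @property
    def n_granule(self) -> int:
        return self.n_mt * self.gc_per_mt

    @property
    def n_mc_total(self) -> int:
        return self.n_hc * self.n_mc

    @property
    def n_pyr(self) -> int:
        return self.n_mc_total * self.pyr_per_mc

    @property
    def n_rsnp(self) -> int:
        return self.n_mc_total * self.rsnp_per_mc

    @property
    def n_basket(self) -> int:
        return self.n_mc_total * self.basket_per_mc

    # global id layout (population-major, 0-based) -------------------------
    @property
    def offsets(self) -> dict:
        off, cursor = {}, 0
        for name, n in (("MT", self.n_mt), ("PYR", self.n_pyr),
                        ("RSNP", self.n_rsnp), ("basket", self.n_basket),
                        ("readout", self.n_readout)):
            off[name] = cursor
            cursor += n
        return off

    def pyr_ids(self, mc: int) -> np.ndarray:
        return self.offsets["PYR"] + mc * self.pyr_per_mc + np.arange(self.pyr_per_mc)

    def rsnp_ids(self, mc: int) -> np.ndarray:
        return self.offsets["RSNP"] + mc * self.rsnp_per_mc + np.arange(self.rsnp_per_mc)

    def basket_ids(self, hc: int) -> np.ndarray:
        start = self.offsets["basket"] + hc * self.n_mc * self.basket_per_mc
        return start + np.arange(self.n_mc * self.basket_per_mc)

    def readout_ids(self) -> np.ndarray:
        return self.offsets["readout"] + np.arange(self.n_readout)


def _table(src, tgt, g, klass) -> pd.DataFrame:
    return pd.DataFrame({
        "source_id": np.asarray(src, dtype=int),
        "target_id": np.asarray(tgt, dtype=int),
        "conductance_nS": np.asarray(g, dtype=float),
        "synapse_class": klass,
    })


EMPTY_TABLE = _table([], [], [], [])


def map_weights_to_conductances(
    w: np.ndarray,
    projection_class: str,
    pos_cap: float = POS_CAP_NS,
    floor: float = CONDUCTANCE_FLOOR_NS,
) -> np.ndarray:
    """Linear abstract-weight → conductance map with class-specific caps.

    Positive and negative weights are scaled by separate linear factors so
    that the largest positive weight maps to ``pos_cap`` and the most
    negative to the class cap (3 nS for ``"mt_to_cortex"``, 1.5 nS for
    ``"pyr_origin"``).  The sign is kept (negative = inhibitory route);
    magnitudes below the 5 pS floor are zeroed (discarded connections).
    """
    caps = {"mt_to_cortex": NEG_CAP_MT_NS, "pyr_origin": NEG_CAP_PYR_NS}
    if projection_class not in caps:
        raise ValueError(f"unknown projection class {projection_class!r}")
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight matrix")
    g = np.zeros_like(w)
    wmax = w.max(initial=0.0)
    wmin = w.min(initial=0.0)
    if wmax > 0:
        g[w > 0] = w[w > 0] / wmax * pos_cap
    if wmin < 0:
        g[w < 0] = w[w < 0] / (-wmin) * caps[projection_class]
    g[np.abs(g) < floor] = 0.0
    if not np.any(g):
        warnings.warn("all weights mapped below the conductance floor")
    return g


def realize_feedforward(
    conductances: np.ndarray, arch: Architecture, seed: int = 0
) -> pd.DataFrame:
    """Expand signed MT→MC conductances into MT→PYR / MT→RSNP synapses."""
    g = np.asarray(conductances, dtype=float)
    rng = np.random.default_rng(seed)
    src, tgt, gs, klass = [], [], [], []
    mt_off = arch.offsets["MT"]
    for i, j in zip(*np.nonzero(g)):
        if g[i, j] > 0:
            targets = rng.choice(arch.pyr_ids(j), size=arch.mt_exc_targets,
                                 replace=False)
            name = "MT→PYR"
        else:
            targets = rng.choice(arch.rsnp_ids(j), size=arch.mt_inh_targets,
                                 replace=False)
            name = "MT→RSNP"
        src.extend([mt_off + i] * targets.size)
        tgt.extend(targets)
        gs.extend([abs(g[i, j])] * targets.size)
        klass.extend([name] * targets.size)
    return _table(src, tgt, gs, klass)


def realize_recurrent(
    conductances: np.ndarray, arch: Architecture, seed: int = 0
) -> pd.DataFrame:
    """Expand signed MC→MC conductances into long-range cell pairs.

    Positive entries: 45 distinct PYR→PYR pairs between the two MCs
    (duplicate draws are resampled).  Negative entries: 10 source PYR each
    contacting the same 3 target RSNP cells.
    """
    g = np.asarray(conductances, dtype=float)
    rng = np.random.default_rng(seed)
    frames = []
    n_pyr = arch.pyr_per_mc
    for i, j in zip(*np.nonzero(g)):
        if g[i, j] > 0:
            flat = rng.choice(n_pyr * n_pyr, size=arch.rec_exc_pairs,
                              replace=False)
            s = arch.pyr_ids(i)[flat // n_pyr]
            t = arch.pyr_ids(j)[flat % n_pyr]
            frames.append(_table(s, t, np.full(s.size, g[i, j]), "PYR→PYR(LR)"))
        else:
            s = rng.choice(arch.pyr_ids(i), size=arch.rec_inh_src_pyr,
                           replace=False)
            t = rng.choice(arch.rsnp_ids(j), size=arch.rec_inh_tgt_rsnp,
                           replace=False)
            ss, tt = np.repeat(s, t.size), np.tile(t, s.size)
            frames.append(_table(ss, tt, np.full(ss.size, abs(g[i, j])),
                                 "PYR→RSNP(LR)"))
    return pd.concat(frames, ignore_index=True) if frames else EMPTY_TABLE.copy()


def _bernoulli_pairs(src_ids, tgt_ids, p, rng, exclude_self=False):
    mask = rng.random((len(src_ids), len(tgt_ids))) < p
    if exclude_self:
        np.fill_diagonal(mask, False)
    si, ti = np.nonzero(mask)
    return np.asarray(src_ids)[si], np.asarray(tgt_ids)[ti]


def build_static_circuit(arch: Architecture, seed: int = 0) -> pd.DataFrame:
    """Bernoulli realization of the fixed (non-learned) cortical circuit."""
    rng = np.random.default_rng(seed)
    frames = []
    for mc in range(arch.n_mc_total):
        pyr = arch.pyr_ids(mc)
        s, t = _bernoulli_pairs(pyr, pyr, arch.p_pyr_pyr, rng, exclude_self=True)
        frames.append(_table(s, t, np.full(s.size, STATIC_G["PYR→PYR(MC)"]),
                             "PYR→PYR(MC)"))
        s, t = _bernoulli_pairs(arch.rsnp_ids(mc), pyr, arch.p_rsnp_pyr, rng)
        frames.append(_table(s, t, np.full(s.size, STATIC_G["RSNP→PYR"]),
                             "RSNP→PYR"))
    for hc in range(arch.n_hc):
        mcs = range(hc * arch.n_mc, (hc + 1) * arch.n_mc)
        pyr = np.concatenate([arch.pyr_ids(mc) for mc in mcs])
        basket = arch.basket_ids(hc)
        s, t = _bernoulli_pairs(pyr, basket, arch.p_pyr_basket, rng)
        frames.append(_table(s, t, np.full(s.size, STATIC_G["PYR→basket"]),
                             "PYR→basket"))
        s, t = _bernoulli_pairs(basket, pyr, arch.p_basket_pyr, rng)
        frames.append(_table(s, t, np.full(s.size, STATIC_G["basket→PYR"]),
                             "basket→PYR"))
    return pd.concat(frames, ignore_index=True)


def connect_readout(arch: Architecture, w_readout: np.ndarray) -> pd.DataFrame:
    """Every PYR of each MC contacts every readout unit at the MC's weight.

    The readout projection keeps the full density (no conductance floor);
    negative weights stay negative and act subtractively on the readout.
    """
    w = np.asarray(w_readout, dtype=float)
    if w.shape != (arch.n_mc_total, arch.n_readout):
        raise ValueError(
            f"readout weights must be {(arch.n_mc_total, arch.n_readout)}, "
            f"got {w.shape}")
    pyr = np.concatenate([arch.pyr_ids(mc) for mc in range(arch.n_mc_total)])
    ro = arch.readout_ids()
    src = np.repeat(pyr, arch.n_readout)
    tgt = np.tile(ro, pyr.size)
    g = np.repeat(w, arch.pyr_per_mc, axis=0).ravel()
    return _table(src, tgt, g, "PYR→Readout")


def jitter_weights(table: pd.DataFrame, fraction: float = 0.10,
                   seed: int = 0) -> pd.DataFrame:
    """Multiply each conductance by a uniform factor in [1-f, 1+f]."""
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["conductance_nS"] = out["conductance_nS"] * rng.uniform(
        1 - fraction, 1 + fraction, size=len(out))
    return out


def census(tables, arch: Architecture) -> dict:
    """Analytic expected counts vs realized counts per projection.

    ``analytic`` holds the architecture-determined cell and connection
    counts; ``realized`` the row counts of the supplied wiring tables,
    grouped by synapse class.  ``notes`` flags reported reference values
    that are inconsistent with the stated probability rules (the stated
    rules are authoritative).
    """
    per_hc_pyr = arch.n_mc * arch.pyr_per_mc
    per_hc_basket = arch.n_mc * arch.basket_per_mc
    analytic = {
        "cells": {
            "ORN": arch.n_orn, "MT": arch.n_mt, "PG": arch.n_pg,
            "granule": arch.n_granule, "PYR": arch.n_pyr,
            "RSNP": arch.n_rsnp, "basket": arch.n_basket,
            "readout": arch.n_readout,
        },
        "ORN→MT": arch.n_orn,  # each ORN drives exactly its MT cell
        "RSNP→PYR": round(arch.n_mc_total * arch.rsnp_per_mc
                          * arch.pyr_per_mc * arch.p_rsnp_pyr),
        "PYR→PYR(MC)": round(arch.n_mc_total * arch.pyr_per_mc
                             * (arch.pyr_per_mc - 1) * arch.p_pyr_pyr),
        "PYR→basket": round(arch.n_hc * per_hc_pyr * per_hc_basket
                            * arch.p_pyr_basket),
        "basket→PYR": round(arch.n_hc * per_hc_basket * per_hc_pyr
                            * arch.p_basket_pyr),
        "PYR→Readout": arch.n_pyr * arch.n_readout,
    }
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    realized = {}
    for t in tables:
        if len(t) == 0:
            continue
        for name, n in t.groupby("synapse_class").size().items():
            realized[name] = realized.get(name, 0) + int(n)
    notes = {
        "basket→PYR": "reference tabulation lists 630; the 70% within-HC "
                      "rule implies the analytic count reported here",
        "PYR→PYR(MC)": "reference tabulation lists ~75,500; the 25% "
                       "within-MC rule implies the analytic count",
        "granule": "reference tabulation lists 32,000; the 200-per-MT rule "
                   "implies the analytic count",
    }
    return {"analytic": analytic, "realized": realized, "notes": notes}
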