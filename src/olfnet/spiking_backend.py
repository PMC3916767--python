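"""Reduced spiking realization of the wired network.

A fixed-step conductance-based leaky-integrate-and-fire simulator for
qualitative verification of the attractor / winner-take-all dynamics at
configurable scale.  Excitatory cells (PYR) carry spike-frequency
adaptation; basket cells are fast-spiking (no adaptation); RSNP cells are
regular-spiking with weak adaptation.  Excitatory synapses have a fast
AMPA (10 ms) and a slow NMDA (≈150 ms, no magnesium-block nonlinearity by
default) component; inhibition is GABA (20 ms).  MT cells enter as
inhomogeneous Poisson spike sources whose rates follow the stimulus
envelope (a single ~400 ms puff or ~4 Hz sniffs); BCPNN biases act as
constant bias currents.  This point-neuron reduction preserves the
network architecture and the computational roles of the cell types, not
their biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wiring import Architecture

EXC_CLASSES = {"MT→PYR", "PYR→PYR(MC)", "PYR→PYR(LR)", "MT→RSNP",
               "PYR→RSNP(LR)", "PYR→basket", "PYR→Readout"}
INH_CLASSES = {"RSNP→PYR", "basket→PYR"}


@dataclass
class SpikingConfig:
    """Simulation parameters (times in ms, conductances in nS)."""

    duration_ms: float = 1600.0
    dt_ms: float = 0.1
    tau_ampa_ms: float = 10.0
    tau_nmda_ms: float = 150.0
    tau_gaba_ms: float = 20.0
    nmda_fraction: float = 0.3  # slow share of each excitatory synapse
    stimulus_mode: str = "puff"  # "puff" (~400 ms) or "sniff" (~4 Hz)
    puff_ms: float = 400.0
    sniff_hz: float = 4.0
    background_hz: float = 0.0  # Poisson background onto every cell
    background_g_ns: float = 0.5
    bias_scale_pa: float = 20.0  # pA per nat of BCPNN bias
    v_init_mean_mv: float = -70.0
    v_init_sd_mv: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.tau_ampa_ms, self.tau_nmda_ms, self.tau_gaba_ms) <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.duration_ms < self.puff_ms and self.stimulus_mode == "puff":
            raise ValueError("duration must cover the stimulus")


# LIF parameters per population
_LIF = {
    #            C_pF  gL_nS  EL_mV  Vth_mV Vres_mV tref_ms  b_adapt tau_w
    "PYR":     (200.0,  10.0, -70.0, -50.0, -60.0,   2.0,    40.0,  150.0),
    "RSNP":    (150.0,  10.0, -70.0, -50.0, -60.0,   2.0,    10.0,  150.0),
    "basket":  (100.0,  10.0, -70.0, -50.0, -65.0,   1.0,     0.0,  150.0),
    "readout": (200.0,  10.0, -70.0, -50.0, -60.0,   2.0,     0.0,  150.0),
}
E_EXC_MV = 0.0
E_INH_MV = -80.0


@dataclass
class SpikeRecord:
    """Spike times per cell over the simulation window."""

    spikes: np.ndarray  # (n_spikes, 2): cell id, time ms, time-sorted
    duration_ms: float
    populations: dict  # name -> (offset, count) of simulated populations

    def counts(self, offset: int, n: int) -> np.ndarray:
        ids = self.spikes[:, 0].astype(int)
        sel = (ids >= offset) & (ids < offset + n)
        return np.bincount(ids[sel] - offset, minlength=n)

    def save(self, path) -> None:
        pd.DataFrame(self.spikes, columns=["cell_id", "time_ms"]).to_csv(
            path, sep="\t", index=False)


def stimulus_envelope(t_ms: np.ndarray, config: SpikingConfig) -> np.ndarray:
    """Stimulus gating in [0, 1]: one puff or a 50%-duty sniff train."""
    if config.stimulus_mode == "puff":
        return (t_ms < config.puff_ms).astype(float)
    if config.stimulus_mode == "sniff":
        period = 1000.0 / config.sniff_hz
        return ((t_ms % period) < period / 2).astype(float)
    raise ValueError(f"unknown stimulus mode {config.stimulus_mode!r}")


def build_and_simulate(
    wiring: pd.DataFrame,
    mt_rates_hz: np.ndarray,
    config: SpikingConfig,
    arch: Architecture,
    mc_bias: np.ndarray | None = None,
) -> SpikeRecord:
    """Simulate the wired cortex driven by Poisson MT input.

    ``mt_rates_hz`` gives each MT cell's mean rate over the window; spikes
    are drawn as an inhomogeneous Poisson process under the stimulus
    envelope (rescaled so the mean count is preserved).  ``mc_bias`` (nats)
    is applied as a constant current to each MC's PYR cells.  Raises if
    the integration produces non-finite voltages.
    """
    rng = np.random.default_rng(config.seed)
    off = arch.offsets
    n_mt = arch.n_mt
    pops = {"PYR": (off["PYR"], arch.n_pyr), "RSNP": (off["RSNP"], arch.n_rsnp),
            "basket": (off["basket"], arch.n_basket),
            "readout": (off["readout"], arch.n_readout)}
    n_sim = sum(n for _, n in pops.values())
    sim_offset = off["PYR"]  # simulated ids are contiguous after MT

    n_steps = int(round(config.duration_ms / config.dt_ms))
    t = np.arange(n_steps) * config.dt_ms
    env = stimulus_envelope(t, config)
    duty = env.mean() if env.any() else 1.0

    # sparse-ish weight accumulation: per receptor type, n_sim x (n_mt+n_sim)
    n_total = n_mt + n_sim
    w_ampa = np.zeros((n_sim, n_total))
    w_gaba = np.zeros((n_sim, n_total))
    if len(wiring):
        src = wiring["source_id"].to_numpy(dtype=int)
        tgt = wiring["target_id"].to_numpy(dtype=int) - sim_offset
        g = wiring["conductance_nS"].to_numpy(dtype=float)
        klass = wiring["synapse_class"].to_numpy()
        if tgt.min(initial=0) < 0 or tgt.max(initial=0) >= n_sim:
            raise ValueError("wiring targets outside the simulated populations")
        for k in np.unique(klass):
            rows = klass == k
            mat = w_gaba if k in INH_CLASSES else w_ampa
            # readout rows may carry signed weights: negatives act as GABA
            neg = rows & (g < 0)
            np.add.at(mat, (tgt[rows & (g >= 0)], src[rows & (g >= 0)]),
                      g[rows & (g >= 0)])
            np.add.at(w_gaba, (tgt[neg], src[neg]), -g[neg])

    params = np.zeros((n_sim, 8))
    cursor = 0
    for name, (o, n) in pops.items():
        params[cursor:cursor + n] = _LIF[name]
        cursor += n
    c_pf, gl_ns, el, vth, vres, tref, b_adapt, tau_w = params.T

    bias_pa = np.zeros(n_sim)
    if mc_bias is not None:
        per_pyr = np.repeat(np.asarray(mc_bias, dtype=float), arch.pyr_per_mc)
        bias_pa[:arch.n_pyr] = config.bias_scale_pa * per_pyr

    v = rng.normal(config.v_init_mean_mv, config.v_init_sd_mv, size=n_sim)
    w_ad = np.zeros(n_sim)
    g_ampa = np.zeros(n_sim)
    g_nmda = np.zeros(n_sim)
    g_gaba = np.zeros(n_sim)
    refract = np.zeros(n_sim)
    dec_a = np.exp(-config.dt_ms / config.tau_ampa_ms)
    dec_n = np.exp(-config.dt_ms / config.tau_nmda_ms)
    dec_g = np.exp(-config.dt_ms / config.tau_gaba_ms)
    dec_w = np.exp(-config.dt_ms / 150.0)
    nm = config.nmda_fraction

    mt_rates_hz = np.asarray(mt_rates_hz, dtype=float)
    if mt_rates_hz.shape != (n_mt,):
        raise ValueError(f"mt_rates_hz must have shape ({n_mt},)")
    p_mt_base = mt_rates_hz / duty * config.dt_ms / 1000.0
    p_bg = config.background_hz * config.dt_ms / 1000.0

    spike_ids, spike_times = [], []
    last_spikes = np.zeros(n_total)
    for step in range(n_steps):
        # external spikes
        mt_spk = (rng.random(n_mt) < p_mt_base * env[step]).astype(float)
        spk_cols = np.flatnonzero(last_spikes)
        if spk_cols.size:
            inc_a = w_ampa[:, spk_cols].sum(axis=1)
            inc_g = w_gaba[:, spk_cols].sum(axis=1)
        else:
            inc_a = inc_g = 0.0
        g_ampa = g_ampa * dec_a + (1 - nm) * inc_a
        g_nmda = g_nmda * dec_n + nm * inc_a
        g_gaba = g_gaba * dec_g + inc_g
        if p_bg > 0:
            g_ampa += config.background_g_ns * (rng.random(n_sim) < p_bg)

        i_syn = ((g_ampa + g_nmda) * (E_EXC_MV - v)
                 + g_gaba * (E_INH_MV - v))  # nS * mV = pA
        dv = (gl_ns * (el - v) + i_syn - w_ad + bias_pa) / c_pf * config.dt_ms
        active = refract <= 0
        v = np.where(active, v + dv, v)
        w_ad *= dec_w
        refract -= config.dt_ms

        fired = active & (v >= vth)
        if np.any(~np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite membrane voltage at t={step * config.dt_ms} ms; "
                f"config={config}")
        if np.any(fired):
            idx = np.flatnonzero(fired)
            v[idx] = vres[idx]
            refract[idx] = tref[idx]
            w_ad[idx] += b_adapt[idx]
            spike_ids.extend((idx + sim_offset).tolist())
            spike_times.extend([step * config.dt_ms] * idx.size)
        mt_idx = np.flatnonzero(mt_spk)
        spike_ids.extend(mt_idx.tolist())
        spike_times.extend([step * config.dt_ms] * mt_idx.size)
        last_spikes[:n_mt] = mt_spk
        last_spikes[n_mt:] = fired

    spikes = np.column_stack([np.asarray(spike_ids, dtype=float),
                              np.asarray(spike_times, dtype=float)])
    if spikes.size:
        spikes = spikes[np.argsort(spikes[:, 1], kind="stable")]
    else:
        spikes = spikes.reshape(0, 2)
    return SpikeRecord(spikes, config.duration_ms, pops)


def readout_rates(
    record: SpikeRecord, window_ms: float | None = None
) -> tuple[np.ndarray, int | None, bool]:
    """Readout firing rates (Hz), winning label and ambiguity flag."""
    if "readout" not in record.populations:
        raise ValueError("record contains no readout population")
    off, n = record.populations["readout"]
    window_ms = record.duration_ms if window_ms is None else window_ms
    counts = record.counts(off, n)
    rates = counts / (window_ms / 1000.0)
    if counts.sum() == 0:
        return rates, None, True
    top = rates.max()
    ambiguous = (rates == top).sum() > 1
    return rates, int(np.argmax(rates)), ambiguous
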