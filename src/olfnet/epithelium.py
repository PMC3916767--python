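"""Olfactory epithelium: populations of saturating ORN dose–response curves.

Each OR is expressed by one ORN family (default 800 neurons) projecting to a
single glomerulus.  An odor stimulus delivers to every ORN of the family the
odor activity value (OAV) — the fraction of activated receptors, equal to
the odorant–OR affinity.  OAV relates to a (unitless) concentration by
``c = OAV / (1 - OAV)``.

Individual ORNs differ in sensitivity (half-activation OAV) and maximum
firing rate.  The family is sorted by sensitivity and cut into contiguous
groups (default 8, one per target mitral/tufted cell); the activity-sorted
grouping is the substrate of the concentration-interval code built in
:mod:`olfnet.bulb`.  Sorting covers both the half-activation points and the
maximum rates, so a more sensitive ORN responds at least as strongly as any
less sensitive one at every OAV — the idealized outcome of
activity-dependent axon sorting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SENSITIVITY_RANGE = (0.02, 0.8)
DEFAULT_RATE_RANGE = (40.0, 80.0)  # spikes/s
DEFAULT_HILL = 4.0
#: Rheobase: fraction of receptors that must be activated before an ORN
#: fires at all (spiking onset of the underlying conductance drive).
DEFAULT_ONSET = 0.1


def oav_to_concentration(oav):
    """c = OAV / (1 - OAV); defined on [0, 1)."""
    oav = np.asarray(oav, dtype=float)
    if np.any((oav < 0) | (oav > 1)):
        raise ValueError("OAV must lie in [0, 1)")
    if np.any(oav == 1):
        raise ValueError("OAV = 1 corresponds to infinite concentration")
    c = oav / (1.0 - oav)
    return float(c) if c.ndim == 0 else c


def concentration_to_oav(c):
    """Inverse map OAV = c / (1 + c); exact round-trip."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    oav = c / (1.0 + c)
    return float(oav) if oav.ndim == 0 else oav


@dataclass(frozen=True)
class ORNFamily:
    """One OR's ORN population, sensitivity-sorted and cut into groups.

    ``sensitivity`` holds per-ORN half-activation OAVs sorted ascending
    (index 0 = most sensitive); ``max_rate`` is sorted descending and paired
    with it.  Groups are contiguous equal-size blocks.
    """

    family_id: int
    sensitivity: np.ndarray  # (n_orn,), ascending, in (0, 1)
    max_rate: np.ndarray  # (n_orn,), spikes/s
    n_groups: int = 8
    hill: float = DEFAULT_HILL
    onset: float = DEFAULT_ONSET

    def __post_init__(self):
        s = np.asarray(self.sensitivity, dtype=float)
        r = np.asarray(self.max_rate, dtype=float)
        if s.shape != r.shape or s.ndim != 1:
            raise ValueError("sensitivity/max_rate must be 1-D and same length")
        if s.size % self.n_groups:
            raise ValueError("n_orn must be divisible by n_groups")
        if np.any((s <= 0) | (s >= 1)):
            raise ValueError("sensitivities must lie in (0, 1)")
        if np.any(np.diff(s) < 0):
            raise ValueError("sensitivities must be sorted ascending")
        object.__setattr__(self, "sensitivity", s)
        object.__setattr__(self, "max_rate", r)

    @property
    def n_orn(self) -> int:
        return self.sensitivity.size

    @property
    def group_size(self) -> int:
        return self.n_orn // self.n_groups


def make_family(
    family_id: int,
    n_orn: int = 800,
    n_groups: int = 8,
    sensitivity_range=DEFAULT_SENSITIVITY_RANGE,
    rate_range=DEFAULT_RATE_RANGE,
    hill: float = DEFAULT_HILL,
    rng: np.random.Generator | None = None,
    onset: float = DEFAULT_ONSET,
) -> ORNFamily:
    """Draw one ORN family: log-uniform sensitivities, uniform max rates.

    Max rates are sorted to co-vary with sensitivity (see module docstring).
    """
    rng = rng if rng is not None else np.random.default_rng(family_id)
    lo, hi = sensitivity_range
    sens = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_orn)))
    rates = np.sort(rng.uniform(rate_range[0], rate_range[1], size=n_orn))[::-1]
    return ORNFamily(family_id, sens, rates.copy(), n_groups=n_groups, hill=hill,
                     onset=onset)


def make_families(
    n_families: int,
    seed: int = 0,
    n_orn: int = 800,
    n_groups: int = 8,
    sensitivity_range=DEFAULT_SENSITIVITY_RANGE,
    rate_range=DEFAULT_RATE_RANGE,
    hill: float = DEFAULT_HILL,
    onset: float = DEFAULT_ONSET,
) -> list[ORNFamily]:
    rng = np.random.default_rng(seed)
    return [
        make_family(j, n_orn, n_groups, sensitivity_range, rate_range, hill, rng,
                    onset)
        for j in range(n_families)
    ]


def orn_response(family: ORNFamily, oav) -> np.ndarray:
    """Per-ORN mean firing rates (spikes/s) at the given OAV(s).

    A saturating Hill curve of the supra-rheobase drive
    ``y = max(0, OAV - onset)``, rescaled so the rate is exactly r_max at
    OAV = 1: ``r = r_max * H(y) / H(1 - onset)`` with
    ``H(y) = y^h / (y^h + K^h)`` and half-activation K.  Monotone in OAV,
    zero below the onset, and for equal r_max pointwise larger for smaller
    K.  Accepts a scalar OAV (returns shape (n_orn,)) or a vector (returns
    (n_orn, len(oav))).
    """
    oav_arr = np.atleast_1d(np.asarray(oav, dtype=float))
    if np.any((oav_arr < 0) | (oav_arr > 1)):
        raise ValueError("OAV must lie in [0, 1]")
    h = family.hill
    kh = family.sensitivity[:, None] ** h
    y = np.maximum(0.0, oav_arr[None, :] - family.onset)
    yh = y**h
    top = (1.0 - family.onset) ** h
    sat = top / (top + kh)  # value of the raw Hill curve at OAV = 1
    rates = family.max_rate[:, None] * (yh / (yh + kh)) / sat
    return rates[:, 0] if np.isscalar(oav) or np.ndim(oav) == 0 else rates


def group_rates(family: ORNFamily, oav) -> np.ndarray:
    """Mean rate per sensitivity-sorted ORN group; group 0 = most sensitive."""
    rates = orn_response(family, np.atleast_1d(oav))
    g = rates.reshape(family.n_groups, family.group_size, -1).mean(axis=1)
    return g[:, 0] if np.isscalar(oav) or np.ndim(oav) == 0 else g
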