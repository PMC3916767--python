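"""Artificial odor panels and stimulus variants.

Odorant–receptor affinities are generated from a distance distribution in a
physico-chemical descriptor space: virtual olfactory receptors (ORs) are
k-means centroids of a clustered odorant cloud, the centroid–odorant
Euclidean distances are pooled over many clusterings, fitted with a
three-component normal mixture, and mapped through a decreasing
transformation onto affinities in [0, 1].  The affinity of pattern *i* at
OR *j* is interpreted downstream as the odor activity value (OAV), i.e. the
fraction of activated receptors.

All stimulus variants used by the evaluation tasks are produced here:
additive uniform noise (clipped to [0, 1]), concentration offsets on active
ORs, incomplete patterns (random silencing of active ORs) and nested
two-odor mixture series.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

#: Expected centroid–odorant distance of the pooled distribution.
EXPECTED_DISTANCE = 7.7

#: Default sharpness of the distance→affinity transformation; chosen so that
#: affinities sampled through the surrogate distance distribution cover the
#: whole range between 0 and 1 even for small sample sizes.
DEFAULT_SHARPNESS = 1.0


@dataclass(frozen=True)
class DescriptorSpace:
    """Odorants embedded in a real-valued descriptor space."""

    matrix: np.ndarray  # (n_odorants, n_dims)
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError("descriptor matrix must be 2-D with >= 2 dimensions")
        if not np.all(np.isfinite(m)):
            raise ValueError("descriptor matrix contains missing/non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def n_odorants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dims(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class TrimodalDistribution:
    """Three-component normal mixture over centroid–odorant distances."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    weights: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.sds):
            raise ValueError("all component sds must be > 0")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be >= 0")
        tot = float(sum(self.weights))
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")

    @property
    def expected_value(self) -> float:
        return float(sum(w * m for w, m in zip(self.weights, self.means)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` non-negative distances (negative draws are rejected)."""
        comp = rng.choice(3, size=n, p=np.asarray(self.weights))
        d = rng.normal(np.take(self.means, comp), np.take(self.sds, comp))
        # distances are non-negative by definition; resample the rare
        # negative draws from the truncated tails
        bad = d < 0
        while np.any(bad):
            k = int(bad.sum())
            comp_b = rng.choice(3, size=k, p=np.asarray(self.weights))
            d[bad] = rng.normal(np.take(self.means, comp_b), np.take(self.sds, comp_b))
            bad = d < 0
        return d

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w / (s * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - m) / s) ** 2)
        return out


def default_distance_distribution() -> TrimodalDistribution:
    """Surrogate pooled-distance mixture with E[D] = 7.7.

    The component parameters are surrogate values standing in for a fit to
    the real descriptor table (which is not shipped); only the expected
    value 7.7 is a constraint.
    """
    return TrimodalDistribution(
        means=(4.9, 7.7, 10.5), sds=(1.5, 1.8, 2.2), weights=(0.25, 0.5, 0.25)
    )


@dataclass
class AffinityMatrix:
    """Panel of odor patterns: rows are patterns, columns are ORs.

    Entries are affinities (= OAV) in [0, 1].  ``active`` marks the
    (pattern, OR) pairs activated at generation time; in noise-free panels
    inactive entries are exactly zero.
    """

    values: np.ndarray  # (n_patterns, n_OR)
    active: np.ndarray  # boolean, same shape
    pattern_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.values.shape != self.active.shape:
            raise ValueError("values and active mask shapes differ")
        if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > 1:
            raise ValueError("affinities must lie in [0, 1]")
        if not self.pattern_labels:
            self.pattern_labels = list(range(self.values.shape[0]))

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_or(self) -> int:
        return self.values.shape[1]

    @property
    def n_activated(self) -> np.ndarray:
        return self.active.sum(axis=1)


# ---------------------------------------------------------------------------
# descriptor space and distance distribution


def synthetic_descriptor_space(
    n_odorants: int, n_dims: int, n_latent_clusters: int, seed: int = 0
) -> DescriptorSpace:
    """Clusterable cloud of odorant points (mixture of isotropic Gaussians).

    Stands in for a real physico-chemical descriptor table; the latent
    cluster structure makes the point cloud k-means friendly.
    """
    if n_odorants < 1 or n_dims < 2 or n_latent_clusters < 1:
        raise ValueError("n_odorants >= 1, n_dims >= 2, n_latent_clusters >= 1 required")
    if n_latent_clusters > n_odorants:
        raise ValueError("more latent clusters than odorants")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 4.0, size=(n_latent_clusters, n_dims))
    assignment = rng.integers(0, n_latent_clusters, size=n_odorants)
    pts = centers[assignment] + rng.normal(0.0, 1.0, size=(n_odorants, n_dims))
    return DescriptorSpace(pts)


def fit_trimodal(samples: np.ndarray, seed: int = 0) -> TrimodalDistribution:
    """Fit a 3-component univariate normal mixture, components sorted by mean."""
    samples = np.asarray(samples, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=3, covariance_type="full", random_state=seed,
                         n_init=3).fit(samples)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    weights = weights[order] / weights.sum()
    return TrimodalDistribution(
        means=tuple(means[order]), sds=tuple(sds[order]), weights=tuple(weights)
    )


def pooled_centroid_distances(
    space: DescriptorSpace,
    n_centroids_range,
    n_trials: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """All centroid–odorant Euclidean distances pooled over k-means runs.

    Returns (distances, weights); each trial's distances are weighted by
    1/n_centroids so every trial contributes equally per odorant.
    """
    rng = np.random.default_rng(seed)
    dists, wts = [], []
    for n_c in n_centroids_range:
        if n_c >= space.n_odorants:
            raise ValueError("centroid count must be < n_odorants")
        for _ in range(n_trials):
            km_seed = int(rng.integers(0, 2**31 - 1))
            try:
                km = KMeans(n_clusters=n_c, n_init=1, random_state=km_seed).fit(
                    space.matrix
                )
            except Exception as exc:  # convergence/placement failure: skip trial
                logger.warning("k-means with %d centroids failed (%s); trial skipped",
                               n_c, exc)
                continue
            _, counts = np.unique(km.labels_, return_counts=True)
            if counts.size < n_c:
                logger.warning("k-means left empty centroids at n=%d; trial skipped", n_c)
                continue
            d = np.linalg.norm(
                space.matrix[:, None, :] - km.cluster_centers_[None, :, :], axis=2
            ).ravel()
            dists.append(d)
            wts.append(np.full(d.size, 1.0 / n_c))
    if not dists:
        raise RuntimeError("no successful k-means trial")
    return np.concatenate(dists), np.concatenate(wts)


def fit_distance_distribution(
    space: DescriptorSpace,
    n_centroids_range=range(20, 67),
    n_trials: int = 100,
    seed: int = 0,
    max_pooled: int = 50_000,
) -> TrimodalDistribution:
    """Pool centroid–odorant distances over k-means runs and fit a trimodal mixture.

    Per centroid count a 3-component mixture is fitted to a weighted
    bootstrap of that count's pooled distances; the fitted parameters are
    then averaged (components aligned by mean rank) over the range.
    """
    rng = np.random.default_rng(seed)
    fits = []
    for n_c in n_centroids_range:
        try:
            d, w = pooled_centroid_distances(space, [n_c], n_trials, seed=int(rng.integers(2**31 - 1)))
        except RuntimeError:
            continue
        take = min(max_pooled, d.size)
        idx = rng.choice(d.size, size=take, p=w / w.sum())
        fits.append(fit_trimodal(d[idx], seed=int(rng.integers(2**31 - 1))))
    if not fits:
        raise RuntimeError("distance-distribution fit failed for every centroid count")
    means = np.mean([f.means for f in fits], axis=0)
    sds = np.mean([f.sds for f in fits], axis=0)
    weights = np.mean([f.weights for f in fits], axis=0)
    weights = weights / weights.sum()
    return TrimodalDistribution(tuple(means), tuple(sds), tuple(weights))


# ---------------------------------------------------------------------------
# affinities and panels


def distance_to_affinity(
    d, dist: TrimodalDistribution | None = None, sharpness: float = DEFAULT_SHARPNESS
):
    """Map a centroid–odorant distance to an affinity in (0, 1].

    ``exp(-sharpness * (d / E[D])**2)``: strictly decreasing, 1 at d = 0,
    scaled by the expected distance of the pooled distribution.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    e = dist.expected_value if dist is not None else EXPECTED_DISTANCE
    out = np.exp(-sharpness * (d / e) ** 2)
    return float(out) if out.ndim == 0 else out


def generate_pattern_set(
    n_patterns: int,
    n_or: int,
    dist: TrimodalDistribution | None = None,
    activation_range: tuple[float, float] = (0.3, 0.5),
    seed: int = 0,
    sharpness: float = DEFAULT_SHARPNESS,
) -> AffinityMatrix:
    """Random odor panel: per pattern, 30–50% of ORs activated by default.

    The number of activated ORs is drawn uniformly from the integer range
    spanned by ``activation_range``; each active (pattern, OR) pair gets an
    affinity sampled through the distance distribution.
    """
    if n_or < 2:
        raise ValueError("need at least 2 ORs")
    dist = dist or default_distance_distribution()
    lo = math.ceil(activation_range[0] * n_or)
    hi = math.floor(activation_range[1] * n_or)
    if hi < lo or lo < 1:
        raise ValueError(f"empty activation range {activation_range} for n_or={n_or}")
    rng = np.random.default_rng(seed)
    values = np.zeros((n_patterns, n_or))
    active = np.zeros((n_patterns, n_or), dtype=bool)
    for k in range(n_patterns):
        n_act = int(rng.integers(lo, hi + 1))
        ors = rng.choice(n_or, size=n_act, replace=False)
        d = dist.sample(n_act, rng)
        values[k, ors] = distance_to_affinity(d, dist, sharpness)
        active[k, ors] = True
    return AffinityMatrix(values, active)


def apply_noise(panel: AffinityMatrix, sigma: float, seed: int = 0) -> AffinityMatrix:
    """Additive uniform(-sigma, sigma) noise on every entry, clipped to [0, 1].

    Zero entries may become non-zero (unrelated background odors); active
    entries may be suppressed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = panel.values + rng.uniform(-sigma, sigma, size=panel.values.shape)
    np.clip(noisy, 0.0, 1.0, out=noisy)
    return AffinityMatrix(noisy, noisy > 0, list(panel.pattern_labels))


def concentration_variants(
    panel: AffinityMatrix, pattern_ids, offsets
) -> AffinityMatrix:
    """Concentration series: add each offset to the *active* ORs of each pattern.

    Returns the expanded panel; ``pattern_labels`` carries (pattern, offset)
    tuples.
    """
    offsets = [float(o) for o in offsets]
    if not all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    rows, masks, labels = [], [], []
    for pid in pattern_ids:
        if pid < 0 or pid >= panel.n_patterns:
            raise ValueError(f"unknown pattern id {pid}")
        for off in offsets:
            row = panel.values[pid].copy()
            mask = panel.active[pid]
            row[mask] = np.clip(row[mask] + off, 0.0, 1.0)
            rows.append(row)
            masks.append(mask.copy())
            labels.append((pid, off))
    return AffinityMatrix(np.array(rows), np.array(masks), labels)


def make_incomplete(
    panel: AffinityMatrix, pattern_id: int, completeness: float, seed: int = 0
) -> np.ndarray:
    """Silence a random subset of a pattern's active ORs.

    ``ceil(completeness * n_activated)`` active ORs are retained.
    """
    if not (0 < completeness <= 1):
        raise ValueError("completeness must be in (0, 1]")
    act = np.flatnonzero(panel.active[pattern_id])
    if act.size == 0:
        raise ValueError(f"pattern {pattern_id} has no active OR")
    rng = np.random.default_rng(seed)
    keep = math.ceil(completeness * act.size)
    kept = rng.choice(act, size=keep, replace=False)
    row = np.zeros(panel.n_or)
    row[kept] = panel.values[pattern_id, kept]
    return row


def make_mixture_series(
    panel: AffinityMatrix,
    id_b: int,
    id_r: int,
    fractions=(0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2),
    seed: int = 0,
) -> np.ndarray:
    """Nested mixture morph between two patterns B and R.

    For B-fraction ``b`` the mixture takes ``round(b * |active(B)|)`` ORs of
    B and ``round((1 - b) * |active(R)|)`` ORs of R, with their original
    affinities.  The OR subsets are nested along the fraction grid (a fixed
    random order per parent), so consecutive mixtures differ by swapping a
    few components.  An OR contributed by both parents takes the value of
    the parent with the larger fraction (ties go to B).
    """
    if id_b == id_r:
        raise ValueError("mixture parents must differ")
    fractions = [float(b) for b in fractions]
    if any(b2 > b1 for b1, b2 in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be non-increasing for parent B")
    rng = np.random.default_rng(seed)
    act_b = rng.permutation(np.flatnonzero(panel.active[id_b]))
    act_r = rng.permutation(np.flatnonzero(panel.active[id_r]))
    rows = np.zeros((len(fractions), panel.n_or))
    for t, b in enumerate(fractions):
        r = 1.0 - b
        take_b = act_b[: round(b * act_b.size)]
        take_r = act_r[: round(r * act_r.size)]
        row = rows[t]
        if b >= r:  # R first, B overwrites shared ORs
            row[take_r] = panel.values[id_r, take_r]
            row[take_b] = panel.values[id_b, take_b]
        else:
            row[take_b] = panel.values[id_b, take_b]
            row[take_r] = panel.values[id_r, take_r]
    return rows


# ---------------------------------------------------------------------------
# I/O


def save_panel(panel: AffinityMatrix, path, metadata: dict | None = None) -> None:
    """Write a panel as CSV (columns ``OR_000``…) plus a JSON sidecar."""
    path = Path(path)
    cols = [f"OR_{j:03d}" for j in range(panel.n_or)]
    pd.DataFrame(panel.values, columns=cols).to_csv(path, index=False)
    side = dict(metadata or {})
    side["pattern_labels"] = [list(l) if isinstance(l, tuple) else l
                              for l in panel.pattern_labels]
    side["active"] = panel.active.astype(int).tolist()
    path.with_suffix(".json").write_text(json.dumps(side))


def load_panel(path) -> AffinityMatrix:
    path = Path(path)
    values = pd.read_csv(path).to_numpy(dtype=float)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        active = np.asarray(meta["active"], dtype=bool)
        labels = [tuple(l) if isinstance(l, list) else l
                  for l in meta.get("pattern_labels", [])]
    else:
        active, labels = values > 0, []
    return AffinityMatrix(values, active, labels)


def load_descriptor_table(path) -> DescriptorSpace:
    """Read an odorants × descriptors delimited table (first column = label)."""
    df = pd.read_csv(path)
    labels = tuple(str(x) for x in df.iloc[:, 0])
    return DescriptorSpace(df.iloc[:, 1:].to_numpy(dtype=float), labels)
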