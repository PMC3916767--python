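"""Self-organization of the bulb→cortex projection and BCPNN learning.

The pipeline implemented here turns a matrix of MT spike counts into an
abstract cortical wiring diagram:

1. per-cell normalization of counts over the training patterns (f → f'),
2. glomerulus-wise half-normalization (f' → ξ), giving a probabilistic
   reading of MT activity,
3. activation and joint-activation probabilities from ξ,
4. a mutual-information distance ``D = 1 - I/E`` between MT cells,
5. a 3-D metric MDS embedding of D,
6. a first vector quantization assigning each MT cell to its m nearest
   hypercolumn (HC) centroids,
7. a second, per-HC vector quantization distributing the training patterns
   over minicolumns (MCs), yielding the binary pattern→MC matrix ζ,
8. Hebbian–Bayesian (BCPNN) weights ``w = log p_ij/(p_i p_j)`` and biases
   ``β = log p_j`` (natural log), with the stated zero/low-probability
   guard cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import smacof


@dataclass
class MIStats:
    """Pairwise activation statistics between units."""

    p: np.ndarray  # (n,)
    p_joint: np.ndarray  # (n, n)
    mutual_information: np.ndarray  # I, nats
    joint_entropy: np.ndarray  # E, nats
    distance: np.ndarray  # D in [0, 1]


@dataclass
class ProjectionMap:
    """Result of the two vector quantizations.

    ``hc_of_mt[i]`` lists the HCs MT cell *i* projects to (empty for silent
    cells); ``mt_of_hc[h]`` the source MT cells of HC *h*; ``zeta`` is the
    binary patterns × (N_HC * N_MC) pattern→MC activation matrix and
    ``hc_of_mc`` the HC id of each MC column.
    """

    coords: np.ndarray  # (n_mt, 3) MDS embedding
    hc_of_mt: list  # list of int arrays
    mt_of_hc: list  # list of int arrays
    zeta: np.ndarray  # (n_patterns, n_hc * n_mc), binary
    n_hc: int
    n_mc: int
    m: int

    @property
    def hc_of_mc(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_hc), self.n_mc)


@dataclass
class BCPNNNet:
    """Abstract BCPNN stage: log-odds weights and log-probability biases."""

    w: np.ndarray  # (n_pre, n_post), nats
    beta: np.ndarray  # (n_post,), nats
    n_patterns: int


# ---------------------------------------------------------------------------
# normalizations and probabilities


def normalize_responses(f: np.ndarray) -> np.ndarray:
    """Divide each cell's counts by its summed count over all patterns.

    Cells silent in every pattern map to all-zero rows.
    """
    f = np.asarray(f, dtype=float)
    if f.min(initial=0.0) < 0:
        raise ValueError("counts must be non-negative")
    tot = f.sum(axis=1, keepdims=True)
    return np.divide(f, tot, out=np.zeros_like(f), where=tot > 0)


def half_normalize(values: np.ndarray, group_index: np.ndarray) -> np.ndarray:
    """Divisively rescale each group to sum 1 wherever its sum exceeds 1.

    ``values`` is (n_units,) or (n_units, n_patterns); ``group_index`` maps
    each unit to its group (glomerulus or hypercolumn).  Groups whose sum is
    already <= 1 are left untouched, preserving the probabilistic reading.
    """
    v = np.asarray(values, dtype=float)
    if v.min(initial=0.0) < 0:
        raise ValueError("values must be non-negative")
    one_d = v.ndim == 1
    v = v[:, None] if one_d else v.copy()
    group_index = np.asarray(group_index)
    n_groups = int(group_index.max()) + 1
    sums = np.zeros((n_groups, v.shape[1]))
    np.add.at(sums, group_index, v)
    scale = np.where(sums > 1.0, sums, 1.0)
    v = v / scale[group_index]
    return v[:, 0] if one_d else v


def activation_probabilities(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """p_i = mean_k ξ_i^k and p_ij = mean_k ξ_i^k ξ_j^k."""
    xi = np.asarray(xi, dtype=float)
    if xi.min(initial=0.0) < 0 or xi.max(initial=0.0) > 1:
        raise ValueError("activations must lie in [0, 1]")
    n_p = xi.shape[1]
    return xi.mean(axis=1), (xi @ xi.T) / n_p


def joint_probabilities(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """p_ij = mean_k pre_i^k post_j^k between two populations."""
    if pre.shape[1] != post.shape[1]:
        raise ValueError("pattern counts differ")
    return (pre @ post.T) / pre.shape[1]


def mi_distance(p: np.ndarray, p_joint: np.ndarray) -> MIStats:
    """Mutual-information distance D = 1 - I/E between unit pairs.

    ``I_ij = p_ij log(p_ij / (p_i p_j))`` (0 when p_i p_j = 0 or p_ij = 0),
    ``E_ij = -p_ij log p_ij`` (0 when p_ij = 0), and ``D = 1 - I/E`` with
    D = 1 when E = 0.  Self-distances are forced to 0 for units with p > 0
    so D can serve as a dissimilarity.  Natural logarithms.
    """
    p = np.asarray(p, dtype=float)
    pj = np.asarray(p_joint, dtype=float)
    pp = np.outer(p, p)
    valid = (pp > 0) & (pj > 0)
    i_mat = np.zeros_like(pj)
    i_mat[valid] = pj[valid] * np.log(pj[valid] / pp[valid])
    e_mat = np.zeros_like(pj)
    nz = pj > 0
    e_mat[nz] = -pj[nz] * np.log(pj[nz])
    d = np.ones_like(pj)
    enz = e_mat != 0
    d[enz] = 1.0 - i_mat[enz] / e_mat[enz]
    np.clip(d, 0.0, 1.0, out=d)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, np.where(p > 0, 0.0, 1.0))
    return MIStats(p, pj, i_mat, e_mat, d)


# ---------------------------------------------------------------------------
# embedding and vector quantization


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering solution, used to seed SMACOF."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]


def embed_mds(d: np.ndarray, dims: int = 3, seed: int = 0) -> np.ndarray:
    """Metric MDS (SMACOF stress minimization) of a distance matrix.

    Initialized from the classical-scaling solution, which makes the result
    deterministic and drives stress to ~0 for exactly embeddable inputs.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    init = _classical_mds(d, dims)
    coords, _ = smacof(
        d, n_components=dims, init=init, n_init=1, max_iter=500, eps=1e-12,
        random_state=seed, normalized_stress=False)
    return coords


def vq_mt_to_hc(
    coords: np.ndarray,
    n_hc: int,
    m: int = 4,
    silent_mask: np.ndarray | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    retry_budget: int = 100,
) -> tuple[list, list, np.ndarray]:
    """First VQ: k-means over MT embeddings; each MT joins its m nearest HCs.

    Silent MT cells are excluded from clustering and get no assignment.
    The clustering is retried with fresh seeds until no HC is empty.
    Returns (hc_of_mt, mt_of_hc, centroids).
    """
    coords = np.asarray(coords, dtype=float)
    n_mt = coords.shape[0]
    silent = (np.zeros(n_mt, dtype=bool) if silent_mask is None
              else np.asarray(silent_mask, dtype=bool))
    live = np.flatnonzero(~silent)
    if n_hc > live.size:
        raise ValueError("more hypercolumns than non-silent MT cells")
    rng = np.random.default_rng(seed)
    centroids = None
    for _ in range(retry_budget):
        km = KMeans(n_clusters=n_hc, n_init=n_restarts,
                    random_state=int(rng.integers(2**31 - 1))).fit(coords[live])
        if np.unique(km.labels_).size == n_hc:
            centroids = km.cluster_centers_
            break
    if centroids is None:
        raise RuntimeError(
            f"could not place {n_hc} non-empty HC centroids in {retry_budget} tries")
    m_eff = min(m, n_hc)
    dist = np.linalg.norm(coords[live][:, None, :] - centroids[None], axis=2)
    nearest = np.argsort(dist, axis=1)[:, :m_eff]
    hc_of_mt = [np.empty(0, dtype=int) for _ in range(n_mt)]
    for row, i in enumerate(live):
        hc_of_mt[i] = np.sort(nearest[row])
    mt_of_hc = [np.flatnonzero([h in hc_of_mt[i] for i in range(n_mt)])
                for h in range(n_hc)]
    return hc_of_mt, mt_of_hc, centroids


def vq_patterns_to_mc(
    xi: np.ndarray,
    mt_of_hc: list,
    n_mc: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """Second VQ: per HC, cluster the patterns in that HC's MT-response space.

    Each pattern is a vector whose dimensions are the HC's source MT cells
    with magnitudes ξ; its cluster marks one MC active for that pattern.
    When fewer distinct pattern vectors than MCs exist, surplus MC columns
    stay unused (all-zero).  Returns the binary ζ matrix,
    (n_patterns, n_hc * n_mc).
    """
    xi = np.asarray(xi, dtype=float)
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    n_p = xi.shape[1]
    n_hc = len(mt_of_hc)
    rng = np.random.default_rng(seed)
    zeta = np.zeros((n_p, n_hc * n_mc))
    for h, sources in enumerate(mt_of_hc):
        x = xi[np.asarray(sources, dtype=int)].T  # (n_p, n_sources)
        n_distinct = np.unique(x, axis=0).shape[0]
        k = min(n_mc, n_distinct)
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(2**31 - 1))).fit(x)
        zeta[np.arange(n_p), h * n_mc + km.labels_] = 1.0
    return zeta


# ---------------------------------------------------------------------------
# BCPNN weights and biases


def bcpnn_weights(
    p_pre: np.ndarray, p_post: np.ndarray, p_joint: np.ndarray, n_patterns: int
) -> np.ndarray:
    """Hebbian–Bayesian log-odds weights, elementwise over pre × post.

    ``w = log(p_ij / (p_i p_j))`` when both marginals are non-zero;
    ``log(1/N_p)`` when they are non-zero but the joint is zero (a strong
    learned anti-correlation); 0 when either unit never activates.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    p_pre = np.asarray(p_pre, dtype=float)
    p_post = np.asarray(p_post, dtype=float)
    p_joint = np.asarray(p_joint, dtype=float)
    pp = np.outer(p_pre, p_post)
    w = np.zeros_like(p_joint)
    both = pp > 0
    never = both & (p_joint == 0)
    w[never] = np.log(1.0 / n_patterns)
    pos = both & (p_joint > 0)
    w[pos] = np.log(p_joint[pos] / pp[pos])
    return w


def bcpnn_bias(p_post: np.ndarray, n_patterns: int) -> np.ndarray:
    """β = log p for active units, log(1/N_p²) for never-active ones."""
    p = np.atleast_1d(np.asarray(p_post, dtype=float))
    beta = np.full(p.shape, np.log(1.0 / n_patterns**2))
    beta[p > 0] = np.log(p[p > 0])
    return beta if np.ndim(p_post) else float(beta[0])
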