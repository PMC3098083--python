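"""Pairwise chaotic map clustering (CMC).

Each item carries a chaotic logistic map x_i in [-1, 1].  Maps are
coupled through the pairwise distances D_ij of the items,

    J_ij = exp(-D_ij^2 / (2 a^2)),

where the local length scale ``a`` is the average distance to the K
nearest neighbours, and the lattice evolves synchronously as

    x_i(t+1) = (1/C_i) * sum_{j != i} J_ij f(x_j(t)),   f(x) = 1 - 2 x^2,

with C_i = sum_{j != i} J_ij.  Strongly coupled maps synchronize; the
degree of synchronization between two maps is measured by the mutual
information I_ij of their sign bit sequences (S_i = 1 iff x_i >= 0),
which ranges from 0 (independent) to ln 2 (exactly synchronized).
Thresholding I_ij > theta and taking connected components yields a
partition at each resolution theta in [0, ln 2]; sweeping theta yields
a hierarchy, and the partition repeated over the longest (and, on ties,
first) run of consecutive theta bins — the flattest plateau of the
cluster entropy S(theta) — is selected as the clustering solution.

The method is non-parametric: the number of clusters is never supplied.
Only the neighbourhood size K and, optionally, a fixed threshold are
chosen by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .matrices import LabeledSquareMatrix

__all__ = [
    "LN2",
    "CMCParams",
    "CouplingMatrix",
    "BitSequences",
    "MIMatrix",
    "CMCResult",
    "PRESETS",
    "compute_couplings",
    "evolve_maps",
    "mutual_information",
    "partition_at",
    "cluster_entropy",
    "sweep_hierarchy",
    "select_plateau",
    "cmc_cluster",
]

LN2 = math.log(2.0)

#: (K, theta) presets for the analyses this toolkit was built around:
#: whole-structure electrostatics, binding-subsite electrostatics /
#: sequences, and ligand-shape matrices.
PRESETS: dict[str, dict[str, float]] = {
    "whole-structure": {"K": 16, "theta": 0.06},
    "subsite": {"K": 10, "theta": 0.08},
    "ligand": {"K": 2, "theta": 0.08},
}

Partition = list[frozenset]


@dataclass(frozen=True)
class CMCParams:
    """Run parameters for the chaotic-map dynamics and the theta sweep.

    K
        neighbourhood size for the coupling graph and the local scale.
    n_iter, transient
        total synchronous updates and the initial burn-in discarded
        before bits are recorded; n_iter - transient bits per map.
    theta_bin
        bin width of the mutual-information threshold sweep over
        [0, ln 2].
    theta_override
        if set, skip plateau selection and cut the MI graph at this
        fixed threshold (the sweep is still computed for diagnostics).
    sparsify
        restrict couplings to the symmetrized K-nearest-neighbour graph
        instead of the (default) dense Gaussian couplings; see
        :func:`compute_couplings`.
    """

    K: int
    n_iter: int = 10000
    transient: int = 1000
    theta_bin: float = 0.01
    seed: int = 0
    theta_override: float | None = None
    sparsify: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.theta_bin < LN2):
            raise ValueError("theta_bin must lie in (0, ln 2)")
        if not (0 <= self.transient < self.n_iter):
            raise ValueError("need 0 <= transient < n_iter")
        if self.theta_override is not None and not (
            0 <= self.theta_override <= LN2
        ):
            raise ValueError("theta_override must lie in [0, ln 2]")


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric non-negative couplings J, local scale a, normalizers C."""

    labels: tuple[str, ...]
    J: np.ndarray = field(repr=False)
    a: float = 0.0

    @property
    def C(self) -> np.ndarray:
        return self.J.sum(axis=1)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BitSequences:
    """Post-transient sign bits of every map; shape (N, n_recorded)."""

    labels: tuple[str, ...]
    bits: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class MIMatrix:
    """Pairwise mutual information (nats); diagonal holds each map's entropy."""

    labels: tuple[str, ...]
    I: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CMCResult:
    mi: MIMatrix
    hierarchy: list[tuple[float, Partition, float]]
    selected_theta: float
    selected_partition: Partition
    coupling: CouplingMatrix

    def assignments(self) -> dict[str, int]:
        """label -> cluster id, clusters numbered by first appearance in label order."""
        order: dict[str, int] = {}
        label_pos = {l: k for k, l in enumerate(self.mi.labels)}
        clusters = sorted(
            self.selected_partition, key=lambda c: min(label_pos[l] for l in c)
        )
        for cid, cluster in enumerate(clusters):
            for label in cluster:
                order[label] = cid
        return {l: order[l] for l in self.mi.labels}


def compute_couplings(
    D: LabeledSquareMatrix, K: int, sparsify: bool = False
) -> CouplingMatrix:
    """Gaussian couplings J_ij = exp(-D_ij^2 / 2a^2) from a distance matrix.

    The local scale ``a`` is the mean, over items, of the mean distance
    from each item to its K nearest neighbours (self excluded).  By
    default every pair is coupled — the exponential decay already makes
    couplings short-ranged on the scale a, and fully coupled groups
    synchronize far more reliably than sparsely coupled ones.  With
    ``sparsify`` the couplings are additionally restricted to the
    symmetrized K-nearest-neighbour graph (a pair is kept when either
    member is among the other's K nearest neighbours); K = N-1 makes
    the two variants coincide.
    """
    if D.kind != "distance":
        raise ValueError("compute_couplings expects a distance matrix")
    n = D.n
    if not (1 <= K <= n - 1):
        raise ValueError(f"K must lie in [1, N-1] = [1, {n - 1}], got {K}")
    dist = D.values
    # self excluded via +inf on the diagonal; argsort is stable so ties
    # resolve to the lower index, deterministically
    masked = dist + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    order = np.argsort(masked, axis=1, kind="stable")[:, :K]
    knn_dists = np.take_along_axis(masked, order, axis=1)
    a = float(knn_dists.mean())
    if a == 0.0:
        raise ValueError("all K-nearest-neighbour distances are zero; scale a undefined")
    if sparsify:
        adj = np.zeros((n, n), dtype=bool)
        rows = np.repeat(np.arange(n), K)
        adj[rows, order.ravel()] = True
        adj |= adj.T
    else:
        adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    J = np.where(adj, np.exp(-(dist ** 2) / (2.0 * a * a)), 0.0)
    return CouplingMatrix(D.labels, J, a)


def evolve_maps(
    coupling: CouplingMatrix, params: CMCParams, return_states: bool = False
):
    """Iterate the coupled logistic lattice and record post-transient sign bits.

    Initial states are drawn uniformly from [-1, 1] with the run's seed.
    Isolated items (C_i = 0) evolve autonomously as x <- f(x); since f
    maps [-1, 1] into itself and each coupled update is a convex
    combination of f values, every state stays in [-1, 1].

    With ``return_states`` the post-transient trajectories are returned
    alongside the bits (shape (N, n_iter - transient)), for diagnostics.
    """
    n = coupling.n
    rng = np.random.default_rng(params.seed)
    x = rng.uniform(-1.0, 1.0, size=n)
    J = coupling.J
    C = coupling.C
    isolated = C == 0.0
    C_safe = np.where(isolated, 1.0, C)
    n_rec = params.n_iter - params.transient
    bits = np.empty((n, n_rec), dtype=np.uint8)
    states = np.empty((n, n_rec)) if return_states else None
    for t in range(params.n_iter):
        fx = 1.0 - 2.0 * x * x
        x = np.where(isolated, fx, (J @ fx) / C_safe)
        if t >= params.transient:
            bits[:, t - params.transient] = x >= 0.0
            if states is not None:
                states[:, t - params.transient] = x
    seqs = BitSequences(coupling.labels, bits)
    if return_states:
        return seqs, states
    return seqs


def _entropy_terms(p: np.ndarray) -> np.ndarray:
    """-p ln p with the 0 ln 0 := 0 convention, elementwise."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = -p[pos] * np.log(p[pos])
    return out


def mutual_information(seqs: BitSequences) -> MIMatrix:
    """I_ij = H_i + H_j - H_ij from empirical bit-state frequencies.

    Probabilities are fractions of occurrence along the recorded
    sequences; entropies are in nats.  I is clipped to [0, ln 2] against
    round-off, and the diagonal carries H_i (the self-information).
    """
    bits = seqs.bits
    n, T = bits.shape
    if T < 1:
        raise ValueError("bit sequences must be non-empty")
    B = bits.astype(np.float64)
    p1 = B.mean(axis=1)
    H = _entropy_terms(p1) + _entropy_terms(1.0 - p1)
    n11 = B @ B.T
    n10 = B.sum(axis=1)[:, None] - n11
    n01 = n10.T
    n00 = T - n11 - n10 - n01
    Hij = sum(_entropy_terms(c / T) for c in (n00, n01, n10, n11))
    I = H[:, None] + H[None, :] - Hij
    I = np.clip(I, 0.0, LN2)
    I = (I + I.T) / 2.0
    np.fill_diagonal(I, H)
    return MIMatrix(seqs.labels, I, H)


def partition_at(mi: MIMatrix, theta: float) -> Partition:
    """Connected components of the graph with an edge wherever I_ij > theta.

    The link condition is strict, so at theta = ln 2 every item is a
    singleton.  Clusters are returned ordered by their first label.
    """
    if not (0 <= theta <= LN2):
        raise ValueError("theta must lie in [0, ln 2]")
    n = mi.n
    adj = mi.I > theta
    np.fill_diagonal(adj, False)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, set] = {}
    for idx, c in enumerate(comp):
        clusters.setdefault(int(c), set()).add(mi.labels[idx])
    label_pos = {l: k for k, l in enumerate(mi.labels)}
    return sorted(
        (frozenset(c) for c in clusters.values()),
        key=lambda c: min(label_pos[l] for l in c),
    )


def cluster_entropy(partition: Partition, n_items: int) -> float:
    """Shannon entropy of cluster-size fractions, S = -sum (N_i/N) ln (N_i/N).

    0 when everything is one cluster, ln N when all items are singletons.
    """
    if not partition:
        raise ValueError("partition is empty")
    sizes = np.array([len(c) for c in partition], dtype=float)
    if int(sizes.sum()) != n_items:
        raise ValueError(
            f"partition covers {int(sizes.sum())} items, expected {n_items}"
        )
    return float(_entropy_terms(sizes / n_items).sum())


def sweep_hierarchy(
    mi: MIMatrix, theta_bin: float = 0.01
) -> list[tuple[float, Partition, float]]:
    """Partitions and cluster entropies at theta = 0, bin, 2*bin, ... <= ln 2.

    Raising theta only removes edges, so successive partitions refine
    each other and the entropy curve is non-decreasing.
    """
    if not (0 < theta_bin < LN2):
        raise ValueError("theta_bin must lie in (0, ln 2)")
    n_bins = int(math.floor(LN2 / theta_bin + 1e-12))
    thetas = [k * theta_bin for k in range(n_bins + 1)]
    out = []
    for theta in thetas:
        part = partition_at(mi, theta)
        out.append((theta, part, cluster_entropy(part, mi.n)))
    return out


def _partition_key(partition: Partition) -> frozenset:
    return frozenset(partition)


def select_plateau(
    hierarchy: list[tuple[float, Partition, float]]
) -> tuple[float, Partition]:
    """The partition held over the longest run of consecutive theta bins.

    Identical partitions across bins mean an exactly flat cluster-entropy
    plateau; among runs of maximal length the one at lowest theta (the
    first plateau) wins, and the run's midpoint theta is reported.
    """
    if not hierarchy:
        raise ValueError("hierarchy is empty")
    runs: list[tuple[int, int]] = []  # (start, length) indices into hierarchy
    start = 0
    key = _partition_key(hierarchy[0][1])
    for i in range(1, len(hierarchy)):
        k = _partition_key(hierarchy[i][1])
        if k != key:
            runs.append((start, i - start))
            start, key = i, k
    runs.append((start, len(hierarchy) - start))
    best_start, best_len = max(runs, key=lambda r: (r[1], -r[0]))
    theta_mid = 0.5 * (
        hierarchy[best_start][0] + hierarchy[best_start + best_len - 1][0]
    )
    return theta_mid, hierarchy[best_start][1]


def cmc_cluster(D: LabeledSquareMatrix, params: CMCParams) -> CMCResult:
    """End-to-end pairwise CMC: couplings -> dynamics -> MI -> sweep -> plateau.

    Bit-for-bit reproducible for a given (matrix, params, seed).  With
    ``theta_override`` set, the partition is read at that threshold
    instead of at the selected plateau.
    """
    if D.n < 2:
        raise ValueError("need at least two items to cluster")
    coupling = compute_couplings(D, params.K, params.sparsify)
    bits = evolve_maps(coupling, params)
    mi = mutual_information(bits)
    hierarchy = sweep_hierarchy(mi, params.theta_bin)
    if params.theta_override is not None:
        theta = float(params.theta_override)
        partition = partition_at(mi, theta)
    else:
        theta, partition = select_plateau(hierarchy)
    return CMCResult(mi, hierarchy, theta, partition, coupling)
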