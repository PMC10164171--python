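"""Cluster-based permutation testing over channel x time, voxel, or
time x time domains.

Element statistics are paired t values (condition contrasts) or signed
Wilcoxon rank sums (decoding accuracy against chance).  Supra-threshold
elements of equal sign are merged into clusters over a spatial adjacency
graph combined with temporal contiguity; the cluster statistic is the sum
of its element statistics.  Family-wise significance comes from the
permutation distribution of the maximal same-sign cluster statistic under
subject-level sign flips (the exchangeability unit of a paired design),
with the two-tailed convention of separate positive/negative searches and
doubling of the one-sided Monte-Carlo p (floor 2/(n_permutations + 1)).

Sensor-level clusters must additionally contain a minimum number of
distinct pairs of adjacent channels that are simultaneously
supra-threshold ("at least two pairs of neighboring electrodes").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse, stats
from scipy.spatial import Delaunay

from .containers import Cluster, ClusterReport

# ---------------------------------------------------------------------------
# adjacency builders
# ---------------------------------------------------------------------------


def channel_adjacency(
    positions: np.ndarray, max_distance_factor: float = 1.8
) -> sparse.csr_matrix:
    """Neighbor structure of a sensor montage.

    Delaunay triangulation of the azimuthal-equidistant projection of the
    (spherical) montage, with edges longer than ``max_distance_factor`` x
    the median edge length removed.  Symmetric, no self-neighbors.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    r = np.linalg.norm(pos, axis=1)
    theta = np.arccos(np.clip(pos[:, 2] / np.maximum(r, 1e-12), -1, 1))
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    plane = np.stack([theta * np.cos(phi), theta * np.sin(phi)], axis=1)
    tri = Delaunay(plane)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)
    keep = lengths <= max_distance_factor * np.median(lengths)
    edges = edges[keep]
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix(
        (np.ones(len(rows), bool), (rows, cols)), shape=(n, n)
    )
    adj.setdiag(False)
    adj.eliminate_zeros()
    return adj


def grid_adjacency(coords: np.ndarray, spacing: float) -> sparse.csr_matrix:
    """6-connectivity on a regular voxel lattice."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    key = np.round(coords / spacing).astype(int)
    index = {tuple(k): i for i, k in enumerate(key)}
    rows, cols = [], []
    offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for i, k in enumerate(key):
        for off in offsets:
            j = index.get((k[0] + off[0], k[1] + off[1], k[2] + off[2]))
            if j is not None:
                rows += [i, j]
                cols += [j, i]
    adj = sparse.csr_matrix((np.ones(len(rows), bool), (rows, cols)), shape=(n, n))
    adj.setdiag(False)
    adj.eliminate_zeros()
    return adj


def lattice_2d_adjacency(n: int) -> sparse.csr_matrix:
    """4-connectivity on an n x n grid (train-time x test-time domain),
    expressed as 'locations' = rows with temporal contiguity across columns
    handled by the cluster domain; here rows are locations."""
    rows, cols = [], []
    for i in range(n - 1):
        rows += [i, i + 1]
        cols += [i + 1, i]
    return sparse.csr_matrix((np.ones(len(rows), bool), (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# element statistics
# ---------------------------------------------------------------------------


def element_stats_paired_t(data_a: np.ndarray, data_b: np.ndarray):
    """Per-element paired t and two-sided p; inputs (n_subjects, ...)."""
    d = np.asarray(data_a, float) - np.asarray(data_b, float)
    return _paired_t_from_diffs(d.reshape(d.shape[0], -1))


def _paired_t_from_diffs(d: np.ndarray):
    n = d.shape[0]
    if n < 2:
        raise ValueError("paired t needs >= 2 subjects")
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    # zero-variance, non-zero mean: infinite t handled as maximal statistic
    with np.errstate(invalid="ignore"):
        t = np.where((sd == 0) & (m != 0), np.sign(m) * np.inf, t)
    t = np.where((sd == 0) & (m == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2 * stats.t.sf(np.abs(np.nan_to_num(t)), n - 1))
    p = np.where(t == 0, 1.0, p)
    return t, p


def signed_rank_arrays(d: np.ndarray):
    """Signed ranks and tie-corrected sd of the signed rank sum.

    ``d`` is (n_subjects, n_elements).  Zeros keep rank weight but
    contribute sign 0 (Pratt handling keeps the permutation scheme simple
    and vectorizable).  Returns (signed_ranks, sigma_T) where
    T = signed_ranks.sum(axis=0).
    """
    a = np.abs(d)
    ranks = stats.rankdata(a, axis=0)
    signed = np.sign(d) * ranks
    sigma = np.sqrt((ranks**2).sum(axis=0))
    return signed, sigma


def element_stats_wilcoxon_vs(data: np.ndarray, null_value: float):
    """Signed Wilcoxon rank-sum statistic per element against a null value.

    Returns (T, p) with T the signed rank sum and p from the normal
    approximation (tie-corrected); with all values equal to the null the
    statistic is 0 and p 1.
    """
    d = np.asarray(data, float) - null_value
    d2 = d.reshape(d.shape[0], -1)
    if d2.shape[0] < 5:
        raise ValueError("Wilcoxon element statistic needs >= 5 subjects")
    signed, sigma = signed_rank_arrays(d2)
    T = signed.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, T / np.maximum(sigma, 1e-12), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(T == 0, 1.0, p)
    return T, p


def max_signed_rank_sum(n: int) -> float:
    return n * (n + 1) / 2.0


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------


class ClusterDomain:
    """Precomputed element graph for a (locations x times) domain.

    Elements are indexed ``e = loc * n_times + t``.  Edges join spatially
    adjacent locations at the same time sample and temporally contiguous
    samples of the same location.
    """

    def __init__(self, adjacency: Optional[sparse.spmatrix], n_locations: int, n_times: int = 1):
        self.n_locations = n_locations
        self.n_times = n_times
        self.n_elements = n_locations * n_times
        if adjacency is not None:
            adj = sparse.csr_matrix(adjacency).astype(bool)
            if adj.shape != (n_locations, n_locations):
                raise ValueError("adjacency must cover all locations")
            if (adj != adj.T).nnz:
                raise ValueError("adjacency must be symmetric")
            self.loc_neighbors = np.split(adj.indices, adj.indptr[1:-1])
        else:
            self.loc_neighbors = [np.array([], dtype=int)] * n_locations

    def neighbors(self, e: int) -> list:
        loc, t = divmod(e, self.n_times)
        out = [n * self.n_times + t for n in self.loc_neighbors[loc]]
        if t > 0:
            out.append(e - 1)
        if t < self.n_times - 1:
            out.append(e + 1)
        return out

    def components(self, mask: np.ndarray) -> list:
        """Connected components (lists of element indices) of supra mask."""
        comps = []
        seen = np.zeros(self.n_elements, bool)
        for start in np.flatnonzero(mask):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            comp = []
            while stack:
                e = stack.pop()
                comp.append(e)
                for nb in self.neighbors(e):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            comps.append(np.array(comp))
        return comps

    def neighbor_pair_count(self, comp: np.ndarray) -> int:
        """Distinct adjacent location pairs co-active at some time sample."""
        members = set(comp.tolist())
        pairs = set()
        for e in comp:
            loc, t = divmod(int(e), self.n_times)
            for nb in self.loc_neighbors[loc]:
                if nb > loc and nb * self.n_times + t in members:
                    pairs.add((loc, int(nb)))
        return len(pairs)


def form_clusters(
    stat: np.ndarray,
    p: np.ndarray,
    alpha_element: float,
    domain: ClusterDomain,
    min_neighbor_pairs: int = 0,
):
    """Candidate clusters of same-signed supra-threshold elements.

    Returns a list of (member_elements, stat_sum, sign) tuples; clusters
    failing the minimum-neighbor-pair requirement are discarded.
    """
    out = []
    finite_stat = np.nan_to_num(stat, posinf=1e12, neginf=-1e12)
    for sign in (1, -1):
        mask = (p < alpha_element) & (np.sign(finite_stat) == sign)
        for comp in domain.components(mask):
            if min_neighbor_pairs and domain.neighbor_pair_count(comp) < min_neighbor_pairs:
                continue
            out.append((comp, float(finite_stat[comp].sum()), sign))
    return out


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _sign_matrix(n_subjects: int, n_permutations: int, seed, exact: bool):
    if exact or 2**n_subjects <= n_permutations:
        n = 2**n_subjects
        bits = (np.arange(n)[:, None] >> np.arange(n_subjects)[None, :]) & 1
        return 2.0 * bits - 1.0, True
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_permutations, n_subjects)), False


def permutation_cluster_test(
    diffs: np.ndarray,
    domain: ClusterDomain,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    alpha_element: float = 0.05,
    stat: str = "t",
    min_neighbor_pairs: int = 0,
    exact: bool = False,
) -> ClusterReport:
    """Cluster permutation test on subject-level difference maps.

    ``diffs`` is ``(n_subjects, n_locations[, n_times])`` — a paired
    condition contrast, or values minus a chance level.  ``stat`` selects
    the element statistic: ``'t'`` (paired t) or ``'wilcoxon'`` (signed
    rank sum).  Permutations flip subject signs; with ``exact`` (or when
    2^n_subjects <= n_permutations) the full sign-flip distribution is
    enumerated.
    """
    if n_permutations < 100 and not exact:
        raise ValueError("need >= 100 permutations")
    d = np.asarray(diffs, float)
    if d.ndim == 2:
        d = d[:, :, None]
    S, L, T = d.shape
    if (L, T) != (domain.n_locations, domain.n_times):
        raise ValueError("domain shape mismatch")
    d2 = d.reshape(S, L * T)

    if stat == "t":
        obs_stat, obs_p = _paired_t_from_diffs(d2)
    elif stat == "wilcoxon":
        obs_stat, obs_p = element_stats_wilcoxon_vs(d2, 0.0)
    else:
        raise ValueError(stat)

    candidates = form_clusters(obs_stat, obs_p, alpha_element, domain, min_neighbor_pairs)

    signs, exhaustive = _sign_matrix(S, n_permutations, seed, exact)
    P = signs.shape[0]

    # permuted element statistics, fully vectorized
    if stat == "t":
        ssq = (d2**2).sum(axis=0)  # invariant under sign flips
        m = signs @ d2 / S
        var = np.maximum(ssq / S - m**2, 0.0) * (S / (S - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            tmap = m / np.sqrt(var / S)
        tmap = np.nan_to_num(tmap, posinf=1e12, neginf=-1e12)
        tcrit = stats.t.isf(alpha_element / 2.0, S - 1)
        supra = np.abs(tmap) > tcrit
        perm_stat = tmap
    else:
        signed, sigma = signed_rank_arrays(d2)
        perm_stat = signs @ signed
        zcrit = stats.norm.isf(alpha_element / 2.0)
        supra = np.abs(perm_stat) > zcrit * sigma[None, :]

    max_pos = np.zeros(P)
    max_neg = np.zeros(P)
    for k in range(P):
        mask_k = supra[k]
        if not mask_k.any():
            continue
        sk = perm_stat[k]
        for sign in (1, -1):
            m_signed = mask_k & (np.sign(sk) == sign)
            if not m_signed.any():
                continue
            best = 0.0
            for comp in domain.components(m_signed):
                if min_neighbor_pairs and domain.neighbor_pair_count(comp) < min_neighbor_pairs:
                    continue
                s = abs(float(sk[comp].sum()))
                best = max(best, s)
            if sign == 1:
                max_pos[k] = best
            else:
                max_neg[k] = best

    clusters = []
    for comp, stat_sum, sign in candidates:
        ref = max_pos if sign == 1 else max_neg
        if exhaustive:
            p_one = float((ref >= abs(stat_sum) - 1e-12).sum()) / P
        else:
            p_one = (float((ref >= abs(stat_sum) - 1e-12).sum()) + 1.0) / (P + 1.0)
        members = np.stack(divmod(comp, domain.n_times), axis=1)  # (k, 2) [loc, t]
        clusters.append(
            Cluster(
                members=members,
                stat_sum=stat_sum,
                p_cluster=min(2.0 * p_one, 1.0),
                sign=sign,
            )
        )
    clusters.sort(key=lambda c: abs(c.stat_sum), reverse=True)
    return ClusterReport(
        clusters=clusters,
        n_permutations=P,
        alpha=alpha,
        max_stat_distribution=np.maximum(max_pos, max_neg),
    )


def sig_element_mask(report: ClusterReport, n_locations: int, n_times: int = 1) -> np.ndarray:
    """Boolean (n_locations, n_times) mask of elements in significant clusters."""
    mask = np.zeros((n_locations, n_times), bool)
    for c in report.significant():
        mask[c.members[:, 0], c.members[:, 1]] = True
    return mask
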