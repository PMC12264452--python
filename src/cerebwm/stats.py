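"""Cluster-based permutation tests over channel x time data, plus the
classical statistics layer (FDR, Bonferroni, normality gating, Pearson).

The cluster test controls the family-wise error over electrodes and time
nonparametrically: pointwise t statistics are thresholded at an uncorrected
alpha, suprathreshold points are grouped into clusters that are contiguous
in time and connected through the electrode neighbourhood graph (clusters
must span at least two distinct electrodes), each cluster is scored by the
sum of its t values ("maxsum" mass), and the observed masses are compared
against the permutation distribution of the maximum cluster mass.  Positive
and negative clusters are tested separately, each against alpha = 0.025,
which together give a two-tailed test at 0.05.  Paired designs permute by
random sign flips of the subject difference maps; independent designs by
full relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

from .containers import Montage

__all__ = [
    "ChannelAdjacency",
    "channel_adjacency",
    "Cluster",
    "ClusterStatResult",
    "cluster_permutation_test",
    "fdr_bh",
    "bonferroni",
    "normality_gate",
    "pearson_corr",
]

_VAR_EPS = 1e-24  # small-variance guard in the t denominator


@dataclass(frozen=True)
class ChannelAdjacency:
    """Boolean electrode neighbourhood matrix (symmetric, zero diagonal)."""

    matrix: np.ndarray
    ch_names: tuple[str, ...]
    radius: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(m, m.T) or m.diagonal().any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        object.__setattr__(self, "matrix", m)

    def neighbour_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def channel_adjacency(montage: Montage, radius: float | None = None,
                      ) -> ChannelAdjacency:
    """Neighbours = electrode pairs within ``radius`` (meters).

    The default radius is 1.3x the median nearest-neighbour distance, which
    on regular 10-10 layouts connects each electrode to its immediate ring.
    A radius leaving any electrode isolated raises with advice to widen it.
    """
    if montage.n_channels < 2:
        raise ValueError("need at least 2 channels")
    d = montage.distances()
    np.fill_diagonal(d, np.inf)
    if radius is None:
        radius = 1.3 * float(np.median(d.min(axis=1)))
    adj = d <= radius
    counts = adj.sum(axis=1)
    if (counts == 0).any():
        lonely = [montage.ch_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"channels {lonely} have no neighbour at radius {radius:.4g} m; "
            "increase the radius")
    return ChannelAdjacency(adj, montage.ch_names, float(radius))


@dataclass(frozen=True)
class Cluster:
    channels: tuple[int, ...]        # distinct channel indices spanned
    points: tuple[tuple[int, int], ...]  # (channel, time) members
    mass: float                      # sum of t values (signed)
    pvalue: float
    tail: str                        # 'pos' or 'neg'

    @property
    def time_indices(self) -> tuple[int, ...]:
        return tuple(sorted({t for _, t in self.points}))


@dataclass
class ClusterStatResult:
    clusters: list[Cluster]
    t_obs: np.ndarray                # channels x times
    cluster_threshold: float         # |t| forming threshold
    n_permutations: int
    alpha: float
    seed: int | None
    null_max_mass: np.ndarray = field(repr=False, default=None)  # (2, n_perm): pos, neg tails

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.pvalue < self.alpha]


def _spacetime_graph(adj: np.ndarray, n_times: int) -> sparse.csr_matrix:
    """Sparse neighbour graph over (channel, time) points: spatial neighbours
    at the same time bin plus the same channel at adjacent bins."""
    n_ch = adj.shape[0]
    eye_t = sparse.identity(n_times, format="csr", dtype=bool)
    spatial = sparse.kron(sparse.csr_matrix(adj), eye_t, format="csr")
    off = sparse.diags([np.ones(n_times - 1)] * 2, [1, -1], format="csr").astype(bool)
    temporal = sparse.kron(sparse.identity(n_ch, format="csr", dtype=bool),
                           off, format="csr")
    return (spatial + temporal).tocsr()


def _clusters_from_tmap(t_flat: np.ndarray, thresh: float, graph: sparse.csr_matrix,
                        n_times: int, min_channels: int = 2):
    """Yield (member node indices, mass) for each admissible cluster, both tails."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t_flat > thresh
        nodes = np.flatnonzero(mask)
        if nodes.size == 0:
            continue
        sub = graph[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for k in range(n_comp):
            members = nodes[labels == k]
            chans = np.unique(members // n_times)
            if chans.size < min_channels:
                continue
            out.append((members, float(t_flat[members].sum())))
    return out


def _tail_maxima(clusters) -> tuple[float, float]:
    """Largest positive mass and largest |negative mass| among clusters."""
    pos = max((m for _, m in clusters if m > 0), default=0.0)
    neg = max((-m for _, m in clusters if m < 0), default=0.0)
    return pos, neg


def _paired_t(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    var = diff.var(axis=0, ddof=1)
    return mean / np.sqrt(var / n + _VAR_EPS)


def _independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    sp = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1))
    sp /= n1 + n2 - 2
    return (m1 - m2) / np.sqrt(sp * (1 / n1 + 1 / n2) + _VAR_EPS)


def cluster_permutation_test(a: np.ndarray, b: np.ndarray,
                             adjacency: ChannelAdjacency, *, paired: bool,
                             n_permutations: int = 5000,
                             cluster_alpha: float = 0.05,
                             alpha: float = 0.025,
                             min_channels: int = 2,
                             seed: int | None = None) -> ClusterStatResult:
    """Cluster-mass permutation test between conditions a and b.

    ``a`` and ``b`` are ``subjects x channels x times`` arrays (for the
    paired design with equal subject counts; for the independent design the
    two groups).  Cluster p-values use the +1-corrected Monte Carlo
    estimate p = (1 + #{null >= observed}) / (1 + n_permutations) against
    the null distribution of the maximum |cluster mass|; each tail is
    declared significant at ``alpha`` (0.025 per tail = 0.05 two-tailed).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("conditions must be subjects x channels x times "
                         "with matching channel/time axes")
    n_ch, n_t = a.shape[1:]
    if n_ch != adjacency.matrix.shape[0]:
        raise ValueError("adjacency does not match the channel axis")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired design needs equal subject counts")
    if n_permutations < 100:
        import warnings
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    graph = _spacetime_graph(adjacency.matrix, n_t)
    P = n_ch * n_t

    if paired:
        n = a.shape[0]
        diff = (a - b).reshape(n, P)
        t_obs = _paired_t(diff)
        df = n - 1
    else:
        n1, n2 = a.shape[0], b.shape[0]
        xa, xb = a.reshape(n1, P), b.reshape(n2, P)
        t_obs = _independent_t(xa, xb)
        df = n1 + n2 - 2
    thresh = float(sps.t.ppf(1 - cluster_alpha / 2, df))

    observed = _clusters_from_tmap(t_obs, thresh, graph, n_t, min_channels)

    # separate null distributions per tail: positive clusters are compared
    # with the permutation maxima of positive mass, negative with the
    # negative maxima, each tested at `alpha` (0.025 per tail = 0.05 FWER)
    null_pos = np.zeros(n_permutations)
    null_neg = np.zeros(n_permutations)
    if paired:
        n = diff.shape[0]
        sumsq = (diff**2).sum(axis=0)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        means = signs @ diff / n
        var = np.maximum((sumsq / n - means**2) * (n / (n - 1)), 0.0)
        t_perm = means / np.sqrt(var / n + _VAR_EPS)
        for i in range(n_permutations):
            cl = _clusters_from_tmap(t_perm[i], thresh, graph, n_t, min_channels)
            null_pos[i], null_neg[i] = _tail_maxima(cl)
    else:
        x = np.concatenate([xa, xb], axis=0)
        n_tot = n1 + n2
        for i in range(n_permutations):
            idx = rng.permutation(n_tot)
            g1, g2 = idx[:n1], idx[n1:]
            t_p = _independent_t(x[g1], x[g2])
            cl = _clusters_from_tmap(t_p, thresh, graph, n_t, min_channels)
            null_pos[i], null_neg[i] = _tail_maxima(cl)

    clusters = []
    for members, mass in observed:
        null = null_pos if mass > 0 else null_neg
        p = (1.0 + np.sum(null >= abs(mass))) / (1.0 + n_permutations)
        pts = tuple((int(m // n_t), int(m % n_t)) for m in members)
        clusters.append(Cluster(
            channels=tuple(sorted({c for c, _ in pts})),
            points=pts, mass=mass, pvalue=float(p),
            tail="pos" if mass > 0 else "neg"))
    clusters.sort(key=lambda c: c.pvalue)
    return ClusterStatResult(clusters=clusters,
                             t_obs=t_obs.reshape(n_ch, n_t),
                             cluster_threshold=thresh,
                             n_permutations=n_permutations,
                             alpha=alpha, seed=seed,
                             null_max_mass=np.stack([null_pos, null_neg]))


# ---------------------------------------------------------------------------
# classical layer
# ---------------------------------------------------------------------------

def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject p(i), i <= max{k : p(k) <= qk/m}."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * np.arange(1, m + 1) / m
    mask = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.flatnonzero(below).max()
        mask[order[: kmax + 1]] = True
    return mask


def bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Reject p <= alpha / m."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return p <= alpha / p.size


def normality_gate(samples, alpha: float = 0.05) -> str:
    """Route to 'parametric' or 'nonparametric' via Shapiro-Wilk per group.

    Any group rejecting normality at ``alpha`` routes the downstream
    analysis to its nonparametric counterpart (ANOVA to Kruskal-Wallis,
    paired t to Wilcoxon signed-rank).
    """
    groups = list(samples.values()) if isinstance(samples, dict) else list(samples)
    if not groups:
        raise ValueError("no groups given")
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise ValueError("each group needs at least 3 observations")
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with the two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
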