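"""Independent brute-force oracles shared by the graph-metric tests."""

import itertools

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def brute_force_metrics(adj):
    """Independent oracle: Floyd-Warshall distances + direct triangle counts."""
    a = np.asarray(adj, float)
    n = a.shape[0]
    d = floyd_warshall(a, directed=False, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / d, 0.0)
    eglob = inv[off].sum() / (n * (n - 1))
    lp = d[finite].mean() if finite.any() else 0.0
    cps = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            cps.append(0.0)
            continue
        tri = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        cps.append(2.0 * tri / (k * (k - 1)))
    eloc = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            eloc.append(0.0)
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        ds = floyd_warshall(sub, directed=False, unweighted=True)
        m = len(nbrs)
        o = ~np.eye(m, dtype=bool)
        fin = np.isfinite(ds) & o
        with np.errstate(divide="ignore"):
            iv = np.where(fin, 1.0 / ds, 0.0)
        eloc.append(iv[o].sum() / (m * (m - 1)))
    return float(np.mean(cps)), float(lp), float(eglob), np.array(eloc)
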