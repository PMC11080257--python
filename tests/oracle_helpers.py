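"""Independent oracles shared by the test modules.

These deliberately avoid the package's own code paths: brute-force
enumeration for the small-sample tests and a dense grid search with profiled
amplitude for the decay model.
"""
import itertools

import numpy as np
from scipy import stats as sps


def brute_force_ranksum_p(x, y):
    """Two-sided rank-sum p by enumerating every group assignment."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, n = len(x), len(pooled)
    e_w = nx * (n + 1) / 2
    dev = abs(ranks[:nx].sum() - e_w)
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        hits += abs(ranks[list(idx)].sum() - e_w) >= dev - 1e-12
        total += 1
    return hits / total


def brute_force_spearman(x, y):
    """(r, two-sided p) by enumerating every permutation of one margin."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    r_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        hits += abs(np.corrcoef(rx, perm)[0, 1]) >= abs(r_obs) - 1e-12
        total += 1
    return r_obs, hits / total


def grid_search_decay_rss(signal, bvalues, n_grid=200, d_max=0.05):
    """Best residual sum of squares over a dense (D, Nfloor) grid.

    S0 is profiled by linear least squares at each grid node (clipped to the
    fit's own bound [0, 2*max signal]); Nfloor spans [0, max signal].
    """
    s = np.asarray(signal, float)
    b = np.asarray(bvalues, float)
    smax = float(s.max())
    ds = np.linspace(0.0, d_max, n_grid)
    ns = np.linspace(0.0, smax, n_grid)
    E = np.exp(-np.outer(ds, b))                    # (nd, nb)
    ee = np.einsum("ij,ij->i", E, E)                # (nd,)
    es = E @ s                                      # (nd,)
    e1 = E.sum(axis=1)                              # (nd,)
    # S0(D, N) = (e.s - N e.1) / e.e, clipped
    s0 = (es[:, None] - np.outer(e1, ns)) / ee[:, None]
    s0 = np.clip(s0, 0.0, 2.0 * smax)
    # rss = |s - N|^2 - 2 S0 e.(s - N) + S0^2 e.e
    ss = float(s @ s)
    s_sum = float(s.sum())
    nb = len(s)
    sn2 = ss - 2.0 * np.outer(np.ones_like(ds), ns) * 0  # placeholder shape
    sn2 = ss - 2.0 * ns * s_sum + nb * ns ** 2           # (nn,)
    cross = es[:, None] - np.outer(e1, ns)               # e.(s - N)
    rss = sn2[None, :] - 2.0 * s0 * cross + s0 ** 2 * ee[:, None]
    return float(rss.min())
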