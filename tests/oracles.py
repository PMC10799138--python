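"""Independent brute-force oracles used to validate the decoder and the HMM.

These deliberately avoid the package's recursion/propagation code paths:
the decoder oracle enumerates all homozygous block configurations, and the
HMM oracle sums over every hidden-state path explicitly.
"""

from __future__ import annotations

import numpy as np


def all_block_configs() -> np.ndarray:
    """All 2^16 homozygous 4x4 dosage grids, shape (65536, 4, 4)."""
    bits = (np.arange(65536, dtype=np.int64)[:, None] >> np.arange(16)) & 1
    return (bits * 2).astype(np.int8).reshape(-1, 4, 4)


def pool_signatures(grids: np.ndarray) -> np.ndarray:
    """Base-3 encoded (rows, cols) outcome signature per grid."""
    rows = np.where(
        grids.max(axis=2) == 0, 0, np.where(grids.min(axis=2) == 2, 2, 1)
    )
    cols = np.where(
        grids.max(axis=1) == 0, 0, np.where(grids.min(axis=1) == 2, 2, 1)
    )
    out = np.concatenate([rows, cols], axis=1)  # (N, 8)
    return (out * 3 ** np.arange(8)).sum(axis=1)


def identifiable_cells(grids: np.ndarray, sig: np.ndarray):
    """For each config: which cells agree across every config sharing its
    pool-outcome signature (those are the identifiable cells)."""
    flat = grids.reshape(len(grids), 16)
    order = np.argsort(sig, kind="stable")
    ssig = sig[order]
    sflat = flat[order]
    starts = np.r_[0, np.flatnonzero(np.diff(ssig)) + 1]
    mn = np.minimum.reduceat(sflat, starts, axis=0)
    mx = np.maximum.reduceat(sflat, starts, axis=0)
    group_of = np.empty(len(grids), dtype=np.int64)
    group_of[order] = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, len(grids)]))
    ident = (mn == mx)[group_of]  # (N, 16)
    common = mn[group_of]  # value where identifiable
    return ident.reshape(-1, 4, 4), common.reshape(-1, 4, 4)


def _copy_table(lam: float) -> np.ndarray:
    T = np.zeros((2, 2, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            for c1 in (0, 1):
                for c2 in (0, 1):
                    p1 = lam if c1 != a1 else 1 - lam
                    p2 = lam if c2 != a2 else 1 - lam
                    T[a1, a2, c1 + c2] += p1 * p2
    return T


def hmm_path_posterior(
    obs: np.ndarray,
    hap: np.ndarray,
    dists: np.ndarray,
    ne: float,
    lam: float,
    projection: str = "conditional",
) -> np.ndarray:
    """Genotype posteriors by explicit summation over all ordered
    template-pair paths (feasible for k <= 3, M <= 4)."""
    k, M = hap.shape
    k2 = k * k
    T = _copy_table(lam)
    r = 1.0 - np.exp(-4.0 * ne * np.asarray(dists, dtype=float) / k)
    A1 = [(1.0 - ri) * np.eye(k) + (ri / k) * np.ones((k, k)) for ri in r]
    A2 = [np.kron(a, a) for a in A1]  # both copies switch independently

    n_un = k * (k + 1) // 2
    pi = np.full((k, k), 0.5 / n_un)
    np.fill_diagonal(pi, 1.0 / n_un)
    pi = pi.ravel()

    # per-marker flattened emission and genotype attribution per state
    E = np.empty((M, k2))
    C = np.empty((M, k2, 3))
    for m in range(M):
        for s in range(k2):
            i, j = divmod(s, k)
            joint = obs[m] * T[hap[i, m], hap[j, m]]
            e = joint.sum()
            E[m, s] = e
            if projection == "template":
                C[m, s] = np.eye(3)[hap[i, m] + hap[j, m]]
            else:
                C[m, s] = joint / e if e > 0 else 0.0

    paths = np.indices((k2,) * M).reshape(M, -1)  # (M, P)
    w = pi[paths[0]] * E[0, paths[0]]
    for m in range(1, M):
        w = w * A2[m - 1][paths[m - 1], paths[m]] * E[m, paths[m]]
    tot = w.sum()
    post = np.empty((M, 3))
    for m in range(M):
        post[m] = (w[:, None] * C[m, paths[m]]).sum(axis=0) / tot
    return post
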