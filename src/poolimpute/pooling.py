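"""4x4 row-column pooling blocks and error-free pool genotyping.

Every block holds 16 samples arranged in a 4x4 grid; its 4 row-pools and 4
column-pools (8 assays) replace the 16 individual assays, halving the
number of wells. A pool outcome is an integer: 0 when all four members are
homozygous reference, 2 when all are homozygous alternate, and 1 when the
pooled DNA mixture contains both alleles — the call an array would make on
a heterogeneous pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import MISSING

BLOCK_SIDE = 4
BLOCK_SIZE = BLOCK_SIDE * BLOCK_SIDE
POOLS_PER_BLOCK = 2 * BLOCK_SIDE


class PoolingError(ValueError):
    pass


@dataclass
class PoolingDesign:
    """Partition of N samples into 4x4 blocks.

    ``blocks`` has shape ``(n_blocks, 4, 4)``: row-major sample indices per
    block. Each sample sits in exactly one block and hence exactly two
    pools (its row and its column).
    """

    blocks: np.ndarray
    seed: int

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_pools(self) -> int:
        return self.n_blocks * POOLS_PER_BLOCK

    def pool_members(self, block: int) -> list[np.ndarray]:
        """The 8 pools of one block: rows 0-3 then columns 0-3."""
        g = self.blocks[block]
        return [g[i, :] for i in range(BLOCK_SIDE)] + [
            g[:, j] for j in range(BLOCK_SIDE)
        ]


def assign_blocks(sample_ids, seed: int) -> PoolingDesign:
    """Randomly partition samples into 4x4 blocks (seeded, reproducible).

    Raises when N is not a multiple of 16; callers should subsample to the
    largest multiple of 16 first (see ``pipeline.subsample_to_block_multiple``).
    """
    n = len(sample_ids)
    if n == 0 or n % BLOCK_SIZE != 0:
        raise PoolingError(
            f"{n} samples cannot fill 4x4 blocks; subsample to a multiple of "
            f"{BLOCK_SIZE} (e.g. keep {n - n % BLOCK_SIZE})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return PoolingDesign(
        blocks=perm.reshape(n // BLOCK_SIZE, BLOCK_SIDE, BLOCK_SIDE), seed=seed
    )


def _pool_call(member_dosages: np.ndarray, axis: int) -> np.ndarray:
    lo = member_dosages.min(axis=axis)
    hi = member_dosages.max(axis=axis)
    return np.where(hi == 0, 0, np.where(lo == 2, 2, 1)).astype(np.int8)


def simulate_pools(block_dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pool outcomes for one 4x4 grid of homozygous dosages at one marker.

    Returns ``(row_outcomes, col_outcomes)``, each length 4 over {0, 1, 2}.
    """
    g = np.asarray(block_dosages)
    if g.shape != (BLOCK_SIDE, BLOCK_SIDE):
        raise PoolingError(f"expected a 4x4 dosage grid, got shape {g.shape}")
    _validate_homozygous(g)
    return _pool_call(g, axis=1), _pool_call(g, axis=0)


def _validate_homozygous(d: np.ndarray) -> None:
    if (d == 1).any():
        raise PoolingError(
            "heterozygous dosage in pooling input; the decoder assumes fully "
            "homozygous samples"
        )
    if (d == MISSING).any():
        raise PoolingError("missing dosage in pooling input")
    if not np.isin(d, (0, 2)).all():
        raise PoolingError("dosages must be 0 or 2")


def add_pool_noise(
    outcomes: np.ndarray, rate: float, seed: int
) -> np.ndarray:
    """Optional noise hook: flip a fraction of pool calls at random.

    Off by default everywhere; the decoder and all accuracy results assume
    error-free pool genotyping. Each selected call is replaced by one of
    the two other outcome values uniformly.
    """
    if not 0.0 <= rate <= 1.0:
        raise PoolingError("noise rate must lie in [0, 1]")
    if rate == 0.0:
        return outcomes
    rng = np.random.default_rng(seed)
    noisy = outcomes.copy()
    hit = rng.random(outcomes.shape) < rate
    shift = rng.integers(1, 3, size=outcomes.shape)
    noisy[hit] = (noisy[hit] + shift[hit]) % 3
    return noisy


def simulate_pools_all(dosages: np.ndarray, design: PoolingDesign) -> np.ndarray:
    """Pool outcomes for every block and marker at once.

    Parameters
    ----------
    dosages
        ``(n_samples, n_markers)`` fully homozygous dosage matrix.
    design
        block assignment from :func:`assign_blocks`.

    Returns
    -------
    ``(n_blocks, 8, n_markers)`` int8 array; pools ordered rows 0-3 then
    columns 0-3, mirroring :meth:`PoolingDesign.pool_members`.
    """
    _validate_homozygous(np.asarray(dosages))
    d = np.asarray(dosages)[design.blocks]  # (B, 4, 4, M)
    rows = _pool_call(d, axis=2)  # (B, 4, M)
    cols = _pool_call(d, axis=1)
    return np.concatenate([rows, cols], axis=1)
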