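"""Linkage-disequilibrium references for instrument pruning.

Two interchangeable forms: a block-structured reference (the synthetic
generator's truth: exchangeable correlation ``rho`` within a block, zero
between blocks) and a dense r^2 matrix for arbitrary user input.  Both
expose ``r2(i, j)`` on variant indices and ``neighbors(i)`` listing the
indices that can have nonzero LD with variant ``i``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


class BlockLD:
    """Block-diagonal exchangeable LD: r^2 = rho_block^2 within a block."""

    def __init__(self, block_ids: Sequence[int], rho: Sequence[float]):
        self.block_ids = np.asarray(block_ids)
        self.rho = np.asarray(rho, dtype=float)
        if len(self.block_ids) != len(self.rho):
            raise ValueError("block_ids and rho must have equal length")
        self._members: dict = {}
        for i, b in enumerate(self.block_ids):
            if b >= 0:
                self._members.setdefault(int(b), []).append(i)

    def __len__(self) -> int:
        return len(self.block_ids)

    def r2(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        bi, bj = self.block_ids[i], self.block_ids[j]
        if bi < 0 or bi != bj:
            return 0.0
        return float(self.rho[i] * self.rho[j])

    def neighbors(self, i: int):
        b = int(self.block_ids[i])
        if b < 0:
            return []
        return [j for j in self._members[b] if j != i]


class DenseLD:
    """Dense m x m r^2 matrix."""

    def __init__(self, r2_matrix: np.ndarray):
        m = np.asarray(r2_matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("r2 matrix must be square")
        self.m = m

    def __len__(self) -> int:
        return self.m.shape[0]

    def r2(self, i: int, j: int) -> float:
        return float(self.m[i, j])

    def neighbors(self, i: int):
        return [int(j) for j in np.flatnonzero(self.m[i] > 0) if j != i]


def empirical_r2(dosages: np.ndarray) -> DenseLD:
    """r^2 from a (n_individuals x m) dosage matrix; monomorphic variants
    get zero off-diagonal LD."""
    x = np.asarray(dosages, dtype=float)
    sd = x.std(axis=0)
    ok = sd > 0
    xc = (x - x.mean(axis=0)) / np.where(ok, sd, 1.0)
    r = (xc.T @ xc) / x.shape[0]
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    np.fill_diagonal(r, 1.0)
    return DenseLD(r ** 2)
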