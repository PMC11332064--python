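"""Shared fixtures and independent oracles for the test suite.

The toy landscape: tree ((A:1,B:1):1,C:2) on a 2x2 unit grid with ranges
A={0}, B={0,1}, C={0,1,2,3}.  All its metric values can be checked by a
hand branch-by-branch summation, which `naive_cell_metrics` reproduces
with an explicit per-cell per-branch double loop (a deliberately slow,
independent code path from the package's matrix implementation).
"""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from endemap import Grid, PresenceMatrix
from endemap.gridio import read_newick

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_grid() -> Grid:
    return Grid(0.0, 0.0, 1.0, 2, 2)


@pytest.fixture
def toy_tree() -> dendropy.Tree:
    return read_newick(TOY_NEWICK, from_path=False)


@pytest.fixture
def toy_presence(toy_grid) -> PresenceMatrix:
    return PresenceMatrix.from_cell_sets(
        toy_grid, {"A": [0], "B": [0, 1], "C": [0, 1, 2, 3]}
    )


def naive_cell_metrics(newick: str, presence: PresenceMatrix,
                       equalize: bool = False):
    """Brute-force SR/PD/PE per cell via an explicit double loop.

    Walks the parsed tree edge by edge, derives each branch's descendant
    tip set and range by scanning the matrix, and accumulates sums cell
    by cell.  Independent of endemap.metrics internals.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    sp_index = {s: j for j, s in enumerate(presence.species)}
    root = tree.seed_node
    branches = []  # (length, tip column indices)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        branches.append((node.edge.length, [sp_index[t] for t in tips]))
    if equalize:
        mean = sum(b[0] for b in branches) / len(branches)
        branches = [(mean, cols) for _, cols in branches]
    n = presence.n_cells
    sr = np.zeros(n)
    pd_ = np.zeros(n)
    pe = np.zeros(n)
    vals = presence.values
    for c in range(n):
        sr[c] = vals[c].sum()
        for length, cols in branches:
            present_here = any(vals[c, j] for j in cols)
            if not present_here:
                continue
            rng_size = sum(1 for cc in range(n)
                           if any(vals[cc, j] for j in cols))
            pd_[c] += length
            pe[c] += length / rng_size
    return sr, pd_, pe


def naive_core_area_order(amounts: np.ndarray, weights: np.ndarray,
                          cost: np.ndarray, seed: int,
                          warp: int = 1) -> list[int]:
    """Reference greedy: recompute every marginal loss from scratch.

    Mirrors the documented tie-break contract: one uniform draw of length
    n_cells per iteration, cells ordered by (delta, draw).
    """
    rng = np.random.default_rng(seed)
    n = amounts.shape[0]
    remaining = list(range(n))
    order: list[int] = []
    while remaining:
        u = rng.random(n)
        totals = amounts[remaining].sum(axis=0)
        deltas = {}
        for i in remaining:
            best = 0.0
            for j in range(amounts.shape[1]):
                if totals[j] > 0:
                    v = weights[j] * (amounts[i, j] / totals[j])
                    if v > best:
                        best = v
            deltas[i] = best / cost[i]
        chosen = sorted(remaining, key=lambda i: (deltas[i], u[i]))[:warp]
        for i in chosen:
            order.append(i)
            remaining.remove(i)
    return order
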