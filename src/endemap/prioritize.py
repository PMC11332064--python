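"""Greedy marginal-loss spatial prioritization (core-area removal rule).

Cells are removed one at a time (or ``warp`` at a time); at every
iteration the marginal loss of each remaining cell i is

    delta_i = max_j [ w_j * q_ij ] / c_i

where ``q_ij`` is the proportion of feature j's remaining distribution
found in cell i, ``w_j`` the feature weight and ``c_i`` the cell cost.
The cell with the lowest marginal loss is removed; the removal order read
backwards is the priority ranking (the last cell removed ranks 1).  This
is the core-area rule: a cell is only as expendable as its most
concentrated feature allows, so cells holding large fractions of narrow-
ranged or heavily weighted features survive longest.

Three feature scenarios mirror common conservation-planning choices:

* **Tx** - one binary feature per taxon, all weights 1;
* **Br** - one feature per non-root phylogenetic branch, distribution =
  the union of its descendant taxa's cells, weight = branch length /
  total tree length (so the Br solution retains phylogenetic diversity);
* **BrCE** - Br plus one unit-weight binary feature per center-of-
  endemism class among {neo, mixed, super}.  Paleo centers are excluded:
  their long branches already make them high-value under Br, whereas neo
  centers (short branches) are cheap to lose unless targeted explicitly.

Ties in marginal loss are broken by a seeded uniform draw, which also
randomizes the removal order of featureless cells (delta = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .metrics import build_branch_table
from .presence import PresenceMatrix

__all__ = [
    "Feature",
    "PriorityRanking",
    "build_features",
    "marginal_loss",
    "core_area_rank",
    "top_fraction",
    "performance_curves",
]

SCENARIOS = ("Tx", "Br", "BrCE")
CENTER_CLASSES_AS_FEATURES = ("neo", "mixed", "super")


@dataclass
class Feature:
    id: str
    kind: str  # taxon | branch | center
    weight: float
    distribution: np.ndarray = field(repr=False)  # (n_cells,) non-negative

    def __post_init__(self) -> None:
        self.distribution = np.asarray(self.distribution, dtype=float)
        if self.weight < 0:
            raise ValueError("feature weight must be non-negative")
        if (self.distribution < 0).any():
            raise ValueError("feature distribution must be non-negative")
        if self.distribution.sum() <= 0:
            raise ValueError(f"feature {self.id} has an empty distribution")


@dataclass
class PriorityRanking:
    """Removal order and ranks: rank = removal position / n_cells.

    The first-removed cell has rank 1/n and the last has rank 1; the
    top-f fraction of the landscape is the cells with rank > 1 - f.
    """

    removal_order: np.ndarray  # cell ids in removal sequence
    rank: np.ndarray  # (n_cells,) in (0, 1]

    @property
    def n_cells(self) -> int:
        return self.rank.size


def build_features(
    scenario: str,
    presence: PresenceMatrix,
    tree: dendropy.Tree | None = None,
    classes: np.ndarray | None = None,
) -> list[Feature]:
    """Conservation features for one scenario (Tx, Br or BrCE)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario == "Tx":
        return [
            Feature(sp, "taxon", 1.0, presence.values[:, j].astype(float))
            for j, sp in enumerate(presence.species)
        ]
    if tree is None:
        raise ValueError(f"scenario {scenario} requires a tree")
    table = build_branch_table(tree, presence.species)
    inc = table.incidence(presence).astype(float)
    total = table.lengths.sum()
    feats = [
        Feature(f"branch_{table.labels[b]}", "branch",
                float(table.lengths[b] / total), inc[:, b])
        for b in range(table.n_branches)
    ]
    if scenario == "Br":
        return feats
    if classes is None:
        raise ValueError("scenario BrCE requires an endemism classification")
    classes = np.asarray(classes, dtype=object)
    n_center = 0
    for cls in CENTER_CLASSES_AS_FEATURES:
        dist = (classes == cls).astype(float)
        if dist.sum() > 0:
            feats.append(Feature(f"center_{cls}", "center", 1.0, dist))
            n_center += 1
    if n_center == 0:
        warnings.warn(
            "BrCE scenario requested but no neo/mixed/super center cells "
            "exist; falling back to Br features", stacklevel=2
        )
    return feats


def _amount_matrix(features: list[Feature]) -> tuple[np.ndarray, np.ndarray]:
    amounts = np.column_stack([f.distribution for f in features])
    weights = np.array([f.weight for f in features])
    return amounts, weights


def marginal_loss(
    cell: int,
    features: list[Feature],
    remaining_totals: np.ndarray,
    cost: np.ndarray | None = None,
) -> float:
    """Core-area marginal loss of one cell given remaining feature totals."""
    amounts, weights = _amount_matrix(features)
    c = 1.0 if cost is None else float(np.asarray(cost, dtype=float)[cell])
    if c <= 0:
        raise ValueError("cell costs must be strictly positive")
    totals = np.asarray(remaining_totals, dtype=float)
    q = np.zeros(len(features))
    live = totals > 0
    q[live] = amounts[cell, live] / totals[live]
    return float(np.max(weights * q) / c)


def core_area_rank(
    features: list[Feature],
    cost: np.ndarray | None = None,
    warp: int = 1,
    seed: int = 0,
) -> PriorityRanking:
    """Greedy core-area cell-removal ranking.

    Each iteration recomputes every remaining cell's marginal loss against
    the remaining feature totals and removes the ``warp`` lowest cells;
    ties (including featureless delta = 0 cells) are broken by a fresh
    seeded uniform draw per iteration.  Deterministic for a fixed seed.
    """
    if not features:
        raise ValueError("need at least one feature")
    if warp < 1:
        raise ValueError("warp must be >= 1")
    amounts, weights = _amount_matrix(features)
    n_cells = amounts.shape[0]
    if cost is None:
        cost = np.ones(n_cells)
    cost = np.asarray(cost, dtype=float)
    if (cost <= 0).any():
        raise ValueError("cell costs must be strictly positive")
    rng = np.random.default_rng(seed)
    remaining = np.ones(n_cells, dtype=bool)
    order = np.empty(n_cells, dtype=np.int64)
    pos = 0
    while pos < n_cells:
        idx = np.flatnonzero(remaining)
        totals = amounts[idx].sum(axis=0)
        live = totals > 0
        q = np.zeros((idx.size, len(features)))
        q[:, live] = amounts[np.ix_(idx, live)] / totals[live]
        delta = (q * weights).max(axis=1) / cost[idx]
        tie = rng.random(n_cells)  # full-length draw; oracle-reproducible
        take = min(warp, idx.size)
        sel = np.lexsort((tie[idx], delta))[:take]
        removed = idx[sel]
        order[pos:pos + take] = removed
        remaining[removed] = False
        pos += take
    rank = np.empty(n_cells)
    rank[order] = (np.arange(n_cells) + 1) / n_cells
    return PriorityRanking(order, rank)


def top_fraction(ranking: PriorityRanking, fraction: float) -> np.ndarray:
    """Cell ids of the ceil(fraction * n) highest-ranked cells."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = ranking.n_cells
    k = int(np.ceil(fraction * n))
    return np.sort(ranking.removal_order[n - k:])


def performance_curves(
    ranking: PriorityRanking, features: list[Feature]
) -> "np.ndarray":
    """Proportion of each feature remaining after each removal step.

    Returns (n_cells + 1, n_features): row r is the state after r cells
    have been removed (row 0 = full landscape, all ones).
    """
    amounts, _ = _amount_matrix(features)
    totals = amounts.sum(axis=0)
    lost = np.cumsum(amounts[ranking.removal_order], axis=0)
    curves = np.vstack([np.ones(len(features)), 1.0 - lost / totals])
    return np.clip(curves, 0.0, 1.0)
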