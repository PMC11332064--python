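"""Per-cell diversity and endemism metrics on a gridded presence matrix.

Given a rooted phylogeny with branch lengths and a cells x species
incidence matrix, this module computes for every grid cell

* **SR** - species richness, the number of species present;
* **PD** - Faith's phylogenetic diversity, the summed length of all
  branches on root-to-tip paths of the species present;
* **PE** - phylogenetic endemism, the same branch set with each branch
  length divided by the branch's range size (the number of cells in which
  any of its descendant tips occurs);
* **PE_alt** - PE recomputed on an alternate tree of identical topology
  whose branch lengths are all set to the mean branch length;
* **RPE** - relative phylogenetic endemism, PE / PE_alt, which exceeds 1
  where endemism is carried by longer-than-average (old) branches and
  falls below 1 where it is carried by shorter-than-average (young) ones.

The branch subtending the root is excluded from every sum: it lies on no
root-to-tip path distinctly and would contribute a constant to all
non-empty cells.  The alternate tree's mean is likewise taken over
non-root branches.  Because each branch contributes ``L_b / |R_b|`` in
exactly ``|R_b|`` cells, PE summed over all cells equals the total tree
length - a conservation law used as a cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .presence import PresenceMatrix

__all__ = [
    "BranchTable",
    "build_branch_table",
    "prune_to_species",
    "equalize_branches",
    "species_richness",
    "faith_pd",
    "phylo_endemism",
    "rpe",
    "compute_cell_metrics",
    "tree_length",
]


def _nonroot_edges(tree: dendropy.Tree):
    """Non-root edges in a stable preorder; the root's edge is skipped."""
    root = tree.seed_node
    return [nd.edge for nd in tree.preorder_node_iter() if nd is not root]


def tree_length(tree: dendropy.Tree) -> float:
    """Sum of non-root branch lengths."""
    return float(sum(e.length or 0.0 for e in _nonroot_edges(tree)))


@dataclass
class BranchTable:
    """Per-branch lengths and descendant-tip membership for fast metrics.

    ``tip_membership[s, b]`` is True when species ``s`` descends from (the
    head of) branch ``b``.  Given a cells x species matrix ``P``, branch
    incidence per cell is ``P @ tip_membership > 0`` and range sizes are
    its column sums - everything downstream is two matrix products.
    """

    species: list[str]
    lengths: np.ndarray  # (n_branches,)
    tip_membership: np.ndarray = field(repr=False)  # (n_species, n_branches) bool
    labels: list[str] = field(default_factory=list)

    @property
    def n_branches(self) -> int:
        return self.lengths.size

    def incidence(self, presence: PresenceMatrix) -> np.ndarray:
        """(n_cells, n_branches) bool: branch has a descendant in the cell."""
        return presence.values @ self.tip_membership > 0

    def range_sizes(self, presence: PresenceMatrix) -> np.ndarray:
        return self.incidence(presence).sum(axis=0)


def build_branch_table(tree: dendropy.Tree, species: list[str]) -> BranchTable:
    """Index the non-root branches of ``tree`` against a species order.

    Every species must map to exactly one tip; extra tips on the tree are
    an error (prune first with :func:`prune_to_species`).
    """
    tips = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in tips]
    if missing:
        raise KeyError(f"species not on tree: {missing[:5]}")
    extra = set(tips) - set(species)
    if extra:
        raise KeyError(
            f"tree has tips absent from the matrix: {sorted(extra)[:5]}; "
            "prune the tree first"
        )
    edges = _nonroot_edges(tree)
    index = {id(e): i for i, e in enumerate(edges)}
    lengths = np.array([e.length if e.length is not None else 0.0 for e in edges])
    if (lengths <= 0).any():
        bad = int((lengths <= 0).sum())
        raise ValueError(f"{bad} non-root branches have non-positive length")
    member = np.zeros((len(species), len(edges)), dtype=bool)
    for j, sp in enumerate(species):
        node = tips[sp]
        while node.parent_node is not None:
            member[j, index[id(node.edge)]] = True
            node = node.parent_node
    labels = []
    for e in edges:
        head = e.head_node
        labels.append(head.taxon.label if head.is_leaf() else f"node_{index[id(e)]}")
    return BranchTable(list(species), lengths, member, labels)


def prune_to_species(tree: dendropy.Tree, species, allow_single: bool = False) -> dendropy.Tree:
    """Restrict a tree to ``species``, collapsing unifurcations.

    Branch lengths of collapsed unifurcations are summed, so root-to-tip
    distances of retained tips are preserved.  Pruning to fewer than two
    species raises by default (``allow_single=True`` keeps a one-tip tree).
    """
    species = list(species)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = [s for s in species if s not in labels]
    if unknown:
        raise KeyError(f"species not on tree: {unknown[:5]}")
    if len(set(species)) < 2 and not allow_single:
        raise ValueError("cannot prune a tree below two species")
    pruned = tree.clone(depth=1)
    if set(species) != labels:
        pruned.retain_taxa_with_labels(species)
    return pruned


def equalize_branches(tree: dendropy.Tree) -> dendropy.Tree:
    """Alternate tree: same topology, every non-root branch set to the mean.

    Total (non-root) tree length is preserved exactly.
    """
    alt = tree.clone(depth=1)
    edges = _nonroot_edges(alt)
    if not edges:
        raise ValueError("tree has no non-root branches")
    mean = float(np.mean([e.length if e.length is not None else 0.0 for e in edges]))
    for e in edges:
        e.length = mean
    return alt


def species_richness(presence: PresenceMatrix) -> np.ndarray:
    return presence.richness()


def faith_pd(presence: PresenceMatrix, table: BranchTable) -> np.ndarray:
    """Faith's PD per cell: summed lengths of incident branches."""
    return table.incidence(presence) @ table.lengths


def phylo_endemism(
    presence: PresenceMatrix,
    table: BranchTable,
    range_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """PE per cell: sum of L_b / |R_b| over incident branches.

    ``range_sizes`` may be supplied to reuse precomputed branch ranges
    (they depend only on the presence matrix, not on branch lengths).
    """
    inc = table.incidence(presence)
    if range_sizes is None:
        range_sizes = inc.sum(axis=0)
    weights = np.zeros_like(table.lengths)
    occupied = range_sizes > 0
    weights[occupied] = table.lengths[occupied] / range_sizes[occupied]
    return inc @ weights


def rpe(
    presence: PresenceMatrix,
    table: BranchTable,
    alt_table: BranchTable | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(PE, PE_alt, RPE) per cell; RPE is NaN where PE_alt is zero."""
    if alt_table is None:
        alt_table = BranchTable(
            table.species,
            np.full_like(table.lengths, table.lengths.mean()),
            table.tip_membership,
            table.labels,
        )
    inc = table.incidence(presence)
    ranges = inc.sum(axis=0)
    pe = phylo_endemism(presence, table, ranges)
    pe_alt = phylo_endemism(presence, alt_table, ranges)
    out = np.full(pe.shape, np.nan)
    np.divide(pe, pe_alt, out=out, where=pe_alt > 0)
    return pe, pe_alt, out


def compute_cell_metrics(
    presence: PresenceMatrix, tree: dendropy.Tree
) -> pd.DataFrame:
    """Tidy per-cell table of SR, PD, PE, PE_alt and RPE.

    RPE is NaN (undefined) in empty cells; SR = 0 forces PD = PE = 0.
    """
    table = build_branch_table(tree, presence.species)
    sr = species_richness(presence)
    pd_vals = faith_pd(presence, table)
    pe, pe_alt, rpe_vals = rpe(presence, table)
    return pd.DataFrame(
        {
            "cell_id": np.arange(presence.n_cells),
            "SR": sr,
            "PD": pd_vals,
            "PE": pe,
            "PE_alt": pe_alt,
            "RPE": rpe_vals,
        }
    )
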