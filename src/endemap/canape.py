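"""CANAPE: categorical analysis of neo- and paleo-endemism.

The procedure classifies grid cells into centers of endemism in three
steps:

1. compute observed PE, alternate-tree PE (``PE_alt``) and their ratio
   RPE for every cell;
2. build a null distribution for each statistic by randomizing the
   presence matrix under a *fixed-fixed* null - both per-cell richness
   (row sums) and per-species occupancy (column sums) are held exactly -
   and rank the observed value among the null replicates with a
   two-tailed test;
3. classify each significantly endemic cell: significantly high RPE ->
   paleo-endemism (endemism carried by long, old branches), significantly
   low RPE -> neo-endemism (short, young branches); if the RPE ratio
   itself is not significant but both its numerator (PE) and denominator
   (PE_alt) are, the cell is a center of mixed endemism, upgraded to
   super-endemism when both are significant at the stricter level.

The fixed-fixed null is sampled with a curveball Markov chain: a trade
picks two species and reallocates the cells unique to either one between
them, preserving both margins by construction.  Swap budgets (burn-in,
thinning) are counted in exchanged presence pairs, so one trade that
moves k cells from each species to the other counts as k swaps.

Post-hoc relabeling masks artifacts: cells with zero richness (e.g.
removed cropland/urban cells) and cells whose entire assemblage is a
designated widespread species rank as extreme PE for uninteresting
reasons and are relabeled non-significant ("masked").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .metrics import BranchTable, build_branch_table, equalize_branches, phylo_endemism
from .presence import PresenceMatrix

__all__ = [
    "NullModelConfig",
    "SignificanceCodes",
    "randomize_matrix",
    "null_distributions",
    "rank_test",
    "classify_canape",
    "relabel_masked",
    "run_canape",
    "CLASS_CODES",
]

SIG_HIGH = "sig_high"
SIG_LOW = "sig_low"
NS = "ns"
UNDEFINED = "undefined"

# integer codes used in class rasters
CLASS_CODES = {"non_significant": 0, "neo": 1, "paleo": 2, "mixed": 3,
               "super": 4, "masked": 9}


@dataclass
class NullModelConfig:
    """Settings for the fixed-fixed randomization test.

    ``burn_in_swaps``/``thinning_swaps`` default to 10x / 1x the number of
    presences in the matrix (the matrix "fill"), a standard budget for
    fixed-margin chains.
    """

    n_rand: int = 999
    alpha: float = 0.05
    alpha_super: float = 0.01
    burn_in_swaps: int | None = None
    thinning_swaps: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if not 0 < self.alpha_super < self.alpha < 1:
            raise ValueError("need 0 < alpha_super < alpha < 1")


@dataclass
class SignificanceCodes:
    """Per-cell two-tailed significance codes for PE, PE_alt and RPE.

    ``at_alpha[stat]`` and ``at_alpha_super[stat]`` are arrays of codes in
    {sig_high, sig_low, ns, undefined}; codes at the stricter level are
    nested inside those at the looser one by construction of the p-value.
    """

    at_alpha: dict[str, np.ndarray]
    at_alpha_super: dict[str, np.ndarray]
    p_high: dict[str, np.ndarray] = field(default_factory=dict)
    p_low: dict[str, np.ndarray] = field(default_factory=dict)


def _curveball_trades(work: np.ndarray, n_swaps: int,
                      rng: np.random.Generator) -> int:
    """Run curveball trades on a species x cells boolean array in place.

    Each trade preserves every row and column sum exactly.  The budget is
    counted in exchanged presence pairs, with every trade consuming at
    least one unit whether or not it moved anything - an unproductive
    trade still advances the chain clock, which both bounds the runtime
    on near-frozen matrices and avoids parity artifacts on tiny ones.
    """
    n_rows = work.shape[0]
    if n_rows < 2 or n_swaps <= 0:
        return 0
    fill = int(work.sum())
    if fill == 0 or fill == work.size:  # no rearrangement possible
        return 0
    done = 0
    while done < n_swaps:
        i, j = rng.choice(n_rows, size=2, replace=False)
        ri, rj = work[i], work[j]
        only_i = np.flatnonzero(ri & ~rj)
        only_j = np.flatnonzero(rj & ~ri)
        na, nb = only_i.size, only_j.size
        if na == 0 or nb == 0:
            done += 1
            continue
        pool = np.concatenate([only_i, only_j])
        rng.shuffle(pool)
        new_i = pool[:na]
        moved = na - np.isin(new_i, only_i).sum()
        ri[only_i] = False
        rj[only_j] = False
        ri[new_i] = True
        rj[pool[na:]] = True
        done += max(int(moved), 1)
    return done


def randomize_matrix(presence: PresenceMatrix, n_swaps: int, seed: int) -> PresenceMatrix:
    """One fixed-fixed randomization of the presence matrix.

    Row sums (cell richness) and column sums (species occupancies) of the
    result equal the input's exactly; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    work = presence.values.T.astype(bool).copy()  # species x cells
    _curveball_trades(work, n_swaps, rng)
    return PresenceMatrix(presence.grid, list(presence.species),
                          work.T.astype(np.uint8))


def null_distributions(
    presence: PresenceMatrix,
    tree: dendropy.Tree,
    config: NullModelConfig,
    table: BranchTable | None = None,
    alt_table: BranchTable | None = None,
) -> dict[str, np.ndarray]:
    """Null samples of PE, PE_alt and RPE from one thinned curveball chain.

    Returns ``{"PE": (n_rand, n_cells), "PE_alt": ..., "RPE": ...}``.
    Branch range sizes are recomputed for every replicate, as the
    randomized matrix changes them.  RPE is NaN in empty cells (which stay
    empty under the fixed-fixed null).
    """
    if table is None:
        table = build_branch_table(tree, presence.species)
    if alt_table is None:
        alt_table = build_branch_table(equalize_branches(tree), presence.species)
    fill = int(presence.values.sum())
    burn = config.burn_in_swaps if config.burn_in_swaps is not None else 10 * fill
    thin = config.thinning_swaps if config.thinning_swaps is not None else fill
    rng = np.random.default_rng(config.seed)
    work = presence.values.T.astype(bool).copy()
    _curveball_trades(work, burn, rng)
    n_cells = presence.n_cells
    out = {
        "PE": np.empty((config.n_rand, n_cells)),
        "PE_alt": np.empty((config.n_rand, n_cells)),
        "RPE": np.empty((config.n_rand, n_cells)),
    }
    for r in range(config.n_rand):
        _curveball_trades(work, thin, rng)
        rep = PresenceMatrix(presence.grid, list(presence.species),
                             work.T.astype(np.uint8))
        inc = rep.values @ table.tip_membership > 0
        ranges = inc.sum(axis=0)
        w = np.zeros_like(table.lengths)
        occ = ranges > 0
        w[occ] = table.lengths[occ] / ranges[occ]
        w_alt = np.zeros_like(alt_table.lengths)
        w_alt[occ] = alt_table.lengths[occ] / ranges[occ]
        pe = inc @ w
        pe_alt = inc @ w_alt
        out["PE"][r] = pe
        out["PE_alt"][r] = pe_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            out["RPE"][r] = np.where(pe_alt > 0, pe / np.where(pe_alt > 0, pe_alt, 1.0), np.nan)
    return out


def rank_test(observed, nulls, alpha: float):
    """Two-tailed rank test of observed values against null replicates.

    ``p_high = (1 + #{null >= obs}) / (n_rand + 1)`` and symmetrically for
    ``p_low``; ties count as extreme.  A cell is ``sig_high`` when
    ``p_high <= alpha / 2`` (the highest 2.5% at alpha = 0.05),
    ``sig_low`` symmetrically, otherwise ``ns``.  NaN observed values are
    ``undefined``.

    Accepts scalars with a 1-D null list, or per-cell arrays with a
    (n_rand, n_cells) null matrix.  Returns (codes, p_high, p_low).
    """
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    nulls = np.asarray(nulls, dtype=float)
    if nulls.ndim == 1:
        nulls = nulls[:, None]
    if nulls.shape[0] < 1:
        raise ValueError("need at least one null replicate")
    n_rand = nulls.shape[0]
    with np.errstate(invalid="ignore"):
        n_ge = (nulls >= obs[None, :]).sum(axis=0)
        n_le = (nulls <= obs[None, :]).sum(axis=0)
    p_high = (1.0 + n_ge) / (n_rand + 1.0)
    p_low = (1.0 + n_le) / (n_rand + 1.0)
    codes = np.full(obs.shape, NS, dtype=object)
    codes[p_high <= alpha / 2] = SIG_HIGH
    codes[p_low <= alpha / 2] = SIG_LOW
    codes[np.isnan(obs)] = UNDEFINED
    if np.isscalar(observed) or np.asarray(observed).ndim == 0:
        return codes[0], float(p_high[0]), float(p_low[0])
    return codes, p_high, p_low


def significance_codes(
    observed: dict[str, np.ndarray],
    nulls: dict[str, np.ndarray],
    config: NullModelConfig,
) -> SignificanceCodes:
    """Apply the rank test to PE, PE_alt and RPE at both alpha levels."""
    at_a, at_s, p_hi, p_lo = {}, {}, {}, {}
    for stat in ("PE", "PE_alt", "RPE"):
        codes, ph, pl = rank_test(observed[stat], nulls[stat], config.alpha)
        codes_s, _, _ = rank_test(observed[stat], nulls[stat], config.alpha_super)
        at_a[stat], at_s[stat] = codes, codes_s
        p_hi[stat], p_lo[stat] = ph, pl
    return SignificanceCodes(at_a, at_s, p_hi, p_lo)


def classify_canape(codes: SignificanceCodes, strict_canape: bool = False) -> np.ndarray:
    """Per-cell endemism class from the significance codes.

    A cell is a candidate only if its PE is significantly endemic (either
    tail of the two-tailed test); with ``strict_canape=True`` the original
    one-tailed gate (PE or PE_alt significantly high) is used instead.
    Candidates are then classified: RPE significantly high -> paleo,
    significantly low -> neo; otherwise mixed when PE and PE_alt are both
    significant, super when both are significant at the stricter level.
    """
    pe = codes.at_alpha["PE"]
    pe_alt = codes.at_alpha["PE_alt"]
    rpe_c = codes.at_alpha["RPE"]
    pe_s = codes.at_alpha_super["PE"]
    pe_alt_s = codes.at_alpha_super["PE_alt"]
    n = pe.shape[0]
    out = np.full(n, "non_significant", dtype=object)
    for i in range(n):
        if strict_canape:
            candidate = pe[i] == SIG_HIGH or pe_alt[i] == SIG_HIGH
        else:
            candidate = pe[i] in (SIG_HIGH, SIG_LOW)
        if not candidate:
            continue
        if rpe_c[i] == SIG_HIGH:
            out[i] = "paleo"
        elif rpe_c[i] == SIG_LOW:
            out[i] = "neo"
        elif pe_s[i] != NS and pe_s[i] != UNDEFINED and pe_alt_s[i] != NS and pe_alt_s[i] != UNDEFINED:
            out[i] = "super"
        elif pe[i] != NS and pe[i] != UNDEFINED and pe_alt[i] != NS and pe_alt[i] != UNDEFINED:
            out[i] = "mixed"
    return out


def relabel_masked(
    classes: np.ndarray,
    presence: PresenceMatrix,
    widespread_only_species=(),
) -> np.ndarray:
    """Mask artifact cells: empty cells and widespread-species-only cells.

    Cells with zero richness, and cells whose entire species set is
    contained in ``widespread_only_species``, are relabeled ``masked``
    whatever their test outcome.  All other cells are untouched.
    """
    out = classes.copy()
    sr = presence.richness()
    out[sr == 0] = "masked"
    if len(widespread_only_species):
        wide = np.array([s in set(widespread_only_species) for s in presence.species])
        if wide.any():
            only_wide = (presence.values[:, ~wide].sum(axis=1) == 0) & (sr > 0)
            out[only_wide] = "masked"
    return out


def run_canape(
    presence: PresenceMatrix,
    tree: dendropy.Tree,
    config: NullModelConfig | None = None,
    widespread_only_species=(),
    strict_canape: bool = False,
) -> pd.DataFrame:
    """Full CANAPE on one landscape; returns the per-cell results table.

    Columns: cell_id, SR, PE, PE_alt, RPE, p_high/p_low per statistic,
    class (str) and class_code (int).  Empty cells are masked up front and
    carry NaN p-values.
    """
    if config is None:
        config = NullModelConfig()
    table = build_branch_table(tree, presence.species)
    alt_table = build_branch_table(equalize_branches(tree), presence.species)
    inc = table.incidence(presence)
    ranges = inc.sum(axis=0)
    pe = phylo_endemism(presence, table, ranges)
    pe_alt = phylo_endemism(presence, alt_table, ranges)
    rpe_vals = np.full(pe.shape, np.nan)
    np.divide(pe, pe_alt, out=rpe_vals, where=pe_alt > 0)
    observed = {"PE": pe, "PE_alt": pe_alt, "RPE": rpe_vals}
    nulls = null_distributions(presence, tree, config, table, alt_table)
    codes = significance_codes(observed, nulls, config)
    classes = classify_canape(codes, strict_canape=strict_canape)
    classes = relabel_masked(classes, presence, widespread_only_species)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(presence.n_cells),
            "SR": presence.richness(),
            "PE": pe,
            "PE_alt": pe_alt,
            "RPE": rpe_vals,
        }
    )
    for stat in ("PE", "PE_alt", "RPE"):
        df[f"p_high_{stat}"] = codes.p_high[stat]
        df[f"p_low_{stat}"] = codes.p_low[stat]
    df["class"] = classes
    df["class_code"] = [CLASS_CODES[c] for c in classes]
    return df
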