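"""Structural-variation and duplication-dynamics statistics.

Two randomization ("scramble") tests over a map dataset:

* **Pivot points** — for each pairwise alignment, the normalized location
  at which half of the optimal cost has accumulated.  Differences piled at
  one map end pull the pivot towards that end (polar variability); a
  shuffled dataset centres around 0.5.

* **Directional bias** — align every pair three times: unrestricted, with
  run generation allowed only from left flanks, and only from right
  flanks.  E_l counts pairs whose left-to-right-restricted cost exceeds
  the optimum, E_r the mirror count, and E_n = (E_l - E_r)/(E_l + E_r)
  summarises the bias: +1 means right-to-left duplications alone already
  achieve near-optimal alignments, i.e. growth from right-side seeds.

Both tests compare the real statistic against datasets with the units of
each map shuffled.  For the bias test maps are first reduced to their
*modular structure* (runs of equal units collapsed), a standard
approximation: type transitions carry the direction signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cost_model import CostModel, MiniMap
from .map_align import Alignment, MapTables, align_cost, align_pair

__all__ = [
    "PivotResult",
    "BiasResult",
    "pivot_point",
    "shuffle_map",
    "modular_structure",
    "normalized_bias",
    "directional_bias_counts",
    "directional_bias_test",
    "structural_variation_test",
    "histogram",
]

_TOL = 1e-9  # strict-inequality tolerance for "cost higher than optimal"


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def pivot_point(a: Alignment) -> float | None:
    """Normalized location of half the alignment cost, or None if cost 0.

    Columns (matched pairs and run units, in map order) are scanned left
    to right, a run's cost spread uniformly over its units; at the first
    column where the cumulative cost reaches half the total, the mean of
    the two maps' fractional positions (consumed units / length) is
    returned.
    """
    cols = a.column_costs()
    total = sum(c for _, _, c in cols)
    if total <= _TOL:
        return None
    la, lb = len(a.map_a_units), len(a.map_b_units)
    half = total / 2.0
    acc = 0.0
    ca = cb = 0
    for da, db, c in cols:
        ca += da
        cb += db
        acc += c
        if acc >= half - _TOL:
            return (ca / la + cb / lb) / 2.0
    return 1.0  # numerically unreachable


def shuffle_map(m: MiniMap, rng: np.random.Generator) -> MiniMap:
    """Uniform random permutation of the map's units (same id, same multiset)."""
    units = list(m.units)
    perm = rng.permutation(len(units))
    return MiniMap(id=m.id, units=tuple(units[p] for p in perm))


def modular_structure(m: MiniMap) -> MiniMap:
    """Collapse each maximal run of equal adjacent units to one unit."""
    units = [m.units[0]]
    for u in m.units[1:]:
        if u != units[-1]:
            units.append(u)
    return MiniMap(id=m.id, units=tuple(units))


def histogram(values, lo: float, hi: float, bins: int):
    """Equal-width histogram over [lo, hi]; out-of-range values clamped.

    Interior bins are half-open [a, b); the last bin is closed.  Returns
    ``(edges, counts)`` with ``sum(counts) == len(values)``.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if not lo < hi:
        raise ValueError("need lo < hi")
    edges = np.linspace(lo, hi, bins + 1)
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return edges, np.zeros(bins, dtype=int)
    vals = np.clip(vals, lo, hi)
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts.astype(int)


def normalized_bias(e_l: int, e_r: int) -> float:
    """E_n = (E_l - E_r)/(E_l + E_r), defined as 0 when both counts are 0."""
    if e_l < 0 or e_r < 0:
        raise ValueError("counts must be non-negative")
    if e_l + e_r == 0:
        return 0.0
    return (e_l - e_r) / (e_l + e_r)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PivotResult:
    """Pivot points of a dataset plus scramble replicates and histograms."""

    real_pivots: list[float]
    random_pivots: list[list[float]]
    n_skipped: int
    bins: int = 20
    edges: np.ndarray = field(init=False)
    real_hist: np.ndarray = field(init=False)
    random_hist: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.edges, self.real_hist = histogram(self.real_pivots, 0.0, 1.0, self.bins)
        flat = [p for rep in self.random_pivots for p in rep]
        _, self.random_hist = histogram(flat, 0.0, 1.0, self.bins)

    @property
    def real_mean(self) -> float:
        return float(np.mean(self.real_pivots)) if self.real_pivots else float("nan")

    @property
    def random_mean(self) -> float:
        flat = [p for rep in self.random_pivots for p in rep]
        return float(np.mean(flat)) if flat else float("nan")


@dataclass
class BiasResult:
    """Directional-bias counts, E_n, and scramble-replicate E_n values."""

    E_l: int
    E_r: int
    replicate_E_n: list[float] = field(default_factory=list)
    bins: int = 20

    def __post_init__(self) -> None:
        if self.E_l < 0 or self.E_r < 0:
            raise ValueError("counts must be non-negative")

    @property
    def E_n(self) -> float:
        return normalized_bias(self.E_l, self.E_r)

    @property
    def replicate_mean(self) -> float:
        return float(np.mean(self.replicate_E_n)) if self.replicate_E_n else float("nan")

    def replicate_histogram(self):
        return histogram(self.replicate_E_n, -1.0, 1.0, self.bins)


# ---------------------------------------------------------------------------
# dataset-level tests
# ---------------------------------------------------------------------------

def _check_dataset(maps: list[MiniMap]) -> None:
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    ids = [m.id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate map ids")


def _all_pivots(maps: list[MiniMap], costs: CostModel) -> tuple[list[float], int]:
    pivots: list[float] = []
    skipped = 0
    tables = [MapTables(m.units, costs) for m in maps]
    for a in range(len(maps)):
        for b in range(a + 1, len(maps)):
            aln = align_pair(maps[a], maps[b], costs, "both",
                             tables_a=tables[a], tables_b=tables[b])
            p = pivot_point(aln)
            if p is None:
                skipped += 1
            else:
                pivots.append(p)
    return pivots, skipped


def structural_variation_test(maps: list[MiniMap], costs: CostModel,
                              iterations: int = 2, seed: int = 0,
                              bins: int = 20) -> PivotResult:
    """Pivot-point scramble test.

    Computes pivot points for all pairwise alignments of the real dataset
    and of ``iterations`` datasets with every map's units shuffled.
    Zero-cost (identical-map) pairs are skipped and counted.
    """
    _check_dataset(maps)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    real, skipped = _all_pivots(maps, costs)
    rng = np.random.default_rng(seed)
    reps: list[list[float]] = []
    for _ in range(iterations):
        shuffled = [shuffle_map(m, rng) for m in maps]
        piv, _ = _all_pivots(shuffled, costs)
        reps.append(piv)
    return PivotResult(real_pivots=real, random_pivots=reps,
                       n_skipped=skipped, bins=bins)


def _bias_counts(maps: list[MiniMap], costs: CostModel) -> tuple[int, int]:
    tables = [MapTables(m.units, costs) for m in maps]
    e_l = e_r = 0
    for a in range(len(maps)):
        for b in range(a + 1, len(maps)):
            kw = dict(tables_a=tables[a], tables_b=tables[b])
            c_both = align_cost(maps[a], maps[b], costs, "both", **kw)
            c_lr = align_cost(maps[a], maps[b], costs, "left_to_right", **kw)
            c_rl = align_cost(maps[a], maps[b], costs, "right_to_left", **kw)
            if c_lr > c_both + _TOL:
                e_l += 1
            if c_rl > c_both + _TOL:
                e_r += 1
    return e_l, e_r


def directional_bias_counts(maps: list[MiniMap], costs: CostModel) -> BiasResult:
    """E_l / E_r / E_n of a dataset (three alignment passes, no scramble)."""
    _check_dataset(maps)
    e_l, e_r = _bias_counts(maps, costs)
    return BiasResult(E_l=e_l, E_r=e_r)


def directional_bias_test(maps: list[MiniMap], costs: CostModel,
                          iterations: int = 25, seed: int = 0,
                          use_modular: bool = True, bins: int = 20) -> BiasResult:
    """Directional-bias scramble test.

    With ``use_modular`` (default, the standard speed approximation) every
    map is first reduced to its modular structure; the real counts and all
    scramble replicates are then computed on the reduced maps, keeping the
    two phases comparable.  Replicates shuffle the (reduced) units of each
    map.
    """
    _check_dataset(maps)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    work = [modular_structure(m) for m in maps] if use_modular else list(maps)
    e_l, e_r = _bias_counts(work, costs)
    rng = np.random.default_rng(seed)
    reps: list[float] = []
    for _ in range(iterations):
        shuffled = [shuffle_map(m, rng) for m in work]
        rl, rr = _bias_counts(shuffled, costs)
        reps.append(normalized_bias(rl, rr))
    return BiasResult(E_l=e_l, E_r=e_r, replicate_E_n=reps, bins=bins)
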