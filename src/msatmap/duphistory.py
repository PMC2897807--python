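"""Minimum-cost single-copy duplication histories.

A *duplication history* derives an observed unit string from one seed unit
through tandem duplications (one unit becomes two adjacent copies, cost
``c_dup``) and unit mutations (priced by the closed mutation matrix).  The
derivation is modelled as an ordered binary tree whose leaves spell the
string, with at most one effective mutation per tree node — sufficient
because the closed matrix already prices mutation chains optimally.

Interval convention: 0-based, half-open throughout.

The interval DP here is shared by the map aligner: :func:`derivation_tables`
computes, for one map, the cost of deriving every interval from every seed
type, and :func:`flank_tables` the cost of generating every interval as
fresh offspring of a flanking inherited unit.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .cost_model import CostModel

__all__ = [
    "derivation_cost",
    "derivation_events",
    "flank_generation_cost",
    "oracle_derivation_cost",
    "derivation_tables",
    "flank_tables",
    "DerivationEvent",
]

_INF = float("inf")


@dataclass(frozen=True)
class DerivationEvent:
    """One event of a reconstructed history.

    ``kind`` is ``"duplication"`` (interval split at ``split``, cost c_dup)
    or ``"mutation"`` (the node covering ``interval`` changes type
    ``from_symbol`` -> ``to_symbol`` at the closed-matrix cost).
    """

    kind: str
    interval: tuple[int, int]
    from_symbol: str | None
    to_symbol: str | None
    split: int | None
    cost: float

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "interval": list(self.interval),
            "from": self.from_symbol,
            "to": self.to_symbol,
            "split": self.split,
            "cost": self.cost,
        }


def derivation_tables(units: tuple[str, ...], costs: CostModel) -> np.ndarray:
    """Interval derivation costs for one unit string.

    Returns ``D`` with ``D[i, j, c]`` = minimal cost of deriving
    ``units[i:j)`` from a single unit of type ``alphabet[c]``, for
    ``0 <= i < j <= n``.  Recurrence: a node of type c may mutate to c'
    (closed cost) and then either *be* the single leaf (j - i == 1) or
    duplicate (c_dup) with the two copies deriving a split of the interval.
    """
    n = len(units)
    k = len(costs.alphabet)
    idx = np.array([costs.index(u) for u in units])
    dc = costs.d_M_closed
    D = np.full((n, n + 1, k), _INF)
    for i in range(n):
        D[i, i + 1, :] = dc[:, idx[i]]
    for length in range(2, n + 1):
        for i in range(n - length + 1):
            j = i + length
            # E[c'] = min over split m of c_dup + D[i,m,c'] + D[m,j,c']
            mids = np.arange(i + 1, j)
            E = (D[i, mids, :] + D[mids, j, :]).min(axis=0) + costs.c_dup
            D[i, j, :] = (dc + E[None, :]).min(axis=1)
    return D


def _check_string(s, costs: CostModel) -> tuple[str, ...]:
    units = tuple(s)
    for u in units:
        if not costs.contains(u):
            raise KeyError(f"symbol {u!r} outside alphabet")
    return units


def derivation_cost(s, c: str, costs: CostModel) -> float:
    """Minimal cost of a duplication history deriving *s* from one unit *c*."""
    units = _check_string(s, costs)
    if not units:
        raise ValueError("cannot derive an empty string")
    D = derivation_tables(units, costs)
    return float(D[0, len(units), costs.index(c)])


def derivation_events(s, c: str, costs: CostModel) -> tuple[float, list[DerivationEvent]]:
    """One optimal history for deriving *s* from *c*, with its events.

    Deterministic tie-breaks: leftmost duplication split, lexicographically
    smallest intermediate symbol.  The event costs sum exactly to the
    returned total.
    """
    units = _check_string(s, costs)
    if not units:
        raise ValueError("cannot derive an empty string")
    D = derivation_tables(units, costs)
    dc = costs.d_M_closed
    events: list[DerivationEvent] = []
    # symbols in lexicographic order for the tie-break
    lex_order = sorted(range(len(costs.alphabet)), key=lambda ci: costs.alphabet[ci])

    def node(i: int, j: int, ci: int) -> None:
        target = D[i, j, ci]
        # choose the effective node symbol c' (after optional mutation)
        best = None
        for cj in lex_order:
            if j - i == 1:
                sub = 0.0 if costs.alphabet[cj] == units[i] else _INF
            else:
                mids = np.arange(i + 1, j)
                sub = float((D[i, mids, cj] + D[mids, j, cj]).min() + costs.c_dup)
            if dc[ci, cj] + sub <= target + 1e-9:
                best = cj
                break
        assert best is not None, "traceback failed to reproduce DP cost"
        cj = best
        if cj != ci:
            events.append(
                DerivationEvent(
                    "mutation", (i, j), costs.alphabet[ci], costs.alphabet[cj], None,
                    float(dc[ci, cj]),
                )
            )
        if j - i == 1:
            return
        sub_target = target - dc[ci, cj]
        for m in range(i + 1, j):  # leftmost optimal split
            if costs.c_dup + D[i, m, cj] + D[m, j, cj] <= sub_target + 1e-9:
                events.append(
                    DerivationEvent("duplication", (i, j), costs.alphabet[cj],
                                    costs.alphabet[cj], m, costs.c_dup)
                )
                node(i, m, cj)
                node(m, j, cj)
                return
        raise AssertionError("traceback failed to find an optimal split")

    total = float(D[0, len(units), costs.index(c)])
    node(0, len(units), costs.index(c))
    return total, events


def flank_tables(units: tuple[str, ...], costs: CostModel,
                 D: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Run-generation costs from flanking units, for every interval of a map.

    ``LG[i, j]`` (defined for ``1 <= i <= j <= n``) is the cost of
    generating ``units[i:j)`` as new offspring of the persistent unit at
    position ``i - 1`` (its left flank).  ``RG[i, j]`` (``0 <= i <= j <= n-1``)
    is the mirror cost from the right flank at position ``j``.  Offspring
    are produced in blocks: each block costs one duplication of the seed
    plus the derivation of the block from a fresh copy of the seed symbol.
    Undefined entries are +inf.
    """
    n = len(units)
    if D is None:
        D = derivation_tables(units, costs)
    sidx = [costs.index(u) for u in units]
    LG = np.full((n + 1, n + 1), _INF)
    for i in range(1, n + 1):
        seed = sidx[i - 1]
        row = LG[i]
        row[i] = 0.0
        Dj = D[:, :, seed]
        for j in range(i + 1, n + 1):
            row[j] = (row[i:j] + Dj[i:j, j]).min() + costs.c_dup
    RG = np.full((n + 1, n + 1), _INF)
    for j in range(n - 1, -1, -1):
        seed = sidx[j]
        col = RG[:, j]
        col[j] = 0.0
        Di = D[:, :, seed]
        for i in range(j - 1, -1, -1):
            col[i] = (col[i + 1 : j + 1] + Di[i, i + 1 : j + 1]).min() + costs.c_dup
    return LG, RG


def flank_generation_cost(x: str, r, side: str, costs: CostModel) -> float:
    """Cost of generating run *r* as new offspring of flanking unit *x*.

    The seed's own symbol is fixed by the alignment column it occupies and
    does not mutate here.  ``side="right"`` computes the mirror by string
    reversal; the block model is reversal-invariant.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    units = _check_string(r, costs)
    if not costs.contains(x):
        raise KeyError(f"symbol {x!r} outside alphabet")
    if not units:
        return 0.0
    if side == "right":
        units = units[::-1]
    seeded = (x,) + units
    D = derivation_tables(seeded, costs)
    LG, _ = flank_tables(seeded, costs, D)
    return float(LG[1, len(seeded)])


def oracle_derivation_cost(s, c: str, costs: CostModel,
                           cost_bound: float | None = None) -> float:
    """Exact derivation cost by uniform-cost search over unit strings.

    Explores strings reachable from ``[c]`` by single-unit tandem
    duplication and single-unit mutation (raw ``d_M`` steps, so mutation
    chains arise explicitly).  Guarded to tiny instances; use the DP for
    anything larger.
    """
    units = _check_string(s, costs)
    if not costs.contains(c):
        raise KeyError(f"symbol {c!r} outside alphabet")
    if len(units) > 7 or len(costs.alphabet) > 4:
        raise ValueError(
            "oracle limited to |s| <= 7 and |alphabet| <= 4; use derivation_cost"
        )
    if cost_bound is None:
        cost_bound = (len(units) - 1) * costs.c_dup + sum(
            costs.mut_cost(c, u) for u in units
        )
    target = units
    n = len(target)
    alphabet = costs.alphabet
    start = (c,)
    best: dict[tuple[str, ...], float] = {start: 0.0}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, start)]
    while heap:
        cost, state = heapq.heappop(heap)
        if state == target:
            return cost
        if cost > best.get(state, _INF):
            continue
        for i, u in enumerate(state):
            if len(state) < n:  # duplication
                nxt = state[:i] + (u, u) + state[i + 1:]
                nc = cost + costs.c_dup
                if nc <= cost_bound + 1e-12 and nc < best.get(nxt, _INF) - 1e-15:
                    best[nxt] = nc
                    heapq.heappush(heap, (nc, nxt))
            for v in alphabet:  # mutation (raw single step)
                if v == u:
                    continue
                nxt = state[:i] + (v,) + state[i + 1:]
                nc = cost + float(costs.d_M[costs.index(u), costs.index(v)])
                if nc <= cost_bound + 1e-12 and nc < best.get(nxt, _INF) - 1e-15:
                    best[nxt] = nc
                    heapq.heappush(heap, (nc, nxt))
    raise AssertionError("target unreachable within cost bound")  # pragma: no cover
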