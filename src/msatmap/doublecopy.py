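"""Double-copy duplication heuristic.

The single-copy model lets one unit duplicate per event.  Arrays of the
form ``xyxy...`` (x != y) hint at *double-copy* events, where the pair xy
duplicated as a block.  The heuristic rewrites each such array over a
composite type X = xy (token ``@x+y``) so that one composite duplication
models one double-copy event, and extends the cost model with derived
distances:

* d(X, z)  = optimal duplication history of "xy" emerging from (or
  contracting to) z — the two are cost-identical under symmetric d_M;
* d(X, X') = cost of aligning "xy" against "x'y'";
* composite duplication costs c_dup (one event), composite indels span
  two physical units.

The transformed dataset then runs through the ordinary aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_model import COMPOSITE_MARKER, CostModel, MiniMap
from .duphistory import derivation_cost

__all__ = ["CompositeType", "find_xy_arrays", "build_composite_costs",
           "transform_dataset", "expand_composites"]


@dataclass(frozen=True)
class CompositeType:
    """A composite double-copy type X = xy."""

    x: str
    y: str

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("composite constituents must differ")

    @property
    def token(self) -> str:
        return f"{COMPOSITE_MARKER}{self.x}+{self.y}"


def find_xy_arrays(m: MiniMap) -> list[tuple[tuple[int, int], str, str]]:
    """Maximal non-overlapping ``xyxy...`` arrays, leftmost-greedy.

    An array needs at least two full xy periods (>= 4 units); odd-length
    alternations contribute their longest even prefix.  Intervals are
    0-based half-open.
    """
    units = m.units
    n = len(units)
    out = []
    i = 0
    while i + 3 < n:
        x, y = units[i], units[i + 1]
        if x == y or units[i + 2] != x or units[i + 3] != y:
            i += 1
            continue
        j = i + 4
        while j < n and units[j] == units[j - 2]:
            j += 1
        even_end = i + 2 * ((j - i) // 2)
        out.append(((i, even_end), x, y))
        i = even_end
    return out


def build_composite_costs(X: CompositeType, costs: CostModel, align_pair):
    """Distance rows for one composite type against the current alphabet.

    Returns ``{symbol: distance}`` for every symbol already in *costs*
    (original types via derivation cost, composite types via 2-unit map
    alignment).
    """
    for s in (X.x, X.y):
        if not costs.contains(s):
            raise KeyError(f"composite constituent {s!r} outside alphabet")
    row: dict[str, float] = {}
    for z in costs.alphabet:
        if z.startswith(COMPOSITE_MARKER):
            x2, y2 = z[1:].split("+")
            if (x2, y2) == (X.x, X.y):
                row[z] = 0.0
            else:
                a = MiniMap(id="_x", units=(X.x, X.y))
                b = MiniMap(id="_y", units=(x2, y2))
                row[z] = align_pair(a, b, costs, "both").total_cost
        else:
            row[z] = derivation_cost((X.x, X.y), z, costs)
    return row


def _extend_model(costs: CostModel, composites: list[CompositeType], align_pair) -> CostModel:
    alphabet = list(costs.alphabet)
    d = costs.d_M
    spans = list(costs.spans)
    cur = costs
    for X in composites:
        row = build_composite_costs(X, cur, align_pair)
        k = len(alphabet)
        nd = np.zeros((k + 1, k + 1))
        nd[:k, :k] = d
        for s, v in row.items():
            i = alphabet.index(s)
            nd[i, k] = nd[k, i] = v
        alphabet = alphabet + [X.token]
        spans = spans + [2]
        d = nd
        cur = CostModel(alphabet=tuple(alphabet), d_M=d, c_dup=costs.c_dup,
                        c_ins=costs.c_ins, c_del=costs.c_del, spans=tuple(spans))
    return cur


def transform_dataset(maps: list[MiniMap], costs: CostModel, align_pair=None):
    """Rewrite ``xyxy...`` arrays over composite types across a dataset.

    Composite types are discovered from arrays of >= 2 periods; a second
    pass also rewrites lone ``xy`` occurrences of types discovered
    elsewhere, so maps sharing the pattern stay comparable.  Returns
    ``(transformed maps, extended CostModel)``.
    """
    if align_pair is None:
        from .map_align import align_pair as align_pair
    discovered: dict[tuple[str, str], CompositeType] = {}
    for m in maps:
        for (_, x, y) in find_xy_arrays(m):
            discovered.setdefault((x, y), CompositeType(x, y))

    ext = _extend_model(costs, list(discovered.values()), align_pair) if discovered else costs

    out = []
    for m in maps:
        units = m.units
        n = len(units)
        new: list[str] = []
        i = 0
        while i < n:
            if i + 1 < n and (units[i], units[i + 1]) in discovered:
                key = (units[i], units[i + 1])
                j = i + 2
                while j < n and units[j] == units[j - 2]:
                    j += 1
                length = 2 * ((j - i) // 2)
                new.extend([discovered[key].token] * (length // 2))
                i += length
                continue
            new.append(units[i])
            i += 1
        out.append(MiniMap(id=m.id, units=tuple(new)))
    return out, ext


def expand_composites(m: MiniMap) -> MiniMap:
    """Inverse rewrite: composite tokens back to their constituent pairs."""
    units: list[str] = []
    for u in m.units:
        if u.startswith(COMPOSITE_MARKER):
            x, y = u[1:].split("+")
            units.extend([x, y])
        else:
            units.append(u)
    return MiniMap(id=m.id, units=tuple(units))
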