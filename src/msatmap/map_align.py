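"""Optimal pairwise alignment of minisatellite maps.

An alignment is a monotone matching between the two maps.  Matched pairs
are common ancestors and cost the (closed) mutation distance of their
types.  Every maximal unmatched run must then have a plausible individual
history: it is explained as

    left-generated prefix | indel middle | right-generated suffix

where the prefix/suffix are offspring of the run's nearest matched
("inherited") unit on that side — blocks of tandem duplications seeded
from the flank, priced by :mod:`msatmap.duphistory` — and the middle is
plain insertions/deletions.  Runs at map ends have a single flank.  Under
a direction restriction (``left_to_right`` / ``right_to_left``) only the
corresponding flank may generate offspring, which can only raise the
optimal cost; comparing restricted to unrestricted costs is the basis of
the directional-bias statistics in :mod:`msatmap.map_stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cost_model import CostModel, MiniMap
from .duphistory import derivation_tables, flank_tables

__all__ = [
    "MODES",
    "Alignment",
    "RunExplanation",
    "MapTables",
    "explain_run",
    "align_pair",
    "align_cost",
    "all_pairwise",
    "render_alignment",
]

MODES = ("both", "left_to_right", "right_to_left")
_INF = float("inf")


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return mode


# ---------------------------------------------------------------------------
# per-map tables
# ---------------------------------------------------------------------------

class MapTables:
    """Derivation / run-explanation tables for one map under one cost model.

    Built once per map and reused across all pairings; the run-cost tables
    additionally depend on the per-unit indel cost (c_del when the run lies
    in map A, c_ins when in map B) and on the direction mode, so those are
    cached per (mode, c_id).
    """

    def __init__(self, units: tuple[str, ...], costs: CostModel):
        self.units = tuple(units)
        self.costs = costs
        self.n = len(units)
        self.idx = np.array([costs.index(u) for u in units])
        self.D = derivation_tables(self.units, costs)
        self.LG, self.RG = flank_tables(self.units, costs, self.D)
        # prefix sums of symbol spans: indel cost of units[u:v) = c_id*(P[v]-P[u])
        self.P = np.concatenate([[0.0], np.cumsum([costs.span(u) for u in units])])
        self._cache: dict[tuple[str, float], tuple] = {}

    def run_costs(self, mode: str, c_id: float):
        """Run-explanation cost tables for this map.

        Returns ``(mid, lead, trail, total_indel)`` where ``mid[i', i]`` is
        the optimal cost of the run strictly between matched positions i'
        and i (both flanks present), ``lead[i]`` / ``trail[i']`` handle the
        single-flank leading/trailing runs, and ``total_indel`` prices the
        whole map as indels (the no-match fallback).
        """
        key = (mode, float(c_id))
        if key in self._cache:
            return self._cache[key]
        n, P, LG, RG = self.n, self.P, self.LG, self.RG
        mid = np.full((n, n), _INF)
        lead = np.full(n, _INF)
        trail = np.full(n, _INF)

        if mode == "left_to_right":
            # suffix may not be generated from the right flank
            for i in range(n):  # leading run [0, i): no left flank -> indels
                lead[i] = c_id * P[i]
            for ip in range(n):  # s = ip + 1
                s = ip + 1
                left_part = LG[s, s:] - c_id * P[s:]
                for i in range(s, n):
                    mid[ip, i] = (left_part[: i - s + 1] + c_id * P[i]).min()
                trail[ip] = (left_part + c_id * P[n]).min()
        elif mode == "right_to_left":
            for ip in range(n):  # trailing run [ip+1, n): no right flank
                s = ip + 1
                trail[ip] = c_id * (P[n] - P[s])
            for i in range(n):
                # runs ending at matched unit i: only right-flank generation
                right_part = c_id * P[: i + 1] + RG[: i + 1, i]
                lead[i] = right_part.min()
                for ip in range(i - 1):
                    s = ip + 1
                    mid[ip, i] = (right_part[s:] - c_id * P[s]).min()
                if i >= 1:
                    mid[i - 1, i] = 0.0
        else:  # both
            for i in range(n):
                # S[u] = min over v in [u, i] of c_id*P[v] + RG[v, i]
                vals = c_id * P[: i + 1] + RG[: i + 1, i]
                S = np.minimum.accumulate(vals[::-1])[::-1]
                lead[i] = S[0]
                T = S - c_id * P[: i + 1]
                for ip in range(i - 1):
                    s = ip + 1
                    mid[ip, i] = (LG[s, s : i + 1] + T[s:]).min()
                if i >= 1:
                    mid[i - 1, i] = 0.0
            for ip in range(n):
                s = ip + 1
                trail[ip] = (LG[s, s:] + c_id * (P[n] - P[s:])).min()

        total_indel = float(c_id * P[n])
        out = (mid, lead, trail, total_indel)
        self._cache[key] = out
        return out


# ---------------------------------------------------------------------------
# standalone run explanation
# ---------------------------------------------------------------------------

def explain_run(r, left_flank: str | None, right_flank: str | None,
                run_in: str, mode: str, costs: CostModel):
    """Optimal explanation of one unmatched run.

    The run splits as prefix | middle | suffix: the prefix is generated
    from *left_flank*, the suffix from *right_flank*, the middle is priced
    as indels (c_del for runs in map A, c_ins for runs in map B).  Absent
    flanks and direction restrictions force their segment empty.  Returns
    ``(cost, (u, v))`` with the split boundaries as offsets into *r*.
    """
    _check_mode(mode)
    if run_in not in ("A", "B"):
        raise ValueError("run_in must be 'A' or 'B'")
    c_id = costs.c_del if run_in == "A" else costs.c_ins
    units = tuple(r)
    for u in units:
        if not costs.contains(u):
            raise KeyError(f"symbol {u!r} outside alphabet")
    n = len(units)
    if n == 0:
        return 0.0, (0, 0)

    # prefix generation costs Lpre[u] for units[0:u) from the left flank
    Lpre = np.full(n + 1, _INF)
    Lpre[0] = 0.0
    if left_flank is not None and mode != "right_to_left":
        seeded = (left_flank,) + units
        LG, _ = flank_tables(seeded, costs)
        Lpre[1:] = LG[1, 2:]
    Rsuf = np.full(n + 1, _INF)
    Rsuf[n] = 0.0
    if right_flank is not None and mode != "left_to_right":
        seeded = units + (right_flank,)
        _, RG = flank_tables(seeded, costs)
        Rsuf[:n] = RG[:n, n]
    P = np.concatenate([[0.0], np.cumsum([costs.span(u) for u in units])])

    best, split = _INF, (0, n)
    for u in range(n + 1):
        if Lpre[u] == _INF:
            continue
        for v in range(u, n + 1):
            c = Lpre[u] + c_id * (P[v] - P[u]) + Rsuf[v]
            if c < best - 1e-12:
                best, split = c, (u, v)
    return float(best), split


# ---------------------------------------------------------------------------
# alignment containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunExplanation:
    """Explanation of one maximal unmatched run.

    ``interval`` is within the run's own map; ``u``/``v`` split it into the
    left-generated prefix [interval[0], u), indel middle [u, v) and
    right-generated suffix [v, interval[1]).  Flank positions index the
    seeding matched units (None at map ends / under restrictions).
    """

    run_in: str  # "A" or "B"
    interval: tuple[int, int]
    left_flank_pos: int | None
    right_flank_pos: int | None
    u: int
    v: int
    cost: float

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    def arcs(self) -> list[dict]:
        """Duplication arcs: seed position -> generated sub-interval."""
        out = []
        if self.u > self.interval[0]:
            out.append({"map": self.run_in, "seed": self.left_flank_pos,
                        "interval": [self.interval[0], self.u]})
        if self.v < self.interval[1]:
            out.append({"map": self.run_in, "seed": self.right_flank_pos,
                        "interval": [self.v, self.interval[1]]})
        return out


@dataclass(frozen=True)
class Alignment:
    """A scored map alignment: monotone matches plus run explanations."""

    map_a_id: str
    map_b_id: str
    map_a_units: tuple[str, ...]
    map_b_units: tuple[str, ...]
    matches: tuple[tuple[int, int, float], ...]  # (pos_a, pos_b, cost)
    runs: tuple[RunExplanation, ...]
    total_cost: float
    mode: str = "both"

    def re_price(self) -> float:
        """Sum of recorded per-column and per-run costs."""
        return float(sum(c for _, _, c in self.matches) + sum(r.cost for r in self.runs))

    def column_costs(self) -> list[tuple[int, int, float]]:
        """Alignment columns in map order as (units_of_A, units_of_B, cost).

        Matched pairs consume one unit of each map; each run unit consumes
        one unit of its own map and carries an equal share of the run's
        cost.  Between two matches the A-run precedes the B-run.
        """
        runs_after: dict[tuple[str, int], RunExplanation] = {
            (r.run_in, r.interval[0]): r for r in self.runs
        }
        cols: list[tuple[int, int, float]] = []
        pa = pb = 0

        def emit_run(run_in: str, start: int) -> None:
            nonlocal pa, pb
            r = runs_after.get((run_in, start))
            if r is None or r.length == 0:
                return
            share = r.cost / r.length
            for _ in range(r.length):
                cols.append((1, 0, share) if run_in == "A" else (0, 1, share))
            if run_in == "A":
                pa = r.interval[1]
            else:
                pb = r.interval[1]

        for i, j, c in self.matches:
            emit_run("A", pa)
            emit_run("B", pb)
            cols.append((1, 1, c))
            pa, pb = i + 1, j + 1
        emit_run("A", pa)
        emit_run("B", pb)
        return cols

    def to_json_dict(self) -> dict:
        return {
            "map_a": self.map_a_id,
            "map_b": self.map_b_id,
            "mode": self.mode,
            "total_cost": self.total_cost,
            "matches": [[i, j, c] for i, j, c in self.matches],
            "runs": [
                {
                    "run_in": r.run_in,
                    "interval": list(r.interval),
                    "left_flank_pos": r.left_flank_pos,
                    "right_flank_pos": r.right_flank_pos,
                    "split": [r.u, r.v],
                    "cost": r.cost,
                    "arcs": r.arcs(),
                }
                for r in self.runs
            ],
        }


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def _prepare(A: MiniMap, B: MiniMap, costs: CostModel,
             ta: MapTables | None, tb: MapTables | None):
    if len(A) == 0 or len(B) == 0:
        raise ValueError("cannot align empty maps")
    A.check_alphabet(costs)
    B.check_alphabet(costs)
    ta = ta if ta is not None else MapTables(A.units, costs)
    tb = tb if tb is not None else MapTables(B.units, costs)
    return ta, tb


def align_cost(A: MiniMap, B: MiniMap, costs: CostModel, mode: str = "both",
               tables_a: MapTables | None = None,
               tables_b: MapTables | None = None) -> float:
    """Total cost of the optimal alignment (fast path, no traceback)."""
    _check_mode(mode)
    ta, tb = _prepare(A, B, costs, tables_a, tables_b)
    RA, leadA, trailA, noneA = ta.run_costs(mode, costs.c_del)
    RB, leadB, trailB, noneB = tb.run_costs(mode, costs.c_ins)
    n, m = ta.n, tb.n
    mis = costs.d_M_closed[np.ix_(ta.idx, tb.idx)]

    M = np.empty((n, m))
    for i in range(n):
        base = leadA[i] + leadB
        if i > 0:
            H = (M[:i, :] + RA[:i, i, None]).min(axis=0)
            inner = (H[:, None] + RB).min(axis=0)
            M[i] = mis[i] + np.minimum(base, inner)
        else:
            M[i] = mis[i] + base
    best = float(np.minimum(noneA + noneB, (M + trailA[:, None] + trailB[None, :]).min()))
    return best


def align_pair(A: MiniMap, B: MiniMap, costs: CostModel, mode: str = "both",
               tables_a: MapTables | None = None,
               tables_b: MapTables | None = None) -> Alignment:
    """Optimal alignment with full traceback.

    Tie-breaks: among minimum-cost alignments, maximise the number of
    matches, then prefer leftmost matches; run splits take the smallest
    (u, v).  Deterministic.
    """
    _check_mode(mode)
    ta, tb = _prepare(A, B, costs, tables_a, tables_b)
    RA, leadA, trailA, noneA = ta.run_costs(mode, costs.c_del)
    RB, leadB, trailB, noneB = tb.run_costs(mode, costs.c_ins)
    n, m = ta.n, tb.n
    mis = costs.d_M_closed[np.ix_(ta.idx, tb.idx)]
    TOL = 1e-9

    # pass 1 — exact cost DP (M[i,j]: optimal cost of the prefix alignment
    # whose last match is (i,j), inclusive of that match)
    M = np.empty((n, m))
    for i in range(n):
        base = leadA[i] + leadB
        if i > 0:
            H = (M[:i, :] + RA[:i, i, None]).min(axis=0)
            inner = (H[:, None] + RB).min(axis=0)
            M[i] = mis[i] + np.minimum(base, inner)
        else:
            M[i] = mis[i] + base

    # pass 2 — among cost-optimal alignments, the max number of matches
    N = np.zeros((n, m), dtype=int)
    for i in range(n):
        for j in range(m):
            target = M[i, j] - mis[i, j]
            best = 1 if leadA[i] + leadB[j] <= target + TOL else 0
            if i > 0 and j > 0:
                P = M[:i, :j] + RA[:i, i, None] + RB[None, :j, j]
                ok = P <= target + TOL
                if ok.any():
                    best = max(best, 1 + int(N[:i, :j][ok].max()))
            N[i, j] = best

    # closing configuration: min cost, then max matches, then leftmost
    total = float(noneA + noneB)
    end_at: tuple[int, int] | None = None
    end_n = 0
    close = M + trailA[:, None] + trailB[None, :]
    cmin = float(close.min()) if n and m else _INF
    if cmin <= total + TOL:
        total = min(total, cmin)
        ok = close <= total + TOL
        end_n = int(N[ok].max())
        cand = np.argwhere(ok & (N == end_n))
        end_at = tuple(cand[0])

    matches: list[tuple[int, int, float]] = []
    cur = end_at
    want = end_n
    while cur is not None:
        i, j = cur
        matches.append((int(i), int(j), float(mis[i, j])))
        target = M[i, j] - mis[i, j]
        if want == 1 or i == 0 or j == 0:
            cur = None
        else:
            P = M[:i, :j] + RA[:i, i, None] + RB[None, :j, j]
            ok = (P <= target + TOL) & (N[:i, :j] == want - 1)
            if not ok.any():
                cur = None  # prefix starts with a leading run
            else:
                cur = tuple(np.argwhere(ok)[0])
                want -= 1
    matches.reverse()

    runs = _build_runs(ta, tb, matches, mode, costs)
    return Alignment(
        map_a_id=A.id, map_b_id=B.id,
        map_a_units=A.units, map_b_units=B.units,
        matches=tuple(matches), runs=tuple(runs),
        total_cost=total, mode=mode,
    )


def _run_split(t: MapTables, s: int, e: int, left_pos: int | None,
               right_pos: int | None, mode: str, c_id: float):
    """Optimal (cost, u, v) split of run units[s:e); smallest (u, v) tie-break."""
    if e == s:
        return 0.0, s, e
    P, LG, RG = t.P, t.LG, t.RG
    allow_left = left_pos is not None and mode != "right_to_left"
    allow_right = right_pos is not None and mode != "left_to_right"
    best, bu, bv = _INF, s, e
    for u in range(s, e + 1):
        lc = 0.0 if u == s else (LG[s, u] if allow_left else _INF)
        if lc == _INF:
            continue
        for v in range(u, e + 1):
            rc = 0.0 if v == e else (RG[v, e] if allow_right else _INF)
            if rc == _INF:
                continue
            c = lc + c_id * (P[v] - P[u]) + rc
            if c < best - 1e-12:
                best, bu, bv = c, u, v
    return float(best), bu, bv


def _build_runs(ta: MapTables, tb: MapTables,
                matches: list[tuple[int, int, float]], mode: str,
                costs: CostModel) -> list[RunExplanation]:
    runs: list[RunExplanation] = []

    def add(t: MapTables, run_in: str, c_id: float, s: int, e: int,
            lp: int | None, rp: int | None) -> None:
        if e <= s:
            return
        cost, u, v = _run_split(t, s, e, lp, rp, mode, c_id)
        runs.append(RunExplanation(run_in, (s, e), lp, rp, u, v, cost))

    if not matches:
        add(ta, "A", costs.c_del, 0, ta.n, None, None)
        add(tb, "B", costs.c_ins, 0, tb.n, None, None)
        return runs

    first_i, first_j, _ = matches[0]
    add(ta, "A", costs.c_del, 0, first_i, None, first_i)
    add(tb, "B", costs.c_ins, 0, first_j, None, first_j)
    for (i0, j0, _), (i1, j1, _) in zip(matches, matches[1:]):
        add(ta, "A", costs.c_del, i0 + 1, i1, i0, i1)
        add(tb, "B", costs.c_ins, j0 + 1, j1, j0, j1)
    last_i, last_j, _ = matches[-1]
    add(ta, "A", costs.c_del, last_i + 1, ta.n, last_i, None)
    add(tb, "B", costs.c_ins, last_j + 1, tb.n, last_j, None)
    return runs


# ---------------------------------------------------------------------------
# all-pairs distances
# ---------------------------------------------------------------------------

def all_pairwise(maps: list[MiniMap], costs: CostModel, mode: str = "both",
                 normalize: bool = False):
    """Symmetric matrix of pairwise alignment costs.

    Returns ``(labels, matrix)``.  With ``normalize`` each cost is divided
    by the summed map lengths, giving a per-unit distance.
    """
    _check_mode(mode)
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    labels = [m.id for m in maps]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate map ids in dataset")
    tables = [MapTables(m.units, costs) for m in maps]
    n = len(maps)
    dm = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            c = align_cost(maps[a], maps[b], costs, mode,
                           tables_a=tables[a], tables_b=tables[b])
            if normalize:
                c /= len(maps[a]) + len(maps[b])
            dm[a, b] = dm[b, a] = c
    return labels, dm


# ---------------------------------------------------------------------------
# text rendering
# ---------------------------------------------------------------------------

def render_alignment(a: Alignment) -> str:
    """Two-row text rendering with gap symbols plus arc records.

    Matched units share a column; a unit explained within a run of the
    other map appears opposite ``-``.  Duplication arcs are printed as
    ``seed_position -> [interval)`` records below the rows.
    """
    row_a: list[str] = []
    row_b: list[str] = []
    pa = pb = 0
    runs_after = {(r.run_in, r.interval[0]): r for r in a.runs}

    def emit(run_in: str, start: int) -> None:
        nonlocal pa, pb
        r = runs_after.get((run_in, start))
        if r is None:
            return
        for p in range(*r.interval):
            if run_in == "A":
                row_a.append(a.map_a_units[p])
                row_b.append("-")
            else:
                row_a.append("-")
                row_b.append(a.map_b_units[p])
        if run_in == "A":
            pa = r.interval[1]
        else:
            pb = r.interval[1]

    for i, j, _ in a.matches:
        emit("A", pa)
        emit("B", pb)
        row_a.append(a.map_a_units[i])
        row_b.append(a.map_b_units[j])
        pa, pb = i + 1, j + 1
    emit("A", pa)
    emit("B", pb)

    width = max((len(t) for t in row_a + row_b), default=1)
    fmt = lambda row: " ".join(t.ljust(width) for t in row).rstrip()
    lines = [
        f"# {a.map_a_id} vs {a.map_b_id} mode={a.mode} cost={a.total_cost:g}",
        f"A: {fmt(row_a)}",
        f"B: {fmt(row_b)}",
    ]
    for r in a.runs:
        for arc in r.arcs():
            lines.append(
                f"arc: {arc['map']}:{arc['seed']} -> "
                f"{arc['map']}:[{arc['interval'][0]},{arc['interval'][1]})"
            )
        if r.u < r.v:
            lines.append(f"indel: {r.run_in}:[{r.u},{r.v})")
    return "\n".join(lines) + "\n"
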