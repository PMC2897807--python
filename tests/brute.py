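"""Independent brute-force oracles for alignment verification.

Everything here is built on :func:`msatmap.oracle_derivation_cost`
(uniform-cost search over unit strings) plus exhaustive enumeration of
monotone matchings and run splits — deliberately sharing no code with the
interval DPs it checks.
"""

from itertools import combinations

from msatmap import CostModel, oracle_derivation_cost

INF = float("inf")


class BruteForce:
    """Exhaustive alignment costs for tiny maps under one cost model."""

    def __init__(self, costs: CostModel):
        self.costs = costs
        self._deriv: dict[tuple[tuple[str, ...], str], float] = {}
        self._gen: dict[tuple[str, tuple[str, ...]], float] = {}

    def derivation(self, s: tuple[str, ...], c: str) -> float:
        key = (s, c)
        if key not in self._deriv:
            self._deriv[key] = oracle_derivation_cost(s, c, self.costs)
        return self._deriv[key]

    def generation(self, x: str, r: tuple[str, ...]) -> float:
        """Min cost of generating run r as duplication blocks of seed x."""
        if not r:
            return 0.0
        key = (x, r)
        if key not in self._gen:
            best = INF
            for blk in range(1, len(r) + 1):
                c = self.costs.c_dup + self.derivation(r[:blk], x)
                c += self.generation(x, r[blk:])
                best = min(best, c)
            self._gen[key] = best
        return self._gen[key]

    def run_cost(self, r: tuple[str, ...], left: str | None, right: str | None,
                 c_id: float, mode: str) -> float:
        """Enumerate all prefix|indel|suffix splits of one unmatched run."""
        best = INF
        allow_left = left is not None and mode != "right_to_left"
        allow_right = right is not None and mode != "left_to_right"
        for u in range(len(r) + 1):
            if u > 0 and not allow_left:
                continue
            for v in range(u, len(r) + 1):
                if v < len(r) and not allow_right:
                    continue
                c = c_id * sum(self.costs.span(t) for t in r[u:v])
                if u > 0:
                    c += self.generation(left, r[:u])
                if v < len(r):
                    # mirror: suffix generated rightward = reversed leftward
                    c += self.generation(right, r[v:][::-1])
                best = min(best, c)
        return best

    def align(self, a: tuple[str, ...], b: tuple[str, ...],
              mode: str = "both") -> float:
        """Minimum cost over all monotone matchings with enumerated runs."""
        n, m = len(a), len(b)
        mut = self.costs.mut_cost
        best = (self.costs.c_del * sum(self.costs.span(t) for t in a)
                + self.costs.c_ins * sum(self.costs.span(t) for t in b))
        for k in range(1, min(n, m) + 1):
            for ia in combinations(range(n), k):
                for jb in combinations(range(m), k):
                    cost = sum(mut(a[i], b[j]) for i, j in zip(ia, jb))
                    # runs in a
                    bounds_a = [(-1, ia[0])] + [
                        (ia[t], ia[t + 1]) for t in range(k - 1)] + [(ia[-1], n)]
                    bounds_b = [(-1, jb[0])] + [
                        (jb[t], jb[t + 1]) for t in range(k - 1)] + [(jb[-1], m)]
                    for (lo, hi) in bounds_a:
                        run = a[lo + 1:hi]
                        if run:
                            cost += self.run_cost(
                                run, a[lo] if lo >= 0 else None,
                                a[hi] if hi < n else None,
                                self.costs.c_del, mode)
                    for (lo, hi) in bounds_b:
                        run = b[lo + 1:hi]
                        if run:
                            cost += self.run_cost(
                                run, b[lo] if lo >= 0 else None,
                                b[hi] if hi < m else None,
                                self.costs.c_ins, mode)
                    if cost < best:
                        best = cost
        return best


def all_strings(alphabet: tuple[str, ...], max_len: int):
    """All non-empty strings over *alphabet* up to *max_len*."""
    out = [(s,) for s in alphabet]
    frontier = list(out)
    for _ in range(max_len - 1):
        frontier = [s + (t,) for s in frontier for t in alphabet]
        out.extend(frontier)
    return out
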