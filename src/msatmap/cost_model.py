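"""Evolution-model costs for minisatellite maps.

A minisatellite map is a sequence of *unit symbols*, one per tandem-repeat
copy, with the symbol encoding the repeat's variant type.  The evolution
model prices four operations:

* unit mutation  -- change of one unit type into another, cost ``d_M(x, y)``;
* duplication    -- a unit gains an adjacent tandem copy, cost ``c_dup``;
* insertion      -- a foreign unit appears, cost ``c_ins``;
* deletion       -- a unit is lost, cost ``c_del``.

``d_M`` is symmetric with zero diagonal.  All downstream dynamic programs
use its min-plus (shortest-path) closure so that a *chain* of mutations
x -> y -> z is priced optimally even when the user matrix is not metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CostModel",
    "MiniMap",
    "validate_symbol",
    "close_mutation_costs",
    "default_cost_model",
    "chain_cost_model",
    "parse_cost_file",
    "write_cost_file",
]

#: token prefix reserved for composite (double-copy) types
COMPOSITE_MARKER = "@"


class CostFileError(ValueError):
    """Raised for malformed or invalid cost files."""


def validate_symbol(token: str) -> str:
    """Check that *token* is a legal unit symbol and return it.

    Symbols are opaque, possibly multi-character tokens (e.g. the MSY1
    variant codes ``1a``, ``4a``).  Whitespace is forbidden because the
    on-disk formats are whitespace-delimited; a leading ``@`` is reserved
    for composite double-copy types.
    """
    if not isinstance(token, str) or not token:
        raise ValueError(f"unit symbol must be a non-empty string, got {token!r}")
    if any(ch.isspace() for ch in token):
        raise ValueError(f"unit symbol may not contain whitespace: {token!r}")
    return token


def close_mutation_costs(d_M: np.ndarray) -> np.ndarray:
    """Min-plus (all-pairs shortest path) closure of a mutation-cost matrix.

    The closure prices a series of unit mutations as one effective cost;
    it is idempotent and never increases any entry.
    """
    d = np.asarray(d_M, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"mutation-cost matrix must be square, got shape {d.shape}")
    closed = d.copy()
    # Floyd-Warshall; explicit so that legitimate zero-cost off-diagonal
    # entries are kept as real (free) edges.
    for k in range(closed.shape[0]):
        np.minimum(closed, closed[:, k : k + 1] + closed[k : k + 1, :], out=closed)
    return closed


@dataclass(frozen=True)
class CostModel:
    """Unit alphabet plus operation costs.

    Parameters
    ----------
    alphabet:
        Ordered tuple of unit symbols.
    d_M:
        Square symmetric mutation-cost matrix indexed by ``alphabet``.
    c_dup, c_ins, c_del:
        Positive event costs for duplication / insertion / deletion.
    spans:
        Physical units spanned by each symbol (1 for ordinary types, 2 for
        composite double-copy types); scales the indel cost per symbol.
    """

    alphabet: tuple[str, ...]
    d_M: np.ndarray
    c_dup: float
    c_ins: float
    c_del: float
    spans: tuple[int, ...] = ()
    d_M_closed: np.ndarray = field(init=False, repr=False)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        alphabet = tuple(validate_symbol(s) for s in self.alphabet)
        if not alphabet:
            raise ValueError("alphabet must be non-empty")
        if len(set(alphabet)) != len(alphabet):
            raise ValueError("alphabet contains duplicate symbols")
        object.__setattr__(self, "alphabet", alphabet)
        d = np.asarray(self.d_M, dtype=float)
        k = len(alphabet)
        if d.shape != (k, k):
            raise ValueError(f"d_M shape {d.shape} does not match alphabet size {k}")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("mutation-cost matrix must be symmetric")
        if np.any(d < 0):
            raise ValueError("mutation costs must be non-negative")
        if np.any(np.diag(d) != 0):
            raise ValueError("mutation-cost matrix must have a zero diagonal")
        for name in ("c_dup", "c_ins", "c_del"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        spans = self.spans or tuple([1] * k)
        if len(spans) != k or any(s < 1 for s in spans):
            raise ValueError("spans must give a positive span per symbol")
        object.__setattr__(self, "spans", tuple(int(s) for s in spans))
        object.__setattr__(self, "d_M", d)
        object.__setattr__(self, "d_M_closed", close_mutation_costs(d))
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(alphabet)})

    # -- lookups ---------------------------------------------------------
    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in alphabet {self.alphabet}") from None

    def mut_cost(self, x: str, y: str) -> float:
        """Effective (closed) mutation cost between two unit types."""
        return float(self.d_M_closed[self.index(x), self.index(y)])

    def span(self, symbol: str) -> int:
        return self.spans[self.index(symbol)]

    def indel_cost(self, symbol: str, c_id: float) -> float:
        """Indel cost of one symbol under per-unit cost *c_id* (span-scaled)."""
        return c_id * self.span(symbol)

    def contains(self, symbol: str) -> bool:
        return symbol in self._index


@dataclass(frozen=True)
class MiniMap:
    """An identified minisatellite map: a non-empty sequence of unit symbols."""

    id: str
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("map id must be non-empty")
        units = tuple(validate_symbol(u) for u in self.units)
        if not units:
            raise ValueError(f"map {self.id!r} has no units")
        object.__setattr__(self, "units", units)

    def __len__(self) -> int:
        return len(self.units)

    def check_alphabet(self, costs: CostModel) -> None:
        for u in self.units:
            if not costs.contains(u):
                raise KeyError(f"map {self.id!r} contains symbol {u!r} outside the alphabet")


def default_cost_model(alphabet) -> CostModel:
    """Uniform model: every distinct-type mutation costs 1.

    Defaults c_dup=0.5, c_ins=c_del=1.5 respect the standard ordering
    duplication < mutation <= indel, under which tandem expansion is the
    preferred explanation of copy-number change.
    """
    alphabet = tuple(alphabet)
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    k = len(alphabet)
    d = np.ones((k, k)) - np.eye(k)
    return CostModel(alphabet=alphabet, d_M=d, c_dup=0.5, c_ins=1.5, c_del=1.5)


def chain_cost_model(alphabet, step: float = 1.0) -> CostModel:
    """Chain-metric model: d_M(i, j) = step * |i - j| in alphabet order.

    Models variant types arranged along a mutational pathway (each type one
    point mutation away from its neighbours), so mutating across several
    types costs proportionally more.  This gradient is what makes the
    direction of run growth identifiable in alignments.  Indels are priced
    at 2.0, strictly above duplication plus a single mutation step
    (0.5 + 1.0): a copy that diverged by one step is a cheaper explanation
    than an unrelated insertion, which is the premise of reading direction
    from run content.  (If c_dup + step >= c_ind, every one-step offspring
    ties with a direction-free indel and no bias is detectable.)
    """
    alphabet = tuple(alphabet)
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    idx = np.arange(len(alphabet))
    d = step * np.abs(idx[:, None] - idx[None, :]).astype(float)
    return CostModel(alphabet=alphabet, d_M=d, c_dup=0.5, c_ins=2.0, c_del=2.0)


# ---------------------------------------------------------------------------
# cost file (TSV)
# ---------------------------------------------------------------------------

def parse_cost_file(text: str) -> CostModel:
    """Parse the TSV cost-file format.

    Line 1: ``units<TAB>s1<TAB>...<TAB>sk``; lines 2..k+1: ``si<TAB>v1...vk``;
    then ``duplication<TAB>x``, ``insertion<TAB>x``, ``deletion<TAB>x``.
    ``#`` lines are comments.
    """
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append((lineno, line.split("\t")))

    if not rows:
        raise CostFileError("empty cost file")
    lineno, header = rows[0]
    if header[0] != "units" or len(header) < 2:
        raise CostFileError(f"line {lineno}: expected header 'units<TAB>s1...', got {header!r}")
    alphabet = tuple(header[1:])
    k = len(alphabet)

    matrix_rows = rows[1 : 1 + k]
    if len(matrix_rows) < k:
        raise CostFileError(f"expected {k} matrix rows, found {len(matrix_rows)}")
    d = np.zeros((k, k))
    for i, (lineno, fields) in enumerate(matrix_rows):
        if len(fields) != k + 1:
            raise CostFileError(f"line {lineno}: expected {k + 1} fields, got {len(fields)}")
        if fields[0] != alphabet[i]:
            raise CostFileError(
                f"line {lineno}: row label {fields[0]!r} does not match header symbol {alphabet[i]!r}"
            )
        try:
            d[i] = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise CostFileError(f"line {lineno}: non-numeric entry ({exc})") from None

    tail = {}
    for lineno, fields in rows[1 + k :]:
        if len(fields) != 2 or fields[0] not in ("duplication", "insertion", "deletion"):
            raise CostFileError(f"line {lineno}: unexpected line {fields!r}")
        try:
            tail[fields[0]] = float(fields[1])
        except ValueError:
            raise CostFileError(f"line {lineno}: non-numeric cost {fields[1]!r}") from None
    missing = {"duplication", "insertion", "deletion"} - tail.keys()
    if missing:
        raise CostFileError(f"missing cost line(s): {', '.join(sorted(missing))}")

    try:
        return CostModel(
            alphabet=alphabet,
            d_M=d,
            c_dup=tail["duplication"],
            c_ins=tail["insertion"],
            c_del=tail["deletion"],
        )
    except ValueError as exc:
        raise CostFileError(str(exc)) from None


def write_cost_file(costs: CostModel) -> str:
    """Serialize a CostModel in the TSV cost-file format (round-trips)."""
    lines = ["units\t" + "\t".join(costs.alphabet)]
    for i, s in enumerate(costs.alphabet):
        lines.append(s + "\t" + "\t".join(repr(float(v)) for v in costs.d_M[i]))
    lines.append(f"duplication\t{costs.c_dup!r}")
    lines.append(f"insertion\t{costs.c_ins!r}")
    lines.append(f"deletion\t{costs.c_del!r}")
    return "\n".join(lines) + "\n"
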