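"""BIONJ tree construction from pairwise map distances.

BIONJ is neighbor joining with a variance-weighted reduction step: after
joining taxa i and j into u, the new distances are

    d(u,k) = lam*d(i,k) + (1-lam)*d(j,k) - lam*b_i - (1-lam)*b_j
    v(u,k) = lam*v(i,k) + (1-lam)*v(j,k) - lam*(1-lam)*v(i,j)

with lam chosen to minimise the variance of the new entries (clamped to
[0, 1]) and variances initialised to the distances.  Pair selection uses
the standard NJ Q-criterion and branch lengths the NJ two-point formulas.
On additive matrices this recovers the generating topology exactly.

Trees are unrooted; dendropy provides the container, Newick writer and
topology comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["DistanceMatrix", "bionj_tree", "write_newick"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with a zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        d = np.asarray(self.d, dtype=float)
        n = len(labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.labels)


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    """Clamp negative branch lengths to 0, moving the deficit to the sibling."""
    if bi < 0:
        bj += bi
        bi = 0.0
    if bj < 0:
        bi += bj
        bj = 0.0
    return max(bi, 0.0), max(bj, 0.0)


def bionj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Agglomerate a BIONJ tree from *dm*; returns an unrooted dendropy Tree."""
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    ns = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for taxon in ns:
        leaf = dendropy.Node(taxon=taxon)
        nodes.append(leaf)

    if n == 2:
        half = float(dm.d[0, 1]) / 2.0
        for leaf in nodes:
            tree.seed_node.add_child(leaf)
            leaf.edge.length = half
        tree.is_rooted = False
        return tree

    D = dm.d.copy()
    V = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        S = sub.sum(axis=1)
        Q = (r - 2) * sub - S[:, None] - S[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = D[i, j]
        bi = dij / 2.0 + (S[ai] - S[aj]) / (2.0 * (r - 2))
        bj = dij - bi
        bi, bj = _clamp_pair(bi, bj)

        vij = V[i, j]
        others = [a for a in active if a != i and a != j]
        if vij > 1e-12:
            lam = 0.5 + (V[j, others].sum() - V[i, others].sum()) / (2.0 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = bi
        parent.add_child(nodes[j])
        nodes[j].edge.length = bj

        ok = np.array(others)
        Dnew = lam * D[i, ok] + (1 - lam) * D[j, ok] - lam * bi - (1 - lam) * bj
        Vnew = lam * V[i, ok] + (1 - lam) * V[j, ok] - lam * (1 - lam) * vij
        D[i, ok] = D[ok, i] = np.maximum(Dnew, 0.0)
        V[i, ok] = V[ok, i] = np.maximum(Vnew, 0.0)
        nodes[i] = parent
        active.remove(j)

    # final star join of the 3 remaining clusters (unrooted)
    a, b, c = active
    ba = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    bb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    bc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    for node, length in ((nodes[a], ba), (nodes[b], bb), (nodes[c], bc)):
        tree.seed_node.add_child(node)
        node.edge.length = max(float(length), 0.0)
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize as Newick with branch lengths, ';'-terminated.

    Labels containing Newick-reserved characters come out single-quoted
    (dendropy's writer handles the quoting rules).
    """
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          preserve_spaces=True).strip()
    if not text.endswith(";"):
        text += ";"
    return text + "\n"
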