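"""Synthetic minisatellite map evolution.

Independent lineages evolve from a shared root map by unit-level events:

* **duplication** — an insertion point (gap) is chosen and a tandem copy
  of one neighbour is inserted; with probability ``beta`` the *right*
  neighbour is copied (the copy grows the array leftward from its seed,
  i.e. right-to-left origin), otherwise the left neighbour (left-to-right).
  With probability ``p_copy_divergence`` the fresh copy immediately
  diverges by one mutation step — tandem copies arise from error-prone
  mechanisms (slippage, unequal exchange with conversion), and it is this
  divergence co-located with growth that leaves a readable direction
  gradient in the map; identical copies are direction-neutral under the
  alignment model.
* **mutation** — one unit changes type; its position is sampled with
  weight ``(rank)^mut_end_bias`` so values > 1 pile mutations towards the
  3' (right) end; by default the target type is an *adjacent* type in
  alphabet order (one point-mutation step along the variant pathway),
  matching :func:`msatmap.cost_model.chain_cost_model`.
* **indel** — a uniform unit is inserted at a uniform gap, or a uniform
  unit deleted (never emptying the map).

Direction bias (``beta``) and end-localised mutation (``mut_end_bias``)
are the two signals the dataset-level scramble tests are designed to
recover; the generator exists to close that loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_model import MiniMap

__all__ = ["SimParams", "evolve_map", "simulate_dataset"]

#: default alphabet: eight variant types along a mutational pathway
#: (real loci carry a handful of types; MSY1 for instance has eight)
DEFAULT_ALPHABET = tuple("abcdefgh")
#: default root: a blocky 42-unit map, as produced by ancestral tandem
#: expansion (real minisatellite arrays run to dozens of units; blocks of
#: three give a modular-structure length in the range reported for real
#: loci).  Block order interleaves the type chain so that adjacent blocks
#: sit >= 2 mutation steps apart, as in real maps where neighbouring
#: blocks are not consecutive variants; one-step offspring of a block
#: seed then cannot be confused with the neighbouring block's type.  The
#: layout is palindromic so neither map end is statistically special.
DEFAULT_ROOT = (tuple(s for s in "adgbehc" for _ in range(3))
                + tuple(s for s in "cheb gda".replace(" ", "") for _ in range(3)))


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated lineage (all rates per event draw)."""

    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    root: tuple[str, ...] = DEFAULT_ROOT
    n_events: int = 30
    p_dup: float = 0.7
    p_mut: float = 0.2
    p_indel: float = 0.1
    beta: float = 0.5
    p_copy_divergence: float = 0.15
    mut_end_bias: float = 1.0
    mut_local: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.root:
            raise ValueError("root map must be non-empty")
        if any(u not in self.alphabet for u in self.root):
            raise ValueError("root contains symbols outside the alphabet")
        probs = (self.p_dup, self.p_mut, self.p_indel)
        if any(not 0.0 <= p <= 1.0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("event probabilities must lie in [0,1] and sum to 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 <= self.p_copy_divergence <= 1.0:
            raise ValueError("p_copy_divergence must lie in [0, 1]")
        if self.mut_end_bias < 1.0:
            raise ValueError("mut_end_bias must be >= 1")
        if self.n_events < 1:
            raise ValueError("n_events must be positive")


def _mut_position(n: int, bias: float, rng: np.random.Generator) -> int:
    # weight ∝ rank^(bias-1): bias=1 is exactly uniform, larger values skew
    # towards the 3' (right) end
    w = np.arange(1, n + 1, dtype=float) ** (bias - 1.0)
    return int(rng.choice(n, p=w / w.sum()))


def _step(symbol: str, alphabet: tuple[str, ...], rng: np.random.Generator) -> str:
    """One mutation step to an adjacent type in alphabet order."""
    cur = alphabet.index(symbol)
    steps = [s for s in (cur - 1, cur + 1) if 0 <= s < len(alphabet)]
    return alphabet[steps[int(rng.integers(len(steps)))]]


def evolve_map(params: SimParams, map_id: str = "sim",
               rng: np.random.Generator | None = None,
               log: list | None = None) -> MiniMap:
    """Evolve one lineage from the root; deterministic under the seed.

    Pass a list as *log* to record one dict per event (kind, position,
    and for duplications the origin side: "right" or "left").
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    units = list(params.root)
    alphabet = params.alphabet
    for _ in range(params.n_events):
        kind = rng.choice(3, p=[params.p_dup, params.p_mut, params.p_indel])
        if kind == 0:  # duplication
            if len(units) == 1:
                units.insert(0, units[0])
                if log is not None:
                    log.append({"kind": "duplication", "gap": 0, "origin": "right"})
            else:
                # choose an internal insertion point, then the seed neighbour:
                # with prob. beta the right neighbour is copied into the gap
                # (the array grows leftward from its seed, right-to-left
                # origin), else the left neighbour (left-to-right origin).
                # The two differ exactly at type boundaries, which is where
                # direction leaves a trace.
                gap = int(rng.integers(1, len(units)))
                right_origin = rng.random() < params.beta
                src = gap if right_origin else gap - 1
                copy = units[src]
                if rng.random() < params.p_copy_divergence:
                    copy = _step(copy, alphabet, rng)
                units.insert(gap, copy)
                if log is not None:
                    log.append({"kind": "duplication", "gap": gap,
                                "origin": "right" if right_origin else "left"})
        elif kind == 1:  # mutation
            pos = _mut_position(len(units), params.mut_end_bias, rng)
            if params.mut_local:
                units[pos] = _step(units[pos], alphabet, rng)
            else:
                others = [s for s in alphabet if s != units[pos]]
                units[pos] = others[int(rng.integers(len(others)))]
            if log is not None:
                log.append({"kind": "mutation", "position": pos})
        else:  # indel
            if len(units) > 1 and rng.random() < 0.5:
                pos = int(rng.integers(len(units)))
                del units[pos]
                if log is not None:
                    log.append({"kind": "deletion", "position": pos})
            else:
                pos = int(rng.integers(0, len(units) + 1))
                units.insert(pos, alphabet[int(rng.integers(len(alphabet)))])
                if log is not None:
                    log.append({"kind": "insertion", "position": pos})
    return MiniMap(id=map_id, units=tuple(units))


def simulate_dataset(params: SimParams, n_maps: int) -> list[MiniMap]:
    """Simulate *n_maps* independent lineages from the shared root.

    Per-lineage generators are spawned deterministically from the master
    seed, so identical parameters reproduce the dataset bit for bit.
    """
    if n_maps < 2:
        raise ValueError("n_maps must be >= 2")
    maps = []
    for i in range(n_maps):
        rng = np.random.default_rng([int(params.seed) % (2**31), i])
        maps.append(evolve_map(params, map_id=f"sim_{i:03d}", rng=rng))
    return maps
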