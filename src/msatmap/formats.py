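"""On-disk formats: map multi-FASTA dialect and PHYLIP distance matrices.

Maps travel in a FASTA dialect whose record bodies are whitespace-
separated unit tokens (required for multi-character variant codes such as
the MSY1 set ``0 1 1a 2 3 3a 4 4a``).  A compact fallback treats a
single-word body as one symbol per character, for published map strings
like ``aabbc``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_model import MiniMap
from .phylogeny import DistanceMatrix

__all__ = ["Dataset", "read_maps_fasta", "write_maps_fasta",
           "write_distance_matrix", "read_distance_matrix"]


class MapFormatError(ValueError):
    """Raised for malformed map FASTA input."""


@dataclass(frozen=True)
class Dataset:
    """Maps read from one source plus the alphabet observed in them."""

    maps: tuple[MiniMap, ...]
    alphabet: tuple[str, ...]
    source: str = "<memory>"


def read_maps_fasta(text: str, source: str = "<memory>") -> Dataset:
    """Parse the map FASTA dialect.

    Body lines are split on whitespace and concatenated across wrapped
    lines; if a record body is a single run of characters each character
    becomes one unit (single-character fallback).  Duplicate ids, empty
    bodies and headerless input are errors.
    """
    records: list[tuple[str, list[str]]] = []
    current: tuple[str, list[str]] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            head = line[1:].strip()
            if not head:
                raise MapFormatError("record with empty id")
            map_id = head.split()[0]
            current = (map_id, [])
            records.append(current)
        else:
            if current is None:
                raise MapFormatError("sequence data before the first '>' header")
            current[1].extend(line.split())
    if not records:
        raise MapFormatError("no records found")

    maps: list[MiniMap] = []
    seen: set[str] = set()
    for map_id, tokens in records:
        if map_id in seen:
            raise MapFormatError(f"duplicate map id {map_id!r}")
        seen.add(map_id)
        if not tokens:
            raise MapFormatError(f"record {map_id!r} has an empty body")
        if len(tokens) == 1 and len(tokens[0]) > 1 and tokens[0].isalpha():
            # single-character fallback dialect for compact published map
            # strings ("aabbc"); bodies with digits (MSY1-style codes such
            # as "3a") stay one token per whitespace-separated word
            tokens = list(tokens[0])
        maps.append(MiniMap(id=map_id, units=tuple(tokens)))

    alphabet = tuple(sorted({u for m in maps for u in m.units}))
    return Dataset(maps=tuple(maps), alphabet=alphabet, source=source)


def write_maps_fasta(maps) -> str:
    lines = []
    for m in maps:
        lines.append(f">{m.id}")
        lines.append(" ".join(m.units))
    return "\n".join(lines) + "\n"


def write_distance_matrix(dm: DistanceMatrix, long_labels: bool = False) -> str:
    """PHYLIP square format; labels padded to 10 characters.

    Labels longer than 10 characters are truncated unless *long_labels*
    (relaxed dialect); truncation collisions are an error.
    """
    labels = []
    for lab in dm.labels:
        out = lab if long_labels else lab[:10]
        labels.append(out)
    if len(set(labels)) != len(labels):
        raise ValueError(
            "label collision after 10-character truncation; use the relaxed dialect"
        )
    width = max(10, max(len(x) for x in labels))
    lines = [f" {len(labels)}"]
    for lab, row in zip(labels, dm.d):
        lines.append(lab.ljust(width) + "  " + "  ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def read_distance_matrix(text: str) -> DistanceMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].strip())
    labels = []
    rows = []
    for ln in lines[1 : n + 1]:
        fields = ln.split()
        labels.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    d = np.array(rows)
    # tolerate asymmetry at the printed precision
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(labels), d=d)
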