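"""NCBI mitochondrial genetic code tables and codon-level queries.

Metazoan mitochondrial genomes use seven variants of the genetic code
(NCBI translation tables 2, 4, 5, 9, 13, 14 and 24).  The variants differ
mainly in which codons terminate translation and which may initiate it,
which is exactly the information the boundary predictor needs.  Table
contents are vendored as static JSON transcribed from the NCBI registry so
that everything works offline and reproducibly.

Codons are handled in the DNA alphabet (T, not U) and uppercased on input.
Codons containing ambiguity characters (N, ...) yield the distinguished
:data:`UNKNOWN` outcome from :func:`translate_codon` and are treated as
neither start nor stop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import product
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "STOP",
    "UNKNOWN",
    "GeneticCode",
    "get_table",
    "registered_tables",
    "is_full_stop",
    "translate_codon",
]

#: Sentinel amino-acid value for termination codons.
STOP = "*"

#: Sentinel returned for codons containing non-ACGT characters.
UNKNOWN = "?"

_DNA = "TCAG"

#: The 64 codons in NCBI registry order (first base slowest, third fastest).
CODON_ORDER: tuple[str, ...] = tuple(
    b1 + b2 + b3 for b1, b2, b3 in product(_DNA, _DNA, _DNA)
)


class UnknownTableError(KeyError):
    """Raised when a translation table id is not in the registry."""

    def __init__(self, table_id: int):
        super().__init__(table_id)
        self.table_id = table_id

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"unknown NCBI translation table id {self.table_id!r}; "
            f"registered tables: {sorted(registered_tables())}"
        )


@dataclass(frozen=True)
class GeneticCode:
    """One NCBI translation table.

    Attributes
    ----------
    table_id:
        NCBI table number (e.g. 2 for vertebrate mitochondria).
    name:
        Human-readable table name from the NCBI registry.
    codon_to_aa:
        Total map from the 64 DNA codons to a one-letter amino acid or
        :data:`STOP`.
    canonical_starts:
        Initiation codons defined by the table.  Always codons that encode
        an amino acid, never stops.
    canonical_stops:
        Exactly the codons that map to :data:`STOP`.
    """

    table_id: int
    name: str
    codon_to_aa: Mapping[str, str]
    canonical_starts: frozenset[str]
    canonical_stops: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODON_ORDER):
            raise ValueError(f"table {self.table_id}: codon map must cover all 64 codons")
        stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)
        if not self.canonical_starts:
            raise ValueError(f"table {self.table_id}: no start codons")
        bad = self.canonical_starts & stops
        if bad:
            raise ValueError(f"table {self.table_id}: start codons map to STOP: {sorted(bad)}")
        object.__setattr__(self, "canonical_stops", stops)

    def translate(self, codon: str) -> str:
        """Translate one codon; :data:`UNKNOWN` for ambiguity characters."""
        return translate_codon(codon, self)


def _normalize(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return codon


def translate_codon(codon: str, code: GeneticCode) -> str:
    """Amino acid (or STOP) for ``codon``; UNKNOWN if it has non-ACGT characters."""
    codon = _normalize(codon)
    return code.codon_to_aa.get(codon, UNKNOWN)


def is_full_stop(codon: str, code: GeneticCode) -> bool:
    """True iff ``codon`` is a complete termination codon of ``code``.

    Ambiguous codons (containing N etc.) are never stops.  A codon with
    characters outside ACGTN raises ``ValueError``.
    """
    codon = _normalize(codon)
    if any(b not in "ACGTN" for b in codon):
        raise ValueError(f"codon contains illegal characters: {codon!r}")
    return codon in code.canonical_stops


@lru_cache(maxsize=None)
def _registry() -> Mapping[int, GeneticCode]:
    raw = json.loads(
        resources.files("mitobound.data").joinpath("genetic_codes.json").read_text()
    )
    tables: dict[int, GeneticCode] = {}
    for tid_str, entry in raw["tables"].items():
        aa = entry["aa"]
        if len(aa) != 64:
            raise ValueError(f"table {tid_str}: amino-acid string must have length 64")
        codon_to_aa = MappingProxyType(dict(zip(CODON_ORDER, aa)))
        tid = int(tid_str)
        tables[tid] = GeneticCode(
            table_id=tid,
            name=entry["name"],
            codon_to_aa=codon_to_aa,
            canonical_starts=frozenset(entry["starts"]),
        )
    return MappingProxyType(tables)


def registered_tables() -> frozenset[int]:
    """Ids of all vendored translation tables."""
    return frozenset(_registry())


def get_table(table_id: int) -> GeneticCode:
    """Look up a translation table by NCBI number.

    Raises
    ------
    UnknownTableError
        If ``table_id`` is not vendored.
    """
    try:
        return _registry()[int(table_id)]
    except (KeyError, ValueError) as exc:
        raise UnknownTableError(table_id) from exc
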