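"""Empirical parameter tables for boundary scoring.

Two kinds of statistics are learned from reference annotations, always
keyed by (genetic code table, gene), because codon usage and gene lengths
vary strongly between genes and between taxa using different code variants:

* codon usage (the phi source): how often each codon is annotated as a
  start codon, a stop codon (including the incomplete stops TA and T,
  stored under the pseudo-codons ``TA-`` and ``T--``), or an internal
  codon.  Start codons with frequency < 0.01 are discarded as likely
  annotation errors, and codons seen internally with frequency >= 0.001
  are disqualified as stop codons.
* gene length distributions (the lambda source): the multiset of reference
  CDS lengths in nucleotides, one value per species, from which an
  empirical two-sided p-value for a candidate gene length is computed as

      lambda(l) = 2 * min(L_le, L_ge) / (L_le + L_ge)

  where ``L_le``/``L_ge`` count species whose gene is at most/at least
  ``l`` nucleotides long (ties count on both sides).

Lengths are kept in nucleotides rather than codons: reference CDS lengths
are frequently not multiples of 3 because of incomplete stop codons, so
nucleotides is the only unit in which reference and candidate lengths are
commensurable.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .annotation_io import Feature, Genome, extract_feature_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "INCOMPLETE_TA",
    "INCOMPLETE_T",
    "RawCounts",
    "UsageEntry",
    "CodonUsageTable",
    "LengthDistribution",
    "ReferenceStatistics",
    "count_codons",
    "build_usage_table",
    "build_length_distribution",
    "build_reference_statistics",
    "lambda_pvalue",
]

#: Pseudo-codon keys for incomplete stop codons completed by polyadenylation.
INCOMPLETE_TA = "TA-"
INCOMPLETE_T = "T--"

STATS_SCHEMA_VERSION = 1

Key = tuple[int, str]


@dataclass
class RawCounts:
    """Raw per-(code table, gene) codon tallies from a reference set."""

    start: dict[Key, Counter] = field(default_factory=lambda: defaultdict(Counter))
    stop: dict[Key, Counter] = field(default_factory=lambda: defaultdict(Counter))
    internal: dict[Key, Counter] = field(default_factory=lambda: defaultdict(Counter))

    def keys(self) -> set[Key]:
        return set(self.start) | set(self.stop) | set(self.internal)


@dataclass(frozen=True)
class UsageEntry:
    """Filtered codon frequencies for one (code table, gene)."""

    start_freq: Mapping[str, float]
    stop_freq: Mapping[str, float]
    internal_freq: Mapping[str, float]
    n_start: int
    n_stop: int
    n_internal: int


class CodonUsageTable:
    """Per-(code table, gene) start/stop/internal codon frequencies."""

    def __init__(self, entries: Mapping[Key, UsageEntry]):
        self._entries = dict(entries)

    def __contains__(self, key: Key) -> bool:
        return key in self._entries

    def keys(self) -> set[Key]:
        return set(self._entries)

    def get(self, code_table: int, gene: str) -> UsageEntry:
        try:
            return self._entries[(code_table, gene)]
        except KeyError:
            raise KeyError(
                f"no codon usage statistics for gene {gene!r} under code table {code_table}"
            ) from None


class LengthDistribution:
    """Per-(code table, gene) sorted multisets of reference CDS lengths (nt)."""

    def __init__(self, lengths: Mapping[Key, Iterable[int]]):
        self._lengths: dict[Key, np.ndarray] = {}
        for key, vals in lengths.items():
            arr = np.sort(np.asarray(list(vals), dtype=np.int64))
            if arr.size == 0:
                continue
            if arr[0] < 3:
                raise ValueError(f"{key}: reference CDS lengths must be >= 3 nt")
            self._lengths[key] = arr

    def __contains__(self, key: Key) -> bool:
        return key in self._lengths

    def keys(self) -> set[Key]:
        return set(self._lengths)

    def values(self, code_table: int, gene: str) -> np.ndarray:
        try:
            return self._lengths[(code_table, gene)]
        except KeyError:
            raise KeyError(
                f"no length distribution for gene {gene!r} under code table {code_table}"
            ) from None

    def pvalue(self, code_table: int, gene: str, length: int) -> float:
        """Empirical two-sided p-value of observing a gene of ``length`` nt."""
        arr = self.values(code_table, gene)
        n_le = int(np.searchsorted(arr, length, side="right"))
        n_ge = int(arr.size - np.searchsorted(arr, length, side="left"))
        denom = n_le + n_ge
        if denom == 0:  # unreachable for non-empty arr, kept for safety
            return 0.0
        return 2.0 * min(n_le, n_ge) / denom


def lambda_pvalue(dist: LengthDistribution, code_table: int, gene: str, length: int) -> float:
    """Functional alias for :meth:`LengthDistribution.pvalue`."""
    return dist.pvalue(code_table, gene, length)


def _is_unambiguous(codon: str) -> bool:
    return all(b in "ACGT" for b in codon)


def count_codons(
    features: Iterable[Feature], genomes: Iterable[Genome]
) -> RawCounts:
    """Tally start, stop and internal codons of reference CDS features.

    The first codon of each CDS counts as a start; the trailing 3, 2 or 1
    nucleotides count as a full or incomplete (``TA-``/``T--``) stop
    depending on the CDS length modulo 3; every complete codon strictly
    between start and stop counts as internal.  Minus-strand CDS are read
    from the reverse complement.  Codons with ambiguity characters are not
    tallied.  CDS shorter than 6 nt are skipped with a warning.
    """
    by_id = {g.id: g for g in genomes}
    counts = RawCounts()
    for feat in features:
        if feat.kind != "CDS":
            continue
        genome = by_id.get(feat.seqid)
        if genome is None:
            continue
        seq = extract_feature_sequence(genome, feat)
        if len(seq) < 6:
            logger.warning("skipping %s/%s: CDS of %d nt", feat.seqid, feat.gene, len(seq))
            continue
        key = (genome.code_table, feat.gene)
        n_cod, rem = divmod(len(seq), 3)
        start = seq[:3]
        if _is_unambiguous(start):
            counts.start[key][start] += 1
        if rem == 0:
            stop = seq[-3:]
            last_internal = n_cod - 1  # exclusive
        else:
            tail = seq[3 * n_cod:]
            stop = tail + "-" * (3 - rem)
            last_internal = n_cod
        if _is_unambiguous(stop.rstrip("-")):
            counts.stop[key][stop] += 1
        for i in range(1, last_internal):
            codon = seq[3 * i: 3 * i + 3]
            if _is_unambiguous(codon):
                counts.internal[key][codon] += 1
    return counts


def build_usage_table(
    counts: RawCounts,
    start_min_freq: float = 0.01,
    internal_stop_max_freq: float = 0.001,
    stop_min_freq: float = 0.0,
) -> CodonUsageTable:
    """Turn raw tallies into filtered frequency tables.

    Frequencies are counts over the within-category total for the key.
    Start codons rarer than ``start_min_freq`` are dropped; full codons
    whose *internal* frequency reaches ``internal_stop_max_freq`` are
    excluded from the stop table.  Incomplete-stop frequencies are stored
    unadjusted; the chance-hit corrections (/3 for TA, /12 for T) are
    applied at scoring time.
    """
    entries: dict[Key, UsageEntry] = {}
    for key in sorted(counts.keys()):
        sc, ec, ic = counts.start[key], counts.stop[key], counts.internal[key]
        n_start, n_stop, n_internal = sum(sc.values()), sum(ec.values()), sum(ic.values())
        if n_start == 0 and n_stop == 0:
            logger.warning("key %s has no start/stop observations; omitted", key)
            continue
        internal_freq = (
            {c: n / n_internal for c, n in sorted(ic.items())} if n_internal else {}
        )
        start_freq = (
            {c: n / n_start for c, n in sorted(sc.items()) if n / n_start >= start_min_freq}
            if n_start
            else {}
        )
        stop_freq = {}
        if n_stop:
            for codon, n in sorted(ec.items()):
                f = n / n_stop
                if f < stop_min_freq:
                    continue
                if internal_freq.get(codon, 0.0) >= internal_stop_max_freq:
                    continue
                stop_freq[codon] = f
        entries[key] = UsageEntry(
            start_freq=start_freq,
            stop_freq=stop_freq,
            internal_freq=internal_freq,
            n_start=n_start,
            n_stop=n_stop,
            n_internal=n_internal,
        )
    return CodonUsageTable(entries)


def build_length_distribution(
    features: Iterable[Feature], genomes: Iterable[Genome]
) -> LengthDistribution:
    """Collect per-(code table, gene) CDS lengths, one per species.

    Lengths are in nucleotides and include the (possibly incomplete) stop
    codon.  If a species carries several copies of a gene, the longest is
    kept, since each species should contribute a single value.
    """
    by_id = {g.id: g for g in genomes}
    per_species: dict[Key, dict[str, int]] = defaultdict(dict)
    for feat in features:
        if feat.kind != "CDS":
            continue
        genome = by_id.get(feat.seqid)
        if genome is None:
            continue
        key = (genome.code_table, feat.gene)
        length = len(feat)
        prev = per_species[key].get(feat.seqid, 0)
        if length > prev:
            per_species[key][feat.seqid] = length
    return LengthDistribution(
        {key: list(vals.values()) for key, vals in per_species.items()}
    )


@dataclass
class ReferenceStatistics:
    """Bundle of the two empirical tables plus JSON persistence."""

    usage: CodonUsageTable
    lengths: LengthDistribution

    def code_tables(self) -> set[int]:
        return {t for t, _ in self.usage.keys()}

    def save(self, path: str | Path) -> None:
        doc: dict = {"schema_version": STATS_SCHEMA_VERSION, "tables": {}}
        for table, gene in sorted(self.usage.keys()):
            entry = self.usage.get(table, gene)
            node = doc["tables"].setdefault(str(table), {})
            node[gene] = {
                "start_freq": dict(entry.start_freq),
                "stop_freq": dict(entry.stop_freq),
                "internal_freq": dict(entry.internal_freq),
                "n_start": entry.n_start,
                "n_stop": entry.n_stop,
                "n_internal": entry.n_internal,
                "lengths": (
                    self.lengths.values(table, gene).tolist()
                    if (table, gene) in self.lengths
                    else []
                ),
            }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceStatistics":
        doc = json.loads(Path(path).read_text())
        version = doc.get("schema_version")
        if version != STATS_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported statistics schema version {version!r} "
                f"(expected {STATS_SCHEMA_VERSION})"
            )
        usage: dict[Key, UsageEntry] = {}
        lengths: dict[Key, list[int]] = {}
        for table_str, genes in doc["tables"].items():
            table = int(table_str)
            for gene, node in genes.items():
                key = (table, gene)
                usage[key] = UsageEntry(
                    start_freq=dict(node["start_freq"]),
                    stop_freq=dict(node["stop_freq"]),
                    internal_freq=dict(node["internal_freq"]),
                    n_start=int(node["n_start"]),
                    n_stop=int(node["n_stop"]),
                    n_internal=int(node["n_internal"]),
                )
                if node.get("lengths"):
                    lengths[key] = [int(x) for x in node["lengths"]]
        return cls(usage=CodonUsageTable(usage), lengths=LengthDistribution(lengths))


def build_reference_statistics(
    genomes: Iterable[Genome],
    features: Iterable[Feature],
    start_min_freq: float = 0.01,
    internal_stop_max_freq: float = 0.001,
) -> ReferenceStatistics:
    """Build both tables from an annotated reference set in one pass."""
    genomes = list(genomes)
    features = list(features)
    counts = count_codons(features, genomes)
    usage = build_usage_table(
        counts,
        start_min_freq=start_min_freq,
        internal_stop_max_freq=internal_stop_max_freq,
    )
    lengths = build_length_distribution(features, genomes)
    return ReferenceStatistics(usage=usage, lengths=lengths)
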