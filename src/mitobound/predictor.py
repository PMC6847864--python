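"""Probabilistic refinement of approximate protein-coding gene boundaries.

A profile-HMM search locates a mitochondrial protein-coding gene only
approximately, and typically too short.  This module refines the hit to
exact start and stop codon positions by maximizing, over candidate start
positions S and stop positions E,

    delta_s(s) * phi_s(s) * delta_e(e) * phi_e(e) * lambda(len(s, e))

where delta measures how well a candidate agrees with the boundary
extrapolated from the query-model alignment, phi is the empirical
probability of the codon acting as start/stop for this gene and code
table, and lambda is the empirical two-sided p-value of the implied gene
length.  S contains the in-frame codons from just after the adjacent
upstream full stop codon through the center of the hit; E the codons from
the center through the nearest downstream full stop codon (inclusive).
Candidates with zero phi are pruned, and pairs whose span would swallow a
whole tRNA gene are forbidden (the tRNA punctuation arrangement makes such
spans implausible).  Incomplete stop codons TA and T are scored with their
empirical frequency divided by 3 and 12 respectively, compensating for how
much more easily they arise by chance than a full three-base stop.

If no candidate survives, the boundary falls back to the raw HMM estimate.
The legacy fixed-window method (nearest canonical codon within +-6 amino
acids) is provided for comparison as :func:`legacy_predict`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation_io import Feature, Genome, HmmHit, reverse_complement
from .genetic_codes import GeneticCode, get_table
from .refstats import INCOMPLETE_T, INCOMPLETE_TA, ReferenceStatistics, UsageEntry

__all__ = [
    "StartCandidate",
    "StopCandidate",
    "BoundaryPrediction",
    "center_codon",
    "delta_start",
    "delta_end",
    "enumerate_start_candidates",
    "enumerate_stop_candidates",
    "predict_boundaries",
    "predict_all",
    "legacy_predict",
    "best_trna_per_type",
]

#: nucleotides consumed at the stop position, per stop kind
_END_OFFSET = {"full": 3, "TA": 2, "T": 1}


@dataclass(frozen=True)
class StartCandidate:
    codon_index: int
    codon: str
    phi: float
    delta: float


@dataclass(frozen=True)
class StopCandidate:
    codon_index: int
    kind: str  # {"full", "TA", "T"}
    codon_or_prefix: str
    phi: float  # already /3 or /12 adjusted for incomplete kinds
    delta: float

    @property
    def end_offset(self) -> int:
        return _END_OFFSET[self.kind]


@dataclass(frozen=True)
class BoundaryPrediction:
    """A refined gene span with its score decomposition."""

    seqid: str
    gene: str
    strand: str
    start: int  # forward axis, 0-based half-open
    end: int    # may exceed genome length for origin-crossing spans
    start_codon: str
    stop_codon: str
    stop_completeness: str  # {"full", "TA", "T", "unknown"}
    score: float | None
    components: tuple[float, float, float, float, float] | None
    start_fallback: bool
    stop_fallback: bool
    method: str = "probabilistic"

    def to_feature(self) -> Feature:
        return Feature(
            seqid=self.seqid, gene=self.gene, kind="CDS",
            start=self.start, end=self.end, strand=self.strand,
            stop_completeness=self.stop_completeness,
        )


def center_codon(hit: HmmHit) -> int:
    """In-frame codon index of the hit's center point (floor of midpoint)."""
    return (hit.s_s + hit.s_e) // 2


def delta_start(p: int, hit: HmmHit) -> float:
    """Distance factor for a candidate start at codon index ``p``.

    Inside the hit the query alignment is extrapolated linearly to a
    relative model position r_s(p); delta = 1 - r_s/l_q.  Outside the hit
    interval delta is 1: hits are biased short, so positions beyond the
    hit are at least as plausible boundaries as its edges.
    """
    if p < hit.s_s or p > hit.s_e:
        return 1.0
    slope = (hit.q_e - hit.q_s) / (hit.s_e - hit.s_s)
    r_s = hit.q_s + slope * (p - hit.s_s)
    # clamp: rounding can push the analytic range [0, 1] out by ~1 ulp
    return min(1.0, max(0.0, 1.0 - r_s / hit.l_q))


def delta_end(p: int, hit: HmmHit, literal: bool = False) -> float:
    """Distance factor for a candidate stop at codon index ``p``.

    The default form ``r_e(p) = (l_q - q_e) + slope * (s_e - p)`` grows
    toward 1 as ``p`` approaches the 3' end of the hit, mirroring
    :func:`delta_start`.  ``literal=True`` selects the alternative
    ``r_e(p) = (l_q - q_s) + slope * (p - s_s)``, which instead decreases
    toward the 3' end (kept for comparison; see the methods note).
    """
    if p < hit.s_s or p > hit.s_e:
        return 1.0
    slope = (hit.q_e - hit.q_s) / (hit.s_e - hit.s_s)
    if literal:
        # the alternative form may fall below 0 near the 3' end; not clamped
        r_e = (hit.l_q - hit.q_s) + slope * (p - hit.s_s)
        return 1.0 - r_e / hit.l_q
    r_e = (hit.l_q - hit.q_e) + slope * (hit.s_e - p)
    return min(1.0, max(0.0, 1.0 - r_e / hit.l_q))


def _local_sequence(genome: Genome, strand: str) -> str:
    return genome.sequence if strand == "+" else reverse_complement(genome.sequence)


def _codon_at(seq: str, pos: int, circular: bool) -> str | None:
    """3-mer starting at local coordinate ``pos``; modular on circles."""
    n = len(seq)
    if circular:
        if 0 <= pos and pos + 3 <= n:
            return seq[pos:pos + 3]
        return seq[pos % n] + seq[(pos + 1) % n] + seq[(pos + 2) % n]
    if pos < 0 or pos + 3 > n:
        return None
    return seq[pos:pos + 3]


def enumerate_start_candidates(
    local_seq: str,
    circular: bool,
    hit: HmmHit,
    code: GeneticCode,
    usage: UsageEntry,
) -> list[StartCandidate]:
    """Candidate starts between the adjacent upstream stop and the hit center.

    Scans in-frame codons upstream from the center; the scan ends at the
    first full stop codon of the code table (excluded) or at the sequence
    edge for linear genomes.  Circular scans are capped at one genome
    length so they always terminate.  Only codons with phi_s > 0 are kept;
    codons containing ambiguity characters are neither candidates nor scan
    terminators.
    """
    c = center_codon(hit)
    max_steps = len(local_seq) // 3 if circular else c - math.ceil(-hit.frame_anchor / 3) + 1
    out: list[StartCandidate] = []
    p = c
    for _ in range(max(0, max_steps) + 1):
        codon = _codon_at(local_seq, hit.frame_anchor + 3 * p, circular)
        if codon is None:
            break
        if codon in code.canonical_stops:
            break
        phi = usage.start_freq.get(codon, 0.0)
        if phi > 0.0:
            out.append(StartCandidate(p, codon, phi, delta_start(p, hit)))
        p -= 1
    out.reverse()
    return out


def enumerate_stop_candidates(
    local_seq: str,
    circular: bool,
    hit: HmmHit,
    code: GeneticCode,
    usage: UsageEntry,
    literal_delta_e: bool = False,
) -> list[StopCandidate]:
    """Candidate stops between the hit center and the nearest downstream stop.

    The delimiting full stop codon is itself included.  At every scanned
    position up to three candidates may be emitted: a full stop (codon in
    the filtered stop table), an incomplete TA (codon starts with TA) and
    an incomplete T (codon starts with T).  The stored incomplete-stop
    frequencies are divided by 3 (TA) and 12 (T) because a matching prefix
    arises by chance much more often than a specific full codon.
    """
    c = center_codon(hit)
    n = len(local_seq)
    max_steps = n // 3 if circular else (n - hit.frame_anchor) // 3
    phi_ta = usage.stop_freq.get(INCOMPLETE_TA, 0.0)
    phi_t = usage.stop_freq.get(INCOMPLETE_T, 0.0)
    out: list[StopCandidate] = []
    p = c
    for _ in range(max(0, max_steps) + 1):
        codon = _codon_at(local_seq, hit.frame_anchor + 3 * p, circular)
        if codon is None:
            break
        d = delta_end(p, hit, literal=literal_delta_e)
        phi_full = usage.stop_freq.get(codon, 0.0)
        if phi_full > 0.0:
            out.append(StopCandidate(p, "full", codon, phi_full, d))
        if phi_ta > 0.0 and codon.startswith("TA"):
            out.append(StopCandidate(p, "TA", codon[:2], phi_ta / 3.0, d))
        if phi_t > 0.0 and codon.startswith("T"):
            out.append(StopCandidate(p, "T", codon[:1], phi_t / 12.0, d))
        if codon in code.canonical_stops:
            break
        p += 1
    return out


def best_trna_per_type(trnas: Iterable[Feature]) -> list[Feature]:
    """Keep one locus per tRNA gene name (first wins)."""
    seen: dict[str, Feature] = {}
    for t in trnas:
        seen.setdefault(t.gene, t)
    return list(seen.values())


def _trna_local_spans(
    trnas: Sequence[Feature], strand: str, n: int
) -> list[tuple[int, int]]:
    spans = []
    for t in trnas:
        if strand == "+":
            spans.append((t.start, t.end))
        else:
            spans.append((n - t.end, n - t.start))
    return spans


def _contains_trna(
    a: int, b: int, spans: Sequence[tuple[int, int]], n: int, circular: bool
) -> bool:
    """Does local span [a, b) fully contain any tRNA span (modular on circles)?"""
    shifts = (-n, 0, n) if circular else (0,)
    for ta, tb in spans:
        for sh in shifts:
            if a <= ta + sh and tb + sh <= b:
                return True
    return False


def _to_forward_span(a: int, b: int, strand: str, n: int, circular: bool) -> tuple[int, int]:
    """Map a local half-open span to the forward axis, unwrapped if circular."""
    length = b - a
    if strand == "+":
        fs = a
    else:
        fs = n - b
    if circular:
        fs %= n
    return fs, fs + length


def predict_boundaries(
    genome: Genome,
    hit: HmmHit,
    trnas: Sequence[Feature],
    stats: ReferenceStatistics,
    literal_delta_e: bool = False,
) -> BoundaryPrediction:
    """Refine one hit to exact start/stop codon positions.

    Returns the candidate pair maximizing the five-factor product; ties are
    broken deterministically (longer gene, then start closer to the hit
    start, then leftmost start).  If S (or E) is empty, or every product is
    zero, the corresponding raw hit boundary is used instead and flagged.

    Raises ``KeyError`` when the statistics lack the (code table, gene) key.
    """
    code = get_table(genome.code_table)
    usage = stats.usage.get(genome.code_table, hit.gene)
    stats.lengths.values(genome.code_table, hit.gene)  # fail fast on missing key

    local_seq = _local_sequence(genome, hit.strand)
    n = len(local_seq)
    starts = enumerate_start_candidates(local_seq, genome.circular, hit, code, usage)
    stops = enumerate_stop_candidates(
        local_seq, genome.circular, hit, code, usage, literal_delta_e=literal_delta_e
    )
    spans = _trna_local_spans(best_trna_per_type(trnas), hit.strand, n)

    def lam(length_nt: int) -> float:
        return stats.lengths.pvalue(genome.code_table, hit.gene, length_nt)

    def forbidden(s_idx: int, e_idx: int, end_offset: int) -> bool:
        a = hit.frame_anchor + 3 * s_idx
        b = hit.frame_anchor + 3 * e_idx + end_offset
        return _contains_trna(a, b, spans, n, genome.circular)

    best: tuple | None = None
    best_pair: tuple[StartCandidate, StopCandidate] | None = None
    for s in starts:
        for e in stops:
            if e.codon_index < s.codon_index:
                continue
            length_nt = 3 * (e.codon_index - s.codon_index) + e.end_offset
            lv = lam(length_nt)
            score = s.delta * s.phi * e.delta * e.phi * lv
            if score <= 0.0:
                continue
            if forbidden(s.codon_index, e.codon_index, e.end_offset):
                continue
            key = (score, length_nt, -abs(s.codon_index - hit.s_s), -s.codon_index)
            if best is None or key > best:
                best = key
                best_pair = (s, e, lv)

    start_fallback = stop_fallback = False
    if best_pair is not None:
        s, e, lv = best_pair
        s_idx, e_idx, end_offset = s.codon_index, e.codon_index, e.end_offset
        score: float | None = best[0]
        components = (s.delta, s.phi, e.delta, e.phi, lv)
        start_codon = s.codon
        stop_codon = e.codon_or_prefix
        completeness = e.kind
    elif starts and not stops:
        # no stop candidate: keep the raw hit end, refine the start alone
        stop_fallback = True
        e_idx, end_offset = hit.s_e, 3
        best_s = None
        for s in starts:
            lv = lam(3 * (e_idx - s.codon_index) + end_offset)
            sc = s.delta * s.phi * lv
            if sc <= 0.0 or forbidden(s.codon_index, e_idx, end_offset):
                continue
            key = (sc, -abs(s.codon_index - hit.s_s), -s.codon_index)
            if best_s is None or key > best_s[0]:
                best_s = (key, s)
        if best_s is None:
            start_fallback = True
            s_idx = hit.s_s
        else:
            s_idx = best_s[1].codon_index
        score, components = None, None
        start_codon = _codon_at(local_seq, hit.frame_anchor + 3 * s_idx, genome.circular) or ""
        stop_codon = _codon_at(local_seq, hit.frame_anchor + 3 * e_idx, genome.circular) or ""
        completeness = "unknown"
    elif stops and not starts:
        start_fallback = True
        s_idx = hit.s_s
        best_e = None
        for e in stops:
            if e.codon_index < s_idx:
                continue
            lv = lam(3 * (e.codon_index - s_idx) + e.end_offset)
            sc = e.delta * e.phi * lv
            if sc <= 0.0 or forbidden(s_idx, e.codon_index, e.end_offset):
                continue
            key = (sc, e.codon_index)
            if best_e is None or key > best_e[0]:
                best_e = (key, e)
        if best_e is None:
            stop_fallback = True
            e_idx, end_offset = hit.s_e, 3
            stop_codon = _codon_at(local_seq, hit.frame_anchor + 3 * e_idx, genome.circular) or ""
            completeness = "unknown"
        else:
            e_cand = best_e[1]
            e_idx, end_offset = e_cand.codon_index, e_cand.end_offset
            stop_codon = e_cand.codon_or_prefix
            completeness = e_cand.kind
        score, components = None, None
        start_codon = _codon_at(local_seq, hit.frame_anchor + 3 * s_idx, genome.circular) or ""
    else:
        # S and E both empty, or every admissible product was zero
        start_fallback = stop_fallback = True
        s_idx, e_idx, end_offset = hit.s_s, hit.s_e, 3
        score, components = None, None
        start_codon = _codon_at(local_seq, hit.frame_anchor + 3 * s_idx, genome.circular) or ""
        stop_codon = _codon_at(local_seq, hit.frame_anchor + 3 * e_idx, genome.circular) or ""
        completeness = "unknown"

    a = hit.frame_anchor + 3 * s_idx
    b = hit.frame_anchor + 3 * e_idx + end_offset
    fs, fe = _to_forward_span(a, b, hit.strand, n, genome.circular)
    return BoundaryPrediction(
        seqid=genome.id, gene=hit.gene, strand=hit.strand,
        start=fs, end=fe,
        start_codon=start_codon, stop_codon=stop_codon,
        stop_completeness=completeness,
        score=score, components=components,
        start_fallback=start_fallback, stop_fallback=stop_fallback,
    )


def predict_all(
    genome: Genome,
    hits: Iterable[HmmHit],
    trnas: Sequence[Feature],
    stats: ReferenceStatistics,
    literal_delta_e: bool = False,
) -> list[BoundaryPrediction]:
    """Refine every hit of one genome."""
    return [
        predict_boundaries(genome, h, trnas, stats, literal_delta_e=literal_delta_e)
        for h in hits
    ]


def legacy_predict(
    genome: Genome,
    hit: HmmHit,
    code: GeneticCode | None = None,
    window_aa: int = 6,
) -> BoundaryPrediction:
    """Fixed-window baseline: nearest canonical codon within +-``window_aa``.

    The start (stop) boundary is moved to the closest canonical start
    (stop) codon of the code table within ``window_aa`` codons of the raw
    hit boundary; at equal distance the upstream position wins.  Without a
    codon in range the raw boundary is kept.  Incomplete stop codons are
    not modeled by this method.
    """
    if code is None:
        code = get_table(genome.code_table)
    local_seq = _local_sequence(genome, hit.strand)
    n = len(local_seq)

    def nearest(center: int, accepted: frozenset[str]) -> int | None:
        for dist in range(window_aa + 1):
            for p in ((center - dist, center + dist) if dist else (center,)):
                codon = _codon_at(local_seq, hit.frame_anchor + 3 * p, genome.circular)
                if codon is not None and codon in accepted:
                    return p
        return None

    s_found = nearest(hit.s_s, code.canonical_starts)
    e_found = nearest(hit.s_e, code.canonical_stops)
    s_idx = hit.s_s if s_found is None else s_found
    e_idx = hit.s_e if e_found is None else e_found
    if e_idx < s_idx:  # degenerate window overlap; keep the raw span
        s_idx, e_idx = hit.s_s, hit.s_e
        s_found = e_found = None
    a = hit.frame_anchor + 3 * s_idx
    b = hit.frame_anchor + 3 * e_idx + 3
    fs, fe = _to_forward_span(a, b, hit.strand, n, genome.circular)
    return BoundaryPrediction(
        seqid=genome.id, gene=hit.gene, strand=hit.strand,
        start=fs, end=fe,
        start_codon=_codon_at(local_seq, a, genome.circular) or "",
        stop_codon=_codon_at(local_seq, b - 3, genome.circular) or "",
        stop_completeness="full" if e_found is not None else "unknown",
        score=None, components=None,
        start_fallback=s_found is None, stop_fallback=e_found is None,
        method="legacy",
    )
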