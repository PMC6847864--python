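"""Independent exhaustive reference scorer for the boundary predictor.

Deliberately re-derives every quantity from first principles with plain
Python loops — no code shared with mitobound.predictor beyond the input
data objects — so it can serve as an oracle in equivalence tests.
"""

from __future__ import annotations

from mitobound.annotation_io import Feature, Genome, HmmHit
from mitobound.genetic_codes import get_table
from mitobound.refstats import ReferenceStatistics

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _codon(seq: str, pos: int, circular: bool) -> str | None:
    n = len(seq)
    if not circular and (pos < 0 or pos + 3 > n):
        return None
    return "".join(seq[(pos + k) % n] for k in range(3))


def _lambda_bruteforce(lengths, l: int) -> float:
    n_le = sum(1 for x in lengths if x <= l)
    n_ge = sum(1 for x in lengths if x >= l)
    return 2.0 * min(n_le, n_ge) / (n_le + n_ge)


def _delta_s(p: int, h: HmmHit) -> float:
    if p < h.s_s or p > h.s_e:
        return 1.0
    r = h.q_s + (h.q_e - h.q_s) / (h.s_e - h.s_s) * (p - h.s_s)
    return 1.0 - r / h.l_q


def _delta_e(p: int, h: HmmHit, literal: bool) -> float:
    if p < h.s_s or p > h.s_e:
        return 1.0
    slope = (h.q_e - h.q_s) / (h.s_e - h.s_s)
    if literal:
        r = (h.l_q - h.q_s) + slope * (p - h.s_s)
    else:
        r = (h.l_q - h.q_e) + slope * (h.s_e - p)
    return 1.0 - r / h.l_q


def oracle_predict(
    genome: Genome,
    hit: HmmHit,
    trnas: list[Feature],
    stats: ReferenceStatistics,
    literal_delta_e: bool = False,
):
    """Exhaustive argmax over every in-frame (s, e) pair in the windows.

    Returns (start, end, score, start_fallback, stop_fallback) with the
    span on the forward axis, matching BoundaryPrediction's convention.
    """
    code = get_table(genome.code_table)
    usage = stats.usage.get(genome.code_table, hit.gene)
    lengths = list(stats.lengths.values(genome.code_table, hit.gene))
    seq = genome.sequence if hit.strand == "+" else _revcomp(genome.sequence)
    n = len(seq)
    center = (hit.s_s + hit.s_e) // 2

    # --- upstream window: codons after the first upstream full stop ---
    start_positions = []
    p = center
    steps = 0
    while True:
        cod = _codon(seq, hit.frame_anchor + 3 * p, genome.circular)
        if cod is None or cod in code.canonical_stops:
            break
        start_positions.append((p, cod))
        p -= 1
        steps += 1
        if genome.circular and steps > n // 3:
            break
    S = [
        (p, cod, usage.start_freq[cod], _delta_s(p, hit))
        for p, cod in start_positions
        if usage.start_freq.get(cod, 0.0) > 0.0
    ]

    # --- downstream window through the nearest full stop (inclusive) ---
    E = []
    p = center
    steps = 0
    while True:
        cod = _codon(seq, hit.frame_anchor + 3 * p, genome.circular)
        if cod is None:
            break
        d = _delta_e(p, hit, literal_delta_e)
        f = usage.stop_freq.get(cod, 0.0)
        if f > 0.0:
            E.append((p, 3, f, d))
        f_ta = usage.stop_freq.get("TA-", 0.0)
        if f_ta > 0.0 and cod[:2] == "TA":
            E.append((p, 2, f_ta / 3.0, d))
        f_t = usage.stop_freq.get("T--", 0.0)
        if f_t > 0.0 and cod[0] == "T":
            E.append((p, 1, f_t / 12.0, d))
        if cod in code.canonical_stops:
            break
        p += 1
        steps += 1
        if genome.circular and steps > n // 3:
            break

    trna_local = []
    for t in trnas:
        if hit.strand == "+":
            trna_local.append((t.start, t.end))
        else:
            trna_local.append((n - t.end, n - t.start))

    def contains_trna(a: int, b: int) -> bool:
        for ta, tb in trna_local:
            for sh in ((-n, 0, n) if genome.circular else (0,)):
                if a <= ta + sh and tb + sh <= b:
                    return True
        return False

    best = None
    for sp, scod, sphi, sdelta in S:
        for ep, off, ephi, edelta in E:
            if ep < sp:
                continue
            ln = 3 * (ep - sp) + off
            score = sdelta * sphi * edelta * ephi * _lambda_bruteforce(lengths, ln)
            if score <= 0.0:
                continue
            if contains_trna(hit.frame_anchor + 3 * sp, hit.frame_anchor + 3 * ep + off):
                continue
            key = (score, ln, -abs(sp - hit.s_s), -sp)
            if best is None or key > best[0]:
                best = (key, sp, ep, off)

    s_fb = e_fb = False
    if best is not None:
        _, sp, ep, off = best
        score = best[0][0]
    elif S and not E:
        e_fb, ep, off = True, hit.s_e, 3
        bs = None
        for sp_, scod, sphi, sdelta in S:
            sc = sdelta * sphi * _lambda_bruteforce(lengths, 3 * (ep - sp_) + off)
            if sc <= 0.0 or contains_trna(hit.frame_anchor + 3 * sp_, hit.frame_anchor + 3 * ep + off):
                continue
            k = (sc, -abs(sp_ - hit.s_s), -sp_)
            if bs is None or k > bs[0]:
                bs = (k, sp_)
        sp = bs[1] if bs else hit.s_s
        s_fb = bs is None
        score = None
    elif E and not S:
        s_fb, sp = True, hit.s_s
        be = None
        for ep_, off_, ephi, edelta in E:
            if ep_ < sp:
                continue
            sc = edelta * ephi * _lambda_bruteforce(lengths, 3 * (ep_ - sp) + off_)
            if sc <= 0.0 or contains_trna(hit.frame_anchor + 3 * sp, hit.frame_anchor + 3 * ep_ + off_):
                continue
            if be is None or (sc, ep_) > be[0]:
                be = ((sc, ep_), ep_, off_)
        if be is None:
            e_fb, ep, off = True, hit.s_e, 3
        else:
            ep, off = be[1], be[2]
        score = None
    else:
        s_fb = e_fb = True
        sp, ep, off = hit.s_s, hit.s_e, 3
        score = None

    a = hit.frame_anchor + 3 * sp
    b = hit.frame_anchor + 3 * ep + off
    length = b - a
    fs = a if hit.strand == "+" else n - b
    if genome.circular:
        fs %= n
    return fs, fs + length, score, s_fb, e_fb
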