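import numpy as np
import pytest

from mitobound.annotation_io import Feature, Genome, HmmHit, reverse_complement
from mitobound.genetic_codes import get_table
from mitobound.predictor import (
    center_codon,
    delta_end,
    delta_start,
    enumerate_start_candidates,
    enumerate_stop_candidates,
    legacy_predict,
    predict_boundaries,
)
from mitobound.refstats import (
    INCOMPLETE_T,
    INCOMPLETE_TA,
    CodonUsageTable,
    LengthDistribution,
    ReferenceStatistics,
    UsageEntry,
)
from mitobound.synthetic import simulate_hits, simulate_reference_set

from ._oracle import oracle_predict


def _usage(start_freq, stop_freq, key=(5, "nad3")):
    return CodonUsageTable(
        {key: UsageEntry(start_freq=start_freq, stop_freq=stop_freq,
                         internal_freq={}, n_start=100, n_stop=100, n_internal=1000)}
    )


def _stats(start_freq, stop_freq, lengths, key=(5, "nad3")):
    return ReferenceStatistics(
        usage=_usage(start_freq, stop_freq, key),
        lengths=LengthDistribution({key: lengths}),
    )


HIT = HmmHit(seqid="g", gene="nad3", strand="+", s_s=0, s_e=80,
             q_s=10, q_e=90, l_q=100)


# --- center and distance factors -----------------------------------------

@pytest.mark.parametrize("s_s, s_e, expected", [(0, 100, 50), (3, 4, 3), (10, 11, 10)])
def test_center_codon_floor(s_s, s_e, expected):
    hit = HmmHit(seqid="g", gene="x", strand="+", s_s=s_s, s_e=s_e,
                 q_s=1, q_e=2, l_q=200)
    assert center_codon(hit) == expected


def test_delta_start_values():
    assert delta_start(-5, HIT) == 1.0  # upstream of the hit
    assert delta_start(0, HIT) == pytest.approx(0.9)   # r_s = q_s = 10
    assert delta_start(80, HIT) == pytest.approx(0.1)  # r_s = q_e = 90


def test_delta_end_corrected_values():
    assert delta_end(85, HIT) == 1.0  # downstream of the hit
    assert delta_end(80, HIT) == pytest.approx(0.9)  # r_e = l_q - q_e = 10
    assert delta_end(0, HIT) == pytest.approx(0.1)


def test_delta_end_literal_form_decreases_toward_3prime():
    # literal r_e(p) = (l_q - q_s) + slope*(p - s_s)
    assert delta_end(0, HIT, literal=True) == pytest.approx(1 - 90 / 100)
    assert delta_end(80, HIT, literal=True) == pytest.approx(1 - 170 / 100)


def test_delta_properties_over_random_hits():
    rng = np.random.default_rng(42)
    for _ in range(10_000):
        l_q = int(rng.integers(10, 600))
        q_s = int(rng.integers(1, l_q - 1))
        q_e = int(rng.integers(q_s + 1, l_q + 1))
        s_s = int(rng.integers(0, 50))
        s_e = int(rng.integers(s_s + 1, s_s + 600))
        h = HmmHit(seqid="g", gene="x", strand="+", s_s=s_s, s_e=s_e,
                   q_s=q_s, q_e=q_e, l_q=l_q)
        ps = range(s_s, s_e + 1)
        ds = [delta_start(p, h) for p in ps]
        de = [delta_end(p, h) for p in ps]
        assert all(0.0 <= d <= 1.0 for d in ds + de)
        assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))  # non-increasing
        assert all(a <= b + 1e-12 for a, b in zip(de, de[1:]))  # non-decreasing
        assert delta_start(s_s - 1, h) == 1.0 and delta_end(s_e + 1, h) == 1.0


# --- candidate enumeration -----------------------------------------------

def test_start_scan_stops_at_upstream_stop_exclusive():
    # codons: 0..7 coding-ish, TAA at codon 2, ATG at codon 4, center 6
    seq = "GCA" * 2 + "TAA" + "GCA" + "ATG" + "GCA" * 3
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=5, s_e=8,
                 q_s=1, q_e=4, l_q=4)
    code = get_table(5)
    usage = _usage({"ATG": 1.0}, {"TAA": 1.0}).get(5, "nad3")
    cands = enumerate_start_candidates(seq, False, hit, code, usage)
    assert [c.codon_index for c in cands] == [4]  # TAA at 2 excluded, scan ends there


def test_start_candidates_require_positive_phi():
    seq = "TAA" + "ATT" + "ATG" + "GCA" * 4
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=1, s_e=6,
                 q_s=1, q_e=6, l_q=6)
    code = get_table(5)
    usage = _usage({"ATG": 1.0}, {"TAA": 1.0}).get(5, "nad3")
    cands = enumerate_start_candidates(seq, False, hit, code, usage)
    assert [c.codon for c in cands] == ["ATG"]  # ATT has phi_s = 0


def test_stop_candidates_full_ta_and_t_adjustments():
    # center codon 0; downstream: TAC (T and TA prefixes), GCA, TAA (full stop)
    seq = "TAC" + "GCA" + "TAA" + "GGG"
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=0, s_e=1,
                 q_s=1, q_e=2, l_q=2)
    code = get_table(5)
    usage = _usage(
        {"ATG": 1.0}, {"TAA": 0.6, INCOMPLETE_TA: 0.6, INCOMPLETE_T: 0.6}
    ).get(5, "nad3")
    cands = enumerate_stop_candidates(seq, False, hit, code, usage)
    by = {(c.codon_index, c.kind): c for c in cands}
    assert by[(0, "TA")].phi == pytest.approx(0.2)    # 0.6 / 3
    assert by[(0, "T")].phi == pytest.approx(0.05)    # 0.6 / 12
    assert by[(2, "full")].phi == pytest.approx(0.6)
    # scan is inclusive of the delimiting stop and goes no further
    assert max(c.codon_index for c in cands) == 2
    assert (1, "full") not in by  # GCA is not a stop


# --- full prediction ------------------------------------------------------

def _toy_instance():
    """Plus-strand gene ATG GCA GCA GCA TAA embedded with flanks."""
    gene = "ATG" + "GCA" * 3 + "TAA"
    seq = "TAAGGG" + gene + "CCCCCC"
    genome = Genome(id="g", sequence=seq, circular=False, code_table=5)
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=1, s_e=3,
                 q_s=2, q_e=4, l_q=5, frame_anchor=6)
    stats = _stats({"ATG": 1.0}, {"TAA": 1.0}, [15, 15, 18])
    return genome, hit, stats, gene


def test_single_candidate_pair_score_is_product_of_components():
    genome, hit, stats, gene = _toy_instance()
    pred = predict_boundaries(genome, hit, [], stats)
    assert (pred.start, pred.end) == (6, 6 + len(gene))
    assert pred.start_codon == "ATG" and pred.stop_codon == "TAA"
    ds, ps, de, pe, lam = pred.components
    assert pred.score == pytest.approx(ds * ps * de * pe * lam)
    assert lam == stats.lengths.pvalue(5, "nad3", 15)
    assert not pred.start_fallback and not pred.stop_fallback


def test_missing_statistics_key_errors():
    genome, _, stats, _ = _toy_instance()
    foreign = HmmHit(seqid="g", gene="cox1", strand="+", s_s=1, s_e=3,
                     q_s=2, q_e=4, l_q=5, frame_anchor=6)
    with pytest.raises(KeyError, match="cox1"):
        predict_boundaries(genome, foreign, [], stats)


def test_empty_candidate_sets_fall_back_to_hit_boundaries():
    genome, hit, stats, _ = _toy_instance()
    empty = _stats({"CCC": 1.0}, {"GGG": 1.0}, [15])  # phi never matches
    pred = predict_boundaries(genome, hit, [], empty)
    assert pred.start_fallback and pred.stop_fallback
    assert (pred.start, pred.end) == (6 + 3 * hit.s_s, 6 + 3 * hit.s_e + 3)


def test_trna_containing_pair_is_never_returned():
    # best unconstrained span would swallow the tRNA placed inside it
    gene = "ATG" + "GCA" * 10 + "TAA"
    seq = "TAATAA" + gene + "C" * 10
    genome = Genome(id="g", sequence=seq, circular=False, code_table=5)
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=2, s_e=9,
                 q_s=3, q_e=10, l_q=12, frame_anchor=6)
    stats = _stats({"ATG": 1.0}, {"TAA": 1.0}, [36])
    trna = Feature(seqid="g", gene="trnF", kind="tRNA", start=10, end=20, strand="+")
    unconstrained = predict_boundaries(genome, hit, [], stats)
    constrained = predict_boundaries(genome, hit, [trna], stats)
    assert unconstrained.start <= trna.start and trna.end <= unconstrained.end
    assert not (constrained.start <= trna.start and trna.end <= constrained.end)
    assert constrained.start_fallback or constrained.start != unconstrained.start


def test_strand_mirror_symmetry(small_bundle):
    """Predicting on the reverse-complemented genome mirrors coordinates."""
    cfg, genomes, features, hits, stats = small_bundle
    genome = genomes[0]
    n = len(genome)
    flipped = Genome(id=genome.id, sequence=reverse_complement(genome.sequence),
                     circular=genome.circular, code_table=genome.code_table)
    trnas = [f for f in features if f.kind == "tRNA" and f.seqid == genome.id]
    trnas_flipped = [
        Feature(seqid=f.seqid, gene=f.gene, kind=f.kind,
                start=n - f.end, end=n - f.start,
                strand="-" if f.strand == "+" else "+")
        for f in trnas
    ]
    for hit in [h for h in hits if h.seqid == genome.id]:
        mirrored = HmmHit(seqid=hit.seqid, gene=hit.gene,
                          strand="-" if hit.strand == "+" else "+",
                          s_s=hit.s_s, s_e=hit.s_e, q_s=hit.q_s, q_e=hit.q_e,
                          l_q=hit.l_q, frame_anchor=hit.frame_anchor)
        a = predict_boundaries(genome, hit, trnas, stats)
        b = predict_boundaries(flipped, mirrored, trnas_flipped, stats)
        assert (b.start, b.end) == (n - a.end, n - a.start)
        if a.score is None:
            assert b.score is None
        else:
            assert b.score == pytest.approx(a.score)
        assert (b.start_codon, b.stop_codon) == (a.start_codon, a.stop_codon)


def test_shrinking_hit_with_same_center_keeps_single_candidate_result():
    genome, hit, stats, gene = _toy_instance()
    pred = predict_boundaries(genome, hit, [], stats)
    shrunk = HmmHit(seqid="g", gene="nad3", strand="+", s_s=2, s_e=2 + 1,
                    q_s=3, q_e=4, l_q=5, frame_anchor=6)
    pred2 = predict_boundaries(genome, shrunk, [], stats)
    assert (pred2.start, pred2.end) == (pred.start, pred.end)


# --- oracle equivalence ---------------------------------------------------

def test_matches_exhaustive_oracle_on_simulated_genomes(small_bundle):
    cfg, genomes, features, hits, stats = small_bundle
    by_id = {g.id: g for g in genomes}
    trnas = {}
    for f in features:
        if f.kind == "tRNA":
            trnas.setdefault(f.seqid, []).append(f)
    checked = 0
    for hit in hits:
        genome = by_id[hit.seqid]
        pred = predict_boundaries(genome, hit, trnas.get(hit.seqid, []), stats)
        o_start, o_end, o_score, o_sfb, o_efb = oracle_predict(
            genome, hit, trnas.get(hit.seqid, []), stats
        )
        assert (pred.start, pred.end) == (o_start, o_end)
        if pred.score is None:
            assert o_score is None
        else:
            assert pred.score == pytest.approx(o_score, rel=1e-9)
        assert (pred.start_fallback, pred.stop_fallback) == (o_sfb, o_efb)
        checked += 1
    assert checked == len(hits) > 0


# --- legacy baseline ------------------------------------------------------

def _legacy_genome(seq):
    return Genome(id="g", sequence=seq, circular=False, code_table=2)


def test_legacy_start_exactly_at_hit():
    seq = "ATG" + "GCA" * 6 + "TAA"
    g = _legacy_genome(seq)
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=0, s_e=7,
                 q_s=1, q_e=8, l_q=8, frame_anchor=0)
    pred = legacy_predict(g, hit)
    assert pred.start == 0 and not pred.start_fallback
    assert pred.end == len(seq) and not pred.stop_fallback


def test_legacy_no_codon_in_window_keeps_approximate_position():
    seq = "GCA" * 20
    g = _legacy_genome(seq)
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=8, s_e=12,
                 q_s=1, q_e=5, l_q=5, frame_anchor=0)
    pred = legacy_predict(g, hit)
    assert pred.start_fallback and pred.stop_fallback
    assert (pred.start, pred.end) == (24, 39)


def test_legacy_nearest_codon_wins():
    # ATG two codons upstream of s_s, GTG one codon downstream: GTG is closer
    codons = ["GCA"] * 10
    codons[3] = "ATG"
    codons[6] = "GTG"
    g = _legacy_genome("".join(codons))
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=5, s_e=9,
                 q_s=1, q_e=5, l_q=5, frame_anchor=0)
    pred = legacy_predict(g, hit)
    assert pred.start == 18 and pred.start_codon == "GTG"


def test_legacy_equidistant_prefers_upstream():
    codons = ["GCA"] * 10
    codons[3] = "ATG"
    codons[7] = "GTG"
    g = _legacy_genome("".join(codons))
    hit = HmmHit(seqid="g", gene="nad3", strand="+", s_s=5, s_e=9,
                 q_s=1, q_e=5, l_q=5, frame_anchor=0)
    pred = legacy_predict(g, hit)
    assert pred.start == 9 and pred.start_codon == "ATG"
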