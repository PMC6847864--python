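"""Synthetic mitogenome fixtures with known truth.

Generates genomes that have the *statistical* structure the boundary
predictor consumes — 13 protein-coding genes with configurable start/stop
codon usage (including incomplete stops), per-gene length variation across
species, interleaved tRNA loci in the manner of the tRNA punctuation
arrangement, AT-rich intergenic spacers, and approximate hits that are
shrunk versions of the true genes (profile-HMM hits are biased short).
No sequence evolution is modeled: fixtures are for exercising the
annotation machinery, not for phylogenetics.

All sampling flows from one seed through per-species substreams, so a
fixed configuration reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import (
    MT_PCGS,
    TRNA_NAMES,
    Feature,
    Genome,
    HmmHit,
    reverse_complement,
)
from .evaluation import DifferenceSummary, match_genes, signed_difference, summarize
from .genetic_codes import get_table
from .predictor import legacy_predict, predict_boundaries
from .refstats import ReferenceStatistics, build_reference_statistics

__all__ = [
    "SimulationConfig",
    "RecoveryReport",
    "simulate_reference_set",
    "simulate_hits",
    "recovery_experiment",
]

#: Approximate metazoan mitochondrial protein lengths (amino acids, incl. start).
DEFAULT_GENE_LENGTHS_AA: dict[str, int] = {
    "atp6": 227, "atp8": 55, "cob": 380, "cox1": 515, "cox2": 227,
    "cox3": 261, "nad1": 318, "nad2": 347, "nad3": 116, "nad4": 459,
    "nad4l": 98, "nad5": 603, "nad6": 174,
}

#: AT-rich base composition for non-coding spacers and tRNA loci.
_BASE_P = (0.35, 0.15, 0.15, 0.35)  # A, C, G, T
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    ``start_dist`` maps start codons to probabilities (codons need not be
    canonical starts of the table, mirroring real non-canonical starts,
    but must not be stop codons).  ``stop_dist`` maps full stop codons of
    the table plus the incomplete prefixes ``"TA"`` and ``"T"`` to
    probabilities.  ``hit_shrink_aa`` is the closed range of codons
    truncated independently at each gene end when hits are simulated.
    """

    code_table: int = 5
    n_species: int = 50
    seed: int = 0
    gene_lengths_aa: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS_AA)
    )
    length_sd_aa: float = 5.0
    start_dist: Mapping[str, float] = field(
        default_factory=lambda: {"ATG": 0.60, "ATA": 0.20, "ATT": 0.15, "GTG": 0.05}
    )
    stop_dist: Mapping[str, float] = field(
        default_factory=lambda: {"TAA": 0.55, "TAG": 0.20, "T": 0.15, "TA": 0.10}
    )
    trna_count: int = 13
    trna_length: int = 70
    spacer_range: tuple[int, int] = (5, 40)
    minus_strand_genes: frozenset[str] = frozenset({"nad6"})
    hit_shrink_aa: tuple[int, int] = (0, 10)
    circular: bool = True

    def __post_init__(self) -> None:
        code = get_table(self.code_table)
        for name, dist in (("start_dist", self.start_dist), ("stop_dist", self.stop_dist)):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} contains negative probabilities")
        for codon in self.start_dist:
            if codon in code.canonical_stops:
                raise ValueError(f"start codon {codon} is a stop codon of table {self.code_table}")
        for key in self.stop_dist:
            if key not in ("T", "TA") and key not in code.canonical_stops:
                raise ValueError(f"{key} is not a stop codon of table {self.code_table}")
        for gene, mean_aa in self.gene_lengths_aa.items():
            if mean_aa < 5:
                raise ValueError(f"{gene}: mean length {mean_aa} aa is not representable")
        if self.length_sd_aa < 0 or self.trna_length < 10:
            raise ValueError("invalid length parameters")
        lo, hi = self.hit_shrink_aa
        if not (0 <= lo <= hi):
            raise ValueError("hit_shrink_aa must be a non-negative closed range")


def _sample_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_BASE_P)])


def _categorical(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _species_rngs(seed: int, n: int, stream: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _simulate_species(
    rng: np.random.Generator, cfg: SimulationConfig, species_id: str
) -> tuple[Genome, list[Feature]]:
    code = get_table(cfg.code_table)
    non_stop = np.array(sorted(set(_all_codons()) - code.canonical_stops))
    parts: list[str] = []
    feats: list[Feature] = []
    pos = 0
    trna_names = [TRNA_NAMES[i % len(TRNA_NAMES)] for i in range(cfg.trna_count)]
    genes = [g for g in MT_PCGS if g in cfg.gene_lengths_aa]
    for i, gene in enumerate(genes):
        spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
        parts.append(_sample_seq(rng, spacer))
        pos += spacer
        if i < len(trna_names):
            tlen = cfg.trna_length + int(rng.integers(-3, 4))
            parts.append(_sample_seq(rng, tlen))
            feats.append(
                Feature(seqid=species_id, gene=trna_names[i], kind="tRNA",
                        start=pos, end=pos + tlen,
                        strand="-" if gene in cfg.minus_strand_genes else "+")
            )
            pos += tlen
            spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
            parts.append(_sample_seq(rng, spacer))
            pos += spacer
        n_aa = max(5, int(round(rng.normal(cfg.gene_lengths_aa[gene], cfg.length_sd_aa))))
        start = _categorical(rng, cfg.start_dist)
        stop = _categorical(rng, cfg.stop_dist)
        internal = "".join(non_stop[rng.integers(0, len(non_stop), size=n_aa - 1)])
        gene_seq = start + internal + stop
        strand = "-" if gene in cfg.minus_strand_genes else "+"
        if strand == "-":
            parts.append(reverse_complement(gene_seq))
        else:
            parts.append(gene_seq)
        completeness = {3: "full", 2: "TA", 1: "T"}[len(stop)]
        feats.append(
            Feature(seqid=species_id, gene=gene, kind="CDS",
                    start=pos, end=pos + len(gene_seq), strand=strand,
                    stop_completeness=completeness)
        )
        pos += len(gene_seq)
    # control-region-like trailing spacer
    tail = int(rng.integers(100, 300))
    parts.append(_sample_seq(rng, tail))
    genome = Genome(
        id=species_id, sequence="".join(parts),
        circular=cfg.circular, code_table=cfg.code_table,
    )
    return genome, feats


def _all_codons() -> set[str]:
    return {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}


def simulate_reference_set(
    cfg: SimulationConfig,
) -> tuple[list[Genome], list[Feature]]:
    """Simulate ``cfg.n_species`` genomes with truth annotations.

    Internal codons are drawn from the non-stop codons of the configured
    table, so true reading frames never contain a full stop codon.
    """
    genomes: list[Genome] = []
    features: list[Feature] = []
    for i, rng in enumerate(_species_rngs(cfg.seed, cfg.n_species, stream=0)):
        g, f = _simulate_species(rng, cfg, f"sim{i:04d}")
        genomes.append(g)
        features.extend(f)
    return genomes, features


def simulate_hits(
    truth: Sequence[Feature],
    genomes: Sequence[Genome],
    cfg: SimulationConfig,
) -> list[HmmHit]:
    """Shrunken approximate hits for every true CDS.

    Each end of the true gene is truncated by an independent draw from
    ``cfg.hit_shrink_aa`` codons (never extended: profile hits under-cover
    the gene).  Query coordinates are set consistently: the profile length
    ``l_q`` equals the true protein length, ``q_s = 1 + shrink5`` and
    ``q_e = l_q - shrink3``.
    """
    by_id = {g.id: g for g in genomes}
    lo, hi = cfg.hit_shrink_aa
    rngs = {g.id: r for g, r in zip(genomes, _species_rngs(cfg.seed, len(genomes), stream=1))}
    hits: list[HmmHit] = []
    for feat in truth:
        if feat.kind != "CDS":
            continue
        genome = by_id[feat.seqid]
        rng = rngs[feat.seqid]
        stop_len = {"full": 3, "TA": 2, "T": 1}[feat.stop_completeness]
        l_q = (len(feat) - stop_len) // 3
        shrink5 = int(rng.integers(lo, hi + 1))
        shrink3 = int(rng.integers(lo, hi + 1))
        shrink3 = min(shrink3, max(0, l_q - 2 - shrink5))
        shrink5 = min(shrink5, max(0, l_q - 2 - shrink3))
        anchor = feat.start if feat.strand == "+" else len(genome) - feat.end
        hits.append(
            HmmHit(
                seqid=feat.seqid, gene=feat.gene, strand=feat.strand,
                s_s=shrink5, s_e=l_q - 1 - shrink3,
                q_s=1 + shrink5, q_e=l_q - shrink3, l_q=l_q,
                frame_anchor=anchor,
            )
        )
    return hits


@dataclass(frozen=True)
class RecoveryReport:
    """How well boundaries are recovered on held-out simulated species."""

    n_genes: int
    start_recovery: float
    stop_recovery: float
    summary: DifferenceSummary
    legacy_start_recovery: float
    legacy_stop_recovery: float
    legacy_summary: DifferenceSummary


def _recovery_fractions(
    predictions: Sequence[Feature], truth: Sequence[Feature]
) -> tuple[float, float, DifferenceSummary]:
    pairs, _, _ = match_genes(predictions, truth)
    if not pairs:
        raise ValueError("no prediction/truth pairs to evaluate")
    d5 = np.array([signed_difference(p, "start") for p in pairs])
    d3 = np.array([signed_difference(p, "stop") for p in pairs])
    return float(np.mean(d5 == 0)), float(np.mean(d3 == 0)), summarize(pairs)


def recovery_experiment(
    cfg: SimulationConfig,
    n_test_species: int = 100,
    stats: ReferenceStatistics | None = None,
) -> RecoveryReport:
    """Train statistics on ``cfg`` species, predict on fresh test species.

    The test set uses an independent seed substream of ``cfg.seed``.
    Reports exact start/stop recovery and the boundary-difference summary
    for both the probabilistic predictor and the legacy fixed-window
    baseline.
    """
    if stats is None:
        train_genomes, train_feats = simulate_reference_set(cfg)
        stats = build_reference_statistics(train_genomes, train_feats)
    test_seed = int(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0] % 2**31)
    test_cfg = replace(cfg, n_species=n_test_species, seed=test_seed)
    genomes, truth = simulate_reference_set(test_cfg)
    hits = simulate_hits(truth, genomes, test_cfg)
    by_id = {g.id: g for g in genomes}
    trnas_by_id: dict[str, list[Feature]] = {}
    for f in truth:
        if f.kind == "tRNA":
            trnas_by_id.setdefault(f.seqid, []).append(f)
    preds: list[Feature] = []
    legacy: list[Feature] = []
    for hit in hits:
        genome = by_id[hit.seqid]
        trnas = trnas_by_id.get(hit.seqid, [])
        preds.append(predict_boundaries(genome, hit, trnas, stats).to_feature())
        legacy.append(legacy_predict(genome, hit).to_feature())
    cds_truth = [f for f in truth if f.kind == "CDS"]
    s_rec, e_rec, summary = _recovery_fractions(preds, cds_truth)
    ls_rec, le_rec, lsummary = _recovery_fractions(legacy, cds_truth)
    return RecoveryReport(
        n_genes=len(cds_truth),
        start_recovery=s_rec, stop_recovery=e_rec, summary=summary,
        legacy_start_recovery=ls_rec, legacy_stop_recovery=le_rec,
        legacy_summary=lsummary,
    )
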