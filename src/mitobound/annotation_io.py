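"""Readers/writers for the formats the tool touches, plus coordinate fixing.

All coordinates are internally 0-based half-open on the forward strand
(BED-native).  GFF3 and GenBank coordinates (1-based inclusive) are shifted
on read and restored on write, so every reader/writer pair round-trips
exactly.  Features crossing the origin of a circular genome keep
``start < end`` by letting ``end`` exceed the genome length; sequence
extraction is modular.

Gene names are normalized to canonical mitochondrial symbols on read
(``COI``/``COX1``/``CO1`` -> ``cox1``, ``CYTB`` -> ``cob``, ``ND4L`` ->
``nad4l``, ``tRNA-Phe`` -> ``trnF``, ...) because reference annotations are
wildly inconsistent and evaluation must match genes by symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_codes import registered_tables

__all__ = [
    "MT_PCGS",
    "TRNA_NAMES",
    "Genome",
    "Feature",
    "HmmHit",
    "normalize_gene_name",
    "read_fasta",
    "read_features",
    "read_genbank",
    "read_hits",
    "write_hits",
    "write_predictions",
    "extract_feature_sequence",
]

#: The 13 protein-coding genes of metazoan mitochondrial genomes.
MT_PCGS: tuple[str, ...] = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)

#: The 22 tRNA genes, in canonical vertebrate naming.
TRNA_NAMES: tuple[str, ...] = (
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA", "trnN",
    "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR", "trnH", "trnS1",
    "trnL1", "trnE", "trnT", "trnP",
)

_AA3_TO_TRNA = {
    "phe": "F", "val": "V", "leu": "L", "ile": "I", "gln": "Q", "met": "M",
    "trp": "W", "ala": "A", "asn": "N", "cys": "C", "tyr": "Y", "ser": "S",
    "asp": "D", "lys": "K", "gly": "G", "arg": "R", "his": "H", "glu": "E",
    "thr": "T", "pro": "P",
}

_PCG_SYNONYMS = {
    "co1": "cox1", "coi": "cox1", "coxi": "cox1", "cox1": "cox1", "mtco1": "cox1",
    "co2": "cox2", "coii": "cox2", "coxii": "cox2", "cox2": "cox2", "mtco2": "cox2",
    "co3": "cox3", "coiii": "cox3", "coxiii": "cox3", "cox3": "cox3", "mtco3": "cox3",
    "cytb": "cob", "cob": "cob", "cyb": "cob", "mtcyb": "cob",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "nd1": "nad1", "nad1": "nad1", "nadh1": "nad1",
    "nd2": "nad2", "nad2": "nad2", "nadh2": "nad2",
    "nd3": "nad3", "nad3": "nad3", "nadh3": "nad3",
    "nd4": "nad4", "nad4": "nad4", "nadh4": "nad4",
    "nd4l": "nad4l", "nad4l": "nad4l", "nadh4l": "nad4l",
    "nd5": "nad5", "nad5": "nad5", "nadh5": "nad5",
    "nd6": "nad6", "nad6": "nad6", "nadh6": "nad6",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def normalize_gene_name(name: str) -> str:
    """Map a raw gene label onto a canonical symbol.

    Protein-coding genes map onto the 13 canonical lowercase symbols,
    tRNAs onto ``trnX`` (numbered isoacceptor suffixes preserved).
    Unrecognized labels are returned lowercased so that downstream symbol
    matching is at least case-insensitive.
    """
    raw = name.strip()
    key = re.sub(r"[\s_\-]+", "", raw).lower()
    if key in _PCG_SYNONYMS:
        return _PCG_SYNONYMS[key]
    m = re.match(r"^trna?([a-z])([12]?)$", key)
    if m:
        return f"trn{m.group(1).upper()}{m.group(2)}"
    m = re.match(r"^trna([a-z]{3})([12]?)$", key)
    if m and m.group(1) in _AA3_TO_TRNA:
        return f"trn{_AA3_TO_TRNA[m.group(1)]}{m.group(2)}"
    return key


@dataclass(frozen=True)
class Genome:
    """One (possibly circular) mitochondrial genome sequence."""

    id: str
    sequence: str
    circular: bool = True
    code_table: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id!r}: illegal characters {sorted(bad)}")
        if self.code_table not in registered_tables():
            raise ValueError(f"genome {self.id!r}: unregistered code table {self.code_table}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    """A located gene/CDS/tRNA span in 0-based half-open forward coordinates.

    For origin-crossing features of circular genomes ``end`` may exceed the
    genome length; coordinates are taken modulo the length on extraction.
    ``stop_completeness`` distinguishes CDS that end in a polyadenylation-
    completed incomplete stop codon: ``full`` (length % 3 == 0), ``T``
    (% 3 == 1) or ``TA`` (% 3 == 2).
    """

    seqid: str
    gene: str
    kind: str  # {"CDS", "gene", "tRNA"}
    start: int
    end: int
    strand: str  # {"+", "-"}
    stop_completeness: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene}: invalid span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: invalid strand {self.strand!r}")
        if self.kind not in ("CDS", "gene", "tRNA"):
            raise ValueError(f"{self.gene}: invalid kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _completeness_from_length(length: int) -> str:
    return {0: "full", 1: "T", 2: "TA"}[length % 3]


@dataclass(frozen=True)
class HmmHit:
    """An approximate gene location from a profile-HMM search.

    ``s_s``/``s_e`` are the first/last aligned codon indices in the
    gene-local reading frame; ``q_s``/``q_e`` the matching 1-based amino
    acid columns of the query profile of length ``l_q``.  ``frame_anchor``
    places codon index 0 on the genome: it is the coordinate of the first
    base of codon 0 on the *gene-local axis*, i.e. the forward axis for
    plus-strand hits and the reverse-complement axis for minus-strand hits.
    """

    seqid: str
    gene: str
    strand: str
    s_s: int
    s_e: int
    q_s: int
    q_e: int
    l_q: int
    frame_anchor: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.q_s < self.q_e <= self.l_q):
            raise ValueError(
                f"hit {self.gene}: query columns violate 1 <= q_s < q_e <= l_q "
                f"({self.q_s}, {self.q_e}, {self.l_q})"
            )
        if self.s_e <= self.s_s:
            raise ValueError(f"hit {self.gene}: target codons must satisfy s_s < s_e")
        if self.strand not in "+-":
            raise ValueError(f"hit {self.gene}: invalid strand {self.strand!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(
    path: str | Path,
    circular: bool = True,
    code_table: int = 2,
) -> list[Genome]:
    """Read genomes from a FASTA file; sequences uppercased.

    Circularity and code table are metadata FASTA cannot carry, so they are
    supplied by the caller and applied to every record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [
        Genome(id=r.id, sequence=str(r.seq).upper(), circular=circular, code_table=code_table)
        for r in records
    ]


def _parse_gff3_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _feature_name(attrs: dict[str, str]) -> str:
    for key in ("Name", "gene", "ID", "product"):
        if key in attrs:
            return attrs[key]
    return "unknown"


_GFF_KINDS = {"cds": "CDS", "gene": "gene", "trna": "tRNA"}


def _read_gff3(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            _, _, ftype, start, end, _, strand, _, attrcol = cols
            kind = _GFF_KINDS.get(ftype.lower())
            if kind is None:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_gff3_attributes(attrcol)
            gene = normalize_gene_name(_feature_name(attrs))
            length = end_i - (start_i - 1)
            note = attrs.get("Note", "")
            if "incomplete_stop:" in note:
                completeness = note.split("incomplete_stop:", 1)[1].split(",")[0]
            elif kind == "CDS":
                completeness = _completeness_from_length(length)
            else:
                completeness = "unknown"
            feats.append(
                Feature(
                    seqid=cols[0], gene=gene, kind=kind,
                    start=start_i - 1, end=end_i, strand=strand,
                    stop_completeness=completeness,
                )
            )
    return feats


def _read_bed(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs at least 3 columns")
            try:
                start_i, end_i = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene = normalize_gene_name(cols[3]) if len(cols) > 3 else "unknown"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            kind = "tRNA" if gene.startswith("trn") else "gene"
            feats.append(
                Feature(seqid=cols[0], gene=gene, kind=kind,
                        start=start_i, end=end_i, strand=strand)
            )
    return feats


def _read_genbank_features(path: Path) -> list[Feature]:
    feats = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for f in rec.features:
            if f.type not in ("CDS", "gene", "tRNA"):
                continue
            quals = f.qualifiers
            raw = (quals.get("gene") or quals.get("product") or ["unknown"])[0]
            gene = normalize_gene_name(raw)
            start = int(f.location.start)
            end = int(f.location.end)
            strand = "-" if f.location.strand == -1 else "+"
            completeness = (
                _completeness_from_length(end - start) if f.type == "CDS" else "unknown"
            )
            feats.append(
                Feature(seqid=rec.id, gene=gene, kind=f.type,
                        start=start, end=end, strand=strand,
                        stop_completeness=completeness)
            )
    return feats


def read_features(path: str | Path, dialect: str = "gff3") -> list[Feature]:
    """Read annotation features, normalizing to 0-based half-open coordinates.

    ``dialect`` is one of ``gff3`` (1-based inclusive), ``bed`` (already
    half-open) or ``genbank-tbl`` (GenBank flat file; CDS/gene/tRNA only).
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed":
        return _read_bed(path)
    if dialect in ("genbank-tbl", "genbank"):
        return _read_genbank_features(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_genbank(path: str | Path) -> tuple[list[Genome], list[Feature]]:
    """Read genomes *and* features from a GenBank flat file.

    The ``/transl_table`` qualifier of the first CDS sets the genome's code
    table (default 2 when absent); topology comes from the record annotations.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        table = 2
        for f in rec.features:
            if f.type == "CDS" and "transl_table" in f.qualifiers:
                table = int(f.qualifiers["transl_table"][0])
                break
        circular = rec.annotations.get("topology", "circular") == "circular"
        genomes.append(
            Genome(id=rec.id, sequence=str(rec.seq).upper(),
                   circular=circular, code_table=table)
        )
    if not genomes:
        raise ValueError(f"{path}: no GenBank records found")
    return genomes, _read_genbank_features(Path(path))


_HIT_COLUMNS = ["gene", "strand", "target_start", "target_end",
                "query_start", "query_end", "query_length"]


def read_hits(path: str | Path) -> list[HmmHit]:
    """Read approximate gene hits from a TSV table.

    Required columns: gene, strand, target_start, target_end, query_start,
    query_end, query_length.  Optional: seqid, frame_anchor (gene-local
    coordinate of codon index 0; defaults to 0).  Rows violating the hit
    invariants are rejected with the offending row identified.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty and df.columns.size == 0:
        return []
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing hit columns {missing}")
    hits = []
    for idx, row in df.iterrows():
        try:
            hits.append(
                HmmHit(
                    seqid=str(row["seqid"]) if "seqid" in df.columns else "genome",
                    gene=normalize_gene_name(str(row["gene"])),
                    strand=str(row["strand"]),
                    s_s=int(row["target_start"]),
                    s_e=int(row["target_end"]),
                    q_s=int(row["query_start"]),
                    q_e=int(row["query_end"]),
                    l_q=int(row["query_length"]),
                    frame_anchor=int(row["frame_anchor"]) if "frame_anchor" in df.columns else 0,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 1}: {exc}") from exc
    return hits


def write_hits(hits: Sequence[HmmHit], path: str | Path) -> None:
    """Write hits as the TSV table `read_hits` consumes."""
    df = pd.DataFrame(
        {
            "seqid": [h.seqid for h in hits],
            "gene": [h.gene for h in hits],
            "strand": [h.strand for h in hits],
            "target_start": [h.s_s for h in hits],
            "target_end": [h.s_e for h in hits],
            "query_start": [h.q_s for h in hits],
            "query_end": [h.q_e for h in hits],
            "query_length": [h.l_q for h in hits],
            "frame_anchor": [h.frame_anchor for h in hits],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_predictions(
    features: Iterable[Feature], path: str | Path, dialect: str = "gff3"
) -> None:
    """Write predicted features to GFF3 or BED.

    Incomplete stop codons are flagged in the GFF3 attribute column as
    ``Note=incomplete_stop:T`` / ``:TA``; the span always ends at the last
    annotated base of the (possibly incomplete) stop codon.
    """
    path = Path(path)
    feats = list(features)
    if dialect == "gff3":
        lines = ["##gff-version 3"]
        for f in feats:
            attrs = f"ID={f.gene};Name={f.gene}"
            if f.stop_completeness in ("T", "TA"):
                attrs += f";Note=incomplete_stop:{f.stop_completeness}"
            lines.append(
                "\t".join(
                    [f.seqid, "mitobound", f.kind, str(f.start + 1), str(f.end),
                     ".", f.strand, "0" if f.kind == "CDS" else ".", attrs]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "bed":
        lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
        for f in feats:
            lines.append(
                "\t".join([f.seqid, str(f.start), str(f.end), f.gene, "0", f.strand])
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def extract_feature_sequence(genome: Genome, feature: Feature) -> str:
    """Feature sequence in reading orientation (minus strand: revcomp).

    Handles origin-crossing spans of circular genomes via modular indexing.
    """
    n = len(genome)
    if feature.end <= n:
        seq = genome.sequence[feature.start:feature.end]
    else:
        if not genome.circular:
            raise ValueError(f"{feature.gene}: span exceeds linear genome")
        seq = genome.sequence[feature.start:] + genome.sequence[: feature.end % n]
    return reverse_complement(seq) if feature.strand == "-" else seq
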