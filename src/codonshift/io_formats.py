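"""Readers/writers for the formats the pipeline touches.

FASTA and GenBank flat files are handled through Biopython; GFF3 through
gffutils.  Feature coordinates are 1-based inclusive externally (the GFF and
GenBank convention) and converted to 0-based half-open slices only at the
point of sequence extraction.  Multi-interval features (``join(...)`` /
multi-line GFF CDS) are stored with their intervals ordered 5'->3' on the
coding strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_codes import CodingSequence

_ORF_NAME = re.compile(r"^orf[_-]?\d+", re.IGNORECASE)

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "ORF")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature on a genome sequence.

    ``intervals`` are 1-based inclusive ``(start, end)`` pairs, ordered
    5'->3' on the coding strand (descending genomic order on the minus
    strand).
    """

    genome_id: str
    feature_type: str
    gene_id: str
    intervals: tuple[tuple[int, int], ...]
    strand: str
    product: str = ""
    anticodon: str = ""
    attributes: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"feature {self.gene_id!r}: strand must be + or -")
        for s, e in self.intervals:
            if not (1 <= s <= e):
                raise ValueError(f"feature {self.gene_id!r}: bad interval {s}..{e}")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def extract(self, genome: str) -> str:
        """Spliced, strand-resolved sequence of this feature."""
        for s, e in self.intervals:
            if e > len(genome):
                raise ValueError(
                    f"feature {self.gene_id!r}: interval {s}..{e} outside "
                    f"sequence of length {len(genome)}"
                )
        parts = sorted(self.intervals)
        seq = "".join(genome[s - 1 : e] for s, e in parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq.upper()


def classify_feature_type(raw_type: str, gene_id: str) -> str:
    """Map a raw annotation type to one of CDS/tRNA/rRNA/ORF.

    Lineage-specific open reading frames (names like ``orf761``) are tagged
    ORF so they can be excluded from conserved-gene analyses by default.
    """
    t = raw_type
    if t == "CDS" and _ORF_NAME.match(gene_id or ""):
        return "ORF"
    return t


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` dict."""
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
            break
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Feature tables


def read_features(path, dialect: str) -> list[FeatureRecord]:
    """Read features from ``gff3``, ``genbank-flat`` or ``tsv`` input."""
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "genbank-flat":
        return _read_genbank(path)
    if dialect == "tsv":
        return _read_feature_tsv(path)
    raise ValueError(f"unknown feature dialect {dialect!r}")


def _orient(intervals: list[tuple[int, int]], strand: str) -> tuple[tuple[int, int], ...]:
    return tuple(sorted(intervals, reverse=(strand == "-")))


def _read_gff3(path) -> list[FeatureRecord]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # Multi-line CDS features share an ID attribute; group their segments.
    grouped: dict[tuple, dict] = {}
    for f in db.all_features():
        if f.featuretype not in ("CDS", "tRNA", "rRNA", "gene", "exon", "mRNA"):
            continue
        if f.featuretype in ("gene", "exon", "mRNA"):
            continue
        raw_id = f.attributes.get("ID", [f.id])[0]
        # undo gffutils' create_unique suffixing when grouping parts
        base_id = re.sub(r"_\d+$", "", raw_id) if "_" in raw_id else raw_id
        key = (f.seqid, f.featuretype, base_id, f.strand)
        entry = grouped.setdefault(
            key,
            {
                "intervals": [],
                "gene": f.attributes.get("gene", [None])[0]
                or f.attributes.get("Name", [None])[0]
                or base_id,
                "product": f.attributes.get("product", [""])[0],
                "anticodon": f.attributes.get("anticodon", [""])[0],
            },
        )
        entry["intervals"].append((f.start, f.end))
    out = []
    for (seqid, ftype, _base, strand), entry in grouped.items():
        gene_id = entry["gene"]
        out.append(
            FeatureRecord(
                genome_id=seqid,
                feature_type=classify_feature_type(ftype, gene_id),
                gene_id=gene_id,
                intervals=_orient(entry["intervals"], strand),
                strand=strand,
                product=entry["product"],
                anticodon=entry["anticodon"].upper().replace("U", "T"),
            )
        )
    return out


def _read_genbank(path) -> list[FeatureRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type not in ("CDS", "tRNA", "rRNA"):
                continue
            quals = feat.qualifiers
            gene_id = (
                quals.get("gene", [None])[0]
                or quals.get("locus_tag", [None])[0]
                or quals.get("product", ["?"])[0]
            )
            strand = "-" if feat.location.strand == -1 else "+"
            intervals = [(int(p.start) + 1, int(p.end)) for p in feat.location.parts]
            anticodon = ""
            note = " ".join(quals.get("note", []) + quals.get("anticodon", []))
            m = re.search(r"anticodon[:=\s]*([ACGTUacgtu]{3})", note)
            if m:
                anticodon = m.group(1).upper().replace("U", "T")
            out.append(
                FeatureRecord(
                    genome_id=rec.id,
                    feature_type=classify_feature_type(feat.type, gene_id),
                    gene_id=gene_id,
                    intervals=_orient(intervals, strand),
                    strand=strand,
                    product=quals.get("product", [""])[0],
                    anticodon=anticodon,
                )
            )
    return out


_TSV_COLUMNS = ["genome_id", "feature_type", "gene_id", "intervals", "strand", "product", "anticodon"]


def _read_feature_tsv(path) -> list[FeatureRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_TSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing feature columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        intervals = []
        for chunk in str(row.intervals).split(","):
            s, e = chunk.split("-")
            intervals.append((int(s), int(e)))
        out.append(
            FeatureRecord(
                genome_id=row.genome_id,
                feature_type=classify_feature_type(row.feature_type, row.gene_id),
                gene_id=row.gene_id,
                intervals=_orient(intervals, row.strand),
                strand=row.strand,
                product=getattr(row, "product", ""),
                anticodon=getattr(row, "anticodon", ""),
            )
        )
    return out


def write_feature_tsv(features: Sequence[FeatureRecord], path) -> None:
    rows = [
        {
            "genome_id": f.genome_id,
            "feature_type": f.feature_type,
            "gene_id": f.gene_id,
            "intervals": ",".join(f"{s}-{e}" for s, e in f.intervals),
            "strand": f.strand,
            "product": f.product,
            "anticodon": f.anticodon,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_gff3(features: Sequence[FeatureRecord], path, source: str = "codonshift") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = "CDS" if f.feature_type == "ORF" else f.feature_type
            attrs = [f"ID={f.gene_id}", f"gene={f.gene_id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.anticodon:
                attrs.append(f"anticodon={f.anticodon}")
            for s, e in sorted(f.intervals):
                fh.write(
                    f"{f.genome_id}\t{source}\t{ftype}\t{s}\t{e}\t.\t{f.strand}\t"
                    f"{0 if ftype == 'CDS' else '.'}\t{';'.join(attrs)}\n"
                )


# ---------------------------------------------------------------------------
# CDS extraction


@dataclass
class ExtractionReport:
    """CDSs extracted from annotations plus the features skipped and why."""

    coding_sequences: list[CodingSequence]
    skipped: list[tuple[str, str]]  # (gene_id, reason)


def extract_coding_sequences(
    genomes: dict[str, str],
    features: Sequence[FeatureRecord],
    *,
    include_orfs: bool = False,
    dedupe_identical: bool = False,
) -> ExtractionReport:
    """Extract every CDS feature as a spliced, strand-resolved CodingSequence.

    Features whose length is not a multiple of 3 or that contain ambiguity
    codes are skipped with a logged reason rather than raising.  With
    ``dedupe_identical``, CDSs with byte-identical extracted sequences within
    one genome (inverted-repeat copies) contribute once.
    """
    out: list[CodingSequence] = []
    skipped: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for f in features:
        if f.feature_type == "ORF" and not include_orfs:
            skipped.append((f.gene_id, "lineage-specific ORF excluded"))
            continue
        if f.feature_type != "CDS" and not (f.feature_type == "ORF" and include_orfs):
            continue
        if f.genome_id not in genomes:
            skipped.append((f.gene_id, f"genome {f.genome_id!r} not provided"))
            continue
        seq = f.extract(genomes[f.genome_id])
        if len(seq) % 3 != 0:
            skipped.append((f.gene_id, f"length {len(seq)} not a multiple of 3"))
            continue
        if dedupe_identical:
            key = (f.genome_id, seq)
            if key in seen:
                skipped.append((f.gene_id, "duplicate sequence (inverted repeat)"))
                continue
            seen.add(key)
        try:
            out.append(CodingSequence(f.gene_id, seq, genome_id=f.genome_id))
        except ValueError as exc:
            skipped.append((f.gene_id, str(exc)))
    return ExtractionReport(out, skipped)
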