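"""Codon-usage tabulation and sense-to-stop candidate detection.

A codon that has become a termination signal leaves two fingerprints in an
annotated genome: it occurs only as the final (annotated termination) codon
of coding sequences, and no tRNA gene in the genome can decode it.  The
stop scan combines both, classifying every codon as *stop-candidate*
(terminal-only, undecodable), *sense* (any internal occurrence), *absent*
(unused), or *ambiguous* (terminal-only but decodable by an annotated
tRNA).

Decodability follows the wobble rules at the codon third position:
``strict-wc`` pairs only Watson-Crick; ``wobble`` additionally allows
G34:U3 and U34:G3; ``superwobble`` lets an (unmodified) U34 read all four
third-position bases, so one tRNA can serve a whole four-codon box.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genetic_codes import ALL_CODONS, CodingSequence, normalize_codon
from .io_formats import FeatureRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

WOBBLE_MODES = ("strict-wc", "wobble", "superwobble")


@dataclass
class CodonUsageTable:
    """Integer codon counts for one genome."""

    genome_id: str
    internal: Counter = field(default_factory=Counter)
    terminal: Counter = field(default_factory=Counter)
    include_orfs: bool = False
    include_terminal_stops: bool = False

    def count(self, codon: str) -> int:
        codon = normalize_codon(codon)
        n = self.internal[codon]
        if self.include_terminal_stops:
            n += self.terminal[codon]
        return n

    @property
    def counts(self) -> dict[str, int]:
        return {c: self.count(c) for c in ALL_CODONS}

    def total(self) -> int:
        return sum(self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_id": self.genome_id,
                    "codon": c,
                    "count": self.count(c),
                    "internal_count": self.internal[c],
                    "terminal_count": self.terminal[c],
                }
                for c in ALL_CODONS
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def count_codons(
    cds_set: Iterable[CodingSequence],
    *,
    genome_id: str = "",
    include_terminal_stops: bool = False,
    dedupe_identical: bool = False,
) -> CodonUsageTable:
    """Tabulate codon usage over a set of coding sequences.

    The annotated terminal codon of each CDS is tallied separately and
    merged into the headline counts only with ``include_terminal_stops``.
    ``dedupe_identical`` drops CDSs with byte-identical sequences
    (inverted-repeat duplicates) after the first occurrence.
    """
    table = CodonUsageTable(genome_id, include_terminal_stops=include_terminal_stops)
    seen: set[str] = set()
    for cds in cds_set:
        if dedupe_identical:
            if cds.nucleotides in seen:
                continue
            seen.add(cds.nucleotides)
        codons = list(cds.codons())
        table.internal.update(codons[:-1])
        if codons:
            table.terminal[codons[-1]] += 1
    return table


def decodable_codons(anticodon: str, wobble_mode: str = "wobble") -> frozenset[str]:
    """Codons readable by a tRNA with *anticodon* (5'->3', position 34 first)."""
    if wobble_mode not in WOBBLE_MODES:
        raise ValueError(f"unknown wobble mode {wobble_mode!r}; options: {WOBBLE_MODES}")
    ac = normalize_codon(anticodon)
    base = ac.translate(_COMPLEMENT)[::-1]  # Watson-Crick codon
    third = {base[2]}
    n34 = ac[0]
    if wobble_mode in ("wobble", "superwobble"):
        if n34 == "G":
            third.add("T")  # G34:U3
        elif n34 == "T":
            third.add("G")  # U34:G3
    if wobble_mode == "superwobble" and n34 == "T":
        third = {"A", "C", "G", "T"}
    return frozenset(base[:2] + t for t in third)


VERDICT_STOP = "stop-candidate"
VERDICT_SENSE = "sense"
VERDICT_ABSENT = "absent"
VERDICT_AMBIGUOUS = "ambiguous"


@dataclass
class StopScanReport:
    """Per-codon internal/terminal occurrence and decodability verdicts."""

    rows: dict[str, dict]
    wobble_mode: str

    def verdict(self, codon: str) -> str:
        return self.rows[normalize_codon(codon)]["verdict"]

    def stop_candidates(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.rows[c]["verdict"] == VERDICT_STOP)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "codon": c,
                    "internal_count": r["internal_count"],
                    "terminal_count": r["terminal_count"],
                    "genes_with_terminal_use": ",".join(r["genes_with_terminal_use"]),
                    "cognate_trnas": ",".join(r["cognate_trnas"]),
                    "verdict": r["verdict"],
                }
                for c, r in ((c, self.rows[c]) for c in ALL_CODONS)
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def stop_scan(
    cds_set: Iterable[CodingSequence],
    trna_features: Sequence[FeatureRecord | str],
    wobble_mode: str = "wobble",
) -> StopScanReport:
    """Classify every codon by terminal-only occurrence and tRNA decodability.

    ``trna_features`` may be FeatureRecords carrying anticodon annotations
    or bare anticodon strings.
    """
    decoders: dict[str, list[str]] = {c: [] for c in ALL_CODONS}
    for t in trna_features:
        if isinstance(t, str):
            name, anticodon = t, t
        else:
            if not t.anticodon:
                continue
            name, anticodon = t.gene_id, t.anticodon
        for codon in decodable_codons(anticodon, wobble_mode):
            decoders[codon].append(name)

    internal: Counter = Counter()
    terminal: Counter = Counter()
    terminal_genes: dict[str, list[str]] = {c: [] for c in ALL_CODONS}
    for cds in cds_set:
        codons = list(cds.codons())
        internal.update(codons[:-1])
        if codons:
            terminal[codons[-1]] += 1
            terminal_genes[codons[-1]].append(cds.gene_id)

    rows = {}
    for codon in ALL_CODONS:
        n_int, n_term = internal[codon], terminal[codon]
        trnas = sorted(set(decoders[codon]))
        if n_int == 0 and n_term == 0:
            verdict = VERDICT_ABSENT
        elif n_int > 0:
            verdict = VERDICT_SENSE
        elif trnas:
            verdict = VERDICT_AMBIGUOUS
        else:
            verdict = VERDICT_STOP
        rows[codon] = {
            "internal_count": n_int,
            "terminal_count": n_term,
            "genes_with_terminal_use": terminal_genes[codon],
            "cognate_trnas": trnas,
            "verdict": verdict,
        }
    return StopScanReport(rows, wobble_mode)
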