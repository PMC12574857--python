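"""Translation tables and conceptual translation.

The unit of inference in this package is the genetic code table: a total map
from the 64 codons to a meaning, where a meaning is a single-letter amino
acid, the stop symbol ``'*'``, or the unknown symbol ``'X'`` (used for codons
whose meaning cannot be deduced).  Besides the standard code and the NCBI
alternative tables relevant to organelles, the module ships the novel
organellar code variants of pedinophytes and of the pedinophyte-derived
plastids of green dinoflagellates (peDinoflagellates), which are not part of
the NCBI list:

``pedinomonadales-mito``
    UGA = Trp, AUA = Met (Pedinomonadales mitochondria).
``marsupiomonadales-mito``
    AGA/AGG = Ala, UUA/UUG = stop; AUA is too rare for its meaning to be
    resolved and defaults to ``'X'`` (overridable).
``resultomonadaceae-okinawensis-mito``
    UGA = Trp, AGA/AGG = Ala, UUA/UUG = stop, AUA = Met.
``pedinophyte-plastid-AUA-Met``
    plastid code with AUA = Met (nascent Ile-to-Met reassignment).
``pedinoflagellate-plastid``
    AUA = Met, AGA/AGG = Ala, UUA/UCA = stop; UCG keeps its standard
    serine meaning.

Codons are normalized internally to the DNA alphabet (T, not U); all public
entry points accept either alphabet.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

from Bio.Data import CodonTable as _NCBICodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
UNKNOWN = "X"
VALID_MEANINGS = frozenset(AMINO_ACIDS) | {STOP, UNKNOWN}

ALL_CODONS = tuple("".join(c) for c in itertools.product("TCAG", repeat=3))


def normalize_codon(codon: str) -> str:
    """Uppercase a codon and convert U to T; reject anything not ACGT^3."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise ValueError(f"invalid codon {codon!r}")
    return c


class CodeError(ValueError):
    """Raised for malformed or unknown genetic-code tables."""


@dataclass(frozen=True)
class GeneticCodeTable:
    """A total codon -> meaning map with exactly 64 entries.

    Parameters
    ----------
    name:
        Short identifier for the table.
    assignments:
        Mapping of the 64 codons (DNA or RNA spelling accepted) to a
        meaning in the 20 amino acids, ``'*'`` or ``'X'``.
    """

    name: str
    assignments: Mapping[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        norm = {normalize_codon(c): m for c, m in dict(self.assignments).items()}
        if len(norm) != 64:
            raise CodeError(f"table {self.name!r} has {len(norm)} codons, need 64")
        bad = {c: m for c, m in norm.items() if m not in VALID_MEANINGS}
        if bad:
            raise CodeError(f"table {self.name!r} has invalid meanings: {bad}")
        if STOP not in norm.values():
            raise CodeError(f"table {self.name!r} defines no stop codon")
        object.__setattr__(self, "assignments", norm)

    def __getitem__(self, codon: str) -> str:
        return self.assignments[normalize_codon(codon)]

    def meaning(self, codon: str) -> str:
        return self[codon]

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.assignments[c] == STOP)

    def codons_for(self, meaning: str) -> tuple[str, ...]:
        """All codons carrying *meaning* under this table."""
        return tuple(c for c in ALL_CODONS if self.assignments[c] == meaning)

    def diff(self, other: "GeneticCodeTable") -> dict[str, tuple[str, str]]:
        """Codons whose meaning differs from *other*: codon -> (self, other)."""
        return {
            c: (self.assignments[c], other.assignments[c])
            for c in ALL_CODONS
            if self.assignments[c] != other.assignments[c]
        }

    def with_assignments(self, changes: Mapping[str, str], name: str | None = None) -> "GeneticCodeTable":
        """A new table with *changes* applied on top of this one."""
        new = dict(self.assignments)
        for codon, meaning in changes.items():
            new[normalize_codon(codon)] = meaning
        return GeneticCodeTable(name or self.name, new)

    # -- serialization (NCBI-style 64-entry JSON map) ----------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "assignments": dict(self.assignments)}, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GeneticCodeTable":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["name"], obj["assignments"])


def _ncbi_table(table_id: int, name: str) -> GeneticCodeTable:
    ncbi = _NCBICodonTable.unambiguous_dna_by_id[table_id]
    assignments = {c: ncbi.forward_table.get(c, STOP) for c in ALL_CODONS}
    return GeneticCodeTable(name, assignments)


STANDARD_CODE = _ncbi_table(1, "standard")

_BUILTIN_DIFFS: dict[str, dict[str, str]] = {
    "standard": {},
    # Mold/protozoan mitochondrial table: UGA = Trp.
    "trans-table-4": {"TGA": "W"},
    # Bacterial/plastid table: codon meanings identical to the standard code
    # (it differs only in permitted initiation codons, which this analysis
    # does not model).
    "trans-table-11": {},
    "pedinomonadales-mito": {"TGA": "W", "ATA": "M"},
    "marsupiomonadales-mito": {"AGA": "A", "AGG": "A", "TTA": STOP, "TTG": STOP, "ATA": UNKNOWN},
    "resultomonadaceae-okinawensis-mito": {
        "TGA": "W", "AGA": "A", "AGG": "A", "TTA": STOP, "TTG": STOP, "ATA": "M",
    },
    "pedinophyte-plastid-AUA-Met": {"ATA": "M"},
    "pedinoflagellate-plastid": {"ATA": "M", "AGA": "A", "AGG": "A", "TTA": STOP, "TCA": STOP},
}

BUILTIN_CODE_NAMES = tuple(_BUILTIN_DIFFS)


def builtin_code(name: str, *, aua: str | None = None) -> GeneticCodeTable:
    """Return a built-in translation table by name.

    Parameters
    ----------
    name:
        One of :data:`BUILTIN_CODE_NAMES`.
    aua:
        Optional override for the AUA codon meaning.  The Marsupiomonadales
        mitochondrial table leaves AUA unresolved (``'X'``); pass e.g.
        ``aua="M"`` to commit to a methionine reading.
    """
    if name not in _BUILTIN_DIFFS:
        raise CodeError(
            f"unknown genetic code {name!r}; available: {', '.join(BUILTIN_CODE_NAMES)}"
        )
    diffs = dict(_BUILTIN_DIFFS[name])
    if aua is not None:
        if aua not in VALID_MEANINGS:
            raise CodeError(f"invalid AUA override {aua!r}")
        diffs["ATA"] = aua
    return STANDARD_CODE.with_assignments(diffs, name=name)


# ---------------------------------------------------------------------------
# Coding sequences and translation


@dataclass(frozen=True)
class CodingSequence:
    """A spliced, strand-resolved coding sequence, 5'->3' on the sense strand.

    The first codon is the annotated initiation codon and the last the
    annotated termination codon.  Ambiguity codes are rejected.
    """

    gene_id: str
    nucleotides: str
    genome_id: str = ""

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError(
                f"CDS {self.gene_id!r}: length {len(seq)} is not a multiple of 3"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"CDS {self.gene_id!r}: ambiguous/invalid bases {sorted(bad)}"
            )
        object.__setattr__(self, "nucleotides", seq)

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> Iterator[str]:
        seq = self.nucleotides
        for i in range(0, len(seq), 3):
            yield seq[i : i + 3]


class TranslationResult(NamedTuple):
    """Protein string plus the codon indices of any internal stop meanings."""

    protein: str
    internal_stops: tuple[int, ...]


def translate(
    cds: CodingSequence,
    code: GeneticCodeTable,
    stop_policy: str = "terminal-only-strip",
) -> TranslationResult:
    """Translate a coding sequence under *code*.

    ``stop_policy='terminal-only-strip'`` removes a terminal stop meaning
    from the protein; internal stops are rendered as ``'*'`` and their codon
    indices (0-based) reported in ``internal_stops`` rather than silently
    dropped.  ``stop_policy='keep-as-star'`` keeps every stop as ``'*'``.
    """
    if stop_policy not in ("terminal-only-strip", "keep-as-star"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    meanings = [code[c] for c in cds.codons()]
    internal = tuple(i for i, m in enumerate(meanings[:-1]) if m == STOP)
    if stop_policy == "terminal-only-strip" and meanings and meanings[-1] == STOP:
        meanings = meanings[:-1]
    return TranslationResult("".join(meanings), internal)
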