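"""Conserved-column profiling of focal codons against reference alignments.

The evidence unit of the codon-meaning inference is the *conserved column*:
a position of a reference protein alignment where a single amino acid
reaches a frequency threshold (default 70%, inclusive) among the compared
sequences.  Each codon of the focal genome maps to one alignment column via
the focal row's gap pattern; the profile accumulates, per codon, how often
it sits in columns conserved for each amino acid.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .genetic_codes import ALL_CODONS, CodingSequence, GeneticCodeTable, STOP

GAP = "-"


@dataclass
class AlignedPanel:
    """One gene's protein alignment: reference rows plus the focal row."""

    gene_id: str
    rows: dict[str, str]
    focal_taxon: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"panel {self.gene_id!r}: unequal row lengths {lengths}")
        if self.focal_taxon not in self.rows:
            raise ValueError(
                f"panel {self.gene_id!r}: focal taxon {self.focal_taxon!r} missing"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def focal_row(self) -> str:
        return self.rows[self.focal_taxon]

    def reference_rows(self) -> dict[str, str]:
        return {t: s for t, s in self.rows.items() if t != self.focal_taxon}

    def subset(self, taxa, keep_focal: bool = True) -> "AlignedPanel":
        keep = set(taxa) | ({self.focal_taxon} if keep_focal else set())
        return AlignedPanel(
            self.gene_id,
            {t: s for t, s in self.rows.items() if t in keep},
            self.focal_taxon,
        )

    def with_focal_protein(self, protein: str) -> "AlignedPanel":
        """Replace the focal row's residues, preserving its gap pattern."""
        old = self.focal_row
        if len(old.replace(GAP, "")) != len(protein):
            raise ValueError(
                f"panel {self.gene_id!r}: replacement protein length "
                f"{len(protein)} != ungapped focal length {len(old.replace(GAP, ''))}"
            )
        it = iter(protein)
        new_row = "".join(next(it) if c != GAP else GAP for c in old)
        rows = dict(self.rows)
        rows[self.focal_taxon] = new_row
        return AlignedPanel(self.gene_id, rows, self.focal_taxon)


def conserved_columns(
    panel: AlignedPanel,
    threshold: float = 0.70,
    *,
    exclude_focal: bool = True,
    gap_policy: str = "count-in-denominator",
    min_residues: int = 4,
    inclusive: bool = True,
) -> list[str | None]:
    """Per-column conservation verdict: the consensus amino acid or ``None``.

    A column is conserved for amino acid ``a`` when ``freq(a) >= threshold``
    (``>`` with ``inclusive=False``).  The denominator counts all rows
    (gaps included) under the default gap policy, or only residue-bearing
    rows with ``gap_policy='exclude'``.  Columns with fewer than
    ``min_residues`` non-gap reference residues get no verdict.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if gap_policy not in ("count-in-denominator", "exclude"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    rows = panel.reference_rows() if exclude_focal else panel.rows
    seqs = list(rows.values())
    verdicts: list[str | None] = []
    for j in range(panel.n_columns):
        col = [s[j] for s in seqs]
        residues = [c for c in col if c != GAP]
        if len(residues) < min_residues:
            verdicts.append(None)
            continue
        denom = len(col) if gap_policy == "count-in-denominator" else len(residues)
        top, top_n = Counter(residues).most_common(1)[0]
        frac = top_n / denom
        ok = frac >= threshold if inclusive else frac > threshold
        # '*' / 'X' in reference rows never define a conserved amino acid
        verdicts.append(top if ok and top not in (STOP, "X") else None)
    return verdicts


def codon_column_map(panel: AlignedPanel, cds: CodingSequence) -> list[tuple[int, int]]:
    """Pair each focal codon index with its alignment column.

    The focal row's ungapped length must equal the number of translated
    codons; the annotated terminal (stop) codon therefore has no column.
    """
    focal = panel.focal_row
    n_mapped = len(focal.replace(GAP, ""))
    if n_mapped != cds.n_codons - 1:
        raise ValueError(
            f"panel {panel.gene_id!r}: focal row has {n_mapped} residues but CDS "
            f"{cds.gene_id!r} has {cds.n_codons - 1} non-terminal codons"
        )
    pairs = []
    codon_idx = 0
    for col, c in enumerate(focal):
        if c != GAP:
            pairs.append((codon_idx, col))
            codon_idx += 1
    return pairs


@dataclass
class ConservedColumnProfile:
    """Per-codon evidence: counts of conserved columns per consensus residue.

    ``conserved[c][a]`` counts alignment columns where the focal CDS carries
    codon ``c`` and the column is conserved for amino acid ``a``;
    ``totals[c]`` counts every mapped occurrence of ``c`` (terminal stop
    codons excluded).
    """

    conserved: dict[str, Counter] = field(default_factory=dict)
    totals: Counter = field(default_factory=Counter)
    evidence: list[tuple[str, int, str, int, str | None]] = field(default_factory=list)

    def conserved_counts(self, codon: str) -> Counter:
        return self.conserved.get(codon, Counter())

    def conserved_occurrences(self, codon: str) -> int:
        return sum(self.conserved_counts(codon).values())

    def total_occurrences(self, codon: str) -> int:
        return self.totals.get(codon, 0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for codon in ALL_CODONS:
            counts = self.conserved_counts(codon)
            for aa in sorted(counts):
                rows.append(
                    {
                        "codon": codon,
                        "amino_acid": aa,
                        "conserved_count": counts[aa],
                        "total_count": self.total_occurrences(codon),
                    }
                )
            if not counts and self.total_occurrences(codon):
                rows.append(
                    {
                        "codon": codon,
                        "amino_acid": "",
                        "conserved_count": 0,
                        "total_count": self.total_occurrences(codon),
                    }
                )
        return pd.DataFrame(rows, columns=["codon", "amino_acid", "conserved_count", "total_count"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def profile_codons(
    panels: dict[str, AlignedPanel],
    cds_set: dict[str, CodingSequence],
    verdicts: dict[str, list[str | None]],
) -> ConservedColumnProfile:
    """Accumulate the conserved-column profile over all genes.

    ``panels``, ``cds_set`` and ``verdicts`` are keyed by gene id; genes in
    ``panels`` must have a CDS and a verdict list.
    """
    missing = set(panels) - set(cds_set)
    if missing:
        raise ValueError(f"no CDS provided for genes: {sorted(missing)}")
    profile = ConservedColumnProfile()
    for gene_id, panel in panels.items():
        cds = cds_set[gene_id]
        v = verdicts[gene_id]
        codons = list(cds.codons())
        for codon_idx, col in codon_column_map(panel, cds):
            codon = codons[codon_idx]
            profile.totals[codon] += 1
            consensus = v[col]
            if consensus is not None:
                profile.conserved.setdefault(codon, Counter())[consensus] += 1
            profile.evidence.append((gene_id, codon_idx, codon, col, consensus))
    return profile


# ---------------------------------------------------------------------------
# Inserting a focal sequence into an existing alignment


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
_SCORE = np.array(
    [[_BLOSUM62[a][b] for b in _ALPHABET] for a in _ALPHABET], dtype=float
)


def attach_focal(
    alignment: dict[str, str],
    focal_protein: str,
    focal_taxon: str = "focal",
    gene_id: str = "",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> AlignedPanel:
    """Insert a focal protein into an alignment by profile alignment.

    A global Needleman-Wunsch alignment with affine gaps is computed between
    the focal sequence and the column-frequency profile of the existing
    alignment, scoring a residue against a column by its expected BLOSUM62
    score over the column's residues ('X', '*' and gaps score 0).  Existing
    rows are unchanged except for all-gap columns inserted where the focal
    sequence has unalignable residues.
    """
    if not alignment or not focal_protein:
        raise ValueError("attach_focal requires a non-empty alignment and focal protein")
    seqs = list(alignment.values())
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("existing alignment rows have unequal lengths")

    # column profile: frequency of each amino acid over all rows (gaps and
    # unknown symbols contribute zero score mass)
    freq = np.zeros((L, len(_ALPHABET)))
    for s in seqs:
        for j, c in enumerate(s):
            if c in _AA_INDEX:
                freq[j, _AA_INDEX[c]] += 1
    freq /= len(seqs)
    # col_score[j, a]: expected score of residue a against column j
    col_score = freq @ _SCORE.T  # (L, 20)

    m = len(focal_protein)
    NEG = -1e9
    M = np.full((m + 1, L + 1), NEG)
    Ix = np.full((m + 1, L + 1), NEG)  # gap in profile: focal residue in new column
    Iy = np.full((m + 1, L + 1), NEG)  # gap in focal
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, L + 1):
        Iy[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        a = focal_protein[i - 1]
        arow = _AA_INDEX.get(a)
        for j in range(0, L + 1):
            if j > 0:
                s = col_score[j - 1, arow] if arow is not None else 0.0
                M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            if j > 0:
                Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)

    # traceback (prefer matches, then focal-gap, then new columns)
    ops: list[str] = []
    i, j = m, L
    state = int(np.argmax([M[i, j], Iy[i, j], Ix[i, j]]))  # 0=M, 1=Iy, 2=Ix
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("M")
            a = focal_protein[i - 1]
            arow = _AA_INDEX.get(a)
            s = col_score[j - 1, arow] if arow is not None else 0.0
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            # pick the predecessor whose score equals prev
            for st, val in ((0, M[i, j]), (1, Iy[i, j]), (2, Ix[i, j])):
                if abs(val - prev) < 1e-6:
                    state = st
                    break
        elif state == 2 or (j == 0 and i > 0):
            ops.append("I")  # focal residue, new all-gap column
            prev = Ix[i, j]
            i -= 1
            state = 0 if abs(M[i, j] + gap_open - prev) < 1e-6 else 2
        else:
            ops.append("D")  # focal gap against existing column
            prev = Iy[i, j]
            j -= 1
            state = 0 if abs(M[i, j] + gap_open - prev) < 1e-6 else 1
    ops.reverse()

    focal_row: list[str] = []
    new_rows: dict[str, list[str]] = {t: [] for t in alignment}
    fi = ci = 0
    for op in ops:
        if op == "M":
            focal_row.append(focal_protein[fi])
            for t in alignment:
                new_rows[t].append(alignment[t][ci])
            fi += 1
            ci += 1
        elif op == "D":
            focal_row.append(GAP)
            for t in alignment:
                new_rows[t].append(alignment[t][ci])
            ci += 1
        else:
            focal_row.append(focal_protein[fi])
            for t in alignment:
                new_rows[t].append(GAP)
            fi += 1
    rows = {t: "".join(v) for t, v in new_rows.items()}
    rows[focal_taxon] = "".join(focal_row)
    return AlignedPanel(gene_id or "gene", rows, focal_taxon)
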