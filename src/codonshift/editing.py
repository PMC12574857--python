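"""RNA-editing site calling from read pileups and sequence correction.

Codon-meaning analyses concern mature mRNA, not the genome: substitutional
editing can turn an apparent in-frame stop into a sense codon (restoring an
intact reading frame) or vice versa.  A position is considered edited only
when the majority of mapped reads -- strictly more than half of the counted
bases -- support a base different from the genomic reference; exact ties
are rejected and positions below the depth cutoff are reported as
uncovered (uncorrectable) rather than called.

Single-nucleotide indel repairs in homopolymer tracks are outside the
automatic caller; supply them as an explicit per-site patch list instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genetic_codes import GeneticCodeTable, STANDARD_CODE, STOP
from .io_formats import FeatureRecord

BASES = ("A", "C", "G", "T")

STATUS_CALLED = "called"
STATUS_UNCOVERED = "uncovered"
STATUS_TIE = "ambiguous-tie"

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_STOP_REMOVAL = "stop-removal"
EFFECT_STOP_GAIN = "stop-gain"
EFFECT_OUTSIDE = "outside-CDS"


@dataclass(frozen=True)
class EditingSite:
    position: int  # 1-based genome coordinate
    ref: str
    edited: str | None
    support: float
    status: str

    @property
    def called(self) -> bool:
        return self.status == STATUS_CALLED


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"pos", "ref", *BASES} - set(df.columns)
    if missing:
        raise ValueError(f"pileup {path}: missing columns {sorted(missing)}")
    return df


def write_pileup(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def call_edits(
    pileup: pd.DataFrame, genome: str, min_depth: int = 4
) -> list[EditingSite]:
    """Call edited positions by strict read majority.

    A site is called when depth >= *min_depth*, the modal base differs from
    the genomic reference, and the modal base carries > 50% of the counted
    reads.  Columns with sub-threshold depth are reported as ``uncovered``
    when they show non-reference signal (or zero coverage); 50/50 splits
    are ``ambiguous-tie``.
    """
    sites: list[EditingSite] = []
    for row in pileup.itertuples(index=False):
        pos = int(row.pos)
        if not 1 <= pos <= len(genome):
            raise ValueError(f"pileup position {pos} outside genome of length {len(genome)}")
        ref = str(row.ref).upper()
        if genome[pos - 1] != ref:
            raise ValueError(
                f"pileup/genome mismatch at {pos}: pileup ref {ref}, genome {genome[pos - 1]}"
            )
        counts = {b: int(getattr(row, b)) for b in BASES}
        depth = sum(counts.values())
        if depth == 0:
            sites.append(EditingSite(pos, ref, None, 0.0, STATUS_UNCOVERED))
            continue
        modal = max(BASES, key=lambda b: counts[b])
        if modal == ref:
            continue
        frac = counts[modal] / depth
        if depth < min_depth:
            sites.append(EditingSite(pos, ref, modal, frac, STATUS_UNCOVERED))
        elif counts[modal] * 2 == depth and counts[ref] == counts[modal]:
            sites.append(EditingSite(pos, ref, modal, frac, STATUS_TIE))
        elif frac > 0.5:
            sites.append(EditingSite(pos, ref, modal, frac, STATUS_CALLED))
        else:
            sites.append(EditingSite(pos, ref, modal, frac, STATUS_TIE))
    return sites


@dataclass(frozen=True)
class CodonEffect:
    """Consequence of one applied edit on one (or no) coding sequence."""

    position: int
    gene_id: str
    codon_index: int  # 0-based within the CDS; -1 outside CDS
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    effect: str


def _genome_to_cds_offset(feature: FeatureRecord, pos: int) -> int | None:
    """Map a genomic position to its 0-based offset within the spliced CDS."""
    offset = 0
    for s, e in feature.intervals:
        if s <= pos <= e:
            within = (pos - s) if feature.strand == "+" else (e - pos)
            return offset + within
        offset += e - s + 1
    return None


def apply_edits(
    genome: str,
    sites: Sequence[EditingSite],
    features: Sequence[FeatureRecord] = (),
    code: GeneticCodeTable = STANDARD_CODE,
    patches: Sequence[tuple[int, str]] = (),
) -> tuple[str, list[CodonEffect]]:
    """Apply called edits (plus explicit patches) and report codon effects.

    Returns the corrected genome and one :class:`CodonEffect` per called
    site per overlapping CDS (a site inside two overlapping CDSs is
    reported for both); sites outside every CDS get an ``outside-CDS``
    record.  Effects are classified under *code*.
    """
    corrected = list(genome)
    applied: list[tuple[int, str]] = []
    for site in sites:
        if not site.called:
            continue
        corrected[site.position - 1] = site.edited
        applied.append((site.position, site.edited))
    for pos, base in patches:
        corrected[pos - 1] = base.upper()
        applied.append((pos, base.upper()))
    corrected_seq = "".join(corrected)

    cds_features = [f for f in features if f.feature_type in ("CDS", "ORF")]
    effects: list[CodonEffect] = []
    for pos, _base in applied:
        hit = False
        for f in cds_features:
            offset = _genome_to_cds_offset(f, pos)
            if offset is None:
                continue
            hit = True
            before = f.extract(genome)
            after = f.extract(corrected_seq)
            ci = offset // 3
            codon_before = before[ci * 3 : ci * 3 + 3]
            codon_after = after[ci * 3 : ci * 3 + 3]
            aa_before = code[codon_before]
            aa_after = code[codon_after]
            if aa_before == aa_after:
                effect = EFFECT_SYNONYMOUS
            elif aa_before == STOP:
                effect = EFFECT_STOP_REMOVAL
            elif aa_after == STOP:
                effect = EFFECT_STOP_GAIN
            else:
                effect = EFFECT_MISSENSE
            effects.append(
                CodonEffect(pos, f.gene_id, ci, codon_before, codon_after, aa_before, aa_after, effect)
            )
        if not hit:
            effects.append(CodonEffect(pos, "", -1, "", "", "", "", EFFECT_OUTSIDE))
    return corrected_seq, effects


def sites_to_dataframe(sites: Sequence[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pos": s.position,
                "ref": s.ref,
                "edited": s.edited or "",
                "support": round(s.support, 4),
                "status": s.status,
            }
            for s in sites
        ],
        columns=["pos", "ref", "edited", "support", "status"],
    )


def effects_to_dataframe(effects: Sequence[CodonEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pos": e.position,
                "gene_id": e.gene_id,
                "codon_index": e.codon_index,
                "codon_before": e.codon_before,
                "codon_after": e.codon_after,
                "aa_before": e.aa_before,
                "aa_after": e.aa_after,
                "effect": e.effect,
            }
            for e in effects
        ],
        columns=[
            "pos", "gene_id", "codon_index", "codon_before", "codon_after",
            "aa_before", "aa_after", "effect",
        ],
    )
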