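"""Release-factor motif reports.

Which codons terminate translation in an organelle is decided by its
release factors (mtRF1a/mtRF2a in mitochondria, pRF1/pRF2 in plastids):
specific substitutions in the codon-binding region recur in lineages that
use non-standard termination codons.  This module reports, for a protein
alignment and a list of labelled reference positions (e.g. the Ser204 of
RF2-type or Gln181 of RF1-type factors, numbered on a stated reference
sequence), the residue every sequence carries at the homologous column and
flags deviations from the expected consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

GAP = "-"


@dataclass(frozen=True)
class ReferenceSite:
    position: int  # 1-based, in the reference sequence's ungapped coordinates
    label: str
    expected: str


@dataclass
class SitePanel:
    """Protein alignment plus labelled positions on a reference row."""

    alignment: dict[str, str]
    reference_id: str
    sites: Sequence[ReferenceSite]

    def __post_init__(self) -> None:
        if self.reference_id not in self.alignment:
            raise ValueError(f"reference sequence {self.reference_id!r} not in alignment")
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {lengths}")
        ref_len = len(self.alignment[self.reference_id].replace(GAP, ""))
        for site in self.sites:
            if not 1 <= site.position <= ref_len:
                raise ValueError(
                    f"site {site.label!r}: position {site.position} beyond reference "
                    f"ungapped length {ref_len}"
                )

    def column_of(self, position: int) -> int:
        """0-based alignment column of an ungapped reference position."""
        seen = 0
        for col, c in enumerate(self.alignment[self.reference_id]):
            if c != GAP:
                seen += 1
                if seen == position:
                    return col
        raise ValueError(f"reference position {position} beyond sequence")


def site_report(panel: SitePanel) -> pd.DataFrame:
    """Residue of each sequence at each labelled site, with deviation flags.

    A residue differing from the expected consensus is flagged
    ``deviation``; a gap is flagged ``deletion``.
    """
    rows = []
    for site in panel.sites:
        col = panel.column_of(site.position)
        for seq_id, seq in panel.alignment.items():
            residue = seq[col]
            if residue == GAP:
                flag = "deletion"
            elif residue != site.expected:
                flag = "deviation"
            else:
                flag = ""
            rows.append(
                {
                    "site": site.label,
                    "reference_position": site.position,
                    "column": col + 1,
                    "sequence_id": seq_id,
                    "residue": residue,
                    "expected": site.expected,
                    "flag": flag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site", "reference_position", "column", "sequence_id", "residue", "expected", "flag"],
    )


def read_sites_tsv(path) -> list[ReferenceSite]:
    df = pd.read_csv(path, sep="\t")
    missing = {"position", "label", "expected"} - set(df.columns)
    if missing:
        raise ValueError(f"sites file {path}: missing columns {sorted(missing)}")
    return [
        ReferenceSite(int(r.position), str(r.label), str(r.expected))
        for r in df.itertuples(index=False)
    ]
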