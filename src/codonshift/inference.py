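"""Codon-meaning decision rules, retranslation, and the two-iteration loop.

A codon's meaning is decided from its conserved-column profile:

1. fewer than ``min_conserved`` conserved placements -> insufficient
   evidence, the standard meaning is kept;
2. if the standard amino acid accounts for ``max_standard_fraction`` (10%)
   or more of the conserved placements -> the codon is standard;
3. otherwise the codon is potentially reassigned: it receives the most
   frequent conserved amino acid when that amino acid occurs at least
   ``min_top_count`` times and at least ``dominance_ratio`` (2x, inclusive)
   as often as the runner-up;
4. otherwise the codon is translated as the unknown amino acid 'X'.

Stop codons participate symmetrically: a stop codon repeatedly found at
conserved sense columns is called reassigned to that amino acid (this is
how a stop-to-Trp UGA reassignment manifests).

The full inference runs twice: first against a taxonomically broad panel
using standard-code translations, then -- after retranslating under the
first-round calls -- against a narrower panel of close relatives, which
sharpens column conservation around the focal lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .conservation import (
    AlignedPanel,
    ConservedColumnProfile,
    conserved_columns,
    profile_codons,
)
from .genetic_codes import (
    ALL_CODONS,
    CodingSequence,
    GeneticCodeTable,
    STANDARD_CODE,
    STOP,
    UNKNOWN,
)

STATUS_STANDARD = "standard"
STATUS_REASSIGNED = "reassigned"
STATUS_UNKNOWN = "unknown-X"
STATUS_INSUFFICIENT = "insufficient-evidence"


@dataclass(frozen=True)
class DecisionParams:
    """Thresholds of the reassignment decision rule."""

    min_conserved: int = 5
    max_standard_fraction: float = 0.10
    min_top_count: int = 5
    dominance_ratio: float = 2.0
    conservation_threshold: float = 0.70
    exclude_focal: bool = True
    gap_policy: str = "count-in-denominator"


@dataclass(frozen=True)
class ReassignmentCall:
    codon: str
    status: str
    meaning: str
    n_conserved: int
    n_total: int
    standard_meaning: str
    top: tuple[str, int] | None = None
    runner_up: tuple[str, int] | None = None

    @property
    def is_reassigned(self) -> bool:
        return self.status == STATUS_REASSIGNED


def decide(
    profile: ConservedColumnProfile,
    codon: str,
    standard_code: GeneticCodeTable = STANDARD_CODE,
    params: DecisionParams = DecisionParams(),
) -> ReassignmentCall:
    """Apply the decision rule to one codon of a conserved-column profile."""
    counts = profile.conserved_counts(codon)
    n_conserved = sum(counts.values())
    n_total = profile.total_occurrences(codon)
    std = standard_code[codon]

    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[0] if ranked else None
    runner = ranked[1] if len(ranked) > 1 else None

    if n_conserved < params.min_conserved:
        return ReassignmentCall(
            codon, STATUS_INSUFFICIENT, std, n_conserved, n_total, std, top, runner
        )
    std_fraction = counts.get(std, 0) / n_conserved
    if std_fraction >= params.max_standard_fraction:
        return ReassignmentCall(
            codon, STATUS_STANDARD, std, n_conserved, n_total, std, top, runner
        )
    top_aa, top_n = top
    runner_n = runner[1] if runner else 0
    if (
        top_n >= params.min_top_count
        and top_n >= params.dominance_ratio * runner_n
        and top_aa != std
    ):
        return ReassignmentCall(
            codon, STATUS_REASSIGNED, top_aa, n_conserved, n_total, std, top, runner
        )
    return ReassignmentCall(
        codon, STATUS_UNKNOWN, UNKNOWN, n_conserved, n_total, std, top, runner
    )


def decide_all(
    profile: ConservedColumnProfile,
    standard_code: GeneticCodeTable = STANDARD_CODE,
    params: DecisionParams = DecisionParams(),
) -> dict[str, ReassignmentCall]:
    return {c: decide(profile, c, standard_code, params) for c in ALL_CODONS}


def amended_code(
    calls: dict[str, ReassignmentCall],
    standard_code: GeneticCodeTable = STANDARD_CODE,
    name: str = "inferred",
) -> GeneticCodeTable:
    """Standard code with reassigned / unknown-X calls applied on top."""
    changes = {
        c: call.meaning
        for c, call in calls.items()
        if call.status in (STATUS_REASSIGNED, STATUS_UNKNOWN)
    }
    return standard_code.with_assignments(changes, name=name)


def retranslate(
    cds_set: dict[str, CodingSequence],
    calls: dict[str, ReassignmentCall],
    standard_code: GeneticCodeTable = STANDARD_CODE,
) -> dict[str, str]:
    """Translate each CDS (minus its annotated terminal codon) under the calls.

    Reassigned codons get their new amino acid, unknown-X codons 'X', and
    everything else its standard meaning.  Codons that newly mean '*' and
    occur internally are kept as '*' in the output so they remain visible.
    """
    code = amended_code(calls, standard_code)
    out = {}
    for gene_id, cds in cds_set.items():
        codons = list(cds.codons())[:-1]
        out[gene_id] = "".join(code[c] for c in codons)
    return out


@dataclass
class IterationResult:
    calls_iter1: dict[str, ReassignmentCall]
    calls_iter2: dict[str, ReassignmentCall]
    final_code: GeneticCodeTable
    profile_iter1: ConservedColumnProfile = field(repr=False, default=None)
    profile_iter2: ConservedColumnProfile = field(repr=False, default=None)


def _profile(
    panels: dict[str, AlignedPanel],
    cds_set: dict[str, CodingSequence],
    params: DecisionParams,
) -> ConservedColumnProfile:
    verdicts = {
        g: conserved_columns(
            p,
            params.conservation_threshold,
            exclude_focal=params.exclude_focal,
            gap_policy=params.gap_policy,
        )
        for g, p in panels.items()
    }
    return profile_codons(panels, cds_set, verdicts)


def iterate(
    cds_set: dict[str, CodingSequence],
    panels_broad: dict[str, AlignedPanel],
    panels_narrow: dict[str, AlignedPanel],
    standard_code: GeneticCodeTable = STANDARD_CODE,
    params: DecisionParams = DecisionParams(),
) -> IterationResult:
    """Run the two-iteration inference and return both call sets.

    Iteration 1 profiles standard-code translations against the broad
    panel; the coding sequences are then retranslated under the resulting
    calls and profiled against the narrow panel.  The final code applies
    the second-iteration calls on top of the standard code.
    """
    for name, panels in (("broad", panels_broad), ("narrow", panels_narrow)):
        missing = sorted(set(cds_set) - set(panels))
        if missing:
            raise ValueError(f"{name} panel set lacks genes: {missing}")
    extra = sorted(set(panels_broad) ^ set(panels_narrow))
    if extra:
        raise ValueError(f"broad/narrow panel gene sets differ: {extra}")

    profile1 = _profile(panels_broad, cds_set, params)
    calls1 = decide_all(profile1, standard_code, params)

    retranslated = retranslate(cds_set, calls1, standard_code)
    panels2 = {
        g: p.with_focal_protein(retranslated[g]) for g, p in panels_narrow.items()
    }
    profile2 = _profile(panels2, cds_set, params)
    calls2 = decide_all(profile2, standard_code, params)

    final = amended_code(calls2, standard_code, name="inferred")
    return IterationResult(calls1, calls2, final, profile1, profile2)


def calls_to_dataframe(calls: dict[str, ReassignmentCall]) -> pd.DataFrame:
    rows = []
    for codon in ALL_CODONS:
        c = calls[codon]
        rows.append(
            {
                "codon": codon,
                "status": c.status,
                "meaning": c.meaning,
                "standard_meaning": c.standard_meaning,
                "n_conserved": c.n_conserved,
                "n_total": c.n_total,
                "top_aa": c.top[0] if c.top else "",
                "top_count": c.top[1] if c.top else 0,
                "runner_up_aa": c.runner_up[0] if c.runner_up else "",
                "runner_up_count": c.runner_up[1] if c.runner_up else 0,
            }
        )
    return pd.DataFrame(rows)
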