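"""tRNA sequence parsing and amino-acid identity-element evaluation.

tRNA genes are interpreted in a standardized coordinate frame derived from
the cloverleaf structure: acceptor-stem base pairs 1:72 ... 7:66, the
discriminator base 73 (the unpaired nucleotide 5' of the post-
transcriptionally added CCA end), and the anticodon at positions 34-36.
Rather than a full covariance-model alignment, the frame is reconstructed
from two robust landmarks: the acceptor stem read off the molecule's ends,
and the anticodon loop located by a cloverleaf-constrained scan for a
5-bp stem enclosing a 7-nt loop near the centre of the molecule.  These
landmarks yield every position consumed by the identity elements evaluated
here (2, 3, 34-36, 70, 71, 73).

Identity elements follow the classical determinants:

* Ala: the G3·U70 wobble pair in the acceptor stem and the A73 discriminator.
* Gly: the C2:G71 and G3:C70 pairs and cytidines C35/C36 in the anticodon.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

STEM_LENGTH = 7
ANTICODON_STEM = 5
ANTICODON_LOOP = 7


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def is_valid_pair(five: str, three: str) -> bool:
    """Watson-Crick or G·U wobble pair."""
    return (five, three) in _WC or (five, three) in _WOBBLE


@dataclass(frozen=True)
class TRNAAssessment:
    """Parsed structural frame of a tRNA gene sequence."""

    sequence: str
    status: str  # "parsed" | "unparseable"
    cca_status: str = ""  # "genomic-no-CCA" | "CCA-stripped"
    acceptor_stem: tuple[tuple[str, str], ...] = ()
    discriminator: str = ""
    anticodon: str = ""
    anticodon_start: int = -1  # 0-based index into the (CCA-stripped) sequence
    failure_reason: str = ""

    @property
    def parsed(self) -> bool:
        return self.status == "parsed"


def parse_trna(sequence: str, *, expect_cca: bool | None = None) -> TRNAAssessment:
    """Parse a tRNA gene sequence (60-100 nt) into its structural frame.

    A terminal CCA, when present (or asserted via ``expect_cca``), is
    stripped and recorded; the discriminator is then the last base.  A
    3'-terminal ``CCA`` is ambiguous -- it may be the added end or simply the
    last stem bases plus an A73 discriminator -- so when ``expect_cca`` is
    not given both readings are evaluated and the one with the cleaner
    acceptor stem wins.  The acceptor stem pairs the first seven bases with
    the seven bases preceding the discriminator.  Parsing fails explicitly
    (``status='unparseable'``) when more than two stem pairs are neither
    Watson-Crick nor G·U, or when no anticodon loop can be located -- it
    never silently guesses.
    """
    raw = _norm(sequence)
    if not 60 <= len(raw) <= 100:
        return TRNAAssessment(raw, "unparseable", failure_reason=f"length {len(raw)} outside 60-100")
    if set(raw) - set("ACGT"):
        return TRNAAssessment(raw, "unparseable", failure_reason="non-ACGT characters")

    if expect_cca is None:
        if raw.endswith("CCA"):
            with_strip = _parse_body(raw, True)
            without = _parse_body(raw, False)
            return min((with_strip, without), key=_parse_badness)
        return _parse_body(raw, False)
    if expect_cca and not raw.endswith("CCA"):
        return TRNAAssessment(raw, "unparseable", failure_reason="CCA expected but absent")
    return _parse_body(raw, expect_cca)


def _parse_badness(a: "TRNAAssessment") -> tuple[int, int]:
    if not a.parsed:
        return (2, 0)
    mism = sum(not is_valid_pair(x, y) for x, y in a.acceptor_stem)
    return (0 if mism == 0 else 1, mism)


def _parse_body(raw: str, has_cca: bool) -> TRNAAssessment:
    body = raw[:-3] if has_cca else raw
    cca_status = "CCA-stripped" if has_cca else "genomic-no-CCA"

    discriminator = body[-1]
    five = body[:STEM_LENGTH]
    # positions 66-72 run 3'->5' relative to stem positions 7..1
    three = body[-1 - STEM_LENGTH : -1]
    stem = tuple((five[k], three[STEM_LENGTH - 1 - k]) for k in range(STEM_LENGTH))
    mismatches = sum(not is_valid_pair(a, b) for a, b in stem)
    if mismatches > 2:
        return TRNAAssessment(
            raw, "unparseable", cca_status,
            failure_reason=f"{mismatches} acceptor-stem mismatches beyond G·U",
        )

    loop_start = _find_anticodon_loop(body)
    if loop_start is None:
        return TRNAAssessment(
            raw, "unparseable", cca_status, stem, discriminator,
            failure_reason="no anticodon loop found",
        )
    anticodon = body[loop_start + 2 : loop_start + 5]
    return TRNAAssessment(
        raw, "parsed", cca_status, stem, discriminator, anticodon, loop_start + 2
    )


def _find_anticodon_loop(body: str) -> int | None:
    """Scan for a 5-bp stem closing a 7-nt loop.

    Among structurally valid candidates, those matching the classical
    conserved anticodon-loop bases best win: C32, the near-universal U33
    immediately 5' of the anticodon, and a purine at 37.  Remaining ties go
    to proximity to the centre of the molecule (where the anticodon arm of
    a cloverleaf sits), binned coarsely so a one-position register shift of
    the same stem cannot outrank the true loop, then 5'-ward.
    """
    candidates = []
    centre = len(body) / 2
    lo = STEM_LENGTH + 2 + ANTICODON_STEM
    hi = len(body) - STEM_LENGTH - 1 - ANTICODON_LOOP - ANTICODON_STEM
    for i in range(lo, hi + 1):
        s5 = body[i - ANTICODON_STEM : i]
        s3 = body[i + ANTICODON_LOOP : i + ANTICODON_LOOP + ANTICODON_STEM]
        if all(
            is_valid_pair(s5[k], s3[ANTICODON_STEM - 1 - k])
            for k in range(ANTICODON_STEM)
        ):
            loop = body[i : i + ANTICODON_LOOP]
            mismatches = (
                (loop[0] != "C") + (loop[1] != "T") + (loop[5] not in "AG")
            )
            loop_centre = i + ANTICODON_LOOP / 2
            candidates.append((mismatches, int(abs(loop_centre - centre) // 4), i))
    if not candidates:
        return None
    return min(candidates)[2]


IDENTITY_ELEMENTS = {
    "Ala": ("G3·U70", "A73"),
    "Gly": ("C2:G71", "G3:C70", "C35", "C36"),
}


@dataclass(frozen=True)
class IdentityVerdict:
    aa_class: str
    elements: tuple[tuple[str, bool], ...]

    @property
    def overall(self) -> str:
        present = [ok for _, ok in self.elements]
        if all(present):
            return "all-present"
        if any(present):
            return "partial"
        return "none"


def identity_check(assessment: TRNAAssessment, aa_class: str) -> IdentityVerdict:
    """Score the identity determinants of *aa_class* on a parsed tRNA."""
    if not assessment.parsed:
        raise ValueError("cannot evaluate identity elements on an unparseable tRNA")
    if aa_class not in IDENTITY_ELEMENTS:
        raise ValueError(f"unknown amino-acid class {aa_class!r}; known: {sorted(IDENTITY_ELEMENTS)}")
    stem = assessment.acceptor_stem
    ac = assessment.anticodon
    if aa_class == "Ala":
        elements = (
            ("G3·U70", stem[2] == ("G", "T")),
            ("A73", assessment.discriminator == "A"),
        )
    else:  # Gly
        elements = (
            ("C2:G71", stem[1] == ("C", "G")),
            ("G3:C70", stem[2] == ("G", "C")),
            ("C35", len(ac) == 3 and ac[1] == "C"),
            ("C36", len(ac) == 3 and ac[2] == "C"),
        )
    return IdentityVerdict(aa_class, elements)
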