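"""Synthetic ortholog panels, focal genomes, editing pileups and tRNA genes.

The generator gives every downstream stage a known ground truth.  Its model
is deliberately minimal but mirrors the statistical structure the inference
relies on:

* Reference taxa diverge from a common ancestral protein on a star
  phylogeny: each taxon substitutes each variable site independently with a
  fixed probability, drawing the replacement uniformly from the other 19
  amino acids.  A configurable fraction of sites (the conservation floor)
  is held invariant across all taxa, emulating the strongly conserved
  positions of organellar marker genes.
* The focal genome is obtained by back-translating the focal taxon's
  protein under a configurable (possibly reassigned) genetic code.  Codons
  whose meaning differs from the standard code are, by default, used only
  at invariant sites (``plant_at_conserved``) and are up-weighted relative
  to their standard synonyms, emulating the strong usage bias observed for
  reassigned codons in real organellar genomes (where e.g. a reassigned
  UGA can outnumber UGG several-fold).
* Stop-reassigned codons appear exclusively as the annotated terminal codon
  of coding sequences.
* RNA editing is emulated by corrupting the genomic sequence at randomly
  chosen coding positions while read pileups support the mature (coding)
  base by a binomial majority.
* tRNA genes are built on a canonical cloverleaf scaffold with chosen
  acceptor-stem pairs, discriminator base and anticodon, so that identity
  elements (e.g. G3·U70 + A73 for alanine acceptance) are controllable.

Everything is driven by one integer seed; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .conservation import AlignedPanel
from .genetic_codes import (
    ALL_CODONS,
    AMINO_ACIDS,
    CodingSequence,
    GeneticCodeTable,
    STANDARD_CODE,
    STOP,
    translate,
)
from .io_formats import FeatureRecord, write_fasta, write_gff3
from .trna import STEM_LENGTH, is_valid_pair

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    The defaults describe the reference conditions used throughout the test
    suite: 15 genes of 200 codons, 20 reference taxa, per-site substitution
    probability 0.15, and 40% invariant sites.
    """

    seed: int = 0
    n_genes: int = 15
    gene_length_range: tuple[int, int] = (200, 200)
    n_reference_taxa: int = 20
    n_narrow_taxa: int = 8
    substitution_prob: float = 0.15
    conservation_floor: float = 0.40
    focal_code: GeneticCodeTable = field(default_factory=lambda: STANDARD_CODE)
    codon_usage_weights: dict[str, float] | None = None
    reassigned_codon_weight: float = 3.0
    stop_codon_set_for_focal: tuple[str, ...] | None = None
    plant_at_conserved: bool = True
    editing_site_rate: float = 0.0
    mean_read_depth: float = 50.0
    sequencing_error_rate: float = 0.01
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_prob <= 1:
            raise ValueError("substitution_prob must be in [0, 1]")
        if not 0 <= self.conservation_floor <= 1:
            raise ValueError("conservation_floor must be in [0, 1]")
        if not 0 <= self.editing_site_rate < 1:
            raise ValueError("editing_site_rate must be in [0, 1)")
        if self.sequencing_error_rate >= 0.5:
            raise ValueError("sequencing error rate must be < 0.5")
        if self.codon_usage_weights is not None:
            for c, w in self.codon_usage_weights.items():
                if w < 0:
                    raise ValueError(f"negative codon weight for {c}")

    def effective_stop_set(self) -> tuple[str, ...]:
        if self.stop_codon_set_for_focal is not None:
            return tuple(self.stop_codon_set_for_focal)
        return self.focal_code.stop_codons

    def codon_weight(self, codon: str) -> float:
        if self.codon_usage_weights and codon in self.codon_usage_weights:
            return self.codon_usage_weights[codon]
        if self.focal_code[codon] != STANDARD_CODE[codon] and self.focal_code[codon] != STOP:
            return self.reassigned_codon_weight
        return 1.0


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream verification."""

    focal_code: GeneticCodeTable
    placements: list[tuple[str, int, str]]  # (gene_id, codon index, codon)
    editing_sites: list[tuple[int, str, str]]  # (1-based pos, genomic base, mature base)
    stop_codons_used: dict[str, str]  # gene_id -> terminal codon

    def placements_for(self, codon: str) -> list[tuple[str, int, str]]:
        return [p for p in self.placements if p[2] == codon]

    def to_json(self, path) -> None:
        obj = {
            "focal_code": {"name": self.focal_code.name, "assignments": dict(self.focal_code.assignments)},
            "placements": self.placements,
            "editing_sites": self.editing_sites,
            "stop_codons_used": self.stop_codons_used,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


@dataclass
class SimulatedStudy:
    """Everything one simulation run produces."""

    config: SimulationConfig
    panels_broad: dict[str, AlignedPanel]
    panels_narrow: dict[str, AlignedPanel]
    focal_cds: dict[str, CodingSequence]
    genome: str
    features: list[FeatureRecord]
    trna_features: list[FeatureRecord]
    trna_sequences: dict[str, str]
    ground_truth: GroundTruth


def simulate_panel(config: SimulationConfig) -> SimulatedStudy:
    """Generate ortholog panels, a focal genome and its annotations."""
    rng = np.random.default_rng(config.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    code = config.focal_code
    stop_set = config.effective_stop_set()
    if not stop_set:
        raise ValueError("focal code defines no stop codons and no stop set given")

    # feasibility: every amino acid must be encodable under the focal code
    for a in AMINO_ACIDS:
        if not code.codons_for(a):
            raise ValueError(f"focal code {code.name!r} has no codon for amino acid {a!r}")

    panels_broad: dict[str, AlignedPanel] = {}
    focal_cds: dict[str, CodingSequence] = {}
    placements: list[tuple[str, int, str]] = []
    stop_used: dict[str, str] = {}
    taxa = [f"taxon{i:02d}" for i in range(config.n_reference_taxa)]

    # every configured stop codon terminates at least one CDS (when the gene
    # count allows), as in real genomes where each termination codon of the
    # operating code is in service; the remainder is drawn at random
    terminals = list(stop_set[: config.n_genes])
    terminals += [
        stop_set[int(rng.integers(len(stop_set)))]
        for _ in range(config.n_genes - len(terminals))
    ]
    terminals = [terminals[i] for i in rng.permutation(len(terminals))]

    for g in range(config.n_genes):
        gene_id = f"gene{g:02d}"
        lo, hi = config.gene_length_range
        L = int(rng.integers(lo, hi + 1))
        ancestor = rng.choice(aa, size=L)
        ancestor[0] = "M"  # initiation codon
        invariant = rng.random(L) < config.conservation_floor
        invariant[0] = True

        def diverge(row: np.ndarray) -> np.ndarray:
            out = row.copy()
            mutate = (~invariant) & (rng.random(L) < config.substitution_prob)
            idx = np.where(mutate)[0]
            for i in idx:
                choices = [x for x in AMINO_ACIDS if x != out[i]]
                out[i] = choices[int(rng.integers(len(choices)))]
            return out

        rows = {t: "".join(diverge(ancestor)) for t in taxa}
        focal_protein = "".join(diverge(ancestor))

        codons: list[str] = []
        for i, a in enumerate(focal_protein):
            if i == 0:
                codons.append("ATG")
                continue
            candidates = list(code.codons_for(a))
            if config.plant_at_conserved and not invariant[i]:
                safe = [c for c in candidates if STANDARD_CODE[c] == a]
                if safe:
                    candidates = safe
            weights = np.array([config.codon_weight(c) for c in candidates])
            if weights.sum() == 0:
                raise ValueError(f"all-zero codon weights for amino acid {a!r}")
            chosen = candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]
            codons.append(chosen)
            if code[chosen] != STANDARD_CODE[chosen]:
                placements.append((gene_id, i, chosen))
        terminal = terminals[g]
        codons.append(terminal)
        stop_used[gene_id] = terminal
        if code[terminal] != STANDARD_CODE[terminal]:
            placements.append((gene_id, L, terminal))

        cds = CodingSequence(gene_id, "".join(codons), genome_id="focal")
        focal_cds[gene_id] = cds
        # focal row: standard-code translation of the CDS minus the annotated
        # terminal codon (internal reassigned stops therefore show as '*')
        focal_row = "".join(STANDARD_CODE[c] for c in codons[:-1])
        rows["focal"] = focal_row
        panels_broad[gene_id] = AlignedPanel(gene_id, rows, "focal")

    narrow_taxa = taxa[: config.n_narrow_taxa]
    panels_narrow = {g: p.subset(narrow_taxa) for g, p in panels_broad.items()}

    genome, features, editing_sites = _assemble_genome(config, focal_cds, rng)
    trna_features, trna_sequences = trna_gene_set(code, rng)
    # place tRNA genes after the coding part of the genome
    placed_trnas: list[FeatureRecord] = []
    for f in trna_features:
        start = len(genome) + 1
        seq = trna_sequences[f.gene_id]
        genome = genome + seq
        placed_trnas.append(
            FeatureRecord(
                genome_id="focal", feature_type="tRNA", gene_id=f.gene_id,
                intervals=((start, start + len(seq) - 1),), strand="+",
                product=f.product, anticodon=f.anticodon,
            )
        )

    truth = GroundTruth(code, placements, editing_sites, stop_used)
    return SimulatedStudy(
        config, panels_broad, panels_narrow, focal_cds, genome,
        features + placed_trnas, placed_trnas, trna_sequences, truth,
    )


_BASES = "ACGT"


def _assemble_genome(
    config: SimulationConfig,
    focal_cds: dict[str, CodingSequence],
    rng: np.random.Generator,
) -> tuple[str, list[FeatureRecord], list[tuple[int, str, str]]]:
    parts: list[str] = []
    features: list[FeatureRecord] = []
    pos = 0
    cds_spans: list[tuple[int, int]] = []
    for gene_id, cds in focal_cds.items():
        spacer = "".join(rng.choice(list(_BASES), size=config.spacer_length))
        parts.append(spacer)
        pos += len(spacer)
        start = pos + 1
        parts.append(cds.nucleotides)
        pos += len(cds)
        features.append(
            FeatureRecord("focal", "CDS", gene_id, ((start, pos),), "+")
        )
        cds_spans.append((start, pos))
    genome = list("".join(parts))

    editing_sites: list[tuple[int, str, str]] = []
    if config.editing_site_rate > 0:
        for start, end in cds_spans:
            for p in range(start, end + 1):
                if rng.random() < config.editing_site_rate:
                    mature = genome[p - 1]
                    others = [b for b in _BASES if b != mature]
                    genomic = others[int(rng.integers(3))]
                    genome[p - 1] = genomic
                    editing_sites.append((p, genomic, mature))
    return "".join(genome), features, editing_sites


# ---------------------------------------------------------------------------
# tRNA genes


AcceptorStem = tuple[tuple[str, str], ...]

GENERIC_STEM: AcceptorStem = (
    ("G", "C"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("T", "A"),
)
ALA_STEM: AcceptorStem = (
    ("G", "C"), ("G", "C"), ("G", "T"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "C"),
)
GLY_STEM: AcceptorStem = (
    ("G", "C"), ("C", "G"), ("G", "C"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "C"),
)


def simulate_trna(
    acceptor_stem: AcceptorStem,
    anticodon: str,
    discriminator: str,
    seed: int,
    *,
    add_cca: bool = False,
) -> str:
    """Build a 72-nt cloverleaf tRNA with the requested landmark features.

    The acceptor stem must give exactly seven Watson-Crick or G·U pairs.
    Arm sequences outside the specified landmarks are drawn from the seeded
    generator, with stems constructed as exact reverse complements.
    """
    if len(acceptor_stem) != STEM_LENGTH:
        raise ValueError(f"acceptor stem needs {STEM_LENGTH} pairs, got {len(acceptor_stem)}")
    for a, b in acceptor_stem:
        if not is_valid_pair(a, b):
            raise ValueError(f"impossible acceptor-stem pair {a}·{b}")
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3 or set(anticodon) - set(_BASES):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    discriminator = discriminator.upper().replace("U", "T")
    if discriminator not in _BASES:
        raise ValueError(f"invalid discriminator {discriminator!r}")

    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(list(_BASES), size=n))

    stem5 = "".join(p[0] for p in acceptor_stem)
    stem3 = "".join(p[1] for p in acceptor_stem)[::-1]  # positions 66..72
    d_stem = rand(4)
    ac_stem = rand(5)
    t_stem = rand(5)
    seq = (
        stem5
        + "TA"                       # positions 8-9
        + d_stem + "AGGTTAGA" + revcomp(d_stem)  # D arm (8-nt loop)
        + "A"                        # position 26
        + ac_stem + "CT" + anticodon + "AA" + revcomp(ac_stem)  # anticodon arm
        + "GTCA"                     # variable loop
        + t_stem + "TTCGAAT" + revcomp(t_stem)   # T arm
        + stem3
        + discriminator
    )
    if add_cca:
        seq += "CCA"
    return seq


def trna_gene_set(
    code: GeneticCodeTable, rng: np.random.Generator
) -> tuple[list[FeatureRecord], dict[str, str]]:
    """One tRNA gene per sense codon of *code*, with matching identity elements.

    Anticodons are the exact Watson-Crick complement of their codon, so
    codons that are stops (or unknowns) under *code* have no decoder.
    Alanine- and glycine-accepting tRNAs carry their classical acceptor-stem
    and discriminator determinants.
    """
    features: list[FeatureRecord] = []
    sequences: dict[str, str] = {}
    for codon in ALL_CODONS:
        aa = code[codon]
        if aa in (STOP, "X"):
            continue
        anticodon = revcomp(codon)
        if aa == "A":
            stem, disc = ALA_STEM, "A"
        elif aa == "G":
            stem, disc = GLY_STEM, "A"
        else:
            stem, disc = GENERIC_STEM, "G"
        name = f"trn{aa}-{anticodon.lower()}"
        seq = simulate_trna(stem, anticodon, disc, seed=int(rng.integers(2**31)))
        sequences[name] = seq
        features.append(
            FeatureRecord(
                genome_id="focal", feature_type="tRNA", gene_id=name,
                intervals=((1, len(seq)),), strand="+",
                product=f"tRNA-{aa}", anticodon=anticodon,
            )
        )
    return features, sequences


# ---------------------------------------------------------------------------
# Read pileups


def simulate_pileup(
    genome: str,
    editing_sites: list[tuple[int, str, str]],
    mean_depth: float,
    error_rate: float,
    seed: int,
    positions: list[int] | None = None,
) -> pd.DataFrame:
    """Simulate a per-position read pileup over *genome*.

    At edited sites reads support the mature base; elsewhere the genomic
    (reference) base.  Depth is Poisson(mean_depth); each read shows the
    true base with probability ``1 - error_rate`` and a uniform other base
    otherwise.  Returns a TSV-ready frame with columns pos/ref/A/C/G/T.
    """
    if error_rate >= 0.5:
        raise ValueError("error rate must be < 0.5")
    site_map = {p: mature for p, _g, mature in editing_sites}
    for p, g, _m in editing_sites:
        if not 1 <= p <= len(genome):
            raise ValueError(f"editing site {p} outside genome")
        if genome[p - 1] != g:
            raise ValueError(f"editing site {p}: genome has {genome[p-1]}, expected {g}")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = list(range(1, len(genome) + 1))
    rows = []
    depths = rng.poisson(mean_depth, size=len(positions))
    for p, depth in zip(positions, depths):
        ref = genome[p - 1]
        true = site_map.get(p, ref)
        probs = np.full(4, error_rate / 3)
        probs["ACGT".index(true)] = 1 - error_rate
        counts = rng.multinomial(depth, probs) if depth > 0 else np.zeros(4, dtype=int)
        rows.append({"pos": p, "ref": ref, "A": counts[0], "C": counts[1], "G": counts[2], "T": counts[3]})
    return pd.DataFrame(rows, columns=["pos", "ref", "A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Writing a run to disk


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write panels (aligned FASTA), genome (FASTA+GFF3), tRNAs and truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    panels_dir = out / "panels"
    panels_dir.mkdir(exist_ok=True)
    for gene_id, panel in study.panels_broad.items():
        write_fasta(panel.rows, panels_dir / f"{gene_id}.broad.faa")
    for gene_id, panel in study.panels_narrow.items():
        write_fasta(panel.rows, panels_dir / f"{gene_id}.narrow.faa")
    write_fasta({"focal": study.genome}, out / "focal_genome.fasta")
    write_gff3(study.features, out / "focal_genome.gff3")
    write_fasta(study.trna_sequences, out / "trna_genes.fasta")
    study.ground_truth.to_json(out / "ground_truth.json")
    cfg = asdict(study.config)
    cfg["focal_code"] = study.config.focal_code.name
    Path(out / "config.json").write_text(json.dumps(cfg, indent=1, default=str) + "\n")
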