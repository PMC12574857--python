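"""End-to-end orchestration: simulate -> [edit-correct] -> profile -> infer
-> usage/stop-scan -> reports.

The run directory holds one plain file per stage output plus a
machine-readable ``summary.json`` (final code table, calls, usage,
stop-scan, tRNA and RF verdicts) and a log of parameters.  Reruns with the
same configuration and seed reproduce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import synthetic_data as sd
from .conservation import AlignedPanel
from .editing import apply_edits, call_edits, sites_to_dataframe, effects_to_dataframe
from .genetic_codes import (
    ALL_CODONS,
    CodingSequence,
    GeneticCodeTable,
    STANDARD_CODE,
    STOP,
    UNKNOWN,
    builtin_code,
)
from .inference import (
    DecisionParams,
    IterationResult,
    calls_to_dataframe,
    iterate,
)
from .io_formats import FeatureRecord, read_fasta, write_fasta
from .trna import identity_check, parse_trna
from .usage import StopScanReport, count_codons, stop_scan

logger = logging.getLogger("codonshift")


def infer_genetic_code(
    cds_set: dict[str, CodingSequence],
    panels_broad: dict[str, AlignedPanel],
    panels_narrow: dict[str, AlignedPanel],
    trna_features=(),
    params: DecisionParams = DecisionParams(),
    wobble_mode: str = "wobble",
    standard_code: GeneticCodeTable = STANDARD_CODE,
    aua_override: str | None = None,
) -> tuple[GeneticCodeTable, IterationResult, StopScanReport]:
    """Full code inference: sense calls plus sense-to-stop candidates.

    The two-iteration conserved-column inference supplies sense meanings;
    the stop scan marks codons used exclusively as annotated termination
    codons and lacking a decoding tRNA as stops.  ``aua_override`` forces a
    meaning for AUA (used when exporting proteins for phylogenomics despite
    a weak sequence signal); it is a configuration choice, not an inference
    outcome.
    """
    result = iterate(cds_set, panels_broad, panels_narrow, standard_code, params)
    scan = stop_scan(cds_set.values(), trna_features, wobble_mode)
    changes: dict[str, str] = {}
    for codon in ALL_CODONS:
        call = result.calls_iter2[codon]
        if call.status in ("reassigned", "unknown-X"):
            changes[codon] = call.meaning
    for codon in scan.stop_candidates():
        changes[codon] = STOP
    if aua_override is not None:
        changes["ATA"] = aua_override
    final = standard_code.with_assignments(changes, name="inferred")
    return final, result, scan


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON file on disk)."""

    seed: int = 0
    outdir: str = "run"
    # either simulate a study ...
    simulate: dict | None = None
    focal_code: str | None = None  # builtin code name for the simulation
    # ... or read real inputs
    genome_fasta: str | None = None
    features: str | None = None
    features_dialect: str = "gff3"
    panel_dir: str | None = None
    pileup: str | None = None
    trna_fasta: str | None = None
    params: dict = field(default_factory=dict)
    wobble_mode: str = "wobble"
    min_depth: int = 4

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        obj = json.loads(Path(path).read_text())
        return cls(**obj)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the machine-readable summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    params = DecisionParams(**config.params)

    stage = "simulate"
    try:
        if config.simulate is not None or config.genome_fasta is None:
            sim_kwargs = dict(config.simulate or {})
            if config.focal_code:
                sim_kwargs["focal_code"] = builtin_code(config.focal_code)
            sim_kwargs.setdefault("seed", config.seed)
            cfg = sd.SimulationConfig(**sim_kwargs)
            study = sd.simulate_panel(cfg)
            sd.write_study(study, out / "inputs")
            cds_set = study.focal_cds
            panels_broad, panels_narrow = study.panels_broad, study.panels_narrow
            trna_features = study.trna_features
            genome = study.genome
            pileup = None
            if cfg.editing_site_rate > 0:
                pileup = sd.simulate_pileup(
                    genome, study.ground_truth.editing_sites,
                    cfg.mean_read_depth, cfg.sequencing_error_rate, cfg.seed + 1,
                )
            features = study.features
        else:
            stage = "load-inputs"
            from .io_formats import extract_coding_sequences, read_features

            genomes = read_fasta(config.genome_fasta)
            genome = next(iter(genomes.values()))
            features = read_features(config.features, config.features_dialect)
            report = extract_coding_sequences(genomes, features)
            cds_set = {c.gene_id: c for c in report.coding_sequences}
            panels_broad = panels_narrow = _load_panels(config.panel_dir, cds_set)
            trna_features = [f for f in features if f.feature_type == "tRNA"]
            pileup = None
            if config.pileup:
                from .editing import read_pileup

                pileup = read_pileup(config.pileup)

        if pileup is not None:
            stage = "editing"
            sites = call_edits(pileup, genome, config.min_depth)
            corrected, effects = apply_edits(genome, sites, features)
            sites_to_dataframe(sites).to_csv(out / "editing_sites.tsv", sep="\t", index=False)
            effects_to_dataframe(effects).to_csv(out / "editing_effects.tsv", sep="\t", index=False)
            write_fasta({"corrected": corrected}, out / "corrected_genome.fasta")
        else:
            logger.info("no pileup provided; editing correction skipped")

        stage = "inference"
        final_code, result, scan = infer_genetic_code(
            cds_set, panels_broad, panels_narrow, trna_features,
            params, config.wobble_mode,
        )
        result.profile_iter1.to_tsv(out / "profile_iter1.tsv")
        result.profile_iter2.to_tsv(out / "profile_iter2.tsv")
        calls_to_dataframe(result.calls_iter1).to_csv(out / "calls_iter1.tsv", sep="\t", index=False)
        calls_to_dataframe(result.calls_iter2).to_csv(out / "calls_iter2.tsv", sep="\t", index=False)
        final_code.to_json(out / "inferred_code.json")
        scan.to_tsv(out / "stop_scan.tsv")

        stage = "codon-usage"
        usage = count_codons(cds_set.values(), genome_id="focal")
        usage.to_tsv(out / "codon_usage.tsv")

        stage = "trna"
        trna_rows = []
        for f in trna_features:
            seq = f.extract(genome) if f.intervals else ""
            if not seq:
                continue
            assessment = parse_trna(seq)
            row = {"gene_id": f.gene_id, "status": assessment.status}
            if assessment.parsed:
                row["anticodon"] = assessment.anticodon
                for aa_class in ("Ala", "Gly"):
                    row[aa_class] = identity_check(assessment, aa_class).overall
            trna_rows.append(row)

        summary = {
            "seed": config.seed,
            "inferred_code": dict(final_code.assignments),
            "diff_from_standard": {
                c: list(v) for c, v in final_code.diff(STANDARD_CODE).items()
            },
            "stop_candidates": list(scan.stop_candidates()),
            "n_cds": len(cds_set),
            "codon_usage_total": usage.total(),
            "trna": trna_rows,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
        summary["summary_digest"] = _digest(out / "summary.json")
        from . import __version__

        log_lines = [
            f"codonshift {__version__}",
            f"seed: {config.seed}",
            f"decision params: {params}",
            f"wobble mode: {config.wobble_mode}",
            f"summary digest: {summary['summary_digest']}",
        ]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _load_panels(panel_dir, cds_set) -> dict[str, AlignedPanel]:
    panels = {}
    for path in sorted(Path(panel_dir).glob("*.faa")) + sorted(Path(panel_dir).glob("*.fasta")):
        gene_id = path.name.split(".")[0]
        rows = read_fasta(path)
        if gene_id not in cds_set:
            continue
        if "focal" not in rows:
            from .conservation import attach_focal
            from .genetic_codes import translate

            cds = cds_set[gene_id]
            protein = "".join(STANDARD_CODE[c] for c in list(cds.codons())[:-1])
            panels[gene_id] = attach_focal(rows, protein, "focal", gene_id)
        else:
            panels[gene_id] = AlignedPanel(gene_id, rows, "focal")
    return panels
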