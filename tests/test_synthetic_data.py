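import numpy as np
import pytest

from codonshift.genetic_codes import STANDARD_CODE, builtin_code
from codonshift.synthetic_data import (
    ALA_STEM,
    SimulationConfig,
    simulate_panel,
    simulate_pileup,
    simulate_trna,
)


def _small(seed=0, **kw):
    kw.setdefault("n_genes", 3)
    kw.setdefault("gene_length_range", (60, 90))
    return SimulationConfig(seed=seed, **kw)


class TestPanelSimulation:
    def test_same_seed_same_config_is_byte_identical(self):
        a = simulate_panel(_small(seed=4))
        b = simulate_panel(_small(seed=4))
        assert a.genome == b.genome
        assert {g: p.rows for g, p in a.panels_broad.items()} == {
            g: p.rows for g, p in b.panels_broad.items()
        }
        assert a.ground_truth.placements == b.ground_truth.placements

    def test_zero_substitution_makes_reference_rows_identical(self):
        study = simulate_panel(_small(substitution_prob=0.0))
        for panel in study.panels_broad.values():
            refs = set(panel.reference_rows().values())
            assert len(refs) == 1

    def test_focal_row_is_standard_translation_without_terminal_codon(self):
        study = simulate_panel(_small(seed=2))
        for gene, panel in study.panels_broad.items():
            cds = study.focal_cds[gene]
            expected = "".join(STANDARD_CODE[c] for c in list(cds.codons())[:-1])
            assert panel.focal_row == expected

    def test_reassigned_codons_placed_at_conserved_positions(self):
        code = builtin_code("pedinomonadales-mito")
        study = simulate_panel(SimulationConfig(seed=3, focal_code=code))
        tga = study.ground_truth.placements_for("TGA")
        assert len(tga) >= 5
        # every UGA placement sits where the references are Trp-invariant
        for gene, idx, _codon in tga:
            col = {row[idx] for row in study.panels_broad[gene].reference_rows().values()}
            assert col == {"W"}

    def test_stop_reassigned_codons_only_terminal(self):
        code = builtin_code("marsupiomonadales-mito")
        study = simulate_panel(SimulationConfig(seed=5, focal_code=code))
        for cds in study.focal_cds.values():
            codons = list(cds.codons())
            assert codons[-1] in code.stop_codons
            assert not set(codons[:-1]) & {"TTA", "TTG"}

    def test_infeasible_codon_weights_raise(self):
        cfg = _small(codon_usage_weights={"TGG": 0.0})
        with pytest.raises(ValueError, match="all-zero"):
            simulate_panel(cfg)

    def test_trna_set_covers_sense_codons_only(self):
        code = builtin_code("marsupiomonadales-mito")
        study = simulate_panel(SimulationConfig(seed=1, focal_code=code, n_genes=2))
        anticodons = {f.anticodon for f in study.trna_features}
        assert "TCT" in anticodons  # decodes the reassigned AGA
        assert "TAA" not in anticodons and "CAA" not in anticodons  # UUA/UUG undecoded
        # the genome carries each tRNA gene at its annotated location
        for f in study.trna_features:
            assert f.extract(study.genome) == study.trna_sequences[f.gene_id]


class TestPileupSimulation:
    def test_edited_site_has_majority_for_edited_base(self):
        genome = "ACGT" * 25
        sites = [(2, "C", "T")]  # genome has C, transcripts read T
        genome = genome[:1] + "C" + genome[2:]
        df = simulate_pileup(genome, sites, mean_depth=50, error_rate=0.01, seed=0)
        row = df[df.pos == 2].iloc[0]
        assert row["T"] > row[["A", "C", "G"]].max()

    def test_no_edits_zero_error_is_all_reference(self):
        genome = "ACGTACGTAC"
        df = simulate_pileup(genome, [], mean_depth=30, error_rate=0.0, seed=1)
        for row in df.itertuples(index=False):
            counts = {b: getattr(row, b) for b in "ACGT"}
            assert sum(counts.values()) == counts[row.ref]

    def test_zero_depth_column_emitted_with_zero_counts(self):
        df = simulate_pileup("ACGT", [], mean_depth=0.0, error_rate=0.01, seed=2)
        assert (df[["A", "C", "G", "T"]].sum(axis=1) == 0).all()

    def test_site_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_pileup("ACGT", [(99, "A", "C")], 10, 0.01, seed=0)


class TestTrnaSimulation:
    def test_same_seed_identical_sequence(self):
        a = simulate_trna(ALA_STEM, "TCT", "A", seed=9)
        b = simulate_trna(ALA_STEM, "TCT", "A", seed=9)
        assert a == b

    def test_impossible_pairing_rejected(self):
        bad = (("A", "A"),) + ALA_STEM[1:]
        with pytest.raises(ValueError, match="impossible"):
            simulate_trna(bad, "TCT", "A", seed=0)

    def test_length_in_trna_range(self):
        assert 60 <= len(simulate_trna(ALA_STEM, "TCT", "A", seed=0)) <= 100
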