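import pandas as pd
import pytest

from codonshift.editing import (
    STATUS_CALLED,
    STATUS_TIE,
    STATUS_UNCOVERED,
    apply_edits,
    call_edits,
)
from codonshift.genetic_codes import builtin_code
from codonshift.io_formats import FeatureRecord
from codonshift.synthetic_data import SimulationConfig, simulate_panel, simulate_pileup


def _pileup(rows):
    return pd.DataFrame(rows, columns=["pos", "ref", "A", "C", "G", "T"])


GENOME = "ATGTGATGGTAACCCCC"
RPOB = FeatureRecord("g", "CDS", "rpoB", ((1, 12),), "+")


class TestCallEdits:
    def test_clear_majority_is_called(self):
        sites = call_edits(_pileup([(4, "T", 1, 9, 0, 0)]), GENOME)
        (site,) = sites
        assert site.status == STATUS_CALLED
        assert (site.ref, site.edited) == ("T", "C")
        assert site.support == pytest.approx(0.9)

    def test_exact_tie_is_ambiguous_not_called(self):
        (site,) = call_edits(_pileup([(4, "T", 0, 5, 0, 5)]), GENOME)
        assert site.status == STATUS_TIE
        assert not site.called

    def test_zero_depth_is_uncovered(self):
        (site,) = call_edits(_pileup([(4, "T", 0, 0, 0, 0)]), GENOME)
        assert site.status == STATUS_UNCOVERED

    def test_below_min_depth_is_uncovered(self):
        (site,) = call_edits(_pileup([(4, "T", 0, 3, 0, 0)]), GENOME, min_depth=4)
        assert site.status == STATUS_UNCOVERED

    def test_reference_majority_emits_nothing(self):
        assert call_edits(_pileup([(4, "T", 0, 1, 0, 49)]), GENOME) == []

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            call_edits(_pileup([(4, "A", 0, 9, 0, 1)]), GENOME)


class TestApplyEdits:
    def test_stop_removal_restores_reading_frame(self):
        # an in-frame UGA whose first position is edited T->C becomes the
        # arginine codon CGA, restoring an intact coding sequence
        sites = call_edits(_pileup([(4, "T", 1, 9, 0, 0)]), GENOME)
        corrected, effects = apply_edits(GENOME, sites, [RPOB])
        assert corrected[3] == "C"
        (e,) = effects
        assert (e.codon_before, e.codon_after) == ("TGA", "CGA")
        assert e.effect == "stop-removal" and e.aa_after == "R"

    def test_intergenic_site_reported_outside_cds(self):
        sites = call_edits(_pileup([(15, "C", 39, 0, 0, 1)]), GENOME)
        _corrected, effects = apply_edits(GENOME, sites, [RPOB])
        assert effects[0].effect == "outside-CDS"

    def test_effect_depends_on_genetic_code(self):
        # UUA edited to CUA: silent under the standard code (Leu->Leu) but a
        # stop-removal where UUA has become a termination codon
        genome = "ATGTTATGGTAA"
        feat = FeatureRecord("g", "CDS", "ycf3", ((1, 12),), "+")
        sites = call_edits(_pileup([(4, "T", 0, 45, 0, 5)]), genome)
        _c, std = apply_edits(genome, sites, [feat], builtin_code("standard"))
        _c, ped = apply_edits(genome, sites, [feat], builtin_code("pedinoflagellate-plastid"))
        assert std[0].effect == "synonymous"
        assert ped[0].effect == "stop-removal" and ped[0].aa_after == "L"

    def test_overlapping_cds_reported_for_both(self):
        genome = "ATGTGATGGTAACCC"
        f1 = FeatureRecord("g", "CDS", "a", ((1, 12),), "+")
        f2 = FeatureRecord("g", "CDS", "b", ((4, 15),), "+")
        sites = call_edits(_pileup([(4, "T", 0, 9, 0, 1)]), genome)
        _c, effects = apply_edits(genome, sites, [f1, f2])
        assert {e.gene_id for e in effects} == {"a", "b"}

    def test_explicit_patch_applied(self):
        corrected, effects = apply_edits(GENOME, [], [RPOB], patches=[(4, "C")])
        assert corrected[3] == "C"
        assert effects[0].effect == "stop-removal"


class TestCallerOnSimulatedPileups:
    def test_idempotence_after_correction(self):
        study = simulate_panel(SimulationConfig(seed=8, n_genes=3, editing_site_rate=0.01))
        truth = study.ground_truth.editing_sites
        pileup = simulate_pileup(study.genome, truth, 50, 0.0, seed=9)
        sites = call_edits(pileup, study.genome)
        corrected, _ = apply_edits(study.genome, sites, study.features)
        # a noise-free pileup from the corrected genome yields no new calls
        clean = simulate_pileup(corrected, [], 50, 0.0, seed=10)
        assert [s for s in call_edits(clean, corrected) if s.called] == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_perfect_sensitivity_and_precision_at_depth(self, seed):
        study = simulate_panel(
            SimulationConfig(seed=seed, n_genes=3, editing_site_rate=0.01)
        )
        truth = {(p, m) for p, _g, m in study.ground_truth.editing_sites}
        assert truth
        pileup = simulate_pileup(study.genome, study.ground_truth.editing_sites, 50, 0.01, seed + 100)
        called = {(s.position, s.edited) for s in call_edits(pileup, study.genome) if s.called}
        assert called == truth
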