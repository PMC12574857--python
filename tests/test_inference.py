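from collections import Counter

import pytest

from codonshift.conservation import ConservedColumnProfile
from codonshift.genetic_codes import STANDARD_CODE, builtin_code
from codonshift.inference import (
    DecisionParams,
    STATUS_INSUFFICIENT,
    STATUS_REASSIGNED,
    STATUS_STANDARD,
    STATUS_UNKNOWN,
    decide,
    iterate,
    retranslate,
)
from codonshift.genetic_codes import CodingSequence
from codonshift.pipeline import infer_genetic_code
from codonshift.synthetic_data import SimulationConfig, simulate_panel


def _profile(codon, counts, total=None):
    p = ConservedColumnProfile()
    p.conserved[codon] = Counter(counts)
    p.totals[codon] = total if total is not None else sum(counts.values())
    return p


class TestDecisionRule:
    @pytest.mark.parametrize(
        "codon,counts,status,meaning",
        [
            # stop codon at 40 conserved Trp columns, 1 Cys -> reassigned W
            ("TGA", {"W": 40, "C": 1}, STATUS_REASSIGNED, "W"),
            # arginine codon, zero R among conserved: 6 >= 5 and 6 >= 2x3
            ("AGA", {"A": 6, "G": 3}, STATUS_REASSIGNED, "A"),
            # dominance fails: 6 < 2x4
            ("AGA", {"A": 6, "G": 4}, STATUS_UNKNOWN, "X"),
            # standard amino acid dominates
            ("AGA", {"R": 30}, STATUS_STANDARD, "R"),
            # below the evidence floor
            ("AGA", {"A": 4}, STATUS_INSUFFICIENT, "R"),
        ],
    )
    def test_worked_examples(self, codon, counts, status, meaning):
        call = decide(_profile(codon, counts), codon)
        assert call.status == status
        assert call.meaning == meaning

    def test_exact_dominance_tie_is_reassigned(self):
        # top == dominance_ratio x runner-up is inclusive
        call = decide(_profile("AGA", {"A": 6, "G": 3}), "AGA")
        assert call.status == STATUS_REASSIGNED
        call = decide(_profile("AGA", {"A": 5, "G": 3}), "AGA")
        assert call.status == STATUS_UNKNOWN

    def test_ten_percent_rule_is_strict(self):
        # standard fraction exactly 10% -> standard (>= boundary)
        call = decide(_profile("AGA", {"A": 45, "R": 5}), "AGA")
        assert call.status == STATUS_STANDARD
        call = decide(_profile("AGA", {"A": 46, "R": 4}), "AGA")
        assert call.status == STATUS_REASSIGNED

    def test_evidence_recorded_on_call(self):
        call = decide(_profile("TGA", {"W": 40, "C": 1}), "TGA")
        assert call.n_conserved == 41
        assert call.top == ("W", 40) and call.runner_up == ("C", 1)
        assert call.standard_meaning == "*"

    def test_parameters_are_configurable(self):
        params = DecisionParams(min_conserved=10)
        call = decide(_profile("TGA", {"W": 8}), "TGA", params=params)
        assert call.status == STATUS_INSUFFICIENT


class TestRetranslate:
    def test_all_standard_calls_reproduce_standard_translation(self):
        cds = {"g": CodingSequence("g", "ATGCGTTGGTAA")}
        calls = {c: decide(ConservedColumnProfile(), c) for c in ("ATG", "CGT", "TGG")}
        out = retranslate(cds, calls)
        assert out == {"g": "MRW"}

    def test_reassigned_and_unknown_codons_change_protein(self):
        cds = {"g": CodingSequence("g", "ATGTGAAGGTAA")}
        calls = {
            "TGA": decide(_profile("TGA", {"W": 40}), "TGA"),
            "AGG": decide(_profile("AGG", {"A": 6, "G": 4}), "AGG"),
        }
        assert retranslate(cds, calls) == {"g": "MWX"}


class TestIterate:
    def test_identical_panels_give_identical_call_sets(self, uga_trp_study):
        study = uga_trp_study
        result = iterate(study.focal_cds, study.panels_broad, study.panels_broad)
        assert result.calls_iter1 == result.calls_iter2

    def test_gene_set_mismatch_names_missing_genes(self, uga_trp_study):
        study = uga_trp_study
        broad = dict(study.panels_broad)
        broad.pop("gene00")
        with pytest.raises(ValueError, match="gene00"):
            iterate(study.focal_cds, broad, study.panels_narrow)

    def test_uga_trp_genome_recovers_final_table(self, uga_trp_study):
        study = uga_trp_study
        result = iterate(study.focal_cds, study.panels_broad, study.panels_narrow)
        assert result.final_code["TGA"] == "W"
        assert result.final_code["ATA"] == "M"
        assert result.calls_iter2["TGA"].is_reassigned

    def test_standard_genome_yields_standard_table(self, small_standard_study):
        study = small_standard_study
        final, result, scan = infer_genetic_code(
            study.focal_cds, study.panels_broad, study.panels_narrow, study.trna_features
        )
        assert final.diff(STANDARD_CODE) == {}

    def test_determinism(self, uga_trp_study):
        study = uga_trp_study
        a = iterate(study.focal_cds, study.panels_broad, study.panels_narrow)
        b = iterate(study.focal_cds, study.panels_broad, study.panels_narrow)
        assert a.calls_iter2 == b.calls_iter2
        assert a.final_code.assignments == b.final_code.assignments


class TestFullInference:
    def test_stop_reassignments_come_from_stop_scan(self):
        code = builtin_code("marsupiomonadales-mito")
        study = simulate_panel(SimulationConfig(seed=13, focal_code=code))
        final, result, scan = infer_genetic_code(
            study.focal_cds, study.panels_broad, study.panels_narrow, study.trna_features
        )
        assert final["TTA"] == "*" and final["TTG"] == "*"
        assert final["AGA"] == "A" and final["AGG"] == "A"
        assert {"TTA", "TTG"} <= set(scan.stop_candidates())

    def test_aua_override_is_config_not_inference(self, small_standard_study):
        study = small_standard_study
        final, _result, _scan = infer_genetic_code(
            study.focal_cds, study.panels_broad, study.panels_narrow,
            study.trna_features, aua_override="M",
        )
        assert final["ATA"] == "M"
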