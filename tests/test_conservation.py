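import pytest
from hypothesis import given, settings, strategies as st

from codonshift.conservation import (
    AlignedPanel,
    attach_focal,
    codon_column_map,
    conserved_columns,
    profile_codons,
)
from codonshift.genetic_codes import CodingSequence


def _panel(columns, focal_row, focal="focal"):
    """Build a panel from per-column reference residue strings."""
    n_rows = len(columns[0])
    rows = {f"t{i}": "".join(col[i] for col in columns) for i in range(n_rows)}
    rows[focal] = focal_row
    return AlignedPanel("g", rows, focal)


class TestConservedColumns:
    def test_eighty_percent_tryptophan_is_conserved(self):
        panel = _panel(["WWWWWWWWCC"], "W")
        assert conserved_columns(panel, 0.70) == ["W"]

    def test_inclusive_boundary_at_exactly_seventy_percent(self):
        panel = _panel(["RRRRRRRKKK"], "R")
        assert conserved_columns(panel, 0.70) == ["R"]
        assert conserved_columns(panel, 0.70, inclusive=False) == [None]

    def test_gaps_in_denominator_defeat_half_filled_column(self):
        panel = _panel(["AAAAA-----"], "A")
        assert conserved_columns(panel, 0.70) == [None]
        # excluding gaps from the denominator flips the verdict
        assert conserved_columns(panel, 0.70, gap_policy="exclude") == ["A"]

    def test_minimum_residue_guard(self):
        panel = _panel(["AAA-------"], "A")
        assert conserved_columns(panel, 0.70, gap_policy="exclude", min_residues=4) == [None]

    def test_focal_row_excluded_by_default(self):
        # 10 references split 7W/3C; the focal residue must not tip the count
        panel = _panel(["WWWWWWWCCC"], "C")
        assert conserved_columns(panel, 0.70) == ["W"]
        assert conserved_columns(panel, 0.70, exclude_focal=False) == [None]

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.text(alphabet="ACDWKR-", min_size=8, max_size=8),
            min_size=3,
            max_size=12,
        ),
        st.floats(min_value=0.3, max_value=0.9),
        st.floats(min_value=0.05, max_value=0.3),
    )
    def test_raising_threshold_never_adds_conserved_columns(self, cols, t, dt):
        panel = _panel(cols, "A" * len(cols))
        low = conserved_columns(panel, t)
        high = conserved_columns(panel, min(1.0, t + dt))
        assert all(h is None or h == l for l, h in zip(low, high))
        assert sum(v is not None for v in high) <= sum(v is not None for v in low)


class TestCodonColumnMap:
    def test_leading_gap_shifts_columns(self):
        rows = {"t0": "MABW", "focal": "---W"}
        # CDS: one mapped codon + terminal stop
        panel = AlignedPanel("g", rows, "focal")
        cds = CodingSequence("g", "TGGTAA")
        assert codon_column_map(panel, cds) == [(0, 3)]

    def test_terminal_stop_codon_has_no_column(self):
        rows = {"t0": "MW", "focal": "MW"}
        panel = AlignedPanel("g", rows, "focal")
        cds = CodingSequence("g", "ATGTGGTAA")
        assert codon_column_map(panel, cds) == [(0, 0), (1, 1)]

    def test_length_mismatch_rejected(self):
        panel = AlignedPanel("g", {"t0": "MW", "focal": "MW"}, "focal")
        with pytest.raises(ValueError, match="non-terminal"):
            codon_column_map(panel, CodingSequence("g", "ATGTGGTGGTAA"))


class TestProfile:
    def test_counts_conserved_and_total_occurrences(self):
        rows = {f"t{i}": "MWW" for i in range(6)}
        rows["focal"] = "M**"  # focal standard translation of ATG TGA TGA
        panel = AlignedPanel("g", rows, "focal")
        cds = CodingSequence("g", "ATGTGATGATAA")
        verdicts = conserved_columns(panel)
        profile = profile_codons({"g": panel}, {"g": cds}, verdicts={"g": verdicts})
        assert profile.conserved_counts("TGA") == {"W": 2}
        assert profile.total_occurrences("TGA") == 2
        assert profile.total_occurrences("ATG") == 1

    def test_total_codons_sum_check(self, small_standard_study):
        study = small_standard_study
        verdicts = {g: conserved_columns(p) for g, p in study.panels_broad.items()}
        profile = profile_codons(study.panels_broad, study.focal_cds, verdicts)
        expected = sum(c.n_codons - 1 for c in study.focal_cds.values())
        assert sum(profile.totals.values()) == expected
        for codon in profile.conserved:
            assert profile.conserved_occurrences(codon) <= profile.total_occurrences(codon)

    def test_profile_invariant_to_focal_residues(self, small_standard_study):
        study = small_standard_study
        verdicts = {g: conserved_columns(p) for g, p in study.panels_broad.items()}
        base = profile_codons(study.panels_broad, study.focal_cds, verdicts)
        mutated = {
            g: p.with_focal_protein("K" * len(p.focal_row.replace("-", "")))
            for g, p in study.panels_broad.items()
        }
        verdicts2 = {g: conserved_columns(p) for g, p in mutated.items()}
        again = profile_codons(mutated, study.focal_cds, verdicts2)
        assert base.conserved == again.conserved and base.totals == again.totals


class TestAttachFocal:
    ALN = {"t1": "MKVLW", "t2": "MKVLW", "t3": "MRVLW"}

    def test_identical_sequence_adds_no_columns(self):
        panel = attach_focal(self.ALN, "MKVLW")
        assert panel.n_columns == 5
        assert panel.focal_row == "MKVLW"
        assert panel.rows["t1"] == "MKVLW"

    def test_one_extra_terminal_residue_adds_exactly_one_column(self):
        panel = attach_focal(self.ALN, "MKVLWE")
        assert panel.n_columns == 6
        assert panel.focal_row == "MKVLWE"
        assert panel.rows["t1"] == "MKVLW-"

    def test_unknown_residues_align_neutrally(self):
        panel = attach_focal(self.ALN, "MKXLW")
        assert panel.n_columns == 5
        assert panel.focal_row == "MKXLW"

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            attach_focal({}, "MKV")
        with pytest.raises(ValueError):
            attach_focal(self.ALN, "")
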