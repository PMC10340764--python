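import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coixpep import (
    ScreenConfig,
    classify_permeability,
    ingest_scores,
    load_table2_scores,
    motif_flags,
    peptide_mass,
    screen,
)
from coixpep.peptides import PeptideRecord, ingest_from_frame
from coixpep.residues import WATER_MONO
from coixpep.seqio import SequenceValidationError

AA = "ACDEFGHIKLMNPQRSTVWY"
peptide_seqs = st.text(alphabet=AA, min_size=1, max_size=30)


class TestPeptideMass:
    @pytest.mark.parametrize(
        "seq,printed",
        [("WGF", 408.18), ("PL", 228.15), ("QPQCSCSPVAVPYYAQQR", 2023.92)],
    )
    def test_published_monoisotopic_anchors(self, seq, printed):
        assert peptide_mass(seq) == pytest.approx(printed, abs=0.01)

    def test_single_residue_is_residue_plus_water(self):
        assert peptide_mass("G") == pytest.approx(57.02146 + 18.01056, abs=1e-3)

    def test_all_47_table_rows_within_a_centidalton(self):
        df = load_table2_scores()
        assert len(df) == 47
        for row in df.itertuples():
            assert peptide_mass(row.sequence) == pytest.approx(
                row.mol_weight, abs=0.01
            ), row.sequence

    def test_average_exceeds_monoisotopic(self):
        for seq in ("G", "PL", "QPQCSCSPVAVPYYAQQR"):
            assert peptide_mass(seq, "average") > peptide_mass(seq, "monoisotopic")

    def test_illegal_residue_rejected(self):
        with pytest.raises(SequenceValidationError):
            peptide_mass("PAX")

    @settings(max_examples=150, deadline=None)
    @given(a=peptide_seqs, b=peptide_seqs)
    def test_mass_additive_up_to_one_water(self, a, b):
        # condensation removes one water per bond formed
        assert peptide_mass(a + b) == pytest.approx(
            peptide_mass(a) + peptide_mass(b) - WATER_MONO, abs=1e-6
        )


class TestMotifFlags:
    def test_pro_penultimate(self):
        f = motif_flags("QQPL")
        assert f["pro_penultimate"] and not f["pro_c_terminal"]
        assert not f["n_term_hydrophobic"]

    def test_all_hydrophobic_with_n_terminal_pro(self):
        f = motif_flags("PAL")
        assert f["pro_n_terminal"] and f["n_term_hydrophobic"]
        assert f["hydrophobic_fraction"] == 1.0

    def test_no_motifs(self):
        f = motif_flags("GG")
        assert f["hydrophobic_fraction"] == 0.0
        assert not any(
            f[k] for k in ("n_term_hydrophobic", "pro_n_terminal",
                           "pro_penultimate", "pro_c_terminal")
        )

    def test_single_residue_positional_flags_false(self):
        f = motif_flags("P")
        assert f["hydrophobic_fraction"] == 1.0
        assert not f["pro_n_terminal"] and not f["pro_c_terminal"]

    @settings(max_examples=100, deadline=None)
    @given(seq=st.text(alphabet=AA, min_size=2, max_size=20))
    def test_flags_consistent_with_direct_inspection(self, seq):
        f = motif_flags(seq)
        assert f["pro_c_terminal"] == (seq[-1] == "P")
        assert f["pro_penultimate"] == (seq[-2] == "P")
        assert f["pro_n_terminal"] == (seq[0] == "P")


class TestIngestScores:
    def test_packaged_table_parses_fully(self):
        df = load_table2_scores()
        assert len(df) == 47
        w = df[df.sequence == "WGF"].iloc[0]
        assert w.caco2_log == pytest.approx(-6.147)
        assert w.mdck_cm_s == pytest.approx(8.90e-6)
        assert w.ppb_percent == pytest.approx(67.13)
        assert df.bioactivity.min() == pytest.approx(0.505)

    def test_notation_variants_and_missing(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text(
            "sequence,bioactivity,dppiv_probability,mdck_cm_s\n"
            "AA,0.9,NA,8.90 × 10^−6\n"
            "AG,0.8,-,8.90E-6\n"
            "AL,0.7,0.5,0.0011\n"
        )
        scores = ingest_scores(p)
        assert scores["AA"].mdck_cm_s == pytest.approx(8.90e-6)
        assert scores["AG"].mdck_cm_s == pytest.approx(8.90e-6)
        assert scores["AA"].dppiv_probability is None
        assert scores["AG"].dppiv_probability is None
        assert scores["AL"].dppiv_probability == 0.5

    def test_empty_file_gives_empty_map(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("sequence,bioactivity\n")
        assert ingest_scores(p) == {}

    def test_duplicate_sequence_rejected(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("sequence,bioactivity\nAA,0.9\nAA,0.8\n")
        with pytest.raises(ValueError, match="duplicate"):
            ingest_scores(p)

    def test_unparseable_numeric_names_line(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("sequence,bioactivity\nAA,0.9\nAG,not_a_number\n")
        with pytest.raises(ValueError, match="line 3"):
            ingest_scores(p)


class TestPermeabilityBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.0, "low"),
            (1.9e-6, "low"),
            (2e-6, "medium"),  # boundary belongs to the inner band
            (8.9e-6, "medium"),
            (20e-6, "medium"),  # boundary belongs to the inner band
            (2.1e-5, "high"),
        ],
    )
    def test_banding(self, value, band):
        assert classify_permeability(value) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_permeability(-1e-6)


class TestScreen:
    def test_fixture_retains_all_47(self):
        result = screen(ingest_from_frame(load_table2_scores()))
        assert len(result) == 47

    def test_dppiv_ranking_head(self):
        result = screen(ingest_from_frame(load_table2_scores()))
        assert list(result.sequence[:5]) == ["PAL", "QQPL", "PL", "PSL", "SSPL"]
        assert result.dppiv_probability.iloc[0] == pytest.approx(0.724)

    def test_absent_probabilities_sort_last(self):
        result = screen(ingest_from_frame(load_table2_scores()))
        missing = result.dppiv_probability.isna().to_numpy()
        first_missing = missing.argmax()
        assert missing[first_missing:].all()

    def test_strict_threshold_empties_table(self):
        df = load_table2_scores().copy()
        df["bioactivity"] = 0.4
        assert screen(ingest_from_frame(df)).empty

    def test_boundary_score_excluded(self):
        # the filter is strictly greater-than
        df = load_table2_scores().copy()
        df.loc[df.sequence == "AQQPL", "bioactivity"] = 0.5
        result = screen(ingest_from_frame(df))
        assert "AQQPL" not in set(result.sequence)

    def test_output_is_subset_with_motifs_and_bands(self):
        df = load_table2_scores()
        result = screen(ingest_from_frame(df))
        assert set(result.sequence) <= set(df.sequence)
        pal = result[result.sequence == "PAL"].iloc[0]
        assert pal.hydrophobic_fraction == 1.0 and pal.mdck_band == "high"
        wgf = result[result.sequence == "WGF"].iloc[0]
        assert wgf.mdck_band == "medium"

    def test_config_threshold_respected(self):
        result = screen(
            ingest_from_frame(load_table2_scores()), ScreenConfig(bioactivity_min=0.9)
        )
        assert (result.bioactivity > 0.9).all() and len(result) == 8


def test_record_from_sequence_consistent():
    rec = PeptideRecord.from_sequence("qqpl")
    assert rec.sequence == "QQPL" and rec.length == 4
    assert rec.mono_mass == pytest.approx(484.26, abs=0.01)
    assert rec.avg_mass > rec.mono_mass
    assert rec.pro_penultimate


def test_predictor_scores_probability_range():
    from coixpep.peptides import PredictorScores

    with pytest.raises(ValueError):
        PredictorScores(bioactivity=1.2)
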