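"""Data model, embedded study tables, and rating-file round trips."""

import io

import pytest

from morphosex import (
    ScoreTable,
    Trait,
    read_recorded_sex,
    read_scores,
    score_frequencies,
    write_scores,
)
from morphosex.dataset import Sex, scores_to_string
from morphosex.errors import ScoreParseError, TableLookupError


class TestBuiltinTables:
    def test_dimensions(self, observer_table, video_table):
        for table in (observer_table, video_table):
            assert len(table.crania) == 20
            assert len(table.observers) == 4

    def test_missing_cells(self, observer_table, video_table):
        # Observer 3 scored only the glabella on cranium 4.
        assert observer_table.n_missing() == 2
        assert observer_table.cell("O3", 4, Trait.MASTOID_PROCESS) is None
        assert observer_table.cell("O3", 4, Trait.SUPRAORBITAL_MARGIN) is None
        assert observer_table.cell("O3", 4, Trait.GLABELLA) == 1
        assert video_table.n_missing() == 0

    @pytest.mark.parametrize(
        "observer, cranium, trait, expected",
        [
            ("O2", 5, Trait.MASTOID_PROCESS, 5),
            ("O1", 1, Trait.MASTOID_PROCESS, 1),
            ("O4", 20, Trait.SUPRAORBITAL_MARGIN, 4),
            ("V4", 20, Trait.GLABELLA, 3),
            ("V1", 4, Trait.MASTOID_PROCESS, 5),
        ],
    )
    def test_spot_cells(self, study, observer, cranium, trait, expected):
        table = study[0] if observer.startswith("O") else study[1]
        assert table.cell(observer, cranium, trait) == expected

    def test_recorded_sexes(self, recorded):
        males = {5, 6, 9, 11, 12, 13, 14, 16, 18, 20}
        for cranium in range(1, 21):
            expected = Sex.MALE if cranium in males else Sex.FEMALE
            assert recorded[cranium] is expected
        assert len(recorded.crania_of(Sex.MALE)) == 10
        assert len(recorded.crania_of(Sex.FEMALE)) == 10


class TestScoreFrequencies:
    def test_observer1_mastoid_score1_count(self, observer_table):
        counts = score_frequencies(observer_table, "O1", Trait.MASTOID_PROCESS)
        assert counts[0] == 9

    def test_observer2_glabella_score5_count(self, observer_table):
        counts = score_frequencies(observer_table, "O2", Trait.GLABELLA)
        assert counts[4] == 10

    @pytest.mark.parametrize("trait", list(Trait))
    def test_counts_sum_to_nonmissing_cells(self, observer_table, trait):
        for observer in observer_table.observers:
            counts = score_frequencies(observer_table, observer, trait)
            n_missing = sum(
                observer_table.cells[(observer, c, trait)] is None
                for c in observer_table.crania
            )
            assert sum(counts) == 20 - n_missing
            assert all(c >= 0 for c in counts)

    def test_unknown_observer_rejected(self, observer_table):
        with pytest.raises(TableLookupError):
            score_frequencies(observer_table, "O9", Trait.GLABELLA)
        with pytest.raises(TableLookupError):
            observer_table.cell("O1", 1, "brow_ridge")


class TestRatingFileIO:
    def test_two_row_file(self):
        text = (
            "observer,cranium,trait,score\n"
            "A,1,glabella,3\n"
            "A,2,glabella,5\n"
        )
        table = read_scores(io.StringIO(text))
        assert table.cell("A", 1, Trait.GLABELLA) == 3
        assert table.cell("A", 2, Trait.GLABELLA) == 5
        # unlisted trait cells exist as missing
        assert table.cell("A", 1, Trait.MASTOID_PROCESS) is None

    def test_empty_score_field_is_missing(self):
        text = "observer,cranium,trait,score\nA,1,glabella,\n"
        table = read_scores(io.StringIO(text))
        assert table.cell("A", 1, Trait.GLABELLA) is None

    @pytest.mark.parametrize(
        "bad_row, fragment",
        [
            ("A,1,glabella,6", "score"),
            ("A,1,glabella,0", "score"),
            ("A,1,glabella,two", "score"),
            ("A,1,eyebrow,3", "trait"),
            ("A,1,glabella", "fields"),
        ],
    )
    def test_malformed_rows_name_line_number(self, bad_row, fragment):
        text = f"observer,cranium,trait,score\nA,1,mastoid_process,3\n{bad_row}\n"
        with pytest.raises(ScoreParseError, match="line 3") as exc:
            read_scores(io.StringIO(text))
        assert fragment in str(exc.value)

    def test_duplicate_triple_rejected(self):
        text = (
            "observer,cranium,trait,score\n"
            "A,1,glabella,3\n"
            "A,1,glabella,4\n"
        )
        with pytest.raises(ScoreParseError, match="duplicate"):
            read_scores(io.StringIO(text))

    def test_bad_header_rejected(self):
        with pytest.raises(ScoreParseError, match="header"):
            read_scores(io.StringIO("obs,skull,feature,value\nA,1,glabella,3\n"))

    @pytest.mark.parametrize("which", ["observers", "video"])
    def test_round_trip_builtin(self, study, which, tmp_path):
        table = study[0] if which == "observers" else study[1]
        path = tmp_path / "scores.csv"
        write_scores(table, path)
        again = read_scores(path)
        assert again == table
        # and byte-identical on the second pass
        assert scores_to_string(again) == path.read_text()

    def test_recorded_sex_round_trip(self, recorded, tmp_path):
        path = tmp_path / "recorded.csv"
        recorded.to_frame().to_csv(path, index=False)
        again = read_recorded_sex(path)
        assert again.sexes == recorded.sexes

    def test_recorded_sex_bad_label(self):
        with pytest.raises(ScoreParseError, match="line 2"):
            read_recorded_sex(io.StringIO("cranium,sex\n1,unknown\n"))


class TestScoreTableInvariants:
    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ScoreTable(("A", "A"), (1,), {})
        with pytest.raises(ValueError, match="duplicate"):
            ScoreTable(("A",), (1, 1), {})

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="1-5"):
            ScoreTable(("A",), (1,), {("A", 1, Trait.GLABELLA): 7})

    def test_unreferenced_cell_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ScoreTable(("A",), (1,), {("B", 1, Trait.GLABELLA): 3})
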