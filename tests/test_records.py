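import logging

import pytest

from fancfid.errors import ParseError, ReferentialIntegrityError, ValidationError
from fancfid.records import (
    CONTENT_ITEMS,
    FACILITATION_ITEMS,
    CohortTable,
    ContentChecklist,
    Provider,
    facilitation_score,
    load_schema,
    read_cohort,
    write_cohort,
)
from fancfid.synthdata import GeneratorConfig, generate_cohort_structural

from conftest import make_checklist, make_cluster, make_woman


class TestChecklist:
    def test_has_exactly_17_items(self):
        assert len(CONTENT_ITEMS) == 17
        assert make_checklist(17).n_delivered == 17
        assert make_checklist(0).n_delivered == 0

    def test_unknown_item_rejected(self):
        with pytest.raises(ValidationError, match="unknown content"):
            ContentChecklist.from_dict({"weight_measured": True, "nope": False})


class TestWomanInvariants:
    def test_non_attender_cannot_have_contents(self):
        from fancfid.records import WomanRecord

        with pytest.raises(ValidationError, match="content items"):
            WomanRecord(
                woman_id="w1",
                cluster_id="hp01",
                n_visits=0,
                contents=make_checklist(3),
                provider=Provider.NONE,
                tt_doses=0,
            )

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_visits=-1), "n_visits"),
            (dict(age_years=10.0), "age_years"),
            (dict(first_visit_month=11), "first_visit_month"),
            (dict(n_visits=2, provider=Provider.NONE), "provider"),
        ],
    )
    def test_field_invariants(self, kwargs, msg):
        with pytest.raises(ValidationError, match=msg):
            make_woman("w1", **kwargs)

    def test_missing_covariates_allowed(self):
        w = make_woman("w1", age_years=None, partner_education=None)
        assert w.age_years is None


class TestCohortValidation:
    def test_duplicate_woman_id(self):
        c = make_cluster("hp01")
        with pytest.raises(ValidationError, match="duplicate woman_id"):
            CohortTable(
                women=[make_woman("w1"), make_woman("w1")], clusters={"hp01": c}
            )

    def test_unresolved_cluster(self):
        with pytest.raises(ReferentialIntegrityError, match="hp99"):
            CohortTable(
                women=[make_woman("w1", "hp99")],
                clusters={"hp01": make_cluster("hp01")},
            )


class TestFacilitationScore:
    @pytest.mark.parametrize("n_true,expected", [(0, 0), (3, 3), (7, 7)])
    def test_counts_items(self, n_true, expected):
        assert facilitation_score(make_cluster(n_fac=n_true)) == expected

    def test_subset_selection(self):
        c = make_cluster(n_fac=7)
        assert facilitation_score(c, items=FACILITATION_ITEMS[:2]) == 2

    def test_monotone_in_items(self):
        # switching one item on never decreases the score
        for k in range(7):
            assert facilitation_score(make_cluster(n_fac=k + 1)) >= facilitation_score(
                make_cluster(n_fac=k)
            )


class TestRoundTrip:
    def test_tiny_cohort_round_trips(self, tiny_cohort, tmp_path):
        w, c = tmp_path / "w.csv", tmp_path / "c.csv"
        write_cohort(tiny_cohort, w, c)
        back = read_cohort(w, c)
        assert back.women == tiny_cohort.women
        assert back.clusters == tiny_cohort.clusters

    def test_empty_cohort_round_trips(self, tmp_path):
        empty = CohortTable()
        w, c = tmp_path / "w.csv", tmp_path / "c.csv"
        write_cohort(empty, w, c)
        back = read_cohort(w, c)
        assert back.n_women == 0 and back.n_clusters == 0

    def test_generated_cohort_round_trips_bit_identically(self, tmp_path):
        cohort = generate_cohort_structural(GeneratorConfig(seed=3, n_women=898))
        w1, c1 = tmp_path / "w1.csv", tmp_path / "c1.csv"
        w2, c2 = tmp_path / "w2.csv", tmp_path / "c2.csv"
        write_cohort(cohort, w1, c1)
        back = read_cohort(w1, c1)
        assert back.women == cohort.women
        write_cohort(back, w2, c2)
        assert w1.read_bytes() == w2.read_bytes()
        assert c1.read_bytes() == c2.read_bytes()


class TestReaderErrors:
    def _write(self, tiny_cohort, tmp_path):
        w, c = tmp_path / "w.csv", tmp_path / "c.csv"
        write_cohort(tiny_cohort, w, c)
        return w, c

    def test_boolean_tokens_case_insensitive(self, tiny_cohort, tmp_path):
        w, c = self._write(tiny_cohort, tmp_path)
        text = w.read_text().replace("\nw2,", "\nw2,").replace(",1,", ",YES,", 1)
        # replace one boolean cell of w2 (prior_pregnancy_problems column is '0')
        lines = text.splitlines()
        header = lines[0].split(",")
        i = header.index("weight_measured")
        row = lines[2].split(",")
        assert row[0] == "w2"
        row[i] = "True"
        lines[2] = ",".join(row)
        w.write_text("\n".join(lines) + "\n")
        back = read_cohort(w, c)
        assert back.women[1].contents.weight_measured

    def test_malformed_cell_names_row_and_column(self, tiny_cohort, tmp_path):
        w, c = self._write(tiny_cohort, tmp_path)
        w.write_text(w.read_text().replace("w3,hp02,28.0,4", "w3,hp02,28.0,four"))
        with pytest.raises(ParseError, match=r"row 2.*'n_visits'"):
            read_cohort(w, c)

    def test_contents_with_zero_visits_rejected(self, tiny_cohort, tmp_path):
        w, c = self._write(tiny_cohort, tmp_path)
        lines = w.read_text().splitlines()
        header = lines[0].split(",")
        i = header.index("weight_measured")
        row = lines[1].split(",")
        assert row[0] == "w1"  # the non-attender
        row[i] = "1"
        lines[1] = ",".join(row)
        w.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="content items"):
            read_cohort(w, c)

    def test_unresolved_cluster_reference(self, tiny_cohort, tmp_path):
        w, c = self._write(tiny_cohort, tmp_path)
        w.write_text(w.read_text().replace("w4,hp02", "w4,hp99"))
        with pytest.raises(ReferentialIntegrityError, match="hp99"):
            read_cohort(w, c)

    def test_unknown_column_warns_but_reads(self, tiny_cohort, tmp_path, caplog):
        w, c = self._write(tiny_cohort, tmp_path)
        lines = w.read_text().splitlines()
        lines[0] += ",interviewer"
        body = [line + ",x" if line else line for line in lines[1:]]
        w.write_text("\n".join([lines[0]] + body) + "\n")
        with caplog.at_level(logging.WARNING):
            back = read_cohort(w, c)
        assert back.n_women == 4
        assert any("interviewer" in r.message for r in caplog.records)

    def test_tt_threshold_one(self, tiny_cohort, tmp_path):
        w, c = self._write(tiny_cohort, tmp_path)
        # w4 has 9 contents -> tt_adequate False, tt_doses 0; give her one dose
        text = w.read_text()
        lines = text.splitlines()
        header = lines[0].split(",")
        i_tt = header.index("tt_doses")
        i_ad = header.index("tt_adequate") if "tt_adequate" in header else None
        row = lines[4].split(",")
        row[i_tt] = "1"
        lines[4] = ",".join(row)
        w.write_text("\n".join(lines) + "\n")
        strict = read_cohort(w, c, tt_threshold=2)
        lax = read_cohort(w, c, tt_threshold=1)
        assert not strict.women[3].contents.tt_adequate
        assert lax.women[3].contents.tt_adequate


def test_schema_ships_both_tables():
    schema = load_schema()
    assert set(schema) >= {"women", "clusters"}
    assert "n_visits" in schema["women"]
    assert "weekly_hc_supervision" in schema["clusters"]
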