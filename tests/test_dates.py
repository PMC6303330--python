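import numpy as np
import pytest

from paleospd.dates import (
    DateSet,
    RadiocarbonDate,
    VettingRules,
    filter_region,
    read_dates_csv,
    select_taxa,
    vet_dates,
    write_dates_csv,
)
from paleospd.errors import ArgumentError, FormatError


def rd(lab_id, c14=12000.0, sigma=50.0, **kw):
    return RadiocarbonDate(lab_id=lab_id, c14_age=c14, sigma_lab=sigma, **kw)


class TestReadDatesCsv:
    def test_well_formed_table(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "lab_id,c14_age,sigma_lab,taxon,state_province\n"
            "AA-1,12000,40,mammoth,AZ\nAA-2,12100,50,mammoth,NM\nAA-3,11900,60,horse,TX\n"
        )
        ds = read_dates_csv(p)
        assert len(ds) == 3
        assert ds.dates[0].taxon == "mammoth"
        assert ds.dates[2].state_province == "TX"

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("lab_id,c14_age\nAA-1,12000\n")
        with pytest.raises(FormatError, match="sigma_lab"):
            read_dates_csv(p)

    def test_unparseable_numeric_names_row(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("lab_id,c14_age,sigma_lab\nAA-1,12000,40\nAA-2,abc,50\n")
        with pytest.raises(FormatError, match="row 1"):
            read_dates_csv(p)

    def test_round_trip(self, tmp_path):
        ds = DateSet([rd("A", taxon="mammoth", anomalous=True),
                      rd("B", context="geological", latitude=45.0)])
        p = tmp_path / "out.csv"
        write_dates_csv(ds, p)
        again = read_dates_csv(p)
        assert again.dates[0].anomalous is True
        assert again.dates[1].context == "geological"
        assert again.dates[1].latitude == 45.0


class TestVetting:
    def make_toy(self):
        # 10 rows: 2 lab duplicates, 1 anomalous, 1 geological context
        dates = [
            rd("L1"), rd("L2"), rd("L3"), rd("L1"), rd("L2"),
            rd("L4", anomalous=True), rd("L5", context="geological"),
            rd("L6"), rd("L7"), rd("L8"),
        ]
        return DateSet(dates, label="toy")

    def test_constructed_counts(self):
        result = vet_dates(self.make_toy())
        assert len(result.dates) == 6
        assert result.audit["duplicate_lab_id"] == 2
        assert result.audit["anomalous"] == 1
        assert result.audit["context"] == 1

    def test_clean_input_unchanged(self):
        ds = DateSet([rd("A"), rd("B"), rd("C")])
        result = vet_dates(ds)
        assert [d.lab_id for d in result.dates] == ["A", "B", "C"]

    def test_one_date_per_individual(self):
        ds = DateSet([rd("A", individual_id="ind1"), rd("B", individual_id="ind1")])
        result = vet_dates(ds)
        assert len(result.dates) == 1
        assert result.audit["duplicate_individual"] == 1

    def test_kill_sites_removed_for_megafauna_rules(self):
        ds = DateSet([rd("A", kill_site=True), rd("B")])
        result = vet_dates(ds, VettingRules.megafauna())
        assert [d.lab_id for d in result.dates] == ["B"]
        assert result.audit["kill_site"] == 1

    def test_idempotent(self):
        once = vet_dates(self.make_toy()).dates
        twice = vet_dates(once).dates
        assert [d.lab_id for d in twice] == [d.lab_id for d in once]

    def test_audit_counts_sum_to_removals(self):
        ds = DateSet([
            rd("L1"), rd("L1", anomalous=True), rd("L2", anomalous=True),
            rd("L3", context="geological", kill_site=True),
            rd("L4", kill_site=True), rd("L5", individual_id="x"),
            rd("L6", individual_id="x"),
        ])
        result = vet_dates(ds, VettingRules(drop_kill_sites=True))
        removals = sum(v for k, v in result.audit.items()
                       if k not in ("retained", "input"))
        assert removals == len(ds) - len(result.dates)
        # attribution goes to the first matching rule only
        assert result.audit["duplicate_lab_id"] == 1
        assert result.audit["anomalous"] == 1
        assert result.audit["context"] == 1
        assert result.audit["kill_site"] == 1
        assert result.audit["duplicate_individual"] == 1


class TestRegions:
    @pytest.mark.parametrize("state,region,included", [
        ("AZ", "southwest", True),
        ("Ontario", "great_lakes", True),
        ("NY", "great_lakes", True),
        ("TX", "southwest", False),
        ("TX", "great_lakes", False),
    ])
    def test_named_regions(self, state, region, included):
        ds = DateSet([rd("A", state_province=state)])
        assert (len(filter_region(ds, region)) == 1) is included

    def test_contiguous_us_latitude_cut(self):
        ds = DateSet([rd("A", latitude=38.0), rd("B", latitude=55.0), rd("C")])
        kept = filter_region(ds, "contiguous_us")
        assert [d.lab_id for d in kept] == ["A"]

    def test_unknown_region_raises(self):
        with pytest.raises(ArgumentError):
            filter_region(DateSet([rd("A")]), "atlantis")


class TestSelectTaxa:
    def test_strict_threshold(self, identity_curve10):
        dates = [rd(f"M{i}", c14=12000 + i, taxon="mammoth") for i in range(21)]
        dates += [rd(f"H{i}", c14=12000 + i, taxon="horse") for i in range(20)]
        ds = DateSet(dates)
        out = select_taxa(ds, identity_curve10, (15000, 10000), min_dates=20)
        assert set(out) == {"mammoth"}
        assert len(out["mammoth"]) == 21

    def test_window_membership_by_modal_year(self, identity_curve10):
        ds = DateSet([rd("A", c14=16000, taxon="sloth"),
                      rd("B", c14=12000, taxon="sloth"),
                      rd("C", c14=12500, taxon="sloth")])
        out = select_taxa(ds, identity_curve10, (15000, 10000), min_dates=1)
        assert len(out["sloth"]) == 2  # the 16 ka date falls outside the window

    def test_empty_dateset_gives_empty_mapping(self, identity_curve10):
        assert select_taxa(DateSet([]), identity_curve10, (15000, 10000)) == {}
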