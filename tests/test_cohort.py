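"""Cohort builder: parsing, exposure episodes, outcomes, switching, round trip."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pgxtwist import DataError
from pgxtwist.cohort import (
    ascertain_outcome,
    assemble_analysis_table,
    build_analysis_table,
    build_exposure,
    detect_switch,
    parse_records,
    subgroup_prior_disease,
)
from pgxtwist.panel import load_drug_class_map, load_outcome_code_map


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def _minimal_bundle(tmp_path, prescription_rows="", diagnosis_rows=""):
    paths = {
        "prescriptions": _write(
            tmp_path, "prescriptions.tsv",
            "patient_id\tissue_date\tcode_system\tcode\n" + prescription_rows,
        ),
        "diagnoses": _write(
            tmp_path, "diagnoses.tsv",
            "patient_id\tevent_date\tvocabulary\tcode\n" + diagnosis_rows,
        ),
        "genotypes": _write(
            tmp_path, "genotypes.tsv",
            "patient_id\trsid\tdosage\nP1\trs877087\t1\n",
        ),
        "covariates": _write(
            tmp_path, "covariates.tsv",
            "patient_id\tsex\tyob\nP1\t1\t1950\n",
        ),
    }
    return paths


class TestParseRecords:
    def test_empty_file_with_header_gives_empty_stream(self, tmp_path, caplog):
        recs = parse_records(_minimal_bundle(tmp_path))
        assert len(recs["prescriptions"]) == 0

    def test_out_of_window_prescription_rejected(self, tmp_path):
        rows = (
            "P1\t2010-01-01\tbnf\t0206020A0\n"
            "P1\t2020-01-01\tbnf\t0206020A0\n"  # after the GP record window
        )
        # 1 of 2 rows malformed exceeds the 1% tolerance -> abort
        with pytest.raises(DataError, match="malformed"):
            parse_records(_minimal_bundle(tmp_path, prescription_rows=rows))

    def test_out_of_window_row_dropped_below_tolerance(self, tmp_path):
        good = "".join(
            f"P1\t2010-01-{d:02d}\tbnf\t0206020A0\n" for d in range(1, 29)
        ) * 4
        rows = good + "P1\t2020-01-01\tbnf\t0206020A0\n"
        recs = parse_records(
            _minimal_bundle(tmp_path, prescription_rows=rows),
            max_malformed_frac=0.05,
        )
        assert (recs["prescriptions"]["issue_date"] <= pd.Timestamp("2017-08-31")).all()

    def test_missing_column_is_schema_error(self, tmp_path):
        paths = _minimal_bundle(tmp_path)
        _write(tmp_path, "prescriptions.tsv", "patient_id\tissue_date\tcode\n")
        with pytest.raises(DataError, match="code_system"):
            parse_records(paths)

    def test_unknown_drug_code_maps_to_other(self, tmp_path):
        recs = parse_records(
            _minimal_bundle(tmp_path, prescription_rows="P1\t2010-01-01\tbnf\tXXXX\n")
        )
        assert recs["prescriptions"]["drug_class"].tolist() == ["other"]


def _rx_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "issue_date", "code_system", "code"])
    df["issue_date"] = pd.to_datetime(df["issue_date"])
    from pgxtwist.panel import classify_drug

    df["drug_class"] = classify_drug(df[["code_system", "code"]], load_drug_class_map())
    return df


class TestBuildExposure:
    def test_first_and_last_dates(self):
        rx = _rx_frame(
            [
                ("P1", "2010-01-01", "bnf", "0206020A0"),
                ("P1", "2010-02-01", "bnf", "0206020A0"),
                ("P1", "2010-03-01", "bnf", "0206020A0"),
            ]
        )
        ep = build_exposure(rx)
        assert ep.loc["P1", "first_rx_date"] == pd.Timestamp("2010-01-01")
        assert ep.loc["P1", "last_rx_date"] == pd.Timestamp("2010-03-01")
        assert ep.loc["P1", "amlodipine_only"]
        assert not ep.loc["P1", "co_antihypertensive"]

    def test_co_antihypertensive_flag(self):
        rx = _rx_frame(
            [
                ("P1", "2010-01-01", "bnf", "0206020A0"),
                ("P1", "2010-02-01", "bnf", "0205051R0"),  # ACE inhibitor between
                ("P1", "2010-03-01", "bnf", "0206020A0"),
            ]
        )
        ep = build_exposure(rx)
        assert ep.loc["P1", "co_antihypertensive"]

    def test_single_script_patient_excluded(self):
        rx = _rx_frame([("P1", "2010-01-01", "bnf", "0206020A0")])
        assert len(build_exposure(rx)) == 0

    def test_non_amlodipine_dccb_clears_flag(self):
        rx = _rx_frame(
            [
                ("P1", "2010-01-01", "bnf", "0206020A0"),
                ("P1", "2010-02-01", "bnf", "0206020R0"),  # nifedipine
            ]
        )
        assert not build_exposure(rx).loc["P1", "amlodipine_only"]


class TestAscertainOutcome:
    def _diag(self, rows):
        df = pd.DataFrame(rows, columns=["patient_id", "event_date", "vocabulary", "code"])
        df["event_date"] = pd.to_datetime(df["event_date"])
        from pgxtwist.panel import classify_diagnosis

        df["outcome_label"] = classify_diagnosis(df, load_outcome_code_map())
        return df

    def test_prior_diagnosis_sets_prior_flag(self):
        origins = pd.Series(pd.Timestamp("2010-01-31"), index=["P1"])
        diag = self._diag([("P1", "2010-01-01", "icd10", "I50.0")])
        out = ascertain_outcome(origins, diag, "hf")
        assert out.loc["P1", "prior_flag"] == 1
        assert out.loc["P1", "event_flag"] == 0

    def test_incident_event_time(self):
        origins = pd.Series(pd.Timestamp("2010-01-01"), index=["P1"])
        diag = self._diag([("P1", "2012-01-01", "icd10", "I50.0")])
        out = ascertain_outcome(
            origins, diag, "hf",
            deductions=pd.Series(pd.Timestamp("2015-01-01"), index=["P1"]),
        )
        assert out.loc["P1", "event_flag"] == 1
        assert out.loc["P1", "time_years"] == pytest.approx(2.0, abs=0.01)

    def test_event_after_censor_is_censored(self):
        origins = pd.Series(pd.Timestamp("2010-01-01"), index=["P1"])
        diag = self._diag([("P1", "2016-01-01", "icd10", "I50.0")])
        out = ascertain_outcome(
            origins, diag, "hf",
            deductions=pd.Series(pd.Timestamp("2015-01-01"), index=["P1"]),
        )
        assert out.loc["P1", "event_flag"] == 0
        assert out.loc["P1", "time_years"] == pytest.approx(5.0, abs=0.01)

    def test_unknown_outcome_label(self):
        origins = pd.Series(pd.Timestamp("2010-01-01"), index=["P1"])
        with pytest.raises(DataError, match="unknown outcome"):
            ascertain_outcome(origins, self._diag([]), "gout")


class TestDetectSwitch:
    def _setup(self, rows):
        rx = _rx_frame(rows)
        ep = build_exposure(rx)
        ep["censor_date"] = pd.Timestamp("2016-05-31")
        return rx, ep

    def test_switch_after_cessation(self):
        rx, ep = self._setup(
            [
                ("P1", "2010-01-01", "bnf", "0206020A0"),
                ("P1", "2010-06-01", "bnf", "0206020A0"),
                ("P1", "2010-09-01", "bnf", "0205051R0"),  # ACE, no later dCCB
                ("P1", "2010-11-01", "bnf", "0205051R0"),
            ]
        )
        sw = detect_switch(rx, ep)
        assert sw.loc["P1", "switch_flag"] == 1
        expected = (pd.Timestamp("2010-09-01") - pd.Timestamp("2010-01-01")).days / 365.25
        assert sw.loc["P1", "switch_time"] == pytest.approx(expected)

    def test_co_therapy_is_not_a_switch(self):
        rx, ep = self._setup(
            [
                ("P1", "2010-01-01", "bnf", "0206020A0"),
                ("P1", "2010-06-01", "bnf", "0205051R0"),  # ACE
                ("P1", "2010-07-01", "bnf", "0206020A0"),  # dCCB continues
            ]
        )
        sw = detect_switch(rx, ep)
        assert sw.loc["P1", "switch_flag"] == 0
        # censored switch time runs to the episode censor date
        assert sw.loc["P1", "switch_time"] > 6.0


class TestSubgroupPriorDisease:
    def test_empty_when_no_prior_disease(self, bundle):
        truth, out = bundle
        table = build_analysis_table(out, outcomes=["hf", "chd"])
        table = table.assign(chd_prior=0, hf_prior=0)
        assert len(subgroup_prior_disease(table)) == 0

    def test_composite_is_earliest_component(self):
        rows = pd.DataFrame(
            {
                "chd_prior": [1, 1],
                "hf_prior": [0, 0],
                "chd_event": [1, 0],
                "chd_time": [3.0, 6.0],
                "hf_event": [1, 0],
                "hf_time": [2.0, 6.0],
            }
        )
        sub = subgroup_prior_disease(rows)
        assert sub["composite_event"].tolist() == [1, 0]
        assert sub["composite_time"].tolist() == [2.0, 6.0]

    def test_subset_fraction_matches_generator(self, bundle):
        truth, out = bundle
        table = build_analysis_table(out, outcomes=["hf", "chd"])
        treated = table[table["treated"] == 1]
        sub = subgroup_prior_disease(treated)
        target = truth.config.p_prior_heart
        assert len(sub) / len(treated) == pytest.approx(target, abs=0.03)


class TestRoundTrip:
    def test_truth_reproduced_exactly(self, bundle):
        truth, out = bundle
        table = build_analysis_table(out, outcomes=["hf", "chd"]).set_index("patient_id")
        t = truth.table.set_index("patient_id")
        assert (table["treated"] == t["treated"]).all()
        treated = t[t["treated"] == 1].index
        assert (table.loc[treated, "hf_event"] == t.loc[treated, "event"]).all()
        err_days = (
            (table.loc[treated, "hf_time"] - t.loc[treated, "observed_time"]).abs()
            * 365.25
        )
        assert err_days.max() <= 0.51
        untreated = t[t["treated"] == 0].index
        assert (table.loc[untreated, "hf_event"] == t.loc[untreated, "event"]).all()

    def test_switch_detection_recovers_truth(self, bundle):
        truth, out = bundle
        table = build_analysis_table(out, outcomes=["hf"]).set_index("patient_id")
        t = truth.table.set_index("patient_id")
        treated = t[t["treated"] == 1].index
        agree = (table.loc[treated, "switch_flag"] == t.loc[treated, "switch"]).mean()
        assert agree >= 0.99

    def test_genotype_group_sizes_match_truth(self, bundle):
        truth, out = bundle
        table = build_analysis_table(out, outcomes=["hf"])
        t = truth.table
        for g in (0, 1, 2):
            assert (table["g_rs877087"] == g).sum() == (t["g_rs877087"] == g).sum()

    def test_episode_duration_near_target(self, bundle):
        truth, out = bundle
        recs = parse_records({"bundle_dir": out})
        ded = recs["covariates"].set_index("patient_id")["deduction_date"]
        ep = build_exposure(recs["prescriptions"], deductions=ded)
        years = (ep["last_rx_date"] - ep["first_rx_date"]).dt.days / 365.25
        assert years.mean() == pytest.approx(5.9, rel=0.10)


class TestAssemble:
    def test_missing_genotype_keeps_patient_for_other_variants(self, bundle):
        truth, out = bundle
        recs = parse_records({"bundle_dir": out})
        geno = recs["genotypes"]
        victim = geno["patient_id"].iloc[0]
        recs["genotypes"] = geno[geno["patient_id"] != victim]
        table = assemble_analysis_table(recs, outcomes=["hf"]).set_index("patient_id")
        assert np.isnan(table.loc[victim, "g_rs877087"])
        assert victim in table.index  # still present for non-genetic analyses

    def test_exclusion_list_sets_unrelated_flag(self, bundle):
        truth, out = bundle
        recs = parse_records({"bundle_dir": out})
        excluded = truth.table["patient_id"].iloc[:25].tolist()
        table = assemble_analysis_table(recs, outcomes=["hf"], exclusions=excluded)
        assert (table["unrelated_flag"] == 0).sum() == 25

    def test_duplicate_patient_id_is_data_error(self, bundle):
        truth, out = bundle
        recs = parse_records({"bundle_dir": out})
        cov = recs["covariates"]
        recs["covariates"] = pd.concat([cov, cov.iloc[[0]]], ignore_index=True)
        with pytest.raises(DataError, match="duplicate"):
            assemble_analysis_table(recs, outcomes=["hf"])
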