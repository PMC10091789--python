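"""Cohort construction from raw prescription / diagnosis / genotype tables.

Turns dated, coded clinical record streams into the per-patient analysis
table used by the association scan and the TWIST estimators: dCCB exposure
episodes with censoring, incident-outcome flags and follow-up times,
prior-disease flags, treatment-switch events and sensitivity subgroups.

Input schemas (tab-delimited, UTF-8, ISO dates):

- prescriptions.tsv: patient_id, issue_date, code_system, code
- diagnoses.tsv:     patient_id, event_date, vocabulary, code
- genotypes.tsv:     patient_id, rsid, dosage
- covariates.tsv:    patient_id, sex, yob, [entry_date, deduction_date,] pc1..pc10
- exclusions.txt:    one patient_id per line (relatedness exclusion list)
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import panel as panel_mod
from .config import GP_CENSOR_DATE, GP_WINDOW_END, OUTCOME_HORIZON, STUDY_START
from .errors import DataError
from .panel import DCCB_CLASSES, OUTCOME_LABELS, VariantDef

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

_SCHEMAS = {
    "prescriptions": ["patient_id", "issue_date", "code_system", "code"],
    "diagnoses": ["patient_id", "event_date", "vocabulary", "code"],
    "genotypes": ["patient_id", "rsid", "dosage"],
    "covariates": ["patient_id", "sex", "yob"],
}
_DATE_COLS = {"prescriptions": "issue_date", "diagnoses": "event_date"}


def _read_table(path: Path, kind: str, max_malformed_frac: float) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    n_raw = len(df)
    if n_raw == 0:
        log.warning("%s: empty %s table", path, kind)
        return df
    bad = pd.Series(False, index=df.index)
    date_col = _DATE_COLS.get(kind)
    if date_col is not None:
        dates = pd.to_datetime(df[date_col], format="%Y-%m-%d", errors="coerce")
        bad |= dates.isna()
        df[date_col] = dates
    if kind == "prescriptions":
        # GP prescribing records are only valid inside the study window
        in_window = (df["issue_date"] >= pd.Timestamp(STUDY_START)) & (
            df["issue_date"] <= pd.Timestamp(GP_WINDOW_END)
        )
        bad |= ~in_window.fillna(False)
    if kind == "genotypes":
        dosage = pd.to_numeric(df["dosage"], errors="coerce")
        bad |= ~dosage.isin([0, 1, 2]) & dosage.notna() | dosage.isna()
        df["dosage"] = dosage
    bad |= df["patient_id"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("%s: dropped %d/%d malformed rows", path, n_bad, n_raw)
        if n_bad / n_raw > max_malformed_frac:
            raise DataError(
                f"{path}: {n_bad}/{n_raw} malformed rows exceeds the "
                f"{max_malformed_frac:.0%} tolerance"
            )
    return df[~bad].reset_index(drop=True)


def parse_records(
    paths: Mapping[str, str | Path],
    *,
    class_map: pd.DataFrame | None = None,
    outcome_map: pd.DataFrame | None = None,
    max_malformed_frac: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Read and validate the raw record tables.

    `paths` maps table kind (prescriptions/diagnoses/genotypes/covariates) to
    file path; a directory may be given under the key 'bundle_dir' instead,
    in which case the conventional file names are used.  Prescriptions gain a
    derived drug_class column and diagnoses an outcome_label column.
    """
    paths = dict(paths)
    if "bundle_dir" in paths:
        d = Path(paths.pop("bundle_dir"))
        for kind, name in [
            ("prescriptions", "prescriptions.tsv"),
            ("diagnoses", "diagnoses.tsv"),
            ("genotypes", "genotypes.tsv"),
            ("covariates", "covariates.tsv"),
        ]:
            paths.setdefault(kind, d / name)
    out: dict[str, pd.DataFrame] = {}
    for kind in ("prescriptions", "diagnoses", "genotypes", "covariates"):
        p = Path(paths[kind])
        if not p.exists():
            raise DataError(f"missing input file: {p}")
        out[kind] = _read_table(p, kind, max_malformed_frac)

    cmap = class_map if class_map is not None else panel_mod.load_drug_class_map()
    omap = outcome_map if outcome_map is not None else panel_mod.load_outcome_code_map()
    rx = out["prescriptions"]
    rx["drug_class"] = (
        panel_mod.classify_drug(rx[["code_system", "code"]], cmap)
        if len(rx)
        else pd.Series(dtype=object)
    )
    n_other = int((rx["drug_class"] == "other").sum()) if len(rx) else 0
    if n_other:
        log.info("prescriptions: %d rows mapped to class 'other'", n_other)
    dg = out["diagnoses"]
    dg["outcome_label"] = (
        panel_mod.classify_diagnosis(dg, omap) if len(dg) else pd.Series(dtype=object)
    )

    cov = out["covariates"]
    for c in ("entry_date", "deduction_date"):
        if c in cov.columns:
            cov[c] = pd.to_datetime(cov[c], format="%Y-%m-%d", errors="coerce")
    cov["yob"] = pd.to_numeric(cov["yob"], errors="coerce")
    cov["sex"] = pd.to_numeric(cov["sex"], errors="coerce")
    if cov["patient_id"].duplicated().any():
        dup = cov.loc[cov["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DataError(f"duplicate patient_id in covariates: {dup}")
    return out


def build_exposure(
    prescriptions: pd.DataFrame,
    *,
    deductions: pd.Series | None = None,
    gp_censor: str = GP_CENSOR_DATE,
    min_prescriptions: int = 2,
) -> pd.DataFrame:
    """Per-patient dCCB exposure episodes.

    Patients qualify with at least `min_prescriptions` dCCB scripts.  The
    censoring date is the GP deduction date where available, else the
    prescribing-data horizon.  Flags: co_antihypertensive if any non-dCCB
    antihypertensive class was issued inside [first_rx, last_rx];
    amlodipine_only if every dCCB script maps to amlodipine.
    """
    rx = prescriptions
    is_dccb = rx["drug_class"].isin(DCCB_CLASSES)
    dccb = rx[is_dccb]
    grp = dccb.groupby("patient_id")["issue_date"]
    ep = pd.DataFrame(
        {
            "first_rx_date": grp.min(),
            "last_rx_date": grp.max(),
            "n_prescriptions": grp.size(),
        }
    )
    ep = ep[ep["n_prescriptions"] >= min_prescriptions]

    years = np.maximum(
        (ep["last_rx_date"] - ep["first_rx_date"]).dt.days / DAYS_PER_YEAR,
        1.0 / DAYS_PER_YEAR,
    )
    ep["prescriptions_per_year"] = ep["n_prescriptions"] / years

    amlo = dccb.groupby("patient_id")["drug_class"].agg(
        lambda s: (s == "dccb_amlodipine").all()
    )
    ep["amlodipine_only"] = amlo.reindex(ep.index).fillna(False)

    other = rx[~is_dccb & (rx["drug_class"] != "other")]
    other = other.merge(
        ep[["first_rx_date", "last_rx_date"]], left_on="patient_id", right_index=True
    )
    inside = other[
        (other["issue_date"] >= other["first_rx_date"])
        & (other["issue_date"] <= other["last_rx_date"])
    ]
    ep["co_antihypertensive"] = ep.index.isin(inside["patient_id"].unique())

    censor = pd.Series(pd.Timestamp(gp_censor), index=ep.index)
    if deductions is not None:
        ded = deductions.reindex(ep.index)
        censor = pd.concat([censor, ded], axis=1).min(axis=1)
    ep["censor_date"] = censor
    bad = ep["last_rx_date"] > ep["censor_date"]
    if bad.any():
        log.warning("%d episodes have scripts after the censor date", int(bad.sum()))
    ep.index.name = "patient_id"
    return ep


def ascertain_outcome(
    origins: pd.Series,
    diagnoses: pd.DataFrame,
    outcome_label: str,
    *,
    deductions: pd.Series | None = None,
    horizon: str = OUTCOME_HORIZON,
) -> pd.DataFrame:
    """Incident-outcome flags and follow-up times for one outcome.

    `origins` maps patient_id -> time origin (first dCCB prescription for
    treated patients, study entry for untreated comparators).  A diagnosis on
    or before the origin sets prior_flag (the patient is excluded from the
    incident analysis of that outcome); the first diagnosis strictly after
    the origin and on/before the patient's censor date is the incident event.
    Time is measured in years from the origin to the event or censor date.
    """
    if outcome_label not in OUTCOME_LABELS:
        raise DataError(
            f"unknown outcome {outcome_label!r}; expected one of {OUTCOME_LABELS}"
        )
    censor = pd.Series(pd.Timestamp(horizon), index=origins.index)
    if deductions is not None:
        censor = pd.concat(
            [censor, deductions.reindex(origins.index)], axis=1
        ).min(axis=1)

    d = diagnoses[diagnoses["outcome_label"] == outcome_label]
    d = d.merge(origins.rename("origin"), left_on="patient_id", right_index=True)
    prior_ids = d.loc[d["event_date"] <= d["origin"], "patient_id"].unique()
    after = d[d["event_date"] > d["origin"]]
    first_event = after.groupby("patient_id")["event_date"].min()

    out = pd.DataFrame(index=origins.index)
    out["prior_flag"] = out.index.isin(prior_ids).astype(int)
    ev_date = first_event.reindex(origins.index)
    in_window = ev_date.notna() & (ev_date <= censor)
    out["event_flag"] = in_window.astype(int)
    end = censor.where(~in_window, ev_date)
    out["time_years"] = (end - origins).dt.days / DAYS_PER_YEAR
    if (out["time_years"] <= 0).any():
        n = int((out["time_years"] <= 0).sum())
        log.warning("%s: clipping %d non-positive follow-up times to 1 day", outcome_label, n)
        out["time_years"] = out["time_years"].clip(lower=1.0 / DAYS_PER_YEAR)
    out.index.name = "patient_id"
    return out


def detect_switch(
    prescriptions: pd.DataFrame,
    episodes: pd.DataFrame,
    gap_days: int = 90,
) -> pd.DataFrame:
    """Treatment-switch detection for each exposure episode.

    A switch is the first issue of a non-dCCB antihypertensive after the
    first dCCB prescription such that no further dCCB script occurs within
    `gap_days` after that issue (co-therapy alongside continuing dCCB scripts
    is not a switch).  switch_time is years from the first dCCB script; for
    non-switchers the time runs to the episode censor date.
    """
    rx = prescriptions[prescriptions["patient_id"].isin(episodes.index)]
    is_dccb = rx["drug_class"].isin(DCCB_CLASSES)
    alt = rx[~is_dccb & (rx["drug_class"] != "other")].merge(
        episodes[["first_rx_date"]], left_on="patient_id", right_index=True
    )
    alt = alt[alt["issue_date"] > alt["first_rx_date"]].sort_values(
        ["patient_id", "issue_date"]
    )

    dccb_dates = rx[is_dccb].groupby("patient_id")["issue_date"].apply(
        lambda s: np.sort(s.to_numpy())
    )
    flags = pd.Series(0, index=episodes.index, dtype=int)
    times = pd.Series(np.nan, index=episodes.index, dtype=float)
    gap = np.timedelta64(gap_days, "D")
    for pid, group in alt.groupby("patient_id", sort=False):
        dd = dccb_dates.get(pid)
        first_rx = episodes.at[pid, "first_rx_date"]
        for issue in group["issue_date"]:
            i = np.searchsorted(dd, np.datetime64(issue), side="right")
            next_dccb = dd[i] if i < len(dd) else None
            if next_dccb is None or next_dccb - np.datetime64(issue) > gap:
                flags[pid] = 1
                times[pid] = (issue - first_rx).days / DAYS_PER_YEAR
                break
    censored = flags == 0
    times[censored] = (
        episodes.loc[censored, "censor_date"] - episodes.loc[censored, "first_rx_date"]
    ).dt.days / DAYS_PER_YEAR
    times = times.clip(lower=1.0 / DAYS_PER_YEAR)
    out = pd.DataFrame({"switch_flag": flags, "switch_time": times})
    out.index.name = "patient_id"
    return out


def subgroup_prior_disease(
    rows: pd.DataFrame, labels: Sequence[str] = ("chd", "hf")
) -> pd.DataFrame:
    """Patients with any of `labels` diagnosed before their time origin.

    Adds a composite endpoint over the same labels: composite_event is 1 if
    any component incident event occurred, composite_time the earliest
    component event time (censoring time when no event).
    """
    prior_cols = [f"{lab}_prior" for lab in labels]
    missing = [c for c in prior_cols if c not in rows.columns]
    if missing:
        raise DataError(f"analysis table lacks prior-disease columns {missing}")
    sub = rows[rows[prior_cols].any(axis=1)].copy()
    ev_cols = [f"{lab}_event" for lab in labels]
    tm_cols = [f"{lab}_time" for lab in labels]
    if sub.empty:
        sub["composite_event"] = pd.Series(dtype=int)
        sub["composite_time"] = pd.Series(dtype=float)
        return sub
    any_event = sub[ev_cols].max(axis=1)
    # earliest component event time; when no component has an event all the
    # component times are censoring times (equal by construction) -> min is fine
    masked = sub[tm_cols].where(sub[ev_cols].to_numpy() == 1)
    sub["composite_event"] = any_event.astype(int)
    sub["composite_time"] = masked.min(axis=1).fillna(sub[tm_cols].min(axis=1))
    return sub


def assemble_analysis_table(
    records: dict[str, pd.DataFrame],
    panel: Sequence[VariantDef] | None = None,
    outcomes: Sequence[str] = ("hf", "chd", "ckd", "stroke", "oedema"),
    *,
    exclusions: Iterable[str] | None = None,
    gap_days: int = 90,
    horizon: str = OUTCOME_HORIZON,
    gp_censor: str = GP_CENSOR_DATE,
    min_prescriptions: int = 2,
) -> pd.DataFrame:
    """One analysis-ready row per patient (treated and untreated).

    Treated rows carry exposure-episode fields and follow-up from the first
    dCCB prescription; untreated comparators (never prescribed a dCCB) have
    follow-up from study entry.  Genotype dosages are wide columns g_<rsid>;
    a missing genotype keeps the patient in the table (the scan drops them
    per variant).  `exclusions` sets unrelated_flag = 0 for listed patients.
    """
    variants = list(panel) if panel is not None else panel_mod.default_panel()
    cov = records["covariates"].set_index("patient_id")
    if cov.index.duplicated().any():
        raise DataError("duplicate patient_id in covariates")
    deductions = cov["deduction_date"] if "deduction_date" in cov.columns else None

    episodes = build_exposure(
        records["prescriptions"],
        deductions=deductions,
        gp_censor=gp_censor,
        min_prescriptions=min_prescriptions,
    )

    table = pd.DataFrame(index=cov.index)
    table["treated"] = table.index.isin(episodes.index).astype(int)
    if "entry_date" in cov.columns:
        entry = cov["entry_date"]
    else:
        entry = pd.Series(pd.Timestamp(STUDY_START), index=cov.index)
    origins = episodes["first_rx_date"].reindex(cov.index)
    origins = origins.where(table["treated"] == 1, entry)
    if origins.isna().any():
        raise DataError("missing time origin (entry_date) for untreated patients")

    dob = pd.to_datetime(
        {"year": cov["yob"].astype(int), "month": 7, "day": 1}, errors="coerce"
    )
    table["age_first_rx"] = (origins - dob).dt.days / DAYS_PER_YEAR
    table["sex"] = cov["sex"]
    for k in range(1, 11):
        col = f"pc{k}"
        if col in cov.columns:
            table[col] = pd.to_numeric(cov[col], errors="coerce")

    geno = records["genotypes"]
    if len(geno):
        wide = geno.pivot_table(
            index="patient_id", columns="rsid", values="dosage", aggfunc="first"
        )
        for v in variants:
            if v.rsid in wide.columns:
                table[f"g_{v.rsid}"] = wide[v.rsid].reindex(table.index)

    for lab in outcomes:
        asc = ascertain_outcome(
            origins, records["diagnoses"], lab, deductions=deductions, horizon=horizon
        )
        table[f"{lab}_prior"] = asc["prior_flag"]
        table[f"{lab}_event"] = asc["event_flag"]
        table[f"{lab}_time"] = asc["time_years"]

    sw = detect_switch(records["prescriptions"], episodes, gap_days=gap_days)
    table["switch_flag"] = sw["switch_flag"].reindex(table.index)
    table["switch_time"] = sw["switch_time"].reindex(table.index)
    for c in ("co_antihypertensive", "amlodipine_only"):
        table[c] = episodes[c].reindex(table.index)
    table["prescriptions_per_year"] = episodes["prescriptions_per_year"].reindex(
        table.index
    )

    excluded = set(exclusions) if exclusions is not None else set()
    table["unrelated_flag"] = (~table.index.isin(excluded)).astype(int)
    return table.reset_index()


def build_analysis_table(
    bundle_dir: str | Path,
    panel: Sequence[VariantDef] | None = None,
    outcomes: Sequence[str] = ("hf", "chd", "ckd", "stroke", "oedema"),
    **kwargs,
) -> pd.DataFrame:
    """Convenience: parse a study bundle directory and assemble the table."""
    exclusions = None
    excl_path = Path(bundle_dir) / "exclusions.txt"
    if excl_path.exists():
        exclusions = [
            line.strip() for line in excl_path.read_text().splitlines() if line.strip()
        ]
    records = parse_records({"bundle_dir": bundle_dir})
    return assemble_analysis_table(
        records, panel=panel, outcomes=outcomes, exclusions=exclusions, **kwargs
    )
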