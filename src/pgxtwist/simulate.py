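"""Synthetic study generator.

Emulates the statistical structure of a primary-care pharmacogenetic cohort:
genotypes in Hardy-Weinberg proportions, dCCB treatment assigned independently
of genotype (optionally violated for assumption-check testing), prescribing
episodes with realistic script rates and durations, and time-to-event outcomes
drawn from a constant additive-hazards model with a genotype-by-treatment
interaction (the true GMTE).  `write_study` serialises a file bundle in the
exact schemas consumed by `pgxtwist.cohort`, so the whole downstream pipeline
is testable without any external data.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .errors import ConfigError

DAYS_PER_YEAR = 365.25

_OUTCOME_EVENT_CODE = {
    "hf": "I50.0",
    "chd": "I21.9",
    "ckd": "N18.3",
    "stroke": "I63.9",
    "oedema": "R60.0",
}
_PRIOR_CHD_CODE = "I21.9"


@dataclass
class SimTruth:
    """Ground truth of one simulated study: per-patient table + parameters."""

    config: SimConfig
    table: pd.DataFrame

    @property
    def treated(self) -> pd.DataFrame:
        return self.table[self.table["treated"] == 1]

    @property
    def untreated(self) -> pd.DataFrame:
        return self.table[self.table["treated"] == 0]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def gen_genotypes(
    n: int, maf: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Minor-allele dosages (0/1/2) in Hardy-Weinberg proportions.

    Two independent Bernoulli(maf) allele draws per individual, i.e. genotype
    frequencies ((1-q)^2, 2q(1-q), q^2) for minor-allele frequency q.
    """
    if not 0.0 <= maf <= 1.0:
        raise ConfigError(f"maf must be in [0, 1], got {maf}")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 0)
    return rng.binomial(2, maf, size=int(n)).astype(np.int8)


def _carrier(dosage: np.ndarray, coding: str) -> np.ndarray:
    if coding == "dominant":
        return (dosage > 0).astype(float)
    if coding == "additive":
        return dosage.astype(float)
    raise ConfigError(f"unsupported truth coding {coding!r}")


def gen_population(config: SimConfig) -> SimTruth:
    """Draw genotypes, treatment, demographics and calendar anchors.

    Treatment is Bernoulli(p_treated) independent of genotype by default.
    Violation modes: ``treat_geno_or`` > 1 makes the treatment odds depend on
    the causal-variant dosage (centred so the marginal rate is preserved);
    ``confounding`` > 0 adds a latent frailty that raises both the odds of
    treatment and, later, the outcome hazard.
    """
    n = config.n_patients
    rng = _rng(config.rng_seed, 1)

    table = pd.DataFrame({"patient_id": [f"P{i:07d}" for i in range(n)]})
    for rsid, maf in config.variant_mafs.items():
        table[f"g_{rsid}"] = gen_genotypes(n, maf, rng)
    dosage = table[f"g_{config.causal_variant}"].to_numpy()
    table["carrier"] = _carrier(dosage, config.coding)

    # latent frailty (confounding mode): raises treatment odds and hazard
    frailty = (rng.random(n) < 0.3).astype(float) if config.confounding > 0 else np.zeros(n)
    table["frailty"] = frailty

    p = np.clip(config.p_treated, 1e-12, 1 - 1e-12)
    logit = np.full(n, np.log(p / (1 - p)))
    if config.treat_geno_or != 1.0:
        q = config.variant_mafs[config.causal_variant]
        logit = logit + np.log(config.treat_geno_or) * (dosage - 2 * q)
    if config.confounding > 0:
        logit = logit + 1.0 * (frailty - 0.3)
    p_i = 1.0 / (1.0 + np.exp(-logit))
    if config.p_treated >= 1.0:
        table["treated"] = 1
    elif config.p_treated <= 0.0:
        table["treated"] = 0
    else:
        table["treated"] = (rng.random(n) < p_i).astype(int)

    table["sex"] = (rng.random(n) < config.p_female).astype(int)  # 1 = female
    lo, hi = config.first_rx_age_range
    a = (lo - config.first_rx_age_mean) / config.first_rx_age_sd
    b = (hi - config.first_rx_age_mean) / config.first_rx_age_sd
    table["age_first_rx"] = stats.truncnorm.rvs(
        a, b, loc=config.first_rx_age_mean, scale=config.first_rx_age_sd,
        size=n, random_state=rng,
    )
    for k in range(1, 11):
        table[f"pc{k}"] = rng.standard_normal(n)

    # calendar anchors: origin of follow-up is first prescription (treated)
    # or study entry (untreated); chosen so origin + horizon stays inside the
    # GP window (1992-01-01 .. 2003-05-31 leaves 13y before 2016-05-31).
    window_start = np.datetime64("1992-01-01")
    window_days = int(
        (np.datetime64("2016-05-31") - window_start)
        / np.timedelta64(1, "D")
        - round(config.admin_censor_years * DAYS_PER_YEAR)
    )
    if window_days <= 0:
        raise ConfigError(
            "admin_censor_years too long for the GP calendar window"
        )
    origin = window_start + rng.integers(0, window_days, n).astype("timedelta64[D]")
    treated = table["treated"].to_numpy() == 1
    entry_back = rng.integers(180, 1096, n).astype("timedelta64[D]")
    table["first_rx_date"] = np.where(treated, origin, np.datetime64("NaT"))
    table["entry_date"] = np.where(treated, origin - entry_back, origin)

    table["scripts_rate"] = np.clip(
        rng.normal(config.scripts_per_year_mean, config.scripts_per_year_sd, n),
        1.0, 25.0,
    )
    table["co_med"] = (rng.random(n) < config.p_co_med).astype(int)
    table["prior_chd"] = np.where(
        treated, (rng.random(n) < config.p_prior_heart).astype(int), 0
    )
    return SimTruth(config=config, table=table)


def gen_event_times(truth: SimTruth, config: SimConfig | None = None) -> SimTruth:
    """Draw event, dropout and prescribing-cessation times.

    Event times are Exponential with rate h_i = h0 + bT*T + bG*G + bGT*G*T
    (plus the frailty increment in confounding mode); observed time is the
    minimum of the event time, dropout (GP deduction) and the administrative
    horizon.  Negative cell hazards are a configuration error, never silently
    truncated.
    """
    config = config or truth.config
    t = truth.table
    n = len(t)
    rng = _rng(config.rng_seed, 2)

    g = t["carrier"].to_numpy()
    trt = t["treated"].to_numpy().astype(float)
    hazard = (
        config.baseline_hazard
        + config.beta_treat * trt
        + config.beta_geno * g
        + config.beta_interact * g * trt
        + config.confounding * t["frailty"].to_numpy()
    )
    if (hazard < 0).any():
        bad = int(np.argmin(hazard))
        raise ConfigError(
            f"negative hazard {hazard[bad]:.3g}/y for genotype={g[bad]:g}, "
            f"treated={trt[bad]:g}"
        )

    def _exp_times(rate: np.ndarray | float) -> np.ndarray:
        rate = np.broadcast_to(np.asarray(rate, dtype=float), (n,))
        u = rng.random(n)
        with np.errstate(divide="ignore"):
            return np.where(rate > 0, -np.log1p(-u) / np.where(rate > 0, rate, 1.0), np.inf)

    event_time = _exp_times(hazard)
    dropout = _exp_times(config.dropout_hazard)
    censor = np.minimum(dropout, config.admin_censor_years)
    observed = np.minimum(event_time, censor)

    t = t.copy()
    t["hazard"] = hazard
    t["event_time_true"] = event_time
    t["dropout_time"] = dropout
    t["censor_time"] = censor
    t["observed_time"] = observed
    t["event"] = (event_time <= censor).astype(int)

    # prescribing episode: cessation competing with censoring; a cessation may
    # be a switch to another antihypertensive class (first alternative script
    # 30 days after the last dCCB one)
    rx_stop = _exp_times(config.rx_stop_hazard)
    rx_end = np.minimum(rx_stop, censor)
    stopped = rx_stop < censor
    switch_draw = rng.random(n) < config.switch_prob
    switch_time = rx_stop + 30.0 / DAYS_PER_YEAR
    switched = stopped & switch_draw & (switch_time < censor) & (t["treated"] == 1)
    t["rx_duration"] = np.where(t["treated"] == 1, rx_end, np.nan)
    t["switch"] = switched.astype(int)
    t["switch_time"] = np.where(switched, switch_time, np.nan)
    return SimTruth(config=config, table=t)


def simulate_cohort(config: SimConfig) -> SimTruth:
    """gen_population followed by gen_event_times."""
    return gen_event_times(gen_population(config), config)


def truth_analysis_table(truth: SimTruth) -> pd.DataFrame:
    """Analysis-ready table straight from the simulation truth.

    Bypasses file serialisation and cohort reconstruction: useful for
    estimator studies where only the statistical structure matters.  Columns
    mirror `cohort.assemble_analysis_table` for the simulated outcome.
    """
    cfg = truth.config
    t = truth.table
    out = pd.DataFrame(
        {
            "patient_id": t["patient_id"],
            "treated": t["treated"],
            "age_first_rx": t["age_first_rx"],
            "sex": t["sex"],
        }
    )
    for k in range(1, 11):
        out[f"pc{k}"] = t[f"pc{k}"]
    for rsid in cfg.variant_mafs:
        out[f"g_{rsid}"] = t[f"g_{rsid}"].astype(float)
    out[f"{cfg.outcome}_prior"] = 0
    out[f"{cfg.outcome}_event"] = t["event"]
    out[f"{cfg.outcome}_time"] = t["observed_time"]
    if "switch" in t.columns:
        out["switch_flag"] = t["switch"].fillna(0).astype(int)
        out["switch_time"] = t["switch_time"].fillna(t["censor_time"])
    out["unrelated_flag"] = 1
    return out


def _days(years: np.ndarray) -> np.ndarray:
    """Round year offsets to whole days, flooring at 1 day."""
    return np.maximum(1, np.rint(np.asarray(years) * DAYS_PER_YEAR).astype(int))


def write_study(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Serialise the study as the TSV bundle consumed by `pgxtwist.cohort`.

    Emits prescriptions.tsv, diagnoses.tsv, genotypes.tsv, covariates.tsv,
    truth.tsv and config.yaml.  Dates are day-resolution; a round trip
    through the cohort builder reproduces treated flags, event flags and
    follow-up times to the day.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    t = truth.table
    if "observed_time" not in t.columns:
        raise ConfigError("write_study needs event times; run gen_event_times first")
    rng = _rng(cfg.rng_seed, 3)

    treated = t[t["treated"] == 1]
    origin_all = np.where(
        t["treated"].to_numpy() == 1,
        t["first_rx_date"].to_numpy("datetime64[D]"),
        t["entry_date"].to_numpy("datetime64[D]"),
    ).astype("datetime64[D]")

    # --- prescriptions -----------------------------------------------------
    pid_col, date_col, sys_col, code_col = [], [], [], []
    amlo_share = 31_357 / 38_211  # amlodipine vs other dCCB user ratio
    is_amlo = rng.random(len(treated)) < amlo_share
    for k, (_, row) in enumerate(treated.iterrows()):
        first = np.datetime64(row["first_rx_date"], "D")
        dur_days = max(int(round(row["rx_duration"] * DAYS_PER_YEAR)), 2)
        n_scripts = max(2, int(round(row["scripts_rate"] * row["rx_duration"])))
        offs = np.unique(np.rint(np.linspace(0, dur_days, n_scripts)).astype(int))
        dccb_code = "0206020A0" if is_amlo[k] else "0206020R0"
        dates = [first + np.timedelta64(int(o), "D") for o in offs]
        codes = [dccb_code] * len(dates)
        if row["co_med"] and len(offs) >= 3:
            # co-prescription placed mid-episode, flanked by dCCB scripts so
            # it is co-therapy rather than a switch; an extra dCCB script 40
            # days later guarantees the switch detector is not fooled
            mid = int(offs[len(offs) // 2])
            dates += [first + np.timedelta64(mid + 1, "D"),
                      first + np.timedelta64(mid + 41, "D")]
            codes += ["0205051R0", dccb_code]
        if row["switch"]:
            sw = first + np.timedelta64(
                int(round(row["switch_time"] * DAYS_PER_YEAR)), "D"
            )
            cend = first + np.timedelta64(
                int(round(row["censor_time"] * DAYS_PER_YEAR)), "D"
            )
            for j in range(3):
                d = sw + np.timedelta64(60 * j, "D")
                if j == 0 or d <= cend:
                    dates.append(d)
                    codes.append("0205051R0")
        pid_col.extend([row["patient_id"]] * len(dates))
        date_col.extend(dates)
        sys_col.extend(["bnf"] * len(dates))
        code_col.extend(codes)
    prescriptions = pd.DataFrame(
        {
            "patient_id": pid_col,
            "issue_date": np.array(date_col, dtype="datetime64[D]").astype(str),
            "code_system": sys_col,
            "code": code_col,
        }
    ).sort_values(["patient_id", "issue_date"], kind="stable")

    # --- diagnoses ---------------------------------------------------------
    ev = t["event"].to_numpy() == 1
    ev_dates = origin_all[ev] + _days(t.loc[ev, "observed_time"].to_numpy()).astype(
        "timedelta64[D]"
    )
    diag = pd.DataFrame(
        {
            "patient_id": t.loc[ev, "patient_id"].to_numpy(),
            "event_date": ev_dates.astype(str),
            "vocabulary": "icd10",
            "code": _OUTCOME_EVENT_CODE[cfg.outcome],
        }
    )
    prior = t["prior_chd"].to_numpy() == 1
    if prior.any():
        back = rng.integers(180, 1826, int(prior.sum())).astype("timedelta64[D]")
        diag = pd.concat(
            [
                diag,
                pd.DataFrame(
                    {
                        "patient_id": t.loc[prior, "patient_id"].to_numpy(),
                        "event_date": (origin_all[prior] - back).astype(str),
                        "vocabulary": "icd10",
                        "code": _PRIOR_CHD_CODE,
                    }
                ),
            ],
            ignore_index=True,
        )
    diag = diag.sort_values(["patient_id", "event_date"], kind="stable")

    # --- genotypes (long) --------------------------------------------------
    rsids = list(cfg.variant_mafs)
    genotypes = pd.DataFrame(
        {
            "patient_id": np.repeat(t["patient_id"].to_numpy(), len(rsids)),
            "rsid": np.tile(np.array(rsids, dtype=object), len(t)),
            "dosage": np.column_stack(
                [t[f"g_{r}"].to_numpy() for r in rsids]
            ).ravel(),
        }
    )

    # --- covariates --------------------------------------------------------
    ded_dates = origin_all + _days(t["censor_time"].to_numpy()).astype("timedelta64[D]")
    origin_year = origin_all.astype("datetime64[Y]").astype(int) + 1970
    covars = pd.DataFrame(
        {
            "patient_id": t["patient_id"],
            "sex": t["sex"],
            "yob": origin_year - np.rint(t["age_first_rx"].to_numpy()).astype(int),
            "entry_date": t["entry_date"].astype("datetime64[s]").dt.strftime("%Y-%m-%d"),
            "deduction_date": ded_dates.astype(str),
        }
    )
    for k in range(1, 11):
        covars[f"pc{k}"] = t[f"pc{k}"].round(6)

    paths = {
        "prescriptions": out / "prescriptions.tsv",
        "diagnoses": out / "diagnoses.tsv",
        "genotypes": out / "genotypes.tsv",
        "covariates": out / "covariates.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    prescriptions.to_csv(paths["prescriptions"], sep="\t", index=False)
    diag.to_csv(paths["diagnoses"], sep="\t", index=False)
    genotypes.to_csv(paths["genotypes"], sep="\t", index=False)
    covars.to_csv(paths["covariates"], sep="\t", index=False, float_format="%.6f")
    t_out = t.copy()
    for c in ("first_rx_date", "entry_date"):
        t_out[c] = pd.to_datetime(t_out[c]).dt.strftime("%Y-%m-%d")
    t_out.to_csv(paths["truth"], sep="\t", index=False, float_format="%.9g")
    paths["config"].write_text(cfg.to_yaml())
    return paths
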