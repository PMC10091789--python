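"""Per-variant, per-outcome Cox proportional-hazards association scan.

Among treated patients, each variant is tested against each outcome with a
Cox model adjusted for age at first prescription, sex and ten genetic
principal components (Efron tie handling, as appropriate for day-resolution
GP dates with many ties).  Genotype contrasts follow the chosen inheritance
model, per-genotype event counts are tabulated in the N / n / % layout of
the study's results tables, and Benjamini-Hochberg adjustment is applied per
outcome across the variant panel.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.base import BaseEstimator

from . import panel as panel_mod
from .errors import DataError, FitError
from .panel import VariantDef

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_first_rx", "sex") + tuple(f"pc{k}" for k in range(1, 11))
SCAN_OUTCOMES = ("hf", "chd", "ckd", "stroke", "oedema", "switch")


def code_genotype(
    dosage: pd.Series, model: str, variant: VariantDef | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Contrast design columns for one variant.

    genotypic -> two indicators (het, hom-minor) vs the common-homozygote
    reference; dominant -> one carrier indicator; additive -> the 0/1/2
    dosage.  Returns (design, contrast labels).  Monomorphic variants raise
    FitError (the scan skips them with a warning).
    """
    d = dosage.astype(float)
    labels = (
        variant.genotype_labels if variant is not None else ("ref", "het", "hom")
    )
    if d.nunique(dropna=True) < 2:
        raise FitError("monomorphic variant")
    if model == "genotypic":
        design = pd.DataFrame(
            {"het": (d == 1).astype(float), "hom": (d == 2).astype(float)},
            index=dosage.index,
        )
        return design, [f"{labels[1]} vs {labels[0]}", f"{labels[2]} vs {labels[0]}"]
    if model == "dominant":
        return (
            pd.DataFrame({"carrier": (d > 0).astype(float)}, index=dosage.index),
            [f"{labels[1]}/{labels[2]} vs {labels[0]}"],
        )
    if model == "additive":
        return pd.DataFrame({"dosage": d}, index=dosage.index), ["per allele"]
    raise DataError(f"unknown inheritance model {model!r}")


@dataclass
class CoxResult:
    """One genotype contrast from one Cox fit."""

    rsid: str
    outcome: str
    contrast: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_at_risk: int
    n_events: int
    covariate_set: str = "age+sex+pc1-10"
    converged: bool = True


def fit_cox(
    rows: pd.DataFrame,
    design: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    *,
    rsid: str = "",
    outcome: str = "",
    contrasts: Sequence[str] | None = None,
    extra_covariates: Sequence[str] = (),
    robust: bool = False,
) -> list[CoxResult]:
    """Cox partial-likelihood fit (Efron ties) with Wald CI and p per contrast.

    Treatment length is handled by the time axis itself: follow-up runs from
    the first prescription.  Non-convergence is flagged on the result rather
    than silently dropped; complete separation raises FitError naming the
    variable.
    """
    covs = [c for c in list(covariates) + list(extra_covariates) if c in rows.columns]
    df = pd.concat(
        [design, rows[covs + [duration_col, event_col]]], axis=1
    ).dropna()
    design_cols = list(design.columns)
    for col in design_cols:
        if df.groupby(df[event_col])[col].nunique().min() == 0 or df[col].nunique() < 2:
            raise FitError(f"separation or constant column for variable {col!r}")
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                robust=robust,
                show_progress=False,
            )
    except ConvergenceError as exc:
        raise FitError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    results = []
    labels = list(contrasts) if contrasts is not None else design_cols
    for col, label in zip(design_cols, labels):
        row = summary.loc[col]
        results.append(
            CoxResult(
                rsid=rsid,
                outcome=outcome,
                contrast=label,
                hr=float(np.exp(row["coef"])),
                ci_low=float(np.exp(row["coef lower 95%"])),
                ci_high=float(np.exp(row["coef upper 95%"])),
                p=float(row["p"]),
                n_at_risk=int(len(df)),
                n_events=int(df[event_col].sum()),
                covariate_set="+".join(covs),
                converged=converged,
            )
        )
    return results


def percent_cell(n: int, N: int, dp: int = 1) -> float:
    """Percent of a genotype group with a diagnosis, rounded as printed.

    Switching tables print 2 decimal places, other outcomes 1.
    """
    if N <= 0:
        raise DataError("group size N must be positive")
    return round(100.0 * n / N, dp)


def count_events(
    rows: pd.DataFrame,
    variant: VariantDef,
    outcome: str,
    *,
    dp: int | None = None,
) -> pd.DataFrame:
    """Per-genotype (N, n, %) tabulation for one variant and outcome."""
    dp = dp if dp is not None else (2 if outcome == "switch" else 1)
    event_col, prior_col = _outcome_cols(outcome)[1], f"{outcome}_prior"
    df = rows.dropna(subset=[f"g_{variant.rsid}"])
    if prior_col in df.columns:
        df = df[df[prior_col] == 0]
    out = []
    for dosage, label in zip((0, 1, 2), variant.genotype_labels):
        grp = df[df[f"g_{variant.rsid}"] == dosage]
        if len(grp) == 0:
            continue
        n_ev = int(grp[event_col].sum())
        out.append(
            {
                "genotype": label,
                "N": len(grp),
                "n": n_ev,
                "percent": percent_cell(n_ev, len(grp), dp),
            }
        )
    return pd.DataFrame(out)


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    `m` overrides the family size (>= len(p_values)), for families where some
    members were untestable.  Output is monotone and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    k = len(p)
    if k == 0:
        return p.copy()
    m = k if m is None else int(m)
    if m < k:
        raise DataError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(k)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _outcome_cols(outcome: str) -> tuple[str, str]:
    if outcome == "switch":
        return "switch_time", "switch_flag"
    return f"{outcome}_time", f"{outcome}_event"


class CoxAssociationScan(BaseEstimator):
    """Scan a variant panel against outcomes among treated patients.

    Parameters mirror the study's sensitivity configurations: adjust for
    co-prescribed antihypertensives, restrict to amlodipine-only (or
    other-dCCB-only) users, or keep unrelated participants only.  Untreated
    individuals never enter the scan: it estimates on-treatment associations.

    After `fit`, `results_` holds one row per genotype contrast with hazard
    ratio, Wald CI, p, per-outcome BH-adjusted p, and group counts.
    """

    def __init__(
        self,
        panel: Sequence[VariantDef] | None = None,
        outcomes: Sequence[str] = SCAN_OUTCOMES,
        model: str | None = None,
        co_med_adjust: bool = False,
        drug_subset: str = "all",
        unrelated_only: bool = False,
        robust: bool = False,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ):
        self.panel = panel
        self.outcomes = outcomes
        self.model = model
        self.co_med_adjust = co_med_adjust
        self.drug_subset = drug_subset
        self.unrelated_only = unrelated_only
        self.robust = robust
        self.covariates = covariates

    def fit(self, table: pd.DataFrame, y=None):
        panel = list(self.panel) if self.panel is not None else panel_mod.default_panel()
        if self.drug_subset not in ("all", "amlodipine", "other"):
            raise DataError(f"unknown drug_subset {self.drug_subset!r}")
        df = table[table["treated"] == 1]
        if self.drug_subset == "amlodipine":
            df = df[df["amlodipine_only"] == True]  # noqa: E712 (nullable bool)
        elif self.drug_subset == "other":
            df = df[df["amlodipine_only"] == False]  # noqa: E712
        if self.unrelated_only:
            df = df[df["unrelated_flag"] == 1]
        extra = ("co_antihypertensive",) if self.co_med_adjust else ()
        if self.co_med_adjust:
            df = df.assign(co_antihypertensive=df["co_antihypertensive"].astype(float))

        rows: list[dict] = []
        for outcome in self.outcomes:
            dur_col, ev_col = _outcome_cols(outcome)
            sub = df
            prior_col = f"{outcome}_prior"
            if prior_col in sub.columns:
                sub = sub[sub[prior_col] == 0]
            for variant in panel:
                gcol = f"g_{variant.rsid}"
                if gcol not in sub.columns:
                    continue
                vdf = sub.dropna(subset=[gcol, dur_col, ev_col])
                model = self.model or variant.inheritance_model
                try:
                    design, contrasts = code_genotype(vdf[gcol], model, variant)
                    fits = fit_cox(
                        vdf,
                        design,
                        dur_col,
                        ev_col,
                        self.covariates,
                        rsid=variant.rsid,
                        outcome=outcome,
                        contrasts=contrasts,
                        extra_covariates=extra,
                        robust=self.robust,
                    )
                except FitError as exc:
                    log.warning("%s/%s skipped: %s", variant.rsid, outcome, exc)
                    continue
                counts = count_events(vdf.assign(**{prior_col: 0}), variant, outcome)
                for res in fits:
                    rows.append(
                        {
                            "outcome": res.outcome,
                            "gene": variant.gene,
                            "rsid": res.rsid,
                            "contrast": res.contrast,
                            "hr": res.hr,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "p": res.p,
                            "n_at_risk": res.n_at_risk,
                            "n_events": res.n_events,
                            "covariate_set": res.covariate_set,
                            "converged": res.converged,
                            "counts": counts,
                        }
                    )
        results = pd.DataFrame(rows)
        if len(results):
            results["fdr_p"] = np.nan
            for outcome in results["outcome"].unique():
                mask = results["outcome"] == outcome
                results.loc[mask, "fdr_p"] = bh_adjust(results.loc[mask, "p"])
        self.results_ = results
        self.n_variants_ = len(panel)
        return self

    def results_table(self) -> pd.DataFrame:
        """`results_` without the nested counts frames (serialisable)."""
        return self.results_.drop(columns=["counts"], errors="ignore")


def scan_all(
    table: pd.DataFrame,
    panel: Sequence[VariantDef] | None = None,
    outcomes: Sequence[str] = SCAN_OUTCOMES,
    **options,
) -> pd.DataFrame:
    """Functional wrapper over `CoxAssociationScan`."""
    scan = CoxAssociationScan(panel=panel, outcomes=outcomes, **options)
    return scan.fit(table).results_table()
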