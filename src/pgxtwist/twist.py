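"""TWIST: triangulation of genetically moderated treatment effect estimates.

The genetically moderated treatment effect (GMTE) is the extra outcome
hazard, in events per person-year on the additive scale, that carriers of a
pharmacogenetic variant experience *while on treatment* compared with
noncarriers.  Five estimators with different identifying assumptions are
computed from constant-coefficient additive-hazards fits and triangulated:

- GMTE1: genotype coefficient among treated patients (assumes no direct
  genotype effect on the outcome);
- GMTE0: genotype coefficient among never-treated patients (a negative
  control: should be null if the variant acts only through treatment);
- RGMTE = GMTE1 - GMTE0: robust to a direct genotype effect;
- MR: full-sample genotype coefficient rescaled by the treated proportion
  (the Mendelian-randomization estimator; needs the exclusion restriction);
- CAT: difference of the treated-vs-untreated hazard contrast between
  carrier strata (as-treated difference-in-differences; needs no unmeasured
  treatment-outcome confounding).

Mutually consistent estimates (Cochran's Q) are combined by inverse-variance
weighting into a single, more efficient GMTE.  Because the estimators share
subjects they are positively correlated; each estimate therefore carries a
per-subject influence decomposition, from which the full covariance matrix
of the candidate set is assembled and used in a generalised (GLS) weighting
and heterogeneity test.  Estimates supplied without influence information
fall back to the classical independence-weighted forms.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .additive import AalenFit, fit_additive_hazards
from .errors import DataError, FitError
from .scan import DEFAULT_COVARIATES, _outcome_cols

Z95 = stats.norm.ppf(0.975)


@dataclass
class EstimateWithSE:
    """A per-year hazard-difference estimate with normal-theory inference.

    `influence` (optional) holds the per-subject influence contributions of
    the estimate, indexed like the analysis table; estimates built by this
    module carry it so that combinations can account for the covariance
    induced by shared subjects.
    """

    label: str
    estimate: float
    se: float
    influence: "pd.Series | None" = field(default=None, repr=False, compare=False)
    p: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise FitError(f"{self.label}: standard error must be positive")
        z = self.estimate / self.se
        self.p = float(2 * stats.norm.sf(abs(z)))
        self.ci_low = float(self.estimate - Z95 * self.se)
        self.ci_high = float(self.estimate + Z95 * self.se)

    @property
    def variance(self) -> float:
        return self.se**2


@dataclass
class CombineResult:
    """Inverse-variance combination with heterogeneity diagnostics."""

    q_table: pd.DataFrame
    combined: EstimateWithSE
    selected: tuple[str, ...]
    note: str = ""


@dataclass
class GMTESuite:
    """All five estimates, heterogeneity tests and the selected combination."""

    gmte1: EstimateWithSE
    gmte0: EstimateWithSE
    rgmte: EstimateWithSE
    mr: EstimateWithSE
    cat: EstimateWithSE
    combination: CombineResult
    assumptions: pd.DataFrame
    fits: dict[str, AalenFit] = field(default_factory=dict, repr=False)

    @property
    def combined(self) -> EstimateWithSE:
        return self.combination.combined

    def estimates(self) -> pd.DataFrame:
        rows = [self.gmte1, self.gmte0, self.rgmte, self.mr, self.cat,
                self.combination.combined]
        return pd.DataFrame(
            {
                "label": [e.label for e in rows],
                "estimate": [e.estimate for e in rows],
                "se": [e.se for e in rows],
                "p": [e.p for e in rows],
                "ci_low": [e.ci_low for e in rows],
                "ci_high": [e.ci_high for e in rows],
            }
        )

    def report(self) -> str:
        lines = ["TWIST genetically moderated treatment effect", "=" * 44, ""]
        lines.append(self.estimates().to_string(index=False))
        lines.append("")
        lines.append(f"Selected combination: {' + '.join(self.combination.selected)}")
        if self.combination.note:
            lines.append(f"Note: {self.combination.note}")
        lines.append("")
        lines.append("Heterogeneity (Cochran Q):")
        lines.append(self.combination.q_table.to_string(index=False))
        lines.append("")
        lines.append("Assumption checks:")
        lines.append(self.assumptions.to_string(index=False))
        g0 = "null" if self.gmte0.p > 0.05 else "NON-NULL"
        lines.append("")
        lines.append(
            f"GMTE0 (genotype effect off treatment) is {g0} (p = {self.gmte0.p:.3g}); "
            "MR/GMTE1-based claims "
            + ("are supported." if g0 == "null" else "should be treated as suspect.")
        )
        return "\n".join(lines)


def _carrier_column(table: pd.DataFrame, variant: str, coding: str) -> pd.Series:
    g = table[f"g_{variant}"]
    if coding == "dominant":
        return (g > 0).astype(float).where(g.notna())
    if coding == "additive":
        return g.astype(float)
    raise DataError(f"TWIST coding must be 'dominant' or 'additive', got {coding!r}")


def _usable_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> list[str]:
    return [
        c for c in covariates if c in df.columns and df[c].nunique(dropna=True) > 1
    ]


def gmte_components(
    table: pd.DataFrame,
    variant: str,
    outcome: str,
    coding: str = "dominant",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[EstimateWithSE, EstimateWithSE, EstimateWithSE, dict[str, AalenFit]]:
    """GMTE1 (treated), GMTE0 (untreated) and their difference RGMTE.

    The two subsets are independent samples, so var(RGMTE) = var1 + var0 and
    RGMTE = GMTE1 - GMTE0 holds exactly.
    """
    dur_col, ev_col = _outcome_cols(outcome)
    df = table.assign(carrier=_carrier_column(table, variant, coding))
    prior_col = f"{outcome}_prior"
    if prior_col in df.columns:
        df = df[df[prior_col] != 1]
    fits = {}
    ests = {}
    for label, treated in (("GMTE1", 1), ("GMTE0", 0)):
        sub = df[df["treated"] == treated]
        if sub.empty:
            raise FitError(f"{label}: no {'' if treated else 'un'}treated rows")
        fit = fit_additive_hazards(
            sub,
            ["carrier"],
            dur_col,
            ev_col,
            covariates=_usable_covariates(sub, covariates),
            subset="treated" if treated else "untreated",
        )
        est, se = fit.estimate("carrier")
        fits[label] = fit
        ests[label] = EstimateWithSE(label, est, se, influence=fit.influence["carrier"])
    rgmte = EstimateWithSE(
        "RGMTE",
        ests["GMTE1"].estimate - ests["GMTE0"].estimate,
        float(np.sqrt(ests["GMTE1"].variance + ests["GMTE0"].variance)),
        influence=pd.concat(
            [fits["GMTE1"].influence["carrier"], -fits["GMTE0"].influence["carrier"]]
        ),
    )
    return ests["GMTE1"], ests["GMTE0"], rgmte, fits


def mr_estimate(
    table: pd.DataFrame,
    variant: str,
    outcome: str,
    coding: str = "dominant",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[EstimateWithSE, AalenFit]:
    """Mendelian-randomization estimator: full-sample genotype coefficient
    divided by the treated proportion (SE scaled identically).

    Valid when the variant affects the outcome only through its interaction
    with treatment (exclusion restriction).
    """
    dur_col, ev_col = _outcome_cols(outcome)
    df = table.assign(carrier=_carrier_column(table, variant, coding))
    prior_col = f"{outcome}_prior"
    if prior_col in df.columns:
        df = df[df[prior_col] != 1]
    p_treated = float(df["treated"].mean())
    if p_treated <= 0:
        raise FitError("MR estimator undefined: no treated patients")
    fit = fit_additive_hazards(
        df, ["carrier"], dur_col, ev_col,
        covariates=_usable_covariates(df, covariates), subset="all",
    )
    est, se = fit.estimate("carrier")
    return (
        EstimateWithSE(
            "MR", est / p_treated, se / p_treated,
            influence=fit.influence["carrier"] / p_treated,
        ),
        fit,
    )


def cat_estimate(
    table: pd.DataFrame,
    variant: str,
    outcome: str,
    coding: str = "dominant",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[EstimateWithSE, dict[str, AalenFit]]:
    """Corrected-as-treated estimator: the treated-vs-untreated hazard
    difference among carriers minus the same contrast among noncarriers
    (difference of adjusted treatment coefficients across carrier strata).

    Requires all four genotype x treatment cells non-empty and no unmeasured
    treatment-outcome confounding.
    """
    dur_col, ev_col = _outcome_cols(outcome)
    df = table.assign(carrier=_carrier_column(table, variant, coding)).dropna(
        subset=["carrier"]
    )
    prior_col = f"{outcome}_prior"
    if prior_col in df.columns:
        df = df[df[prior_col] != 1]
    carrier = df["carrier"] > 0
    cells = df.groupby([carrier, df["treated"]]).size()
    if len(cells) < 4 or (cells == 0).any():
        raise FitError("CAT estimator needs all four genotype x treatment cells")
    fits = {}
    coefs = {}
    for label, stratum in (("carriers", True), ("noncarriers", False)):
        sub = df[carrier == stratum].assign(treated=df["treated"].astype(float))
        fit = fit_additive_hazards(
            sub, ["treated"], dur_col, ev_col,
            covariates=_usable_covariates(sub, covariates), subset=label,
        )
        fits[label] = fit
        coefs[label] = fit.estimate("treated")
    est = coefs["carriers"][0] - coefs["noncarriers"][0]
    se = float(np.sqrt(coefs["carriers"][1] ** 2 + coefs["noncarriers"][1] ** 2))
    influence = pd.concat(
        [fits["carriers"].influence["treated"], -fits["noncarriers"].influence["treated"]]
    )
    return EstimateWithSE("CAT", est, se, influence=influence), fits


def assumption_checks(
    table: pd.DataFrame,
    variant: str,
    coding: str = "dominant",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pharmacogenetic core assumptions, testable from the data.

    1. Genotype does not predict treatment (chi-square on the genotype x
       treated contingency table).
    2. Genotype is not associated with any measured covariate (per-covariate
       least-squares regression of the covariate on carrier status).
    Constant covariates are skipped with a note.
    """
    g = table[f"g_{variant}"].dropna()
    treated = table.loc[g.index, "treated"]
    rows = []
    contingency = pd.crosstab(g, treated)
    if contingency.shape[0] > 1 and contingency.shape[1] > 1:
        chi2, p, dof, _ = stats.chi2_contingency(contingency)
        rows.append(
            {
                "check": "genotype_independent_of_treatment",
                "statistic": chi2,
                "p": p,
                "passed": p > alpha,
                "note": f"chi-square, dof={dof}",
            }
        )
    carrier = _carrier_column(table, variant, coding).loc[g.index]
    for cov in covariates:
        if cov not in table.columns:
            continue
        y = pd.to_numeric(table.loc[g.index, cov], errors="coerce")
        ok = y.notna() & carrier.notna()
        if y[ok].nunique() < 2:
            rows.append(
                {
                    "check": f"genotype_vs_{cov}",
                    "statistic": np.nan,
                    "p": np.nan,
                    "passed": True,
                    "note": "skipped: constant covariate",
                }
            )
            continue
        res = stats.linregress(carrier[ok], y[ok])
        rows.append(
            {
                "check": f"genotype_vs_{cov}",
                "statistic": res.slope / res.stderr if res.stderr > 0 else np.nan,
                "p": res.pvalue,
                "passed": res.pvalue > alpha,
                "note": "covariate ~ carrier regression",
            }
        )
    return pd.DataFrame(rows)


def _covariance_matrix(estimates: Sequence[EstimateWithSE]) -> np.ndarray:
    """Covariance of a set of estimates from their influence decompositions.

    Off-diagonals are inner products of per-subject influences over shared
    subjects; a pair lacking influence information is treated as independent.
    Diagonals are the estimates' own variances (identical to the influence
    sum of squares when influence is available).
    """
    k = len(estimates)
    cov = np.zeros((k, k))
    for i, a in enumerate(estimates):
        cov[i, i] = a.variance
        for j in range(i + 1, k):
            b = estimates[j]
            if a.influence is not None and b.influence is not None:
                common = a.influence.index.intersection(b.influence.index)
                if len(common):
                    cov[i, j] = cov[j, i] = float(
                        (a.influence.loc[common] * b.influence.loc[common]).sum()
                    )
    return cov


def _gls_mean(est: np.ndarray, cov: np.ndarray) -> tuple[float, float, np.ndarray]:
    ones = np.ones(len(est))
    try:
        ci = np.linalg.solve(cov, np.column_stack([ones, est]))
    except np.linalg.LinAlgError:
        pinv = np.linalg.pinv(cov)
        ci = pinv @ np.column_stack([ones, est])
    denom = float(ones @ ci[:, 0])
    mean = float(ones @ ci[:, 1]) / denom
    var = 1.0 / denom
    weights = ci[:, 0] / denom
    return mean, var, weights


def cochran_q(estimates: Sequence[EstimateWithSE]) -> tuple[float, int, float]:
    """Heterogeneity statistic for a set of (possibly correlated) estimates.

    With influence-based covariances this is the generalised Q
    r' Sigma^{-1} r at the GLS mean; for independent (influence-free)
    estimates it reduces to classical Cochran's Q.
    """
    est = np.array([e.estimate for e in estimates])
    dof = len(estimates) - 1
    if dof < 1:
        return 0.0, 0, 1.0
    cov = _covariance_matrix(estimates)
    mean, _, _ = _gls_mean(est, cov)
    r = est - mean
    try:
        q = float(r @ np.linalg.solve(cov, r))
    except np.linalg.LinAlgError:
        q = float(r @ np.linalg.pinv(cov) @ r)
    return q, dof, float(stats.chi2.sf(q, dof))


def combine_ivw(
    estimates: Sequence[EstimateWithSE], alpha: float = 0.05
) -> CombineResult:
    """Inverse-variance-weighted combination gated on Cochran's Q.

    If the set is homogeneous at level `alpha` the IVW mean (variance
    1/sum of weights) is returned; a single estimate passes through with a
    note; a heterogeneous set is not combined (the first, most robust,
    estimate is reported alone and the note records the refusal).
    """
    if len(estimates) == 0:
        raise FitError("combine_ivw needs at least one estimate")
    rows = []
    for subset in itertools.combinations(estimates, 2):
        q, dof, p = cochran_q(subset)
        rows.append(
            {
                "set": " + ".join(e.label for e in subset),
                "Q": q,
                "dof": dof,
                "p": p,
            }
        )
    if len(estimates) > 2:
        q, dof, p = cochran_q(estimates)
        rows.append(
            {"set": " + ".join(e.label for e in estimates), "Q": q, "dof": dof, "p": p}
        )
    q_table = pd.DataFrame(rows)

    if len(estimates) == 1:
        e = estimates[0]
        combined = EstimateWithSE(f"combined ({e.label})", e.estimate, e.se)
        return CombineResult(
            q_table, combined, (e.label,), note="single estimate: passthrough"
        )

    q, dof, p = cochran_q(estimates)
    if p <= alpha:
        e = estimates[0]
        combined = EstimateWithSE(f"combined ({e.label})", e.estimate, e.se)
        return CombineResult(
            q_table,
            combined,
            (e.label,),
            note=(
                f"heterogeneous set (Q={q:.2f}, p={p:.3g} <= {alpha}); "
                "components reported separately, no combination"
            ),
        )
    est = np.array([e.estimate for e in estimates])
    cov = _covariance_matrix(estimates)
    mean, var, _ = _gls_mean(est, cov)
    labels = tuple(e.label for e in estimates)
    combined = EstimateWithSE(
        "combined (" + " + ".join(labels) + ")", mean, float(np.sqrt(var))
    )
    return CombineResult(q_table, combined, labels)


def _select_combination(
    rgmte: EstimateWithSE,
    mr: EstimateWithSE,
    cat: EstimateWithSE,
    alpha: float = 0.05,
) -> CombineResult:
    """Prefer the largest mutually consistent set among {RGMTE, MR, CAT},
    robust estimators first; fall back to RGMTE alone."""
    candidates = [
        (rgmte, mr, cat),
        (rgmte, mr),
        (rgmte, cat),
        (mr, cat),
        (rgmte,),
    ]
    for cand in candidates:
        q, dof, p = cochran_q(cand) if len(cand) > 1 else (0.0, 0, 1.0)
        if p > alpha:
            return combine_ivw(list(cand), alpha=alpha)
    return combine_ivw([rgmte], alpha=alpha)


def run_twist(
    table: pd.DataFrame,
    variant: str,
    outcome: str,
    coding: str = "dominant",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> GMTESuite:
    """Full TWIST analysis of one variant against one outcome."""
    gmte1, gmte0, rgmte, fits = gmte_components(
        table, variant, outcome, coding, covariates
    )
    mr, mr_fit = mr_estimate(table, variant, outcome, coding, covariates)
    cat, cat_fits = cat_estimate(table, variant, outcome, coding, covariates)
    fits["MR"] = mr_fit
    fits.update({f"CAT_{k}": v for k, v in cat_fits.items()})
    combination = _select_combination(rgmte, mr, cat, alpha=alpha)
    if gmte0.p <= 0.05:
        extra = (
            "GMTE0 is non-null: direct genotype effect suspected; treat "
            "MR- and GMTE1-based estimates as suspect"
        )
        combination.note = (combination.note + "; " if combination.note else "") + extra
    assumptions = assumption_checks(table, variant, coding, covariates, alpha)
    return GMTESuite(
        gmte1=gmte1,
        gmte0=gmte0,
        rgmte=rgmte,
        mr=mr,
        cat=cat,
        combination=combination,
        assumptions=assumptions,
        fits=fits,
    )


class TwistGMTE(BaseEstimator):
    """Estimator interface over `run_twist`.

    >>> tw = TwistGMTE(variant="rs877087", outcome="hf").fit(analysis_table)
    >>> tw.combined_.estimate  # per-year excess hazard in carriers  # doctest: +SKIP

    Fitted attributes: `gmte1_`, `gmte0_`, `rgmte_`, `mr_`, `cat_`
    (EstimateWithSE), `combined_`, `suite_` (full GMTESuite),
    `assumptions_` (DataFrame).
    """

    def __init__(
        self,
        variant: str = "rs877087",
        outcome: str = "hf",
        coding: str = "dominant",
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        alpha: float = 0.05,
    ):
        self.variant = variant
        self.outcome = outcome
        self.coding = coding
        self.covariates = covariates
        self.alpha = alpha

    def fit(self, table: pd.DataFrame, y=None):
        suite = run_twist(
            table, self.variant, self.outcome, self.coding, self.covariates, self.alpha
        )
        self.suite_ = suite
        self.gmte1_ = suite.gmte1
        self.gmte0_ = suite.gmte0
        self.rgmte_ = suite.rgmte
        self.mr_ = suite.mr
        self.cat_ = suite.cat
        self.combined_ = suite.combined
        self.assumptions_ = suite.assumptions
        return self

    def report(self) -> str:
        return self.suite_.report()
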