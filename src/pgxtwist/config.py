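"""Simulation and pipeline run configuration.

`SimConfig` parameterises the synthetic-cohort generator: a constant additive
hazards data-generating process

    h_i = h0 + bT * treated_i + bG * G_i + bGT * G_i * treated_i   [events / person-year]

with genotypes in Hardy-Weinberg proportions, treatment assigned independently
of genotype (unless a violation mode is switched on), and prescribing episodes
whose moments match a large UK primary-care hypertension cohort (age at first
prescription ~N(61.3, 7.7) truncated to [40, 79.3], ~9.2 scripts/year, mean
5.9 years between first and last dCCB script).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError

#: study calendar anchors (configurable per run)
STUDY_START = "1990-01-01"
GP_CENSOR_DATE = "2016-05-31"  # primary-care prescribing horizon
GP_WINDOW_END = "2017-08-31"  # last valid GP record date
OUTCOME_HORIZON = "2020-09-30"  # hospital-record follow-up horizon


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    Hazard-rate parameters are per person-year on the additive scale;
    ``beta_interact`` (bGT) is the true genetically moderated treatment
    effect the downstream estimators try to recover.
    """

    n_patients: int = 20_000
    p_treated: float = 0.145
    variant_mafs: dict[str, float] = field(
        default_factory=lambda: {"rs877087": 0.46}
    )
    causal_variant: str = "rs877087"
    coding: str = "dominant"  # carrier status used in the true hazard
    baseline_hazard: float = 0.002
    beta_treat: float = 0.0029
    beta_geno: float = 0.0
    beta_interact: float = 0.00069
    admin_censor_years: float = 13.0
    dropout_hazard: float = 0.02  # GP deduction (list removal) rate, per year
    rx_stop_hazard: float = 0.14  # dCCB cessation rate -> mean episode ~5.9y
    switch_prob: float = 0.135  # P(switch to another class | cessation)
    scripts_per_year_mean: float = 9.2
    scripts_per_year_sd: float = 4.6
    p_co_med: float = 0.61  # co-prescribed another antihypertensive
    p_prior_heart: float = 0.071  # prior MI/angina at first prescription
    p_female: float = 0.456
    first_rx_age_mean: float = 61.3
    first_rx_age_sd: float = 7.7
    first_rx_age_range: tuple[float, float] = (40.0, 79.3)
    outcome: str = "hf"
    treat_geno_or: float = 1.0  # violation mode: OR of treatment per allele
    confounding: float = 0.0  # frailty -> treatment + additive hazard effect
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if not 0.0 <= self.p_treated <= 1.0:
            raise ConfigError("p_treated must be a probability")
        for rsid, maf in self.variant_mafs.items():
            if not 0.0 <= maf <= 0.5:
                raise ConfigError(f"maf for {rsid} is {maf}, outside [0, 0.5]")
        if self.causal_variant not in self.variant_mafs:
            raise ConfigError(
                f"causal variant {self.causal_variant!r} not in variant_mafs"
            )
        if self.coding not in ("dominant", "additive"):
            raise ConfigError(
                f"truth coding must be 'dominant' or 'additive', got {self.coding!r}"
            )
        for name in ("admin_censor_years", "dropout_hazard", "rx_stop_hazard"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        self._check_hazard_cells()

    def _check_hazard_cells(self) -> None:
        """Every genotype x treatment cell must have a non-negative hazard."""
        g_max = 2.0 if self.coding == "additive" else 1.0
        for g in (0.0, g_max):
            for t in (0.0, 1.0):
                h = (
                    self.baseline_hazard
                    + self.beta_treat * t
                    + self.beta_geno * g
                    + self.beta_interact * g * t
                )
                if h < 0:
                    raise ConfigError(
                        "negative hazard "
                        f"({h:.3g}/y) in subgroup genotype={g:g}, treated={t:g}; "
                        "additive-hazards generation requires all cells >= 0"
                    )

    def cell_hazard(self, g: float, treated: float) -> float:
        return (
            self.baseline_hazard
            + self.beta_treat * treated
            + self.beta_geno * g
            + self.beta_interact * g * treated
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["first_rx_age_range"] = list(self.first_rx_age_range)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "first_rx_age_range" in d:
            d["first_rx_age_range"] = tuple(d["first_rx_age_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def ryr3_hf_config(
    n_treated: int = 31_074,
    n_untreated: int = 190_000,
    seed: int = 0,
    **overrides: Any,
) -> SimConfig:
    """Study conditions of the rs877087 (RYR3) heart-failure analysis.

    Treated cohort of ~31k dCCB users with T-allele carrier frequency 0.708
    (MAF 0.46), untreated comparator pool of 190k, no direct genotype effect
    off treatment, and a genotype-by-treatment interaction of 0.00069
    additional HF events per carrier person-year.  With a 13-year follow-up
    horizon and 0.02/y deduction rate these settings yield ~1850 treated HF
    diagnoses and ~243k carrier patient-years on treatment.
    """
    n_total = n_treated + n_untreated
    params: dict[str, Any] = dict(
        n_patients=n_total,
        p_treated=n_treated / n_total,
        variant_mafs={"rs877087": 0.46},
        causal_variant="rs877087",
        coding="dominant",
        baseline_hazard=0.002,
        beta_treat=0.0029,
        beta_geno=0.0,
        beta_interact=0.00069,
        admin_censor_years=13.0,
        dropout_hazard=0.02,
        outcome="hf",
        rng_seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)
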