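"""Variant panel and clinical code maps.

The default panel holds the 23 candidate variants (16 genes) studied for
dihydropyridine calcium-channel blocker (dCCB) response, with minor-allele
frequencies in the 3-46% range typical of a European-ancestry cohort.  The
drug-class and diagnosis-code maps are shipped as editable TSV tables; the
entries are illustrative defaults (full primary-care code lists are
deployment-specific) and any table with the same columns can be substituted.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigError

INHERITANCE_MODELS = ("genotypic", "dominant", "additive")

#: antihypertensive drug classes recognised by the exposure builder
DRUG_CLASSES = (
    "dccb_amlodipine",
    "dccb_other",
    "ace",
    "arb",
    "beta_blocker",
    "alpha_blocker",
    "diuretic",
    "vasodilator",
    "other",
)
DCCB_CLASSES = ("dccb_amlodipine", "dccb_other")

OUTCOME_LABELS = ("chd", "hf", "ckd", "stroke", "oedema")


@dataclass(frozen=True)
class VariantDef:
    """One candidate variant: identity, alleles, frequency and coding model."""

    rsid: str
    gene: str
    effect_allele: str
    other_allele: str
    maf: float
    inheritance_model: str = "genotypic"

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ConfigError(f"{self.rsid}: effect and other allele are identical")
        if not 0.0 <= self.maf <= 0.5:
            raise ConfigError(f"{self.rsid}: maf {self.maf} outside [0, 0.5]")
        if self.inheritance_model not in INHERITANCE_MODELS:
            raise ConfigError(
                f"{self.rsid}: unknown inheritance model {self.inheritance_model!r}"
            )

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        """Genotype strings for dosage 0/1/2 of the effect allele."""
        a, b = self.other_allele, self.effect_allele
        return (a + a, b + a, b + b)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pgxtwist.data").joinpath(name)))


def load_panel(path: str | Path | None = None) -> list[VariantDef]:
    """Load a variant panel from TSV (rsid, gene, alleles, maf, model)."""
    path = _data_path("variants.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    required = {"rsid", "gene", "effect_allele", "other_allele", "maf"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"variant panel {path} missing columns {sorted(missing)}")
    variants = []
    for row in df.itertuples(index=False):
        variants.append(
            VariantDef(
                rsid=row.rsid,
                gene=row.gene,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                maf=float(row.maf),
                inheritance_model=getattr(row, "inheritance_model", "genotypic"),
            )
        )
    return variants


def default_panel() -> list[VariantDef]:
    """The shipped 23-variant dCCB pharmacogenetics panel."""
    return load_panel(None)


def panel_by_rsid(panel: list[VariantDef] | None = None) -> dict[str, VariantDef]:
    return {v.rsid: v for v in (panel if panel is not None else default_panel())}


def load_drug_class_map(path: str | Path | None = None) -> pd.DataFrame:
    """(code_system, code) -> drug_class mapping table."""
    path = _data_path("drug_classes.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"code_system", "code", "drug_class"}
    if not required <= set(df.columns):
        raise ConfigError(f"drug class map {path} must have columns {sorted(required)}")
    bad = set(df["drug_class"]) - set(DRUG_CLASSES)
    if bad:
        raise ConfigError(f"unknown drug classes in {path}: {sorted(bad)}")
    return df


def load_outcome_code_map(path: str | Path | None = None) -> pd.DataFrame:
    """(vocabulary, code_prefix) -> outcome_label mapping table.

    Codes are matched by prefix, mirroring ICD-10 chapter-style groupings
    (e.g. every I50.x record maps to heart failure).
    """
    path = _data_path("outcome_codes.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"vocabulary", "code_prefix", "outcome_label"}
    if not required <= set(df.columns):
        raise ConfigError(f"outcome map {path} must have columns {sorted(required)}")
    bad = set(df["outcome_label"]) - set(OUTCOME_LABELS)
    if bad:
        raise ConfigError(f"unknown outcome labels in {path}: {sorted(bad)}")
    return df


def classify_drug(codes: pd.DataFrame, class_map: pd.DataFrame) -> pd.Series:
    """Map prescription rows to drug classes; unknown codes become 'other'."""
    merged = codes.merge(class_map[["code_system", "code", "drug_class"]],
                         on=["code_system", "code"], how="left")
    return merged["drug_class"].fillna("other").to_numpy()


def classify_diagnosis(diag: pd.DataFrame, outcome_map: pd.DataFrame) -> pd.Series:
    """Map diagnosis rows to outcome labels by (vocabulary, code-prefix).

    Longest matching prefix wins so one input row maps to at most one label;
    unmatched rows map to 'none'.
    """
    labels = pd.Series("none", index=diag.index, dtype=object)
    match_len = pd.Series(-1, index=diag.index)
    for row in outcome_map.itertuples(index=False):
        mask = (diag["vocabulary"] == row.vocabulary) & diag["code"].str.startswith(
            row.code_prefix
        )
        better = mask & (len(row.code_prefix) > match_len)
        labels[better] = row.outcome_label
        match_len[better] = len(row.code_prefix)
    return labels.to_numpy()
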