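"""Deterministic clinical derivations for the baseline and biomarker blocks.

Implements the study's standard clinical codings for newly diagnosed
type 1 diabetes: insulin-dose-adjusted HbA1c (IDAA1c) and the partial
remission criterion, diabetic ketoacidosis (DKA) grading from standard
bicarbonate, the HLA-DQB1 genotype risk score, islet autoantibody
positivity cutoffs, additive risk-allele coding of SNP genotypes, and
onset age groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_idaa1c",
    "is_partial_remission",
    "classify_dka",
    "classify_hla_risk",
    "collapse_hla_risk",
    "antibody_positive",
    "ANTIBODY_CUTOFFS",
    "encode_genotype",
    "age_group",
    "derive_baseline_features",
]


def compute_idaa1c(hba1c_pct: float, insulin_dose_u_per_kg_per_24h: float) -> float:
    """Insulin-dose-adjusted HbA1c: HbA1c (%) + 4 x daily dose (U/kg/24 h)."""
    if hba1c_pct <= 0:
        raise ValueError("hba1c_pct must be positive")
    if insulin_dose_u_per_kg_per_24h < 0:
        raise ValueError("insulin dose must be nonnegative")
    return hba1c_pct + 4.0 * insulin_dose_u_per_kg_per_24h


def is_partial_remission(idaa1c: float) -> bool:
    """Partial remission: IDAA1c <= 9 (boundary inclusive)."""
    if idaa1c <= 0:
        raise ValueError("idaa1c must be positive")
    return idaa1c <= 9.0


def classify_dka(hco3_mmol_per_l: float) -> str:
    """DKA grade from standard bicarbonate at diagnosis.

    severe_dka if HCO3- <= 5 mmol/L, dka if <= 15 mmol/L, else none; both
    thresholds inclusive. In block encodings severe DKA also sets the DKA
    flag (severity is nested).
    """
    if hco3_mmol_per_l <= 0:
        raise ValueError("hco3 must be positive")
    if hco3_mmol_per_l <= 5.0:
        return "severe_dka"
    if hco3_mmol_per_l <= 15.0:
        return "dka"
    return "none"


_HLA_ALLELES = {"02", "0301", "0302", "0304", "0602", "0603", "0604", "X"}
# alleles named explicitly in the risk templates; everything else typed
# behaves as the wildcard class "X"
_HLA_NAMED = {"02", "0301", "0302", "0602", "0603"}


def _normalize_hla_allele(a) -> str:
    a = str(a)
    if a in _HLA_ALLELES:
        return a
    # tolerate leading zeros lost in numeric round-trips ("302" -> "0302")
    if a.isdigit():
        for cand in (a.zfill(4), "0" + a):
            if cand in _HLA_ALLELES:
                return cand
    raise ValueError(f"unknown DQB1 allele {a!r}")


def _hla_pair_key(a1: str, a2: str):
    a1, a2 = _normalize_hla_allele(a1), _normalize_hla_allele(a2)
    return tuple(sorted(a if a in _HLA_NAMED else "X" for a in (a1, a2)))


def classify_hla_risk(allele1: str, allele2: str) -> str:
    """HLA-DQB1 genotype risk group from an unordered allele pair.

    Rules in priority order: very_high = 0302/02; high = 0302/0302, 0302/X,
    02/02, 02/X; moderate = 0302/0301, 0302/0603, 02/0301, 02/0603, X/X;
    low = 0302/0602, 02/0602, 0301/X, 0603/X (X = any allele not named in
    the templates). Pairs matching no template carry only protective or
    neutral alleles and are assigned low.
    """
    cls = _hla_pair_key(allele1, allele2)
    very_high = {("02", "0302")}
    high = {("0302", "0302"), ("0302", "X"), ("02", "02"), ("02", "X")}
    moderate = {
        ("0301", "0302"),
        ("0302", "0603"),
        ("02", "0301"),
        ("02", "0603"),
        ("X", "X"),
    }
    low = {("0302", "0602"), ("02", "0602"), ("0301", "X"), ("0603", "X")}
    if cls in very_high:
        return "very_high"
    if cls in high:
        return "high"
    if cls in moderate:
        return "moderate"
    if cls in low:
        return "low"
    return "low"


def collapse_hla_risk(risk: str) -> str:
    """Collapse the 4-level risk score to the modelled 3 groups."""
    if risk in ("very_high", "high"):
        return risk
    if risk in ("moderate", "low"):
        return "moderate_low"
    raise ValueError(f"unknown risk level {risk!r}")


#: positivity cutoffs; conventional autoantibodies in assay units
#: (JDFU for ICA, relative units otherwise), ZnT8 variants in U/ml.
ANTIBODY_CUTOFFS = {
    "ICA": 2.5,
    "IAA": 2.80,
    "GADA": 5.36,
    "IA2A": 0.43,
    "ZnT8Arg": 60.0,
    "ZnT8Trp": 58.0,
    "ZnT8Gln": 65.0,
    "ZnT8Triple": 58.0,
}


def antibody_positive(analyte: str, titer: float) -> bool:
    """Autoantibody positivity: titer >= the analyte's cutoff (inclusive)."""
    if analyte not in ANTIBODY_CUTOFFS:
        raise ValueError(f"unknown analyte {analyte!r}")
    if titer < 0:
        raise ValueError("titer must be nonnegative")
    return titer >= ANTIBODY_CUTOFFS[analyte]


def encode_genotype(genotype, risk_allele: str):
    """Additive coding: count of risk alleles in {0, 1, 2}; None stays missing.

    ``genotype`` is a pair of allele labels (e.g. ("A", "G")) or None for a
    failed genotyping; each allele must equal the declared risk allele or
    the declared other allele is implied.
    """
    if genotype is None:
        return None
    a1, a2 = genotype
    for a in (a1, a2):
        if not isinstance(a, str) or not a:
            raise ValueError(f"bad allele label {a!r}")
    return int(a1 == risk_allele) + int(a2 == risk_allele)


def age_group(age_years: float) -> str:
    """Onset age groups: [0, 5), [5, 10), [10, inf)."""
    if age_years < 0:
        raise ValueError("age must be nonnegative")
    if age_years < 5:
        return "<5"
    if age_years < 10:
        return "5-<10"
    return ">=10"


def derive_baseline_features(table: pd.DataFrame) -> pd.DataFrame:
    """Derive modelled baseline variables from a raw clinical table.

    Expects columns (one row per subject): subject_id, age_years, sex,
    symptom_duration_weeks, blood_glucose_mmol_per_l, hco3_mmol_per_l,
    pubertal, hba1c_pct, insulin_dose_u_per_kg, hla_allele1, hla_allele2.
    Returns the input plus idaa1c, partial_remission, dka, severe_dka,
    hla_risk, hla_risk_3group, age_group and numeric codings (sex_male,
    pubertal as 0/1).
    """
    out = table.copy()
    out["idaa1c"] = [
        compute_idaa1c(h, d)
        for h, d in zip(table["hba1c_pct"], table["insulin_dose_u_per_kg"])
    ]
    out["partial_remission"] = [is_partial_remission(v) for v in out["idaa1c"]]
    grades = [classify_dka(v) for v in table["hco3_mmol_per_l"]]
    out["severe_dka"] = [g == "severe_dka" for g in grades]
    out["dka"] = [g in ("dka", "severe_dka") for g in grades]  # nested flag
    out["hla_risk"] = [
        classify_hla_risk(a, b)
        for a, b in zip(table["hla_allele1"], table["hla_allele2"])
    ]
    out["hla_risk_3group"] = [collapse_hla_risk(r) for r in out["hla_risk"]]
    out["age_group"] = [age_group(a) for a in table["age_years"]]
    out["sex_male"] = (table["sex"].astype(str).str.lower() == "male").astype(int)
    out["pubertal"] = table["pubertal"].astype(bool).astype(int)
    return out


def encode_genotype_table(
    genotypes: pd.DataFrame, risk_alleles: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Additive-code a subjects x SNPs table of 'A/G'-style genotype strings.

    ``risk_alleles`` maps SNP column name -> risk allele label. Missing
    cells (NaN or empty) propagate to the mask. Returns (counts, mask).
    """
    snps = list(genotypes.columns)
    n = len(genotypes)
    counts = np.zeros((n, len(snps)))
    mask = np.ones((n, len(snps)), dtype=bool)
    for j, snp in enumerate(snps):
        risk = risk_alleles.get(snp)
        if risk is None:
            raise ValueError(f"no risk allele declared for {snp!r}")
        for i, val in enumerate(genotypes[snp]):
            if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                mask[i, j] = False
                continue
            pair = str(val).split("/")
            if len(pair) != 2:
                raise ValueError(f"bad genotype {val!r} for {snp!r}")
            counts[i, j] = encode_genotype(tuple(pair), risk)
    return counts, mask
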