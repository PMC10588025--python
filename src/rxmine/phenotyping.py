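"""Rule-based T2DM phenotyping of mapped pharmacy claims.

Claims data here carry no diagnosis (ICD) codes, so type 2 diabetes status is
inferred from prescription and provider signals alone.  A patient is labeled
T2DM when all three criteria hold:

1. **Drug criterion** — some prescription contains at least one drug from ATC
   level-2 class A10 ("Drugs Used in Diabetes"), excluding insulin
   syringe/device products that the national coding files under A10.
2. **Prescriber criterion** — that same prescription was written by a general
   practitioner, internist, or endocrinologist (the strict per-prescription
   conjunction; a looser any-prescription reading is configurable).
3. **No competing indication** — none of four exclusion branches fires, each
   limited to patients under the exclusion age cutoff (30 years):

   * *T1DM (male)*: any insulin in a male's history.
   * *T1DM (female)*: any insulin other than human insulin in a female's
     history.
   * *PCOS*: metformin prescribed by a gynecologist to a female (off-label
     polycystic-ovary-syndrome use).
   * *Pregnancy*: human insulin in a female's history, unless the patient took
     at least one oral anti-diabetic (OAD, A10B) in a non-PCOS prescription —
     i.e. a prescription that does not itself meet the PCOS condition.

After labeling, all A10 records of non-T2DM patients are censored so that
downstream mining never attributes anti-diabetic exposure to confounder
patients (T1DM, PCOS, gestational diabetes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import PhenotypeConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExclusionFlags:
    """Patient-level competing-indication flags (criterion 3)."""

    t1dm_male: bool = False
    t1dm_female: bool = False
    pcos: bool = False
    pregnancy: bool = False

    @property
    def any(self) -> bool:
        return self.t1dm_male or self.t1dm_female or self.pcos or self.pregnancy


class DrugClassPredicates:
    """Row-level drug-class predicates over mapped claims.

    All predicates derive from the ATC hierarchy columns plus two configurable
    escape hatches: human insulin is identified by generic-name match (with an
    optional explicit ATC list), and insulin syringes by a national-code
    exclusion list, since ATC itself has no device class.
    """

    def __init__(self, cfg: PhenotypeConfig | None = None) -> None:
        self.cfg = cfg or PhenotypeConfig()

    def a10(self, claims: pd.DataFrame) -> pd.Series:
        """A10 drug, excluding insulin syringe national codes."""
        syringe = claims["national_drug_code"].isin(self.cfg.syringe_national_codes)
        return (claims["atc_l2"] == "A10") & ~syringe

    def insulin_any(self, claims: pd.DataFrame) -> pd.Series:
        return claims["atc_l5"].str.startswith("A10A").fillna(False)

    def oad(self, claims: pd.DataFrame) -> pd.Series:
        return claims["atc_l5"].str.startswith("A10B").fillna(False)

    def insulin_human(self, claims: pd.DataFrame) -> pd.Series:
        name = claims["generic_name"].str.lower().fillna("")
        by_name = pd.Series(False, index=claims.index)
        for needle in self.cfg.insulin_human_names:
            by_name |= name.str.contains(needle, regex=False)
        by_atc = claims["atc_l5"].isin(self.cfg.insulin_human_atc)
        return (by_name | by_atc) & self.insulin_any(claims)

    def metformin(self, claims: pd.DataFrame) -> pd.Series:
        by_name = claims["generic_name"].str.lower().str.contains(
            "metformin", regex=False
        ).fillna(False)
        return (claims["atc_l5"] == "A10BA02") | by_name


def _record_flags(claims: pd.DataFrame, preds: DrugClassPredicates) -> pd.DataFrame:
    cfg = preds.cfg
    gyn = claims["prescriber_specialty"].isin(cfg.gynecology_specialties)
    qualifying_spec = claims["prescriber_specialty"].isin(cfg.qualifying_specialties)
    return pd.DataFrame(
        {
            "patient_id": claims["patient_id"],
            "prescription_id": claims["prescription_id"],
            "a10": preds.a10(claims),
            "insulin": preds.insulin_any(claims),
            "insulin_human": preds.insulin_human(claims),
            "insulin_nonhuman": preds.insulin_any(claims)
            & ~preds.insulin_human(claims),
            "oad": preds.oad(claims),
            "metformin_gyn": preds.metformin(claims) & gyn,
            "qualifies": preds.a10(claims) & qualifying_spec,
            "a10_any_spec": preds.a10(claims),
            "qualifying_spec": qualifying_spec,
        }
    )


def phenotype(
    claims: pd.DataFrame, cfg: PhenotypeConfig | None = None
) -> pd.DataFrame:
    """Label every patient in a mapped-claims table.

    Returns one row per patient with demographics, the four exclusion flags,
    ``has_qualifying_rx`` and the final ``is_t2dm`` label.  Invariant to the
    order of records.
    """
    cfg = cfg or PhenotypeConfig()
    preds = DrugClassPredicates(cfg)
    rec = _record_flags(claims, preds)

    demo = (
        claims.groupby("patient_id")
        .agg(age=("age", "min"), gender=("gender", "first"),
             age_category=("age_category", "first"))
    )

    # prescription-level aggregates
    presc = rec.groupby(["patient_id", "prescription_id"]).agg(
        has_a10=("a10", "any"),
        has_oad=("oad", "any"),
        pcos_rx=("metformin_gyn", "any"),
        qualifies_strict=("qualifies", "any"),
        qualifying_spec=("qualifying_spec", "any"),
    )
    if cfg.per_prescription:
        presc["qualifies"] = presc["qualifies_strict"]
    else:
        # loose reading: drug criterion and specialty criterion may be met by
        # different prescriptions
        by_pat = presc.groupby(level="patient_id")
        presc["qualifies"] = by_pat["has_a10"].transform("any") & by_pat[
            "qualifying_spec"
        ].transform("any")

    pat_presc = presc.groupby(level="patient_id").agg(
        has_qualifying_rx=("qualifies", "any"),
        oad_non_pcos=("has_oad", "any"),  # placeholder, refined below
    )
    # OAD taken in a prescription that does not itself meet the PCOS condition
    pat_presc["oad_non_pcos"] = (
        (presc["has_oad"] & ~presc["pcos_rx"]).groupby(level="patient_id").any()
    )

    pat_rec = rec.groupby("patient_id").agg(
        any_insulin=("insulin", "any"),
        any_insulin_nonhuman=("insulin_nonhuman", "any"),
        any_insulin_human=("insulin_human", "any"),
        any_metformin_gyn=("metformin_gyn", "any"),
    )

    patients = demo.join(pat_presc).join(pat_rec)
    young = patients["age"] < cfg.exclusion_age_cutoff
    male = patients["gender"] == "male"
    female = patients["gender"] == "female"

    patients["t1dm_male"] = male & young & patients["any_insulin"]
    patients["t1dm_female"] = female & young & patients["any_insulin_nonhuman"]
    patients["pcos"] = female & young & patients["any_metformin_gyn"]
    patients["pregnancy"] = (
        female
        & young
        & patients["any_insulin_human"]
        & ~patients["oad_non_pcos"]
    )
    excluded = (
        patients["t1dm_male"]
        | patients["t1dm_female"]
        | patients["pcos"]
        | patients["pregnancy"]
    )
    patients["is_t2dm"] = patients["has_qualifying_rx"] & ~excluded
    cols = [
        "age",
        "gender",
        "age_category",
        "has_qualifying_rx",
        "t1dm_male",
        "t1dm_female",
        "pcos",
        "pregnancy",
        "is_t2dm",
    ]
    return patients[cols]


def qualifying_prescription(
    prescription: pd.DataFrame, cfg: PhenotypeConfig | None = None
) -> bool:
    """Criteria 1+2 on a single prescription's mapped records."""
    cfg = cfg or PhenotypeConfig()
    preds = DrugClassPredicates(cfg)
    has_a10 = bool(preds.a10(prescription).any())
    spec_ok = bool(
        prescription["prescriber_specialty"].isin(cfg.qualifying_specialties).any()
    )
    return has_a10 and spec_ok


def detect_exclusions(
    patient_claims: pd.DataFrame, cfg: PhenotypeConfig | None = None
) -> ExclusionFlags:
    """Criterion-3 flags for one patient's mapped records."""
    row = phenotype(patient_claims, cfg).iloc[0]
    return ExclusionFlags(
        t1dm_male=bool(row["t1dm_male"]),
        t1dm_female=bool(row["t1dm_female"]),
        pcos=bool(row["pcos"]),
        pregnancy=bool(row["pregnancy"]),
    )


def label_t2dm(
    patient_claims: pd.DataFrame, cfg: PhenotypeConfig | None = None
) -> bool:
    """Full composite label for one patient's mapped records."""
    return bool(phenotype(patient_claims, cfg)["is_t2dm"].iloc[0])


def censor_a10(
    claims: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, int]:
    """Remove A10 records (all of level-2 class A10, devices included) from
    patients not labeled T2DM.

    ``labels`` maps patient_id → bool.  Returns censored claims and the count
    removed.
    """
    is_t2dm = labels.reindex(claims["patient_id"], fill_value=False).astype(bool)
    is_t2dm.index = claims.index
    drop = (claims["atc_l2"] == "A10") & ~is_t2dm
    n = int(drop.sum())
    if n:
        logger.info("censored %d A10 records of non-T2DM patients", n)
    return claims.loc[~drop].reset_index(drop=True), n
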