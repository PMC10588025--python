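"""Synthetic pharmacy-claims cohorts with known generative structure.

The generator emulates the statistical features the pipeline assumes of a
claims extract: roughly 10% latent type-2-diabetes prevalence with the
diabetic subpopulation skewed female and old, comorbidity-driven
co-prescription (statins with dyslipidemia, renin-angiotensin drugs with
hypertension, thiamine/gabapentin with diabetic neuropathy, ...), prescriber
specialties correlated with the patient's conditions, deliberate confounder
subpopulations exercising every phenotyping branch (young insulin users,
PCOS metformin from gynecologists, pregnant human-insulin users), and a
fraction of patients with blanked demographics.

Generative model
----------------
Each patient draws a latent condition profile (T2DM status, then age
category, gender, and comorbidities conditionally), a prescription count
``1 + Poisson(λ)`` with λ depending on T2DM status, and, per prescription,
independent Bernoulli inclusion of each formulary drug with a probability
determined by the active conditions: ``p_d = 1 − ∏_c (1 − p_{d|c})``.
Two "background" drugs are instead sampled once per patient, independently
of everything else, giving planted-independent item pairs whose lift is
exactly 1.  Because drug draws are independent across drugs given the
profile and the prescription count, patient-level co-occurrence
probabilities — hence support, confidence, and lift of any ATC-level rule —
have the closed form implemented in :func:`expected_rule_metrics`, which the
parameter-recovery tests compare against mined values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PhenotypeConfig
from .ingestion import ATC_LEVEL_LENGTHS, PATIENT_ID_DELIMITER

AGE_CATS = ("Young", "Middle-Aged", "Old")

#: national code → (generic name, ATC level-5 code).  The syringe entry is a
#: device the national coding files under A10; ATC itself has no device class.
FORMULARY: dict[str, tuple[str, str]] = {
    "01001": ("Metformin", "A10BA02"),
    "01002": ("Glibenclamide", "A10BB01"),
    "01003": ("Gliclazide", "A10BB09"),
    "01004": ("Pioglitazone", "A10BG03"),
    "01005": ("Insulin (Human)", "A10AB01"),
    "01006": ("Insulin Aspart", "A10AB05"),
    "01007": ("Insulin Glargine", "A10AE04"),
    "09001": ("Insulin Syringe", "A10AB01"),
    "02023": ("Asa 100 mg - tablet", "B01AC06"),
    "01010": ("Atorvastatin", "C10AA05"),
    "01011": ("Losartan", "C09CA01"),
    "01012": ("Enalapril", "C09AA02"),
    "01013": ("Hydrochlorothiazide", "C03AA03"),
    "01014": ("Furosemide", "C03CA01"),
    "01015": ("Thiamine (Vit B1)", "A11DA01"),
    "01016": ("Gabapentin", "N03AX12"),
    "01017": ("Levothyroxine", "H03AA01"),
    "01018": ("Metoprolol", "C07AB02"),
    "01019": ("Folic Acid", "B03BB01"),
    "01020": ("Cetirizine", "R06AE07"),
    "01021": ("Amoxicillin", "J01CA04"),
    "01022": ("Acetaminophen", "N02BE01"),
    "01023": ("Omeprazole", "A02BC01"),
}

SYRINGE_CODES = ("09001",)

_SPECIALTY_POOLS = {
    "General practitioner": [str(c) for c in range(1000, 1080)],
    "Internist": [str(c) for c in range(1100, 1140)],
    "Endocrinologist": [str(c) for c in range(1780, 1800)],  # includes 1787
    "Cardiologist": [str(c) for c in range(1200, 1230)],
    "Gynecologist": [str(c) for c in range(1300, 1330)],
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; the defaults are the study
    conditions (marginals matched to a large urban insured population with
    ~10% diabetic prevalence, diabetics ~63% female and ~77% old)."""

    n_patients: int = 10_000
    seed: int = 0
    p_t2dm: float = 0.10
    p_missing: float = 0.02
    # age-category distribution conditional on T2DM status
    age_dist_t2dm: dict[str, float] = field(
        default_factory=lambda: {"Young": 0.0738, "Middle-Aged": 0.1540, "Old": 0.7722}
    )
    age_dist_other: dict[str, float] = field(
        default_factory=lambda: {"Young": 0.4242, "Middle-Aged": 0.2297, "Old": 0.3461}
    )
    p_female_t2dm: float = 0.634
    p_female_other: float = 0.550
    # prescriptions per patient: 1 + Poisson(lambda)
    lambda_presc_t2dm: float = 4.0
    lambda_presc_other: float = 2.0
    # comorbidity probabilities conditional on latent status
    p_hypertension: dict[str, float] = field(
        default_factory=lambda: {"t2dm": 0.50, "other": 0.20}
    )
    p_dyslipidemia: dict[str, float] = field(
        default_factory=lambda: {"t2dm": 0.60, "other": 0.15}
    )
    # hypothyroidism by (status, gender) — thyroid disease is female-skewed
    p_hypothyroidism: dict[str, float] = field(
        default_factory=lambda: {
            "t2dm_female": 0.12,
            "t2dm_male": 0.04,
            "other_female": 0.06,
            "other_male": 0.02,
        }
    )
    # neuropathy by (status, old age)
    p_neuropathy: dict[str, float] = field(
        default_factory=lambda: {"t2dm_old": 0.25, "t2dm_young": 0.08, "other": 0.02}
    )
    # confounders, drawn only among young non-diabetics (females for PCOS and
    # pregnancy), mutually exclusive
    p_t1dm_young: float = 0.004
    p_pcos_young_female: float = 0.010
    p_pregnancy_young_female: float = 0.015
    # per-prescription drug inclusion probabilities by condition;
    # "t2dm_insulin" is active for non-young diabetics only (young T2DM is
    # managed on oral agents here, keeping the T1DM exclusion specific)
    drug_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # everyday primary-care drugs, active for every patient, so that
            # nearly all patients actually appear in the dispensing table
            "baseline": {"01022": 0.30, "01023": 0.15},
            "t2dm": {
                "01001": 0.55,
                "01002": 0.20,
                "01003": 0.15,
                "01004": 0.10,
                "02023": 0.06,
            },
            "t2dm_insulin": {
                "01005": 0.15,
                "01006": 0.08,
                "01007": 0.08,
                "09001": 0.06,
            },
            "hypertension": {
                "01012": 0.35,
                "01011": 0.30,
                "01013": 0.18,
                "01014": 0.08,
                "01018": 0.16,
                "02023": 0.04,
            },
            "dyslipidemia": {"01010": 0.60},
            "hypothyroidism": {"01017": 0.70},
            "neuropathy": {"01016": 0.45, "01015": 0.40},
            "t1dm": {"01006": 0.45, "01007": 0.45, "01005": 0.15, "09001": 0.35},
            "pcos": {"01001": 0.80},
            "pregnancy": {"01005": 0.60, "01019": 0.80},
        }
    )
    # patient-level (not per-prescription) drugs, independent of all
    # conditions: exact-independence controls for lift calibration
    background_drugs: dict[str, float] = field(
        default_factory=lambda: {"01020": 0.18, "01021": 0.25}
    )
    # specialty distribution per prescription by patient profile
    specialty_dists: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "base": {
                "General practitioner": 0.72,
                "Internist": 0.18,
                "Cardiologist": 0.10,
            },
            "t2dm": {
                "General practitioner": 0.50,
                "Internist": 0.25,
                "Endocrinologist": 0.20,
                "Cardiologist": 0.05,
            },
            "t1dm": {
                "Endocrinologist": 0.60,
                "General practitioner": 0.30,
                "Internist": 0.10,
            },
        }
    )

    def validate(self) -> None:
        probs = [self.p_t2dm, self.p_missing, self.p_female_t2dm, self.p_female_other,
                 self.p_t1dm_young, self.p_pcos_young_female,
                 self.p_pregnancy_young_female]
        for table in (self.p_hypertension, self.p_dyslipidemia,
                      self.p_hypothyroidism, self.p_neuropathy,
                      self.background_drugs):
            probs.extend(table.values())
        for table in self.drug_probs.values():
            probs.extend(table.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for name, dist in (("age_dist_t2dm", self.age_dist_t2dm),
                           ("age_dist_other", self.age_dist_other)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name, dist in self.specialty_dists.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"specialty_dists[{name!r}] must sum to 1")


def default_phenotype_config() -> PhenotypeConfig:
    """Phenotyping config matching the synthetic formulary (syringe codes)."""
    return PhenotypeConfig(syringe_national_codes=SYRINGE_CODES)


def drug_mapping_frame() -> pd.DataFrame:
    """The formulary as a national-code → ATC levels 1–5 mapping table."""
    rows = []
    for code, (name, atc5) in FORMULARY.items():
        rows.append(
            {
                "national_drug_id": code,
                "generic_name": name,
                **{f"atc_l{lv}": atc5[: ATC_LEVEL_LENGTHS[lv]] for lv in range(1, 6)},
            }
        )
    return pd.DataFrame(rows).set_index("national_drug_id")


def specialty_mapping_frame() -> pd.DataFrame:
    rows = [
        {"prescriber_code": code, "specialty": spec}
        for spec, pool in _SPECIALTY_POOLS.items()
        for code in pool
    ]
    return pd.DataFrame(rows).set_index("prescriber_code")


def _atc_at_level(atc5: str, level: int) -> str:
    return atc5[: ATC_LEVEL_LENGTHS[level]]


def _categorical(rng: np.random.Generator, dist: dict[str, float], size: int,
                 labels: list[str] | None = None) -> np.ndarray:
    labels = labels if labels is not None else list(dist)
    p = np.array([dist[k] for k in labels], dtype=float)
    cum = np.cumsum(p)
    u = rng.random(size)
    idx = np.searchsorted(cum, u, side="right").clip(max=len(labels) - 1)
    return np.array(labels, dtype=object)[idx]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a claims table and its patient-level ground truth.

    Returns ``(claims, truth)``: claims in the canonical schema (with blanked
    demographics where planted), truth with one row per patient recording the
    latent conditions, the pre-blanking demographics, and two bookkeeping
    columns — ``has_qualifying_rx`` (whether a prescription satisfying the
    drug+prescriber criteria was actually generated) and ``expected_label``
    (the label a correct phenotyper should emit).  Diabetics for whom no
    qualifying prescription was generated are the deliberate ambiguity cases.
    Fully deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    t2dm = rng.random(n) < spec.p_t2dm
    p_female = np.where(t2dm, spec.p_female_t2dm, spec.p_female_other)
    female = rng.random(n) < p_female
    gender = np.where(female, "female", "male").astype(object)

    age_cat = np.empty(n, dtype=object)
    for status, dist in ((True, spec.age_dist_t2dm), (False, spec.age_dist_other)):
        mask = t2dm == status
        age_cat[mask] = _categorical(rng, dist, int(mask.sum()), list(AGE_CATS))
    lo = np.select([age_cat == "Young", age_cat == "Middle-Aged"], [18, 30], 45)
    hi = np.select([age_cat == "Young", age_cat == "Middle-Aged"], [30, 45], 90)
    age = rng.integers(lo, hi)

    old = age_cat == "Old"
    young = age_cat == "Young"
    ht = rng.random(n) < np.where(t2dm, spec.p_hypertension["t2dm"],
                                  spec.p_hypertension["other"])
    dl = rng.random(n) < np.where(t2dm, spec.p_dyslipidemia["t2dm"],
                                  spec.p_dyslipidemia["other"])
    hypo_key = np.where(
        t2dm,
        np.where(female, spec.p_hypothyroidism["t2dm_female"],
                 spec.p_hypothyroidism["t2dm_male"]),
        np.where(female, spec.p_hypothyroidism["other_female"],
                 spec.p_hypothyroidism["other_male"]),
    )
    hypo = rng.random(n) < hypo_key
    neuro_p = np.where(
        t2dm,
        np.where(old, spec.p_neuropathy["t2dm_old"], spec.p_neuropathy["t2dm_young"]),
        spec.p_neuropathy["other"],
    )
    neuro = rng.random(n) < neuro_p

    # mutually exclusive confounder conditions among young non-diabetics
    u = rng.random(n)
    eligible = young & ~t2dm
    t1dm = eligible & (u < spec.p_t1dm_young)
    pcos = eligible & female & (u >= spec.p_t1dm_young) & (
        u < spec.p_t1dm_young + spec.p_pcos_young_female
    )
    preg = eligible & female & (
        u >= spec.p_t1dm_young + spec.p_pcos_young_female
    ) & (
        u < spec.p_t1dm_young + spec.p_pcos_young_female
        + spec.p_pregnancy_young_female
    )

    lam = np.where(t2dm, spec.lambda_presc_t2dm, spec.lambda_presc_other)
    n_presc = 1 + rng.poisson(lam)
    pat_of_presc = np.repeat(np.arange(n), n_presc)
    first_presc = np.concatenate(([0], np.cumsum(n_presc)[:-1]))
    n_p = int(n_presc.sum())
    presc_seq = np.arange(n_p) - first_presc[pat_of_presc]

    # per-patient per-prescription inclusion probability for every
    # condition-driven drug: p = 1 - prod over active conditions of (1 - p|c)
    cond_flags = {
        "baseline": np.ones(n, dtype=bool),
        "t2dm": t2dm,
        "t2dm_insulin": t2dm & ~young,
        "hypertension": ht,
        "dyslipidemia": dl,
        "hypothyroidism": hypo,
        "neuropathy": neuro,
        "t1dm": t1dm,
        "pcos": pcos,
        "pregnancy": preg,
    }
    drug_codes = sorted({d for table in spec.drug_probs.values() for d in table})
    p_miss = np.ones((n, len(drug_codes)))
    for cond, table in spec.drug_probs.items():
        flag = cond_flags[cond]
        for j, d in enumerate(drug_codes):
            p = table.get(d)
            if p:
                p_miss[:, j] *= np.where(flag, 1.0 - p, 1.0)
    p_incl = 1.0 - p_miss

    include = rng.random((n_p, len(drug_codes))) < p_incl[pat_of_presc]

    # specialty per prescription by profile, then gynecology overrides
    profile = np.where(t1dm, 2, np.where(t2dm, 1, 0))[pat_of_presc]
    spec_labels = sorted({s for d in spec.specialty_dists.values() for s in d})
    dist_rows = []
    for key in ("base", "t2dm", "t1dm"):
        d = spec.specialty_dists[key]
        dist_rows.append([d.get(s, 0.0) for s in spec_labels])
    cum = np.cumsum(np.array(dist_rows), axis=1)
    u_spec = rng.random(n_p)
    spec_idx = (u_spec[:, None] <= cum[profile]).argmax(axis=1)
    specialty = np.array(spec_labels, dtype=object)[spec_idx]

    jcol = {d: j for j, d in enumerate(drug_codes)}
    has_metformin = include[:, jcol["01001"]] if "01001" in jcol else np.zeros(n_p, bool)
    preg_drug = np.zeros(n_p, dtype=bool)
    for d in ("01005", "01019"):
        if d in jcol:
            preg_drug |= include[:, jcol[d]]
    gyn_override = (pcos[pat_of_presc] & has_metformin) | (
        preg[pat_of_presc] & preg_drug
    )
    specialty[gyn_override] = "Gynecologist"

    code_pools = {s: np.array(p) for s, p in _SPECIALTY_POOLS.items()}
    prescriber = np.empty(n_p, dtype=object)
    for s, pool in code_pools.items():
        mask = specialty == s
        m = int(mask.sum())
        if m:
            prescriber[mask] = pool[rng.integers(0, len(pool), m)]

    # identity: families share an insurance ID, members differ by serial
    fam = np.arange(n) // 3
    insurance_id = np.char.add("F", (100000 + fam).astype(str)).astype(object)
    serial = np.char.zfill(((np.arange(n) % 3) + 1).astype(str), 2).astype(object)
    patient_id = insurance_id + PATIENT_ID_DELIMITER + serial

    presc_id = np.char.add(
        np.char.add(patient_id[pat_of_presc].astype(str), "-RX"),
        presc_seq.astype(str),
    ).astype(object)

    rows_p, rows_d = np.nonzero(include)
    claim_pat = pat_of_presc[rows_p]
    claim_code = np.array(drug_codes, dtype=object)[rows_d]
    claim_presc = presc_id[rows_p]
    claim_prescriber = prescriber[rows_p]

    # background drugs: one patient-level draw, dispensed with the first
    # prescription (placement is irrelevant once baskets deduplicate)
    bg_codes = sorted(spec.background_drugs)
    bg_pat, bg_code, bg_presc, bg_prescriber = [], [], [], []
    for d in bg_codes:
        has = np.nonzero(rng.random(n) < spec.background_drugs[d])[0]
        bg_pat.append(has)
        bg_code.append(np.full(len(has), d, dtype=object))
        fp = first_presc[has]
        bg_presc.append(presc_id[fp])
        bg_prescriber.append(prescriber[fp])
    if bg_codes:
        claim_pat = np.concatenate([claim_pat] + bg_pat)
        claim_code = np.concatenate([claim_code] + bg_code)
        claim_presc = np.concatenate([claim_presc] + bg_presc)
        claim_prescriber = np.concatenate([claim_prescriber] + bg_prescriber)

    claims = pd.DataFrame(
        {
            "insurance_id": insurance_id[claim_pat],
            "insurance_serial": serial[claim_pat],
            "prescription_id": claim_presc,
            "age": age[claim_pat].astype(float),
            "gender": gender[claim_pat],
            "prescriber_code": claim_prescriber,
            "national_drug_code": claim_code,
        }
    )
    order = np.lexsort((claims["prescription_id"], claims["insurance_serial"],
                        claims["insurance_id"]))
    claims = claims.iloc[order].reset_index(drop=True)

    # planted missing demographics: blank one field across the whole history
    missing = rng.random(n) < spec.p_missing
    blank_age = rng.random(n) < 0.5
    miss_age_ids = set(np.nonzero(missing & blank_age)[0])
    miss_gender_ids = set(np.nonzero(missing & ~blank_age)[0])
    in_miss_age = np.isin(claim_pat[order], list(miss_age_ids))
    in_miss_gender = np.isin(claim_pat[order], list(miss_gender_ids))
    claims.loc[in_miss_age, "age"] = np.nan
    claims.loc[in_miss_gender, "gender"] = np.nan

    # bookkeeping: was a qualifying prescription actually generated?
    drug_map = drug_mapping_frame()
    a10_cols = [
        jcol[d]
        for d in drug_codes
        if drug_map.loc[d, "atc_l2"] == "A10" and d not in SYRINGE_CODES
    ]
    presc_has_a10 = include[:, a10_cols].any(axis=1)
    qual_specs = {"General practitioner", "Internist", "Endocrinologist"}
    presc_qual_spec = np.isin(specialty, list(qual_specs))
    presc_qualifies = presc_has_a10 & presc_qual_spec
    has_qual = np.zeros(n, dtype=bool)
    np.logical_or.at(has_qual, pat_of_presc, presc_qualifies)

    truth = pd.DataFrame(
        {
            "patient_id": patient_id,
            "insurance_id": insurance_id,
            "insurance_serial": serial,
            "age": age,
            "gender": gender,
            "age_category": age_cat,
            "t2dm": t2dm,
            "hypertension": ht,
            "dyslipidemia": dl,
            "hypothyroidism": hypo,
            "neuropathy": neuro,
            "t1dm": t1dm,
            "pcos": pcos,
            "pregnancy": preg,
            "n_prescriptions": n_presc,
            "missing_demographics": missing,
            "has_qualifying_rx": has_qual,
        }
    )
    truth["no_qualifying_rx"] = truth["t2dm"] & ~truth["has_qualifying_rx"]
    truth["expected_label"] = truth["t2dm"] & truth["has_qualifying_rx"]
    return claims, truth.set_index("patient_id")


def expected_rule_metrics(
    spec: CohortSpec,
    antecedent: set[str] | frozenset[str],
    consequent: str,
    level: int,
) -> tuple[float, float, float]:
    """Closed-form (support, confidence, lift) of an ATC-level rule under the
    generative model.

    Marginalizes patient-level item probabilities over the latent condition
    profiles and the prescription-count distribution.  Per profile with
    prescription count m, the probability that a patient ever receives any
    drug matching code c is ``1 − B_c (1 − q_c)^m`` where ``q_c`` aggregates
    the per-prescription probabilities of the condition-driven drugs under c
    and ``B_c`` the miss probability of the patient-level background drugs;
    distinct same-level codes are conditionally independent, so itemset
    probabilities multiply inside the expectation.
    """
    spec.validate()
    if level not in ATC_LEVEL_LENGTHS:
        raise ValueError(f"ATC level must be 1..5, got {level}")
    items_a = frozenset(antecedent)
    if not items_a:
        raise ValueError("antecedent must be non-empty")
    if consequent in items_a:
        raise ValueError("consequent must not appear in the antecedent")
    all_codes = items_a | {consequent}

    cond_drugs: dict[str, list[str]] = {}
    bg_miss: dict[str, float] = {}
    every_cond_drug = sorted({d for t in spec.drug_probs.values() for d in t})
    for code in all_codes:
        if len(code) != ATC_LEVEL_LENGTHS[level]:
            raise ValueError(f"item {code!r} is not a level-{level} ATC code")
        matches = [
            d for d in every_cond_drug
            if _atc_at_level(FORMULARY[d][1], level) == code
        ]
        bg = [
            d for d in spec.background_drugs
            if _atc_at_level(FORMULARY[d][1], level) == code
        ]
        if not matches and not bg:
            raise ValueError(f"no formulary drug maps to item {code!r}")
        cond_drugs[code] = matches
        bg_miss[code] = float(np.prod([1.0 - spec.background_drugs[d] for d in bg]))

    # prescription-count pmf per T2DM status: m = 1 + Poisson(lambda)
    kmax = 60
    ks = np.arange(kmax)
    pmf = {
        status: stats.poisson.pmf(ks, lam)
        for status, lam in (
            (True, spec.lambda_presc_t2dm),
            (False, spec.lambda_presc_other),
        )
    }
    ms = ks + 1.0

    p_a = p_b = p_ab = 0.0
    for prob, flags, is_t2dm in _iter_profiles(spec):
        if prob == 0.0:
            continue
        q = {}
        for code in all_codes:
            miss = 1.0
            for d in cond_drugs[code]:
                pd_ = 1.0
                for cond in flags:
                    pd_ *= 1.0 - spec.drug_probs.get(cond, {}).get(d, 0.0)
                miss *= pd_
            q[code] = 1.0 - miss
        have = {
            code: 1.0 - bg_miss[code] * (1.0 - q[code]) ** ms
            for code in all_codes
        }
        w = pmf[is_t2dm]
        pa = float(np.sum(w * np.prod([have[c] for c in items_a], axis=0)))
        pb = float(np.sum(w * have[consequent]))
        pab = float(np.sum(w * np.prod([have[c] for c in all_codes], axis=0)))
        p_a += prob * pa
        p_b += prob * pb
        p_ab += prob * pab

    support = p_ab
    confidence = p_ab / p_a
    lift = confidence / p_b
    return support, confidence, lift


def _iter_profiles(spec: CohortSpec):
    """Yield (probability, active-condition names, is_t2dm) over the latent
    profile space."""
    for t2 in (True, False):
        p_t2 = spec.p_t2dm if t2 else 1.0 - spec.p_t2dm
        for female in (True, False):
            pf = spec.p_female_t2dm if t2 else spec.p_female_other
            p_g = pf if female else 1.0 - pf
            age_dist = spec.age_dist_t2dm if t2 else spec.age_dist_other
            for cat in AGE_CATS:
                p_cat = age_dist[cat]
                specials: list[tuple[float, str | None]] = [(1.0, None)]
                if cat == "Young" and not t2:
                    if female:
                        rest = 1.0 - spec.p_t1dm_young - spec.p_pcos_young_female \
                            - spec.p_pregnancy_young_female
                        specials = [
                            (spec.p_t1dm_young, "t1dm"),
                            (spec.p_pcos_young_female, "pcos"),
                            (spec.p_pregnancy_young_female, "pregnancy"),
                            (rest, None),
                        ]
                    else:
                        specials = [
                            (spec.p_t1dm_young, "t1dm"),
                            (1.0 - spec.p_t1dm_young, None),
                        ]
                p_hypo = spec.p_hypothyroidism[
                    ("t2dm_" if t2 else "other_") + ("female" if female else "male")
                ]
                p_neu = (
                    spec.p_neuropathy["t2dm_old" if cat == "Old" else "t2dm_young"]
                    if t2
                    else spec.p_neuropathy["other"]
                )
                p_ht = spec.p_hypertension["t2dm" if t2 else "other"]
                p_dl = spec.p_dyslipidemia["t2dm" if t2 else "other"]
                for p_sp, sp in specials:
                    if p_sp == 0.0:
                        continue
                    for ht in (True, False):
                        for dl in (True, False):
                            for hyp in (True, False):
                                for neu in (True, False):
                                    prob = (
                                        p_t2 * p_g * p_cat * p_sp
                                        * (p_ht if ht else 1 - p_ht)
                                        * (p_dl if dl else 1 - p_dl)
                                        * (p_hypo if hyp else 1 - p_hypo)
                                        * (p_neu if neu else 1 - p_neu)
                                    )
                                    flags = ["baseline"]
                                    if t2:
                                        flags.append("t2dm")
                                        if cat != "Young":
                                            flags.append("t2dm_insulin")
                                    if ht:
                                        flags.append("hypertension")
                                    if dl:
                                        flags.append("dyslipidemia")
                                    if hyp:
                                        flags.append("hypothyroidism")
                                    if neu:
                                        flags.append("neuropathy")
                                    if sp:
                                        flags.append(sp)
                                    yield prob, flags, t2


def fixture_patients() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hand-specified claims exercising every phenotyping branch.

    Returns ``(claims, expected)``: raw canonical claims and a patient-indexed
    frame with the expected label and the branch each patient exercises.
    Prescriber codes: 1000 = general practitioner, 1100 = internist,
    1787 = endocrinologist, 1300 = gynecologist (see the specialty pools).
    """
    rows: list[tuple] = []

    def rx(iid, serial, rxn, age, gender, prescriber, *codes):
        for c in codes:
            rows.append((iid, serial, f"{iid}-{rxn}", age, gender, prescriber, c))

    rx("P1", "01", "r1", 55, "female", "1100", "01001")  # clean T2DM, internist
    rx("P2", "01", "r1", 25, "male", "1787", "01007")  # young male insulin
    rx("P3", "01", "r1", 27, "female", "1000", "01006")  # young female analog insulin
    rx("P4", "01", "r1", 24, "female", "1300", "01001")  # metformin from gynecology
    rx("P5", "01", "r1", 26, "female", "1000", "01005", "01019")  # human insulin, no OAD
    rx("P6", "01", "r1", 26, "female", "1000", "01005")  # human insulin ...
    rx("P6", "01", "r2", 26, "female", "1000", "01001")  # ... but OAD elsewhere
    rx("P7", "01", "r1", 60, "male", "1100", "01010")  # no A10 at all
    rx("P8", "01", "r1", 50, "female", "1300", "01001")  # qualifying drug, wrong specialty
    rx("P9", "01", "r1", 52, "male", "1000", "09001")  # insulin syringe only
    rx("P10", "01", "r1", 40, "male", "1787", "01005")  # T2DM on human insulin

    claims = pd.DataFrame(
        rows,
        columns=[
            "insurance_id",
            "insurance_serial",
            "prescription_id",
            "age",
            "gender",
            "prescriber_code",
            "national_drug_code",
        ],
    )
    claims["age"] = claims["age"].astype(float)
    expected = pd.DataFrame(
        {
            "patient_id": [f"P{i}{PATIENT_ID_DELIMITER}01" for i in range(1, 11)],
            "expected_label": [
                True, False, False, False, False, True, False, False, False, True,
            ],
            "branch": [
                "clean_t2dm",
                "t1dm_male",
                "t1dm_female",
                "pcos",
                "pregnancy",
                "pregnancy_rescinded_by_oad",
                "no_a10",
                "wrong_specialty",
                "syringe_exclusion",
                "t2dm_on_insulin",
            ],
        }
    ).set_index("patient_id")
    return claims, expected


def write_cohort(
    claims: pd.DataFrame,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write claims, truth, and both mapping tables as CSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": outdir / "claims.csv",
        "truth": outdir / "truth.csv",
        "drug_mapping": outdir / "drug_mapping.csv",
        "specialty_mapping": outdir / "specialty_mapping.csv",
    }
    claims.to_csv(paths["claims"], index=False)
    truth.to_csv(paths["truth"])
    drug_mapping_frame().to_csv(paths["drug_mapping"])
    specialty_mapping_frame().to_csv(paths["specialty_mapping"])
    return paths
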