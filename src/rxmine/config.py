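"""Run configuration: input schemas, drug-class predicates, mining thresholds.

Claims files from different insurers never share a schema, so column names,
delimiters, the specialty vocabulary, and the drug-class code sets used by the
phenotyping rules are all configuration, loadable from a YAML file and
overridable programmatically.  The defaults match the synthetic cohort emitted
by :mod:`rxmine.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Physician specialties whose prescriptions count toward the T2DM case
#: definition (criterion 2 of the phenotyping rule framework).
QUALIFYING_SPECIALTIES = ("General practitioner", "Internist", "Endocrinologist")

#: Specialties treated as gynecology for the PCOS exclusion.
GYNECOLOGY_SPECIALTIES = ("Gynecologist",)


@dataclass
class ColumnMap:
    """Claims-file column names mapped onto the canonical schema."""

    insurance_id: str = "insurance_id"
    insurance_serial: str = "insurance_serial"
    prescription_id: str = "prescription_id"
    age: str = "age"
    gender: str = "gender"
    prescriber_code: str = "prescriber_code"
    national_drug_code: str = "national_drug_code"

    def as_dict(self) -> dict[str, str]:
        return asdict(self)


@dataclass
class PhenotypeConfig:
    """Tunables of the rule-based T2DM case definition."""

    qualifying_specialties: tuple[str, ...] = QUALIFYING_SPECIALTIES
    gynecology_specialties: tuple[str, ...] = GYNECOLOGY_SPECIALTIES
    #: generic-name substrings identifying human insulin products
    insulin_human_names: tuple[str, ...] = ("insulin (human)", "insulin human")
    #: optional explicit ATC level-5 codes for human insulin (unioned with names)
    insulin_human_atc: tuple[str, ...] = ()
    #: national drug codes excluded from A10 (insulin syringes / devices)
    syringe_national_codes: tuple[str, ...] = ()
    #: exclusion age cutoff in years; the four "other condition" branches only
    #: fire strictly below this age
    exclusion_age_cutoff: int = 30
    #: "any": drop a patient when age OR gender is ever missing (MCAR listwise
    #: deletion); "all": drop only when both are missing
    missing_rule: str = "any"
    #: evaluate drug and specialty criteria on the same prescription (strict,
    #: default) or independently across the patient history (loose)
    per_prescription: bool = True


@dataclass
class MiningConfig:
    """Support/confidence thresholds for frequent-itemset and rule mining."""

    min_support: float = 0.0001
    min_confidence: float = 0.1
    max_itemset_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")
        if not 0.0 < self.min_confidence <= 1.0:
            raise ValueError(
                f"min_confidence must be in (0, 1], got {self.min_confidence}"
            )


@dataclass
class AppConfig:
    columns: ColumnMap = field(default_factory=ColumnMap)
    delimiter: str = ","
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)


def load_config(path: str | Path) -> AppConfig:
    """Load an :class:`AppConfig` from a nested key-value YAML file.

    Unknown keys raise, so typos in a config file fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = AppConfig()
    sections = {
        "columns": (ColumnMap, "columns"),
        "phenotype": (PhenotypeConfig, "phenotype"),
        "mining": (MiningConfig, "mining"),
    }
    for key, value in raw.items():
        if key == "delimiter":
            cfg.delimiter = str(value)
        elif key in sections:
            cls, attr = sections[key]
            known = {f for f in cls.__dataclass_fields__}
            bad = set(value) - known
            if bad:
                raise ValueError(f"unknown keys in config section '{key}': {sorted(bad)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            setattr(cfg, attr, cls(**coerced))
        else:
            raise ValueError(f"unknown config section '{key}'")
    return cfg
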