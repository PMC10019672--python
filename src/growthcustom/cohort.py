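"""Cohort data model, CSV I/O and design-matrix encoding.

One delivery is a :class:`PregnancyRecord`.  All three customization engines
share the same covariate encoding: polynomial deviations of gestational age,
maternal height and pre-pregnancy weight from fixed centres, effect-coded
fetal sex, and dummy-coded race/ethnicity and parity against a reference
profile (term delivery at 280 days, height 163 cm, weight 64 kg, nulliparous,
Non-Hispanic White).  At the reference profile every non-intercept
physiologic column is zero, so a model's intercept is directly the term
optimal weight (TOW).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RACE_LEVELS = ("NH-White", "NH-Black", "Hispanic", "Asian/PI")
SEX_LEVELS = ("male", "female")

# accepted spellings for categorical CSV tokens, lowercased
_RACE_ALIASES = {
    "nh-white": "NH-White", "non-hispanic white": "NH-White", "white": "NH-White",
    "nh-black": "NH-Black", "non-hispanic black": "NH-Black", "black": "NH-Black",
    "hispanic": "Hispanic",
    "asian/pi": "Asian/PI", "asian": "Asian/PI", "asian/pacific islander": "Asian/PI",
}
_SEX_ALIASES = {"male": "male", "m": "male", "female": "female", "f": "female"}
_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n", ""}

# design column names, fixed order ----------------------------------------
PHYSIOLOGIC_COLUMNS = (
    "intercept",
    "ga", "ga2", "ga3",
    "sex",
    "height", "height2", "height3",
    "weight", "weight2", "weight3",
    "race_nh_black", "race_hispanic", "race_asian_pi",
    "parity_1", "parity_2plus",
)
PATHOLOGIC_COLUMNS = ("smoking", "bmi", "gdm", "hypertensive", "bleeding")
PATERNAL_COLUMNS = ("paternal_height", "paternal_weight")

#: physiologic covariate fields required for complete-case analysis
_REQUIRED_FIELDS = (
    "maternal_height", "maternal_weight_prepreg", "parity", "race",
    "infant_sex", "ga_delivery", "birthweight",
)


@dataclass
class UltrasoundVisit:
    """One sonographic examination: GA in days, biometry in mm, EFW in g."""

    ga: float
    hc: float | None = None
    ac: float | None = None
    fl: float | None = None
    efw: float | None = None

    def validate(self) -> list[str]:
        problems = []
        for name in ("hc", "ac", "fl", "efw"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                problems.append(f"visit {name} must be positive, got {v}")
        return problems


@dataclass
class PregnancyRecord:
    """One delivery with customization covariates and outcome birthweight.

    Units: heights cm, weights kg, gestational age days, birthweight g,
    BMI kg/m^2 (derived from height and pre-pregnancy weight when absent).
    """

    maternal_height: float
    maternal_weight_prepreg: float
    parity: int
    race: str
    infant_sex: str
    ga_delivery: float
    birthweight: float
    smoking: bool = False
    gestational_diabetes: bool = False
    hypertensive_disease: str = "none"
    antepartum_bleeding: bool = False
    bmi: float | None = None
    paternal_height: float | None = None
    paternal_weight: float | None = None
    morbidity_sga: bool | None = None
    morbidity_lga: bool | None = None
    visits: list[UltrasoundVisit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bmi is None and self.maternal_height and self.maternal_weight_prepreg:
            h_m = self.maternal_height / 100.0
            self.bmi = self.maternal_weight_prepreg / (h_m * h_m)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.birthweight > 0:
            problems.append(f"birthweight must be positive, got {self.birthweight}")
        if not (100.0 <= self.maternal_height <= 220.0):
            problems.append(f"maternal_height {self.maternal_height} cm outside [100, 220]")
        if not self.maternal_weight_prepreg > 0:
            problems.append("maternal pre-pregnancy weight must be positive")
        if self.parity < 0 or int(self.parity) != self.parity:
            problems.append(f"parity must be a non-negative integer, got {self.parity}")
        if self.race not in RACE_LEVELS:
            problems.append(f"unknown race level {self.race!r}")
        if self.infant_sex not in SEX_LEVELS:
            problems.append(f"unknown infant_sex level {self.infant_sex!r}")
        if not (168.0 <= self.ga_delivery <= 301.0):
            problems.append(f"ga_delivery {self.ga_delivery} d outside [168, 301]")
        for v in self.visits:
            problems.extend(v.validate())
            if v.ga >= self.ga_delivery:
                problems.append(f"visit at ga {v.ga} not before delivery {self.ga_delivery}")
        return problems


@dataclass(frozen=True)
class CenteringConvention:
    """Covariate centres defining the reference profile.

    Defaults: 280 days' gestation, height 163 cm, pre-pregnancy weight
    64 kg, nulliparous, Non-Hispanic White.
    """

    ga_center: float = 280.0
    height_center: float = 163.0
    weight_center: float = 64.0
    reference_race: str = "NH-White"
    reference_parity: int = 0

    def __post_init__(self) -> None:
        for name in ("ga_center", "height_center", "weight_center"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CenteringConvention":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        return cls(**known)


DEFAULT_CONVENTION = CenteringConvention()


class SchemaError(ValueError):
    """A required CSV column is missing."""


@dataclass
class CohortReadResult:
    """Validated records plus a row-indexed exclusion/warning log."""

    records: list[PregnancyRecord]
    exclusions: list[tuple[int, str]]
    warnings: list[tuple[int, str]]

    @property
    def n(self) -> int:
        return len(self.records)


# ------------------------------------------------------------------------
# centering and design encoding
# ------------------------------------------------------------------------

def center_covariates(record: PregnancyRecord,
                      conv: CenteringConvention = DEFAULT_CONVENTION) -> dict:
    """Deviations of the continuous covariates from the convention's centres."""
    return {
        "ga_dev": record.ga_delivery - conv.ga_center,
        "height_dev": record.maternal_height - conv.height_center,
        "weight_dev": record.maternal_weight_prepreg - conv.weight_center,
    }


def _sex_code(sex: str | None) -> float:
    # effect coding: +1 male, -1 female; None means "sex-averaged profile"
    # (used for worked percentile charts where the fetus sex is unspecified)
    if sex is None or sex == "average":
        return 0.0
    if sex == "male":
        return 1.0
    if sex == "female":
        return -1.0
    raise ValueError(f"unknown infant_sex level {sex!r}")


def build_design_row(ga_dev: float = 0.0,
                     height_dev: float = 0.0,
                     weight_dev: float = 0.0,
                     sex: str | None = "average",
                     race: str = "NH-White",
                     parity: int = 0,
                     *,
                     include_pathologic: bool = False,
                     smoking: bool = False,
                     bmi_dev: float = 0.0,
                     gdm: bool = False,
                     hypertensive: bool = False,
                     bleeding: bool = False,
                     include_paternal: bool = False,
                     paternal_height_dev: float = 0.0,
                     paternal_weight_dev: float = 0.0) -> pd.Series:
    """Encode one covariate profile as a named design row.

    Polynomial columns are exact powers of the linear deviation; race and
    parity are dummy-coded against NH-White / nulliparous; parity of two or
    more collapses into a single ``parity_2plus`` group.
    """
    if race not in RACE_LEVELS:
        raise ValueError(f"unknown race level {race!r}")
    row = {
        "intercept": 1.0,
        "ga": ga_dev, "ga2": ga_dev ** 2, "ga3": ga_dev ** 3,
        "sex": _sex_code(sex),
        "height": height_dev, "height2": height_dev ** 2, "height3": height_dev ** 3,
        "weight": weight_dev, "weight2": weight_dev ** 2, "weight3": weight_dev ** 3,
        "race_nh_black": float(race == "NH-Black"),
        "race_hispanic": float(race == "Hispanic"),
        "race_asian_pi": float(race == "Asian/PI"),
        "parity_1": float(parity == 1),
        "parity_2plus": float(parity >= 2),
    }
    if include_pathologic:
        row.update({
            "smoking": float(smoking), "bmi": bmi_dev, "gdm": float(gdm),
            "hypertensive": float(hypertensive), "bleeding": float(bleeding),
        })
    if include_paternal:
        row.update({"paternal_height": paternal_height_dev,
                    "paternal_weight": paternal_weight_dev})
    return pd.Series(row, dtype=float)


def reference_profile(conv: CenteringConvention = DEFAULT_CONVENTION, *,
                      ga: float | None = None,
                      height: float | None = None,
                      weight: float | None = None,
                      sex: str | None = "average",
                      race: str = "NH-White",
                      parity: int = 0) -> pd.Series:
    """Design row for a hypothetical profile given in natural units.

    Unspecified covariates sit at the convention's centres, so
    ``reference_profile()`` with no arguments is the reference profile
    itself (only the intercept and, for a sexed fetus, the sex code are
    nonzero among physiologic columns).
    """
    return build_design_row(
        ga_dev=(conv.ga_center if ga is None else ga) - conv.ga_center,
        height_dev=(conv.height_center if height is None else height) - conv.height_center,
        weight_dev=(conv.weight_center if weight is None else weight) - conv.weight_center,
        sex=sex, race=race, parity=parity,
    )


def records_to_frame(records: list[PregnancyRecord]) -> pd.DataFrame:
    """Flatten records (without visits) to a tidy DataFrame."""
    rows = []
    for r in records:
        rows.append({
            "maternal_height": r.maternal_height,
            "maternal_weight_prepreg": r.maternal_weight_prepreg,
            "parity": r.parity,
            "race": r.race,
            "infant_sex": r.infant_sex,
            "ga_delivery": r.ga_delivery,
            "birthweight": r.birthweight,
            "smoking": r.smoking,
            "gestational_diabetes": r.gestational_diabetes,
            "hypertensive_disease": r.hypertensive_disease,
            "antepartum_bleeding": r.antepartum_bleeding,
            "bmi": r.bmi,
            "paternal_height": r.paternal_height,
            "paternal_weight": r.paternal_weight,
            "morbidity_sga": r.morbidity_sga,
            "morbidity_lga": r.morbidity_lga,
        })
    return pd.DataFrame(rows)


def design_matrix(records: list[PregnancyRecord],
                  conv: CenteringConvention = DEFAULT_CONVENTION,
                  *,
                  include_pathologic: bool = True,
                  include_paternal: bool = False,
                  bmi_center: float | None = None) -> pd.DataFrame:
    """Stack design rows for a cohort.

    BMI enters linearly, centred at ``bmi_center`` (cohort mean when None)
    so that the intercept remains the TOW at the reference profile.
    Hypertensive disease enters as a single any-hypertension indicator.
    """
    if include_pathologic and bmi_center is None:
        bmis = [r.bmi for r in records if r.bmi is not None]
        bmi_center = float(np.mean(bmis)) if bmis else 0.0
    rows = []
    for r in records:
        dev = center_covariates(r, conv)
        rows.append(build_design_row(
            ga_dev=dev["ga_dev"], height_dev=dev["height_dev"],
            weight_dev=dev["weight_dev"], sex=r.infant_sex, race=r.race,
            parity=int(r.parity),
            include_pathologic=include_pathologic,
            smoking=r.smoking,
            bmi_dev=((r.bmi if r.bmi is not None else bmi_center) - bmi_center)
            if include_pathologic else 0.0,
            gdm=r.gestational_diabetes,
            hypertensive=(r.hypertensive_disease not in ("none", "", None)),
            bleeding=r.antepartum_bleeding,
            include_paternal=include_paternal,
            paternal_height_dev=0.0 if r.paternal_height is None
            else r.paternal_height - 177.7,
            paternal_weight_dev=0.0 if r.paternal_weight is None
            else r.paternal_weight - 84.8,
        ))
    X = pd.DataFrame(rows).reset_index(drop=True)
    X.attrs["bmi_center"] = bmi_center
    X.attrs["convention"] = conv
    return X


# ------------------------------------------------------------------------
# CSV reading / writing
# ------------------------------------------------------------------------

#: default CSV column names -> record fields; override via the schema map
DEFAULT_SCHEMA = {
    "maternal_height": "maternal_height",
    "maternal_weight_prepreg": "maternal_weight_prepreg",
    "parity": "parity",
    "race": "race",
    "infant_sex": "infant_sex",
    "ga_delivery": "ga_delivery",
    "birthweight": "birthweight",
    "smoking": "smoking",
    "gestational_diabetes": "gestational_diabetes",
    "hypertensive_disease": "hypertensive_disease",
    "antepartum_bleeding": "antepartum_bleeding",
    "bmi": "bmi",
    "paternal_height": "paternal_height",
    "paternal_weight": "paternal_weight",
    "morbidity_sga": "morbidity_sga",
    "morbidity_lga": "morbidity_lga",
}

_OPTIONAL_FIELDS = tuple(f for f in DEFAULT_SCHEMA if f not in _REQUIRED_FIELDS)


def _parse_bool(token: str, row_idx: int, col: str,
                warnings: list[tuple[int, str]]) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        if t == "":
            warnings.append((row_idx, f"missing pathologic flag {col!r} treated as absent"))
        return False
    raise ValueError(f"unparseable boolean token {token!r} in column {col!r}")


def read_cohort(path, schema: dict | None = None,
                ga_range: tuple[float, float] | None = (259.0, 294.0)) -> CohortReadResult:
    """Read and validate a delivery-level cohort CSV.

    Rows violating record invariants, or with a missing physiologic
    covariate, are rejected with a row-indexed message (row index counts
    data rows from 1).  ``ga_range`` is the half-open delivery-GA inclusion
    window in days; the default keeps 37-41 completed weeks.  Missing
    pathologic flags are treated as absent with a logged warning.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    records: list[PregnancyRecord] = []
    exclusions: list[tuple[int, str]] = []
    warnings: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("empty file: no header row")
        for fieldname in _REQUIRED_FIELDS:
            if colmap[fieldname] not in reader.fieldnames:
                raise SchemaError(f"missing required column {colmap[fieldname]!r}")
        for i, row in enumerate(reader, start=1):
            try:
                rec = _parse_row(row, colmap, i, warnings)
            except ValueError as exc:
                exclusions.append((i, str(exc)))
                continue
            problems = rec.validate()
            if problems:
                exclusions.append((i, "; ".join(problems)))
                continue
            if ga_range is not None and not (ga_range[0] <= rec.ga_delivery < ga_range[1]):
                exclusions.append(
                    (i, f"ga_delivery {rec.ga_delivery} outside analysis window {ga_range}"))
                continue
            records.append(rec)
    return CohortReadResult(records, exclusions, warnings)


def _parse_row(row: dict, colmap: dict, idx: int,
               warnings: list[tuple[int, str]]) -> PregnancyRecord:
    def get(fieldname):
        return row.get(colmap[fieldname], "")

    for fieldname in _REQUIRED_FIELDS:
        if str(get(fieldname)).strip() == "":
            raise ValueError(f"missing physiologic covariate {fieldname!r}")

    race_token = str(get("race")).strip().lower()
    if race_token not in _RACE_ALIASES:
        raise ValueError(f"unparseable race level {get('race')!r}")
    sex_token = str(get("infant_sex")).strip().lower()
    if sex_token not in _SEX_ALIASES:
        raise ValueError(f"unparseable infant_sex level {get('infant_sex')!r}")

    def opt_float(fieldname):
        v = str(get(fieldname)).strip()
        return float(v) if v else None

    def opt_bool(fieldname):
        v = str(get(fieldname))
        return _parse_bool(v, idx, colmap[fieldname], warnings)

    morb_sga = str(get("morbidity_sga")).strip()
    morb_lga = str(get("morbidity_lga")).strip()
    return PregnancyRecord(
        maternal_height=float(get("maternal_height")),
        maternal_weight_prepreg=float(get("maternal_weight_prepreg")),
        parity=int(float(get("parity"))),
        race=_RACE_ALIASES[race_token],
        infant_sex=_SEX_ALIASES[sex_token],
        ga_delivery=float(get("ga_delivery")),
        birthweight=float(get("birthweight")),
        smoking=opt_bool("smoking"),
        gestational_diabetes=opt_bool("gestational_diabetes"),
        hypertensive_disease=(str(get("hypertensive_disease")).strip() or "none"),
        antepartum_bleeding=opt_bool("antepartum_bleeding"),
        bmi=opt_float("bmi"),
        paternal_height=opt_float("paternal_height"),
        paternal_weight=opt_float("paternal_weight"),
        morbidity_sga=(_parse_bool(morb_sga, idx, "morbidity_sga", warnings)
                       if morb_sga else None),
        morbidity_lga=(_parse_bool(morb_lga, idx, "morbidity_lga", warnings)
                       if morb_lga else None),
    )


def write_cohort(records: list[PregnancyRecord], path) -> None:
    """Write records to CSV in the default schema (UTF-8, comma, header)."""
    cols = list(DEFAULT_SCHEMA)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow([
                r.maternal_height, r.maternal_weight_prepreg, r.parity, r.race,
                r.infant_sex, r.ga_delivery, r.birthweight,
                int(r.smoking), int(r.gestational_diabetes),
                r.hypertensive_disease, int(r.antepartum_bleeding),
                "" if r.bmi is None else repr(r.bmi),
                "" if r.paternal_height is None else r.paternal_height,
                "" if r.paternal_weight is None else r.paternal_weight,
                "" if r.morbidity_sga is None else int(r.morbidity_sga),
                "" if r.morbidity_lga is None else int(r.morbidity_lga),
            ])


def read_visits(path, records: list[PregnancyRecord] | None = None) -> pd.DataFrame:
    """Read a longitudinal visits CSV (subject, ga, hc, ac, fl, efw).

    When ``records`` is given, visits are attached in subject order
    (``subject`` is the 0-based index into the record list).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("subject", "ga"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    if records is not None:
        for r in records:
            r.visits = []
        for _, row in frame.iterrows():
            subj = int(row["subject"])
            if 0 <= subj < len(records):
                records[subj].visits.append(UltrasoundVisit(
                    ga=float(row["ga"]),
                    hc=None if pd.isna(row.get("hc")) else float(row["hc"]),
                    ac=None if pd.isna(row.get("ac")) else float(row["ac"]),
                    fl=None if pd.isna(row.get("fl")) else float(row["fl"]),
                    efw=None if pd.isna(row.get("efw")) else float(row["efw"]),
                ))
    return frame


def write_visits(records: list[PregnancyRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "ga", "hc", "ac", "fl", "efw"])
        for i, r in enumerate(records):
            for v in r.visits:
                writer.writerow([
                    i, v.ga,
                    "" if v.hc is None else v.hc,
                    "" if v.ac is None else v.ac,
                    "" if v.fl is None else v.fl,
                    "" if v.efw is None else repr(v.efw),
                ])
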