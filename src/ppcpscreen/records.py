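"""Literature-record domain model, quality-index scoring and plant typology.

A *record* is one chemical observed at one wastewater treatment plant (WWTP)
in one source study.  Each record carries three data-quality sub-scores
(molecule identification, removal-efficiency data, general plant information),
each an integer 0-2.  Their sum (0-6) is the quality index (QI), mapped onto
four classes; records in the lowest class are excluded from every downstream
stage, and chemicals whose every record is excluded drop out of the roster.

Plants are classified into two treatment tiers: WWTP1 (primary/secondary
treatment only) and WWTP2 (tertiary or advanced treatment present).  When the
declared treatment level is missing, the classification falls back on the
reported technology tokens, with a worst-case rule: a single ambiguous
tertiary technology is not enough evidence for WWTP2.
"""

from __future__ import annotations

import enum
from collections.abc import Callable, Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from ._errors import SchemaError

__all__ = [
    "QIClass",
    "PlantType",
    "ChemicalIdentity",
    "WWTPInfo",
    "QualityScores",
    "ConcentrationMeasurement",
    "MassBalanceInputs",
    "LiteratureRecord",
    "score_quality",
    "filter_records",
    "classify_wwtp",
    "canonicalize_smiles",
    "load_records_csv",
    "records_to_frame",
    "DEFAULT_TERTIARY_KEYWORDS",
]


class QIClass(str, enum.Enum):
    LOW = "Low"
    MODERATE = "Moderate"
    GOOD = "Good"
    EXCELLENT = "Excellent"


class PlantType(str, enum.Enum):
    WWTP1 = "WWTP1"
    WWTP2 = "WWTP2"


CONTINENTS = ("Europe", "Asia", "America", "Africa", "Oceania")

#: Technology tokens taken as evidence of tertiary/advanced treatment.
#: Config-exposed: pass a custom list to :func:`classify_wwtp`.
DEFAULT_TERTIARY_KEYWORDS = (
    "aop",
    "advanced oxidation",
    "disinfection",
    "sand filtration",
    "chemical nutrient removal",
    "ozonation",
    "uv",
    "activated carbon",
)


def canonicalize_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string through RDKit when available.

    The canonicalizer is a pluggable external dependency with one contract:
    idempotence (``canonical(canonical(s)) == canonical(s)``).  Without RDKit
    the string is returned whitespace-stripped, which trivially satisfies the
    contract but performs no chemistry.
    """
    s = smiles.strip()
    if not s:
        raise ValueError("empty SMILES string")
    try:
        from rdkit import Chem  # noqa: PLC0415 - optional heavy import
    except ImportError:
        return s
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


class ChemicalIdentity(BaseModel):
    """Identity of one curated chemical (salts as the neutral parent form)."""

    cas: str
    name: str
    smiles: str
    use_class: str = ""
    molecular_weight: float = Field(gt=0)

    @field_validator("smiles")
    @classmethod
    def _non_empty_smiles(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("smiles must be non-empty after curation")
        return v.strip()


class WWTPInfo(BaseModel):
    plant_id: str
    continent: str
    declared_level: str | None = None
    technologies: tuple[str, ...] = ()
    classification: PlantType | None = None

    @field_validator("continent")
    @classmethod
    def _known_continent(cls, v: str) -> str:
        if v not in CONTINENTS:
            raise ValueError(f"continent must be one of {CONTINENTS}, got {v!r}")
        return v


class QualityScores(BaseModel):
    """The three 0-2 sub-scores, their 0-6 total and the QI class."""

    molecule_id_score: int = Field(ge=0, le=2)
    re_data_score: int = Field(ge=0, le=2)
    general_info_score: int = Field(ge=0, le=2)
    total: int = Field(ge=0, le=6)
    qi_class: QIClass

    @model_validator(mode="after")
    def _consistent(self) -> "QualityScores":
        if self.total != (self.molecule_id_score + self.re_data_score
                          + self.general_info_score):
            raise ValueError("total must equal the sum of the sub-scores")
        if self.qi_class is not _qi_class_for_total(self.total):
            raise ValueError("qi_class inconsistent with total")
        return self


class ConcentrationMeasurement(BaseModel):
    """One concentration value in ng/L; censored values carry no number."""

    value: float | None = Field(default=None, ge=0)
    censored: bool = False
    statistic: str = "single"  # median | mean | single

    @model_validator(mode="after")
    def _censoring(self) -> "ConcentrationMeasurement":
        if self.censored != (self.value is None):
            raise ValueError("censored=True exactly when value is absent")
        return self


class MassBalanceInputs(BaseModel):
    """Inputs for the load-based removal equation (all non-negative, F > 0)."""

    ci: float = Field(ge=0, description="influent concentration, ng/L")
    ce: float = Field(ge=0, description="effluent concentration, ng/L")
    cs: float = Field(ge=0, description="sludge concentration, ng/g ww")
    f: float = Field(gt=0, description="influent flow, L/d")
    tsp: float = Field(ge=0, description="total sludge production, g/d ww")


class LiteratureRecord(BaseModel):
    chemical: ChemicalIdentity
    plant: WWTPInfo
    source_id: str
    quality: QualityScores
    influent: ConcentrationMeasurement | None = None
    effluent: ConcentrationMeasurement | None = None
    mass_balance: MassBalanceInputs | None = None
    reported_re: float | None = None
    effluent_ca: float | None = Field(default=None, ge=0)


def _qi_class_for_total(total: int) -> QIClass:
    # Fixed mapping: 0-1 Low, 2-3 Moderate, 4-5 Good, 6 Excellent.
    if total <= 1:
        return QIClass.LOW
    if total <= 3:
        return QIClass.MODERATE
    if total <= 5:
        return QIClass.GOOD
    return QIClass.EXCELLENT


def score_quality(molecule_id_score: int, re_data_score: int,
                  general_info_score: int) -> QualityScores:
    """Combine the three sub-scores into a QualityScores value.

    Each sub-score must be in {0, 1, 2}; the total is their sum and the QI
    class follows the fixed 0-6 mapping.
    """
    for name, v in (("molecule_id_score", molecule_id_score),
                    ("re_data_score", re_data_score),
                    ("general_info_score", general_info_score)):
        if v not in (0, 1, 2):
            raise ValueError(f"{name} must be in {{0, 1, 2}}, got {v!r}")
    total = molecule_id_score + re_data_score + general_info_score
    return QualityScores(
        molecule_id_score=molecule_id_score,
        re_data_score=re_data_score,
        general_info_score=general_info_score,
        total=total,
        qi_class=_qi_class_for_total(total),
    )


def filter_records(
    records: Sequence[LiteratureRecord],
) -> tuple[list[LiteratureRecord], list[LiteratureRecord]]:
    """Split records into (kept, excluded) by the QI-Low rule.

    Records in the lowest quality class are excluded; the excluded list is
    retained for reporting.  Chemicals whose every record is excluded are
    thereby absent from the kept roster.
    """
    kept = [r for r in records if r.quality.qi_class is not QIClass.LOW]
    excluded = [r for r in records if r.quality.qi_class is QIClass.LOW]
    return kept, excluded


def roster(records: Iterable[LiteratureRecord]) -> list[str]:
    """CAS numbers of chemicals with at least one kept record, sorted."""
    return sorted({r.chemical.cas for r in records})


def classify_wwtp(
    declared_level: str | None,
    technologies: Sequence[str] = (),
    *,
    tertiary_keywords: Sequence[str] = DEFAULT_TERTIARY_KEYWORDS,
) -> PlantType:
    """Classify a plant as WWTP1 or WWTP2.

    A declared tertiary/advanced level decides immediately; a declared
    primary or secondary level gives WWTP1.  Otherwise the technology tokens
    are matched against ``tertiary_keywords``: two or more distinct tertiary
    technologies, or an explicit "tertiary" token, give WWTP2.  A single
    tertiary technology with an unclear level is treated as insufficient
    evidence (worst case, WWTP1), as is no evidence at all.
    """
    level = declared_level.strip().lower() if declared_level else None
    tokens = [t.strip().lower() for t in technologies if t and t.strip()]
    if not level and not tokens:
        raise ValueError("need a declared level or at least one technology token")
    if level:
        if "tertiary" in level or "advanced" in level:
            return PlantType.WWTP2
        if level in ("primary", "secondary"):
            return PlantType.WWTP1
    if any(t == "tertiary" for t in tokens):
        return PlantType.WWTP2
    keywords = [k.lower() for k in tertiary_keywords]
    hits = {k for k in keywords if any(k in t for t in tokens)}
    if len(hits) >= 2:
        return PlantType.WWTP2
    return PlantType.WWTP1


def preferred_measurement(
    candidates: Sequence[ConcentrationMeasurement],
) -> ConcentrationMeasurement | None:
    """Pick the preferred measurement among candidates: median > mean > single."""
    order = {"median": 0, "mean": 1, "single": 2}
    usable = [c for c in candidates if c is not None]
    if not usable:
        return None
    return min(usable, key=lambda c: order.get(c.statistic, 3))


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

RECORDS_REQUIRED_COLUMNS = (
    "cas", "name", "smiles", "use_class", "mw", "source_id", "plant_id",
    "continent", "declared_level", "technologies",
    "molecule_id_score", "re_data_score", "general_info_score",
)

RECORDS_OPTIONAL_COLUMNS = (
    "c_infl", "c_infl_censored", "c_infl_stat",
    "c_effl", "c_effl_censored", "c_effl_stat",
    "ci", "ce", "cs", "f", "tsp", "reported_re",
)


def _opt_float(row: pd.Series, col: str) -> float | None:
    v = row.get(col)
    if v is None or pd.isna(v):
        return None
    return float(v)


def _measurement(row: pd.Series, prefix: str) -> ConcentrationMeasurement | None:
    value = _opt_float(row, prefix)
    censored = bool(row.get(f"{prefix}_censored", False))
    stat = row.get(f"{prefix}_stat")
    stat = str(stat) if stat is not None and not pd.isna(stat) else "single"
    if value is None and not censored:
        return None
    return ConcentrationMeasurement(
        value=None if censored else value, censored=censored, statistic=stat
    )


def _mass_balance(row: pd.Series) -> MassBalanceInputs | None:
    vals = {c: _opt_float(row, c) for c in ("ci", "ce", "cs", "f", "tsp")}
    if any(v is None for v in vals.values()):
        return None
    return MassBalanceInputs(**vals)


def load_records_csv(
    path,
    *,
    canonicalizer: Callable[[str], str] | None = None,
    tertiary_keywords: Sequence[str] = DEFAULT_TERTIARY_KEYWORDS,
) -> list[LiteratureRecord]:
    """Parse a literature-records CSV into scored, plant-classified records.

    Raises :class:`SchemaError` naming the file, row and column on any
    missing required column or invalid cell.
    """
    df = pd.read_csv(path)
    for col in RECORDS_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError("missing required column", source=str(path),
                              column=col)
    canon = canonicalizer or (lambda s: s.strip())
    out: list[LiteratureRecord] = []
    for i, row in df.iterrows():
        try:
            chem = ChemicalIdentity(
                cas=str(row["cas"]),
                name=str(row["name"]),
                smiles=canon(str(row["smiles"])),
                use_class=str(row["use_class"]),
                molecular_weight=float(row["mw"]),
            )
            level = row["declared_level"]
            level = None if pd.isna(level) else str(level)
            techs_raw = row["technologies"]
            techs = tuple(
                t.strip() for t in str(techs_raw).split(";") if t.strip()
            ) if not pd.isna(techs_raw) else ()
            plant = WWTPInfo(
                plant_id=str(row["plant_id"]),
                continent=str(row["continent"]),
                declared_level=level,
                technologies=techs,
                classification=classify_wwtp(
                    level, techs, tertiary_keywords=tertiary_keywords
                ),
            )
            quality = score_quality(
                int(row["molecule_id_score"]),
                int(row["re_data_score"]),
                int(row["general_info_score"]),
            )
            effl = _measurement(row, "c_effl")
            rec = LiteratureRecord(
                chemical=chem,
                plant=plant,
                source_id=str(row["source_id"]),
                quality=quality,
                influent=_measurement(row, "c_infl"),
                effluent=effl,
                mass_balance=_mass_balance(row),
                reported_re=_opt_float(row, "reported_re"),
                effluent_ca=(effl.value if effl is not None else None),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(str(exc), source=str(path), row=int(i)) from exc
        out.append(rec)
    return out


def records_to_frame(records: Sequence[LiteratureRecord]) -> pd.DataFrame:
    """Flatten records back to the tabular interface (one row per record)."""
    rows = []
    for r in records:
        rows.append({
            "cas": r.chemical.cas,
            "name": r.chemical.name,
            "smiles": r.chemical.smiles,
            "use_class": r.chemical.use_class,
            "mw": r.chemical.molecular_weight,
            "source_id": r.source_id,
            "plant_id": r.plant.plant_id,
            "continent": r.plant.continent,
            "plant_type": r.plant.classification.value
            if r.plant.classification else "",
            "qi_total": r.quality.total,
            "qi_class": r.quality.qi_class.value,
            "reported_re": r.reported_re,
        })
    return pd.DataFrame(rows)
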