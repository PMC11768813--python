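"""PMT/PBT/ED hazard screening from aggregated QSAR predictions.

Per-chemical property predictions (multiple models per endpoint, each with an
applicability-domain flag) are aggregated into one value per endpoint:
experimental values take priority; otherwise in-domain regulatory-level
predictions are averaged.  For Log Koc, when the MCI-based model is out of
its domain the soil-sorption model alone is used as the fallback.

Aggregated values are compared against a named threshold profile:

=============  ==========================  =====================
flag           criterion (conservative)    criterion (EU 2023)
=============  ==========================  =====================
pP / pvP       BIOWIN3 < 2.25 and a fast-  same
               biodegradation probability
               (BIOWIN2 or 6) < 0.5
pB             Log Kow > 4.5 or            same
               Log BCF > 3.3
pvB            Log BCF > 3.7               same
pM             Log Koc < 4                 Log Koc < 3
pvM            Log Koc < 3                 Log Koc < 2
pT             min EC50/LC50 < 0.1 mg/L    same (0.01 variant)
pED            ER, AR or hTTR binding      same
=============  ==========================  =====================

All comparisons are strict.  Combined labels: PBT = pP & pB & pT, PMT = pP &
pM & pT, vPvB = pvP & pvB, vPvM = pvP & pvM.  The screening persistence rule
cannot distinguish P from vP, so the verdict stores one joint persistence
flag and asserts the very-persistent flag only when a caller supplies it
explicitly; vPvB/vPvM therefore never fire from screening predictions alone.

Toxicity models predict -log10 concentrations (pEC50/pLC50) in mol/L or
mmol/L; they are converted to mg/L through the molecular weight before the
minimum across trophic levels is taken.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from ._errors import ConfigError, SchemaError

__all__ = [
    "ModelPrediction",
    "PropertyBundle",
    "ThresholdProfile",
    "HazardFlags",
    "HazardVerdict",
    "aggregate_endpoint",
    "convert_toxicity",
    "flag_persistence",
    "flag_bioaccumulation",
    "flag_mobility",
    "flag_toxicity",
    "flag_ed",
    "combine_labels",
    "assess",
    "assess_table",
    "load_profiles_yaml",
    "BUILTIN_PROFILES",
]

#: model_id of the MCI-based Koc model and its fallback.
KOCWIN_MCI = "KOCWIN_MCI"
SOIL_KOC = "SOIL_KOC"

#: Endpoints whose sole model is catalogued at the additional screening level
#: but which the regulatory criteria use directly.
_LEVELS_BY_ENDPOINT: dict[str, tuple[str, ...]] = {
    "log_bcf": ("L1", "L2"),
}
_DEFAULT_LEVELS = ("L1",)

#: L2 model ids whose predictions only annotate the verdict.
ANNOTATION_MODELS = ("GHLI", "PBT_INDEX")


class ModelPrediction(BaseModel):
    model_id: str
    endpoint: str
    value: float
    units: str = "log10"
    in_ad: bool = True
    screening_level: str = "L1"

    @model_validator(mode="after")
    def _finite_probability(self) -> "ModelPrediction":
        if self.units == "probability" and not (0.0 <= self.value <= 1.0):
            raise ValueError("probability endpoint outside [0, 1]")
        return self


class PropertyBundle(BaseModel):
    """Everything known about one chemical's predicted properties."""

    cas: str
    name: str = ""
    molecular_weight: float = Field(gt=0)
    exp_log_kow: float | None = None
    exp_log_koc: float | None = None
    predictions: list[ModelPrediction] = Field(default_factory=list)
    er_binder: bool = False
    ar_binder: bool = False
    httr_binder: str = "none"  # none | weak | moderate | strong


class ThresholdProfile(BaseModel):
    """A named, versioned set of P/B/M/T screening cut-offs.

    ``conservative_2019`` uses the pre-2023 screening values (Log Koc < 4 for
    M, < 3 for vM); ``eu_2023`` the tightened mobility cut-offs (< 3 / < 2)
    proposed for the pH 4-9 range.  The toxicity cut-off defaults to the less
    strict 0.1 mg/L (worst-case screening); 0.01 mg/L is the strict variant.
    ``fast_probability_rule`` controls how the two fast-biodegradation
    probabilities combine within the persistence rule ("or" is standard).
    """

    name: str
    p_biowin3_max: float = 2.25
    p_fastprob_max: float = 0.5
    b_logkow_min: float = 4.5
    b_logbcf_min: float = 3.3
    vb_logbcf_min: float = 3.7
    m_logkoc_max: float = 4.0
    vm_logkoc_max: float = 3.0
    t_ec50_max_mg_l: float = 0.1
    fast_probability_rule: str = "or"  # "or" | "and"

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdProfile":
        if not self.vm_logkoc_max < self.m_logkoc_max:
            raise ValueError("vM cut-off must be below the M cut-off")
        if not self.vb_logbcf_min > self.b_logbcf_min:
            raise ValueError("vB cut-off must be above the B cut-off")
        if self.fast_probability_rule not in ("or", "and"):
            raise ValueError("fast_probability_rule must be 'or' or 'and'")
        return self

    @classmethod
    def conservative_2019(cls, **overrides) -> "ThresholdProfile":
        return cls(name="conservative_2019", m_logkoc_max=4.0,
                   vm_logkoc_max=3.0, **overrides)

    @classmethod
    def eu_2023(cls, **overrides) -> "ThresholdProfile":
        return cls(name="eu_2023", m_logkoc_max=3.0, vm_logkoc_max=2.0,
                   **overrides)


BUILTIN_PROFILES = ("conservative_2019", "eu_2023")


def get_profile(name: str, **overrides) -> ThresholdProfile:
    if name == "conservative_2019":
        return ThresholdProfile.conservative_2019(**overrides)
    if name == "eu_2023":
        return ThresholdProfile.eu_2023(**overrides)
    raise ConfigError(
        f"unknown threshold profile {name!r}; available: "
        + ", ".join(BUILTIN_PROFILES)
    )


def load_profiles_yaml(path) -> dict[str, ThresholdProfile]:
    """Load user profiles from YAML ({name: {field: value, ...}, ...}).

    Fields omitted in the YAML fall back to the built-in defaults; a profile
    whose name matches a built-in starts from that built-in's values.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError(f"profile YAML must map names to settings: {path}")
    out: dict[str, ThresholdProfile] = {}
    for name, settings in raw.items():
        settings = dict(settings or {})
        settings.pop("name", None)
        if name in BUILTIN_PROFILES:
            out[name] = get_profile(name, **settings)
        else:
            out[name] = ThresholdProfile(name=name, **settings)
    return out


@dataclass(frozen=True)
class HazardFlags:
    """Screening flags for one chemical under one profile.

    ``p`` is the joint "potentially P or vP" flag; ``vp`` is only True when
    very-persistence is explicitly asserted (never from the screening rule).
    None means the endpoint was unassessable (missing/out-of-domain inputs).
    """

    p: bool | None = None
    vp: bool = False
    b: bool | None = None
    vb: bool | None = None
    m: bool | None = None
    vm: bool | None = None
    t: bool | None = None
    ed: bool | None = None


@dataclass(frozen=True)
class HazardVerdict:
    cas: str
    profile_name: str
    flags: HazardFlags
    labels: frozenset[str]
    provenance: dict[str, tuple[float | None, str]] = field(default_factory=dict)
    annotations: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _in_ad_values(bundle: PropertyBundle, endpoint: str) -> list[ModelPrediction]:
    levels = _LEVELS_BY_ENDPOINT.get(endpoint, _DEFAULT_LEVELS)
    return [p for p in bundle.predictions
            if p.endpoint == endpoint and p.in_ad
            and p.screening_level in levels]


def aggregate_endpoint(
    bundle: PropertyBundle, endpoint: str
) -> tuple[float | None, str]:
    """One value per partition endpoint: (value, source).

    Source is "experimental", "mean-of-models", "fallback-model" or "absent".
    For log_koc the soil-sorption model alone is used when the MCI model's
    prediction is out of its applicability domain.
    """
    exp = {"log_kow": bundle.exp_log_kow, "log_koc": bundle.exp_log_koc}
    if exp.get(endpoint) is not None:
        return exp[endpoint], "experimental"
    usable = _in_ad_values(bundle, endpoint)
    if endpoint == "log_koc":
        mci_out = any(
            p.model_id == KOCWIN_MCI and not p.in_ad
            for p in bundle.predictions if p.endpoint == endpoint
        )
        mci_in = any(p.model_id == KOCWIN_MCI for p in usable)
        if mci_out and not mci_in:
            soil = [p for p in usable if p.model_id == SOIL_KOC]
            if soil:
                return soil[0].value, "fallback-model"
            return None, "absent"
    if not usable:
        return None, "absent"
    return sum(p.value for p in usable) / len(usable), "mean-of-models"


def convert_toxicity(p_value: float, units: str, mw: float) -> float:
    """Convert a -log10 molar toxicity (pEC50/pLC50) to mg/L.

    mol/L:  C = 10**(-p) * mw * 1000 mg/L;  mmol/L:  C = 10**(-p) * mw mg/L.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if units == "mol/L":
        return 10.0 ** (-p_value) * mw * 1000.0
    if units == "mmol/L":
        return 10.0 ** (-p_value) * mw
    raise ValueError(f"unknown toxicity units {units!r} (want mol/L or mmol/L)")


def toxicity_values_mg_l(bundle: PropertyBundle) -> dict[str, list[float]]:
    """In-domain regulatory toxicity predictions converted to mg/L.

    Keyed by endpoint token (e.g. "plc50_fish", "pec50_algae").
    """
    out: dict[str, list[float]] = {}
    for p in bundle.predictions:
        if not p.endpoint.startswith(("plc50", "pec50")):
            continue
        if not p.in_ad or p.screening_level != "L1":
            continue
        out.setdefault(p.endpoint, []).append(
            convert_toxicity(p.value, p.units, bundle.molecular_weight)
        )
    return out


# ---------------------------------------------------------------------------
# Flag rules (all comparisons strict, as printed)
# ---------------------------------------------------------------------------

def flag_persistence(
    biowin2: float | None,
    biowin3: float | None,
    biowin6: float | None,
    profile: ThresholdProfile,
) -> bool | None:
    """Joint pP/pvP flag from the biodegradability battery.

    Requires the ultimate-timeframe score (BIOWIN3) and at least one
    fast-biodegradation probability; otherwise unassessable (None).
    """
    fast = [v for v in (biowin2, biowin6) if v is not None]
    if biowin3 is None or not fast:
        return None
    hits = [v < profile.p_fastprob_max for v in fast]
    fast_ok = all(hits) if profile.fast_probability_rule == "and" else any(hits)
    return biowin3 < profile.p_biowin3_max and fast_ok


def flag_bioaccumulation(
    log_kow: float | None,
    log_bcf: float | None,
    profile: ThresholdProfile,
) -> tuple[bool | None, bool | None]:
    """(pB, pvB) from Log Kow and Log BCF; None where unassessable."""
    if log_kow is None and log_bcf is None:
        return None, None
    b = ((log_kow is not None and log_kow > profile.b_logkow_min)
         or (log_bcf is not None and log_bcf > profile.b_logbcf_min))
    vb = None if log_bcf is None else log_bcf > profile.vb_logbcf_min
    return b, vb


def flag_mobility(
    log_koc: float | None, profile: ThresholdProfile
) -> tuple[bool | None, bool | None]:
    """(pM, pvM) from Log Koc; lower Koc means more mobile."""
    if log_koc is None:
        return None, None
    return log_koc < profile.m_logkoc_max, log_koc < profile.vm_logkoc_max


def flag_toxicity(
    tox_values_mg_l: Iterable[float], profile: ThresholdProfile
) -> tuple[bool | None, float | None]:
    """(pT, minimum mg/L) over all available trophic-level values."""
    values = list(tox_values_mg_l)
    if not values:
        return None, None
    m = min(values)
    return m < profile.t_ec50_max_mg_l, m


def flag_ed(er_binder: bool, ar_binder: bool, httr_binder: str) -> bool:
    """Potential endocrine disruptor: any receptor/transporter binding."""
    return bool(er_binder or ar_binder
                or httr_binder in ("weak", "moderate", "strong"))


def combine_labels(flags: HazardFlags) -> frozenset[str]:
    """Combined hazard labels from the screening flags.

    Unassessable endpoints (None) propagate as not-flagged: removing a true
    flag can never add a label.
    """
    labels = set()
    if flags.p and flags.b and flags.t:
        labels.add("PBT")
    if flags.p and flags.m and flags.t:
        labels.add("PMT")
    if flags.vp and flags.vb:
        labels.add("vPvB")
    if flags.vp and flags.vm:
        labels.add("vPvM")
    return frozenset(labels)


def assess(bundle: PropertyBundle, profile: ThresholdProfile) -> HazardVerdict:
    """Aggregate a chemical's predictions and apply one threshold profile."""
    prov: dict[str, tuple[float | None, str]] = {}

    def biowin(model_id: str) -> float | None:
        vals = [p.value for p in bundle.predictions
                if p.model_id == model_id and p.in_ad]
        return vals[0] if vals else None

    b2, b3, b6 = biowin("BIOWIN2"), biowin("BIOWIN3"), biowin("BIOWIN6")
    for mid, v in (("BIOWIN2", b2), ("BIOWIN3", b3), ("BIOWIN6", b6)):
        prov[mid.lower()] = (v, "model" if v is not None else "absent")

    kow, kow_src = aggregate_endpoint(bundle, "log_kow")
    koc, koc_src = aggregate_endpoint(bundle, "log_koc")
    bcf, bcf_src = aggregate_endpoint(bundle, "log_bcf")
    prov["log_kow"] = (kow, kow_src)
    prov["log_koc"] = (koc, koc_src)
    prov["log_bcf"] = (bcf, bcf_src)

    tox = [v for vs in toxicity_values_mg_l(bundle).values() for v in vs]
    p = flag_persistence(b2, b3, b6, profile)
    b, vb = flag_bioaccumulation(kow, bcf, profile)
    m, vm = flag_mobility(koc, profile)
    t, tox_min = flag_toxicity(tox, profile)
    prov["tox_min_mg_l"] = (tox_min,
                            "min-of-models" if tox_min is not None else "absent")
    ed = flag_ed(bundle.er_binder, bundle.ar_binder, bundle.httr_binder)

    flags = HazardFlags(p=p, vp=False, b=b, vb=vb, m=m, vm=vm, t=t, ed=ed)
    annotations = tuple(
        f"{pr.model_id}={pr.value:g}" for pr in bundle.predictions
        if pr.model_id in ANNOTATION_MODELS and pr.in_ad
    )
    return HazardVerdict(
        cas=bundle.cas,
        profile_name=profile.name,
        flags=flags,
        labels=combine_labels(flags),
        provenance=prov,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Tabular interface
# ---------------------------------------------------------------------------

PREDICTIONS_REQUIRED_COLUMNS = (
    "cas", "model_id", "endpoint", "value", "units", "in_ad", "screening_level",
)


def bundles_from_tables(
    predictions: pd.DataFrame,
    *,
    chemicals: pd.DataFrame | None = None,
    experimental: pd.DataFrame | None = None,
    ed_flags: pd.DataFrame | None = None,
    source: str = "predictions",
) -> list[PropertyBundle]:
    """Assemble per-chemical PropertyBundles from the CSV-shaped tables.

    ``chemicals`` must provide cas -> mw (and optionally name); ``experimental``
    has columns (cas, endpoint, value); ``ed_flags`` has columns
    (cas, er_binder, ar_binder, httr_binder).
    """
    for col in PREDICTIONS_REQUIRED_COLUMNS:
        if col not in predictions.columns:
            raise SchemaError("missing required column", source=source,
                              column=col)
    mw_map: dict[str, float] = {}
    name_map: dict[str, str] = {}
    if chemicals is not None:
        for _, row in chemicals.iterrows():
            mw_map[str(row["cas"])] = float(row["mw"])
            if "name" in chemicals.columns:
                name_map[str(row["cas"])] = str(row["name"])
    exp_map: dict[str, dict[str, float]] = {}
    if experimental is not None and len(experimental):
        for _, row in experimental.iterrows():
            exp_map.setdefault(str(row["cas"]), {})[str(row["endpoint"])] = (
                float(row["value"])
            )
    ed_map: dict[str, tuple[bool, bool, str]] = {}
    if ed_flags is not None and len(ed_flags):
        for _, row in ed_flags.iterrows():
            ed_map[str(row["cas"])] = (
                bool(row["er_binder"]), bool(row["ar_binder"]),
                str(row["httr_binder"]),
            )
    bundles = []
    for cas, grp in predictions.groupby("cas", sort=True):
        cas = str(cas)
        preds = [
            ModelPrediction(
                model_id=str(r["model_id"]), endpoint=str(r["endpoint"]),
                value=float(r["value"]), units=str(r["units"]),
                in_ad=bool(r["in_ad"]),
                screening_level=str(r["screening_level"]),
            )
            for _, r in grp.iterrows()
        ]
        er, ar, httr = ed_map.get(cas, (False, False, "none"))
        exp = exp_map.get(cas, {})
        bundles.append(PropertyBundle(
            cas=cas,
            name=name_map.get(cas, ""),
            molecular_weight=mw_map.get(cas, float("nan"))
            if cas in mw_map else _mw_from_group(grp, cas),
            exp_log_kow=exp.get("log_kow"),
            exp_log_koc=exp.get("log_koc"),
            predictions=preds,
            er_binder=er, ar_binder=ar, httr_binder=httr,
        ))
    return bundles


def _mw_from_group(grp: pd.DataFrame, cas: str) -> float:
    if "mw" in grp.columns:
        return float(grp["mw"].iloc[0])
    raise SchemaError("molecular weight unavailable for chemical",
                      column="mw", source=f"cas={cas}")


def assess_table(
    bundles: Sequence[PropertyBundle],
    profiles: Sequence[ThresholdProfile],
) -> pd.DataFrame:
    """Verdicts for every bundle under every profile, one row each."""
    rows = []
    for bundle in bundles:
        for profile in profiles:
            v = assess(bundle, profile)
            f = v.flags
            rows.append({
                "cas": v.cas,
                "name": bundle.name,
                "profile": v.profile_name,
                "pP": f.p, "pB": f.b, "pvB": f.vb,
                "pM": f.m, "pvM": f.vm, "pT": f.t, "pED": f.ed,
                "labels": "|".join(sorted(v.labels)),
                "log_kow": v.provenance["log_kow"][0],
                "log_kow_source": v.provenance["log_kow"][1],
                "log_koc": v.provenance["log_koc"][0],
                "log_koc_source": v.provenance["log_koc"][1],
                "log_bcf": v.provenance["log_bcf"][0],
                "tox_min_mg_l": v.provenance["tox_min_mg_l"][0],
                "annotations": ";".join(v.annotations),
            })
    return pd.DataFrame(rows, columns=[
        "cas", "name", "profile", "pP", "pB", "pvB", "pM", "pvM", "pT", "pED",
        "labels", "log_kow", "log_kow_source", "log_koc", "log_koc_source",
        "log_bcf", "tox_min_mg_l", "annotations",
    ])
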