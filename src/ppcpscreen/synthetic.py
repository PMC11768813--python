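"""Synthetic literature records and property predictions with known truth.

The generator emulates the inputs of the screening pipeline — literature-style
record tables, per-model property predictions and measured effluent
concentrations — for a roster of synthetic chemicals drawn from four hazard
archetypes:

``pmt``
    persistent, mobile, toxic: low biodegradation scores, low Log Koc,
    sub-0.1 mg/L toxicity, unremarkable Kow/BCF.
``pbt``
    persistent, bioaccumulative, toxic: high Log Kow and Log BCF, high
    Log Koc (not mobile), sub-0.1 mg/L toxicity.
``ed_only``
    an endocrine-activity flag with benign partitioning/degradation values.
``benign``
    clears no screening threshold.

Each archetype's true property values are drawn from narrow normals whose
means sit several prediction-noise standard deviations away from every
threshold the archetype is designed to clear (draws are clipped at 3.5
truth-sd), so at the default noise the screening verdict recovers the true
label for essentially every chemical.  Model predictions are the truth plus
independent Gaussian noise per endpoint, with applicability-domain dropout as
an opt-in stressor.  Influent concentrations are log-normal; effluents follow
the chemical's true removal efficiency with multiplicative noise, which at
high noise produces realistic negative-RE records; values below the limit of
quantification are censored.  Identical configurations (same seed) produce
byte-identical CSV output.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import hazard, removal
from .hazard import (
    HazardFlags,
    ModelPrediction,
    PropertyBundle,
    ThresholdProfile,
    assess,
)
from .removal import REClass, classify_re
from .risk import compute_pnec

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticBundle",
    "ARCHETYPES",
    "generate",
    "write_bundle",
    "recovery_report",
]


#: Truth distributions per archetype: endpoint -> (mean, truth sd).
#: ``designed`` lists (endpoint, threshold, side) pairs the archetype is
#: built to clear by a wide margin; ``ed`` gives the endocrine flags.
ARCHETYPES: dict[str, dict] = {
    "pmt": {
        "truth": {
            "biowin2": (0.25, 0.02), "biowin3": (1.70, 0.05),
            "biowin6": (0.25, 0.02), "log_kow": (2.0, 0.30),
            "log_bcf": (1.5, 0.30), "log_koc": (1.8, 0.15),
            "log10_tox_mg_l": (-2.0, 0.10),
        },
        "designed": [
            ("biowin3", 2.25, "below"), ("biowin2", 0.5, "below"),
            ("biowin6", 0.5, "below"), ("log_koc", 3.0, "below"),
            ("log_kow", 4.5, "below"), ("log_bcf", 3.3, "below"),
            ("log10_tox_mg_l", -1.0, "below"),
        ],
        "ed": {"er": False, "ar": False, "httr": "moderate"},
    },
    "pbt": {
        "truth": {
            "biowin2": (0.25, 0.02), "biowin3": (1.70, 0.05),
            "biowin6": (0.25, 0.02), "log_kow": (6.0, 0.20),
            "log_bcf": (4.8, 0.10), "log_koc": (5.8, 0.25),
            "log10_tox_mg_l": (-2.0, 0.10),
        },
        "designed": [
            ("biowin3", 2.25, "below"), ("biowin2", 0.5, "below"),
            ("biowin6", 0.5, "below"), ("log_kow", 4.5, "above"),
            ("log_bcf", 3.7, "above"), ("log_koc", 4.0, "above"),
            ("log10_tox_mg_l", -1.0, "below"),
        ],
        "ed": {"er": False, "ar": True, "httr": "none"},
    },
    "ed_only": {
        "truth": {
            "biowin2": (0.85, 0.02), "biowin3": (3.20, 0.10),
            "biowin6": (0.85, 0.02), "log_kow": (2.0, 0.30),
            "log_bcf": (1.5, 0.30), "log_koc": (5.8, 0.25),
            "log10_tox_mg_l": (1.5, 0.20),
        },
        "designed": [
            ("biowin3", 2.25, "above"), ("biowin2", 0.5, "above"),
            ("biowin6", 0.5, "above"), ("log_kow", 4.5, "below"),
            ("log_bcf", 3.3, "below"), ("log_koc", 4.0, "above"),
            ("log10_tox_mg_l", -1.0, "above"),
        ],
        "ed": {"er": True, "ar": False, "httr": "none"},
    },
    "benign": {
        "truth": {
            "biowin2": (0.85, 0.02), "biowin3": (3.20, 0.10),
            "biowin6": (0.85, 0.02), "log_kow": (2.0, 0.30),
            "log_bcf": (1.5, 0.30), "log_koc": (5.8, 0.25),
            "log10_tox_mg_l": (1.5, 0.20),
        },
        "designed": [
            ("biowin3", 2.25, "above"), ("biowin2", 0.5, "above"),
            ("biowin6", 0.5, "above"), ("log_kow", 4.5, "below"),
            ("log_bcf", 3.3, "below"), ("log_koc", 4.0, "above"),
            ("log10_tox_mg_l", -1.0, "above"),
        ],
        "ed": {"er": False, "ar": False, "httr": "none"},
    },
}

#: Prediction noise standard deviation per endpoint family.
DEFAULT_PREDICTION_NOISE_SD: dict[str, float] = {
    "log_kow": 0.15, "log_koc": 0.15, "log_bcf": 0.15,
    "biowin3": 0.10, "biowin_prob": 0.05, "tox": 0.15,
}

#: Plants per continent: (number of WWTP1, number of WWTP2).
DEFAULT_PLANTS: dict[str, tuple[int, int]] = {
    "Europe": (2, 2), "Asia": (2, 1), "America": (1, 1),
    "Africa": (1, 0), "Oceania": (1, 0),
}


class GeneratorConfig(BaseModel):
    """Study conditions for one synthetic dataset."""

    n_chemicals: int = Field(default=200, gt=0)
    archetype_mix: dict[str, float] = Field(
        default_factory=lambda: {"pmt": 0.25, "pbt": 0.25,
                                 "ed_only": 0.2, "benign": 0.3})
    n_plants: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: dict(DEFAULT_PLANTS))
    records_per_plant: tuple[int, int] = (1, 2)
    #: log-normal influent: log-space location (ln ng/L) and scale.
    concentration_log_loc: float = float(np.log(1000.0))
    concentration_log_scale: float = 1.0
    noise_cv: float = Field(default=0.05, ge=0)
    loq: float = Field(default=5.0, ge=0, description="censoring limit, ng/L")
    ad_dropout: float = Field(default=0.0, ge=0, le=1)
    prediction_noise_sd: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PREDICTION_NOISE_SD))
    #: probability of each sub-score value {0, 1, 2} for the three QI scores.
    qi_score_distribution: tuple[float, float, float] = (0.1, 0.45, 0.45)
    #: mean/sd of the true removal efficiency in WWTP1 and the WWTP2 uplift.
    true_re_wwtp1: tuple[float, float] = (55.0, 25.0)
    true_re_uplift: tuple[float, float] = (15.0, 5.0)
    reported_re_fraction: float = Field(default=0.3, ge=0, le=1)
    mass_balance_fraction: float = Field(default=0.1, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "GeneratorConfig":
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype proportions must sum to 1, got {total}")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if self.records_per_plant[0] > self.records_per_plant[1]:
            raise ValueError("records_per_plant range inverted")
        if self.qi_score_distribution and abs(
                sum(self.qi_score_distribution) - 1.0) > 1e-9:
            raise ValueError("qi_score_distribution must sum to 1")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Per-chemical truth: properties, removal, labels, risk flags."""

    chemicals: pd.DataFrame        # cas, name, archetype, mw, truth values
    true_re: pd.DataFrame          # cas, plant_type, true_re_percent
    true_labels: pd.DataFrame      # cas, profile, labels
    true_risk: pd.DataFrame        # cas, risk_flagged (vs generated CA)


@dataclass(frozen=True)
class SyntheticBundle:
    records: pd.DataFrame
    predictions: pd.DataFrame
    experimental: pd.DataFrame
    ed_flags: pd.DataFrame
    ca: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               size: int) -> np.ndarray:
    draws = rng.normal(mean, sd, size)
    return np.clip(draws, mean - 3.5 * sd, mean + 3.5 * sd)


def _truth_bundle(row: pd.Series) -> PropertyBundle:
    """Noiseless, fully in-domain bundle for one chemical's true values."""
    mw = float(row["mw"])
    tox = 10.0 ** float(row["log10_tox_mg_l"])  # mg/L
    preds = [
        ModelPrediction(model_id="BIOWIN2", endpoint="biowin2",
                        value=float(row["biowin2"]), units="probability"),
        ModelPrediction(model_id="BIOWIN3", endpoint="biowin3",
                        value=float(row["biowin3"]), units="score"),
        ModelPrediction(model_id="BIOWIN6", endpoint="biowin6",
                        value=float(row["biowin6"]), units="probability"),
        ModelPrediction(model_id="KOWWIN", endpoint="log_kow",
                        value=float(row["log_kow"])),
        ModelPrediction(model_id="OPERA_LOGP", endpoint="log_kow",
                        value=float(row["log_kow"])),
        ModelPrediction(model_id="KOCWIN_MCI", endpoint="log_koc",
                        value=float(row["log_koc"])),
        ModelPrediction(model_id="SOIL_KOC", endpoint="log_koc",
                        value=float(row["log_koc"])),
        ModelPrediction(model_id="LOGBCF", endpoint="log_bcf",
                        value=float(row["log_bcf"]), screening_level="L2"),
        ModelPrediction(model_id="FISH_MOD1", endpoint="plc50_fish",
                        value=float(np.log10(mw * 1000.0 / tox)),
                        units="mol/L"),
        ModelPrediction(model_id="ALGAE_MOD1", endpoint="pec50_algae",
                        value=float(np.log10(mw * 1000.0 / tox)),
                        units="mol/L"),
        ModelPrediction(model_id="DAPHNIA_MOD1", endpoint="pec50_daphnia",
                        value=float(np.log10(mw * 1000.0 / tox)),
                        units="mol/L"),
    ]
    ed = ARCHETYPES[row["archetype"]]["ed"]
    return PropertyBundle(
        cas=str(row["cas"]), name=str(row["name"]), molecular_weight=mw,
        predictions=preds, er_binder=ed["er"], ar_binder=ed["ar"],
        httr_binder=ed["httr"],
    )


#: Noisy prediction battery: (model_id, endpoint, units, level, noise family).
_PREDICTION_BATTERY = (
    ("BIOWIN2", "biowin2", "probability", "L1", "biowin_prob"),
    ("BIOWIN3", "biowin3", "score", "L1", "biowin3"),
    ("BIOWIN6", "biowin6", "probability", "L1", "biowin_prob"),
    ("KOWWIN", "log_kow", "log10", "L1", "log_kow"),
    ("OPERA_LOGP", "log_kow", "log10", "L1", "log_kow"),
    ("KOCWIN_MCI", "log_koc", "log10", "L1", "log_koc"),
    ("SOIL_KOC", "log_koc", "log10", "L1", "log_koc"),
    ("LOGBCF", "log_bcf", "log10", "L2", "log_bcf"),
    ("FISH_MOD1", "plc50_fish", "mol/L", "L1", "tox"),
    ("FISH_MOD2", "plc50_fish", "mmol/L", "L1", "tox"),
    ("ALGAE_MOD1", "pec50_algae", "mol/L", "L1", "tox"),
    ("DAPHNIA_MOD1", "pec50_daphnia", "mol/L", "L1", "tox"),
    ("DAPHNIA_MOD2", "pec50_daphnia", "mmol/L", "L1", "tox"),
)


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate one synthetic dataset under the given study conditions."""
    rng = np.random.default_rng(config.seed)
    n = config.n_chemicals

    # --- chemical roster with archetype truth -----------------------------
    names = sorted(config.archetype_mix)
    probs = np.array([config.archetype_mix[a] for a in names])
    archetypes = rng.choice(names, size=n, p=probs)
    chem = pd.DataFrame({
        "cas": [f"SYN-{i:04d}" for i in range(n)],
        "name": [f"synthetic-{i:04d}" for i in range(n)],
        "archetype": archetypes,
        "use_class": rng.choice(["ANTB", "PDAM", "OIDM", "AIMB", "SHA"], n),
        "mw": rng.uniform(150.0, 450.0, n).round(2),
    })
    endpoints = list(ARCHETYPES["pmt"]["truth"])
    for ep in endpoints:
        vals = np.empty(n)
        for a in names:
            mask = archetypes == a
            mean, sd = ARCHETYPES[a]["truth"][ep]
            vals[mask] = _truncnorm(rng, mean, sd, int(mask.sum()))
        chem[ep] = vals
    chem["biowin2"] = chem["biowin2"].clip(0.0, 1.0)
    chem["biowin6"] = chem["biowin6"].clip(0.0, 1.0)

    # --- plants -----------------------------------------------------------
    plants = []
    for continent, (n1, n2) in sorted(config.n_plants.items()):
        for k in range(n1):
            plants.append({"plant_id": f"{continent[:2].upper()}-P1-{k}",
                           "continent": continent, "plant_type": "WWTP1",
                           "declared_level": "secondary",
                           "technologies": "activated sludge"})
        for k in range(n2):
            plants.append({"plant_id": f"{continent[:2].upper()}-P2-{k}",
                           "continent": continent, "plant_type": "WWTP2",
                           "declared_level": "tertiary/advanced",
                           "technologies": "ozonation;uv"})

    # --- true removal efficiency per chemical x plant type ----------------
    re1_mean, re1_sd = config.true_re_wwtp1
    up_mean, up_sd = config.true_re_uplift
    re1 = np.clip(rng.normal(re1_mean, re1_sd, n), -30.0, 99.0)
    re2 = np.clip(re1 + rng.normal(up_mean, up_sd, n), -30.0, 99.0)
    true_re = pd.DataFrame({
        "cas": np.repeat(chem["cas"].to_numpy(), 2),
        "plant_type": np.tile(["WWTP1", "WWTP2"], n),
        "true_re_percent": np.column_stack([re1, re2]).ravel(),
    })
    re_map = {(r["cas"], r["plant_type"]): r["true_re_percent"]
              for _, r in true_re.iterrows()}

    # --- literature records ----------------------------------------------
    lo, hi = config.records_per_plant
    qi_probs = np.array(config.qi_score_distribution)
    rec_rows = []
    for _, c in chem.iterrows():
        for p in plants:
            n_rec = int(rng.integers(lo, hi + 1))
            for _ in range(n_rec):
                infl = float(rng.lognormal(config.concentration_log_loc,
                                           config.concentration_log_scale))
                eps = float(np.clip(rng.normal(0.0, config.noise_cv),
                                    -0.95, None)) if config.noise_cv > 0 else 0.0
                re_true = re_map[(c["cas"], p["plant_type"])]
                effl = infl * (1.0 - re_true / 100.0) * (1.0 + eps)
                infl_cens = infl < config.loq
                effl_cens = effl < config.loq
                scores = rng.choice(3, size=3, p=qi_probs)
                row = {
                    "cas": c["cas"], "name": c["name"], "smiles": "CCO",
                    "use_class": c["use_class"], "mw": c["mw"],
                    "source_id": f"SRC-{int(rng.integers(0, 8)):02d}",
                    "plant_id": p["plant_id"], "continent": p["continent"],
                    "declared_level": p["declared_level"],
                    "technologies": p["technologies"],
                    "molecule_id_score": int(scores[0]),
                    "re_data_score": int(scores[1]),
                    "general_info_score": int(scores[2]),
                    "c_infl": np.nan if infl_cens else round(infl, 4),
                    "c_infl_censored": bool(infl_cens),
                    "c_infl_stat": "median",
                    "c_effl": np.nan if effl_cens else round(effl, 4),
                    "c_effl_censored": bool(effl_cens),
                    "c_effl_stat": "median",
                    "ci": np.nan, "ce": np.nan, "cs": np.nan,
                    "f": np.nan, "tsp": np.nan,
                    "reported_re": np.nan,
                }
                u = rng.random()
                if not (infl_cens or effl_cens):
                    if u < config.reported_re_fraction:
                        row["reported_re"] = round(
                            (1.0 - effl / infl) * 100.0, 6)
                    elif u < (config.reported_re_fraction
                              + config.mass_balance_fraction):
                        # sludge term zero keeps the load balance consistent
                        # with the concentration ratio
                        row.update(ci=round(infl, 4), ce=round(effl, 4),
                                   cs=0.0, f=1.0e6, tsp=1.0e4)
                rec_rows.append(row)
    records = pd.DataFrame(rec_rows)

    # --- predictions ------------------------------------------------------
    sd = config.prediction_noise_sd
    pred_rows = []
    for _, c in chem.iterrows():
        mw = float(c["mw"])
        tox = 10.0 ** float(c["log10_tox_mg_l"])
        for model_id, endpoint, units, level, family in _PREDICTION_BATTERY:
            if endpoint in ("biowin2", "biowin3", "biowin6"):
                truth_val = float(c[endpoint])
            elif endpoint.startswith(("plc50", "pec50")):
                scale = 1000.0 if units == "mol/L" else 1.0
                truth_val = float(np.log10(mw * scale / tox))
            else:
                truth_val = float(c[endpoint])
            noise = float(rng.normal(0.0, sd.get(family, 0.0))) \
                if sd.get(family, 0.0) > 0 else 0.0
            value = truth_val + noise
            if units == "probability":
                value = float(np.clip(value, 0.0, 1.0))
            pred_rows.append({
                "cas": c["cas"], "model_id": model_id, "endpoint": endpoint,
                "value": round(value, 6), "units": units,
                "in_ad": bool(rng.random() >= config.ad_dropout),
                "screening_level": level,
            })
        pred_rows.append({
            "cas": c["cas"], "model_id": "GHLI", "endpoint": "ghli",
            "value": round(float(rng.uniform(0, 5)), 3), "units": "score",
            "in_ad": True, "screening_level": "L2",
        })
    predictions = pd.DataFrame(pred_rows)

    experimental = pd.DataFrame(columns=["cas", "endpoint", "value"])
    ed_flags = pd.DataFrame({
        "cas": chem["cas"],
        "er_binder": [ARCHETYPES[a]["ed"]["er"] for a in chem["archetype"]],
        "ar_binder": [ARCHETYPES[a]["ed"]["ar"] for a in chem["archetype"]],
        "httr_binder": [ARCHETYPES[a]["ed"]["httr"] for a in chem["archetype"]],
    })

    ca = records.loc[~records["c_effl_censored"],
                     ["cas", "plant_id", "continent", "c_effl"]].copy()
    ca = ca.rename(columns={"c_effl": "ca_ng_l"}).reset_index(drop=True)

    # --- ground truth -----------------------------------------------------
    profiles = [ThresholdProfile.conservative_2019(), ThresholdProfile.eu_2023()]
    label_rows = []
    for _, c in chem.iterrows():
        bundle = _truth_bundle(c)
        for prof in profiles:
            verdict = assess(bundle, prof)
            label_rows.append({"cas": c["cas"], "profile": prof.name,
                               "labels": "|".join(sorted(verdict.labels))})
    true_labels = pd.DataFrame(label_rows)

    risk_rows = []
    for _, c in chem.iterrows():
        tox_mg_l = 10.0 ** float(c["log10_tox_mg_l"])
        pnec = compute_pnec(tox_mg_l)
        cas_ca = ca.loc[ca["cas"] == c["cas"], "ca_ng_l"]
        risk_rows.append({
            "cas": c["cas"],
            "risk_records": int(len(cas_ca)),
            "risk_flagged": bool((cas_ca / pnec > 1.0).any()),
        })
    true_risk = pd.DataFrame(risk_rows)

    truth = GroundTruth(chemicals=chem, true_re=true_re,
                        true_labels=true_labels, true_risk=true_risk)
    return SyntheticBundle(records=records, predictions=predictions,
                           experimental=experimental, ed_flags=ed_flags,
                           ca=ca, truth=truth, config=config)


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write the generated tables as the CSV dialects the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "records": bundle.records,
        "predictions": bundle.predictions,
        "experimental": bundle.experimental,
        "ed_flags": bundle.ed_flags,
        "ca": bundle.ca,
        "truth_chemicals": bundle.truth.chemicals,
        "truth_re": bundle.truth.true_re,
        "truth_labels": bundle.truth.true_labels,
        "truth_risk": bundle.truth.true_risk,
    }
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    return paths


def recovery_report(truth: GroundTruth, outputs) -> pd.DataFrame:
    """Per-stage recovery rates of the pipeline against the ground truth.

    Compares the consensus removal class against the class of the true
    removal efficiency, the hazard label sets per profile, and the
    any-quotient-exceeds risk flag.  With no measurement noise, no censoring
    and no domain dropout every rate is 1.0.
    """
    rows = []

    cons = outputs.consensus
    if len(cons):
        re_map = {(r["cas"], r["plant_type"]): r["true_re_percent"]
                  for _, r in truth.true_re.iterrows()}
        hits = total = 0
        for _, r in cons.iterrows():
            key = (r["cas"], r["plant_type"])
            if key not in re_map:
                continue
            total += 1
            if REClass(r["consensus_class"]) is classify_re(re_map[key]):
                hits += 1
        rows.append({"stage": "consensus_re", "n": total,
                     "recovery": hits / total if total else float("nan")})

    verd = outputs.verdicts
    for profile in sorted(truth.true_labels["profile"].unique()):
        expected = truth.true_labels[truth.true_labels["profile"] == profile]
        exp_map = dict(zip(expected["cas"], expected["labels"].fillna("")))
        got = verd[verd["profile"] == profile]
        got_map = dict(zip(got["cas"], got["labels"].fillna("")))
        common = [cas for cas in exp_map if cas in got_map]
        hits = sum(got_map[cas] == exp_map[cas] for cas in common)
        rows.append({"stage": f"hazard_{profile}", "n": len(common),
                     "recovery": hits / len(common) if common else float("nan")})

    risk = outputs.risk
    exp = truth.true_risk[truth.true_risk["risk_records"] > 0]
    exp_map = dict(zip(exp["cas"], exp["risk_flagged"]))
    if len(risk):
        got = risk.groupby("cas")["exceeds"].any()
        common = [cas for cas in exp_map if cas in got.index]
        hits = sum(bool(got[cas]) == bool(exp_map[cas]) for cas in common)
        rows.append({"stage": "risk_flag", "n": len(common),
                     "recovery": hits / len(common) if common else float("nan")})

    return pd.DataFrame(rows, columns=["stage", "n", "recovery"])
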