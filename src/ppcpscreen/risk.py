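"""Risk quotients from measured effluent concentrations and predicted toxicity.

The predicted no-effect concentration (PNEC) for each chemical is the minimum
acute toxicity across trophic levels divided by an assessment factor (default
1000).  Lethal fish endpoints (pLC50) and effect endpoints for algae/Daphnia
(pEC50) are kept separate, yielding PNEC(LC50) and PNEC(EC50).  The risk
quotient PR = CA / PNEC is computed for every measured effluent concentration
(CA, in ng/L); a chemical is risk-flagged when any of its quotients exceeds 1
(strict).  Chemicals with no measured CA are excluded from quantification.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from ._errors import SchemaError
from .hazard import PropertyBundle, toxicity_values_mg_l

__all__ = [
    "ToxicityMinima",
    "compute_pnec",
    "compute_pr",
    "toxicity_minima",
    "risk_table",
    "prioritize",
    "DEFAULT_ASSESSMENT_FACTOR",
]

DEFAULT_ASSESSMENT_FACTOR = 1000.0

#: Endpoint-token prefixes feeding each PNEC basis (config-overridable).
DEFAULT_ENDPOINT_PARTITION: dict[str, str] = {
    "plc50": "lc50",  # lethal (fish) endpoints
    "pec50": "ec50",  # effect (algae, Daphnia) endpoints
}


@dataclass(frozen=True)
class ToxicityMinima:
    """Per-chemical minimum predicted acute toxicity, mg/L, by basis."""

    cas: str
    min_lc50: float | None
    min_ec50: float | None
    per_endpoint: dict[str, float]


def toxicity_minima(
    bundle: PropertyBundle,
    partition: Mapping[str, str] = DEFAULT_ENDPOINT_PARTITION,
) -> ToxicityMinima:
    """Minimum in-domain toxicity per basis across trophic levels."""
    per_endpoint: dict[str, float] = {}
    basis_values: dict[str, list[float]] = {"lc50": [], "ec50": []}
    for endpoint, values in toxicity_values_mg_l(bundle).items():
        per_endpoint[endpoint] = min(values)
        for prefix, basis in partition.items():
            if endpoint.startswith(prefix):
                basis_values[basis].extend(values)
                break
    return ToxicityMinima(
        cas=bundle.cas,
        min_lc50=min(basis_values["lc50"]) if basis_values["lc50"] else None,
        min_ec50=min(basis_values["ec50"]) if basis_values["ec50"] else None,
        per_endpoint=per_endpoint,
    )


def compute_pnec(
    minimum_mg_l: float,
    assessment_factor: float = DEFAULT_ASSESSMENT_FACTOR,
) -> float:
    """PNEC in ng/L from a minimum toxicity in mg/L.

    1 mg/L = 1e6 ng/L, so PNEC = minimum * 1e6 / AF ng/L.
    """
    if minimum_mg_l <= 0:
        raise ValueError("minimum toxicity must be positive")
    if assessment_factor <= 0:
        raise ValueError("assessment factor must be positive")
    return minimum_mg_l * 1.0e6 / assessment_factor


def compute_pr(ca_ng_l: float, pnec_ng_l: float) -> float:
    """Risk quotient CA / PNEC (both in ng/L)."""
    if pnec_ng_l <= 0:
        raise ValueError("PNEC must be positive")
    if ca_ng_l < 0:
        raise ValueError("CA must be non-negative")
    return ca_ng_l / pnec_ng_l


CA_REQUIRED_COLUMNS = ("cas", "plant_id", "continent", "ca_ng_l")


def risk_table(
    ca: pd.DataFrame,
    minima: Sequence[ToxicityMinima],
    assessment_factor: float = DEFAULT_ASSESSMENT_FACTOR,
    *,
    source: str = "ca",
) -> pd.DataFrame:
    """One row per CA record with both risk quotients.

    Chemicals without any usable toxicity minimum, or without CA records,
    are absent from the result.
    """
    for col in CA_REQUIRED_COLUMNS:
        if col not in ca.columns:
            raise SchemaError("missing required column", source=source,
                              column=col)
    by_cas = {m.cas: m for m in minima}
    rows = []
    for _, rec in ca.iterrows():
        m = by_cas.get(str(rec["cas"]))
        if m is None or (m.min_lc50 is None and m.min_ec50 is None):
            continue
        ca_val = float(rec["ca_ng_l"])
        pnec_lc = compute_pnec(m.min_lc50, assessment_factor) \
            if m.min_lc50 is not None else None
        pnec_ec = compute_pnec(m.min_ec50, assessment_factor) \
            if m.min_ec50 is not None else None
        pr_lc = compute_pr(ca_val, pnec_lc) if pnec_lc is not None else None
        pr_ec = compute_pr(ca_val, pnec_ec) if pnec_ec is not None else None
        rows.append({
            "cas": str(rec["cas"]),
            "plant_id": str(rec["plant_id"]),
            "continent": str(rec["continent"]),
            "ca_ng_l": ca_val,
            "pnec_lc50_ng_l": pnec_lc,
            "pnec_ec50_ng_l": pnec_ec,
            "pr_lc50": pr_lc,
            "pr_ec50": pr_ec,
            "exceeds": any(pr is not None and pr > 1.0
                           for pr in (pr_lc, pr_ec)),
        })
    return pd.DataFrame(rows, columns=[
        "cas", "plant_id", "continent", "ca_ng_l", "pnec_lc50_ng_l",
        "pnec_ec50_ng_l", "pr_lc50", "pr_ec50", "exceeds",
    ])


def prioritize(
    verdicts: pd.DataFrame,
    risk: pd.DataFrame,
    consensus: pd.DataFrame,
) -> pd.DataFrame:
    """Per-chemical roll-up combining hazard, risk and removal consensus.

    One row per chemical appearing in any stage: hazard labels per profile,
    the any-quotient-exceeds flag, consensus removal class per plant type,
    the continents where exceedance records occur, and whether the chemical
    lands on the hazard-and-risk intersection list (PMT or PBT label plus a
    risk flag).
    """
    all_cas = sorted(
        set(verdicts.get("cas", pd.Series(dtype=str)).astype(str))
        | set(risk.get("cas", pd.Series(dtype=str)).astype(str))
        | set(consensus.get("cas", pd.Series(dtype=str)).astype(str))
    )
    label_map: dict[str, dict[str, str]] = {}
    if len(verdicts):
        for (cas, profile), grp in verdicts.groupby(["cas", "profile"]):
            label_map.setdefault(str(cas), {})[str(profile)] = (
                str(grp["labels"].iloc[0]) if pd.notna(grp["labels"].iloc[0])
                else ""
            )
    cons_map: dict[str, dict[str, str]] = {}
    if len(consensus):
        for _, row in consensus.iterrows():
            cons_map.setdefault(str(row["cas"]), {})[str(row["plant_type"])] = (
                str(row["consensus_class"])
            )
    rows = []
    profiles = sorted({p for d in label_map.values() for p in d})
    for cas in all_cas:
        labels = label_map.get(cas, {})
        chem_risk = risk[risk["cas"].astype(str) == cas] if len(risk) \
            else pd.DataFrame(columns=risk.columns)
        has_ca = len(chem_risk) > 0
        exceeds = bool(chem_risk["exceeds"].any()) if has_ca else False
        exceed_continents = ";".join(sorted(
            chem_risk.loc[chem_risk["exceeds"], "continent"].unique()
        )) if has_ca else ""
        hazard_flagged = any(
            lab in ("PMT", "PBT")
            for labs in labels.values() for lab in labs.split("|") if lab
        )
        row = {
            "cas": cas,
            "risk_records": int(len(chem_risk)),
            "risk_flagged": exceeds,
            "exceed_continents": exceed_continents,
            "hazard_flagged": hazard_flagged,
            "intersection": hazard_flagged and exceeds,
            "consensus_wwtp1": cons_map.get(cas, {}).get("WWTP1", ""),
            "consensus_wwtp2": cons_map.get(cas, {}).get("WWTP2", ""),
        }
        for p in profiles:
            row[f"labels_{p}"] = labels.get(p, "")
        rows.append(row)
    cols = ["cas", "risk_records", "risk_flagged", "exceed_continents",
            "hazard_flagged", "intersection", "consensus_wwtp1",
            "consensus_wwtp2"] + [f"labels_{p}" for p in profiles]
    return pd.DataFrame(rows, columns=cols)
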