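"""Removal efficiency (RE): per-record computation, classing and consensus.

RE is the percent reduction of a chemical between WWTP influent and effluent.
Two computations exist: the concentration ratio

    RE% = (1 - c_effl / c_infl) * 100

and a load-based mass balance that also accounts for sorption to sludge,

    RE% = (Ci*F - [Ce*F + Cs*TSP]) / (Ci*F) * 100

with Ci, Ce in ng/L, Cs in ng/g wet weight, F in L/d and TSP in g/d wet
weight, so every term is a load in ng/d.  Negative RE is meaningful (apparent
in-plant formation, e.g. de-conjugation of metabolites) and is kept.

Per-record percentages map to six classes (Other <= 0 < Low <= 50 < Moderate
<= 75 < High <= 95 < Excellent; NoData for censored/missing inputs).  When a
chemical has several records for a plant type, a consensus class is assigned:
the modal class wins, ties break to the worst class (Other < Low < Moderate <
High < Excellent), and a NoData mode defers to the remaining classes.
"""

from __future__ import annotations

import enum
import json
import math
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd

from .records import (
    ConcentrationMeasurement,
    LiteratureRecord,
    MassBalanceInputs,
    PlantType,
)

__all__ = [
    "REClass",
    "REValue",
    "ConsensusResult",
    "CensoringPolicy",
    "re_simple",
    "re_mass_balance",
    "select_re",
    "classify_re",
    "consensus_re",
    "is_resistant",
    "consensus_table",
    "re_table",
]


class REClass(str, enum.Enum):
    OTHER = "Other"
    LOW = "Low"
    MODERATE = "Moderate"
    HIGH = "High"
    EXCELLENT = "Excellent"
    NODATA = "NoData"


#: Worst-to-best ordering used for tie-breaking; NoData sits outside it.
WORST_CASE_ORDER = (
    REClass.OTHER,
    REClass.LOW,
    REClass.MODERATE,
    REClass.HIGH,
    REClass.EXCELLENT,
)
_RANK = {c: i for i, c in enumerate(WORST_CASE_ORDER)}


class CensoringPolicy(str, enum.Enum):
    """How censored influent/effluent concentrations are handled.

    NODATA: any censored concentration yields class NoData (default).
    FORMATION: a censored influent with a detected effluent is read as
    in-plant formation and yields class Other; other censoring yields NoData.
    """

    NODATA = "nodata"
    FORMATION = "formation"


@dataclass(frozen=True)
class REValue:
    percent: float | None
    method: str  # reported | eq2 | eq1 | none
    re_class: REClass


@dataclass(frozen=True)
class ConsensusResult:
    plant_type: PlantType
    class_counts: dict[REClass, int]
    consensus_class: REClass
    tie_broken: bool


def re_simple(c_infl: float | None, c_effl: float | None) -> float | None:
    """Concentration-ratio RE percent; None when not computable.

    Requires a positive influent and both values present.  The result may be
    negative and is always <= 100.
    """
    if c_infl is None or c_effl is None or c_infl <= 0 or c_effl < 0:
        return None
    return (1.0 - c_effl / c_infl) * 100.0


def re_mass_balance(mb: MassBalanceInputs) -> float | None:
    """Load-based RE percent; None when the influent load is not positive.

    When the sludge term Cs*TSP vanishes the result is bit-identical to the
    concentration ratio (the identity is guaranteed, not merely approximate).
    """
    sludge_load = mb.cs * mb.tsp  # ng/d
    if sludge_load == 0.0:
        return re_simple(mb.ci, mb.ce)
    influent_load = mb.ci * mb.f  # ng/d
    if influent_load <= 0:
        return None
    out_load = mb.ce * mb.f + sludge_load  # ng/d
    return (influent_load - out_load) / influent_load * 100.0


def classify_re(percent: float | None) -> REClass:
    """Map an RE percent onto its class; None maps to NoData.

    Bins are closed on the upper side exactly as printed: Other (-inf, 0],
    Low (0, 50], Moderate (50, 75], High (75, 95], Excellent (95, +inf).
    No rounding is applied before comparison.
    """
    if percent is None or (isinstance(percent, float) and math.isnan(percent)):
        return REClass.NODATA
    if percent <= 0:
        return REClass.OTHER
    if percent <= 50:
        return REClass.LOW
    if percent <= 75:
        return REClass.MODERATE
    if percent <= 95:
        return REClass.HIGH
    return REClass.EXCELLENT


def _censored(m: ConcentrationMeasurement | None) -> bool:
    return m is not None and m.censored


def select_re(
    record: LiteratureRecord,
    *,
    censoring_policy: CensoringPolicy = CensoringPolicy.NODATA,
) -> REValue:
    """Choose and evaluate the RE for one quality-filtered record.

    Precedence: the RE reported by the source; else the mass balance when all
    five parameters are present; else the concentration ratio; else NoData.
    Censoring in either concentration yields NoData under the default policy;
    under the FORMATION policy a censored influent with a detected effluent
    is classed Other (apparent in-plant formation).
    """
    if record.reported_re is not None:
        pct = record.reported_re
        return REValue(pct, "reported", classify_re(pct))
    if record.mass_balance is not None:
        pct = re_mass_balance(record.mass_balance)
        if pct is not None:
            return REValue(pct, "eq2", classify_re(pct))
    infl, effl = record.influent, record.effluent
    if _censored(infl) or _censored(effl):
        if (censoring_policy is CensoringPolicy.FORMATION
                and _censored(infl) and effl is not None and not effl.censored):
            return REValue(None, "eq1", REClass.OTHER)
        return REValue(None, "none", REClass.NODATA)
    if infl is not None and effl is not None:
        pct = re_simple(infl.value, effl.value)
        if pct is not None:
            return REValue(pct, "eq1", classify_re(pct))
    return REValue(None, "none", REClass.NODATA)


def consensus_re(
    classes: Iterable[REClass],
    plant_type: PlantType,
) -> ConsensusResult:
    """Consensus class for one chemical in one plant type.

    The most represented class wins.  Ties among modal classes break to the
    worst class in the Other < Low < Moderate < High < Excellent order.  When
    NoData is (among) the modal class(es), the vote recurses on the remaining
    classes; all-NoData gives NoData.  WWTP1 and WWTP2 pools are consensused
    separately by the caller.
    """
    counts = Counter(classes)
    if not counts:
        raise ValueError("consensus requires at least one RE class")
    result, tie = _vote(counts)
    return ConsensusResult(
        plant_type=plant_type,
        class_counts=dict(counts),
        consensus_class=result,
        tie_broken=tie,
    )


def _vote(counts: Counter) -> tuple[REClass, bool]:
    informative = {c: n for c, n in counts.items() if c is not REClass.NODATA}
    if not informative:
        return REClass.NODATA, False
    top = max(counts.values())
    modal = [c for c, n in counts.items() if n == top]
    if REClass.NODATA in modal:
        # a NoData mode defers to the remaining classes
        return _vote(Counter(informative))
    if len(modal) > 1:
        return min(modal, key=_RANK.get), True
    return modal[0], False


def is_resistant(consensus_class: REClass) -> bool:
    """Resistant to treatment: consensus class Low or Other (worst case)."""
    return consensus_class in (REClass.LOW, REClass.OTHER)


# ---------------------------------------------------------------------------
# Tabular interface
# ---------------------------------------------------------------------------

def re_table(
    records: Sequence[LiteratureRecord],
    *,
    censoring_policy: CensoringPolicy = CensoringPolicy.NODATA,
) -> pd.DataFrame:
    """Per-record RE table: one row per record with percent, method, class."""
    columns = ["cas", "name", "plant_id", "plant_type", "continent",
               "re_percent", "re_method", "re_class"]
    rows = []
    for r in records:
        rev = select_re(r, censoring_policy=censoring_policy)
        rows.append({
            "cas": r.chemical.cas,
            "name": r.chemical.name,
            "plant_id": r.plant.plant_id,
            "plant_type": r.plant.classification.value,
            "continent": r.plant.continent,
            "re_percent": rev.percent,
            "re_method": rev.method,
            "re_class": rev.re_class.value,
        })
    return pd.DataFrame(rows, columns=columns)


def consensus_table(per_record: pd.DataFrame) -> pd.DataFrame:
    """Per-chemical consensus table from the per-record RE table.

    One row per chemical x plant type, with the class counts (JSON), the
    consensus class and whether a tie was broken.
    """
    columns = ["cas", "plant_type", "n_records", "class_counts",
               "consensus_class", "tie_broken", "resistant"]
    if per_record.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    for (cas, ptype), grp in per_record.groupby(["cas", "plant_type"],
                                                sort=True):
        classes = [REClass(c) for c in grp["re_class"]]
        res = consensus_re(classes, PlantType(ptype))
        rows.append({
            "cas": cas,
            "plant_type": ptype,
            "n_records": len(classes),
            "class_counts": json.dumps(
                {c.value: n for c, n in sorted(res.class_counts.items(),
                                               key=lambda kv: kv[0].value)}
            ),
            "consensus_class": res.consensus_class.value,
            "tie_broken": res.tie_broken,
            "resistant": is_resistant(res.consensus_class),
        })
    return pd.DataFrame(rows, columns=columns)
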