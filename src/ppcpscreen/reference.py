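"""Published reference tables bundled for validation and benchmarking.

These small tables transcribe the headline results of a global, literature-
based screening of PPCP removal in wastewater treatment plants (2014-2019
monitoring literature; 2034 records, 245 curated chemicals, 76 plants).  They
serve as fixed inputs for regression checks: the rule engine, the summary
renderer and the cross-tabulation code must reproduce the printed totals,
shares and classifications from these cells.

Contents
--------
SCREENING_FLAGS
    The per-chemical screening flags for the 16 substances prioritized as
    potentially PMT or PBT, under both threshold profiles, together with the
    published combined labels.
RE_CLASS_DISTRIBUTION
    Counts of chemicals per consensus removal class and plant type.
RISK_CROSSTAB
    Counts of risk-quotient exceedance cases by continent and removal class.
QI_RECORD_COUNTS, PLANTS_BY_CONTINENT
    Headline record-quality and plant-geography counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hazard import HazardFlags

__all__ = [
    "ReferenceFlagRow",
    "SCREENING_FLAGS",
    "RE_CLASS_DISTRIBUTION",
    "RISK_CROSSTAB",
    "RISK_CROSSTAB_CLASSES",
    "QI_RECORD_COUNTS",
    "TOTAL_RECORDS",
    "PLANTS_BY_CONTINENT",
    "TOTAL_PLANTS",
]


@dataclass(frozen=True)
class ReferenceFlagRow:
    """One prioritized chemical's screening flags under both profiles.

    ``flags_conservative`` / ``flags_eu2023`` are the transcribed screening
    flags (the persistence flag is the joint pP-or-pvP flag in every row);
    ``labels_*`` are the published combined classifications.
    """

    name: str
    use_class: str
    flags_conservative: HazardFlags
    flags_eu2023: HazardFlags
    labels_conservative: frozenset[str]
    labels_eu2023: frozenset[str]


def _row(name, use_class, *, b=False,
         m_cons=False, vm_cons=False, m_eu=False, vm_eu=False,
         labels_cons=(), labels_eu=()):
    # every prioritized row is flagged pP-or-pvP and pT
    return ReferenceFlagRow(
        name=name,
        use_class=use_class,
        flags_conservative=HazardFlags(p=True, b=b, vb=False,
                                       m=m_cons, vm=vm_cons, t=True),
        flags_eu2023=HazardFlags(p=True, b=b, vb=False,
                                 m=m_eu, vm=vm_eu, t=True),
        labels_conservative=frozenset(labels_cons),
        labels_eu2023=frozenset(labels_eu),
    )


SCREENING_FLAGS: tuple[ReferenceFlagRow, ...] = (
    _row("EDDP", "OIDM", b=True,
         labels_cons={"PBT"}, labels_eu={"PBT"}),
    _row("Atrazine", "HERB", m_cons=True, vm_cons=True, m_eu=True,
         labels_cons={"PMT"}, labels_eu={"PMT"}),
    _row("Chloramphenicol", "ANTB", m_cons=True, vm_cons=True, m_eu=True,
         labels_cons={"PMT"}, labels_eu={"PMT"}),
    _row("Citalopram", "PDAM", m_cons=True,
         labels_cons={"PMT"}, labels_eu=()),
    _row("Clopidogrel", "APLM", m_cons=True,
         labels_cons={"PMT"}, labels_eu=()),
    _row("Desmethylcitalopram", "PDAM", m_cons=True,
         labels_cons={"PMT"}, labels_eu=()),
    _row("Lorazepam", "SHA", m_cons=True, vm_cons=True, m_eu=True,
         labels_cons={"PMT"}, labels_eu={"PMT"}),
    _row("Lormetazepam", "PDAM", m_cons=True, vm_cons=True, m_eu=True,
         labels_cons={"PMT"}, labels_eu={"PMT"}),
    _row("Methadone", "OIDM", m_cons=True,
         labels_cons={"PMT"}, labels_eu=()),
    _row("Miconazole", "ANTB", b=True,
         labels_cons={"PBT"}, labels_eu={"PBT"}),
    _row("Nafronyl", "AHCV", b=True,
         labels_cons={"PBT"}, labels_eu={"PBT"}),
    _row("Norsertraline", "PDAM", b=True,
         labels_cons={"PBT"}, labels_eu={"PBT"}),
    _row("Olanzapine", "PDAM", m_cons=True,
         labels_cons={"PMT"}, labels_eu=()),
    _row("Sertraline", "PDAM", b=True,
         labels_cons={"PBT"}, labels_eu={"PBT"}),
    _row("Sulfachloropyridazine", "ANTB", m_cons=True, vm_cons=True, m_eu=True,
         labels_cons={"PMT"}, labels_eu={"PMT"}),
    _row("Triclocarban", "ANTB", b=True, m_cons=True,
         labels_cons={"PBT", "PMT"}, labels_eu={"PBT"}),
)


#: Chemicals per consensus removal class, by plant type (column totals are the
#: numbers of chemicals detected in each plant type's effluents).
RE_CLASS_DISTRIBUTION: dict[str, dict[str, int]] = {
    "WWTP1": {"Other": 53, "Low": 50, "Moderate": 28, "High": 24,
              "Excellent": 32, "NoData": 37},
    "WWTP2": {"Other": 15, "Low": 13, "Moderate": 10, "High": 20,
              "Excellent": 36, "NoData": 15},
}

#: Risk-quotient exceedance cases by continent (rows) and removal class
#: (columns, in RISK_CROSSTAB_CLASSES order).
RISK_CROSSTAB_CLASSES = ("Low", "Other", "Moderate", "High", "Excellent")
RISK_CROSSTAB: dict[str, tuple[int, ...]] = {
    "America": (18, 3, 7, 5, 0),
    "Africa": (9, 1, 3, 5, 0),
    "Europe": (51, 66, 32, 19, 1),
    "Asia": (7, 18, 10, 1, 3),
    "Oceania": (0, 2, 1, 2, 0),
}

#: Records per quality-index class, out of TOTAL_RECORDS extracted records.
QI_RECORD_COUNTS: dict[str, int] = {
    "Low": 282, "Moderate": 940, "Good": 794, "Excellent": 18,
}
TOTAL_RECORDS = 2034

#: Analyzed plants per continent, out of TOTAL_PLANTS.
PLANTS_BY_CONTINENT: dict[str, int] = {
    "Europe": 36, "Asia": 28, "America": 10, "Africa": 1, "Oceania": 1,
}
TOTAL_PLANTS = 76
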