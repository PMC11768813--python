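"""Pipeline orchestration, configuration and the standard summary tables.

``run_pipeline`` executes the four stages in order — quality filtering,
removal-efficiency consensus, hazard screening, risk quotients — from the
CSV interfaces, and writes every stage table plus a run manifest.
``summarize`` renders the standard report tables: the removal-class
distribution per plant type, the risk-case cross-tabulation by continent and
removal class, the verdict table, and the hazard-and-risk intersection list.
Percentages are computed against column totals at full precision and rounded
only at render time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from ._errors import ConfigError
from .hazard import (
    BUILTIN_PROFILES,
    ThresholdProfile,
    assess_table,
    bundles_from_tables,
    get_profile,
)
from .records import filter_records, load_records_csv, records_to_frame, roster
from .removal import CensoringPolicy, consensus_table, re_table
from .risk import (
    DEFAULT_ASSESSMENT_FACTOR,
    prioritize,
    risk_table,
    toxicity_minima,
)

logger = logging.getLogger("ppcpscreen")

__all__ = ["PipelineConfig", "PipelineOutputs", "run_pipeline", "summarize",
           "distribution_table", "crosstab_table", "render_percent"]


class PipelineConfig(BaseModel):
    """Everything one pipeline run depends on; YAML-serializable."""

    records_csv: str
    predictions_csv: str
    experimental_csv: str | None = None
    ed_csv: str | None = None
    ca_csv: str | None = None
    profiles: list[str] = Field(
        default_factory=lambda: list(BUILTIN_PROFILES))
    censoring_policy: str = "nodata"
    p_rule: str = "or"
    t_threshold: float = 0.1
    assessment_factor: float = DEFAULT_ASSESSMENT_FACTOR
    out_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def resolved_profiles(self) -> list[ThresholdProfile]:
        out = []
        for name in self.profiles:
            out.append(get_profile(
                name,
                t_ec50_max_mg_l=self.t_threshold,
                fast_probability_rule=self.p_rule,
            ))
        return out


@dataclass
class PipelineOutputs:
    curated: pd.DataFrame
    exclusions: pd.DataFrame
    per_record_re: pd.DataFrame
    consensus: pd.DataFrame
    verdicts: pd.DataFrame
    risk: pd.DataFrame
    prioritized: pd.DataFrame
    manifest: dict = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineOutputs:
    """Execute all stages; write stage CSVs and a manifest if out_dir is set.

    All tables are computed before anything is written, so a failure leaves
    no partial output behind.
    """
    logging.basicConfig(level=config.log_level)
    policy = CensoringPolicy(config.censoring_policy)
    profiles = config.resolved_profiles()

    records = load_records_csv(config.records_csv)
    kept, excluded = filter_records(records)
    logger.info("quality filter: %d kept, %d excluded", len(kept),
                len(excluded))
    curated = records_to_frame(kept)
    exclusions = records_to_frame(excluded)
    if len(exclusions):
        exclusions = exclusions.assign(reason="QI Low")
    else:
        exclusions = exclusions.reindex(columns=[*exclusions.columns, "reason"])
    kept_roster = set(roster(kept))

    per_record = re_table(kept, censoring_policy=policy)
    consensus = consensus_table(per_record)

    predictions = pd.read_csv(config.predictions_csv)
    predictions = predictions[predictions["cas"].astype(str).isin(kept_roster)]
    chem_info = curated[["cas", "name", "mw"]].drop_duplicates("cas") \
        if len(curated) else None
    experimental = pd.read_csv(config.experimental_csv) \
        if config.experimental_csv else None
    ed = pd.read_csv(config.ed_csv) if config.ed_csv else None
    bundles = bundles_from_tables(
        predictions, chemicals=chem_info, experimental=experimental,
        ed_flags=ed, source=config.predictions_csv,
    )
    verdicts = assess_table(bundles, profiles)

    if config.ca_csv:
        ca = pd.read_csv(config.ca_csv)
        ca = ca[ca["cas"].astype(str).isin(kept_roster)]
        minima = [toxicity_minima(b) for b in bundles]
        risk = risk_table(ca, minima,
                          assessment_factor=config.assessment_factor,
                          source=config.ca_csv)
    else:
        risk = risk_table(
            pd.DataFrame(columns=["cas", "plant_id", "continent", "ca_ng_l"]),
            [],
        )
    prioritized = prioritize(verdicts, risk, consensus)

    manifest = {
        "config": config.model_dump(),
        "config_sha256": _config_hash(config),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_records": len(records),
        "n_kept": len(kept),
        "n_chemicals": len(kept_roster),
    }
    outputs = PipelineOutputs(
        curated=curated, exclusions=exclusions, per_record_re=per_record,
        consensus=consensus, verdicts=verdicts, risk=risk,
        prioritized=prioritized, manifest=manifest,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "curated_records": curated, "exclusions": exclusions,
            "per_record_re": per_record, "consensus_re": consensus,
            "verdicts": verdicts, "risk": risk, "prioritized": prioritized,
        }
        for name, df in tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.10g")
            outputs.paths[name] = path
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        outputs.paths["manifest"] = manifest_path
    return outputs


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

def render_percent(value: float, decimals: int = 0) -> str:
    """Render a percentage for display ("33%" or "32.20%")."""
    return f"{value:.{decimals}f}%"


def distribution_table(
    counts_by_group: Mapping[str, Mapping[str, int]],
    *,
    class_order: Sequence[str] = ("Other", "Low", "Moderate", "High",
                                  "Excellent", "NoData"),
    percent_decimals: int = 0,
) -> pd.DataFrame:
    """Class-count distribution with per-column percentages.

    One row per class, plus a "Total" row; for each group (column) the
    percentage is computed against that column's total at full precision and
    rendered at ``percent_decimals``.
    """
    data: dict[str, list] = {"class": list(class_order) + ["Total"]}
    for group, counts in counts_by_group.items():
        col = [int(counts.get(c, 0)) for c in class_order]
        total = sum(col)
        pcts = [100.0 * v / total if total else 0.0 for v in col]
        data[f"{group}_n"] = col + [total]
        data[f"{group}_pct"] = pcts + [sum(pcts)]
        data[f"{group}_pct_rendered"] = [
            render_percent(p, percent_decimals) for p in pcts
        ] + [render_percent(sum(pcts), percent_decimals)]
    return pd.DataFrame(data)


def crosstab_table(
    cells: Mapping[str, Sequence[int]],
    classes: Sequence[str],
    *,
    percent_decimals: int = 2,
) -> pd.DataFrame:
    """Cross-tabulation with row totals, column totals and column percentages.

    ``cells`` maps each row label (e.g. continent) to its per-class counts in
    ``classes`` order.  Percentages are shares of the column total; the
    bottom Total row carries each class's share of the grand total.
    """
    col_totals = [sum(cells[r][j] for r in cells) for j in range(len(classes))]
    grand = sum(col_totals)
    rows = []
    for label, values in cells.items():
        row: dict = {"row": label}
        for j, cls in enumerate(classes):
            v = int(values[j])
            pct = 100.0 * v / col_totals[j] if col_totals[j] else 0.0
            row[f"{cls}_n"] = v
            row[f"{cls}_pct"] = pct
            row[f"{cls}_pct_rendered"] = render_percent(pct, percent_decimals)
        row["Total_n"] = int(sum(values))
        rows.append(row)
    total_row: dict = {"row": "Total"}
    for j, cls in enumerate(classes):
        pct = 100.0 * col_totals[j] / grand if grand else 0.0
        total_row[f"{cls}_n"] = col_totals[j]
        total_row[f"{cls}_pct"] = pct
        total_row[f"{cls}_pct_rendered"] = render_percent(pct, percent_decimals)
    total_row["Total_n"] = grand
    rows.append(total_row)
    return pd.DataFrame(rows)


def summarize(outputs: PipelineOutputs) -> dict[str, pd.DataFrame]:
    """The standard report tables from one pipeline run.

    Returns the removal-class distribution per plant type, the risk-case
    cross-tab (continent x consensus removal class of the measured plant's
    type), the verdict table, and the hazard-and-risk intersection list.
    """
    cons = outputs.consensus
    counts_by_ptype: dict[str, dict[str, int]] = {}
    if len(cons):
        for ptype, grp in cons.groupby("plant_type"):
            counts_by_ptype[str(ptype)] = (
                grp["consensus_class"].value_counts().to_dict()
            )
    re_distribution = distribution_table(counts_by_ptype)

    classes = ("Low", "Other", "Moderate", "High", "Excellent")
    risk = outputs.risk
    cells: dict[str, list[int]] = {}
    if len(risk):
        exceed = risk[risk["exceeds"]].copy()
        # each exceedance record is attributed to the chemical's consensus
        # class in the plant type where it was measured
        ptype_map = {}
        if len(outputs.per_record_re):
            ptype_map = dict(
                outputs.per_record_re.drop_duplicates("plant_id")[
                    ["plant_id", "plant_type"]].itertuples(index=False,
                                                           name=None))
        cons_map = {(r["cas"], r["plant_type"]): r["consensus_class"]
                    for _, r in cons.iterrows()} if len(cons) else {}
        for _, r in exceed.iterrows():
            ptype = ptype_map.get(r["plant_id"])
            cls = cons_map.get((r["cas"], ptype), "NoData")
            if cls not in classes:
                continue
            row = cells.setdefault(str(r["continent"]),
                                   [0] * len(classes))
            row[classes.index(cls)] += 1
    risk_by_continent = crosstab_table(cells, classes) if cells else \
        pd.DataFrame(columns=["row", "Total_n"])

    intersection = outputs.prioritized[
        outputs.prioritized["intersection"]].reset_index(drop=True) \
        if len(outputs.prioritized) else outputs.prioritized

    return {
        "re_distribution": re_distribution,
        "risk_by_continent": risk_by_continent,
        "verdicts": outputs.verdicts,
        "intersection": intersection,
    }
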