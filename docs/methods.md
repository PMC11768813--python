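# Methods

This note documents the models and procedures implemented in `ppcpscreen`,
the choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Record quality and plant typology

A literature record is one chemical × plant × source observation. Its
quality index (QI) is the sum of three sub-scores in {0, 1, 2} — molecule
identification, removal-efficiency data, general plant information — mapped
to classes as 0–1 Low, 2–3 Moderate, 4–5 Good, 6 Excellent. The class
mapping is fixed; the rubric that produces each sub-score is deliberately
*not* fixed here, because how a curator awards 0/1/2 depends on the corpus
being curated. The package therefore accepts pre-assigned sub-scores in the
records CSV, and the generator draws them from a configurable distribution.
QI-Low records are excluded before any downstream stage, and a chemical
whose every record is excluded disappears from the roster.

Plant typology separates WWTP1 (primary/secondary treatment only) from
WWTP2 (tertiary/advanced treatment present). A declared treatment level
decides directly. When only free-text technology tokens are available, they
are matched against a configurable tertiary-keyword list (advanced
oxidation, disinfection, sand filtration, chemical nutrient removal,
ozonation, UV, activated carbon): at least two distinct tertiary
technologies, or an explicit "tertiary" token, give WWTP2; a single
ambiguous tertiary token gives WWTP1. The two-token rule operationalizes a
worst-case reading of ambiguous plant descriptions: one isolated mention of,
say, sand filtration is weak evidence that a full tertiary train exists.

## Removal efficiency

Per record, in order of precedence:

1. the RE reported by the source, if any;
2. the load-based mass balance
   `RE% = (Ci·F − [Ce·F + Cs·TSP]) / (Ci·F) · 100`
   when all five parameters are present (Ci, Ce in ng/L; Cs in ng/g wet
   weight; F in L/d; TSP in g/d wet weight — every term is a load in ng/d);
3. the concentration ratio `RE% = (1 − c_effl/c_infl)·100`, preferring
   median over mean statistics when both are on offer;
4. NoData.

Negative RE is retained: it reflects apparent in-plant formation
(de-conjugation of excreted conjugates, metabolite back-transformation).
When the sludge term Cs·TSP is exactly zero the mass balance delegates to
the concentration ratio, so the algebraic identity between the two holds
bit-for-bit rather than to rounding error.

Classes partition the real line with upper-closed bins: Other (−∞, 0], Low
(0, 50], Moderate (50, 75], High (75, 95], Excellent (95, ∞). Class bins
are evaluated on the unrounded percent.

Censoring: by default any censored influent or effluent concentration
yields NoData. An alternative policy (`formation`) reads a censored
influent with a detected effluent as in-plant formation and assigns Other;
both policies are explicit options because non-detect handling is a
corpus-level curation decision.

Consensus per chemical × plant type: the modal class wins; ties among modal
classes break to the worst class under Other < Low < Moderate < High <
Excellent (Other sits below Low because a negative RE is worse evidence than
a small positive one); a NoData mode defers to the remaining classes; only
an all-NoData pool yields NoData. WWTP1 and WWTP2 pools are voted
separately. Chemicals with consensus Low or Other are labelled resistant to
treatment. The vote is permutation-invariant and is tested exhaustively
against a brute-force mode-then-worst enumeration over all multisets of size
≤ 5.

## Hazard screening

Each endpoint used by the threshold rules is reduced to one value per
chemical:

- experimental Log Kow / Log Koc, when available, wins outright;
- otherwise the arithmetic mean of predictions that are inside their model's
  applicability domain (AD) at the regulatory screening level;
- for Log Koc, when the MCI-based model is out of its AD, the soil-sorption
  model alone is used (when both are in the AD their mean is used — the
  fallback governs only the out-of-AD case);
- the bioconcentration endpoint has a single model, catalogued at the
  additional screening level; it nevertheless feeds the regulatory B/vB
  rules because those rules are defined on Log BCF;
- no usable value leaves the endpoint unassessable, which propagates as
  "not flagged" (never as a default value).

Screening rules, all strict comparisons:

| flag | rule |
|------|------|
| pP/pvP | BIOWIN3 < 2.25 **and** (BIOWIN2 < 0.5 **or** BIOWIN6 < 0.5) |
| pB | Log Kow > 4.5 **or** Log BCF > 3.3 |
| pvB | Log BCF > 3.7 |
| pM | Log Koc < 4 (conservative) / < 3 (EU-2023) |
| pvM | Log Koc < 3 (conservative) / < 2 (EU-2023) |
| pT | min EC50/LC50 < 0.1 mg/L (strict variant: 0.01) |
| pED | ER or AR binder, or any hTTR binding strength |

The or-combination of the two fast-biodegradation probabilities is the
default (standard screening practice: either probability below 0.5 is
sufficient evidence against fast degradation); an and-variant is
config-selectable. Toxicity models predict −log10 molar concentrations;
mol/L values convert as `10^(−p)·MW·1000` mg/L and mmol/L as `10^(−p)·MW`.

Labels: PBT = pP∧pB∧pT, PMT = pP∧pM∧pT, vPvB = pvP∧pvB, vPvM = pvP∧pvM.
The BIOWIN battery cannot distinguish P from vP, so the verdict carries one
joint persistence flag and the very-persistent flag defaults to false; vPvB
and vPvM therefore only appear when very-persistence is asserted
explicitly. This matches how screening verdicts are reported in practice: a
chemical with pvM but unconfirmed vP is labelled PMT, not vPvM.

Additional (L2) models — the global half-life index and the combined
PBT-index — contribute annotation strings to the verdict's provenance and
never enter the label logic.

Ionizable chemicals are assessed as neutral species. This is a known
limitation: partitioning and sorption of ionized forms differ substantially
from the neutral form, so Log Kow/Log Koc screening for strong acids and
bases should be read as indicative only.

Two built-in threshold profiles are provided, `conservative_2019`
(Log Koc < 4 / < 3) and `eu_2023` (Log Koc < 3 / < 2); YAML files can
override any cut-off or add named profiles. The conservative mobile set
provably contains the EU-2023 mobile set for every input.

## Risk quotients

PNEC = (minimum predicted acute toxicity across trophic levels) / AF, with
AF = 1000 by default. Lethal fish endpoints (pLC50) and effect endpoints for
algae/*Daphnia* (pEC50) are kept separate, giving PNEC(LC50) and
PNEC(EC50); the endpoint-token prefix decides the partition and is
overridable. Only in-AD predictions enter the minima. For every measured
effluent concentration CA (ng/L), PR = CA/PNEC; a chemical is risk-flagged
when any PR > 1 (strictly — PR = 1.0 is not a flag), and chemicals without
measured CA are excluded from risk quantification entirely rather than
imputed. The prioritized table intersects hazard labels (PMT or PBT under
any evaluated profile) with the risk flag.

## Synthetic benchmark

The generator emulates the pipeline's full input stack from four archetypes
(PMT-like, PBT-like, ED-only, benign) in configurable proportions (default
0.25/0.25/0.2/0.3). Per chemical, true property values are drawn from
narrow normals clipped at 3.5 truth-sd, whose means keep every drawn value
at least three prediction-noise-sd away from each threshold the archetype
is designed to clear (e.g. PMT-like: BIOWIN3 ~ N(1.7, 0.05) against the
2.25 cut-off, Log Koc ~ N(1.8, 0.15) against 3, true toxicity ~ 0.01 mg/L
against 0.1). Predictions are truth plus independent Gaussian noise per
endpoint family (defaults: 0.15 log-units for Kow/Koc/BCF and toxicity,
0.10 for BIOWIN3, 0.05 for the probabilities), with AD dropout as an
opt-in stressor (default 0: the margin guarantee concerns measurement
noise, and losing the single BIOWIN3 model would make persistence
unassessable regardless of margins).

Removal: true RE per chemical is N(55, 25) in WWTP1 plus an uplift of
N(15, 5) in WWTP2, clipped to [−30, 99] — the lower tail produces genuine
negative-RE/Other-class chemicals. Influents are log-normal (median 1000
ng/L, log-scale 1.0); effluent = influent·(1 − RE/100)·(1 + ε) with
ε ~ N(0, cv), cv = 0.05 by default, so high cv produces negative-RE records
even for well-removed chemicals. Values below the limit of quantification
(default 5 ng/L) are censored on influent and effluent independently,
exercising both censoring policies. A fraction of records carry a reported
RE (0.3) or mass-balance parameters with a zero sludge term (0.1) to
exercise the full precedence chain without perturbing the ground truth.
Default problem sizes — 200 chemicals, 13 plants across five continents,
roughly 3 300 records — run the full generate-and-recover cycle in a couple
of seconds.

Ground-truth labels are defined as what the verdict engine returns on the
noiseless truth, which makes label recovery a pure measure of noise
robustness, and by construction recovery is 1.0 at zero noise and ≥ 0.99 at
the default noise. What passing these tests shows: the stages compose
correctly, the thresholds are applied exactly, and Gaussian prediction
error within the stated sd does not flip verdicts built with the stated
margins. What they do not show: robustness to real QSAR error structure
(correlated across models, heavy-tailed, chemistry-dependent), to mixtures
of statistics in the literature, or to borderline chemicals sitting *on*
thresholds — the published screening's borderline cases (e.g. a chemical
with mean Log Koc 3.25 flagged mobile under one profile and not the other)
are covered instead by the transcribed reference tables.

## Numerical and degenerate-input choices

- Class bins and threshold comparisons use exact floating-point comparisons
  on unrounded values; percentages in summary tables are computed against
  column totals at full precision and rounded only at render time (integer
  percent for distribution tables, two decimals for the risk cross-tab).
- A zero or censored influent makes the concentration ratio undefined →
  NoData, never an exception; an empty class pool is a validation error.
- Probability endpoints are validated into [0, 1]; the generator clips
  noisy probabilities rather than redrawing.
- All randomness flows through one `numpy` Generator seeded from the
  config; identical configs produce byte-identical CSVs (fixed float
  format `%.10g`).
- The pipeline computes every stage before writing anything, so a failure
  leaves no partial output directory; the manifest records the config hash,
  package version and stage row counts.
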