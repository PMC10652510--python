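# Cohort column dictionary

One row per patient; CSV (UTF-8, header row) or columnar (parquet) with
identical content. Missing values are empty cells; booleans serialize as
`true`/`false`; minute lists are `;`-joined integers. All times are integer
minutes; in-hospital event minutes count from hospital arrival on a 0–120
clock (an event at minute t occupies [t, t+1); 120 marks administrative
censoring).

## Baseline / pre-hospital covariates

| column | type | levels / units | missing allowed |
|---|---|---|---|
| id | string | unique patient id | no |
| sex | categorical | male, female | yes |
| age | integer | years (>= 0) | yes |
| witnessed | boolean | arrest witnessed | yes |
| bystander_cpr | boolean | | yes |
| initial_rhythm | categorical | VF_VT, PEA, asystole | yes |
| bystander_aed | boolean | AED applied by bystander | yes |
| physician_staffed | boolean | physician-staffed ambulance/helicopter | yes |
| shock_by_paramedic | boolean | defibrillation by paramedic | yes |
| advanced_airway | categorical | intubation, SGA, none | yes |
| prehosp_adrenaline_n | integer | IV adrenaline doses, 0–5 (top-coded at 5) | yes |
| prehosp_rosc | boolean | any pre-hospital ROSC | yes |
| call_to_hospital_min | integer | minutes, > 0 | yes |
| rhythm_on_arrival | categorical | VF_VT, PEA, asystole | yes |
| hospital_id | string | | no |
| arrest_cause | categorical | medical, external | no |
| resuscitation_attempted | boolean | | no |
| arrest_on_ems_contact | boolean | arrest present at first EMS evaluation | no |
| rosc_before_arrival_sustained | boolean | sustained ROSC before/on arrival | no |

The first listed level of each categorical is the reference level for
model coding. Shockable rhythm = VF_VT; non-shockable = PEA or asystole.

## In-hospital timeline and outcomes

| column | type | levels / units | missing allowed |
|---|---|---|---|
| defib_minutes | minute list | in-hospital defibrillations | list may be empty |
| intubation_minute | integer | minute of in-hospital intubation | yes (never intubated) |
| adrenaline_minutes | minute list | in-hospital adrenaline doses | list may be empty |
| ecpr_minute | integer | minute ECPR started | yes (no ECPR) |
| disposition | categorical | ROSC, death, ECPR, censored | yes (raw data only; excluded) |
| disposition_minute | integer | minute of final ED disposition | with disposition |
| survival_30d | boolean | alive at 30 days | no |
| cpc_1_2 | boolean | favourable neurological outcome (CPC 1–2) | no |

Consistency rules enforced on read: `disposition == ECPR` iff
`ecpr_minute == disposition_minute`; `disposition == censored` iff
`disposition_minute == 120`; `cpc_1_2` implies `survival_30d`; intervention
minutes are sorted and never after the final disposition.
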