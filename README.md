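# traumacast

Population PTSD caseload projection across trauma-exposure strata.

The package implements an evidence-based burden model in four stages:

1. **Screening** (`traumacast.screening`) — eligibility rules for
   study-level prevalence records: minimum months after exposure,
   point-prevalence only, exclusion of help-seeking/clinical-setting
   samples and re-analyses, an exposure-specific requirement for
   questionnaire measurements, a corpus-wide preference for clinical
   assessments, highest-prevalence wave selection in longitudinal samples,
   and a configurable correction factor (default 0.71) deflating
   questionnaire-only corpora.
2. **Meta-analysis** (`traumacast.meta`) — random-effects pooling of
   prevalence proportions implemented from the formulas: raw/logit effect
   sizes with continuity correction, DerSimonian–Laird and REML τ²
   estimators, inverse-variance pooling, Q/I² heterogeneity, z-based
   confidence intervals and t-based prediction intervals.
3. **Estimate derivation** (`traumacast.derivation`) — per-stratum
   estimates assembled by meta-analysis, borrowing another stratum's
   estimate, or averaging two strata's points and interval endpoints;
   dependencies are resolved topologically and cycles rejected. Displayed
   (rounded) values and unrounded *carried* rates are propagated
   separately, so borrowed/averaged strata project from exact source rates.
4. **Projection** (`traumacast.projection` / `traumacast.pipeline`) —
   resolution of exclusive group sizes (reassignments toward
   higher-prevalence strata, residual group absorbs the remainder),
   size × prevalence caseload projection with half-up person rounding, and
   national totals, ranges, and percentage.

`traumacast.simulate` generates every input synthetically — study corpora
with known random-effects structure and planted screening violations
(with ground-truth labels), and full multi-group scenarios with known true
prevalences — so the whole pipeline is testable offline.

Two scenario fixtures ship with the package (`traumacast/fixtures/`):
`national_table.yaml` encodes a published six-stratum national results
table verbatim (sizes, estimates, ranges, counts), and
`national_model.yaml` recomputes the two modeled strata (borrow and
average modes) from their source groups' carried rates.

## CLI

```sh
# screen a corpus and write the decision audit
traumacast screen --corpus corpus.csv --out decisions.json

# screening + random-effects meta-analysis of one corpus
traumacast pool --corpus corpus.csv --estimator REML --scale raw \
    --intervals both --out pooled.json --forest forest.csv

# full model on a scenario (alias: traumacast report)
traumacast project --scenario src/traumacast/fixtures/national_table.yaml \
    --out out/

# synthetic inputs
traumacast simulate meta --config meta_cfg.yaml --out sim/
traumacast simulate scenario --config scen_cfg.yaml --out scen/
```

`project` writes `report.json` / `report.csv` (per-stratum sizes,
estimates, expected counts, totals, national percentage), one
`meta_<group>.json` per corpus-backed stratum, and a screening audit log.
Identical inputs give byte-identical outputs.

Corpus files are CSV (header `study_id,sample_id,events,n,prevalence,
method,months_post_exposure,prevalence_type,population,exposure_specific,
wave,reanalysis_of`; empty = missing) or the equivalent JSON-lines.
Scenarios are YAML/JSON: `national_population` plus a list of groups with
`raw_size`, optional `reassignments`, optional `residual: true`, and a
`derivation` block (`mode: meta|meta_adjusted|borrow|average` with either a
`corpus` path, injected `estimate`/`counts` constants, or `sources`).

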