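# ddst

An adaptive, decision-supported delirium screening instrument (CAM-based),
together with a longitudinal record store, a randomized crossover
usability-trial simulator, and the matching comparison statistics.

The package has five parts:

- **`ddst.item_bank`** — the 22-item instrument definition: items mapped to
  the four CAM features, reminders on items 1, 2 and 5, interpretation cues
  on items 11–20, eight display pages, and a hidden auto-derived
  record-comparison item (item 22). The built-in bank is a generic
  reconstruction; a licensed wording can be supplied as YAML/JSON with the
  same schema.
- **`ddst.engine`** — the assessment stepper. Items are administered in page
  order; any item whose feature already has positive evidence is jumped.
  In `fast` mode the session terminates as soon as the diagnosis is
  decidable (classifier on currently-present features equals the classifier
  on present-or-still-reachable features). The diagnostic rule is
  F1 AND F2 AND (F3 OR F4), yielding 16 outcome categories
  (3 positive, 13 negative). Item 22 is re-derived after every response by
  comparing the emerging pattern with the stored baseline.
- **`ddst.records`** — per-patient JSONL session store with strict
  `latest_before` lookup (for the item-22 derivation) and `baseline`
  (earliest session) access.
- **`ddst.simulate`** — synthetic patients (configurable delirium
  prevalence), noisy nurse assessments, 5-point Likert usability
  questionnaires (26 items paper / 43 items app), and the full 72-nurse
  two-group crossover trial. Defaults are calibrated to the published
  summary statistics (prevalence 0.26, time medians 4.4 / 2.3 min,
  usability-total means 3.40 / 4.35, 203/216 vs 212/216 successes).
- **`ddst.analyze`** — Yates-corrected chi-square / Fisher exact
  completion-rate tests, paired Wilcoxon signed-rank (exact sign-flip
  distribution for n ≤ 25, tie-corrected normal approximation otherwise),
  one-way ANOVA order-effect test, descriptive report tables, and
  sample-size planning with attrition inflation
  (`ceil(n / (1 - attrition))`).

## CLI

```sh
ddst outcomes                     # the 16-category outcome catalog
ddst assess --patient P01 --nurse N01 --mode fast --records records/
ddst history --patient P01 --records records/
ddst simulate --seed 7 --out trial.csv        # also writes trial_usability.csv
ddst analyze trial.csv trial_usability.csv --json report.json
ddst sample-size --n-analysable 54 --attrition 0.25
ddst sample-size --delta 1 --sd 1 --power 0.9
```

`ddst simulate` accepts `--design design.yaml` (keys of `TrialDesign`:
`n_nurses`, `patients_per_nurse_per_modality`, `n_patients`,
`washout_hours`) and `--config sim.yaml` (keys of `SimConfig`) to override
the calibrated defaults. Reruns with the same seed are byte-identical.

## Records format

One JSONL file per patient under the records directory; each line is a
session summary:

```json
{"patient_id": "P01", "timestamp": "2024-01-01T10:00:00+00:00",
 "combo": [false, false, false, false], "delirium": false,
 "item_values": {"1": "normal", "...": "..."}, "modality": "dst", "mode": "fast"}
```

`combo` holds the present flags for features F1–F4; `item_values` keeps the
cognitive test items (1–7) used by the change-from-baseline derivation.

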