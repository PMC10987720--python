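# CSV table schemas

All pipeline artefacts are plain CSV files with one header row. A run
directory written by `wmtransfer simulate-study` contains the tables
below plus `run_config.yaml`, the full configuration (master seed
included) that reproduces it.

## participants.csv

One row per retained participant.

| column | type | meaning |
|---|---|---|
| participant_id | str | unique id |
| group | EG \| CG | randomized arm (experimental / control) |
| age | float | years |
| gender | male \| female | |
| schooling_years | float | years of formal schooling (ANCOVA covariate) |
| memory_complaints | float | subjective complaint score |
| gds | int | depression screening score (0–15) |
| mmse | int | global cognition screening score (0–30) |
| sessions_missed | int | of the 10 training sessions |
| cognition_medication | bool | medication affecting cognition |
| R_verbal, R_spatial | float | latent recollection probabilities |
| d_f_verbal, d_f_spatial | float | latent familiarity strengths |
| c | float | familiarity criterion |
| K | float | latent span capacity (items) |
| p_proc | float | processing-task accuracy |
| simple_digit, simple_spatial | float | backward-span abilities (items) |
| pretest_version, posttest_version | 1 \| 2 | counterbalanced form versions |

`excluded.csv` has the same columns plus `reason` (the triggered
eligibility rules, `; `-joined) and no version columns.

## trials.csv

One row per recognition response.

| column | type | meaning |
|---|---|---|
| participant_id | str | |
| session | pre \| post | |
| modality | verbal \| visuospatial | |
| condition | inclusion \| exclusion \| global \| local | |
| form_id | str | which frozen form was administered |
| item_id | str | item on that form |
| truth | target \| intrusion_lure \| new_lure | form's label for the item |
| response | yes \| no | |

## span_protocols.csv

One row per span level-trial.

| column | type | meaning |
|---|---|---|
| participant_id | str | |
| session | pre \| post | |
| task | reading_span \| digit_span \| spatial_span | |
| set_size | int | items to recall at this level |
| n_recalled | int | items recalled, 0..set_size |

## training_log.csv

One row per training trial.

| column | type | meaning |
|---|---|---|
| participant_id | str | |
| session | 1–10 | |
| task | one of the 7 training tasks | |
| block | 1–5 | |
| trial | 1–3 | |
| level | int ≥ 2 | difficulty (items) of the block |
| recall_correct | bool | whole-list serial recall |
| proc_accuracy | float | processing accuracy of the trial |
| block_recall_correct | int 0–3 | block feedback: trials recalled |
| block_proc_accuracy | float | block feedback: pooled processing accuracy |

## scores.csv

One row per participant × session × measure.

| column | type | meaning |
|---|---|---|
| participant_id | str | |
| group | EG \| CG | |
| session | pre \| post | |
| measure | d_i_verbal, d_n_verbal, d_i_spatial, d_n_spatial, reading_span, digit_span, spatial_span | |
| score | float | d′ value or partial-credit unit score |

## forms.csv

One row per test item of every frozen form: `form_id, modality,
condition, version, position, item_id, truth, quadrant` (quadrant is
1–4, `center`, or empty for verbal items).
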