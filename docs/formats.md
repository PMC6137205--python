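# File formats

All files are delimited text, UTF-8, one header line. The default dialect
is comma-separated (`csv`); the `smi-like` dialect uses the same columns
tab-separated. Timestamps are integer milliseconds from trial start
(0-based). Coordinates are scene-camera pixels (1280 x 960 frame).

## Gaze stream (`*_gaze.csv`)

| column | type | meaning |
|---|---|---|
| `t_ms` | int | sample timestamp, strictly increasing |
| `x_px` | float | horizontal gaze position |
| `y_px` | float | vertical gaze position |
| `valid` | 0/1 | tracker validity flag |

Rows with coordinates outside the frame (or non-finite) are kept but
re-flagged invalid on read (logged reason `out_of_range`). Non-monotone
timestamps are a format error naming the first offending row.

## Frame annotations (`*_annot.csv`)

| column | type | meaning |
|---|---|---|
| `t_ms` | int | frame timestamp |
| `cyl_base_x`, `cyl_base_y` | float | cylinder base point |
| `cyl_apex_x`, `cyl_apex_y` | float | cylinder apex point |
| `tip_x`, `tip_y` | float or empty | chopstick-tip point; empty = occluded |
| `phase` | str | `with_marble`, `without_marble`, or `other` |
| `in_setup` | 0/1 | frame shows the experimental setup |

A phase label outside the vocabulary is a schema error.

## Trial events (`*_events.csv`)

Tidy event log, one timestamp per row:

| column | type | meaning |
|---|---|---|
| `event` | str | `trial_start`, `trial_end`, `grasp_onset`, `grasp_success`, `drop`, `return_complete` |
| `cycle` | int or empty | cycle index for cycle events; empty for trial rows |
| `t_ms` | int | timestamp |

Exactly one `trial_start` and one `trial_end` row are required. Cycles
missing any of the four cycle events are dropped with a logged
`incomplete_cycle` reason. An empty cycle list is a valid trial with zero
successful drops.

## Run configuration (JSON)

Keys of `RunConfig`: `dispersion_px` (default 100), `min_fix_duration_ms`
(80), `lead_threshold_mm` (36), `cylinder_physical_length_mm` (required),
`setup_roi` = `[x0, y0, x1, y1]`, `dialect` (`csv` | `smi-like`),
`max_gap_samples` (2). A combined pipeline config may nest these under
`"run"` and generator parameters under `"simulation"`.

## Outputs

* `summaries.csv` — one row per subject x session: `mdpm_mean`,
  `mdpm_sem`, `mdpm_per_trial` (`;`-joined), `grasp_ms_mean`,
  `liftdrop_ms_mean`, `return_ms_mean`, and for eye-tracked sessions the
  percentage columns (`anticipatory_pct`, `confirmatory_pct`,
  `<strategy>_<difficulty>_pct`), `<strategy>_per_drop`, and the cell
  means `dur_<strategy>_<difficulty>` / `lead_<strategy>_<difficulty>`.
* `classified_fixations.csv` — one row per detected fixation with
  centroid, dispersion, `lead_mm`, `strategy`, `difficulty`, and
  `exclusion_reason` (`not_transport`, `off_setup`, `no_tip`, or empty).
* `report/*.csv` — one table per multiplicity family (`effect`,
  `stat_kind`, `stat`, `df`, `df_denom`, `p_raw`, `p_adjusted`,
  `effect_size_r`); `report/narrative.txt` — plain-text summary.
* `learning_curve.json` — `a`, `b`, `r_squared` of the MDPM ~ ln(session)
  fit.
* `manifest.json` — config hash, seed, package versions, input/output
  checksums, per-stage record counts and exclusion tallies.
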