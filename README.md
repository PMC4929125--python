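# vigortrend

Age-related trends in vigorous- (VPA) and moderate-intensity (MPA)
physical activity estimated from epoch-level accelerometer count
series, with a synthetic cohort generator so the entire pipeline is
testable end-to-end without any external data.

The pipeline has four stages:

1. **Synthetic cohort** (`vigortrend.cohort`) — participant metadata and
   60-s epoch count traces whose expected daily VPA/MPA minutes decline
   geometrically with age at known per-year ratios, with configurable
   subgroup-specific baselines and ratios, person-level log-normal noise
   and day-level jitter. Also provides targeted fixtures
   (`generate_day_trace`, `inject_nonwear`) and a model-level fast path
   (`generate_person_table`) for statistical recovery studies.
2. **Epoch processing** (`vigortrend.processing`) — reintegration to
   60-s epochs, non-wear detection (≥60 min of consecutive zeros
   allowing up to 2 isolated nonzero interruption epochs), Evenson-style
   cut-point classification (sedentary <100, light 100–2295, moderate
   2296–4011, vigorous ≥4012 cpm), wear time within 07:00–24:00, valid
   days at ≥500 wear minutes, and person means over valid days
   (included at ≥1 valid day). `vigortrend.oracle` holds an exhaustive
   window-scan reference used to validate the detector.
3. **Modelling** (`vigortrend.model`) — analysis dataset construction
   (first measurement per participant, ages 5.0–18.0), winsorization of
   VPA at the 99th percentile, natural-log transform, OLS of the log
   outcome on age + wear time + study indicators, back-transformed
   per-year geometric-mean ratios with 95% CIs, age-by-subgroup
   interaction tests with stratified fits, a 2-year age-band linearity
   check, and leave-one-study-out sensitivity refits.
4. **Reporting** (`vigortrend.report`) — baseline 5.0–5.9-y band
   means, the 13-year extrapolation `ratio^13 × mean − mean`, predicted
   end values, report tables, and a reproduction of the published table
   arithmetic from its printed inputs.

## CLI

```sh
vigortrend simulate --config cohort.yaml --seed 1 --out sim/
vigortrend process  --epochs sim/epochs.csv --params params.yaml --out proc/
vigortrend analyze  --persons proc/persons.csv --metadata sim/metadata.csv --out ana/
vigortrend report   --persons proc/persons.csv --metadata sim/metadata.csv --out rep/
vigortrend repro-tables --out repro/
```

All inputs/outputs are plain CSV/JSON/YAML. `repro-tables` recomputes
every percent change and 13-year extrapolation from the printed
ratio/baseline inputs shipped in `vigortrend/data/reference_inputs.json`
and flags the one row known to disagree at the last printed digit.

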