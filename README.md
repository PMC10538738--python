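# qmus

Quantitative muscle ultrasound diagnostics as a reusable, tested pipeline:

- **`qmus.cohort`** — subject-level data model (8 studied muscles, relaxed +
  contracted thickness, fasciculation presence, MRC scores) with validated
  delimited-text I/O. Missing cells stay missing; they are never coerced to
  zeros.
- **`qmus.reference`** — age/sex-stratified lower-percentile (default 5th)
  normative thickness cutoffs built from healthy controls, with an empirical
  (type-7 quantile) and a Gaussian-parametric estimator, JSON serialization,
  and strict no-extrapolation lookup.
- **`qmus.rules`** — per-subject decision rules: per-muscle reduced-thickness
  flags (strictly below cutoff), the ≥1-abnormal-muscle rules over the relaxed
  (8) and contracted (4) muscle sets, the biceps−EDB proximal-distal
  differential, the elbow-flexion−big-toe-extension strength differential, and
  the fasciculation-count criteria (≥2 of 8 muscles; ≥1 of the proximal pair).
- **`qmus.accuracy`** — per-group sensitivity, specificity, pooled
  sensitivity, and three clearly separated AUC estimators: binary-threshold
  identity `(Se+Sp)/2`, rank-based empirical (ties = ½, no orientation
  flipping), and the binormal closed form.
- **`qmus.simulate`** — a seeded synthetic cohort generator whose default
  configuration reproduces the published group sizes (65/22/36/91/31),
  demographics, thickness means ± SDs, and fasciculation frequencies.
  Thickness marginals are independent truncated normals; per-muscle
  fasciculation probabilities are moment-matched from the published mean
  muscle counts.
- **`qmus.cli`** — `simulate`, `build-ref`, `classify`, `evaluate` commands;
  every run writes a `<out>.manifest.json` with a config digest, seed, and
  package version.

## CLI quick start

```sh
qmus simulate --defaults --seed 1 --out cohort.csv
qmus build-ref cohort.csv --out reference.json
qmus classify cohort.csv reference.json --out profiles.csv
qmus evaluate cohort.csv reference.json --out report.json
qmus evaluate cohort.csv reference.json --normal-strength-only --out subset.json
```

`evaluate` emits per-muscle abnormality rates per group, the overall
thickness-rule sensitivities/specificity with their binary-identity AUCs
(patients vs controls), and the two fasciculation rules (ALS vs everyone
else). `--normal-strength-only` restricts patients to those whose recorded
MRC scores are all 5.

## Notes on design

- "Reduced" thickness is strict: a value exactly equal to the cutoff is
  normal.
- Unmeasured muscles are excluded from rule numerators and denominators; a
  subject with no usable observations gets a missing verdict, not a negative
  one.
- Control strata too thin even for the parametric estimator fall back to
  sex-pooled (then fully pooled) controls with a warning; pass
  `allow_fallback=False` to fail instead.
- The simulator draws muscles independently, so cross-muscle correlation
  (and hence the multi-muscle rules' exact specificity) is not reproduced —
  only marginal distributions and rates are.
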