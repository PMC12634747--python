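# maskscope

Lesion **masking** — the obscuration of a breast cancer on a mammogram by
superimposed fibroglandular tissue — is a leading reason cancers are
missed at screening and surface later as interval cancers. Volumetric
breast density (VBD) predicts masking risk, but density alone is not the
whole story: *where* and *how* the dense tissue is arranged matters.

`maskscope` is a self-contained Python implementation of a masking-risk
analysis pipeline for researchers in quantitative mammography and
screening epidemiology. It covers:

- a **synthetic screening-cohort generator**: power-law breast-texture
  phantoms rendered through a two-compartment attenuation model, with
  group-wise age/VBD/visible-mass marginals calibrated to a Dutch
  screening sample (screen-detected vs interval-cancer examinations);
- **open-beam self-calibration** and per-pixel dense-tissue (VBD)
  mapping;
- **model-observer detectability maps**: prewhitening ideal-observer
  d′ = √(Σ_{f≠0} |S(f)|²/NPS(f)) for a Gaussian lesion against the local
  noise-power spectrum, evaluated over a grid of ROIs;
- **radiomic features** (detectability-map SD, GLCM Haralick correlation
  of the density map) plus age, feeding a **logistic masking-score
  model** with optional stepwise-AIC selection;
- the four-category **masking reference standard** (screen-detected /
  interval × mass visible in retrospect / not) with all inclusion and
  exclusion windows;
- **ROC validation**: Mann–Whitney AUCs with percentile-bootstrap CIs,
  a paired jackknife (pseudo-value) comparison of the masking score vs
  VBD, a Z-test against a published AUC, the three-category cumulative
  ROC, and chi-square proportion comparisons.

See `docs/methods.md` for the models, assumptions, defaults and
limitations.

## Worked example

Run the full pipeline — generate, score, evaluate — on a small synthetic
cohort of 60 examinations per group:

```sh
cat > demo.yaml <<EOF
n_screen: 60
n_interval: 60
image_size: small
out_dir: demo_run
bootstrap_B: 1000
EOF
maskscope all --config demo.yaml --seed 7
```

which writes the rendered TIFF views, the cohort and scored CSVs, ROC
figures and `report.json` under `demo_run/`, and prints the analysis-1
summary (shown here rounded to three decimals):

```json
{
 "model": {"auc": 0.726, "ci": [0.623, 0.818], "n_pos": 60, "n_neg": 60},
 "vbd":   {"auc": 0.671, "ci": [0.571, 0.763], "n_pos": 60, "n_neg": 60},
 "paired_diff": 0.055,
 "paired_p": 0.398,
 "ztest_vs_original": {"z": -0.386, "p": 0.700, "original_auc": 0.75}
}
```

Reading: the three-feature masking score separates interval-cancer from
screen-detected examinations with AUC 0.73, ahead of VBD alone
(AUC 0.67) on the same cases; at n = 60/group the paired jackknife test
does not resolve the difference (p = 0.40), and the score's AUC is
statistically compatible with the literature reference of 0.75. The
report also contains the three-category cumulative ROC (low vs
intermediate+high and low+intermediate vs high masking risk) and the
visible-mass proportion comparison.

The same steps are available as library calls
(`maskscope.pipeline.run_generate/run_score/run_evaluate`, or
`score_cohort`/`evaluate_scored` for in-memory work), and the generator
can be pointed at user-supplied grayscale images plus a cohort CSV using
the documented column schema in `maskscope.cohort_rules`.

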