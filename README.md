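# dyadlds

Latent difference score (LDS) analysis of two-informant questionnaire data:
measurement-invariance testing with a capped partial-invariance search,
LDS structural equation models for parent-vs-adolescent report discrepancy,
conditional models for binary moderators, inverse-probability nonresponse
weighting, and a synthetic dyad generator with known latent truth.

## What is in the box

| module | role |
|---|---|
| `dyadlds.instruments` | item dictionary (five 5-item subscales on a 0–2 scale, 6-item distress screen on 0–4), deterministic scoring, reverse-coding, covariate recoding, CSV dialect |
| `dyadlds.synthetic` | dyadic generator: correlated reporter factors with a latent discrepancy, ordinal items via thresholding, explicit non-invariance channel, covariate effects, unit/item missingness, exact calibration to target item moments |
| `dyadlds.weights` | IRLS logistic propensity model, trimmed inverse-probability weights, survey-weight combination (normalized to mean 1) |
| `dyadlds.sem` | SEM engine with mean structure: implied moments and analytic gradients, weighted ML and FIML estimation, observed-information and sandwich SEs, CFI/RMSEA/SRMR, chi-square differences, score-test modification indices |
| `dyadlds.invariance` | configural → metric → scalar ladder across reporters (ΔCFI ≤ .010, ΔRMSEA ≤ .015 acceptance), partial-invariance rescue freeing at most 2 loadings + 2 intercepts per construct |
| `dyadlds.lds` | unconditional and conditional LDS models, standardized discrepancy estimates, delta-method 95% CIs for per-level nonlinear combinations |
| `dyadlds.pipeline` / CLI | config-driven orchestration: descriptives → univariate CFA gate → invariance → LDS → conditional models → FIML sensitivity rerun |

Conventions (flagged in output): marker-variable identification (first item
loading 1, intercept 0; latent means free), chi-square `T = Σ n_g F_g` with
group size `n` (not `n−1`), SRMR over covariance residuals only. Robust
(scaled) test statistics are not implemented; sandwich SEs stand in.

## CLI

```bash
# generate a synthetic cohort (CSV + latent-truth sidecar)
dyadlds simulate --n 2000 --seed 7 --out dyads.csv

# invariance ladder for one construct
dyadlds invariance --data dyads.csv --construct conduct

# unconditional LDS (runs the ladder first unless --skip-invariance)
dyadlds lds --data dyads.csv --construct conduct

# full pipeline from a YAML config
dyadlds fit --config study.yaml --seed 1 --out out_dir
```

A minimal `study.yaml`:

```yaml
generator:            # or: input_csv: path/to/dyads.csv
  n_dyads: 2000
  with_missingness: true
constructs: [conduct, emotion, peer, prosocial]
moderators: [sex, distress, edu]
seed: 1
out_dir: study_out
```

Input CSV layout: one row per dyad with columns
`<construct>_<reporter>_i{1..5}` (raw ratings; reverse-coded items are
flipped internally), `k6_i{1..6}`, `sex`, `edu`, `svywt`, `complete`.
Blank cells are missing.

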