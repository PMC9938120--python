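# dsrt

An ex vivo drug sensitivity and resistance testing (DSRT) analysis pipeline
for patient-derived cancer cell screens, from raw 384-well plate luminescence
readouts to cohort-level statistics:

- **plate normalization** — DMSO-negative / cytotoxic-positive control based
  conversion of raw signal to %inhibition, with Z′-factor plate QC
  (`dsrt.normalize`);
- **dose-response fitting** — constrained four-parameter logistic fits with a
  multi-start grid and closed-form asymptote profiling (`dsrt.curves`);
- **drug sensitivity scoring** — closed-form partial AUC over a 10–100%
  activity window (DSS1 and the asymptote-penalised DSS3), selective DSS
  against healthy-control profiles, and DSS ≥ 10 effectiveness calls
  (`dsrt.dss`);
- **target addiction scoring** — per-target mean DSS over all inhibitors
  hitting a target (potency-thresholded polypharmacology map), with one-sided
  permutation p-values (`dsrt.tas`);
- **combination synergy** — highest-single-agent (HSA) excess scoring of 7×7
  dose matrices (`dsrt.synergy`);
- **cohort analysis** — subtype group statistics (Welch t, one-way ANOVA,
  SEM), pairwise-subtype Spearman correlations, Ward/Euclidean clustering,
  PCA, and empirical-Bayes moderated-t differential drug sensitivity with
  Benjamini–Hochberg adjustment (`dsrt.cohort`);
- **synthetic screens** — a generator of raw plate tables, drug libraries,
  drug–target bioactivity maps, healthy-control panels and planted-synergy
  combination matrices with full ground truth, so every stage is testable
  without access to patient data (`dsrt.simulate`).

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (DSS closed form vs
adaptive quadrature, monotonicity/unit-invariance properties, 4PL parameter
recovery, TAS oracle equivalence and permutation-null uniformity, HSA
planted-excess recovery, cohort subtype recovery on the default 16-sample /
526-drug synthetic cohort, closed-form statistical oracles, and end-to-end
byte reproducibility).

## CLI

```sh
# generate a synthetic cohort screen (raw wells + library + targets +
# healthy controls + two combination matrices + ground-truth sidecar)
dsrt simulate --out sim/ --seed 1

# run every stage: normalize -> fit -> dss -> sdss/tas/cohort/synergy
dsrt run-all --indir sim/ --out run/ --seed 1
```

Individual stages are also exposed (`dsrt normalize`, `dsrt fit`, `dsrt dss`,
`dsrt tas`, `dsrt synergy`, `dsrt cohort`); every stage reads and writes plain
CSV with documented schemas (`dsrt.io`), and `run/manifest.txt` records the
config digest, seed, per-stage row counts and output SHA-256 digests — two
runs with the same inputs and seed are byte-identical.

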