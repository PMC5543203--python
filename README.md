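# ki67assay

A reimplementation of the computational workflow behind a Ki-67
immunohistochemistry clinical trial assay for neoadjuvant endocrine therapy
monitoring, exercised end-to-end on synthetic histology:

- **`synthetic`** — generators for ground-truth cell maps (nucleus class,
  position, Ki-67 status), rendered RGB fields (hematoxylin/DAB Beer-Lambert
  color model), patient cohorts with stratum-specific relapse hazards, and
  paired blinded-rater scores (logit-normal field noise + binomial counting).
- **`vpc`** — visual point counting: systematic horizontal grid-line sampling
  with the ≥200-cell rule, every-third-line counting, and exhaustive fallback.
- **`image_scoring`** — the automated pathway: AOI selection (3–10 clean
  windows), a transparent color-deconvolution nuclei detector standing in for
  commercial software, the four complex-histology triage flags (lymphocyte-rich,
  sparse/streaming tumor, fibroblast marking, faint stain), and the SOP that
  routes each case to image analysis or VPC.
- **`pepi`** — 2.7% / 10% cut-point calls and (modified) PEPI-0 classification.
- **`concordance`** — 2×2 contingency tables, PPA/NPA with exact
  Clopper–Pearson intervals, Cohen's kappa (Fleiss–Cohen–Everitt CI),
  Pearson/Spearman correlations, Bland–Altman bias.
- **`survival`** — Kaplan–Meier, two-group log-rank, reverse-KM median
  follow-up.
- **`cutpoint`** — ROC (midpoint thresholds, Mann–Whitney-consistent AUC) and
  Youden-optimal cut-point selection.
- **`pipeline`** — the full validation run (simulate → two-rater SOP scoring →
  concordance at 2.7/10 → PEPI → KM/log-rank → ROC) with REMARK-style flow
  accounting and seed/config-hash provenance; byte-reproducible per seed.

## CLI

```bash
ki67 run --out rundir --n 200 --seed 1          # full pipeline
ki67 simulate --n 50 --seed 1 --out sim --emit-maps 5
ki67 vpc --cellmaps sim/maps --grid-spacing 12 --count-every 1 --out vpc.csv
ki67 sop --cases sim/cohort.csv --fields sim/maps --out sop.csv
ki67 concordance --pairs pairs.csv --cutpoint 2.7 --out stats.json
ki67 pepi --cohort sim/cohort.csv --out pepi.csv
ki67 survival --cohort pepi.csv --stratify modified_pepi0 --out km.json
ki67 roc --cohort sim/cohort.csv --out roc.json
```

Cohorts and scores are CSV; cell maps are JSON (one record per nucleus);
summaries are JSON with a provenance block (seed, config SHA-256, version).

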