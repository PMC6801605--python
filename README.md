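# mabpen

Quantification of monoclonal-antibody microdistribution in tumor tissue
sections, and two-arm dosing-regimen efficacy analysis — built as a tested,
fully synthetic-data-driven analysis pipeline.

## The problem

In radioimmunotherapy of solid tumors, a radiolabeled antibody (here an
anti-HER2 antibody in a gastric-cancer xenograft model) must penetrate from
the tumor edge and from perfused blood vessels into the tumor core. Whether
splitting the dose (fractionated dose, **FD**) improves penetration or
efficacy over a single dose (**SD**) is assessed from:

* **penetration profiles** — fluorescence intensity *I(d)* of the labeled
  antibody versus distance *d* (µm) from the tumor edge or from the nearest
  vessel wall, out to 80 µm, summarized by the trapezoidal area under the
  curve, AUC = ∫ I(d) dd;
* **whole-tumor accumulation** — total antibody intensity inside the tumor
  divided by tumor area (a.u./µm²);
* **efficacy** — caliper tumor volume *V* = width² × length × 0.5 (mm³)
  followed for 30 days, and Kaplan–Meier survival with a two-group log-rank
  test; scalar endpoints are compared with a two-sided Welch *t*-test.

The original tissue images and animal tables are not public, so the pipeline
is driven by a synthetic three-channel section generator (nuclei / antibody /
vessel) whose antibody field is a known double-exponential,

> I(x) = b + A_e·exp(−d_edge(x)/λ_e) + A_v·exp(−d_vessel(x)/λ_v),

giving every downstream stage an exact ground-truth oracle, plus a two-arm
exponential-growth cohort generator for the efficacy stage.

## Worked example

The numbered scripts under `analysis/` reproduce the whole study at desk
scale (2 groups × 3 tumors × 10 sections, both groups generated under
identical — null — conditions):

```bash
python analysis/01_simulate_study.py --seed 1   # sections -> scratch/, tables -> results/
python analysis/02_analyze_study.py  --seed 1
python analysis/03_calibration.py    --seed 1
```

The analysis step prints:

```
mabpen run 5f0cf067d2ff (seed 1): 60 sections
mean per-section AUC_raw (a.u.·µm):
  SD/edge: 43.91
  SD/vessel: 49.61
  FD/edge: 44.70
  FD/vessel: 51.38
mean accumulation (a.u./µm²):
  SD: 0.3416
  FD: 0.3415
two-group comparisons:
  welch_t_auc_edge: stat=-1.556 p=0.125 (not significant)
  welch_t_auc_vessel: stat=-1.617 p=0.111 (not significant)
  welch_t_accumulation: stat=0.068 p=0.946 (not significant)
  welch_t_volume_day30: stat=1.260 p=0.228 (not significant)
  logrank_survival: stat=0.220 p=0.639 (not significant)
```

AUC_raw integrates the mean intensity profile over the 80-µm depth (so a
uniform intensity of 1 would give 80 a.u.·µm); accumulation is intensity per
µm² of tumor. Because both arms are simulated from the same parameters,
every p-value lands above 0.05 — the expected no-difference outcome. The
calibration step reports that the fitted penetration decay lengths recover
the generator's λ within a few percent (median) and that the null rejection
rate of the Welch comparison is ≈5% at α = 0.05.

Tables (`profiles.csv`, `auc.csv`, `accumulation.csv`, `km_curves.csv`,
`comparisons.csv`, …) and plots land in `results/`. The same pipeline is
scriptable via the `mabpen` CLI (`simulate`, `analyze`, `report`, with
`--config/--seed/--outdir/--pixel-size-um/--max-depth-um`) or directly
through the library (`mabpen.generate_section`, `mabpen.edge_profiles`,
`mabpen.vessel_profiles`, `mabpen.profile_auc`, `mabpen.total_accumulation`,
`mabpen.km_estimate`, …). Real sections exported as 3-page TIFFs (and
optional hand-drawn mask TIFFs) can be analyzed by pointing the config at
them instead of the generator.

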