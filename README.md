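# cthasym — cortical thickness asymmetry analysis

`cthasym` studies whether schooling experience leaves a structural trace in
the brain. Cortical thickness (CTh) is remarkably symmetric between
hemispheres in healthy development, so small, regionally specific
asymmetries are a candidate marker of experience-dependent plasticity.
The package implements a complete analysis pipeline for a cross-sectional
schooling cohort — students from two pedagogies (Montessori vs
traditional) plus a young-adult reference group — working from
FreeSurfer-style regional statistics, together with a synthetic-cohort
generator that reproduces the cohort's statistical structure so the whole
pipeline is testable without access to the original MRI data.

It is written for researchers in pediatric neuroimaging and educational
neuroscience who want a tested, reproducible implementation of the
region-gated asymmetry analysis, or who want to run power/recovery
experiments against its published effect sizes.

## The statistics

For the ROIs *R* of the Desikan–Killiany parcellation (34 labels per
hemisphere), each with mean thickness CTh_R (mm) and pial surface area
CSA_R (mm²), the surface-area-weighted thickness of a region set *L*
(a lobe, or the whole brain) is, per hemisphere,

    WCTh_L = Σ_{R∈L} CTh_R · CSA_R / Σ_{R∈L} CSA_R

and the asymmetry index of a region is

    AI = (WCTh_lh − WCTh_rh) / (WCTh_lh + WCTh_rh)

dimensionless, in (−1, 1), positive = thicker left cortex. AI is computed
at three levels: whole brain, six lobes (frontal, parietal, temporal,
occipital, cingulate, insula — the temporal lobe has exactly nine
subregions, including parahippocampal), and each subregion.

Inference proceeds in three layers:

1. **Group homogeneity** — pooled-variance Student *t* (with Cohen's *d*)
   on age, socioeconomic status (SES), fluid intelligence (FIV) and home
   environment (HEV); plain Pearson χ² (df 1, no continuity correction) on
   sex and handedness.
2. **Students vs adults** — pooled *t* on whole-brain AI plus an ANCOVA on
   group + age + group×age (each term F with (1, n−4) df).
3. **Down-scaling cascade** — per region, OLS of AI on age, pedagogy
   (traditional − Montessori), sex (male − female), SES, and age×pedagogy,
   with listwise deletion. The whole-brain model gates the four classical
   lobes; each lobe whose omnibus F-test reaches α = 0.05 gates its own
   subregions. Within each stage, every term's p-values are
   Benjamini–Hochberg FDR-adjusted across the family of sibling regions
   (4 lobes; 9 temporal subregions).

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic cohort (seed 1270) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_compute_asymmetry.py
python analysis/03_demographic_homogeneity.py
python analysis/04_adults_vs_students.py
python analysis/05_hierarchical_regression.py
python analysis/06_parameter_recovery.py
```

The cascade output of step 05:

```
whole_brain: gates open -> ['whole_brain']
lobe: gates open -> ['temporal']
subregion: gates open -> ['bankssts', 'entorhinal', 'fusiform', ...]
  ...
  parahippocampal: age x pedagogy beta = -0.00648, p = 0.000
```

reads: the whole-brain regression was significant, so the four lobes were
tested; only the temporal lobe survived its omnibus test, so only its nine
subregions were fitted. The negative age×pedagogy coefficient means that
with every year of schooling, traditionally schooled students drift toward
a relatively thicker *right* parahippocampal cortex compared with
Montessori students (who stay leftward) — the pattern the generator
injected. Step 06 closes the loop quantitatively: refitting a fresh
n = 1000 cohort recovers every injected coefficient within 2 standard
errors (`largest |recovered - injected| = 1.81 SE`).

The same pipeline runs from the shell (`cthasym run --seed 5 --out out/`),
and each stage is a subcommand (`simulate`, `compute-ai`, `homogeneity`,
`compare-groups`, `downscale`, `report`) that composes to identical
outputs. Real FreeSurfer `?h.aparc.stats` files or long-format cohort
tables can be supplied through the `inputs:` block of the YAML config
instead of the simulation block.

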