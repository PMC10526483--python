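# Methods

## The measurement model

The pipeline consumes per-subject, per-hemisphere regional statistics in
the FreeSurfer `?h.aparc.stats` text dialect (or an equivalent long-format
table): for each of the 34 Desikan–Killiany (DK) cortical labels, a mean
cortical thickness CTh (mm, the gray/white-to-pial distance averaged over
the ROI's vertices) and a pial surface area CSA (mm²). The per-ROI mean
thickness column (`ThickAvg`) is taken as CTh_R. No image-domain
processing is performed; segmentation quality control is assumed to have
happened upstream.

ROI labels are normalized to lower case without hemisphere prefixes so
that left/right measurements join on the label. The lobe partition is the
canonical FreeSurfer assignment of the 34 DK labels with cingulate and
insula kept as separate lobes; this choice yields exactly nine temporal
subregions (superiortemporal, middletemporal, inferiortemporal, bankssts,
fusiform, transversetemporal, entorhinal, temporalpole, parahippocampal),
the granularity at which the hierarchical analysis bottoms out. The
partition property (every label in exactly one lobe) is asserted by
exhaustive enumeration in the tests.

## Aggregation and the asymmetry index

Surface-area-weighted thickness over a region set L, per hemisphere:
WCTh_L = Σ CTh_R·CSA_R / Σ CSA_R. For a single ROI the weighting
degenerates to the ROI's own thickness, which is how subregion-level AI is
defined. The asymmetry index AI = (WCTh_lh − WCTh_rh)/(WCTh_lh +
WCTh_rh) is dimensionless and scale-free; no intracranial-volume
normalization is applied because the ratio already cancels global scale.
The sign convention is left-minus-right: positive = leftward asymmetry.

Two algebraic identities are load-bearing and tested: (i) whole-brain
WCTh equals the CSA-weighted combination of the six lobe WCTh values
(partition consistency, tolerance 1e−10), and (ii) swapping hemispheres
negates every AI. The whole-brain aggregate includes all 34 ROIs,
cingulate and insula included — the definition is a sum over all R with
no stated exclusion, and the inclusion is flagged here because the
alternative (four classical lobes only) is defensible too.

Subjects missing an ROI in either hemisphere lose that region's AI (and
the ROI is dropped from that subject's lobe/whole-brain aggregates) with
a logged warning; they are not excluded wholesale. This is the
least-destructive default for a contract the input format does not
enforce.

## Demographic scores and homogeneity

SES is the arithmetic mean of parental education and profession levels
(each 0–4, one or two parents), hence in [0, 4]. HEV is the equal-weight
mean of four home-life components each mapped to [0, 100] (green-space
access, weekly family meals as n/7·100, parental interest in pedagogy,
extracurricular activity); qualitative items map through a configurable
scoring dictionary defaulting to yes/high → 100, no/low → 0. FIV is the
number of correct answers over the 36 Raven progressive-matrices items.

Homogeneity between pedagogy groups uses pooled-variance Student t-tests
(df n₁+n₂−2) with Cohen's d on the pooled SD for continuous variables,
listwise per variable, and plain Pearson χ² with df 1 and no Yates
correction for sex and handedness. Pooled (not Welch) variance and the
uncorrected χ² are deliberate: they are the classical textbook forms and
reproduce integer df bookkeeping (e.g. df 109 for 56+55 subjects, df 99
when ten SES values are missing). A variable entirely missing in one
group yields a "not computable" row rather than an exception.

## The regression layers

**Students vs adults.** Whole-brain AI per group is checked with
Shapiro–Wilk (reported descriptively; it gates nothing), compared with a
pooled two-sample t (df n₁+n₂−2), and with an ANCOVA of AI on
group + age + group×age. The ANCOVA uses Type-III sums of squares with
sum-to-zero group coding and mean-centered age (the convention of
GUI statistics packages for ANCOVA), so each term carries (1, n−4) df.

**Per-region MLR.** OLS of a region's AI on age (years), pedagogy (0/1
dummy, Montessori = 0, so the coefficient is the traditional−Montessori
contrast), sex (0/1, female = 0, male−female contrast), SES, and
age×pedagogy. Missing predictors cause listwise deletion per model; the
residual df is n_complete − 6. Rank-deficiency (a constant predictor) and
under-determined fits raise immediately rather than returning silently
unstable estimates.

**Hierarchical down-scaling.** Stage 1 fits the whole-brain model; the
cascade continues only if its omnibus F-test p ≤ α (default 0.05). Stage
2 fits the four classical lobes; stage 3 fits the subregions of every
lobe whose omnibus p ≤ α. Gating always uses the raw omnibus p. Multiple
comparisons are handled within each stage by Benjamini–Hochberg FDR
applied per coefficient across the family of sibling regions at the same
level (family of 4 at the lobe stage, of 9 for temporal subregions); both
raw and adjusted p are reported, and ties are resolved by stable sort.
BH was chosen because the family-minimum adjustments it implies
(0.030 → 0.12 and 0.004 → 0.016 in a family of four) are exact
multiplications by the family size, which pins down both the method and
the family definition. The intercept is not FDR-adjusted (it is not a
hypothesis of interest).

## The synthetic cohort generator

The generator emulates the study conditions: 56 Montessori + 55
traditional students with ages uniform on [4, 18] (the distributional
family is not identifiable from min/max/mean summaries; uniform preserves
the range), 51 adults uniform on [20, 30], sex and left-handedness
frequencies at the reported counts, SES from a truncated normal(3.1, 0.6)
on [0, 4], FIV and HEV from clipped normals around the reported group
means. Missingness is an observation mask applied as exact counts
(10 SES, 11 FIV, 13 HEV of 111 students): covariates are generated
complete, morphometry is generated from the latent complete values, and
the mask only hides table entries — missingness hides data, it does not
alter anatomy. Adults carry no SES/FIV/HEV, as in the study.

Effects are injected in AI space because the analysis models AI, not
thickness; bilateral thicknesses are a derived representation via
left = m(1+AI), right = m(1−AI) around per-subject ROI baselines. Each
configured region model (keyed by ROI, lobe, or `whole_brain`) draws one
per-subject target AI from its linear predictor plus Gaussian noise;
every ROI resolves the most specific model available, falling back to an
independent per-ROI default (null) model. Because CSA is shared across
hemispheres by default, the AI recomputed by the pipeline equals the
drawn target *exactly* at the injection level — the common (1±AI) factor
passes through the area weighting unchanged — which is what makes
coefficient-recovery experiments exact rather than approximate. An
option (`csa_asymmetric`) breaks this for stress tests.

Default coefficient sets are the published temporal-lobe and
parahippocampal regressions (e.g. temporal age×pedagogy −2.04×10⁻³ AI per
year, parahippocampal age 4.16×10⁻³), with AI noise SD 0.01. Whole-brain
group moments (students 3.82×10⁻³ ± 4.02×10⁻³, adults 2.51×10⁻³ ±
6.47×10⁻³) back a separate intercept-only *moment calibration* preset.
The default structural preset injects effects only where the study
localized them (temporal + parahippocampal) over a small uniform leftward
default (intercept 5×10⁻³), letting the whole-brain signal emerge from
aggregation; a `whole_brain_structural` preset instead carries the one
published whole-brain slope (age×pedagogy −9.23×10⁻⁴) with the intercept
calibrated so the student group mean matches the reported moment. The
structural and moment presets are deliberately separate: the published
whole-brain slope together with all other coefficients unpublished cannot
reproduce the published whole-brain SD in a single model, so conflating
them would silently mis-state one or the other.

ROI baseline thicknesses and areas (e.g. parahippocampal ≈ 2.7 mm,
700 mm²) are plausible magnitudes for healthy cortex, documented as
arbitrary configuration data: every statistic in the pipeline is
invariant to them by the scale-freeness of AI.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: within-subject covariance across regions
(regions are independent given the shared draw of their injected model),
spatial autocorrelation, realistic cortical geometry, age-dependent
thickness trajectories, and any systematic left/right CSA asymmetry.
Recovery results certify the estimator, not the biology.

## Numerical and design choices

- All randomness flows from one integer seed; per-stage sub-seeds are
  derived by hashing `seed:stage` (kept below 2³¹). Identical seed and
  config reproduce byte-identical output tables (readers use
  round-trip float parsing to keep write→read lossless).
- Problem sizes: recovery designs use n = 1000 students (balanced 500/500,
  no missingness — the recovery question is estimator calibration, not
  df bookkeeping) and noise SD 0.01; moment checks use n = 5000; the
  null-gating calibration uses 200 study-sized null cohorts, where the
  subregion stage may open in at most an α-level fraction of seeds (it
  requires the whole-brain gate *and* a lobe gate to fire by chance, so
  the observed rate sits well below α).
- Monte-Carlo bias checks compare the 50-seed mean estimate against the
  injected value with tolerance max(10 % of the truth, 3 standard errors
  of the mean): below the Monte-Carlo noise floor a bias statement is
  not falsifiable, so the floor is part of the criterion.
- The home-environment worked example in the source questionnaire (91.43 %)
  is not reproducible from its narrated equal-weight components (which
  give 96.43 %); the component scoring used for the qualitative items is
  therefore config data with a documented default, and no test asserts
  the 91.43 % figure.
- p-value families never include the omnibus test; gating and FDR are
  decoupled on purpose (gating is a hierarchical *exploration* rule; FDR
  is an *error-rate* correction within a stage).

## Known limitations

Cross-sectional emulation only; no longitudinal structure. The default
cohort's sex frequencies differ between pedagogy groups (as reported), so
occasional homogeneity flags on sex are expected sampling behaviour, not
a bug. Subregion models inside an injected lobe share that lobe's draw
exactly, so their fits are unrealistically concordant compared with real
data, where single-ROI noise would dominate. The ANCOVA's Type-III /
sum-coding convention matters only for the main-effect F values in the
presence of the interaction; df bookkeeping is convention-independent.
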