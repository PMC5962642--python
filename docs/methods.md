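# Methods

`stressdyn` implements the post-imaging analysis of a live-cell adaptive
stress-response reporter screen for drug-induced liver injury (DILI)
assessment: HepG2 BAC-GFP reporter lines for the Nrf2 oxidative-stress
(SRXN1), ER-stress (CHOP), DNA-damage (p21), and NF-κB cytokine (ICAM1)
pathways, imaged hourly for 24 h after exposure to drugs at 1–100 × C-max
(peak therapeutic plasma concentration), with propidium iodide (PI) viability
staining at 24 h. The package starts from per-cell feature tables — the image
segmentation that produces them is upstream of its scope — and carries the
analysis through to a severe-vs-non-severe DILI classifier.

## Compound set

The packaged table (`stressdyn/data/compound_annotations.csv`) holds 123
screened compounds: 118 drugs with FDA DILI-concern labels (16 no-concern,
36 less-severe, 12 ambiguous, 54 most-severe) and 5 controls (DMSO vehicle,
TNFα, and the pathway positives diethylmaleate, thapsigargin, etoposide).
Severity is derived deterministically from the concern label: most-severe
concern → `severe`, all other labelled drugs → `non_severe`. C-max values are
stored exactly as transcribed, in µM (2 nM – 0.94 mM; a narrative source
quotes 1.7 nM as the lower end, which does not match any tabulated value and
is left unreconciled). A few abbreviations were repaired during transcription
because the source rendering collides or garbles them (FA for folic acid,
MTX methotrexate, MXL mexiletine); abbreviation uniqueness is enforced at
load time.

## Synthetic screen generator

Because the deposited image-derived data is external, a generator produces
per-cell tables with the statistical structure the analysis assumes. It is
first-class, tested code; its defaults are the study conditions and are not
tuned per test.

**Latent drug effect.** Per compound × reporter, the population mean scaled
response is `m(t, x) = emax · x^h/(x^h + bmc^h) · 1/(1 + exp(−k(t − t50)))`:
a Hill function of concentration `x` (C-max multiples) with half-maximum at
the true benchmark concentration `bmc`, and a logistic onset in time. Severe
compounds draw `log10(bmc)` from N(0.9, 0.4), non-severe from N(1.6, 0.4),
both truncated to [0, 2.3] so the latent point of departure lies inside the
tested decade range; severe compounds are also more likely to respond at all
(e.g. 0.85 vs 0.35 for SRXN1) and to be cytotoxic. These class differences
encode the screen's central finding — severe-DILI drugs are more potent
stress-pathway activators relative to their therapeutic exposure — and give
the downstream statistics something real to detect. Remaining parameters
(emax ∈ [0.5, 0.9], Hill 1.5–3, onset half-time 6–16 h) are drawn uniformly
from ranges chosen to look like the screen's time courses.

**ICAM1.** All ICAM1 wells are TNFα-primed, so the control trajectory is a
saturating ramp `r(t) = r0 + A·t/(t + τ)` (r0 = 0.3, A = 2, τ = 6 h) and a
compound multiplies the ramp by `1 + (mult − 1)·Hill(x)` with `mult < 1`
suppression or `> 1` enhancement. ICAM1 plates carry their own TNFα + DMSO
controls, recorded in a `control_kind` column.

**Observation model.** A cell's GFP is `baseline·(1 + gain·m)` (baseline 100
a.u., gain 4) times mean-one lognormal noise with CV 0.3; Hoechst intensity
and nuclear area are lognormal around their baselines. Cytotoxicity acts
through a saturating load `s(x) = (x/tox)²/(1 + (x/tox)²)`: it raises the
per-cell 24-h death probability (hazard 0.06/h at saturation, i.e. ~76%
death), reverses the 0.02/h population growth, slows the positional random
walk (15 px/h steps), shrinks nuclei, and condenses chromatin. Dead cells at
the final frame receive a PI/nucleus overlap of at least 10% of the nuclear
area; 5% of live cells get a small sub-threshold overlap as staining noise.
PI is recorded only at the final frame, matching the assay.

**Layout and determinism.** One plate per reporter × concentration ×
replicate (default 3 replicates), each with one well per compound plus
control wells. Every well's random stream derives deterministically from the
master seed plus plate/well indices, so identical seeds give byte-identical
tables. The default 200 cells per well is a deliberate scale-down of the
8000 seeded in the physical assay; tests use 15–40.

**What the generator does not emulate.** Pixel-level imaging artefacts,
plate-position and batch effects, metabolic activation, non-monotone
dose-responses, and cell-cycle structure in the reporters. Passing tests
therefore demonstrate that the analysis recovers what this model encodes —
not that it would reach any particular performance on the deposited screen.

## Descriptors

Per plate, the control wells define per-timepoint background statistics.
Reporter descriptors per well and timepoint: population mean GFP intensity;
%GFP-positive fractions above 2× / 3× the control mean and above
mean + 3 sd; for ICAM1, fractions beyond the interquartile fences
Q3 + k·IQR and Q1 − k·IQR (k = 1.5, 2, 3) of the TNFα control, and their
difference — the IQR fences accommodate the skewed ICAM1 intensity
distribution. Quartiles use linear interpolation between order statistics.
Thresholds always come from the same plate's controls at the matched
timepoint. The PI dead/alive rule is an overlap ratio of at least 10%
(inclusive), and treated PI fractions are control-subtracted. Cytotoxicity
slopes (cell count normalized to the initial count, mean speed from
frame-to-frame displacements, nuclear size, Hoechst) are per-plate OLS
slopes against time, averaged over plates.

Mean-intensity series are min-max scaled to [0, 1] within a replicate, per
reporter, across all compounds, concentrations, and timepoints (reading
"replicate" as the replicate set rather than the single plate; the
alternative changes only the scaling scope). ICAM1 intensity is scaled to
[−1, 1] as the deviation from the matched control trajectory divided by the
largest absolute deviation in the replicate, so the control maps to 0.
Fraction descriptors are already fractions and bypass scaling.

## Time-course statistics

Replicate courses are condensed by natural cubic spline regression (8 df,
via the `cr` basis) evaluated at 24 equidistant timepoints and averaged
across replicates; splines reproduce constant and linear courses exactly and
track smooth sigmoids to < 2% of range.

Whole-curve treatment-vs-control comparisons use a permutation ANOVA for
functional data on 100-point linear interpolations of each replicate course
(dense linear interpolation keeps the original noise). The statistic is the
grid average of the squared group-mean difference standardized by the pooled
pointwise variance; for the up reporters only positive pointwise differences
count (one-sided upregulation), ICAM1 is two-sided. The null comes from
permuting replicate labels — exhaustively over all distinct assignments when
there are at most `n_perm` (default 1999) of them, otherwise by random
assignments with the add-one correction. Because 2–3 replicates alone give a
very coarse permutation grid, every control well contributes its own curve
and controls are pooled across all plates of the same reporter (the plates'
controls are exchangeable under the generator); this widens the permutation
space beyond the per-concentration pooling that a plate-effect-ridden real
screen would require. Benjamini–Hochberg FDR is applied across curves with
significance at q < 0.01.

Multi-reporter clustering: per reporter, each compound's condensed courses
over all concentrations are concatenated into one vector; pairwise Manhattan
(L1) distances are averaged over reporters (pairwise-complete when a
compound lacks a reporter) and fed to Ward agglomerative linkage. Leaf order
follows the dendrogram; no optimal-leaf reordering.

## Dose-response modelling

Max-over-time summaries (signed extreme for ICAM1 difference descriptors) of
the replicate-mean scaled courses are fit per compound × reporter to the
four-parameter log-logistic `f(x) = c + (d−c)/(1 + exp(b(ln x − ln e)))` by
bounded least squares with multi-start initialization (both slope signs,
several inflection starts; asymptotes bounded to the descriptor range,
`ln e` bounded one decade beyond the tested range). Flat responses yield a
degenerate converged fit flagged non-identifiable.

The benchmark concentration (BMC) is the concentration at which the fitted
curve departs from its low-concentration asymptote by +0.25 (−0.25 for
suppressed ICAM1), solved by inverting the log-logistic in closed form. The
low-concentration asymptote — not the observed response at 1 × C-max — is
the baseline, making the BMC a property of the fitted curve and robust to
single-point noise. Censoring applies when the plateau never departs by
|0.25|, the departure has the wrong sign, or the crossing falls outside the
tested 1–100 × C-max range; no extrapolation. For ICAM1 both signs are
attempted and the more potent uncensored crossing is the headline. A
10⁴-point grid search over the fitted curve serves as the test oracle for
the inversion.

Class statistics: a Welch unequal-variance t-test on log10(BMC/C-max)
between severity classes (log scale chosen because potency ratios span
decades), and a nested OLS comparison — log10 BMC on log10 C-max, with and
without the severity indicator, F-tested. Censored compounds are excluded
from both.

## Classification

Features per compound: for each reporter × descriptor × concentration
condensed course, the max magnitude, time of the extreme, trapezoidal AUC,
and early (0–8 h) / late (8–24 h) OLS slopes; cytotoxicity summaries per
concentration, kept separately for TNFα-primed (ICAM1) and plain plates;
per reporter the log10 BMC (absolute µM and C-max-normalized) with censored
values imputed at the maximum tested concentration plus an explicit
censoring indicator (censoring is informative, never silent); log10 C-max;
and per-reporter missing-course flags (absent courses zero-imputed). The
realized catalog is written to a manifest rather than forced to any fixed
count.

The classifier repeats (default 200 times): stratified 80/20 train/test
compound split; on training data only, a two-sample Kolmogorov–Smirnov test
per feature (keep p < 0.05), then a greedy correlation filter in ascending
KS-p order dropping features with |Pearson r| > 0.8 against anything kept;
training-set standardization; RBF-kernel SVM tuned over a small log grid
(C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1}) by repeated stratified k-fold
cross-validated ROC-AUC (default 10 × 10; folds shrink if a class is rarer
than the fold count). CV-AUC ties are broken by CV accuracy — AUC is
threshold-free, and without this the smallest-complexity rule can pick a
well-ranked but badly thresholded model — and remaining ties go to the least
complex setting. The SVM is unweighted by default (switchable). Test metrics
(AUC from decision values, sensitivity with severe as positive, specificity)
are averaged over iterations; per-feature selection counts define the stable
set (selected in > 75% of iterations, the 150-of-200 rule), and per-compound
correct-prediction fractions quantify prediction consistency. Feature
selection and standardization never see test data; a shuffle probe on the
held-out labels is part of the test suite.

## Pipeline and problem sizes

`stressdyn.pipeline.run_pipeline` chains annotation → simulation →
descriptors → time-course statistics → BMC → classification, writing
delimited tables plus a JSON manifest of config, seed, package version, and
output hashes; stages with unchanged inputs are reused from cache, and equal
seeds reproduce byte-identical outputs. The numbered scripts under
`analysis/` run the same stages as a narrative sequence.

Default problem sizes in the analysis scripts and acceptance script are
deliberate scale-downs chosen to keep a full run on one CPU in minutes: 25–40
cells per well, 2 replicates, ~60-compound subsets for classifier runs with
50 iterations and 2 × 5-fold CV tuning. The statistical structure is
unchanged by these sizes; only Monte-Carlo resolution is.

## Numerical choices and limitations

- Quantiles: linear interpolation (the common statistical default).
- PI ratio boundary 0.10 is inclusive.
- Min-max scaling over a degenerate range returns zeros with a warning.
- Permutation p-values use exhaustive enumeration when feasible, else the
  add-one estimator; identical groups short-circuit to statistic 0, p = 1.
- The IQR-fence up/down difference of a well drawn from its own control
  distribution is *not* zero in expectation for skewed intensities — the
  fences are not probability-symmetric; tests assert the actual tail-mass
  imbalance.
- The 4PL fit is monotone by construction; non-monotone (e.g. hormetic)
  responses are outside the model class.
- Real-data headline numbers (e.g. a mean test ROC of ~0.73 on the deposited
  screen) are not reproducible from this package alone and are not asserted
  anywhere; synthetic-screen classifier results are properties of the
  generator configuration used.
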