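# Methods

This note documents the models behind `floodcyto`: what the simulator
generates and why, how gating and the cohort statistics are defined, how
the control-anchored response model is constructed, and which choices were
genuinely open.

## Synthetic cohorts

The simulator emulates a 28-subject endurance cohort sampled at six time
points (evenings of days 0/4/7, mornings of days 1/5/8) plus an optional
acute-endotoxemia (LPS-challenge) sample, at event level.

**Mixture model.** Each sample is a four-component mixture: the three
CD16/CD62L neutrophil subsets plus a generic "other-leukocyte" cluster
(lower scatter, CD66b-negative, CD14-positive) that exists to exercise the
scatter/CD66b gate; eosinophil or lymphocyte realism is out of scope.
Neutrophils are a fixed fraction (default 0.6) of acquired events, and the
automated-counter concentration stored with each sample is
`true total neutrophil concentration / 0.6`, so gated fractions convert
back to concentrations the way they would for a haematology counter.

**Intensity model.** Each channel of each component is log-normal:
location is the log of the component median (arbitrary units), scale
derives from a CV on the natural scale (`σ = sqrt(log(1+CV²))`; default CV
0.35 for fluorescence, 0.12–0.30 for scatter). A zero-centred Gaussian
background/compensation term (SD 25 a.u.) is added to fluorescence draws,
so a small fraction of stored intensities is negative — real exports
contain negatives from background subtraction and compensation, and the
preprocessing's shift-to-positive step must be exercised. Latent component
labels are stored with every event; gating never reads them, tests do.

**Calibration.** Defaults reproduce the published cohort means:

* total neutrophil concentration per time point (10⁶ cells/ml): 2.40,
  1.78, 3.51, 1.89, 3.67, 2.24 across evening d0 → morning d8. The
  printed per-subset morning means do not sum exactly to the printed
  totals, so the total is taken as primary and subset mixing fractions are
  the printed subset values renormalised to 1 (e.g. morning d1:
  0.861/0.127/0.012). Cohort-mean subset concentrations then land within
  ~3% of the printed subset numbers.
* pooled marker medians at morning d1 (a.u.): CD35 951, CD66b 2442, CD11b
  2989, CBRM1/5 250, CD49d 6039, LAIR-1 3967; later time points apply
  per-marker multipliers equal to the printed day-5/day-8 ratios (CBRM1/5
  ×2.41/×3.31, CD49d ×1.80/×2.38, LAIR-1 ×1.82/×2.00, CD11b ×0.95/×0.80,
  CD35 and CD66b ≈ flat). No evening medians are tabulated; since the
  phenotype shift is maintained overnight, evenings share the multiplier
  of the following morning.
* CD62L declines ×0.85/×0.70 at the later time points on top of the
  growing CD62L-dim mixing fraction: the response cells drift away from
  CD62L as a population, not only by subset replacement. No printed value
  pins the magnitude; a moderate decline was fixed once.
* per-subset medians equal the pooled values — the published per-subset
  differences are described as small — and remain configurable.

**Between-subject structure.** One multiplicative log-normal random
effect per subject per marker (CV 0.20) and one per subject for
concentration (CV 0.30), shared across that subject's time points,
produce the paired structure repeated-measures inference needs and the
visible subject heterogeneity (e.g. the two LAIR-1 responder groups); a
residual per-sample concentration factor (CV 0.15) adds day-to-day noise.
These CVs are not published quantities; they were fixed once at values
giving realistic cohort spread.

**What the simulator does not model:** doublets, spillover matrices,
acquisition drift, detector saturation, or subject-level covariates. A
passing pipeline on synthetic data demonstrates correctness of the
computations and calibration recovery, not robustness to those artefacts.

Defaults use 20 000 events per sample (the assay stains ~500 000 cells;
scaled for desk speed). Identical (config, seed) pairs are bit-identical.

## Gating

Neutrophils are `FSC/SSC gate ∧ CD66b ≥ θ ∧ CD16 ≥ θ_pos`; gated cells are
classified by quadrant against CD16 and CD62L dim/bright thresholds. All
thresholds are closed on the bright/positive side, making gating
deterministic including exact boundary ties. The CD16-dim/CD62L-dim
quadrant is not a reported subset: those events are excluded from the
three subsets but counted and logged.

Because the source analysis gates manually and prints no thresholds,
defaults are derived from the pooled control (morning day 1) cells: each
threshold sits at the minimum-density valley between the two most
prominent modes of the (smoothed, log10) intensity histogram, falling back
to the 5th percentile of the main mode if unimodal. The CD16 positivity
bound of the neutrophil definition is the dim/bright split divided by 50 —
far enough below the CD16-dim population that the banded subset is
retained in full. CD14 is available as an optional monocyte-exclusion
channel (off by default; CD66b gating already excludes monocytes).
Singlet gating is a pass-through hook (no doublets are simulated).

## Cohort statistics

One-way within-subject ANOVA (subject block, time factor) is computed by
direct sums-of-squares decomposition; subjects missing any analysed cell
are excluded (complete-case). Pairwise time contrasts use the RM error
mean square with Tukey's studentized-range distribution for all-pairs
multiplicity (the common default of commercial ANOVA software;
`multiplicity="none"` gives unadjusted t intervals). The fold change
between time points is the ratio of time-point means; its CI is the
mean-difference CI shifted by the baseline mean and divided by it, which
brackets the fold point estimate by construction. No sphericity correction
is applied by default. Per-subset MFIs use the analogous two-way
fully-within design (error term of each effect = its interaction with
subject). `statsmodels.stats.anova.AnovaRM` serves as an independent
cross-check in the test suite; the implementation itself stays
self-contained because the contrast/fold-CI construction on the RM error
term is not exposed by library ANOVAs.

Printed p-values of the original cohort are not reproducible (the
underlying data are not deposited, and the original multiplicity
procedure is unstated); the suite therefore checks calibration (type-I
error ≈ α under null simulation) and unbiasedness of fold estimates
rather than specific p-values.

## Response-specific model

Preprocessing: one shift constant per analysis, fitted on the union of
control and response pools so the global minimum is exactly 1; log10; per
marker centre/scale by the control pool's mean and sample SD (n−1
throughout). The log base is cosmetic (standardization cancels it) but
fixed for reproducibility.

Model: control-subspace PCA → orthogonal deflation → PCA on the deflated
response pool. Explained fractions are eigenvalue shares of the deflated
response covariance; loadings are sign-fixed (largest-magnitude element
positive) so refits are bit-identical. This decomposition is this
package's own reconstruction of a control-anchored "orthogonal
orientation" analysis; no numerical identity with any other
implementation is claimed, and published explained-variance percentages
from unavailable cohorts are not expected to be reproduced.

`k_r` defaults to 2 (a 2-D biplot). For `k_c`, a fixed
explained-variance quota fails on control-standardized data: the control
spectrum is near-isotropic (every marker contributes ~1/p after
scaling), so a 90% quota would consume nearly all dimensions. The
default instead keeps the control components whose eigenvalue exceeds
the Marchenko–Pastur noise edge `(1 + sqrt(p/n))²` — exactly the
directions with genuine control correlation structure — clipped to
`[1, p − k_r]`. An explicit `k_c` always wins.

Benchmark regions are Mahalanobis ellipses: score mean, score covariance,
squared radius at the empirical coverage quantile (default 0.80) of the
defining cells' squared distances — closed-form, testable against the
χ²(2) quantile on Gaussian scores, and visually an ellipse. Per-sample
benchmarks are refit per sample by default (pooled-covariance shape is
available via an option). Degenerate inputs (singular score covariance,
fewer than 50 cells, coverage outside (0,1)) are rejected; model fits on
control pools of fewer than 50 cells simply omit the benchmark.

## Pipeline

`simulate`, `gate`, `stats`, `flood` and `all` run from one YAML config
with CLI overrides; the `flood` stage fits two analyses by default — the
exercise cohort alone, and the exercise cohort pooled with simulated
LPS-challenge samples so both responses share one response space. Every
stage writes a manifest (config echo, versions, seed, SHA-256 of
artefacts); identical (config, seed) runs are bit-identical.

## Problem sizes

The test suite and the acceptance script run on reduced problem sizes
chosen once for desk-scale runtimes: 6-subject/2000-event cohorts for
unit fixtures, 28-subject/5000-event cohorts (20 seeds) for fold-change
recovery, and ≥50 000 pooled control cells for benchmark coverage. These
sizes keep Monte-Carlo error well inside the tolerances asserted.
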