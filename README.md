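# floodcyto

Neutrophil flow-cytometry analysis for repeated-measures exercise (and
challenge) cohorts: seeded synthetic cytometry cohorts, CD16/CD62L subset
gating, fold-change/repeated-measures-ANOVA statistics, and a
control-anchored response-specific single-cell PCA model with benchmark
ellipses and biplots.

## The problem

During repeated strenuous endurance exercise the blood neutrophil
compartment changes in ways a single marker cannot capture: total counts
rise and fail to normalise overnight, two extra CD16/CD62L subsets appear
(CD16^bright CD62L^dim "hypersegmented-associated" cells and CD16^dim
CD62L^bright banded cells from the bone marrow), and the whole population
shifts its activation phenotype (CBRM1/5, CD49d and LAIR-1 up, CD11b and
CD62L down) — a pattern distinct from the acute LPS-challenge response
(CD35/CD11b up, CD16/LAIR-1 down). `floodcyto` packages that analysis as
a reusable, fully tested pipeline for anyone working with multi-parameter
neutrophil panels sampled longitudinally: immunologists, exercise
physiologists, and methodologists who need a reproducible desk-scale test
bed. Because event-level cytometry cohorts of this kind are rarely
deposited, the package ships a first-class simulator whose defaults
reproduce the published cohort means, so the entire pipeline is testable
without any download.

## What it computes

**Gating.** Neutrophils are `scatter-gate ∧ CD66b⁺ ∧ CD16⁺`; gated cells
are classified into the three quadrant subsets by CD16/CD62L thresholds
placed at the density valley of each marker's log-intensity histogram.
Subset concentrations follow from the automated-counter leukocyte count
`c`: for subset *s*, `conc_s = c · f_neut · f_s`.

**Cohort statistics.** For each measure *y* (concentration or median
fluorescence intensity, MFI) observed on subject *i* at time *t*, the
one-way within-subject model `y_it = μ + π_i + τ_t + ε_it` is fitted by
sums of squares; pairwise time contrasts use the within-subject error mean
square with Tukey's studentized-range adjustment. A fold change between
time points is the ratio of time-point means `ȳ_t / ȳ_b`, with its CI
obtained by shifting the mean-difference CI by the baseline mean and
dividing by it. Per-subset MFIs get the analogous two-way
(subset × time) fully-within-subject ANOVA.

**Response-specific model.** Gated intensities are shifted so the global
minimum is 1, log10-transformed, and centred/scaled per marker on the
control pool (all morning-day-1 cells). The control subspace is spanned by
the leading principal directions of the control pool (`V_c`); response
cells are deflated by `P = I − V_c V_cᵀ`, and the response loadings `W`
are the top principal directions of the deflated response pool. Cells are
plotted by their scores `z P W` together with marker loading vectors
(length = importance, angle = correlation), and a *benchmark region* — the
Mahalanobis ellipse containing 80% of the reference cells in score space —
anchors every plot. A sample's overlap with the control benchmark measures
how far its neutrophils have left the homeostatic state.

## Worked example

```python
import numpy as np
import floodcyto as fc
from floodcyto.stats import cohort_table, rm_anova_oneway

cfg = fc.default_cohort_config(n_subjects=28, events_per_sample=5000)
records = fc.simulate_cohort(cfg, seed=1)

controls = [r for r in records if r.group == "control"]
pooled = fc.EventMatrix(
    values=np.vstack([r.events.values for r in controls]),
    panel=controls[0].events.panel,
)
gates = fc.derive_gates(pooled)

table = cohort_table(records, gates)
morning = table[table["session"] == "morning"]
wide = morning.pivot(index="subject", columns="day", values="total")
wide.columns = [f"d{c}" for c in wide.columns]
res = rm_anova_oneway(wide)
c = res.contrast("d1", "d8")
print(f"fold d8/d1 = {c.fold:.2f}  95% CI {c.fold_ci[0]:.2f}-{c.fold_ci[1]:.2f}")

fres, per = fc.flood_from_records(records, gates)
print(fres.summary())
```

prints (seed 1):

```
fold d8/d1 = 1.28  95% CI 1.19-1.37
Response-specific component model
  markers:             10
  control components:  4
  response components: 2
  explained response-specific variance: PC1 32.5%, PC2 16.4%
  ...
         CD11b: PC1 -0.172, PC2 +0.008
        LAIR-1: PC1 +0.397, PC2 +0.180
         CD62L: PC1 -0.204, PC2 +0.852
         CD49d: PC1 +0.603, PC2 +0.062
  ...
  control benchmark: coverage 80%, squared radius 3.255
```

The d8/d1 fold of ~1.26–1.28 is the simulated cohort's morning-day-8
neutrophilia relative to baseline; the first response component loads
CBRM1/5, CD49d and LAIR-1 together and opposite to CD11b and CD62L — the
exercise-induced phenotype shift — and the mean overlap of day-8 cells
with the 80% control benchmark drops to ~0.02 (day-1 samples sit at
~0.80), i.e. the whole population has left the homeostatic region.

The same pipeline runs from a shell:

```sh
floodcyto all --seed 1 --out run1        # simulate → gate → stats → model
floodcyto stats --config run.yaml        # individual stages, config-driven
```

Every run writes a manifest (config echo, versions, seed, artefact
hashes); identical config and seed give bit-identical outputs.

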