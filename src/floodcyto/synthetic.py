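"""Seeded synthetic flow-cytometry cohorts for the neutrophil pipeline.

The generator emulates a 28-subject endurance-exercise cohort sampled at six
time points (evenings of day 0/4/7, mornings of day 1/5/8). Each sample is a
mixture of three CD16/CD62L neutrophil subsets plus a generic
"other-leukocyte" cluster:

* ``CD16brightCD62Lbright`` — mature segmented neutrophils, the dominant
  population under homeostasis;
* ``CD16brightCD62Ldim`` — the activated/hypersegmented-associated subset
  that expands over the exercise week;
* ``CD16dimCD62Lbright`` — banded, bone-marrow-derived cells appearing late.

Fluorescence intensities are drawn log-normally around per-subset medians
(location = log median, scale from a CV on the natural scale), modulated by

* per-time-point mixing fractions (subset mobilisation),
* per-marker time-course multipliers (activation-marker up/down-regulation:
  CBRM1/5, CD49d and LAIR-1 rise 2-3x by day 8, CD11b falls),
* one multiplicative log-normal random effect per subject per marker and one
  per subject for blood concentration (between-subject heterogeneity),
* a small additive zero-centred Gaussian "background/compensation" term, so
  a fraction of stored intensities is negative, as in real exports.

Default numeric targets (total neutrophil concentrations, subset mixing,
marker medians) reproduce the cohort means of the endurance time course;
an LPS-challenge configuration produces the contrasting acute-inflammation
phenotype (CD35/CD11b up, CD16/LAIR-1 down, distinct CD16dim and CD62Ldim
subsets with elevated CD11b on the CD62Ldim cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import EventMatrix, SampleRecord, TIME_POINTS
from .panel import FLUORESCENCE_MARKERS, PanelDef, default_panel

NEUTROPHIL_SUBSETS = (
    "CD16brightCD62Lbright",
    "CD16brightCD62Ldim",
    "CD16dimCD62Lbright",
)
OTHER_LABEL = "other-leukocyte"


class ConfigurationError(ValueError):
    """A simulation configuration field violates its invariants."""


@dataclass(frozen=True)
class SubsetSpec:
    """Location/dispersion of one latent population.

    ``medians`` maps channel name to the population median intensity in
    arbitrary units; ``cv`` maps channel name to the coefficient of
    variation of the log-normal intensity distribution (the log-scale sigma
    is ``sqrt(log(1 + cv^2))``).
    """

    label: str
    medians: dict[str, float]
    cv: dict[str, float]

    def validate(self, panel: PanelDef) -> None:
        for ch in panel.channels:
            if ch not in self.medians:
                raise ConfigurationError(
                    f"subset {self.label!r}: medians missing channel {ch!r}"
                )
            if not self.medians[ch] > 0:
                raise ConfigurationError(
                    f"subset {self.label!r}: median for {ch!r} must be > 0"
                )
            if not self.cv.get(ch, 0) > 0:
                raise ConfigurationError(
                    f"subset {self.label!r}: cv for {ch!r} must be > 0"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``total_concentration`` maps time label (e.g. ``"morning_d1"``) to the
    cohort-mean total neutrophil concentration in 1e6 cells/ml;
    ``subset_fractions`` maps time label to the mixing fractions of the
    three neutrophil subsets (must sum to 1); ``marker_multipliers`` maps
    marker to per-time-point multiplicative shifts of its median.
    """

    panel: PanelDef
    subsets: tuple[SubsetSpec, ...]
    other: SubsetSpec
    n_subjects: int = 28
    time_points: tuple[tuple[int, str], ...] = TIME_POINTS
    total_concentration: dict[str, float] = field(default_factory=dict)
    subset_fractions: dict[str, tuple[float, ...]] = field(default_factory=dict)
    marker_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    neutrophil_event_fraction: float = 0.6
    subject_marker_cv: float = 0.20
    subject_concentration_cv: float = 0.30
    residual_concentration_cv: float = 0.15
    events_per_sample: int = 20_000
    background_sd: float = 25.0

    def time_labels(self) -> list[str]:
        return [f"{session}_d{day}" for day, session in self.time_points]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.events_per_sample < 1000:
            raise ConfigurationError("events_per_sample must be >= 1000")
        if not 0 < self.neutrophil_event_fraction <= 1:
            raise ConfigurationError("neutrophil_event_fraction must be in (0, 1]")
        labels = [s.label for s in self.subsets]
        if labels != list(NEUTROPHIL_SUBSETS):
            raise ConfigurationError(
                f"subsets must carry labels {NEUTROPHIL_SUBSETS} in order, got {labels}"
            )
        for spec in (*self.subsets, self.other):
            spec.validate(self.panel)
        for t in self.time_labels():
            if t not in self.total_concentration:
                raise ConfigurationError(f"total_concentration missing {t!r}")
            if not self.total_concentration[t] > 0:
                raise ConfigurationError(
                    f"total_concentration[{t!r}] must be > 0"
                )
            fr = self.subset_fractions.get(t)
            if fr is None or len(fr) != len(self.subsets):
                raise ConfigurationError(
                    f"subset_fractions[{t!r}] must give one fraction per subset"
                )
            if any(f < 0 for f in fr) or not math.isclose(
                sum(fr), 1.0, abs_tol=1e-9
            ):
                raise ConfigurationError(
                    f"subset_fractions[{t!r}] must be non-negative and sum to 1"
                )


@dataclass(frozen=True)
class LpsConfig:
    """Single post-endotoxin-challenge sample.

    Phenotype overrides relative to the homeostatic baseline are fixed in
    direction: CD35 and CD11b medians raised and CD16 and LAIR-1 medians
    lowered on all neutrophils, with distinct CD16-dim and CD62L-dim
    subsets and elevated CD11b on the CD62L-dim subset.
    """

    panel: PanelDef
    subsets: tuple[SubsetSpec, ...]
    other: SubsetSpec
    subset_fractions: tuple[float, ...] = (0.45, 0.30, 0.25)
    total_concentration: float = 4.5
    neutrophil_event_fraction: float = 0.6
    subject_marker_cv: float = 0.20
    events_per_sample: int = 20_000
    background_sd: float = 25.0

    def validate(self) -> None:
        if self.events_per_sample < 1000:
            raise ConfigurationError("events_per_sample must be >= 1000")
        if not self.total_concentration > 0:
            raise ConfigurationError("total_concentration must be > 0")
        if len(self.subset_fractions) != len(self.subsets):
            raise ConfigurationError(
                "subset_fractions must give one fraction per subset"
            )
        if any(f < 0 for f in self.subset_fractions) or not math.isclose(
            sum(self.subset_fractions), 1.0, abs_tol=1e-9
        ):
            raise ConfigurationError(
                "subset_fractions must be non-negative and sum to 1"
            )
        for spec in (*self.subsets, self.other):
            spec.validate(self.panel)


# --------------------------------------------------------------------------
# Default configurations
# --------------------------------------------------------------------------

#: Cohort-mean total neutrophil concentration (1e6 cells/ml) per time point.
DEFAULT_TOTAL_CONCENTRATION = {
    "evening_d0": 2.40,
    "morning_d1": 1.78,
    "evening_d4": 3.51,
    "morning_d5": 1.89,
    "evening_d7": 3.67,
    "morning_d8": 2.24,
}

#: Morning subset concentrations (1e6 cells/ml) used to derive mixing
#: fractions: (bright/bright, bright/dim, dim/bright) per morning.
_MORNING_SUBSET_CONC = {
    "d1": (1.49, 0.22, 0.02),
    "d5": (1.39, 0.37, 0.05),
    "d8": (1.44, 0.58, 0.07),
}


def _normalise(values: tuple[float, ...]) -> tuple[float, ...]:
    s = sum(values)
    return tuple(v / s for v in values)


DEFAULT_SUBSET_FRACTIONS = {
    "evening_d0": _normalise(_MORNING_SUBSET_CONC["d1"]),
    "morning_d1": _normalise(_MORNING_SUBSET_CONC["d1"]),
    "evening_d4": _normalise(_MORNING_SUBSET_CONC["d5"]),
    "morning_d5": _normalise(_MORNING_SUBSET_CONC["d5"]),
    "evening_d7": _normalise(_MORNING_SUBSET_CONC["d8"]),
    "morning_d8": _normalise(_MORNING_SUBSET_CONC["d8"]),
}

#: Baseline (morning day 1) pooled-neutrophil marker medians, arbitrary units.
BASELINE_MFI = {
    "CD35": 951.0,
    "CD66b": 2442.0,
    "CD11b": 2989.0,
    "CBRM1/5": 250.0,
    "CD49d": 6039.0,
    "LAIR-1": 3967.0,
}

#: Morning marker medians at day 5 / day 8, arbitrary units.
_MORNING_MFI = {
    "CD35": (905.0, 909.0),
    "CD66b": (2638.0, 2441.0),
    "CD11b": (2842.0, 2380.0),
    "CBRM1/5": (602.0, 827.0),
    "CD49d": (10891.0, 14346.0),
    "LAIR-1": (7209.0, 7953.0),
}


def _default_multipliers() -> dict[str, dict[str, float]]:
    # Evening medians are not tabulated; the evening shift is maintained
    # overnight, so evenings share the multiplier of the following morning.
    out: dict[str, dict[str, float]] = {}
    for marker, (d5, d8) in _MORNING_MFI.items():
        base = BASELINE_MFI[marker]
        out[marker] = {
            "evening_d0": 1.0,
            "morning_d1": 1.0,
            "evening_d4": d5 / base,
            "morning_d5": d5 / base,
            "evening_d7": d8 / base,
            "morning_d8": d8 / base,
        }
    # Response cells drift away from CD62L on top of the growing CD62L-dim
    # mixture: the whole population is progressively more CD62L-dim at the
    # later mornings. No pooled CD62L median is tabulated; a moderate
    # 15%/30% decline matches the reported qualitative shift.
    out["CD62L"] = {
        "evening_d0": 1.0,
        "morning_d1": 1.0,
        "evening_d4": 0.85,
        "morning_d5": 0.85,
        "evening_d7": 0.70,
        "morning_d8": 0.70,
    }
    return out


# Subset-defining channels: CD16 and CD62L bright vs dim medians are ~20x
# apart so the quadrant structure is unambiguous at default dispersions.
_CD16_BRIGHT, _CD16_DIM = 12000.0, 500.0
_CD62L_BRIGHT, _CD62L_DIM = 8000.0, 350.0

_NEUT_COMMON = {
    "FSC": 150_000.0,
    "SSC": 120_000.0,
    "CD64": 600.0,
    "CD14": 150.0,
    **BASELINE_MFI,
}

_DEFAULT_CV = {ch: 0.35 for ch in FLUORESCENCE_MARKERS}
_DEFAULT_CV.update({"FSC": 0.12, "SSC": 0.15})


def _subset(label: str, cd16: float, cd62l: float, **overrides: float) -> SubsetSpec:
    medians = dict(_NEUT_COMMON)
    medians.update({"CD16": cd16, "CD62L": cd62l})
    medians.update(overrides)
    return SubsetSpec(label=label, medians=medians, cv=dict(_DEFAULT_CV))


def _default_other() -> SubsetSpec:
    # Generic mononuclear cluster: CD66b-negative, lower scatter, some CD14.
    medians = {
        "FSC": 70_000.0,
        "SSC": 25_000.0,
        "CD35": 300.0,
        "CD64": 900.0,
        "CBRM1/5": 100.0,
        "CD11b": 800.0,
        "LAIR-1": 1500.0,
        "CD14": 2500.0,
        "CD16": 250.0,
        "CD62L": 4000.0,
        "CD49d": 3000.0,
        "CD66b": 80.0,
    }
    cv = dict(_DEFAULT_CV)
    cv.update({"FSC": 0.20, "SSC": 0.30})
    return SubsetSpec(label=OTHER_LABEL, medians=medians, cv=cv)


def default_cohort_config(**overrides) -> CohortConfig:
    """Default 28-subject, six-time-point cohort configuration.

    Keyword overrides replace any :class:`CohortConfig` field, e.g.
    ``default_cohort_config(events_per_sample=2000)``.
    """
    panel = default_panel()
    cfg = CohortConfig(
        panel=panel,
        subsets=(
            _subset("CD16brightCD62Lbright", _CD16_BRIGHT, _CD62L_BRIGHT),
            _subset("CD16brightCD62Ldim", _CD16_BRIGHT, _CD62L_DIM),
            _subset("CD16dimCD62Lbright", _CD16_DIM, _CD62L_BRIGHT),
        ),
        other=_default_other(),
        total_concentration=dict(DEFAULT_TOTAL_CONCENTRATION),
        subset_fractions={k: tuple(v) for k, v in DEFAULT_SUBSET_FRACTIONS.items()},
        marker_multipliers=_default_multipliers(),
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def default_lps_config(**overrides) -> LpsConfig:
    """Post-LPS-challenge sample configuration.

    Relative to the homeostatic baseline all neutrophils carry raised CD35
    and CD11b and lowered CD16 and LAIR-1; the CD62L-dim subset in addition
    expresses more CD11b than the other subsets.
    """
    up_cd35, up_cd11b = 2.5, 1.8
    down_cd16, down_lair = 0.45, 0.5
    base = dict(_NEUT_COMMON)
    common = {
        "CD35": base["CD35"] * up_cd35,
        "CD11b": base["CD11b"] * up_cd11b,
        "LAIR-1": base["LAIR-1"] * down_lair,
    }
    cfg = LpsConfig(
        panel=default_panel(),
        subsets=(
            _subset(
                "CD16brightCD62Lbright",
                _CD16_BRIGHT * down_cd16,
                _CD62L_BRIGHT,
                **common,
            ),
            _subset(
                "CD16brightCD62Ldim",
                _CD16_BRIGHT * down_cd16,
                _CD62L_DIM,
                **{**common, "CD11b": base["CD11b"] * up_cd11b * 2.0},
            ),
            _subset(
                "CD16dimCD62Lbright",
                _CD16_DIM * down_cd16,
                _CD62L_BRIGHT,
                **common,
            ),
        ),
        other=_default_other(),
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


# --------------------------------------------------------------------------
# Config serialization
# --------------------------------------------------------------------------

def save_cohort_config(config: CohortConfig, path) -> None:
    """Write a cohort configuration as YAML (keys mirror the fields)."""
    import yaml

    d = {
        "n_subjects": config.n_subjects,
        "time_points": [list(tp) for tp in config.time_points],
        "panel": list(config.panel.channels),
        "total_concentration": dict(config.total_concentration),
        "subset_fractions": {k: list(v) for k, v in config.subset_fractions.items()},
        "marker_multipliers": {m: dict(v) for m, v in config.marker_multipliers.items()},
        "neutrophil_event_fraction": config.neutrophil_event_fraction,
        "subject_marker_cv": config.subject_marker_cv,
        "subject_concentration_cv": config.subject_concentration_cv,
        "residual_concentration_cv": config.residual_concentration_cv,
        "events_per_sample": config.events_per_sample,
        "background_sd": config.background_sd,
        "subsets": [
            {"label": s.label, "medians": dict(s.medians), "cv": dict(s.cv)}
            for s in config.subsets
        ],
        "other": {
            "label": config.other.label,
            "medians": dict(config.other.medians),
            "cv": dict(config.other.cv),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_cohort_config(path) -> CohortConfig:
    """Read a cohort configuration written by :func:`save_cohort_config`."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    panel = PanelDef(channels=tuple(d["panel"]))

    def spec(entry):
        return SubsetSpec(
            label=entry["label"], medians=entry["medians"], cv=entry["cv"]
        )

    return CohortConfig(
        panel=panel,
        subsets=tuple(spec(e) for e in d["subsets"]),
        other=spec(d["other"]),
        n_subjects=d["n_subjects"],
        time_points=tuple((int(day), sess) for day, sess in d["time_points"]),
        total_concentration=d["total_concentration"],
        subset_fractions={k: tuple(v) for k, v in d["subset_fractions"].items()},
        marker_multipliers=d["marker_multipliers"],
        neutrophil_event_fraction=d["neutrophil_event_fraction"],
        subject_marker_cv=d["subject_marker_cv"],
        subject_concentration_cv=d["subject_concentration_cv"],
        residual_concentration_cv=d["residual_concentration_cv"],
        events_per_sample=d["events_per_sample"],
        background_sd=d["background_sd"],
    )


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _log_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _draw_events(
    rng: np.random.Generator,
    panel: PanelDef,
    specs: list[SubsetSpec],
    weights: np.ndarray,
    n_events: int,
    median_factors: dict[str, float],
    background_sd: float,
) -> tuple[np.ndarray, np.ndarray, dict[str, dict[str, float]]]:
    """Draw a log-normal mixture; returns (values, labels, effective medians)."""
    labels_idx = rng.choice(len(specs), size=n_events, p=weights)
    values = np.empty((n_events, panel.n_channels))
    eff_medians: dict[str, dict[str, float]] = {}
    for si, spec in enumerate(specs):
        mask = labels_idx == si
        n = int(mask.sum())
        eff = {}
        for ci, ch in enumerate(panel.channels):
            med = spec.medians[ch]
            if spec.label != OTHER_LABEL:
                med *= median_factors.get(ch, 1.0)
            eff[ch] = med
            sigma = _log_sigma(spec.cv[ch])
            draws = np.exp(rng.normal(math.log(med), sigma, size=n))
            if panel.roles[ch] == "fluorescence" and background_sd > 0:
                draws += rng.normal(0.0, background_sd, size=n)
            values[mask, ci] = draws
        eff_medians[spec.label] = eff
    labels = np.array([specs[i].label for i in labels_idx])
    return values, labels, eff_medians


def simulate_cohort(config: CohortConfig, seed: int) -> list[SampleRecord]:
    """Simulate one cohort: one sample per subject per time point.

    Subject-level multiplicative random effects (one per marker and one for
    concentration) are shared across a subject's time points, so the output
    has the paired structure repeated-measures inference relies on.
    Identical ``(config, seed)`` pairs give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    panel = config.panel
    fluor = panel.fluorescence_channels
    records: list[SampleRecord] = []

    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        b_conc = float(
            np.exp(rng.normal(0.0, _log_sigma(config.subject_concentration_cv)))
        )
        b_marker = {
            ch: float(np.exp(rng.normal(0.0, _log_sigma(config.subject_marker_cv))))
            for ch in fluor
        }
        for day, session in config.time_points:
            t = f"{session}_d{day}"
            total = (
                config.total_concentration[t]
                * b_conc
                * float(
                    np.exp(
                        rng.normal(0.0, _log_sigma(config.residual_concentration_cv))
                    )
                )
            )
            counter = total / config.neutrophil_event_fraction
            fr = np.asarray(config.subset_fractions[t])
            weights = np.concatenate(
                [
                    fr * config.neutrophil_event_fraction,
                    [1.0 - config.neutrophil_event_fraction],
                ]
            )
            factors = {
                ch: config.marker_multipliers.get(ch, {}).get(t, 1.0)
                * b_marker.get(ch, 1.0)
                for ch in panel.channels
            }
            values, labels, eff = _draw_events(
                rng,
                panel,
                [*config.subsets, config.other],
                weights,
                config.events_per_sample,
                factors,
                config.background_sd,
            )
            records.append(
                SampleRecord(
                    subject=subject,
                    day=day,
                    session=session,
                    group="control" if t == "morning_d1" else "response",
                    events=EventMatrix(values=values, panel=panel, labels=labels),
                    counter_concentration=counter,
                    extra={
                        "true_total_concentration": total,
                        "true_subset_medians": eff,
                        "true_subset_fractions": dict(
                            zip([s_.label for s_ in config.subsets], fr)
                        ),
                    },
                )
            )
    return records


def simulate_lps_sample(config: LpsConfig, seed: int, subject: str = "LPS01") -> SampleRecord:
    """Simulate one post-endotoxin-challenge blood sample."""
    config.validate()
    rng = np.random.default_rng(seed)
    panel = config.panel
    fr = np.asarray(config.subset_fractions)
    weights = np.concatenate(
        [fr * config.neutrophil_event_fraction, [1.0 - config.neutrophil_event_fraction]]
    )
    b_marker = {
        ch: float(np.exp(rng.normal(0.0, _log_sigma(config.subject_marker_cv))))
        for ch in panel.fluorescence_channels
    }
    values, labels, eff = _draw_events(
        rng,
        panel,
        [*config.subsets, config.other],
        weights,
        config.events_per_sample,
        b_marker,
        config.background_sd,
    )
    return SampleRecord(
        subject=subject,
        day=0,
        session="lps",
        group="response",
        events=EventMatrix(values=values, panel=panel, labels=labels),
        counter_concentration=config.total_concentration
        / config.neutrophil_event_fraction,
        extra={"true_subset_medians": eff},
    )
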