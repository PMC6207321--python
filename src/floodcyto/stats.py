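"""Cohort-level statistics: MFIs, fold changes and within-subject ANOVA.

The inference path follows the classical repeated-measures design: subjects
are the blocking factor, time (and optionally subset) are within-subject
factors, and pairwise time-point contrasts use the within-subject error
mean square with Tukey's studentized-range adjustment for all-pairs
multiplicity. Fold changes between time points are ratios of time-point
means; their confidence intervals are obtained by shifting the
mean-difference interval by the baseline mean and dividing by it, which
keeps the fold interval bracketing the fold point estimate.

The model/results split follows the statsmodels idiom:

>>> res = RepeatedMeasuresAnova(long_df, dv="total", subject="subject",
...                             within="time").fit()
>>> res.f_statistic, res.p_value
>>> print(res.summary())
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import EventMatrix, TIME_POINTS
from .gating import (
    EmptyGateError,
    SubsetGates,
    classify_subsets,
    gate_neutrophils,
    subset_concentration,
)
from .panel import MFI_MARKERS
from .synthetic import NEUTROPHIL_SUBSETS


class InsufficientDataError(ValueError):
    """Fewer complete subjects than the design requires."""


class DegenerateVarianceError(ValueError):
    """The within-subject error variance is zero."""


# --------------------------------------------------------------------------
# Elementary operations
# --------------------------------------------------------------------------

def median_fluorescence(events: EventMatrix, mask: np.ndarray, marker: str) -> float:
    """Median intensity of ``marker`` over masked events (a.u.).

    Even-length inputs use the mean-of-middle-pair convention (numpy's
    default). Raises :class:`EmptyGateError` on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyGateError(f"no events in gate for marker {marker!r}")
    return float(np.median(events.channel(marker)[mask]))


def fold_change(mean_follow: float, mean_base: float) -> float:
    """Ratio of a follow-up mean to a baseline mean; both must be > 0."""
    if not (mean_follow > 0 and mean_base > 0):
        raise ValueError("fold change requires strictly positive means")
    return mean_follow / mean_base


def pearson_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r * r), float(p)


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise time-point comparison on the within-subject error term."""

    baseline: str
    follow_up: str
    mean_difference: float
    diff_ci: tuple[float, float]
    fold: float
    fold_ci: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        lo, hi = self.diff_ci
        if not lo <= self.mean_difference <= hi:
            raise ValueError("difference CI must bracket the estimate")


# --------------------------------------------------------------------------
# Repeated-measures ANOVA
# --------------------------------------------------------------------------

class RepeatedMeasuresAnova:
    """Within-subject ANOVA with one or two within factors.

    Parameters
    ----------
    data
        Long-format frame with one row per subject x factor-level cell.
    dv
        Column holding the dependent variable.
    subject
        Column identifying subjects (the blocking factor).
    within
        Name of the within-subject factor, or a pair of names for the
        two-factor design. Subjects missing any cell of the full design
        are dropped (complete-case analysis).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        subject: str,
        within: str | tuple[str, str],
    ) -> None:
        self.data = data
        self.dv = dv
        self.subject = subject
        self.within = (within,) if isinstance(within, str) else tuple(within)
        if len(self.within) not in (1, 2):
            raise ValueError("within must name one or two factors")

    def _complete_cube(self) -> tuple[np.ndarray, list, list[list]]:
        """Complete-case data cube (subjects x level-grid) and level lists."""
        df = self.data[[self.subject, *self.within, self.dv]].dropna()
        levels = [list(pd.unique(df[f])) for f in self.within]
        n_cells = math.prod(len(lv) for lv in levels)
        piv = df.pivot_table(
            index=self.subject, columns=list(self.within), values=self.dv,
            aggfunc="mean", sort=False,
        )
        full = [
            c if isinstance(c, tuple) else (c,)
            for c in itertools.product(*levels)
        ]
        cols = [c if len(self.within) > 1 else c[0] for c in full]
        piv = piv.reindex(columns=cols)
        complete = piv.dropna()
        if complete.shape[0] < 3:
            raise InsufficientDataError(
                f"need >= 3 subjects with all {n_cells} cells; "
                f"have {complete.shape[0]}"
            )
        cube = complete.to_numpy(dtype=float).reshape(
            complete.shape[0], *[len(lv) for lv in levels]
        )
        return cube, list(complete.index), levels

    def fit(self, alpha: float = 0.05, multiplicity: str = "tukey") -> "RMAnovaResults":
        cube, subjects, levels = self._complete_cube()
        if len(self.within) == 1:
            table = _oneway_table(cube, self.within[0])
        else:
            table = _twoway_table(cube, self.within)
        return RMAnovaResults(
            model=self,
            anova_table=table,
            cube=cube,
            subjects=subjects,
            levels=levels,
            alpha=alpha,
            multiplicity=multiplicity,
        )


def _oneway_table(cube: np.ndarray, factor: str) -> pd.DataFrame:
    n, t = cube.shape
    grand = cube.mean()
    subj_means = cube.mean(axis=1)
    time_means = cube.mean(axis=0)
    ss_total = float(((cube - grand) ** 2).sum())
    ss_subject = float(t * ((subj_means - grand) ** 2).sum())
    ss_factor = float(n * ((time_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_factor, 0.0)
    df_factor, df_error = t - 1, (n - 1) * (t - 1)
    ms_error = ss_error / df_error
    if ms_error <= 0 and ss_factor > 0:
        raise DegenerateVarianceError("zero within-subject error variance")
    if ms_error <= 0:
        # every subject constant over time: no effect, nothing to test
        f, p = float("nan"), 1.0
    else:
        f = (ss_factor / df_factor) / ms_error
        p = float(sps.f.sf(f, df_factor, df_error))
    return pd.DataFrame(
        {
            "SS": [ss_subject, ss_factor, ss_error],
            "df": [n - 1, df_factor, df_error],
            "MS": [ss_subject / (n - 1), ss_factor / df_factor, ms_error],
            "F": [np.nan, f, np.nan],
            "p": [np.nan, p, np.nan],
        },
        index=["subject", factor, "error"],
    )


def _twoway_table(cube: np.ndarray, factors: tuple[str, str]) -> pd.DataFrame:
    n, a, b = cube.shape
    g = cube.mean()
    s_i = cube.mean(axis=(1, 2))
    a_j = cube.mean(axis=(0, 2))
    b_k = cube.mean(axis=(0, 1))
    sa = cube.mean(axis=2)
    sb = cube.mean(axis=1)
    ab = cube.mean(axis=0)

    ss_s = a * b * ((s_i - g) ** 2).sum()
    ss_a = n * b * ((a_j - g) ** 2).sum()
    ss_b = n * a * ((b_k - g) ** 2).sum()
    ss_ab = n * ((ab - a_j[:, None] - b_k[None, :] + g) ** 2).sum()
    ss_sa = b * ((sa - s_i[:, None] - a_j[None, :] + g) ** 2).sum()
    ss_sb = a * ((sb - s_i[:, None] - b_k[None, :] + g) ** 2).sum()
    resid = (
        cube
        - sa[:, :, None]
        - sb[:, None, :]
        - ab[None, :, :]
        + s_i[:, None, None]
        + a_j[None, :, None]
        + b_k[None, None, :]
        - g
    )
    ss_sab = (resid ** 2).sum()

    rows = {}
    fa, fb = factors
    for name, ss, df, err_ss, err_df in (
        (fa, ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        (fb, ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        (f"{fa}:{fb}", ss_ab, (a - 1) * (b - 1), ss_sab, (n - 1) * (a - 1) * (b - 1)),
    ):
        if df == 0 or err_df == 0:
            # single-level factor: the effect does not exist in this design
            rows[name] = (ss, df, np.nan, np.nan, np.nan)
            rows[f"error({name})"] = (err_ss, err_df, np.nan, np.nan, np.nan)
            continue
        ms_err = err_ss / err_df
        if ms_err <= 0:
            raise DegenerateVarianceError(f"zero error variance for effect {name}")
        f_stat = (ss / df) / ms_err
        rows[name] = (ss, df, ss / df, f_stat, float(sps.f.sf(f_stat, df, err_df)))
        rows[f"error({name})"] = (err_ss, err_df, ms_err, np.nan, np.nan)
    rows["subject"] = (ss_s, n - 1, ss_s / (n - 1), np.nan, np.nan)
    return pd.DataFrame(rows, index=["SS", "df", "MS", "F", "p"]).T


from functools import lru_cache


@lru_cache(maxsize=256)
def _tukey_critical(alpha: float, t: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1 - alpha, t, df))


def _time_contrasts(cube, levels, table, alpha, multiplicity):
    """All-pairs contrasts on the RM error mean square (one-way only)."""
    if cube is None:
        return []
    n, t = cube.shape
    means = cube.mean(axis=0)
    factor_levels = [str(lv) for lv in levels[0]]
    ms_error = float(table.loc["error", "MS"])
    df_error = int(table.loc["error", "df"])
    se_unit = math.sqrt(ms_error / n)
    out = []
    for j, k in itertools.combinations(range(t), 2):
        base, follow = factor_levels[j], factor_levels[k]
        d = float(means[k] - means[j])
        if se_unit == 0:
            p, half = 1.0, 0.0
        elif multiplicity == "tukey":
            q = abs(d) / se_unit
            p = float(sps.studentized_range.sf(q, t, df_error))
            half = _tukey_critical(alpha, t, df_error) * se_unit
        elif multiplicity == "none":
            se_d = se_unit * math.sqrt(2.0)
            tt = abs(d) / se_d
            p = float(2 * sps.t.sf(tt, df_error))
            half = float(sps.t.ppf(1 - alpha / 2, df_error)) * se_d
        else:
            raise ValueError(f"unknown multiplicity {multiplicity!r}")
        ci = (d - half, d + half)
        if means[j] > 0 and means[k] > 0:
            fold = means[k] / means[j]
            fold_ci = ((ci[0] + means[j]) / means[j], (ci[1] + means[j]) / means[j])
        else:
            fold = float("nan")
            fold_ci = (float("nan"), float("nan"))
        out.append(
            ContrastResult(
                baseline=base,
                follow_up=follow,
                mean_difference=d,
                diff_ci=ci,
                fold=fold,
                fold_ci=fold_ci,
                p_value=min(p, 1.0),
            )
        )
    return out


class RMAnovaResults:
    """Fitted repeated-measures ANOVA: table, contrasts, summary.

    Pairwise contrasts (studentized-range p-values are comparatively
    expensive) are computed on first access of :attr:`contrasts`.
    """

    def __init__(self, model, anova_table, cube, subjects, levels, alpha,
                 multiplicity="tukey"):
        self.model = model
        self.anova_table = anova_table
        self.subjects = subjects
        self.levels = levels
        self.alpha = alpha
        self.multiplicity = multiplicity
        self._cube = cube
        self._contrasts: list[ContrastResult] | None = None

    @property
    def contrasts(self) -> list[ContrastResult]:
        if self._contrasts is None:
            self._contrasts = _time_contrasts(
                self._cube if self._cube.ndim == 2 else None,
                self.levels, self.anova_table, self.alpha, self.multiplicity,
            )
        return self._contrasts

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def f_statistic(self) -> float:
        """Omnibus F of the (first) within factor."""
        return float(self.anova_table.loc[self.model.within[0], "F"])

    @property
    def p_value(self) -> float:
        return float(self.anova_table.loc[self.model.within[0], "p"])

    def contrast(self, baseline: str, follow_up: str) -> ContrastResult:
        for c in self.contrasts:
            if {c.baseline, c.follow_up} == {str(baseline), str(follow_up)}:
                if c.baseline == str(baseline):
                    return c
                # flip orientation on request
                lo, hi = c.diff_ci
                return ContrastResult(
                    baseline=str(baseline),
                    follow_up=str(follow_up),
                    mean_difference=-c.mean_difference,
                    diff_ci=(-hi, -lo),
                    fold=1.0 / c.fold,
                    fold_ci=(
                        1.0 / c.fold_ci[1],
                        1.0 / c.fold_ci[0],
                    ),
                    p_value=c.p_value,
                )
        raise KeyError(f"no contrast between {baseline!r} and {follow_up!r}")

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "baseline": c.baseline,
                    "follow_up": c.follow_up,
                    "mean_difference": c.mean_difference,
                    "diff_ci_low": c.diff_ci[0],
                    "diff_ci_high": c.diff_ci[1],
                    "fold": c.fold,
                    "fold_ci_low": c.fold_ci[0],
                    "fold_ci_high": c.fold_ci[1],
                    "p_value": c.p_value,
                }
                for c in self.contrasts
            ]
        )

    def summary(self) -> str:
        lines = [
            "Repeated-measures ANOVA",
            f"  dependent variable: {self.model.dv}",
            f"  within factors:     {', '.join(self.model.within)}",
            f"  complete subjects:  {self.n_subjects}",
            "",
            self.anova_table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        if self.contrasts:
            lines += ["", "Pairwise contrasts (Tukey on the RM error term):",
                      self.contrasts_frame().to_string(
                          index=False, float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)


def rm_anova_oneway(
    wide: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    multiplicity: str = "tukey",
) -> RMAnovaResults:
    """One-way RM-ANOVA on a subjects x time-points wide table."""
    if isinstance(wide, np.ndarray):
        wide = pd.DataFrame(wide, columns=[f"t{i}" for i in range(wide.shape[1])])
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="time", value_name="y"
    )
    return RepeatedMeasuresAnova(long, dv="y", subject="subject", within="time").fit(
        alpha=alpha, multiplicity=multiplicity
    )


def rm_anova_twoway(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: tuple[str, str],
    alpha: float = 0.05,
) -> RMAnovaResults:
    """Two-way fully-within-subject ANOVA on a long-format table."""
    return RepeatedMeasuresAnova(data, dv=dv, subject=subject, within=within).fit(
        alpha=alpha
    )


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

def cohort_table(records, gates: SubsetGates) -> pd.DataFrame:
    """One row per sample: concentrations and pooled-neutrophil MFIs.

    Columns: subject, day, session, time, group, total and per-subset
    concentrations (1e6 cells/ml), ``mfi_<marker>`` for the six tracked
    markers, and a ``complete`` flag marking subjects observed at all six
    time points (incomplete subjects are excluded from inference).
    """
    rows = []
    for rec in records:
        mask = gate_neutrophils(rec.events, gates)
        result = classify_subsets(rec.events, mask, gates)
        conc = subset_concentration(result, rec.counter_concentration)
        neut_mask = np.isin(result.labels, NEUTROPHIL_SUBSETS)
        row = {
            "subject": rec.subject,
            "day": rec.day,
            "session": rec.session,
            "time": rec.time_label,
            "group": rec.group,
            "counter_concentration": rec.counter_concentration,
            **conc,
        }
        for marker in MFI_MARKERS:
            try:
                row[f"mfi_{marker}"] = median_fluorescence(rec.events, neut_mask, marker)
            except EmptyGateError:
                row[f"mfi_{marker}"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    expected = {f"{s}_d{d}" for d, s in TIME_POINTS}
    seen = df[df["session"] != "lps"].groupby("subject")["time"].agg(set)
    complete = {subj: times >= expected for subj, times in seen.items()}
    df["complete"] = df["subject"].map(complete).fillna(False)
    return df


def subset_mfi_table(records, gates: SubsetGates) -> pd.DataFrame:
    """Long table of per-subset MFIs: subject x time x subset rows."""
    rows = []
    for rec in records:
        mask = gate_neutrophils(rec.events, gates)
        result = classify_subsets(rec.events, mask, gates)
        for subset in NEUTROPHIL_SUBSETS:
            sub_mask = result.labels == subset
            row = {
                "subject": rec.subject,
                "time": rec.time_label,
                "day": rec.day,
                "session": rec.session,
                "subset": subset,
            }
            for marker in MFI_MARKERS:
                try:
                    row[f"mfi_{marker}"] = median_fluorescence(rec.events, sub_mask, marker)
                except EmptyGateError:
                    row[f"mfi_{marker}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
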