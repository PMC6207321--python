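"""Neutrophil gating and CD16/CD62L subset classification.

The strategy mirrors manual analysis of a granulocyte panel: a scatter gate
selects the granulocyte cluster (high FSC/SSC), CD66b positivity removes
monocytes and other mononuclear cells, and CD16 positivity completes the
neutrophil definition. Gated neutrophils are then classified into the
three CD16/CD62L quadrant subsets; the CD16-dim/CD62L-dim quadrant is not a
reported subset and is counted separately. Gated fractions are converted
to absolute concentrations against the automated-counter leukocyte count.

Thresholds are quadrant gates, not clusters: every threshold is closed on
the bright/positive side (an event exactly on a boundary is bright), which
makes gating fully deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import EventMatrix
from .panel import PanelError
from .synthetic import NEUTROPHIL_SUBSETS

logger = logging.getLogger(__name__)

NON_NEUTROPHIL = "non-neutrophil"


class EmptyGateError(ValueError):
    """No events pass the gate."""


@dataclass(frozen=True)
class SubsetGates:
    """Gate geometry: scatter rectangle plus marker thresholds (a.u.).

    ``scatter`` is ``(fsc_min, fsc_max, ssc_min, ssc_max)``; upper bounds
    may be ``inf``. ``cd16_positive`` is the low CD16-positivity bound of
    the neutrophil definition (below the dim/bright split), ``cd16`` and
    ``cd62l`` the dim-vs-bright quadrant thresholds. ``cd14_max`` optionally
    excludes CD14-high events (monocyte exclusion beyond CD66b); off by
    default.
    """

    scatter: tuple[float, float, float, float]
    cd66b: float
    cd16: float
    cd62l: float
    cd16_positive: float = 1.0
    cd14_max: float | None = None

    def __post_init__(self) -> None:
        fsc_min, fsc_max, ssc_min, ssc_max = self.scatter
        if not (fsc_min < fsc_max and ssc_min < ssc_max):
            raise ValueError("scatter gate is degenerate")
        for name in ("cd66b", "cd16", "cd62l", "cd16_positive"):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be strictly positive")

    def to_dict(self) -> dict:
        d = {
            "scatter": list(self.scatter),
            "cd66b": self.cd66b,
            "cd16": self.cd16,
            "cd62l": self.cd62l,
            "cd16_positive": self.cd16_positive,
        }
        if self.cd14_max is not None:
            d["cd14_max"] = self.cd14_max
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubsetGates":
        return cls(
            scatter=tuple(d["scatter"]),
            cd66b=float(d["cd66b"]),
            cd16=float(d["cd16"]),
            cd62l=float(d["cd62l"]),
            cd16_positive=float(d.get("cd16_positive", 1.0)),
            cd14_max=d.get("cd14_max"),
        )


@dataclass
class GatingResult:
    """Per-event labels plus the derived fractions.

    ``subset_fractions`` are fractions *of neutrophils* and sum to 1 over
    the three subset labels; ``neutrophil_fraction`` is the neutrophil
    share of all events. ``dim_dim_count`` logs the CD16-dim/CD62L-dim
    remainder excluded from the subsets.
    """

    labels: np.ndarray
    neutrophil_fraction: float
    subset_fractions: dict[str, float]
    dim_dim_count: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subset_fractions.values())
        if self.subset_fractions and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("subset fractions must sum to 1 over neutrophil labels")


# --------------------------------------------------------------------------
# Threshold derivation
# --------------------------------------------------------------------------

def valley_threshold(
    values: np.ndarray, fallback_quantile: float = 0.05, bins: int = 256
) -> float:
    """Dim/bright split at the density valley of the log-intensity histogram.

    Intensities are shifted positive, log10-transformed and binned; the
    histogram is smoothed and the threshold placed at the minimum between
    the two most prominent modes. If the distribution is unimodal the
    threshold falls back to the ``fallback_quantile`` of the (shifted) main
    mode, mapped back to the original scale.
    """
    values = np.asarray(values, dtype=float)
    shift = min(values.min() - 1.0, 0.0)
    logv = np.log10(values - shift)
    hist, edges = np.histogram(logv, bins=bins)
    smooth = gaussian_filter1d(hist.astype(float), sigma=3.0)
    peaks, props = find_peaks(smooth, prominence=smooth.max() * 0.05)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        lo, hi = sorted(top2)
        valley = lo + int(np.argmin(smooth[lo : hi + 1]))
        return float(10 ** centers[valley] + shift)
    return float(10 ** np.quantile(logv, fallback_quantile) + shift)


def derive_gates(
    control_events: EventMatrix,
    cd16_positive_ratio: float = 50.0,
    use_cd14: bool = False,
) -> SubsetGates:
    """Derive default gates from a pooled baseline (control) sample.

    Scatter and CD66b thresholds come from the valley between the
    granulocyte and mononuclear modes; the CD16 and CD62L dim/bright
    thresholds from the valley of each marker's log-intensity histogram
    over the scatter+CD66b-gated events. The low CD16-positivity bound of
    the neutrophil definition is placed well below the dim/bright split
    (that split divided by ``cd16_positive_ratio``) so the CD16-dim
    subset is retained in full.
    """
    control_events.panel.require("FSC", "SSC", "CD66b", "CD16", "CD62L")
    fsc_min = valley_threshold(control_events.channel("FSC"))
    ssc_min = valley_threshold(control_events.channel("SSC"))
    cd66b = valley_threshold(control_events.channel("CD66b"))

    pre = (
        (control_events.channel("FSC") >= fsc_min)
        & (control_events.channel("SSC") >= ssc_min)
        & (control_events.channel("CD66b") >= cd66b)
    )
    if not pre.any():
        raise EmptyGateError("no events pass the derived scatter/CD66b gate")
    cd16_vals = control_events.channel("CD16")[pre]
    cd62l_vals = control_events.channel("CD62L")[pre]
    cd16 = valley_threshold(cd16_vals)
    cd62l = valley_threshold(cd62l_vals)
    cd16_pos = max(cd16 / cd16_positive_ratio, 1e-6)
    cd14_max = None
    if use_cd14:
        control_events.panel.require("CD14")
        cd14_max = valley_threshold(control_events.channel("CD14"))
    return SubsetGates(
        scatter=(fsc_min, math.inf, ssc_min, math.inf),
        cd66b=cd66b,
        cd16=cd16,
        cd62l=cd62l,
        cd16_positive=cd16_pos,
        cd14_max=cd14_max,
    )


# --------------------------------------------------------------------------
# Gating
# --------------------------------------------------------------------------

def gate_singlets(events: EventMatrix) -> np.ndarray:
    """Singlet gate hook; pass-through (doublets are not modelled)."""
    return np.ones(events.n_events, dtype=bool)


def gate_neutrophils(events: EventMatrix, gates: SubsetGates) -> np.ndarray:
    """Boolean mask of neutrophils: scatter gate ∧ CD66b⁺ ∧ CD16⁺.

    All bounds are closed on the included side. An all-false mask is legal
    (a warning is logged); downstream statistics must handle it.
    """
    try:
        events.panel.require("FSC", "SSC", "CD66b", "CD16")
    except PanelError:
        raise
    fsc_min, fsc_max, ssc_min, ssc_max = gates.scatter
    fsc, ssc = events.channel("FSC"), events.channel("SSC")
    mask = (
        (fsc >= fsc_min)
        & (fsc <= fsc_max)
        & (ssc >= ssc_min)
        & (ssc <= ssc_max)
        & (events.channel("CD66b") >= gates.cd66b)
        & (events.channel("CD16") >= gates.cd16_positive)
    )
    if gates.cd14_max is not None:
        events.panel.require("CD14")
        mask &= events.channel("CD14") <= gates.cd14_max
    if not mask.any():
        logger.warning("neutrophil gate is empty (%d events examined)", events.n_events)
    return mask


def classify_subsets(
    events: EventMatrix, mask: np.ndarray, gates: SubsetGates
) -> GatingResult:
    """Quadrant classification of gated neutrophils by CD16/CD62L.

    Each masked event gets exactly one of the three subset labels; the
    CD16-dim/CD62L-dim quadrant is relabelled non-neutrophil and its count
    logged. Fractions are computed over the three retained labels.
    """
    events.panel.require("CD16", "CD62L")
    mask = np.asarray(mask, dtype=bool)
    labels = np.full(events.n_events, NON_NEUTROPHIL, dtype=object)
    cd16_bright = events.channel("CD16") >= gates.cd16
    cd62l_bright = events.channel("CD62L") >= gates.cd62l

    labels[mask & cd16_bright & cd62l_bright] = "CD16brightCD62Lbright"
    labels[mask & cd16_bright & ~cd62l_bright] = "CD16brightCD62Ldim"
    labels[mask & ~cd16_bright & cd62l_bright] = "CD16dimCD62Lbright"
    dim_dim = mask & ~cd16_bright & ~cd62l_bright
    n_dim_dim = int(dim_dim.sum())
    if n_dim_dim:
        logger.info(
            "excluded %d CD16dimCD62Ldim events from the neutrophil subsets",
            n_dim_dim,
        )

    counts = {s: int((labels == s).sum()) for s in NEUTROPHIL_SUBSETS}
    n_neut = sum(counts.values())
    fractions = (
        {s: counts[s] / n_neut for s in NEUTROPHIL_SUBSETS} if n_neut else {}
    )
    return GatingResult(
        labels=np.asarray(labels, dtype=str),
        neutrophil_fraction=n_neut / events.n_events,
        subset_fractions=fractions,
        dim_dim_count=n_dim_dim,
        n_events=events.n_events,
    )


def subset_concentration(
    result: GatingResult, counter_concentration: float
) -> dict[str, float]:
    """Absolute subset concentrations (1e6 cells/ml) from gated fractions.

    Each subset concentration is counter concentration x neutrophil
    fraction x subset fraction; ``"total"`` is the sum over the three
    subsets.
    """
    if not counter_concentration > 0:
        raise ValueError("counter_concentration must be > 0")
    total = counter_concentration * result.neutrophil_fraction
    out = {
        s: total * result.subset_fractions.get(s, 0.0) for s in NEUTROPHIL_SUBSETS
    }
    out["total"] = total
    return out
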