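"""Control-anchored response-specific single-cell PCA ("FLOOD-style").

Given standardized single-cell marker data split into a control pool (the
homeostatic reference, here all morning day 1 cells) and a response pool,
the model separates the variation shared with controls from the variation
specific to the response:

1. the *control subspace* is spanned by the top ``k_c`` principal
   directions of the control pool (default: the smallest number of
   components explaining >= 90% of control variance);
2. response cells are *deflated* by projecting onto the orthogonal
   complement of the control subspace, removing everything a control-like
   cell could explain;
3. the *response loadings* are the top ``k_r`` principal directions of the
   deflated response pool (default 2, for a 2-D biplot), and each
   component's explained fraction is its eigenvalue share of the deflated
   response covariance.

Cells are visualised by their scores on the response components together
with per-marker loading vectors (a biplot: vector length is the marker's
importance, angles between vectors its correlations). A *benchmark region*
— the Mahalanobis ellipse containing a nominal fraction (default 80%) of
the reference cells in score space — anchors the plots: a sample whose
cells fall outside the control benchmark has left the homeostatic state.

Preprocessing is a single fixed map per analysis: shift all intensities so
the global minimum is exactly 1 (background subtraction and compensation
leave negative values), log10-transform, then centre and scale each marker
by its control-pool mean and SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .panel import PanelDef


class DegenerateMarkerError(ValueError):
    """A marker has zero variance in the control pool."""


class RankError(ValueError):
    """Requested more components than the data's rank supports."""


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def shift_to_positive(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract (global minimum - 1) so the smallest value is exactly 1.

    Returns the shifted matrix and the shift constant (global minimum - 1);
    pairwise differences are preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("shift_to_positive requires finite input")
    shift = float(values.min() - 1.0)
    return values - shift, shift


@dataclass(frozen=True)
class PreprocessParams:
    """Fixed preprocessing map: shift constant + control log10 mean/SD."""

    shift: float
    markers: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd) <= 0):
            raise DegenerateMarkerError("control SDs must be > 0")


def fit_preprocess(
    control_values: np.ndarray, markers: tuple[str, ...], shift: float
) -> PreprocessParams:
    """Per-marker mean and sample SD (n-1) of log10 shifted control cells.

    ``shift`` is the constant fitted on the full analysis data (control
    and response pools together), so that one preprocessing map serves
    every sample of the analysis.
    """
    shifted = np.asarray(control_values, dtype=float) - shift
    if shifted.shape[0] < 2:
        raise ValueError("need >= 2 control events")
    if shifted.min() <= 0:
        raise ValueError("post-shift control values must be positive")
    logv = np.log10(shifted)
    sd = logv.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateMarkerError(
            f"zero-variance control marker(s): {[markers[i] for i in zero]}"
        )
    return PreprocessParams(
        shift=shift, markers=tuple(markers), mean=logv.mean(axis=0), sd=sd
    )


def preprocess(values: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Standardize raw intensities: z = (log10(x - shift) - mean) / SD."""
    shifted = np.asarray(values, dtype=float) - params.shift
    if shifted.min() <= 0:
        raise ValueError(
            "values fall below the fitted shift; refit the shift on the "
            "union of all pools of this analysis"
        )
    return (np.log10(shifted) - params.mean) / params.sd


# --------------------------------------------------------------------------
# Benchmark regions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRegion:
    """Mahalanobis ellipse containing ~``coverage`` of its defining cells."""

    center: np.ndarray
    shape: np.ndarray
    threshold: float
    coverage: float

    def __post_init__(self) -> None:
        shape = np.asarray(self.shape, dtype=float)
        if not np.allclose(shape, shape.T):
            raise ValueError("shape matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(shape) <= 0):
            raise ValueError("shape matrix must be positive definite")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")

    def mahalanobis_sq(self, scores: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(scores) - self.center
        return np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.shape), d)

    def contains(self, scores: np.ndarray) -> np.ndarray:
        return self.mahalanobis_sq(scores) <= self.threshold


def benchmark_region(scores: np.ndarray, coverage: float = 0.80) -> BenchmarkRegion:
    """Fit the coverage ellipse of a score cloud.

    The ellipse is centred on the score mean with the score covariance as
    shape; its squared Mahalanobis radius is the empirical ``coverage``
    quantile of the defining cells' squared distances, so by construction
    the inside-fraction of the defining cells is within 1/n of coverage.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 50:
        raise ValueError("need >= 50 scores to fit a benchmark region")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in the open interval (0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise ValueError("degenerate benchmark: singular score covariance")
    d = scores - center
    d2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
    threshold = float(np.quantile(d2, coverage))
    return BenchmarkRegion(center=center, shape=cov, threshold=threshold, coverage=coverage)


def overlap_fraction(scores: np.ndarray, region: BenchmarkRegion) -> float:
    """Fraction of scores inside the region (squared distance <= radius)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot compute overlap of an empty score set")
    return float(region.contains(scores).mean())


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

def _sign_fix(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude element of each column positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _pca(z: np.ndarray, rank_tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the (n-1)-covariance, sorted descending."""
    zc = z - z.mean(axis=0)
    cov = (zc.T @ zc) / (zc.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    return eigval, eigvec[:, order]


class FloodModel:
    """Response-specific component model of standardized single-cell data.

    Parameters
    ----------
    control_z, response_z
        Standardized (events x markers) pools; see :func:`preprocess`.
    markers
        Marker names, in column order.
    k_c
        Control-subspace dimension. ``None`` keeps every control component
        whose eigenvalue exceeds the Marchenko-Pastur noise edge
        ``(1 + sqrt(p / n))^2`` of the standardized control pool (at least
        one, at most ``p - k_r``): on control-standardized data the bulk
        of the spectrum sits at 1, and only genuinely correlated control
        structure rises above the edge, so the rule removes exactly the
        directions a control-like cell can explain without consuming the
        whole marker space.
    k_r
        Number of response components (default 2, plotted as PC1/PC2).
    """

    def __init__(
        self,
        control_z: np.ndarray,
        response_z: np.ndarray,
        markers: tuple[str, ...],
        k_c: int | None = None,
        k_r: int = 2,
    ) -> None:
        self.control_z = np.asarray(control_z, dtype=float)
        self.response_z = np.asarray(response_z, dtype=float)
        self.markers = tuple(markers)
        if self.control_z.shape[0] == 0 or self.response_z.shape[0] == 0:
            raise ValueError("both pools must be non-empty")
        if self.control_z.shape[1] != len(self.markers) or self.response_z.shape[
            1
        ] != len(self.markers):
            raise ValueError("pool width must equal the number of markers")
        self.k_c = k_c
        self.k_r = k_r

    def fit(self, coverage: float = 0.80) -> "FloodResults":
        p = len(self.markers)
        c_eigval, c_eigvec = _pca(self.control_z)
        if self.k_c is None:
            edge = (1.0 + math.sqrt(p / self.control_z.shape[0])) ** 2
            k_c = int(np.sum(c_eigval > edge))
            k_c = max(1, min(k_c, p - self.k_r))
        else:
            k_c = self.k_c
        if k_c + self.k_r > p:
            raise RankError(
                f"k_c + k_r = {k_c + self.k_r} exceeds the {p} markers"
            )
        if c_eigval[k_c - 1] <= 1e-12:
            raise RankError(f"control pool rank is below k_c = {k_c}")
        control_loadings = _sign_fix(c_eigvec[:, :k_c])

        # Deflate: remove everything the control subspace can explain.
        proj = np.eye(p) - control_loadings @ control_loadings.T
        response_centered = self.response_z - self.response_z.mean(axis=0)
        deflated = response_centered @ proj
        r_eigval, r_eigvec = _pca(deflated)
        if r_eigval[self.k_r - 1] <= 1e-12:
            raise RankError(
                f"deflated response rank is below k_r = {self.k_r}"
            )
        response_loadings = _sign_fix(r_eigvec[:, : self.k_r])
        explained = r_eigval[: self.k_r] / r_eigval.sum()

        results = FloodResults(
            model=self,
            markers=self.markers,
            control_loadings=control_loadings,
            response_loadings=response_loadings,
            explained_fractions=explained,
            response_mean=self.response_z.mean(axis=0),
            deflation=proj,
        )
        control_scores = results.project(self.control_z)
        if control_scores.shape[0] >= 50:
            results.benchmark = benchmark_region(control_scores, coverage=coverage)
        return results


class FloodResults:
    """Fitted model: loadings, explained fractions, projection, benchmark."""

    def __init__(
        self,
        model,
        markers,
        control_loadings,
        response_loadings,
        explained_fractions,
        response_mean,
        deflation,
        params: PreprocessParams | None = None,
    ):
        self.model = model
        self.markers = tuple(markers)
        self.control_loadings = np.asarray(control_loadings)
        self.response_loadings = np.asarray(response_loadings)
        self.explained_fractions = np.asarray(explained_fractions)
        self.response_mean = np.asarray(response_mean)
        self.deflation = np.asarray(deflation)
        self.params = params
        self.benchmark: BenchmarkRegion | None = None

    @property
    def k_c(self) -> int:
        return self.control_loadings.shape[1]

    @property
    def k_r(self) -> int:
        return self.response_loadings.shape[1]

    def project(self, z: np.ndarray) -> np.ndarray:
        """Scores on the response components: deflated z x loadings.

        The map is linear (no re-centering), so standardized pools keep
        their mean structure: the control pool, centred by construction of
        the preprocessing, projects to scores with mean zero.
        """
        z = np.asarray(z, dtype=float)
        return z @ self.deflation @ self.response_loadings

    def summary(self) -> str:
        lines = [
            "Response-specific component model",
            f"  markers:             {len(self.markers)}",
            f"  control components:  {self.k_c}",
            f"  response components: {self.k_r}",
            "  explained response-specific variance: "
            + ", ".join(
                f"PC{i + 1} {f * 100:.1f}%"
                for i, f in enumerate(self.explained_fractions)
            ),
            "",
            "  response loadings:",
        ]
        for i, m in enumerate(self.markers):
            weights = ", ".join(
                f"PC{j + 1} {self.response_loadings[i, j]:+.3f}"
                for j in range(self.k_r)
            )
            lines.append(f"    {m:>10s}: {weights}")
        if self.benchmark is not None:
            lines.append(
                f"  control benchmark: coverage {self.benchmark.coverage:.0%}, "
                f"squared radius {self.benchmark.threshold:.3f}"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "markers": list(self.markers),
            "control_loadings": self.control_loadings.tolist(),
            "response_loadings": self.response_loadings.tolist(),
            "explained_fractions": self.explained_fractions.tolist(),
            "response_mean": self.response_mean.tolist(),
        }
        if self.params is not None:
            d["preprocess"] = {
                "shift": self.params.shift,
                "mean": np.asarray(self.params.mean).tolist(),
                "sd": np.asarray(self.params.sd).tolist(),
            }
        if self.benchmark is not None:
            d["benchmark"] = {
                "center": self.benchmark.center.tolist(),
                "shape": self.benchmark.shape.tolist(),
                "threshold": self.benchmark.threshold,
                "coverage": self.benchmark.coverage,
            }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FloodResults":
        with open(path) as fh:
            d = json.load(fh)
        markers = tuple(d["markers"])
        control_loadings = np.asarray(d["control_loadings"])
        params = None
        if "preprocess" in d:
            pp = d["preprocess"]
            params = PreprocessParams(
                shift=pp["shift"],
                markers=markers,
                mean=np.asarray(pp["mean"]),
                sd=np.asarray(pp["sd"]),
            )
        res = cls(
            model=None,
            markers=markers,
            control_loadings=control_loadings,
            response_loadings=np.asarray(d["response_loadings"]),
            explained_fractions=np.asarray(d["explained_fractions"]),
            response_mean=np.asarray(d["response_mean"]),
            deflation=np.eye(len(markers)) - control_loadings @ control_loadings.T,
            params=params,
        )
        if "benchmark" in d:
            b = d["benchmark"]
            res.benchmark = BenchmarkRegion(
                center=np.asarray(b["center"]),
                shape=np.asarray(b["shape"]),
                threshold=b["threshold"],
                coverage=b["coverage"],
            )
        return res


def fit_flood(
    control_z: np.ndarray,
    response_z: np.ndarray,
    k_c: int | None = None,
    k_r: int = 2,
    markers: tuple[str, ...] | None = None,
    coverage: float = 0.80,
) -> FloodResults:
    """Convenience wrapper: build and fit a :class:`FloodModel`."""
    if markers is None:
        markers = tuple(f"M{i + 1}" for i in range(np.asarray(control_z).shape[1]))
    return FloodModel(control_z, response_z, markers, k_c=k_c, k_r=k_r).fit(
        coverage=coverage
    )


# --------------------------------------------------------------------------
# Records-level analysis
# --------------------------------------------------------------------------

def flood_from_records(
    records,
    gates,
    k_c: int | None = None,
    k_r: int = 2,
    coverage: float = 0.80,
    per_sample_benchmark: str = "per-sample",
):
    """Fit the response model on gated neutrophils of a cohort.

    The control pool is every sample with ``group == "control"`` (all
    morning day 1 samples by construction); everything else forms the
    response pool. The shift constant is fitted once on the union of both
    pools, preprocessing statistics on the control pool only.

    Returns ``(results, per_sample)`` where ``per_sample`` maps
    ``(subject, time_label)`` to a dict with the sample's scores, its own
    benchmark region and its overlap with the control benchmark.
    """
    from .gating import gate_neutrophils  # local import avoids cycle

    panel: PanelDef = records[0].events.panel
    markers = panel.fluorescence_channels
    idx = [panel.index(m) for m in markers]

    pools: dict[str, list[np.ndarray]] = {"control": [], "response": []}
    sample_values: list[tuple[object, np.ndarray]] = []
    for rec in records:
        mask = gate_neutrophils(rec.events, gates)
        vals = rec.events.values[mask][:, idx]
        if vals.shape[0] == 0:
            continue
        pools[rec.group].append(vals)
        sample_values.append((rec, vals))
    if not pools["control"] or not pools["response"]:
        raise ValueError("need gated cells in both the control and response group")

    control_raw = np.vstack(pools["control"])
    response_raw = np.vstack(pools["response"])
    _, shift = shift_to_positive(np.vstack([control_raw, response_raw]))
    params = fit_preprocess(control_raw, markers, shift)
    control_z = preprocess(control_raw, params)
    response_z = preprocess(response_raw, params)

    results = FloodModel(control_z, response_z, markers, k_c=k_c, k_r=k_r).fit(
        coverage=coverage
    )
    results.params = params

    per_sample = {}
    for rec, vals in sample_values:
        scores = results.project(preprocess(vals, params))
        entry = {
            "scores": scores,
            "overlap": overlap_fraction(scores, results.benchmark),
        }
        if scores.shape[0] >= 50:
            if per_sample_benchmark == "per-sample":
                entry["benchmark"] = benchmark_region(scores, coverage=coverage)
            else:  # pooled covariance, sample-specific centre
                entry["benchmark"] = BenchmarkRegion(
                    center=scores.mean(axis=0),
                    shape=results.benchmark.shape,
                    threshold=results.benchmark.threshold,
                    coverage=coverage,
                )
        per_sample[(rec.subject, rec.time_label)] = entry
    return results, per_sample
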