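"""The four information markers computed from a feature matrix.

Given a patches-by-features table, the suite summarises how much independent
structure the representation carries:

* **Normalised Shannon entropy** — spread of the feature value distribution,
  in [0, 1].
* **Cumulative explained-variance curve** of a PCA on the (standardised)
  matrix, from which come
* **1-AUC** — one minus the normalised area under that curve; higher means the
  variance is spread over more components, and
* **PC95** — the smallest number of ranked components explaining 95% of the
  variance.
* **Inverse power law** ``IP(n) = a * n**(-b) + c`` fitted to the curve, with
  ``a`` the learning rate, ``b`` the decay rate and asymptote ``c in [0, 1]``;
  summarised by the signed log-parameter metric ``M = log10(|a|) - b``
  (less negative = slower spectral decay = more information).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from sklearn.decomposition import PCA

from .features import FeatureMatrix

__all__ = [
    "VarianceCurve",
    "PowerLawFit",
    "InfoReport",
    "standardize",
    "cumulative_variance",
    "pc95",
    "inverse_auc",
    "fit_inverse_power_law",
    "loglaw_metric",
    "shannon_entropy",
    "info_report",
    "LOGLAW_VARIANTS",
    "ENTROPY_METHODS",
]


class MetricValidationError(ValueError):
    """Raised on degenerate or invalid inputs to a marker computation."""


@dataclass(frozen=True)
class VarianceCurve:
    """Cumulative explained-variance fractions over ranked components."""

    y: np.ndarray
    d: int
    n_samples: int

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if y.ndim != 1 or y.shape[0] != self.d or self.d < 1:
            raise MetricValidationError(f"curve length {y.shape} != d={self.d}")
        if y[0] <= 0 or np.any(np.diff(y) < -1e-9):
            raise MetricValidationError("cumulative variance must be positive and nondecreasing")
        if abs(y[-1] - 1.0) > 1e-9:
            raise MetricValidationError(f"curve must terminate at 1, got {y[-1]!r}")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of ``IP(n) = a * n**(-b) + c`` to a variance curve."""

    a: float
    b: float
    c: float
    rss: float
    r2: float
    converged: bool
    n_points: int
    a_se: float = math.nan
    b_se: float = math.nan
    c_se: float = math.nan

    def predict(self, n: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(n, dtype=float) ** (-self.b) + self.c


@dataclass(frozen=True)
class InfoReport:
    """The four markers for one dataset/modality, with provenance."""

    entropy: float
    auc1: float
    pc95: int
    loglaw: float
    fit: PowerLawFit
    modality_tag: str = ""
    extractor_name: str = ""
    curve: VarianceCurve | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "entropy": self.entropy,
            "auc1": self.auc1,
            "pc95": self.pc95,
            "loglaw": self.loglaw,
            "fit": {
                "a": self.fit.a,
                "b": self.fit.b,
                "c": self.fit.c,
                "rss": self.fit.rss,
                "r2": self.fit.r2,
                "converged": self.fit.converged,
                "n_points": self.fit.n_points,
            },
            "modality_tag": self.modality_tag,
            "extractor_name": self.extractor_name,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column (mean 0, sample SD 1); drop constant columns.

    Dropped column names are recorded in ``provenance["dropped_constant_columns"]``.
    """
    if fm.n_patches < 2:
        raise MetricValidationError("standardize needs at least 2 rows")
    sd = fm.values.std(axis=0, ddof=1)
    # a column is constant iff its range is exactly zero (the fp mean of a
    # repeated value can leave a ~1e-16 standard deviation)
    keep = fm.values.max(axis=0) > fm.values.min(axis=0)
    if not keep.any():
        raise MetricValidationError("all columns are constant; nothing to standardize")
    vals = fm.values[:, keep]
    z = (vals - vals.mean(axis=0)) / sd[keep]
    dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
    prov = dict(fm.provenance)
    prov["standardized"] = True
    prov["dropped_constant_columns"] = dropped
    return FeatureMatrix(
        values=z,
        feature_names=tuple(n for n, k in zip(fm.feature_names, keep) if k),
        patch_ids=fm.patch_ids,
        extractor_name=fm.extractor_name,
        modality_tag=fm.modality_tag,
        provenance=prov,
    )


def cumulative_variance(fm: FeatureMatrix) -> VarianceCurve:
    """PCA cumulative explained-variance curve of the matrix as given.

    Components are ranked by decreasing eigenvalue of the sample covariance;
    ``d = min(n_samples - 1, n_features)`` components are retained (centred
    data have rank at most ``n_samples - 1``, so the retained components carry
    all the variance and the curve terminates at 1).
    """
    n, p = fm.values.shape
    if n < 2:
        raise MetricValidationError("cumulative_variance needs at least 2 rows")
    if p < 1:
        raise MetricValidationError("cumulative_variance needs at least 1 column")
    d = min(n - 1, p)
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(fm.values)
    ratios = pca.explained_variance_ratio_[:d]
    total = pca.explained_variance_ratio_.sum()
    if total <= 0:
        raise MetricValidationError("matrix has zero total variance")
    y = np.cumsum(ratios) / total
    y[-1] = 1.0  # rank <= d guarantees this analytically; pin the fp residue
    return VarianceCurve(y=y, d=d, n_samples=n)


def pc95(curve: VarianceCurve, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained variance reaches ``threshold``."""
    if not 0 < threshold < 1:
        raise MetricValidationError("threshold must be in (0, 1)")
    # the >= comparison gets a tiny slack so exact analytic crossings survive fp
    hits = np.nonzero(curve.y >= threshold - 1e-12)[0]
    return int(hits[0]) + 1


def inverse_auc(curve: VarianceCurve) -> float:
    """1-AUC of the cumulative-variance curve.

    The component index is mapped onto [0, 1] with the first and last retained
    components at the endpoints (``x_k = (k-1)/(d-1)``) and the area computed
    by the trapezoid rule; the result lies in [0, (d-1)/(2d)], attained at 0
    by a rank-1 spectrum and at the upper bound by an isotropic one.
    """
    if curve.d == 1:
        warnings.warn("1-AUC of a single-point curve is defined as 0", stacklevel=2)
        return 0.0
    x = np.linspace(0.0, 1.0, curve.d)
    return float(1.0 - np.trapezoid(curve.y, x))


def fit_inverse_power_law(curve: VarianceCurve | np.ndarray) -> PowerLawFit:
    """Fit ``IP(n) = a * n**(-b) + c`` to the curve by least squares.

    Accepts a :class:`VarianceCurve` or any 1-D sequence ``y_1..y_d`` indexed
    by component rank. ``c`` is bounded to [0, 1]; ``a`` and ``b`` are free.
    Initialisation is fixed (``a0 = y1 - 1, b0 = 0.5, c0 = 1``) so the fit is
    deterministic. Non-convergence never raises: the best-effort parameters
    are returned with ``converged=False``.
    """
    y = curve.y if isinstance(curve, VarianceCurve) else np.asarray(curve, dtype=float)
    d = y.shape[0]
    if d < 4:
        raise MetricValidationError(
            f"power-law fit needs >= 4 points (3 parameters), got d={d}"
        )
    n = np.arange(1, d + 1, dtype=float)

    def resid(theta: np.ndarray) -> np.ndarray:
        a, b, c = theta
        return a * n ** (-b) + c - y

    x0 = np.array([y[0] - 1.0, 0.5, 1.0])
    try:
        res = least_squares(
            resid,
            x0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, 1.0]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=20000,
        )
        a, b, c = (float(v) for v in res.x)
        rss = float(np.sum(res.fun**2))
        converged = bool(res.success)
        J = res.jac
    except Exception:  # noqa: BLE001 - never propagate optimizer failures
        a, b, c = float(x0[0]), float(x0[1]), float(x0[2])
        rss = float(np.sum(resid(x0) ** 2))
        converged = False
        J = None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else (1.0 if rss < 1e-12 else 0.0)
    ses = [math.nan] * 3
    if J is not None and d > 3:
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / (d - 3))
            diag = np.diag(cov)
            if np.all(diag >= 0):
                ses = list(np.sqrt(diag))
        except np.linalg.LinAlgError:
            pass
    return PowerLawFit(
        a=a,
        b=b,
        c=c,
        rss=rss,
        r2=r2,
        converged=converged,
        n_points=d,
        a_se=float(ses[0]),
        b_se=float(ses[1]),
        c_se=float(ses[2]),
    )


LOGLAW_VARIANTS = ("log10_abs_a_minus_b", "inverse_a", "inverse_b")


def loglaw_metric(fit: PowerLawFit, variant: str = "log10_abs_a_minus_b") -> float:
    """Scalar summary of the power-law parameters.

    The default ``M = log10(|a|) - b`` is monotone-decreasing in the decay
    rate, so a less negative value means a slower eigenspectrum decay (more
    information). ``inverse_a``/``inverse_b`` give the 1/a and 1/b radar axes.
    """
    if variant not in LOGLAW_VARIANTS:
        raise MetricValidationError(
            f"unknown loglaw variant {variant!r}; expected one of {LOGLAW_VARIANTS}"
        )
    if variant == "log10_abs_a_minus_b":
        if fit.a == 0:
            raise MetricValidationError("loglaw metric undefined for a = 0")
        return float(math.log10(abs(fit.a)) - fit.b)
    if variant == "inverse_a":
        if fit.a == 0:
            raise MetricValidationError("inverse_a undefined for a = 0")
        return float(1.0 / fit.a)
    if fit.b == 0:
        raise MetricValidationError("inverse_b undefined for b = 0")
    return float(1.0 / fit.b)


ENTROPY_METHODS = ("per_feature", "pooled")


def shannon_entropy(fm: FeatureMatrix, bins: int = 256, method: str = "per_feature") -> float:
    """Normalised Shannon entropy of the feature value distribution, in [0, 1].

    Each non-constant column is min–max normalised to [0, 1] (making the
    marker invariant to monotone affine rescaling of any feature) and its
    ``bins``-bin histogram entropy in bits is divided by ``log2(bins)``;
    ``method="per_feature"`` (default) reports the mean over non-constant
    columns. ``method="pooled"`` instead pools all normalised values into one
    histogram, which lets a representation whose features cover *different*
    value distributions score higher than either part alone (the per-feature
    mean of a column concatenation is a convex combination of the parts and
    can never exceed both). Per-feature entropy is invariant to any strictly
    monotone affine rescaling of a column; pooled entropy to increasing ones
    (reversing one column rearranges the pooled mixture). A matrix of only
    constant features has entropy 0 under both methods.
    """
    if bins < 2:
        raise MetricValidationError("bins must be >= 2")
    if method not in ENTROPY_METHODS:
        raise MetricValidationError(
            f"unknown entropy method {method!r}; expected one of {ENTROPY_METHODS}"
        )
    if fm.n_patches < 2 or fm.n_features < 1:
        raise MetricValidationError("entropy needs >= 2 rows and >= 1 column")
    vals = fm.values
    lo, hi = vals.min(axis=0), vals.max(axis=0)
    live = hi > lo
    if not live.any():
        return 0.0
    norm = (vals[:, live] - lo[live]) / (hi[live] - lo[live])
    log_bins = math.log2(bins)

    def _h(col: np.ndarray) -> float:
        counts, _ = np.histogram(col, bins=bins, range=(0.0, 1.0))
        p = counts[counts > 0] / col.size
        return float(-(p * np.log2(p)).sum())

    if method == "pooled":
        return _h(norm.ravel()) / log_bins
    return float(np.mean([_h(norm[:, j]) for j in range(norm.shape[1])])) / log_bins


def info_report(
    fm: FeatureMatrix,
    *,
    standardize_features: bool = True,
    entropy_bins: int = 256,
    entropy_method: str = "per_feature",
    pc_threshold: float = 0.95,
    loglaw_variant: str = "log10_abs_a_minus_b",
) -> InfoReport:
    """Run the full marker suite on one feature matrix.

    Entropy is computed on the raw (unstandardised) matrix; the PCA-based
    markers on the z-scored matrix (correlation-scaled PCA) unless
    ``standardize_features=False``.
    """
    entropy = shannon_entropy(fm, bins=entropy_bins, method=entropy_method)
    z = standardize(fm) if standardize_features else fm
    curve = cumulative_variance(z)
    k95 = pc95(curve, pc_threshold)
    auc1 = inverse_auc(curve)
    if curve.d >= 4:
        fit = fit_inverse_power_law(curve)
    else:  # too few components to identify 3 parameters
        fit = PowerLawFit(
            a=float(curve.y[0] - 1.0), b=0.0, c=1.0,
            rss=math.nan, r2=math.nan, converged=False, n_points=curve.d,
        )
    try:
        loglaw = loglaw_metric(fit, loglaw_variant)
    except MetricValidationError:
        loglaw = math.nan
    prov = {
        "standardized": standardize_features,
        "dropped_constant_columns": z.provenance.get("dropped_constant_columns", []),
        "entropy_bins": entropy_bins,
        "entropy_method": entropy_method,
        "pc_threshold": pc_threshold,
        "loglaw_variant": loglaw_variant,
        "n_patches": fm.n_patches,
        "n_features": fm.n_features,
    }
    return InfoReport(
        entropy=entropy,
        auc1=auc1,
        pc95=k95,
        loglaw=loglaw,
        fit=fit,
        modality_tag=fm.modality_tag,
        extractor_name=fm.extractor_name,
        curve=curve,
        provenance=prov,
    )
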