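"""Model/Results interface to the information-content marker suite.

``InformationContentModel`` is constructed from a feature table (a
:class:`~imginfo.features.FeatureMatrix`, a pandas DataFrame, or a CSV file)
and ``fit()`` returns an :class:`InformationContentResults` carrying the four
markers, the fitted inverse-power-law parameters with standard errors, the
cumulative-variance curve, and a ``summary()`` table.

Example
-------
>>> model = InformationContentModel.from_csv("features.csv")
>>> res = model.fit()
>>> print(res.summary())
>>> res.plot_variance_curve()
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix, read_feature_table
from .metrics import InfoReport, info_report

__all__ = ["InformationContentModel", "InformationContentResults"]


class InformationContentModel:
    """Information-content marker model for one patches-by-features table.

    Parameters
    ----------
    data : FeatureMatrix
        Feature table (rows = patches, columns = named features).
    standardize : bool, default True
        Z-score columns before PCA (correlation-scaled PCA). Entropy is always
        computed on the raw table.
    entropy_bins : int, default 256
        Histogram bins for the normalised Shannon entropy.
    entropy_method : {"per_feature", "pooled"}
        Average per-feature normalised histogram entropies (default) or pool
        all min–max-normalised feature values into one histogram.
    pc_threshold : float, default 0.95
        Cumulative-variance threshold defining PC95.
    loglaw_variant : str
        Scalar summary of the power-law parameters; default
        ``log10(|a|) - b``.
    """

    def __init__(
        self,
        data: FeatureMatrix,
        *,
        standardize: bool = True,
        entropy_bins: int = 256,
        entropy_method: str = "per_feature",
        pc_threshold: float = 0.95,
        loglaw_variant: str = "log10_abs_a_minus_b",
    ) -> None:
        if not isinstance(data, FeatureMatrix):
            raise TypeError(
                "data must be a FeatureMatrix; use from_dataframe/from_csv"
            )
        self.data = data
        self.standardize = standardize
        self.entropy_bins = entropy_bins
        self.entropy_method = entropy_method
        self.pc_threshold = pc_threshold
        self.loglaw_variant = loglaw_variant

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        modality_tag: str = "",
        extractor_name: str = "",
        **kwargs,
    ) -> "InformationContentModel":
        fm = FeatureMatrix.from_dataframe(
            df, extractor_name=extractor_name, modality_tag=modality_tag
        )
        return cls(fm, **kwargs)

    @classmethod
    def from_feature_matrix(cls, fm: FeatureMatrix, **kwargs) -> "InformationContentModel":
        return cls(fm, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "InformationContentModel":
        return cls(read_feature_table(path), **kwargs)

    def fit(self) -> "InformationContentResults":
        """Compute all markers and return the results object."""
        report = info_report(
            self.data,
            standardize_features=self.standardize,
            entropy_bins=self.entropy_bins,
            entropy_method=self.entropy_method,
            pc_threshold=self.pc_threshold,
            loglaw_variant=self.loglaw_variant,
        )
        return InformationContentResults(self, report)


class InformationContentResults:
    """Marker estimates, power-law parameters and diagnostics for one table."""

    def __init__(self, model: InformationContentModel, report: InfoReport) -> None:
        self.model = model
        self.report = report

    # -- marker accessors ---------------------------------------------------
    @property
    def entropy(self) -> float:
        return self.report.entropy

    @property
    def auc1(self) -> float:
        return self.report.auc1

    @property
    def pc95(self) -> int:
        return self.report.pc95

    @property
    def loglaw(self) -> float:
        return self.report.loglaw

    @property
    def curve(self):
        return self.report.curve

    @property
    def params(self) -> pd.Series:
        f = self.report.fit
        return pd.Series({"a": f.a, "b": f.b, "c": f.c})

    @property
    def bse(self) -> pd.Series:
        f = self.report.fit
        return pd.Series({"a": f.a_se, "b": f.b_se, "c": f.c_se})

    @property
    def rsquared(self) -> float:
        return self.report.fit.r2

    def markers(self) -> pd.Series:
        return pd.Series(
            {
                "entropy": self.entropy,
                "auc1": self.auc1,
                "pc95": self.pc95,
                "loglaw": self.loglaw,
            }
        )

    def to_dict(self) -> dict:
        return self.report.to_dict()

    def to_json(self, path: str | Path | None = None) -> str:
        return self.report.to_json(path)

    def summary(self) -> str:
        """Formatted text summary of markers, fit parameters and diagnostics."""
        r = self.report
        f = r.fit
        lines = [
            "            Information Content Results",
            "=" * 52,
            f"Modality:           {r.modality_tag or '-'}",
            f"Extractor:          {r.extractor_name or '-'}",
            f"Patches:            {r.provenance.get('n_patches', '-')}",
            f"Features:           {r.provenance.get('n_features', '-')}",
            f"Components (d):     {f.n_points}",
            "-" * 52,
            f"Shannon entropy     {r.entropy:12.4f}   (normalised, [0,1])",
            f"1-AUC               {r.auc1:12.4f}",
            f"PC{int(r.provenance.get('pc_threshold', 0.95) * 100):<17d}{r.pc95:12d}",
            f"log-law metric      {r.loglaw:12.4f}   ({r.provenance.get('loglaw_variant')})",
            "-" * 52,
            "Inverse power law  IP(n) = a*n^(-b) + c",
            f"  a (learning rate) {f.a:12.4f}   se {f.a_se:10.4f}",
            f"  b (decay rate)    {f.b:12.4f}   se {f.b_se:10.4f}",
            f"  c (asymptote)     {f.c:12.4f}   se {f.c_se:10.4f}",
            f"  R^2               {f.r2:12.6f}",
            f"  RSS               {f.rss:12.3e}",
            f"  converged         {str(f.converged):>12s}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def plot_variance_curve(self, ax=None, show_fit: bool = True):
        """Plot the cumulative explained-variance curve and the fitted law."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.report.curve
        n = np.arange(1, curve.d + 1)
        label = self.report.modality_tag or "data"
        ax.plot(n, curve.y, ".", ms=4, label=f"{label} (cumulative variance)")
        if show_fit and np.isfinite(self.report.fit.rss):
            ax.plot(n, self.report.fit.predict(n), "-", lw=1.2, label="IP(n) fit")
        thr = self.model.pc_threshold
        ax.axhline(thr, color="gray", ls=":", lw=0.8)
        ax.axvline(self.pc95, color="gray", ls=":", lw=0.8)
        ax.set_xlabel("principal component n")
        ax.set_ylabel("cumulative explained variance")
        ax.set_ylim(0, 1.02)
        ax.legend(frameon=False, fontsize=8)
        return ax
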