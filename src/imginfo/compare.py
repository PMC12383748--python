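"""Modality comparison designs, tables and radar plots.

The three study designs compare the marker suite across (1) a stained
brightfield image vs a multimodal composite vs their combination, (2) the
individual RGB/channel planes of a composite vs the full composite, and
(3) two CARS wavenumber channels vs their combination. "Combined" defaults to
feature concatenation over spatially corresponding patches, which widens the
feature space (channel stacking before extraction is available at the image
level via :func:`imginfo.io.stack_channels`; row pooling via
``mode="pool_rows"``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .metrics import InfoReport, PowerLawFit, info_report

__all__ = [
    "ComparisonTable",
    "combine_matrices",
    "run_comparison",
    "radar_plot",
    "export_table",
    "import_table",
    "polygon_area",
    "DESIGNS",
    "MARKERS",
]

DESIGNS = (
    "he_vs_mm_vs_combined",
    "rgb_channel_split",
    "cars_wavenumber_split",
    "custom",
)
#: designs that automatically add a combined entry when one is not supplied
_AUTO_COMBINED = ("he_vs_mm_vs_combined", "rgb_channel_split", "cars_wavenumber_split")
MARKERS = ("entropy", "auc1", "pc95", "loglaw")


class ComparisonValidationError(ValueError):
    """Raised on inconsistent comparison inputs."""


def combine_matrices(
    matrices: Sequence[FeatureMatrix],
    mode: str = "concat_features",
    modality_tag: str = "combined",
) -> FeatureMatrix:
    """Join feature matrices of spatially corresponding patches.

    ``concat_features`` (default) concatenates columns with modality-prefixed
    names, preserving the row count; ``pool_rows`` stacks rows instead
    (patch ids get a modality suffix). ``stack_channels`` operates on images,
    not feature tables — combine channels with
    :func:`imginfo.io.stack_channels` before extraction.
    """
    if len(matrices) < 2:
        raise ComparisonValidationError("need at least 2 matrices to combine")
    if mode == "stack_channels":
        raise ComparisonValidationError(
            "stack_channels applies at the image level: stack channels with "
            "imginfo.io.stack_channels and extract features from the composite"
        )
    if mode not in ("concat_features", "pool_rows"):
        raise ComparisonValidationError(f"unknown combine mode {mode!r}")
    tags = [m.modality_tag or f"m{i}" for i, m in enumerate(matrices)]
    sources = [
        {"modality_tag": m.modality_tag, "extractor_name": m.extractor_name}
        for m in matrices
    ]
    extractor = matrices[0].extractor_name
    if mode == "pool_rows":
        names = matrices[0].feature_names
        for m in matrices[1:]:
            if m.feature_names != names:
                raise ComparisonValidationError(
                    "pool_rows requires identical feature columns"
                )
        ids = tuple(
            f"{pid}@{tag}" for m, tag in zip(matrices, tags) for pid in m.patch_ids
        )
        return FeatureMatrix(
            values=np.vstack([m.values for m in matrices]),
            feature_names=names,
            patch_ids=ids,
            extractor_name=extractor,
            modality_tag=modality_tag,
            provenance={"combined_mode": mode, "sources": sources},
        )
    ref_ids = matrices[0].patch_ids
    for m in matrices[1:]:
        if m.patch_ids != ref_ids:
            offending = next(
                (a for a, b in zip(ref_ids, m.patch_ids) if a != b),
                f"row-count {len(ref_ids)} vs {len(m.patch_ids)}",
            )
            raise ComparisonValidationError(
                f"patch_ids are not aligned across matrices (first mismatch: {offending}); "
                "combined datasets require spatially corresponding patches"
            )
    names = tuple(f"{tag}|{n}" for m, tag in zip(matrices, tags) for n in m.feature_names)
    return FeatureMatrix(
        values=np.hstack([m.values for m in matrices]),
        feature_names=names,
        patch_ids=ref_ids,
        extractor_name=extractor,
        modality_tag=modality_tag,
        provenance={"combined_mode": mode, "sources": sources},
    )


@dataclass(frozen=True)
class ComparisonTable:
    """One :class:`InfoReport` per modality plus shared radar normalisation."""

    reports: dict[str, InfoReport]
    design: str = "custom"
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.reports) < 2:
            raise ComparisonValidationError("a comparison needs at least 2 rows")
        extractors = {r.extractor_name for r in self.reports.values()}
        if len(extractors) > 1:
            raise ComparisonValidationError(
                f"all rows must share one extractor, got {sorted(extractors)}"
            )
        if not self.normalization:
            object.__setattr__(self, "normalization", self._fit_normalization())

    def _fit_normalization(self) -> dict:
        norm = {}
        for m in MARKERS:
            vals = [float(getattr(r, m)) for r in self.reports.values()]
            finite = [v for v in vals if math.isfinite(v)]
            lo = min(finite) if finite else 0.0
            hi = max(finite) if finite else 1.0
            norm[m] = {"min": lo, "max": hi}
        return norm

    def normalized_coordinates(self) -> dict[str, list[float]]:
        """Min–max-normalised marker values per modality (the radar vertices).

        A marker that is constant across modalities maps to 0.5 for every row.
        """
        coords = {}
        for tag, rep in self.reports.items():
            row = []
            for m in MARKERS:
                lo, hi = self.normalization[m]["min"], self.normalization[m]["max"]
                v = float(getattr(rep, m))
                row.append(0.5 if hi == lo else (v - lo) / (hi - lo))
            coords[tag] = row
        return coords

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tag, r in self.reports.items():
            rows.append(
                {
                    "modality": tag,
                    "entropy": r.entropy,
                    "auc1": r.auc1,
                    "pc95": r.pc95,
                    "loglaw": r.loglaw,
                    "a": r.fit.a,
                    "b": r.fit.b,
                    "c": r.fit.c,
                    "r2": r.fit.r2,
                    "rss": r.fit.rss,
                    "converged": r.fit.converged,
                    "n_components": r.fit.n_points,
                    "extractor_name": r.extractor_name,
                }
            )
        return pd.DataFrame(rows).set_index("modality")

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "normalization": self.normalization,
            "reports": {tag: r.to_dict() for tag, r in self.reports.items()},
            "normalized_coordinates": self.normalized_coordinates(),
            "markers": list(MARKERS),
        }


def run_comparison(
    datasets: Mapping[str, FeatureMatrix],
    design: str = "custom",
    combined_label: str = "combined",
    combine_mode: str = "concat_features",
    **report_kwargs,
) -> ComparisonTable:
    """Run the marker suite per modality, adding a combined entry when the
    design calls for one and none was supplied."""
    if design not in DESIGNS:
        raise ComparisonValidationError(f"unknown design {design!r}; one of {DESIGNS}")
    if len(datasets) < 2:
        raise ComparisonValidationError("a comparison needs at least 2 datasets")
    extractors = {m.extractor_name for m in datasets.values()}
    if len(extractors) > 1:
        raise ComparisonValidationError(
            f"datasets use different extractors: {sorted(extractors)}"
        )
    datasets = dict(datasets)
    if design in _AUTO_COMBINED and combined_label not in datasets:
        mats = []
        for tag, m in datasets.items():
            if not m.modality_tag:
                m = FeatureMatrix(
                    values=m.values,
                    feature_names=m.feature_names,
                    patch_ids=m.patch_ids,
                    extractor_name=m.extractor_name,
                    modality_tag=tag,
                    provenance=m.provenance,
                )
            mats.append(m)
        datasets[combined_label] = combine_matrices(
            mats, mode=combine_mode, modality_tag=combined_label
        )
    reports = {}
    for tag, m in datasets.items():
        rep = info_report(m, **report_kwargs)
        if not rep.modality_tag:
            rep = InfoReport(
                entropy=rep.entropy, auc1=rep.auc1, pc95=rep.pc95, loglaw=rep.loglaw,
                fit=rep.fit, modality_tag=tag, extractor_name=rep.extractor_name,
                curve=rep.curve, provenance=rep.provenance,
            )
        reports[tag] = rep
    return ComparisonTable(reports=reports, design=design)


def polygon_area(values: Sequence[float]) -> float:
    """Shoelace area of the radar polygon with vertices ``values`` on evenly
    spaced axes (test helper)."""
    v = np.asarray(values, dtype=float)
    k = len(v)
    theta = 2 * np.pi * np.arange(k) / k
    x, y = v * np.cos(theta), v * np.sin(theta)
    return float(
        0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    )


def radar_plot(table: ComparisonTable, path: str | Path) -> Path:
    """Render the comparison as a radar chart (SVG or PNG).

    One polygon per modality over the axes entropy, 1-AUC, PC95 and the
    log-law metric, each min–max normalised across the table's rows. The
    normalised vertex coordinates are also written to ``<path>.coords.json``
    for downstream checks.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    coords = table.normalized_coordinates()
    k = len(MARKERS)
    theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4.5, 4.5))
    labels = {"entropy": "entropy", "auc1": "1-AUC", "pc95": "PC95", "loglaw": "log-law"}
    for tag, row in coords.items():
        closed = np.r_[row, row[0]]
        ang = np.r_[theta, theta[0]]
        ax.plot(ang, closed, lw=1.5, label=tag)
        ax.fill(ang, closed, alpha=0.15)
    ax.set_xticks(theta)
    ax.set_xticklabels([labels[m] for m in MARKERS])
    ax.set_ylim(0, 1.05)
    ax.set_yticks([0.25, 0.5, 0.75, 1.0])
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8, frameon=False)
    fig.tight_layout()
    try:
        fig.savefig(path)
    except OSError as exc:
        raise IOError(f"could not write radar plot to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    coords_path = path.with_suffix(path.suffix + ".coords.json")
    coords_path.write_text(
        json.dumps({"markers": list(MARKERS), "coordinates": coords}, sort_keys=True, indent=2)
    )
    return path


def _table_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def export_table(table: ComparisonTable, path: str | Path) -> Path:
    """Write the comparison as CSV plus a JSON sidecar (design, normalisation,
    provenance); :func:`import_table` restores an equivalent table."""
    path = Path(path)
    table.to_dataframe().to_csv(path)
    meta = {
        "design": table.design,
        "normalization": table.normalization,
        "provenance": {tag: r.provenance for tag, r in table.reports.items()},
        "modality_tags": {tag: r.modality_tag for tag, r in table.reports.items()},
    }
    _table_sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=2))
    return path


def import_table(path: str | Path) -> ComparisonTable:
    """Rebuild a :class:`ComparisonTable` from :func:`export_table` output.

    Variance curves are not persisted, so re-imported reports carry
    ``curve=None``; all markers and fit parameters round-trip exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col="modality")
    sidecar = _table_sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    prov = meta.get("provenance", {})
    reports = {}
    for tag, row in df.iterrows():
        fit = PowerLawFit(
            a=float(row["a"]), b=float(row["b"]), c=float(row["c"]),
            rss=float(row["rss"]), r2=float(row["r2"]),
            converged=bool(row["converged"]), n_points=int(row["n_components"]),
        )
        reports[str(tag)] = InfoReport(
            entropy=float(row["entropy"]),
            auc1=float(row["auc1"]),
            pc95=int(row["pc95"]),
            loglaw=float(row["loglaw"]),
            fit=fit,
            modality_tag=str(meta.get("modality_tags", {}).get(str(tag), tag)),
            extractor_name=str(row["extractor_name"]) if pd.notna(row["extractor_name"]) else "",
            provenance=dict(prov.get(str(tag), {})),
        )
    return ComparisonTable(
        reports=reports,
        design=str(meta.get("design", "custom")),
        normalization=dict(meta.get("normalization", {})),
    )
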