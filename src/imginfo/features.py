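"""Patch-level feature extraction.

Each patch becomes one fixed-length named feature vector. The native
extractors are radiomics-style first-order statistics and gray-level
co-occurrence (GLCM/Haralick) texture features, computed per channel and
concatenated with channel-prefixed names. Deep-network extractors (VGG16,
ResNet50, DenseNet121, InceptionV3, MobileNetV2 in global-average-pooling
mode) and full radiomics suites are supported through a plugin registry that
defines the contract only — a patch in, a deterministic fixed-length pooled
vector out — so the core never downloads weights.

Feature tables round-trip through CSV plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from skimage.feature import graycomatrix, graycoprops

from .io import PatchSet

__all__ = [
    "FeatureMatrix",
    "ExtractorSpec",
    "first_order_features",
    "glcm_features",
    "extract_features",
    "pooled_plugin_adapter",
    "register_plugin",
    "available_plugins",
    "write_feature_table",
    "read_feature_table",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
]

FIRST_ORDER_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "minimum",
    "maximum",
    "p10",
    "p50",
    "p90",
    "energy",
    "hist_entropy",
)
GLCM_NAMES = (
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_entropy",
)

#: default Haralick offsets: distance 1, four directions (E, S, SE, SW)
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
DEFAULT_GLCM_LEVELS = 32
HIST_ENTROPY_BINS = 64


class FeatureValidationError(ValueError):
    """Raised when a feature matrix or extractor request is invalid."""


class PluginUnavailableError(RuntimeError):
    """Raised when a plugin extractor is requested but not registered."""


@dataclass(frozen=True)
class FeatureMatrix:
    """Patches-by-features table with provenance.

    ``values`` is ``(n_patches, n_features)`` float64 with no missing entries;
    ``patch_ids`` label rows (``"source:row:col"``) and ``feature_names``
    label columns.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    patch_ids: tuple[str, ...]
    extractor_name: str = ""
    modality_tag: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # C-contiguous so identical values give bit-identical downstream
        # linear algebra regardless of the constructor's memory layout
        vals = np.ascontiguousarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise FeatureValidationError(f"values must be 2-D, got shape {vals.shape}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "patch_ids", tuple(str(p) for p in self.patch_ids))
        if vals.shape != (len(self.patch_ids), len(self.feature_names)):
            raise FeatureValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.patch_ids)} patch_ids x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = sorted(
                n for n in set(self.feature_names) if self.feature_names.count(n) > 1
            )
            raise FeatureValidationError(f"duplicate feature names: {dupes}")
        if len(set(self.patch_ids)) != len(self.patch_ids):
            raise FeatureValidationError("patch_ids must be unique")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FeatureValidationError(
                f"non-finite value at row {self.patch_ids[bad[0]]}, "
                f"column {self.feature_names[bad[1]]}"
            )

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.patch_ids, name="patch_id"),
            columns=list(self.feature_names),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        extractor_name: str = "",
        modality_tag: str = "",
        provenance: dict | None = None,
    ) -> "FeatureMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=tuple(str(c) for c in df.columns),
            patch_ids=tuple(str(i) for i in df.index),
            extractor_name=extractor_name,
            modality_tag=modality_tag,
            provenance=dict(provenance or {}),
        )


# ---------------------------------------------------------------------------
# native extractors
# ---------------------------------------------------------------------------


def _as_patch(patch: np.ndarray) -> np.ndarray:
    arr = np.asarray(patch, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise FeatureValidationError(
            f"patch must be a non-empty 2-D grid, got shape {arr.shape}"
        )
    return arr


def first_order_features(
    patch: np.ndarray, hist_bins: int = HIST_ENTROPY_BINS
) -> pd.Series:
    """First-order intensity statistics of a single-channel patch.

    Moments are population moments (skewness/kurtosis are 0 for a constant
    patch); ``energy`` is the sum of squared min–max-normalised intensities;
    ``hist_entropy`` is the Shannon entropy in bits of a ``hist_bins``-bin
    histogram over the patch's own min–max range.
    """
    arr = _as_patch(patch)
    flat = arr.ravel()
    lo, hi = flat.min(), flat.max()
    if hi > lo:
        norm = (flat - lo) / (hi - lo)
        counts, _ = np.histogram(flat, bins=hist_bins, range=(lo, hi))
        p = counts[counts > 0] / flat.size
        hist_entropy = float(-(p * np.log2(p)).sum())
        skew = float(_sstats.skew(flat, bias=True))
        kurt = float(_sstats.kurtosis(flat, bias=True))
        energy = float((norm**2).sum())
    else:
        hist_entropy = 0.0
        skew = kurt = energy = 0.0
    vals = [
        float(flat.mean()),
        float(flat.var()),  # population variance
        skew,
        kurt,
        float(lo),
        float(hi),
        float(np.percentile(flat, 10)),
        float(np.percentile(flat, 50)),
        float(np.percentile(flat, 90)),
        energy,
        hist_entropy,
    ]
    return pd.Series(vals, index=list(FIRST_ORDER_NAMES))


def quantize(patch: np.ndarray, levels: int) -> np.ndarray:
    """Quantise intensities to ``levels`` equal-width bins over patch min–max."""
    if levels < 2:
        raise FeatureValidationError("levels must be >= 2")
    arr = _as_patch(patch)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int32)
    q = ((arr - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def _cooccurrence(
    q: np.ndarray, levels: int, offsets: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix averaged over offsets."""
    mats = []
    for dr, dc in offsets:
        if abs(dr) >= q.shape[0] or abs(dc) >= q.shape[1]:
            raise FeatureValidationError(
                f"patch of shape {q.shape} smaller than offset ({dr}, {dc})"
            )
        d = float(np.hypot(dr, dc))
        angle = float(np.arctan2(dr, dc))
        P = graycomatrix(
            q.astype(np.uint8),
            distances=[d],
            angles=[angle],
            levels=levels,
            symmetric=True,
            normed=True,
        )
        mats.append(P[:, :, 0, 0])
    return np.mean(mats, axis=0)


def glcm_features(
    patch: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
) -> pd.Series:
    """Haralick texture features from the offset-averaged co-occurrence matrix.

    Intensities are quantised to ``levels`` equal-width bins over the patch's
    min–max range (so the features are invariant to affine intensity
    rescaling); the symmetric normalised GLCM is computed per offset and
    averaged. ``glcm_energy`` is the angular second moment; a zero-variance
    (constant) patch has correlation defined as 1.
    """
    if not offsets:
        raise FeatureValidationError("at least one offset is required")
    q = quantize(patch, levels)
    P = _cooccurrence(q, levels, offsets)
    P4 = P[:, :, None, None]  # (levels, levels, n_dist=1, n_angle=1)
    contrast = float(graycoprops(P4, "contrast")[0, 0])
    correlation = float(graycoprops(P4, "correlation")[0, 0])
    asm = float(graycoprops(P4, "ASM")[0, 0])
    homogeneity = float(graycoprops(P4, "homogeneity")[0, 0])
    pz = P[P > 0]
    glcm_entropy = float(-(pz * np.log2(pz)).sum())
    return pd.Series(
        [contrast, correlation, asm, homogeneity, glcm_entropy],
        index=list(GLCM_NAMES),
    )


def pooled_plugin_adapter(feature_map: np.ndarray) -> np.ndarray:
    """Global average pooling: collapse an ``(h, w, k)`` map to ``k`` means."""
    arr = np.asarray(feature_map, dtype=float)
    if arr.ndim != 3 or arr.size == 0:
        raise FeatureValidationError(
            f"feature map must be a non-empty (h, w, k) grid, got shape {arr.shape}"
        )
    return arr.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# extractor specification and dispatch
# ---------------------------------------------------------------------------

_PLUGIN_REGISTRY: dict[str, tuple[Callable[[np.ndarray], np.ndarray], tuple[str, ...]]] = {}


def register_plugin(
    name: str,
    fn: Callable[[np.ndarray], np.ndarray],
    feature_names: Sequence[str],
) -> None:
    """Register a plugin extractor.

    ``fn`` receives the full ``(h, w, c)`` patch pixel array and must return a
    deterministic 1-D vector of length ``len(feature_names)`` (deep networks
    should pool spatial maps with :func:`pooled_plugin_adapter`).
    """
    _PLUGIN_REGISTRY[name] = (fn, tuple(feature_names))


def available_plugins() -> tuple[str, ...]:
    return tuple(sorted(_PLUGIN_REGISTRY))


@dataclass(frozen=True)
class ExtractorSpec:
    """Declares which extractor to run and with what parameters.

    ``kind`` is one of ``first_order``, ``glcm_texture``, ``composite``
    (first-order + GLCM) or ``plugin``; plugin specs name a registered plugin
    in ``parameters["plugin"]`` (defaulting to ``name``).
    """

    name: str
    kind: str = "composite"
    parameters: Mapping[str, object] = field(default_factory=dict)

    _KINDS = ("first_order", "glcm_texture", "composite", "plugin")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise FeatureValidationError(
                f"unknown extractor kind {self.kind!r}; expected one of {self._KINDS}"
            )
        object.__setattr__(self, "parameters", dict(self.parameters))

    @property
    def glcm_levels(self) -> int:
        return int(self.parameters.get("levels", DEFAULT_GLCM_LEVELS))

    @property
    def glcm_offsets(self) -> tuple[tuple[int, int], ...]:
        offs = self.parameters.get("offsets", DEFAULT_OFFSETS)
        return tuple((int(r), int(c)) for r, c in offs)

    @property
    def hist_bins(self) -> int:
        return int(self.parameters.get("hist_bins", HIST_ENTROPY_BINS))

    def _plugin(self) -> tuple[Callable[[np.ndarray], np.ndarray], tuple[str, ...]]:
        key = str(self.parameters.get("plugin", self.name))
        if key not in _PLUGIN_REGISTRY:
            raise PluginUnavailableError(
                f"plugin extractor {key!r} is not registered; "
                f"available: {list(available_plugins())}. Deep-network and "
                "radiomics extractors must be registered by the caller."
            )
        return _PLUGIN_REGISTRY[key]

    def per_channel_names(self) -> tuple[str, ...]:
        if self.kind == "first_order":
            return FIRST_ORDER_NAMES
        if self.kind == "glcm_texture":
            return GLCM_NAMES
        if self.kind == "composite":
            return FIRST_ORDER_NAMES + GLCM_NAMES
        raise FeatureValidationError("plugin extractors are not per-channel")

    def output_names(self, channel_names: Sequence[str]) -> tuple[str, ...]:
        """Declared output feature names for a patch with these channels."""
        if self.kind == "plugin":
            return self._plugin()[1]
        per = self.per_channel_names()
        return tuple(f"{ch}_{f}" for ch in channel_names for f in per)

    def extract_patch(self, pixels: np.ndarray, channel_names: Sequence[str]) -> np.ndarray:
        if self.kind == "plugin":
            fn, names = self._plugin()
            vec = np.asarray(fn(pixels), dtype=float).ravel()
            if vec.shape[0] != len(names):
                raise FeatureValidationError(
                    f"plugin returned {vec.shape[0]} values, declared {len(names)}"
                )
            return vec
        parts = []
        for c in range(pixels.shape[2]):
            ch = pixels[:, :, c]
            if self.kind in ("first_order", "composite"):
                parts.append(first_order_features(ch, self.hist_bins).to_numpy())
            if self.kind in ("glcm_texture", "composite"):
                parts.append(
                    glcm_features(ch, self.glcm_levels, self.glcm_offsets).to_numpy()
                )
        return np.concatenate(parts)


def extract_features(patches: PatchSet, spec: ExtractorSpec) -> FeatureMatrix:
    """Run an extractor on every patch; one row per patch in grid order."""
    if len(patches) == 0:
        raise FeatureValidationError("empty patch set")
    ch_names = patches.patches[0].channel_names
    names = spec.output_names(ch_names)
    rows = [spec.extract_patch(p.pixels, ch_names) for p in patches.patches]
    ids = tuple(f"{src}:{r}:{c}" for src, r, c in patches.patch_ids)
    modality = patches.patches[0].modality_tag
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        patch_ids=ids,
        extractor_name=spec.name,
        modality_tag=modality,
        provenance={
            "extractor_kind": spec.kind,
            "parameters": {k: str(v) for k, v in spec.parameters.items()},
            "grid_shape": list(patches.grid_shape),
            "channel_names": list(ch_names),
        },
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> Path:
    """Write a feature table as CSV (+ JSON sidecar with provenance)."""
    path = Path(path)
    df = fm.to_dataframe()
    df.to_csv(path, float_format=None)  # default str() keeps full precision
    meta = {
        "extractor_name": fm.extractor_name,
        "modality_tag": fm.modality_tag,
        "provenance": fm.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=2))
    return path


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a CSV feature table written by :func:`write_feature_table`.

    Duplicate column names and missing cells are rejected with the offending
    location named.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    cols = header[1:]
    dupes = sorted({c for c in cols if cols.count(c) > 1})
    if dupes:
        raise FeatureValidationError(f"duplicate column names in {path}: {dupes}")
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FeatureValidationError(
            f"missing cell in {path} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FeatureMatrix.from_dataframe(
        df,
        extractor_name=str(meta.get("extractor_name", "")),
        modality_tag=str(meta.get("modality_tag", "")),
        provenance=dict(meta.get("provenance", {})),
    )
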