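"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from imginfo import ExtractorSpec, FeatureMatrix, MultiChannelImage


def make_feature_matrix(values, names=None, modality="", extractor="") -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    if names is None:
        names = tuple(f"f{j}" for j in range(values.shape[1]))
    return FeatureMatrix(
        values=values,
        feature_names=tuple(names),
        patch_ids=tuple(f"p:{i}" for i in range(values.shape[0])),
        modality_tag=modality,
        extractor_name=extractor,
    )


def data_with_sample_covariance(cov_diag, n_rows: int, seed: int = 0) -> FeatureMatrix:
    """Rows whose *sample* covariance is exactly ``diag(cov_diag)``.

    Draw random data, whiten it empirically (Cholesky of its own sample
    covariance), then scale columns — an exact construction, not asymptotic.
    """
    cov_diag = np.asarray(cov_diag, dtype=float)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_rows, cov_diag.size))
    X -= X.mean(axis=0)
    L = np.linalg.cholesky(np.cov(X, rowvar=False))
    W = X @ np.linalg.inv(L).T
    return make_feature_matrix(W * np.sqrt(cov_diag))


def brute_force_cumulative_variance(values: np.ndarray) -> np.ndarray:
    """Independent oracle: dense eigendecomposition of the sample covariance."""
    n, p = values.shape
    lam = np.linalg.eigvalsh(np.cov(values, rowvar=False, ddof=1))
    lam = np.clip(lam[::-1], 0.0, None)
    d = min(n - 1, p)
    return np.cumsum(lam[:d]) / lam.sum()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def rgb_image(rng) -> MultiChannelImage:
    pixels = rng.integers(0, 256, size=(60, 80, 3), dtype=np.uint8)
    return MultiChannelImage(
        pixels=pixels,
        channel_names=("R", "G", "B"),
        modality_tag="HE",
        bit_depth=8,
        source_id="slide0",
    )


@pytest.fixture
def composite_spec() -> ExtractorSpec:
    return ExtractorSpec(name="first_order+glcm", kind="composite")
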