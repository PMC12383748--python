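"""Seeded synthetic multi-channel image pairs.

Real co-registered stain/multimodal tissue pairs are not redistributable, so
the test bed generates Gaussian random fields with a power-law radial power
spectrum (amplitude ∝ f^(−β/2)): β = 0 is white noise, larger β gives
smoother, more spatially correlated texture. A pair of modalities is coupled
through shared fields — channel i of modality B is
``ρ·shared_i + sqrt(1−ρ²)·independent_i`` — so the pixelwise correlation
between paired channels equals ρ by construction and the images are
co-registered by construction. No histological realism is claimed; the point
is analytic control of per-channel complexity and cross-modality dependence.

Defaults emulate the study layout: a smooth three-channel brightfield stain
("HE", β = 3 per channel) against a sharper three-channel multimodal
composite ("MM": CARS β = 1.5, TPEF β = 2.0, SHG β = 2.5), mixing ρ = 0.5,
8-bit, 300×300 px (so a 10×10 grid gives 30×30 patches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import MultiChannelImage

__all__ = ["SyntheticSpec", "generate_field", "generate_modality_pair"]


class SyntheticSpecError(ValueError):
    """Raised for invalid synthetic-image specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic co-registered modality pair.

    ``slopes_*`` are the per-channel power-spectrum exponents β (≥ 0);
    ``rho`` ∈ [0, 1] is the mixing weight tying each B channel to the shared
    field underlying the corresponding A channel. All randomness derives from
    ``seed``; no global random state is touched.
    """

    height: int = 300
    width: int = 300
    channels_a: tuple[str, ...] = ("R", "G", "B")
    channels_b: tuple[str, ...] = ("CARS_2930", "TPEF", "SHG")
    slopes_a: tuple[float, ...] = (3.0, 3.0, 3.0)
    slopes_b: tuple[float, ...] = (1.5, 2.0, 2.5)
    rho: float = 0.5
    seed: int = 0
    bit_depth: int = 8
    modality_a: str = "HE"
    modality_b: str = "MM"
    source_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise SyntheticSpecError("image dimensions must be >= 16")
        if not 0.0 <= self.rho <= 1.0:
            raise SyntheticSpecError(f"rho must be in [0, 1], got {self.rho}")
        for slopes, chans, side in (
            (self.slopes_a, self.channels_a, "a"),
            (self.slopes_b, self.channels_b, "b"),
        ):
            if len(slopes) != len(chans):
                raise SyntheticSpecError(
                    f"modality {side}: {len(slopes)} slopes for {len(chans)} channels"
                )
            if any(s < 0 for s in slopes):
                raise SyntheticSpecError("spectral slopes must be >= 0")
        if len(self.channels_a) != len(self.channels_b):
            raise SyntheticSpecError(
                "modalities must have equal channel counts so channels pair up"
            )
        if self.bit_depth not in (8, 16):
            raise SyntheticSpecError("bit_depth must be 8 or 16")


def _grf(height: int, width: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with spectrum f^(−β)."""
    white = rng.standard_normal((height, width))
    if beta == 0:
        f = white
    else:
        fy = np.fft.fftfreq(height)[:, None]
        fx = np.fft.fftfreq(width)[None, :]
        radial = np.sqrt(fy**2 + fx**2)
        radial[0, 0] = np.inf  # kill the DC term
        amp = radial ** (-beta / 2.0)
        f = np.fft.ifft2(np.fft.fft2(white) * amp).real
    sd = f.std()
    if sd == 0:  # degenerate only for pathological sizes
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def _channel_rng(seed: int, modality_index: int, channel_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(modality_index), int(channel_index)])
    )


def _to_bit_range(f: np.ndarray, bit_depth: int) -> np.ndarray:
    """Affinely map a field onto the full unsigned integer range."""
    lo, hi = f.min(), f.max()
    top = 2**bit_depth - 1
    if hi == lo:
        scaled = np.zeros_like(f)
    else:
        scaled = (f - lo) / (hi - lo) * top
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.round(scaled).astype(dtype)


def generate_field(spec: SyntheticSpec, channel: int | str, modality: str = "a") -> np.ndarray:
    """One channel's raw field (unit variance, before bit-range scaling).

    Fully determined by ``(spec.seed, modality, channel index)``: modality "a"
    channels are the shared fields, modality "b" channels the independent
    components mixed in by :func:`generate_modality_pair`.
    """
    if modality not in ("a", "b"):
        raise SyntheticSpecError("modality must be 'a' or 'b'")
    chans = spec.channels_a if modality == "a" else spec.channels_b
    slopes = spec.slopes_a if modality == "a" else spec.slopes_b
    idx = chans.index(channel) if isinstance(channel, str) else int(channel)
    if not 0 <= idx < len(chans):
        raise SyntheticSpecError(f"channel index {idx} out of range")
    rng = _channel_rng(spec.seed, 0 if modality == "a" else 1, idx)
    return _grf(spec.height, spec.width, slopes[idx], rng)


def generate_modality_pair(spec: SyntheticSpec) -> tuple[MultiChannelImage, MultiChannelImage]:
    """Generate one co-registered (modality A, modality B) image pair.

    Channel i of B is ``rho * shared_i + sqrt(1 - rho^2) * independent_i``
    where ``shared_i`` is A's channel-i field, so the pixelwise Pearson
    correlation of paired channels is rho (up to quantisation); with rho = 1
    and identical slopes B duplicates A exactly.
    """
    a_planes, b_planes = [], []
    for i in range(len(spec.channels_a)):
        shared = generate_field(spec, i, "a")
        indep = generate_field(spec, i, "b")
        a_planes.append(_to_bit_range(shared, spec.bit_depth))
        mix = spec.rho * shared + np.sqrt(1.0 - spec.rho**2) * indep
        b_planes.append(_to_bit_range(mix, spec.bit_depth))
    img_a = MultiChannelImage(
        pixels=np.stack(a_planes, axis=2),
        channel_names=spec.channels_a,
        modality_tag=spec.modality_a,
        bit_depth=spec.bit_depth,
        source_id=spec.source_id,
    )
    img_b = MultiChannelImage(
        pixels=np.stack(b_planes, axis=2),
        channel_names=spec.channels_b,
        modality_tag=spec.modality_b,
        bit_depth=spec.bit_depth,
        source_id=spec.source_id,
    )
    return img_a, img_b
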