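"""Synthetic overlapping-fingermark scenes with analytic ground truth.

The generator emulates the statistical regime of a static-limit ToF-SIMS
macroraster: per-pixel per-peak counts of 0 or 1 ("barcode" spectra), per-pixel
total ion counts far below 100, and four spatial classes — bare substrate, two
fingermark ridge patterns, and the zone where the ridges of both marks cross.
Ridges are sinusoidal gratings inside axis-aligned ellipses so every label is
analytic; biometric realism (minutiae, pores) is deliberately out of scope.

Because ToF-SIMS only probes the top monolayers, the overlap zone's signature
is a convex combination weighted toward the print deposited last
(``occlusion_alpha``), optionally plus a small mixing component of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io import SparseCube

__all__ = [
    "PrintGeometry",
    "PhantomConfig",
    "PhantomTruth",
    "default_config",
    "build_default_signatures",
    "ridge_mask",
    "compose_scene",
    "sample_cube",
    "SUBSTRATE",
    "PRINT_A",
    "PRINT_B",
    "OVERLAP",
]

SUBSTRATE, PRINT_A, PRINT_B, OVERLAP = 0, 1, 2, 3


@dataclass(frozen=True)
class PrintGeometry:
    """Elliptical footprint plus a sinusoidal ridge grating for one fingermark."""

    center: tuple[float, float]      # (row, col), pixels
    axes: tuple[float, float]        # (semi-axis along rows, along cols), pixels
    ridge_frequency: float           # cycles per pixel
    ridge_phase: float = 0.0         # radians
    ridge_angle: float = 0.0         # grating direction, radians


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 504
    width: int = 504
    n_peaks: int = 64
    print_a: PrintGeometry = PrintGeometry(
        center=(252.0, 182.0), axes=(160.0, 120.0),
        ridge_frequency=1.0 / 16.0, ridge_phase=0.3, ridge_angle=0.26,
    )
    print_b: PrintGeometry = PrintGeometry(
        center=(252.0, 322.0), axes=(160.0, 120.0),
        ridge_frequency=1.0 / 16.0, ridge_phase=1.1, ridge_angle=1.83,
    )
    duty: float = 0.5                # fraction of each ridge period that is "on"
    signatures: np.ndarray = field(default=None)  # (4, K) per-peak event rates
    occlusion_alpha: float = 0.8     # weight of the top print in the overlap
    order: Literal["A", "B"] = "A"   # which print was deposited last (on top)
    shared_component: np.ndarray | None = None    # extra overlap-only rates
    sampling_mode: Literal["bernoulli", "poisson"] = "bernoulli"
    tic_cap: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.signatures is None:
            sig, shared = build_default_signatures(
                self.n_peaks, self.occlusion_alpha, self.order
            )
            object.__setattr__(self, "signatures", sig)
            object.__setattr__(self, "shared_component", shared)
        sig = np.asarray(self.signatures, dtype=float)
        if sig.shape != (4, self.n_peaks):
            raise ValueError(f"signatures must be (4, {self.n_peaks}), got {sig.shape}")
        if self.sampling_mode == "bernoulli" and (sig.min() < 0 or sig.max() > 1):
            raise ValueError("bernoulli mode requires all rates in [0, 1]")
        if np.any(sig.sum(axis=1) > self.tic_cap):
            raise ValueError("class rate sums exceed the configured TIC cap")
        if not 0.0 <= self.occlusion_alpha <= 1.0:
            raise ValueError("occlusion_alpha must lie in [0, 1]")
        object.__setattr__(self, "signatures", sig)

    def with_seed(self, seed: int) -> "PhantomConfig":
        return replace(self, seed=int(seed))


@dataclass
class PhantomTruth:
    """Ground truth for a composed scene: per-pixel class, realized rates, order."""

    class_map: np.ndarray    # (H, W) labels in {0: substrate, 1: A, 2: B, 3: overlap}
    signatures: np.ndarray   # (4, K) realized per-peak rates
    order: str               # which print is on top

    def class_fractions(self) -> np.ndarray:
        return np.bincount(self.class_map.ravel(), minlength=4) / self.class_map.size


def build_default_signatures(
    n_peaks: int = 64, occlusion_alpha: float = 0.8, order: str = "A",
    template_seed: int = 20210518,
) -> tuple[np.ndarray, np.ndarray]:
    """Default (4, K) rate matrix: sparse seeded templates with print overlap.

    Peak budget for K >= 54: 10 substrate peaks at 0.35, 14 exclusive peaks per
    print at 0.45, 6 peaks shared by both prints at 0.45, 4 overlap-only mixing
    peaks at 0.30, everything on a 0.02 background; prints retain a faint 0.05
    substrate show-through.  Positions are a seeded permutation so the
    templates are not block-structured.  Returns (signatures, shared_component).
    """
    if n_peaks < 54:
        raise ValueError("default signatures need at least 54 peaks")
    rng = np.random.default_rng(template_seed)
    perm = rng.permutation(n_peaks)
    sub_idx = perm[:10]
    a_idx = perm[10:24]
    b_idx = perm[24:38]
    ab_idx = perm[38:44]
    mix_idx = perm[44:48]

    background = 0.02
    sig = np.full((4, n_peaks), background)
    sig[SUBSTRATE, sub_idx] = 0.35
    for cls, own in ((PRINT_A, a_idx), (PRINT_B, b_idx)):
        sig[cls, own] = 0.45
        sig[cls, ab_idx] = 0.45
        sig[cls, sub_idx] = 0.05   # substrate show-through between residue spots
    shared = np.zeros(n_peaks)
    shared[mix_idx] = 0.30
    top, bottom = (PRINT_A, PRINT_B) if order == "A" else (PRINT_B, PRINT_A)
    sig[OVERLAP] = np.clip(
        occlusion_alpha * sig[top] + (1.0 - occlusion_alpha) * sig[bottom] + shared,
        0.0, 1.0,
    )
    return sig, shared


def ridge_mask(config: PhantomConfig, which_print: Literal["A", "B"]) -> np.ndarray:
    """Boolean (H, W) mask: inside the print's ellipse and on a ridge crest.

    A pixel is on a ridge when the grating sinusoid exceeds the duty-cycle
    threshold ``cos(pi * duty)``, so a fraction ``duty`` of each period is on.
    Deterministic in the config; no randomness involved.
    """
    geom = config.print_a if which_print == "A" else config.print_b
    rr, cc = np.mgrid[0 : config.height, 0 : config.width].astype(float)
    ar, ac = geom.axes
    if ar <= 0 or ac <= 0:
        return np.zeros((config.height, config.width), dtype=bool)
    inside = ((rr - geom.center[0]) / ar) ** 2 + ((cc - geom.center[1]) / ac) ** 2 <= 1.0
    if config.duty >= 1.0:
        return inside
    if config.duty <= 0.0:
        return np.zeros_like(inside)
    u = cc * np.cos(geom.ridge_angle) + rr * np.sin(geom.ridge_angle)
    wave = np.sin(2.0 * np.pi * geom.ridge_frequency * u + geom.ridge_phase)
    return inside & (wave > np.cos(np.pi * config.duty))


def compose_scene(config: PhantomConfig) -> PhantomTruth:
    """Label every pixel: overlap where both ridge masks hit, prints where one
    does, substrate elsewhere.  An empty overlap (disjoint prints) is legal."""
    mask_a = ridge_mask(config, "A")
    mask_b = ridge_mask(config, "B")
    class_map = np.zeros((config.height, config.width), dtype=np.int64)
    class_map[mask_a & ~mask_b] = PRINT_A
    class_map[mask_b & ~mask_a] = PRINT_B
    class_map[mask_a & mask_b] = OVERLAP
    return PhantomTruth(class_map, config.signatures.copy(), config.order)


def sample_cube(truth: PhantomTruth, config: PhantomConfig) -> SparseCube:
    """Draw the event list: count ~ Bernoulli(rate) or Poisson(rate) per
    (pixel, peak), keeping only nonzero draws.  Reproducible from config.seed."""
    H, W = truth.class_map.shape
    K = config.n_peaks
    rng = np.random.default_rng(config.seed)
    rates = truth.signatures[truth.class_map.ravel()]       # (H*W, K)
    if config.sampling_mode == "bernoulli":
        if rates.min() < 0 or rates.max() > 1:
            raise ValueError("bernoulli mode requires rates in [0, 1]")
        counts = (rng.random(rates.shape) < rates).astype(np.int64)
    else:
        counts = rng.poisson(rates).astype(np.int64)
    pix, peak = np.nonzero(counts)
    cube = SparseCube(
        H, W, K,
        rows=pix // W, cols=pix % W, peaks=peak, counts=counts[pix, peak],
        meta={
            "bin_factor": 1,
            "provenance": [f"phantom:seed={config.seed}:mode={config.sampling_mode}"],
        },
    )
    return cube


def config_from_dict(d: dict) -> PhantomConfig:
    """Build a config from plain JSON data (nested geometry dicts, lists)."""
    d = dict(d)
    for key in ("print_a", "print_b"):
        if key in d and isinstance(d[key], dict):
            g = dict(d[key])
            g["center"] = tuple(float(v) for v in g["center"])
            g["axes"] = tuple(float(v) for v in g["axes"])
            d[key] = PrintGeometry(**g)
    for key in ("signatures", "shared_component"):
        if d.get(key) is not None:
            d[key] = np.asarray(d[key], dtype=float)
    return PhantomConfig(**d)


def default_config(seed: int = 0, **overrides) -> PhantomConfig:
    """The default scene: 504 x 504 pixels, K = 64 peaks, Bernoulli counts,
    print A deposited on top of print B with occlusion 0.8."""
    return PhantomConfig(seed=seed, **overrides)
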