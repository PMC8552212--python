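"""Peak picking, pixel binning, and densification.

Binning sums counts over B x B neighborhoods — summation (not averaging)
preserves counting statistics, trading lateral resolution for per-pixel
signal.  A 7000 x 7000 raster binned 14 x 14 becomes 500 x 500.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .io import PeakList, SparseCube

__all__ = ["BinSpec", "peak_pick", "bin_cube", "densify"]


@dataclass(frozen=True)
class BinSpec:
    """B x B neighborhood summation; ``crop`` drops trailing rows/cols that do
    not fill a block, ``error`` requires exact divisibility."""

    factor: int
    edge_policy: Literal["crop", "error"] = "crop"

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("bin factor must be >= 1")
        if self.edge_policy not in ("crop", "error"):
            raise ValueError(f"unknown edge policy {self.edge_policy!r}")


def peak_pick(
    mz: np.ndarray,
    intensity: np.ndarray,
    min_prominence: float = 5.0,
    min_separation: float = 0.5,
) -> PeakList:
    """Pick peaks from a total spectrum: local maxima with at least
    ``min_prominence`` counts of prominence and centroids at least
    ``min_separation`` m/z apart (greedy, keeping the taller apex).

    Integration windows extend to the midpoints toward neighboring accepted
    peaks, clipped to +-0.5 m/z; half-open ``[lo, hi)``.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        raise ValueError("empty spectrum")
    if mz.size != intensity.size:
        raise ValueError("mz and intensity lengths differ")
    if np.any(np.diff(mz) < 0):
        raise ValueError("spectrum must be sorted by m/z")
    apex, _ = find_peaks(intensity, prominence=min_prominence)
    # greedy separation filter, tallest first
    keep: list[int] = []
    for i in apex[np.argsort(-intensity[apex], kind="stable")]:
        if all(abs(mz[i] - mz[j]) >= min_separation for j in keep):
            keep.append(i)
    keep.sort()
    centroids = mz[keep]
    lo = np.empty_like(centroids)
    hi = np.empty_like(centroids)
    for n, c in enumerate(centroids):
        left = (centroids[n - 1] + c) / 2.0 if n > 0 else c - 0.5
        right = (c + centroids[n + 1]) / 2.0 if n + 1 < centroids.size else c + 0.5
        lo[n] = max(left, c - 0.5)
        hi[n] = min(right, c + 0.5)
    return PeakList.from_arrays(centroids, lo, hi)


def bin_cube(cube: SparseCube, spec: BinSpec) -> SparseCube:
    """Sum counts over B x B pixel blocks; output dims (H // B, W // B).

    Under ``crop``, events in trailing rows/cols that do not fill a block are
    discarded with a logged warning; under ``error`` the dims must divide.
    Total counts are conserved over the retained region.
    """
    B = spec.factor
    if B > min(cube.height, cube.width):
        raise ValueError(f"bin factor {B} exceeds cube dims {cube.height}x{cube.width}")
    if spec.edge_policy == "error" and (cube.height % B or cube.width % B):
        raise ValueError(
            f"bin factor {B} does not divide dims {cube.height}x{cube.width}"
        )
    Hb, Wb = cube.height // B, cube.width // B
    keep = (cube.rows < Hb * B) & (cube.cols < Wb * B)
    dropped = int(cube.counts[~keep].sum())
    if dropped:
        warnings.warn(
            f"edge crop discarded {dropped} count(s) outside the {Hb * B}x{Wb * B} region",
            stacklevel=2,
        )
    meta = dict(cube.meta)
    meta["bin_factor"] = int(meta.get("bin_factor", 1)) * B
    meta.setdefault("provenance", [])
    meta["provenance"] = list(meta["provenance"]) + [f"bin:{B}x{B}:{spec.edge_policy}"]
    with warnings.catch_warnings():
        # collapsing a block onto one pixel merges triplets by design; the
        # constructor's duplicate warning is meant for file ingestion
        warnings.filterwarnings("ignore", message="merged .* duplicate")
        return SparseCube(
            Hb, Wb, cube.n_peaks,
            rows=cube.rows[keep] // B,
            cols=cube.cols[keep] // B,
            peaks=cube.peaks[keep],
            counts=cube.counts[keep],
            meta=meta,
            peak_list=cube.peak_list,
        )


def densify(cube: SparseCube, max_elements: int = 500_000_000) -> np.ndarray:
    """Dense (N, K) pixel-by-peak count matrix, N = H * W in row-major pixel
    order, so matrix row ``r * W + c`` is pixel (r, c).

    Refuses cubes whose dense form exceeds ``max_elements`` entries; stream in
    row blocks (slice the cube) for anything larger.
    """
    N = cube.height * cube.width
    if N * cube.n_peaks > max_elements:
        raise MemoryError(
            f"dense matrix would hold {N * cube.n_peaks} elements "
            f"(> budget {max_elements}); process the cube in row blocks"
        )
    X = np.zeros((N, cube.n_peaks), dtype=np.int64)
    X[cube.rows * cube.width + cube.cols, cube.peaks] = cube.counts
    return X
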