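"""Sparse hyperspectral-cube containers and readers/writers.

A ToF-SIMS macroraster image, after integrating each pixel's spectrum over a
peak list of K m/z windows, is an H x W x K cube of non-negative integer
counts.  In the low-dose ("static") regime almost every entry is zero, so the
cube is stored as an event list: one ``(row, col, peak_index, count)`` record
per nonzero entry.  The native on-disk container is a plain TSV triplet table
plus a JSON sidecar and a peak-list TSV, which keeps files diffable and
vendor-independent; imzML import is the standards bridge.

Conventions: 0-based indices, row-major pixel order, origin top-left;
integration windows are half-open ``[lo, hi)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "PeakList",
    "SparseCube",
    "load_cube",
    "write_cube",
    "total_ion_map",
    "ion_map",
    "read_imzml",
    "save_png",
]


class CubeFormatError(ValueError):
    """A cube container violates the declared format or its invariants."""


@dataclass(frozen=True)
class PeakList:
    """Ordered list of K integration windows on the m/z axis.

    Entries are sorted by centroid m/z; ``peak_index`` is the position in this
    order.  Windows are half-open ``[lo, hi)`` and must contain their centroid.
    """

    ids: tuple[str, ...]
    mz: np.ndarray          # (K,) centroid m/z
    lo: np.ndarray          # (K,) window lower bound
    hi: np.ndarray          # (K,) window upper bound (exclusive)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if not (len(self.ids) == mz.size == lo.size == hi.size):
            raise CubeFormatError("peak list field lengths disagree")
        if mz.size and not np.all(np.diff(mz) >= 0):
            raise CubeFormatError("peak centroids must be sorted ascending")
        if np.any(lo >= hi):
            raise CubeFormatError("every window needs lo < hi")
        if np.any((mz < lo) | (mz >= hi)):
            raise CubeFormatError("centroid must lie inside its half-open window")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_arrays(cls, mz, lo, hi, ids: Sequence[str] | None = None) -> "PeakList":
        mz = np.asarray(mz, dtype=float)
        order = np.argsort(mz, kind="stable")
        mz, lo, hi = mz[order], np.asarray(lo, float)[order], np.asarray(hi, float)[order]
        if ids is None:
            ids = [f"p{i:04d}" for i in range(mz.size)]
        else:
            ids = [ids[j] for j in order]
        return cls(tuple(ids), mz, lo, hi)

    def assign(self, mz_values: np.ndarray) -> np.ndarray:
        """Map m/z values to peak indices; -1 where no window contains them."""
        mz_values = np.asarray(mz_values, dtype=float)
        idx = np.searchsorted(self.lo, mz_values, side="right") - 1
        idx = np.clip(idx, 0, len(self) - 1)
        ok = (mz_values >= self.lo[idx]) & (mz_values < self.hi[idx])
        out = np.where(ok, idx, -1)
        return out.astype(np.int64)

    def to_tsv(self, path: Path | str) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("peak_id\tcentroid_mz\twindow_lo\twindow_hi\n")
            for pid, m, l, h in zip(self.ids, self.mz, self.lo, self.hi):
                fh.write(f"{pid}\t{m:.6f}\t{l:.6f}\t{h:.6f}\n")
        return path

    @classmethod
    def from_tsv(cls, path: Path | str) -> "PeakList":
        path = Path(path)
        ids, mz, lo, hi = [], [], [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["peak_id", "centroid_mz", "window_lo", "window_hi"]:
                raise CubeFormatError(f"bad peak-list header in {path}: {header!r}")
            for ln, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise CubeFormatError(f"{path}:{ln}: expected 4 fields, got {len(parts)}")
                ids.append(parts[0])
                mz.append(float(parts[1]))
                lo.append(float(parts[2]))
                hi.append(float(parts[3]))
        return cls(tuple(ids), np.array(mz), np.array(lo), np.array(hi))


@dataclass
class SparseCube:
    """Event-list hyperspectral image: H x W pixels by K peaks, integer counts.

    Events are kept canonically sorted by ``(row, col, peak)``; zeros are never
    stored and duplicate triplets are merged by summation (with a warning) at
    construction, so two cubes equal as multisets compare equal array-wise.
    """

    height: int
    width: int
    n_peaks: int
    rows: np.ndarray
    cols: np.ndarray
    peaks: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)
    peak_list: PeakList | None = None

    def __post_init__(self):
        self.height = int(self.height)
        self.width = int(self.width)
        self.n_peaks = int(self.n_peaks)
        if min(self.height, self.width, self.n_peaks) < 0:
            raise CubeFormatError("dimensions must be non-negative")
        r = np.asarray(self.rows, dtype=np.int64)
        c = np.asarray(self.cols, dtype=np.int64)
        k = np.asarray(self.peaks, dtype=np.int64)
        n = np.asarray(self.counts, dtype=np.int64)
        if not (r.size == c.size == k.size == n.size):
            raise CubeFormatError("event field lengths disagree")
        if r.size:
            bad = np.flatnonzero(
                (r < 0) | (r >= self.height)
                | (c < 0) | (c >= self.width)
                | (k < 0) | (k >= self.n_peaks)
            )
            if bad.size:
                b = bad[0]
                raise CubeFormatError(
                    f"event ({r[b]},{c[b]},{k[b]},{n[b]}) outside declared "
                    f"bounds {self.height}x{self.width}x{self.n_peaks}"
                )
            bad = np.flatnonzero(n < 1)
            if bad.size:
                b = bad[0]
                raise CubeFormatError(
                    f"event ({r[b]},{c[b]},{k[b]}) has non-positive count {n[b]}"
                )
        # canonical order + duplicate merge
        flat = (r * self.width + c) * self.n_peaks + k
        order = np.argsort(flat, kind="stable")
        flat, n = flat[order], n[order]
        uniq, start = np.unique(flat, return_index=True)
        if uniq.size != flat.size:
            warnings.warn(
                f"merged {flat.size - uniq.size} duplicate event triplet(s) by summing counts",
                stacklevel=2,
            )
            n = np.add.reduceat(n, start) if flat.size else n
            flat = uniq
        self.peaks = flat % self.n_peaks if self.n_peaks else flat
        pix = flat // self.n_peaks if self.n_peaks else flat
        self.cols = pix % self.width if self.width else pix
        self.rows = pix // self.width if self.width else pix
        self.counts = n

    @property
    def n_events(self) -> int:
        return int(self.counts.size)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.n_peaks)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SparseCube):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.rows, other.rows)
            and np.array_equal(self.cols, other.cols)
            and np.array_equal(self.peaks, other.peaks)
            and np.array_equal(self.counts, other.counts)
        )


def total_ion_map(cube: SparseCube) -> np.ndarray:
    """Per-pixel sum of counts over all peaks (the TIC map), shape (H, W)."""
    img = np.zeros((cube.height, cube.width), dtype=np.int64)
    np.add.at(img, (cube.rows, cube.cols), cube.counts)
    return img


def ion_map(cube: SparseCube, peak_index: int) -> np.ndarray:
    """Per-pixel counts of a single peak, shape (H, W)."""
    if not 0 <= peak_index < cube.n_peaks:
        raise IndexError(f"peak_index {peak_index} outside [0, {cube.n_peaks})")
    img = np.zeros((cube.height, cube.width), dtype=np.int64)
    sel = cube.peaks == peak_index
    np.add.at(img, (cube.rows[sel], cube.cols[sel]), cube.counts[sel])
    return img


def _base_path(path: Path | str) -> Path:
    """Strip a trailing .events.tsv / .meta.json / .peaks.tsv if present."""
    p = Path(path)
    name = p.name
    for suffix in (".events.tsv", ".meta.json", ".peaks.tsv"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p


def write_cube(cube: SparseCube, path: Path | str) -> Path:
    """Write the native container ``<path>.events.tsv`` + ``<path>.meta.json``
    (+ ``<path>.peaks.tsv`` when a peak list is attached); returns the base path.

    Events are written in (row, col, peak) lexicographic order, so multiset-equal
    cubes produce byte-identical files.
    """
    base = _base_path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_name(base.name + ".events.tsv"), "w") as fh:
        fh.write("row\tcol\tpeak\tcount\n")
        for r, c, k, n in zip(cube.rows, cube.cols, cube.peaks, cube.counts):
            fh.write(f"{r}\t{c}\t{k}\t{n}\n")
    meta = {
        "height": cube.height,
        "width": cube.width,
        "n_peaks": cube.n_peaks,
        "bin_factor": cube.meta.get("bin_factor", 1),
        "pixel_size_um": cube.meta.get("pixel_size_um"),
        "provenance": cube.meta.get("provenance", []),
    }
    with open(base.with_name(base.name + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if cube.peak_list is not None:
        cube.peak_list.to_tsv(base.with_name(base.name + ".peaks.tsv"))
    return base


def load_cube(path: Path | str) -> SparseCube:
    """Load a cube from the native container (or an imzML file, dispatching on
    suffix).  Duplicate triplets are merged by summation with a warning;
    malformed records raise :class:`CubeFormatError` naming the offender.
    """
    p = Path(path)
    if p.suffix.lower() == ".imzml":
        raise CubeFormatError(
            "imzML input needs a peak list; call read_imzml(path, peak_list)"
        )
    base = _base_path(p)
    events_path = base.with_name(base.name + ".events.tsv")
    meta_path = base.with_name(base.name + ".meta.json")
    if not meta_path.exists():
        raise CubeFormatError(f"missing sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in ("height", "width", "n_peaks"):
        if key not in meta:
            raise CubeFormatError(f"{meta_path}: missing {key!r}")
    rows, cols, peaks, counts = [], [], [], []
    with open(events_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["row", "col", "peak", "count"]:
            raise CubeFormatError(f"bad events header in {events_path}: {header!r}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise CubeFormatError(
                    f"{events_path}:{ln}: expected 4 fields, got {len(parts)}"
                )
            try:
                r, c, k, n = (int(x) for x in parts)
            except ValueError as exc:
                raise CubeFormatError(f"{events_path}:{ln}: non-integer field") from exc
            rows.append(r)
            cols.append(c)
            peaks.append(k)
            counts.append(n)
    peaks_path = base.with_name(base.name + ".peaks.tsv")
    plist = PeakList.from_tsv(peaks_path) if peaks_path.exists() else None
    try:
        return SparseCube(
            meta["height"], meta["width"], meta["n_peaks"],
            np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64),
            np.array(peaks, dtype=np.int64), np.array(counts, dtype=np.int64),
            meta={k: v for k, v in meta.items() if k not in ("height", "width", "n_peaks")},
            peak_list=plist,
        )
    except CubeFormatError as exc:
        raise CubeFormatError(f"{events_path}: {exc}") from exc


def read_imzml(path: Path | str, peak_list: PeakList) -> SparseCube:
    """Import an imzML pair, integrating each spectrum into the peak windows.

    Pixel coordinates come from the standard imzML position tags (1-based x/y,
    mapped to 0-based col/row).  Intensities falling in no window are dropped;
    integrated intensities are rounded to the nearest integer count.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    xs = np.array([c[0] for c in parser.coordinates])
    ys = np.array([c[1] for c in parser.coordinates])
    width = int(xs.max())
    height = int(ys.max())
    K = len(peak_list)
    rows, cols, peaks, counts = [], [], [], []
    for i, (x, y) in enumerate(zip(xs, ys)):
        mzs, intens = parser.getspectrum(i)
        idx = peak_list.assign(np.asarray(mzs))
        keep = idx >= 0
        if not np.any(keep):
            continue
        per_peak = np.zeros(K)
        np.add.at(per_peak, idx[keep], np.asarray(intens)[keep])
        nz = np.flatnonzero(np.rint(per_peak) >= 1)
        for k in nz:
            rows.append(int(y) - 1)
            cols.append(int(x) - 1)
            peaks.append(int(k))
            counts.append(int(round(per_peak[k])))
    return SparseCube(
        height, width, K,
        np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64),
        np.array(peaks, dtype=np.int64), np.array(counts, dtype=np.int64),
        meta={"provenance": [f"imzml:{Path(path).name}"]},
        peak_list=peak_list,
    )


def save_png(image: np.ndarray, path: Path | str, bit_depth: int = 8) -> Path:
    """Write a 2-D grayscale or (H, W, 3) RGB array as PNG.

    Float images must already be in [0, 1]; integer images are written as-is
    (16-bit grayscale supported for count maps).
    """
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype.kind == "f":
        arr = np.clip(arr, 0.0, 1.0)
        arr = (arr * (65535 if bit_depth == 16 else 255)).round()
    if bit_depth == 16:
        if arr.ndim != 2:
            raise ValueError("16-bit export supports grayscale images only")
        Image.fromarray(arr.astype(np.uint16)).save(path)
    else:
        Image.fromarray(arr.astype(np.uint8)).save(path)
    return path
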