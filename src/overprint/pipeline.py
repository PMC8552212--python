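"""End-to-end bin -> train -> backfit -> cluster runs on phantom scenes.

Glue used by the binning sweep, the CLI, and the acceptance checks: generate
(or accept) a scene, bin it, fit the parametric embedding on the binned
matrix, backfit the unbinned matrix, cluster the full-resolution coordinates,
and score against the phantom truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .binning import BinSpec, bin_cube, densify
from .cluster import LabelImage, cluster_pixels
from .embed import ParametricUMAP
from .io import SparseCube
from .phantom import PhantomConfig, PhantomTruth, compose_scene, sample_cube

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_on_cube"]


@dataclass
class PipelineResult:
    labels: LabelImage          # full-resolution cluster map
    coords: np.ndarray          # (H*W, 3) backfitted embedding
    model: ParametricUMAP
    truth: PhantomTruth | None
    cube: SparseCube
    ari: float | None           # vs truth.class_map, when truth known
    silhouette: float           # of the selected clustering, on a subsample


def run_pipeline_on_cube(
    cube: SparseCube,
    truth: PhantomTruth | None = None,
    bin_factor: int = 14,
    seed: int = 0,
    n_components: int = 3,
    k_clusters: int | str = "auto",
    embed_params: dict | None = None,
) -> PipelineResult:
    binned = bin_cube(cube, BinSpec(bin_factor))
    X_binned = densify(binned).astype(np.float64)
    embed_params = dict(embed_params or {})
    embed_params.setdefault("dose_augment", 1.0 / bin_factor**2)
    model = ParametricUMAP(
        n_components=n_components, random_state=seed, **embed_params
    ).fit(X_binned)
    X_full = densify(cube).astype(np.float64)
    coords = model.transform(X_full)
    labels = cluster_pixels(coords, (cube.height, cube.width),
                            k_clusters=k_clusters, seed=seed)
    flat = labels.labels.ravel()
    rng = np.random.default_rng(seed)
    sub = rng.choice(flat.size, size=min(flat.size, 5000), replace=False)
    if np.unique(flat[sub]).size > 1:
        sil = float(silhouette_score(coords[sub].astype(np.float64), flat[sub]))
    else:
        sil = float("nan")
    ari = None
    if truth is not None:
        ari = float(adjusted_rand_score(truth.class_map.ravel(), flat))
    return PipelineResult(labels, coords, model, truth, cube, ari, sil)


def run_pipeline(config: PhantomConfig, bin_factor: int = 14, seed: int = 0,
                 **kwargs) -> PipelineResult:
    """Phantom-to-verdict convenience wrapper: compose, sample, then run."""
    truth = compose_scene(config)
    cube = sample_cube(truth, config)
    return run_pipeline_on_cube(cube, truth=truth, bin_factor=bin_factor,
                                seed=seed, **kwargs)
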