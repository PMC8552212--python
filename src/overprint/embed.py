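"""Fuzzy neighborhood graphs and a parametric (neural-encoder) UMAP.

The bin-train-backfit strategy hinges on the embedding being a *function*:
UMAP's low-dimensional layout is produced by a multilayer perceptron trained
to minimize the fuzzy cross-entropy between the high-dimensional neighborhood
graph and the embedded similarities ``1 / (1 + a * d^(2b))``.  The encoder is
fitted on the pixel-binned matrix (statistically rich) and then applied
row-wise to the unbinned matrix (statistically poor) without re-optimization,
recovering full lateral resolution.

Graph construction follows the standard UMAP recipe: per point, distances to
the k nearest neighbors, local connectivity offset ``rho_i`` (distance to the
nearest neighbor), bandwidth ``sigma_i`` solved by bisection so that the
directed weights sum to ``log2(k)``, and a probabilistic-union symmetrization
``w_ij + w_ji - w_ij * w_ji``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted

from ._nn import MLP

__all__ = [
    "FuzzyGraph",
    "smooth_knn_bandwidths",
    "build_fuzzy_graph",
    "find_ab_params",
    "ParametricUMAP",
    "train_embedding",
    "backfit",
    "rgb_map",
]

_SMOOTH_TOL = 1e-5
_MIN_DIST_SCALE = 1e-3


@dataclass
class FuzzyGraph:
    """k-NN fuzzy simplicial set: per-point offsets/bandwidths and the
    symmetrized sparse weight matrix (entries in (0, 1])."""

    n_points: int
    k_neighbors: int
    knn_indices: np.ndarray   # (N, k), self excluded
    knn_dists: np.ndarray     # (N, k), ascending
    rho: np.ndarray           # (N,) distance to nearest neighbor
    sigma: np.ndarray         # (N,) bandwidth from the log2(k) constraint
    weights: sp.csr_matrix    # (N, N) symmetric

    def directed_weights(self) -> sp.csr_matrix:
        w = np.exp(
            -np.maximum(self.knn_dists - self.rho[:, None], 0.0) / self.sigma[:, None]
        )
        rows = np.repeat(np.arange(self.n_points), self.k_neighbors)
        return sp.csr_matrix(
            (w.ravel(), (rows, self.knn_indices.ravel())),
            shape=(self.n_points, self.n_points),
        )


def smooth_knn_bandwidths(
    knn_dists: np.ndarray, target: float | None = None, n_iter: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Solve, per point, sum_j exp(-max(0, d_ij - rho_i) / sigma_i) = log2(k).

    Vectorized bisection on sigma (monotone increasing sum); returns
    (rho, sigma).  Degenerate rows (so many coincident neighbors that no root
    exists) fall back to a small multiple of the mean neighbor distance, as is
    standard for this construction.
    """
    knn_dists = np.asarray(knn_dists, dtype=np.float64)
    n, k = knn_dists.shape
    if target is None:
        target = np.log2(k)
    rho = knn_dists[:, 0].copy()
    adj = np.maximum(knn_dists - rho[:, None], 0.0)
    lo = np.zeros(n)
    hi = np.full(n, np.inf)
    mid = np.ones(n)
    for _ in range(n_iter):
        psum = np.exp(-adj / mid[:, None]).sum(axis=1)
        greater = psum > target
        hi = np.where(greater, mid, hi)
        lo = np.where(greater, lo, mid)
        mid = np.where(np.isinf(hi), mid * 2.0, (lo + hi) / 2.0)
    sigma = mid
    mean_all = knn_dists.mean() if knn_dists.size else 1.0
    mean_i = knn_dists.mean(axis=1)
    floor = np.where(rho > 0.0, _MIN_DIST_SCALE * mean_i, _MIN_DIST_SCALE * mean_all)
    sigma = np.maximum(sigma, np.maximum(floor, 1e-12))
    return rho, sigma


def _exact_knn(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact k nearest neighbors excluding self (one self-slot dropped per row,
    robust to duplicate points)."""
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, ind = nn.kneighbors(X)
    is_self = ind == np.arange(n)[:, None]
    drop = np.where(is_self.any(axis=1), is_self.argmax(axis=1), k)
    keep = np.ones_like(ind, dtype=bool)
    keep[np.arange(n), drop] = False
    return dist[keep].reshape(n, k), ind[keep].reshape(n, k)


def build_fuzzy_graph(X: np.ndarray, k_neighbors: int = 15,
                      metric: str = "euclidean") -> FuzzyGraph:
    """Construct the fuzzy neighborhood graph of the rows of X.

    Exact k-NN throughout (the problem sizes this package targets after
    binning are at most a few tens of thousands of rows); Euclidean metric
    only for now.
    """
    X = check_array(X, dtype=np.float64)
    n = X.shape[0]
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} points, got {n}")
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    dists, inds = _exact_knn(X, k_neighbors)
    rho, sigma = smooth_knn_bandwidths(dists)
    graph = FuzzyGraph(n, k_neighbors, inds, dists, rho, sigma, None)
    w = graph.directed_weights()
    sym = w + w.T - w.multiply(w.T)
    sym.eliminate_zeros()
    graph.weights = sym.tocsr()
    return graph


def find_ab_params(min_dist: float, spread: float = 1.0) -> tuple[float, float]:
    """Least-squares fit of the embedded-similarity curve 1/(1 + a d^(2b)) to
    the target kernel (flat at 1 below ``min_dist``, exponential decay beyond)."""
    def curve(d, a, b):
        return 1.0 / (1.0 + a * d ** (2.0 * b))

    d = np.linspace(0.0, 3.0 * spread, 300)
    target = np.where(d < min_dist, 1.0, np.exp(-(d - min_dist) / spread))
    (a, b), _ = curve_fit(curve, d, target, p0=(1.0, 1.0), maxfev=10000)
    return float(a), float(b)


class ParametricUMAP(TransformerMixin, BaseEstimator):
    """UMAP with a neural-network encoder, trained by negative sampling.

    Parameters
    ----------
    n_components : embedding dimension (3 for the pixel domain's RGB maps,
        2 for the transposed mass domain).
    n_neighbors : k for the fuzzy graph.
    min_dist : minimum embedded distance; converted to the (a, b) curve
        constants by least squares.
    n_epochs : passes over the (weight-sampled) edge set.
    learning_rate : Adam step size.
    hidden_layers : MLP hidden widths.
    negative_sample_rate : uniform negative points drawn per positive edge.
    batch_size : edges per optimization step.
    max_samples_per_epoch : cap on weighted edge draws per epoch (bounds the
        cost of one epoch on large binned matrices).
    tic_normalize : scale each row to unit total count before embedding
        (off by default: the pipeline embeds raw counts).
    dose_augment : None, or the minimum dose u_min in (0, 1].  When set (and
        the training matrix is integer counts), every row fed to the encoder
        during optimization is Binomial-thinned at a dose drawn log-uniformly
        from [u_min, 1].  Thinning a count spectrum is statistically exactly a
        lower-fluence acquisition of the same chemistry, so this teaches the
        encoder dose invariance — the property the backfit from binned to
        unbinned scale relies on.  The fuzzy graph is still built on the raw
        rows.  The pipeline sets u_min = 1/B**2 for bin factor B.
    random_state : seed for initialization and all edge/negative sampling.

    After ``fit`` the encoder is a pure function: identical input rows map to
    identical coordinates, across calls, serialization round-trips, and row
    permutations.
    """

    def __init__(self, n_components: int = 3, n_neighbors: int = 15,
                 min_dist: float = 0.1, n_epochs: int = 50,
                 learning_rate: float = 1e-3, hidden_layers: tuple[int, ...] = (128, 128),
                 negative_sample_rate: int = 5, batch_size: int = 1024,
                 max_samples_per_epoch: int = 30000, metric: str = "euclidean",
                 tic_normalize: bool = False, dose_augment: float | None = None,
                 random_state: int = 0, verbose: bool = False):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.hidden_layers = hidden_layers
        self.negative_sample_rate = negative_sample_rate
        self.batch_size = batch_size
        self.max_samples_per_epoch = max_samples_per_epoch
        self.metric = metric
        self.tic_normalize = tic_normalize
        self.dose_augment = dose_augment
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ---------------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = check_array(X, dtype=np.float64)
        if self.tic_normalize:
            tic = X.sum(axis=1, keepdims=True)
            tic[tic == 0.0] = 1.0
            X = X / tic
        return X

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y=None):
        X = self._prepare(X)
        M, K = X.shape
        if M < 50:
            raise ValueError(f"need at least 50 training rows, got {M}")
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        rng = np.random.default_rng(self.random_state)
        self.a_, self.b_ = find_ab_params(self.min_dist)
        self.graph_ = build_fuzzy_graph(X, self.n_neighbors, self.metric)
        scale = float(X.std())
        self.input_scale_ = 1.0 / scale if scale > 0 else 1.0
        self.n_features_in_ = K
        self.training_hash_ = hashlib.sha1(
            np.ascontiguousarray(X)
        ).hexdigest()
        self.encoder_ = MLP(K, tuple(self.hidden_layers), self.n_components, rng)
        self._optimize(X, rng)
        self.embedding_ = self.transform(X, _skip_prepare=True)
        return self

    def _optimize(self, X: np.ndarray, rng: np.random.Generator) -> None:
        coo = sp.triu(self.graph_.weights, k=1).tocoo()
        heads, tails, w = coo.row, coo.col, coo.data.astype(np.float64)
        if heads.size == 0:
            raise RuntimeError("fuzzy graph has no edges")
        p = w / w.sum()
        n_points = X.shape[0]
        Xs = (X * self.input_scale_).astype(np.float32)
        if self.dose_augment is not None:
            if not 0.0 < self.dose_augment <= 1.0:
                raise ValueError("dose_augment must lie in (0, 1]")
            if not np.allclose(X, np.rint(X)) or X.min() < 0:
                raise ValueError("dose_augment needs a non-negative integer count matrix")
            self._X_counts = np.rint(X).astype(np.int64)
        else:
            self._X_counts = None
        m = self.negative_sample_rate
        a, b = self.a_, self.b_
        n_samples = int(min(heads.size, self.max_samples_per_epoch))
        self.loss_history_ = []
        for epoch in range(self.n_epochs):
            picks = rng.choice(heads.size, size=n_samples, p=p, replace=True)
            epoch_loss = 0.0
            for start in range(0, n_samples, self.batch_size):
                batch = picks[start : start + self.batch_size]
                i, j = heads[batch], tails[batch]
                neg = rng.integers(0, n_points, size=(batch.size, m))
                epoch_loss += self._step(Xs, i, j, neg, a, b, rng)
            self.loss_history_.append(epoch_loss / n_samples)
            if not np.isfinite(epoch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {epoch_loss!r}; "
                    "inspect learning_rate / input scaling"
                )
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.n_epochs} loss {epoch_loss / n_samples:.4f}")

    def _step(self, Xs, i, j, neg, a, b, rng) -> float:
        B = i.size
        m = neg.shape[1]
        d = self.n_components
        idx = np.concatenate([i, j, neg.ravel()])
        if self._X_counts is not None:
            dose = np.exp(rng.uniform(np.log(self.dose_augment), 0.0, size=idx.size))
            x_in = rng.binomial(self._X_counts[idx], dose[:, None]).astype(np.float32)
            x_in *= self.input_scale_
        else:
            x_in = Xs[idx]
        y, cache = self.encoder_.forward(x_in, keep_cache=True)
        yi, yj = y[:B], y[B : 2 * B]
        yn = y[2 * B :].reshape(B, m, d)

        eps = 1e-12
        diff = yi - yj
        d2 = np.maximum(np.einsum("bd,bd->b", diff, diff), eps)
        q = 1.0 / (1.0 + a * d2 ** b)
        # attractive: dL/d(d2) for L = -log q
        coeff_att = (a * b * d2 ** (b - 1.0)) / (1.0 + a * d2 ** b)
        g_pos = np.clip(2.0 * coeff_att[:, None] * diff, -4.0, 4.0)

        diff_n = yi[:, None, :] - yn
        d2n = np.maximum(np.einsum("bmd,bmd->bm", diff_n, diff_n), eps)
        qn = 1.0 / (1.0 + a * d2n ** b)
        # repulsive: dL/d(d2) for L = -log(1 - q)
        coeff_rep = -b / ((0.001 + d2n) * (1.0 + a * d2n ** b))
        g_neg = np.clip(2.0 * coeff_rep[:, :, None] * diff_n, -4.0, 4.0)
        # a negative draw hitting an edge endpoint is skipped
        same = (neg == i[:, None]) | (neg == j[:, None])
        g_neg[same] = 0.0
        qn = np.where(same, 0.0, qn)

        grad = np.empty_like(y)
        grad[:B] = g_pos + g_neg.sum(axis=1)
        grad[B : 2 * B] = -g_pos
        grad[2 * B :] = (-g_neg).reshape(B * m, d)
        grad /= B

        gw, gb = self.encoder_.backward(cache, grad)
        self.encoder_.adam_step(gw, gb, self.learning_rate)
        loss = -np.log(q + eps).sum() - np.log(1.0 - qn + eps).sum()
        return float(loss)

    def transform(self, X, _skip_prepare: bool = False):
        check_is_fitted(self, "encoder_")
        if not _skip_prepare:
            X = self._prepare(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.n_features_in_}"
            )
        out = np.empty((X.shape[0], self.n_components), dtype=np.float32)
        block = 1 << 16
        for start in range(0, X.shape[0], block):
            xb = (X[start : start + block] * self.input_scale_).astype(np.float32)
            out[start : start + block] = self.encoder_.forward(xb)
        return out

    # -- persistence -----------------------------------------------------

    _FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Single-file container: hyperparameter JSON header + weight arrays."""
        check_is_fitted(self, "encoder_")
        header = {
            "format_version": self._FORMAT_VERSION,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "a": self.a_,
            "b": self.b_,
            "input_scale": self.input_scale_,
            "n_features_in": self.n_features_in_,
            "training_hash": self.training_hash_,
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        ), **self.encoder_.state_dict())

    @classmethod
    def load(cls, path) -> "ParametricUMAP":
        with np.load(path) as blob:
            header = json.loads(bytes(blob["__header__"]).decode())
            if header.get("format_version") != cls._FORMAT_VERSION:
                raise ValueError(f"unsupported model format: {header.get('format_version')}")
            state = {k: blob[k] for k in blob.files if k != "__header__"}
        params = header["params"]
        params["hidden_layers"] = tuple(params["hidden_layers"])
        model = cls(**params)
        model.a_ = header["a"]
        model.b_ = header["b"]
        model.input_scale_ = header["input_scale"]
        model.n_features_in_ = header["n_features_in"]
        model.training_hash_ = header["training_hash"]
        model.encoder_ = MLP.from_state(state)
        return model


def train_embedding(X_binned: np.ndarray, d: int = 3, **hyperparams) -> ParametricUMAP:
    """Fit a parametric embedding on the binned pixel-by-peak matrix."""
    return ParametricUMAP(n_components=d, **hyperparams).fit(X_binned)


def backfit(model: ParametricUMAP, X_full: np.ndarray) -> np.ndarray:
    """Apply a trained encoder row-wise to the unbinned matrix (no re-training)."""
    return model.transform(X_full)


def rgb_map(coords: np.ndarray, geometry: tuple[int, int]) -> np.ndarray:
    """Map a 3-D embedding to an (H, W, 3) RGB image in [0, 1].

    Each axis is rescaled by its 1st-99th percentile range (clipped); an axis
    with a degenerate range renders as the 0.5 midpoint.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("rgb_map needs N x 3 coordinates")
    H, W = geometry
    if coords.shape[0] != H * W:
        raise ValueError(f"{coords.shape[0]} coordinates cannot fill {H}x{W}")
    out = np.empty_like(coords)
    for axis in range(3):
        lo, hi = np.percentile(coords[:, axis], [1.0, 99.0])
        if hi - lo < 1e-12:
            out[:, axis] = 0.5
        else:
            out[:, axis] = np.clip((coords[:, axis] - lo) / (hi - lo), 0.0, 1.0)
    return out.reshape(H, W, 3)
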