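"""Late fusion of per-CNN class probabilities and correlation-distance KNN.

Architecture 1 trains one CNN per feature map (XA, XD, XL) and concatenates
the three class-probability vectors (length ``3*l``).  Architecture 2 trains
one CNN per channel of every map (23 + 8 + 25 = 56 models) and concatenates
all per-channel probability vectors (length ``56*l``).  The fused vectors
are classified by a KNN with the correlation distance (1 - Pearson r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .network import CNNConfig, CNNModel, build_cnn, train_cnn

#: Channel counts of (XA, XD, XL); their sum (56) fixes the Architecture 2
#: fused-vector length 56 * l.
CHANNEL_COUNTS: tuple[int, int, int] = (23, 8, 25)

MAP_ORDER: tuple[str, str, str] = ("XA", "XD", "XL")


@dataclass(frozen=True)
class KNNConfig:
    k: int = 12

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class FusedVector:
    """Concatenated class-probability vector with its architecture tag."""

    architecture: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def fuse_architecture1(
    p_a: np.ndarray, p_d: np.ndarray, p_l: np.ndarray
) -> FusedVector:
    """Concatenate the three per-map probability vectors in (A, D, L) order."""
    vecs = [np.asarray(p, dtype=float).ravel() for p in (p_a, p_d, p_l)]
    lengths = {v.shape[0] for v in vecs}
    if len(lengths) != 1:
        raise ValueError(f"probability vectors differ in length: {sorted(lengths)}")
    return FusedVector(architecture=1, values=np.concatenate(vecs))


def fuse_architecture2(
    per_channel_probs: Sequence[np.ndarray],
    channel_counts: tuple[int, int, int] = CHANNEL_COUNTS,
) -> FusedVector:
    """Concatenate per-channel probability vectors (XA then XD then XL).

    Expects exactly ``sum(channel_counts)`` vectors of a common length l;
    the result has length ``l * sum(channel_counts)`` (336 for l = 6).
    """
    expected = sum(channel_counts)
    if len(per_channel_probs) != expected:
        raise ValueError(
            f"expected {expected} per-channel vectors, got {len(per_channel_probs)}"
        )
    vecs = [np.asarray(p, dtype=float).ravel() for p in per_channel_probs]
    lengths = {v.shape[0] for v in vecs}
    if len(lengths) != 1:
        raise ValueError(f"probability vectors differ in length: {sorted(lengths)}")
    return FusedVector(architecture=2, values=np.concatenate(vecs))


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation of two vectors; in [0, 2].

    If either vector is constant the correlation is undefined; by convention
    the distance is 1 (uncorrelated).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    if u.shape[0] < 2:
        raise ValueError("vectors must have length >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    su = np.sqrt(np.dot(du, du))
    sv = np.sqrt(np.dot(dv, dv))
    if su == 0.0 or sv == 0.0:
        return 1.0
    r = float(np.dot(du, dv) / (su * sv))
    return 1.0 - min(1.0, max(-1.0, r))


def _correlation_distances(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Pairwise correlation distances, vectorized; constant rows give 1."""
    q = queries - queries.mean(axis=1, keepdims=True)
    t = train - train.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(q, axis=1)
    tn = np.linalg.norm(t, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (q @ t.T) / np.outer(qn, tn)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    return 1.0 - r


def knn_predict(
    train_vectors: np.ndarray,
    train_labels: np.ndarray,
    query: np.ndarray,
    config: KNNConfig = KNNConfig(),
    n_classes: int = 6,
) -> tuple[int, np.ndarray]:
    """Classify one fused vector by majority vote among the k nearest.

    Ties are broken by the smaller summed neighbor distance, then by the
    lower class label.  The returned per-class score vector is the
    inverse-distance-weighted vote share over the k neighbors (classes
    ordered 1..n_classes), usable as a decision score for ROC analysis.
    """
    train_vectors = np.asarray(train_vectors, dtype=float)
    train_labels = np.asarray(train_labels, dtype=int)
    if train_vectors.shape[0] == 0:
        raise ValueError("empty training set")
    if config.k > train_vectors.shape[0]:
        raise ValueError(
            f"k={config.k} exceeds training-set size {train_vectors.shape[0]}"
        )
    q = np.asarray(query, dtype=float).ravel()
    dists = _correlation_distances(q[None, :], train_vectors)[0]
    order = np.argsort(dists, kind="stable")[: config.k]
    nn_labels = train_labels[order]
    nn_dists = dists[order]

    votes = np.zeros(n_classes)
    summed = np.full(n_classes, np.inf)
    weights = np.zeros(n_classes)
    inv = 1.0 / (nn_dists + 1e-12)
    for lbl, d, wv in zip(nn_labels, nn_dists, inv):
        c = lbl - 1
        votes[c] += 1
        summed[c] = d if not np.isfinite(summed[c]) else summed[c] + d
        weights[c] += wv
    scores = weights / weights.sum() if weights.sum() > 0 else votes / config.k

    best = np.flatnonzero(votes == votes.max())
    if len(best) > 1:
        best = best[np.argsort(summed[best], kind="stable")]
        tied = summed[best] == summed[best[0]]
        best = best[tied]
    return int(best[0]) + 1, scores


class KNNClassifier:
    """Stored training vectors + labels + config; no opaque state."""

    def __init__(self, config: KNNConfig = KNNConfig(), n_classes: int = 6):
        self.config = config
        self.n_classes = n_classes
        self.train_vectors: np.ndarray | None = None
        self.train_labels: np.ndarray | None = None

    def fit(self, vectors: np.ndarray, labels: np.ndarray) -> "KNNClassifier":
        vectors = np.asarray(vectors, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if len(vectors) != len(labels):
            raise ValueError("vectors/labels length mismatch")
        if self.config.k > len(vectors):
            raise ValueError("k exceeds training-set size")
        self.train_vectors, self.train_labels = vectors, labels
        return self

    def predict(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, scores) for a batch of fused vectors."""
        if self.train_vectors is None:
            raise ValueError("classifier not fitted")
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        labels = np.empty(len(queries), dtype=int)
        scores = np.empty((len(queries), self.n_classes))
        for i, q in enumerate(queries):
            labels[i], scores[i] = knn_predict(
                self.train_vectors, self.train_labels, q, self.config, self.n_classes
            )
        return labels, scores


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

class FusionPipeline:
    """Parallel CNNs + late fusion + correlation-distance KNN.

    ``fit`` takes a dict of stacked feature maps (``{"XA": (N,19,19,23),
    "XD": (N,23,23,8), "XL": (N,20,20,25)}``) and EC labels in 1..n_classes.
    """

    def __init__(
        self,
        architecture: int = 1,
        cnn_config: CNNConfig | None = None,
        knn_config: KNNConfig = KNNConfig(),
        seed: int = 0,
    ):
        if architecture not in (1, 2):
            raise ValueError("architecture must be 1 or 2")
        self.architecture = architecture
        self.cnn_config = cnn_config or (
            CNNConfig.architecture1() if architecture == 1 else CNNConfig.architecture2()
        )
        self.knn_config = knn_config
        self.seed = seed
        self.models: list[CNNModel] = []
        self.knn = KNNClassifier(knn_config, n_classes=self.cnn_config.n_classes)
        self.histories: list = []

    # -- internals ---------------------------------------------------------
    def _streams(self, maps: Mapping[str, np.ndarray]) -> list[np.ndarray]:
        """Per-CNN input stacks, channels-last."""
        out: list[np.ndarray] = []
        if self.architecture == 1:
            for key in MAP_ORDER:
                out.append(np.asarray(maps[key], dtype=float))
        else:
            for key in MAP_ORDER:
                arr = np.asarray(maps[key], dtype=float)
                for ch in range(arr.shape[-1]):
                    out.append(arr[..., ch:ch + 1])
        return out

    def fit(
        self,
        maps: Mapping[str, np.ndarray],
        labels: np.ndarray,
        test_maps: Mapping[str, np.ndarray] | None = None,
        test_labels: np.ndarray | None = None,
    ) -> "FusionPipeline":
        labels = np.asarray(labels, dtype=int)
        y = labels - 1
        streams = self._streams(maps)
        test_streams = self._streams(test_maps) if test_maps is not None else None
        y_test = (
            np.asarray(test_labels, dtype=int) - 1 if test_labels is not None else None
        )
        self.models, self.histories = [], []
        for i, x in enumerate(streams):
            cfg = CNNConfig(
                **{**self.cnn_config.__dict__, "seed": self.seed + 1000 * i}
            )
            model = build_cnn(tuple(x.shape[1:]), cfg)
            hist = train_cnn(
                model, x, y, cfg,
                x_test=test_streams[i] if test_streams is not None else None,
                y_test=y_test,
            )
            self.models.append(model)
            self.histories.append(hist)
        self.knn.fit(self.fused_vectors(maps), labels)
        return self

    def fused_vectors(self, maps: Mapping[str, np.ndarray]) -> np.ndarray:
        """Fused class-probability vectors, one row per sample."""
        if not self.models:
            raise ValueError("pipeline not fitted")
        streams = self._streams(maps)
        probs = [m.predict_proba(x) for m, x in zip(self.models, streams)]
        n = probs[0].shape[0]
        fuse = fuse_architecture1 if self.architecture == 1 else fuse_architecture2
        rows = []
        for i in range(n):
            per_sample = [p[i] for p in probs]
            if self.architecture == 1:
                rows.append(fuse_architecture1(*per_sample).values)
            else:
                rows.append(fuse_architecture2(per_sample).values)
        return np.vstack(rows)

    def predict(self, maps: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """(EC labels in 1..l, per-class decision scores)."""
        return self.knn.predict(self.fused_vectors(maps))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint: configs + all model/KNN arrays."""
        meta = {
            "architecture": self.architecture,
            "seed": self.seed,
            "cnn_config": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.cnn_config.__dict__.items()
            },
            "knn_k": self.knn_config.k,
            "input_shapes": [list(m.input_shape) for m in self.models],
            "n_models": len(self.models),
        }
        arrays: dict[str, np.ndarray] = {
            "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        }
        for i, model in enumerate(self.models):
            for j, arr in enumerate(model.state_arrays()):
                arrays[f"m{i}_a{j}"] = arr
        arrays["knn_X"] = self.knn.train_vectors
        arrays["knn_y"] = self.knn.train_labels
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FusionPipeline":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        ccfg = dict(meta["cnn_config"])
        for key in ("kernel_sizes", "filters"):
            ccfg[key] = tuple(ccfg[key])
        pipe = cls(
            architecture=meta["architecture"],
            cnn_config=CNNConfig(**ccfg),
            knn_config=KNNConfig(k=meta["knn_k"]),
            seed=meta["seed"],
        )
        for i, shape in enumerate(meta["input_shapes"]):
            cfg = CNNConfig(**{**ccfg, "seed": meta["seed"] + 1000 * i})
            model = build_cnn(tuple(shape), cfg)
            arrs = []
            j = 0
            while f"m{i}_a{j}" in data:
                arrs.append(data[f"m{i}_a{j}"])
                j += 1
            model.load_state_arrays(arrs)
            pipe.models.append(model)
        pipe.knn.fit(data["knn_X"], data["knn_y"])
        return pipe
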