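"""Amplitude gate: KNN split into peripheral vs cardiac Doppler patterns.

Peripheral views (UA, MCA) show one-sided flow, cardiac/aortic views (AoI,
LVIO) show signal on both sides of the zero line.  A K-nearest-neighbours
classifier (K = 13) on the amplitude features ``(v_min, v_range)`` routes
each image to the matching pair classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

UA_MCA = "UA_MCA"
AOI_LVIO = "AOI_LVIO"
GROUPS = (UA_MCA, AOI_LVIO)

#: which gate group each view belongs to
VIEW_TO_GROUP = {"UA": UA_MCA, "MCA": UA_MCA, "AoI": AOI_LVIO, "LVIO": AOI_LVIO}

DEFAULT_K = 13


@dataclass
class KnnModel:
    """Fitted KNN gate: z-scaled training points, labels and K.

    Distances are Euclidean in standardized feature space; ties in distance
    are broken by training-point order (stable sort).  K is odd so a binary
    majority vote can never tie.
    """

    k: int
    points: np.ndarray  # (n, 2) standardized
    labels: np.ndarray  # (n,) strings in GROUPS
    mean: np.ndarray  # (2,)
    scale: np.ndarray  # (2,)

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                dict(
                    k=self.k,
                    points=self.points.tolist(),
                    labels=self.labels.tolist(),
                    mean=self.mean.tolist(),
                    scale=self.scale.tolist(),
                )
            )
        )

    @classmethod
    def load(cls, path) -> "KnnModel":
        d = json.loads(Path(path).read_text())
        return cls(
            k=int(d["k"]),
            points=np.asarray(d["points"], dtype=float),
            labels=np.asarray(d["labels"], dtype=object),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )


def fit_knn(features, labels, k: int = DEFAULT_K) -> KnnModel:
    """Fit the amplitude gate.

    ``features`` is an (n, 2) array of ``(v_min, v_range)`` per image and
    ``labels`` the matching group names.  Features are standardized
    per-dimension (zero mean, unit variance) before distances are taken.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"features must be (n, 2) [v_min, v_range], got {X.shape}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd to avoid vote ties, got {k}")
    if len(X) < k:
        raise ValueError(f"need at least k={k} training points, got {len(X)}")
    present = set(y.tolist())
    if len(present) < 2:
        raise ValueError(f"training data must contain both groups, got {present}")
    unknown = present - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels {unknown}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return KnnModel(k=k, points=(X - mean) / scale, labels=y, mean=mean, scale=scale)


def predict_group(model: KnnModel, features) -> tuple[str, float] | list[tuple[str, float]]:
    """Majority vote among the K nearest training points.

    Accepts a single ``(v_min, v_range)`` pair or an (n, 2) array; returns
    ``(group, vote_fraction)`` (or a list of those).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    single = np.asarray(features).ndim == 1
    Xs = (X - model.mean) / model.scale
    D = cdist(Xs, model.points)
    out = []
    for row in D:
        nn = np.argsort(row, kind="stable")[: model.k]
        votes = model.labels[nn]
        counts = {g: int(np.sum(votes == g)) for g in GROUPS}
        label = max(GROUPS, key=lambda g: counts[g])
        out.append((label, counts[label] / model.k))
    return out[0] if single else out


def gate_accuracy(model: KnnModel, features, labels) -> float:
    """Fraction of correctly grouped test points."""
    preds = predict_group(model, np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=object)
    return float(np.mean([p[0] == t for p, t in zip(preds, y)]))
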