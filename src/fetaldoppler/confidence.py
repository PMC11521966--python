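"""Keep/skip confidence models: out-of-domain rejection per view.

Images routed to a view by the upstream classifiers may actually show
other anatomies (heart valves, other vessels).  A per-view, per-dataset
confidence model embeds the Doppler (or B-mode) region with a generic
convolutional encoder, reduces the embedding by PCA to the components
explaining 85% of the variance, and classifies keep vs skip with a
gradient-boosted tree ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .views import ResidualEncoder

DEFAULT_VARIANCE_TARGET = 0.85
DEFAULT_THRESHOLD = 0.5
DEFAULT_BOOSTER_PARAMS = dict(n_estimators=300, max_depth=3, learning_rate=0.1)

_ENCODER_CACHE: dict = {}


def embedding_encoder(profile: str = "reduced", seed: int = 12345) -> ResidualEncoder:
    """Generic fixed-weight convolutional embedding encoder.

    Weights are seeded-random and deterministic; untrained convolutional
    features are a serviceable generic image descriptor for the small
    keep/skip problems this stage solves.
    """
    key = (profile, seed)
    if key not in _ENCODER_CACHE:
        _ENCODER_CACHE[key] = ResidualEncoder(profile, rng=np.random.default_rng(seed))
    return _ENCODER_CACHE[key]


def embed_image(region: np.ndarray, encoder: ResidualEncoder | None = None) -> np.ndarray:
    """Fixed-length embedding of a preprocessed region raster."""
    if encoder is None:
        encoder = embedding_encoder()
    region = np.asarray(region, dtype=np.float32)
    if region.ndim != 2:
        raise ValueError(f"expected a 2-d grayscale region, got shape {region.shape}")
    return encoder.features(region[None, :, :, None])[0]


def embed_images(regions, encoder=None) -> np.ndarray:
    if encoder is None:
        encoder = embedding_encoder()
    x = np.stack([np.asarray(r, dtype=np.float32) for r in regions])[..., None]
    return encoder.features(x)


@dataclass
class KeepSkipDecision:
    decision: str  # "keep" | "skip"
    score: float


@dataclass
class ConfidenceModel:
    """PCA projection + boosted-tree keep/skip classifier for one view."""

    view: str
    region_used: str  # "doppler" | "bmode"
    pca: PCA
    booster: object
    n_components: int
    explained_variance: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    context: str = "default"  # dataset context key
    encoder_profile: str = "reduced"
    encoder_seed: int = 12345

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ConfidenceModel":
        import joblib

        return joblib.load(path)


def minimal_components(explained_variance_ratio, variance_target: float) -> int:
    """Smallest component count whose cumulative explained variance reaches
    the target (oracle: cumulative sum)."""
    csum = np.cumsum(explained_variance_ratio)
    idx = np.searchsorted(csum, variance_target - 1e-12)
    return int(min(idx + 1, len(csum)))


def fit_confidence_model(
    embeddings,
    keep_labels,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    view: str = "",
    region_used: str = "doppler",
    booster_params: dict | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    context: str = "default",
    seed: int = 0,
) -> ConfidenceModel:
    """Fit the PCA + XGBoost keep/skip model.

    ``keep_labels`` is boolean (True = genuinely the view of interest).
    The PCA retains the minimal number of components whose cumulative
    explained variance reaches ``variance_target``.
    """
    from xgboost import XGBClassifier

    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(keep_labels, dtype=bool)
    if not (0.0 < variance_target <= 1.0):
        raise ValueError(f"variance_target must lie in (0, 1], got {variance_target}")
    if y.all() or not y.any():
        raise ValueError("need both keep and skip examples to fit a confidence model")
    pca = PCA(n_components=min(X.shape[0], X.shape[1]), random_state=seed)
    pca.fit(X)
    k = minimal_components(pca.explained_variance_ratio_, variance_target)
    evr = pca.explained_variance_ratio_.copy()
    pca = PCA(n_components=k, random_state=seed)
    Z = pca.fit_transform(X)
    params = dict(DEFAULT_BOOSTER_PARAMS, **(booster_params or {}))
    booster = XGBClassifier(random_state=seed, verbosity=0, **params)
    booster.fit(Z, y.astype(int))
    return ConfidenceModel(
        view=view,
        region_used=region_used,
        pca=pca,
        booster=booster,
        n_components=k,
        explained_variance=evr,
        threshold=threshold,
        context=context,
    )


def keep_or_skip(model: ConfidenceModel, region: np.ndarray, view: str | None = None) -> KeepSkipDecision:
    """Score one region raster; keep iff score >= threshold."""
    if view is not None and view != model.view:
        raise ValueError(f"model is for view {model.view!r}, got image routed as {view!r}")
    enc = embedding_encoder(model.encoder_profile, model.encoder_seed)
    z = model.pca.transform(embed_image(region, enc)[None, :])
    score = float(model.booster.predict_proba(z)[0, 1])
    return KeepSkipDecision(decision="keep" if score >= model.threshold else "skip", score=score)


def keep_scores(model: ConfidenceModel, regions) -> np.ndarray:
    enc = embedding_encoder(model.encoder_profile, model.encoder_seed)
    z = model.pca.transform(embed_images(regions, enc))
    return model.booster.predict_proba(z)[:, 1]


def evaluate_confidence(decisions, truth) -> dict:
    """FNR/FPR (%), AUC and keep/skip counts of a decision batch.

    ``decisions`` are :class:`KeepSkipDecision`; ``truth`` booleans (True =
    image really belongs to the view).  FNR: skipped true-view images /
    true-view images; FPR: kept other-view images / other-view images; AUC
    by the rank statistic on the keep scores.
    """
    if len(decisions) == 0 or len(decisions) != len(truth):
        raise ValueError("need equal, non-zero numbers of decisions and truth labels")
    t = np.asarray(truth, dtype=bool)
    kept = np.array([d.decision == "keep" for d in decisions])
    scores = np.array([d.score for d in decisions])
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    fnr = 100.0 * float((~kept & t).sum()) / n_pos if n_pos else np.nan
    fpr = 100.0 * float((kept & ~t).sum()) / n_neg if n_neg else np.nan
    if n_pos and n_neg:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(t, scores))
    else:
        auc = np.nan
    return dict(
        fnr_pct=fnr,
        fpr_pct=fpr,
        auc=auc,
        n_keep=int(kept.sum()),
        n_skip=int((~kept).sum()),
        n=len(decisions),
    )
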