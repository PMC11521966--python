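"""End-to-end study analysis: preprocess -> amplitude gate -> pair
classifier -> confidence keep/skip -> view-specific delineation ->
post-processing -> Doppler index report.

The stages run in a fixed order; a skip decision short-circuits the
pipeline after classification, and every report carries provenance
(model identifiers, seeds, warnings) so batch tables are regenerable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import confidence as conf
from . import delineation as dl
from . import gate
from . import indices as ix
from . import preprocessing as pre
from . import views as vw
from .synthetic import SyntheticStudy

log = logging.getLogger(__name__)


@dataclass
class ModelBundle:
    """All fitted stage models keyed by gate group / view."""

    gate_model: gate.KnnModel
    view_models: dict  # pair -> DualEncoderModel
    confidence_models: dict  # view -> ConfidenceModel
    delineators: dict  # view -> WNet
    meta: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gate_model.save(out / "gate.json")
        for pair, m in self.view_models.items():
            m.save(out / f"view_{pair}.npz")
        for view, m in self.confidence_models.items():
            m.save(out / f"confidence_{view}.joblib")
        for view, m in self.delineators.items():
            m.save(out / f"delineator_{view}.npz")
        (out / "bundle.json").write_text(
            json.dumps(
                dict(
                    meta=self.meta,
                    pairs=sorted(self.view_models),
                    confidence_views=sorted(self.confidence_models),
                    delineator_views=sorted(self.delineators),
                )
            )
        )

    @classmethod
    def load(cls, in_dir) -> "ModelBundle":
        p = Path(in_dir)
        manifest = json.loads((p / "bundle.json").read_text())
        return cls(
            gate_model=gate.KnnModel.load(p / "gate.json"),
            view_models={
                pair: vw.DualEncoderModel.load(p / f"view_{pair}.npz")
                for pair in manifest["pairs"]
            },
            confidence_models={
                v: conf.ConfidenceModel.load(p / f"confidence_{v}.joblib")
                for v in manifest["confidence_views"]
            },
            delineators={
                v: dl.WNet.load(p / f"delineator_{v}.npz")
                for v in manifest["delineator_views"]
            },
            meta=manifest.get("meta", {}),
        )

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(sorted(self.view_models)).encode())
        for p in self.gate_model.points.ravel()[:64]:
            h.update(np.float64(p).tobytes())
        return h.hexdigest()[:12]


def _as_study(obj) -> tuple[np.ndarray, np.ndarray, object, str]:
    """Normalize input to (bmode grey, doppler grey, calibration, source_id)."""
    if isinstance(obj, pre.DopplerStudyImage):
        return obj.bmode, obj.doppler, obj.calibration, obj.source_id
    if isinstance(obj, SyntheticStudy):
        b = obj.bmode
        if b is not None and b.ndim == 3:
            b = b @ np.array([0.299, 0.587, 0.114])
        return b, obj.doppler, obj.calibration, obj.study_id
    raise TypeError(f"cannot analyze object of type {type(obj).__name__}")


def analyze_study(study, bundle: ModelBundle, config: dict | None = None) -> dict:
    """Run the full pipeline on one study; returns the report dict.

    Report fields: predicted view and score, gate group and vote fraction,
    keep/skip decision and score, events, per-cycle and per-image indices,
    warnings, and provenance.  A ``skip`` decision ends the report without
    delineation fields.
    """
    config = config or {}
    bmode, doppler, cal, source_id = _as_study(study)
    report: dict = dict(source_id=source_id, warnings=[], provenance=dict(
        bundle=bundle.fingerprint(), config=config
    ))
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # stage 1: amplitude gate
        binary = pre.binarize_doppler(doppler, config.get("binarize_threshold", 0.1))
        try:
            feats = pre.extract_velocity_metrics(binary, cal)
        except ValueError as exc:
            raise RuntimeError(f"stage preprocessing failed: {exc}") from exc
        group, vote = gate.predict_group(bundle.gate_model, feats.as_array())
        report["gate"] = dict(group=group, vote_fraction=vote,
                              v_max=feats.v_max, v_min=feats.v_min, v_range=feats.v_range)

        # stage 2: pair classifier
        if group not in bundle.view_models:
            raise RuntimeError(f"stage view-classification failed: no model for group {group!r}")
        pred = vw.predict_view(bundle.view_models[group], bmode, doppler)
        report["view"] = dict(label=pred.label, score=pred.score, scores=pred.scores)

        # stage 3: confidence keep/skip
        cm = bundle.confidence_models.get(pred.label)
        if cm is not None:
            region = doppler if cm.region_used == "doppler" else bmode
            decision = conf.keep_or_skip(cm, region, view=pred.label)
            report["confidence"] = dict(decision=decision.decision, score=decision.score)
            if decision.decision == "skip":
                report["warnings"] = [str(w.message) for w in wlist]
                return report
        else:
            report["confidence"] = dict(decision="keep", score=None)

        # stage 4: delineation
        if pred.label not in bundle.delineators:
            raise RuntimeError(
                f"stage delineation failed: no delineation model for view {pred.label!r}"
            )
        mask = dl.predict_masks(bundle.delineators[pred.label], doppler)

        # stage 5: post-processing and indices
        try:
            curve, events = ix.postprocess_masks(mask, cal)
            idx_report = ix.compute_report(curve, events, pred.label)
            report["events"] = [asdict(e) for e in events]
            report["indices"] = dict(
                per_cycle=idx_report.per_cycle,
                medians=idx_report.medians,
                n_cycles=len(idx_report.per_cycle),
            )
            report["warnings"].extend(idx_report.warnings)
        except ValueError as exc:
            report["warnings"].append(f"post-processing: {exc}")
        report["warnings"].extend(str(w.message) for w in wlist)
    return report


def train_bundle(
    studies,
    seed: int = 0,
    view_epochs: int = 6,
    delineation_epochs: int = 12,
    delineator_views=None,
    include_confidence: bool = True,
) -> ModelBundle:
    """Fit every pipeline stage from a list of synthetic studies.

    Expects studies of the four target views (plus OTHER examples when
    confidence models are requested).  Stage scale is controlled by the
    epoch arguments so desk-scale bundles stay cheap.
    """
    from .training import TrainConfig
    from .synthetic import VIEWS

    by_view: dict[str, list] = {}
    for st in studies:
        by_view.setdefault(st.view, []).append(st)

    # amplitude gate on (v_min, v_range)
    feats, labels = [], []
    for v in VIEWS:
        for st in by_view.get(v, []):
            binary = pre.binarize_doppler(st.doppler)
            f = pre.extract_velocity_metrics(binary, st.calibration)
            feats.append(f.as_array())
            labels.append(gate.VIEW_TO_GROUP[v])
    gate_model = gate.fit_knn(np.array(feats), labels)

    def grey(st):
        b = st.bmode
        return b @ np.array([0.299, 0.587, 0.114]) if b.ndim == 3 else b

    view_models = {}
    for pair, (c0, c1) in vw.PAIR_CLASSES.items():
        samples = [(grey(st), st.doppler, 0) for st in by_view.get(c0, [])]
        samples += [(grey(st), st.doppler, 1) for st in by_view.get(c1, [])]
        if not samples:
            continue
        rng = np.random.default_rng(seed)
        rng.shuffle(samples)
        n_val = max(2, len(samples) // 5)
        cfg = TrainConfig(epochs=view_epochs, seed=seed, batch_size=8)
        model, _ = vw.train_view_classifier(samples[n_val:], samples[:n_val], cfg, pair=pair)
        view_models[pair] = model

    confidence_models = {}
    if include_confidence and by_view.get("OTHER"):
        others = [st.doppler for st in by_view["OTHER"]]
        for v in VIEWS:
            if not by_view.get(v):
                continue
            keeps = [st.doppler for st in by_view[v]]
            emb = conf.embed_images(keeps + others)
            y = np.array([True] * len(keeps) + [False] * len(others))
            confidence_models[v] = conf.fit_confidence_model(
                emb, y, view=v, region_used="doppler", seed=seed
            )

    delineators = {}
    for v in delineator_views or [v for v in VIEWS if by_view.get(v)]:
        pairs = [
            (st.doppler, dl.encode_truth_mask(st.truth, v, st.calibration).channels)
            for st in by_view.get(v, [])
        ]
        if not pairs:
            continue
        cfg = TrainConfig(epochs=delineation_epochs, seed=seed, crop_size=96)
        model, _ = dl.train_delineator(pairs, v, cfg)
        delineators[v] = model

    return ModelBundle(
        gate_model=gate_model,
        view_models=view_models,
        confidence_models=confidence_models,
        delineators=delineators,
        meta=dict(seed=seed, n_studies=len(studies)),
    )


def analyze_batch(studies, bundle: ModelBundle, config: dict | None = None):
    """Analyze a batch; failures are logged per study, not fatal.

    Returns ``(DataFrame with one row per study, list of report dicts)``.
    """
    rows, reports = [], []
    n_fail = 0
    for study in studies:
        try:
            rep = analyze_study(study, bundle, config)
        except Exception as exc:  # noqa: BLE001 — batch must survive bad studies
            sid = getattr(study, "study_id", getattr(study, "source_id", "?"))
            log.error("study %s failed: %s", sid, exc)
            rows.append(dict(source_id=sid, status="error", error=str(exc)))
            n_fail += 1
            continue
        reports.append(rep)
        row = dict(
            source_id=rep["source_id"],
            status="skip" if rep.get("confidence", {}).get("decision") == "skip" else "ok",
            gate_group=rep["gate"]["group"],
            view=rep["view"]["label"],
            view_score=rep["view"]["score"],
            keep_score=rep.get("confidence", {}).get("score"),
        )
        for k, v in rep.get("indices", {}).get("medians", {}).items():
            row[f"median_{k}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    log.info("analyzed %d studies (%d failed)", len(studies), n_fail)
    return df, reports
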