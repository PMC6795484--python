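"""Train-on-year-1 / test-on-year-2 experiment driver.

Mirrors the deployment scenario: the vocabulary and every model are fit
on the training year only; the held-out year is vectorized with the
training-year vocabulary (unseen n-grams contribute nothing) and scored.
The comparison report carries PPV/sensitivity/specificity/F and the
confusion matrix per method, plus one-tailed pooled two-proportion
z-tests comparing the best ML model against the rule baseline on
sensitivity and PPV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .certificates import (
    DeathCertificate,
    FieldSet,
    combine_fields,
    read_certificates,
)
from .errors import ConfigurationError, ValidationError
from .evaluation import (
    EvaluationReport,
    ProportionTestResult,
    confusion,
    format_report_table,
    metrics,
    two_proportion_z_test,
)
from .features import VectorizerConfig, Vocabulary, fit_vocabulary, transform
from .models import (
    CVConfig,
    DEFAULT_GRIDS,
    ModelSpec,
    TrainedModel,
    config_hash,
    train_final,
    tune,
)
from .rules import PhraseList, default_phrases, load_phrases, rule_predict

__all__ = ["ComparisonReport", "RunConfig", "fit_pipeline", "predict_unlabeled", "run_experiment"]

log = logging.getLogger("odcert")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a full experiment run."""

    seed: int = 0
    field_set: FieldSet = FieldSet.NO_SCC
    vectorizer: VectorizerConfig = dc_field(default_factory=VectorizerConfig)
    families: tuple[str, ...] = ("linear_svm", "random_forest", "mlp")
    grids: Mapping[str, Mapping[str, list]] = dc_field(default_factory=dict)
    cv_k: int = 10
    cv_repeats: int = 3
    max_rounds: int = 5
    tol: float = 1e-3
    phrase_path: Optional[str] = None
    column_map: Mapping[str, str] = dc_field(default_factory=dict)

    def cv(self) -> CVConfig:
        return CVConfig(k=self.cv_k, repeats=self.cv_repeats, seed=self.seed)

    def spec_for(self, family: str) -> ModelSpec:
        grid = self.grids.get(family, DEFAULT_GRIDS[family])
        return ModelSpec(family, grid)

    def phrases(self) -> PhraseList:
        if self.phrase_path:
            return load_phrases(self.phrase_path)
        return default_phrases()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "field_set": self.field_set.value,
            "vectorizer": self.vectorizer.to_dict(),
            "families": list(self.families),
            "grids": {f: dict(g) for f, g in self.grids.items()},
            "cv_k": self.cv_k,
            "cv_repeats": self.cv_repeats,
            "max_rounds": self.max_rounds,
            "tol": self.tol,
            "phrase_path": self.phrase_path,
            "column_map": dict(self.column_map),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "field_set" in d:
            d["field_set"] = FieldSet(d["field_set"])
        if "vectorizer" in d and not isinstance(d["vectorizer"], VectorizerConfig):
            d["vectorizer"] = VectorizerConfig.from_dict(d["vectorizer"])
        if "families" in d:
            d["families"] = tuple(d["families"])
        if "grids" in d:
            d["grids"] = {
                fam: {
                    k: [tuple(v) if isinstance(v, list) and k == "hidden_layer_sizes" else v for v in vals]
                    for k, vals in grid.items()
                }
                for fam, grid in d["grids"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        return cls.from_dict(payload)

    def content_hash(self) -> str:
        return config_hash(self.to_dict())


@dataclass
class ComparisonReport:
    """Per-method evaluation plus the ML-vs-rule significance tests."""

    reports: dict[str, EvaluationReport]
    best_ml: str
    z_sensitivity: Optional[ProportionTestResult]
    z_ppv: Optional[ProportionTestResult]
    config: dict
    n_train: int
    n_test: int

    def render_text(self) -> str:
        lines = [
            f"Train records: {self.n_train}   Test records: {self.n_test}",
            f"Field set: {self.config.get('field_set')}",
            "",
            format_report_table(self.reports),
            "",
            f"Best ML model: {self.best_ml}",
        ]
        if self.z_sensitivity is not None:
            lines.append(
                f"Sensitivity, {self.best_ml} vs rule_based: "
                f"z = {self.z_sensitivity.z:.4f}, one-tailed p = {self.z_sensitivity.p:.4g}"
            )
        if self.z_ppv is not None:
            lines.append(
                f"PPV, {self.best_ml} vs rule_based: "
                f"z = {self.z_ppv.z:.4f}, one-tailed p = {self.z_ppv.p:.4g}"
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        out: dict = {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "config": self.config,
            "methods": {name: rep.to_dict() for name, rep in self.reports.items()},
            "best_ml": self.best_ml,
        }
        for key, test in (("sensitivity", self.z_sensitivity), ("ppv", self.z_ppv)):
            if test is not None:
                out[f"z_test_{key}"] = {"z": test.z, "p": test.p, "degenerate": test.degenerate}
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _load(source) -> list[DeathCertificate]:
    if isinstance(source, (str, Path)):
        return read_certificates(source)
    return list(source)


def _texts(certs: Sequence[DeathCertificate], fs: FieldSet) -> list[str]:
    return [combine_fields(dc, fs) for dc in certs]


def _labels(certs: Sequence[DeathCertificate], role: str) -> np.ndarray:
    missing = sum(1 for dc in certs if dc.label is None)
    if missing:
        raise ConfigurationError(
            f"{missing} {role} records lack a UCOD-derived label; "
            "labeled data is required here — use `predict` for unlabeled deployment"
        )
    return np.array([bool(dc.label) for dc in certs])


def fit_pipeline(
    train: Sequence[DeathCertificate], cfg: RunConfig
) -> tuple[Vocabulary, dict[str, TrainedModel]]:
    """Fit vocabulary and all requested model families on training data only.

    The test year is deliberately not an argument: nothing downstream of
    it can leak into the vocabulary, the grids, or the tuning.
    """
    texts = _texts(train, cfg.field_set)
    y = _labels(train, "training")
    vocab = fit_vocabulary(texts, cfg.vectorizer)
    log.info("featureization: %d records, %d features kept", len(texts), vocab.size)
    X = transform(texts, vocab)
    cv = cfg.cv()
    models: dict[str, TrainedModel] = {}
    for family in cfg.families:
        spec = cfg.spec_for(family)
        params, score, history = tune(
            X, y, spec, cv, max_rounds=cfg.max_rounds, tol=cfg.tol
        )
        log.info(
            "%s: tuned over %d round(s), CV F = %.4f at %s",
            family, len(history), score, params,
        )
        models[family] = train_final(
            X,
            y,
            family,
            params,
            seed=cfg.seed,
            vocabulary=vocab,
            field_set=cfg.field_set,
            cfg_hash=cfg.content_hash(),
        )
    return vocab, models


def run_experiment(train_source, test_source, cfg: RunConfig) -> ComparisonReport:
    """Full experiment: fit on year 1, evaluate every method on year 2."""
    train = _load(train_source)
    test = _load(test_source)
    log.info("loaded %d training and %d test records", len(train), len(test))
    _labels(test, "test")  # fail early, before spending time on training
    vocab, models = fit_pipeline(train, cfg)

    test_texts = _texts(test, cfg.field_set)
    y_test = _labels(test, "test")
    X_test = transform(test_texts, vocab)

    reports: dict[str, EvaluationReport] = {}
    for family, model in models.items():
        reports[family] = metrics(confusion(y_test, model.predict(X_test)))
    phrases = cfg.phrases()
    rule_pred = rule_predict(test_texts, phrases)
    reports["rule_based"] = metrics(confusion(y_test, rule_pred))
    log.info("evaluated %d methods on %d test records", len(reports), len(test))

    ml_reports = {f: reports[f] for f in models}
    best_ml = max(
        ml_reports,
        key=lambda f: (ml_reports[f].f_score if ml_reports[f].f_score is not None else -1.0, f),
    )
    rule_rep = reports["rule_based"]
    best_rep = reports[best_ml]
    z_sens = two_proportion_z_test(
        best_rep.cm.tp, best_rep.cm.n_positive, rule_rep.cm.tp, rule_rep.cm.n_positive
    )
    z_ppv = None
    if best_rep.cm.n_predicted_positive and rule_rep.cm.n_predicted_positive:
        z_ppv = two_proportion_z_test(
            best_rep.cm.tp,
            best_rep.cm.n_predicted_positive,
            rule_rep.cm.tp,
            rule_rep.cm.n_predicted_positive,
        )
    return ComparisonReport(
        reports=reports,
        best_ml=best_ml,
        z_sensitivity=z_sens,
        z_ppv=z_ppv,
        config=cfg.to_dict(),
        n_train=len(train),
        n_test=len(test),
    )


def predict_unlabeled(
    source, model: TrainedModel
) -> pd.DataFrame:
    """Apply a trained model to (possibly unlabeled) certificates.

    Returns a frame with the record id, predicted label, the family's
    decision score where available, and a ``flag`` column marking records
    whose combined text yields no features at all.
    """
    certs = _load(source)
    fs = model.field_set or FieldSet.NO_SCC
    texts = _texts(certs, fs)
    if model.vocabulary is None:
        raise ConfigurationError("model artifact carries no vocabulary")
    X = transform(texts, model.vocabulary)
    preds = model.predict(X)
    scores = model.decision_scores(X)
    row_feature_counts = np.asarray(X.sum(axis=1)).ravel() if X.shape[1] else np.zeros(len(certs))
    flags = ["no features" if c == 0 else "" for c in row_feature_counts]
    out = pd.DataFrame(
        {
            "id": [dc.id for dc in certs],
            "predicted_overdose": [int(p) for p in preds],
            "flag": flags,
        }
    )
    if scores is not None:
        out.insert(2, "decision_score", scores)
    return out
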