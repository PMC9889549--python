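"""Model/Results interface over the training engine.

:class:`DiseaseRiskModel` is constructed from data (a :class:`PairedDataset`
or raw arrays / a DataFrame of clinical features), configured with a
:class:`TrainConfig`, and fitted with :meth:`fit` (one model on all data) or
:meth:`fit_cv` (stratified cross-validation).  Both return a
:class:`DiseaseRiskResults` carrying the fitted parameters, the loss trace,
the evaluation metrics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .metrics import MetricsReport, aggregate_folds, confusion_matrix, multiclass_metrics
from .synthetic import PairedDataset
from .training import LossTrace, TrainConfig, TrainedModel, cross_validate, train_model

__all__ = ["DiseaseRiskModel", "DiseaseRiskResults"]


class DiseaseRiskModel:
    """Multimodal disease-risk classifier bound to a dataset.

    Parameters
    ----------
    dataset:
        Paired volumes + clinical records + labels.
    config:
        Optimization and architecture settings; defaults follow the
        published protocol at desk scale.
    """

    def __init__(self, dataset: PairedDataset, config: TrainConfig | None = None):
        self.dataset = dataset
        self.config = config or TrainConfig()

    @classmethod
    def from_arrays(cls, volumes, ehr, labels, config: TrainConfig | None = None):
        return cls(PairedDataset(volumes, ehr, labels), config)

    @classmethod
    def from_dataframe(cls, volumes, frame: pd.DataFrame, label_col: str = "label",
                       config: TrainConfig | None = None):
        """Clinical features from a DataFrame: every non-label numeric column
        is a feature; ``label_col`` holds the integer class."""
        feats = frame.drop(columns=[label_col]).select_dtypes("number")
        return cls(PairedDataset(volumes, feats.to_numpy(float),
                                 frame[label_col].to_numpy(int)), config)

    def fit(self, max_steps: int | None = None) -> "DiseaseRiskResults":
        """Train one model on the full dataset; in-sample metrics are
        reported as a single 'fold'."""
        trained, trace = train_model(self.dataset, self.config, max_steps=max_steps)
        probs = trained.predict_proba(self.dataset.volumes, self.dataset.ehr)
        cm = confusion_matrix(self.dataset.labels, probs.argmax(-1), self.dataset.n_classes)
        fold = multiclass_metrics(cm, scores=probs, labels=self.dataset.labels)
        report = aggregate_folds([fold])
        return DiseaseRiskResults(self, trained, trace, report, in_sample=True)

    def fit_cv(self) -> "DiseaseRiskResults":
        """Stratified k-fold cross-validation; also fits a final model on the
        full dataset for downstream prediction and attention export."""
        report, per_fold = cross_validate(self.dataset, self.config, return_folds=True)
        trained, trace = train_model(self.dataset, self.config)
        res = DiseaseRiskResults(self, trained, trace, report, in_sample=False)
        res.per_fold = per_fold
        return res


class DiseaseRiskResults:
    """Fitted-model container: trained parameters, loss trace, metrics."""

    def __init__(self, model: DiseaseRiskModel, trained: TrainedModel,
                 trace: LossTrace, metrics: MetricsReport, in_sample: bool):
        self.model = model
        self.trained = trained
        self.loss_trace = trace
        self.metrics = metrics
        self.in_sample = in_sample
        self.per_fold: list[dict] | None = None

    @property
    def final_loss(self) -> float:
        return self.loss_trace.loss[-1]

    def predict_proba(self, volumes, ehr) -> np.ndarray:
        return self.trained.predict_proba(volumes, ehr)

    def predict(self, volumes, ehr) -> np.ndarray:
        return self.trained.predict(volumes, ehr)

    def save(self, path):
        self.trained.save(path)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Disease-risk fusion model",
            "=" * 60,
            f"variant: {cfg.fusion_variant}   SAM={cfg.sam} TAM={cfg.tam} CAM={cfg.cam}",
            f"classes: {self.model.dataset.n_classes}   samples: {len(self.model.dataset)}"
            f"   heads: {cfg.n_heads}   channels: {cfg.channels}",
            f"optimizer: SGD(lr0={cfg.initial_lr}, momentum={cfg.momentum}, "
            f"wd={cfg.weight_decay}, poly power={cfg.power})",
            f"evaluation: {'in-sample (single fit)' if self.in_sample else str(cfg.n_folds) + '-fold stratified CV'}",
            "-" * 60,
            f"{'metric':<14}{'mean':>10}{'std':>10}",
        ]
        for name in ("sensitivity", "accuracy", "specificity", "auroc"):
            m, s = getattr(self.metrics, name)
            lines.append(f"{name:<14}{m:>10.3f}{s:>10.3f}")
        lines.append("-" * 60)
        lines.append(f"final training loss: {self.final_loss:.4f} "
                     f"({len(self.loss_trace.loss)} steps)")
        return "\n".join(lines)
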