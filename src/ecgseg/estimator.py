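"""Scikit-learn style estimator wrapping the full detection pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .masks import MaskWindows
from .network import ModelConfig, UNet1d
from .postprocess import PostprocessConfig, beats_from_mask, merge_leads
from .records import ECGRecord
from .training import TrainConfig, train, validate


class BeatSegmenter(BaseEstimator):
    """End-to-end beat detector: segmentation U-Net + mask post-processing.

    Follows the scikit-learn estimator protocol: hyperparameters are
    constructor arguments, ``fit`` trains on annotated records, ``predict``
    returns beat detections, and fitted state lives in trailing-underscore
    attributes (``model_``, ``history_``).

    Parameters
    ----------
    base_filters : int
        Encoder width of the first stage (doubles per stage).
    blocks_per_stage : tuple of int
        ConvNeXt V2 block count per encoder stage.
    epochs, batch_size, lr_max : training budget and one-cycle peak rate.
    qrs_threshold : float
        Post-processing threshold on the QRS (1 - background) mask.
    val_fraction : float
        Trailing fraction of the training set held out for early stopping
        when ``fit`` is not given an explicit validation set.
    augment : bool
        Apply the training-time augmentation stack.
    seed : int
        Master seed for initialization, sampling and augmentation.

    Examples
    --------
    >>> seg = BeatSegmenter(epochs=2, seed=0)
    >>> seg.fit(records, annotations)  # doctest: +SKIP
    >>> beats = seg.predict(records[0])  # doctest: +SKIP
    """

    def __init__(
        self,
        base_filters: int = 16,
        blocks_per_stage: tuple = (1, 1, 1, 1),
        epochs: int = 10,
        batch_size: int = 8,
        lr_max: float = 1e-3,
        early_stop_patience: int = 3,
        oversample_pvc: float = 4.0,
        oversample_pac: float = 4.0,
        qrs_threshold: float = 0.9,
        min_duration_ms: float = 40.0,
        tol_ms: float = 75.0,
        val_fraction: float = 0.15,
        augment: bool = True,
        seed: int = 0,
    ):
        self.base_filters = base_filters
        self.blocks_per_stage = blocks_per_stage
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_max = lr_max
        self.early_stop_patience = early_stop_patience
        self.oversample_pvc = oversample_pvc
        self.oversample_pac = oversample_pac
        self.qrs_threshold = qrs_threshold
        self.min_duration_ms = min_duration_ms
        self.tol_ms = tol_ms
        self.val_fraction = val_fraction
        self.augment = augment
        self.seed = seed

    # -- config assembly ----------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            base_filters=self.base_filters,
            blocks_per_stage=tuple(self.blocks_per_stage),
        )

    def _train_config(self) -> TrainConfig:
        from .augment import AugmentConfig
        from .records import PAC, PVC

        return TrainConfig(
            lr_init=self.lr_max,
            lr_max=self.lr_max,
            batch_size=self.batch_size,
            epochs=self.epochs,
            early_stop_patience=self.early_stop_patience,
            oversample_factors={PVC: self.oversample_pvc, PAC: self.oversample_pac},
            tol_ms=self.tol_ms,
            seed=self.seed,
            augment=AugmentConfig() if self.augment else None,
        )

    def _post_config(self) -> PostprocessConfig:
        return PostprocessConfig(
            qrs_threshold=self.qrs_threshold,
            min_duration_ms=self.min_duration_ms,
        )

    # -- estimator protocol -------------------------------------------------
    def fit(self, X, y, validation=None):
        """Train on annotated records.

        Parameters
        ----------
        X : list of ECGRecord
        y : list of list of BeatAnnotation
            Ground-truth beats, one list per record.
        validation : optional (X_val, y_val) tuple for early stopping;
            otherwise the trailing ``val_fraction`` of (X, y) is held out.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        data = list(zip(X, y))
        if validation is not None:
            train_data = data
            val_data = list(zip(validation[0], validation[1]))
        else:
            n_val = max(int(round(self.val_fraction * len(data))), 1)
            if len(data) <= n_val:
                raise ValueError("not enough records to hold out a validation split")
            train_data, val_data = data[:-n_val], data[-n_val:]
        model = UNet1d(self._model_config(), seed=self.seed)
        self.model_, self.history_ = train(
            model, train_data, val_data, self._train_config()
        )
        self.n_features_in_ = 1
        return self

    def predict_proba_mask(self, record: ECGRecord):
        """Per-lead probability masks for one record."""
        self._check_fitted()
        return [
            self.model_.predict_proba(record.lead(i), fs=record.fs)
            for i in range(record.n_leads)
        ]

    def predict_record(self, record: ECGRecord):
        """Beat detections for one record (multi-lead voting when >1 lead)."""
        self._check_fitted()
        cfg = self._post_config()
        per_lead = [beats_from_mask(p, cfg) for p in self.predict_proba_mask(record)]
        return merge_leads(per_lead, cfg, fs=record.fs)

    def predict(self, X):
        """Beat detections for a list of records (or a single record)."""
        self._check_fitted()
        if isinstance(X, ECGRecord):
            return self.predict_record(X)
        return [self.predict_record(rec) for rec in X]

    def score(self, X, y):
        """Mean of PVC and PAC F1 over the given annotated records
        (the early-stopping metric)."""
        self._check_fitted()
        report, _ = validate(
            self.model_, list(zip(X, y)), tol_ms=self.tol_ms,
            post_config=self._post_config(),
        )
        from .records import CLASS_NAMES, PAC, PVC

        vals = [report.metrics[CLASS_NAMES[c]]["F1"] for c in (PVC, PAC)]
        return float(np.mean([0.0 if v is None else v for v in vals]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("BeatSegmenter is not fitted; call fit() first")
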