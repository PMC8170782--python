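"""scikit-learn estimator facade over the graph network and training loop."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import PriorFeatureSet
from .model import ModelConfig
from .training import TrainConfig, predict_from_checkpoint, train

__all__ = ["GraphProteinRegressor"]


class GraphProteinRegressor(BaseEstimator, RegressorMixin):
    """Multi-output regressor predicting protein abundances from RNA.

    A two-layer encoder produces a per-cell RNA representation; N per-protein
    heads, an optional prior-knowledge embedding of protein–protein
    association scores, one sigmoid graph-propagation round over a trainable
    adjacency, and a PReLU predictor map it to N (possibly negative,
    log-scale) abundances.  Trained by Adam on a summed-per-cell MSE with
    best-epoch checkpointing.

    Parameters
    ----------
    priors : PriorFeatureSet or array of shape (M, N, N), optional
        Prior association score matrices.  When None, the knowledge
        embedding is disabled and nodes carry only the learned RNA heads.
    hidden : pair of int, default (1024, 128)
        Encoder hidden sizes.
    d_r, d_c : int
        Width of the per-protein RNA representation and of the knowledge
        channel encoding (d_k = N * d_c).
    epochs, batch_size, learning_rate, optimizer
        Optimization settings; defaults follow the published configuration.
    per_protein_predictor : bool
        Use one predictor per protein instead of a single shared map.
    random_state : int, default 0
        Seeds initialization and batch shuffling.

    Attributes
    ----------
    checkpoint_ : Checkpoint
        Best-epoch parameter snapshot (lowest epoch-level training loss).
    loss_history_ : list of float
        Per-epoch training loss.
    best_epoch_, best_loss_ : int, float
        Location and value of the minimum of ``loss_history_``.
    n_features_in_, n_outputs_ : int
    """

    def __init__(
        self,
        priors=None,
        hidden=(1024, 128),
        d_r: int = 64,
        d_c: int = 32,
        epochs: int = 350,
        batch_size: int = 32,
        learning_rate: float = 1e-6,
        optimizer: str = "adam",
        prelu_slope: float = 0.25,
        share_encoders: bool = True,
        per_protein_predictor: bool = False,
        random_state: int = 0,
    ):
        self.priors = priors
        self.hidden = hidden
        self.d_r = d_r
        self.d_c = d_c
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.prelu_slope = prelu_slope
        self.share_encoders = share_encoders
        self.per_protein_predictor = per_protein_predictor
        self.random_state = random_state

    def _prior_matrices(self, n_proteins: int) -> np.ndarray | None:
        if self.priors is None:
            return None
        if isinstance(self.priors, PriorFeatureSet):
            mats = self.priors.matrices
        else:
            mats = np.asarray(self.priors, dtype=np.float64)
        if mats.ndim != 3 or mats.shape[1:] != (n_proteins, n_proteins):
            raise ValueError(
                f"priors must be (M, {n_proteins}, {n_proteins}), got {mats.shape}"
            )
        return mats

    def fit(self, X, y):
        X = check_array(X, dtype=np.float64)
        y = check_array(y, dtype=np.float64, ensure_2d=True)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of cells")
        priors = self._prior_matrices(y.shape[1])
        config = ModelConfig(
            n_genes=X.shape[1],
            n_proteins=y.shape[1],
            n_prior_features=1 if priors is None else priors.shape[0],
            hidden=tuple(self.hidden),
            d_r=self.d_r,
            d_c=self.d_c,
            prelu_slope=self.prelu_slope,
            use_prior=priors is not None,
            share_encoders=self.share_encoders,
            per_protein_predictor=self.per_protein_predictor,
        )
        tc = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
            optimizer=self.optimizer,
        )
        self.checkpoint_, self.loss_history_ = train(X, y, priors, config, tc)
        self.best_epoch_ = self.checkpoint_.epoch
        self.best_loss_ = self.checkpoint_.loss
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "checkpoint_")
        X = check_array(X, dtype=np.float64)
        return predict_from_checkpoint(self.checkpoint_, X)
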