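"""Sigmoid-output matrix factorization of the drug-disease association matrix.

The association score of drug *i* and disease *j* is

    F_ij = sigmoid(a_i . b_j)

where ``a_i`` and ``b_j`` are rows of the factor matrices ``A`` (drugs x k)
and ``B`` (diseases x k). Integrating the genomic space means *warm-starting*
A and B from the network-derived drug/disease feature vectors instead of
random values; training then minimizes the L2-regularized squared loss over
labeled pairs by stochastic gradient descent.

:class:`MatrixFactorization` is a scikit-learn-style estimator (``fit`` /
``decision_function`` / ``predict_proba``; fitted attributes ``A_``, ``B_``,
``loss_trace_``). The module-level functions (:func:`init_model`,
:func:`predict`, :func:`loss`, :func:`sgd_epoch`, :func:`train`) are thin
wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._sgd import objective, sgd_epoch_inplace, sigmoid_scores
from .network import FeatureSpace

#: Training defaults: L2 regularization and SGD learning rate.
DEFAULT_LAMBDA = 2.0 ** -7
DEFAULT_ETA = 2.0 ** -4
DEFAULT_MAX_EPOCHS = 500
DEFAULT_TOL = 1e-5


@dataclass(frozen=True)
class LabeledPairSet:
    """Labeled (drug index, disease index) samples; labels in {0, 1}.

    A (drug, disease) pair may appear at most once.
    """

    drug_idx: np.ndarray = field(repr=False)
    disease_idx: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def __post_init__(self):
        di = np.asarray(self.drug_idx, dtype=np.intp)
        si = np.asarray(self.disease_idx, dtype=np.intp)
        y = np.asarray(self.labels, dtype=np.float64)
        if not (di.shape == si.shape == y.shape) or di.ndim != 1:
            raise ValueError("index and label arrays must be 1-D of equal length")
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("labels must be 0 or 1")
        if len(set(zip(di.tolist(), si.tolist()))) != len(di):
            raise ValueError("duplicate (drug, disease) pairs in sample set")
        object.__setattr__(self, "drug_idx", di)
        object.__setattr__(self, "disease_idx", si)
        object.__setattr__(self, "labels", y)

    @classmethod
    def from_samples(cls, samples) -> "LabeledPairSet":
        """Build from an iterable of (drug_index, disease_index, label)."""
        samples = list(samples)
        if samples:
            di, si, y = (np.array(x) for x in zip(*samples))
        else:
            di = si = y = np.empty(0)
        return cls(drug_idx=di, disease_idx=si, labels=y)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask_or_idx) -> "LabeledPairSet":
        return LabeledPairSet(
            drug_idx=self.drug_idx[mask_or_idx],
            disease_idx=self.disease_idx[mask_or_idx],
            labels=self.labels[mask_or_idx],
        )

    def concat(self, other: "LabeledPairSet") -> "LabeledPairSet":
        return LabeledPairSet(
            drug_idx=np.concatenate([self.drug_idx, other.drug_idx]),
            disease_idx=np.concatenate([self.disease_idx, other.disease_idx]),
            labels=np.concatenate([self.labels, other.labels]),
        )

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.drug_idx.tolist(), self.disease_idx.tolist()))


class MatrixFactorization(BaseEstimator):
    """Drug-disease association model F_ij = sigmoid(a_i . b_j).

    Parameters
    ----------
    k : latent dimension (columns of A and B).
    lambda_reg : L2 regularization coefficient (lambda).
    eta : SGD learning rate.
    max_epochs, tol : stopping rule — training ends when the relative change
        of the full objective between epochs falls below ``tol``, or after
        ``max_epochs`` epochs.
    init : ``"warm"`` copies the genomic-space feature matrices passed to
        :meth:`warm_start` (or ``fit``'s ``A_init``/``B_init``); ``"random"``
        draws entries from Uniform(-init_scale, +init_scale).
    n_drugs, n_diseases : factor matrix row counts; required for random
        init when they cannot be inferred.
    random_state : seed for the per-epoch sample shuffle (and random init).

    Attributes
    ----------
    A_, B_ : fitted factor matrices.
    loss_trace_ : objective value after each epoch (index 0 = warm-start loss).
    n_epochs_ : number of SGD epochs run.
    """

    def __init__(
        self,
        k: int = 32,
        lambda_reg: float = DEFAULT_LAMBDA,
        eta: float = DEFAULT_ETA,
        max_epochs: int = DEFAULT_MAX_EPOCHS,
        tol: float = DEFAULT_TOL,
        init: str = "warm",
        init_scale: float = 0.1,
        n_drugs: int | None = None,
        n_diseases: int | None = None,
        random_state: int = 0,
    ):
        self.k = k
        self.lambda_reg = lambda_reg
        self.eta = eta
        self.max_epochs = max_epochs
        self.tol = tol
        self.init = init
        self.init_scale = init_scale
        self.n_drugs = n_drugs
        self.n_diseases = n_diseases
        self.random_state = random_state

    # -- initialization ----------------------------------------------------

    def warm_start(self, A0: np.ndarray, B0: np.ndarray) -> "MatrixFactorization":
        """Set the factor matrices (copies); returns self."""
        A0 = np.asarray(A0, dtype=np.float64)
        B0 = np.asarray(B0, dtype=np.float64)
        if A0.ndim != 2 or B0.ndim != 2 or A0.shape[1] != B0.shape[1]:
            raise ValueError(
                f"factor matrices must share the latent dimension "
                f"(got k={A0.shape[-1]} and k={B0.shape[-1]})"
            )
        if not (np.isfinite(A0).all() and np.isfinite(B0).all()):
            raise ValueError("factor matrices must be finite")
        self.A_ = A0.copy()
        self.B_ = B0.copy()
        self.k = A0.shape[1]
        return self

    def _random_init(self, seed) -> None:
        if self.n_drugs is None or self.n_diseases is None:
            raise ValueError("random init requires n_drugs and n_diseases")
        rng = np.random.default_rng(seed)
        self.A_ = rng.uniform(-self.init_scale, self.init_scale, (self.n_drugs, self.k))
        self.B_ = rng.uniform(-self.init_scale, self.init_scale, (self.n_diseases, self.k))

    # -- training ----------------------------------------------------------

    def fit(self, X, y, A_init=None, B_init=None) -> "MatrixFactorization":
        """Train on integer pair indices ``X`` (n x 2) with binary labels ``y``."""
        X = np.asarray(X, dtype=np.intp)
        samples = LabeledPairSet(drug_idx=X[:, 0], disease_idx=X[:, 1], labels=np.asarray(y))
        if A_init is not None or B_init is not None:
            self.warm_start(A_init, B_init)
        elif self.init == "random" or not hasattr(self, "A_"):
            if self.init == "warm" and not hasattr(self, "A_"):
                raise ValueError("init='warm' requires warm_start() or A_init/B_init")
            self._random_init(self.random_state)
        self._train(samples, seed=self.random_state)
        return self

    def _train(self, samples: LabeledPairSet, seed: int) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.eta <= 0:
            raise ValueError("learning rate eta must be positive")
        A, B = self.A_, self.B_
        di, si, y = samples.drug_idx, samples.disease_idx, samples.labels
        if len(samples):
            if di.max() >= A.shape[0] or si.max() >= B.shape[0]:
                raise IndexError("sample indices exceed factor matrix rows")
        rng = np.random.default_rng(seed)
        prev = objective(A, B, di, si, y, self.lambda_reg)
        trace = [prev]
        n_epochs = 0
        for epoch in range(self.max_epochs):
            if len(samples) == 0:
                break
            order = rng.permutation(len(samples))
            sgd_epoch_inplace(A, B, di, si, y, order, self.eta, self.lambda_reg)
            cur = objective(A, B, di, si, y, self.lambda_reg)
            if not np.isfinite(cur):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            trace.append(cur)
            n_epochs = epoch + 1
            if abs(prev - cur) / max(prev, 1e-12) < self.tol:
                break
            prev = cur
        self.loss_trace_ = np.array(trace)
        self.n_epochs_ = n_epochs

    # -- prediction --------------------------------------------------------

    def _check_pairs(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=np.intp)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (drug, disease) indices")
        di, si = X[:, 0], X[:, 1]
        if len(di) and (
            di.min() < 0 or si.min() < 0
            or di.max() >= self.A_.shape[0] or si.max() >= self.B_.shape[0]
        ):
            raise IndexError("pair index out of range")
        return di, si

    def decision_function(self, X) -> np.ndarray:
        """Raw dot products a_i . b_j (monotone in the association score)."""
        di, si = self._check_pairs(X)
        return np.einsum("ij,ij->i", self.A_[di], self.B_[si])

    def predict_proba(self, X) -> np.ndarray:
        """Association scores F_ij, strictly inside (0, 1)."""
        di, si = self._check_pairs(X)
        return sigmoid_scores(self.A_, self.B_, di, si)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def score_matrix(self) -> np.ndarray:
        """Full N_u x N_s scoring matrix F."""
        z = np.clip(self.A_ @ self.B_.T, -30.0, 30.0)
        return 1.0 / (1.0 + np.exp(-z))


# -- thin functional wrappers ----------------------------------------------


def init_model(
    drug_space: FeatureSpace,
    disease_space: FeatureSpace,
    lambda_reg: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
    **kwargs,
) -> MatrixFactorization:
    """Warm-start a model from drug/disease feature spaces (copy semantics)."""
    if drug_space.k != disease_space.k:
        raise ValueError(
            f"feature spaces must share the latent dimension "
            f"(got k={drug_space.k} and k={disease_space.k})"
        )
    model = MatrixFactorization(
        k=drug_space.k, lambda_reg=lambda_reg, eta=eta, init="warm", **kwargs
    )
    model.warm_start(drug_space.X, disease_space.X)
    model.drug_ids_ = list(drug_space.ids)
    model.disease_ids_ = list(disease_space.ids)
    return model


def init_model_random(
    n_drugs: int,
    n_diseases: int,
    k: int = 32,
    lambda_reg: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
    init_scale: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> MatrixFactorization:
    """Randomly initialized model (the genomic-space-free MF ablation)."""
    model = MatrixFactorization(
        k=k, lambda_reg=lambda_reg, eta=eta, init="random", init_scale=init_scale,
        n_drugs=n_drugs, n_diseases=n_diseases, random_state=seed, **kwargs,
    )
    model._random_init(seed)
    return model


def predict(model: MatrixFactorization, drug_index: int, disease_index: int) -> float:
    """Association score F_ij for one pair."""
    return float(model.predict_proba([[drug_index, disease_index]])[0])


def loss(model: MatrixFactorization, samples: LabeledPairSet) -> float:
    """Regularized squared loss of the model on the given samples."""
    return objective(
        model.A_, model.B_, samples.drug_idx, samples.disease_idx,
        samples.labels, model.lambda_reg,
    )


def sgd_epoch(model: MatrixFactorization, samples: LabeledPairSet, seed: int = 0):
    """One pass over the samples in a seeded shuffled order (in place)."""
    order = np.random.default_rng(seed).permutation(len(samples))
    sgd_epoch_inplace(
        model.A_, model.B_, samples.drug_idx, samples.disease_idx,
        samples.labels, order, model.eta, model.lambda_reg,
    )
    return model


def train(
    model: MatrixFactorization,
    samples: LabeledPairSet,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
):
    """Train until the relative loss change falls below ``tol``.

    Returns ``(model, loss_trace)``; ``loss_trace[0]`` is the pre-training
    loss, one entry per epoch thereafter.
    """
    model.max_epochs = max_epochs
    model.tol = tol
    model._train(samples, seed=seed)
    return model, model.loss_trace_
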