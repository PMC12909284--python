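"""Extreme learning machine with a closed-form ridge solve.

A single hidden layer whose parameters are random and fixed — uniform
weights/biases for the sigmoid activation, data-range centers with
median-heuristic widths for the Gaussian RBF — and output weights obtained
by ridge-regularized least squares,

    B = (H'H + lambda I)^{-1} H'T,

solved through a Cholesky factorization of the regularized Gram matrix
rather than an explicit inverse.  When the hidden layer is wider than the
sample (L > N) the algebraically equivalent dual form
B = H'(HH' + lambda I)^{-1}T is used so the factorized system is always the
smaller of L x L and N x N.  All computation is double precision.

Binary problems use a single output column with targets in {0,1}; one-hot
two-column targets are supported for completeness and yield identical
labels.  The decision score is the class margin of the regression output —
t_hat - 1/2 for a single column, t_hat_1 - t_hat_0 for one-hot — so that a
margin of zero sits exactly on the boundary between the two target values.
Probabilities are the logistic of the margin and a label is 1 iff the
probability is >= tau (non-strict), making tau = 0.5 the natural operating
point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist

logger = logging.getLogger("gsoelm.elm")

ACTIVATIONS = ("sigmoid", "rbf")


@dataclass
class ElmConfig:
    """Hyperparameters of the ELM.

    L: hidden units (customary search range [20, 200]).
    lam: ridge coefficient, searched on a log grid over [1e-6, 1e2].
    a: half-width of the uniform [-a, a] init for weights and biases.
    tau: decision threshold on the output probability.
    rbf_width: fixed RBF width; None uses the median pairwise center
        distance heuristic.
    """

    L: int = 60
    lam: float = 1e-2
    activation: str = "sigmoid"
    a: float = 1.0
    tau: float = 0.5
    class_weighting: str = "none"  # none | balanced
    rbf_width: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be positive for the regularized solve")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")


def sigmoid(z: np.ndarray) -> np.ndarray:
    # guarded against overflow in exp for large |z|
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_hidden_params(
    d: int,
    config: ElmConfig,
    X_train: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Draw the random hidden layer: (W, b) for sigmoid, (C, widths) for RBF.

    Sigmoid weights and biases are i.i.d. uniform on [-a, a].  RBF centers
    are drawn uniformly within the training-data column ranges (requires
    X_train); widths default to the median pairwise center distance.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.activation == "sigmoid":
        W = rng.uniform(-config.a, config.a, size=(config.L, d))
        b = rng.uniform(-config.a, config.a, size=config.L)
        return {"W": W, "b": b}
    if X_train is None:
        raise ValueError("RBF initialization needs X_train for column ranges")
    lo, hi = X_train.min(axis=0), X_train.max(axis=0)
    C = rng.uniform(lo, hi, size=(config.L, d))
    if config.rbf_width is not None:
        width = float(config.rbf_width)
    elif config.L > 1:
        width = float(np.median(pdist(C)))
    else:
        width = 1.0
    width = max(width, 1e-6)
    widths = np.full(config.L, width)
    return {"C": C, "widths": widths}


def hidden_sigmoid(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """H = g(XW' + 1b') with the logistic g; entries in (0, 1)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in input matrix")
    return sigmoid(X @ W.T + b[None, :])


def hidden_rbf(X: np.ndarray, C: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Gaussian RBF activations exp(-||x_i - c_j||^2 / (2 sigma_j^2)).

    Squared distances come from the Gram decomposition
    D = r 1' + 1 s' - 2 XC' with r_i = ||x_i||^2 and s_j = ||c_j||^2;
    tiny negative entries caused by rounding are clamped to zero before the
    exponential, so H stays in (0, 1].
    """
    X = np.asarray(X, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("RBF widths must be positive")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in input matrix")
    r = np.sum(X * X, axis=1)[:, None]
    s = np.sum(C * C, axis=1)[None, :]
    D = r + s - 2.0 * (X @ C.T)
    np.maximum(D, 0.0, out=D)
    return np.exp(-D / (2.0 * widths[None, :] ** 2))


def solve_output_weights(
    H: np.ndarray,
    T: np.ndarray,
    lam: float,
    sample_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Solve (H'H + lambda I) B = H'T by Cholesky; dual form when L > N.

    With sample weights Omega the weighted system (H'OmegaH + lambda I)B =
    H'OmegaT is solved via the square-root trick H~ = Omega^{1/2} H.  Never
    forms an explicit inverse.
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite entries in hidden matrix")
    if T.ndim == 1:
        T = T[:, None]
    if sample_weights is not None:
        w = np.sqrt(np.asarray(sample_weights, dtype=float))[:, None]
        H = H * w
        T = T * w
    N, L = H.shape
    if L <= N:  # primal: L x L system
        A = H.T @ H + lam * np.eye(L)
        return cho_solve(cho_factor(A), H.T @ T)
    # dual: N x N system, algebraically identical
    A = H @ H.T + lam * np.eye(N)
    return H.T @ cho_solve(cho_factor(A), T)


def conditioning_report(H: np.ndarray, lam: float) -> dict[str, float]:
    """Condition numbers of the Gram matrix before and after regularization.

    Ridge guarantees the smallest eigenvalue of H'H + lambda I is at least
    lambda, which is what makes the closed-form solve stable.
    """
    H = np.asarray(H, dtype=float)
    G = H.T @ H
    eig = np.linalg.eigvalsh(G)
    eig_reg = eig + lam
    kappa = float(eig[-1] / eig[0]) if eig[0] > 0 else float("inf")
    kappa_reg = float(eig_reg[-1] / eig_reg[0]) if eig_reg[0] > 0 else float("inf")
    min_eig_reg = float(eig_reg[0])
    # lambda floor up to eigensolver rounding, which scales with ||G||
    tol = 1e-12 * max(1.0, float(eig[-1]))
    assert min_eig_reg >= lam - tol, "regularized Gram lost its lambda floor"
    return {
        "kappa_gram": kappa,
        "kappa_regularized": kappa_reg,
        "min_eig_regularized": min_eig_reg,
    }


@dataclass
class ElmModel:
    """A trained ELM: fixed hidden layer plus solved output weights."""

    config: ElmConfig
    params: dict[str, np.ndarray]
    B: np.ndarray
    n_features: int
    mask: np.ndarray | None = None  # encoded-column mask this model was trained under
    diagnostics: dict[str, float] = field(default_factory=dict)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}"
                + (f"; model mask: {self.mask.astype(int).tolist()}" if self.mask is not None else "")
            )
        if self.config.activation == "sigmoid":
            return hidden_sigmoid(X, self.params["W"], self.params["b"])
        return hidden_rbf(X, self.params["C"], self.params["widths"])

    def raw_outputs(self, X: np.ndarray) -> np.ndarray:
        """Regression outputs T_hat = H B (N x m)."""
        return self.hidden(X) @ self.B

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Class margin: T_hat - 1/2 for m=1, column difference for m=2.

        Zero margin is the midpoint between the two target values, so the
        logistic of the margin is 0.5 exactly on the boundary.
        """
        T_hat = self.raw_outputs(X)
        if T_hat.shape[1] == 1:
            return T_hat.ravel() - 0.5
        return T_hat[:, 1] - T_hat[:, 0]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": {
                "L": self.config.L, "lam": self.config.lam,
                "activation": self.config.activation, "a": self.config.a,
                "tau": self.config.tau, "class_weighting": self.config.class_weighting,
                "rbf_width": self.config.rbf_width, "seed": self.config.seed,
            },
            "params": {k: v.tolist() for k, v in self.params.items()},
            "B": self.B.tolist(),
            "n_features": self.n_features,
            "mask": self.mask.astype(int).tolist() if self.mask is not None else None,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ElmModel":
        mask = data.get("mask")
        return cls(
            config=ElmConfig(**data["config"]),
            params={k: np.asarray(v, dtype=float) for k, v in data["params"].items()},
            B=np.asarray(data["B"], dtype=float),
            n_features=int(data["n_features"]),
            mask=np.asarray(mask, dtype=bool) if mask is not None else None,
            diagnostics=dict(data.get("diagnostics", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ElmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_elm(
    X: np.ndarray,
    y: np.ndarray,
    config: ElmConfig,
    mask: np.ndarray | None = None,
    hidden_params: dict[str, np.ndarray] | None = None,
    one_hot_targets: bool = False,
) -> ElmModel:
    """Train an ELM: draw (or accept) the hidden layer, solve the ridge system.

    ``mask`` restricts X to selected columns and is remembered by the model.
    ``hidden_params`` allows externally tuned weights (e.g. swarm-optimized
    W, b) instead of a fresh random draw.  ``one_hot_targets`` regresses a
    two-column one-hot T instead of the default single {0,1} column; both
    forms give the same labels at tau = 0.5.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        X = X[:, mask]
    if X.shape[1] == 0:
        raise ValueError("mask selects no columns")
    if hidden_params is None:
        hidden_params = init_hidden_params(X.shape[1], config, X_train=X)
    model = ElmModel(config=config, params=hidden_params, B=np.zeros((config.L, 1)),
                     n_features=X.shape[1], mask=mask)
    H = model.hidden(X)
    weights = None
    if config.class_weighting == "balanced":
        # w_c = N / (2 N_c): each class contributes equally to the objective
        n = len(y)
        w1 = n / (2.0 * max(y.sum(), 1.0))
        w0 = n / (2.0 * max(n - y.sum(), 1.0))
        weights = np.where(y > 0.5, w1, w0)
    T = np.column_stack([1.0 - y, y]) if one_hot_targets else y
    model.B = solve_output_weights(H, T, config.lam, sample_weights=weights)
    model.diagnostics = conditioning_report(H, config.lam)
    return model


def predict(
    model: ElmModel,
    X_new: np.ndarray,
    tau: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores, logistic probabilities, and thresholded labels for new rows.

    If the model was trained under a column mask, ``X_new`` may be passed
    either already masked or at full width (it is masked automatically).
    A label is 1 iff probability >= tau (non-strict, so a probability of
    exactly tau classifies positive).
    """
    if tau is None:
        tau = model.config.tau
    X_new = np.asarray(X_new, dtype=float)
    if model.mask is not None and X_new.shape[1] == model.mask.size:
        X_new = X_new[:, model.mask]
    scores = model.decision_scores(X_new)
    probs = sigmoid(scores)
    labels = (probs >= tau).astype(int)
    return scores, probs, labels
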