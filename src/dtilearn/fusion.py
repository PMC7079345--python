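"""Drug-protein feature fusion and sparse-PCA compression.

A drug-target pair is represented by the 1842-dimensional concatenation of
the drug's 881-bit substructure fingerprint and the protein's 961-D
Legendre-moment descriptor.  Sparse principal component analysis (SPCA)
compresses this mixed binary/real vector into a lower-dimensional unified
space (400-D by default).

The SPCA estimator solves the elastic-net formulation

    min_{A,B} ||X - X B A^T||_F^2 + ridge ||B||_F^2 + l1 ||B||_1
    s.t. A^T A = I,

by alternating an orthogonal-Procrustes update of A with a proximal-gradient
elastic-net update of the loadings B.  With l1 = ridge = 0 the fixed point
is the classical principal subspace, which the tests exploit as an oracle;
a positive l1 drives loading entries to exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fingerprints import FINGERPRINT_LENGTH, SubstructureFingerprint
from .legendre import LMDescriptor

PAIR_VECTOR_LENGTH = FINGERPRINT_LENGTH + 961  # 881 fingerprint + 961 LM

__all__ = [
    "PAIR_VECTOR_LENGTH",
    "PairFeatureVector",
    "concatenate_pair_features",
    "build_pair_matrix",
    "ElasticNetSparsePCA",
    "fit_spca",
    "transform_spca",
    "save_spca",
    "load_spca",
]


class DimensionError(ValueError):
    """Raised when feature-vector shapes do not match the contracts."""


@dataclass
class PairFeatureVector:
    """Concatenated drug + protein features of one candidate pair."""

    drug_id: str
    target_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != PAIR_VECTOR_LENGTH:
            raise DimensionError(
                f"pair vector must have length {PAIR_VECTOR_LENGTH}, "
                f"got {self.values.size}"
            )
        head = self.values[:FINGERPRINT_LENGTH]
        if not np.isin(head, (0.0, 1.0)).all():
            raise DimensionError("first 881 entries must be binary fingerprint bits")


def concatenate_pair_features(
    fp: SubstructureFingerprint, lm: LMDescriptor
) -> PairFeatureVector:
    """Fingerprint bits (881) followed by LM descriptor values (961)."""
    if fp.bits.size != FINGERPRINT_LENGTH:
        raise DimensionError(f"fingerprint length {fp.bits.size} != {FINGERPRINT_LENGTH}")
    if lm.values.size != PAIR_VECTOR_LENGTH - FINGERPRINT_LENGTH:
        raise DimensionError(
            f"LM descriptor length {lm.values.size} != "
            f"{PAIR_VECTOR_LENGTH - FINGERPRINT_LENGTH}"
        )
    return PairFeatureVector(
        drug_id=fp.drug_id,
        target_id=lm.protein_id,
        values=np.concatenate([fp.bits.astype(float), lm.values]),
    )


def build_pair_matrix(pairs, fingerprints: dict, descriptors: dict) -> np.ndarray:
    """Stack pair vectors for (drug_id, target_id) tuples into an (n, d) array.

    d = 881 + descriptor length (1842 at the default moment orders).  The
    strict 1842-D contract lives in :func:`concatenate_pair_features`;
    this helper accepts any descriptor length so pipelines can run at
    reduced orders.
    """
    rows = []
    for drug_id, target_id in pairs:
        fp = fingerprints[drug_id]
        lm = descriptors[target_id]
        rows.append(np.concatenate([fp.bits.astype(float), lm.values]))
    return np.vstack(rows)


def _soft_threshold(M: np.ndarray, t: float) -> np.ndarray:
    return np.sign(M) * np.maximum(np.abs(M) - t, 0.0)


class ElasticNetSparsePCA:
    """Sparse PCA with elastic-net penalized loadings (sklearn-style).

    Parameters
    ----------
    n_components:
        Output dimension (default 400).
    l1_weight:
        Lasso penalty on the loadings; larger values produce more exact
        zeros.  0 recovers the classical principal subspace.
    ridge_weight:
        Ridge penalty stabilizing the regression step.
    standardize:
        Scale columns to unit variance before fitting (binary fingerprint
        and real moment columns live on incomparable scales).
    max_iter, tol:
        Outer alternation cap and convergence tolerance on the loadings.
    random_state:
        Recorded seed; the solver itself is deterministic (SVD-initialized).

    Attributes
    ----------
    loadings_ : (input_dim, n_components) array with unit-norm columns.
    center_ : column means used for centering.
    scale_ : column scales (all ones when standardize=False).
    n_iter_ : outer iterations actually run.
    """

    def __init__(
        self,
        n_components: int = 400,
        l1_weight: float = 0.1,
        ridge_weight: float = 1e-2,
        standardize: bool = True,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.l1_weight = l1_weight
        self.ridge_weight = ridge_weight
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "l1_weight": self.l1_weight,
            "ridge_weight": self.ridge_weight,
            "standardize": self.standardize,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "ElasticNetSparsePCA":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "ElasticNetSparsePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 samples")
        n, p = X.shape
        k = int(self.n_components)
        if k < 1 or k > min(n, p):
            raise ValueError(
                f"n_components={k} must lie in [1, min(n_samples={n}, input_dim={p})]"
            )
        if self.l1_weight < 0 or self.ridge_weight < 0:
            raise ValueError("penalty weights must be non-negative")

        self.center_ = X.mean(axis=0)
        Xc = X - self.center_
        if self.standardize:
            sd = Xc.std(axis=0, ddof=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_ = np.ones(p)
        Xs = Xc / self.scale_
        if not np.any(Xs):
            raise ValueError("degenerate input: all columns are constant")

        # SVD initialization: A starts at the classical principal directions.
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        A = Vt[:k].T  # (p, k)
        B = A.copy()

        col_sq = np.einsum("ij,ij->j", Xs, Xs)  # ||x_l||^2 per feature
        half_l1 = 0.5 * self.l1_weight
        total_sq = float(np.sum(Xs**2))

        def objective(A, B, T, M):
            # ||Xs - Xs B A^T||^2 = ||Xs||^2 - 2 tr(A^T Sigma B) + tr(B^T Sigma B)
            # with T = Xs B and M = Sigma B, all terms are cheap.
            return (
                total_sq - 2.0 * float(np.sum(A * M)) + float(np.sum(T**2))
                + self.ridge_weight * float(np.sum(B**2))
                + self.l1_weight * float(np.sum(np.abs(B)))
            )

        J_prev = np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # B-step: one cyclic coordinate-descent sweep of the elastic-net
            # regression of X A on X, vectorized across the k components via
            # the shared residual matrix R = X A - X B.  Alternating single
            # sweeps with A-updates converges faster than nested loops.
            R = Xs @ (A - B)
            for l in range(p):
                b_old = B[l]
                rho = Xs[:, l] @ R + col_sq[l] * b_old
                b_new = _soft_threshold(rho, half_l1) / (col_sq[l] + self.ridge_weight)
                diff = b_old - b_new
                if np.any(diff):
                    R += np.outer(Xs[:, l], diff)
                    B[l] = b_new
            # A-step: Procrustes — A = UV^T from the SVD of Sigma B
            T = Xs @ B
            M = Xs.T @ T
            Um, _, Vm = np.linalg.svd(M, full_matrices=False)
            A = Um @ Vm
            # outer convergence on relative objective decrease (individual
            # components may keep rotating within the fitted subspace)
            J = objective(A, B, T, M)
            if np.isfinite(J_prev) and abs(J_prev - J) <= self.tol * max(1.0, abs(J_prev)):
                break
            J_prev = J

        # unit-norm loading columns (zeroed-out components stay zero)
        norms = np.linalg.norm(B, axis=0)
        B = B / np.where(norms > 0, norms, 1.0)
        self.loadings_ = B
        self.n_iter_ = n_iter
        self.n_features_in_ = p
        self.fit_seed_ = self.random_state
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "loadings_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise DimensionError(
                f"X has {X.shape[1]} columns; model expects {self.n_features_in_}"
            )
        return (X - self.center_) / self.scale_ @ self.loadings_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def zero_loading_fraction(self) -> float:
        """Fraction of exactly-zero entries in the fitted loadings."""
        return float(np.mean(self.loadings_ == 0.0))


# -- thin functional wrappers ---------------------------------------------

def fit_spca(
    X: np.ndarray,
    n_components: int = 400,
    l1_weight: float = 0.1,
    ridge_weight: float = 1e-2,
    seed: int = 0,
    standardize: bool = True,
) -> ElasticNetSparsePCA:
    return ElasticNetSparsePCA(
        n_components=n_components,
        l1_weight=l1_weight,
        ridge_weight=ridge_weight,
        standardize=standardize,
        random_state=seed,
    ).fit(X)


def transform_spca(model: ElasticNetSparsePCA, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


def save_spca(model: ElasticNetSparsePCA, path) -> None:
    """Persist a fitted model to a single NPZ archive (exact round-trip)."""
    np.savez(
        Path(path),
        loadings=model.loadings_,
        center=model.center_,
        scale=model.scale_,
        n_components=model.n_components,
        l1_weight=model.l1_weight,
        ridge_weight=model.ridge_weight,
        standardize=model.standardize,
        random_state=-1 if model.random_state is None else model.random_state,
    )


def load_spca(path) -> ElasticNetSparsePCA:
    with np.load(Path(path)) as data:
        seed = int(data["random_state"])
        model = ElasticNetSparsePCA(
            n_components=int(data["n_components"]),
            l1_weight=float(data["l1_weight"]),
            ridge_weight=float(data["ridge_weight"]),
            standardize=bool(data["standardize"]),
            random_state=None if seed == -1 else seed,
        )
        model.loadings_ = data["loadings"]
        model.center_ = data["center"]
        model.scale_ = data["scale"]
        model.n_features_in_ = model.center_.size
        model.fit_seed_ = model.random_state
        model.n_iter_ = 0
    return model
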