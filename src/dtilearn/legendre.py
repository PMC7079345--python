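"""Discrete Legendre-moment descriptors of protein PSSMs.

A PSSM of N residues is treated as a function g(x, y) sampled on an N x 20
grid over [-1, 1]^2.  Its projection onto products of Legendre polynomials
P_a(x) P_b(y) gives a fixed-length, low-redundancy global descriptor of the
evolutionary profile, independent of protein length: at the default maximum
order a = b = 30 every protein maps to a 961-dimensional vector.

The moments are computed with the zeroth-order (midpoint) approximation on
cell centers,

    L_ab = (2a+1)(2b+1) / (K*L) * sum_ij P_a(x_i) P_b(y_j) g_ij,

with x_i = (2i - K - 1)/K, i = 1..K, and likewise for y.  Polynomials are
evaluated by the stable three-term recurrence rather than the explicit
Rodrigues sum, which cancels catastrophically near order 30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pssm import PSSM, normalize_pssm

__all__ = [
    "LegendreOrderConfig",
    "LMDescriptor",
    "legendre_polynomial",
    "legendre_vandermonde",
    "sample_grid",
    "legendre_moments",
    "featurize_protein",
    "LegendreMomentTransformer",
    "descriptor_feature_names",
]


@dataclass(frozen=True)
class LegendreOrderConfig:
    """Maximum moment orders along rows (a) and columns (b)."""

    a_max: int = 30
    b_max: int = 30

    def __post_init__(self) -> None:
        if self.a_max < 0 or self.b_max < 0:
            raise ValueError("moment orders must be non-negative")

    @property
    def n_features(self) -> int:
        return (self.a_max + 1) * (self.b_max + 1)


@dataclass
class LMDescriptor:
    """Legendre-moment feature vector of one protein.

    values are ordered row-major over (a, b): index = a * (b_max+1) + b.
    """

    protein_id: str
    values: np.ndarray
    order_config: LegendreOrderConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.order_config.n_features:
            raise ValueError(
                f"descriptor length {self.values.size} does not match order "
                f"config ({self.order_config.n_features} expected)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values must be finite")


def legendre_polynomial(a: int, x) -> np.ndarray | float:
    """Evaluate the Legendre polynomial P_a at x in [-1, 1].

    Uses the three-term recurrence
    (a+1) P_{a+1}(x) = (2a+1) x P_a(x) - a P_{a-1}(x).
    """
    if not float(a).is_integer() or a < 0:
        raise ValueError(f"order must be a non-negative integer, got {a!r}")
    a = int(a)
    x_arr = np.asarray(x, dtype=float)
    if np.any(np.abs(x_arr) > 1.0 + 1e-12):
        raise ValueError("Legendre polynomials are evaluated on [-1, 1]")
    p_prev = np.ones_like(x_arr)
    if a == 0:
        return p_prev if p_prev.shape else float(p_prev)
    p = x_arr.copy()
    for k in range(1, a):
        p, p_prev = ((2 * k + 1) * x_arr * p - k * p_prev) / (k + 1), p
    return p if p.shape else float(p)


def legendre_vandermonde(max_order: int, x: np.ndarray) -> np.ndarray:
    """Matrix V[a, i] = P_a(x_i) for a = 0..max_order, built by recurrence."""
    x = np.asarray(x, dtype=float)
    V = np.empty((max_order + 1, x.size))
    V[0] = 1.0
    if max_order >= 1:
        V[1] = x
    for k in range(1, max_order):
        V[k + 1] = ((2 * k + 1) * x * V[k] - k * V[k - 1]) / (k + 1)
    return V


def sample_grid(K: int, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center sample points of a uniform K x L partition of [-1, 1]^2.

    x_i = (2i - K - 1)/K for i = 1..K (spacing 2/K), likewise y_j.
    """
    if K < 1 or L < 1:
        raise ValueError("grid dimensions must be >= 1")
    i = np.arange(1, K + 1, dtype=float)
    j = np.arange(1, L + 1, dtype=float)
    return (2 * i - K - 1) / K, (2 * j - L - 1) / L


def legendre_moments(
    g: np.ndarray,
    config: LegendreOrderConfig = LegendreOrderConfig(),
    protein_id: str = "",
) -> LMDescriptor:
    """All moments L_ab, 0 <= a <= a_max, 0 <= b <= b_max, of a K x L matrix.

    Vectorized as V_a G V_b^T with Legendre-Vandermonde matrices on the
    cell-center grid; identical (to rounding) to the naive double sum.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.size == 0:
        raise ValueError("input must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(g)):
        raise ValueError("input matrix contains non-finite entries")
    K, L = g.shape
    x, y = sample_grid(K, L)
    Va = legendre_vandermonde(config.a_max, x)  # (a_max+1, K)
    Vb = legendre_vandermonde(config.b_max, y)  # (b_max+1, L)
    raw = Va @ g @ Vb.T  # (a_max+1, b_max+1)
    a = np.arange(config.a_max + 1)[:, None]
    b = np.arange(config.b_max + 1)[None, :]
    moments = (2 * a + 1) * (2 * b + 1) / (K * L) * raw
    return LMDescriptor(protein_id=protein_id, values=moments.ravel(), order_config=config)


def featurize_protein(
    pssm: PSSM,
    config: LegendreOrderConfig = LegendreOrderConfig(),
    normalization: str = "minmax",
) -> LMDescriptor:
    """Normalize a PSSM and compute its Legendre-moment descriptor.

    The descriptor length is (a_max+1)(b_max+1) — 961 at defaults —
    regardless of protein length N.
    """
    g = normalize_pssm(pssm, normalization)
    return legendre_moments(g, config, protein_id=pssm.protein_id)


def descriptor_feature_names(config: LegendreOrderConfig = LegendreOrderConfig()) -> list[str]:
    return [
        f"lm_a{a}_b{b}"
        for a in range(config.a_max + 1)
        for b in range(config.b_max + 1)
    ]


class LegendreMomentTransformer:
    """Sklearn-style transformer: list of PSSMs -> (n_proteins, n_features).

    Parameters
    ----------
    a_max, b_max:
        Maximum moment orders; descriptor length (a_max+1)(b_max+1).
    normalization:
        PSSM rescaling applied before the moments ("minmax", "sigmoid",
        "none").
    """

    def __init__(self, a_max: int = 30, b_max: int = 30, normalization: str = "minmax"):
        self.a_max = a_max
        self.b_max = b_max
        self.normalization = normalization

    # stateless transformer; fit only validates parameters
    def fit(self, X=None, y=None) -> "LegendreMomentTransformer":
        self.order_config_ = LegendreOrderConfig(self.a_max, self.b_max)
        self.n_features_out_ = self.order_config_.n_features
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "order_config_"):
            self.fit()
        rows = []
        for item in X:
            if isinstance(item, PSSM):
                rows.append(featurize_protein(item, self.order_config_, self.normalization).values)
            else:
                g = normalize_pssm(np.asarray(item, dtype=float), self.normalization)
                rows.append(legendre_moments(g, self.order_config_).values)
        return np.vstack(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit().transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"a_max": self.a_max, "b_max": self.b_max, "normalization": self.normalization}

    def set_params(self, **params) -> "LegendreMomentTransformer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
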