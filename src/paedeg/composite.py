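"""Entropy-weighted composite biodegradability index.

Combines several enzyme-docking endpoints into a single "comprehensive
biodegradability" score per compound:

1. min-max range normalization of each endpoint column onto ``[1 - a, 1]``
   (benefit orientation: higher raw score -> higher normalized value; cost
   orientation reversed), with floor parameter ``a`` (default 0.9);
2. Shannon-type information entropy per endpoint,
   ``E_j = -(1/ln m) * sum_i Y_ij ln Y_ij`` over the *m* compounds, applied
   to the normalized values directly;
3. difference coefficients ``H_j = |1 - E_j|`` and weights
   ``W_j = H_j / sum_j H_j`` (more dispersed, hence more informative,
   endpoints receive larger weights);
4. composite score ``Z_i = sum_j W_j Y_ij``.

Note on step 2: the textbook entropy-weight method first renormalizes each
column to proportions ``p_ij = Y_ij / sum_i Y_ij``.  The workflow implemented
here applies the entropy formula to the normalized scores themselves, which
makes ``E_j`` exceed 1 for dispersed columns; step 3 takes the absolute
difference so both regimes behave sensibly.  The proportion variant is
available via ``use_proportions=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateColumnError",
    "ScoreMatrix",
    "NormalizedMatrix",
    "EntropyWeightResult",
    "range_normalize",
    "entropy_per_endpoint",
    "entropy_weights",
    "composite_scores",
    "comprehensive_table",
]


class DegenerateColumnError(ValueError):
    """Raised when an endpoint column is constant (weights undefined)."""


@dataclass
class ScoreMatrix:
    """Compounds x endpoints raw score table.

    Parameters
    ----------
    compound_ids, endpoint_ids
        Row and column labels.
    X
        Raw scores, shape ``(m, n)`` (dimensionless docking-score units).
    orientation
        Per-endpoint ``"benefit"`` (higher better) or ``"cost"``; defaults
        to all-benefit, which is the docking-score case.
    """

    compound_ids: list[str]
    endpoint_ids: list[str]
    X: np.ndarray
    orientation: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not self.orientation:
            self.orientation = ["benefit"] * len(self.endpoint_ids)
        m, n = self.X.shape
        if m < 2 or n < 1:
            raise ValueError("need at least 2 compounds and 1 endpoint")
        if len(self.compound_ids) != m or len(self.endpoint_ids) != n:
            raise ValueError("label/matrix shape mismatch")
        if len(self.orientation) != n:
            raise ValueError("orientation length mismatch")
        bad = set(self.orientation) - {"benefit", "cost"}
        if bad:
            raise ValueError(f"unknown orientation(s): {sorted(bad)}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite raw scores")
        for j, name in enumerate(self.endpoint_ids):
            if self.X[:, j].max() == self.X[:, j].min():
                raise DegenerateColumnError(
                    f"endpoint {name!r} is constant; range normalization "
                    "and entropy weighting are undefined"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   orientation: Sequence[str] | None = None) -> "ScoreMatrix":
        """Build from a DataFrame whose index holds compound ids."""
        return cls(
            compound_ids=[str(i) for i in df.index],
            endpoint_ids=[str(c) for c in df.columns],
            X=df.to_numpy(dtype=float),
            orientation=list(orientation) if orientation else [],
        )


@dataclass
class NormalizedMatrix:
    compound_ids: list[str]
    endpoint_ids: list[str]
    Y: np.ndarray
    floor_a: float


@dataclass
class EntropyWeightResult:
    """Full output of the composite-index pipeline (one table run)."""

    compound_ids: list[str]
    endpoint_ids: list[str]
    E: np.ndarray              # information entropy per endpoint
    H: np.ndarray              # difference coefficient per endpoint
    W: np.ndarray              # weight per endpoint (sums to 1)
    Z: np.ndarray              # composite score per compound
    k: float                   # entropy constant 1/ln(m)
    m: int
    n_endpoints: int
    normalized: NormalizedMatrix = None

    def to_frame(self) -> pd.DataFrame:
        """Report in the published layout: raw-free derived columns."""
        data = {}
        for j, name in enumerate(self.endpoint_ids):
            data[f"Y_{name}"] = self.normalized.Y[:, j]
        data["Z"] = self.Z
        return pd.DataFrame(data, index=pd.Index(self.compound_ids,
                                                 name="compound"))


def range_normalize(scores: ScoreMatrix, floor_a: float = 0.9) -> NormalizedMatrix:
    """Min-max normalize each endpoint column onto ``[1 - a, 1]``.

    Benefit columns map the column maximum to 1 and the minimum to ``1 - a``;
    cost columns the reverse.
    """
    if not 0.0 < floor_a < 1.0:
        raise ValueError(f"floor_a must lie strictly in (0, 1), got {floor_a}")
    X = scores.X
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    Y = np.empty_like(X)
    for j, orient in enumerate(scores.orientation):
        if orient == "benefit":
            frac = (X[:, j] - lo[j]) / span[j]
        else:
            frac = (hi[j] - X[:, j]) / span[j]
        Y[:, j] = (1.0 - floor_a) + floor_a * frac
    return NormalizedMatrix(scores.compound_ids, scores.endpoint_ids, Y, floor_a)


def entropy_per_endpoint(normed: NormalizedMatrix,
                         use_proportions: bool = False) -> np.ndarray:
    """Information entropy ``E_j = -(1/ln m) sum_i v_ij ln v_ij``.

    By default ``v = Y`` (normalized scores used directly).  With
    ``use_proportions=True`` the textbook variant is computed on column
    proportions ``p_ij = Y_ij / sum_i Y_ij`` instead.
    """
    Y = normed.Y
    if np.any(Y <= 0):
        raise ValueError("entropy requires strictly positive normalized values")
    m = Y.shape[0]
    V = Y / Y.sum(axis=0) if use_proportions else Y
    k = 1.0 / np.log(m)
    return -k * (V * np.log(V)).sum(axis=0)


def entropy_weights(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Difference coefficients ``H = |1 - E|`` and weights ``W = H / sum H``."""
    E = np.asarray(E, dtype=float)
    if E.size == 0:
        raise ValueError("empty entropy vector")
    H = np.abs(1.0 - E)
    total = H.sum()
    if total == 0:
        raise ValueError("all difference coefficients are zero: "
                         "no endpoint carries weightable information")
    return H, H / total


def composite_scores(normed: NormalizedMatrix, W: np.ndarray) -> np.ndarray:
    """Weighted composite ``Z_i = sum_j W_j Y_ij``."""
    W = np.asarray(W, dtype=float)
    if W.shape != (normed.Y.shape[1],):
        raise ValueError(
            f"weight vector of length {W.size} does not match "
            f"{normed.Y.shape[1]} endpoints")
    if not np.isclose(W.sum(), 1.0, atol=1e-8):
        raise ValueError("weights must sum to 1")
    return normed.Y @ W


def comprehensive_table(scores: ScoreMatrix, floor_a: float = 0.9,
                        use_proportions: bool = False) -> EntropyWeightResult:
    """Run the full composite-index pipeline on a score matrix."""
    normed = range_normalize(scores, floor_a)
    E = entropy_per_endpoint(normed, use_proportions=use_proportions)
    H, W = entropy_weights(E)
    Z = composite_scores(normed, W)
    return EntropyWeightResult(
        compound_ids=scores.compound_ids,
        endpoint_ids=scores.endpoint_ids,
        E=E, H=H, W=W, Z=Z,
        k=1.0 / np.log(scores.X.shape[0]),
        m=scores.X.shape[0],
        n_endpoints=scores.X.shape[1],
        normalized=normed,
    )
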