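"""Winsorisation-based robust correlation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class CorrelationMatrix:
    proteins: list[str]
    r: np.ndarray  # symmetric, unit diagonal; NaN marks undefined pairs
    gamma: float

    def validate(self) -> None:
        finite = np.isfinite(self.r)
        if not np.array_equal(finite, finite.T):
            raise ValueError("undefined entries must be symmetric")
        mask = finite & finite.T
        if not np.allclose(self.r[mask], self.r.T[mask]):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("diagonal must be 1")
        if np.any(np.abs(self.r[finite]) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


def winsorize(values: Sequence[float], gamma: float) -> np.ndarray:
    """Replace the floor(gamma*n) smallest values by the smallest retained
    value, symmetrically at the top; gamma=0 is the identity."""
    if not 0 <= gamma < 0.5:
        raise ValueError("gamma must lie in [0, 0.5)")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be nonempty")
    k = int(math.floor(gamma * x.size))
    if k == 0:
        return x.copy()
    s = np.sort(x)
    return np.clip(x, s[k], s[x.size - 1 - k])


def wincor_matrix(X: np.ndarray, gamma: float = 0.2,
                  proteins: Sequence[str] | None = None) -> CorrelationMatrix:
    """Product-moment correlation of column-wise winsorised values.

    Zero-variance columns after winsorisation yield NaN for the affected
    off-diagonal pairs (not an exception); the diagonal stays 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need a matrix with >= 3 rows and >= 2 columns")
    if proteins is None:
        proteins = [str(j) for j in range(X.shape[1])]
    W = np.column_stack([winsorize(X[:, j], gamma) for j in range(X.shape[1])])
    W = W - W.mean(axis=0)
    sd = np.sqrt(np.mean(W ** 2, axis=0))
    cov = (W.T @ W) / X.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.outer(sd, sd)
    r[np.outer(sd == 0, np.ones(len(sd), bool))] = np.nan
    r[np.outer(np.ones(len(sd), bool), sd == 0)] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)  # NaN propagates through clip
    cm = CorrelationMatrix(proteins=list(proteins), r=r, gamma=gamma)
    cm.validate()
    return cm


def save_heatmap(cm: CorrelationMatrix, path) -> None:
    """Minimal heatmap of the correlation matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(cm.proteins)),) * 2)
    im = ax.imshow(cm.r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm.proteins)), cm.proteins, rotation=90, fontsize=6)
    ax.set_yticks(range(len(cm.proteins)), cm.proteins, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
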