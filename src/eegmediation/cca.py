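"""Whitening-based canonical correlation analysis for two data blocks.

Integrates a high-dimensional qEEG block (vectorized log source spectra,
p >> n) with a low-dimensional cognitive block by jointly whitening both
blocks with shrinkage-regularized correlation matrices and rotating so
that the cross-correlation between the whitened blocks is diagonal.  The
diagonal entries are signed canonical correlations: unlike classical
CCA, the sign convention (positive loading sum on each block) lets the
first pair express either a positive or a negative association.

The shrinkage intensity is the analytic optimum of Schäfer & Strimmer
for correlation matrices shrunk toward the identity, computed with a
Gram-matrix identity so that p ~ 10^4 never requires forming a p x p
matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DataBlockPair:
    """Row-aligned blocks: X (n x p, spectra) and Y (n x q, cognition)."""

    X: np.ndarray
    Y: np.ndarray
    row_keys: list[tuple] | None = None
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"misaligned blocks: X has {self.X.shape[0]} rows, "
                f"Y has {self.Y.shape[0]}")
        if self.row_keys is not None and len(self.row_keys) != self.X.shape[0]:
            raise ValueError("row_keys length does not match the blocks")


@dataclass
class WhiteningModel:
    """Fitted joint whitening transform and signed canonical correlations.

    ``x_weights`` / ``y_weights`` hold the retained rows of the whitening
    (unmixing) transforms as columns: latent scores are the standardized
    columns of ``X_std @ x_weights``.  ``rho`` are the signed canonical
    correlations of the shrunken-whitening decomposition (singular
    values, with the sign induced by the loading-sum convention); at
    zero shrinkage they equal the classical canonical correlations and
    the in-sample correlation of each score pair.  ``score_corr`` keeps
    the raw in-sample correlations as an overfitting diagnostic: with
    p >> n they approach 1 for every component regardless of signal.
    """

    x_weights: np.ndarray
    y_weights: np.ndarray
    rho: np.ndarray
    score_corr: np.ndarray
    lambda_x: float
    lambda_y: float
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    x_score_scale: np.ndarray
    y_score_scale: np.ndarray
    sign_flips: dict = field(default_factory=dict)
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    n_fit: int = 0

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "x_weights": self.x_weights.tolist(),
            "y_weights": self.y_weights.tolist(),
            "rho": self.rho.tolist(),
            "score_corr": self.score_corr.tolist(),
            "lambda_x": self.lambda_x,
            "lambda_y": self.lambda_y,
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center.tolist(),
            "y_scale": self.y_scale.tolist(),
            "x_score_scale": self.x_score_scale.tolist(),
            "y_score_scale": self.y_score_scale.tolist(),
            "sign_flips": {k: list(map(int, v)) for k, v in self.sign_flips.items()},
            "x_names": self.x_names,
            "y_names": self.y_names,
            "n_fit": self.n_fit,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "WhiteningModel":
        with open(path) as fh:
            d = json.load(fh)
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(x_weights=arr("x_weights"), y_weights=arr("y_weights"),
                   rho=arr("rho"), score_corr=arr("score_corr"),
                   lambda_x=d["lambda_x"], lambda_y=d["lambda_y"],
                   x_center=arr("x_center"), x_scale=arr("x_scale"),
                   y_center=arr("y_center"), y_scale=arr("y_scale"),
                   x_score_scale=arr("x_score_scale"),
                   y_score_scale=arr("y_score_scale"),
                   sign_flips=d.get("sign_flips", {}),
                   x_names=d.get("x_names"), y_names=d.get("y_names"),
                   n_fit=d.get("n_fit", 0))


@dataclass
class LatentScores:
    """First canonical pair per subject-visit (unit variance on fit data)."""

    scores: pd.DataFrame          # columns qEEG1, Cog1 (+ key columns if known)


def _standardize(M: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        raise ValueError(f"constant column(s) in {name}: indices {bad.tolist()}")
    return (M - center) / scale, center, scale


def shrinkage_intensity(Ms: np.ndarray) -> float:
    """Analytic optimal shrinkage toward identity for standardized data.

    lambda* = sum_{i != j} Var(r_ij) / sum_{i != j} r_ij^2 (clipped to
    [0, 1]).  Both sums are computed from the n x n Gram matrix, so the
    cost is O(n^2 p) regardless of p.
    """
    n, d = Ms.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if d < 2:
        return 0.0
    G = Ms @ Ms.T
    fro2 = np.sum(G * G)
    sum_r2_off = fro2 / (n - 1) ** 2 - d          # diag of R is exactly 1
    if sum_r2_off <= 0:
        return 0.0
    diag_term = np.sum(Ms ** 4) - d * (n - 1) ** 2 / n
    var_all = np.sum(np.diag(G) ** 2) - fro2 / n
    var_off = n / (n - 1) ** 3 * (var_all - diag_term)
    return float(np.clip(var_off / sum_r2_off, 0.0, 1.0))


def shrinkage_covariance(M: np.ndarray,
                         lambda_override: float | None = None
                         ) -> tuple[np.ndarray, float]:
    """Shrunken correlation-scale covariance (1-l)*S + l*I of a data matrix.

    Columns are standardized first, so the empirical matrix S is a
    correlation matrix and the diagonal target is the identity.  The
    result is symmetric positive definite whenever ``l > 0`` or S is
    full rank.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D")
    n, d = M.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    Ms, _, _ = _standardize(M, "M")
    lam = shrinkage_intensity(Ms) if lambda_override is None else float(lambda_override)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    S = (Ms.T @ Ms) / (n - 1)
    out = (1.0 - lam) * S + lam * np.eye(d)
    return out, lam


class _InvSqrtOperator:
    """Applies R^{-1/2} of a shrunken correlation matrix via the data SVD.

    R = (1-l) V diag(e) V^T + l I with e the nonzero eigenvalues of the
    empirical correlation matrix; orthogonal directions have eigenvalue
    l, so R^{-1/2} = V (f(e) - l^{-1/2}) V^T + l^{-1/2} I with
    f(e) = ((1-l) e + l)^{-1/2}.  Never forms a p x p matrix.
    """

    def __init__(self, Ms: np.ndarray, lam: float):
        n, d = Ms.shape
        U, s, Vt = np.linalg.svd(Ms, full_matrices=False)
        tol = max(n, d) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        r = int(np.sum(s > tol))
        if lam == 0.0 and r < d:
            raise ValueError(
                f"rank collapse: empirical correlation has rank {r} < {d}; "
                "zero shrinkage is not invertible")
        self.V = Vt[:r].T                     # (d, r)
        e = s[:r] ** 2 / (n - 1)
        self.f = ((1.0 - lam) * e + lam) ** -0.5
        self.lam = lam
        self.d = d

    def apply(self, B: np.ndarray) -> np.ndarray:
        """R^{-1/2} @ B for B of shape (d, k)."""
        core = self.V @ (self.f[:, None] * (self.V.T @ B))
        if self.lam > 0:
            core += self.lam ** -0.5 * (B - self.V @ (self.V.T @ B))
        return core


def fit_cca_whitening(pair: DataBlockPair,
                      lambda_x: float | None = None,
                      lambda_y: float | None = None) -> WhiteningModel:
    """Fit the joint shrinkage-whitening CCA of the two blocks.

    Columns are standardized (correlation scale), each block's shrunken
    correlation matrix is inverted to the -1/2 power, and the SVD of
    ``Rx^{-1/2} Rxy Ry^{-1/2}`` gives the paired rotations.  Components
    are ordered by decreasing |rho| (ties by first occurrence) and signs
    are fixed so each component's loading sum is positive on both blocks
    (so the first cognitive variate has a positive loading pattern).
    """
    n = pair.X.shape[0]
    if n < 4:
        raise ValueError(f"need n >= 4 rows, got {n}")
    Xs, xc, xs = _standardize(pair.X, "X")
    Ys, yc, ys = _standardize(pair.Y, "Y")
    lam_x = shrinkage_intensity(Xs) if lambda_x is None else float(lambda_x)
    lam_y = shrinkage_intensity(Ys) if lambda_y is None else float(lambda_y)

    op_x = _InvSqrtOperator(Xs, lam_x)
    op_y = _InvSqrtOperator(Ys, lam_y)
    # joint shrinkage: the cross block of the shrunken joint correlation
    # matrix is sqrt((1-lx)(1-ly)) * Rxy, which keeps the joint matrix
    # positive semidefinite and hence every |rho| <= 1.  The scale only
    # affects the canonical correlations, so it is applied to the
    # singular values after the SVD (keeping the directions well defined
    # in the full-shrinkage limit).
    shrink_xy = np.sqrt((1.0 - lam_x) * (1.0 - lam_y))
    Rxy = (Xs.T @ Ys) / (n - 1)                   # (p, q)
    K = op_x.apply(op_y.apply(Rxy.T).T)           # Px^{-1/2} Rxy Py^{-1/2}
    U, sv, Vt = np.linalg.svd(K, full_matrices=False)
    sv = shrink_xy * sv

    alpha = op_x.apply(U)                         # (p, m) canonical directions
    beta = op_y.apply(Vt.T)                       # (q, m)

    Zx = Xs @ alpha
    Zy = Ys @ beta
    sx = Zx.std(axis=0, ddof=1)
    sy = Zy.std(axis=0, ddof=1)
    degenerate = (sx == 0) | (sy == 0)
    if degenerate.any():
        raise ValueError("rank collapse: degenerate latent score variance")
    Zx /= sx
    Zy /= sy

    flips_x = np.where(alpha.sum(axis=0) < 0, -1, 1)
    flips_y = np.where(beta.sum(axis=0) < 0, -1, 1)
    alpha = alpha * flips_x
    beta = beta * flips_y
    Zx = Zx * flips_x
    Zy = Zy * flips_y

    # signed canonical correlations: the SVD singular values carry the
    # magnitude, the loading-sum sign convention carries the sign
    rho = sv * flips_x * flips_y
    score_corr = np.einsum("ni,ni->i", Zx, Zy) / (n - 1)
    order = np.argsort(-np.abs(rho), kind="stable")

    return WhiteningModel(
        x_weights=alpha[:, order], y_weights=beta[:, order],
        rho=rho[order], score_corr=score_corr[order],
        lambda_x=lam_x, lambda_y=lam_y,
        x_center=xc, x_scale=xs, y_center=yc, y_scale=ys,
        x_score_scale=sx[order], y_score_scale=sy[order],
        sign_flips={"x": flips_x[order].tolist(), "y": flips_y[order].tolist()},
        x_names=pair.x_names, y_names=pair.y_names, n_fit=n)


def transform(model: WhiteningModel, pair: DataBlockPair,
              n_components: int = 1) -> LatentScores:
    """Latent scores for each row; first pair named (qEEG1, Cog1)."""
    if pair.X.shape[1] != model.x_weights.shape[0]:
        raise ValueError(
            f"X has {pair.X.shape[1]} columns, model expects "
            f"{model.x_weights.shape[0]}")
    if pair.Y.shape[1] != model.y_weights.shape[0]:
        raise ValueError(
            f"Y has {pair.Y.shape[1]} columns, model expects "
            f"{model.y_weights.shape[0]}")
    Xs = (pair.X - model.x_center) / model.x_scale
    Ys = (pair.Y - model.y_center) / model.y_scale
    Zx = (Xs @ model.x_weights) / model.x_score_scale
    Zy = (Ys @ model.y_weights) / model.y_score_scale
    cols = {}
    for i in range(min(n_components, Zx.shape[1])):
        suffix = str(i + 1)
        cols[f"qEEG{suffix}"] = Zx[:, i]
        cols[f"Cog{suffix}"] = Zy[:, i]
    df = pd.DataFrame(cols)
    if pair.row_keys is not None:
        df.insert(0, "subject_id", [k[0] for k in pair.row_keys])
        df.insert(1, "visit", [k[1] for k in pair.row_keys])
    return LatentScores(scores=df)


@dataclass
class LoadingSummaries:
    """First-component loading summaries for reporting."""

    cog_loadings: pd.Series           # one loading per cognitive score
    freq_minmax: pd.DataFrame         # frequency, min_loading, max_loading
    top_positive: np.ndarray          # column indices, size ceil(0.01 p)
    top_negative: np.ndarray


def loading_summaries(model: WhiteningModel,
                      geometry: pd.DataFrame) -> LoadingSummaries:
    """Summarize first-pair loadings over the source x frequency geometry.

    ``geometry`` maps each X column to columns ``source`` and either
    ``frequency`` (Hz) or ``freq_bin``.  Top-1% sets have exactly
    ceil(0.01 p) members; ties are broken by lower column index (stable
    sort).
    """
    p = model.x_weights.shape[0]
    if len(geometry) != p:
        raise ValueError(f"geometry has {len(geometry)} rows, model has {p} "
                         "X columns")
    w = model.x_weights[:, 0]
    freq_col = "frequency" if "frequency" in geometry.columns else "freq_bin"
    grouped = pd.DataFrame({"freq": geometry[freq_col].to_numpy(), "w": w})
    minmax = grouped.groupby("freq")["w"].agg(min_loading="min",
                                              max_loading="max").reset_index()
    minmax = minmax.rename(columns={"freq": freq_col})
    k = int(np.ceil(0.01 * p))
    order_desc = np.argsort(-w, kind="stable")
    order_asc = np.argsort(w, kind="stable")
    names = model.y_names or [f"y{i}" for i in range(model.y_weights.shape[0])]
    cog = pd.Series(model.y_weights[:, 0], index=names, name="W_Cog")
    return LoadingSummaries(cog_loadings=cog, freq_minmax=minmax,
                            top_positive=np.sort(order_desc[:k]),
                            top_negative=np.sort(order_asc[:k]))
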