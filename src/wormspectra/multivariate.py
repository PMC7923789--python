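"""PCA and NIPALS PLS1 over the descriptor matrices.

Block A matrices (7 locomotion descriptors in mixed units) are
autoscaled before PCA; Block B matrices (100 spectrum bins, shared
units) are mean-centered only. PCA is the singular value decomposition
of the preprocessed matrix, with per-component explained variance
reported as a percentage of total variance. PLS1 is the classical
NIPALS sequence — weight w proportional to X'y, score t = Xw, loadings
p = X't/t't, y-loading q = y't/t't, deflation of X and y — with the
calibration R^2 evaluated on the training rows. Sign indeterminacies
are fixed: the largest-magnitude PCA loading is positive, and each PLS
latent-variable score has positive covariance with y.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MEAN_CENTER = "mean_center"
AUTOSCALE = "autoscale"


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique")
        return X.to_numpy(dtype=float), names, list(X.index)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    return arr, [f"var{i}" for i in range(arr.shape[1])], list(range(arr.shape[0]))


@dataclass
class Preprocessor:
    """Stored centering/scaling parameters, reapplicable to new rows."""

    mode: str
    mean_: np.ndarray
    scale_: np.ndarray
    constant_columns: np.ndarray  # flags of zero-variance columns (left centered)

    def transform(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        return (arr - self.mean_) / self.scale_

    def inverse_transform(self, Xp) -> np.ndarray:
        return np.asarray(Xp, dtype=float) * self.scale_ + self.mean_


def preprocess(X, mode: str = MEAN_CENTER) -> tuple[np.ndarray, Preprocessor]:
    """Mean-center (and for autoscale, unit-variance scale) a data matrix.

    Zero-variance columns are left centered and flagged rather than divided
    by zero.
    """
    arr, _, _ = _as_matrix(X)
    if arr.shape[0] < 2:
        raise ValueError("preprocessing needs at least 2 rows")
    if np.any(~np.isfinite(arr)):
        raise ValueError("X must contain no missing/non-finite values")
    if mode not in (MEAN_CENTER, AUTOSCALE):
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    constant = sd == 0.0
    scale = np.ones_like(sd)
    if mode == AUTOSCALE:
        scale = np.where(constant, 1.0, sd)
    pre = Preprocessor(mode=mode, mean_=mean, scale_=scale, constant_columns=constant)
    return pre.transform(arr), pre


@dataclass
class PCAModel:
    scores: np.ndarray                 # rows x k
    loadings: np.ndarray               # variables x k, orthonormal columns
    explained_variance_pct: np.ndarray
    singular_values: np.ndarray
    preprocessor: Preprocessor
    variable_names: list
    row_labels: list

    def reconstruct(self) -> np.ndarray:
        """Preprocessed-scale reconstruction from the retained components."""
        return self.scores @ self.loadings.T


def pca_fit(X, n_components: int, preprocessing: str = MEAN_CENTER) -> PCAModel:
    """Principal component analysis by SVD of the preprocessed matrix."""
    arr, names, rows = _as_matrix(X)
    Xp, pre = preprocess(arr, preprocessing)
    max_k = min(Xp.shape[0] - 1, Xp.shape[1])
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must lie in [1, {max_k}]")
    U, S, Vt = np.linalg.svd(Xp, full_matrices=False)
    total = float((S**2).sum())
    explained = 100.0 * S[:n_components] ** 2 / total
    loadings = Vt[:n_components].T.copy()
    scores = U[:, :n_components] * S[:n_components]
    for j in range(n_components):  # sign convention: dominant loading positive
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAModel(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=explained,
        singular_values=S[:n_components],
        preprocessor=pre,
        variable_names=names,
        row_labels=rows,
    )


@dataclass
class PLSModel:
    n_lv: int
    weights: np.ndarray      # variables x k
    x_scores: np.ndarray     # rows x k
    x_loadings: np.ndarray   # variables x k
    y_loadings: np.ndarray   # k
    coef_: np.ndarray        # regression coefficients on preprocessed X
    x_preprocessor: Preprocessor
    y_mean: float
    r2_calibration: float
    variable_names: list

    def predict(self, X) -> np.ndarray:
        Xp = self.x_preprocessor.transform(np.asarray(X, dtype=float))
        return Xp @ self.coef_ + self.y_mean


def pls1_fit(X, y, n_lv: int = 2, preprocessing: str = MEAN_CENTER) -> PLSModel:
    """NIPALS PLS1 of a response vector on a data matrix."""
    arr, names, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if len(yv) != arr.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if arr.shape[0] < n_lv + 1:
        raise ValueError("need at least n_lv + 1 rows")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if np.std(yv) == 0:
        raise ValueError("y has zero variance")

    Xp, pre = preprocess(arr, preprocessing)
    y_mean = float(yv.mean())
    Xd = Xp.copy()
    yd = yv - y_mean

    p_vars = Xd.shape[1]
    W = np.zeros((p_vars, n_lv))
    T = np.zeros((Xd.shape[0], n_lv))
    P = np.zeros((p_vars, n_lv))
    q = np.zeros(n_lv)
    k_used = 0
    for k in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break  # X residual carries no covariance with y
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = Xd.T @ t / tt
        qk = float(yd @ t / tt)
        if qk < 0:  # sign convention: LV score-y covariance positive
            w, t, p, qk = -w, -t, -p, -qk
        W[:, k], T[:, k], P[:, k], q[k] = w, t, p, qk
        Xd = Xd - np.outer(t, p)
        yd = yd - qk * t
        k_used = k + 1

    W, T, P, q = W[:, :k_used], T[:, :k_used], P[:, :k_used], q[:k_used]
    if k_used == 0:
        raise ValueError("no latent variable could be extracted")
    coef = W @ np.linalg.solve(P.T @ W, q)
    pred = Xp @ coef + y_mean
    ss_res = float(((yv - pred) ** 2).sum())
    ss_tot = float(((yv - y_mean) ** 2).sum())
    return PLSModel(
        n_lv=k_used,
        weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
        coef_=coef,
        x_preprocessor=pre,
        y_mean=y_mean,
        r2_calibration=1.0 - ss_res / ss_tot,
        variable_names=names,
    )


def lv1_loading_spectrum(model: PLSModel, variable_names=None) -> pd.DataFrame:
    """LV1 x-loadings per variable, in variable (spectrum-bin) order."""
    names = variable_names if variable_names is not None else model.variable_names
    if len(names) != model.x_loadings.shape[0]:
        raise ValueError("variable name count does not match the model")
    return pd.DataFrame({"variable": list(names), "loading": model.x_loadings[:, 0]})


def save_biplot(model: PCAModel, path, title: str = "") -> None:
    """Scores + loadings biplot of the first two components (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if model.scores.shape[1] < 2:
        raise ValueError("biplot needs at least 2 components")
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(model.scores[:, 0], model.scores[:, 1], s=25, c="tab:blue")
    scale = 0.9 * np.abs(model.scores[:, :2]).max() / max(np.abs(model.loadings[:, :2]).max(), 1e-12)
    for name, (lx, ly) in zip(model.variable_names, model.loadings[:, :2]):
        ax.annotate(name, (lx * scale, ly * scale), color="tab:red", fontsize=7)
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel(f"PC1 ({model.explained_variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({model.explained_variance_pct[1]:.1f}%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_loading_spectrum(models: dict, path, title: str = "") -> None:
    """Overlay LV1 loading spectra of several PLS models over the 100 bins."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, model in models.items():
        ax.plot(np.arange(model.x_loadings.shape[0]), model.x_loadings[:, 0], label=label)
    ax.axvline(50, color="red", lw=0.8, ls=":")
    ax.axvline(85, color="green", lw=0.8, ls=":")
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("% worm length bin")
    ax.set_ylabel("LV1 loading")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
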