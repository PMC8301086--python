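"""OSC-PLSDA: orthogonal signal correction + PLS discriminant analysis.

The model is fitted in two stages on autoscaled (or Pareto-scaled) data:

1. *Orthogonal signal correction* (Wold-style): iteratively finds rank-one
   components ``t p'`` whose score ``t`` is orthogonalized against the class
   indicator ``y``, and removes them from ``X``. This strips structured
   variation that cannot discriminate the classes (batch effects, size
   effects) before the discriminant step.
2. *PLS1 discriminant analysis* via NIPALS on the filtered matrix against
   the centered 0/1 class indicator. Scores/loadings per component are
   retained together with explained-variance diagnostics (R2X per
   component, cumulative R2Y) and a cross-validated predictive fraction Q2
   from stratified k-fold CV; the OSC filter is refitted inside every fold
   so Q2 is not inflated by the class-aware filtering.

S-plot output (per-feature covariance and correlation with the first
predictive score) and coefficient-colored loadings reproduce the standard
chemometric displays used to pick discriminating metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import QuantMatrix

__all__ = [
    "OscComponent",
    "OscPlsModel",
    "scale_matrix",
    "osc_filter",
    "fit_plsda",
    "s_plot",
    "coefficient_loadings",
]

_ORTH_TOL = 1e-8


def scale_matrix(X: np.ndarray, method: str = "uv"):
    """Mean-center and scale columns. ``uv`` = unit variance, ``pareto`` =
    sqrt-of-SD scaling, ``center`` = centering only. Returns (Xs, mean, scale)."""
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if method == "uv":
        scale = np.where(sd > 0, sd, 1.0)
    elif method == "pareto":
        scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif method == "center":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {method!r}")
    return (X - center) / scale, center, scale


@dataclass
class OscComponent:
    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    removed_variance: float  # fraction of SS(X) removed


def _orthogonalize(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return t - y * (y @ t) / (y @ y)


def osc_filter(
    X: np.ndarray, y: np.ndarray, n_osc: int = 1, max_iter: int = 200, tol: float = 1e-12
) -> tuple[np.ndarray, list[OscComponent]]:
    """Remove ``n_osc`` rank-one components orthogonal to ``y`` from ``X``.

    ``X`` must already be column-centered/scaled and ``y`` centered. Each
    removed score is exactly orthogonalized against ``y`` before deflation,
    so ``|corr(t, y)|`` is at machine precision by construction. If nothing
    orthogonal to ``y`` remains (e.g. every column is a multiple of ``y``),
    remaining components are skipped and ``X`` is returned as-is.
    """
    X = np.array(X, dtype=float)
    y = np.asarray(y, dtype=float) - np.mean(y)
    if n_osc >= min(X.shape):
        raise ValueError(f"n_osc={n_osc} must be below rank bound {min(X.shape)}")
    ssx0 = float(np.sum(X**2))
    comps: list[OscComponent] = []
    for _ in range(n_osc):
        # initialize with the dominant principal-component score
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        t = U[:, 0] * S[0]
        for _ in range(max_iter):
            t_orth = _orthogonalize(t, y)
            nrm = float(np.linalg.norm(t_orth))
            if nrm**2 < tol * max(ssx0, 1.0):
                t_orth = None
                break
            w = X.T @ t_orth / (t_orth @ t_orth)
            w /= np.linalg.norm(w)
            t_new = X @ w
            if np.linalg.norm(t_new - t) <= 1e-12 * max(np.linalg.norm(t), 1.0):
                t = t_new
                break
            t = t_new
        if t_orth is None:
            break
        t = _orthogonalize(t, y)
        if float(t @ t) < tol * max(ssx0, 1.0):
            break
        p = X.T @ t / (t @ t)
        X -= np.outer(t, p)
        comps.append(
            OscComponent(
                weights=w,
                loadings=p,
                scores=t,
                removed_variance=float((t @ t) * (p @ p) / ssx0) if ssx0 else 0.0,
            )
        )
    for comp in comps:
        c = abs(comp.scores @ y) / (np.linalg.norm(comp.scores) * np.linalg.norm(y))
        if c >= _ORTH_TOL:
            raise RuntimeError(f"OSC score not orthogonal to y (|corr|={c:.2e})")
    return X, comps


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_comp: int):
    """PLS1 via NIPALS with p-deflation. Returns W, P, T, c, residual y."""
    n, p = X.shape
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    T = np.zeros((n, n_comp))
    c = np.zeros(n_comp)
    Xd, yd = X.copy(), y.copy()
    for k in range(n_comp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        P[:, k] = Xd.T @ t / tt
        c[k] = float(yd @ t / tt)
        W[:, k], T[:, k] = w, t
        Xd -= np.outer(t, P[:, k])
        yd = yd - c[k] * t
    return W, P, T, c, Xd, yd


@dataclass
class OscPlsModel:
    """Fitted OSC-PLSDA model for one two-class comparison."""

    feature_names: list[str]
    class_labels: tuple[str, str]  # (label coded 0, label coded 1)
    preprocessing: str
    center: np.ndarray
    scale: np.ndarray
    osc_components: list[OscComponent]
    pls_weights: np.ndarray  # W (p x a)
    pls_loadings: np.ndarray  # P (p x a)
    pls_scores: np.ndarray  # T (n x a), training scores
    y_loadings: np.ndarray  # c (a,)
    n_osc: int
    n_pls: int
    y_mean: float
    r2x: np.ndarray  # per PLS component
    r2x_residual: float
    r2y: np.ndarray  # cumulative per component
    q2: float
    osc_variant: str = "wold"
    sample_ids: list[str] = field(default_factory=list)
    y_train: np.ndarray | None = None

    # -- application to (new) data -------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.center) / self.scale
        for comp in self.osc_components:
            t = Xs @ comp.weights
            Xs = Xs - np.outer(t, comp.loadings)
        return Xs

    def transform(self, X: np.ndarray) -> np.ndarray:
        """PLS scores for (scaled, OSC-filtered) new observations."""
        Xs = self._prepare(X)
        W, P = self.pls_weights, self.pls_loadings
        R = W @ np.linalg.inv(P.T @ W)  # W* such that T = Xs W*
        return Xs @ R

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        T = self.transform(X)
        return self.y_mean + T @ self.y_loadings

    def predict_class(self, X: np.ndarray) -> list[str]:
        yhat = self.predict_value(X)
        return [self.class_labels[int(v >= 0.5)] for v in yhat]

    def scores_frame(self, quant: QuantMatrix) -> pd.DataFrame:
        """Score-plot table for any cohort (fitted groups or projections)."""
        idx = [quant.feature_names.index(f) for f in self.feature_names]
        T = self.transform(quant.values[:, idx])
        df = pd.DataFrame(T, columns=[f"t{k + 1}" for k in range(T.shape[1])])
        df.insert(0, "group", quant.groups)
        df.insert(0, "sample_id", quant.sample_ids)
        return df


def _stratified_folds(y01: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f)) for f in folds if f]


def fit_plsda(
    X: QuantMatrix | np.ndarray,
    y,
    n_pls: int = 2,
    n_osc: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
    scaling: str = "uv",
    feature_names: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> OscPlsModel:
    """Fit an OSC-PLSDA model for a two-class comparison.

    ``y`` may be a pair of group labels (samples taken from the
    :class:`QuantMatrix` group column, first label coded 0) or an explicit
    0/1 vector. Q2 is computed by stratified ``cv_folds``-fold CV with fold
    assignment drawn from ``seed``; scaling and OSC are refitted per fold.
    """
    if isinstance(X, QuantMatrix):
        if isinstance(y, (tuple, list)) and len(y) == 2 and isinstance(y[0], str):
            ga, gb = y
            sub = X.select_groups([ga, gb])
            y01 = np.array([0 if g == ga else 1 for g in sub.groups])
            labels = (ga, gb)
        else:
            sub = X
            y01 = np.asarray(y, dtype=int)
            labels = ("class0", "class1")
        Xmat = sub.values
        feature_names = list(sub.feature_names)
        sample_ids = list(sub.sample_ids)
    else:
        Xmat = np.asarray(X, dtype=float)
        y01 = np.asarray(y, dtype=int)
        labels = ("class0", "class1")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(Xmat.shape[1])]
        sample_ids = sample_ids or [f"s{i}" for i in range(Xmat.shape[0])]

    if set(np.unique(y01)) != {0, 1}:
        raise ValueError("y must encode exactly two classes")
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 3:
        raise ValueError("need at least 3 samples per class")
    if n_pls < 1:
        raise ValueError("n_pls must be >= 1")

    # drop constant columns (undefined under unit-variance scaling)
    sd = Xmat.std(axis=0, ddof=1)
    if np.any(sd == 0) and scaling != "center":
        dropped = [feature_names[j] for j in np.flatnonzero(sd == 0)]
        warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=2)
        keep = sd > 0
        Xmat = Xmat[:, keep]
        feature_names = [f for f, k in zip(feature_names, keep) if k]

    yc = y01 - y01.mean()
    Xs, center, scale = scale_matrix(Xmat, scaling)
    Xf, comps = osc_filter(Xs, yc, n_osc) if n_osc > 0 else (Xs, [])

    ssx0 = float(np.sum(Xf**2))
    ssy0 = float(np.sum(yc**2))
    W, P, T, c, Xres, yres = _nipals_pls1(Xf, yc, n_pls)
    r2x = np.array(
        [float(T[:, k] @ T[:, k]) * float(P[:, k] @ P[:, k]) / ssx0 for k in range(n_pls)]
    )
    # cumulative R2Y per component
    r2y = np.zeros(n_pls)
    y_acc = yc.copy()
    for k in range(n_pls):
        y_acc = y_acc - c[k] * T[:, k]
        r2y[k] = 1.0 - float(y_acc @ y_acc) / ssy0

    # orthogonality diagnostics (construction guarantees)
    for a in range(n_pls):
        for b in range(a + 1, n_pls):
            na, nb = np.linalg.norm(T[:, a]), np.linalg.norm(T[:, b])
            if na > 0 and nb > 0 and abs(T[:, a] @ T[:, b]) / (na * nb) >= _ORTH_TOL:
                raise RuntimeError("PLS scores lost mutual orthogonality")

    # cross-validated Q2 with the full pipeline refitted per fold
    press = tss = 0.0
    for test in _stratified_folds(y01, cv_folds, seed):
        train = np.setdiff1d(np.arange(len(y01)), test)
        if len(np.unique(y01[train])) < 2:
            continue
        Xtr, Xte = Xmat[train], Xmat[test]
        ytr = y01[train].astype(float)
        ym = ytr.mean()
        Xtr_s, ctr, str_ = scale_matrix(Xtr, scaling)
        str_ = np.where(str_ > 0, str_, 1.0)
        Xte_s = (Xte - ctr) / str_
        ytr_c = ytr - ym
        if n_osc > 0:
            Xtr_f, fcomps = osc_filter(Xtr_s, ytr_c, n_osc)
            for comp in fcomps:
                Xte_s = Xte_s - np.outer(Xte_s @ comp.weights, comp.loadings)
        else:
            Xtr_f = Xtr_s
        Wf, Pf, Tf, cf, _, _ = _nipals_pls1(Xtr_f, ytr_c, n_pls)
        Rf = Wf @ np.linalg.pinv(Pf.T @ Wf)
        yhat = ym + (Xte_s @ Rf) @ cf
        press += float(np.sum((y01[test] - yhat) ** 2))
        tss += float(np.sum((y01[test] - ym) ** 2))
    q2 = 1.0 - press / tss if tss > 0 else float("nan")

    return OscPlsModel(
        feature_names=feature_names,
        class_labels=labels,
        preprocessing=f"mean-center + {scaling}",
        center=center,
        scale=scale,
        osc_components=comps,
        pls_weights=W,
        pls_loadings=P,
        pls_scores=T,
        y_loadings=c,
        n_osc=len(comps),
        n_pls=n_pls,
        y_mean=float(y01.mean()),
        r2x=r2x,
        r2x_residual=float(np.sum(Xres**2)) / ssx0 if ssx0 else 0.0,
        r2y=r2y,
        q2=q2,
        sample_ids=sample_ids,
        y_train=y01,
    )


def s_plot(model: OscPlsModel, X: QuantMatrix | np.ndarray) -> pd.DataFrame:
    """Per-feature covariance and correlation with the first PLS score.

    Columns: ``feature``, ``p_cov`` (covariance of the scaled, OSC-filtered
    feature with t1), ``p_corr`` (its correlation, in [-1, 1]) and
    ``zero_variance`` flag (correlation reported as 0 for flat features).
    """
    if isinstance(X, QuantMatrix):
        idx = [X.feature_names.index(f) for f in model.feature_names]
        Xmat = X.values[:, idx]
    else:
        Xmat = np.asarray(X, dtype=float)
    Xs = model._prepare(Xmat)
    t1 = Xs @ model.pls_weights[:, 0]
    n = len(t1)
    tc = t1 - t1.mean()
    Xc = Xs - Xs.mean(axis=0)
    p_cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    flat = (sx == 0) | (st == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_corr = np.where(flat, 0.0, p_cov / (sx * st))
    return pd.DataFrame(
        {
            "feature": model.feature_names,
            "p_cov": p_cov,
            "p_corr": np.clip(p_corr, -1.0, 1.0),
            "zero_variance": flat,
        }
    )


def coefficient_loadings(model: OscPlsModel, X: QuantMatrix | np.ndarray) -> pd.DataFrame:
    """Back-scaled component-1 loadings with a significance color score.

    ``loading`` is the first predictive loading multiplied back by the
    feature scale (so magnitudes are comparable in the original units);
    ``color_score`` equals ``|p_corr|`` from the S-plot, the 0 (blue, no
    discrimination) to 1 (red, perfectly class-correlated) coloring used on
    coefficient loading plots.
    """
    sp = s_plot(model, X)
    return pd.DataFrame(
        {
            "feature": model.feature_names,
            "loading": model.pls_loadings[:, 0] * model.scale,
            "color_score": np.abs(sp["p_corr"].to_numpy()),
            "zero_variance": sp["zero_variance"].to_numpy(),
        }
    )
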