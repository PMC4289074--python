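"""Canonical discriminant analysis, quadratic discriminant
classification, and the 2-D fire-weather plane.

Canonical functions are eigenvectors of W⁻¹B (within- and between-group
cross-product matrices of the standardized variables), ordered by
eigenvalue; each axis's share of the summed eigenvalues is its
percentage of variation explained.  Coefficients are scaled so the
pooled within-class variance of each score is 1, scores are centred on
the grand mean, and each axis is oriented so its largest-|loading|
variable has a positive structural correlation.  Classification uses
quadratic discriminant analysis (class-specific covariances, equal
priors by default) with an exact rank-one-downdate leave-one-out
cross-validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass
class CanonicalFunction:
    coef: np.ndarray
    eigenvalue: float
    pct_variance: float
    structural_correlations: dict[str, float]
    F_approx: float
    p_value: float


@dataclass
class DiscriminantModel:
    variables: tuple[str, ...]
    classes: np.ndarray
    functions: list[CanonicalFunction]
    scores: np.ndarray                 # training-day canonical coordinates
    grand_mean: np.ndarray
    class_means: dict[int, np.ndarray]
    class_covs: dict[int, np.ndarray]
    priors: dict[int, float]
    misclassification: float | None = None


def _groups(values: np.ndarray, labels: np.ndarray):
    X = np.asarray(values, float)
    g = np.asarray(labels)
    m = g > 0
    return X[m], g[m]


def _rao_f(lmbda: np.ndarray, j: int, n: int, d: int, k: int):
    """Rao's approximate F for the test of canonical roots j.. (0-based)."""
    lam = lmbda[j:]
    wilks = float(np.prod(1.0 / (1.0 + lam)))
    p = d - j
    q = k - 1 - j
    df_h = p * q
    denom = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df_e = ((n - 1) - (d + k) / 2.0) * s - (df_h - 2) / 2.0
    w = wilks ** (1.0 / s)
    F = (1 - w) / w * df_e / df_h
    pval = float(stats.f.sf(F, df_h, df_e))
    return float(F), pval


def canonical_functions(
    values: np.ndarray,
    labels: np.ndarray,
    variables: tuple[str, ...],
    raw_values: np.ndarray | None = None,
    priors: str = "equal",
) -> DiscriminantModel:
    """Fit canonical discriminant functions and the QDA classifier.

    ``raw_values`` (post-transform, pre-standardization) are only used
    for structural correlations; Pearson correlation is unchanged by
    standardization so ``values`` is the default.
    """
    X, g = _groups(values, labels)
    n, d = X.shape
    ids = np.unique(g)
    k = len(ids)
    if k < 2:
        raise ValueError("discriminant analysis needs at least 2 classes")
    if n <= d + k:
        raise ValueError("too few observations")

    grand = X.mean(axis=0)
    B = np.zeros((d, d))
    W = np.zeros((d, d))
    for c in ids:
        Xi = X[g == c]
        dm = Xi.mean(axis=0) - grand
        B += Xi.shape[0] * np.outer(dm, dm)
        C = Xi - Xi.mean(axis=0)
        W += C.T @ C
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError:
        warnings.warn("singular within-group matrix; ridge regularization applied")
        evals, evecs = linalg.eigh(B, W + 1e-8 * np.trace(W) / d * np.eye(d))
    order = np.argsort(evals)[::-1]
    q = min(d, k - 1)
    evals = np.clip(evals[order][:q], 0.0, None)
    A = evecs[:, order][:, :q]

    # scale: unit pooled within-class variance of each score
    Sw = W / (n - k)
    for j in range(q):
        A[:, j] /= math.sqrt(A[:, j] @ Sw @ A[:, j])

    scores = (X - grand) @ A
    corr_base = np.asarray(raw_values, float)[np.asarray(labels) > 0] \
        if raw_values is not None else X
    total = float(evals.sum())
    functions = []
    for j in range(q):
        sc = scores[:, j]
        corr = {
            v: float(np.corrcoef(corr_base[:, i], sc)[0, 1])
            for i, v in enumerate(variables)
        }
        # orientation: largest-|loading| variable positive
        lead = max(corr, key=lambda v: abs(corr[v]))
        if corr[lead] < 0:
            A[:, j] *= -1
            scores[:, j] *= -1
            corr = {v: -c for v, c in corr.items()}
        F, pval = _rao_f(evals, j, n, d, k)
        functions.append(CanonicalFunction(
            coef=A[:, j].copy(),
            eigenvalue=float(evals[j]),
            pct_variance=float(100.0 * evals[j] / total) if total > 0 else 0.0,
            structural_correlations=corr,
            F_approx=F,
            p_value=pval,
        ))

    class_means, class_covs = {}, {}
    pooled = Sw
    for c in ids:
        Xi = X[g == c]
        class_means[int(c)] = Xi.mean(axis=0)
        if Xi.shape[0] > d:
            class_covs[int(c)] = np.atleast_2d(np.cov(Xi, rowvar=False, ddof=1))
        else:
            warnings.warn(f"class {c}: n <= d; pooled covariance fallback")
            class_covs[int(c)] = pooled.copy()
    if priors == "equal":
        pri = {int(c): 1.0 / k for c in ids}
    elif priors == "proportional":
        pri = {int(c): float((g == c).sum()) / n for c in ids}
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")

    model = DiscriminantModel(
        variables=tuple(variables), classes=ids, functions=functions,
        scores=scores, grand_mean=grand, class_means=class_means,
        class_covs=class_covs, priors=pri,
    )
    pred = qda_classify(model, X)
    model.misclassification = float((pred != g).mean())
    return model


def _qda_scores(values, means, covs, priors, classes) -> np.ndarray:
    X = np.asarray(values, float)
    out = np.empty((X.shape[0], len(classes)))
    for j, c in enumerate(classes):
        c = int(c)
        S = covs[c]
        sign, logdet = np.linalg.slogdet(S)
        diff = X - means[c]
        mahal = np.einsum("ij,ij->i", np.linalg.solve(S, diff.T).T, diff)
        out[:, j] = -0.5 * (logdet + mahal) + math.log(priors[c])
    return out


def qda_classify(model: DiscriminantModel, values: np.ndarray) -> np.ndarray:
    """Quadratic discriminant prediction (argmax Gaussian score)."""
    sc = _qda_scores(values, model.class_means, model.class_covs,
                     model.priors, model.classes)
    return model.classes[sc.argmax(axis=1)]


def loocv(
    values: np.ndarray,
    labels: np.ndarray,
    priors: str = "equal",
    dates: pd.DatetimeIndex | None = None,
    boundary_doys: tuple[int, ...] = (),
    boundary_window: int = 7,
) -> dict:
    """Leave-one-out cross-validated QDA misclassification.

    For each held-out day only its own class's mean and covariance
    change, so they are downdated exactly (rank-one) instead of refit.
    When ``dates`` and season-boundary days of year are supplied, also
    reports the fraction of misclassified days within
    ±``boundary_window`` days of a boundary.
    """
    X, g = _groups(values, labels)
    n, d = X.shape
    ids = np.unique(g)
    k = len(ids)
    stats_by_class = {}
    for c in ids:
        Xi = X[g == c]
        nc = Xi.shape[0]
        if nc <= d + 1:
            raise ValueError(f"class {c}: too few members for leave-one-out QDA")
        stats_by_class[int(c)] = (nc, Xi.mean(axis=0), (Xi - Xi.mean(axis=0)).T
                                  @ (Xi - Xi.mean(axis=0)))
    if priors == "equal":
        pri = {int(c): 1.0 / k for c in ids}
    else:
        pri = {int(c): stats_by_class[int(c)][0] / n for c in ids}

    covs = {c: S / (nc - 1) for c, (nc, mu, S) in stats_by_class.items()}
    means = {c: mu for c, (nc, mu, S) in stats_by_class.items()}

    # scores under every *full* model first; fix up the own-class column
    full = _qda_scores(X, means, covs, pri, ids)
    pred = np.empty(n, dtype=ids.dtype)
    col = {int(c): j for j, c in enumerate(ids)}
    for i in range(n):
        c = int(g[i])
        nc, mu, S = stats_by_class[c]
        x = X[i]
        mu1 = (nc * mu - x) / (nc - 1)
        dev = x - mu
        S1 = S - (nc / (nc - 1)) * np.outer(dev, dev)
        cov1 = S1 / (nc - 2)
        sign, logdet = np.linalg.slogdet(cov1)
        diff = x - mu1
        mahal = diff @ np.linalg.solve(cov1, diff)
        row = full[i].copy()
        row[col[c]] = -0.5 * (logdet + mahal) + math.log(pri[c])
        pred[i] = ids[row.argmax()]

    errors = pred != g
    rate = float(errors.mean())
    confusion = pd.crosstab(pd.Series(g, name="true"),
                            pd.Series(pred, name="predicted"))
    out = {"rate": rate, "confusion": confusion, "predicted": pred}

    if dates is not None and len(boundary_doys):
        from .weather_io import folded_doy

        doy = folded_doy(dates[np.asarray(labels) > 0])
        near = np.zeros(doy.shape, dtype=bool)
        for b in boundary_doys:
            delta = np.abs((doy - b + 182) % 365 - 182)
            near |= delta <= boundary_window
        out["boundary_fraction"] = (
            float(near[errors].mean()) if errors.any() else float("nan")
        )
    return out


def project(model: DiscriminantModel, values: np.ndarray) -> np.ndarray:
    """(function I, function II) coordinates for new standardized data;
    the second axis is zero-padded when only one function exists."""
    X = np.asarray(values, float)
    if X.shape[1] != len(model.variables):
        raise ValueError("variable mismatch: expected "
                         f"{len(model.variables)} columns, got {X.shape[1]}")
    A = np.column_stack([f.coef for f in model.functions])
    sc = (X - model.grand_mean) @ A
    if sc.shape[1] == 1:
        sc = np.column_stack([sc, np.zeros(len(sc))])
    return sc[:, :2]


def table_style_summary(model: DiscriminantModel) -> pd.DataFrame:
    """Long-format summary: one row per (function, variable) with the
    structural correlation and the function's variance share."""
    rows = []
    for i, f in enumerate(model.functions, start=1):
        for v, c in f.structural_correlations.items():
            rows.append({
                "function": i, "variable": v,
                "structural_correlation": c,
                "pct_variance": f.pct_variance,
            })
    return pd.DataFrame(rows)
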