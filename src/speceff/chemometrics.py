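"""Multivariate statistics for spectrum-effect and metabolomics modeling.

NIPALS partial least-squares regression with R2X/R2Y/Q2 and VIP scores,
PCA by singular value decomposition, OPLS-DA with an S-plot and a label
permutation test, per-feature volcano statistics (Welch t-test with
Benjamini-Hochberg adjustment), and hierarchical clustering.

Scaling conventions follow common chemometrics practice: unit-variance
(autoscaling) by default for regression on peak areas, Pareto scaling
offered for metabolomics intensities.  Standard deviations use N-1.

Sign convention: the first element of every weight/loading vector is forced
non-negative so that fitted models are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .metabolomics import FeatureTable


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass
class ScaledMatrix:
    """A centered/scaled matrix retaining the back-transform parameters."""

    values: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    mode: str
    names: list | None = None

    def transform(self, new: np.ndarray) -> np.ndarray:
        return (np.asarray(new, dtype=float) - self.mean) / self.scale

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.scale + self.mean


def autoscale(matrix, mode: str = "unit-variance") -> ScaledMatrix:
    """Center and scale columns: ``unit-variance``, ``pareto`` or ``none``.

    Pareto divides by the square root of the standard deviation, damping the
    dominance of high-abundance variables without fully equalizing them.
    """
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to scale")
    if mode == "none":
        return ScaledMatrix(X.copy(), np.zeros(X.shape[1]), np.ones(X.shape[1]),
                            mode, names)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if mode == "unit-variance":
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            labels = [names[i] if names else i for i in bad]
            raise ValueError(f"constant columns cannot be unit-variance scaled: {labels}")
        scale = sd
    elif mode == "pareto":
        scale = np.sqrt(sd)
        scale[scale == 0] = 1.0
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return ScaledMatrix((X - mean) / scale, mean, scale, mode, names)


def _as_scaled(matrix, mode: str = "unit-variance") -> ScaledMatrix:
    return matrix if isinstance(matrix, ScaledMatrix) else autoscale(matrix, mode)


def _fix_sign(*vectors: np.ndarray) -> None:
    """Flip the sign of all vectors in-place if the first's leading entry is negative."""
    if vectors[0].flat[0] < 0:
        for v in vectors:
            v *= -1.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    scores: np.ndarray
    loadings: np.ndarray  # variables x components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca(matrix, n_components: int | None = None) -> PCAModel:
    """Principal component analysis of the column-centered matrix via SVD."""
    X = np.asarray(matrix.values if isinstance(matrix, ScaledMatrix) else matrix,
                   dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = S**2 / np.sum(S**2)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T.copy()
    for j in range(n_components):
        if loadings[0, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAModel(scores, loadings, evr[:n_components], mean)


# ---------------------------------------------------------------------------
# PLSR (NIPALS) + VIP + Q2
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    """A NIPALS PLSR fit on scaled X and Y.

    Weights ``W`` (p x A, unit columns), scores ``T`` (n x A), X-loadings
    ``P`` (p x A) and Y-loadings ``C`` (m x A).  ``r2x``/``r2y`` hold the
    per-component explained fractions; the ``*_cum`` arrays their cumulative
    sums.  ``coefficients`` maps scaled X to scaled Y.
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    C: np.ndarray
    r2x: np.ndarray
    r2y: np.ndarray
    x_scaler: ScaledMatrix | None = None
    y_scaler: ScaledMatrix | None = None

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def r2x_cum(self) -> np.ndarray:
        return np.cumsum(self.r2x)

    @property
    def r2y_cum(self) -> np.ndarray:
        return np.cumsum(self.r2y)

    @property
    def coefficients(self) -> np.ndarray:
        # B = W (P'W)^-1 C'
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.C.T)

    def predict_scaled(self, X_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(X_scaled, dtype=float) @ self.coefficients


def plsr_fit(X, Y, n_components: int, max_iter: int = 2000,
             tol: float = 1e-9) -> PLSRModel:
    """Fit a PLSR model by NIPALS with deflation of both blocks.

    ``X`` and ``Y`` may be raw arrays/DataFrames (autoscaled to unit
    variance) or pre-built :class:`ScaledMatrix` objects.  For a single y
    variable each component is exact in one pass; with multivariate Y the
    inner loop iterates to convergence of the score vector.
    """
    xs = _as_scaled(X)
    ys = _as_scaled(Y)
    E = xs.values.copy()
    F = ys.values.copy()
    n, p = E.shape
    m = F.shape[1]
    if F.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    ssx_total = np.sum(E**2)
    ssy_total = np.sum(F**2)
    if ssx_total == 0 or ssy_total == 0:
        raise ValueError("X and Y must have non-zero variance")

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((m, n_components))
    r2x = np.zeros(n_components)
    r2y = np.zeros(n_components)

    for a in range(n_components):
        u = F[:, int(np.argmax(np.sum(F**2, axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = E.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                raise ConvergenceError(
                    f"component {a + 1}: residual X carries no covariance with Y"
                )
            w /= norm_w
            t = E @ w
            c = F.T @ t / (t @ t)
            if m == 1:
                break
            u = F @ c / (c @ c)
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1e-300):
                break
            t_old = t
        else:
            raise ConvergenceError(
                f"NIPALS did not converge in {max_iter} iterations "
                f"(component {a + 1})"
            )
        p_vec = E.T @ t / (t @ t)
        _fix_sign(w, t, p_vec, c)
        E = E - np.outer(t, p_vec)
        F = F - np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p_vec, c
        r2x[a] = (t @ t) * (p_vec @ p_vec) / ssx_total
        r2y[a] = (t @ t) * (c @ c) / ssy_total

    return PLSRModel(W, T, P, C, r2x, r2y, x_scaler=xs, y_scaler=ys)


def vip(model: PLSRModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt(p * sum_a SSY_a * w_aj^2 / sum_a SSY_a)`` with unit-norm
    weight vectors; the mean of squared VIPs is exactly 1.
    """
    p = model.W.shape[0]
    ssy = model.r2y
    denom = ssy.sum()
    if denom <= 0:
        raise ValueError("model explains no Y-variance; VIP undefined")
    return np.sqrt(p * (model.W**2 @ ssy) / denom)


def q2_cross_validation(X, Y, n_components: int, n_folds: int = 7,
                        seed: int = 0, scale: str = "unit-variance") -> np.ndarray:
    """Cumulative Q2 per component by k-fold cross-validation.

    ``Q2_a = 1 - PRESS_a / SS`` where PRESS sums squared out-of-fold
    prediction errors of the a-component model and SS the squared deviations
    of held-out responses from the training means, both on the training
    fold's scale.  Fold assignment is a seeded random permutation dealt
    round-robin, so identical seeds give identical folds.
    """
    X = np.asarray(X.values if isinstance(X, ScaledMatrix) else X, dtype=float)
    Y = np.asarray(Y.values if isinstance(Y, ScaledMatrix) else Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if not 2 <= n_folds <= n:
        raise ValueError("n_folds must be between 2 and the number of rows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [order[k::n_folds] for k in range(n_folds)]

    press = np.zeros(n_components)
    ss = 0.0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        xs = autoscale(X[train_idx], scale)
        ys = autoscale(Y[train_idx], scale)
        model = plsr_fit(xs, ys, n_components)
        Xt = xs.transform(X[test_idx])
        Yt = ys.transform(Y[test_idx])
        ss += float(np.sum(Yt**2))
        # cumulative prediction over components: sum_a t_a c_a'
        E = Xt.copy()
        pred = np.zeros_like(Yt)
        for a in range(n_components):
            t = E @ model.W[:, a]
            pred = pred + np.outer(t, model.C[:, a])
            E = E - np.outer(t, model.P[:, a])
            press[a] += float(np.sum((Yt - pred) ** 2))
    return 1.0 - press / ss


def select_n_components(q2: np.ndarray, min_gain: float = 0.0) -> int:
    """Smallest component count attaining the maximal Q2 (within min_gain)."""
    q2 = np.asarray(q2, dtype=float)
    best = np.max(q2)
    return int(np.argmax(q2 >= best - min_gain)) + 1


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class OPLSDAModel:
    """A two-class OPLS-DA fit: one predictive + n orthogonal components."""

    predictive_scores: np.ndarray
    predictive_weights: np.ndarray
    predictive_loadings: np.ndarray
    orthogonal_scores: np.ndarray  # n x n_orth
    orthogonal_loadings: np.ndarray  # p x n_orth
    vip: np.ndarray
    s_plot_cov: np.ndarray
    s_plot_corr: np.ndarray
    r2y: float
    q2: float | None
    classes: tuple
    y: np.ndarray
    x_scaler: ScaledMatrix | None = None


def _class_vector(class_labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(class_labels)
    classes = tuple(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {len(classes)}")
    y = np.where(labels == classes[0], -1.0, 1.0)
    return y - y.mean(), classes


def oplsda_fit(X, class_labels, n_orthogonal: int = 1,
               scale: str = "unit-variance", cv_folds: int | None = 7,
               seed: int = 0) -> OPLSDAModel:
    """Fit OPLS-DA: split X-variation into class-predictive and orthogonal parts.

    Classes are coded -1/+1 and centered.  Orthogonal components are removed
    from X one at a time (each has, by construction, zero covariance with the
    class vector); the predictive component is then a one-component PLS on
    the filtered X.  The S-plot pairs each variable's covariance and
    correlation with the predictive score.  ``q2`` is the cross-validated
    predictive fraction from :func:`q2_cross_validation` on a one-component
    PLS of the orthogonal-filtered data (None when ``cv_folds`` is None).
    """
    xs = _as_scaled(X, scale)
    E = xs.values.copy()
    y, classes = _class_vector(class_labels)
    ssy = float(y @ y)
    if ssy == 0:
        raise ValueError("class vector has no variance")

    w = E.T @ y / ssy
    w_norm = np.linalg.norm(w)
    if w_norm == 0:
        raise ValueError("X carries no class-correlated variation")
    w /= w_norm
    T_orth = np.zeros((E.shape[0], n_orthogonal))
    P_orth = np.zeros((E.shape[1], n_orthogonal))
    for k in range(n_orthogonal):
        t = E @ w
        p_vec = E.T @ t / (t @ t)
        w_orth = p_vec - (w @ p_vec) * w
        norm = np.linalg.norm(w_orth)
        if norm < 1e-12:
            # no orthogonal variation left; keep zero component
            break
        w_orth /= norm
        t_orth = E @ w_orth
        p_orth = E.T @ t_orth / (t_orth @ t_orth)
        _fix_sign(w_orth, t_orth, p_orth)
        E = E - np.outer(t_orth, p_orth)
        T_orth[:, k] = t_orth
        P_orth[:, k] = p_orth

    t_pred = E @ w
    p_pred = E.T @ t_pred / (t_pred @ t_pred)
    w_signed = w.copy()
    _fix_sign(w_signed, t_pred, p_pred)
    c = float(y @ t_pred) / float(t_pred @ t_pred)
    resid = y - c * t_pred
    r2y = 1.0 - float(resid @ resid) / ssy

    n = len(y)
    cov = xs.values.T @ t_pred / (n - 1)
    sd_x = xs.values.std(axis=0, ddof=1)
    sd_t = t_pred.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sd_x > 0, cov / (sd_x * sd_t), 0.0)

    p_vars = xs.values.shape[1]
    vip_vals = np.sqrt(p_vars * w_signed**2)

    q2 = None
    if cv_folds is not None:
        q2 = float(q2_cross_validation(E, y[:, None], 1, n_folds=min(cv_folds, n),
                                       seed=seed, scale="none")[-1])

    return OPLSDAModel(
        predictive_scores=t_pred,
        predictive_weights=w_signed,
        predictive_loadings=p_pred,
        orthogonal_scores=T_orth,
        orthogonal_loadings=P_orth,
        vip=vip_vals,
        s_plot_cov=cov,
        s_plot_corr=np.clip(corr, -1.0, 1.0),
        r2y=r2y,
        q2=q2,
        classes=classes,
        y=y,
        x_scaler=xs,
    )


def permutation_test(X, class_labels, n_permutations: int = 200, seed: int = 0,
                     n_orthogonal: int = 1, scale: str = "unit-variance",
                     cv_folds: int = 7) -> dict:
    """Label permutation test for an OPLS-DA model.

    The class labels are permuted ``n_permutations`` times; R2Y and Q2 are
    refitted for each permutation and the add-one p-value
    ``p = (1 + #{permuted >= observed}) / (1 + n_permutations)`` is reported
    for both statistics.  The minimum attainable p is 1/(n_permutations+1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = np.asarray(class_labels)
    rng = np.random.default_rng(seed)
    observed = oplsda_fit(X, labels, n_orthogonal, scale, cv_folds, seed=seed)
    perm_r2y = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        m = oplsda_fit(X, perm, n_orthogonal, scale, cv_folds, seed=seed)
        perm_r2y[i] = m.r2y
        perm_q2[i] = m.q2
    p_r2y = (1 + int(np.sum(perm_r2y >= observed.r2y))) / (1 + n_permutations)
    p_q2 = (1 + int(np.sum(perm_q2 >= observed.q2))) / (1 + n_permutations)
    return {
        "r2y_observed": observed.r2y,
        "q2_observed": observed.q2,
        "p_r2y": p_r2y,
        "p_q2": p_q2,
        "permuted_r2y": perm_r2y,
        "permuted_q2": perm_q2,
    }


def s_plot_table(model: OPLSDAModel, variable_ids=None) -> pd.DataFrame:
    """Tidy S-plot coordinates: per-variable covariance and correlation."""
    n = model.s_plot_cov.size
    if variable_ids is None:
        variable_ids = (
            model.x_scaler.names
            if model.x_scaler is not None and model.x_scaler.names
            else [f"V{j + 1}" for j in range(n)]
        )
    return pd.DataFrame(
        {"covariance": model.s_plot_cov, "correlation": model.s_plot_corr,
         "vip": model.vip},
        index=pd.Index(variable_ids, name="variable"),
    )


# ---------------------------------------------------------------------------
# volcano / differential analysis
# ---------------------------------------------------------------------------


def volcano(table: FeatureTable, alpha: float = 0.05,
            vip_threshold: float = 1.0, vip_values: np.ndarray | None = None,
            scale: str = "pareto", n_orthogonal: int = 1,
            seed: int = 0) -> pd.DataFrame:
    """Per-feature differential statistics between the table's two groups.

    Welch t-test and group-mean fold change (second group over first, in the
    order the labels first appear), Benjamini-Hochberg adjusted p-values, and
    OPLS-DA VIP (computed here on Pareto-scaled data unless supplied).  A
    feature is ``selected`` when VIP exceeds ``vip_threshold`` and its raw
    t-test p-value is below ``alpha`` — raw, because the univariate check is
    a validation of the VIP screen, not an independent discovery scan; the
    adjusted p-value is reported alongside.
    """
    y, classes = _class_vector(table.groups)
    ga = table.intensities[np.asarray(table.groups) == classes[0]].to_numpy(float)
    gb = table.intensities[np.asarray(table.groups) == classes[1]].to_numpy(float)
    if min(len(ga), len(gb)) < 2:
        raise ValueError("each group needs at least 2 samples")

    if vip_values is None:
        try:
            model = oplsda_fit(table.intensities, table.groups,
                               n_orthogonal=n_orthogonal, scale=scale,
                               cv_folds=None, seed=seed)
            vip_values = model.vip
        except ValueError:
            # no class-correlated variation: no multivariate evidence at all
            vip_values = np.zeros(len(table.feature_ids))
    vip_values = np.asarray(vip_values, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(gb, ga, axis=0, equal_var=False)
        mean_a, mean_b = ga.mean(axis=0), gb.mean(axis=0)
        fc = np.where(mean_a > 0, mean_b / mean_a, np.nan)
        log2fc = np.where(fc > 0, np.log2(fc), np.nan)

    p_adj = np.full_like(p_val, np.nan)
    ok = np.isfinite(p_val)
    if ok.any():
        p_adj[ok] = stats.false_discovery_control(p_val[ok], method="bh")
    selected = ok & (vip_values > vip_threshold) & (p_val < alpha)

    return pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "t_statistic": t_stat,
            "p_value": p_val,
            "p_adjusted": p_adj,
            "vip": vip_values,
            "selected": selected,
        },
        index=table.feature_ids,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def hierarchical_clustering(matrix, method: str = "ward",
                            metric: str = "euclidean") -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of the rows; returns (linkage matrix, leaf order).

    Delegates to scipy's linkage, which breaks distance ties
    deterministically by lowest observation index; the leaf order is the
    dendrogram's left-to-right leaf sequence.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix entries must be finite")
    Z = hierarchy.linkage(X, method=method, metric=metric)
    return Z, hierarchy.leaves_list(Z)
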