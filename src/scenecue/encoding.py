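"""Layer-wise decoding of behavioral scores from DNN feature maps.

Per-image behavioral scores (realness ratings, 2AFC responses,
categorization accuracy) are predicted from each model instance's
layer-wise feature matrices via leave-one-out cross-validated ridge
regression, after sparse-random-projection dimensionality reduction.
Decoding quality per feature map is the Pearson correlation between
predicted and actual scores; layer scores are binned into 10 slices of
normalized depth and trained instances are compared to randomly
initialized instances per bin with a label-permutation test,
Benjamini-Hochberg FDR across bins, bootstrap CIs, and paired JZS Bayes
factors.

The statsmodels-style entry point is :class:`EncodingAnalysis` (built from
a FeatureStore plus a score vector) whose ``fit()`` returns
:class:`EncodingResults` carrying per-layer scores, per-bin means, and the
trained-vs-random bin comparison table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import t as t_dist
from sklearn.random_projection import SparseRandomProjection, johnson_lindenstrauss_min_dim
from statsmodels.stats.multitest import multipletests

from .synthetic import FeatureStore

logger = logging.getLogger(__name__)

__all__ = [
    "srp_project",
    "loo_ridge_decode",
    "loo_ridge_fixed_alpha",
    "decode_feature_store",
    "bin_scores",
    "permutation_bin_test",
    "fdr_bh",
    "bootstrap_diff_ci",
    "jzs_bf_paired",
    "compare_bins",
    "EncodingAnalysis",
    "EncodingResults",
]

DEFAULT_ALPHA_GRID = np.logspace(-1, 5, 13)


# ---------------------------------------------------------------------------
# sparse random projection


def srp_project(X: np.ndarray, target_dim: int | None = None,
                eps: float | None = None, seed: int = 0) -> np.ndarray:
    """Sparse random projection to `target_dim` columns (or to the
    Johnson-Lindenstrauss minimum dimension for distortion `eps`).

    Projection entries are in {-1, 0, +1} times a scale with nonzero density
    1/sqrt(D), scaled to preserve pairwise distances in expectation. If the
    requested dimension is not below the input dimension the input is
    returned unchanged (logged).
    """
    X = np.asarray(X, dtype=float)
    n, D = X.shape
    if target_dim is None:
        if eps is None:
            raise ValueError("give either target_dim or eps")
        target_dim = int(johnson_lindenstrauss_min_dim(n, eps=eps))
    if target_dim >= D:
        logger.info("srp_project: target_dim %d >= input dim %d; passing through",
                    target_dim, D)
        return X
    proj = SparseRandomProjection(n_components=target_dim, density=1.0 / np.sqrt(D),
                                  random_state=seed)
    return proj.fit_transform(X)


# ---------------------------------------------------------------------------
# leave-one-out ridge


def _ridge_gcv_predict(X_tr, yc_tr, x_new, alpha_grid):
    """Ridge fit on the training fold with GCV-selected alpha; predict x_new.

    X columns are standardized with training-fold statistics (constant
    columns get unit scale); yc_tr is the already-centered response.
    GCV(alpha) = n * ||e||^2 / (n - edf)^2 with edf = sum_j d_j,
    d_j = s_j^2 / (s_j^2 + alpha).
    """
    n, p = X_tr.shape
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X_tr - mu) / sd

    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ yc_tr
    yy = float(yc_tr @ yc_tr)
    best_alpha, best_gcv = None, np.inf
    for alpha in alpha_grid:
        d = S**2 / (S**2 + alpha)
        rss = yy - float((d * (2 - d) * uty**2).sum())
        denom = max(n - float(d.sum()), 1e-10)
        gcv = n * rss / denom**2
        if gcv < best_gcv:
            best_gcv, best_alpha = gcv, alpha
    beta = Vt.T @ (S / (S**2 + best_alpha) * uty)
    pred = float((x_new - mu) / sd @ beta)
    return pred, best_alpha


def loo_ridge_decode(X: np.ndarray, y: np.ndarray,
                     alpha_grid: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out cross-validated ridge predictions of y from X.

    For each held-out image the penalty is chosen on the training fold by
    closed-form generalized cross-validation over `alpha_grid` (default 13
    log-spaced points in 10^-1..10^5) and the held-out score is predicted
    from the training-fold fit. X standardization statistics come from the
    training fold only; y is centered once on the full sample — correlation
    scoring is location-invariant, and per-fold centering would make a
    fully-shrunk (null) fit predict the leave-one-out mean, which is
    perfectly anti-correlated with the held-out values (the constant-model
    LOO artifact).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y disagree in length")
    if len(y) < 10:
        raise ValueError("need at least 10 images for leave-one-out decoding")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if np.all(y == y[0]):
        raise ValueError("constant y: downstream correlation undefined")
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid, float)
    if np.any(grid <= 0):
        raise ValueError("alpha grid must be positive")
    ybar = y.mean()
    yc = y - ybar
    preds = np.empty(len(y))
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        preds[i], _ = _ridge_gcv_predict(X[mask], yc[mask], X[i], grid)
        mask[i] = True
    return preds + ybar


def loo_ridge_fixed_alpha(X: np.ndarray, y: np.ndarray, alpha: float,
                          add_intercept: bool = True) -> np.ndarray:
    """Closed-form leave-one-out residuals for ridge at a fixed penalty.

    Uses the linear-smoother identity e_loo_i = e_i / (1 - h_ii) with
    H = Z (Z'Z + alpha*P)^-1 Z', intercept column unpenalized. The design is
    used exactly as given (no per-fold re-standardization), which is the
    regime in which the identity is exact.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(len(y)), X]) if add_intercept else X
    P = np.eye(Z.shape[1])
    if add_intercept:
        P[0, 0] = 0.0
    A = Z.T @ Z + alpha * P
    Ainv_Zt = np.linalg.solve(A, Z.T)
    h = np.einsum("ij,ji->i", Z, Ainv_Zt)
    resid = y - Z @ (Ainv_Zt @ y)
    return resid / (1.0 - h)


def decode_feature_store(store: FeatureStore, y, alpha_grid=None,
                         srp_dim: int | None = None, seed: int = 0) -> pd.DataFrame:
    """LOO-ridge decoding score r = corr(predicted, actual) for every
    (model, layer) matrix in the store; optional SRP reduction first.

    Returns tidy columns model, layer, depth, trained, r.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    for row in store.meta.itertuples(index=False):
        X = store.matrix(row.model, int(row.layer))
        if srp_dim is not None:
            X = srp_project(X, target_dim=srp_dim, seed=seed)
        preds = loo_ridge_decode(X, y, alpha_grid)
        r = float(np.corrcoef(preds, y)[0, 1]) if np.std(preds) > 0 else 0.0
        rows.append((row.model, int(row.layer), float(row.depth), bool(row.trained), r))
    return pd.DataFrame(rows, columns=["model", "layer", "depth", "trained", "r"])


# ---------------------------------------------------------------------------
# depth bins and group inference


def bin_scores(scores: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Average layer scores within depth bins.

    Bin b (1-based) covers [(b-1)/n, b/n), the last bin closed at depth 1.
    Bins with no member layers for a model are kept as missing (NaN).
    Returns tidy columns model, trained, bin, mean_r.
    """
    depths = scores["depth"].to_numpy(float)
    if np.any(depths < 0) or np.any(depths > 1):
        raise ValueError("depths must lie in [0, 1]")
    b = np.minimum((depths * n_bins).astype(int), n_bins - 1) + 1
    df = scores.assign(bin=b)
    agg = df.groupby(["model", "trained", "bin"])["r"].mean()
    full = pd.MultiIndex.from_product(
        [scores["model"].unique(), range(1, n_bins + 1)], names=["model", "bin"])
    trained_by_model = scores.drop_duplicates("model").set_index("model")["trained"]
    out = agg.reset_index().set_index(["model", "bin"])["r"].reindex(full).reset_index()
    out["trained"] = out["model"].map(trained_by_model)
    out = out.rename(columns={"r": "mean_r"})
    return out[["model", "trained", "bin", "mean_r"]]


def _bin_matrix(binned: pd.DataFrame, trained: bool) -> np.ndarray:
    sub = binned[binned["trained"] == trained]
    wide = sub.pivot(index="model", columns="bin", values="mean_r").sort_index()
    return wide.to_numpy(float)


def permutation_bin_test(trained: np.ndarray, random: np.ndarray,
                         n_perm: int = 10000, seed: int = 0) -> dict:
    """One-sided permutation test of mean(trained) - mean(random) per bin.

    The null distribution permutes the trained/random labels over the
    pooled model scores; p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    trained = np.atleast_2d(np.asarray(trained, float))
    random = np.atleast_2d(np.asarray(random, float))
    if trained.shape[0] < 2 or random.shape[0] < 2:
        raise ValueError("need at least 2 model instances per group")
    if trained.shape[1] != random.shape[1]:
        raise ValueError("groups disagree in number of bins")
    if n_perm < 1000:
        warnings.warn("n_perm < 1000 gives coarse p-values", stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    n_t = trained.shape[0]
    pooled = np.vstack([trained, random])          # (n_total, n_bins)
    n_total, n_bins = pooled.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (empty) bins
        observed = np.nanmean(trained, axis=0) - np.nanmean(random, axis=0)
        # one permutation matrix reused across bins keeps the per-bin nulls
        # coupled the same way the data are (same models in every bin)
        perm_idx = np.argsort(rng.random((n_perm, n_total)), axis=1)
        perm_vals = pooled[perm_idx]               # (n_perm, n_total, n_bins)
        stat = (np.nanmean(perm_vals[:, :n_t, :], axis=1)
                - np.nanmean(perm_vals[:, n_t:, :], axis=1))
    with np.errstate(invalid="ignore"):
        count = np.sum(stat >= observed[None, :], axis=0)
    p = (1.0 + count) / (n_perm + 1.0)
    p[~np.isfinite(observed)] = np.nan             # empty bins carry no test
    return {"observed": observed, "p": p, "n_perm": n_perm, "n_bins": n_bins}


def fdr_bh(p, alpha: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up FDR correction.

    Returns monotone q-values and the rejection set at `alpha`. Missing
    p-values (empty bins) are excluded from the correction and come back
    as NaN / not rejected.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, qf, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
        q[finite] = qf
        reject[finite] = rej
    return {"q": q, "reject": reject}


def bootstrap_diff_ci(diffs, n_boot: int = 1000, seed: int = 0) -> dict:
    """Bootstrap mean and percentile 95% CI of paired per-model differences,
    resampling models with replacement."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ValueError("need at least 2 paired differences")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
    means = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return {"mean": float(means.mean()), "ci": (float(lo), float(hi)), "n_boot": n_boot}


def jzs_bf_paired(diffs, prior_scale: float = 0.707) -> float:
    """One-sample JZS (Jeffreys-Zellner-Siow) Bayes factor BF10 on paired
    differences, testing mean 0 against a Cauchy(0, prior_scale) prior on
    the standardized effect size.

    BF10 = int (1 + N g r^2)^{-1/2} [1 + t^2 / (nu (1 + N g r^2))]^{-(nu+1)/2}
               pi(g) dg  /  [1 + t^2/nu]^{-(nu+1)/2},

    with pi(g) = inverse-chi^2(1), evaluated by adaptive quadrature; the
    ratio is monotone in |t| for fixed n.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    return jzs_bf_from_t(t, n, prior_scale)


def jzs_bf_from_t(t: float, n: int, prior_scale: float = 0.707) -> float:
    """JZS BF10 from a one-sample t statistic with n observations."""
    nu = n - 1
    r2 = prior_scale**2
    log_h0 = -(nu + 1) / 2 * np.log1p(t**2 / nu)

    def integrand(g):
        c = 1.0 + n * g * r2
        log_lik = -0.5 * np.log(c) - (nu + 1) / 2 * np.log1p(t**2 / (nu * c))
        log_prior = -1.5 * np.log(g) - 1.0 / (2.0 * g) - 0.5 * np.log(2.0 * np.pi)
        return np.exp(log_lik + log_prior - log_h0)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=0.0, epsrel=1e-10, limit=400)
    return float(val)


def compare_bins(trained_bins: np.ndarray, random_bins: np.ndarray,
                 n_perm: int = 10000, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05, prior_scale: float = 0.707) -> pd.DataFrame:
    """Trained-vs-random inference per depth bin.

    Columns: bin, diff (mean trained - mean random), p (one-sided
    permutation), q (BH-FDR across bins), reject, boot_mean, ci_lower,
    ci_upper (bootstrap over models), bf10 (paired JZS Bayes factor on the
    per-rank model differences).
    """
    trained_bins = np.atleast_2d(np.asarray(trained_bins, float))
    random_bins = np.atleast_2d(np.asarray(random_bins, float))
    perm = permutation_bin_test(trained_bins, random_bins, n_perm=n_perm, seed=seed)
    fdr = fdr_bh(perm["p"], alpha=alpha)
    n_bins = trained_bins.shape[1]
    rows = []
    for b in range(n_bins):
        tcol = trained_bins[:, b]
        rcol = random_bins[:, b]
        ok = np.isfinite(tcol) & np.isfinite(rcol)
        if ok.sum() >= 2:
            diffs = tcol[ok] - rcol[ok]
            boot = bootstrap_diff_ci(diffs, n_boot=n_boot, seed=seed + b)
            if np.std(diffs, ddof=1) > 0:
                bf10 = jzs_bf_paired(diffs, prior_scale=prior_scale)
            else:
                bf10 = np.nan
            rows.append((b + 1, perm["observed"][b], perm["p"][b], fdr["q"][b],
                         bool(fdr["reject"][b]), boot["mean"], boot["ci"][0],
                         boot["ci"][1], bf10))
        else:
            rows.append((b + 1, np.nan, np.nan, np.nan, False,
                         np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["bin", "diff", "p", "q", "reject",
                                       "boot_mean", "ci_lower", "ci_upper", "bf10"])


# ---------------------------------------------------------------------------
# model-object front end


class EncodingAnalysis:
    """Layer-wise encoding analysis of one behavioral score vector.

    Parameters
    ----------
    store : FeatureStore
        Per (model instance, layer) image-by-feature matrices with depth and
        trained/random metadata; image order must match `y`.
    y : array-like
        One behavioral score per image.
    srp_dim : int, optional
        Sparse-random-projection target dimensionality applied to each
        feature matrix before decoding (pass-through when not below the
        input dimension).
    """

    def __init__(self, store: FeatureStore, y, srp_dim: int | None = None,
                 alpha_grid=None, n_bins: int = 10, seed: int = 0):
        store.validate()
        self.store = store
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(store.image_ids):
            raise ValueError("y length must match the store's image count")
        self.srp_dim = srp_dim
        self.alpha_grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
        self.n_bins = n_bins
        self.seed = seed

    def fit(self, n_perm: int = 10000, n_boot: int = 1000,
            alpha: float = 0.05, prior_scale: float = 0.707) -> "EncodingResults":
        scores = decode_feature_store(self.store, self.y, self.alpha_grid,
                                      srp_dim=self.srp_dim, seed=self.seed)
        binned = bin_scores(scores, n_bins=self.n_bins)
        trained = _bin_matrix(binned, True)
        random = _bin_matrix(binned, False)
        comparison = compare_bins(trained, random, n_perm=n_perm, n_boot=n_boot,
                                  seed=self.seed, alpha=alpha, prior_scale=prior_scale)
        return EncodingResults(scores=scores, binned=binned, comparison=comparison,
                               n_bins=self.n_bins, seed=self.seed)


@dataclass
class EncodingResults:
    """Results of an EncodingAnalysis fit."""

    scores: pd.DataFrame       # model, layer, depth, trained, r
    binned: pd.DataFrame       # model, trained, bin, mean_r
    comparison: pd.DataFrame   # bin, diff, p, q, reject, boot_mean, ci, bf10
    n_bins: int
    seed: int

    def summary(self) -> str:
        sig = self.comparison[self.comparison["reject"]]["bin"].tolist()
        lines = [
            f"Layer-wise encoding analysis ({self.scores['model'].nunique()} model "
            f"instances, {self.n_bins} depth bins)",
            f"FDR-significant bins (q < 0.05): {sig if sig else 'none'}",
            self.comparison.to_string(index=False,
                                      float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)
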