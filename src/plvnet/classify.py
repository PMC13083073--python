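"""L1-regularized logistic classification with fold-internal selection,
Bolasso stability selection, ROC/AUC, permutation testing, and BCa
bootstrap intervals.

The regularization path mirrors the glmnet convention: features are
standardized inside the procedure, lambda_max is the smallest penalty that
zeroes every coefficient, and the grid descends log-linearly over a fixed
ratio. Cross-validated loss is the per-observation binomial deviance;
lambda_min minimizes the mean CV deviance and lambda_1se is the largest
lambda within one standard error of that minimum. Every observation is one
subject, so no subject ever contributes to the fold it is predicted in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "LassoResult", "RocResult", "PermutationResult", "BolassoResult", "ModelReport",
    "lasso_cv", "bolasso", "roc_auc", "confusion_metrics", "permutation_test",
    "bca_interval", "run_comparison", "sparsity_label", "COMPARISONS",
]

COMPARISONS = {
    "HC_vs_PDMCI": ("HC", "PD_MCI"),
    "HC_vs_PDD": ("HC", "PDD"),
    "HC_vs_DLB": ("HC", "DLB"),
}


def sparsity_label(k: int) -> str:
    """Model-complexity terminology for K non-zero coefficients."""
    if k == 0:
        return "intercept_only"
    if k == 1:
        return "single_feature"
    if k <= 5:
        return "sparse_multivariate"
    return "compact_multivariate"


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population sd, as in glmnet
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe, mu, sd


def _lambda_grid(xs: np.ndarray, y: np.ndarray, n_lambda: int,
                 min_ratio: float) -> np.ndarray:
    n = len(y)
    resid = y - y.mean()
    lam_max = np.max(np.abs(xs.T @ resid)) / n
    lam_max = max(lam_max, 1e-10)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


try:  # numba keeps the warm-started path fast enough for Bolasso resampling
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        def deco(fn):
            return fn
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _path_kernel(xs, y, lambdas, tol, max_outer):  # pragma: no cover - jitted
    n, p = xs.shape
    beta = np.zeros(p)
    ybar = y.mean()
    icpt = np.log((ybar + 1e-12) / (1 - ybar + 1e-12))
    coefs = np.empty((len(lambdas), p))
    icpts = np.empty(len(lambdas))
    for li in range(len(lambdas)):
        lam = lambdas[li]
        for _outer in range(max_outer):
            eta = xs @ beta + icpt
            prob = 1.0 / (1.0 + np.exp(-eta))
            w = prob * (1.0 - prob)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            wn = w / n
            v = (xs * xs).T @ wn
            r = (y - prob) / w  # working residual z - eta
            beta_old = beta.copy()
            icpt_old = icpt
            for _sweep in range(200):
                delta = 0.0
                for j in range(p):
                    if v[j] <= 0.0:
                        continue
                    rho = 0.0
                    for i in range(n):
                        rho += xs[i, j] * wn[i] * r[i]
                    rho += v[j] * beta[j]
                    if rho > lam:
                        bj = (rho - lam) / v[j]
                    elif rho < -lam:
                        bj = (rho + lam) / v[j]
                    else:
                        bj = 0.0
                    d = bj - beta[j]
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= d * xs[i, j]
                        beta[j] = bj
                        if abs(d) > delta:
                            delta = abs(d)
                num = 0.0
                den = 0.0
                for i in range(n):
                    num += wn[i] * r[i]
                    den += wn[i]
                d0 = num / den
                if d0 != 0.0:
                    icpt += d0
                    for i in range(n):
                        r[i] -= d0
                    if abs(d0) > delta:
                        delta = abs(d0)
                if delta < tol:
                    break
            move = abs(icpt - icpt_old)
            for j in range(p):
                if abs(beta[j] - beta_old[j]) > move:
                    move = abs(beta[j] - beta_old[j])
            if move < 1e-7:
                break
        coefs[li] = beta
        icpts[li] = icpt
    return coefs, icpts


def _l1_logistic_path(
    xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
    tol: float = 1e-8, max_outer: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started L1 logistic path by IRLS + cyclic coordinate descent.

    Minimizes (1/n) sum binomial NLL + lam * ||beta||_1 (intercept
    unpenalized) on pre-standardized features, descending the lambda grid
    with warm starts. Returns (coefs[n_lambda, p], intercepts[n_lambda]).
    """
    coefs, icpts = _path_kernel(np.ascontiguousarray(xs, dtype=np.float64),
                                np.asarray(y, dtype=np.float64),
                                np.asarray(lambdas, dtype=np.float64),
                                tol, max_outer)
    coefs[np.abs(coefs) < 1e-10] = 0.0  # round-off survivors of soft-thresholding
    return coefs, icpts


def _deviance(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return -2 * (y * np.log(p) + (1 - y) * np.log(1 - p))


@dataclass
class LassoResult:
    lambda_path: np.ndarray
    cv_deviance: np.ndarray          # mean per lambda
    cv_deviance_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    coef_min: np.ndarray             # at lambda_min, standardized scale
    coef_1se: np.ndarray
    intercept_min: float
    intercept_1se: float
    k_min: int
    k_1se: int
    sparsity_min: str
    sparsity_1se: str
    fold_assignments: np.ndarray
    oof_scores: np.ndarray           # out-of-fold probabilities at lambda_min
    feature_names: list[str] = field(default_factory=list)

    def top_features(self, solution: str = "min") -> list[tuple[str, float]]:
        coef = self.coef_min if solution == "min" else self.coef_1se
        order = np.argsort(-np.abs(coef))
        return [(self.feature_names[i], float(coef[i])) for i in order if coef[i] != 0]


def lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    rng: np.random.Generator | int | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
    feature_names: list[str] | None = None,
) -> LassoResult:
    """LASSO logistic regression over a 100-point lambda path with stratified
    K-fold cross-validation; refits the full data at lambda_min and lambda_1se."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if n < folds:
        raise ValueError("fewer subjects than folds")
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    const = X.std(axis=0) == 0
    if const.any():
        log.warning("lasso_cv: dropping %d constant feature(s)", int(const.sum()))
    rng = np.random.default_rng(rng)
    xs_full, _, sd_full = _standardize(X)
    xs_full[:, const] = 0.0
    lambdas = _lambda_grid(xs_full, y, n_lambda, lambda_min_ratio)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    fold_assign = np.empty(n, dtype=int)
    fold_dev = np.zeros((folds, len(lambdas)))
    oof = np.empty((n, len(lambdas)))
    for fi, (tr, te) in enumerate(skf.split(X, y)):
        fold_assign[te] = fi
        if len(np.unique(y[tr])) != 2 or len(np.unique(y[te])) == 0:
            raise ValueError("a CV fold lacks both classes")
        xs_tr, mu, sd = _standardize(X[tr])
        mask = sd > 0
        xs_tr[:, ~mask] = 0.0
        xs_te = (X[te] - mu) / np.where(mask, sd, 1.0)
        xs_te[:, ~mask] = 0.0
        coefs, icpts = _l1_logistic_path(xs_tr, y[tr], lambdas)
        probs = 1 / (1 + np.exp(-(xs_te @ coefs.T + icpts)))  # (n_te, n_lambda)
        oof[te, :] = probs
        fold_dev[fi, :] = _deviance(probs, y[te][:, None]).mean(axis=0)
    cvm = fold_dev.mean(axis=0)
    cvse = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(cvm))
    ok = cvm <= cvm[i_min] + cvse[i_min]
    i_1se = int(np.flatnonzero(ok)[0])  # grid descends, so first hit = largest lambda
    coefs_full, icpts_full = _l1_logistic_path(xs_full, y, lambdas)
    coef_min, icpt_min = coefs_full[i_min], float(icpts_full[i_min])
    coef_1se, icpt_1se = coefs_full[i_1se], float(icpts_full[i_1se])
    k_min = int(np.count_nonzero(coef_min))
    k_1se = int(np.count_nonzero(coef_1se))
    return LassoResult(
        lambda_path=lambdas, cv_deviance=cvm, cv_deviance_se=cvse,
        lambda_min=float(lambdas[i_min]), lambda_1se=float(lambdas[i_1se]),
        coef_min=coef_min, coef_1se=coef_1se,
        intercept_min=icpt_min, intercept_1se=icpt_1se,
        k_min=k_min, k_1se=k_1se,
        sparsity_min=sparsity_label(k_min), sparsity_1se=sparsity_label(k_1se),
        fold_assignments=fold_assign, oof_scores=oof[:, i_min],
        feature_names=list(feature_names) if feature_names is not None
        else [f"x{i}" for i in range(p)],
    )


@dataclass
class BolassoResult:
    B: int
    threshold: float
    selection_frequency: np.ndarray
    retained: list[str]
    feature_names: list[str]


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bolasso(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 100,
    threshold: float = 0.85,
    rng: np.random.Generator | int | None = None,
    folds: int = 5,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-2,
    feature_names: list[str] | None = None,
) -> BolassoResult:
    """Bootstrap-enhanced LASSO: per stratified resample, select features at
    that resample's cross-validated lambda_min; retain features selected in
    at least ``threshold`` of resamples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(rng)
    names = list(feature_names) if feature_names is not None \
        else [f"x{i}" for i in range(X.shape[1])]
    counts = np.zeros(X.shape[1])
    for _ in range(B):
        idx = _stratified_bootstrap(y, rng)
        res = lasso_cv(X[idx], y[idx], folds=folds, rng=rng, n_lambda=n_lambda,
                       lambda_min_ratio=lambda_min_ratio, feature_names=names)
        counts += res.coef_min != 0
    freq = counts / B
    # threshold 0 means "ever selected", so never-selected features stay out
    retained = [names[i] for i in np.flatnonzero((freq >= threshold) & (freq > 0))]
    return BolassoResult(B=B, threshold=threshold, selection_frequency=freq,
                         retained=retained, feature_names=names)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Sensitivity, specificity, precision, accuracy, F1; undefined ratios are NaN."""
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    def ratio(num, den):
        return num / den if den > 0 else float("nan")
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    acc = (tp + tn) / (tp + fp + fn + tn)
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else float("nan"))
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "f1": f1}


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    operating_point: float
    confusion: dict[str, float]
    counts: dict[str, int]


def _trapezoid_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, ...]:
    fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr, float(np.trapezoid(tpr, fpr))


def roc_auc(
    scores,
    labels,
    n_boot: int = 5000,
    rng: np.random.Generator | int | None = None,
    operating_point: float = 0.5,
    level: float = 0.95,
) -> RocResult:
    """Trapezoidal AUC with a stratified-bootstrap percentile CI and confusion
    metrics at the 0.5 probability operating point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr, auc = _trapezoid_auc(scores, labels)
    rng = np.random.default_rng(rng)
    boots = np.empty(n_boot)
    for bi in range(n_boot):
        idx = _stratified_bootstrap(labels, rng)
        boots[bi] = _trapezoid_auc(scores[idx], labels[idx])[3]
    alpha = (1 - level) / 2
    ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))
    pred = (scores >= operating_point).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, auc_ci=ci,
        operating_point=operating_point,
        confusion=confusion_metrics(tp, fp, fn, tn),
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


@dataclass
class PermutationResult:
    observed: float
    null_stats: np.ndarray
    M: int
    p_raw: float          # (1/M) sum[theta_i >= Theta], exactly as printed
    p_smoothed: float     # (b + 1) / (M + 1)


def permutation_test(
    statistic_fn,
    data,
    labels,
    M: int = 5000,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Label-shuffling permutation test preserving group sizes.

    ``statistic_fn(data, labels)`` must be deterministic; the raw p-value is
    the plain exceedance fraction (can be 0) and the smoothed form adds the
    +1 correction. With ``exhaustive=True`` every distinct label assignment
    is enumerated instead of sampling M shuffles (small n only).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("need two groups")
    observed = float(statistic_fn(data, labels))
    if not np.isfinite(observed):
        raise ValueError("non-finite observed statistic")
    if exhaustive:
        from itertools import combinations

        values = np.unique(labels)
        n1 = int(np.sum(labels == values[1]))
        null_stats = []
        for pos in combinations(range(len(labels)), n1):
            perm = np.full(len(labels), values[0])
            perm[list(pos)] = values[1]
            null_stats.append(statistic_fn(data, perm))
        null_stats = np.asarray(null_stats, dtype=float)
        M = len(null_stats)
    else:
        if M < 100:
            warnings.warn("permutation test with M < 100 is unreliable", stacklevel=2)
        rng = np.random.default_rng(rng)
        null_stats = np.empty(M)
        for i in range(M):
            null_stats[i] = statistic_fn(data, rng.permutation(labels))
    b = int(np.sum(null_stats >= observed))
    return PermutationResult(observed=observed, null_stats=null_stats, M=M,
                             p_raw=b / M, p_smoothed=(b + 1) / (M + 1))


def bca_interval(
    statistic_fn,
    data,
    n_boot: int = 5000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    ``data`` is one sample or a tuple of independent samples;
    ``statistic_fn`` takes them positionally. A degenerate bootstrap
    distribution yields a zero-width interval with a warning.
    """
    samples = data if isinstance(data, (tuple, list)) else (data,)
    samples = tuple(np.asarray(s, dtype=float) for s in samples)
    if min(len(s) for s in samples) < 4:
        raise ValueError("need at least 4 observations per sample")
    observed = float(statistic_fn(*samples))
    if all(np.ptp(s) == 0 for s in samples):
        warnings.warn("degenerate data: zero-width BCa interval", stacklevel=2)
        return (observed, observed)
    rng = np.random.default_rng(rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.bootstrap(
            samples, statistic_fn, n_resamples=n_boot, confidence_level=level,
            method="BCa", vectorized=False, paired=False, rng=rng,
        )
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        warnings.warn("degenerate bootstrap distribution: zero-width BCa interval",
                      stacklevel=2)
        return (observed, observed)
    return (lo, hi)


@dataclass
class ModelReport:
    comparison: str
    band: str
    groups: tuple[str, str]
    n_subjects: tuple[int, int]
    lasso: LassoResult
    roc: RocResult
    bolasso_result: BolassoResult
    feature_table: pd.DataFrame

    def summary_row(self) -> dict:
        c = self.roc.confusion
        return {
            "comparison": self.comparison, "band": self.band,
            "f1": c["f1"], "precision": c["precision"],
            "sensitivity": c["sensitivity"], "specificity": c["specificity"],
            "lambda_min": self.lasso.lambda_min, "lambda_1se": self.lasso.lambda_1se,
            "K_min": self.lasso.k_min, "K_1se": self.lasso.k_1se,
            "sparsity_min": self.lasso.sparsity_min,
            "sparsity_1se": self.lasso.sparsity_1se,
            "auc_overall": self.roc.auc,
            "auc_ci_low": self.roc.auc_ci[0], "auc_ci_high": self.roc.auc_ci[1],
        }


def _feature_auc_boot(x: np.ndarray, y: np.ndarray, n_boot: int,
                      rng: np.random.Generator) -> tuple[float, float]:
    """Bootstrap mean +/- SD of a single feature's univariate AUC.

    Orientation is fixed on the full sample (like pROC's automatic
    direction), then held constant across resamples.
    """
    flip = np.mean(x[y == 1]) < np.mean(x[y == 0])
    s = -x if flip else x
    vals = np.empty(n_boot)
    for bi in range(n_boot):
        idx = _stratified_bootstrap(y, rng)
        vals[bi] = _trapezoid_auc(s[idx], y[idx])[3]
    return float(vals.mean()), float(vals.std(ddof=1))


def run_comparison(
    feature_matrix: pd.DataFrame,
    comparison: str,
    band: str,
    rng: np.random.Generator | int | None = None,
    cv_folds: int = 10,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
    bolasso_B: int = 100,
    bolasso_threshold: float = 0.85,
    bolasso_folds: int = 5,
    n_boot: int = 1000,
    n_perm: int = 1000,
    top_k: int = 6,
) -> ModelReport:
    """Full classification panel for one group comparison and band.

    ``feature_matrix``: one row per subject with ``subject``, ``group`` and
    one PLV column per electrode pair. The non-reference (patient) group is
    the positive class. Per-feature statistics (bootstrap AUC mean +/- SD and
    permutation p with BH-FDR over the reported set) cover the ``top_k``
    largest-\\|coefficient\\| features at lambda_min.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    g_ref, g_pos = COMPARISONS[comparison]
    sub = feature_matrix[feature_matrix["group"].isin([g_ref, g_pos])]
    feature_cols = [c for c in sub.columns if c not in ("subject", "group")]
    X = sub[feature_cols].to_numpy(float)
    y = (sub["group"] == g_pos).to_numpy(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"both groups must be present for {comparison}")
    rng = np.random.default_rng(rng)
    lasso = lasso_cv(X, y, folds=cv_folds, rng=rng, n_lambda=n_lambda,
                     lambda_min_ratio=lambda_min_ratio, feature_names=feature_cols)
    roc = roc_auc(lasso.oof_scores, y, n_boot=n_boot, rng=rng)
    bl = bolasso(X, y, B=bolasso_B, threshold=bolasso_threshold, rng=rng,
                 folds=bolasso_folds, n_lambda=max(25, n_lambda // 2),
                 lambda_min_ratio=lambda_min_ratio, feature_names=feature_cols)
    rows = []
    top = lasso.top_features("min")[:top_k]
    for name, coef in top:
        xcol = X[:, feature_cols.index(name)]
        auc_mean, auc_sd = _feature_auc_boot(xcol, y, n_boot, rng)
        perm = permutation_test(
            lambda d, lab: abs(d[lab == 1].mean() - d[lab == 0].mean()),
            xcol, y, M=n_perm, rng=rng,
        )
        rows.append({"feature": name, "coefficient": coef,
                     "auc_mean": auc_mean, "auc_sd": auc_sd,
                     "perm_p": perm.p_raw, "perm_p_smoothed": perm.p_smoothed,
                     "bolasso_frequency": float(
                         bl.selection_frequency[feature_cols.index(name)])})
    feature_table = pd.DataFrame(rows)
    if len(feature_table):
        feature_table["perm_q"] = multipletests(
            feature_table["perm_p_smoothed"], method="fdr_bh")[1]
    return ModelReport(
        comparison=comparison, band=band, groups=(g_ref, g_pos),
        n_subjects=(int((y == 0).sum()), int((y == 1).sum())),
        lasso=lasso, roc=roc, bolasso_result=bl, feature_table=feature_table,
    )
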