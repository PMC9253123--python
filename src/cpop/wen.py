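"""Penalised regression with per-feature penalty factors (Weighted Elastic Net).

The solver minimises, over intercept b0 (absent for Cox) and coefficients b,

    -(1/n) loglik(family; b0, b) + lambda * sum_j f_j * P_alpha(b_j),
    P_alpha(b) = alpha*|b| + (1 - alpha)/2 * b^2,

where the per-feature penalty factors ``f_j`` are rescaled to mean one, so
solutions are invariant to a common rescaling of the factors.  Setting all
factors equal recovers the ordinary elastic net (alpha = 1: lasso;
alpha = 0: ridge).  Families: ``gaussian`` (squared error), ``binomial``
(logistic), ``cox`` (Breslow partial likelihood, no intercept).

Columns are centred and, by default, scaled to unit variance before
fitting; coefficients are reported back on the original feature scale.
Generalised families are handled by iteratively reweighted least squares
around the coordinate-descent core in :mod:`cpop._cd`; lambda paths are
warm-started from the all-zero solution at ``lambda_max`` downwards, and
``lambda`` may be selected by K-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._cd import cd_wls
from .containers import OutcomeVector
from .ratios import FeatureWeights, LogRatioMatrix

__all__ = [
    "PenalisedFit",
    "CVResult",
    "fit_penalised",
    "cross_validate_lambda",
    "fit_ridge",
    "kkt_residual",
    "make_folds",
]

FAMILIES = ("gaussian", "binomial", "cox")

#: Penalty factors this many times above the median are treated as a hard
#: exclusion: the feature's coefficient is pinned to exactly zero.
HARD_EXCLUSION_FACTOR = 1e6

_P_CLIP = 1e-5  # probability clipping for the logistic IRLS weights
_MIN_ALPHA_FOR_PATH = 1e-3  # lambda_max is undefined at alpha = 0


# --------------------------------------------------------------------------
# results


@dataclass
class CVResult:
    """Cross-validation curve over a lambda path.

    ``lambda_min`` minimises the CV deviance; ``lambda_1se`` is the
    largest lambda within one standard error of the minimum (sparser);
    ``lambda_deep`` is the *smallest* lambda within one standard error —
    the most inclusive model statistically indistinguishable from the
    optimum, useful when the fit screens features for a later stage.
    """

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    lambda_deep: float
    n_folds: int
    seed: int


@dataclass
class PenalisedFit:
    """A fitted penalised model at one selected lambda."""

    family: str
    alpha: float
    lambda_: float
    lambda_path: np.ndarray
    coefficients: np.ndarray
    intercept: float | None
    penalty_factors: np.ndarray
    converged: bool
    n_iterations: int
    feature_ids: list[str] | None = None
    cv: CVResult | None = None
    dropped_features: list[int] = field(default_factory=list)
    path_coefficients: np.ndarray | None = None
    path_intercepts: np.ndarray | None = None
    objective_history: np.ndarray | None = None
    standardized: bool = True

    @property
    def nonzero(self) -> np.ndarray:
        """Indices of features with non-zero coefficients."""
        return np.flatnonzero(self.coefficients != 0.0)

    def predict(self, Z, output: str = "link") -> np.ndarray:
        """Linear predictor (or transformed score) for new rows.

        ``output``: ``link`` for the raw linear predictor; ``response`` for
        the logistic transform (binomial only); ``risk`` for the relative
        hazard exp(link) (cox only).
        """
        X = _extract_X(Z)[0]
        eta = X @ self.coefficients
        if self.intercept is not None:
            eta = eta + self.intercept
        if output == "link":
            return eta
        if output == "response":
            if self.family != "binomial":
                raise ValueError("response scale requires a binomial fit")
            return 1.0 / (1.0 + np.exp(-eta))
        if output == "risk":
            if self.family != "cox":
                raise ValueError("risk scale requires a cox fit")
            return np.exp(eta)
        raise ValueError(f"unknown output scale {output!r}")

    def path_nonzero_counts(self) -> np.ndarray:
        if self.path_coefficients is None:
            raise ValueError("fit was created without keep_path=True")
        return (self.path_coefficients != 0.0).sum(axis=1)


# --------------------------------------------------------------------------
# input extraction and standardisation


def _extract_X(Z) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(Z, LogRatioMatrix):
        return Z.values, list(Z.feature_ids)
    if hasattr(Z, "to_numpy"):  # DataFrame
        return Z.to_numpy(dtype=float), [str(c) for c in Z.columns]
    X = np.asarray(Z, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    return X, None


def _extract_y(y, family: str, n: int):
    """Return family-specific response arrays."""
    if isinstance(y, OutcomeVector):
        if family == "cox":
            if y.kind != "survival":
                raise ValueError("cox family requires a survival outcome")
            time, event = y.time, y.event
        elif family == "binomial":
            if y.kind != "binary":
                raise ValueError("binomial family requires a binary outcome")
            return np.asarray(y.class_label, dtype=float)
        else:
            if y.kind == "binary":
                return np.asarray(y.class_label, dtype=float)
            raise ValueError("gaussian family requires a numeric response")
    elif family == "cox":
        time, event = y
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
    else:
        yy = np.asarray(y, dtype=float)
        if yy.shape != (n,):
            raise ValueError("response length does not match design matrix")
        if family == "binomial" and not np.all(np.isin(yy, (0.0, 1.0))):
            raise ValueError("binomial response must be 0/1")
        return yy
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event length does not match design matrix")
    if event.sum() < 1:
        raise ValueError("cox family requires at least one observed event")
    return time, event


def _standardise(X: np.ndarray, scale: bool):
    m = X.mean(axis=0)
    s = X.std(axis=0)
    constant = s == 0.0
    if not scale:
        s = np.ones_like(s)
    else:
        s = np.where(constant, 1.0, s)
    Xs = (X - m) / s
    return np.ascontiguousarray(Xs), m, s, constant


def _rescale_penalty_factors(pf: np.ndarray) -> np.ndarray:
    """Rescale factors to mean one; an all-zero vector means 'unweighted'."""
    pf = np.asarray(pf, dtype=float)
    if np.any(pf < 0) or not np.all(np.isfinite(pf)):
        raise ValueError("penalty factors must be finite and non-negative")
    total = pf.sum()
    if total == 0.0:
        return np.ones_like(pf)
    return pf * (pf.size / total)


# --------------------------------------------------------------------------
# family internals (working responses, deviances)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _CoxData:
    """Pre-sorted survival data with Breslow tie handling."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        order = np.argsort(time, kind="mergesort")
        self.order = order
        self.time = time[order]
        self.event = event[order]
        n = len(time)
        ts = self.time
        first = np.r_[True, ts[1:] != ts[:-1]]
        self.block = np.cumsum(first) - 1  # tie-block index per position
        self.block_start = np.flatnonzero(first)
        self.d_block = np.bincount(self.block, weights=self.event)
        self.n = n

    def working(self, eta: np.ndarray):
        """Score u, curvature h per sample and the Breslow log partial lik."""
        eta_s = eta[self.order]
        es = np.exp(eta_s - eta_s.max())  # partial lik is shift-invariant
        W_pos = np.cumsum(es[::-1])[::-1]
        W_blk = W_pos[self.block_start]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(self.d_block > 0, self.d_block / W_blk, 0.0)
            t2 = np.where(self.d_block > 0, self.d_block / W_blk**2, 0.0)
        A = np.cumsum(t1)[self.block]
        B = np.cumsum(t2)[self.block]
        u_s = self.event - es * A
        h_s = es * A - es**2 * B
        mask = self.d_block > 0
        loglik = float(
            np.sum((eta_s - eta_s.max())[self.event == 1.0])
            - np.sum(self.d_block[mask] * np.log(W_blk[mask]))
        )
        u = np.empty_like(u_s)
        h = np.empty_like(h_s)
        u[self.order] = u_s
        h[self.order] = h_s
        return u, h, loglik


def cox_log_partial_likelihood(eta: np.ndarray, time: np.ndarray,
                               event: np.ndarray) -> float:
    """Breslow log partial likelihood at linear predictor ``eta``."""
    return _CoxData(np.asarray(time, float),
                    np.asarray(event, float)).working(np.asarray(eta, float))[2]


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# --------------------------------------------------------------------------
# path fitting


def _lambda_path(Xs, ydata, family, pf, alpha, excluded, n_lambda,
                 lambda_min_ratio, lambda_floor=None):
    n = Xs.shape[0]
    if family == "gaussian":
        y = ydata
        resid = y - y.mean()
    elif family == "binomial":
        y = ydata
        resid = y - y.mean()
    else:
        cox = ydata
        resid, _, _ = cox.working(np.zeros(n))
    g = np.abs(Xs.T @ resid) / n
    a_eff = max(alpha, _MIN_ALPHA_FOR_PATH)
    with np.errstate(divide="ignore"):
        cand = np.where((pf > 0) & ~excluded, g / (a_eff * np.maximum(pf, 1e-300)),
                        0.0)
    lam_max = float(cand.max()) if cand.size else 0.0
    if lam_max <= 0.0:
        lam_max = 1.0
    lam_max *= 1.0 + 1e-6
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-2 if family == "cox" else 1e-3
    # Heterogeneous penalty factors can inflate lam_max by orders of
    # magnitude (a feature with a near-zero factor enters almost
    # immediately).  Anchor the path floor to the unweighted problem's
    # scale so ordinarily-penalised features still get a chance to enter,
    # instead of compressing the usable range out of the path.
    g_incl = g[~excluded]
    lam_max_uniform = float(g_incl.max()) / a_eff if g_incl.size else lam_max
    floor = min(lam_max, lam_max_uniform) * lambda_min_ratio
    path = np.geomspace(lam_max, floor, n_lambda)
    if lambda_floor is not None and lambda_floor < path[-1]:
        path = np.unique(np.r_[path, lambda_floor])[::-1]
    return path


def _penalty_value(beta, lam, alpha, pf) -> float:
    return float(lam * np.sum(pf * (alpha * np.abs(beta)
                                    + 0.5 * (1 - alpha) * beta**2)))


def _fit_path(Xs, ydata, family, pf, alpha, lambdas, excluded, tol,
              max_passes, outer_tol=None, max_outer=30, record_objective=False,
              dfmax=None):
    """Warm-started coefficient path on the standardised scale.

    The path stops early once the active set reaches ``dfmax`` features
    (the model is saturated beyond that point); remaining path entries
    repeat the last solution.  Returns per-lambda convergence flags.
    """
    n, q = Xs.shape
    L = len(lambdas)
    beta = np.zeros(q)
    b0_box = np.zeros(1)
    coefs = np.zeros((L, q))
    b0s = np.zeros(L)
    total_passes = 0
    conv_flags = np.zeros(L, dtype=bool)
    obj_hist_buf = np.empty(min(max_passes, 10000))
    obj_histories: list[np.ndarray] = []
    if outer_tol is None:
        outer_tol = max(tol * 10, 1e-8)
    if dfmax is None:
        # saturation guard for over-parameterised sparse fits only; ridge
        # (alpha = 0) and small designs are dense by nature
        if alpha == 0.0 or q <= n:
            dfmax = q + 1
        else:
            dfmax = max(int(0.95 * n), 5)

    def _truncate(li):
        for lj in range(li + 1, L):
            coefs[lj] = beta
            b0s[lj] = b0_box[0]
            conv_flags[lj] = conv_flags[li]

    if family == "gaussian":
        y = ydata
        v = np.full(n, 1.0 / n)
        b0_box[0] = y.mean()
        for li, lam in enumerate(lambdas):
            npass, conv = cd_wls(Xs, v, y, beta, b0_box, lam, alpha, pf,
                                 excluded, True, tol, len(obj_hist_buf),
                                 obj_hist_buf)
            total_passes += npass
            conv_flags[li] = bool(conv)
            coefs[li] = beta
            b0s[li] = b0_box[0]
            if record_objective:
                obj_histories.append(obj_hist_buf[:npass].copy())
            if np.count_nonzero(beta) >= dfmax:
                _truncate(li)
                break
    elif family == "binomial":
        y = ydata
        pbar = float(np.clip(y.mean(), _P_CLIP, 1 - _P_CLIP))
        b0_box[0] = np.log(pbar / (1 - pbar))
        for li, lam in enumerate(lambdas):
            delta = np.inf
            for _ in range(max_outer):
                eta = b0_box[0] + Xs @ beta
                p = np.clip(_sigmoid(eta), _P_CLIP, 1 - _P_CLIP)
                w = p * (1 - p)
                z = eta + (y - p) / w
                v = w / n
                beta_old = beta.copy()
                b0_old = b0_box[0]
                npass, conv = cd_wls(Xs, v, z, beta, b0_box, lam, alpha, pf,
                                     excluded, True, tol, len(obj_hist_buf),
                                     obj_hist_buf)
                total_passes += npass
                delta = max(np.abs(beta - beta_old).max(initial=0.0),
                            abs(b0_box[0] - b0_old))
                if delta < outer_tol:
                    break
            conv_flags[li] = bool(conv) and delta < outer_tol
            coefs[li] = beta
            b0s[li] = b0_box[0]
            if np.count_nonzero(beta) >= dfmax:
                _truncate(li)
                break
    elif family == "cox":
        cox = ydata

        def cox_objective(b):
            ll = cox.working(Xs @ b)[2]
            return -ll / n + _penalty_value(b, lam, alpha, pf)

        for li, lam in enumerate(lambdas):
            delta = np.inf
            obj_cur = cox_objective(beta)
            for _ in range(max_outer):
                eta = Xs @ beta
                u, h, _ = cox.working(eta)
                # near-zero curvature: drop the observation from the
                # quadratic rather than divide by a vanishing weight
                ok = h > 1e-8
                v = np.where(ok, h, 0.0) / n
                z = np.where(ok, eta + u / np.maximum(h, 1e-8), eta)
                beta_old = beta.copy()
                npass, conv = cd_wls(Xs, v, z, beta, b0_box, lam, alpha, pf,
                                     excluded, False, tol, len(obj_hist_buf),
                                     obj_hist_buf)
                total_passes += npass
                # step-halving keeps the penalised partial likelihood monotone
                obj_new = cox_objective(beta)
                halvings = 0
                while obj_new > obj_cur + 1e-12 and halvings < 8:
                    beta = 0.5 * (beta + beta_old)
                    obj_new = cox_objective(beta)
                    halvings += 1
                if obj_new > obj_cur + 1e-12:
                    beta = beta_old
                    obj_new = obj_cur
                delta = np.abs(beta - beta_old).max(initial=0.0)
                obj_stalled = obj_cur - obj_new < 1e-12
                obj_cur = obj_new
                if delta < outer_tol or obj_stalled:
                    break
            conv_flags[li] = bool(conv) and delta < max(outer_tol, 1e-6)
            coefs[li] = beta
            b0s[li] = 0.0
            if np.count_nonzero(beta) >= dfmax:
                _truncate(li)
                break
    else:
        raise ValueError(f"unknown family {family!r}")

    return coefs, b0s, total_passes, conv_flags, obj_histories


# --------------------------------------------------------------------------
# cross-validation


def make_folds(n: int, n_folds: int, seed: int,
               strata: np.ndarray | None = None) -> np.ndarray:
    """Deterministic fold assignment, optionally stratified.

    Samples within each stratum are shuffled and dealt round-robin, so
    strata are balanced across folds as evenly as integer counts allow.
    """
    if n_folds < 3:
        raise ValueError("need at least 3 folds")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=np.int64)
    if strata is None:
        strata = np.zeros(n)
    strata = np.asarray(strata)
    offset = 0
    for val in np.unique(strata):
        idx = np.flatnonzero(strata == val)
        idx = rng.permutation(idx)
        assign[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset += len(idx)
    return assign


def _cv_strata(ydata, family):
    if family == "binomial":
        return ydata
    if family == "cox":
        return ydata[1]  # event indicator
    return None


def cross_validate_lambda(Z, y, penalty_factors=None, alpha: float = 0.9,
                          family: str = "gaussian", n_folds: int = 5,
                          seed: int = 0, n_lambda: int = 100,
                          lambda_min_ratio: float | None = None,
                          standardize: bool = True, tol: float = 1e-7,
                          max_passes: int = 100_000,
                          n_repeats: int = 1,
                          deep_band: float = 1.0) -> CVResult:
    """K-fold cross-validation of the lambda path.

    Folds are stratified by class (binomial) or by event status (cox) and
    are a pure function of ``seed``.  With ``n_repeats > 1`` the whole
    K-fold procedure is repeated on fresh fold splits and the deviance
    curves averaged (repeated cross-validation), which stabilises the
    selected lambda at proportional cost.  Returns the
    deviance-minimising ``lambda_min`` together with the two ends of its
    one-standard-error band (``lambda_1se``, ``lambda_deep``).
    """
    X, _ = _extract_X(Z)
    n = X.shape[0]
    yraw = _extract_y(y, family, n)
    if family == "cox":
        time, event = yraw
        n_events = int(event.sum())
        if n_events < 3:
            raise ValueError(f"only {n_events} events; cannot cross-validate")
        if n_events < n_folds:
            warnings.warn(
                f"reducing folds from {n_folds} to {n_events} (too few events)")
            n_folds = n_events
    strata = _cv_strata(yraw, family)

    Xs, m, s, constant = _standardise(X, standardize)
    pf = (np.ones(X.shape[1]) if penalty_factors is None
          else _rescale_penalty_factors(_pf_values(penalty_factors)))
    excluded = constant | _hard_exclusions(pf)
    ydata = _CoxData(time, event) if family == "cox" else yraw
    lambdas = _lambda_path(Xs, ydata, family, pf, alpha, excluded, n_lambda,
                           lambda_min_ratio)

    splits = [(rep, k, make_folds(n, n_folds, seed + 77_000 * rep, strata))
              for rep in range(n_repeats) for k in range(n_folds)]

    # raise the top of the path to cover every training fold's lambda_max,
    # so the first path point is the null model in every fold
    lam_top = lambdas[0]
    for _, k, folds in splits:
        tr = folds != k
        ytr = (_CoxData(time[tr], event[tr]) if family == "cox"
               else yraw[tr])
        fold_path = _lambda_path(np.ascontiguousarray(Xs[tr]), ytr, family,
                                 pf, alpha, excluded, 2, lambda_min_ratio)
        lam_top = max(lam_top, fold_path[0])
    if lam_top > lambdas[0]:
        lambdas = np.geomspace(lam_top, lambdas[-1], len(lambdas))

    L = len(lambdas)
    fold_dev = np.empty((n_folds * n_repeats, L))
    for row, (rep, k, folds) in enumerate(splits):
        tr = folds != k
        te = ~tr
        Xtr = np.ascontiguousarray(Xs[tr])
        if family == "cox":
            tr_events = event[tr].sum()
            if tr_events < 1:
                raise ValueError(f"training fold {k} contains no events")
            cox_tr = _CoxData(time[tr], event[tr])
            coefs, b0s, _, _, _ = _fit_path(Xtr, cox_tr, family, pf, alpha,
                                            lambdas, excluded, tol, max_passes)
            # Verweij & van Houwelingen: dev_k = -2 (l_all(b) - l_train(b))
            cox_all = _CoxData(time, event)
            for li in range(L):
                eta_all = Xs @ coefs[li]
                l_all = cox_all.working(eta_all)[2]
                l_tr = cox_tr.working(eta_all[tr])[2]
                fold_dev[row, li] = -2.0 * (l_all - l_tr) / max(te.sum(), 1)
        else:
            ytr = yraw[tr]
            coefs, b0s, _, _, _ = _fit_path(Xtr, ytr, family, pf, alpha,
                                            lambdas, excluded, tol, max_passes)
            for li in range(L):
                eta_te = b0s[li] + Xs[te] @ coefs[li]
                if family == "gaussian":
                    fold_dev[row, li] = float(np.mean((yraw[te] - eta_te) ** 2))
                else:
                    fold_dev[row, li] = _binomial_deviance(yraw[te],
                                                           _sigmoid(eta_te))
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(fold_dev.shape[0])
    i_min = int(np.flatnonzero(mean_dev <= mean_dev.min() + 1e-12)[0])
    lambda_min = float(lambdas[i_min])
    i_1se = int(np.flatnonzero(
        mean_dev <= mean_dev[i_min] + se_dev[i_min] + 1e-12)[0])
    i_deep = int(np.flatnonzero(
        mean_dev <= mean_dev[i_min] + deep_band * se_dev[i_min] + 1e-12)[-1])
    return CVResult(lambdas, mean_dev, se_dev, lambda_min,
                    float(lambdas[i_1se]), float(lambdas[i_deep]),
                    n_folds, seed)


def _pf_values(penalty_factors) -> np.ndarray:
    if isinstance(penalty_factors, FeatureWeights):
        return penalty_factors.w
    return np.asarray(penalty_factors, dtype=float)


def _hard_exclusions(pf_rescaled: np.ndarray) -> np.ndarray:
    """Features whose rescaled factor dwarfs the median are pinned to zero."""
    positive = pf_rescaled[pf_rescaled > 0]
    ref = float(np.median(positive)) if positive.size else 1.0
    if ref <= 0:
        ref = 1.0
    return pf_rescaled > HARD_EXCLUSION_FACTOR * ref


# --------------------------------------------------------------------------
# top-level fits


def fit_penalised(Z, y, penalty_factors=None, alpha: float = 0.9,
                  lam="cv", family: str = "gaussian", *, n_folds: int = 5,
                  seed: int = 0, n_lambda: int = 100,
                  lambda_min_ratio: float | None = None,
                  standardize: bool = True, tol: float = 1e-7,
                  max_passes: int = 100_000, cv_rule: str = "lambda_min",
                  n_repeats: int = 1, deep_band: float = 1.0,
                  keep_path: bool = False,
                  record_objective: bool = False) -> PenalisedFit:
    """Fit a weighted elastic net (or lasso/ridge) at one lambda.

    Parameters
    ----------
    Z : LogRatioMatrix, DataFrame or ndarray (n x q)
    y : OutcomeVector, ndarray, or (time, event) pair for ``family="cox"``
    penalty_factors : per-feature weights (rescaled internally to mean 1);
        ``None`` or an all-zero vector means uniform penalties
    alpha : elastic-net mixing in [0, 1]; 1 = lasso, 0 = ridge
    lam : a positive number, or ``"cv"`` to select by cross-validation
    cv_rule : ``"lambda_min"`` (default) or ``"lambda_1se"``

    Constant feature columns are dropped (coefficient zero) with a warning.
    A penalty factor more than ``HARD_EXCLUSION_FACTOR`` times the median
    pins its feature's coefficient to exactly zero.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    X, feature_ids = _extract_X(Z)
    n, q = X.shape
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    yraw = _extract_y(y, family, n)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")

    pf = (np.ones(q) if penalty_factors is None
          else _rescale_penalty_factors(_pf_values(penalty_factors)))
    if pf.shape != (q,):
        raise ValueError("penalty factor length does not match feature count")

    Xs, m, s, constant = _standardise(X, standardize)
    if constant.any():
        names = ([feature_ids[j] for j in np.flatnonzero(constant)]
                 if feature_ids else list(np.flatnonzero(constant)))
        warnings.warn(f"dropping {int(constant.sum())} constant feature "
                      f"column(s): {names[:5]}")
    excluded = constant | _hard_exclusions(pf)

    ydata = _CoxData(*yraw) if family == "cox" else yraw

    cv = None
    if isinstance(lam, str):
        if lam != "cv":
            raise ValueError("lam must be a positive number or 'cv'")
        cv = cross_validate_lambda(X, y, penalty_factors, alpha, family,
                                   n_folds=n_folds, seed=seed,
                                   n_lambda=n_lambda,
                                   lambda_min_ratio=lambda_min_ratio,
                                   standardize=standardize, tol=tol,
                                   max_passes=max_passes,
                                   n_repeats=n_repeats, deep_band=deep_band)
        try:
            lam_sel = {"lambda_min": cv.lambda_min,
                       "lambda_1se": cv.lambda_1se,
                       "lambda_deep": cv.lambda_deep}[cv_rule]
        except KeyError:
            raise ValueError(f"unknown cv_rule {cv_rule!r}") from None
        # refit only down to the selected lambda; the deeper (overfit)
        # region of the path is never used
        lambdas = cv.lambdas[cv.lambdas >= lam_sel * (1 - 1e-12)]
    else:
        lam_sel = float(lam)
        if lam_sel <= 0:
            raise ValueError("lambda must be positive")
        lambdas = _lambda_path(Xs, ydata, family, pf, alpha, excluded,
                               n_lambda, lambda_min_ratio,
                               lambda_floor=lam_sel)
        lambdas = lambdas[lambdas >= lam_sel]
        if len(lambdas) == 0 or not np.isclose(lambdas[-1], lam_sel):
            lambdas = np.r_[lambdas, lam_sel]

    coefs, b0s, total_passes, conv_flags, obj_hist = _fit_path(
        Xs, ydata, family, pf, alpha, lambdas, excluded, tol, max_passes,
        record_objective=record_objective)

    li = int(np.argmin(np.abs(lambdas - lam_sel)))
    converged = bool(conv_flags[li])
    beta_std = coefs[li]
    beta = beta_std / s
    beta[excluded] = 0.0
    if family == "cox":
        intercept = None
    else:
        intercept = float(b0s[li] - np.dot(beta_std / s, m))

    path_coefs = coefs / s if keep_path else None
    return PenalisedFit(
        family=family, alpha=alpha, lambda_=float(lambdas[li]),
        lambda_path=np.asarray(lambdas, dtype=float), coefficients=beta,
        intercept=intercept, penalty_factors=pf, converged=bool(converged),
        n_iterations=int(total_passes), feature_ids=feature_ids, cv=cv,
        dropped_features=list(np.flatnonzero(constant)),
        path_coefficients=path_coefs,
        path_intercepts=(b0s.copy() if keep_path else None),
        objective_history=(obj_hist[-1] if obj_hist else None),
        standardized=standardize,
    )


def fit_ridge(Z, y, family: str = "gaussian", lam="cv", *, n_folds: int = 5,
              seed: int = 0, standardize: bool = True,
              **kwargs) -> PenalisedFit:
    """Unweighted ridge fit (alpha = 0, uniform penalty factors)."""
    return fit_penalised(Z, y, penalty_factors=None, alpha=0.0, lam=lam,
                         family=family, n_folds=n_folds, seed=seed,
                         standardize=standardize, **kwargs)


# --------------------------------------------------------------------------
# optimality diagnostics


def kkt_residual(fit: PenalisedFit, Z, y) -> float:
    """Largest violation of the subgradient optimality conditions.

    Computed on the standardised feature scale (matching the solver's
    internal objective).  For a non-zero coefficient the penalised score
    must vanish; for a zero coefficient the score must not exceed the
    l1 threshold ``lambda * f_j * alpha``.
    """
    X, _ = _extract_X(Z)
    n = X.shape[0]
    yraw = _extract_y(y, fit.family, n)
    # recover standardised-scale coefficients: beta_std = beta_orig * s
    Xs, m, s, _ = _standardise(X, fit.standardized)
    beta_std = fit.coefficients * s
    eta = X @ fit.coefficients
    if fit.intercept is not None:
        eta = eta + fit.intercept
    if fit.family == "gaussian":
        resid = yraw - eta
    elif fit.family == "binomial":
        resid = yraw - _sigmoid(eta)
    else:
        resid = _CoxData(*yraw).working(eta)[0]
    G = Xs.T @ resid / n
    lam, a, pf = fit.lambda_, fit.alpha, fit.penalty_factors
    viol = np.empty_like(G)
    nz = beta_std != 0.0
    viol[nz] = np.abs(G[nz] - lam * pf[nz] * ((1 - a) * beta_std[nz]
                                              + a * np.sign(beta_std[nz])))
    viol[~nz] = np.maximum(0.0, np.abs(G[~nz]) - lam * pf[~nz] * a)
    for j in fit.dropped_features:
        viol[j] = 0.0
    return float(viol.max(initial=0.0))
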