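"""The CPOP procedure: stable feature selection across two training
datasets, the averaged final model, prediction without renormalisation,
and imputation of wholly-missing features in incoming samples.

Training runs in five stages.  Given two gene-aligned log-scale expression
matrices X1, X2 with outcomes y1, y2:

1. build the all-pairs log-ratio matrices Z1, Z2;
2. compute per-feature instability weights w_j = |mean(Z1j) - mean(Z2j)|;
3. fit a weighted elastic net to each dataset with the w_j as penalty
   factors, and keep S1 = features with non-zero coefficients in *both*
   fits (optionally iterating: previously selected features are removed
   and the elastic nets refitted until a target signature size is
   reached);
4. fit unweighted ridge models on S1 to each dataset and keep
   S2 = features whose two ridge coefficients agree in sign, iterated to
   a fixed point;
5. refit ridge on S2 in each dataset and average the two coefficient
   vectors into the single deployable model.

Prediction on a new sample builds only the S2 ratio columns from its raw
log-scale values — no renormalisation, no access to other samples — which
is exactly why the model transfers across platforms: any per-sample global
shift cancels in every ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix, OutcomeVector
from .ratios import (
    FeatureWeights,
    LogRatioMatrix,
    build_log_ratio_matrix,
    compute_feature_weights,
    split_feature_id,
)
from .wen import PenalisedFit, fit_penalised, fit_ridge

__all__ = [
    "CPOPConfig",
    "CPOPModel",
    "select_common_features",
    "filter_sign_concordant",
    "fit_cpop",
    "predict_cpop",
    "impute_missing_features",
]


@dataclass
class CPOPConfig:
    """Training configuration for :func:`fit_cpop`.

    ``n_features_target`` controls the iterative stage-3 selection: rounds
    of paired elastic-net fits accumulate features until at least this many
    are selected (or ``max_iterations`` rounds have run).  ``alpha`` is the
    elastic-net mixing of the stage-3 fits; the stage-4/5 ridge fits always
    use alpha = 0.
    """

    family: str = "binomial"
    alpha: float = 0.5
    n_features_target: int = 50
    max_iterations: int = 4
    sign_filter_max_rounds: int = 10
    n_folds: int = 5
    cv_repeats: int = 3
    deep_band: float = 2.0
    seed: int = 0
    cv_rule: str = "lambda_deep"


@dataclass
class CPOPModel:
    """A trained CPOP model.

    ``s2`` is the signature: ratio features selected in both datasets with
    sign-concordant ridge coefficients.  ``beta_avg`` (and
    ``intercept_avg``) define the deployable averaged model; ``beta1`` /
    ``beta2`` are the per-dataset ridge coefficients it averages.  The
    training ratio columns over ``s2`` are retained so wholly-missing
    features of incoming samples can be imputed by regression on the
    observed ones.
    """

    family: str
    source_genes: list[str]
    s1: list[str]
    s2: list[str]
    beta1: dict[str, float]
    beta2: dict[str, float]
    beta_avg: dict[str, float]
    intercept1: float | None
    intercept2: float | None
    intercept_avg: float | None
    config: CPOPConfig
    iteration_trace: list[dict] = field(default_factory=list)
    training_feature_means: dict[str, float] = field(default_factory=dict)
    training_feature_variances: dict[str, float] = field(default_factory=dict)
    training_ratio_columns: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not set(self.s2) <= set(self.s1):
            raise ValueError("signature s2 must be a subset of s1")
        for j in self.s2:
            avg = 0.5 * (self.beta1[j] + self.beta2[j])
            if not np.isclose(self.beta_avg[j], avg, rtol=0, atol=1e-12):
                raise ValueError(f"beta_avg[{j}] is not the mean of beta1/beta2")

    @property
    def signature_genes(self) -> list[str]:
        """Genes appearing in at least one signature ratio, sorted."""
        genes: set[str] = set()
        for fid in self.s2:
            genes.update(split_feature_id(fid))
        return sorted(genes)

    def edge_list(self) -> pd.DataFrame:
        """Signature as a gene-pair edge list with averaged coefficients."""
        rows = [(l, m, self.beta_avg[fid])
                for fid in self.s2
                for (l, m) in [split_feature_id(fid)]]
        return pd.DataFrame(rows, columns=["gene_l", "gene_m", "coefficient"])


# --------------------------------------------------------------------------
# stage 3: common predictive features


def select_common_features(
    Z1: LogRatioMatrix,
    y1,
    Z2: LogRatioMatrix,
    y2,
    weights: FeatureWeights,
    family: str,
    alpha: float = 0.5,
    n_features_target: int = 50,
    max_iterations: int = 4,
    n_folds: int = 5,
    cv_repeats: int = 3,
    deep_band: float = 2.0,
    seed: int = 0,
    cv_rule: str = "lambda_deep",
) -> tuple[list[str], list[dict]]:
    """Features with non-zero weighted-elastic-net coefficients in *both*
    datasets, accumulated over selection rounds.

    Each round fits one weighted elastic net per dataset on the features
    that dataset has not yet selected, so a feature shadowed by a
    correlated proxy in one round can enter once the proxy is out of that
    dataset's candidate pool.  The result is the intersection of the two
    cumulative supports.  Rounds stop when the intersection reaches
    ``n_features_target``, a round adds no new support in either dataset,
    or ``max_iterations`` is hit.  This stage screens for *sensitivity*;
    precision is restored by the sign-concordance filter that follows.
    Returns the selected ids in canonical feature order plus a per-round
    trace.
    """
    if Z1.feature_ids != Z2.feature_ids:
        raise ValueError("stage 3: ratio matrices are not feature-aligned")
    if weights.feature_ids != Z1.feature_ids:
        raise ValueError("stage 3: weights are not aligned to the features")

    all_ids = list(Z1.feature_ids)
    q = len(all_ids)

    # Penalty factors are the instability weights shifted by their mean:
    # f_j = w_j + mean(w).  An estimated mean-discrepancy near zero
    # reflects sampling luck, not certain stability; the shift is an
    # uncertainty floor that keeps such features from entering the model
    # penalty-free and drowning the fit, while preserving the ordering
    # and relative penalisation of the weights.  An all-zero weight
    # vector (identical training data) falls back to uniform penalties.
    w_all = weights.w
    pf_all = w_all + w_all.mean() if w_all.sum() > 0 else np.ones_like(w_all)

    data = ((Z1, y1), (Z2, y2))
    ever: list[set[int]] = [set(), set()]
    pools: list[np.ndarray] = [np.arange(q), np.arange(q)]
    trace: list[dict] = []

    for round_no in range(max_iterations):
        n_new = [0, 0]
        n_nonzero = [0, 0]
        for d, (Z, y) in enumerate(data):
            pool = pools[d]
            if len(pool) == 0:
                continue
            fit = fit_penalised(Z.values[:, pool], y,
                                penalty_factors=pf_all[pool], alpha=alpha,
                                lam="cv", family=family, n_folds=n_folds,
                                n_repeats=cv_repeats, deep_band=deep_band,
                                seed=seed + 1000 * round_no,
                                cv_rule=cv_rule)
            support = {int(pool[k]) for k in fit.nonzero}
            n_nonzero[d] = len(support)
            n_new[d] = len(support - ever[d])
            ever[d] |= support
            pools[d] = np.array([j for j in pool if j not in ever[d]])
        common = ever[0] & ever[1]
        trace.append({
            "round": round_no,
            "n_nonzero_data1": n_nonzero[0],
            "n_nonzero_data2": n_nonzero[1],
            "n_new_data1": n_new[0],
            "n_new_data2": n_new[1],
            "n_selected_total": len(common),
        })
        if len(common) >= n_features_target or sum(n_new) == 0:
            break

    if not common:
        raise ValueError(
            "no features selected in both datasets (stage 3): cumulative "
            f"supports have {len(ever[0])} features in data 1 and "
            f"{len(ever[1])} in data 2 with empty intersection"
        )
    s1 = [all_ids[j] for j in sorted(common)]
    return s1, trace


# --------------------------------------------------------------------------
# stage 4: between-data sign concordance


def filter_sign_concordant(
    Z1: LogRatioMatrix,
    y1,
    Z2: LogRatioMatrix,
    y2,
    s1: Sequence[str],
    family: str,
    n_folds: int = 5,
    seed: int = 0,
    max_rounds: int = 10,
) -> tuple[list[str], PenalisedFit, PenalisedFit]:
    """Keep the features of `s1` whose per-dataset ridge coefficients agree
    in sign, iterated to a fixed point.

    Each round fits an unweighted ridge model per dataset on the current
    set and drops features whose two coefficients disagree in sign (an
    exactly-zero coefficient matches no sign and also drops the feature).
    Returns the stable set together with the final two ridge fits, which
    are the stage-5 models.
    """
    if not s1:
        raise ValueError("stage 4: empty stage-3 feature set")
    current = list(s1)
    for round_no in range(max_rounds):
        X1 = Z1.columns(current)
        X2 = Z2.columns(current)
        # same fold seed for both datasets: fold construction depends only
        # on n and the outcome strata, and sharing it makes training exactly
        # symmetric under swapping or duplicating the two datasets
        fit1 = fit_ridge(X1, y1, family=family, n_folds=n_folds,
                         seed=seed + 2000 * round_no)
        fit2 = fit_ridge(X2, y2, family=family, n_folds=n_folds,
                         seed=seed + 2000 * round_no)
        sign1 = np.sign(fit1.coefficients)
        sign2 = np.sign(fit2.coefficients)
        keep = (sign1 == sign2) & (sign1 != 0.0)
        kept = [f for f, k in zip(current, keep) if k]
        if not kept:
            raise ValueError(
                "stage 4: no sign-concordant features remain; consider a "
                "larger stage-3 set or weaker filtering"
            )
        if kept == current:
            return kept, fit1, fit2
        current = kept
    # max_rounds reached without a fixed point: refit on the final set
    fit1 = fit_ridge(Z1.columns(current), y1, family=family, n_folds=n_folds,
                     seed=seed + 2000 * max_rounds)
    fit2 = fit_ridge(Z2.columns(current), y2, family=family, n_folds=n_folds,
                     seed=seed + 2000 * max_rounds)
    return current, fit1, fit2


# --------------------------------------------------------------------------
# full training


def fit_cpop(
    X1: GeneExpressionMatrix,
    y1: OutcomeVector,
    X2: GeneExpressionMatrix,
    y2: OutcomeVector,
    config: CPOPConfig | None = None,
) -> CPOPModel:
    """Train a CPOP model from two gene-aligned datasets.

    The two expression matrices must share an identical gene list (use
    :func:`cpop.io.align_common_genes` first) and carry outcomes of the
    same kind.  The result is fully reproducible from ``config.seed``.
    """
    cfg = config or CPOPConfig()
    if X1.gene_ids != X2.gene_ids:
        raise ValueError("training matrices are not gene-aligned; call "
                         "align_common_genes first")
    y1.check_aligned(X1)
    y2.check_aligned(X2)
    if y1.kind != y2.kind:
        raise ValueError("the two training outcomes have different kinds")
    expected = "survival" if cfg.family == "cox" else "binary"
    if cfg.family != "gaussian" and y1.kind != expected:
        raise ValueError(
            f"family {cfg.family!r} requires {expected!r} outcomes, "
            f"got {y1.kind!r}")

    Z1 = build_log_ratio_matrix(X1)
    Z2 = build_log_ratio_matrix(X2)
    weights = compute_feature_weights(Z1, Z2)

    yy1 = _family_response(y1, cfg.family)
    yy2 = _family_response(y2, cfg.family)

    s1, trace = select_common_features(
        Z1, yy1, Z2, yy2, weights, family=cfg.family, alpha=cfg.alpha,
        n_features_target=cfg.n_features_target,
        max_iterations=cfg.max_iterations, n_folds=cfg.n_folds,
        cv_repeats=cfg.cv_repeats, deep_band=cfg.deep_band, seed=cfg.seed,
        cv_rule=cfg.cv_rule)

    s2, fit1, fit2 = filter_sign_concordant(
        Z1, yy1, Z2, yy2, s1, family=cfg.family, n_folds=cfg.n_folds,
        seed=cfg.seed, max_rounds=cfg.sign_filter_max_rounds)

    beta1 = dict(zip(s2, fit1.coefficients))
    beta2 = dict(zip(s2, fit2.coefficients))
    beta_avg = {f: 0.5 * (beta1[f] + beta2[f]) for f in s2}
    if cfg.family == "cox":
        i1 = i2 = iavg = None
    else:
        i1, i2 = fit1.intercept, fit2.intercept
        iavg = 0.5 * (i1 + i2)

    # retained training columns (both datasets stacked) back the imputation
    # regressions for incoming samples with wholly-missing features
    ztrain = pd.DataFrame(
        np.vstack([Z1.columns(s2), Z2.columns(s2)]),
        index=[f"d1:{s}" for s in Z1.sample_ids]
        + [f"d2:{s}" for s in Z2.sample_ids],
        columns=s2,
    )
    return CPOPModel(
        family=cfg.family,
        source_genes=list(X1.gene_ids),
        s1=s1,
        s2=s2,
        beta1=beta1,
        beta2=beta2,
        beta_avg=beta_avg,
        intercept1=i1,
        intercept2=i2,
        intercept_avg=iavg,
        config=cfg,
        iteration_trace=trace,
        training_feature_means={f: float(ztrain[f].mean()) for f in s2},
        training_feature_variances={f: float(ztrain[f].var(ddof=0))
                                    for f in s2},
        training_ratio_columns=ztrain,
    )


def _family_response(y: OutcomeVector, family: str):
    if family == "cox":
        return (y.time, y.event)
    if y.kind == "binary":
        return y.class_label
    raise ValueError(f"cannot use a {y.kind!r} outcome with family {family!r}")


# --------------------------------------------------------------------------
# prediction


def _signature_ratios(model: CPOPModel, Xnew: GeneExpressionMatrix,
                      features: Sequence[str]) -> pd.DataFrame:
    """Build the requested signature ratio columns from raw expression."""
    index = {g: j for j, g in enumerate(Xnew.gene_ids)}
    cols = {}
    for fid in features:
        l, m = split_feature_id(fid)
        cols[fid] = Xnew.values[:, index[l]] - Xnew.values[:, index[m]]
    return pd.DataFrame(cols, index=Xnew.sample_ids)


def predict_cpop(
    model: CPOPModel,
    Xnew: GeneExpressionMatrix,
    output: str = "link",
    impute: bool = False,
) -> pd.Series:
    """Score new samples with the averaged CPOP model.

    No renormalisation of ``Xnew`` is performed or needed: only the
    signature ratio columns are computed from the raw log-scale values.
    ``output``: ``link`` (linear predictor), ``response`` (probability,
    binomial family) or ``risk`` (relative hazard exp(link), cox family).

    If signature genes are absent from ``Xnew`` and ``impute=True``, the
    affected ratio features are imputed from the observed ones via ridge
    regressions trained on the retained training columns.
    """
    have = set(Xnew.gene_ids)
    observed, missing = [], []
    for fid in model.s2:
        l, m = split_feature_id(fid)
        (observed if l in have and m in have else missing).append(fid)
    if missing and not impute:
        genes = sorted({g for fid in missing
                        for g in split_feature_id(fid) if g not in have})
        raise ValueError(
            f"{len(missing)} signature feature(s) need absent gene(s) "
            f"{genes}; pass impute=True to impute them"
        )
    Zobs = _signature_ratios(model, Xnew, observed)
    Znew = impute_missing_features(model, Zobs) if missing else Zobs

    beta = np.array([model.beta_avg[f] for f in model.s2])
    link = Znew[model.s2].to_numpy() @ beta
    if model.intercept_avg is not None:
        link = link + model.intercept_avg
    link = pd.Series(link, index=Xnew.sample_ids, name="score")
    if output == "link":
        return link
    if output == "response":
        if model.family != "binomial":
            raise ValueError("response scale requires a binomial model")
        return 1.0 / (1.0 + np.exp(-link))
    if output == "risk":
        if model.family != "cox":
            raise ValueError("risk scale requires a cox model")
        return np.exp(link)
    raise ValueError(f"unknown output scale {output!r}")


def impute_missing_features(model: CPOPModel,
                            Znew_partial: pd.DataFrame) -> pd.DataFrame:
    """Complete partially-observed signature ratio values.

    Every signature feature absent from ``Znew_partial`` is predicted by a
    ridge regression (gaussian, lambda by cross-validation) trained on the
    retained training ratio columns, with the observed signature features
    as covariates.  Deterministic given the model.
    """
    if model.training_ratio_columns is None:
        raise ValueError("model carries no training columns; re-train with "
                         "imputation support or supply complete features")
    observed = [f for f in model.s2 if f in Znew_partial.columns]
    missing = [f for f in model.s2 if f not in Znew_partial.columns]
    if not observed:
        raise ValueError("cannot impute: no signature feature is observed")
    if not missing:
        return Znew_partial

    ztrain = model.training_ratio_columns
    Xtr = ztrain[observed].to_numpy()
    Xnew = Znew_partial[observed].to_numpy()
    out = Znew_partial.copy()
    for fid in missing:
        # the deep end of the CV tie band: when observed features predict
        # the missing one (near-)exactly, regularisation bias vanishes
        fit = fit_ridge(Xtr, ztrain[fid].to_numpy(), family="gaussian",
                        n_folds=5, seed=model.config.seed + 7,
                        lambda_min_ratio=1e-10, cv_rule="lambda_deep")
        out[fid] = fit.predict(Xnew)
    return out[model.s2]
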