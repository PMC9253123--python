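"""Synthetic multi-platform expression cohorts with a planted ratio signal.

The generator emulates the structure that motivates ratio-based transfer
learning: several cohorts measure the same biology but each platform
distorts location and scale.  For dataset d, sample i, gene g the observed
log-scale value is

    x_{d,i,g} = s_d * e_{i,g} + gamma_{d,g} + c_{d,i}

where ``e = mu_g + eps`` is the clean biological signal
(``mu_g ~ Uniform(base_mean_range)``, ``eps ~ N(0, noise_sd^2)``),
``gamma_{d,g} ~ N(0, platform_gene_shift_sd^2)`` is a per-platform
per-gene offset, ``c_{d,i} ~ N(0, sample_shift_sd^2)`` a per-sample global
shift, and ``s_d ~ Uniform(platform_scale_range)`` a per-platform stretch.
Outcomes depend only on the *clean* values through disjoint signal gene
pairs:

    eta_i = effect_size * sum_pairs (e_{i,l} - e_{i,m})   (centred),

binary outcomes by logistic sampling of eta, survival times as exponential
with rate proportional to exp(eta) plus uniform censoring calibrated to
the requested censoring rate.  Platform distortions are therefore pure
nuisance: the planted signal features are unambiguous ratio columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GeneExpressionMatrix, OutcomeVector
from .ratios import feature_id

__all__ = [
    "SyntheticStudyConfig",
    "GroundTruth",
    "generate_multiplatform_study",
    "derive_prognosis_classes",
    "DEFAULT_CONFIG",
]

#: Baseline hazard: median survival of 24 months for a sample at eta = 0.
_BASE_HAZARD = np.log(2.0) / 24.0


@dataclass
class SyntheticStudyConfig:
    """Study-design parameters for :func:`generate_multiplatform_study`.

    Defaults describe the documented three-platform scenario used
    throughout the test-suite: two training cohorts plus one external
    validation cohort of 100 samples each, 60 genes, five disjoint signal
    ratios of unit effect, unit biological noise, per-sample shifts of
    sd 1.0 and per-platform gene shifts of sd 0.5 (all in log2 units).
    """

    seed: int = 2022
    n_datasets: int = 3
    n_per_dataset: tuple[int, ...] | int = 100
    p: int = 60
    n_signal_ratios: int = 5
    effect_size: float = 1.0
    pair_coexpression_sd: float = 2.0
    base_mean_range: tuple[float, float] = (6.0, 12.0)
    noise_sd: float = 1.0
    sample_shift_sd: float = 1.0
    platform_gene_shift_sd: float = 0.5
    platform_scale_range: tuple[float, float] = (0.9, 1.1)
    outcome_kind: str = "binary"
    censoring_rate: float = 0.3

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_dataset, int):
            return [self.n_per_dataset] * self.n_datasets
        sizes = list(self.n_per_dataset)
        if len(sizes) != self.n_datasets:
            raise ValueError("n_per_dataset length must equal n_datasets")
        return sizes

    def validate(self) -> None:
        if self.n_datasets < 2:
            raise ValueError("need at least 2 datasets")
        if any(n < 2 for n in self.sizes()):
            raise ValueError("each dataset needs at least 2 samples")
        if self.p < 2:
            raise ValueError("need at least 2 genes")
        if not 0 <= self.n_signal_ratios <= self.p // 2:
            raise ValueError(
                "n_signal_ratios must be at most p/2 (disjoint gene pairs)")
        for name in ("noise_sd", "sample_shift_sd", "platform_gene_shift_sd",
                     "pair_coexpression_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.outcome_kind not in ("binary", "survival"):
            raise ValueError("outcome_kind must be 'binary' or 'survival'")
        lo, hi = self.base_mean_range
        if hi < lo:
            raise ValueError("base_mean_range must be an interval")
        lo, hi = self.platform_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("platform_scale_range must be a positive interval")


DEFAULT_CONFIG = SyntheticStudyConfig()


@dataclass
class GroundTruth:
    """Everything needed to recompute the planted signal exactly."""

    signal_pairs: list[tuple[str, str]]
    signal_feature_ids: list[str]
    true_coefficients: dict[str, float]
    gene_means: dict[str, float]
    intercept: float
    linear_predictors: list[np.ndarray]
    platform_scales: list[float]
    platform_gene_shifts: list[np.ndarray]
    sample_shifts: list[np.ndarray]
    config: SyntheticStudyConfig = field(repr=False, default=None)


def _gene_names(p: int) -> list[str]:
    width = max(3, len(str(p)))
    return [f"G{i + 1:0{width}d}" for i in range(p)]


def generate_multiplatform_study(
    config: SyntheticStudyConfig | None = None,
) -> tuple[list[tuple[GeneExpressionMatrix, OutcomeVector]], GroundTruth]:
    """Generate a seeded multi-platform study with known signal features.

    Returns one ``(expression, outcome)`` pair per dataset plus the ground
    truth (planted ratio features, true coefficients, platform shifts).
    """
    cfg = config or DEFAULT_CONFIG
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p
    genes = _gene_names(p)

    mu = rng.uniform(*cfg.base_mean_range, size=p)

    # disjoint signal pairs; canonical ids keep the lexicographically
    # smaller gene first, so a pair drawn the other way round simply has a
    # negative true coefficient
    perm = rng.permutation(p)
    pairs_idx = [(perm[2 * k], perm[2 * k + 1])
                 for k in range(cfg.n_signal_ratios)]
    # distinct per-pair effects (spread around effect_size) make the
    # planted pairs the *unique* sparsest representation of the signal;
    # with equal effects any perfect matching of up- to down-genes would
    # be an equivalent model and "the" signal features would be ambiguous
    k = cfg.n_signal_ratios
    multipliers = (np.linspace(0.8, 1.2, k) if k > 1 else np.ones(max(k, 1)))
    pair_effects = cfg.effect_size * multipliers[:k]
    signal_pairs, signal_fids, true_coef = [], [], {}
    for (a, b), eff in zip(pairs_idx, pair_effects):
        ga, gb = genes[a], genes[b]
        signal_pairs.append((ga, gb))
        if a < b:
            fid, coef = feature_id(ga, gb), float(eff)
        else:
            fid, coef = feature_id(gb, ga), -float(eff)
        signal_fids.append(fid)
        true_coef[fid] = coef
    intercept = -float(sum(eff * (mu[a] - mu[b])
                           for (a, b), eff in zip(pairs_idx, pair_effects)))

    sizes = cfg.sizes()
    datasets = []
    etas, scales, gene_shifts, sample_shifts = [], [], [], []
    for d, n in enumerate(sizes):
        e = mu + rng.normal(0.0, cfg.noise_sd, size=(n, p))
        # signal-pair genes are co-expressed: a shared per-sample level
        # factor raises or lowers both genes of a pair together.  It
        # cancels exactly in the pair's own ratio (which carries the
        # outcome signal) while inflating the variance of every other
        # ratio touching these genes — the co-regulation structure that
        # makes ratio features informative in real expression data.
        for k2, (a, b) in enumerate(pairs_idx):
            f_k = rng.normal(0.0, cfg.pair_coexpression_sd, size=n)
            e[:, a] += f_k
            e[:, b] += f_k
        eta = intercept + np.sum(
            [eff * (e[:, a] - e[:, b])
             for (a, b), eff in zip(pairs_idx, pair_effects)], axis=0)
        s_d = float(rng.uniform(*cfg.platform_scale_range))
        gamma = rng.normal(0.0, cfg.platform_gene_shift_sd, size=p)
        c = rng.normal(0.0, cfg.sample_shift_sd, size=n)
        x = s_d * e + gamma[None, :] + c[:, None]

        ids = [f"D{d + 1}S{i + 1:04d}" for i in range(n)]
        X = GeneExpressionMatrix(x, ids, genes)
        if cfg.outcome_kind == "binary":
            prob = 1.0 / (1.0 + np.exp(-eta))
            y = OutcomeVector("binary", ids,
                              class_label=(rng.random(n) < prob).astype(float))
        else:
            t = rng.exponential(1.0, size=n) / (_BASE_HAZARD * np.exp(eta))
            time, event = _censor(t, cfg.censoring_rate, rng)
            y = OutcomeVector("survival", ids, time=time, event=event)
        datasets.append((X, y))
        etas.append(eta)
        scales.append(s_d)
        gene_shifts.append(gamma)
        sample_shifts.append(c)

    truth = GroundTruth(
        signal_pairs=signal_pairs,
        signal_feature_ids=signal_fids,
        true_coefficients=true_coef,
        gene_means=dict(zip(genes, mu)),
        intercept=intercept,
        linear_predictors=etas,
        platform_scales=scales,
        platform_gene_shifts=gene_shifts,
        sample_shifts=sample_shifts,
        config=cfg,
    )
    return datasets, truth


def _censor(t: np.ndarray, rate: float, rng: np.random.Generator):
    """Uniform censoring calibrated so the realised censored fraction is
    as close as possible to ``rate``."""
    n = len(t)
    if rate == 0.0:
        return t, np.ones(n)
    u = rng.random(n)  # censoring times C = u * c_max

    def censored_fraction(c_max: float) -> float:
        return float(np.mean(u * c_max < t))

    lo, hi = 1e-9, float(t.max()) * 2
    # censored fraction decreases in c_max; bisect to the target
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > rate:
            lo = mid
        else:
            hi = mid
    c = u * hi
    event = (t <= c).astype(float)
    return np.minimum(t, c), event


def derive_prognosis_classes(time_months: float, dead_of_disease: bool,
                             recurrence: bool) -> str:
    """Assign a prognosis class from recurrence-free survival follow-up.

    ``good``: more than four years (48 months) recurrence-free and alive;
    ``poor``: less than one year (12 months) and died of disease;
    everything else is ``excluded`` from the two-class analysis.
    """
    if time_months < 0:
        raise ValueError("survival time must be non-negative")
    if time_months > 48.0 and not dead_of_disease and not recurrence:
        return "good"
    if time_months < 12.0 and dead_of_disease:
        return "poor"
    return "excluded"
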