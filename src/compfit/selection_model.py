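"""One-locus haploid selection model and relative-fitness estimation.

The competition between two strains A and a with per-generation fitnesses
W_AA and W_aa follows the classic recurrence

    p_{t+1} = p_t * w / (p_t * w + (1 - p_t)),    w = W_AA / W_aa,

whose closed form is p_t = p0 * w**t / (p0 * w**t + 1 - p0).  On the logit
scale this is a straight line,

    logit(p_t) = logit(p0) + t * log(w),

so log(w) is the slope of an ordinary least-squares regression of
logit(proportion) on generation number.  The selection coefficient of the
focal allele is s = w - 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class UnfittableTrajectoryError(ValueError):
    """Raised when no trajectory carries enough finite-logit points to fit."""


@dataclass(frozen=True)
class AlleleTrajectory:
    """Measured proportions of allele/strain A over generations, one replicate.

    Parameters
    ----------
    pair_label : str
        Which two strains were competed, e.g. ``"N2 vs barcoded CX12311"``.
    replicate_id : str
        Identifier of the biological replicate (one competition plate series).
    generations : tuple of int
        Measurement times in generations (one generation per transfer),
        strictly increasing and non-negative.
    proportions : tuple of float
        Measured proportion of allele A at each generation, each in [0, 1].
    """

    pair_label: str
    replicate_id: str
    generations: tuple
    proportions: tuple

    def __post_init__(self):
        gens = tuple(int(g) for g in self.generations)
        props = tuple(float(p) for p in self.proportions)
        object.__setattr__(self, "generations", gens)
        object.__setattr__(self, "proportions", props)
        if len(gens) != len(props):
            raise ValueError(
                f"{self.pair_label}/{self.replicate_id}: generations and "
                f"proportions differ in length ({len(gens)} vs {len(props)})"
            )
        if any(g < 0 for g in gens):
            raise ValueError("generations must be non-negative")
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must be strictly increasing")
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ValueError("proportions must lie in [0, 1]")

    def __len__(self):
        return len(self.generations)


@dataclass(frozen=True)
class FitConfig:
    """Options for the relative-fitness fit.

    ``generations_per_transfer`` rescales measurement times (the protocol
    assumes one generation per transfer; the scalar makes that assumption
    testable).  Boundary proportions (0 or 1) carry no logit information;
    ``boundary_policy`` either drops them (default) or clamps into
    [epsilon, 1-epsilon].
    """

    generations_per_transfer: float = 1.0
    boundary_policy: str = "drop"  # or "epsilon_clamp"
    epsilon: float = 1e-6
    ci_method: str = "replicate_t"  # or "bootstrap"
    ci_level: float = 0.95
    bootstrap_n: int = 2000
    seed: int = 0
    method: str = "per_replicate_slopes"  # or "pooled_fixed_intercepts"

    def __post_init__(self):
        if self.generations_per_transfer <= 0:
            raise ValueError("generations_per_transfer must be positive")
        if self.boundary_policy not in ("drop", "epsilon_clamp"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")
        if not (0.0 < self.epsilon < 0.01):
            raise ValueError("epsilon must lie in (0, 0.01)")
        if self.ci_method not in ("replicate_t", "bootstrap"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        if self.bootstrap_n < 100:
            raise ValueError("bootstrap_n must be >= 100")
        if self.method not in ("per_replicate_slopes", "pooled_fixed_intercepts"):
            raise ValueError(f"unknown fit method {self.method!r}")


@dataclass(frozen=True)
class FitnessEstimate:
    """Result of fitting the selection model to one competition experiment.

    ``w_hat`` is the per-generation relative fitness W_AA/W_aa of the focal
    strain; ``s_hat = w_hat - 1`` its selection coefficient.  The confidence
    interval bounds are reported on the scale named by ``ci_scale``
    (default ``"s"``); ``ci_low``/``ci_high`` are None when the interval is
    undefined (a single replicate under the replicate-t method).
    """

    w_hat: float
    log_w_hat: float
    s_hat: float
    ci_low: float | None
    ci_high: float | None
    ci_level: float
    ci_scale: str
    n_replicates: int
    n_points_total: int
    method: str
    replicate_slopes: tuple = field(default=(), repr=False)

    def __post_init__(self):
        if not self.w_hat > 0:
            raise ValueError("w_hat must be positive")

    def to_dict(self):
        return {
            "w_hat": self.w_hat,
            "log_w_hat": self.log_w_hat,
            "s_hat": self.s_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "ci_scale": self.ci_scale,
            "n_replicates": self.n_replicates,
            "n_points_total": self.n_points_total,
            "method": self.method,
        }


def predict_frequency(p0, w, t):
    """Closed-form allele frequency after ``t`` generations of selection.

    p_t = p0 * w**t / (p0 * w**t + 1 - p0); the boundaries p0 = 0, 1 are
    absorbing.  Vectorized over ``t``.
    """
    p0 = np.asarray(p0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("p0 must lie in [0, 1]")
    if w <= 0:
        raise ValueError("w must be positive")
    # odds form avoids overflow of w**t at large t: log-odds shift by t*log(w)
    with np.errstate(divide="ignore"):
        logit0 = np.log(p0) - np.log1p(-p0)
    logit_t = logit0 + t * math.log(w)
    out = _expit(logit_t)
    # enforce absorbing boundaries exactly
    out = np.where(p0 == 0.0, 0.0, out)
    out = np.where(p0 == 1.0, 1.0, out)
    return out.item() if out.ndim == 0 else out


def _expit(x):
    return stats.logistic.cdf(x)


def logit(p, boundary_policy="drop", epsilon=1e-6):
    """log(p / (1-p)) with explicit boundary handling.

    Under policy ``"drop"`` boundary values map to ±inf, which downstream
    fits treat as excluded points; under ``"epsilon_clamp"`` p is clamped to
    [epsilon, 1-epsilon] first.  Vectorized.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if boundary_policy == "epsilon_clamp":
        p = np.clip(p, epsilon, 1.0 - epsilon)
    elif boundary_policy != "drop":
        raise ValueError(f"unknown boundary_policy {boundary_policy!r}")
    with np.errstate(divide="ignore"):
        out = np.log(p) - np.log1p(-p)
    return out.item() if out.ndim == 0 else out


def selection_coefficient(w):
    """Selection coefficient s = w - 1 of the focal allele."""
    if w <= 0:
        raise ValueError("w must be positive")
    return w - 1.0


def _finite_points(traj: AlleleTrajectory, config: FitConfig):
    """Times and logits surviving the boundary policy, for one replicate."""
    t = np.asarray(traj.generations, dtype=float) * config.generations_per_transfer
    y = logit(np.asarray(traj.proportions, dtype=float),
              config.boundary_policy, config.epsilon)
    y = np.atleast_1d(y)
    keep = np.isfinite(y)
    return t[keep], y[keep]


def _ols_slope(t, y):
    """Slope and intercept of OLS y ~ 1 + t (2 parameters, >= 2 points)."""
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef[1], coef[0]


def fit_relative_fitness(trajectories, config: FitConfig | None = None) -> FitnessEstimate:
    """Estimate relative fitness w and selection coefficient s from trajectories.

    Default method ``per_replicate_slopes``: OLS of logit(p) on t separately
    per replicate (free intercept, so the founding proportion need not be
    0.5); log(w) is the mean of the replicate slopes and the CI a
    t-interval over them.  Method ``pooled_fixed_intercepts`` fits one
    shared slope with a separate intercept per replicate in a single OLS.

    The CI is computed on the log(w) scale and transformed to the s scale
    (monotone map s = exp(logw) - 1), so ci_low <= s_hat <= ci_high.
    """
    if config is None:
        config = FitConfig()
    trajectories = list(trajectories)
    if not trajectories:
        raise UnfittableTrajectoryError("no trajectories supplied")

    points = []
    for traj in trajectories:
        t, y = _finite_points(traj, config)
        if len(t) >= 2:
            points.append((traj, t, y))
        else:
            warnings.warn(
                f"replicate {traj.replicate_id!r}: fewer than 2 finite-logit "
                "points after boundary policy; excluded from fit",
                stacklevel=2,
            )
    if not points:
        raise UnfittableTrajectoryError(
            "no trajectory has >= 2 finite-logit points after boundary policy"
        )

    n_points_total = sum(len(t) for _, t, _ in points)
    n_replicates = len(points)

    if config.method == "per_replicate_slopes":
        slopes = np.array([_ols_slope(t, y)[0] for _, t, y in points])
        log_w = float(np.mean(slopes))
        ci_logw = _ci_log_w(slopes, config)
    else:  # pooled_fixed_intercepts
        slopes, log_w, ci_logw = _fit_pooled(points, config)

    w_hat = math.exp(log_w)
    s_hat = w_hat - 1.0
    if ci_logw is None:
        ci_low = ci_high = None
    else:
        ci_low = math.exp(ci_logw[0]) - 1.0
        ci_high = math.exp(ci_logw[1]) - 1.0
    return FitnessEstimate(
        w_hat=w_hat,
        log_w_hat=log_w,
        s_hat=s_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=config.ci_level,
        ci_scale="s",
        n_replicates=n_replicates,
        n_points_total=n_points_total,
        method=config.method,
        replicate_slopes=tuple(float(s) for s in np.atleast_1d(slopes)),
    )


def _ci_log_w(slopes, config: FitConfig):
    """CI for mean log(w), on the log scale, or None if undefined."""
    n = len(slopes)
    if config.ci_method == "replicate_t":
        if n < 2:
            warnings.warn(
                "replicate_t CI undefined with a single replicate; "
                "returning no interval",
                stacklevel=3,
            )
            return None
        se = float(np.std(slopes, ddof=1)) / math.sqrt(n)
        tcrit = stats.t.ppf(0.5 + config.ci_level / 2.0, df=n - 1)
        m = float(np.mean(slopes))
        return (m - tcrit * se, m + tcrit * se)
    # bootstrap over replicates
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(config.bootstrap_n, n))
    boot_means = np.asarray(slopes)[idx].mean(axis=1)
    alpha = 1.0 - config.ci_level
    lo, hi = np.quantile(boot_means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(lo), float(hi))


def _fit_pooled(points, config: FitConfig):
    """One shared slope, one intercept per replicate, via statsmodels OLS."""
    import statsmodels.api as sm

    t_all, y_all, blocks = [], [], []
    for i, (_, t, y) in enumerate(points):
        t_all.append(t)
        y_all.append(y)
        blocks.append(np.full(len(t), i))
    t_all = np.concatenate(t_all)
    y_all = np.concatenate(y_all)
    blocks = np.concatenate(blocks)
    dummies = (blocks[:, None] == np.arange(len(points))[None, :]).astype(float)
    X = np.column_stack([dummies, t_all])
    res = sm.OLS(y_all, X).fit()
    log_w = float(res.params[-1])
    if config.ci_method == "replicate_t":
        ci = res.conf_int(alpha=1.0 - config.ci_level)
        ci_logw = (float(ci[-1][0]), float(ci[-1][1]))
        if res.df_resid < 1:
            ci_logw = None
    else:
        rng = np.random.default_rng(config.seed)
        n = len(points)
        boot = np.empty(config.bootstrap_n)
        for b in range(config.bootstrap_n):
            pick = rng.integers(0, n, size=n)
            sub = [points[j] for j in pick]
            _, lw, _ = _fit_pooled_once(sub)
            boot[b] = lw
        alpha = 1.0 - config.ci_level
        lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        ci_logw = (float(lo), float(hi))
    # per-replicate slopes reported for diagnostics even under pooling
    slopes = np.array([_ols_slope(t, y)[0] for _, t, y in points])
    return slopes, log_w, ci_logw


def _fit_pooled_once(points):
    t_all = np.concatenate([t for _, t, _ in points])
    y_all = np.concatenate([y for _, _, y in points])
    blocks = np.concatenate(
        [np.full(len(t), i) for i, (_, t, _) in enumerate(points)]
    )
    dummies = (blocks[:, None] == np.arange(len(points))[None, :]).astype(float)
    X = np.column_stack([dummies, t_all])
    coef, *_ = np.linalg.lstsq(X, y_all, rcond=None)
    return None, float(coef[-1]), None
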