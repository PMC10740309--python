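"""Robust two-sample estimators and bootstrap machinery.

This module collects the distribution-free building blocks used by every
downstream battery: the Harrell–Davis (HD) quantile estimator, a decile
shift function with percentile-bootstrap confidence intervals, Cliff's
delta / probability-of-superiority inference, the kernel-density overlap
index, an empirically counted Cohen's U3, a Wald-type inter-quartile-range
ratio test, percentile-bootstrap comparisons of skewness and kurtosis,
Benjamini–Hochberg adjustment, and effect-size magnitude benchmarks.

All estimators are location/scale-free in the sense that they assume
neither normality nor homoscedasticity.  Group "A" is always the first
argument; positive dominance statistics mean A tends to exceed B.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapConfig",
    "EffectEstimate",
    "DecileShiftResult",
    "DominanceResult",
    "hd_quantile",
    "hd_quantiles",
    "decile_shift_test",
    "cliff_delta_inference",
    "global_wmw_test",
    "overlap_eta",
    "cohens_u3_empirical",
    "iqr_ratio_test",
    "bootstrap_moment_difference",
    "fdr_adjust",
    "classify_magnitude",
    "derive_rng",
    "DECILES",
]

DECILES: NDArray[np.float64] = np.arange(1, 10) / 10.0

#: |d| benchmarks (Cohen) and |delta| benchmarks (Romano et al. style):
#: negligible < t0 <= small < t1 <= medium < t2 <= large
MAGNITUDE_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "cohen_d": (0.2, 0.5, 0.8),
    "cliff_delta": (0.147, 0.33, 0.474),
}


@dataclass(frozen=True)
class BootstrapConfig:
    """Shared bootstrap settings for the two-sample batteries.

    The default repetition counts follow common practice for each family:
    4000 for decile shifts, 1000 for the overlap index, 2000 for U3 and
    for the moment comparisons.  ``seed`` drives every derived stream; see
    :func:`derive_rng`.
    """

    n_boot_deciles: int = 4000
    n_boot_overlap: int = 1000
    n_boot_u3: int = 2000
    n_boot_moments: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_boot_deciles", "n_boot_overlap", "n_boot_u3", "n_boot_moments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def scaled(self, factor: float) -> "BootstrapConfig":
        """Return a copy with all repetition counts multiplied by ``factor``
        (floored at 1); convenient for quick runs."""
        return replace(
            self,
            n_boot_deciles=max(1, int(self.n_boot_deciles * factor)),
            n_boot_overlap=max(1, int(self.n_boot_overlap * factor)),
            n_boot_u3=max(1, int(self.n_boot_u3 * factor)),
            n_boot_moments=max(1, int(self.n_boot_moments * factor)),
        )


@dataclass
class EffectEstimate:
    """A point estimate with an optional CI, p-value and magnitude label."""

    value: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    p: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")


@dataclass
class DecileShiftResult:
    """Outcome of the HD decile comparison of two groups."""

    quantiles: NDArray[np.float64]
    hd_a: NDArray[np.float64]
    hd_b: NDArray[np.float64]
    difference: NDArray[np.float64]  # hd_a - hd_b
    ci_low: NDArray[np.float64]
    ci_high: NDArray[np.float64]
    p: NDArray[np.float64]
    significant: NDArray[np.bool_]  # Hochberg-controlled across the deciles


@dataclass
class DominanceResult:
    """Probability of superiority and Cliff's delta for two groups."""

    ps_a: float
    ps_b: float
    delta: EffectEstimate


def derive_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """Deterministically derive an independent generator from ``seed`` and a
    sequence of integer or string keys (operation name, ROI index, ...).

    String keys are hashed with CRC32 so the scheme is stable across runs
    and Python processes.
    """
    ints = [zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *ints]))


# ---------------------------------------------------------------------------
# Harrell–Davis quantiles


def _hd_weights(n: int, q: float) -> NDArray[np.float64]:
    a = (n + 1) * q
    b = (n + 1) * (1.0 - q)
    edges = stats.beta.cdf(np.arange(n + 1) / n, a, b)
    return np.diff(edges)


def hd_quantile(x: ArrayLike, q: float) -> float:
    """Harrell–Davis estimate of the ``q`` quantile of ``x``.

    A beta-weighted average of all order statistics: the weight on the i-th
    order statistic is the increment of the Beta((n+1)q, (n+1)(1-q)) CDF
    over ((i-1)/n, i/n].
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("hd_quantile: empty input")
    if not 0.0 < q < 1.0:
        raise ValueError(f"hd_quantile: q must be in (0, 1), got {q}")
    return float(np.sort(x) @ _hd_weights(x.size, q))


def hd_quantiles(x: ArrayLike, qs: Sequence[float]) -> NDArray[np.float64]:
    """Vectorised :func:`hd_quantile` over several probabilities."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("hd_quantiles: empty input")
    w = np.stack([_hd_weights(x.size, q) for q in qs])
    return w @ x


def _hd_of_rows(sorted_rows: NDArray[np.float64], q: float) -> NDArray[np.float64]:
    """HD quantile of each (already sorted) row of a matrix."""
    return sorted_rows @ _hd_weights(sorted_rows.shape[1], q)


def _boot_matrix(rng: np.random.Generator, x: NDArray[np.float64], reps: int) -> NDArray[np.float64]:
    idx = rng.integers(0, x.size, size=(reps, x.size))
    return x[idx]


# ---------------------------------------------------------------------------
# Decile shift function


def _hochberg_reject(p: NDArray[np.float64], alpha: float) -> NDArray[np.bool_]:
    """Hochberg step-up rejections at familywise level ``alpha``."""
    m = p.size
    order = np.argsort(p)[::-1]  # descending
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):  # rank 0 -> largest p, critical alpha/1
        if p[idx] <= alpha / (rank + 1):
            # reject this and every smaller p
            reject[p <= p[idx]] = True
            break
    return reject


def _percentile_p(boot: NDArray[np.float64]) -> float:
    """Two-sided percentile-bootstrap p for H0: parameter difference = 0."""
    b = boot.size
    p_low = (np.count_nonzero(boot < 0) + 0.5 * np.count_nonzero(boot == 0)) / b
    return float(min(1.0, 2.0 * min(p_low, 1.0 - p_low)))


def decile_shift_test(
    x_a: ArrayLike, x_b: ArrayLike, cfg: BootstrapConfig, rng: np.random.Generator | None = None
) -> DecileShiftResult:
    """Compare the nine deciles of two groups with the HD estimator and a
    percentile bootstrap.

    The point differences are ``HD_q(A) - HD_q(B)``; CIs come from
    independent within-group resampling, and the nine simultaneous
    comparisons are controlled with Hochberg's step-up procedure at
    ``cfg.alpha``.  On robust z-scores the differences read as Cohen-d-like
    standardized shifts.
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if min(x_a.size, x_b.size) < 10:
        raise ValueError("decile_shift_test: each group needs n >= 10")
    rng = rng if rng is not None else derive_rng(cfg.seed, "deciles")

    hd_a = hd_quantiles(x_a, DECILES)
    hd_b = hd_quantiles(x_b, DECILES)
    diff = hd_a - hd_b

    boot_a = np.sort(_boot_matrix(rng, x_a, cfg.n_boot_deciles), axis=1)
    boot_b = np.sort(_boot_matrix(rng, x_b, cfg.n_boot_deciles), axis=1)
    lo_q, hi_q = 100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)
    ci_low = np.empty(9)
    ci_high = np.empty(9)
    pvals = np.empty(9)
    for k, q in enumerate(DECILES):
        d_star = _hd_of_rows(boot_a, q) - _hd_of_rows(boot_b, q)
        ci_low[k], ci_high[k] = np.percentile(d_star, [lo_q, hi_q])
        pvals[k] = _percentile_p(d_star)

    return DecileShiftResult(
        quantiles=DECILES.copy(),
        hd_a=hd_a,
        hd_b=hd_b,
        difference=diff,
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        significant=_hochberg_reject(pvals, cfg.alpha),
    )


# ---------------------------------------------------------------------------
# Cliff's delta / probability of superiority


def _dominance_counts(x_a: NDArray[np.float64], x_b: NDArray[np.float64]) -> NDArray[np.float64]:
    """Sign matrix sign(a_i - b_j), exhaustively over all pairs."""
    return np.sign(x_a[:, None] - x_b[None, :])


def cliff_delta_inference(
    x_a: ArrayLike, x_b: ArrayLike, cfg: BootstrapConfig | None = None, alpha: float | None = None
) -> DominanceResult:
    """Probability of superiority and Cliff's delta by exhaustive pair
    counting, with the consistent-variance normal-theory interval.

    PS(A) = [#(a > b) + 0.5 #(a = b)] / (n_A n_B); delta = P(A>B) - P(A<B)
    = 2 PS(A) - 1 under this tie convention.  The CI uses Cliff's
    asymmetric transformation, which respects the [-1, 1] bounds, and the
    p-value is the normal-theory test of delta = 0.
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("cliff_delta_inference: empty group")
    if alpha is None:
        alpha = cfg.alpha if cfg is not None else 0.05
    n_a, n_b = x_a.size, x_b.size

    dom = _dominance_counts(x_a, x_b)
    delta = float(dom.mean())
    ps_a = (np.count_nonzero(dom > 0) + 0.5 * np.count_nonzero(dom == 0)) / (n_a * n_b)

    # Consistent variance estimate (Cliff 1996)
    d_i = dom.mean(axis=1)
    d_j = dom.mean(axis=0)
    if n_a > 1 and n_b > 1:
        s2 = (
            n_b**2 * np.sum((d_i - delta) ** 2)
            + n_a**2 * np.sum((d_j - delta) ** 2)
            - np.sum((dom - delta) ** 2)
        ) / (n_a * n_b * (n_a - 1) * (n_b - 1))
        s2 = max(s2, 0.0)
    else:
        s2 = np.nan
    sd = math.sqrt(s2) if np.isfinite(s2) else math.nan

    z_crit = stats.norm.ppf(1 - alpha / 2)
    if not np.isfinite(sd) or sd == 0.0:
        lo = hi = delta
        p = 1.0 if delta == 0.0 else 0.0
    else:
        d2 = delta * delta
        root = math.sqrt((1 - d2) ** 2 + z_crit**2 * sd**2)
        den = 1 - d2 + z_crit**2 * sd**2
        lo = (delta - delta * d2 - z_crit * sd * root) / den
        hi = (delta - delta * d2 + z_crit * sd * root) / den
        p = float(2 * stats.norm.sf(abs(delta) / sd))
    lo, hi = max(lo, -1.0), min(hi, 1.0)

    est = EffectEstimate(value=delta, ci_low=lo, ci_high=hi, p=min(p, 1.0))
    est.label = classify_magnitude(delta, "cliff_delta")
    return DominanceResult(ps_a=float(ps_a), ps_b=float(1.0 - ps_a), delta=est)


def global_wmw_test(
    x_a: ArrayLike,
    x_b: ArrayLike,
    cfg: BootstrapConfig | None = None,
    method: Literal["cliff", "brunner-munzel"] = "cliff",
) -> dict:
    """Heteroscedastic rank test of a global distributional shift.

    By default the Cliff dominance machinery supplies the p-value (the same
    approach as the PS/delta inference); the Brunner–Munzel test is offered
    as an alternative.  The reported shift is the HD-median difference
    A - B, a robust standardized location shift when inputs are z-scores.
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("global_wmw_test: empty group")
    shift = hd_quantile(x_a, 0.5) - hd_quantile(x_b, 0.5)
    if method == "cliff":
        dom = cliff_delta_inference(x_a, x_b, cfg)
        p = dom.delta.p
    elif method == "brunner-munzel":
        p = float(stats.brunnermunzel(x_a, x_b).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"shift": EffectEstimate(value=float(shift), p=p), "p": p}


# ---------------------------------------------------------------------------
# Overlap index


def _silverman_bw(x: NDArray[np.float64]) -> float:
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("overlap_eta: degenerate (zero-spread) group")
    return 0.9 * scale * n ** (-0.2)


def _kde_on_grid(x: NDArray[np.float64], grid: NDArray[np.float64], bw: float) -> NDArray[np.float64]:
    z = (grid[:, None] - x[None, :]) / bw
    return np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw * math.sqrt(2 * math.pi))


def _overlap_from_densities(fa: NDArray, fb: NDArray, grid: NDArray) -> float:
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def overlap_eta(
    x_a: ArrayLike,
    x_b: ArrayLike,
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
    grid_size: int = 512,
) -> EffectEstimate:
    """Overlap index: area under the pointwise minimum of the two group
    KDEs, in [0, 1] (reported here as a proportion; multiply by 100 for
    percent).

    Gaussian kernels with per-group Silverman bandwidths are evaluated on a
    common grid spanning the pooled range padded by three pooled
    bandwidths.  The percentile-bootstrap CI resamples each group
    independently; for speed the bandwidths are held at their full-sample
    values across resamples (bootstrap samples have near-identical spread).
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if min(x_a.size, x_b.size) < 10:
        raise ValueError("overlap_eta: each group needs n >= 10")
    rng = rng if rng is not None else derive_rng(cfg.seed, "overlap")

    bw_a, bw_b = _silverman_bw(x_a), _silverman_bw(x_b)
    pad = 3.0 * max(bw_a, bw_b)
    lo = min(x_a.min(), x_b.min()) - pad
    hi = max(x_a.max(), x_b.max()) + pad
    grid = np.linspace(lo, hi, grid_size)

    eta = _overlap_from_densities(_kde_on_grid(x_a, grid, bw_a), _kde_on_grid(x_b, grid, bw_b), grid)

    # Bootstrap via linear binning: density* = kernel matrix @ normalized histogram
    step = grid[1] - grid[0]
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])

    def boot_etas() -> NDArray[np.float64]:
        ka = _kernel_matrix(grid, bw_a)
        kb = _kernel_matrix(grid, bw_b)
        out = np.empty(cfg.n_boot_overlap)
        for r in range(cfg.n_boot_overlap):
            sa = x_a[rng.integers(0, x_a.size, x_a.size)]
            sb = x_b[rng.integers(0, x_b.size, x_b.size)]
            ha = np.histogram(np.clip(sa, grid[0], grid[-1]), bins=edges)[0] / sa.size
            hb = np.histogram(np.clip(sb, grid[0], grid[-1]), bins=edges)[0] / sb.size
            out[r] = _overlap_from_densities(ka @ ha, kb @ hb, grid)
        return out

    etas = boot_etas()
    lo_ci, hi_ci = np.percentile(etas, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])
    return EffectEstimate(value=min(eta, 1.0), ci_low=float(lo_ci), ci_high=float(min(hi_ci, 1.0)))


def _kernel_matrix(grid: NDArray[np.float64], bw: float) -> NDArray[np.float64]:
    z = (grid[:, None] - grid[None, :]) / bw
    return np.exp(-0.5 * z * z) / (bw * math.sqrt(2 * math.pi))


# ---------------------------------------------------------------------------
# Cohen's U3, IQR ratio, moment differences


def cohens_u3_empirical(
    x_a: ArrayLike, x_b: ArrayLike, cfg: BootstrapConfig, rng: np.random.Generator | None = None
) -> EffectEstimate:
    """Percent of group A strictly above the HD median of group B, with a
    percentile-bootstrap CI (both groups resampled independently)."""
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("cohens_u3_empirical: empty group")
    rng = rng if rng is not None else derive_rng(cfg.seed, "u3")

    med_b = hd_quantile(x_b, 0.5)
    u3 = 100.0 * np.count_nonzero(x_a > med_b) / x_a.size

    boot_b = np.sort(_boot_matrix(rng, x_b, cfg.n_boot_u3), axis=1)
    med_star = _hd_of_rows(boot_b, 0.5)
    boot_a = _boot_matrix(rng, x_a, cfg.n_boot_u3)
    u3_star = 100.0 * np.count_nonzero(boot_a > med_star[:, None], axis=1) / x_a.size
    lo, hi = np.percentile(u3_star, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])
    return EffectEstimate(value=float(u3), ci_low=float(lo), ci_high=float(hi))


def _hd_iqr_of_rows(sorted_rows: NDArray[np.float64]) -> NDArray[np.float64]:
    return _hd_of_rows(sorted_rows, 0.75) - _hd_of_rows(sorted_rows, 0.25)


def iqr_ratio_test(
    x_a: ArrayLike, x_b: ArrayLike, cfg: BootstrapConfig, rng: np.random.Generator | None = None
) -> EffectEstimate:
    """Wald-type comparison of the two groups' inter-quartile ranges.

    IQRs are HD(0.75) - HD(0.25); the test statistic is the log ratio
    log(IQR_A / IQR_B) divided by its bootstrap standard error, referred to
    the standard normal.  Returns the ratio A/B with a log-scale Wald CI.
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if min(x_a.size, x_b.size) < 10:
        raise ValueError("iqr_ratio_test: each group needs n >= 10")
    rng = rng if rng is not None else derive_rng(cfg.seed, "iqr")

    iqr_a = hd_quantile(x_a, 0.75) - hd_quantile(x_a, 0.25)
    iqr_b = hd_quantile(x_b, 0.75) - hd_quantile(x_b, 0.25)
    if iqr_a <= 0 or iqr_b <= 0:
        raise ValueError("iqr_ratio_test: zero IQR in a group")

    reps = cfg.n_boot_moments
    star_a = _hd_iqr_of_rows(np.sort(_boot_matrix(rng, x_a, reps), axis=1))
    star_b = _hd_iqr_of_rows(np.sort(_boot_matrix(rng, x_b, reps), axis=1))
    good_a, good_b = star_a[star_a > 0], star_b[star_b > 0]
    se = math.sqrt(np.log(good_a).var(ddof=1) + np.log(good_b).var(ddof=1))
    log_ratio = math.log(iqr_a / iqr_b)
    if se == 0:
        z = math.inf if log_ratio != 0 else 0.0
        p = 0.0 if log_ratio != 0 else 1.0
        lo = hi = iqr_a / iqr_b
    else:
        z = log_ratio / se
        p = float(2 * stats.norm.sf(abs(z)))
        z_crit = stats.norm.ppf(1 - cfg.alpha / 2)
        lo = math.exp(log_ratio - z_crit * se)
        hi = math.exp(log_ratio + z_crit * se)
    return EffectEstimate(value=iqr_a / iqr_b, ci_low=lo, ci_high=hi, p=p)


def _moment(x: NDArray[np.float64], which: str, axis: int = -1) -> NDArray[np.float64] | float:
    if which == "skewness":
        return stats.skew(x, axis=axis, bias=True)
    if which == "kurtosis":
        # non-excess convention: a Gaussian scores 3
        return stats.kurtosis(x, axis=axis, fisher=False, bias=True)
    raise ValueError(f"unknown moment {which!r}")


def bootstrap_moment_difference(
    x_a: ArrayLike,
    x_b: ArrayLike,
    moment: Literal["skewness", "kurtosis"],
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> EffectEstimate:
    """Percentile-bootstrap comparison of a plug-in moment estimator
    (skewness or non-excess kurtosis) between two independent groups.

    The p-value is 2 * min(P*(diff < 0), P*(diff > 0)); the CI is the
    percentile interval of the bootstrapped difference A - B.
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if min(x_a.size, x_b.size) < 20:
        raise ValueError("bootstrap_moment_difference: each group needs n >= 20")
    if x_a.std() == 0 or x_b.std() == 0:
        raise ValueError("bootstrap_moment_difference: degenerate variance")
    rng = rng if rng is not None else derive_rng(cfg.seed, f"moment-{moment}")

    diff = float(_moment(x_a, moment) - _moment(x_b, moment))
    star = _moment(_boot_matrix(rng, x_a, cfg.n_boot_moments), moment) - _moment(
        _boot_matrix(rng, x_b, cfg.n_boot_moments), moment
    )
    lo, hi = np.percentile(star, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])
    return EffectEstimate(value=diff, ci_low=float(lo), ci_high=float(hi), p=_percentile_p(star))


# ---------------------------------------------------------------------------
# Multiplicity and benchmarks


def fdr_adjust(p_values: ArrayLike) -> NDArray[np.float64]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("fdr_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_magnitude(
    value: float,
    index: Literal["cohen_d", "cliff_delta"],
    thresholds: tuple[float, float, float] | None = None,
) -> str:
    """Benchmark label for an effect size: |d| against 0.2/0.5/0.8 or
    |delta| against 0.147/0.33/0.474 (upper boundaries inclusive)."""
    if not np.isfinite(value):
        raise ValueError("classify_magnitude: value must be finite")
    if thresholds is None:
        try:
            thresholds = MAGNITUDE_THRESHOLDS[index]
        except KeyError:
            raise ValueError(f"classify_magnitude: unknown index {index!r}") from None
    t_small, t_medium, t_large = thresholds
    v = abs(value)
    if v >= t_large:
        return "large"
    if v >= t_medium:
        return "medium"
    if v >= t_small:
        return "small"
    return "negligible"
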