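"""Multivariate sex-difference estimation from classification probabilities.

An L2-penalized logistic regression predicts sex from the 18 robust-z ROI
volumes; the fitted per-subject probabilities ("Pclass scores") compress
the multivariate contrast into one continuous score on [0, 1], on which
the same robust two-sample battery used per ROI can be run.  The module
also provides Harrell-style bootstrap optimism correction of the
discrimination indexes (Nagelkerke R^2, C-index, Somers' Dxy), calibration
curves, nomogram tables, the all-pairwise-differences summary (with POMP
reading), cross-model coefficient-structure comparisons, and the
intersection analysis of significant predictors.

The reference sex (the class coded 1) is chosen from the direction of the
univariate effects so that higher Pclass always means "more gray matter"
on the dataset's own scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats
from scipy.special import expit

from .effects import (
    BootstrapConfig,
    EffectEstimate,
    bootstrap_moment_difference,
    cliff_delta_inference,
    cohens_u3_empirical,
    decile_shift_test,
    derive_rng,
    fdr_adjust,
    hd_quantile,
    hd_quantiles,
    iqr_ratio_test,
    overlap_eta,
    DECILES,
)
from .univariate import UnivariateTable

__all__ = [
    "PclassModel",
    "ScoreSet",
    "PairwiseDiffSummary",
    "select_reference_category",
    "fit_penalized_lr",
    "bootstrap_validate",
    "calibration_curve",
    "pclass_scores",
    "score_battery",
    "pairwise_difference_summary",
    "build_nomogram",
    "compare_model_structure",
    "significant_predictor_intersections",
    "fit_tiv_augmented",
    "DEFAULT_PENALTY_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_PENALTY_GRID: tuple[float, ...] = (0.0, *(2.0**k for k in range(-4, 9)))


@dataclass
class PclassModel:
    """A fitted L2-penalized logistic regression for sex classification."""

    reference_sex: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: pd.Series
    penalty: float
    cov: NDArray[np.float64]  # sandwich covariance, intercept first
    apparent: dict[str, float]
    wald: pd.DataFrame  # per-predictor z, p, fdr_p
    includes_tiv: bool = False
    corrected: dict[str, float] | None = None
    penalty_trace: pd.DataFrame | None = None

    def linear_predictor(self, X: pd.DataFrame) -> NDArray[np.float64]:
        return self.intercept + X[list(self.predictors)].to_numpy() @ self.coefficients.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> NDArray[np.float64]:
        return expit(self.linear_predictor(X))


@dataclass
class ScoreSet:
    """Per-subject continuous scores with sex labels."""

    scores: pd.Series
    sex: pd.Series
    score_kind: str  # "pclass" or "projected_distance"
    reference_sex: str = "F"

    def __post_init__(self) -> None:
        if not {"F", "M"} <= set(self.sex):
            raise ValueError("ScoreSet: both sexes must be present")
        if self.score_kind == "pclass" and (
            (self.scores < 0).any() or (self.scores > 1).any()
        ):
            raise ValueError("ScoreSet: Pclass scores must lie in [0, 1]")

    def group(self, sex_code: str) -> NDArray[np.float64]:
        return self.scores[self.sex.to_numpy() == sex_code].to_numpy()


@dataclass
class PairwiseDiffSummary:
    """Summary of all reference-minus-other pairwise score differences."""

    deciles: NDArray[np.float64]  # HD deciles of the difference distribution
    percent_favoring_reference: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_ties: int
    pomp_deciles: NDArray[np.float64] | None  # deciles as percent of max range


def select_reference_category(uni: UnivariateTable, alpha: float = 0.05) -> str:
    """Reference sex = the one favored by the direction of the observed
    univariate differences (delta > 0 means F > M).

    The median Cliff's delta is taken over the FDR-significant ROIs when
    any exist — those are the differences the univariate analysis actually
    observed — and over all ROIs otherwise.  Restricting to significant
    ROIs keeps the choice stable when most ROIs carry no signal and the
    all-ROI median is noise.  An exact tie falls back to F with a warning.
    """
    dom = uni.dominance
    if "fdr_p" in dom.columns and (dom["fdr_p"] < alpha).any():
        med = float(dom.loc[dom["fdr_p"] < alpha, "delta"].median())
    else:
        med = float(dom["delta"].median())
    if med > 0:
        return "F"
    if med < 0:
        return "M"
    logger.warning("select_reference_category: median delta exactly 0; defaulting to F")
    return "F"


# ---------------------------------------------------------------------------
# Penalized fit


def _neg_loglik(beta: NDArray, X1: NDArray, y: NDArray) -> float:
    eta = X1 @ beta
    # log(1 + exp(eta)) - y*eta, numerically stable
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _newton_ridge(
    X1: NDArray, y: NDArray, lam: float, max_iter: int = 100, tol: float = 1e-10
) -> tuple[NDArray, NDArray, bool]:
    """Penalized ML for logistic regression: penalty lam/2 * sum(beta_slopes^2).

    Returns (beta, unpenalized Fisher information at beta, converged).
    """
    n, p1 = X1.shape
    pen = np.ones(p1) * lam
    pen[0] = 0.0  # intercept unpenalized
    beta = np.zeros(p1)
    beta[0] = math.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12))
    converged = False
    for _ in range(max_iter):
        eta = X1 @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X1.T @ (y - mu) - pen * beta
        info = (X1 * w[:, None]).T @ X1
        hess = info + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"penalized logistic fit is rank deficient: {err}") from err
        # step-halving on the penalized objective
        obj0 = _neg_loglik(beta, X1, y) + 0.5 * float(pen @ beta**2)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _neg_loglik(cand, X1, y) + 0.5 * float(pen @ cand**2) <= obj0 + 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    eta = X1 @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    info = (X1 * w[:, None]).T @ X1
    return beta, info, converged


def _c_index(scores: NDArray, y: NDArray) -> float:
    """Concordance of scores with the binary outcome (rank AUC)."""
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-index undefined: one class absent")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _discrimination(scores: NDArray, y: NDArray, loglik: float, loglik_null: float) -> dict[str, float]:
    n = y.size
    lr_chi2 = 2.0 * (loglik - loglik_null)
    r2_cs = 1.0 - math.exp(-lr_chi2 / n)
    r2_max = 1.0 - math.exp(2.0 * loglik_null / n)
    c = _c_index(scores, y)
    return {
        "nagelkerke_r2": r2_cs / r2_max if r2_max > 0 else 0.0,
        "c_index": c,
        "somers_dxy": 2.0 * (c - 0.5),
        "lr_chi2": lr_chi2,
    }


def _effective_df(info: NDArray, lam: float) -> float:
    pen = np.ones(info.shape[0]) * lam
    pen[0] = 0.0
    return float(np.trace(np.linalg.solve(info + np.diag(pen), info)))


def fit_penalized_lr(
    X: pd.DataFrame,
    y_sex: Sequence[str] | pd.Series,
    reference_sex: str,
    penalty_grid: Sequence[float] | None = None,
    includes_tiv: bool = False,
    alpha: float = 0.05,
) -> PclassModel:
    """Fit the ridge-penalized logistic model, selecting the penalty over a
    grid by corrected AIC with effective degrees of freedom
    trace(I (I + lam P)^-1).

    Wald statistics use the sandwich covariance
    (I + lam P)^-1 I (I + lam P)^-1 (approximate for penalized fits); the
    apparent discrimination indexes are computed on the training data.
    """
    if X.isna().any().any():
        raise ValueError("fit_penalized_lr: missing values in predictors")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"fit_penalized_lr: need n > predictors ({n} <= {p})")
    const_cols = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const_cols:
        raise ValueError(f"fit_penalized_lr: degenerate (constant) predictors: {const_cols}")
    y = (np.asarray(y_sex) == reference_sex).astype(float)
    if y.sum() in (0, n):
        raise ValueError("fit_penalized_lr: reference class absent or universal")
    grid = tuple(penalty_grid) if penalty_grid is not None else DEFAULT_PENALTY_GRID

    X1 = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    p_null = y.mean()
    loglik_null = float(n * (p_null * math.log(p_null) + (1 - p_null) * math.log(1 - p_null)))

    trace_rows = []
    best = None
    for lam in grid:
        try:
            beta, info, conv = _newton_ridge(X1, y, lam)
        except ValueError as err:
            if len(grid) == 1:
                if lam == 0.0:
                    raise ValueError(
                        "fit_penalized_lr: unstable unpenalized fit (likely class "
                        "separation); supply a positive penalty"
                    ) from err
                raise
            continue
        if not conv or np.max(np.abs(beta)) > 1e6:
            if lam == 0.0 and len(grid) == 1:
                raise ValueError(
                    "fit_penalized_lr: separation with penalty 0; supply a positive penalty"
                )
            continue
        edf = _effective_df(info, lam)
        ll = -_neg_loglik(beta, X1, y)
        aic = -2 * ll + 2 * edf
        denom = n - edf - 1
        aicc = aic + (2 * edf * (edf + 1) / denom if denom > 0 else math.inf)
        trace_rows.append({"penalty": lam, "edf": edf, "loglik": ll, "aicc": aicc})
        if best is None or aicc < best["aicc"]:
            best = {"lam": lam, "beta": beta, "info": info, "loglik": ll, "aicc": aicc}
    if best is None:
        raise ValueError("fit_penalized_lr: no penalty in the grid produced a stable fit")

    lam, beta, info = best["lam"], best["beta"], best["info"]
    pen = np.ones(p + 1) * lam
    pen[0] = 0.0
    h_inv = np.linalg.inv(info + np.diag(pen))
    cov = h_inv @ info @ h_inv
    se = np.sqrt(np.diag(cov))[1:]
    z = beta[1:] / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    wald = pd.DataFrame(
        {"coef": beta[1:], "se": se, "z": z, "p": pvals, "fdr_p": fdr_adjust(pvals)},
        index=X.columns,
    )
    wald["significant"] = wald["fdr_p"] < alpha

    scores = expit(X1 @ beta)
    apparent = _discrimination(scores, y, best["loglik"], loglik_null)
    return PclassModel(
        reference_sex=reference_sex,
        predictors=tuple(X.columns),
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=X.columns),
        penalty=float(lam),
        cov=cov,
        apparent=apparent,
        wald=wald,
        includes_tiv=includes_tiv,
        penalty_trace=pd.DataFrame(trace_rows),
    )


def fit_tiv_augmented(
    X: pd.DataFrame,
    tiv: pd.Series,
    y_sex: Sequence[str] | pd.Series,
    reference_sex: str,
    penalty_grid: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> PclassModel:
    """Refit with robust-z TIV added as an extra predictor column "TIV"."""
    from .tiv import robust_z_transform

    tiv_arr = np.asarray(tiv, dtype=float)
    if np.ptp(tiv_arr) == 0:
        raise ValueError("fit_tiv_augmented: TIV is constant (degenerate predictor)")
    X_aug = X.copy()
    X_aug["TIV"] = robust_z_transform(tiv_arr, label="TIV")
    return fit_penalized_lr(
        X_aug, y_sex, reference_sex, penalty_grid=penalty_grid, includes_tiv=True, alpha=alpha
    )


# ---------------------------------------------------------------------------
# Validation and calibration


def bootstrap_validate(
    model: PclassModel,
    X: pd.DataFrame,
    y_sex: Sequence[str] | pd.Series,
    n_reps: int = 200,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """Harrell optimism bootstrap of the discrimination indexes.

    Each resample is refitted at the model's selected penalty; optimism is
    the mean of (index on the resample) - (resampled model's index on the
    original data), and corrected = apparent - optimism.  Failed refits are
    skipped (error if more than 20% fail).  Updates ``model.corrected``
    and returns it.
    """
    rng = rng if rng is not None else derive_rng(0 if seed is None else seed, "validate")
    y = (np.asarray(y_sex) == model.reference_sex).astype(float)
    n = y.size
    X1 = np.column_stack([np.ones(n), X[list(model.predictors)].to_numpy(dtype=float)])
    p_null = y.mean()
    ll_null = float(n * (p_null * math.log(p_null) + (1 - p_null) * math.log(1 - p_null)))

    keys = ("nagelkerke_r2", "c_index", "somers_dxy")
    optimism = {k: [] for k in keys}
    failures = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() in (0, n):
            failures += 1
            continue
        try:
            beta_b, _, conv = _newton_ridge(X1[idx], yb, model.penalty)
        except ValueError:
            failures += 1
            continue
        if not conv:
            failures += 1
            continue
        pb = yb.mean()
        llb_null = float(yb.size * (pb * math.log(pb) + (1 - pb) * math.log(1 - pb)))
        boot_idx = _discrimination(expit(X1[idx] @ beta_b), yb, -_neg_loglik(beta_b, X1[idx], yb), llb_null)
        orig_idx = _discrimination(expit(X1 @ beta_b), y, -_neg_loglik(beta_b, X1, y), ll_null)
        for k in keys:
            optimism[k].append(boot_idx[k] - orig_idx[k])
    if failures > 0.2 * n_reps:
        raise ValueError(f"bootstrap_validate: {failures}/{n_reps} refits failed")
    if failures:
        logger.info("bootstrap_validate: skipped %d failed refits", failures)

    corrected = {k: model.apparent[k] - float(np.mean(optimism[k])) for k in keys}
    corrected["n_reps_used"] = n_reps - failures
    model.corrected = corrected
    return corrected


def calibration_curve(
    model: PclassModel, X: pd.DataFrame, y_sex: Sequence[str] | pd.Series, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency reliability curve: mean predicted Pclass vs observed
    reference-class fraction per bin."""
    y = (np.asarray(y_sex) == model.reference_sex).astype(float)
    if n_bins > y.size:
        raise ValueError("calibration_curve: more bins than observations")
    scores = model.predict_proba(X)
    order = np.argsort(scores)
    bins = np.array_split(order, n_bins)
    rows = [
        {"mean_predicted": float(scores[b].mean()), "observed_fraction": float(y[b].mean()), "n": b.size}
        for b in bins
        if b.size
    ]
    return pd.DataFrame(rows)


def pclass_scores(model: PclassModel, X: pd.DataFrame, sex: pd.Series) -> ScoreSet:
    """Package the fitted per-subject probabilities as a ScoreSet."""
    return ScoreSet(
        scores=pd.Series(model.predict_proba(X), index=X.index, name="pclass"),
        sex=sex,
        score_kind="pclass",
        reference_sex=model.reference_sex,
    )


# ---------------------------------------------------------------------------
# Score batteries and pairwise differences


def score_battery(scores: ScoreSet, cfg: BootstrapConfig) -> dict:
    """Run the univariate battery on a continuous multivariate score.

    Group A is the reference sex, so positive shifts/deltas favor it.
    Adds per-sex CDF deciles and, for Pclass scores, the accuracy at the
    0.5 cutoff (per-sex correct rates and their balanced mean).
    """
    ref = scores.reference_sex
    other = "M" if ref == "F" else "F"
    a = scores.group(ref)
    b = scores.group(other)

    out: dict = {"reference_sex": ref, "score_kind": scores.score_kind}
    out["global"] = global_shift = hd_quantile(a, 0.5) - hd_quantile(b, 0.5)
    dom = cliff_delta_inference(a, b, cfg)
    out["dominance"] = dom
    out["overlap"] = overlap_eta(a, b, cfg, rng=derive_rng(cfg.seed, "score-overlap"))
    out["u3"] = cohens_u3_empirical(a, b, cfg, rng=derive_rng(cfg.seed, "score-u3"))
    out["deciles"] = decile_shift_test(a, b, cfg, rng=derive_rng(cfg.seed, "score-deciles"))
    out["iqr"] = iqr_ratio_test(a, b, cfg, rng=derive_rng(cfg.seed, "score-iqr"))
    out["skewness"] = bootstrap_moment_difference(a, b, "skewness", cfg, rng=derive_rng(cfg.seed, "score-skew"))
    out["kurtosis"] = bootstrap_moment_difference(a, b, "kurtosis", cfg, rng=derive_rng(cfg.seed, "score-kurt"))
    out["per_sex_moments"] = {
        ref: {"skewness": float(stats.skew(a)), "kurtosis": float(stats.kurtosis(a, fisher=False)),
              "iqr": float(hd_quantile(a, 0.75) - hd_quantile(a, 0.25))},
        other: {"skewness": float(stats.skew(b)), "kurtosis": float(stats.kurtosis(b, fisher=False)),
                "iqr": float(hd_quantile(b, 0.75) - hd_quantile(b, 0.25))},
    }
    out["cdf_deciles"] = pd.DataFrame(
        {ref: hd_quantiles(a, DECILES), other: hd_quantiles(b, DECILES)}, index=np.round(DECILES, 1)
    )
    if scores.score_kind == "pclass":
        rate_ref = float(np.mean(a >= 0.5))
        rate_other = float(np.mean(b < 0.5))
        out["accuracy"] = {
            f"rate_{ref}": 100 * rate_ref,
            f"rate_{other}": 100 * rate_other,
            "balanced_pct": 100 * 0.5 * (rate_ref + rate_other),
        }
    return out


def pairwise_difference_summary(
    scores: ScoreSet,
    cfg: BootstrapConfig,
    n_boot: int = 500,
    pair_cap: int = 4_000_000,
    subsample: bool = True,
    rng: np.random.Generator | None = None,
) -> PairwiseDiffSummary:
    """Distribution of all reference-minus-other pairwise differences.

    Reports HD deciles of the difference distribution and the percent of
    pairs favoring the reference sex (ties excluded from both numerator
    and denominator), with a subject-level percentile-bootstrap CI.  For
    Pclass scores the deciles are also expressed as POMP (percent of the
    maximum possible difference, i.e. 100 x the difference).

    If the pair count exceeds ``pair_cap``, each group is subsampled
    (seeded) when ``subsample`` is enabled, else an error is raised.
    """
    rng = rng if rng is not None else derive_rng(cfg.seed, "pairwise")
    ref = scores.reference_sex
    other = "M" if ref == "F" else "F"
    a = scores.group(ref)
    b = scores.group(other)
    if a.size * b.size > pair_cap:
        if not subsample:
            raise ValueError(
                f"pairwise_difference_summary: {a.size * b.size} pairs exceed cap {pair_cap}"
            )
        k = int(math.sqrt(pair_cap))
        a = rng.choice(a, size=min(a.size, k), replace=False)
        b = rng.choice(b, size=min(b.size, k), replace=False)

    diffs = (a[:, None] - b[None, :]).ravel()
    n_ties = int(np.count_nonzero(diffs == 0))
    n_informative = diffs.size - n_ties
    if n_ties:
        logger.info("pairwise_difference_summary: excluded %d tied pairs", n_ties)
    if n_informative == 0:
        raise ValueError("pairwise_difference_summary: all pairs tied")
    pct = 100.0 * np.count_nonzero(diffs > 0) / n_informative
    deciles = hd_quantiles(diffs, DECILES)

    pct_star = np.empty(n_boot)
    for r in range(n_boot):
        sa = a[rng.integers(0, a.size, a.size)]
        sb = b[rng.integers(0, b.size, b.size)]
        d = sa[:, None] - sb[None, :]
        pos = np.count_nonzero(d > 0)
        inf = d.size - np.count_nonzero(d == 0)
        pct_star[r] = 100.0 * pos / inf if inf else np.nan
    lo, hi = np.nanpercentile(pct_star, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])

    pomp = 100.0 * deciles if scores.score_kind == "pclass" else None
    return PairwiseDiffSummary(
        deciles=deciles,
        percent_favoring_reference=float(pct),
        ci_low=float(lo),
        ci_high=float(hi),
        n_pairs=int(diffs.size),
        n_ties=n_ties,
        pomp_deciles=pomp,
    )


# ---------------------------------------------------------------------------
# Nomogram and model-structure analyses


def build_nomogram(model: PclassModel, X: pd.DataFrame, sex: pd.Series | None = None) -> dict:
    """Point-scale representation of the model over the observed predictor
    ranges.

    Each predictor's scale length is proportional to |beta_j| x range_j;
    the longest scale spans 0-100 points, oriented so that more points
    always push toward the reference class.  The returned mapping converts
    total points back to a Pclass probability; optional per-sex median
    markers report where a typical female/male sits on each scale.
    """
    Xv = X[list(model.predictors)]
    beta = model.coefficients.to_numpy()
    if np.all(beta == 0):
        raise ValueError("build_nomogram: all coefficients are zero")
    lo = Xv.min().to_numpy()
    hi = Xv.max().to_numpy()
    rng_ = hi - lo
    importance = np.abs(beta) * rng_
    top = importance.max()
    # anchor at the end that minimizes the linear predictor
    anchor = np.where(beta >= 0, lo, hi)

    def points_of(values: NDArray) -> NDArray:
        return 100.0 * np.abs(beta) * np.abs(values - anchor) / top

    table = pd.DataFrame(
        {
            "coef": beta,
            "range_low": lo,
            "range_high": hi,
            "max_points": points_of(np.where(beta >= 0, hi, lo)),
        },
        index=model.predictors,
    )
    if sex is not None:
        for code in ("F", "M"):
            med = Xv[sex.to_numpy() == code].median().to_numpy()
            table[f"median_points_{code}"] = points_of(med)

    base_lp = model.intercept + float(anchor @ beta)
    slope = top / 100.0

    def total_points_to_pclass(total_points: float | NDArray) -> NDArray:
        return expit(base_lp + slope * np.asarray(total_points, dtype=float))

    return {"table": table, "total_points_to_pclass": total_points_to_pclass, "max_total_points": float(table["max_points"].sum())}


def _shared_roi_coefs(models: Sequence[PclassModel]) -> pd.DataFrame:
    """Coefficient matrix over the predictors shared by all models, with
    TIV excluded from cross-model comparisons."""
    shared = set(models[0].predictors)
    for m in models[1:]:
        shared &= set(m.predictors)
    shared -= {"TIV"}
    rois = [p for p in models[0].predictors if p in shared]
    if len(rois) < 3:
        raise ValueError("compare_model_structure: fewer than 3 shared predictors")
    for m in models[1:]:
        if [p for p in m.predictors if p in shared] != rois:
            # order by the first model's layout; presence already checked
            pass
    return pd.DataFrame({i: m.coefficients.loc[rois] for i, m in enumerate(models)})


def compare_model_structure(
    models: Sequence[PclassModel],
    model_names: Sequence[str] | None = None,
    uni_tables: Sequence[UnivariateTable] | None = None,
) -> dict:
    """Cross-model and model-vs-univariate coefficient-ordering analysis.

    Returns the pairwise matrices of signed and absolute Spearman rho over
    the shared ROI coefficients (TIV excluded), and, when univariate
    tables are supplied, each model's rho between its coefficients and the
    univariate medians' differences, Cliff's deltas, and Cohen's U3.
    """
    if len(models) < 2:
        raise ValueError("compare_model_structure: need at least 2 models")
    names = list(model_names) if model_names is not None else [f"model_{i}" for i in range(len(models))]
    coefs = _shared_roi_coefs(models)
    coefs.columns = names
    k = len(models)
    signed = np.eye(k)
    for i, j in combinations(range(k), 2):
        rho = stats.spearmanr(coefs.iloc[:, i], coefs.iloc[:, j]).statistic
        signed[i, j] = signed[j, i] = rho
    signed_df = pd.DataFrame(signed, index=names, columns=names)

    out = {"coefficients": coefs, "rho_signed": signed_df, "rho_abs": signed_df.abs()}
    if uni_tables is not None:
        if len(uni_tables) != len(models):
            raise ValueError("compare_model_structure: one univariate table per model required")
        rows = []
        for name, model, uni in zip(names, models, uni_tables):
            c = coefs[name]
            rois = c.index
            for stat_name, values in (
                ("median_shift", uni.global_test.loc[rois, "shift"]),
                ("cliff_delta", uni.dominance.loc[rois, "delta"]),
                ("cohens_u3", uni.dominance.loc[rois, "u3_pct"]),
            ):
                res = stats.spearmanr(c, values)
                rows.append({"model": name, "statistic": stat_name,
                             "rho": float(res.statistic), "p": float(res.pvalue)})
        out["coef_vs_univariate"] = pd.DataFrame(rows)
    return out


def significant_predictor_intersections(
    models: Sequence[PclassModel], model_names: Sequence[str] | None = None, alpha: float = 0.05
) -> dict:
    """Intersection analysis of FDR-significant coefficients across models.

    Returns, for every combination of models, the predictors significant
    in exactly that combination (UpSet-style exclusive intersections), and
    a per-predictor count of models in which it is significant.
    """
    if len(models) < 2:
        raise ValueError("significant_predictor_intersections: need at least 2 models")
    names = list(model_names) if model_names is not None else [f"model_{i}" for i in range(len(models))]
    flags = {
        name: set(m.wald.index[m.wald["fdr_p"] < alpha]) - {"TIV"}
        for name, m in zip(names, models)
    }
    all_preds = sorted(set().union(*flags.values()))
    exclusive: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inset = set(all_preds)
            for name in combo:
                inset &= flags[name]
            for name in set(names) - set(combo):
                inset -= flags[name]
            if inset:
                exclusive[combo] = sorted(inset)
    counts = pd.Series(
        {p: sum(p in flags[name] for name in names) for p in all_preds}, dtype=int
    ).sort_values(ascending=False)
    return {"flags": flags, "exclusive_intersections": exclusive, "counts": counts}
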