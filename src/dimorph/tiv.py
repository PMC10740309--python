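"""Total-intracranial-volume adjustment and robust standardization.

Regional gray-matter volumes scale allometrically with head size, so any
between-group comparison confounds regional effects with the groups' TIV
gap.  The power-corrected-proportions (PCP) method removes this by
dividing each volume by TIV^b, where b is the slope of the pooled
log(VOL) ~ log(TIV) regression.  This module builds the two parallel
analysis datasets — raw and PCP-adjusted — each expressed as robust
z-scores 0.6745 (x - median) / MAD, and records how much variance TIV
explains in each ROI before and after adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import stats

__all__ = [
    "CohortTable",
    "AnalysisDataset",
    "fit_pcp_exponent",
    "pcp_adjust",
    "robust_z_transform",
    "tiv_variance_explained",
    "build_datasets",
]

SEX_CODES = ("F", "M")


@dataclass
class CohortTable:
    """Per-subject table of sex, TIV (ml) and positive ROI volumes (ml).

    ``data`` must carry columns ``subject_id``, ``sex`` (coded F/M),
    ``tiv_ml`` and one column per ROI label.
    """

    data: pd.DataFrame
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.roi_labels = tuple(self.roi_labels)
        required = ["subject_id", "sex", "tiv_ml", *self.roi_labels]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        bad_sex = sorted(set(self.data["sex"]) - set(SEX_CODES))
        if bad_sex:
            raise ValueError(f"unknown sex codes {bad_sex}; accepted codes are {list(SEX_CODES)}")
        if not set(SEX_CODES) <= set(self.data["sex"]):
            raise ValueError("both sex levels (F and M) must be present")
        if (self.data["tiv_ml"] <= 0).any():
            raise ValueError("tiv_ml must be positive for every subject")
        vols = self.data[list(self.roi_labels)]
        nonpos = [c for c in self.roi_labels if (vols[c] <= 0).any()]
        if nonpos:
            raise ValueError(f"non-positive volumes in ROI column(s): {nonpos}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    @property
    def tiv(self) -> pd.Series:
        return self.data["tiv_ml"]

    def volumes(self) -> pd.DataFrame:
        return self.data[list(self.roi_labels)]

    def to_csv(self, path) -> None:
        cols = ["subject_id", "sex", "tiv_ml", *self.roi_labels]
        self.data[cols].to_csv(path, index=False)


@dataclass
class AnalysisDataset:
    """One analysis variant (raw or PCP-adjusted), robust-z standardized.

    ``zscores`` is subjects x ROIs in robust-z units (per ROI: median 0,
    MAD rescaled by 0.6745).  ``volumes`` keeps the pre-standardization
    values (raw or adjusted) for TIV-relationship checks; ``b_hat`` holds
    the fitted PCP exponents (None for the raw variant); ``tiv_r2`` is the
    per-ROI proportion of variance explained by TIV in ``volumes``.
    """

    kind: Literal["raw", "pcp"]
    zscores: pd.DataFrame
    sex: pd.Series
    tiv: pd.Series
    volumes: pd.DataFrame
    tiv_r2: pd.Series
    b_hat: pd.Series | None = None

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return tuple(self.zscores.columns)

    def group(self, sex_code: str, roi: str) -> NDArray[np.float64]:
        return self.zscores.loc[self.sex.to_numpy() == sex_code, roi].to_numpy()


def fit_pcp_exponent(vol: ArrayLike, tiv: ArrayLike) -> float:
    """Pooled-sample OLS slope of log(vol) on log(tiv)."""
    vol = np.asarray(vol, dtype=float).ravel()
    tiv = np.asarray(tiv, dtype=float).ravel()
    if vol.size != tiv.size:
        raise ValueError("fit_pcp_exponent: vol and tiv lengths differ")
    if vol.size < 3:
        raise ValueError("fit_pcp_exponent: need n >= 3")
    if np.any(vol <= 0) or np.any(tiv <= 0):
        raise ValueError("fit_pcp_exponent: volumes and TIV must be positive")
    log_tiv = np.log(tiv)
    if np.ptp(log_tiv) == 0:
        raise ValueError("fit_pcp_exponent: TIV is constant (singular fit)")
    slope, _ = np.polyfit(log_tiv, np.log(vol), 1)
    return float(slope)


def pcp_adjust(vol: ArrayLike, tiv: ArrayLike, b_hat: float) -> NDArray[np.float64]:
    """Power-corrected proportions: VOL / TIV^b."""
    vol = np.asarray(vol, dtype=float)
    tiv = np.asarray(tiv, dtype=float)
    if np.any(vol <= 0) or np.any(tiv <= 0):
        raise ValueError("pcp_adjust: volumes and TIV must be positive")
    return vol / tiv**b_hat


def robust_z_transform(x: ArrayLike, label: str | None = None) -> NDArray[np.float64]:
    """Robust z-scores 0.6745 (x - median) / MAD, with the raw (unscaled)
    median absolute deviation; the 0.6745 factor puts the result on the
    conventional z scale."""
    x = np.asarray(x, dtype=float).ravel()
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        where = f" for {label!r}" if label else ""
        raise ValueError(f"robust_z_transform: MAD is zero{where} (degenerate scale)")
    return 0.6745 * (x - med) / mad


def tiv_variance_explained(
    vol: ArrayLike, tiv: ArrayLike, log_scale: bool = False
) -> float:
    """Proportion of variance in ``vol`` explained by a simple linear
    regression on TIV (R^2); optionally computed on the log-log scale."""
    vol = np.asarray(vol, dtype=float).ravel()
    tiv = np.asarray(tiv, dtype=float).ravel()
    if vol.size < 3:
        raise ValueError("tiv_variance_explained: need n >= 3")
    if np.ptp(tiv) == 0:
        raise ValueError("tiv_variance_explained: TIV is constant")
    if log_scale:
        vol, tiv = np.log(vol), np.log(tiv)
    r = stats.pearsonr(tiv, vol).statistic
    return float(r * r)


def build_datasets(
    cohort: CohortTable, r2_log_scale: bool = False
) -> tuple[AnalysisDataset, AnalysisDataset]:
    """Build the (raw, pcp) analysis-dataset pair from a cohort.

    The PCP exponent is fitted per ROI on the pooled sample; robust-z
    standardization and the TIV R^2 bookkeeping are applied to each
    variant on its own volumes.
    """
    tiv = cohort.tiv.to_numpy()
    raw_vols = cohort.volumes()

    b_hat = {}
    adj_cols = {}
    for roi in cohort.roi_labels:
        v = raw_vols[roi].to_numpy()
        if np.ptp(v) == 0:
            raise ValueError(f"build_datasets: ROI {roi!r} is constant")
        b = fit_pcp_exponent(v, tiv)
        b_hat[roi] = b
        adj_cols[roi] = pcp_adjust(v, tiv, b)
    adj_vols = pd.DataFrame(adj_cols, index=raw_vols.index)

    def _make(kind: str, vols: pd.DataFrame, b: pd.Series | None) -> AnalysisDataset:
        z = pd.DataFrame(
            {roi: robust_z_transform(vols[roi].to_numpy(), label=roi) for roi in cohort.roi_labels},
            index=vols.index,
        )
        r2 = pd.Series(
            {roi: tiv_variance_explained(vols[roi], tiv, log_scale=r2_log_scale) for roi in cohort.roi_labels}
        )
        return AnalysisDataset(
            kind=kind,  # type: ignore[arg-type]
            zscores=z,
            sex=cohort.sex.copy(),
            tiv=cohort.tiv.copy(),
            volumes=vols,
            tiv_r2=r2,
            b_hat=b,
        )

    raw_ds = _make("raw", raw_vols.copy(), None)
    pcp_ds = _make("pcp", adj_vols, pd.Series(b_hat))
    return raw_ds, pcp_ds
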